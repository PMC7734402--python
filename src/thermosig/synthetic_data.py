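"""Synthetic genomes, proteomes and species tables with known ground truth.

The generators emulate the measured properties of a low-G+C bacterial
chromosome — configurable length and target G+C, embedded protein-coding
genes on both strands, and several near-identical 16S-like rRNA gene
copies derived from one template by per-site mutation — so that every
analysis stage can be exercised against a known answer without any
download.  Each generator is a pure function of its spec (seed included).

Proteome composition targets (CvP, IVYWREL) are met in expectation by
solving a small linear program for a 20-residue frequency vector rather
than by rejection sampling.  Every residue is given a floor frequency of
0.001 (real proteomes contain all twenty residues), which also makes the
degenerate extremes (|CvP| = 100) correctly infeasible.

The 16S-like template is a fixed 1,500-base sequence generated from a
hard-coded seed: tests need the *structure* of an rRNA-copy analysis
(multiplicity, small divergence), not biological homology, so no real
rRNA sequence ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .io_formats import Feature, GenomeRecord, ProteinRecord, ProteinSet
from .proteome_metrics import CANONICAL_AA, CHARGED, IVYWREL_SET, POLAR

_STOPS = ("TAA", "TAG", "TGA")
_RRNA_TEMPLATE_SEED = 20200918
_RRNA_TEMPLATE_LEN = 1500
_FREQ_FLOOR = 1e-3


@dataclass(frozen=True)
class GenomeSpec:
    length: int = 200_000
    gc_target: float = 0.258
    n_cds: int = 60
    cds_length_range: tuple[int, int] = (300, 1500)
    rrn_copies: int = 6
    rrn_divergence: float = 0.001
    topology: str = "circular"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.rrn_copies < 0:
            raise ValueError("rrn_copies must be >= 0")
        if not 0 <= self.rrn_divergence < 1:
            raise ValueError("rrn_divergence must be in [0, 1)")


@dataclass(frozen=True)
class ProteomeSpec:
    n_proteins: int = 500
    length_range: tuple[int, int] = (100, 500)
    cvp_target: float = 0.0
    ivywrel_target: float = 0.40
    tm_protein_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not -100 <= self.cvp_target <= 100:
            raise ValueError("cvp_target outside [-100, 100]")
        if not 0 <= self.ivywrel_target <= 1:
            raise ValueError("ivywrel_target outside [0, 1]")
        if not 0 <= self.tm_protein_fraction <= 1:
            raise ValueError("tm_protein_fraction outside [0, 1]")


class InfeasibleSpecError(ValueError):
    """Raised when spec targets cannot be met jointly."""


def solve_composition(cvp_target: float, ivywrel_target: float,
                      floor: float = _FREQ_FLOOR) -> dict[str, float]:
    """Residue frequency vector meeting CvP and IVYWREL targets exactly.

    Minimizes the maximum deviation from the uniform composition (an LP)
    subject to: frequencies sum to 1; charged-minus-polar equals
    cvp_target/100; the IVYWREL sum equals ivywrel_target; every frequency
    at least ``floor``.
    """
    aas = list(CANONICAL_AA)
    n = len(aas)
    # variables: f_1..f_20, t (max |f_i - 1/20|); minimize t
    c = np.zeros(n + 1)
    c[-1] = 1.0
    a_eq = np.zeros((3, n + 1))
    a_eq[0, :n] = 1.0
    for k, aa in enumerate(aas):
        if aa in CHARGED:
            a_eq[1, k] = 1.0
        if aa in POLAR:
            a_eq[1, k] = -1.0
        if aa in IVYWREL_SET:
            a_eq[2, k] = 1.0
    b_eq = [1.0, cvp_target / 100.0, ivywrel_target]
    # |f_i - 1/20| <= t
    a_ub = np.zeros((2 * n, n + 1))
    b_ub = np.zeros(2 * n)
    for k in range(n):
        a_ub[2 * k, k] = 1.0
        a_ub[2 * k, -1] = -1.0
        b_ub[2 * k] = 1.0 / n
        a_ub[2 * k + 1, k] = -1.0
        a_ub[2 * k + 1, -1] = -1.0
        b_ub[2 * k + 1] = -1.0 / n
    bounds = [(floor, 1.0)] * n + [(0.0, None)]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleSpecError(
            f"no composition with CvP={cvp_target}, IVYWREL={ivywrel_target} "
            f"and per-residue floor {floor} (each residue must appear): "
            f"{res.message}"
        )
    freqs = np.clip(res.x[:n], floor, None)
    freqs = freqs / freqs.sum()
    return dict(zip(aas, freqs))


# ---------------------------------------------------------------------------
# genome generation


def _rrna_template() -> str:
    rng = np.random.default_rng(_RRNA_TEMPLATE_SEED)
    return "".join(rng.choice(list("ACGT"), size=_RRNA_TEMPLATE_LEN,
                              p=[0.25, 0.25, 0.25, 0.25]))


def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    bases = b"ACGT"
    for i in hits:
        cur = arr[i]
        alt = [bytes([b]) for b in bases if bytes([b]) != cur]
        arr[i] = alt[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _sense_codons(n: int, gc: float, rng) -> str:
    """n codons with base-wise G+C probability gc, stop codons rejected."""
    out = []
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    while len(out) < n:
        draw = rng.choice(list("AGCT"), size=3, p=p)
        codon = "".join(draw)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _place_intervals(length: int, sizes: list[int], rng,
                     max_tries: int = 2000) -> list[int]:
    """Random non-overlapping starts for blocks of the given sizes."""
    if sum(sizes) > 0.85 * length:
        raise InfeasibleSpecError(
            f"features need {sum(sizes)} bases but only "
            f"{int(0.85 * length)} of {length} are placeable"
        )
    taken: list[tuple[int, int]] = []
    starts = []
    for size in sizes:
        for _ in range(max_tries):
            s = int(rng.integers(0, length - size))
            if all(e2 <= s or s + size <= s2 for s2, e2 in taken):
                taken.append((s, s + size))
                starts.append(s)
                break
        else:
            raise InfeasibleSpecError(
                f"could not place a {size}-base feature after {max_tries} tries"
            )
    return starts


def generate_genome(spec: GenomeSpec) -> GenomeRecord:
    """Deterministic synthetic chromosome matching the spec.

    Background bases are i.i.d.; the background G+C probability is adjusted
    to compensate for the realized G+C of the embedded features, so the
    whole-genome G+C lands on ``gc_target`` up to background binomial noise.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.cds_length_range
    n_codons = [int(rng.integers(lo // 3, hi // 3 + 1)) for _ in range(spec.n_cds)]

    blocks: list[tuple[str, str, str]] = []  # (kind, sequence-as-placed, strand)
    template = _rrna_template()
    for _ in range(spec.rrn_copies):
        copy = _mutate(template, spec.rrn_divergence, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append(("rRNA_16S", copy, strand))
    for nc in n_codons:
        body = _sense_codons(max(nc - 2, 1), spec.gc_target, rng)
        coding = "ATG" + body + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append(("CDS", coding, strand))

    sizes = [len(seq) for _, seq, _ in blocks]
    starts = _place_intervals(spec.length, sizes, rng)

    feature_gc = sum(seq.count("G") + seq.count("C") for _, seq, _ in blocks)
    feature_len = sum(sizes)
    bg_len = spec.length - feature_len
    if bg_len > 0:
        bg_gc = (spec.gc_target * spec.length - feature_gc) / bg_len
    else:
        bg_gc = spec.gc_target
    if not 0 <= bg_gc <= 1:
        raise InfeasibleSpecError(
            f"feature G+C forces background G+C probability {bg_gc:.3f} "
            "outside [0, 1]; adjust gc_target, feature density or template"
        )
    p = [(1 - bg_gc) / 2, bg_gc / 2, bg_gc / 2, (1 - bg_gc) / 2]
    seq = rng.choice(list("AGCT"), size=spec.length, p=p)

    features = []
    from Bio.Seq import Seq as _Seq

    for (kind, block, strand), start in zip(blocks, starts):
        placed = block if strand == "+" else str(_Seq(block).reverse_complement())
        seq[start : start + len(block)] = list(placed)
        quals = (
            {"product": "16S ribosomal RNA (synthetic template)"}
            if kind == "rRNA_16S"
            else {"product": "hypothetical protein"}
        )
        features.append(Feature(kind, ((start, start + len(block)),), strand, quals))

    features.sort(key=lambda f: f.intervals[0][0])
    return GenomeRecord(
        id=f"SYN{spec.seed:06d}",
        sequence="".join(seq),
        topology=spec.topology,
        features=features,
    )


# ---------------------------------------------------------------------------
# proteome generation

_HYDROPHOBIC = "ILVF"


def generate_proteome(spec: ProteomeSpec) -> ProteinSet:
    """Random proteins whose composition meets the spec targets in
    expectation; a ``tm_protein_fraction`` share receives one >= 25-residue
    hydrophobic insert so the membrane filter has something to remove."""
    freqs = solve_composition(spec.cvp_target, spec.ivywrel_target)
    rng = np.random.default_rng(spec.seed)
    aas = list(CANONICAL_AA)
    p = np.array([freqs[a] for a in aas])
    p = p / p.sum()
    lo, hi = spec.length_range
    proteins = []
    n_tm = int(round(spec.tm_protein_fraction * spec.n_proteins))
    tm_ids = set(rng.choice(spec.n_proteins, size=n_tm, replace=False)) if n_tm else set()
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(aas, size=length, p=p))
        if i in tm_ids:
            # two >=25-residue hydrophobic stretches with a polar spacer so
            # the surrogate detects >= 2 helices and the membrane filter
            # removes the protein
            stretch = lambda: "".join(rng.choice(list(_HYDROPHOBIC), size=25))
            insert = stretch() + "S" * 30 + stretch()
            pos = int(rng.integers(0, length + 1))
            residues = residues[:pos] + insert + residues[pos:]
        proteins.append(ProteinRecord(f"synprot{i:05d}", residues))
    return ProteinSet(proteins)


# ---------------------------------------------------------------------------
# species tables


def generate_species_table(n_species: int, line: tuple[float, float],
                           noise_sd: float, ogt_range: tuple[float, float],
                           seed: int = 0, metric_name: str = "metric"):
    """Species table with metric = intercept + slope*OGT + N(0, noise_sd).

    ``line`` is (slope, intercept).  Returns (DataFrame with columns
    species_id / ogt_c / <metric_name>, truth dict with the generating
    parameters and noiseless metric values).
    """
    import pandas as pd

    if n_species < 3:
        raise ValueError("need at least 3 species")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    slope, intercept = line
    rng = np.random.default_rng(seed)
    ogt = rng.uniform(ogt_range[0], ogt_range[1], size=n_species)
    clean = intercept + slope * ogt
    metric = clean + rng.normal(0.0, noise_sd, size=n_species)
    df = pd.DataFrame(
        {
            "species_id": [f"sp{i:03d}" for i in range(n_species)],
            "ogt_c": ogt,
            metric_name: metric,
        }
    )
    truth = {
        "slope": slope,
        "intercept": intercept,
        "noise_sd": noise_sd,
        "clean_metric": clean,
    }
    return df, truth
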