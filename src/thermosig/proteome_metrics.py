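"""Proteome composition indices and the membrane-protein filter.

CvP bias is the percentage of charged residues (D, E, K, R) minus the
percentage of polar residues (N, Q, S, T); IVYWREL is the summed fraction
of Ile, Val, Tyr, Trp, Arg, Glu and Leu.  Both indices rise with the
optimal growth temperature of the source organism, and both are computed
here — as in the comparative analyses they support — after removing
proteins with two or more predicted transmembrane helices, since membrane
proteins have a strongly biased composition unrelated to thermal
adaptation.  Transmembrane helices are detected with a Kyte–Doolittle
sliding-window hydropathy heuristic; a per-protein count table produced by
a dedicated TM predictor can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CHARGED = frozenset("DEKR")  # His excluded by convention
POLAR = frozenset("NQST")
IVYWREL_SET = frozenset("IVYWREL")

#: Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class HydropathyParams:
    """Sliding-window TM-helix detection parameters."""

    scale: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    window: int = 19
    threshold: float = 1.6
    min_separation: int = 10

    def __post_init__(self):
        if self.window < 7 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 7")


@dataclass
class CompositionVector:
    frequencies: dict  # aa -> fraction over the 20 canonical residues
    n_residues: int
    n_proteins: int

    def __post_init__(self):
        if self.n_residues > 0:
            total = sum(self.frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")


@dataclass
class ThermalProfile:
    """One genome's full thermal-signature metric vector."""

    genome_id: str
    genome_size: int
    gc_genome: float
    gc_16s: Optional[float]
    cvp_bias: Optional[float]
    ivywrel: Optional[float]
    at3_fraction: Optional[float]
    rrna_operon_count: int
    min_16s_copy_identity: Optional[float]  # percent
    ogt_observed: Optional[float] = None  # degrees C


def aa_composition(proteins, mode: str = "pooled") -> CompositionVector:
    """Amino-acid composition of a protein set.

    mode="pooled": residue counts pooled over all usable proteins.
    mode="per_protein_mean": unweighted mean of per-protein frequency
    vectors.  Non-canonical residues (X, U, B, Z) are excluded from both
    numerator and denominator.
    """
    records = getattr(proteins, "usable", None)
    if records is None:
        records = list(proteins)
    seqs = [getattr(p, "residues", p) for p in records]
    seqs = [s for s in seqs if any(c in CANONICAL_AA for c in s)]
    if not seqs:
        raise ValueError("no usable proteins for composition")
    if mode == "pooled":
        counts = {aa: 0 for aa in CANONICAL_AA}
        for s in seqs:
            for c in s:
                if c in counts:
                    counts[c] += 1
        total = sum(counts.values())
        freqs = {aa: k / total for aa, k in counts.items()}
        return CompositionVector(freqs, total, len(seqs))
    if mode == "per_protein_mean":
        acc = {aa: 0.0 for aa in CANONICAL_AA}
        n_res = 0
        for s in seqs:
            counts = {aa: 0 for aa in CANONICAL_AA}
            for c in s:
                if c in counts:
                    counts[c] += 1
            tot = sum(counts.values())
            n_res += tot
            for aa in CANONICAL_AA:
                acc[aa] += counts[aa] / tot
        freqs = {aa: v / len(seqs) for aa, v in acc.items()}
        return CompositionVector(freqs, n_res, len(seqs))
    raise ValueError(f"unknown composition mode {mode!r}")


def cvp_bias(comp: CompositionVector,
             charged=CHARGED, polar=POLAR) -> float:
    """100 x (sum of charged fractions - sum of polar fractions)."""
    f = comp.frequencies
    return 100.0 * (sum(f[a] for a in charged) - sum(f[a] for a in polar))


def ivywrel_fraction(comp: CompositionVector, members=IVYWREL_SET) -> float:
    """Summed fraction of the I, V, Y, W, R, E, L residues."""
    return sum(comp.frequencies[a] for a in members)


def count_tm_helices(protein, params: HydropathyParams = HydropathyParams()) -> int:
    """Predicted TM-helix count from sliding-window mean hydropathy.

    A helix is a maximal run of window positions whose mean hydropathy is at
    or above the threshold; runs separated by fewer than ``min_separation``
    positions merge.  Proteins shorter than the window score 0.  U maps to
    the Cys hydropathy; other non-canonical residues are neutral (0).
    """
    seq = getattr(protein, "residues", protein)
    w = params.window
    if len(seq) < w:
        return 0
    scale = params.scale
    vals = np.array([scale.get("C" if c == "U" else c, 0.0) for c in seq])
    means = np.convolve(vals, np.ones(w), mode="valid") / w
    hits = np.flatnonzero(means >= params.threshold - 1e-12)
    if hits.size == 0:
        return 0
    gaps = np.diff(hits)
    # a new run starts where the gap between consecutive hit positions is
    # at least min_separation (closer runs merge)
    return 1 + int(np.sum(gaps >= params.min_separation))


def filter_soluble(proteins, max_helices_exclusive: int = 2):
    """Keep proteins with fewer than ``max_helices_exclusive`` TM helices."""
    from .io_formats import ProteinSet

    records = list(proteins)
    unset = [p.id for p in records if p.usable and p.tm_helix_count is None]
    if unset:
        raise ValueError(
            f"{len(unset)} proteins lack tm_helix_count (e.g. {unset[0]!r}); "
            "run count_tm_helices or supply an external TM table"
        )
    return ProteinSet(
        [p for p in records
         if p.usable and p.tm_helix_count < max_helices_exclusive]
    )


def assign_tm_counts(proteins, params: HydropathyParams = HydropathyParams(),
                     external_table: Optional[dict] = None):
    """Set tm_helix_count on every usable record, in place; returns the set.

    ``external_table`` (protein id -> count) overrides the hydropathy
    surrogate where present.
    """
    for p in proteins:
        if not p.usable:
            continue
        if external_table is not None and p.id in external_table:
            p.tm_helix_count = int(external_table[p.id])
        else:
            p.tm_helix_count = count_tm_helices(p, params)
    return proteins


def read_tm_table(path) -> dict:
    """Read an external TSV of protein_id <tab> tm_helix_count."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, count = line.split("\t")[:2]
            table[pid] = int(count)
    return table


def proteome_thermal_profile(
    genome,
    hydropathy: HydropathyParams = HydropathyParams(),
    external_tm_table: Optional[dict] = None,
    composition_mode: str = "pooled",
    max_helices_exclusive: int = 2,
) -> ThermalProfile:
    """Full thermal-signature profile of one annotated genome.

    Pipeline: extract and translate CDS -> assign TM counts -> drop membrane
    proteins -> composition -> CvP and IVYWREL; plus whole-genome G+C, 16S
    G+C and inter-copy identity, rRNA operon count, and third-position A/T
    usage.  Deterministic for a fixed input.
    """
    from .io_formats import extract_and_translate_cds, extract_rrna_copies
    from .nucleotide_metrics import codon_usage, gc_content
    from .phylo import global_align, percent_identity

    errors_from = lambda stage, exc: RuntimeError(f"[{stage}] {exc}")

    gc_genome = gc_content(genome.sequence)
    copies = extract_rrna_copies(genome, "rRNA_16S")
    gc_16s = (
        sum(gc_content(c) for c in copies) / len(copies) if copies else None
    )
    min_ident = None
    if len(copies) >= 2:
        idents = []
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                pair = global_align(copies[i], copies[j])
                idents.append(percent_identity(pair))
        min_ident = min(idents)

    cvp = ivw = at3 = None
    try:
        proteins = extract_and_translate_cds(genome)
    except ValueError:
        proteins = None
    if proteins is not None and proteins.usable:
        try:
            assign_tm_counts(proteins, hydropathy, external_tm_table)
            soluble = filter_soluble(proteins, max_helices_exclusive)
            comp = aa_composition(soluble, mode=composition_mode)
            cvp = cvp_bias(comp)
            ivw = ivywrel_fraction(comp)
        except ValueError as exc:
            raise errors_from("proteome", exc)
        cds_nt = [
            genome.feature_sequence(f)
            for f in genome.features
            if f.kind == "CDS" and f.length % 3 == 0
        ]
        at3 = codon_usage(cds_nt).at3_fraction if cds_nt else None

    return ThermalProfile(
        genome_id=genome.id,
        genome_size=len(genome),
        gc_genome=gc_genome,
        gc_16s=gc_16s,
        cvp_bias=cvp,
        ivywrel=ivw,
        at3_fraction=at3,
        rrna_operon_count=len(copies),
        min_16s_copy_identity=min_ident,
    )
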