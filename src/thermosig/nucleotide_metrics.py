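"""Nucleotide-level metrics: G+C content, windowed G+C, codon usage.

G+C is reported as a fraction; "mol%" in output tables is the fraction
times 100, rounded to one decimal.  Ambiguity symbols are excluded from
both numerator and denominator everywhere.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

STOP_CODONS_T11 = set(CodonTable.unambiguous_dna_by_id[11].stop_codons)
_ACGT = set("ACGT")


@dataclass
class GcProfile:
    window_size: int
    step: int
    starts: list[int]
    values: list[float]
    whole_genome_gc: float
    #: unambiguous bases actually covered by each window (tail may be short)
    window_lengths: list[int] = field(default_factory=list)


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T), ambiguity symbols excluded."""
    seq = sequence.upper()
    counts = Counter(seq)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases; G+C undefined")
    return (counts["G"] + counts["C"]) / denom


def windowed_gc(genome, window: int = 10_000, step: int = 10_000) -> GcProfile:
    """G+C per window of the genome sequence.

    Windows are non-overlapping by default (step == window).  For a linear
    genome the final short tail is emitted as its own window; for a circular
    genome the final window wraps past the origin to full size.  The
    length-weighted mean of window values under the linear convention equals
    the whole-genome G+C exactly (pure-ACGT sequences).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    seq = genome.sequence if hasattr(genome, "sequence") else str(genome)
    seq = seq.upper()
    topology = getattr(genome, "topology", "linear")
    n = len(seq)
    whole = gc_content(seq)
    if window > n:
        warnings.warn("window exceeds genome length; single whole-genome window")
        return GcProfile(window, step, [0], [whole], whole, [n])
    starts, values, lengths = [], [], []
    pos = 0
    while pos < n:
        end = pos + window
        if end <= n:
            chunk = seq[pos:end]
        elif topology == "circular":
            chunk = seq[pos:] + seq[: end - n]
        else:
            chunk = seq[pos:]
        starts.append(pos)
        values.append(gc_content(chunk))
        lengths.append(sum(1 for b in chunk if b in _ACGT))
        pos += step
    return GcProfile(window, step, starts, values, whole, lengths)


@dataclass
class CodonUsageTable:
    counts: dict  # codon -> count, all 64 codons present
    per_aa_fractions: dict  # aa -> {codon: fraction}
    at3_fraction: float
    gc3_fraction: float
    n_sense: int
    n_stop: int
    n_ambiguous: int


def codon_usage(cds_sequences) -> CodonUsageTable:
    """Codon counts and third-position composition over a CDS set.

    Stop codons are counted but excluded from at3/gc3; codons containing an
    ambiguity symbol are excluded everywhere.  Sequences whose length is not
    a multiple of 3 are skipped with a warning.
    """
    table = CodonTable.unambiguous_dna_by_id[11]
    counts: Counter = Counter()
    n_ambiguous = 0
    for i, cds in enumerate(cds_sequences):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            warnings.warn(f"CDS #{i} length {len(cds)} not a multiple of 3; skipped")
            continue
        for j in range(0, len(cds), 3):
            codon = cds[j : j + 3]
            if set(codon) <= _ACGT:
                counts[codon] += 1
            else:
                n_ambiguous += 1

    all_codons = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
    full_counts = {c: counts.get(c, 0) for c in all_codons}

    n_stop = sum(counts[c] for c in STOP_CODONS_T11)
    sense = {c: k for c, k in counts.items() if c not in STOP_CODONS_T11}
    n_sense = sum(sense.values())
    at3 = sum(k for c, k in sense.items() if c[2] in "AT")
    at3_fraction = at3 / n_sense if n_sense else float("nan")
    gc3_fraction = 1.0 - at3_fraction if n_sense else float("nan")

    per_aa: dict = {}
    for codon, k in sense.items():
        aa = table.forward_table[codon]
        per_aa.setdefault(aa, {})[codon] = k
    per_aa_fractions = {
        aa: {c: k / sum(d.values()) for c, k in d.items()} for aa, d in per_aa.items()
    }
    return CodonUsageTable(
        full_counts, per_aa_fractions, at3_fraction, gc3_fraction,
        n_sense, n_stop, n_ambiguous,
    )
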