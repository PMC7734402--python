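"""Reading and writing annotated genomes, CDS translation, rRNA extraction.

Coordinates are 0-based half-open internally.  GenBank locations (1-based
inclusive) are converted once, on read, by Biopython.  The alternative
"fasta+table" dialect pairs a FASTA file with a tab-separated feature table
whose columns are ``kind  start  end  strand  product`` with 1-based
inclusive coordinates (GFF-like), converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_KINDS = ("CDS", "rRNA_16S", "rRNA_23S", "rRNA_5S", "other")

#: default maximum tolerated fraction of ambiguous (X) residues per protein
MAX_X_FRACTION = 0.05


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class Feature:
    """One located genome feature.

    intervals are 0-based half-open; multi-interval features arise from
    GenBank ``join()`` locations.
    """

    kind: str
    intervals: tuple[tuple[int, int], ...]
    strand: str  # '+' or '-'
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.intervals:
            raise ValueError("feature needs at least one interval")
        for s, e in self.intervals:
            if not 0 <= s < e:
                raise ValueError(f"bad interval [{s}, {e})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class GenomeRecord:
    """One replicon: sequence plus typed, located features."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty genome sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear/circular, got {self.topology!r}")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if e > n:
                    raise ValueError(
                        f"feature interval [{s}, {e}) outside genome of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feature: Feature) -> str:
        """Spliced, strand-normalized nucleotide sequence of a feature."""
        raw = "".join(self.sequence[s:e] for s, e in feature.intervals)
        if feature.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw


@dataclass
class ProteinRecord:
    id: str
    residues: str
    tm_helix_count: Optional[int] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.residues) < 1 and not self.flags:
            raise ValueError("empty protein sequence")

    @property
    def usable(self) -> bool:
        """True when the record participates in composition statistics."""
        return not self.flags


@dataclass
class ProteinSet:
    """Translated CDS products, flagged records carried but excluded."""

    proteins: list[ProteinRecord]

    @property
    def usable(self) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.usable]

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs, order preserved.

    Duplicate ids provoke a warning but both records are kept; an empty file
    or a zero-length sequence is a :class:`FormatError`.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"zero-length sequence for record {rec.id!r}")
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r}; keeping both")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def _classify_rrna(product: str) -> str:
    p = product.lower()
    if "16s" in p:
        return "rRNA_16S"
    if "23s" in p:
        return "rRNA_23S"
    if "5s" in p:
        return "rRNA_5S"
    return "other"


def read_genome(path, format: str = "genbank") -> GenomeRecord:
    """Read an annotated genome.

    format="genbank": a GenBank flat file; rRNA subtypes are classified by a
    case-insensitive substring match on the product qualifier.
    format="fasta+table": ``path`` is the FASTA; a sibling file with suffix
    ``.features.tsv`` (or ``path`` with that suffix appended) holds the table.
    A FASTA without a table yields an empty feature list with a warning.
    """
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+table":
        return _read_fasta_table(path)
    raise ValueError(f"unknown genome format {format!r}")


def _read_genbank(path) -> GenomeRecord:
    rec = SeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "linear")
    features: list[Feature] = []
    for f in rec.features:
        if f.type == "CDS":
            kind = "CDS"
        elif f.type == "rRNA":
            kind = _classify_rrna(f.qualifiers.get("product", [""])[0])
        else:
            continue
        try:
            intervals = tuple(
                (int(p.start), int(p.end)) for p in f.location.parts
            )
            strand = "-" if f.location.strand == -1 else "+"
        except Exception as exc:  # unparseable location
            tag = f.qualifiers.get("locus_tag", ["?"])[0]
            raise FormatError(f"unparseable location for locus {tag}: {exc}") from exc
        quals = {k: v[0] for k, v in f.qualifiers.items() if v}
        features.append(Feature(kind, intervals, strand, quals))
    return GenomeRecord(rec.id, str(rec.seq), topology, features)


def _feature_table_path(fasta_path) -> Path:
    p = Path(fasta_path)
    sib = p.with_suffix(".features.tsv")
    return sib if sib.exists() else Path(str(p) + ".features.tsv")


def _read_fasta_table(path) -> GenomeRecord:
    (rec_id, seq), *extra = read_fasta(path)
    if extra:
        warnings.warn("multi-record FASTA; using first record as the replicon")
    table = _feature_table_path(path)
    features: list[Feature] = []
    topology = "linear"
    if table.exists():
        with open(table) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    if line.startswith("#topology="):
                        topology = line.split("=", 1)[1].strip()
                    continue
                kind, start, end, strand, *rest = line.split("\t")
                product = rest[0] if rest else ""
                if kind not in FEATURE_KINDS:
                    kind = _classify_rrna(product) if kind == "rRNA" else "other"
                features.append(
                    Feature(
                        kind,
                        ((int(start) - 1, int(end)),),  # 1-based inclusive in
                        strand,
                        {"product": product} if product else {},
                    )
                )
    else:
        warnings.warn(f"no feature table next to {path}; empty feature list")
    return GenomeRecord(rec_id, seq, topology, features)


# ---------------------------------------------------------------------------
# writers


def write_genome(genome: GenomeRecord, fasta_path) -> Path:
    """Write a genome in the fasta+table dialect; returns the FASTA path.

    Round-trips exactly through ``read_genome(..., format="fasta+table")``.
    """
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    table = fasta_path.with_suffix(".features.tsv")
    with open(table, "w") as fh:
        fh.write(f"#topology={genome.topology}\n")
        for f in genome.features:
            for s, e in f.intervals:
                fh.write(
                    "\t".join(
                        [f.kind, str(s + 1), str(e), f.strand,
                         f.qualifiers.get("product", "")]
                    )
                    + "\n"
                )
    return fasta_path


def write_fasta(records: Iterable[tuple[str, str]], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return path


# ---------------------------------------------------------------------------
# feature extraction


def extract_and_translate_cds(
    genome: GenomeRecord,
    code_table: int = 11,
    max_x_fraction: float = MAX_X_FRACTION,
) -> ProteinSet:
    """Translate every CDS feature with the given genetic code table.

    Minus-strand features are reverse-complemented first.  A trailing stop
    is removed.  Records are flagged (and thereby excluded from composition
    statistics) when the CDS length is not a multiple of 3, when an internal
    stop appears, or when more than ``max_x_fraction`` of residues are X
    (ambiguous codons).
    """
    cds = [f for f in genome.features if f.kind == "CDS"]
    if not cds:
        raise ValueError(f"genome {genome.id} has no CDS features")
    proteins: list[ProteinRecord] = []
    for i, f in enumerate(cds):
        pid = f.qualifiers.get("locus_tag", f"{genome.id}_cds{i:05d}")
        nt = genome.feature_sequence(f)
        if len(nt) % 3 != 0:
            proteins.append(ProteinRecord(pid, "", flags=("length_not_multiple_of_3",)))
            continue
        aa = str(Seq(nt).translate(table=code_table))
        if aa.endswith("*"):
            aa = aa[:-1]
        flags: list[str] = []
        if "*" in aa:
            flags.append("internal_stop")
        if aa and aa.count("X") / len(aa) > max_x_fraction:
            flags.append("high_ambiguity")
        if not aa:
            flags.append("empty_translation")
        proteins.append(ProteinRecord(pid, aa, flags=tuple(flags)))
    return ProteinSet(proteins)


def extract_rrna_copies(genome: GenomeRecord, kind: str = "rRNA_16S") -> list[str]:
    """Strand-normalized sequences of all rRNA features of one subtype."""
    if kind in ("16S", "23S", "5S"):
        kind = f"rRNA_{kind}"
    return [genome.feature_sequence(f) for f in genome.features if f.kind == kind]


def write_profile_table(profiles, path) -> Path:
    """Write ThermalProfile rows as TSV with fixed float formatting."""
    from .proteome_metrics import ThermalProfile  # local import, no cycle at load

    path = Path(path)
    cols = [
        "genome_id", "genome_size", "gc_genome_molpct", "gc_16s_molpct",
        "cvp_bias", "ivywrel", "at3_fraction", "rrna_operon_count",
        "min_16s_copy_identity_pct", "ogt_observed_c",
    ]

    def fmt(x, nd):
        return "" if x is None else f"{x:.{nd}f}"

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in profiles:
            assert isinstance(p, ThermalProfile)
            fh.write(
                "\t".join(
                    [
                        p.genome_id,
                        str(p.genome_size),
                        fmt(None if p.gc_genome is None else 100 * p.gc_genome, 1),
                        fmt(None if p.gc_16s is None else 100 * p.gc_16s, 1),
                        fmt(p.cvp_bias, 4),
                        fmt(p.ivywrel, 4),
                        fmt(p.at3_fraction, 4),
                        str(p.rrna_operon_count),
                        fmt(p.min_16s_copy_identity, 2),
                        fmt(p.ogt_observed, 1),
                    ]
                )
                + "\n"
            )
    return path
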