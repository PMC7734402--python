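#!/usr/bin/env python
"""Simulate the study inputs: a focal low-G+C chromosome and species tables.

Generates (a) one synthetic circular chromosome matching the focal
organism's measured properties — 25.8 mol% G+C target, 60 protein-coding
genes, six 16S-like rRNA copies at 0.1% per-site divergence — written as
FASTA + feature table under results/simulated/, and (b) species tables for
two metric-vs-OGT relationships (a declining 16S G+C trend and a rising
IVYWREL trend) with known slopes, written as TSV for the regression step.
"""

from pathlib import Path

import pandas as pd

from thermosig.io_formats import write_genome
from thermosig.synthetic_data import (
    GenomeSpec,
    generate_genome,
    generate_species_table,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    spec = GenomeSpec(length=200_000, gc_target=0.258, n_cds=60,
                      rrn_copies=6, rrn_divergence=0.001, seed=SEED)
    genome = generate_genome(spec)
    fasta = write_genome(genome, OUT / "focal_genome.fasta")
    print(f"focal genome {genome.id}: {len(genome):,} bp, "
          f"{sum(f.kind == 'CDS' for f in genome.features)} CDS, "
          f"{sum(f.kind == 'rRNA_16S' for f in genome.features)} 16S copies "
          f"-> {fasta}")

    # 16S G+C falls with OGT; IVYWREL rises with OGT
    lines = {
        "gc_16s_molpct": ((0.10, 52.0), 0.35),   # (slope per C, intercept), noise sd
        "ivywrel": ((0.001, 0.335), 0.003),
    }
    tables = []
    for metric, (line, sd) in lines.items():
        df, truth = generate_species_table(
            24, line=line, noise_sd=sd, ogt_range=(25, 95),
            seed=SEED, metric_name=metric,
        )
        tables.append(df.set_index(["species_id", "ogt_c"]))
        print(f"species table for {metric}: n=24, true slope {truth['slope']}")
    merged = pd.concat(tables, axis=1).reset_index()
    merged.to_csv(OUT / "species_table.tsv", sep="\t", index=False,
                  float_format="%.6f")
    print(f"wrote {OUT / 'species_table.tsv'}")


if __name__ == "__main__":
    main()
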