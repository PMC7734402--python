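# Methods

## Scope and model

`thermosig` treats thermal adaptation as a set of genome-level composition
signals that co-vary with optimal growth temperature (OGT) across
prokaryotes, and asks two questions of a genome: *where does it sit* on
each cross-species metric-vs-OGT trend, and *how far off the line* is it.
The underlying assumption is the standard one for these comparative
analyses: each metric responds approximately linearly to OGT over the
25–100 °C range, with species scatter treated as i.i.d. noise (no
phylogenetic correlation structure; generalized least squares on a tree is
out of scope).

## Metrics

**G+C.**  Fraction (#G+#C)/(#A+#C+#G+#T); IUPAC ambiguity codes are
excluded from numerator and denominator.  Output tables print mol% =
fraction × 100 at one decimal.  Windowed G+C uses non-overlapping 10-kb
windows by default.  A final short tail is emitted as its own window on a
linear replicon; on a circular replicon the final window wraps past the
origin to full size.  Under the linear convention the length-weighted mean
of window values equals the whole-genome G+C exactly (the wrap
double-covers origin bases, so the identity is only approximate for
circular output); the conservation test therefore uses the linear
convention.

**CvP bias.**  100 × (f_D+f_E+f_K+f_R − f_N−f_Q−f_S−f_T), charged set
{D,E,K,R} (His excluded), polar set {N,Q,S,T}; both sets are arguments and
can be overridden.  **IVYWREL** is the summed fraction of {I,V,Y,W,R,E,L}.
Composition is pooled residue counts over the proteome by default; an
unweighted per-protein mean is available because "average" is genuinely
ambiguous in this literature — both modes are exposed and the default is
documented rather than silently chosen.  Non-canonical residues (X, U, B,
Z) never enter composition counts.

**Membrane filter.**  Both indices are computed after removing proteins
with ≥ 2 predicted transmembrane helices, because integral membrane
proteins carry a strong hydrophobic composition bias unrelated to growth
temperature.  The detector is a Kyte–Doolittle sliding-window heuristic:
window 19 (odd, ≥ 7 enforced), threshold 1.6 mean hydropathy, maximal
qualifying runs counted as helices, runs closer than 10 window positions
merged.  These are conventional hydropathy-plot settings, not a trained
predictor; when counts from a dedicated TM predictor are available they
can be supplied as a TSV and bypass the heuristic per protein.
Selenocysteine maps to the Cys hydropathy value; unknown residues are
neutral (0).

**Codon usage.**  Counts over all 64 codons per CDS set (genetic code
table 11).  AT3/GC3 are defined over unambiguous *sense* codons only —
stops are tallied separately and codons containing ambiguity symbols are
excluded everywhere — so AT3 + GC3 = 1 holds exactly.

**Translation.**  CDS features are spliced (join locations), minus-strand
features reverse-complemented, and translated with code table 11.
Alternative start codons translate as their table-11 amino acid (no
forcing to Met): annotation consumers see at most a one-residue
difference, and the synthetic generator always opens with ATG so
round-trips are exact.  Records are flagged and excluded from composition
statistics when the nucleotide length is not a multiple of 3, when an
internal stop appears, or when more than 5% of residues are X (threshold
configurable).

## OGT models and residual scoring

Lines are fitted by ordinary least squares in the `metric_on_ogt`
orientation (metric on y, OGT on x, as these relationships are plotted);
`predict_ogt` inverts the line explicitly and refuses a zero slope.  The
vestige score for a species is the signed residual: observed metric minus
the line's value at the species' observed OGT.  Positive CvP/IVYWREL
residuals read as "still thermophilic for its temperature".  Correlation
tests (Pearson default, Spearman optional) use pairwise-complete rows per
metric, since comparative tables routinely have missing fields.
Literature lines from larger surveys are read from a flat key=value
config; the shipped template deliberately leaves the coefficients blank
because the source surveys publish them, this package does not, and baking
in transcribed constants would hide their provenance.

## Phylogenetics

Percent identity comes from affine-gap global alignment (match +1,
mismatch −1, gap open −5, extend −1; a length-k gap costs open +
(k−1)·extend) via Biopython's PairwiseAligner; the suite checks the score
against an independent Gotoh dynamic program.  By default identity is
computed over columns without gaps or N ("compared columns"); an
include-gaps mode counts them as mismatches.  Distances from a pre-aligned
set use pairwise gap deletion; Jukes–Cantor correction d = −(3/4)·ln(1 −
4p/3) raises a labelled error at saturation (p ≥ 0.75).  Neighbor joining
is the standard Saitou–Nei agglomeration written in-package (tie-break:
lowest label-index pair; negative branch-length estimates clamped to zero
with the deficit moved to the sister branch so path lengths are
preserved); on additive matrices it reproduces the input path lengths to
machine precision, and scikit-bio's independent implementation serves as a
cross-check in the tests, never as the implementation.  Bootstrap support
is column resampling with a seeded generator, 100 replicates by default
(the convention for NJ figures; replicate count is a parameter).

## Synthetic data

The generators define the test conditions; their defaults mirror the
measured properties of the motivating use case — a low-G+C chromosome
(target 25.8 mol%) carrying six 16S-like rRNA copies at 0.1% per-site
divergence — scaled to desk size.  Chromosome lengths default to 200 kb
(60 CDS of 300–1500 bp) rather than megabases: every statistic involved
concentrates well below the stated tolerances at this size, and the whole
suite stays fast.  The acceptance script states the sizes it uses next to
each number.

Mechanics worth knowing:

* Background bases are i.i.d.; after the features are built, the
  background G+C probability is solved so the *whole genome* hits the
  target exactly in expectation (features — template-derived rRNA at
  ~50% G+C, stop-free CDS codons — would otherwise bias it).  Realized
  G+C then deviates only by background binomial noise, ±0.005 at ≥ 60 kb.
* The 16S-like template is a fixed 1,500-base sequence from a hard-coded
  seed.  Tests need rRNA-copy *structure* (multiplicity, small
  divergence), not homology, and this keeps biological data out of the
  repository.
* Proteome composition targets are met by a linear program over the 20
  residue frequencies: minimize the maximum deviation from uniform
  subject to the CvP and IVYWREL equality constraints and a floor of
  0.001 per residue.  The floor encodes that real proteomes contain every
  residue, keeps sampled proteins realistic, and makes the degenerate
  extremes (|CvP| = 100, which would require four residue frequencies to
  be exactly zero) correctly infeasible with an informative error.
* Proteins tagged as membrane proteins receive two 25-residue hydrophobic
  stretches separated by a 30-residue polar spacer, so the TM surrogate
  counts ≥ 2 helices and the soluble filter removes them — the property
  the generator exists to exercise.
* Species tables draw OGT uniformly on a range and add Gaussian noise
  around a known line; the noiseless values are returned alongside as
  ground truth.

What the generators do **not** emulate: codon-usage structure beyond a
G+C target (no amino-acid-driven codon model), operon architecture (16S
copies are placed independently, no 16S–23S–5S clusters), sequence
evolution along a tree (copies radiate from one template), lateral gene
transfer, and compositional heterogeneity along the chromosome beyond
feature placement.  Passing tests therefore demonstrate that the
*measurement and inference machinery* is correct under controlled
conditions — not that real genomes satisfy the generators' assumptions.
Claims about a real strain still require its deposited genome; the test
that checks the real chromosome's published values runs only against a
user-downloaded copy, and the repository ships no sequence data.

## Numerical and degenerate-input choices

* Window/identity/distance computations use exact integer counts where
  possible; the windowed-G+C conservation identity is asserted at 1e-12
  and measured at ~1e-16.
* `fit_linear_model` refuses n < 2 and constant x; `fit_all_metrics`
  skips constant metrics with a warning instead of failing a whole run.
* A flat fitted line yields an undefined Pearson r (NaN), which the model
  container accepts.
* Zero compared columns (all-gap overlap) is an error, not 0% or 100%.
* The profile pipeline isolates failures per genome in the CLI; a genome
  without CDS features still yields its nucleotide metrics, with proteome
  fields empty.

## Known limitations

* The TM-helix surrogate is a hydropathy heuristic; its absolute counts
  differ from HMM-based predictors, which is why an external count table
  can replace it.  The <2-helix filter threshold is exposed.
* Exact reproduction of published pairwise 16S similarities from other
  programs' aligners is not promised; alignment parameters and identity
  conventions differ across tools.  Robust statements (e.g. "below 90%")
  are the intended use.
* No phylogenetic correction in the regressions; residual scoring
  inherits the i.i.d.-scatter assumption.
* NJ bootstrap supports are resampling frequencies of splits, reported on
  the original topology; they are not posterior probabilities.
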