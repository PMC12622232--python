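# Methods

## Metric definitions and counting rules

For a genome pair (Q, S), each direction's hit table is filtered to
conserved matches — e-value < 10⁻⁵, identity > 40%, aligned region > 50% of
the query protein length — and two counts are taken per direction: hit rows
(*C*) and distinct query ids (*Cu*). POCP divides the summed row counts,
POCPu the summed distinct-query counts, by *T_Q + T_S*.

Three choices here deserve explanation:

* **All three filter comparisons are strict.** The defining cutoffs are
  written as strict inequalities, and boundary hits (identity exactly 40%,
  coverage exactly 50%, e-value exactly 10⁻⁵) are excluded. Many
  reimplementations use ≥; comparability of published values argues for the
  strict reading, and the thresholds are configurable for users who need
  the other convention (non-default runs are marked in the output
  metadata).
* **POCP counts rows, POCPu counts distinct queries.** Row counting is the
  only reading consistent with observed POCP values above 100%: when a
  query matches *k* paralogous subjects it contributes *k* rows. Unique
  counting caps each query at one, which bounds POCPu by 100. Note the
  asymmetry this creates within a pair: a genome carrying two paralogs that
  both match one query protein of the partner contributes 2 from its own
  direction (two distinct queries) but only 1 from the partner's, so POCPu
  counts one pair of duplicated genes once rather than twice.
* **Coverage uses the hit's alignment-column count** (the tabular `length`
  column, gaps included) against the query length from the proteome — not
  `qend − qstart + 1`. "Aligned region" is ambiguous across tools; the
  length column is the one quantity the 12-column tabular format guarantees
  identically for BLAST, DIAMOND and MMseqs2.

Percentages are computed in floating point from exact integer counts; any
rounding (4 decimals in pair TSVs, 2/1 decimals for MCC/thresholds in
reports) is presentation-only.

## Hit-table sources

Hit tables are directional; the pair layer requests both directions.
`parse_hits` ingests 12-column BLAST-tabular TSV and normalises the MMseqs2
dialect's fractional identity ([0, 1]) onto the percent scale, so the
filter logic never depends on the producing tool. `run_external` wraps
named tool profiles (BLASTP with and without a prebuilt database, DIAMOND
at four sensitivity levels, MMseqs2 at four `-s` settings), each shipping
its sensitivity flags and a 1e-5 e-value reporting cutoff; every invocation
is appended to a run log with its full command line, because reporting caps
and sensitivity settings demonstrably shift POCP (row counting) even where
they leave POCPu unchanged.

The built-in aligner exists so the whole metric layer is testable with no
external binary: exhaustive Smith–Waterman (BLOSUM62, gap open 11 /
extend 1, via Biopython's PairwiseAligner) over all query–subject protein
pairs, one best-local-alignment hit per pair (no multiple HSPs — the
simplest reproducible contract). Reportability uses an approximate
Karlin–Altschul e-value with gapped BLOSUM62 constants (λ = 0.267,
K = 0.041) over a search space of query length × total subject residues,
cut off at E < 10. This e-value is deliberately crude: it only decides
whether a hit is emitted, and the conservation filter re-applies the exact
10⁻⁵ cutoff downstream, so metric values never depend on which aligner
produced the hits. Two consequences are documented rather than hidden:
random same-length proteins typically do receive a spurious local hit with
E on the order of 1 (as Karlin–Altschul statistics dictate), and the
direction-dependent search space means such marginal hits need not appear
in both directions. Neither affects conserved (E ≪ 10⁻⁵) matches.

## Pair set and genome shortlisting

Evaluation pairs are unordered, within-family only, self-comparisons
banned, labelled same-genus or not; a family of *n* genomes yields
*n(n−1)/2* pairs and twice that many directional comparisons. Genome
shortlisting applies the genus-size criterion first (≥ 10 genomes per
genus by default) and then requires ≥ 2 surviving genera per family — the
order follows the criteria's nested numbering; the alternative order would
retain small genera in diverse families. The name-validity criterion of
genome curation is modelled as an optional boolean taxonomy column rather
than a live nomenclature query, keeping the package self-contained.

## Classifier evaluation

The decision rule is "same genus iff value > threshold", boundary to the
negative class, default threshold 50%. MCC summarises the confusion matrix;
when any marginal sum is zero the coefficient is undefined and 0 (the
random-classification value) is returned. Products are taken in exact
integer arithmetic (Python ints in the scalar path, float64 marginals in
the vectorised sweep), correct for counts well beyond 10⁷.

Threshold optimization is an exact sweep: MCC is piecewise constant in the
threshold, changing only at observed values, so evaluating the midpoints
between consecutive distinct sorted values plus one candidate below the
minimum, the maximum itself and the 50% default covers every attainable
confusion matrix. Ties are broken toward the candidate closest to 50 (then
the smaller), so a perfectly separated family whose gap spans the reference
threshold reports 50 rather than an arbitrary gap endpoint. A bounded
Brent-style continuous mode is provided for parity with analyses that used
a generic 1-D optimizer; being a local method on a step function it can
stall on plateaus and is dominated by the sweep by construction — a
property the test suite asserts. The global MCC is computed over pooled
pairs, not by averaging family MCCs.

Method concordance is ordinary least squares of the reference method's
values on the evaluated method's, reported as R² (bounded, interpretable)
with slope, intercept and the classical F-test p-value; the p-value carries
no decision role.

## Synthetic data generator

`generate_pair` emulates exactly the features the metrics respond to: a
shared ortholog core (identical across genomes, or diverged by per-site
substitutions applied to one side), within-genome paralog duplications
(exact copies of their template, so the POCP/POCPu divergence is
hand-checkable), and accessory proteins drawn i.i.d. uniform over the 20
residues — expected pairwise identity near 5%, far below the 40% filter, so
they act as true negatives. Protein lengths default to uniform on
[80, 120] residues: long enough that random identity concentrates well
below the filter, short enough that exhaustive alignment is instant. The
closed form for undiverged pairs,
POCPu = 100 · (n_core + dup_a + n_core + dup_b) / (T_a + T_b), is what the
full-stack recovery tests check to within ±5 percentage points.

What the generator does not emulate: realistic amino-acid composition,
indels, domain shuffling, gene gain/loss along a phylogeny, or genuine
evolutionary divergence models. Passing recovery tests therefore
demonstrates that the pipeline's counting and filtering are correct, not
that any particular threshold generalises to real proteomes.

`generate_family_dataset` skips sequences and draws labelled values
directly from per-class uniform ranges — the archetypes of neatly distinct,
overlapping, or intermediate family distributions — giving the evaluation
layer ground truth with a known optimal-threshold gap.

## Problem sizes and numerical choices

The test and acceptance workloads use proteomes of up to ~25 proteins,
1,000 randomized hit-table instances, 200 optimizer-oracle instances of up
to 400 points and a 3×3×5 grid of generator settings — sizes chosen so the
exhaustive built-in aligner and brute-force oracles stay instant while
every code path is exercised; the metrics themselves are
sample-size-agnostic (the MCC layer is validated against confusion matrices
with counts in the hundreds of thousands). Determinism: all synthetic
randomness flows through seeded NumPy generators; the built-in aligner and
sweep optimizer are deterministic given their inputs.

## Known limitations

* POCP values from different aligners or reporting caps are not mutually
  comparable (row counting inherits tool reporting behaviour); POCPu is
  robust to this and is the recommended metric.
* The built-in aligner is quadratic in proteome size and meant for
  desk-scale work; genome-scale runs should use the DIAMOND or MMseqs2
  profiles.
* Family-specific thresholds optimized on the same data they are evaluated
  on are optimistic by construction; the report exposes both the default
  and optimized MCC so users can judge the gain.
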