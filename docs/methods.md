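# Methods

## Model

A panel of M binary markers, thresholded into positive/negative (in
practice FMO-guided), is gated as a nested tree of levels holding one or two
markers each: a two-marker level splits its parent into four quadrants, a
one-marker level into two halves. The exported statistic at every node is
its frequency as **percent of parent**.

A *population* assigns each marker one of three states — positive, negative,
or "any" (not considered) — with at least one marker defined, giving
3^M − 1 populations. The 2^M fully defined populations (the tree's leaves)
carry all the information: their percent-of-root values are the chained
products of percent-of-parent values down each path, and every other
population is an exact marginal sum over the leaves that agree with it on
its defined markers. Both facts are consequences of frequencies being event
counts divided by parent counts; the package assumes nothing else about the
data.

### Canonical order and naming

Combinations are enumerated in mixed-radix base-3 order over the state
vector (ANY = 0, POS = 1, NEG = 2, marker 0 most significant), skipping the
all-ANY vector. This order is deterministic, so repeated runs produce
byte-identical outputs. Names concatenate `<marker><sign>` for defined
markers in panel order (`M1+M2-M4+`), with ASCII signs for file portability.

### Implementation of the expansion

`compute_all` builds the leaf table once as a (2,)×M tensor and expands each
marker axis from (POS, NEG) to (ANY, POS, NEG), where the ANY slice is the
sum of the other two. Flattening the resulting (3,)×M tensor in C order *is*
the canonical enumeration order. This is algebraically identical to the
naive recursion over undefined-marker subtrees (the percent-chain product
distributes over sums); that recursion is retained in the test suite as an
independent oracle.

## Input handling

Two regional CSV dialects are supported: comma-separated fields with `.`
decimals (POINT) and semicolon-separated fields with `,` decimals (COMMA).
Dialect sniffing is conservative: a semicolon is decisive for COMMA; a
`digit.digit` pattern, or any comma not flanked by digits on both sides
(which cannot be a decimal mark), is decisive for POINT; anything else
raises rather than guessing, and an explicit override always wins. Output
reuses the input dialect, UTF-8, LF line endings, 6 fixed decimal places —
enough to exceed gating-software export precision and make write → parse →
write round trips byte-identical.

Canonical input headers are self-describing gate paths,
`CD62L+CD27-/IL22+IL17A+ | Freq. of Parent`, ordered from higher to lower
gating levels. We chose sign paths over quadrant numbering (Q1–Q4) because
Q-number conventions differ between software versions while sign paths are
unambiguous and invertible; exports with arbitrary headers (including
Q-numbered ones) are handled by a schema file mapping each header to a gate
path.

### Tolerances and degenerate inputs

- Values must lie in [0, 100]; anything else is an error naming the cell.
- Sibling gates should sum to 100 % of their parent. Export rounding leaves
  small drift, so the reader warns above ±0.5 and fails above ±2. Inputs
  are never renormalized: drift propagates and is visible in the
  conservation check (fully defined populations summing to 100).
- Descendants of a 0 % gate contribute nothing; if they are missing
  entirely (empty gates export inconsistently) they are imputed as 0 with a
  warning. A missing node under a non-empty gate is a structural error
  naming the path.
- Panels above 12 markers trigger a soft warning (3^12 ≈ 531 k columns) but
  no hard limit.

## Synthetic data and verification

Events carry binary marker states, not fluorescence intensities: the method
consumes post-threshold gating, so simulating intensities would add nothing
the pipeline can see. A sample is a multinomial draw of n events over the
2^M phenotypes; gating it through the tree reproduces exactly what analysis
software would export. Real data differ in ways the generator ignores —
continuous expression, imperfect thresholds, compensation artifacts,
acquisition variation — so passing tests demonstrate the *arithmetic* of
the expansion and the clustering workflow, not robustness to gating error.

Verification automates the computed-vs-directly-gated comparison: for
random phenotype distributions (Dirichlet(1) draws) and panels of 2, 3, 4,
and 6 markers, every expanded population value is compared with a direct
event count. Both routes are exact rational computations, so agreement is
required to 1e−9 relative (absolute where the count is 0); observed
deviations are at machine precision (~1e−16). The `verify` subcommand runs
this check (default 25 trials per panel size, 10 000 events each) plus the
closed-form count identities for 1–8 markers.

Cohorts draw each sample's phenotype probabilities from
Dirichlet(concentration × centroid), keeping samples on the simplex with
one dispersion knob; centroid entries are floored at 1e−9 so structurally
absent phenotypes cannot zero a concentration parameter. The default
two-group cohort (`two_group_cohort_spec`) uses a four-marker quadrant
panel, 10 samples per group, 20 000 events per sample, concentration 300,
and deterministic opposing-gradient centroids (group A weights phenotype i
proportionally to i + 1, group B the reverse): every marker's marginal
differs between groups while no single population separates them, which is
the regime the classification workflow targets. With these conditions the
k = 2 cut separates the groups in 20 of 20 seeds tested.

## Downstream analysis

Autoscaling centers each population column and scales to unit sample
standard deviation (n − 1 denominator); zero-variance columns are set to 0
and flagged rather than dropped, so column order is preserved. The sample
distance is 1 − Pearson correlation between population profiles; a constant
profile has no defined correlation and is assigned r = 0 (distance 1) with
a warning instead of propagating NaN. Average linkage is the default — the
distance measure is fixed by the workflow this package reproduces, the
linkage is our documented assumption — with complete and Ward offered, and
Euclidean distance as the alternative metric. PCA is a numpy SVD of the
centered matrix with a fixed sign convention (largest-magnitude loading of
each component made positive) for reproducibility across BLAS builds.

The separation score cuts the dendrogram at k clusters, assigns each
cluster its majority true label (ties broken by label sort order), and
counts samples whose label differs from their cluster's majority; 0 means
the cut recovers the grouping. An optional minimum-frequency column filter
is deliberately *not* applied by default: all 3^M − 1 populations enter the
analysis, and near-empty columns are handled by the constant-column flag.

## Problem sizes

The test suite and acceptance script run at M ≤ 10 for pure enumeration
(59 048 combinations, well under a second), M ≤ 6 for event-based checks
(100 random event sets of 10 000 events), and 10+10-sample cohorts for
clustering — sizes at which every check completes in seconds while
exercising the same code paths as larger panels.

## Known limitations

- Raw FCS files, compensation, transformation, and automated gate placement
  are out of scope; the input is the exported frequency table.
- Markers are strictly bimodal here: dim/bright gradations collapse into
  one positive state.
- The bootstrap-based cluster-stability analysis, survival models, and
  feature selection sometimes layered on top of this workflow are not
  included.
- Percent-of-parent inputs are trusted as given; systematic gating error
  propagates multiplicatively down the tree.
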