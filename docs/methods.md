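# Methods

## Data model

A gene's evidence is a 2×N table of supporting-read counts n_ij over its N
tandem poly(A) sites, ordered proximal → distal by 3'-UTR length L_j (nt
from the stop codon to the cleavage site; for minus-strand genes the
distance is taken in transcript orientation upstream of the table, so the
statistics never touch strand). A gene enters testing only with at least
two sites and at least one read. The on-disk tandem-table schema (TSV with
semicolon-separated per-site vectors) is this package's own format: the
pipelines that produce such tables do not define a standard one, so ours
is a documented stand-in chosen to be compact and diff-friendly.

## Independence tests

**Chi-squared.** Plain Pearson X² = Σ (O−E)²/E with E = row·col/n, no
continuity correction (a Yates-style correction would visibly change the
worked-example p-values; the plain statistic reproduces them). All-zero
columns are dropped and the degrees of freedom (N−1) reduced accordingly;
a table left with fewer than two informative columns, or with an empty
sample row, is reported untestable rather than given a p-value. Tail
probabilities come from the χ² survival function, never 1−CDF, so
p-values as small as ~1e-300 (the most extreme worked example is
5.1e-212) are represented exactly.

**Fisher (Freeman–Halton) for 2×N.** For grand totals below the
small-sample threshold (default 30, applied to the table's grand total;
configurable) the exact conditional test replaces chi-squared: the
p-value is the sum of multivariate-hypergeometric probabilities, given
the observed margins, of every table no more probable than the observed
one. Enumeration recurses over the first row's column allocations with
log-space probabilities; two probabilities are treated as tied when they
agree to a relative 1e-7, which absorbs floating-point noise in the sum.
A workload cap (default 2×10⁶ visited allocations) guards against calling
the exact test on tables that belong to chi-squared. scipy's R×C
`fisher_exact` is Monte-Carlo-based for N > 2 and therefore serves
neither as implementation nor oracle; tests compare against an exhaustive
rational-arithmetic enumeration instead.

## Linear-by-linear trend test

Row scores are fixed at (1, 2), column scores are the L_j. With the cell
counts as weights, r is the weighted Pearson correlation between row and
column scores and M² = (n−1) r² is referred to χ²(1). If either weighted
score variance is zero (an empty sample row, or effectively a single
site), r is defined as 0 and p as 1 — the data carry no trend
information. r is clamped to [−1, 1] against rounding. Two exact
identities are kept under test: M² = (n−1) r² for every gene, and
M² = ((n−1)/n) X² for 2×2 tables, which ties the two test families
together. The trend p is invariant under positive affine rescaling of the
column scores and flips the sign of r under score reversal; it is *not*
invariant under column permutation, which is precisely what distinguishes
it from the independence test.

Genes dispatched to the exact test report no trend result: at grand
totals below ~30 the χ²(1) reference for M² is unreliable, and the
small-sample regime is exactly where the exact independence test is the
honest choice. The trend FDR therefore runs only over trend-tested genes.

## FDR and grouping

Benjamini–Hochberg step-up: q_(i) = min_{j≥i} p_(j)·m/j capped at 1,
computed separately for each test across the analyzed cohort (each test's
gene list is filtered by its own FDR). Groups at a cutoff (default 0.01):
CL both tests significant, CO independence only, LO trend only, NS
neither; genes without a trend result can only be CO or NS.

## Effect metrics

Usage ratios are counts over the sample's gene total; both samples must
have reads, otherwise the metrics are undefined and flagged.
DiffInRatio = Σ_j (n_1j/n_1· − n_2j/n_2·)² is the plain sum of squared
ratio differences, bounded by 2; a `sqrt` flag gives the Euclidean
variant (the between-gene ordering is identical, so the choice only
matters for absolute scales). The average 3'-UTR length is the
count-weighted mean of the L_j — an unweighted mean could not differ
between samples over a fixed site set, so weighting is forced — and is
normalized by the most distal length, giving values in (0, 1]; the change
is sample 2 − sample 1 throughout the package (sample order is
meaningful and logged by the CLI).

## Pattern classification

Per-site ratio changes Δ_j are reduced to an alternating sign sequence:
(1) near-zero changes (|Δ| < ε, default ε = 0.05 absolute ratio change)
are dropped at the edges and absorbed into the stronger neighbor in the
interior, smallest first; (2) consecutive same-sign changes are summed
into runs; (3) the sign string is labelled `+-` → `/\` (shortening),
`-+` → `\/` (lengthening), `+-+` → `/\/`, `-+-` → `\/\`. Longer
alternations are reported as `other` rather than forced into the four
classes; an optional `collapse` mode folds the weakest run into its
stronger neighbor until one of the four classes remains. If everything is
near zero — or absorption leaves a single residual run, i.e. no change
point — the label is `none`. ε is a free parameter with no canonical
value; 0.05 means "a site must shift at least 5% of the gene's reads to
count", and the CLI exposes it. Two-site genes can only be `/\`, `\/` or
`none`, and for them `/\` is equivalent to a negative average-length
change. Group comparisons of the effect metrics use two-sided
Wilcoxon rank-sum tests (exact for tie-free groups under 20 values,
tie-corrected normal approximation otherwise, via scipy).

## Simulated data

**Worked examples.** Fifteen deterministic three-site genes in three
scenarios: T1 (lengths 1000/2500/4000 nt, middle at the flank mean, only
the middle site's expression changes — trend p is exactly 1 at any effect
size), T2 (fixed counts 100,100,100 vs 100,500,100 while the middle
site's distance sweeps 2000→3000 nt — trend p rises to 1 at 2500 nt and
falls symmetrically beyond), and T3 (lengths 1000/2000/4000 nt with
switches tuned to preserve the count-weighted average length). These are
the package's reference points; the acceptance checks hold their
p-values to 1% relative (10⁻³ absolute for values of ~1).

**Random cohorts.** Reproducible multinomial counts at fixed per-sample
depth. Sample 1 draws from uniform site probabilities; sample 2 from a
perturbed vector: `shortening` moves `effect_size` of probability mass
onto the proximal site (taken equally from the rest), `lengthening`
mirrors it distally, `up_down_up` moves the mass off the interior site(s)
onto the two flanks equally, `down_up_down` reverses that, and `null`
changes nothing. Site 3'-UTR lengths are evenly spaced 1000–4000 nt, so
with three sites the middle sits at the flank mean and the complex
effects preserve the expected average 3'-UTR length — the regime the
toolkit exists to expose. Defaults used by the test suite and acceptance
script: 1000 genes at depth 300 for null calibration; 2000 genes per
pattern at depth 1000, effect size 0.3, for recovery — sizes chosen to
estimate the reported rates to well under a percentage point while the
whole suite runs in seconds.

The generator emulates sampling noise in site assignment only. It does
not model sequencing error, internal-priming artifacts, overdispersion
across biological replicates (counts are multinomial at fixed depth, as
in a single library), gene-to-gene depth variation, or uncertainty in
site positions. Passing tests therefore demonstrate the statistics'
behavior under clean multinomial sampling, not robustness to library
artifacts — the preprocessing filters exist for those, and their
parameters (24 nt clustering window, 5-read minimum, 40/80 nt merge
distances) follow the values established for this assay type. The
5-read filter is applied to the *combined* two-sample count (the
per-sample alternative is a configuration away); clustering is
single-linkage on sorted positions, chosen for determinism and
idempotence; merged-site length is the count-weighted mean of members,
which preserves the trend test's distance semantics better than keeping
the dominant member's length.

## A boundary property worth knowing

For complex (mean-length-preserving) switching sampled multinomially at
equal depths, the trend statistic remains asymptotically χ²(1): the
variance of the between-sample mean-score difference equals the
pooled-variance denominator when the two samples have equal totals. The
trend p-value is then uniform on (0, 1), so the expected fraction of
complex genes with trend p > 0.1 is 0.90 — the deterministic "p ≈ 1"
of the worked examples turns, under sampling, into *exactly borderline*
insensitivity, and measured fractions hover around 0.90 by sampling
noise. The chi-squared side is unaffected (q ≪ 0.01 essentially always
at depth 1000, effect 0.3).

## Degenerate inputs and numerical conventions

Untestable genes (one site, no reads, one empty sample for the
independence test) are skipped with a logged reason and excluded from
FDR; NaN p-values are rejected outright. The Fisher tie tolerance,
the r = 0 convention, and zero-column dropping are described above. All
cohort generation flows through a single integer seed
(`numpy.random.default_rng`); identical seeds give byte-identical output
files.

## Known limitations

Two samples only — no replicate-aware or ANOVA-style designs. No
internal-priming or poly(A)-signal filtering. The classifier's ε and the
`other`/`collapse` handling of >3-run genes are conventions, not fitted
values. Real-data gene tallies depend on upstream read mapping and site
calling, which are out of scope here; the statistics are validated on
the deterministic examples and simulated cohorts instead.
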