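# Methods

## The measurement model

One titration experiment is a set of ten affinity pulldowns at bait
concentrations L₁ < … < L₁₀ forming a 3-fold dilution series from a top
concentration of 3 μM (L₁ ≈ 0.15 nM), each quantified in one channel of a
TMT 10-plex run. For a protein with apparent dissociation constant K_d^App
and Hill coefficient n, the expected bound fraction is

θ(L) = 1 / ((K_d^App / L)^n + 1).

The assay does not observe θ directly; it observes reporter intensities
proportional to the amount of protein captured. Two assumptions convert
intensities to θ:

1. **Saturating reference.** The heaviest channel (top concentration) is
   taken to represent complete binding, so θ at channel c is the intensity
   ratio I_c / I_ref. This is accurate for K_d^App ≪ 3 μM and compresses
   fitted values for weak binders: at K_d^App = 500 nM the true θ at 3 μM is
   0.857, so the measured curve saturates "too early" and the fit
   underestimates K_d^App by ~20–30%. This compression is a property of the
   assay design, not of the software; it is visible in the recovery benchmark
   and bounded there.
2. **Flat background.** Non-specific proteins bind proportionally to input at
   every concentration, producing ratios near 1 throughout; they are removed
   by the goodness-of-fit and endpoint filters rather than by any
   abundance-based rule.

## Fitting pipeline and order of operations

Per replicate, θ is computed against the reference channel (rows with any
missing channel, or a missing/zero reference, are excluded: θ must be
measured at every titration point of every replicate). Replicates are then
averaged pointwise, and the **mean** profile is min–max scaled to [0, 1]
before fitting. Scaling after averaging is deliberate: min–max anchors the
scale on the most extreme observed values, and with multiplicative noise the
per-replicate maximum is biased upward by extreme-value selection
(~+1.3σ per replicate). Scaling each replicate individually propagates that
inflation into the mean and measurably worsens K_d recovery (median
|relative error| 0.21 vs 0.15 under the standard benchmark conditions);
scaling the averaged profile incurs it only once at √3-reduced noise. The
per-replicate order remains available (`scale_per_replicate=True`).

The scaled mean is fit by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, trust-region reflective) minimizing
Σ_c (θ̄_c − θ(L_c; K_d, n))², initialized at K_d = 100 nM, n = 1, with box
bounds K_d ∈ [10⁻³, 10⁵] nM and n ∈ [0.1, 10]. The bounds are wide enough to
span every plausible affinity while keeping the solver finite on flat
background profiles. Non-convergence is recorded as a flag, never an
exception. r² is the squared Pearson correlation between observed and fitted
values. Acceptance requires convergence, r² ≥ 0.95 (DNA preset; 0.90 for
nucleosome experiments, whose reconstituted baits are noisier), predicted
θ < 0.25 at L₁ and > 0.75 at L₁₀. Degenerate (constant) profiles are flagged
and excluded before fitting.

Per-point uncertainty on the mean profile is a bootstrap SEM: replicates are
resampled with replacement `n_boot` times (default 1000, seeded) and the SEM
is the standard deviation of the resampled means. Replicate concordance is
summarized as the CV (sample SD / mean) of replicate-wise K_d fits, computed
for QC-passing proteins with ≥ 2 converged replicate fits; replicate-wise
fits reuse the mean-fit initialization and bounds.

Total-signal normalization (equalizing channel column sums to their mean)
corrects channel-loading imbalance in real tables and is near-identity when
totals are dominated by flat background. It is skipped for synthetic
benchmarks: the generator has no loading imbalance, and equalizing column
sums on a background-free cocktail of specific binders would erase the very
concentration dependence being fitted.

## Competition mode

In competition, the bait stays immobilized (200 nM) and a free competitor is
titrated over the same series; retained signal falls with the decreasing
mirror curve θ = 1 − 1/((IC50/L)^n + 1). Retention is anchored by ratioing to
the **lightest** channel — the lowest competitor concentration, where binding
is maximal — which makes the first point exactly 1 by self-ratio. No
data-driven min–max rescale follows: forcing the observed top-concentration
point to 0 would presume complete displacement and biases IC50 downward by
20–30% whenever displacement is incomplete. QC mirrors the direct mode
(r² ≥ 0.95, retention > 0.75 at the lowest and < 0.25 at the highest
competitor concentration), so only curves spanning essentially full-to-none
retention are accepted. Accepted IC50s are converted with the Cheng–Prusoff
correction, K_d_free = IC50 / (1 + [immobilized]/K_d_immobilized); the
correction is monotone in both arguments and tends to the raw IC50 as the
immobilized bait weakens.

## Clustering and group comparison

Accepted fits across baits are assembled into a proteins × baits matrix of
log10 K_d^App; proteins without an accepted fit for a bait are imputed at
log10 of the assay ceiling (3000 nM — "no measurable binding up to the top of
the titration") and masked, or optionally dropped. Clustering is hierarchical
agglomerative (average linkage, Euclidean distance by default; both
configurable) with a deterministic flat cut at k clusters; k is a user choice
(manual inspection), defaulting to 15 in the CLI. Cluster summaries average
log10 K_d over non-missing cells per cluster-bait, falling back (flagged) to
the imputed ceiling where a cluster-bait cell is entirely missing. Group
comparisons between complex subunits use Welch's two-sided t test, since
subunit groups differ in size and variance.

## Interval enrichment

Coordinates are BED 0-based half-open; book-ended intervals do not overlap.
G4 peaks from both strands are merged (strand ignored, strict >0 bp overlap).
The statistic is the number of ChIP peaks overlapping the merged G4 set by
≥ 1 bp, each peak counted once. Under the null, every ChIP peak is re-placed
uniformly at random within its own chromosome (lengths and per-chromosome
counts preserved, overlaps among placed peaks allowed). The empirical p uses
the add-one estimator (1 + #{perm ≥ obs})/(1 + n_perm), which avoids p = 0
and floors at 1/(n_perm+1). With sparse peak sets the overlap count ties at
small integers and the test becomes conservative — a generic property of
discrete permutation statistics; the calibration benchmark therefore uses
peak densities at which the count is quasi-continuous (150 × 1 kb peaks
against 300 × 1 kb targets on a 10 Mb toy genome), where the 5% coverage of
null p values falls in the nominal band.

## Cross-link outlier calling

Duplicate forward/control dimethyl ratio tables are log2-transformed; per
replicate the fence is Q3 + 1.5·(Q3−Q1) with quartiles by linear
interpolation (Tukey boxplot convention), and a peptide is called only if it
exceeds the fence in **every** replicate. Calling is upper-tail only (the
question is enrichment in the forward channel). Because a per-replicate scale
factor becomes an additive shift in log2 that moves data and fence equally,
calls are invariant to rescaling any replicate.

## Synthetic data

The generator emulates the study conditions: ten-point 3-fold titration from
3 μM, triplicate, specific binders with K_d log-uniform over 5–500 nM
(n = 1), a large flat background, abundances log-uniform over three decades
(10⁵–10⁸ intensity units), and multiplicative log-normal noise with
σ² = ln(1 + CV²) at CV = 10% — typical inter-replicate variation for
reporter-ion quantification. Competition fixtures invert the Cheng–Prusoff
relation (IC50 = K_d·(1 + 200/K_d_imm)) so the fit-and-correct pipeline
should land back on K_d; the competition benchmark draws K_d from 5–100 nM,
the window in which the 0.15–3000 nM competitor series can actually span
full-to-complete displacement given that geometry. Optional stress knobs add
a tilted ("sticky") background and random cell dropout.

What the generator does **not** emulate: peptide-to-protein roll-up,
reporter-ion ratio compression from co-isolation, channel-loading imbalance,
abundance-dependent missingness, or correlated noise between channels.
Passing benchmarks therefore demonstrate correctness of the estimation
procedure under its own stated noise model, not robustness to every artifact
of real MS data.

## Benchmark sizes and numerical choices

The standard benchmarks use 200 specific binders (recovery), 500 background
proteins (specificity), 50 competition proteins (round trip), and 500 × 200
permutations (calibration) — sizes at which the measured quantities are
stable to a few percent while the whole suite runs in well under a minute.
The recovered-vs-true "1:1" regression is computed on log10 K_d: affinities
are compared on log scale by convention, and at n = 50 a linear-scale slope
is dominated by heteroscedastic high-K_d leverage points (its spread across
seeds is ±10% purely from estimator variance, while the log-scale slope is
stable near 1). Median |relative K_d error| under the standard conditions is
~14–16%: roughly 10% irreducible noise scatter plus the assay's systematic
end biases (upward at K_d ≲ 10 nM from the min–max floor, downward at
K_d ≳ 200 nM from the saturating-reference assumption).

## Known limitations

- K_d^App values near the top titration concentration are compressed (see
  above); the endpoint filter removes the worst cases but values above
  ~500 nM should be read as lower bounds.
- No weighting by SEM in the fit and no shared-parameter fitting across
  proteins; each protein is fit independently on its unweighted mean.
- The permutation null preserves chromosome of origin; enrichment driven by
  chromosome-scale composition differences is invisible to it.
- Quartile conventions other than linear interpolation will shift IQR fences
  slightly on small tables.
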