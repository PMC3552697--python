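# Methods

## The ΔCT calculus and pseudo-controls

All normalization here operates on raw cycle-threshold (CT) values,
which are inversely and logarithmically related to abundance (one cycle
≈ one doubling).  A pseudo-control method produces one CT₀ per sample;
ΔCT = CT − CT₀, ΔΔCT = ΔCT − ΔCT_control, and FC = 2^(−ΔΔCT) under the
perfect-doubling assumption.  No amplification-efficiency correction is
attempted: the calculus is exactly the ideal-efficiency one.

Implemented CT₀ constructions:

- **mean / median / geometric mean** of all observed genes in the
  sample.  The geometric mean is taken on the CT scale itself (CT is
  already a log-scale quantity; in practice it differs little from the
  arithmetic mean and that near-equivalence is itself informative).
- **top-k**: the arithmetic mean of the k genes with smallest
  across-sample sd (ddof = 1).  The selected set is identical for all
  samples; ties in sd break by gene id for determinism.  Default k = 8.
- **weighted mean**: CT₀ = Σⱼ wⱼCTⱼ with
  wⱼ ∝ (1/max(sdⱼ, ε))^wmp, normalized to sum to 1.  The power is
  applied in both numerator and denominator so the weights are a
  proper convex combination; this makes wmp = 0 collapse *exactly*
  (bitwise, by construction of the weights) to the arithmetic mean and
  large wmp converge to the most stable gene.  ε (default 0.01
  cycles) floors the sd so a zero-variance gene cannot take infinite
  weight; it matters only for near-constant genes and is recorded in
  provenance.
- **rank-invariant set**: genes whose within-sample rank differs from
  their rank in a reference sample by at most `rank_window` in every
  sample; CT₀ is the mean CT of that set.  The reference defaults to
  the sample whose mean CT is the (lower) median of the sample means;
  `rank_window` defaults to ⌈0.05 · n_genes⌉.

Full-matrix baselines: **quantile** (identical sorted CT multiset per
sample, midrank handling of ties), **median-shift** (per-sample
constant shift to the median of per-sample medians), and **cyclic
loess** (pairwise M-vs-A lowess on log CT, fit split evenly between the
two samples, all pairs cycled until the largest mean |F| < tol;
defaults span 0.7, max 3 cycles, tol 0.01 — log CT is used, even though
CT is already log-scale abundance, because the M/A construction is
defined on logged values).  Quantile and loess require complete
matrices and direct the caller to `filter_genes`.

## Stability scoring

Two criteria score genes and candidate CT₀ vectors:

- across-sample standard deviation (ddof = 1);
- a geNorm-style M: for entries j, k let V_jk = sd over samples of
  (CT_j − CT_k); M_j is the mean of V_jk over all partners k.  CT
  differences play the role of log expression ratios since CT is
  log-scale.  A candidate CT₀ is scored by appending it as a
  pseudo-gene to the full gene set.  Pairs with fewer than two
  overlapping observed samples are skipped.  On complete matrices M is
  computed through the gene-by-gene covariance matrix
  (V²_jk = C_jj + C_kk − 2C_jk, clipped at 0 before the square root),
  which is algebraically identical to the pairwise definition.

The iterative geNorm gene-elimination procedure and its V(n/n+1)
cutoffs are out of scope; only the M statistic is used.

`scan_wmp` chooses the weighted-mean power by enumeration over a grid
(default 0 and the odd powers 1–19), scoring the resulting CT₀ by both
criteria; ties go to the smallest power.  Note a structural fact: when
the grid contains 0 and selection is by geNorm M, the selected power's
M can never exceed the plain mean's, so the sd criterion is the
discriminating one on data where the mean is already the M-optimal
compromise.

## Bias diagnostics

A gene's *fluctuation* in a sample is its CT minus the gene's own mean;
a sample's *mean fluctuation* is the sample mean minus the overall
mean.  On a complete matrix the mean fluctuation equals the
gene-average of gene fluctuations, which forces the average of the
per-gene regression slopes of gene fluctuation on mean fluctuation to
be exactly 1 — a useful internal consistency check, asserted in the
tests to machine tolerance.

Reported per gene: mean CT, sd, Pearson correlation of the gene's
fluctuations with the mean fluctuations (NaN, not 0, for zero-variance
genes), the OLS sensitivity slope, and the mean per-sample ratio of
gene fluctuation to mean fluctuation.  The ratio is unstable when a
sample's mean fluctuation is near zero, so samples with
|mean fluctuation| below a guard (default 0.05 cycles) are excluded;
when gene fluctuations are exact multiples of the mean fluctuation the
ratio and the slope coincide exactly.  The sd-vs-mean trend is an
ordinary least-squares line of per-gene sd on per-gene mean CT.  All
regressions are plain OLS.  Genes with missing wells are diagnosed over
their observed samples, with the mean-fluctuation vector re-centered on
that subset.

## Cross-platform concordance

ΔCT values are inner-joined with log2 microarray intensities on gene
id; Spearman's ρ is computed overall and within half-open bins of mean
raw CT (default 5-cycle bins from 15 to 35).  Because lower CT means
higher abundance, concordant platforms give negative ρ.  On tie-free
data ρ is computed by the classic 1 − 6Σd²/(n(n²−1)) formula, which
returns exactly ±1 for perfectly monotone data; with ties, Pearson on
midranks.  P-values use a seeded two-sided permutation test (default
10 000 permutations) below n = 50 and the asymptotic approximation
above.  Bins with fewer than 3 genes are reported with ρ undefined.

## Synthetic data: what it emulates and what it does not

The generator draws

    CT[g, s] = μ_g + s_g·δ_s + ε[g, s],  ε ~ N(0, σ_g²)

with μ_g uniform on 15–35 cycles, loading offsets δ_s ~ N(0, τ²)
centered to sum to zero, sensitivity s_g = a + b·μ_g and noise
σ_g = c + d·μ_g.  Defaults: 666 genes × 20 samples, τ = 0.6,
(a, b) = (−0.5, 0.06), (c, d) = (0.1, 0.02).  The shape mirrors a
typical miRNA low-density-array study; τ is set so pseudo-control sds
land in the 0.5–0.7-cycle range typical of such panels, (a, b) makes
the gene-averaged sensitivity exactly 1 (the fluctuation regression
can only identify sensitivities relative to their mean), and (c, d)
puts individual-gene sds around 0.4–0.9 cycles.  With b, d > 0 the
matrix reproduces the three empirical bias signatures: sd rising with
mean CT, pervasive correlation with the mean fluctuation, and
sensitivity slopes increasing with mean CT.

Expected per-gene sd under the model is
√(s_g²τ²(1 − 1/n) + σ_g²) — the (1 − 1/n) factor comes from centering
the offsets — and the tests check the simulated sds against this
closed form.

The model deliberately omits: PCR kinetics (no cycle-by-cycle
saturation; the sensitivity mechanism is imposed linearly rather than
emerging from chemistry), plate/card batch structure, correlated gene
blocks (co-regulated miRNA families), non-Gaussian heavy-tailed wells,
and truly informative censoring at the detection limit
(`spike_undetected` imposes dropout by rank of mean CT, not by a
thermodynamic model).  Tests passing on this generator therefore
demonstrate the algebraic and statistical behavior of the methods
under a clean loading-offset bias, not performance on any particular
real panel.

`generate_paired` produces intensities 2^(K − μ_g + noise) so log2
intensity is exactly linear in −μ_g; it emulates only the monotone
abundance relation between platforms, not probe-specific effects.

## Missing data and numerical choices

- Wells with CT at or above the undetected sentinel (default 40) are
  set missing on read by default; retaining them is an option, and
  `filter_genes` offers drop-any / drop-all / max-missing-fraction
  policies (boundary inclusive).
- A gene needs ≥ 2 observed wells for an sd and is otherwise excluded
  from stability weighting; CT₀ weights are renormalized per sample
  over the genes observed in that sample.
- Median-shift equalizes medians up to one floating-point rounding
  step (adding a shift constant to a float median cannot be bitwise
  exact); quantile normalization's sorted-multiset postcondition is
  exact.
- Ties: top-k and ranking tie-break by gene id; quantile ties receive
  the mean of the reference values they span; scan ties go to the
  smallest power.
- All simulation-backed defaults (problem sizes above) run the full
  test suite and the acceptance script in well under a minute of CPU.

## Estimator interface

The normalizers follow scikit-learn conventions (samples × genes
arrays, `fit`/`transform`, `get_params`, fitted attributes with
trailing underscores).  For pseudo-control methods, `fit` learns the
per-gene state (sds, weights, selected sets) and `transform` subtracts
a CT₀ computed from each new sample's own values with the *fitted*
weights — so a reference panel can be fit once and applied to new
samples.  `CyclicLoessNormalizer` is inherently a whole-matrix
operation: `transform` re-runs the pairwise procedure on the matrix it
receives and records cycle count and convergence on the estimator.
The functional API (`ctnorm.normalize`) fits and applies on the same
matrix, which is the standard single-study usage.
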