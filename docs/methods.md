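# Methods

## Model and procedure

`qstratify` allocates subjects to sensory phenotypes by density-based
similarity of their QST z-profile to phenotype centroids.  The design
premise is that QST z-values are approximately normally distributed within
a phenotype, so the plausibility of observing $z_i$ under phenotype $m$ is
proportional to the normal density
$\phi\big((z_i-\mu_i^{(m)})/\sigma_i^{(m)}\big)$.  Densities of broad and
narrow parameters peak at different heights, so each is normalized by its
own maximum, giving the per-parameter similarity

$$F_i^{(m)}(z) = 100\,\exp\!\big(-(z-\mu_i^{(m)})^2 / 2\sigma_i^{(m)2}\big),$$

a percentage that equals 100 exactly at the centroid mean.  The phenotype
probability is the arithmetic mean of $F_i^{(m)}$ over non-missing
parameters.  This averaging is the reason for the density formulation:
a Euclidean/Mahalanobis distance to the centroid is undefined with missing
coordinates, whereas dropping terms from a mean is well defined and
unbiased when the dropped term would have been typical.  Imputation is
deliberately not offered — imputed values would pull every profile toward
the imputation model and bias the allocation.

The healthy reference uses $\mu=0,\ \sigma=1$ for all 13 parameters,
including the two discrete-coded ones; this is the definition of the
z-scale, and the same single formula is applied to PHS and DMA codes as to
continuous z-values (one rule for all 13 parameters, at the price of
treating a discrete code as if Gaussian).

Deterministic allocation takes the arg-max over {SL, TH, MH} and, by
default, the healthy profile as a fourth competitor (`include_healthy`,
matching the final recommended form; the three-label variant is one flag
away).  Probabilistic allocation assigns every phenotype whose probability
strictly exceeds the cutoff and excludes subjects with no phenotype
exceedance; a lone healthy exceedance also excludes, but the healthy flag
is reported either way.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 64 (%) | probabilistic membership threshold; the Youden-optimal operating point of the healthy-probability ROC, applied to both protocols. Comparison is strict (> 64). |
| `include_healthy` | `True` | healthy profile competes in deterministic mode |
| `min_params` | 7 (full), 2 (simplified) | minimum non-missing parameters per profile. The algorithm tolerates any missingness in principle; averaging over very few parameters is statistically fragile, so a floor of 7 of 13 is enforced by default and is configurable down to 1. The simplified protocol needs both of its parameters. |
| `protocol` | `full` | `full` = all 13 parameters; `simplified` = WDT + MPS only |

Tie-breaks in the deterministic arg-max (a measure-zero event for
continuous profiles, reachable for coded or degenerate inputs) use the
fixed order SL > TH > MH > HEALTHY and set an explicit `tie_flag`, so runs
are deterministic and auditable.

## ROC, cutoff and agreement conventions

The healthy-profile probability is the diagnostic score; a subject is
classified healthy when the score exceeds the threshold, so sensitivity is
defined for *detecting patients* (score ≤ threshold).  The sweep uses all
distinct observed scores plus a −∞ sentinel (an integer-percent grid is
available to mimic step-per-percent presentations).  The AUC is the
trapezoid integral of the empirical curve, which equals the Mann–Whitney
U statistic scaled by $n_1 n_2$ with ties counted ½ — the test suite checks
this identity exhaustively on small instances.  The 95 % CI uses the
Hanley–McNeil standard error by default (the classical normal
approximation), with DeLong's variance one flag away.  The Youden cutoff
maximizes $J = \text{sensitivity} - \text{FPR}$; ties are broken toward
the higher specificity and then the higher threshold (the more
conservative operating point).  Whether the boundary value itself counts
as healthy is resolved as strict `>` throughout.

Cohen's kappa uses the standard $(p_o-p_e)/(1-p_e)$ with the large-sample
standard error $\sqrt{p_o(1-p_o)/(n(1-p_e)^2)}$ and no bias correction;
labels are nominal, so weighted kappa is not implemented.  Two identical
constant labelings ($p_e = 1$) are defined as kappa = 1 with a warning.

## Sample-size arithmetic

Designs map to test families: parallel → two-sample t (result is *per
group*), crossover → paired t on within-subject differences with d on the
difference scale (result is *total subjects*; carry-over and period
effects are out of scope), dichotomous → chi-square with Cohen's w.  Tests
are two-sided by default with a one-sided flag.  Power at a given n is
evaluated via the noncentral-t / noncentral-chi-square routines in
`statsmodels.stats.power`; the returned n is the exact smallest integer
reaching the target, found by bisection on the integers rather than by
rounding a continuous solution (the df change with n, so rounding can be
off by one).  Screening sizes are `ceil(n / frequency)`; for parallel
designs the inflated quantity is the *total* trial size (both arms are
recruited from the screened, phenotyped population).  All counts are
ceiling-rounded and per-group vs total is labelled explicitly in outputs.

## Synthetic cohorts

The generator draws each continuous parameter independently from
$N(\mu_i^{(m)}, (\text{sd\_scale}\cdot\sigma_i^{(m)})^2)$ and healthy
subjects from $N(0,1)$, using NumPy's `default_rng` (PCG64), so cohorts
are bit-reproducible given the seed.  PHS/DMA have no published
within-cluster distribution; the conformant default samples the same
Gaussian and snaps to the nearest legal code, and a continuous `gaussian`
mode exists purely to stress-test validation paths (profiles are marked
non-conformant).  Missingness is independent per cell, with the guarantee
that a profile never loses its last value.

What this emulates — and what it does not: real QST parameters are
mechanistically intercorrelated (e.g. the thermal detection block), real
clusters are not exactly Gaussian, and real missingness is not completely
at random.  Only per-parameter means and SDs enter the generator
(a user-supplied correlation structure can be injected by generating
profiles externally and reading them in).  Passing recovery tests
therefore show that the allocator inverts its own generative assumptions —
they bound, but do not measure, performance on clinical data.

## Centroid table

The packaged table (`data/centroids_synthetic.csv`) is a synthetic
stand-in: per-parameter (μ, σ) for SL/TH/MH chosen once to express the
published qualitative profiles — SL with pronounced thermal and mechanical
detection loss, TH near-normal detection with heat/cold hyperalgesia, MH
with thermal loss plus pinprick hyperalgesia and allodynia — under the
sign convention in which negative z means loss of function.  No numeric
claim in the package depends on these values; all quantitative anchors are
either closed-form (similarity normalization, coding rules, cutoff logic)
or computed relative to whatever table is loaded.  Users with access to a
defining cohort's table supply it as CSV; no re-signing of z-values is
performed.

## Numerical notes

- The similarity is mathematically in (0, 100], but underflows to exactly
  0 beyond ≈ 37σ from the centroid (float64); this is harmless in the
  averaging and documented in the tests.
- Allocation output percentages are full precision in CSV and rounded to
  one decimal only in human-readable console output.
- Monte-Carlo verification of the powered sample sizes uses 50 000
  replicates per design point of the actual simulated test (not the
  noncentral distribution), giving a standard error of ≈ 0.18 % on power —
  enough to certify minimality to ±1 subject across
  d ∈ {0.3, 0.5, 0.7} × {parallel, crossover}.
- Simulation-based tests use 40–800 subjects per cohort; these sizes were
  chosen so the whole suite runs in well under a minute while keeping
  binomial noise far from every asserted margin.

## Known limitations

- Diagonal-covariance classification: correlated parameter blocks (e.g.
  CDT/WDT/TSL) are effectively over-weighted, a known property of the
  published algorithm retained here by design.
- The fixed-seed recovery rate pinned in the tests (77.1 % overall at
  sd_scale = 1 with the synthetic table) is a regression fixture for this
  package's default conditions, not a clinical performance claim.
- No dropout inflation, interim analyses, or multiplicity adjustment in
  the trial-planning module.
- Raw-measurement → z transformation (age/sex/site normative tables) is
  out of scope; inputs are z-values.
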