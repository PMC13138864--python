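# Methods

## Model and estimand

A two-arm cluster randomized trial with longitudinal measurements: cluster
*i* (*i* = 1..*n*) carries arm indicator u_i ∈ {0,1} with
P(u_i = 1) = p; its J_i subjects are each measured at the common schedule
t = (t_1, …, t_T). The marginal mean is linear in time with an
intervention-by-time interaction,

    E(y_ijr) = β1 + β2 u_i + β3 t_r + β4 u_i t_r,   Var(y_ijr) = σ²,

and the estimand is β4, the difference in slopes. The second-moment model
has three layers: within-subject correlation Ω (repeated measurements on one
subject), the intra-cluster correlation ρ2 (concurrent measurements on two
cluster-mates, the diagonal of Φ), and the between-subject between-period
correlation ρ3 (nonconcurrent measurements on cluster-mates, the
off-diagonal of Φ). The full cluster correlation matrix is the exchangeable
block form R = I ⊗ (Ω − Φ) + 11′ ⊗ Φ, whose eigenvalues are those of Ω − Φ
(multiplicity J−1) and of Ω + (J−1)Φ; feasibility checks work on these two
T×T blocks rather than the JT×JT matrix.

Estimation is by GEE under an **independence working correlation** — pooled
least squares over the observed rows — because it is consistent under any
true correlation, needs no nuisance-parameter estimation, and admits a
closed-form design formula; the sandwich variance restores valid inference.
The centred parameterization b = (β1+β2p, β2, β3+β4p, β4) with design rows
Z_ijr = (1, u_i−p, t_r, (u_i−p)t_r) diagonalizes the limiting matrices and
is what the code fits; β̂ is recovered exactly from b̂.

## Missing data

Missingness is MCAR and time-dependent: δ_r = P(observed at t_r), with joint
probabilities δ_rr′ fixed by the pattern — independent (IM, δ_r δ_r′),
monotone dropout (MM, δ_max(r,r′)), or a w/(1−w) mixture (MIX). The design
formulas are valid for any marginals under IM, but MM and MIX are generated
by a dropout process, which exists only for nonincreasing δ; the validator
therefore enforces monotonicity for MM/MIX only. The simulator generates MM
by thresholding one uniform per subject against the survivor probabilities
(m_r = 1{U ≤ δ_r}), the unique mechanism reproducing both the marginals and
the MM joints for monotone δ. Subjects who lose every observation are kept
in the data (contributing nothing) so the marginals stay exact.

## Sample size

With Δ the joint-observation matrix and
Qm = (1/J)(Ω ∘ Δ) + (CV_J² + 1 − 1/J) diag(δ) Φ diag(δ),

    σ4² = σ² (μ_m1·1 − t)′ Qm (μ_m1·1 − t) / (μ_m0² vp² v_mt⁴),
    n    = ⌈ (z_{1−α/2} + z_{1−γ})² σ4² / β4² ⌉,

where μ_m0 = Σ δ_r, μ_m1, μ_m2 are δ-weighted grid moments,
v_mt² = μ_m2 − μ_m1², vp² = p(1−p). Useful consequences, all covered by
tests: complete data (δ = 1) reduces Qm to Q and μ_m0 to T; J = 1 drops Φ
and reduces to the individually randomized longitudinal formula; σ4² ∝
1/p(1−p), so p = 0.5 is optimal; n is nondecreasing in CV_J when
ρ2 ≥ ρ3 ≥ 0; and for nonnegative within-subject correlations MM ≥ MIX ≥ IM
at equal marginals, because the MM joints dominate the IM joints
elementwise. Mirrored measurement schedules (t ↦ t_1 + t_T − t) leave the
power invariant.

Cluster counts are always rounded up and may be odd; allocating an odd n is
the simulator's job. Only normal quantiles enter the closed form. As a
clearly-labelled extension, `required_clusters(..., threshold="t")` keeps
inflating n until the power computed with the t(n−4) critical value reaches
the target; the default path never uses it.

## Simulation engine

One replicate: (1) allocate arms — intervention count ⌊np⌋ or ⌈np⌉, the
remainder granted by a Bernoulli(fraction) coin, which is the fair coin
between (n±1)/2 for p = 0.5 and odd n; the general-p rule is this package's
choice since only balanced designs are standard; (2) draw cluster sizes from
the discrete uniform DU[a,b] (inclusive; variance ((b−a+1)²−1)/12); (3) draw
each cluster's outcomes from MVN(mean model, σ²R) via a Cholesky factor of
the JT×JT matrix, cached per distinct J; (4) apply the missingness process;
(5) fit the GEE, form the cluster-level sandwich Σn = An⁻¹VnAn⁻¹ (subject
scores are summed within a cluster before the outer product, so all
within-cluster correlation is captured empirically), and reject when
√n|β̂4|/σ̂4 exceeds z_{1−α/2} or t_{1−α/2, n−4}; (6) average the rejection
indicators over L replicates, reporting the binomial Monte-Carlo standard
error √(π̂(1−π̂)/L).

Each replicate uses a spawned child of a single `SeedSequence`, so the
rejection sequence is reproducible from the seed and independent of any
parallel scheduling. Replicates whose fit is rank-deficient are counted and
excluded; if more than 0.1% fail, the run raises instead of silently
averaging. The degrees of freedom for the t threshold are fixed at n − 4
(clusters minus regression parameters).

What the generator emulates — and does not. Outcomes are exactly Gaussian
with exactly the specified block correlation, missingness is exactly MCAR,
and cluster sizes are independent of outcomes. Passing tests therefore
validate the formulas *under their own assumptions*; they say nothing about
robustness to non-Gaussian outcomes, informative cluster size, or
outcome-dependent (MAR/MNAR) missingness, none of which the formulas claim
to cover.

## Numerical choices

- Normal equations are solved with `numpy.linalg.solve` after a condition
  check; relative condition above 1e12 raises a rank-deficiency error naming
  the weakest design direction. No explicit matrix inversion happens on the
  solve path (the 4×4 sandwich inversion is exact to machine precision).
- The AR(1) exponent uses the actual time grid normalised by its span, not
  visit indices; the two coincide on evenly spaced grids.
- Negative correlation parameters are accepted whenever the eigen-block
  feasibility checks pass; the MM ≥ IM ordering is only guaranteed (and only
  asserted) for nonnegative within-subject correlations.
- Ceilings are taken with a 1e-12 guard so values within rounding noise of
  an integer are not bumped up a cluster.
- `p` used in the design rows is the known randomization proportion, not the
  realized arm fraction; the realized fraction can be passed explicitly for
  sensitivity checks.

## Benchmark grids and the worked example

The reproduction module (`crtlm.report`) pins the benchmark conditions:
p = 0.5, σ² = 1, α = 0.05, power 0.8, grid t_r = r−1, β4 = 0.2/(T−1),
T ∈ {3, 6, 12}, mean sizes {5, 15, 30} with three DU spreads, correlation
combinations R1–R4 (ρ1 ∈ {0.30, 0.15}, ρ2 ∈ {0.05, 0.03}, ρ3 = ρ2/2), and
four δ sets sharing 40% final dropout. The missing-data table uses the CS
structure — the complete-data rows of that table equal the CS rows of the
complete-data table, which fixes the choice. The depression example uses
the 3-week interval as the time unit (grid 0..5) with standardized slope
difference 0.6/6.4 = 0.09375 per interval; a "−0.09 per week" reading of
the same trial does not reproduce the published clinic counts, so the
interval-unit convention is the one implemented.

Problem sizes for the stochastic checks were chosen as the package's own
desk-scale defaults: 2000 replicates for empirical power/type-I error
(MC SE ≈ 0.009 near 0.8, ≈ 0.006 near 0.05) and 1000 replicates of a
500-cluster trial for the sandwich-consistency check (mean σ̂4²/n within 5%
of the empirical variance of β̂4).

## Known limitations

Two arms, Gaussian outcomes, and the four-term mean model only; no
covariates. No small-sample sandwich corrections beyond the t threshold —
the fit object exposes An/Vn so such corrections can be layered on. The
moments-only cluster-size model supports every formula but refuses to
simulate (no concrete law to draw from). MM/MIX with increasing δ is
rejected even though the algebraic formulas would evaluate.
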