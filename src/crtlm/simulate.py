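"""Monte-Carlo validation engine for CRTLM designs.

One replicate runs the full trial pipeline: allocate clusters to arms, draw
cluster sizes, draw each cluster's outcome vector from a multivariate normal
with the exchangeable block correlation R, apply the missingness process, fit
the independence GEE, and apply the Wald test.  Repeating L times gives the
empirical rejection rate — the empirical power when the generating slope
difference is at its design value, the empirical type-I error when it is
forced to zero.

Replicates use spawned substreams of a single seeded generator, so the
rejection sequence D_1..D_L is reproducible from the seed and invariant to
any parallel scheduling of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import (
    ClusterSizeModel,
    CorrelationSpec,
    DesignSpec,
    MissingnessSpec,
    assert_feasible,
    build_cluster_corr,
)
from .gee import TrialData, fit_gee_independent, sandwich_variance, wald_test

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "allocate_arms",
    "draw_cluster_sizes",
    "simulate_cluster",
    "apply_missingness",
    "simulate_trial",
    "empirical_rates",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything one Monte-Carlo run needs.

    ``null_mode=True`` sets the generating slope difference to zero (type-I
    error); the fitted test is unchanged.  ``betas`` are the ancillary
    intercept/arm/time coefficients, which do not affect rejection rates.
    """

    design: DesignSpec
    corr: CorrelationSpec
    cluster: ClusterSizeModel
    miss: MissingnessSpec = field(default_factory=MissingnessSpec.complete)
    n_clusters: int | None = None
    reps: int = 5000
    seed: int = 0
    threshold: str = "z"
    null_mode: bool = False
    betas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    keep_diagnostics: bool = False


@dataclass(frozen=True)
class SimulationResult:
    """Rejection proportion with its Monte-Carlo standard error."""

    rejection_rate: float
    mc_se: float
    n_clusters: int
    reps: int
    n_failures: int
    beta4_hat: np.ndarray | None = None
    sigma4_hat_sq: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "rejection_rate": self.rejection_rate,
            "mc_se": self.mc_se,
            "n_clusters": self.n_clusters,
            "reps": self.reps,
            "n_failures": self.n_failures,
        }


def allocate_arms(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Assign n clusters to arms targeting intervention fraction p.

    The intervention count is floor(n*p) or ceil(n*p); when n*p is fractional
    the extra cluster is granted with probability equal to the fraction, which
    reduces to a fair coin between (n+1)/2 and (n-1)/2 for p = 0.5 with odd n.
    Which clusters get which arm is a uniform permutation.
    """
    if n < 2:
        raise ValueError(f"need at least 2 clusters, got {n}")
    target = n * p
    k = int(np.floor(target))
    frac = target - k
    if frac > 1e-12 and rng.random() < frac:
        k += 1
    if k == 0 or k == n:
        raise ValueError(
            f"allocation left an empty arm (n={n}, p={p}); increase n or move p"
        )
    arm = np.zeros(n, dtype=int)
    arm[rng.permutation(n)[:k]] = 1
    return arm


def draw_cluster_sizes(
    cluster: ClusterSizeModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. cluster sizes from the model's discrete uniform distribution."""
    return cluster.draw(n, rng)


class _ClusterSampler:
    """Caches the Cholesky factor of sigma^2 * R(J) per distinct cluster size."""

    def __init__(self, design: DesignSpec, corr: CorrelationSpec):
        self.design = design
        self.omega = corr.omega(design.times)
        self.phi = corr.phi(design.n_times)
        self._chol: dict[int, np.ndarray] = {}

    def chol(self, J: int) -> np.ndarray:
        if J not in self._chol:
            assert_feasible(self.omega, self.phi, J)
            R = build_cluster_corr(self.omega, self.phi, J)
            self._chol[J] = np.linalg.cholesky(self.design.sigma2 * R)
        return self._chol[J]

    def draw(
        self,
        arms: np.ndarray,
        J: int,
        rng: np.random.Generator,
        beta4: float,
        betas: tuple[float, float, float],
    ) -> np.ndarray:
        """(n_c, J, T) outcomes for n_c same-size clusters with given arms."""
        n_c = arms.size
        T = self.design.n_times
        L = self.chol(J)
        z = rng.standard_normal((n_c, J * T))
        noise = (z @ L.T).reshape(n_c, J, T)
        b1, b2, b3 = betas
        t = self.design.t
        u = arms.astype(float)[:, None, None]
        mean = b1 + b2 * u + (b3 + beta4 * u) * t[None, None, :]
        return mean + noise


def simulate_cluster(
    arm: int,
    J: int,
    design: DesignSpec,
    corr: CorrelationSpec,
    rng: np.random.Generator,
    betas: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """One cluster's complete (J, T) outcome array.

    Multivariate normal with mean beta1 + beta2 u + (beta3 + beta4 u) t and
    covariance sigma^2 [I (x) (Omega - Phi) + 11' (x) Phi], sampled through a
    Cholesky factor of the full J*T matrix.
    """
    sampler = _ClusterSampler(design, corr)
    out = sampler.draw(np.array([arm]), int(J), rng, design.beta4, betas)
    return out[0]


def apply_missingness(
    outcomes: np.ndarray, miss: MissingnessSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mask a (S, T) outcome array; returns (y with NaN, boolean mask).

    IM draws independent Bernoulli(delta_r) per time.  MM thresholds a single
    uniform per subject against the survivor probabilities: m_r = 1{U <= delta_r},
    the unique dropout mechanism whose marginals are delta_r and whose joints
    are delta_max(r, r') for monotone delta.  MIX picks IM with probability w
    per subject.  Subjects losing every entry are retained (they contribute
    nothing to the fit), keeping the marginals exact.
    """
    S, T = outcomes.shape
    d = miss.delta_vector(T)
    if miss.pattern in ("NONE",) or np.all(d == 1.0):
        return outcomes.copy(), np.ones((S, T), dtype=bool)
    if miss.pattern == "IM":
        m = rng.random((S, T)) < d[None, :]
    elif miss.pattern == "MM":
        m = rng.random((S, 1)) <= d[None, :]
    elif miss.pattern == "MIX":
        use_im = rng.random(S) < miss.w
        m_im = rng.random((S, T)) < d[None, :]
        m_mm = rng.random((S, 1)) <= d[None, :]
        m = np.where(use_im[:, None], m_im, m_mm)
    else:
        raise ValueError(f"unknown pattern {miss.pattern!r}")
    y = np.where(m, outcomes, np.nan)
    return y, m


def simulate_trial(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> TrialData:
    """Generate one complete trial (allocation, sizes, outcomes, missingness)."""
    design, corr = config.design, config.corr
    beta4 = 0.0 if config.null_mode else design.beta4
    arms = allocate_arms(n, design.p, rng)
    sizes = draw_cluster_sizes(config.cluster, n, rng)
    sampler = _ClusterSampler(design, corr)
    T = design.n_times
    S = int(sizes.sum())
    y = np.empty((S, T))
    cluster_of = np.repeat(np.arange(n), sizes)
    # draw all clusters of a common size in one vectorized MVN call
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for J in np.unique(sizes):
        idx = np.flatnonzero(sizes == J)
        out = sampler.draw(arms[idx], int(J), rng, beta4, config.betas)
        for k, ci in enumerate(idx):
            y[offsets[ci] : offsets[ci] + J] = out[k]
    y_masked, m = apply_missingness(y, config.miss, rng)
    return TrialData(
        times=design.t, arm=arms, cluster_of=cluster_of, y=y_masked, observed=m
    )


def empirical_rates(config: SimulationConfig) -> SimulationResult:
    """Run the full replicate loop and return the empirical rejection rate.

    Fit failures (rank deficiency in extreme scenarios) are counted and
    excluded from the rate's denominator; if they exceed 0.1% of replicates a
    RuntimeError flags the result instead of silently averaging.
    """
    if config.n_clusters is None:
        raise ValueError("config.n_clusters must be set (e.g. from required_clusters)")
    n = int(config.n_clusters)
    L = int(config.reps)
    if L < 1:
        raise ValueError("reps must be >= 1")
    streams = np.random.SeedSequence(config.seed).spawn(L)
    rejections = np.zeros(L, dtype=bool)
    ok = np.zeros(L, dtype=bool)
    b4s = np.full(L, np.nan)
    s42s = np.full(L, np.nan)
    for l in range(L):
        rng = np.random.Generator(np.random.PCG64(streams[l]))
        data = simulate_trial(config, n, rng)
        try:
            fit = fit_gee_independent(data, config.design.p)
            sandwich_variance(fit, data)
            test = wald_test(fit, n, config.design.alpha, config.threshold)
        except (np.linalg.LinAlgError, ValueError):
            continue
        ok[l] = True
        rejections[l] = test.reject
        if config.keep_diagnostics:
            b4s[l] = fit.beta4_hat
            s42s[l] = fit.sigma4_hat_sq
    n_fail = int(L - ok.sum())
    if n_fail > max(1, L // 1000):
        raise RuntimeError(
            f"{n_fail}/{L} replicates failed to fit; the scenario is too "
            "extreme to average over silently"
        )
    n_ok = int(ok.sum())
    rate = float(rejections[ok].mean()) if n_ok else float("nan")
    mc_se = float(np.sqrt(rate * (1.0 - rate) / n_ok)) if n_ok else float("nan")
    return SimulationResult(
        rejection_rate=rate,
        mc_se=mc_se,
        n_clusters=n,
        reps=L,
        n_failures=n_fail,
        beta4_hat=b4s if config.keep_diagnostics else None,
        sigma4_hat_sq=s42s if config.keep_diagnostics else None,
    )
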