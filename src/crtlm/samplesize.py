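"""Closed-form sample size and power for comparing slopes in CRTLMs.

The slope-difference estimator from the independence-working-correlation GEE
satisfies sqrt(n) (beta4_hat - beta4) -> N(0, sigma4^2) with

    sigma4^2 = sigma^2 (mu_m1 1 - t)' Qm (mu_m1 1 - t) / (mu_m0^2 vp^2 vmt^4),

where mu_m0 = sum_r delta_r, mu_m1 and mu_m2 are the delta-weighted first and
second moments of the time grid, vmt^2 = mu_m2 - mu_m1^2, vp^2 = p(1-p) and Qm
is the missingness-adjusted weighting matrix from :mod:`crtlm.design`.  The
number of clusters for two-sided level alpha and power 1 - gamma is

    n = (z_{1-alpha/2} + z_{1-gamma})^2 sigma4^2 / beta4^2,

rounded up.  With complete data (delta = 1) mu_m0 = T and the expression
reduces to the familiar complete-data formula; with J = 1 the design collapses
to an individually randomized longitudinal study and Phi drops out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import (
    ClusterSizeModel,
    CorrelationSpec,
    DesignSpec,
    MissingnessSpec,
    build_Qm,
    joint_obs_probs,
)

__all__ = [
    "MissingMoments",
    "SampleSizeResult",
    "slope_variance",
    "required_clusters",
    "achieved_power",
    "required_subjects_individual",
]


@dataclass(frozen=True)
class MissingMoments:
    """Observation-probability-weighted moments of the time grid.

    mu_m0 = sum_r delta_r (expected observations per subject),
    mu_m1 = sum_r delta_r t_r / mu_m0, mu_m2 = sum_r delta_r t_r^2 / mu_m0,
    v_mt2 = mu_m2 - mu_m1^2.  With delta = 1 these are T, the plain mean and
    mean square of the grid, and its variance.
    """

    mu_m0: float
    mu_m1: float
    mu_m2: float

    @classmethod
    def from_delta(cls, delta: np.ndarray, times: np.ndarray) -> "MissingMoments":
        d = np.asarray(delta, dtype=float)
        t = np.asarray(times, dtype=float)
        mu0 = float(d.sum())
        mu1 = float((d * t).sum() / mu0)
        mu2 = float((d * t * t).sum() / mu0)
        return cls(mu_m0=mu0, mu_m1=mu1, mu_m2=mu2)

    @property
    def v_mt2(self) -> float:
        return self.mu_m2 - self.mu_m1**2


@dataclass(frozen=True)
class SampleSizeResult:
    """Output of :func:`required_clusters`.

    ``n`` is the ceiling of the real-valued solution ``n_raw``; both are
    reported so near-integer ties are auditable.  ``achieved_power`` is the
    normal-approximation power at the rounded n.
    """

    sigma4_sq: float
    n_raw: float
    n: int
    achieved_power: float
    moments: MissingMoments
    quadratic_form: float

    def as_dict(self) -> dict:
        return {
            "sigma4_sq": self.sigma4_sq,
            "n_raw": self.n_raw,
            "n": self.n,
            "achieved_power": self.achieved_power,
            "mu_m0": self.moments.mu_m0,
            "mu_m1": self.moments.mu_m1,
            "mu_m2": self.moments.mu_m2,
            "v_mt2": self.moments.v_mt2,
            "quadratic_form": self.quadratic_form,
        }


def _variance_parts(
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec,
    cluster: ClusterSizeModel,
) -> tuple[float, MissingMoments, float]:
    """(sigma4_sq, moments, quadratic_form) shared by all calculators."""
    t = design.t
    T = t.size
    d = miss.delta_vector(T)
    omega = corr.omega(design.times)
    phi = corr.phi(T)
    Qm = build_Qm(omega, phi, miss, cluster)
    mom = MissingMoments.from_delta(d, t)
    if mom.v_mt2 <= 0:
        raise ValueError(
            "degenerate time grid: the observation-weighted variance of the "
            "measurement times is not positive"
        )
    c = mom.mu_m1 * np.ones(T) - t
    qf = float(c @ Qm @ c)
    sigma4_sq = design.sigma2 * qf / (mom.mu_m0**2 * design.vp2 * mom.v_mt2**2)
    return sigma4_sq, mom, qf


def slope_variance(
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec | None = None,
    cluster: ClusterSizeModel | None = None,
) -> float:
    """Asymptotic variance sigma4^2 of sqrt(n) (beta4_hat - beta4).

    With complete data this is the complete-data expression with mu_m0 = T;
    passing ``miss=None`` is equivalent to delta identically 1.
    """
    miss = miss or MissingnessSpec.complete()
    cluster = cluster or ClusterSizeModel.fixed(1)
    s42, _, _ = _variance_parts(design, corr, miss, cluster)
    return s42


def achieved_power(
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec | None = None,
    cluster: ClusterSizeModel | None = None,
    n: int = 1,
    threshold: str = "z",
) -> float:
    """Power of the two-sided level-alpha Wald test with n clusters.

    P( Z < sqrt(n) |beta4| / sigma4 - q ), with q the normal quantile
    z_{1-alpha/2} (default) or, as an extension, the t quantile with n - 4
    degrees of freedom (``threshold="t"``); monotone increasing in n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    sigma4_sq = slope_variance(design, corr, miss, cluster)
    if threshold == "z":
        q = stats.norm.ppf(1.0 - design.alpha / 2.0)
    elif threshold == "t":
        if n <= 4:
            raise ValueError("t threshold needs n > 4 (degrees of freedom n - 4)")
        q = stats.t.ppf(1.0 - design.alpha / 2.0, df=n - 4)
    else:
        raise ValueError(f"threshold must be 'z' or 't', got {threshold!r}")
    shift = math.sqrt(n) * abs(design.beta4) / math.sqrt(sigma4_sq)
    return float(stats.norm.cdf(shift - q))


def required_clusters(
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec | None = None,
    cluster: ClusterSizeModel | None = None,
    threshold: str = "z",
) -> SampleSizeResult:
    """Number of clusters for the target power, rounded up.

    ``threshold="t"`` is an extension that further inflates n until the
    power computed with the t(n-4) critical value reaches the target; the
    default is the z-based closed form.
    """
    if design.beta4 == 0:
        raise ValueError("beta4 = 0: no finite sample size detects a null effect")
    miss = miss or MissingnessSpec.complete()
    cluster = cluster or ClusterSizeModel.fixed(1)
    sigma4_sq, mom, qf = _variance_parts(design, corr, miss, cluster)
    za = stats.norm.ppf(1.0 - design.alpha / 2.0)
    zg = stats.norm.ppf(design.power_target)
    n_raw = (za + zg) ** 2 * sigma4_sq / design.beta4**2
    n = max(1, math.ceil(n_raw - 1e-12))
    if threshold == "t":
        n = max(n, 5)
        while (
            achieved_power(design, corr, miss, cluster, n, threshold="t")
            < design.power_target
        ):
            n += 1
    elif threshold != "z":
        raise ValueError(f"threshold must be 'z' or 't', got {threshold!r}")
    power = achieved_power(design, corr, miss, cluster, n, threshold=threshold)
    return SampleSizeResult(
        sigma4_sq=sigma4_sq,
        n_raw=float(n_raw),
        n=int(n),
        achieved_power=power,
        moments=mom,
        quadratic_form=qf,
    )


def required_subjects_individual(
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec | None = None,
) -> SampleSizeResult:
    """Subjects needed in an individually randomized longitudinal study.

    The J = 1 specialization: the between-subject matrix Phi drops out and
    the weighting matrix is Omega o Delta alone.
    """
    return required_clusters(design, corr, miss, ClusterSizeModel.fixed(1))


def quadratic_form_double_sum(
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec,
    cluster: ClusterSizeModel,
) -> float:
    """Explicit double-sum rewrite of (mu_m1 1 - t)' Qm (mu_m1 1 - t).

    sum_r sum_r' (mu_m1 - t_r)(mu_m1 - t_r') [ omega_rr' delta_rr' / J
    + (CV_J^2 + 1 - 1/J) phi_rr' delta_r delta_r' ].

    Kept as a readable reference form; the matrix path in
    :func:`slope_variance` is the production route.
    """
    t = design.t
    T = t.size
    d = miss.delta_vector(T)
    omega = corr.omega(design.times)
    phi = corr.phi(T)
    D = joint_obs_probs(miss, T)
    mom = MissingMoments.from_delta(d, t)
    J = cluster.mean_J
    w_between = cluster.cv2 + 1.0 - 1.0 / J
    total = 0.0
    for r in range(T):
        for s in range(T):
            total += (
                (mom.mu_m1 - t[r])
                * (mom.mu_m1 - t[s])
                * (omega[r, s] * D[r, s] / J + w_between * phi[r, s] * d[r] * d[s])
            )
    return total
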