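"""Design inputs for cluster randomized trials with longitudinal measurements.

A two-arm trial randomizes whole clusters (clinics, schools, ...) with
probability ``p`` to the intervention arm; every subject in a cluster is
measured at the same scheduled times ``t = (t_1, ..., t_T)``.  The marginal
mean model is linear in time with an intervention-by-time interaction,

    E(y_ijr) = beta1 + beta2*u_i + beta3*t_r + beta4*u_i*t_r,

and the estimand is the slope difference ``beta4``.  The second-moment
structure is captured by two T x T correlation matrices: ``Omega`` for
repeated measurements on the same subject (within-subject, longitudinal) and
``Phi`` for measurements on different subjects in the same cluster (diagonal:
the intra-cluster correlation rho2; off-diagonal: the between-subject
between-period correlation rho3).  The full correlation matrix of a cluster
with J subjects is the exchangeable block form

    R = I_J (x) (Omega - Phi) + 1_J 1_J' (x) Phi,

whose eigenvalues are those of ``Omega - Phi`` (multiplicity J-1 each) and of
``Omega + (J-1) Phi``.

Missing data enter through marginal observational probabilities
``delta_r = P(subject observed at time r)`` and a pattern (independent,
monotone dropout, or a mixture) that fixes the joint probabilities
``delta_rr'``.  Cluster sizes may vary; only their mean and variance (through
the coefficient of variation CV_J) enter the design formulas.

This module builds every matrix object the sample-size formulas and the
simulator consume: Omega, Phi, R, the joint-observation matrix Delta, and the
weighting matrices Q (complete data) and Qm (incomplete data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DesignSpec",
    "CorrelationSpec",
    "MissingnessSpec",
    "ClusterSizeModel",
    "build_omega",
    "build_phi",
    "build_cluster_corr",
    "joint_obs_probs",
    "build_Q",
    "build_Qm",
]

Pattern = Literal["IM", "MM", "MIX", "NONE"]


def _as_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times must be a 1-d vector with at least 2 entries")
    if np.ptp(t) == 0:
        raise ValueError("measurement times must not all be equal")
    return t


@dataclass(frozen=True)
class DesignSpec:
    """Trial-level design parameters.

    Parameters
    ----------
    p : float
        Proportion of clusters randomized to the intervention arm, in (0, 1).
    sigma2 : float
        Marginal outcome variance, > 0.
    beta4 : float
        True slope difference between arms, per unit of the time grid.  Sample
        size depends on it only through ``beta4**2``; the sign is free.
    alpha : float
        Two-sided type-I error rate.
    power_target : float
        Desired power 1 - gamma.
    times : sequence of float
        Scheduled measurement times, T >= 2, not all equal.
    """

    p: float
    sigma2: float
    beta4: float
    alpha: float = 0.05
    power_target: float = 0.8
    times: Sequence[float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power_target < 1:
            raise ValueError(
                f"power_target must be in (0, 1), got {self.power_target}"
            )
        object.__setattr__(self, "times", tuple(float(x) for x in self.times))
        _as_times(self.times)

    @property
    def t(self) -> np.ndarray:
        """Time grid as an array."""
        return np.asarray(self.times, dtype=float)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def vp2(self) -> float:
        """Allocation variance p(1-p); the sample size scales as 1/vp2."""
        return self.p * (1.0 - self.p)


@dataclass(frozen=True)
class CorrelationSpec:
    """Within-subject (Omega) and between-subject (Phi) correlation.

    ``structure`` selects the generator for Omega:

    * ``"CS"`` — compound symmetry, all off-diagonals equal ``rho1``;
    * ``"AR1"`` — geometric decay on the actual time grid,
      ``omega_rr' = rho1 ** (|t_r - t_r'| / (t_T - t_1))``, so the first/last
      correlation equals ``rho1`` exactly;
    * ``"CUSTOM"`` — explicit ``omega_matrix`` (and optionally
      ``phi_matrix``), validated for symmetry and unit diagonal.

    Phi is generated parametrically as ``11' rho3 + I (rho2 - rho3)`` unless a
    custom ``phi_matrix`` is given.
    """

    structure: Literal["CS", "AR1", "CUSTOM"] = "CS"
    rho1: float = 0.0
    rho2: float = 0.0
    rho3: float = 0.0
    omega_matrix: np.ndarray | None = None
    phi_matrix: np.ndarray | None = None

    def omega(self, times: Sequence[float]) -> np.ndarray:
        return build_omega(self, times)

    def phi(self, T: int) -> np.ndarray:
        if self.phi_matrix is not None:
            P = np.asarray(self.phi_matrix, dtype=float)
            _check_square_symmetric(P, "phi_matrix")
            if P.shape[0] != T:
                raise ValueError(
                    f"phi_matrix is {P.shape[0]}x{P.shape[0]}, expected {T}x{T}"
                )
            return P
        return build_phi(self.rho2, self.rho3, T)


@dataclass(frozen=True)
class MissingnessSpec:
    """Marginal observational probabilities and the missing-data pattern.

    ``delta[r]`` is the probability that a subject is observed at time r
    (MCAR).  The pattern fixes the joint probabilities delta_rr':

    * IM  — misses occur independently over time: delta_rr' = delta_r delta_r'.
    * MM  — monotone dropout: a miss at r implies misses at all later times,
      so delta_rr' = delta_max(r, r').
    * MIX — each subject follows IM with probability ``w``, MM otherwise:
      delta_rr' = w delta_r delta_r' + (1 - w) delta_max(r, r').
    * NONE — complete data, delta identically 1.

    Monotone (nonincreasing) delta is required for MM and MIX because the
    dropout process cannot generate increasing marginals; IM accepts any
    marginals.
    """

    pattern: Pattern = "NONE"
    delta: Sequence[float] | None = None
    w: float = 0.5

    def __post_init__(self) -> None:
        if self.pattern not in ("IM", "MM", "MIX", "NONE"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0 <= self.w <= 1:
            raise ValueError(f"mixture weight w must be in [0, 1], got {self.w}")
        if self.delta is not None:
            d = np.asarray(self.delta, dtype=float)
            if np.any(d <= 0) or np.any(d > 1):
                raise ValueError("delta entries must lie in (0, 1]")
            object.__setattr__(self, "delta", tuple(float(x) for x in d))
            if self.pattern in ("MM", "MIX") and np.any(np.diff(d) > 1e-12):
                raise ValueError(
                    "MM/MIX require nonincreasing delta (a dropout process "
                    "cannot produce increasing observation probabilities)"
                )
        elif self.pattern != "NONE":
            raise ValueError(f"pattern {self.pattern!r} requires delta")

    def delta_vector(self, T: int) -> np.ndarray:
        """Marginal probabilities as a length-T array (ones for NONE)."""
        if self.delta is None:
            return np.ones(T)
        d = np.asarray(self.delta, dtype=float)
        if d.size != T:
            raise ValueError(f"delta has length {d.size}, expected {T}")
        return d

    @classmethod
    def complete(cls) -> "MissingnessSpec":
        return cls(pattern="NONE")


@dataclass(frozen=True)
class ClusterSizeModel:
    """First two moments of the cluster-size distribution.

    Only ``mean_J`` and ``var_J`` enter the design formulas (through
    ``CV_J = sd/mean``).  Simulation additionally needs a concrete law; a
    discrete uniform DU[a, b] (inclusive) is supported, with mean (a+b)/2 and
    variance ((b-a+1)^2 - 1)/12.
    """

    mean_J: float
    var_J: float = 0.0
    du_bounds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mean_J <= 0:
            raise ValueError(f"mean cluster size must be > 0, got {self.mean_J}")
        if self.var_J < 0:
            raise ValueError(f"cluster-size variance must be >= 0, got {self.var_J}")
        if self.du_bounds is not None:
            a, b = self.du_bounds
            if not (isinstance(a, (int, np.integer)) and isinstance(b, (int, np.integer))):
                raise TypeError("DU bounds must be integers")
            if a < 1 or b < a:
                raise ValueError(f"DU bounds must satisfy 1 <= a <= b, got [{a}, {b}]")
            mean = (a + b) / 2.0
            var = ((b - a + 1) ** 2 - 1) / 12.0
            if abs(mean - self.mean_J) > 1e-12 * max(1.0, mean) or abs(
                var - self.var_J
            ) > 1e-12 * max(1.0, var):
                raise ValueError(
                    f"DU[{a}, {b}] has mean {mean}, variance {var}; "
                    f"inconsistent with ({self.mean_J}, {self.var_J})"
                )

    @classmethod
    def fixed(cls, J: int) -> "ClusterSizeModel":
        """All clusters share size J (CV_J = 0)."""
        return cls(mean_J=float(J), var_J=0.0, du_bounds=(int(J), int(J)))

    @classmethod
    def discrete_uniform(cls, a: int, b: int) -> "ClusterSizeModel":
        """Cluster sizes i.i.d. DU[a, b], both endpoints included."""
        return cls(
            mean_J=(a + b) / 2.0,
            var_J=((b - a + 1) ** 2 - 1) / 12.0,
            du_bounds=(int(a), int(b)),
        )

    @classmethod
    def from_moments(cls, mean_J: float, var_J: float) -> "ClusterSizeModel":
        """Moments only; formula operations work, simulation refuses."""
        return cls(mean_J=mean_J, var_J=var_J, du_bounds=None)

    @property
    def cv_J(self) -> float:
        return float(np.sqrt(self.var_J) / self.mean_J)

    @property
    def cv2(self) -> float:
        """Squared coefficient of variation var/mean^2."""
        return self.var_J / self.mean_J**2

    @property
    def is_fixed(self) -> bool:
        return self.var_J == 0.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n cluster sizes; requires a concrete DU distribution."""
        if self.du_bounds is None:
            raise ValueError(
                "cluster-size model has moments only; a concrete DU[a, b] "
                "distribution is required for simulation"
            )
        a, b = self.du_bounds
        return rng.integers(a, b + 1, size=n)


def _check_square_symmetric(M: np.ndarray, name: str) -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")


def build_omega(spec: CorrelationSpec, times: Sequence[float]) -> np.ndarray:
    """Within-subject correlation matrix on the given time grid.

    CS fills every off-diagonal with rho1.  AR1 uses the actual measurement
    times, normalised by the total span, so the correlation between the first
    and last scheduled times is rho1 exactly regardless of spacing.
    """
    t = _as_times(times)
    T = t.size
    if spec.structure == "CUSTOM":
        if spec.omega_matrix is None:
            raise ValueError("CUSTOM structure requires omega_matrix")
        O = np.asarray(spec.omega_matrix, dtype=float)
        _check_square_symmetric(O, "omega_matrix")
        if O.shape[0] != T:
            raise ValueError(f"omega_matrix is {O.shape[0]}x{O.shape[0]}, expected {T}x{T}")
        if not np.allclose(np.diag(O), 1.0, atol=1e-10):
            raise ValueError("omega_matrix must have unit diagonal")
        return O
    if spec.structure == "CS":
        if not -1 < spec.rho1 <= 1:
            raise ValueError(f"CS requires rho1 in (-1, 1], got {spec.rho1}")
        O = np.full((T, T), spec.rho1)
        np.fill_diagonal(O, 1.0)
        return O
    if spec.structure == "AR1":
        if not 0 < spec.rho1 <= 1:
            raise ValueError(f"AR1 requires rho1 in (0, 1], got {spec.rho1}")
        span = t[-1] - t[0]
        if span <= 0:
            raise ValueError("AR1 requires distinct first and last times")
        return spec.rho1 ** (np.abs(t[:, None] - t[None, :]) / span)
    raise ValueError(f"unknown structure {spec.structure!r}")


def build_phi(rho2: float, rho3: float, T: int) -> np.ndarray:
    """Between-subject correlation matrix: diagonal rho2 (the ICC), off-diagonal rho3."""
    P = np.full((T, T), float(rho3))
    np.fill_diagonal(P, float(rho2))
    return P


def build_cluster_corr(
    omega: np.ndarray,
    phi: np.ndarray,
    J: int,
    *,
    check_pd: bool = False,
) -> np.ndarray:
    """Full (J*T) x (J*T) correlation matrix of one cluster.

    Exchangeable block form: Omega on the diagonal blocks, Phi everywhere
    else.  Its spectrum is the union of eig(Omega - Phi), with multiplicity
    J - 1, and eig(Omega + (J-1) Phi); with ``check_pd=True`` both eigen-blocks
    are checked and the offending block is named on failure.
    """
    omega = np.asarray(omega, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if omega.shape != phi.shape:
        raise ValueError("Omega and Phi must have the same shape")
    J = int(J)
    if J < 1:
        raise ValueError(f"cluster size must be >= 1, got {J}")
    if check_pd:
        assert_feasible(omega, phi, J)
    R = np.kron(np.eye(J), omega - phi) + np.kron(np.ones((J, J)), phi)
    return R


def assert_feasible(omega: np.ndarray, phi: np.ndarray, J: int) -> None:
    """Raise unless both eigen-blocks of R are positive definite.

    ``Omega - Phi`` and ``Omega + (J-1) Phi`` carry the full spectrum of the
    cluster correlation matrix, so checking them is equivalent to (and far
    cheaper than) checking R itself.
    """
    for name, block in (
        ("Omega - Phi", omega - phi),
        (f"Omega + (J-1)*Phi with J={J}", omega + (J - 1) * phi),
    ):
        lam = np.linalg.eigvalsh(block)
        if lam[0] <= 0:
            raise ValueError(
                f"cluster correlation matrix is not positive definite: "
                f"eigen-block {name} has minimum eigenvalue {lam[0]:.3e}"
            )


def joint_obs_probs(miss: MissingnessSpec, T: int | None = None) -> np.ndarray:
    """Joint-observation matrix Delta.

    Entry (r, r) is delta_r; entry (r, r') is the pattern-specific joint
    probability delta_rr' of being observed at both times.  For every pattern
    0 <= delta_rr' <= min(delta_r, delta_r'), and the MIX matrix is the
    elementwise convex combination w * Delta_IM + (1 - w) * Delta_MM.
    """
    if miss.delta is None:
        if T is None:
            raise ValueError("complete-data spec needs an explicit T")
        return np.ones((T, T))
    d = miss.delta_vector(T if T is not None else len(miss.delta))
    outer = np.outer(d, d)  # IM joints
    # MM joints: delta at the later of the two times
    later = np.maximum.outer(np.arange(d.size), np.arange(d.size))
    mono = d[later]
    if miss.pattern == "IM":
        D = outer
    elif miss.pattern == "MM":
        D = mono
    elif miss.pattern == "MIX":
        D = miss.w * outer + (1.0 - miss.w) * mono
    else:  # NONE with explicit delta of ones
        D = outer
    np.fill_diagonal(D, d)
    return D


def build_Q(
    omega: np.ndarray, phi: np.ndarray, cluster: ClusterSizeModel
) -> np.ndarray:
    """Complete-data weighting matrix Q = (1/J) Omega + (CV_J^2 + 1 - 1/J) Phi.

    Q is the limit of the average within-cluster cross-products per subject
    pair; the within-subject part shrinks with mean cluster size J while the
    between-subject part grows with cluster-size variability.
    """
    J = cluster.mean_J
    return omega / J + (cluster.cv2 + 1.0 - 1.0 / J) * np.asarray(phi, dtype=float)


def build_Qm(
    omega: np.ndarray,
    phi: np.ndarray,
    miss: MissingnessSpec,
    cluster: ClusterSizeModel,
) -> np.ndarray:
    """Incomplete-data weighting matrix.

    Qm = (1/J) (Omega o Delta) + (CV_J^2 + 1 - 1/J) diag(delta) Phi diag(delta),

    where ``o`` is the Hadamard product: within-subject terms are damped by the
    joint observation probabilities, between-subject terms by the product of
    marginals (misses are independent across subjects).  With delta = 1 this
    reduces exactly to :func:`build_Q`.
    """
    omega = np.asarray(omega, dtype=float)
    phi = np.asarray(phi, dtype=float)
    T = omega.shape[0]
    d = miss.delta_vector(T)
    if d.size != T:
        raise ValueError(f"delta has length {d.size}, expected {T}")
    D = joint_obs_probs(miss, T)
    J = cluster.mean_J
    scaled_phi = phi * np.outer(d, d)
    return (omega * D) / J + (cluster.cv2 + 1.0 - 1.0 / J) * scaled_phi
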