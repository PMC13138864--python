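"""GEE estimation of the marginal slope model with sandwich variance.

Under the independence working correlation the GEE estimator of the centred
parameterization

    E(y_ijr) = b1 + b2 (u_i - p) + b3 t_r + b4 (u_i - p) t_r,

with b2 = beta2, b4 = beta4, b1 = beta1 + beta2 p, b3 = beta3 + beta4 p, is
pooled least squares over the observed rows: each observed (i, j, r) triplet
contributes a design row Z_ijr = (1, u_i - p, t_r, (u_i - p) t_r).  Missing
entries carry weight m_ijr = 0 and never enter any sum.

Inference uses the cluster-level sandwich: with

    An = n^-1 sum_i sum_j sum_r m_ijr Z_ijr' Z_ijr,
    Vn = n^-1 sum_i [ sum_j Z_ij' (m_ij o e_ij) ]^(x)2,

(outer products of whole-cluster score contributions, so all within-cluster
correlation is captured empirically) the covariance of b_hat is estimated by
Sigma_n / n with Sigma_n = An^-1 Vn An^-1.  The Wald statistic for
H0: beta4 = 0 is sqrt(n) |b4_hat| / sigma4_hat, compared against a standard
normal quantile or, to repair small-sample inflation, a t quantile with n - 4
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrialData", "GeeFit", "WaldTest", "fit_gee_independent", "sandwich_variance", "wald_test"]

#: relative condition number above which the normal equations are declared singular
_COND_LIMIT = 1e12


@dataclass
class TrialData:
    """One trial in subject-major arrays.

    ``y`` is (S, T) with NaN at unobserved entries, ``observed`` the matching
    boolean mask, ``cluster_of`` maps each of the S subjects to its cluster
    index, and ``arm`` gives each cluster's 0/1 assignment.  Subjects with no
    observed entries are legal and contribute nothing to the fit.
    """

    times: np.ndarray
    arm: np.ndarray
    cluster_of: np.ndarray
    y: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.arm = np.asarray(self.arm, dtype=int)
        self.cluster_of = np.asarray(self.cluster_of, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        S, T = self.y.shape
        if self.observed.shape != (S, T):
            raise ValueError("y and observed must have the same shape")
        if self.times.size != T:
            raise ValueError("times length must match the number of columns of y")
        if self.cluster_of.size != S:
            raise ValueError("cluster_of must have one entry per subject")
        if self.cluster_of.min(initial=0) < 0 or (
            self.cluster_of.size and self.cluster_of.max() >= self.arm.size
        ):
            raise ValueError("cluster_of indexes outside arm")
        if np.any(np.isnan(self.y) & self.observed):
            raise ValueError("observed entries must not be NaN")

    @property
    def n_clusters(self) -> int:
        return int(self.arm.size)

    @property
    def n_subjects(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_times(self) -> int:
        return int(self.y.shape[1])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TrialData":
        """Build from a long table (cluster_id, subject_id, time, arm, y, observed).

        Rows absent from the table are treated as unobserved; an explicit
        ``observed`` column (0/1) may also mark missingness in a dense table.
        """
        df = df.copy()
        if "observed" not in df:
            df["observed"] = 1
        times = np.sort(df["time"].unique())
        t_index = {t: i for i, t in enumerate(times)}
        clusters = pd.unique(df["cluster_id"])
        c_index = {c: i for i, c in enumerate(clusters)}
        arm = np.zeros(len(clusters), dtype=int)
        subj_keys = list(
            dict.fromkeys(zip(df["cluster_id"], df["subject_id"]))
        )
        s_index = {k: i for i, k in enumerate(subj_keys)}
        S, T = len(subj_keys), len(times)
        y = np.full((S, T), np.nan)
        m = np.zeros((S, T), dtype=bool)
        cluster_of = np.zeros(S, dtype=int)
        for row in df.itertuples(index=False):
            ci = c_index[row.cluster_id]
            si = s_index[(row.cluster_id, row.subject_id)]
            arm[ci] = int(row.arm)
            cluster_of[si] = ci
            if int(row.observed):
                ti = t_index[row.time]
                y[si, ti] = float(row.y)
                m[si, ti] = True
        return cls(times=times, arm=arm, cluster_of=cluster_of, y=y, observed=m)

    def to_long(self) -> pd.DataFrame:
        S, T = self.y.shape
        rows = []
        for s in range(S):
            c = self.cluster_of[s]
            for r in range(T):
                rows.append(
                    {
                        "cluster_id": int(c),
                        "subject_id": int(s),
                        "time": float(self.times[r]),
                        "arm": int(self.arm[c]),
                        "y": self.y[s, r] if self.observed[s, r] else np.nan,
                        "observed": int(self.observed[s, r]),
                    }
                )
        return pd.DataFrame(rows)

    def design_tensor(self, p: float) -> np.ndarray:
        """(S, T, 4) array of design rows Z_ijr = (1, u - p, t_r, (u - p) t_r)."""
        S, T = self.y.shape
        u = self.arm[self.cluster_of].astype(float) - p
        t = self.times
        Z = np.empty((S, T, 4))
        Z[:, :, 0] = 1.0
        Z[:, :, 1] = u[:, None]
        Z[:, :, 2] = t[None, :]
        Z[:, :, 3] = u[:, None] * t[None, :]
        return Z


@dataclass
class GeeFit:
    """Estimates and (after :func:`sandwich_variance`) the sandwich pieces."""

    b_hat: np.ndarray
    beta_hat: np.ndarray
    p: float
    residuals: np.ndarray  # (S, T), zero at unobserved entries
    An: np.ndarray | None = None
    Vn: np.ndarray | None = None
    Sigma_n: np.ndarray | None = None
    sigma4_hat_sq: float | None = None

    @property
    def beta4_hat(self) -> float:
        return float(self.b_hat[3])


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    critical: float
    reject: bool
    threshold: str


def fit_gee_independent(data: TrialData, p: float) -> GeeFit:
    """Solve the independence-working-correlation GEE (pooled least squares).

    ``p`` is the design randomization proportion used to centre the arm
    indicator; pass the realized cluster fraction only for sensitivity checks.
    Raises on rank deficiency (e.g., a single arm or a single observed time),
    naming the deficient design direction.
    """
    Z = data.design_tensor(p)
    m = data.observed.astype(float)
    y0 = np.where(data.observed, data.y, 0.0)
    Zm = Z * m[:, :, None]
    A_sum = np.einsum("srk,srl->kl", Zm, Z)
    rhs = np.einsum("srk,sr->k", Zm, y0)
    cond = np.linalg.cond(A_sum)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        w = np.linalg.eigh(A_sum)[1][:, 0]
        labels = ["intercept", "arm", "time", "arm:time"]
        dominant = labels[int(np.argmax(np.abs(w)))]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (condition {cond:.2e}); "
            f"no information in the {dominant} direction — check that both "
            "arms and at least two distinct times are observed"
        )
    b_hat = np.linalg.solve(A_sum, rhs)
    resid = (y0 - np.einsum("srk,k->sr", Z, b_hat)) * m
    beta_hat = np.array(
        [
            b_hat[0] - b_hat[1] * p,
            b_hat[1],
            b_hat[2] - b_hat[3] * p,
            b_hat[3],
        ]
    )
    return GeeFit(b_hat=b_hat, beta_hat=beta_hat, p=p, residuals=resid)


def sandwich_variance(fit: GeeFit, data: TrialData) -> tuple[np.ndarray, float]:
    """Cluster-level sandwich covariance Sigma_n = An^-1 Vn An^-1.

    Subject score contributions Z_ij' (m_ij o e_ij) are summed within each
    cluster before the outer product, so Vn absorbs all empirical
    within-cluster covariance.  Var(b_hat) is estimated by Sigma_n / n;
    ``sigma4_hat_sq`` is the (4, 4) element of Sigma_n.  Results are stored on
    ``fit`` and returned.
    """
    n = data.n_clusters
    Z = data.design_tensor(fit.p)
    m = data.observed.astype(float)
    An = np.einsum("srk,srl->kl", Z * m[:, :, None], Z) / n
    subj_scores = np.einsum("srk,sr->sk", Z, fit.residuals)
    cluster_scores = np.zeros((n, 4))
    np.add.at(cluster_scores, data.cluster_of, subj_scores)
    Vn = cluster_scores.T @ cluster_scores / n
    Ainv = np.linalg.inv(An)
    Sigma_n = Ainv @ Vn @ Ainv
    fit.An, fit.Vn, fit.Sigma_n = An, Vn, Sigma_n
    fit.sigma4_hat_sq = float(Sigma_n[3, 3])
    return Sigma_n, fit.sigma4_hat_sq


def wald_test(
    fit: GeeFit, n: int, alpha: float = 0.05, threshold: str = "z"
) -> WaldTest:
    """Two-sided Wald test of H0: beta4 = 0.

    Statistic sqrt(n) |beta4_hat| / sigma4_hat against z_{1-alpha/2} or
    t_{1-alpha/2, n-4}.  Requires :func:`sandwich_variance` to have run.
    """
    if fit.sigma4_hat_sq is None:
        raise ValueError("run sandwich_variance before wald_test")
    if fit.sigma4_hat_sq <= 0:
        raise ValueError("sigma4_hat_sq must be positive for a Wald test")
    stat = float(np.sqrt(n) * abs(fit.beta4_hat) / np.sqrt(fit.sigma4_hat_sq))
    if threshold == "z":
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    elif threshold == "t":
        if n <= 4:
            raise ValueError("t threshold requires n > 4 (df = n - 4)")
        crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 4))
    else:
        raise ValueError(f"threshold must be 'z' or 't', got {threshold!r}")
    return WaldTest(statistic=stat, critical=crit, reject=stat > crit, threshold=threshold)
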