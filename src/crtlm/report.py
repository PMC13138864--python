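"""Scenario grids, benchmark-table reproduction, the worked example, and config IO.

The benchmark grid fixes p = 0.5, sigma^2 = 1, alpha = 0.05, power 0.8, time
grid t_r = r - 1 and slope difference beta4 = 0.2/(T-1), and sweeps
correlation structure (CS / AR(1)), mean cluster size J in {5, 15, 30},
T in {3, 6, 12}, four correlation combinations R1-R4 with rho3 = rho2/2,
three cluster-size laws (fixed, moderate DU, wide DU) and, for T = 6, three
missingness marginal sets sharing a 40% final dropout.  ``run_table`` emits
the closed-form cluster counts for each cell and can attach empirical
power/type-I estimates at a requested replicate count.

The worked example is a depression trial: clinics randomized 1:1, Hamilton
depression scores at baseline and every 3 weeks to week 15 (T = 6, grid in
3-week units), baseline 19.6 (SD 6.4) declining to 11 vs 14, so the
standardized slope difference per 3-week interval is 0.6/6.4 = 0.09375.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .design import ClusterSizeModel, CorrelationSpec, DesignSpec, MissingnessSpec
from .samplesize import required_clusters
from .simulate import SimulationConfig, empirical_rates

__all__ = [
    "R_COMBOS",
    "DELTA_SETS",
    "DU_LAWS",
    "run_table",
    "run_example",
    "load_config",
    "save_config",
]

#: correlation parameter combinations (rho1, rho2, rho3) with rho3 = rho2/2
R_COMBOS = {
    "R1": (0.30, 0.05, 0.025),
    "R2": (0.30, 0.03, 0.015),
    "R3": (0.15, 0.05, 0.025),
    "R4": (0.15, 0.03, 0.015),
}

#: marginal observational probabilities for T = 6, all with 40% end dropout
DELTA_SETS = {
    "delta1": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    "delta2": (1.00, 0.97, 0.94, 0.90, 0.75, 0.60),
    "delta3": (1.00, 0.92, 0.84, 0.76, 0.68, 0.60),
    "delta4": (1.00, 0.85, 0.70, 0.66, 0.63, 0.60),
}

#: cluster-size discrete-uniform laws per mean size: none / moderate / large spread
DU_LAWS = {
    "DU0": {5: (5, 5), 15: (15, 15), 30: (30, 30)},
    "DU1": {5: (3, 7), 15: (10, 20), 30: (15, 45)},
    "DU2": {5: (1, 9), 15: (5, 25), 30: (5, 55)},
}


def _grid_design(T: int) -> DesignSpec:
    return DesignSpec(
        p=0.5,
        sigma2=1.0,
        beta4=0.2 / (T - 1),
        alpha=0.05,
        power_target=0.8,
        times=tuple(range(T)),
    )


def _corr(structure: str, combo: str) -> CorrelationSpec:
    r1, r2, r3 = R_COMBOS[combo]
    return CorrelationSpec(structure=structure, rho1=r1, rho2=r2, rho3=r3)


def _cell(
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec,
    cluster: ClusterSizeModel,
    reps: int,
    seed: int,
    threshold: str,
) -> dict[str, Any]:
    res = required_clusters(design, corr, miss, cluster)
    out: dict[str, Any] = {
        "n": res.n,
        "n_raw": res.n_raw,
        "sigma4_sq": res.sigma4_sq,
        "achieved_power": res.achieved_power,
    }
    if reps > 0:
        power = empirical_rates(
            SimulationConfig(
                design=design, corr=corr, cluster=cluster, miss=miss,
                n_clusters=res.n, reps=reps, seed=seed, threshold=threshold,
            )
        )
        type1 = empirical_rates(
            SimulationConfig(
                design=design, corr=corr, cluster=cluster, miss=miss,
                n_clusters=res.n, reps=reps, seed=seed + 1, threshold=threshold,
                null_mode=True,
            )
        )
        out["empirical_power"] = power.rejection_rate
        out["empirical_type1"] = type1.rejection_rate
        out["mc_se_power"] = power.mc_se
        out["mc_se_type1"] = type1.mc_se
    return out


def run_table(
    table: int, reps: int = 0, seed: int = 0, threshold: str = "t"
) -> pd.DataFrame:
    """Reproduce one benchmark table of required cluster counts.

    Table 2: complete data, fixed sizes, CS and AR(1), J x T x R1-R4.
    Table 3: complete data, CS, varying sizes (DU0/DU1/DU2).
    Table 4: fixed sizes, CS, T = 6, J in {15, 30}, IM/MM/MIX x delta sets.
    With ``reps > 0`` each cell also carries empirical power and type-I error
    from the Monte-Carlo engine (threshold 't' by default).
    """
    rows = []
    if table == 2:
        for structure, J, T, combo in itertools.product(
            ("CS", "AR1"), (5, 15, 30), (3, 6, 12), R_COMBOS
        ):
            cell = _cell(
                _grid_design(T),
                _corr(structure, combo),
                MissingnessSpec.complete(),
                ClusterSizeModel.fixed(J),
                reps, seed, threshold,
            )
            rows.append({"structure": structure, "J": J, "T": T, "R": combo, **cell})
    elif table == 3:
        for J, T, du, combo in itertools.product(
            (5, 15, 30), (3, 6, 12), DU_LAWS, R_COMBOS
        ):
            a, b = DU_LAWS[du][J]
            cell = _cell(
                _grid_design(T),
                _corr("CS", combo),
                MissingnessSpec.complete(),
                ClusterSizeModel.discrete_uniform(a, b),
                reps, seed, threshold,
            )
            rows.append({"J": J, "T": T, "DU": f"[{a},{b}]", "R": combo, **cell})
    elif table == 4:
        for J, pattern, dname, combo in itertools.product(
            (15, 30), ("IM", "MM", "MIX"), DELTA_SETS, R_COMBOS
        ):
            if dname == "delta1":
                if pattern != "IM":
                    continue  # complete data: one row regardless of pattern
                miss = MissingnessSpec.complete()
            else:
                miss = MissingnessSpec(pattern=pattern, delta=DELTA_SETS[dname], w=0.5)
            cell = _cell(
                _grid_design(6),
                _corr("CS", combo),
                miss,
                ClusterSizeModel.fixed(J),
                reps, seed, threshold,
            )
            rows.append(
                {"J": J, "pattern": pattern, "delta": dname, "R": combo, **cell}
            )
    else:
        raise ValueError(f"no such table: {table} (choose 2, 3 or 4)")
    return pd.DataFrame(rows)


#: depression-trial settings: 3-week time unit, standardized effect 0.6/6.4
_EXAMPLE_TIMES = (0, 1, 2, 3, 4, 5)
_EXAMPLE_BETA4 = 0.6 / 6.4
_EXAMPLE_DELTA = (1.00, 0.85, 0.70, 0.66, 0.63, 0.60)


def run_example(
    structure: str = "AR1",
    missing: str = "complete",
    cluster_sizes: str = "fixed",
) -> dict[str, Any]:
    """Required clinics for the depression-trial design.

    ``structure`` in {AR1, CS}; ``missing`` in {complete, IM, MM};
    ``cluster_sizes`` in {fixed, DU} (fixed J = 10 or DU[5, 15]).
    """
    design = DesignSpec(
        p=0.5, sigma2=1.0, beta4=_EXAMPLE_BETA4,
        alpha=0.05, power_target=0.8, times=_EXAMPLE_TIMES,
    )
    corr = CorrelationSpec(structure=structure, rho1=0.15, rho2=0.05, rho3=0.025)
    if missing == "complete":
        miss = MissingnessSpec.complete()
    elif missing in ("IM", "MM"):
        miss = MissingnessSpec(pattern=missing, delta=_EXAMPLE_DELTA)
    else:
        raise ValueError(f"missing must be complete/IM/MM, got {missing!r}")
    if cluster_sizes == "fixed":
        cluster = ClusterSizeModel.fixed(10)
    elif cluster_sizes == "DU":
        cluster = ClusterSizeModel.discrete_uniform(5, 15)
    else:
        raise ValueError(f"cluster_sizes must be fixed/DU, got {cluster_sizes!r}")
    res = required_clusters(design, corr, miss, cluster)
    return {
        "structure": structure,
        "missing": missing,
        "cluster_sizes": cluster_sizes,
        "n_clinics": res.n,
        "n_raw": res.n_raw,
        "sigma4_sq": res.sigma4_sq,
        "achieved_power": res.achieved_power,
    }


# ---------------------------------------------------------------------------
# config files


def _specs_to_dict(design, corr, miss, cluster) -> dict:
    cfg: dict[str, Any] = {
        "design": {
            "p": design.p,
            "sigma2": design.sigma2,
            "beta4": design.beta4,
            "alpha": design.alpha,
            "power": design.power_target,
            "times": list(design.times),
        },
        "correlation": {
            "structure": corr.structure,
            "rho1": corr.rho1,
            "rho2": corr.rho2,
            "rho3": corr.rho3,
        },
    }
    if corr.omega_matrix is not None:
        cfg["correlation"]["omega_matrix"] = np.asarray(corr.omega_matrix).tolist()
    if corr.phi_matrix is not None:
        cfg["correlation"]["phi_matrix"] = np.asarray(corr.phi_matrix).tolist()
    cfg["missing"] = {"pattern": miss.pattern}
    if miss.delta is not None:
        cfg["missing"]["delta"] = list(miss.delta)
    if miss.pattern == "MIX":
        cfg["missing"]["w"] = miss.w
    if cluster.du_bounds is not None:
        cfg["cluster"] = {"du": list(cluster.du_bounds)}
    else:
        cfg["cluster"] = {"mean": cluster.mean_J, "var": cluster.var_J}
    return cfg


def save_config(
    path: str | Path,
    design: DesignSpec,
    corr: CorrelationSpec,
    miss: MissingnessSpec | None = None,
    cluster: ClusterSizeModel | None = None,
) -> None:
    """Write the four design objects to YAML or JSON (by extension)."""
    miss = miss or MissingnessSpec.complete()
    cluster = cluster or ClusterSizeModel.fixed(1)
    cfg = _specs_to_dict(design, corr, miss, cluster)
    path = Path(path)
    text = (
        json.dumps(cfg, indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(cfg, sort_keys=False)
    )
    path.write_text(text)


def load_config(
    path: str | Path,
) -> tuple[DesignSpec, CorrelationSpec, MissingnessSpec, ClusterSizeModel]:
    """Read a YAML/JSON config into the four design objects."""
    path = Path(path)
    raw = path.read_text()
    cfg = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    d = cfg["design"]
    design = DesignSpec(
        p=d["p"], sigma2=d["sigma2"], beta4=d["beta4"],
        alpha=d.get("alpha", 0.05), power_target=d.get("power", 0.8),
        times=tuple(d["times"]),
    )
    c = cfg.get("correlation", {})
    corr = CorrelationSpec(
        structure=c.get("structure", "CS"),
        rho1=c.get("rho1", 0.0), rho2=c.get("rho2", 0.0), rho3=c.get("rho3", 0.0),
        omega_matrix=np.asarray(c["omega_matrix"]) if "omega_matrix" in c else None,
        phi_matrix=np.asarray(c["phi_matrix"]) if "phi_matrix" in c else None,
    )
    m = cfg.get("missing", {"pattern": "NONE"})
    miss = MissingnessSpec(
        pattern=m.get("pattern", "NONE"),
        delta=tuple(m["delta"]) if m.get("delta") is not None else None,
        w=m.get("w", 0.5),
    )
    cl = cfg.get("cluster", {"mean": 1, "var": 0})
    if "du" in cl:
        cluster = ClusterSizeModel.discrete_uniform(*cl["du"])
    elif "J" in cl:
        cluster = ClusterSizeModel.fixed(cl["J"])
    else:
        cluster = ClusterSizeModel.from_moments(cl["mean"], cl.get("var", 0.0))
    return design, corr, miss, cluster
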