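"""Closed-form sample-size and power calculator checks.

Printed benchmark counts are asserted exactly; reduction identities,
allocation optimality, cluster-size-variability monotonicity and the
missing-pattern ordering are asserted as properties over the full parameter
grid used by the Monte-Carlo study.
"""

import itertools

import numpy as np
import pytest

from crtlm import (
    ClusterSizeModel,
    CorrelationSpec,
    DesignSpec,
    MissingnessSpec,
    achieved_power,
    required_clusters,
    required_subjects_individual,
    slope_variance,
)
from crtlm.report import DELTA_SETS, R_COMBOS
from crtlm.samplesize import quadratic_form_double_sum

from .conftest import DELTA4


def _design(T, beta4=None, p=0.5):
    return DesignSpec(p=p, sigma2=1.0, beta4=beta4 if beta4 is not None else 0.2 / (T - 1),
                      times=tuple(range(T)))


def _corr(name, structure="CS"):
    r1, r2, r3 = R_COMBOS[name]
    return CorrelationSpec(structure=structure, rho1=r1, rho2=r2, rho3=r3)


class TestSlopeVariance:
    def test_reference_value_is_032(self, design_t3, corr_r1_cs, cluster_j5):
        # quadratic form (1,0,-1)'Q(1,0,-1) = 0.32 over unit denominator
        s42 = slope_variance(design_t3, corr_r1_cs, cluster=cluster_j5)
        assert s42 == pytest.approx(0.32, abs=1e-12)

    def test_scales_inversely_with_allocation_variance(self, corr_r1_cs, cluster_j5):
        s_half = slope_variance(_design(3, 0.1, p=0.5), corr_r1_cs, cluster=cluster_j5)
        s_third = slope_variance(_design(3, 0.1, p=0.3), corr_r1_cs, cluster=cluster_j5)
        assert s_third / s_half == pytest.approx(0.25 / 0.21, rel=1e-12)

    def test_all_observed_equals_complete_path(self, design_t3, corr_r1_cs, cluster_j5):
        miss = MissingnessSpec("MM", (1.0, 1.0, 1.0))
        assert slope_variance(design_t3, corr_r1_cs, miss, cluster_j5) == pytest.approx(
            slope_variance(design_t3, corr_r1_cs, cluster=cluster_j5), abs=1e-15
        )

    def test_degenerate_time_grid_raises(self, corr_r1_cs, cluster_j5):
        with pytest.raises(ValueError):
            DesignSpec(p=0.5, sigma2=1.0, beta4=0.1, times=(2.0, 2.0, 2.0))


class TestRequiredClusters:
    @pytest.mark.parametrize(
        "structure, T, J, combo, miss, expected",
        [
            ("CS", 3, 5, "R1", None, 252),
            ("CS", 6, 5, "R1", None, 180),
            ("AR1", 12, 5, "R1", None, 268),
            ("CS", 6, 15, "R1", MissingnessSpec("IM", DELTA4), 103),
            ("CS", 6, 15, "R1", MissingnessSpec("MM", DELTA4), 108),
        ],
    )
    def test_printed_counts_fixed_sizes(self, structure, T, J, combo, miss, expected):
        res = required_clusters(
            _design(T), _corr(combo, structure), miss, ClusterSizeModel.fixed(J)
        )
        assert res.n == expected

    def test_printed_count_varying_sizes(self):
        res = required_clusters(
            _design(3), _corr("R1"), None, ClusterSizeModel.discrete_uniform(1, 9)
        )
        assert res.n == 262

    def test_rounding_brackets_target_power(self, design_t3, corr_r1_cs, cluster_j5):
        res = required_clusters(design_t3, corr_r1_cs, cluster=cluster_j5)
        assert res.n == int(np.ceil(res.n_raw))
        below = achieved_power(design_t3, corr_r1_cs, cluster=cluster_j5, n=res.n - 1)
        at = achieved_power(design_t3, corr_r1_cs, cluster=cluster_j5, n=res.n)
        assert below < 0.8 <= at + 1e-12

    def test_null_effect_raises(self, corr_r1_cs, cluster_j5):
        d = DesignSpec(p=0.5, sigma2=1.0, beta4=0.0, times=(0, 1, 2))
        with pytest.raises(ValueError, match="beta4"):
            required_clusters(d, corr_r1_cs, cluster=cluster_j5)

    def test_t_threshold_extension_inflates_n(self, design_t3, corr_r1_cs, cluster_j5):
        rz = required_clusters(design_t3, corr_r1_cs, cluster=cluster_j5)
        rt = required_clusters(design_t3, corr_r1_cs, cluster=cluster_j5, threshold="t")
        assert rt.n >= rz.n
        assert rt.achieved_power >= 0.8 - 1e-12


class TestReductionsAndOrderings:
    @pytest.mark.parametrize("combo", list(R_COMBOS))
    @pytest.mark.parametrize("structure", ["CS", "AR1"])
    def test_complete_delta_equals_no_missingness(self, structure, combo):
        design = _design(6)
        corr = _corr(combo, structure)
        cluster = ClusterSizeModel.fixed(15)
        for pattern in ("IM", "MM", "MIX"):
            miss = MissingnessSpec(pattern, (1.0,) * 6)
            assert required_clusters(design, corr, miss, cluster).n == required_clusters(
                design, corr, None, cluster
            ).n

    def test_single_subject_clusters_match_individual_formula(self, rng):
        for _ in range(10):
            T = int(rng.integers(2, 7))
            design = DesignSpec(
                p=float(rng.uniform(0.2, 0.8)),
                sigma2=float(rng.uniform(0.5, 3.0)),
                beta4=float(rng.uniform(0.05, 0.5)),
                times=tuple(np.sort(rng.uniform(0, 5, T))),
            )
            corr = CorrelationSpec("CS", rho1=float(rng.uniform(0, 0.5)),
                                   rho2=float(rng.uniform(0, 0.2)),
                                   rho3=float(rng.uniform(0, 0.05)))
            d = tuple(np.sort(rng.uniform(0.5, 1.0, T))[::-1])
            miss = MissingnessSpec("MM", d)
            a = required_clusters(design, corr, miss, ClusterSizeModel.fixed(1))
            b = required_subjects_individual(design, corr, miss)
            assert a.n == b.n
            assert a.sigma4_sq == pytest.approx(b.sigma4_sq, rel=1e-14)

    @pytest.mark.parametrize("combo", list(R_COMBOS))
    @pytest.mark.parametrize("dname", ["delta2", "delta3", "delta4"])
    @pytest.mark.parametrize("J", [15, 30])
    def test_monotone_missing_requires_most_clusters(self, combo, dname, J):
        # MM >= MIX >= IM for nonnegative within-subject correlations
        design = _design(6)
        corr = _corr(combo)
        cluster = ClusterSizeModel.fixed(J)
        delta = DELTA_SETS[dname]
        raws = {
            pattern: required_clusters(
                design, corr, MissingnessSpec(pattern, delta, w=0.5), cluster
            ).n_raw
            for pattern in ("IM", "MIX", "MM")
        }
        assert raws["MM"] >= raws["MIX"] - 1e-12
        assert raws["MIX"] >= raws["IM"] - 1e-12

    def test_balanced_allocation_is_optimal(self, corr_r1_cs, cluster_j5):
        n_half = required_clusters(_design(3, 0.1, p=0.5), corr_r1_cs, cluster=cluster_j5).n_raw
        for p in np.arange(0.1, 0.95, 0.1):
            n_p = required_clusters(_design(3, 0.1, p=float(p)), corr_r1_cs, cluster=cluster_j5).n_raw
            assert n_p >= n_half - 1e-9

    def test_cluster_size_variability_increases_n(self, corr_r1_cs):
        # CV monotonicity at fixed mean size, rho2 >= rho3 >= 0
        design = _design(3, 0.1)
        raws = [
            required_clusters(
                design, corr_r1_cs, None, ClusterSizeModel.from_moments(5.0, var)
            ).n_raw
            for var in (0.0, 1.0, 80 / 12, 10.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(raws, raws[1:]))

    def test_mirrored_time_grid_gives_identical_power(self, corr_r1_cs):
        # early-loaded and late-loaded schedules are reflections of each other
        t_fwd = (0.0, 0.4, 0.9, 1.5, 3.2, 5.0)
        t_rev = tuple(sorted(t_fwd[0] + t_fwd[-1] - np.array(t_fwd)))
        cluster = ClusterSizeModel.fixed(5)
        p_fwd = achieved_power(
            DesignSpec(p=0.5, sigma2=1.0, beta4=0.1, times=t_fwd),
            corr_r1_cs, cluster=cluster, n=30,
        )
        p_rev = achieved_power(
            DesignSpec(p=0.5, sigma2=1.0, beta4=0.1, times=t_rev),
            corr_r1_cs, cluster=cluster, n=30,
        )
        assert p_fwd == pytest.approx(p_rev, abs=1e-12)


class TestDoubleSumOracle:
    def test_quadratic_form_matches_explicit_double_sum(self, rng):
        for _ in range(20):
            T = int(rng.integers(2, 7))
            design = DesignSpec(
                p=float(rng.uniform(0.2, 0.8)),
                sigma2=float(rng.uniform(0.5, 2.0)),
                beta4=0.1,
                times=tuple(np.sort(rng.uniform(0, 4, T))),
            )
            corr = CorrelationSpec("CS", rho1=float(rng.uniform(0, 0.6)),
                                   rho2=float(rng.uniform(0, 0.2)),
                                   rho3=float(rng.uniform(0, 0.1)))
            d = tuple(np.sort(rng.uniform(0.4, 1.0, T))[::-1])
            miss = MissingnessSpec("MIX", d, w=float(rng.uniform(0, 1)))
            cluster = ClusterSizeModel.from_moments(
                float(rng.uniform(2, 30)), float(rng.uniform(0, 20))
            )
            res = required_clusters(design, corr, miss, cluster)
            oracle = quadratic_form_double_sum(design, corr, miss, cluster)
            assert res.quadratic_form == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize(
        "pattern, expected", [("IM", 1.8040190725348724), ("MM", 1.9945902548557364)]
    )
    def test_missingness_weighted_quadratic_form(self, pattern, expected):
        # J=10 fixed, AR(1) rho1=0.15 on t=0..5, 40% dropout marginals;
        # frozen values from an independent double-sum evaluation
        design = DesignSpec(p=0.5, sigma2=1.0, beta4=0.1, times=tuple(range(6)))
        corr = CorrelationSpec("AR1", rho1=0.15, rho2=0.05, rho3=0.025)
        res = required_clusters(
            design, corr, MissingnessSpec(pattern, DELTA4), ClusterSizeModel.fixed(10)
        )
        assert res.quadratic_form == pytest.approx(expected, abs=1e-4)
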