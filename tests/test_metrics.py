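"""Unit and property tests for the mixing-model and trophic-position
equations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isofoodweb import (
    DegenerateEndmembersError,
    DegenerateRangeError,
    EndmemberSet,
    MetricConfig,
    Role,
    Tissue,
    boundary_violation_stats,
    clip_lcu,
    compute_lcu,
    compute_metric_suite,
    mix_d13c,
    pooled_baseline,
    rescale_lcu,
    tp_one_source,
    tp_two_source,
    tp_two_source_abs,
)
from tests.conftest import make_measurement

finite_alpha = st.floats(min_value=-2.0, max_value=3.0)


def endmember_strategy():
    """Endmember sets with distinct d13c (littoral enriched) and any d15n."""
    return st.builds(
        lambda p, spread, nl, np_: EndmemberSet(
            d13c_littoral=p + spread,
            d13c_pelagic=p,
            d15n_littoral=nl,
            d15n_pelagic=np_,
            lambda_littoral=2.25,
            lambda_pelagic=2.0,
        ),
        p=st.floats(min_value=-35.0, max_value=-25.0),
        spread=st.floats(min_value=0.5, max_value=15.0),
        nl=st.floats(min_value=2.0, max_value=10.0),
        np_=st.floats(min_value=2.0, max_value=10.0),
    )


class TestLcu:
    @pytest.mark.parametrize(
        "consumer, expected",
        [(-20.0, 1.0), (-28.0, 0.0), (-24.0, 0.5), (-18.0, 1.25)],
    )
    def test_mixing_line_position(self, em, consumer, expected):
        assert compute_lcu(consumer, em) == pytest.approx(expected, abs=1e-12)

    def test_equal_endmembers_signal_one_source_system(self):
        em = EndmemberSet(
            d13c_littoral=-24.0, d13c_pelagic=-24.0,
            d15n_littoral=6.0, d15n_pelagic=4.0,
        )
        with pytest.raises(DegenerateEndmembersError, match="one-source"):
            compute_lcu(-22.0, em)

    @pytest.mark.parametrize("x, expected", [(1.3, 1.0), (-0.2, 0.0), (0.6, 0.6)])
    def test_clip(self, x, expected):
        assert clip_lcu(x) == expected

    @given(x=st.floats(min_value=-5, max_value=5), y=st.floats(min_value=-5, max_value=5))
    def test_clip_idempotent_and_monotone(self, x, y):
        assert clip_lcu(clip_lcu(x)) == clip_lcu(x)
        if x <= y:
            assert clip_lcu(x) <= clip_lcu(y)

    def test_rescale_hand_case(self):
        np.testing.assert_allclose(
            rescale_lcu([0.2, 0.6, 1.0]), [0.0, 0.5, 1.0], atol=1e-12
        )

    def test_rescale_two_point_and_extremes(self):
        np.testing.assert_allclose(rescale_lcu([-0.4, 1.6]), [0.0, 1.0], atol=1e-12)
        vals = [0.3, -0.7, 2.1, 0.9]
        out = rescale_lcu(vals)
        assert out[np.argmin(vals)] == 0.0
        assert out[np.argmax(vals)] == 1.0

    @given(
        values=st.lists(
            st.integers(min_value=-3000, max_value=3000),
            min_size=3, max_size=20, unique=True,
        ),
        a=st.floats(min_value=0.1, max_value=5.0),
        b=st.floats(min_value=-10, max_value=10),
    )
    def test_rescale_order_preserving_and_affine_invariant(self, values, a, b):
        arr = np.array(values) / 1000.0  # distinct values on a 1e-3 grid
        out = rescale_lcu(arr)
        # strictly order-preserving
        order = np.argsort(arr)
        assert np.all(np.diff(out[order]) > 0)
        # invariant under positive affine maps of the input
        np.testing.assert_allclose(rescale_lcu(a * arr + b), out, atol=1e-9)

    def test_rescale_degenerate(self):
        with pytest.raises(DegenerateRangeError):
            rescale_lcu([0.5, 0.5, 0.5])
        with pytest.raises(DegenerateRangeError):
            rescale_lcu([0.5])


class TestMixing:
    def test_endmember_identities(self, em):
        assert mix_d13c(1.0, em) == em.d13c_littoral
        assert mix_d13c(0.0, em) == em.d13c_pelagic
        assert mix_d13c(0.5, em) == pytest.approx(-24.0)

    @given(alpha=finite_alpha, em=endmember_strategy())
    def test_round_trip_is_identity(self, alpha, em):
        assert compute_lcu(mix_d13c(alpha, em), em) == pytest.approx(alpha, abs=1e-12)

    @given(
        em=endmember_strategy(),
        d13c=st.lists(
            st.floats(min_value=-33, max_value=-18), min_size=2, max_size=30
        ),
    )
    def test_linearity_cohort_mean(self, em, d13c):
        """Mean LCU of a cohort equals the LCU of the cohort-mean d13c."""
        arr = np.array(d13c)
        assert np.mean(compute_lcu(arr, em)) == pytest.approx(
            float(compute_lcu(arr.mean(), em)), abs=1e-12
        )


class TestTrophicPosition:
    @pytest.mark.parametrize(
        "consumer, base, lam, expected",
        [(5.0, 5.0, 2.0, 2.0), (8.4, 5.0, 2.0, 3.0), (12.0, 5.2, 2.0, 4.0)],
    )
    def test_one_source(self, consumer, base, lam, expected):
        assert tp_one_source(consumer, base, lam, 3.4) == pytest.approx(expected)

    def test_one_source_rejects_nonpositive_delta_n(self):
        with pytest.raises(ValueError, match="delta_n"):
            tp_one_source(10.0, 5.0, 2.0, 0.0)

    def test_two_source_hand_case(self, em):
        assert tp_two_source(10.0, 0.5, em, 2.0, 3.4) == pytest.approx(
            3.4706, abs=1e-4
        )

    def test_two_source_reduces_to_one_source_at_pure_alpha(self, em):
        for alpha, base in [(1.0, em.d15n_littoral), (0.0, em.d15n_pelagic)]:
            assert tp_two_source(9.0, alpha, em, 2.0, 3.4) == pytest.approx(
                float(tp_one_source(9.0, base, 2.0, 3.4)), abs=1e-12
            )

    def test_two_source_abs_hand_case(self, em):
        assert tp_two_source_abs(10.0, 0.4, em, 3.4) == pytest.approx(3.6294, abs=1e-4)

    def test_two_source_abs_at_alpha_one(self, em):
        expected = em.lambda_littoral + (10.0 - em.d15n_littoral) / 3.4
        assert tp_two_source_abs(10.0, 1.0, em, 3.4) == pytest.approx(expected, abs=1e-12)

    @given(alpha=finite_alpha, d15n=st.floats(min_value=4, max_value=18))
    def test_abs_lambda_reduces_to_two_source_when_lambdas_equal(
        self, alpha, d15n, em_equal_lambda
    ):
        assert tp_two_source_abs(d15n, alpha, em_equal_lambda, 3.4) == pytest.approx(
            float(tp_two_source(d15n, alpha, em_equal_lambda, 2.0, 3.4)), abs=1e-12
        )

    @given(
        alpha=st.floats(min_value=0, max_value=1),
        d15n=st.floats(min_value=4, max_value=18),
        em=endmember_strategy(),
    )
    def test_two_source_brackets_one_source_pair(self, alpha, d15n, em):
        """For alpha in [0,1] and a common lambda, the two-source TP lies
        between the littoral-only and pelagic-only one-source TPs."""
        lam = 2.0
        tps = sorted(
            [
                float(tp_one_source(d15n, em.d15n_littoral, lam, 3.4)),
                float(tp_one_source(d15n, em.d15n_pelagic, lam, 3.4)),
            ]
        )
        tp2 = float(tp_two_source(d15n, alpha, em, lam, 3.4))
        assert tps[0] - 1e-12 <= tp2 <= tps[1] + 1e-12

    @given(alpha=finite_alpha, d15n=st.floats(min_value=4, max_value=18))
    def test_abs_minus_plain_identity(self, alpha, d15n, em):
        """tp2abs - tp2 = alpha (lamL - lam) + (1 - alpha) (lamP - lam)."""
        lam = 2.0
        diff = float(tp_two_source_abs(d15n, alpha, em, 3.4)) - float(
            tp_two_source(d15n, alpha, em, lam, 3.4)
        )
        expected = alpha * (em.lambda_littoral - lam) + (1 - alpha) * (
            em.lambda_pelagic - lam
        )
        assert diff == pytest.approx(expected, abs=1e-9)


class TestPooledBaseline:
    def test_hand_mean(self):
        samples = [
            make_measurement("l1", -20.0, 6.0, role=Role.LITTORAL_BASELINE),
            make_measurement("p1", -28.0, 4.0, role=Role.PELAGIC_BASELINE),
        ]
        assert pooled_baseline(samples) == pytest.approx(5.0)

    def test_constant_identity(self):
        samples = [
            make_measurement(f"l{i}", -24.0, 7.5, role=Role.LITTORAL_BASELINE)
            for i in range(3)
        ] + [make_measurement("p0", -24.0, 7.5, role=Role.PELAGIC_BASELINE)]
        assert pooled_baseline(samples) == pytest.approx(7.5)

    def test_missing_habitat_errors(self):
        only_littoral = [
            make_measurement("l1", -20.0, 6.0, role=Role.LITTORAL_BASELINE)
        ]
        with pytest.raises(ValueError):
            pooled_baseline(only_littoral)
        with pytest.raises(ValueError):
            pooled_baseline([])

    def test_mean_of_means_option(self, em):
        samples = [
            make_measurement("l1", -20.0, 6.0, role=Role.LITTORAL_BASELINE),
            make_measurement("l2", -20.0, 8.0, role=Role.LITTORAL_BASELINE),
            make_measurement("l3", -20.0, 10.0, role=Role.LITTORAL_BASELINE),
            make_measurement("p1", -28.0, 4.0, role=Role.PELAGIC_BASELINE),
        ]
        # habitat-weighted option ignores the 3:1 count imbalance
        assert pooled_baseline(
            samples, method="mean_of_means", endmembers=em
        ) == pytest.approx(5.0)
        assert pooled_baseline(samples) == pytest.approx(7.0)


class TestViolationStats:
    def test_all_inside(self):
        v = boundary_violation_stats([0.1, 0.5, 0.9])
        assert v.pct_outside == 0.0 and not v.exceeds_threshold

    def test_hand_count(self):
        v = boundary_violation_stats([1.2, -0.1, 0.5, 0.7], threshold=0.05)
        assert (v.n_above_1, v.n_below_0) == (1, 1)
        assert v.pct_outside == pytest.approx(50.0)
        assert v.exceeds_threshold

    def test_bounds_inclusive(self):
        v = boundary_violation_stats([0.0, 1.0])
        assert v.pct_outside == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            boundary_violation_stats([])


class TestMetricSuite:
    def test_endmember_identity_cascade(self, em, baseline_cohort):
        consumer = make_measurement("c1", em.d13c_littoral, em.d15n_littoral)
        other = make_measurement("c2", -24.0, 8.0)
        records = compute_metric_suite([consumer, other], em, baseline_cohort)
        r = records[0]
        assert r.lcu == pytest.approx(1.0, abs=1e-12)
        assert r.tp["tp1_lb"] == pytest.approx(2.0, abs=1e-12)
        assert r.tp["tp2"] == pytest.approx(r.tp["tp1_lb"], abs=1e-12)

    def test_noise_free_cohort_recovers_alpha(self, em, baseline_cohort):
        alphas = np.linspace(-0.2, 1.3, 16)
        consumers = [
            make_measurement(f"c{i}", float(mix_d13c(a, em)), 10.0)
            for i, a in enumerate(alphas)
        ]
        records = compute_metric_suite(consumers, em, baseline_cohort)
        np.testing.assert_allclose([r.lcu for r in records], alphas, atol=1e-12)

    def test_abs_identity_holds_per_record(self, em, baseline_cohort):
        rng = np.random.default_rng(5)
        consumers = [
            make_measurement(f"c{i}", rng.uniform(-30, -18), rng.uniform(6, 14))
            for i in range(12)
        ]
        cfg = MetricConfig()
        records = compute_metric_suite(consumers, em, baseline_cohort, cfg)
        for r in records:
            expected = r.lcu * (em.lambda_littoral - cfg.lambda_default) + (
                1 - r.lcu
            ) * (em.lambda_pelagic - cfg.lambda_default)
            assert r.tp["tp2abs"] - r.tp["tp2"] == pytest.approx(expected, abs=1e-9)

    def test_per_stratum_rescaling(self, em, baseline_cohort):
        consumers = [
            make_measurement("a1", -27.0, 9.0, stratum="east"),
            make_measurement("a2", -21.0, 9.0, stratum="east"),
            make_measurement("b1", -25.0, 9.0, stratum="west"),
            make_measurement("b2", -19.0, 9.0, stratum="west"),
        ]
        cfg = MetricConfig(rescale_scope="per_stratum")
        records = compute_metric_suite(consumers, em, baseline_cohort, cfg)
        by_id = {r.specimen_id: r for r in records}
        # each stratum's own min/max map to 0/1
        assert by_id["a1"].lcu_r == 0.0 and by_id["a2"].lcu_r == 1.0
        assert by_id["b1"].lcu_r == 0.0 and by_id["b2"].lcu_r == 1.0

    def test_empty_consumers_error(self, em, baseline_cohort):
        with pytest.raises(ValueError):
            compute_metric_suite([], em, baseline_cohort)
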