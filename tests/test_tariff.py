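"""Tariff engine: endorsement rates, the Tariff formula, bootstrap
significance, and 0.5-grid rounding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tariffva as tv
from conftest import make_random_spec


def _dataset_from_bits(bit_rows, causes_of_rows, causes=None):
    """Build a binary-symptom dataset straight from a bit table."""
    n_symp = len(bit_rows[0])
    schema = [tv.SymptomSchema(f"s{i}", "adult", "binary") for i in range(n_symp)]
    records = []
    for k, (bits, cause) in enumerate(zip(bit_rows, causes_of_rows)):
        responses = {
            f"s{i}": (tv.YES if b == 1 else (tv.DONT_KNOW if b == "dk" else tv.NO))
            for i, b in enumerate(bits)
        }
        records.append(tv.VARecord(f"r{k}", "adult", "s", cause, "1", responses))
    causes = causes or list(dict.fromkeys(causes_of_rows))
    return tv.GSDataset("adult", causes, schema, records)


class TestEndorsementRates:
    def test_half_yes_gives_point_five(self):
        ds = _dataset_from_bits([[1], [0]], ["AMI", "AMI"], causes=["AMI"])
        assert tv.endorsement_rates(ds).x[0, 0] == 0.5

    def test_all_yes_gives_one(self):
        ds = _dataset_from_bits([[1], [1]], ["A", "A"])
        assert tv.endorsement_rates(ds).x[0, 0] == 1.0

    def test_dont_know_counts_in_denominator(self):
        ds = _dataset_from_bits([[1], [0], ["dk"]], ["A"] * 3)
        assert tv.endorsement_rates(ds).x[0, 0] == pytest.approx(1 / 3)

    def test_empty_cause_dropped_with_warning(self, caplog):
        ds = _dataset_from_bits([[1], [0]], ["A", "A"], causes=["A", "B"])
        with caplog.at_level("WARNING", logger="tariffva"):
            em = tv.endorsement_rates(ds)
        assert em.causes == ["A"]
        assert any("dropped" in m for m in caplog.messages)


class TestComputeTariffs:
    def _em(self, x, causes=None):
        x = np.asarray(x, dtype=float)
        causes = causes or [f"C{j}" for j in range(x.shape[1])]
        return tv.EndorsementMatrix(
            x=x, symptoms=[f"s{i}" for i in range(x.shape[0])], causes=causes,
            n_cases={c: 10 for c in causes}, module="adult",
        )

    def test_worked_example_is_one_point_six(self):
        tm = tv.compute_tariffs(self._em([[0.08, 0.10, 0.18, 0.30, 0.50]]))
        assert tm.median[0] == pytest.approx(0.18)
        assert tm.iqr[0] == pytest.approx(0.20)
        assert tm.raw[0, -1] == pytest.approx((0.50 - 0.18) / 0.20)  # = 1.6

    def test_rate_at_median_scores_zero(self):
        tm = tv.compute_tariffs(self._em([[0.1, 0.3, 0.5]]))
        assert tm.raw[0, 1] == 0.0

    def test_zero_iqr_pair_is_undefined(self):
        tm = tv.compute_tariffs(self._em([[0.3, 0.3, 0.3]]))
        assert not tm.defined[0].any()
        assert np.all(tm.raw[0] == 0.0)

    def test_single_cause_rejected(self):
        with pytest.raises(ValueError):
            tv.compute_tariffs(self._em([[0.5]]))

    def test_hand_oracle_three_causes(self):
        tm = tv.compute_tariffs(self._em([[0.1, 0.3, 0.6], [0.2, 0.2, 0.5]]))
        np.testing.assert_allclose(tm.raw, [[-0.8, 0.0, 1.2], [0.0, 0.0, 2.0]])

    def test_two_cause_rows_are_antisymmetric(self):
        tm = tv.compute_tariffs(self._em([[0.2, 0.6], [0.9, 0.1]]))
        np.testing.assert_allclose(tm.raw[:, 0], -tm.raw[:, 1])
        np.testing.assert_allclose(np.abs(tm.raw), 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        x=st.lists(st.floats(0.0, 0.5), min_size=4, max_size=4),
        a=st.floats(0.0, 0.4),
        b=st.floats(0.05, 1.0),
    )
    def test_location_scale_invariance(self, x, a, b):
        """Affine maps of a symptom's endorsement rates leave its Tariffs
        unchanged: the numerator and IQR both scale by b, the median
        shifts by a."""
        x = np.array([x])
        before = tv.compute_tariffs(self._em(x))
        if not before.defined.any() or before.iqr[0] < 1e-3:
            return  # degenerate row: Tariff undefined or numerically hollow
        after = tv.compute_tariffs(self._em(a + b * x))
        np.testing.assert_allclose(after.raw, before.raw, rtol=1e-9, atol=1e-9)


class TestRounding:
    def _tm(self, raw, significant):
        raw = np.asarray(raw, dtype=float)
        sig = np.asarray(significant, dtype=bool)
        return tv.TariffMatrix(
            raw=raw, median=np.zeros(raw.shape[0]), iqr=np.ones(raw.shape[0]),
            defined=np.ones_like(sig), significant=sig,
            symptoms=[f"s{i}" for i in range(raw.shape[0])],
            causes=[f"C{j}" for j in range(raw.shape[1])], module="adult",
        )

    @pytest.mark.parametrize(
        "raw, sig, expected",
        [
            (1.6, True, 1.5),
            (98.2, False, 0.0),  # the mask dominates any magnitude
            (-0.75, True, -1.0),  # tie rounds away from zero
            (0.25, True, 0.5),
            (-0.2, True, 0.0),
            (1.74, True, 1.5),
            (1.76, True, 2.0),
        ],
    )
    def test_rounding_rules(self, raw, sig, expected):
        tm = tv.round_tariffs(self._tm([[raw]], [[sig]]))
        assert tm.rounded[0, 0] == expected

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-50, 50, allow_nan=False))
    def test_rounded_values_sit_on_half_grid(self, raw):
        tm = tv.round_tariffs(self._tm([[raw]], [[True]]))
        assert float(tm.rounded[0, 0] * 2) == int(tm.rounded[0, 0] * 2)
        assert abs(tm.rounded[0, 0] - raw) <= 0.25 + 1e-12


class TestBootstrap:
    def test_constant_symptom_never_significant(self):
        ds = _dataset_from_bits([[0]] * 40, ["A"] * 20 + ["B"] * 20)
        tm = tv.bootstrap_significance(ds, cfg=tv.BootstrapConfig(n_reps=50, seed=0))
        assert not tm.significant.any()

    def test_discriminating_symptom_significant_and_positive(self):
        rng = np.random.default_rng(0)
        causes, rows, labels = ["A", "B", "C"], [], []
        for j, c in enumerate(causes):
            p = 0.9 if c == "A" else 0.05
            for _ in range(200):
                rows.append([int(rng.random() < p)])
                labels.append(c)
        ds = _dataset_from_bits(rows, labels, causes=causes)
        tm = tv.bootstrap_significance(ds, cfg=tv.BootstrapConfig(n_reps=100, seed=1))
        assert tm.significant[0, 0]
        assert tm.raw[0, 0] > 0 and tm.ui_lower[0, 0] > 0

    def test_fit_is_deterministic_given_seed(self):
        spec = make_random_spec(4, 6, 40, seed=12)
        ds = tv.generate(spec)
        a = tv.fit(ds, cfg=tv.BootstrapConfig(n_reps=60, seed=3))
        b = tv.fit(ds, cfg=tv.BootstrapConfig(n_reps=60, seed=3))
        np.testing.assert_array_equal(a.rounded, b.rounded)
        np.testing.assert_array_equal(a.ui_lower, b.ui_lower)

    def test_intervals_widen_as_cases_shrink(self):
        spec = make_random_spec(4, 8, 400, seed=21)
        ds = tv.generate(spec)
        widths = []
        for keep in (400, 50):
            sub = [r for c in ds.causes
                   for r in [x for x in ds.records if x.gs_cause == c][:keep]]
            small = tv.GSDataset(ds.module, ds.causes, ds.schema, sub)
            tm = tv.bootstrap_significance(small, cfg=tv.BootstrapConfig(n_reps=80, seed=4))
            widths.append(np.mean(tm.ui_upper - tm.ui_lower))
        assert widths[1] > widths[0]

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            tv.BootstrapConfig(n_reps=1)
        with pytest.raises(ValueError):
            tv.BootstrapConfig(ui_level=1.0)


def test_fit_recovers_signs_of_strong_pairs():
    """With 500 cases per cause, every pair whose population Tariff has
    magnitude >= 1 is fitted with the correct sign."""
    spec = make_random_spec(8, 20, 500, seed=17)
    tt = tv.true_tariffs(spec)
    tm = tv.fit(tv.generate(spec), cfg=tv.BootstrapConfig(n_reps=100, seed=2))
    strong = np.abs(tt.raw) >= 1.0
    assert strong.sum() > 20
    assert np.all(np.sign(tm.raw[strong]) == np.sign(tt.raw[strong]))


def test_perfectly_discriminating_symptom_two_causes():
    """A symptom endorsed by every A death and no B death is significant
    with opposite signs for the two causes."""
    ds = _dataset_from_bits([[1]] * 25 + [[0]] * 25, ["A"] * 25 + ["B"] * 25)
    tm = tv.fit(ds, cfg=tv.BootstrapConfig(n_reps=60, seed=5))
    assert tm.significant.all()
    assert tm.raw[0, 0] > 0 > tm.raw[0, 1]
    assert tm.raw[0, 0] == -tm.raw[0, 1]
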