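"""Relative expression, group statistics and dose-response shapes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rfdosim import qpcr
from rfdosim.qpcr import DoseResponseProfile
from rfdosim.synth import PROFILES, GeneratorConfig, gen_ct_table


def _table(rows):
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


def _flat_table(shift=0.0):
    rows = []
    for cond in ("sham", "treated"):
        for rep in (1, 2, 3):
            rows.append(("GAPDH", cond, rep, 17.0))
            rows.append(("TGT", cond, rep, 24.0 - (shift if cond == "treated" else 0.0)))
    return _table(rows)


class TestRelativeExpression:
    def test_no_effect_gives_fold_one(self):
        res = qpcr.relative_expression(_flat_table(), "GAPDH", "sham")
        assert res["fold_change"].to_numpy() == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles(self):
        res = qpcr.relative_expression(_flat_table(shift=1.0), "GAPDH", "sham")
        treated = res.loc[res["condition"] == "treated", "fold_change"].iloc[0]
        assert treated == pytest.approx(2.0)

    def test_control_fold_exactly_one(self):
        ct = gen_ct_table(PROFILES["kiaa_biphasic"], GeneratorConfig(seed=5))
        res = qpcr.relative_expression(ct, "GAPDH", "sham")
        ctrl = res.loc[res["condition"] == "sham", "fold_change"]
        assert ctrl.to_numpy() == pytest.approx(1.0, rel=1e-12)

    def test_recovery_of_true_fold(self):
        ct = gen_ct_table(PROFILES["kiaa_biphasic"], GeneratorConfig(seed=42))
        res = qpcr.relative_expression(ct, "GAPDH", "sham")
        f = res.loc[res["condition"] == "+10dBm", "fold_change"].iloc[0]
        assert f == pytest.approx(2.5, rel=0.15)

    def test_sample_shift_invariance(self):
        """Adding a constant to all Cts of one (condition, replicate) sample
        models a loading difference; the reference normalization must cancel
        it exactly."""
        ct = gen_ct_table(PROFILES["kiaa_biphasic"], GeneratorConfig(seed=7))
        base = qpcr.relative_expression(ct, "GAPDH", "sham")
        bumped = ct.copy()
        sel = (bumped["condition"] == "-10dBm") & (bumped["replicate"] == 2)
        bumped.loc[sel, "ct"] += 3.7
        shifted = qpcr.relative_expression(bumped, "GAPDH", "sham")
        pd.testing.assert_frame_equal(base, shifted)

    def test_missing_reference_named(self):
        ct = _flat_table()
        ct = ct[~((ct["gene"] == "GAPDH") & (ct["condition"] == "treated")
                  & (ct["replicate"] == 2))]
        with pytest.raises(ValueError, match="GAPDH"):
            qpcr.relative_expression(ct, "GAPDH", "sham")


class TestNormality:
    def test_normal_sample_usually_passes(self):
        passed = 0
        for seed in range(100):
            vals = np.random.default_rng(seed).normal(size=50)
            if qpcr.normality_check(vals) > 0.05:
                passed += 1
        assert passed >= 90

    def test_bimodal_sample_fails(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
        assert qpcr.normality_check(vals) < 0.05

    def test_degenerate_inputs_flagged(self):
        assert qpcr.normality_check([1.0, 1.0, 1.0]) is None
        assert qpcr.normality_check([1.0, 2.0]) is None


class TestAnovaTukey:
    def test_null_case_nothing_significant(self):
        ct = gen_ct_table(PROFILES["null_flat"], GeneratorConfig(seed=1))
        rq = qpcr.replicate_quantities(ct, "GAPDH", "sham")
        sig = qpcr.anova_tukey(rq, "sham")
        assert (sig["p_adj"] > 0.05).all()

    def test_two_groups_tukey_equals_t(self):
        """With k=2 the studentized-range test collapses to the pooled
        t-test; the adjusted p must match the plain t-test p."""
        rng = np.random.default_rng(3)
        rq = pd.DataFrame({
            "gene": "G", "condition": ["sham"] * 6 + ["treated"] * 6,
            "rq": np.concatenate([rng.normal(1.0, 0.1, 6),
                                  rng.normal(1.4, 0.1, 6)])})
        p_adj = qpcr.anova_tukey(rq, "sham")["p_adj"].iloc[0]
        a = rq.loc[rq["condition"] == "sham", "rq"]
        b = rq.loc[rq["condition"] == "treated", "rq"]
        p_t = stats.ttest_ind(a, b).pvalue
        assert p_adj == pytest.approx(p_t, rel=1e-3, abs=1e-4)

    def test_identical_groups_p_one(self):
        rq = pd.DataFrame({"gene": "G",
                           "condition": ["sham", "sham", "a", "a", "b", "b"],
                           "rq": [1.0] * 6})
        sig = qpcr.anova_tukey(rq, "sham")
        assert (sig["p_adj"] == 1.0).all()

    def test_expected_significance_pattern(self):
        """Extreme-amplitude conditions respond, interior ones do not, on
        the seeded biphasic profile."""
        ct = gen_ct_table(PROFILES["kiaa_biphasic"],
                          GeneratorConfig(seed=42, replicates=3))
        res = qpcr.analyze(ct, "GAPDH", "sham")
        p = res.set_index("condition")["p_adj"]
        assert p["+10dBm"] < 0.05
        assert p["-30dBm"] < 0.05
        assert p["-40dBm"] < 0.05
        for cond in ("0dBm", "-10dBm", "-20dBm"):
            assert p[cond] > 0.05


class TestStars:
    @pytest.mark.parametrize("p, label", [
        (0.03, "*"), (0.05, "ns"), (5e-5, "****"), (0.2, "ns"),
        (0.009, "**"), (0.01, "*"), (5e-4, "***"), (1e-3, "**"),
        (1e-4, "***"), (0.0, "****"), (1.0, "ns")])
    def test_thresholds_strict(self, p, label):
        assert qpcr.significance_stars(p) == label

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_p(self, p1, p2):
        order = ["****", "***", "**", "*", "ns"]
        lo, hi = sorted((p1, p2))
        assert order.index(qpcr.significance_stars(lo)) <= order.index(
            qpcr.significance_stars(hi))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qpcr.significance_stars(1.5)


class TestDoseResponseShapes:
    AMPS = (-40.0, -30.0, -20.0, -10.0, 0.0, 10.0)

    def _profile(self, folds, ps):
        return DoseResponseProfile("G", self.AMPS, tuple(folds), tuple(ps))

    def test_biphasic_up_with_terminal_runs(self):
        # responses at both amplitude extremes (including a two-rung low
        # run), silent interior: the hormetic U shape
        prof = self._profile([5.0, 5.0, 1.0, 1.1, 0.9, 2.5],
                             [1e-4, 1e-4, 0.9, 0.8, 0.9, 0.01])
        assert qpcr.classify_dose_response(prof) == "biphasic-U"

    def test_biphasic_inverted(self):
        prof = self._profile([0.3, 0.4, 1.0, 1.0, 1.0, 0.5],
                             [1e-3, 1e-3, 0.9, 0.9, 0.9, 1e-3])
        assert qpcr.classify_dose_response(prof) == "biphasic-inverted"

    def test_all_ns_is_flat(self):
        prof = self._profile([1.0] * 6, [0.5] * 6)
        assert qpcr.classify_dose_response(prof) == "flat"

    def test_monotonic_up(self):
        prof = self._profile([1.1, 1.5, 2.0, 2.6, 3.5, 5.0],
                             [0.2, 0.01, 0.01, 1e-3, 1e-3, 1e-4])
        assert qpcr.classify_dose_response(prof) == "monotonic-up"

    def test_mixed_when_incoherent(self):
        prof = self._profile([2.0, 1.0, 0.4, 1.0, 3.0, 1.0],
                             [0.01, 0.9, 0.01, 0.9, 0.01, 0.9])
        assert qpcr.classify_dose_response(prof) == "mixed"

    def test_too_short_ladder_rejected(self):
        prof = DoseResponseProfile("G", (-10.0, 0.0), (1.0, 2.0), (0.5, 0.01))
        with pytest.raises(ValueError, match="at least 3"):
            qpcr.classify_dose_response(prof)

    def test_generated_biphasic_profile_classified(self):
        ct = gen_ct_table(PROFILES["kiaa_biphasic"], GeneratorConfig(seed=42))
        res = qpcr.analyze(ct, "GAPDH", "sham")
        prof = qpcr.profile_from_results(res, "KIAA", "sham")
        assert qpcr.classify_dose_response(prof) == "biphasic-U"
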