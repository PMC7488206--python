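"""ANOVA / paired-t / effect-size oracles and the unit-modulation pipeline."""

import numpy as np
import pandas as pd
import pytest

from dnmp.config import ModulationSpec, StudyConfig
from dnmp.binning import compute_rate_tensor, split_by_rate
from dnmp.simulate import generate_cohort
from dnmp.stats import (classify_trajectory_modulated, cohens_d,
                        modulation_proportions, paired_ttests_by_bin,
                        pearson_r, session_behavior_table, two_way_anova,
                        unit_trajectory_table)


def _balanced_table(rng, n_per_cell=4, effect=0.0):
    rows = []
    for cls in ("L", "R"):
        for b in range(1, 8):
            mu = effect if cls == "L" else 0.0
            for _ in range(n_per_cell):
                rows.append((rng.normal(mu, 1.0), cls, b))
    return pd.DataFrame(rows, columns=["value", "cls", "bin"])


def _anova_oracle(df):
    """Brute-force balanced two-way sums of squares from cell means."""
    grand = df["value"].mean()
    classes = sorted(df["cls"].unique())
    bins = sorted(df["bin"].unique())
    n_cell = len(df) // (len(classes) * len(bins))
    cell = {(c, b): df[(df.cls == c) & (df.bin == b)]["value"].mean()
            for c in classes for b in bins}
    m_c = {c: df[df.cls == c]["value"].mean() for c in classes}
    m_b = {b: df[df.bin == b]["value"].mean() for b in bins}
    ss_class = n_cell * len(bins) * sum((m_c[c] - grand) ** 2 for c in classes)
    ss_bin = n_cell * len(classes) * sum((m_b[b] - grand) ** 2 for b in bins)
    ss_int = n_cell * sum((cell[(c, b)] - m_c[c] - m_b[b] + grand) ** 2
                          for c in classes for b in bins)
    ss_err = sum((v - cell[(c, b)]) ** 2
                 for c, b, v in zip(df.cls, df.bin, df.value))
    df_c, df_b = len(classes) - 1, len(bins) - 1
    df_i = df_c * df_b
    df_e = len(df) - len(classes) * len(bins)
    return {"class": (ss_class / df_c) / (ss_err / df_e),
            "bin": (ss_bin / df_b) / (ss_err / df_e),
            "interaction": (ss_int / df_i) / (ss_err / df_e)}


class TestTwoWayAnova:
    def test_identical_observations_give_zero_F(self):
        df = _balanced_table(np.random.default_rng(0))
        df["value"] = 7.3
        res = two_way_anova(df)
        for eff in ("class", "bin", "interaction"):
            assert res.F(eff) == 0.0
            assert res.p(eff) == 1.0

    def test_class_label_swap_symmetry(self, rng):
        df = _balanced_table(rng, effect=1.0)
        res1 = two_way_anova(df)
        df2 = df.copy()
        df2["cls"] = df2["cls"].map({"L": "R", "R": "L"})
        res2 = two_way_anova(df2)
        for eff in ("class", "bin", "interaction"):
            assert res1.F(eff) == pytest.approx(res2.F(eff), abs=1e-10)

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(5):
            df = _balanced_table(rng, n_per_cell=5, effect=0.6)
            res = two_way_anova(df)
            oracle = _anova_oracle(df)
            for eff in ("class", "bin", "interaction"):
                assert res.F(eff) == pytest.approx(oracle[eff], abs=1e-10)

    def test_empty_cell_named_in_error(self, rng):
        df = _balanced_table(rng)
        df = df[~((df.cls == "R") & (df.bin == 3))]
        with pytest.raises(ValueError, match="class=R, bin=3"):
            two_way_anova(df)


class TestPairedTTests:
    def test_corrected_alpha_families(self, rng):
        A = rng.normal(0, 1, size=(10, 7))
        B = rng.normal(0, 1, size=(10, 7))
        out = paired_ttests_by_bin(A, B)
        assert out.corrected_alpha == pytest.approx(0.05 / 7)
        out2 = paired_ttests_by_bin(A[:, :2], B[:, :2])
        assert out2.corrected_alpha == pytest.approx(0.025)

    def test_matches_textbook_oracle(self, rng):
        A = rng.normal(1.0, 1.0, size=(12, 7))
        B = rng.normal(0.0, 1.0, size=(12, 7))
        out = paired_ttests_by_bin(A, B)
        from scipy.stats import t as tdist
        for b in range(7):
            d = A[:, b] - B[:, b]
            t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p_oracle = 2 * tdist.sf(abs(t_oracle), len(d) - 1)
            row = out.table.iloc[b]
            assert row["t"] == pytest.approx(t_oracle, abs=1e-10)
            assert row["p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_zero_variance_bin_flagged_untestable(self, rng):
        A = rng.normal(0, 1, size=(6, 3))
        B = A.copy()
        B[:, 1] = A[:, 1] - 2.0   # constant difference -> zero variance
        B[:, 0] = rng.normal(0, 1, 6)
        B[:, 2] = rng.normal(0, 1, 6)
        out = paired_ttests_by_bin(A, B)
        assert not out.table.iloc[1]["testable"]
        assert not out.table.iloc[1]["significant"]

    def test_bonferroni_monotone_in_family_alpha(self, rng):
        A = rng.normal(0.8, 1.0, size=(15, 7))
        B = rng.normal(0.0, 1.0, size=(15, 7))
        loose = paired_ttests_by_bin(A, B, family_alpha=0.05)
        tight = paired_ttests_by_bin(A, B, family_alpha=0.01)
        assert set(tight.table[tight.table.significant]["bin"]) <= \
            set(loose.table[loose.table.significant]["bin"])


class TestEffectSizes:
    def test_cohens_d_examples(self, rng):
        a = rng.normal(0, 1, 50)
        assert cohens_d(a, a.copy()) == pytest.approx(0.0)
        b = np.array([1.0, 2.0, 3.0, 4.0])
        shifted = b + b.std(ddof=1)   # equal group sds -> pooled = group sd
        assert cohens_d(shifted, b) == pytest.approx(1.0)

    def test_cohens_d_formula_oracle(self, rng):
        a, b = rng.normal(1, 2, 20), rng.normal(0, 1.5, 30)
        pooled = np.sqrt((19 * a.var(ddof=1) + 29 * b.var(ddof=1)) / 48)
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled,
                                               abs=1e-12)

    def test_cohens_d_degenerate(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_pearson_exact_lines(self):
        u = np.array([1.0, 2.0, 5.0, 9.0])
        r, _ = pearson_r(u, 2 * u + 3)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(u, -u)
        assert r == pytest.approx(-1.0)

    def test_pearson_covariance_oracle(self, rng):
        u, v = rng.normal(size=40), rng.normal(size=40)
        r, _ = pearson_r(u, v)
        oracle = (((u - u.mean()) * (v - v.mean())).sum()
                  / np.sqrt(((u - u.mean()) ** 2).sum()
                            * ((v - v.mean()) ** 2).sum()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_pearson_degenerate(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _unit_cohort(gain, n_sessions, seed, rate_class="any", bins=(2,)):
    mods = () if gain is None else (
        ModulationSpec(phase="choice", trajectory="L", bins=bins, gain=gain,
                       fraction=1.0, rate_class=rate_class),)
    cfg = StudyConfig(n_sessions=n_sessions, n_animals=1,
                      neurons_per_session=4, modulations=mods)
    return generate_cohort(cfg, seed=seed)


def _poisson_unit_table(rng, baseline, gain, n_per_traj=8, occ=0.605,
                        bins_mod=(2,)):
    rows = []
    for traj in ("L", "R"):
        for i in range(n_per_traj):
            for b in range(1, 8):
                g = gain if (traj == "L" and b in bins_mod) else 1.0
                rows.append((rng.poisson(baseline * g * occ) / occ, traj,
                             b, i))
    return pd.DataFrame(rows, columns=["rate", "trajectory", "bin",
                                       "trial_index"])


class TestTrajectoryModulation:
    def test_strong_modulation_detected_with_power(self):
        # 3x gain at bin 2 in a 4 Hz unit is detectable in nearly every
        # 18-trial session (power measured > 0.9 by this same oracle)
        rng = np.random.default_rng(71)
        hits = sum(classify_trajectory_modulated(
            _poisson_unit_table(rng, 4.0, 3.0))["modulated"]
            for _ in range(100))
        assert hits / 100 > 0.9

    def test_twofold_gain_detected_above_chance_rate(self):
        # the study-analog 2x gain at the study's rate regime: detection is
        # partial (single-bin effect, ~1 spike per bin) but far above the
        # type-I rate of the same pipeline
        study = _unit_cohort(2.0, n_sessions=25, seed=61)
        hits = total = 0
        for s in study.sessions:
            tensor = compute_rate_tensor(s)
            for n in s.neurons:
                rep = classify_trajectory_modulated(
                    unit_trajectory_table(tensor, n.neuron_id, "choice"))
                if rep["testable"]:
                    total += 1
                    hits += rep["modulated"]
        assert total >= 90
        assert hits / total > 0.2

    def test_type_one_error_calibrated_on_flat_units(self):
        study = _unit_cohort(None, n_sessions=50, seed=62)
        hits = total = 0
        for s in study.sessions:
            tensor = compute_rate_tensor(s)
            for n in s.neurons:
                rep = classify_trajectory_modulated(
                    unit_trajectory_table(tensor, n.neuron_id, "choice"))
                if rep["testable"]:
                    total += 1
                    hits += rep["modulated"]
        assert total >= 180
        # joint criterion (main effect OR interaction) at nominal 0.05 each
        assert hits / total <= 0.10

    def test_constant_rate_unit_untestable(self):
        table = pd.DataFrame({
            "rate": 0.0,
            "trajectory": ["L", "R"] * 14,
            "bin": list(range(1, 8)) * 4,
            "trial_index": np.repeat(np.arange(1, 5), 7)})
        with pytest.warns(UserWarning):
            rep = classify_trajectory_modulated(table)
        assert not rep["testable"]
        assert not rep["modulated"]

    def test_followup_alpha_is_half_of_family(self):
        study = _unit_cohort(3.0, n_sessions=3, seed=63)
        s = study.sessions[0]
        tensor = compute_rate_tensor(s)
        rep = classify_trajectory_modulated(
            unit_trajectory_table(tensor, s.neurons[0].neuron_id, "choice"),
            followup_bins=(2, 7), followup_family_alpha=0.05)
        assert set(rep["followup"]) == {2, 7}
        # significance calls are made against 0.05 / 2 = 0.025
        for b, f in rep["followup"].items():
            if f["testable"]:
                assert f["significant"] == (f["p"] < 0.025)


class TestModulationProportions:
    def test_arithmetic_and_partition(self):
        reports = {f"u{i}": {"testable": True, "modulated": i < 31,
                             "followup": {2: {"significant": i < 18},
                                          7: {"significant": i < 7}}}
                   for i in range(100)}
        rate_class = {f"u{i}": "high" for i in range(100)}
        out = modulation_proportions(reports, rate_class)
        high = out[out.rate_class == "high"].iloc[0]
        assert high["pct_modulated"] == pytest.approx(31.0)
        assert high["pct_bin2"] == pytest.approx(18.0)
        assert high["pct_bin7"] == pytest.approx(7.0)
        low = out[out.rate_class == "low"].iloc[0]
        assert low["n_units"] == 0 and np.isnan(low["pct_modulated"])

    def test_zero_modulated_is_zero_pct(self):
        reports = {"a": {"testable": True, "modulated": False, "followup": {}}}
        out = modulation_proportions(reports, {"a": "low"})
        assert out[out.rate_class == "low"]["pct_modulated"].iloc[0] == 0.0


class TestSessionBehaviorTable:
    def test_sessions_by_bins_layout(self, small_cohort):
        from dnmp.binning import compute_behavior_tensors
        bts = [compute_behavior_tensors(s) for s in small_cohort.sessions]
        tab = session_behavior_table(bts, "lateral_cm", phase="choice",
                                     split_by="trajectory")
        assert set(tab["cls"]) == {"L", "R"}
        assert set(tab["bin"]) == set(range(1, 8))
        assert tab["session"].nunique() == len(small_cohort.sessions)
        # divergence at the T-junction appears in the session means
        piv = tab.pivot_table(index="session", columns=["cls", "bin"],
                              values="value")
        assert (piv[("R", 7)] - piv[("L", 7)]).mean() > 2.0
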