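"""Behavioural and single-unit statistics.

Two-way fixed-effects ANOVA (class x stem bin), Bonferroni-corrected paired
t-tests per bin with Cohen's d, Pearson correlation, and the single-unit
trajectory-modulation classification with group proportions.  Standard model
fits go through statsmodels/scipy; this module owns only the study-specific
decision rules (modulation criteria, correction families, pairing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "AnovaResult",
    "BinwiseTests",
    "two_way_anova",
    "paired_ttests_by_bin",
    "cohens_d",
    "pearson_r",
    "classify_trajectory_modulated",
    "modulation_proportions",
    "unit_trajectory_table",
    "session_behavior_table",
]


@dataclass(frozen=True)
class AnovaResult:
    """F, degrees of freedom and p for class, bin and interaction effects."""

    effects: dict  # name -> dict(F, df_num, df_den, p)

    def F(self, effect: str) -> float:
        return self.effects[effect]["F"]

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects).T


def two_way_anova(data: pd.DataFrame, value: str = "value",
                  class_col: str = "cls", bin_col: str = "bin") -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    Expects long-format data with one row per observation.  Balanced designs
    give the classical sums-of-squares decomposition; Type II is used, which
    coincides with it when the design is balanced and stays well-defined
    under mild imbalance.  An empty cell is an error naming the cell.  If
    every observation is identical the F statistics are defined as 0
    (no variance to apportion) with p = 1.
    """
    df = data[[value, class_col, bin_col]].copy()
    df.columns = ["value", "cls", "bin"]
    counts = df.groupby(["cls", "bin"], observed=True).size()
    classes = df["cls"].unique()
    bins = df["bin"].unique()
    for c in classes:
        for b in bins:
            if (c, b) not in counts.index or counts.loc[(c, b)] < 1:
                raise ValueError(f"empty cell: class={c}, bin={b}")
    if counts.min() < 2:
        raise ValueError("need >= 2 observations per cell")

    names = {"C(cls)": "class", "C(bin)": "bin", "C(cls):C(bin)": "interaction"}
    if np.ptp(df["value"].to_numpy()) == 0:
        n = len(df)
        a, b = len(classes), len(bins)
        dfs = {"class": a - 1, "bin": b - 1, "interaction": (a - 1) * (b - 1)}
        df_res = n - a * b
        return AnovaResult({k: {"F": 0.0, "df_num": v, "df_den": df_res, "p": 1.0}
                            for k, v in dfs.items()})

    fit = ols("value ~ C(cls) * C(bin)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    df_res = float(table.loc["Residual", "df"])
    effects = {}
    for key, name in names.items():
        row = table.loc[key]
        effects[name] = {"F": float(row["F"]), "df_num": float(row["df"]),
                         "df_den": df_res, "p": float(row["PR(>F)"])}
    return AnovaResult(effects)


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference with the classical pooled sd (n−1 weights)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def pearson_r(u, v) -> tuple[float, float]:
    """Sample Pearson correlation with its two-tailed p (t transformation)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) != len(v) or len(u) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if u.std() == 0 or v.std() == 0:
        raise ValueError("constant vector has no defined correlation")
    r, p = sps.pearsonr(u, v)
    return float(r), float(p)


@dataclass
class BinwiseTests:
    """Paired t per bin under a Bonferroni family correction."""

    table: pd.DataFrame          # bin, t, df, p, d, significant, testable
    family_alpha: float
    corrected_alpha: float


def paired_ttests_by_bin(values_a: np.ndarray, values_b: np.ndarray,
                         family_alpha: float = 0.05) -> BinwiseTests:
    """Follow-up paired t-tests, one per stem bin, Bonferroni corrected.

    ``values_a``/``values_b`` are (n_pairs, n_bins) arrays aligned by pair
    (e.g. session means per class).  A bin whose paired differences have
    zero variance is flagged untestable rather than silently significant.
    Cohen's d (pooled) accompanies every testable bin.
    """
    A = np.asarray(values_a, dtype=float)
    B = np.asarray(values_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("paired arrays must share shape (n_pairs, n_bins)")
    if A.shape[0] < 2:
        raise ValueError("need >= 2 pairs per bin")
    n_pairs, n_bins = A.shape
    corrected = family_alpha / n_bins
    rows = []
    for b in range(n_bins):
        a_col, b_col = A[:, b], B[:, b]
        keep = ~(np.isnan(a_col) | np.isnan(b_col))
        a_col, b_col = a_col[keep], b_col[keep]
        diff = a_col - b_col
        if len(diff) < 2 or np.allclose(diff.std(ddof=1), 0):
            rows.append((b + 1, np.nan, len(diff) - 1, np.nan, np.nan,
                         False, False))
            continue
        t, p = sps.ttest_rel(a_col, b_col)
        try:
            d = cohens_d(a_col, b_col)
        except ValueError:
            d = np.nan
        rows.append((b + 1, float(t), len(diff) - 1, float(p), d,
                     bool(p < corrected), True))
    table = pd.DataFrame(rows, columns=["bin", "t", "df", "p", "cohens_d",
                                        "significant", "testable"])
    return BinwiseTests(table, family_alpha, corrected)


# ---------------------------------------------------------------------------
# single-unit trajectory modulation

def unit_trajectory_table(tensor, neuron_id: str, phase: str = "choice",
                          correct_only: bool = True) -> pd.DataFrame:
    """Long-format per-trial rates of one unit: rate, trajectory, bin."""
    j = tensor.neuron_ids.index(neuron_id)
    m = tensor.meta
    sel = (m["phase"] == phase).to_numpy() & m["valid"].to_numpy()
    if correct_only:
        sel &= m["correct"].to_numpy().astype(bool)
    rows = []
    for i in np.flatnonzero(sel):
        traj = m["trajectory"].iloc[i]
        for b in range(tensor.n_bins):
            rows.append((tensor.rates[i, j, b], traj, b + 1,
                         int(m["trial_index"].iloc[i])))
    return pd.DataFrame(rows, columns=["rate", "trajectory", "bin", "trial_index"])


def classify_trajectory_modulated(unit_table: pd.DataFrame,
                                  followup_bins=(2, 7),
                                  followup_family_alpha: float = 0.05,
                                  alpha: float = 0.05) -> dict:
    """Trajectory-modulation call for a single unit.

    A unit is modulated when the two-way ANOVA (trajectory x stem bin) on
    its per-trial rates yields a trajectory main effect or an interaction at
    ``alpha``.  Follow-up t-tests at the designated bins use a corrected
    alpha of ``followup_family_alpha / len(followup_bins)``; the i-th left
    trial is paired with the i-th right trial (no natural pairing exists at
    the unit level).  A rate-constant unit is untestable.
    """
    out = {"testable": True, "modulated": False,
           "p_trajectory": np.nan, "p_interaction": np.nan,
           "followup": {}}
    if np.ptp(unit_table["rate"].to_numpy()) == 0:
        warnings.warn("unit with constant rate is untestable; excluded",
                      stacklevel=2)
        out["testable"] = False
        return out
    try:
        res = two_way_anova(unit_table, value="rate", class_col="trajectory",
                            bin_col="bin")
    except ValueError as err:
        warnings.warn(f"unit untestable: {err}", stacklevel=2)
        out["testable"] = False
        return out
    out["p_trajectory"] = res.p("class")
    out["p_interaction"] = res.p("interaction")
    out["modulated"] = (res.p("class") < alpha) or (res.p("interaction") < alpha)

    corrected = followup_family_alpha / len(followup_bins)
    for b in followup_bins:
        sub = unit_table[unit_table["bin"] == b]
        left = sub[sub.trajectory == "L"].sort_values("trial_index")["rate"].to_numpy()
        right = sub[sub.trajectory == "R"].sort_values("trial_index")["rate"].to_numpy()
        k = min(len(left), len(right))
        if k < 2 or np.allclose((left[:k] - right[:k]).std(ddof=1), 0):
            out["followup"][b] = {"t": np.nan, "p": np.nan,
                                  "significant": False, "testable": False}
            continue
        t, p = sps.ttest_rel(left[:k], right[:k])
        out["followup"][b] = {"t": float(t), "p": float(p),
                              "significant": bool(p < corrected),
                              "testable": True}
    return out


def modulation_proportions(reports: dict, rate_class_of: dict,
                           followup_bins=(2, 7)) -> pd.DataFrame:
    """Percent of trajectory-modulated units per rate class.

    ``reports`` maps unit id -> output of
    :func:`classify_trajectory_modulated`; ``rate_class_of`` maps unit id ->
    "high"/"low".  Untestable units are excluded from denominators; an empty
    class reports NaN (undefined), not 0.
    """
    rows = []
    for cls in ("high", "low"):
        ids = [u for u, c in rate_class_of.items()
               if c == cls and u in reports and reports[u]["testable"]]
        n = len(ids)
        if n == 0:
            row = {"rate_class": cls, "n_units": 0, "pct_modulated": np.nan}
            for b in followup_bins:
                row[f"pct_bin{b}"] = np.nan
            rows.append(row)
            continue
        n_mod = sum(reports[u]["modulated"] for u in ids)
        row = {"rate_class": cls, "n_units": n,
               "pct_modulated": 100.0 * n_mod / n}
        for b in followup_bins:
            hits = sum(reports[u]["followup"].get(b, {}).get("significant", False)
                       for u in ids)
            row[f"pct_bin{b}"] = 100.0 * hits / n
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# session-level behaviour tables

def session_behavior_table(behavior_tensors, measure: str = "lateral_cm",
                           phase: str | None = None,
                           split_by: str = "trajectory",
                           correct_only: bool = True) -> pd.DataFrame:
    """Session x bin x class means of a behavioural measure.

    The session is the unit of observation: per session and class level,
    traversal values are averaged within each bin.  ``split_by`` is either
    "trajectory" (L vs R, optionally within ``phase``) or "phase"
    (sample vs choice).
    """
    rows = []
    for bt in behavior_tensors:
        arr = getattr(bt, measure)
        m = bt.meta
        sel = m["valid"].to_numpy().astype(bool)
        if correct_only:
            sel &= m["correct"].to_numpy().astype(bool)
        if phase is not None:
            sel &= (m["phase"] == phase).to_numpy()
        levels = m[split_by].unique()
        for level in levels:
            lsel = sel & (m[split_by] == level).to_numpy()
            if not lsel.any():
                continue
            means = np.nanmean(arr[lsel], axis=0)
            for b, v in enumerate(means):
                rows.append((bt.session_id, level, b + 1, v))
    return pd.DataFrame(rows, columns=["session", "cls", "bin", "value"])
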