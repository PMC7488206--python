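"""Neuron-adding curves and log-linear forecasting of decoding accuracy.

How many units does an ensemble need before a decoder clears chance?  The
neuron-adding curve estimates mean leave-one-out accuracy as a function of
ensemble size by drawing random unit subsets (in increments of ``step``,
``n_subsets_per_size`` independent subsets per size, one fresh
pseudo-population draw per subset).  The curve is then modelled in decibel
style: both size and accuracy (%) are transformed as v' = 10·log10(v), an
ordinary least-squares line y' = a + b·x' is fit, and predictions are
mapped back through the anti-log,

    accuracy(N) = min(100, 10^((a + b·10·log10 N) / 10)) = min(100, 10^(a/10) · N^b)

i.e. a power law in the raw variables.  Fitted and forecast sizes are tested
against the full-population shuffled distribution with a z-test; the
minimal significant ensemble size is the smallest size whose (mean or
predicted) accuracy is significantly above the null mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .binning import RateTensor
from .decoding import (NullDistribution, build_pseudo_population,
                       loocv_accuracy, minmax_scale, standard_problem,
                       z_test_vs_null)

__all__ = [
    "ScalingCurve",
    "PowerLawModel",
    "PowerLawResults",
    "neuron_adding_curve",
    "log_transform_curve",
    "fit_power_law",
    "minimal_significant_size",
]


@dataclass
class ScalingCurve:
    """Mean/sd decoding accuracy per ensemble size."""

    sizes: np.ndarray
    mean_accuracy: np.ndarray   # percent
    sd_accuracy: np.ndarray
    n_subsets: int
    problem: str = ""
    bin: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.sizes) > 0):
            raise ValueError("sizes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "problem": self.problem, "bin": self.bin, "size": self.sizes,
            "mean_acc": self.mean_accuracy, "sd_acc": self.sd_accuracy,
            "n_subsets": self.n_subsets})

    def plot(self, ax=None, results: "PowerLawResults | None" = None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.sizes, self.mean_accuracy, "o", color="gray",
                label="mean accuracy")
        if results is not None:
            grid = np.linspace(self.sizes[0], self.sizes[-1], 200)
            ax.plot(grid, results.predict(grid), "r-", label="power-law fit")
        ax.set_xlabel("ensemble size (neurons)")
        ax.set_ylabel("classification accuracy (%)")
        ax.legend()
        return ax


def neuron_adding_curve(tensors, problem, bin_1based: int,
                        scaling_config, seed: int = 0, C: float = 1.0,
                        scale_01: bool = False, sizes=None,
                        neuron_ids=None) -> ScalingCurve:
    """Mean LOOCV accuracy over random unit subsets of increasing size.

    Per size, ``n_subsets_per_size`` subsets are drawn without replacement
    (independently across sizes — subsets are not nested), each scored on
    one fresh pseudo-population draw.  Deterministic under ``seed``.
    """
    if isinstance(tensors, RateTensor):
        tensors = [tensors]
    problem = standard_problem(problem) if isinstance(problem, str) else problem
    pool = [nid for t in tensors for nid in t.neuron_ids]
    if neuron_ids is not None:
        wanted = set(neuron_ids)
        pool = [nid for nid in pool if nid in wanted]
    pool = np.array(pool)
    max_size = scaling_config.max_size or len(pool)
    if max_size > len(pool):
        raise ValueError(f"max_size {max_size} exceeds pool of {len(pool)}")
    if sizes is None:
        sizes = np.arange(scaling_config.step, max_size + 1, scaling_config.step)
    sizes = np.asarray(sizes, dtype=int)
    if sizes.max() > len(pool):
        raise ValueError("requested size exceeds the neuron pool")

    rng = np.random.default_rng(seed)
    means = np.empty(len(sizes))
    sds = np.empty(len(sizes))
    for si, s in enumerate(sizes):
        accs = np.empty(scaling_config.n_subsets_per_size)
        for k in range(scaling_config.n_subsets_per_size):
            subset = rng.choice(pool, size=s, replace=False)
            pp = build_pseudo_population(tensors, problem, bin_1based, rng,
                                         neuron_ids=subset)
            X = minmax_scale(pp.X) if scale_01 else pp.X
            accs[k] = loocv_accuracy(X, pp.y, C)
        means[si] = accs.mean()
        sds[si] = accs.std(ddof=0)
    return ScalingCurve(sizes, means, sds, scaling_config.n_subsets_per_size,
                        problem=problem.name, bin=bin_1based)


def log_transform_curve(sizes, accuracies):
    """Decibel-style transform: v' = 10 · log10(v), elementwise, both vectors."""
    sizes = np.asarray(sizes, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if np.any(sizes <= 0) or np.any(accuracies <= 0):
        raise ValueError("log transform requires strictly positive values")
    return 10.0 * np.log10(sizes), 10.0 * np.log10(accuracies)


class PowerLawModel:
    """OLS in 10·log10 space relating ensemble size to accuracy.

    ``PowerLawModel(sizes, accuracies).fit()`` returns a
    :class:`PowerLawResults`; ``PowerLawModel.from_curve(curve)`` builds the
    model from a :class:`ScalingCurve`.
    """

    def __init__(self, sizes, accuracies):
        self.sizes = np.asarray(sizes, dtype=float)
        self.accuracies = np.asarray(accuracies, dtype=float)
        if len(self.sizes) < 3:
            raise ValueError("need at least 3 points to fit")
        if np.allclose(self.sizes, self.sizes[0]):
            raise ValueError("degenerate predictor: all sizes equal")

    @classmethod
    def from_curve(cls, curve: ScalingCurve) -> "PowerLawModel":
        return cls(curve.sizes, curve.mean_accuracy)

    def fit(self) -> "PowerLawResults":
        xp, yp = log_transform_curve(self.sizes, self.accuracies)
        ols = sm.OLS(yp, sm.add_constant(xp)).fit()
        return PowerLawResults(self, ols)


class PowerLawResults:
    """Fitted log-linear accuracy model with forecasting."""

    def __init__(self, model: PowerLawModel, ols_results):
        self.model = model
        self._ols = ols_results
        self.intercept_a = float(ols_results.params[0])
        self.slope_b = float(ols_results.params[1])
        self.sse = float(ols_results.ssr)
        self.adj_r2 = float(ols_results.rsquared_adj)

    def predict(self, sizes) -> np.ndarray:
        """Anti-log predictions (%), capped at 100."""
        sizes = np.atleast_1d(np.asarray(sizes, dtype=float))
        if np.any(sizes <= 0):
            raise ValueError("sizes must be positive")
        yp = self.intercept_a + self.slope_b * 10.0 * np.log10(sizes)
        return np.minimum(100.0, 10.0 ** (yp / 10.0))

    def forecast(self, sizes, null: NullDistribution,
                 alpha: float = 0.05) -> pd.DataFrame:
        """Predicted accuracy per size with z/p against a shuffled null."""
        sizes = np.atleast_1d(np.asarray(sizes))
        pred = self.predict(sizes)
        rows = []
        for s, a in zip(sizes, pred):
            z, p = z_test_vs_null(float(a), null)
            rows.append((int(s), float(a), z, p,
                         (p < alpha) and (a > null.mean)))
        return pd.DataFrame(rows, columns=["size", "predicted_acc", "z", "p",
                                           "significant"])

    def summary(self) -> str:
        return (f"accuracy' = {self.intercept_a:.4f} + {self.slope_b:.4f} * size'"
                f"   (v' = 10*log10 v)\n"
                f"SSE = {self.sse:.4g}, adj R^2 = {self.adj_r2:.4f}\n"
                f"equivalent power law: accuracy = "
                f"{10 ** (self.intercept_a / 10):.3f} * size^{self.slope_b:.3f}")


def fit_power_law(sizes, accuracies) -> PowerLawResults:
    """Functional wrapper around :class:`PowerLawModel`."""
    return PowerLawModel(sizes, accuracies).fit()


def minimal_significant_size(sizes, accuracies, null: NullDistribution,
                             alpha: float = 0.05) -> int | None:
    """Smallest ensemble size whose accuracy clears the shuffled distribution.

    Accepts either empirical curve means or model predictions; returns None
    if no size is significantly above the null mean at ``alpha`` (two-tailed).
    """
    sizes = np.asarray(sizes)
    accuracies = np.asarray(accuracies, dtype=float)
    if not np.all(np.diff(sizes) > 0):
        raise ValueError("sizes must be ascending")
    for s, a in zip(sizes, accuracies):
        z, p = z_test_vs_null(float(a), null)
        if p < alpha and a > null.mean:
            return int(s)
    return None
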