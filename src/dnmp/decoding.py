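"""Pseudo-simultaneous permutation-style linear decoding with shuffled nulls.

The decoder asks whether a population of units — pooled across sessions and
animals — carries information about a binary trial class (task phase,
trajectory, or a phase x trajectory pair) in each stem bin.  Because units
were not recorded simultaneously, population vectors are assembled
*pseudo-simultaneously*: for every unit independently, ``n_per_class``
correct trials of each class are drawn at random without replacement from
that unit's own session, and the drawn rates form one class-balanced
2n x M matrix.  A soft-margin linear SVM (hinge loss, C = 1, bias term, no
internal standardization) is scored by leave-one-out cross-validation, the
draw is repeated ``n_iterations`` times, and chance is estimated by
re-scoring the final iteration's matrix under ``n_shuffles`` random label
permutations.  Significance is a z-test of the true-label mean against the
shuffled distribution.

The model/results split follows the statsmodels convention:
``PopulationDecoder(tensors, problem, config).fit(seed)`` returns a
:class:`DecodingResults` carrying per-bin accuracies, null moments, z, p and
the fraction of individually significant iterations, with ``summary()`` and
``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.svm import SVC

from .binning import RateTensor

__all__ = [
    "DecodingProblem",
    "STANDARD_PROBLEMS",
    "standard_problem",
    "PseudoPopulation",
    "NullDistribution",
    "DecodingResults",
    "PopulationDecoder",
    "build_pseudo_population",
    "loocv_predictions",
    "loocv_accuracy",
    "minmax_scale",
    "shuffled_null",
    "z_test_vs_null",
    "significant_fraction",
    "classic_decode",
]


@dataclass(frozen=True)
class DecodingProblem:
    """A binary classification target over (phase, trajectory) traversals.

    ``class_pos`` / ``class_neg`` are the (phase, trajectory) combinations
    mapped to the +1 / −1 label; ``n_per_class`` is the number of trials
    drawn per unit and class (the least correct-trial count across the
    study's sessions: 15 for pooled task phase, 6 for any other class).
    """

    name: str
    class_pos: tuple[tuple[str, str], ...]
    class_neg: tuple[tuple[str, str], ...]
    n_per_class: int
    correct_only: bool = True

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if not self.class_pos or not self.class_neg:
            raise ValueError("both classes need at least one (phase, trajectory)")


def _combos(phase: str | None, trajectory: str | None):
    phases = [phase] if phase else ["sample", "choice"]
    trajs = [trajectory] if trajectory else ["L", "R"]
    return tuple((p, t) for p in phases for t in trajs)


STANDARD_PROBLEMS: dict[str, DecodingProblem] = {
    # sample (+1) vs choice (−1), trajectories pooled
    "task_phase": DecodingProblem("task_phase", _combos("sample", None),
                                  _combos("choice", None), 15),
    # left vs right within a phase
    "sample_traj": DecodingProblem("sample_traj", _combos("sample", "L"),
                                   _combos("sample", "R"), 6),
    "choice_traj": DecodingProblem("choice_traj", _combos("choice", "L"),
                                   _combos("choice", "R"), 6),
    # task-phase/trajectory pairs that co-occur on correct trials
    "pair_LsRc": DecodingProblem("pair_LsRc", _combos("sample", "L"),
                                 _combos("choice", "R"), 6),
    "pair_RsLc": DecodingProblem("pair_RsLc", _combos("sample", "R"),
                                 _combos("choice", "L"), 6),
}


def standard_problem(name: str) -> DecodingProblem:
    try:
        return STANDARD_PROBLEMS[name]
    except KeyError:
        raise KeyError(f"unknown problem {name!r}; choose from "
                       f"{sorted(STANDARD_PROBLEMS)}") from None


@dataclass
class PseudoPopulation:
    """One iteration's class-balanced rate matrix with full provenance."""

    X: np.ndarray                 # (2 * n_per_class, M)
    y: np.ndarray                 # +1 block then −1 block
    provenance: np.ndarray        # (2 * n_per_class, M) traversal row indices
    neuron_ids: list[str]


@dataclass
class NullDistribution:
    """Shuffled-label accuracies (%) approximating chance performance."""

    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=0))


# ---------------------------------------------------------------------------
# building blocks

def _eligible_rows(tensor: RateTensor, combos, correct_only: bool) -> np.ndarray:
    m = tensor.meta
    sel = np.zeros(len(m), dtype=bool)
    for phase, traj in combos:
        sel |= (m["phase"] == phase).to_numpy() & (m["trajectory"] == traj).to_numpy()
    if correct_only:
        sel &= m["correct"].to_numpy().astype(bool)
    sel &= m["valid"].to_numpy().astype(bool)
    return np.flatnonzero(sel)


def _column_index(tensors: list[RateTensor],
                  neuron_ids=None) -> list[tuple[int, int, str]]:
    """(tensor index, local column, neuron id) for every included unit."""
    wanted = None if neuron_ids is None else set(neuron_ids)
    cols = []
    for ti, t in enumerate(tensors):
        for j, nid in enumerate(t.neuron_ids):
            if wanted is None or nid in wanted:
                cols.append((ti, j, nid))
    if not cols:
        raise ValueError("no neurons selected")
    return cols


def build_pseudo_population(tensors: RateTensor | list[RateTensor],
                            problem: DecodingProblem,
                            bin_1based: int,
                            rng: np.random.Generator,
                            neuron_ids=None) -> PseudoPopulation:
    """Draw one pseudo-simultaneous population matrix for a stem bin.

    For each unit independently, ``n_per_class`` eligible trials per class
    are drawn without replacement from the unit's own session.  Row ``i`` of
    a class block holds each unit's i-th drawn rate; labels are the +1 block
    followed by the −1 block.
    """
    if isinstance(tensors, RateTensor):
        tensors = [tensors]
    cols = _column_index(tensors, neuron_ids)
    b = bin_1based - 1
    n = problem.n_per_class
    elig_cache: dict[tuple[int, int], np.ndarray] = {}
    short = []
    for ti, t in enumerate(tensors):
        for ci, combos in enumerate((problem.class_pos, problem.class_neg)):
            elig_cache[(ti, ci)] = _eligible_rows(t, combos, problem.correct_only)
    for ti, j, nid in cols:
        for ci in (0, 1):
            if len(elig_cache[(ti, ci)]) < n:
                short.append(nid)
                break
    if short:
        raise ValueError(
            f"{len(short)} neuron(s) lack {n} eligible trials per class: "
            f"{sorted(set(short))}")

    M = len(cols)
    X = np.empty((2 * n, M))
    prov = np.empty((2 * n, M), dtype=int)
    for c_out, (ti, j, nid) in enumerate(cols):
        for ci, offset in ((0, 0), (1, n)):
            rows = rng.choice(elig_cache[(ti, ci)], size=n, replace=False)
            X[offset:offset + n, c_out] = tensors[ti].rates[rows, j, b]
            prov[offset:offset + n, c_out] = rows
    y = np.concatenate([np.ones(n), -np.ones(n)])
    return PseudoPopulation(X, y, prov, [nid for _, _, nid in cols])


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Scale each column (unit) to [0, 1]; constant columns map to zeros."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    out = np.zeros_like(X)
    nz = rng_ > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / rng_[nz]
    return out


def loocv_predictions(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Leave-one-out predictions of a linear soft-margin SVM.

    Each row in turn is withheld, the classifier is refit on the rest, and
    the withheld row is predicted from the sign of the decision value
    (an exact zero predicts +1).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    n = len(y)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for r in range(n):
        mask[r] = False
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[mask], y[mask])
        d = float(clf.decision_function(X[r:r + 1])[0])
        preds[r] = 1.0 if d >= 0 else -1.0
        mask[r] = True
    return preds


def loocv_accuracy(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> float:
    """Leave-one-out accuracy in percent."""
    preds = loocv_predictions(X, y, C)
    return float(100.0 * np.mean(preds == np.asarray(y, dtype=float)))


def shuffled_null(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                  n_shuffles: int = 1000,
                  rng: np.random.Generator | None = None) -> NullDistribution:
    """Chance distribution: LOOCV accuracy under random label permutations.

    Labels are permuted uniformly on the fixed data matrix (class counts are
    preserved automatically), once per shuffle.
    """
    rng = rng or np.random.default_rng()
    accs = np.empty(n_shuffles)
    y = np.asarray(y, dtype=float)
    for s in range(n_shuffles):
        accs[s] = loocv_accuracy(X, rng.permutation(y), C)
    return NullDistribution(accs)


def z_test_vs_null(true_mean: float, null: NullDistribution) -> tuple[float, float]:
    """z and two-tailed p of a true-label mean accuracy against the null."""
    if null.sd <= 0:
        raise ValueError("degenerate null distribution (zero sd)")
    z = (true_mean - null.mean) / null.sd
    p = float(2.0 * norm.sf(abs(z)))
    return float(z), p


def significant_fraction(iteration_accuracies: np.ndarray,
                         null: NullDistribution,
                         alpha: float = 0.05,
                         two_tailed: bool = True) -> float:
    """Percent of iterations individually above chance (p < alpha, acc > null mean)."""
    if len(iteration_accuracies) == 0:
        raise ValueError("no iteration accuracies")
    if null.sd <= 0:
        raise ValueError("degenerate null distribution (zero sd)")
    acc = np.asarray(iteration_accuracies, dtype=float)
    z = (acc - null.mean) / null.sd
    p = 2.0 * norm.sf(np.abs(z)) if two_tailed else norm.sf(z)
    hits = (p < alpha) & (acc > null.mean)
    return float(100.0 * np.mean(hits))


# ---------------------------------------------------------------------------
# the model / results pair

class PopulationDecoder:
    """Permutation-style pseudo-simultaneous decoder over all stem bins.

    Parameters
    ----------
    tensors : RateTensor or list of RateTensor
        Per-session rate tensors (the pool to decode from).
    problem : DecodingProblem or str
        The binary target; a string is looked up in ``STANDARD_PROBLEMS``.
    config : DecoderConfig
        Iteration/shuffle counts, regularization and scaling switch.
    neuron_ids : optional iterable of str
        Restrict the population (e.g. the high-rate subset or one animal).
    """

    def __init__(self, tensors, problem, config, neuron_ids=None):
        from .config import DecoderConfig
        self.tensors = [tensors] if isinstance(tensors, RateTensor) else list(tensors)
        self.problem = standard_problem(problem) if isinstance(problem, str) else problem
        self.config = config if config is not None else DecoderConfig()
        self.neuron_ids = None if neuron_ids is None else list(neuron_ids)
        self.n_bins = self.tensors[0].n_bins

    def fit(self, seed: int = 0, bins=None) -> "DecodingResults":
        """Run the decoder; ``bins`` restricts to a subset of stem bins.

        Each bin consumes its own child seed by position, so the result for
        bin b is identical whether or not other bins are fitted.
        """
        cfg = self.config
        bin_seeds = np.random.SeedSequence(seed).spawn(self.n_bins)
        wanted = set(range(1, self.n_bins + 1)) if bins is None else set(bins)
        per_bin = []
        for b, ss in zip(range(1, self.n_bins + 1), bin_seeds):
            if b not in wanted:
                continue
            rng = np.random.default_rng(ss)
            accs = np.empty(cfg.n_iterations)
            final = None
            null_accs = [] if cfg.null_per_iteration else None
            for it in range(cfg.n_iterations):
                pp = build_pseudo_population(self.tensors, self.problem, b, rng,
                                             self.neuron_ids)
                X = minmax_scale(pp.X) if cfg.scale_01 else pp.X
                accs[it] = loocv_accuracy(X, pp.y, cfg.C)
                final = (X, pp.y)
                if cfg.null_per_iteration:
                    null_accs.append(loocv_accuracy(X, rng.permutation(pp.y), cfg.C))
            if cfg.null_per_iteration:
                null = NullDistribution(np.asarray(null_accs))
            else:
                null = shuffled_null(final[0], final[1], cfg.C, cfg.n_shuffles, rng)
            z, p = z_test_vs_null(float(accs.mean()), null)
            frac = significant_fraction(accs, null)
            per_bin.append({"bin": b, "accuracies": accs, "null": null,
                            "z": z, "p": p, "sig_fraction_pct": frac,
                            "final_X": final[0], "final_y": final[1]})
        return DecodingResults(self.problem, cfg, per_bin,
                               neuron_ids=self.neuron_ids, seed=seed)


@dataclass
class DecodingResults:
    """Per-bin outcome of a permutation-style decoding run."""

    problem: DecodingProblem
    config: object
    per_bin: list[dict]
    neuron_ids: list[str] | None = None
    seed: int = 0

    @property
    def bins(self) -> np.ndarray:
        return np.array([d["bin"] for d in self.per_bin])

    def _entry(self, bin_1based: int) -> dict:
        for d in self.per_bin:
            if d["bin"] == bin_1based:
                return d
        raise KeyError(f"bin {bin_1based} was not fitted")

    def iteration_accuracies(self, bin_1based: int) -> np.ndarray:
        return self._entry(bin_1based)["accuracies"]

    def null(self, bin_1based: int) -> NullDistribution:
        return self._entry(bin_1based)["null"]

    def final_matrix(self, bin_1based: int):
        d = self._entry(bin_1based)
        return d["final_X"], d["final_y"]

    def z(self, bin_1based: int) -> float:
        return self._entry(bin_1based)["z"]

    def p(self, bin_1based: int) -> float:
        return self._entry(bin_1based)["p"]

    def summary(self) -> pd.DataFrame:
        rows = []
        for d in self.per_bin:
            accs = d["accuracies"]
            rows.append((self.problem.name, d["bin"], accs.mean(),
                         accs.std(ddof=0), d["null"].mean, d["null"].sd,
                         d["z"], d["p"], d["sig_fraction_pct"]))
        return pd.DataFrame(rows, columns=[
            "problem", "bin", "mean_acc", "sd_acc", "null_mean", "null_sd",
            "z", "p", "sig_fraction"])

    def iterations_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.per_bin:
            for it, a in enumerate(d["accuracies"]):
                rows.append((self.problem.name, d["bin"], it, a))
        return pd.DataFrame(rows, columns=["problem", "bin", "iteration",
                                           "accuracy"])

    def plot(self, ax=None):
        """Mean ± sd accuracy per bin with the chance band."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        s = self.summary()
        ax.errorbar(s["bin"], s["mean_acc"], yerr=s["sd_acc"], fmt="o-",
                    label="true labels")
        ax.fill_between(s["bin"], s["null_mean"] - 2 * s["null_sd"],
                        s["null_mean"] + 2 * s["null_sd"], alpha=0.2,
                        label="shuffled ± 2 sd")
        ax.set_xlabel("stem bin")
        ax.set_ylabel("classification accuracy (%)")
        ax.set_title(self.problem.name)
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# classic fixed-trial variant

def classic_decode(tensors, problem, k_per_class: int = 6, C: float = 1.0,
                   n_shuffles: int = 1000, family_alpha: float = 0.05,
                   seed: int = 0, neuron_ids=None) -> pd.DataFrame:
    """Fixed-trial decoding: each unit contributes its first k eligible trials.

    One pseudo-population per bin (row i = every unit's i-th eligible trial
    in temporal order), a single leave-one-out accuracy, a shuffled null and
    a two-tailed z-test at the Bonferroni-corrected level
    ``family_alpha / n_bins``.
    """
    if isinstance(tensors, RateTensor):
        tensors = [tensors]
    problem = standard_problem(problem) if isinstance(problem, str) else problem
    cols = _column_index(tensors, neuron_ids)
    n_bins = tensors[0].n_bins
    rows_cache = {}
    for ti, t in enumerate(tensors):
        for ci, combos in enumerate((problem.class_pos, problem.class_neg)):
            elig = _eligible_rows(t, combos, problem.correct_only)
            if len(elig) < k_per_class:
                raise ValueError(
                    f"session {t.session_id} has only {len(elig)} eligible "
                    f"trials for class {ci}; needs {k_per_class}")
            rows_cache[(ti, ci)] = elig[:k_per_class]  # temporal order

    corrected_alpha = family_alpha / n_bins
    rng = np.random.default_rng(seed)
    out = []
    y = np.concatenate([np.ones(k_per_class), -np.ones(k_per_class)])
    for b in range(n_bins):
        X = np.empty((2 * k_per_class, len(cols)))
        for c_out, (ti, j, _) in enumerate(cols):
            X[:k_per_class, c_out] = tensors[ti].rates[rows_cache[(ti, 0)], j, b]
            X[k_per_class:, c_out] = tensors[ti].rates[rows_cache[(ti, 1)], j, b]
        acc = loocv_accuracy(X, y, C)
        null = shuffled_null(X, y, C, n_shuffles, rng)
        z, p = z_test_vs_null(acc, null)
        out.append((problem.name, b + 1, acc, null.mean, null.sd, z, p,
                    corrected_alpha, p < corrected_alpha))
    return pd.DataFrame(out, columns=[
        "problem", "bin", "accuracy", "null_mean", "null_sd", "z", "p",
        "corrected_alpha", "significant"])
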