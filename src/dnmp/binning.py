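"""Spatial binning of the maze stem and occupancy-normalized firing rates.

The stem of the T-maze is partitioned into seven equal-width bins; the last
bin is the T-junction, where trajectories diverge toward the goal arms.
Position samples are assigned to bins by a half-open convention (a boundary
point belongs to the downstream bin; the far stem end belongs to the last
bin), spikes are assigned to the position sample nearest in time, and the
firing rate of a neuron in a bin on one traversal is

    rate = (spikes assigned to the bin) / (occupancy seconds in the bin).

Behavioural covariates (lateral position, running speed, time spent) are
binned the same way so that decoding results can be compared against overt
behaviour bin by bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StemBinning",
    "RateTensor",
    "BehaviorTensor",
    "RateClassSplit",
    "make_stem_bins",
    "assign_bins",
    "compute_rate_tensor",
    "compute_behavior_tensors",
    "session_mean_rates",
    "split_by_rate",
    "stability_correlation",
]

N_BINS_DEFAULT = 7


@dataclass(frozen=True)
class StemBinning:
    """Equal-width partition of the stem; ``edges`` has ``n_bins + 1`` entries."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("edges must be a 1-d array of length >= 2")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def t_junction_bin(self) -> int:
        """1-based index of the final (T-junction) bin."""
        return self.n_bins

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


def make_stem_bins(stem_start_cm: float = 0.0, stem_end_cm: float = 127.0,
                   n_bins: int = N_BINS_DEFAULT) -> StemBinning:
    """Equal-width stem bins; bin ``n_bins`` isolates the T-junction."""
    if stem_end_cm <= stem_start_cm:
        raise ValueError("stem_end_cm must exceed stem_start_cm")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return StemBinning(np.linspace(stem_start_cm, stem_end_cm, n_bins + 1))


def assign_bins(x: np.ndarray, binning: StemBinning) -> np.ndarray:
    """Map stem positions to 0-based bin indices (−1 for off-stem samples).

    Boundary points go to the downstream (higher-index) bin; the final
    edge belongs to the last bin.
    """
    x = np.asarray(x, dtype=float)
    idx = np.searchsorted(binning.edges, x, side="right") - 1
    idx[x == binning.edges[-1]] = binning.n_bins - 1
    off = (x < binning.edges[0]) | (x > binning.edges[-1])
    idx[off] = -1
    return idx


@dataclass
class RateTensor:
    """Per-session firing rates: traversals x neurons x stem bins (Hz).

    ``meta`` carries one row per traversal (trial_index, phase, trajectory,
    correct, valid); ``valid`` is False for traversals with a zero-occupancy
    bin, which are excluded from per-bin analyses.
    """

    rates: np.ndarray          # (n_traversals, n_neurons, n_bins)
    occupancy: np.ndarray      # (n_traversals, n_bins) seconds
    meta: pd.DataFrame
    neuron_ids: list[str]
    session_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.rates.shape[0] != len(self.meta):
            raise ValueError("meta rows must match tensor traversal axis")
        if self.rates.shape[2] != self.occupancy.shape[1]:
            raise ValueError("rates and occupancy disagree on bin count")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: traversal metadata + neuron, bin, rate, occupancy."""
        n_trav, n_neur, n_bins = self.rates.shape
        rows = []
        for i in range(n_trav):
            m = self.meta.iloc[i]
            for j, nid in enumerate(self.neuron_ids):
                for b in range(n_bins):
                    rows.append((m.trial_index, m.phase, m.trajectory,
                                 bool(m.correct), nid, b + 1,
                                 self.rates[i, j, b], self.occupancy[i, b]))
        return pd.DataFrame(rows, columns=[
            "trial_index", "phase", "trajectory", "correct",
            "neuron", "bin", "rate_hz", "occupancy_s"])


@dataclass
class BehaviorTensor:
    """Binned behavioural covariates: traversals x bins."""

    lateral_cm: np.ndarray
    velocity_cm_s: np.ndarray
    time_spent_s: np.ndarray
    meta: pd.DataFrame
    session_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        n_trav, n_bins = self.lateral_cm.shape
        rows = []
        for i in range(n_trav):
            m = self.meta.iloc[i]
            for b in range(n_bins):
                rows.append((m.trial_index, m.phase, m.trajectory, bool(m.correct),
                             b + 1, self.lateral_cm[i, b],
                             self.velocity_cm_s[i, b], self.time_spent_s[i, b]))
        return pd.DataFrame(rows, columns=[
            "trial_index", "phase", "trajectory", "correct", "bin",
            "lateral_cm", "velocity_cm_s", "time_s"])


def _traversal_bins(trace: pd.DataFrame, binning: StemBinning,
                    sampling_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Bin index per trace sample and occupancy seconds per bin."""
    idx = assign_bins(trace["x"].to_numpy(), binning)
    occ = np.bincount(idx[idx >= 0], minlength=binning.n_bins) / sampling_hz
    return idx, occ


def compute_rate_tensor(session, binning: StemBinning | None = None) -> RateTensor:
    """Occupancy-normalized per-bin firing rates for every stem traversal.

    ``session`` provides ``traversals`` (each with trial_index, phase,
    trajectory, correct and a 30 Hz trace), ``spike_trains`` (absolute
    seconds) and ``task``.  Spikes are matched to the nearest trace sample
    in time; spikes farther than half a sample period from any sample of a
    traversal belong to no traversal.
    """
    if binning is None:
        binning = make_stem_bins(0.0, session.task.stem_length_cm)
    fs = session.task.sampling_hz
    dt = 1.0 / fs
    neuron_ids = list(session.spike_trains)
    n_trav = len(session.traversals)
    rates = np.zeros((n_trav, len(neuron_ids), binning.n_bins))
    occupancy = np.zeros((n_trav, binning.n_bins))
    valid = np.ones(n_trav, dtype=bool)
    meta_rows = []

    for i, trav in enumerate(session.traversals):
        trace = trav.trace
        t = trace["t"].to_numpy()
        idx, occ = _traversal_bins(trace, binning, fs)
        occupancy[i] = occ
        if np.any(occ <= 0):
            valid[i] = False
            warnings.warn(
                f"traversal trial={trav.trial_index} phase={trav.phase} has a "
                "zero-occupancy stem bin; excluded from per-bin analyses",
                stacklevel=2)
        t0, t_last = t[0], t[-1]
        for j, nid in enumerate(neuron_ids):
            s = session.spike_trains[nid]
            s = s[(s >= t0 - dt / 2) & (s < t_last + dt / 2)]
            if len(s):
                nearest = np.clip(np.round((s - t0) * fs).astype(int), 0, len(t) - 1)
                b = idx[nearest]
                counts = np.bincount(b[b >= 0], minlength=binning.n_bins)
            else:
                counts = np.zeros(binning.n_bins)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(occ > 0, counts / np.where(occ > 0, occ, 1.0), 0.0)
            rates[i, j] = r
        meta_rows.append((trav.trial_index, trav.phase, trav.trajectory,
                          trav.correct, valid[i]))

    meta = pd.DataFrame(meta_rows, columns=[
        "trial_index", "phase", "trajectory", "correct", "valid"])
    return RateTensor(rates, occupancy, meta, neuron_ids,
                      session_id=session.session_id, animal_id=session.animal_id)


def compute_behavior_tensors(session, binning: StemBinning | None = None) -> BehaviorTensor:
    """Binned lateral position, speed and time spent per traversal.

    Speed is the magnitude of the central-difference velocity of (x, y)
    (one-sided at the endpoints), averaged within each bin; no smoothing.
    """
    if binning is None:
        binning = make_stem_bins(0.0, session.task.stem_length_cm)
    fs = session.task.sampling_hz
    n_trav = len(session.traversals)
    nb = binning.n_bins
    lateral = np.full((n_trav, nb), np.nan)
    velocity = np.full((n_trav, nb), np.nan)
    time_spent = np.zeros((n_trav, nb))
    meta_rows = []

    for i, trav in enumerate(session.traversals):
        trace = trav.trace
        x = trace["x"].to_numpy()
        y = trace["y"].to_numpy()
        idx, occ = _traversal_bins(trace, binning, fs)
        time_spent[i] = occ
        speed = np.hypot(np.gradient(x, 1.0 / fs), np.gradient(y, 1.0 / fs))
        for b in range(nb):
            sel = idx == b
            if np.any(sel):
                lateral[i, b] = y[sel].mean()
                velocity[i, b] = speed[sel].mean()
        meta_rows.append((trav.trial_index, trav.phase, trav.trajectory,
                          trav.correct, bool(np.all(occ > 0))))

    meta = pd.DataFrame(meta_rows, columns=[
        "trial_index", "phase", "trajectory", "correct", "valid"])
    return BehaviorTensor(lateral, velocity, time_spent, meta,
                          session_id=session.session_id)


@dataclass(frozen=True)
class RateClassSplit:
    """Partition of neurons into high- and low-rate classes."""

    threshold_hz: float
    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]
    session_mean_rates: dict[str, float] = field(default_factory=dict)
    median_rate_hz: float = float("nan")

    def rate_class(self, neuron_id: str) -> str:
        return "high" if neuron_id in set(self.high_ids) else "low"


def session_mean_rates(session) -> dict[str, float]:
    """Session-averaged firing rate per neuron: total spikes / session duration."""
    T = session.duration_s
    return {nid: len(s) / T for nid, s in session.spike_trains.items()}


def split_by_rate(sessions, threshold_hz: float = 2.0) -> RateClassSplit:
    """Split neurons into high (session mean strictly above threshold) vs low.

    Accepts a single session or an iterable of sessions; the mean for each
    neuron is computed within its own session.
    """
    if hasattr(sessions, "spike_trains"):
        sessions = [sessions]
    means: dict[str, float] = {}
    for s in sessions:
        means.update(session_mean_rates(s))
    if not means:
        raise ValueError("no neurons to split")
    high = tuple(n for n, r in means.items() if r > threshold_hz)
    low = tuple(n for n, r in means.items() if r <= threshold_hz)
    return RateClassSplit(threshold_hz, high, low, means,
                          median_rate_hz=float(np.median(list(means.values()))))


def stability_correlation(peak_amplitudes: dict[str, tuple[np.ndarray, np.ndarray]],
                          session_duration_s: float,
                          window_s: float = 600.0):
    """Recording-stability screen: correlate early vs late waveform heights.

    ``peak_amplitudes`` maps cluster id -> (spike times, peak amplitudes).
    For each cluster the mean peak amplitude over the first ``window_s``
    seconds is compared with the mean over the last ``window_s`` seconds;
    the Pearson r across clusters is returned together with the per-cluster
    means.  Clusters silent in either window are dropped with a warning.
    """
    first, last, kept = [], [], []
    for cid, (t, a) in peak_amplitudes.items():
        t = np.asarray(t, float)
        a = np.asarray(a, float)
        sel_first = t < window_s
        sel_last = t >= session_duration_s - window_s
        if not sel_first.any() or not sel_last.any():
            warnings.warn(f"cluster {cid} silent in a stability window; excluded",
                          stacklevel=2)
            continue
        first.append(a[sel_first].mean())
        last.append(a[sel_last].mean())
        kept.append(cid)
    if len(kept) < 2:
        raise ValueError("need >= 2 clusters with spikes in both windows")
    r, _ = sps.pearsonr(first, last)
    means = pd.DataFrame({"cluster": kept, "first_mean": first, "last_mean": last})
    return float(r), means
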