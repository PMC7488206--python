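"""Synthetic delayed non-match to position (DNMP) studies.

Generates whole cohorts — behaviour, position tracking and spiking — with
the statistical structure the downstream analyses assume:

* per-session trial sequences that are balanced left/right with no more
  than ``max_run`` identical forced turns in a row;
* paired sample/choice stem traversals at 30 Hz, with a logistic lateral
  divergence toward the chosen goal arm near the T-junction;
* lognormal baseline firing rates calibrated so that roughly 56% of units
  sit below 2 Hz (median ≈ 1.86 Hz);
* multiplicative trajectory/phase gain modulations planted in configurable
  stem bins and rate classes, with Poisson spike counts per bin.

Every unit fires background spikes at its baseline rate throughout the
session (traversals, delay and inter-trial intervals alike), so the
session-averaged rate of a unit estimates its baseline; within stem bins the
rate is baseline x gain(phase, trajectory, bin).  Within-bin spike timing is
uniform — the analyses consume bin-level rates only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import StemBinning, assign_bins, make_stem_bins
from .config import ModulationSpec, StudyConfig, TaskConfig, config_hash, _to_dict

__all__ = [
    "NeuronSpec",
    "Traversal",
    "Session",
    "Study",
    "generate_trial_sequence",
    "generate_position_trace",
    "generate_spike_counts",
    "generate_session",
    "generate_cohort",
    "simulate_peak_amplitudes",
    "write_study",
    "read_study",
]

PHASES = ("sample", "choice")
TRAJECTORIES = ("L", "R")
SESSION_TRIAL_CAP = 18  # inclusion rule: only the first 18 trials are analysed


@dataclass
class NeuronSpec:
    """One simulated unit: baseline rate plus a multiplicative gain map.

    ``gains`` has shape (2 phases, 2 trajectories, n_bins) and defaults to 1
    everywhere (unmodulated).  ``rate_class_true`` is derived from the
    baseline against the study threshold, before any spikes are drawn.
    """

    neuron_id: str
    session_id: str
    baseline_rate_hz: float
    gains: np.ndarray
    rate_class_true: str = "low"

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be >= 0")
        self.gains = np.asarray(self.gains, dtype=float)
        if np.any(self.gains < 0):
            raise ValueError("gains must be >= 0")

    def gain(self, phase: str, trajectory: str, bin_1based: int) -> float:
        return float(self.gains[PHASES.index(phase),
                                TRAJECTORIES.index(trajectory),
                                bin_1based - 1])


@dataclass
class Traversal:
    trial_index: int
    phase: str           # "sample" | "choice"
    trajectory: str      # "L" | "R"
    correct: bool        # correctness of the parent trial
    trace: pd.DataFrame  # columns t (s, absolute), x (cm), y (cm)


@dataclass
class Session:
    session_id: str
    animal_id: str
    task: TaskConfig
    trials: pd.DataFrame                 # long form: trial_index, traversal, trajectory, correct
    traversals: list[Traversal]
    spike_trains: dict[str, np.ndarray]  # absolute seconds, sorted
    neurons: list[NeuronSpec]
    duration_s: float

    def neuron_frame(self) -> pd.DataFrame:
        rows = [(n.neuron_id, n.session_id, n.baseline_rate_hz, n.rate_class_true,
                 json.dumps(np.round(n.gains, 10).tolist()))
                for n in self.neurons]
        return pd.DataFrame(rows, columns=[
            "neuron_id", "session_id", "baseline_rate_hz", "rate_class_true",
            "gains_json"])


@dataclass
class Study:
    sessions: list[Session]
    animal_ids: list[str]
    params: StudyConfig
    seed: int

    @property
    def neuron_ids(self) -> list[str]:
        return [n.neuron_id for s in self.sessions for n in s.neurons]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": config_hash(self.params),
                "params": _to_dict(self.params)}


# ---------------------------------------------------------------------------
# trial sequences

def generate_trial_sequence(n_trials: int, max_run: int,
                            rng: np.random.Generator) -> list[str]:
    """Pseudo-randomized forced-turn sequence: balanced L/R, runs <= max_run.

    Sequential random construction: at every position a label is drawn
    uniformly among those that keep the sequence completable (a balanced
    arrangement with runs <= max_run exists for the remaining letters).
    Every output satisfies both constraints; uniformity over valid
    sequences is not promised.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    m = max_run
    rem = {"L": n_trials // 2, "R": n_trials // 2}
    seq: list[str] = []
    run_label, run_len = "", 0
    for _ in range(n_trials):
        feasible = []
        for lab in ("L", "R"):
            if rem[lab] == 0:
                continue
            new_len = run_len + 1 if lab == run_label else 1
            if new_len > m:
                continue
            other = "R" if lab == "L" else "L"
            a, b = rem[lab] - 1, rem[other]
            # remaining 'lab' letters fill at most (m - new_len) slots adjoining
            # the trailing run plus m per gap created by the b other letters;
            # the other letters get b <= m * (a + 1) slots of their own
            if a <= (m - new_len) + m * b and b <= m * (a + 1):
                feasible.append(lab)
        if not feasible:  # pragma: no cover - construction rule is exact
            raise ValueError(f"no valid sequence for n_trials={n_trials}, "
                             f"max_run={max_run}")
        lab = feasible[int(rng.integers(len(feasible)))]
        seq.append(lab)
        rem[lab] -= 1
        run_len = run_len + 1 if lab == run_label else 1
        run_label = lab
    return seq


def _max_run(seq) -> int:
    longest = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


# ---------------------------------------------------------------------------
# position traces

def generate_position_trace(trajectory: str, task: TaskConfig,
                            rng: np.random.Generator,
                            divergence_amp_cm: float = 3.0,
                            divergence_onset_frac: float = 0.8,
                            divergence_steepness: float = 0.3,
                            speed_cm_s: float = 30.0,
                            noise_sd_cm: float = 1.0,
                            t0: float = 0.0) -> pd.DataFrame:
    """One stem traversal at the tracking rate.

    x advances at constant speed from 0 to the stem length; y follows a
    logistic divergence toward +amp (right trajectory) or −amp (left),
    anchored to 0 at stem entry, starting around ``divergence_onset_frac``
    of the stem, plus i.i.d. Gaussian tracking noise.  Sign convention:
    y > 0 toward the right goal arm.
    """
    if not 0.0 <= divergence_onset_frac <= 1.0:
        raise ValueError("divergence_onset_frac must lie in [0, 1]")
    if speed_cm_s <= 0:
        raise ValueError("speed_cm_s must be positive")
    L = task.stem_length_cm
    fs = task.sampling_hz
    duration = L / speed_cm_s
    n = int(np.ceil(duration * fs))
    t = t0 + np.arange(n) / fs
    x = np.minimum(speed_cm_s * np.arange(n) / fs, L)
    sign = +1.0 if trajectory == "R" else -1.0
    x0 = divergence_onset_frac * L
    k = divergence_steepness
    sigma = lambda z: 1.0 / (1.0 + np.exp(-z))
    y = sign * divergence_amp_cm * (sigma(k * (x - x0)) - sigma(-k * x0))
    if noise_sd_cm > 0:
        y = y + rng.normal(0.0, noise_sd_cm, size=n)
    y = np.clip(y, -task.stem_width_cm, task.stem_width_cm)
    return pd.DataFrame({"t": t, "x": x, "y": y})


# ---------------------------------------------------------------------------
# spiking

def generate_spike_counts(neuron: NeuronSpec, phase: str, trajectory: str,
                          occupancy_s_per_bin: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Poisson spike counts per stem bin for one traversal.

    count_b ~ Poisson(baseline x gain(phase, trajectory, b) x occupancy_b),
    independent across bins.
    """
    occ = np.asarray(occupancy_s_per_bin, dtype=float)
    if np.any(occ < 0):
        raise ValueError("occupancy times must be >= 0")
    g = neuron.gains[PHASES.index(phase), TRAJECTORIES.index(trajectory), :len(occ)]
    lam = neuron.baseline_rate_hz * g * occ
    return rng.poisson(lam)


def _traversal_spike_times(counts: np.ndarray, bin_idx: np.ndarray,
                           t: np.ndarray, fs: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Place spikes uniformly within the occupancy of each bin.

    Each spike picks a random trace sample of its bin and jitters within
    half a sample period, so a nearest-sample assignment recovers the bin.
    """
    dt = 1.0 / fs
    times = []
    for b, c in enumerate(counts):
        if c == 0:
            continue
        samples = np.flatnonzero(bin_idx == b)
        picks = rng.integers(0, len(samples), size=c)
        times.append(t[samples[picks]] + rng.uniform(-dt / 2, dt / 2, size=c))
    if not times:
        return np.empty(0)
    return np.concatenate(times)


# ---------------------------------------------------------------------------
# sessions and cohorts

def _draw_trials(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial table for one session, enforcing the correct-trial minima.

    The forced sample sequence is balanced with bounded runs; the choice
    trajectory opposes the sample on correct trials and repeats it on
    errors.  Error flags are redrawn until the session supports its
    intended decoding problems (enough correct trials per class).
    """
    task = cfg.task
    n_run = task.n_trials_per_session
    n_even = n_run + (n_run % 2)
    retained = min(n_run, SESSION_TRIAL_CAP)
    for _ in range(10_000):
        seq = generate_trial_sequence(n_even, task.max_run, rng)[:n_run]
        errors = rng.random(n_run) < cfg.error_prob
        sub_seq = np.array(seq[:retained])
        sub_err = errors[:retained]
        n_correct = int((~sub_err).sum())
        ok = n_correct >= cfg.min_correct_total
        for traj in TRAJECTORIES:
            ok &= int(((sub_seq == traj) & ~sub_err).sum()) >= cfg.min_correct_per_class
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely at default settings
        raise RuntimeError("could not satisfy correct-trial minima")
    rows = []
    for i in range(retained):
        samp = seq[i]
        correct = not errors[i]
        choice = _opposite(samp) if correct else samp
        rows.append((i + 1, "sample", samp, correct))
        rows.append((i + 1, "choice", choice, correct))
    return pd.DataFrame(rows, columns=["trial_index", "traversal", "trajectory",
                                       "correct"])


def _opposite(traj: str) -> str:
    return "R" if traj == "L" else "L"


def generate_session(cfg: StudyConfig, session_id: str, animal_id: str,
                     neurons: list[NeuronSpec],
                     rng: np.random.Generator) -> Session:
    """Assemble one session: trials, traces, and spiking for given units."""
    task = cfg.task
    fs = task.sampling_hz
    binning = make_stem_bins(0.0, task.stem_length_cm)
    trials = _draw_trials(cfg, rng)

    traversals: list[Traversal] = []
    clock = 0.0
    windows = []  # (t_start, t_end, bin_idx, t_samples, phase, trajectory)
    for trial_index, group in trials.groupby("trial_index", sort=True):
        for phase in PHASES:
            row = group[group.traversal == phase].iloc[0]
            trace = generate_position_trace(
                row.trajectory, task, rng,
                divergence_amp_cm=cfg.divergence_amp_cm,
                divergence_onset_frac=cfg.divergence_onset_frac,
                divergence_steepness=cfg.divergence_steepness,
                speed_cm_s=cfg.speed_cm_s,
                noise_sd_cm=cfg.noise_sd_cm,
                t0=clock)
            traversals.append(Traversal(int(trial_index), phase, row.trajectory,
                                        bool(row.correct), trace))
            t = trace["t"].to_numpy()
            bin_idx = assign_bins(trace["x"].to_numpy(), binning)
            windows.append((t[0] - 0.5 / fs, t[-1] + 0.5 / fs, bin_idx, t,
                            phase, row.trajectory))
            clock = t[-1] + 1.0 / fs
            clock += task.delay_s if phase == "sample" else task.iti_s
    duration = clock

    spike_trains: dict[str, np.ndarray] = {}
    for neuron in neurons:
        # background spiking at baseline across the whole session, excluding
        # traversal windows (which get their own modulated counts)
        n_bg = rng.poisson(neuron.baseline_rate_hz * duration)
        bg = rng.uniform(0.0, duration, size=n_bg)
        for (w0, w1, *_rest) in windows:
            bg = bg[(bg < w0) | (bg >= w1)]
        parts = [bg]
        for (w0, w1, bin_idx, t, phase, trajectory) in windows:
            occ = np.bincount(bin_idx[bin_idx >= 0], minlength=binning.n_bins) / fs
            counts = generate_spike_counts(neuron, phase, trajectory, occ, rng)
            parts.append(_traversal_spike_times(counts, bin_idx, t, fs, rng))
        train = np.sort(np.concatenate(parts))
        spike_trains[neuron.neuron_id] = np.clip(train, 0.0, duration)

    return Session(session_id, animal_id, task, trials, traversals,
                   spike_trains, neurons, duration)


def _make_neurons(cfg: StudyConfig, session_ids: list[str],
                  rng: np.random.Generator,
                  n_bins: int = 7) -> dict[str, list[NeuronSpec]]:
    """Draw baselines for every unit, then plant modulations cohort-wide."""
    per_session: dict[str, list[NeuronSpec]] = {}
    all_neurons: list[NeuronSpec] = []
    for sid in session_ids:
        units = []
        for j in range(cfg.neurons_per_session):
            baseline = float(rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma))
            spec = NeuronSpec(
                neuron_id=f"{sid}_n{j:03d}",
                session_id=sid,
                baseline_rate_hz=baseline,
                gains=np.ones((2, 2, n_bins)),
                rate_class_true="high" if baseline > cfg.rate_threshold_hz else "low",
            )
            units.append(spec)
            all_neurons.append(spec)
        per_session[sid] = units

    for mod in cfg.modulations:
        pool = [n for n in all_neurons
                if mod.rate_class == "any" or n.rate_class_true == mod.rate_class]
        k = int(round(mod.fraction * len(pool)))
        if k > len(pool):
            raise ValueError(f"modulation fraction {mod.fraction} infeasible")
        chosen = rng.choice(len(pool), size=k, replace=False) if k else []
        pi = PHASES.index(mod.phase)
        ti = TRAJECTORIES.index(mod.trajectory)
        for c in chosen:
            unit = pool[c]
            g = mod.gain
            if mod.gain_jitter_sd > 0:
                g = g * float(np.exp(rng.normal(0.0, mod.gain_jitter_sd)))
            for b in mod.bins:
                unit.gains[pi, ti, b - 1] *= g
    return per_session


def generate_cohort(cfg: StudyConfig | None = None, seed: int = 0) -> Study:
    """Generate a full synthetic study, deterministic under ``seed``."""
    cfg = cfg or StudyConfig()
    root = np.random.SeedSequence(seed)
    ss_neurons, ss_sessions = root.spawn(2)
    session_ids = [f"s{i + 1:02d}" for i in range(cfg.n_sessions)]
    animal_ids = [f"rat{i + 1:02d}" for i in range(cfg.n_animals)]
    animal_of = {sid: animal_ids[i % cfg.n_animals]
                 for i, sid in enumerate(session_ids)}
    per_session = _make_neurons(cfg, session_ids,
                                np.random.default_rng(ss_neurons))
    sessions = []
    for sid, child in zip(session_ids, ss_sessions.spawn(cfg.n_sessions)):
        sessions.append(generate_session(cfg, sid, animal_of[sid],
                                         per_session[sid],
                                         np.random.default_rng(child)))
    return Study(sessions, animal_ids, cfg, seed)


def simulate_peak_amplitudes(session: Session, rng: np.random.Generator,
                             mean_uv_range: tuple[float, float] = (60.0, 200.0),
                             noise_sd_uv: float = 8.0,
                             drift_uv: float = 0.0):
    """Synthetic waveform peak-amplitude series per unit, for the stability screen.

    Each unit gets a characteristic mean height (uniform over
    ``mean_uv_range``) plus i.i.d. noise at each of its spikes; ``drift_uv``
    adds a linear drift across the session to emulate unstable clusters.
    """
    out = {}
    for nid, t in session.spike_trains.items():
        base = rng.uniform(*mean_uv_range)
        amp = base + rng.normal(0.0, noise_sd_uv, size=len(t))
        if drift_uv:
            amp = amp + drift_uv * (t / session.duration_s)
        out[nid] = (t.copy(), amp)
    return out


# ---------------------------------------------------------------------------
# writers / readers (delimited UTF-8, seconds and centimeters)

def write_study(study: Study, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = study.provenance()
    manifest["sessions"] = {}
    for s in study.sessions:
        sdir = out / s.session_id
        sdir.mkdir(exist_ok=True)
        s.trials.to_csv(sdir / "trials.csv", index=False)
        for trav in s.traversals:
            name = f"trace_{trav.trial_index:02d}_{trav.phase}.csv"
            trav.trace.to_csv(sdir / name, index=False)
        for nid, train in s.spike_trains.items():
            np.savetxt(sdir / f"spikes_{nid}.csv", train, fmt="%.6f",
                       header="spike_time_s", comments="")
        s.neuron_frame().to_csv(sdir / "neurons.csv", index=False)
        manifest["sessions"][s.session_id] = {
            "animal_id": s.animal_id, "duration_s": s.duration_s,
            "n_neurons": len(s.neurons)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")


def read_study(in_dir: str | Path) -> Study:
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text(encoding="utf-8"))
    from .config import _build  # strict reconstruction
    cfg = _build(StudyConfig, manifest["params"])
    sessions = []
    for sid, info in manifest["sessions"].items():
        sdir = root / sid
        trials = pd.read_csv(sdir / "trials.csv")
        trials["correct"] = trials["correct"].astype(bool)
        traversals = []
        for trial_index, group in trials.groupby("trial_index", sort=True):
            for phase in PHASES:
                row = group[group.traversal == phase].iloc[0]
                trace = pd.read_csv(sdir / f"trace_{trial_index:02d}_{phase}.csv")
                traversals.append(Traversal(int(trial_index), phase,
                                            row.trajectory, bool(row.correct),
                                            trace))
        nf = pd.read_csv(sdir / "neurons.csv")
        neurons = [NeuronSpec(r.neuron_id, r.session_id, r.baseline_rate_hz,
                              np.array(json.loads(r.gains_json)),
                              r.rate_class_true)
                   for r in nf.itertuples()]
        spike_trains = {}
        for n in neurons:
            arr = np.loadtxt(sdir / f"spikes_{n.neuron_id}.csv", skiprows=1,
                             ndmin=1)
            spike_trains[n.neuron_id] = arr
        sessions.append(Session(sid, info["animal_id"], cfg.task, trials,
                                traversals, spike_trains, neurons,
                                info["duration_s"]))
    animal_ids = sorted({s.animal_id for s in sessions})
    return Study(sessions, animal_ids, cfg, manifest["seed"])
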