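"""Configuration objects for the simulation and analysis pipeline.

Every stage of the pipeline is parameterized by a small frozen dataclass.
Configs round-trip losslessly through YAML (``load_config`` / ``dump_config``)
and unknown keys are rejected so that typos never silently fall back to
defaults.  A single master seed drives every stochastic stage; per-stage
generators are spawned from it with :func:`numpy.random.SeedSequence.spawn`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "TaskConfig",
    "ModulationSpec",
    "StudyConfig",
    "DecoderConfig",
    "ScalingConfig",
    "RunConfig",
    "PROFILES",
    "load_config",
    "dump_config",
    "config_hash",
    "spawn_rngs",
]

# Median session rate (Hz) and sub-2 Hz fraction jointly pin the lognormal:
# P(rate < 2) = Phi((ln 2 - mu)/sigma) = 0.56 with median exp(mu) = 1.86.
_LOGNORMAL_MU = math.log(1.86)
_LOGNORMAL_SIGMA = 0.48063


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and schedule of the delayed non-match to position task."""

    n_trials_per_session: int = 18
    delay_s: float = 20.0
    iti_s: float = 40.0
    stem_length_cm: float = 127.0
    stem_width_cm: float = 9.0
    sampling_hz: float = 30.0
    max_run: int = 3

    def __post_init__(self) -> None:
        if self.n_trials_per_session % 2:
            raise ValueError("n_trials_per_session must be even")
        if self.max_run < 1:
            raise ValueError("max_run must be >= 1")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.stem_length_cm <= 0:
            raise ValueError("stem_length_cm must be positive")


@dataclass(frozen=True)
class ModulationSpec:
    """A planted multiplicative firing-rate modulation.

    ``fraction`` of the units in ``rate_class`` get their rate multiplied by
    ``gain`` whenever the animal traverses one of ``bins`` during ``phase``
    on a ``trajectory`` run.  ``gain_jitter_sd`` spreads per-unit gains
    lognormally around ``gain`` (0 = all selected units share the gain).
    """

    phase: str = "sample"            # "sample" | "choice"
    trajectory: str = "L"            # "L" | "R"
    bins: tuple[int, ...] = (7,)     # 1-based stem bins
    gain: float = 2.0
    fraction: float = 0.4
    rate_class: str = "any"          # "any" | "high" | "low"
    gain_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in ("sample", "choice"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.trajectory not in ("L", "R"):
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.rate_class not in ("any", "high", "low"):
            raise ValueError(f"unknown rate_class {self.rate_class!r}")
        if any(b < 1 or b > 7 for b in self.bins):
            raise ValueError("bins are 1-based stem bin indices in 1..7")


# Default modulations emulate the study's empirical structure: a trajectory
# signal at the T-junction on sample runs across the population, and a
# prospective choice-trajectory signal at the second stem bin carried by
# high-rate units only.
_DEFAULT_MODULATIONS = (
    ModulationSpec(phase="sample", trajectory="L", bins=(7,), gain=2.0,
                   fraction=0.4, rate_class="any"),
    ModulationSpec(phase="choice", trajectory="L", bins=(2,), gain=2.0,
                   fraction=0.4, rate_class="high"),
)


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a whole synthetic study (cohort of sessions)."""

    n_sessions: int = 45
    n_animals: int = 5
    neurons_per_session: int = 4
    task: TaskConfig = field(default_factory=TaskConfig)
    # lognormal baseline rates, calibrated to the study's rate histogram
    lognormal_mu: float = _LOGNORMAL_MU
    lognormal_sigma: float = _LOGNORMAL_SIGMA
    rate_threshold_hz: float = 2.0
    # behaviour
    error_prob: float = 0.1
    min_correct_total: int = 15
    min_correct_per_class: int = 6
    speed_cm_s: float = 30.0
    noise_sd_cm: float = 1.0
    divergence_amp_cm: float = 3.0
    divergence_onset_frac: float = 0.8
    divergence_steepness: float = 0.3   # logistic slope, 1/cm
    modulations: tuple[ModulationSpec, ...] = _DEFAULT_MODULATIONS

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.neurons_per_session < 1:
            raise ValueError("need at least one session and one neuron")
        if self.n_animals < 1 or self.n_animals > self.n_sessions:
            raise ValueError("n_animals must be in [1, n_sessions]")
        if not 0.0 <= self.error_prob < 1.0:
            raise ValueError("error_prob must lie in [0, 1)")
        if self.speed_cm_s <= 0:
            raise ValueError("speed_cm_s must be positive")
        if not 0.0 <= self.divergence_onset_frac <= 1.0:
            raise ValueError("divergence_onset_frac must lie in [0, 1]")
        n = self.task.n_trials_per_session
        if self.min_correct_total > n:
            raise ValueError("min_correct_total exceeds trial count")
        if self.min_correct_per_class > n // 2:
            raise ValueError("min_correct_per_class exceeds trials per class")


@dataclass(frozen=True)
class DecoderConfig:
    """Settings of the permutation-style linear classification."""

    C: float = 1.0
    n_iterations: int = 1000
    n_shuffles: int = 1000
    scale_01: bool = False
    null_per_iteration: bool = False  # sensitivity variant; default reuses final matrix

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_iterations < 1 or self.n_shuffles < 1:
            raise ValueError("iteration/shuffle counts must be >= 1")


@dataclass(frozen=True)
class ScalingConfig:
    """Settings for neuron-adding curves."""

    step: int = 5
    n_subsets_per_size: int = 5000
    max_size: int | None = None    # None -> pool size

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.n_subsets_per_size < 1:
            raise ValueError("n_subsets_per_size must be >= 1")


# Fidelity profiles: "full" reproduces the study-scale computation, "test"
# shrinks the Monte-Carlo depth (not the data-generating conditions) so the
# pipeline runs in minutes on one core.
PROFILES: dict[str, dict[str, int]] = {
    "full": {"n_iterations": 1000, "n_shuffles": 1000, "n_subsets_per_size": 5000},
    "test": {"n_iterations": 100, "n_shuffles": 100, "n_subsets_per_size": 200},
}


@dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration."""

    study: StudyConfig = field(default_factory=StudyConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    problems: tuple[str, ...] = ("task_phase", "sample_traj", "choice_traj")
    populations: tuple[str, ...] = ("all",)   # all | high | low | rat:<id>
    profile: str = "test"
    seed: int = 0
    run_scaling: bool = False
    scaling_problem: str = "sample_traj"
    scaling_bin: int = 7

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    def effective_decoder(self) -> DecoderConfig:
        p = PROFILES[self.profile]
        return dataclasses.replace(
            self.decoder, n_iterations=p["n_iterations"], n_shuffles=p["n_shuffles"]
        ) if self.profile == "test" else self.decoder

    def effective_scaling(self) -> ScalingConfig:
        p = PROFILES[self.profile]
        return dataclasses.replace(
            self.scaling, n_subsets_per_size=p["n_subsets_per_size"]
        ) if self.profile == "test" else self.scaling


# ---------------------------------------------------------------------------
# (de)serialization

_TUPLE_FIELDS = {"bins", "modulations", "problems", "populations"}


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def _build(cls, data: dict):
    if not isinstance(data, dict):
        raise TypeError(f"expected mapping for {cls.__name__}, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise KeyError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name == "task":
            value = _build(TaskConfig, value)
        elif name == "study":
            value = _build(StudyConfig, value)
        elif name == "decoder":
            value = _build(DecoderConfig, value)
        elif name == "scaling":
            value = _build(ScalingConfig, value)
        elif name == "modulations":
            value = tuple(_build(ModulationSpec, v) for v in value)
        elif name in _TUPLE_FIELDS or isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def dump_config(config, path: str | Path | None = None) -> str:
    """Serialize a config dataclass to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(_to_dict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_config(source: str | Path, cls=RunConfig):
    """Load a config from a YAML file path or YAML string (strict keys)."""
    text = str(source)
    if "\n" not in text:
        try:
            if Path(text).exists():
                text = Path(text).read_text(encoding="utf-8")
        except OSError:
            pass
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    return _build(cls, data)


def config_hash(config) -> str:
    """Stable short hash of a config, for manifests and logs."""
    payload = json.dumps(_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
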