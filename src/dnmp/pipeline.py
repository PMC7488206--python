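"""End-to-end orchestration: simulate -> bin -> decode -> scale -> stats.

``run_pipeline`` executes the stages in dependency order under one master
seed, collects every stage's tables into a :class:`ResultsBundle`, and can
write the bundle (CSV tables + ``manifest.json`` + ``summary.json``) to
disk.  Reruns with the same config and seed reproduce the tables exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, decoding, scaling, simulate, stats
from .config import RunConfig, config_hash, _to_dict

__all__ = ["ResultsBundle", "run_pipeline", "population_filter"]


@dataclass
class ResultsBundle:
    """Machine-readable results of one pipeline run."""

    manifest: dict
    tables: dict = field(default_factory=dict)   # name -> DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        (out / "summary.json").write_text(
            json.dumps(self.summary, indent=2, default=_jsonify), encoding="utf-8")
        # manifest last: its presence marks a complete bundle
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=_jsonify), encoding="utf-8")
        return out


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def population_filter(name: str, study, split: binning.RateClassSplit):
    """Resolve a population selector to a neuron-id list (None = all)."""
    if name == "all":
        return None
    if name == "high":
        return list(split.high_ids)
    if name == "low":
        return list(split.low_ids)
    if name.startswith("rat:"):
        animal = name.split(":", 1)[1]
        ids = [n.neuron_id for s in study.sessions if s.animal_id == animal
               for n in s.neurons]
        if not ids:
            raise ValueError(f"no sessions for animal {animal!r}")
        return ids
    raise ValueError(f"unknown population selector {name!r}")


def _stage(name, fn, runtimes):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
    runtimes[name] = round(time.perf_counter() - t0, 3)
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> ResultsBundle:
    """Run the full analysis pipeline on a synthetic study."""
    runtimes: dict[str, float] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    sim_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    dec_cfg = config.effective_decoder()
    scale_cfg = config.effective_scaling()

    study = _stage("simulate",
                   lambda: simulate.generate_cohort(config.study, sim_seed),
                   runtimes)

    def _bin():
        tensors = [binning.compute_rate_tensor(s) for s in study.sessions]
        behaviors = [binning.compute_behavior_tensors(s) for s in study.sessions]
        return tensors, behaviors

    tensors, behaviors = _stage("bin", _bin, runtimes)
    split = binning.split_by_rate(study.sessions,
                                  config.study.rate_threshold_hz)

    def _decode():
        summaries, iteration_rows = [], []
        headline = {}
        decode_seeds = seeds[1].spawn(len(config.problems) * len(config.populations))
        k = 0
        for prob in config.problems:
            for pop in config.populations:
                ids = population_filter(pop, study, split)
                model = decoding.PopulationDecoder(tensors, prob, dec_cfg,
                                                   neuron_ids=ids)
                res = model.fit(int(decode_seeds[k].generate_state(1)[0] % 2 ** 31))
                k += 1
                s = res.summary()
                s.insert(1, "population", pop)
                summaries.append(s)
                it = res.iterations_frame()
                it.insert(1, "population", pop)
                iteration_rows.append(it)
                headline[f"{prob}|{pop}"] = {
                    str(b): {"z": res.z(b), "p": res.p(b)} for b in res.bins}
        return pd.concat(summaries, ignore_index=True), \
            pd.concat(iteration_rows, ignore_index=True), headline

    decoding_summary, iterations, headline = _stage("decode", _decode, runtimes)

    tables = {"decoding_summary": decoding_summary, "iterations": iterations}
    summary = {"decoding": headline}

    if config.run_scaling:
        def _scale():
            seed = int(seeds[2].generate_state(1)[0] % 2 ** 31)
            curve = scaling.neuron_adding_curve(
                tensors, config.scaling_problem, config.scaling_bin,
                scale_cfg, seed=seed, C=dec_cfg.C)
            fit = scaling.PowerLawModel.from_curve(curve).fit()
            # the null of the full population for this problem/bin
            model = decoding.PopulationDecoder(tensors, config.scaling_problem,
                                               dec_cfg)
            res = model.fit(seed + 1)
            null = res.null(config.scaling_bin)
            min_size = scaling.minimal_significant_size(
                curve.sizes, curve.mean_accuracy, null)
            forecast = fit.forecast(curve.sizes, null)
            return curve, fit, forecast, min_size

        curve, fit, forecast, min_size = _stage("scale", _scale, runtimes)
        tables["scaling_curve"] = curve.to_frame()
        tables["forecast"] = forecast
        summary["scaling"] = {
            "intercept_a": fit.intercept_a, "slope_b": fit.slope_b,
            "sse": fit.sse, "adj_r2": fit.adj_r2,
            "minimal_significant_size": min_size}

    def _stats():
        lat = stats.session_behavior_table(behaviors, "lateral_cm",
                                           phase="choice",
                                           split_by="trajectory")
        anova = stats.two_way_anova(lat, value="value", class_col="cls",
                                    bin_col="bin")
        piv = lat.pivot_table(index="session", columns=["cls", "bin"],
                              values="value")
        n_bins = tensors[0].n_bins
        A = piv["L"].reindex(columns=range(1, n_bins + 1)).to_numpy()
        B = piv["R"].reindex(columns=range(1, n_bins + 1)).to_numpy()
        ttests = stats.paired_ttests_by_bin(A, B)
        behavior_rows = anova.to_frame().reset_index(names="effect")
        behavior_rows.insert(0, "analysis", "lateral_choice_LvR")

        reports = {}
        rate_class_of = {}
        for t in tensors:
            for nid in t.neuron_ids:
                table = stats.unit_trajectory_table(t, nid, phase="choice")
                reports[nid] = stats.classify_trajectory_modulated(table)
                rate_class_of[nid] = split.rate_class(nid)
        props = stats.modulation_proportions(reports, rate_class_of)
        unit_rows = []
        for nid, rep in reports.items():
            row = {"unit": nid, "rate_class": rate_class_of[nid],
                   "testable": rep["testable"], "modulated": rep["modulated"],
                   "p_trajectory": rep["p_trajectory"],
                   "p_interaction": rep["p_interaction"]}
            for b, f in rep["followup"].items():
                row[f"t_bin{b}"] = f["t"]
                row[f"p_bin{b}"] = f["p"]
                row[f"sig_bin{b}"] = f["significant"]
            unit_rows.append(row)
        return behavior_rows, ttests.table, pd.DataFrame(unit_rows), props

    behavior_rows, ttest_table, unit_table, props = _stage("stats", _stats,
                                                           runtimes)
    tables["behavior_stats"] = behavior_rows
    tables["behavior_ttests"] = ttest_table
    tables["unit_modulation"] = unit_table
    tables["modulation_proportions"] = props
    summary["modulation_proportions"] = props.to_dict(orient="records")
    summary["rate_split"] = {
        "threshold_hz": split.threshold_hz,
        "n_high": len(split.high_ids), "n_low": len(split.low_ids),
        "median_rate_hz": split.median_rate_hz}

    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": _to_dict(config),
        "profile": config.profile,
        "n_sessions": len(study.sessions),
        "n_neurons": len(study.neuron_ids),
        "stage_runtimes_s": runtimes,
    }
    bundle = ResultsBundle(manifest, tables, summary)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
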