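"""End-to-end orchestration: simulate -> process -> fit -> compare.

A run is described by a :class:`RunConfig` (usually loaded from YAML): a
global seed, an output directory and an ordered list of stages.  Each stage
is a mapping with a ``stage`` key naming the operation plus its parameters;
stages may reference the file outputs of earlier stages by name.  Outputs
are CSV/JSON files whose ``#`` provenance headers carry the config hash and
package version, so a rerun with the same config and seed is byte-identical.

Statistical hypothesis testing (ANOVA/ANCOVA, post-hoc comparisons) is
deliberately delegated to external tooling: :func:`export_tidy_stats` emits
a long-format table ready for statsmodels/pingouin/R.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import fscav, fscv, mm, oscillation, pk, synthetic
from .datatypes import (ConcentrationTrace, FSCAVSeries, StimulationProtocol,
                        ValidationError, read_csv, write_csv_with_provenance)

__all__ = ["RunConfig", "ResultBundle", "StageOutput", "run_experiment",
           "export_tidy_stats", "load_config"]

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate-basal", "simulate-evoked", "simulate-cv",
                "fit-mm", "fcm-predict", "oscillation-compare",
                "fscav-process")
STOCHASTIC_STAGES = ("simulate-basal", "simulate-evoked", "simulate-cv",
                     "fit-mm")


@dataclass
class RunConfig:
    """Validated run description."""

    stages: list[dict[str, Any]]
    out_dir: Path
    seed: int | None = None
    raw: dict[str, Any] = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(source: str | Path | dict[str, Any],
                out_dir: str | Path | None = None) -> RunConfig:
    """Load and validate a run config from YAML (path) or a mapping."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        raw = dict(source)
    if not isinstance(raw, dict) or "stages" not in raw:
        raise ValidationError("config must be a mapping with a 'stages' list")
    stages = raw["stages"]
    if not isinstance(stages, list) or not stages:
        raise ValidationError("'stages' must be a non-empty list")
    names = []
    for i, st in enumerate(stages):
        if not isinstance(st, dict) or "stage" not in st:
            raise ValidationError(f"stage {i} must be a mapping with 'stage'")
        if st["stage"] not in KNOWN_STAGES:
            raise ValidationError(
                f"stage {i}: unknown stage {st['stage']!r}; "
                f"known: {KNOWN_STAGES}")
        names.append(st.get("name", f"{st['stage']}-{i}"))
    if len(set(names)) != len(names):
        raise ValidationError("stage output names must be distinct")
    seed = raw.get("seed")
    if seed is None and any(st["stage"] in STOCHASTIC_STAGES for st in stages):
        raise ValidationError("a seed is required when stochastic stages run")
    out = Path(out_dir if out_dir is not None else raw.get("out_dir", "."))
    return RunConfig(stages=stages, out_dir=out, seed=seed, raw=raw)


@dataclass
class StageOutput:
    """One file produced by one stage."""

    stage: str
    name: str
    path: Path
    kind: str                      # "trace" | "series" | "cv" | "report"
    labels: dict[str, Any] = field(default_factory=dict)


@dataclass
class ResultBundle:
    """Everything a completed run produced, with provenance."""

    outputs: list[StageOutput]
    config_hash: str
    out_dir: Path
    log_path: Path | None = None

    def by_name(self, name: str) -> StageOutput:
        for out in self.outputs:
            if out.name == name:
                return out
        raise KeyError(name)

    def paths(self) -> list[Path]:
        return [o.path for o in self.outputs]


def _provenance(config: RunConfig) -> dict[str, Any]:
    from . import __version__
    return {"config_hash": config.config_hash, "serovolt_version": __version__}


def _protocol_from(params: dict[str, Any]) -> StimulationProtocol:
    return StimulationProtocol(**params.get("protocol", {}))


def _mm_params_from(params: dict[str, Any], key: str = "params") -> mm.MMParams:
    return mm.MMParams(**params.get(key, {}))


def _stage_seed(base: int | None, index: int) -> int:
    # independent per-stage streams derived from the run seed
    return int((0 if base is None else base) + 7919 * index) % (2 ** 31)


def run_experiment(config: RunConfig) -> ResultBundle:
    """Execute the configured stage graph.

    Any stage failure aborts with the stage name attached.  All outputs are
    written under ``config.out_dir`` with provenance headers.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    outputs: list[StageOutput] = []
    for i, st in enumerate(config.stages):
        kind = st["stage"]
        name = st.get("name", f"{kind}-{i}")
        labels = {k: st[k] for k in ("animal", "phase") if k in st}
        seed = st.get("seed", _stage_seed(config.seed, i))
        try:
            outputs.extend(_run_stage(kind, name, st, seed, out_dir, prov,
                                      labels, outputs))
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} ({kind}) failed: {exc}") from exc
    return ResultBundle(outputs=outputs, config_hash=config.config_hash,
                        out_dir=out_dir)


def _resolve_input(ref: str, outputs: list[StageOutput],
                   out_dir: Path) -> Path:
    """A stage input is either an earlier stage's name or a file path."""
    for out in outputs:
        if out.name == ref:
            return out.path
    return Path(ref)


def _run_stage(kind: str, name: str, st: dict[str, Any], seed: int,
               out_dir: Path, prov: dict[str, Any], labels: dict[str, Any],
               prior: list[StageOutput]) -> list[StageOutput]:
    if kind == "simulate-basal":
        spec = synthetic.SyntheticBasalSpec(**{**st.get("spec", {}),
                                               "seed": seed})
        series = synthetic.simulate_basal_series(spec)
        path = out_dir / f"{name}.csv"
        series.to_csv(path, provenance={**prov, "stage": kind})
        return [StageOutput(kind, name, path, "series", labels)]

    if kind == "simulate-evoked":
        params = _mm_params_from(st)
        protocol = _protocol_from(st)
        trace = synthetic.simulate_evoked_trace(
            params, protocol, noise_sd=st.get("noise_sd", 0.0), seed=seed,
            duration=st.get("duration", 30.0),
            stim_start=st.get("stim_start", 5.0))
        path = out_dir / f"{name}.csv"
        trace.to_csv(path, provenance={**prov, "stage": kind})
        return [StageOutput(kind, name, path, "trace", labels)]

    if kind == "simulate-cv":
        shape = synthetic.CVShapeSpec(**st.get("shape", {}))
        plot = synthetic.synthesize_voltammograms(
            st["concentrations"], shape, seed=seed)
        path = out_dir / f"{name}.csv"
        plot.to_csv(path)
        return [StageOutput(kind, name, path, "cv", labels)]

    if kind == "fit-mm":
        trace_path = _resolve_input(st["trace"], prior, out_dir)
        trace = ConcentrationTrace.from_csv(trace_path)
        protocol = _protocol_from(st)
        init = _mm_params_from(st, "init")
        result = mm.fit(trace, protocol, init,
                        frozen=st.get("freeze", ()), seed=seed,
                        n_starts=st.get("n_starts", 5))
        report = {
            "rmse_nM": result.rmse, "iterations": result.iterations,
            "converged": result.converged, "frozen": sorted(result.frozen),
            **{f"fitted_{p}": getattr(result.fitted, p)
               for p in mm.FITTABLE_PARAMS},
            **prov,
        }
        path = out_dir / f"{name}.json"
        path.write_text(json.dumps(report, indent=1, sort_keys=True),
                        encoding="utf-8")
        return [StageOutput(kind, name, path, "report", labels)]

    if kind == "fcm-predict":
        control = _mm_params_from(st, "control")
        fcm_kwargs = dict(st.get("fcm", {}))
        if not fcm_kwargs:
            raise ValidationError("fcm-predict requires an 'fcm' parameter "
                                  "mapping (rate constants are not defaulted)")
        if fcm_kwargs.pop("synthetic_rates", False):
            params = pk.synthetic_rate_constants(**fcm_kwargs)
        else:
            params = pk.FCMParams(**fcm_kwargs)
        times = st.get("times_min", [5.0, 30.0, 60.0, 90.0, 120.0])
        protocol = _protocol_from(st)
        trajectory = pk.simulate_fcm(
            params, duration_min=max(times) * 1.2 + 1.0)
        outs: list[StageOutput] = []
        rows = []
        for t_post in times:
            trace = pk.predict_post_drug_trace(
                control, trajectory, t_post, protocol, K_i_nM=params.K_i_nM)
            path = out_dir / f"{name}-t{t_post:g}.csv"
            trace.to_csv(path, provenance={**prov, "stage": kind,
                                           "t_post_min": t_post})
            outs.append(StageOutput(kind, f"{name}-t{t_post:g}", path,
                                    "trace", {**labels, "time_min": t_post}))
            summary = fscv.summarize_kinetics(trace)
            rows.append({"time_min": t_post,
                         "C_brain_nM": trace.metadata["C_brain_nM"],
                         "K_m1_app_nM": trace.metadata["K_m1_app_nM"],
                         "amp_max_nM": summary.amp_max_nM if summary else np.nan,
                         "t_half_s": summary.t_half_s if summary else np.nan})
        table_path = out_dir / f"{name}-summary.csv"
        write_csv_with_provenance(pd.DataFrame(rows), table_path,
                                  {**prov, "stage": kind})
        outs.append(StageOutput(kind, f"{name}-summary", table_path,
                                "report", labels))
        return outs

    if kind == "oscillation-compare":
        pre = [FSCAVSeries.from_csv(_resolve_input(r, prior, out_dir))
               for r in st["pre"]]
        post = [FSCAVSeries.from_csv(_resolve_input(r, prior, out_dir))
                for r in st["post"]]
        table, summary = oscillation.compare_pre_post(pre, post)
        path = out_dir / f"{name}.csv"
        write_csv_with_provenance(table, path,
                                  {**prov, "stage": kind, **summary})
        return [StageOutput(kind, name, path, "report", labels)]

    if kind == "fscav-process":
        from .datatypes import VoltammogramSet
        files = [VoltammogramSet.from_csv(_resolve_input(r, prior, out_dir))
                 for r in st["files"]]
        model = fscav.fit_calibration([tuple(s) for s in st["standards"]])
        series = fscav.process_series(files, model,
                                      tuple(st["search_window"]))
        path = out_dir / f"{name}.csv"
        series.to_csv(path, provenance={**prov, "stage": kind})
        return [StageOutput(kind, name, path, "series", labels)]

    raise ValidationError(f"unknown stage kind {kind!r}")


def export_tidy_stats(bundle: ResultBundle,
                      path: str | Path | None = None) -> pd.DataFrame:
    """Long-format table (animal, phase, time, value, stage) for statistics.

    Every series/trace output contributes one row per timepoint; label
    columns come from the stage's ``animal``/``phase`` entries.  The table
    round-trips bit-exactly against the stage output files.
    """
    rows = []
    for out in bundle.outputs:
        if out.kind not in ("series", "trace"):
            continue
        df = read_csv(out.path)
        time_col = "time_min" if "time_min" in df.columns else "time_s"
        for t, v in zip(df[time_col], df["concentration_nM"]):
            rows.append({"animal": out.labels.get("animal"),
                         "phase": out.labels.get("phase"),
                         "time": t, "value": v, "stage": out.name})
    if not rows:
        raise ValidationError("bundle contains no series/trace outputs "
                              "to export")
    table = pd.DataFrame(rows,
                         columns=["animal", "phase", "time", "value", "stage"])
    if path is not None:
        write_csv_with_provenance(table, path,
                                  {"config_hash": bundle.config_hash})
    return table
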