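"""Shared data containers for the voltammetry pipeline.

The currency of the evoked-release (FSCV) side is :class:`ConcentrationTrace`,
a uniformly sampled concentration-vs-time series at 10 Hz with an annotated
stimulation window.  The basal-level (FSCAV) side works in
:class:`FSCAVSeries`, one point per 60 s acquisition cycle.  Raw single-sweep
voltammograms travel as a :class:`VoltammogramSet` ("color plot"): a matrix of
current with rows = successive sweeps and columns = intra-sweep sample index.

All CSV output is UTF-8, comma separated, ``.`` decimal, with a header row and
optional ``#``-prefixed provenance comment lines.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "StimulationProtocol",
    "ConcentrationTrace",
    "FSCAVSeries",
    "Voltammogram",
    "VoltammogramSet",
    "ValidationError",
    "IntegrationError",
    "write_csv_with_provenance",
    "read_csv",
]

#: FSCV acquisition rate: waveform applications per second.
FSCV_SWEEP_RATE_HZ = 10.0
#: FSCAV cycle: one basal measurement per 60 s file.
FSCAV_SAMPLING_PERIOD_S = 60.0


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class IntegrationError(RuntimeError):
    """Raised when a numerical integration produces a non-finite state."""


def write_csv_with_provenance(df: pd.DataFrame, path: str | Path,
                              provenance: dict[str, Any] | None = None) -> None:
    """Write ``df`` with ``#``-prefixed provenance comment lines first."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class StimulationProtocol:
    """Electrical stimulation train delivered to the medial forebrain bundle.

    The in vivo protocol is a 60 Hz train of biphasic 360 uA, 2 ms pulses
    lasting 2 s (120 pulses total); cell-culture work uses a 1 s, 60 Hz train.
    """

    frequency_hz: float = 60.0
    pulse_amplitude_ua: float = 360.0
    pulse_width_ms: float = 2.0
    duration_s: float = 2.0
    biphasic: bool = True

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValidationError("stimulation frequency must be > 0 Hz")
        if self.duration_s < 0:
            raise ValidationError("stimulation duration must be >= 0 s")

    @property
    def pulse_count(self) -> int:
        """Number of pulses delivered: round(frequency x duration)."""
        return int(round(self.frequency_hz * self.duration_s))


@dataclass
class ConcentrationTrace:
    """Uniformly sampled concentration vs time (nM, s) from FSCV.

    ``stim_start``/``stim_end`` delimit the stimulation window in seconds on
    the same clock as ``time``.  ``metadata`` carries provenance (ground-truth
    parameters for synthetic traces, processing history for measured ones).
    """

    time_s: np.ndarray
    concentration_nM: np.ndarray
    stim_start_s: float | None = None
    stim_end_s: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.concentration_nM = np.asarray(self.concentration_nM, dtype=float)
        if self.time_s.shape != self.concentration_nM.shape:
            raise ValidationError("time and concentration must have equal length")
        if self.time_s.size >= 2:
            steps = np.diff(self.time_s)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValidationError("trace must be uniformly sampled")

    @property
    def dt_s(self) -> float:
        if self.time_s.size < 2:
            raise ValidationError("trace too short to define a sampling step")
        return float(self.time_s[1] - self.time_s[0])

    def baseline_segment(self) -> np.ndarray:
        """Samples strictly before the stimulation onset."""
        if self.stim_start_s is None:
            raise ValidationError("trace has no stimulation annotation")
        return self.concentration_nM[self.time_s < self.stim_start_s]

    def to_csv(self, path: str | Path,
               provenance: dict[str, Any] | None = None) -> None:
        prov = dict(provenance or {})
        if self.stim_start_s is not None:
            prov.setdefault("stim_start_s", self.stim_start_s)
            prov.setdefault("stim_end_s", self.stim_end_s)
        df = pd.DataFrame({"time_s": self.time_s,
                           "concentration_nM": self.concentration_nM})
        write_csv_with_provenance(df, path, prov)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationTrace":
        stim_start = stim_end = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].partition(":")
                key = key.strip()
                if key == "stim_start_s":
                    stim_start = float(value)
                elif key == "stim_end_s":
                    stim_end = float(value)
        df = read_csv(path)
        return cls(df["time_s"].to_numpy(), df["concentration_nM"].to_numpy(),
                   stim_start_s=stim_start, stim_end_s=stim_end,
                   metadata={"source": str(path)})


@dataclass
class FSCAVSeries:
    """Minute-resolution ambient serotonin series from FSCAV (nM vs min)."""

    time_min: np.ndarray
    concentration_nM: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.concentration_nM = np.asarray(self.concentration_nM, dtype=float)
        if self.time_min.shape != self.concentration_nM.shape:
            raise ValidationError("time and concentration must have equal length")

    @property
    def sampling_period_s(self) -> float:
        if self.time_min.size < 2:
            return FSCAV_SAMPLING_PERIOD_S
        return float((self.time_min[1] - self.time_min[0]) * 60.0)

    def to_csv(self, path: str | Path,
               provenance: dict[str, Any] | None = None) -> None:
        df = pd.DataFrame({"time_min": self.time_min,
                           "concentration_nM": self.concentration_nM})
        write_csv_with_provenance(df, path, provenance)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FSCAVSeries":
        df = read_csv(path)
        return cls(df["time_min"].to_numpy(), df["concentration_nM"].to_numpy(),
                   metadata={"source": str(path)})


@dataclass
class Voltammogram:
    """A single sweep: current (nA) vs intra-sweep sample index."""

    current_nA: np.ndarray
    sample_interval_s: float

    def __post_init__(self) -> None:
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        if self.sample_interval_s <= 0:
            raise ValidationError("sample interval must be > 0")


@dataclass
class VoltammogramSet:
    """A color plot: successive single-sweep voltammograms.

    ``currents_nA`` has shape (n_sweeps, sweep_length).  ``sweep_rate_hz`` is
    the rate at which the waveform was applied (10 Hz for FSCV acquisition);
    ``sample_interval_s`` is the intra-sweep digitisation step.  For FSCAV
    files ``metadata['adsorption_boundary']`` holds the 0-based index of the
    first sweep after the controlled-adsorption hold.
    """

    currents_nA: np.ndarray
    sweep_rate_hz: float = FSCV_SWEEP_RATE_HZ
    sample_interval_s: float = 2.2e-6
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.currents_nA = np.atleast_2d(np.asarray(self.currents_nA, dtype=float))
        if self.sweep_rate_hz <= 0 or self.sample_interval_s <= 0:
            raise ValidationError("sweep rate and sample interval must be > 0")

    @property
    def n_sweeps(self) -> int:
        return int(self.currents_nA.shape[0])

    @property
    def sweep_length(self) -> int:
        return int(self.currents_nA.shape[1])

    def sweep(self, index: int) -> Voltammogram:
        return Voltammogram(self.currents_nA[index], self.sample_interval_s)

    def to_csv(self, path: str | Path) -> None:
        """Matrix CSV (rows = sweeps) plus a ``.meta.json`` sidecar."""
        path = Path(path)
        pd.DataFrame(self.currents_nA).to_csv(path, index=False, header=False)
        meta = {"sweep_rate_hz": self.sweep_rate_hz,
                "sample_interval_s": self.sample_interval_s,
                **_jsonable(self.metadata)}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1), encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "VoltammogramSet":
        path = Path(path)
        currents = pd.read_csv(path, header=None).to_numpy(dtype=float)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta: dict[str, Any] = {}
        if meta_path.exists():
            meta = json.loads(meta_path.read_text(encoding="utf-8"))
        return cls(currents,
                   sweep_rate_hz=float(meta.pop("sweep_rate_hz", FSCV_SWEEP_RATE_HZ)),
                   sample_interval_s=float(meta.pop("sample_interval_s", 2.2e-6)),
                   metadata=meta)


def _jsonable(obj: Any) -> Any:
    """Best-effort conversion of metadata to JSON-serialisable values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
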