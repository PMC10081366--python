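"""Synthetic-data generation with known ground truth.

Every input the pipeline consumes can be generated here with explicit seeds
and the generating parameters stored in metadata:

- evoked FSCV transients: forward solutions of the dual-uptake model under a
  stimulation protocol (2 s at 60 Hz by default), 10 Hz sampling, optional
  additive Gaussian noise;
- basal FSCAV series: baseline + sinusoid (period drawn in the 6-10 min
  band) + AR(1) noise + a piecewise-linear post-drug ramp, one point per
  60 s;
- single-sweep voltammograms: a capacitive background polynomial plus a
  Gaussian Faradaic peak whose integrated charge is calibration_slope x
  concentration, with optional current noise.

All randomness flows through one integer seed per call; no global state.
The generators are phenomenological: no adsorption-isotherm or double-layer
electrochemistry is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import mm
from .datatypes import (ConcentrationTrace, FSCAVSeries, StimulationProtocol,
                        ValidationError, VoltammogramSet,
                        FSCAV_SAMPLING_PERIOD_S)

__all__ = [
    "SyntheticBasalSpec", "CVShapeSpec", "pulse_count",
    "simulate_evoked_trace", "simulate_basal_series",
    "synthesize_voltammograms", "synthesize_fscav_file",
    "synthesize_calibration_standards",
]

#: Oscillation period bounds (minutes) for the ambient-serotonin rhythm.
OSCILLATION_PERIOD_BOUNDS_MIN = (6.0, 10.0)


def pulse_count(protocol: StimulationProtocol) -> int:
    """Pulses delivered by a stimulation train: round(frequency x duration).

    60 Hz for 2 s gives 120 pulses (the in vivo protocol); 60 Hz for 1 s
    gives 60 (the cell-culture protocol).
    """
    return protocol.pulse_count


def simulate_evoked_trace(params: mm.MMParams, protocol: StimulationProtocol,
                          *, dt: float = 0.01, duration: float = 30.0,
                          stim_start: float = 5.0, noise_sd: float = 0.0,
                          seed: int = 0) -> ConcentrationTrace:
    """Evoked FSCV transient: dual-uptake forward solution plus noise.

    With ``noise_sd = 0`` this is exactly the kinetic module's Euler
    solution on the same grid (shared oracle).  Ground truth (parameters,
    noise level, seed) is recorded in the trace metadata.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    trace = mm.simulate(params, protocol, dt=dt, duration=duration,
                        stim_start=stim_start)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace.concentration_nM = (trace.concentration_nM
                                  + rng.normal(0.0, noise_sd,
                                               trace.concentration_nM.size))
    trace.metadata.update({"noise_sd": noise_sd, "seed": seed,
                           "synthetic": True})
    return trace


@dataclass(frozen=True)
class SyntheticBasalSpec:
    """Generative description of an FSCAV basal series.

    series = baseline + sinusoid(period, amplitude) + AR(1) noise
             + ramp of ``drug_ramp_slope`` starting at ``drug_onset``.

    The sampling period is fixed at 60 s (one concentration per FSCAV
    cycle).  A ``oscillation_period_min`` of None draws the period uniformly
    from the 6-10 min band observed in vivo.
    """

    baseline_nM: float = 60.0
    oscillation_period_min: float | None = None
    oscillation_amplitude_nM: float = 5.0
    drug_onset_min: float | None = None
    drug_ramp_slope_nM_per_min: float = 0.0
    noise_sd_nM: float = 1.0
    ar1_coefficient: float = 0.3
    duration_min: float = 60.0
    sampling_period_s: float = FSCAV_SAMPLING_PERIOD_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_period_s != FSCAV_SAMPLING_PERIOD_S:
            raise ValidationError("FSCAV sampling period is fixed at 60 s")
        if self.oscillation_period_min is not None:
            lo, hi = OSCILLATION_PERIOD_BOUNDS_MIN
            if not 0 < self.oscillation_period_min:
                raise ValidationError("oscillation period must be > 0")
        if self.duration_min < 0 or self.noise_sd_nM < 0:
            raise ValidationError("duration and noise_sd must be >= 0")
        if not -1.0 < self.ar1_coefficient < 1.0:
            raise ValidationError("AR(1) coefficient must lie in (-1, 1)")


def simulate_basal_series(spec: SyntheticBasalSpec) -> FSCAVSeries:
    """Generate a basal ambient-serotonin series from its spec.

    The AR(1) noise is driven by Gaussian innovations scaled so the
    stationary SD equals ``noise_sd_nM``.  Durations shorter than one
    oscillation period produce a warning in the metadata rather than an
    error.  Length = floor(duration_min * 60 / 60) samples.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(math.floor(spec.duration_min * 60.0 / spec.sampling_period_s))
    t_min = np.arange(n) * (spec.sampling_period_s / 60.0)
    period = spec.oscillation_period_min
    if period is None:
        lo, hi = OSCILLATION_PERIOD_BOUNDS_MIN
        period = float(rng.uniform(lo, hi))
    x = spec.baseline_nM + spec.oscillation_amplitude_nM * np.sin(
        2.0 * np.pi * t_min / period)
    warnings_list = []
    if spec.duration_min < period:
        warnings_list.append("duration shorter than one oscillation period")
    if spec.noise_sd_nM > 0:
        phi = spec.ar1_coefficient
        innov_sd = spec.noise_sd_nM * math.sqrt(1.0 - phi * phi)
        eps = rng.normal(0.0, innov_sd, n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, spec.noise_sd_nM)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + eps[i]
        x = x + noise
    if spec.drug_onset_min is not None and spec.drug_ramp_slope_nM_per_min:
        ramp = np.clip(t_min - spec.drug_onset_min, 0.0, None)
        x = x + spec.drug_ramp_slope_nM_per_min * ramp
    return FSCAVSeries(t_min, x, metadata={
        "spec": spec, "oscillation_period_min": period,
        "warnings": warnings_list, "synthetic": True})


@dataclass(frozen=True)
class CVShapeSpec:
    """Phenomenological single-sweep voltammogram geometry.

    The sweep is a capacitive background polynomial (coefficients in nA,
    evaluated on the raw sample index, lowest order first) plus a Gaussian
    Faradaic peak centred at ``peak_center`` with SD ``peak_width`` samples.
    The peak's time-integrated charge is ``calibration_slope_pC_per_nM``
    times the analyte concentration.  The default background is a linear
    ramp: the charge-integration baseline subtraction removes straight lines
    exactly, so linear backgrounds keep the synthetic round trip faithful.
    """

    peak_center: int = 300
    peak_width: float = 20.0
    calibration_slope_pC_per_nM: float = 0.5
    background_polynomial_coefficients: tuple[float, ...] = (100.0, 0.05)
    noise_sd_nA: float = 0.0
    sweep_length: int = 1000
    sample_interval_s: float = 2.2e-6

    def __post_init__(self) -> None:
        if self.calibration_slope_pC_per_nM <= 0:
            raise ValidationError("calibration slope must be > 0")
        if self.peak_width <= 0 or self.sweep_length < 3:
            raise ValidationError("invalid peak width or sweep length")
        if not (0 <= self.peak_center - 3 * self.peak_width
                and self.peak_center + 3 * self.peak_width < self.sweep_length):
            raise ValidationError(
                "peak_center +/- 3*peak_width must lie inside the sweep")
        if self.noise_sd_nA < 0 or self.sample_interval_s <= 0:
            raise ValidationError("invalid noise SD or sample interval")

    def background(self) -> np.ndarray:
        idx = np.arange(self.sweep_length, dtype=float)
        bg = np.zeros(self.sweep_length)
        for power, coeff in enumerate(self.background_polynomial_coefficients):
            bg += coeff * idx ** power
        return bg

    def peak(self, concentration_nM: float) -> np.ndarray:
        """Gaussian peak current (nA) whose integral is slope * c (pC)."""
        idx = np.arange(self.sweep_length, dtype=float)
        area_nA_s = self.calibration_slope_pC_per_nM * concentration_nM * 1e-3
        sigma_s = self.peak_width * self.sample_interval_s
        amplitude = area_nA_s / (math.sqrt(2.0 * math.pi) * sigma_s)
        return amplitude * np.exp(-0.5 * ((idx - self.peak_center)
                                          / self.peak_width) ** 2)


def synthesize_voltammograms(concentrations_nM: Sequence[float],
                             shape: CVShapeSpec, seed: int = 0,
                             *, metadata: dict | None = None
                             ) -> VoltammogramSet:
    """One sweep per concentration: background + Faradaic peak + noise.

    Sweeps are ordered as given; the integrated peak charge is exactly
    linear in concentration when the noise SD is 0.
    """
    concentrations = np.asarray(list(concentrations_nM), dtype=float)
    if np.any(concentrations < 0):
        raise ValidationError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    background = shape.background()
    sweeps = np.empty((concentrations.size, shape.sweep_length))
    for i, c in enumerate(concentrations):
        sweeps[i] = background + shape.peak(c)
    if shape.noise_sd_nA > 0:
        sweeps = sweeps + rng.normal(0.0, shape.noise_sd_nA, sweeps.shape)
    meta = {"concentrations_nM": concentrations.tolist(), "shape": shape,
            "seed": seed, "synthetic": True}
    meta.update(metadata or {})
    return VoltammogramSet(sweeps, sample_interval_s=shape.sample_interval_s,
                           metadata=meta)


def synthesize_fscav_file(concentration_nM: float, shape: CVShapeSpec,
                          *, n_background: int = 12, n_post: int = 5,
                          seed: int = 0) -> VoltammogramSet:
    """One 60 s FSCAV file: background-only sweeps, then post-adsorption CVs.

    The first ``n_background`` sweeps carry no Faradaic peak (waveform
    re-equilibration before the hold); the ``n_post`` sweeps after the
    adsorption boundary all carry the peak for ``concentration_nM``, so the
    third post-boundary CV used for quantification reflects the ambient
    level.  The boundary index is stored in metadata.
    """
    concentrations = [0.0] * n_background + [concentration_nM] * n_post
    return synthesize_voltammograms(
        concentrations, shape, seed=seed,
        metadata={"adsorption_boundary": n_background,
                  "true_concentration_nM": concentration_nM})


def synthesize_calibration_standards(shape: CVShapeSpec,
                                     concentrations_nM: Sequence[float] = (
                                         10.0, 25.0, 50.0, 100.0),
                                     *, intercept_pC: float = 0.0
                                     ) -> list[tuple[float, float]]:
    """(concentration, charge) standards on the generator's exact line."""
    return [(float(c),
             float(shape.calibration_slope_pC_per_nM * c + intercept_pC))
            for c in concentrations_nM]
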