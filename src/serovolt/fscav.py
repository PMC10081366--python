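"""FSCAV processing: from voltammogram files to calibrated basal serotonin.

Each 60 s FSCAV cycle yields one file of sweeps: the waveform is applied
rapidly, a controlled-adsorption hold lets ambient serotonin preconcentrate
on the fiber, and the waveform is reapplied.  Per file the chain is:

1. background subtraction — the mean of the first 10 sweeps is subtracted
   from every sweep;
2. the *third* CV after the adsorption boundary is selected (the adsorbed
   analyte is stripped over the first reapplied sweeps; the third gives a
   stable estimate);
3. the charge under the serotonin Faradaic peak is computed with Simpson's
   rule between bounds found by a local-minima search, minus the capacitive
   baseline (the trapezoid under the straight line joining the endpoint
   currents);
4. charge maps to concentration through an electrode-specific linear
   calibration fitted on standards (10, 25, 50, 100 nM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .datatypes import (FSCAVSeries, ValidationError, Voltammogram,
                        VoltammogramSet, FSCAV_SAMPLING_PERIOD_S)

__all__ = [
    "CalibrationModel", "background_subtract", "select_measurement_cv",
    "integrate_peak", "fit_calibration", "process_series",
]

logger = logging.getLogger(__name__)

#: Number of initial sweeps averaged into the subtracted background.
N_BACKGROUND_SWEEPS = 10
#: Moving-average span used only for local-minima detection.
MINIMA_SMOOTHING_SPAN = 5


def background_subtract(sweeps: VoltammogramSet) -> VoltammogramSet:
    """Subtract the mean of the first 10 sweeps from every sweep."""
    if sweeps.n_sweeps < N_BACKGROUND_SWEEPS + 1:
        raise ValidationError(
            f"background subtraction needs >= {N_BACKGROUND_SWEEPS + 1} sweeps")
    background = sweeps.currents_nA[:N_BACKGROUND_SWEEPS].mean(axis=0)
    return VoltammogramSet(sweeps.currents_nA - background,
                           sweep_rate_hz=sweeps.sweep_rate_hz,
                           sample_interval_s=sweeps.sample_interval_s,
                           metadata={**sweeps.metadata,
                                     "background_subtracted": True})


def select_measurement_cv(sweeps: VoltammogramSet) -> Voltammogram:
    """The third CV (1-based) after the adsorption boundary.

    ``metadata['adsorption_boundary']`` must hold the 0-based index of the
    first sweep recorded after the adsorption hold; the sweep at
    ``boundary + 2`` is returned.
    """
    boundary = sweeps.metadata.get("adsorption_boundary")
    if boundary is None:
        raise ValidationError("metadata lacks 'adsorption_boundary'")
    boundary = int(boundary)
    index = boundary + 2
    if index >= sweeps.n_sweeps:
        raise ValidationError(
            f"need >= 3 sweeps after the adsorption boundary "
            f"(boundary {boundary}, {sweeps.n_sweeps} sweeps)")
    return sweeps.sweep(index)


def _smooth(x: np.ndarray, span: int) -> np.ndarray:
    kernel = np.ones(span) / span
    pad = span // 2
    ext = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    return np.convolve(ext, kernel, mode="valid")


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict sign changes (- to +) of the first difference."""
    d = np.diff(x)
    return np.where((d[:-1] < 0) & (d[1:] > 0))[0] + 1


def integrate_peak(cv: Voltammogram, search_window: tuple[int, int],
                   *, bounds: str = "auto") -> float:
    """Charge (pC) under the Faradaic peak inside ``search_window``.

    With ``bounds="auto"`` (default) the integration bounds are the local
    minima nearest the window's global maximum on either side, detected on
    a 5-point moving-average smoothed copy (the smoothing is used only for
    bounds detection); if a flank has no minimum inside the window the
    bound falls back to the window edge with a logged warning.
    ``bounds="window"`` pins both bounds to the window edges, which makes
    the charge exactly invariant to adding any straight line to the sweep.
    The charge is the Simpson integral of current between the bounds minus
    the trapezoid under the straight line joining the endpoint currents
    (capacitive-baseline subtraction).  Current is in nA and the time base
    comes from the sweep sample interval, so nA * s * 1e3 = pC.
    """
    lo, hi = int(search_window[0]), int(search_window[1])
    current = cv.current_nA
    if not (0 <= lo < hi <= current.size):
        raise ValidationError("search window outside sweep")
    if bounds not in ("auto", "window"):
        raise ValidationError("bounds must be 'auto' or 'window'")
    seg = current[lo:hi]
    if seg.size < 3:
        raise ValidationError("search window too short")
    left, right = 0, seg.size - 1
    if bounds == "auto":
        smooth = _smooth(seg, MINIMA_SMOOTHING_SPAN)
        peak = int(np.argmax(smooth))
        minima = _local_minima(smooth)
        left_candidates = minima[minima < peak]
        right_candidates = minima[minima > peak]
        if left_candidates.size:
            left = int(left_candidates.max())  # minimum nearest the peak
        else:
            logger.warning("no left flanking minimum; using window edge")
        if right_candidates.size:
            right = int(right_candidates.min())
        else:
            logger.warning("no right flanking minimum; using window edge")
    y = seg[left:right + 1]
    t = np.arange(y.size) * cv.sample_interval_s
    total = float(integrate.simpson(y, x=t))
    baseline = 0.5 * (y[0] + y[-1]) * float(t[-1])  # trapezoid under chord
    return (total - baseline) * 1e3  # nA*s -> pC


@dataclass
class CalibrationModel:
    """Electrode-specific linear charge-vs-concentration calibration."""

    slope_pC_per_nM: float
    intercept_pC: float
    r_squared: float
    standards: list[tuple[float, float]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.slope_pC_per_nM > 0

    def concentration(self, charge_pC: float) -> float:
        """Invert the calibration; floored at 0 nM with a logged event."""
        c = (charge_pC - self.intercept_pC) / self.slope_pC_per_nM
        if c < 0:
            logger.warning("charge %.3g pC below intercept; flooring at 0 nM",
                           charge_pC)
            return 0.0
        return c


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of charge (pC) on concentration (nM).

    Standards are (concentration_nM, charge_pC) pairs; at least two distinct
    concentrations are required.  A non-positive fitted slope leaves the
    model flagged invalid (``model.valid``).
    """
    if len(standards) < 2:
        raise ValidationError("need >= 2 calibration standards")
    conc = np.array([s[0] for s in standards], dtype=float)
    charge = np.array([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise ValidationError("calibration standards must span >= 2 "
                              "distinct concentrations")
    res = stats.linregress(conc, charge)
    model = CalibrationModel(slope_pC_per_nM=float(res.slope),
                             intercept_pC=float(res.intercept),
                             r_squared=float(res.rvalue ** 2),
                             standards=[(float(c), float(q))
                                        for c, q in standards])
    if not model.valid:
        logger.warning("calibration slope %.3g pC/nM is non-positive; "
                       "model flagged invalid", model.slope_pC_per_nM)
    return model


def process_series(files: Sequence[VoltammogramSet], model: CalibrationModel,
                   search_window: tuple[int, int]) -> FSCAVSeries:
    """Run the full per-file chain and assemble the basal series.

    Files are assumed consecutive 60 s cycles; timestamps are minutes from
    the first file.  Any stage error is re-raised with the file index.
    """
    if not model.valid:
        raise ValidationError("calibration model is invalid (slope <= 0)")
    concentrations = []
    for i, f in enumerate(files):
        try:
            subtracted = background_subtract(f)
            cv = select_measurement_cv(subtracted)
            charge = integrate_peak(cv, search_window)
            concentrations.append(model.concentration(charge))
        except ValidationError as exc:
            raise ValidationError(f"file {i}: {exc}") from exc
    time_min = np.arange(len(concentrations)) * (FSCAV_SAMPLING_PERIOD_S / 60.0)
    return FSCAVSeries(time_min, np.array(concentrations),
                       metadata={"n_files": len(files),
                                 "search_window": (int(search_window[0]),
                                                   int(search_window[1])),
                                 "slope_pC_per_nM": model.slope_pC_per_nM,
                                 "intercept_pC": model.intercept_pC})
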