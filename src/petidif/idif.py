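"""From blood factor to calibrated, fitted, metabolite-corrected input function.

The factor analysis returns curves in arbitrary concentration-like units.
Calibration to absolute activity follows the whole-body bookkeeping: the
summed factor reconstruction is compared with the whole-body TAC (in Bq) and
the ratio, averaged over frames from 10 min onwards (once the fast vascular
transient is over and the ratio is stable), rescales the blood factor into Bq.
The calibrated curve can then be fitted with a linear-rise + tri-exponential
model, corrected to parent plasma with a population parent-fraction curve,
and converted to percent injected dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .factor_analysis import FactorModel
from .io import Curve, FrameSchedule
from .phantom import frame_average


@dataclass(frozen=True)
class InputFit:
    """Parameters of the linear-rise + tri-exponential input model.

    The curve is 0 before ``rise_start``, rises linearly to ``sum(amps)`` at
    ``peak_time`` and decays as ``sum_i amps_i * exp(-rates_i (t - peak_time))``.
    Amplitudes in the curve's unit (Bq), rates in 1/s.
    """

    rise_start: float
    peak_time: float
    amps: tuple[float, float, float]
    rates: tuple[float, float, float]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        peak = float(sum(self.amps))
        rising = (t >= self.rise_start) & (t < self.peak_time)
        out[rising] = peak * (t[rising] - self.rise_start) / (self.peak_time - self.rise_start)
        after = t >= self.peak_time
        tail = np.zeros(int(after.sum()))
        for a, r in zip(self.amps, self.rates):
            tail += a * np.exp(-r * (t[after] - self.peak_time))
        out[after] = tail
        return out


@dataclass
class InputFunction:
    """Blood input curve in absolute units with provenance flags.

    ``whole_blood`` is total blood-pool activity (Bq) per frame;
    ``parent_plasma`` appears after metabolite correction.  ``fine_times`` /
    ``fine_values`` hold a dense version (from a parametric fit or a fine
    simulation grid) used for convolution-based modelling downstream.
    """

    times: np.ndarray
    whole_blood: np.ndarray
    schedule: FrameSchedule
    parent_plasma: np.ndarray | None = None
    calibration_scale: float | None = None
    fit: InputFit | None = None
    fit_failed: bool = False
    fine_times: np.ndarray | None = None
    fine_values: np.ndarray | None = None
    unit: str = "Bq"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        if self.times.shape != self.whole_blood.shape:
            raise ValueError("times and whole_blood must have the same length")
        if self.parent_plasma is not None:
            self.parent_plasma = np.asarray(self.parent_plasma, dtype=float)
            if np.any(self.parent_plasma > self.whole_blood * (1 + 1e-9) + 1e-9):
                raise ValueError("parent_plasma cannot exceed whole_blood")

    @property
    def is_metabolite_corrected(self) -> bool:
        return self.parent_plasma is not None

    def as_concentration(self) -> "InputFunction":
        """Undo the whole-body calibration, returning the curve at the blood
        factor's native voxel scale (a Bq/cc plasma-concentration proxy).

        Kinetic modelling divides tissue concentration by plasma
        concentration, so V_T maps built from this view land near their
        physical mL/cc scale (biased by the blood pool's partial-volume
        recovery); the calibrated Bq view is for %ID and dose bookkeeping.
        """
        if self.calibration_scale is None or self.calibration_scale == 0:
            return self
        s = self.calibration_scale
        return replace(
            self,
            whole_blood=self.whole_blood / s,
            parent_plasma=None if self.parent_plasma is None else self.parent_plasma / s,
            fine_values=None if self.fine_values is None else self.fine_values / s,
            unit="Bq/cc",
        )

    def whole_blood_curve(self) -> Curve:
        return Curve(self.times, self.whole_blood, unit=self.unit)

    def parent_curve(self) -> Curve:
        if self.parent_plasma is None:
            raise ValueError("metabolite correction has not been applied")
        return Curve(self.times, self.parent_plasma, unit=self.unit)

    def parent_on_grid(self, t: np.ndarray) -> np.ndarray:
        """Parent-plasma values on an arbitrary grid: the dense fitted curve
        when available, otherwise linear interpolation anchored at (0, 0)."""
        t = np.asarray(t, dtype=float)
        if self.parent_plasma is None:
            raise ValueError("metabolite correction has not been applied")
        if self.fine_times is not None and self.fine_values is not None:
            src_t, src_v = self.fine_times, self.fine_values
            # fine grid holds whole blood; rescale by the parent fraction
            frac = np.ones_like(self.whole_blood)
            nz = self.whole_blood > 0
            frac[nz] = self.parent_plasma[nz] / self.whole_blood[nz]
            fine_frac = np.interp(src_t, self.times, frac)
            src_v = src_v * fine_frac
        else:
            src_t, src_v = self.times, self.parent_plasma
            if src_t[0] > 0:
                src_t = np.concatenate([[0.0], src_t])
                src_v = np.concatenate([[0.0], src_v])
        return np.interp(t, src_t, src_v)


@dataclass
class MetaboliteCurve:
    """Population parent-fraction curve: fraction of plasma activity that is
    unmetabolised tracer.  Convention: parent_fraction(0) = 1, non-increasing."""

    times: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
        if self.times.shape != self.parent_fraction.shape:
            raise ValueError("times and parent_fraction must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.parent_fraction < 0) | (self.parent_fraction > 1)):
            raise ValueError("parent fraction must lie in [0, 1]")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation inside the table, constant extrapolation outside."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.parent_fraction)


def population_metabolite_curve() -> MetaboliteCurve:
    """Editable default population parent-fraction table.

    These values are a synthetic placeholder with the typical shape of a
    TSPO-tracer parent fraction (unity at injection, ~40% at one hour); for
    real studies supply a measured population table instead.
    """
    path = Path(__file__).parent / "data" / "population_parent_fraction.tsv"
    rows = np.loadtxt(path, comments="#", skiprows=1)
    return MetaboliteCurve(rows[:, 0], rows[:, 1])


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def normalize_to_activity(
    model: FactorModel, wb_tac: Curve, t_start: float = 600.0
) -> InputFunction:
    """Calibrate the blood factor via the whole-body ratio.

    The summed factor reconstruction ``F(t) = sum_k f_k(t) * sum_i a_k(i)``
    is compared with the whole-body TAC; the ratio, averaged over frames with
    mid-time >= ``t_start`` (default 10 min), rescales the blood factor curve:
    ``whole_blood = scale * f_blood``.

    The ratio is anchored to the total image signal and the blood curve to
    its strongest voxel, both of which are stable quantities; the blood
    factor's *image-weight total* deliberately does not enter the output —
    how the unmixing distributes small vascular coefficients across thousands
    of tissue voxels varies between runs and would leak into the amplitude.
    The result is proportional to delivered activity and consistent across
    animals (which is what downstream V_T and dose-linearity need), at an
    arbitrary overall scale set by the whole-body bookkeeping.
    """
    wb_tac.require_unit("Bq")
    totals = model.factor_totals()
    F = totals @ model.factor_curves  # summed factor reconstruction per frame
    mids = model.schedule.mids
    late = mids >= t_start
    if late.sum() < 2:
        raise ValueError("need at least 2 frames after t_start for calibration")
    if np.any(F[late] <= 0):
        raise ValueError("summed factor curve vanishes inside the calibration window")
    scale = float(np.mean(wb_tac.values[late] / F[late]))
    return InputFunction(
        times=mids,
        whole_blood=scale * model.factor_curves[model.blood_index],
        schedule=model.schedule,
        calibration_scale=scale,
    )


# --------------------------------------------------------------------------
# Parametric fit
# --------------------------------------------------------------------------

_RATE_STARTS = (
    (0.05, 0.005, 0.0005),
    (0.02, 0.002, 0.0002),
    (0.1, 0.01, 0.001),
)


def fit_input_function(raw: InputFunction, dt: float = 1.0) -> InputFunction:
    """Weighted multi-start fit of the linear-rise + tri-exponential model.

    The model is frame-averaged on a fine grid before comparison with the
    measured frame values; weights are proportional to frame duration.  On
    success the frame values are replaced by the fitted ones and a dense
    fitted curve is attached; on failure the raw curve is returned with
    ``fit_failed`` set.
    """
    sched = raw.schedule
    if len(sched) < 8:
        raise ValueError("need at least 8 frames to fit the input model")
    y = raw.whole_blood
    if np.allclose(y, 0.0):
        fit = InputFit(0.0, sched.mids[1], (0.0, 0.0, 0.0), _RATE_STARTS[1])
        return replace(raw, fit=fit, fit_failed=False)

    w = np.sqrt(sched.durations / sched.durations.max())
    t_fine = np.arange(0.0, sched.total_duration, dt)
    peak_idx = int(np.argmax(y))
    tp0 = float(sched.mids[peak_idx])
    peak0 = float(y.max())

    def unpack(p):
        t0, tp = p[0], p[1]
        amps = tuple(np.exp(p[2:5]))
        rates = tuple(np.exp(p[5:8]))
        return InputFit(t0, tp, amps, rates)

    def residuals(p):
        fit = unpack(p)
        if fit.peak_time <= fit.rise_start + 1.0:
            return 1e6 * np.ones_like(y)
        pred = frame_average(fit.evaluate(t_fine), dt, sched)
        return (pred - y) * w

    best, best_cost = None, np.inf
    for rates in _RATE_STARTS:
        amp0 = np.maximum(np.array([0.5, 0.3, 0.2]) * peak0, 1e-12)
        p0 = np.concatenate([[0.0, tp0], np.log(amp0), np.log(rates)])
        lo = [-60.0, 5.0] + [np.log(1e-12)] * 3 + [np.log(1e-6)] * 3
        hi = [tp0, sched.total_duration / 4] + [np.log(peak0 * 10 + 1e-12)] * 3 + [np.log(1.0)] * 3
        p0 = np.clip(p0, lo, hi)
        try:
            sol = least_squares(residuals, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    rel = np.sqrt(2 * best_cost) / (np.linalg.norm(y * w) + 1e-30) if best is not None else np.inf
    if best is None or not np.isfinite(rel):
        return replace(raw, fit_failed=True)
    fit = unpack(best.x)
    fitted_fine = fit.evaluate(t_fine)
    fitted_frames = frame_average(fitted_fine, dt, sched)
    return replace(
        raw,
        whole_blood=fitted_frames,
        fit=fit,
        fit_failed=False,
        fine_times=t_fine,
        fine_values=fitted_fine,
    )


# --------------------------------------------------------------------------
# Metabolite correction and unit conversions
# --------------------------------------------------------------------------

def apply_metabolite_correction(ifn: InputFunction, met: MetaboliteCurve) -> InputFunction:
    """Parent plasma = whole blood x parent fraction, interpolated at frame mids."""
    frac = met.at(ifn.times)
    return replace(ifn, parent_plasma=ifn.whole_blood * frac)


_PERCENT_ID_UNITS = {"Bq": "percent_id", "Bq/cc": "percent_id_per_cc"}


def to_percent_id(curve: Curve, injected_dose: float) -> Curve:
    """Convert an activity curve to percent of injected dose."""
    if injected_dose <= 0:
        raise ValueError("injected dose must be positive (Bq)")
    try:
        unit = _PERCENT_ID_UNITS[curve.unit]
    except KeyError:
        raise ValueError(f"cannot convert a {curve.unit!r} curve to %ID") from None
    return Curve(curve.times, curve.values * 100.0 / injected_dose, unit=unit)


def average_idif(curves: list[Curve]) -> tuple[Curve, Curve]:
    """Pointwise mean and standard deviation of curves on a common time grid."""
    if not curves:
        raise ValueError("need at least one curve")
    t0, unit = curves[0].times, curves[0].unit
    for c in curves[1:]:
        if len(c) != len(t0) or not np.allclose(c.times, t0):
            raise ValueError("curves are on different time grids; resample first")
        if c.unit != unit:
            raise ValueError("curves have mixed units")
    stack = np.stack([c.values for c in curves])
    return (
        Curve(t0, stack.mean(axis=0), unit=unit),
        Curve(t0, stack.std(axis=0), unit=unit),
    )
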