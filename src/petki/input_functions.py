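"""Plasma input functions: population bolus, IDIF, hybrid and dual-injection.

Four ways of obtaining the plasma input Cp(t) are implemented:

* a **population bolus model** — the Feng sum-of-exponentials form
  ``Cp(t) = (A1*t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t}``,
  used when no image-derived curve covers the full scan;
* the **image-derived input function (IDIF)** — per-frame mean over a
  blood-pool mask (ascending aorta in practice), interpolated to the fine
  grid;
* the **hybrid input function** for the dual-time-point protocol — the
  early and late IDIF segments joined across the unscanned gap by a scaled,
  exponentially tilted population curve ``mu * e^{-gamma (t - t1)} * Cp0(t)``
  with mu and gamma fixed by continuity at the junctions t1 and t2;
* the **dual-injection decomposition** for the single-window protocol —
  the pre-second-injection tail is fitted with ``C_B0 e^{-b t}`` and
  subtracted from the post-injection IDIF, isolating the second bolus,
  whose shape is assumed identical to the first injection's.

The composite input driving the dual-injection model is then the first
input function plus the (dose-scaled) bolus shifted to the second injection
time — exact superposition, since the tissue model is linear and
time-invariant in Cp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .curves import DEFAULT_DT, SampledCurve, uniform_grid
from .errors import CurveError, DecompositionError, JunctionError
from .protocols import DynamicImage


@dataclass(frozen=True)
class FengParams:
    """Coefficients of the Feng bolus model, time in minutes.

    Defaults are the classic published FDG values: amplitudes in kBq/mL
    (A1 in kBq/mL/min) and decay rates in min^-1.  ``scale`` multiplies the
    whole curve (injected-dose / calibration factor).
    """

    A1: float = 851.1225
    A2: float = 21.8798
    A3: float = 20.8113
    l1: float = 4.133859
    l2: float = 0.01043
    l3: float = 0.1190996
    scale: float = 1.0

    def __call__(self, t_s):
        """Evaluate at times in seconds."""
        tm = np.asarray(t_s, dtype=float) / 60.0
        v = ((self.A1 * tm - self.A2 - self.A3) * np.exp(-self.l1 * tm)
             + self.A2 * np.exp(-self.l2 * tm)
             + self.A3 * np.exp(-self.l3 * tm))
        return self.scale * v


def population_if(params: FengParams | None = None,
                  grid: np.ndarray | None = None) -> SampledCurve:
    """Sample the population bolus model on a time grid.

    The curve must be a physically plausible bolus: nonnegative (within a
    small tolerance, then clipped) with its peak inside the first minute.
    """
    params = params or FengParams()
    if grid is None:
        grid = uniform_grid(3600.0, DEFAULT_DT)
    if not all(np.isfinite(getattr(params, f))
               for f in ("A1", "A2", "A3", "l1", "l2", "l3", "scale")):
        raise CurveError("population-model coefficients must be finite")
    v = params(grid)
    peak = float(np.max(np.abs(v)))
    if peak > 0 and float(v.min()) < -1e-6 * peak:
        raise CurveError("population model produces negative concentrations")
    return SampledCurve(grid, np.clip(v, 0.0, None))


def extract_idif(dyn: DynamicImage, blood_mask: np.ndarray,
                 dt: float = DEFAULT_DT) -> SampledCurve:
    """Image-derived input function from a blood-pool mask.

    The per-frame mask mean is taken as the curve value at the frame
    midpoint and interpolated piecewise-linearly onto a fine uniform grid
    spanning the acquisition, with constant extrapolation at both ends.
    """
    means = dyn.frame_means(blood_mask)  # validates the mask
    mid = dyn.schedule.midpoints
    grid = uniform_grid(dyn.schedule.frame_ends[-1], dt,
                        t_start=dyn.schedule.frame_starts[0])
    return SampledCurve(grid, np.interp(grid, mid, means))


@dataclass(frozen=True)
class HybridIFSpec:
    """Junction parameters of a hybrid input function.

    mu scales the population curve to meet the early IDIF at t1; gamma
    (per second) tilts it so the scaled curve meets the late IDIF at t2.
    """

    t1: float
    t2: float
    mu: float
    gamma: float


def build_hybrid_if(early: SampledCurve, late: SampledCurve,
                    pop: SampledCurve, t1: float, t2: float,
                    dt: float = DEFAULT_DT):
    """Stitch early/late IDIF segments across the gap with the population curve.

    Returns the full-support curve on ``[0, late.t_end]`` and the
    :class:`HybridIFSpec`.  Continuity at t1 and t2 is exact by
    construction::

        mu    = early(t1) / pop(t1)
        gamma = ln(mu * pop(t2) / late(t2)) / (t2 - t1)
    """
    if t1 >= t2:
        raise JunctionError(f"t1 = {t1} must precede t2 = {t2}")
    e1, p1 = float(early(t1)), float(pop(t1))
    l2, p2 = float(late(t2)), float(pop(t2))
    if min(e1, p1, l2, p2) <= 0:
        raise JunctionError("junction values must be positive")
    mu = e1 / p1
    gamma = np.log(mu * p2 / l2) / (t2 - t1)
    t_end = late.t_end
    grid = uniform_grid(t_end, dt)
    v = np.empty_like(grid)
    a = grid <= t1
    b = (grid > t1) & (grid < t2)
    c = grid >= t2
    v[a] = early(grid[a])
    v[b] = mu * np.exp(-gamma * (grid[b] - t1)) * pop(grid[b])
    v[c] = late(grid[c])
    # enforce the continuity identities at the junction grid points exactly
    v[np.isclose(grid, t1)] = e1
    v[np.isclose(grid, t2)] = l2
    return SampledCurve(grid, v), HybridIFSpec(float(t1), float(t2),
                                               float(mu), float(gamma))


@dataclass(frozen=True)
class DualInjectionFit:
    """Single-exponential fit ``C_B0 * exp(-b t)`` to the pre-t0 tail.

    t is absolute time from the first injection (seconds); b in s^-1.
    """

    C_B0: float
    b: float
    t0: float

    def __call__(self, t_s):
        return self.C_B0 * np.exp(-self.b * np.asarray(t_s, dtype=float))


def decompose_dual_injection(idif_window: SampledCurve, t0: float,
                             b_tol: float = 1e-7):
    """Separate the second-injection bolus from a late-window IDIF.

    ``idif_window`` is the IDIF over the single scanning window (nominally
    [3000, 3600] s); ``t0`` is the second injection time.  The tail before
    t0 is fitted with ``C_B0 e^{-b t}`` (nonlinear least squares on the
    linear scale, log-linear initialization); the fitted curve extrapolated
    past t0 is subtracted from the IDIF and the difference — clipped at
    zero — is the recovered second bolus, re-indexed to start at 0.

    Returns ``(early_phase, late_phase, fit)`` where ``late_phase`` is the
    measured pre-t0 IDIF segment.
    """
    t, v = idif_window.t, idif_window.v
    pre = t < t0
    if pre.sum() < max(2, int(round(120.0 / idif_window.dt))):
        raise DecompositionError("need >= 120 s of data before t0")
    if not (t0 < t[-1]):
        raise DecompositionError("t0 must lie inside the IDIF window")
    tp, vp = t[pre], v[pre]
    if np.any(vp <= 0):
        raise DecompositionError("pre-t0 IDIF values must be positive")
    # log-linear initialization, then least squares on the linear scale;
    # fitted in time relative to the window start (fitting C_B0*exp(-b*t)
    # directly is ill-conditioned for windows far from t = 0)
    t_ref = tp[0]
    tr = tp - t_ref
    slope, logc = np.polyfit(tr, np.log(vp), 1)
    p0 = (float(np.exp(logc)), max(-slope, 0.0))
    try:
        popt, _ = curve_fit(lambda tt, c0, b: c0 * np.exp(-b * tt),
                            tr, vp, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover
        raise DecompositionError(f"tail fit did not converge: {exc}") from exc
    b = float(popt[1])
    c0 = float(popt[0] * np.exp(b * t_ref))  # back to absolute time
    if c0 <= 0 or b < -b_tol:
        raise DecompositionError(
            f"tail fit unphysical (C_B0 = {c0:.4g}, b = {b:.4g} /s)")
    b = max(b, 0.0)
    fit = DualInjectionFit(c0, b, float(t0))
    post = t >= t0
    tau = t[post] - t0
    bolus = np.clip(v[post] - fit(t[post]), 0.0, None)
    early = SampledCurve(tau, bolus)
    late = SampledCurve(tp, vp)
    return early, late, fit


def assemble_composite_if(first_if: SampledCurve, second_bolus: SampledCurve,
                          t0: float, dose_ratio: float = 1.0) -> SampledCurve:
    """Two-injection input: ``Cp(t) + dose_ratio * bolus(t - t0)``.

    The second bolus is assumed to share the first injection's shape; the
    model is linear and time-invariant in Cp, so superposition is exact.
    The bolus contributes only on ``[t0, t0 + bolus support]`` and is
    truncated at the first curve's end.  Grids are unified at the finer dt.
    """
    if dose_ratio <= 0:
        raise CurveError("dose_ratio must be positive")
    dt = min(first_if.dt, second_bolus.dt)
    out = first_if.resample(dt) if dt != first_if.dt else first_if
    tau = out.t - t0
    inside = (tau >= second_bolus.t_start) & (tau <= second_bolus.t_end)
    add = np.zeros_like(out.v)
    add[inside] = dose_ratio * second_bolus(tau[inside])
    return SampledCurve(out.t, out.v + add)


def auc_ratio(a: SampledCurve, b: SampledCurve) -> float:
    """Trapezoidal AUC(a) / AUC(b) over the common support."""
    lo = max(a.t_start, b.t_start)
    hi = min(a.t_end, b.t_end)
    if hi <= lo:
        raise CurveError("curves share no common support")
    denom = b.auc(lo, hi)
    if denom == 0:
        raise ZeroDivisionError("AUC of the reference curve is zero")
    return a.auc(lo, hi) / denom
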