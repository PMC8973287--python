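"""Uniformly sampled time curves (plasma input functions, tissue TACs).

A :class:`SampledCurve` is the package's in-memory representation of a
continuous-time activity-concentration curve: a uniform time grid in seconds
and one value (kBq/mL) per grid point.  Evaluation between grid points is
piecewise linear; outside the grid the curve is held constant at the end
values (operations that need zero-fill, e.g. delay shifting, say so
explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CurveError

#: default fine-grid step, seconds.  The shortest acquisition frame is 5 s;
#: a 1 s grid resolves the bolus peak with sub-percent quadrature error.
DEFAULT_DT = 1.0


@dataclass(frozen=True)
class SampledCurve:
    """A curve sampled on a uniform time grid.

    Parameters
    ----------
    t : ndarray
        Sample times, seconds.  Must be strictly increasing with a constant
        step.
    v : ndarray
        Values at the sample times, kBq/mL (or the unit the context states).
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise CurveError("t and v must be 1-D arrays of equal length")
        if t.size < 2:
            raise CurveError("a curve needs at least two samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise CurveError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-9):
            raise CurveError("time grid must be uniform")
        if not np.all(np.isfinite(v)):
            raise CurveError("curve values must be finite")

    # -- basic geometry -------------------------------------------------

    @property
    def dt(self) -> float:
        """Grid step, seconds."""
        return float(self.t[1] - self.t[0])

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def __len__(self) -> int:
        return self.t.size

    # -- evaluation -----------------------------------------------------

    def __call__(self, tq):
        """Evaluate at arbitrary times.

        Piecewise-linear inside the grid, constant extrapolation outside.
        """
        return np.interp(np.asarray(tq, dtype=float), self.t, self.v)

    def restrict(self, a: float, b: float) -> "SampledCurve":
        """Return the sub-curve with ``a <= t <= b`` (grid points only)."""
        sel = (self.t >= a - 1e-9) & (self.t <= b + 1e-9)
        if sel.sum() < 2:
            raise CurveError(f"restriction to [{a}, {b}] leaves <2 samples")
        return SampledCurve(self.t[sel], self.v[sel])

    def resample(self, dt: float, t_start: float | None = None,
                 t_end: float | None = None) -> "SampledCurve":
        """Linearly resample onto a new uniform grid."""
        a = self.t_start if t_start is None else t_start
        b = self.t_end if t_end is None else t_end
        n = int(round((b - a) / dt))
        grid = a + dt * np.arange(n + 1)
        return SampledCurve(grid, self(grid))

    # -- integrals ------------------------------------------------------

    def auc(self, a: float | None = None, b: float | None = None) -> float:
        """Trapezoidal area under the curve over ``[a, b]`` (kBq*s/mL).

        Endpoints inside the grid are handled by interpolation; endpoints
        outside the grid are clamped to the support.
        """
        a = self.t_start if a is None else max(a, self.t_start)
        b = self.t_end if b is None else min(b, self.t_end)
        if b <= a:
            return 0.0
        inner = self.t[(self.t > a) & (self.t < b)]
        grid = np.concatenate(([a], inner, [b]))
        return float(np.trapezoid(self(grid), grid))

    def shift_values(self, delta: float) -> np.ndarray:
        """Values of ``curve(t - delta)`` on the curve's own grid.

        Zero-filled before the grid start (pre-injection), constant
        extrapolation past the end.
        """
        return np.interp(self.t - delta, self.t, self.v,
                         left=0.0, right=float(self.v[-1]))


def uniform_grid(t_end: float, dt: float = DEFAULT_DT,
                 t_start: float = 0.0) -> np.ndarray:
    """Uniform time grid ``t_start, t_start+dt, ..., >= t_end`` (seconds)."""
    n = int(np.ceil((t_end - t_start) / dt - 1e-9))
    return t_start + dt * np.arange(n + 1)
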