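"""The irreversible two-tissue-compartment FDG model and its basis form.

The tissue model is

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    X(t)   = vb*Cp(t) + C1(t) + C2(t)

with rate constants in min^-1 (K1 in mL/min/mL) and the plasma input Cp in
kBq/mL.  FDG-6-phosphate is essentially trapped in tumor cells, so the fitted
model sets k4 = 0; the ODE solution then reduces algebraically to the
Patlak-like basis form

    X(t) = vb*Cp(t) + K1' * exp(-k2' t) (x) Cp(t) + Ki * Int_0^t Cp ds

with K1' = K1*k2/(k2+k3), k2' = k2+k3 and the net influx rate
Ki = K1*k3/(k2+k3)  ((x) denotes causal convolution).  This reduction is the
backbone of the estimator; its equivalence with the ODE solution is covered
by tests.

All curves live on a uniform fine grid in seconds; convolution and integral
outputs are converted to kBq*min/mL so that rate constants in min^-1 yield
predictions in kBq/mL.  PET frames measure integrated counts, so the
per-frame model value is the *time average* over the frame, not a midpoint
sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.signal import lfilter

from .curves import SampledCurve
from .errors import ConfigError, SupportError
from .protocols import FrameSchedule

#: default bound on the input-function delay magnitude, seconds.
MAX_DELAY_S = 60.0


@dataclass(frozen=True)
class TissueParams:
    """Microparameters of one tissue: K1 (mL/min/mL), k2..k4 (1/min), vb."""

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    vb: float = 0.05

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "vb"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.vb > 1:
            raise ConfigError("vb must lie in [0, 1]")

    # macroparameters of the k4 = 0 reduction -------------------------

    @property
    def k2p(self) -> float:
        """k2' = k2 + k3, 1/min."""
        return self.k2 + self.k3

    @property
    def K1p(self) -> float:
        """K1' = K1*k2/(k2+k3); 0 when k2+k3 = 0."""
        s = self.k2 + self.k3
        return self.K1 * self.k2 / s if s > 0 else 0.0

    @property
    def Ki(self) -> float:
        """Net influx rate Ki = K1*k3/(k2+k3), 1/min; 0 when k2+k3 = 0."""
        s = self.k2 + self.k3
        return self.K1 * self.k3 / s if s > 0 else 0.0


def solve_2tc(params: TissueParams, cp: SampledCurve) -> SampledCurve:
    """Integrate the two-compartment ODE; return X = vb*Cp + C1 + C2.

    Direct numerical integration (LSODA with a piecewise-linear reading of
    Cp), independent of the convolution-based basis machinery — it serves as
    the phantom's forward simulator and as the oracle the basis form is
    validated against.  Supports k4 > 0 for model-mismatch studies.
    """
    t, v = cp.t, cp.v
    per_s = 1.0 / 60.0  # rate constants are min^-1, the grid is seconds
    K1, k2, k3, k4 = (params.K1 * per_s, params.k2 * per_s,
                      params.k3 * per_s, params.k4 * per_s)

    def rhs(tt, y):
        cpt = np.interp(tt, t, v)
        c1, c2 = y
        return (K1 * cpt - (k2 + k3) * c1 + k4 * c2,
                k3 * c1 - k4 * c2)

    if v.max() == 0.0 or params.K1 == 0.0:
        tissue = np.zeros((2, t.size))
    else:
        sol = solve_ivp(rhs, (t[0], t[-1]), [0.0, 0.0], t_eval=t,
                        method="LSODA", max_step=2.0 * cp.dt,
                        rtol=1e-8, atol=1e-12)
        if not sol.success:  # pragma: no cover - LSODA on a linear system
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        tissue = sol.y
    x = params.vb * v + tissue[0] + tissue[1]
    return SampledCurve(t, x)


def expconv(cp: SampledCurve, k2p: float) -> SampledCurve:
    """Causal convolution ``exp(-k2p t) (x) Cp`` (k2p in 1/min).

    Exact for piecewise-linear Cp via the trapezoidal in-frame recursion

        y[n+1] = a*y[n] + dt/2 * (a*Cp[n] + Cp[n+1]),  a = exp(-k2p*dt)

    Returned values are in kBq*min/mL (the time integral is taken in
    minutes) so multiplying by K1' in min^-1 yields kBq/mL.
    """
    if k2p < 0:
        raise ConfigError("k2p must be nonnegative")
    dt_min = cp.dt / 60.0
    a = float(np.exp(-k2p * dt_min))
    v = cp.v
    half = 0.5 * dt_min
    # drive u[n] = dt/2 * (a*v[n-1] + v[n]) through y[n] = a*y[n-1] + u[n]
    u = np.empty_like(v)
    u[0] = 0.0
    u[1:] = half * (a * v[:-1] + v[1:])
    y = lfilter([1.0], [1.0, -a], u)
    return SampledCurve(cp.t, y)


def cumint(cp: SampledCurve) -> SampledCurve:
    """Running integral ``Ci(t) = Int_0^t Cp ds`` in kBq*min/mL."""
    ci = cumulative_trapezoid(cp.v, cp.t / 60.0, initial=0.0)
    return SampledCurve(cp.t, ci)


def apply_delay(cp: SampledCurve, delta: float,
                max_delay: float = MAX_DELAY_S) -> SampledCurve:
    """Shift the input function: ``Cp(t - delta)``, zero before injection.

    A positive delta models tracer arriving later at the tissue than at the
    blood-pool sampling site.  Grid unchanged; zero-fill before the grid
    start, constant extrapolation past the end.
    """
    if abs(delta) > max_delay:
        raise ConfigError(f"|delta| = {abs(delta)} s exceeds {max_delay} s")
    return SampledCurve(cp.t, cp.shift_values(delta))


def frame_averages(curve: SampledCurve, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a fine-grid curve over each frame ``[start, end)``.

    Uses the cumulative trapezoidal integral, evaluated at the (possibly
    off-grid) frame boundaries by interpolation.  Boundaries before the grid
    start contribute zero (pre-injection); boundaries past the end use
    constant extrapolation of the final value.
    """
    t, v = curve.t, curve.v
    ct = cumulative_trapezoid(v, t, initial=0.0)

    def cum(x):
        x = np.asarray(x, dtype=float)
        out = np.interp(x, t, ct)
        over = x > t[-1]
        if np.any(over):
            out = out + np.where(over, (x - t[-1]) * v[-1], 0.0)
        return out

    s, e = schedule.frame_starts, schedule.frame_ends
    return (cum(e) - cum(s)) / (e - s)


@dataclass(frozen=True)
class BasisSet:
    """Per-frame basis of the linearized model at fixed (k2', delay).

    Bp — frame average of the delayed Cp (kBq/mL); Bexp — of
    ``exp(-k2' t) (x) Cp`` (kBq*min/mL); Bi — of ``Int Cp`` (kBq*min/mL);
    w — frame weights proportional to duration, max-normalized (the
    count-scale surrogate in the scaled-Poisson likelihood).
    """

    Bp: np.ndarray
    Bexp: np.ndarray
    Bi: np.ndarray
    w: np.ndarray
    k2p: float
    delta: float


def make_basis(cp: SampledCurve, k2p: float, delta: float,
               schedule: FrameSchedule) -> BasisSet:
    """Build the per-frame basis for one (k2', delay) setting."""
    # pre-grid times are legitimate zero-fill (pre-injection); what must be
    # guarded is extrapolation past the end of the sampled curve
    if (schedule.frame_ends[-1] - min(delta, 0.0) > cp.t_end + 1e-6
            or schedule.frame_starts[0] < cp.t_start - max(delta, 0.0) - 1e-6):
        raise SupportError("frame schedule extends beyond the Cp support")
    cpd = apply_delay(cp, delta)
    bp = frame_averages(cpd, schedule)
    bexp = frame_averages(apply_delay(expconv(cp, k2p), delta), schedule)
    bi = frame_averages(apply_delay(cumint(cp), delta), schedule)
    w = schedule.durations / schedule.durations.max()
    return BasisSet(bp, bexp, bi, w, float(k2p), float(delta))


def forward_model(vb: float, K1p: float, Ki: float,
                  basis: BasisSet) -> np.ndarray:
    """Per-frame predicted activity ``vb*Bp + K1'*Bexp + Ki*Bi`` (kBq/mL)."""
    return vb * basis.Bp + K1p * basis.Bexp + Ki * basis.Bi
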