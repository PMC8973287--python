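"""Voxelwise maximum-likelihood kinetic estimation and the Patlak reference.

Dynamic-image voxel values are treated as approximately scaled-Poisson
distributed, with frame duration as the count-scale surrogate; the weighted
Poisson log-likelihood of a voxel TAC X given the model prediction X^ is

    L = sum_t  w_t * ( X_t * ln X^_t  -  X^_t ),    w_t prop. frame duration.

For the linear coefficients (Ki, K1', vb) the maximizer admits MLEM-style
multiplicative updates, e.g. for the net influx rate

    Ki  <-  Ki * [ sum_t w_t Bi_t (X_t / X^_t) ] / [ sum_t w_t Bi_t ],

with Bi the frame-averaged running integral of the input function (weighting
by frame duration is algebraically equivalent to folding frame lengths into
Cp and Ci in the update ratio).  The nonlinear parameters — k2' and the
input-function delay — are profiled: a bounded geometric-step local search
for k2' and a local grid search for the delay.  Five parameters (Ki, K1',
k2', vb, delay) are estimated jointly per voxel with an alternating schedule:
by default 27 main iterations, each with 6 sweeps of the linear triplet
(162 multiplicative subiterations per linear parameter in total), 2 delay
subiterations and 1 k2' subiteration.

The classical Patlak graphical estimator (OLS of X/Cp against Ci/Cp after
t*) is provided as the linear reference method.

Model objects follow the statsmodels convention: construct from data, call
``fit()``, get a results object with maps, diagnostics and ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import SampledCurve
from .errors import (ConfigError, DegenerateBasisError,
                     InsufficientDataError, MaskError)
from .kinetics import cumint, expconv, frame_averages
from .protocols import DynamicImage, FrameSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig", "ParamMaps", "NonlinearKineticModel", "KineticFitResults",
    "PatlakModel", "PatlakResults", "fit_image", "patlak_fit",
    "update_ki", "update_k1p", "update_vb", "update_linear",
    "update_k2p", "update_delay", "poisson_loglik", "BasisTable",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Iteration schedule, initial values and bounds of the joint fit."""

    n_main: int = 27
    sub_linear: int = 6          # sweeps of (Ki, K1', vb) per main iteration
    sub_delay: int = 2
    sub_k2p: int = 1
    init_ki: float = 0.01        # min^-1
    init_k1p: float = 0.05       # min^-1
    init_vb: float = 0.05
    init_k2p: float = 1.0        # min^-1
    init_delay: float = 0.0      # s
    k2p_bounds: tuple = (0.01, 3.0)
    delay_grid: tuple = tuple(float(d) for d in range(-10, 31))
    epsilon: float = 1e-9        # kBq/mL floor on predictions in ratios
    # geometric step of the k2' pattern search: expanded on an accepted
    # move, shrunk when no candidate improves the likelihood
    k2p_step_init: float = 1.6
    k2p_step_expand: float = 1.3
    k2p_step_shrink: float = 0.5
    k2p_step_max: float = 2.5
    k2p_step_min: float = 1.0005
    k2p_table_size: int = 128
    #: linear sweeps applied when evaluating a nonlinear-parameter
    #: candidate: deep enough that accept/reject decisions approximate
    #: profile-likelihood comparisons (shallow adaptation misorders
    #: candidates mid-convergence and strands the delay in sub-frame
    #: local modes)
    candidate_sweeps: int = 8
    chunk_size: int = 20000
    estimate_delay: bool = True

    def __post_init__(self) -> None:
        if min(self.n_main, self.sub_linear, self.sub_delay,
               self.sub_k2p) < 1:
            raise ConfigError("all iteration counts must be >= 1")
        lo, hi = self.k2p_bounds
        if not (0 < lo < hi):
            raise ConfigError("k2p_bounds must be an ordered positive pair")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if len(self.delay_grid) < 1 or np.any(np.diff(self.delay_grid) <= 0):
            raise ConfigError("delay_grid must be increasing")

    def next_k2p_step(self, step, moved):
        """Adapt the k2' search step: grow after a move, shrink otherwise."""
        grown = np.minimum(np.asarray(step) * self.k2p_step_expand,
                           self.k2p_step_max)
        shrunk = np.maximum(1.0 + (np.asarray(step) - 1.0)
                            * self.k2p_step_shrink, self.k2p_step_min)
        return np.where(moved, grown, shrunk)


@dataclass(frozen=True)
class ParamMaps:
    """Voxelwise parameter maps: Ki, K1', k2' (min^-1), vb, delay (s).

    ``flags``: 0 fitted, 1 non-finite data (excluded), 2 all-zero TAC (left
    at initialization), -1 outside the fitted mask.
    """

    ki: np.ndarray
    k1p: np.ndarray
    k2p: np.ndarray
    vb: np.ndarray
    delta: np.ndarray
    flags: np.ndarray

    def as_dict(self) -> dict:
        return {"Ki": self.ki, "K1p": self.k1p, "k2p": self.k2p,
                "vb": self.vb, "delay": self.delta}


# ---------------------------------------------------------------------------
# likelihood and elementary updates
# ---------------------------------------------------------------------------

def poisson_loglik(X, Xhat, w, epsilon: float = 1e-9):
    """Weighted Poisson log-likelihood (up to the X-only constant).

    Works on ``(..., F)`` arrays; returns the sum over the frame axis.
    Frames with X = 0 contribute only the -X^ term.
    """
    Xh = np.maximum(Xhat, epsilon)
    term = np.where(X > 0, X * np.log(Xh), 0.0)
    return ((term - Xh) * w).sum(axis=-1)


def _mult_update(coef, X, Xhat, B, w, epsilon):
    num = (w * B * np.where(X > 0, X / np.maximum(Xhat, epsilon), 0.0)
           ).sum(axis=-1)
    den = (w * B).sum(axis=-1)
    if np.any(den <= 0):
        raise DegenerateBasisError("basis column sums to zero")
    return coef * num / den


def update_ki(ki, X, Xhat, Bi, w, epsilon: float = 1e-9):
    """One multiplicative ML update of the net influx rate Ki."""
    return _mult_update(ki, X, Xhat, Bi, w, epsilon)


def update_k1p(k1p, X, Xhat, Bexp, w, epsilon: float = 1e-9):
    """One multiplicative ML update of K1' (convolution coefficient)."""
    return _mult_update(k1p, X, Xhat, Bexp, w, epsilon)


def update_vb(vb, X, Xhat, Bp, w, epsilon: float = 1e-9):
    """One multiplicative ML update of the blood fraction, clipped to [0, 1]."""
    return np.clip(_mult_update(vb, X, Xhat, Bp, w, epsilon), 0.0, 1.0)


def update_linear(vb, k1p, ki, X, basis, epsilon: float = 1e-9):
    """One sweep of the three multiplicative updates (Ki, K1', vb).

    Each coefficient is updated against a freshly recomputed prediction, so
    a sweep is three successive EM coordinate steps; the weighted Poisson
    log-likelihood never decreases across a sweep.
    """
    Bp, Bexp, Bi, w = basis.Bp, basis.Bexp, basis.Bi, basis.w

    def pred():
        # broadcasts both scalar coefficients with (F,) bases and (V,)
        # coefficient vectors with (V, F) basis blocks
        return (np.asarray(vb)[..., None] * Bp
                + np.asarray(k1p)[..., None] * Bexp
                + np.asarray(ki)[..., None] * Bi)

    ki = update_ki(ki, X, pred(), Bi, w, epsilon)
    k1p = update_k1p(k1p, X, pred(), Bexp, w, epsilon)
    vb = update_vb(vb, X, pred(), Bp, w, epsilon)
    return vb, k1p, ki


def update_k2p(current, X, vb, k1p, ki, basis_for, step=None,
               bounds=(0.01, 3.0), epsilon: float = 1e-9,
               config: FitConfig | None = None):
    """One bounded geometric pattern-search step for k2'.

    Evaluates the weighted Poisson log-likelihood at ``current/step``,
    ``current`` and ``current*step`` (clipped to bounds) with the linear
    coefficients held fixed and moves only on strict improvement, so the
    likelihood never decreases.  ``basis_for(k2p)`` must return the
    :class:`~petki.kinetics.BasisSet` at the candidate value.

    Returns ``(value, next_step)``: the step factor expands after an
    accepted move and shrinks toward 1 when neither neighbor improves, so
    repeated calls first travel and then refine, converging to the profile
    optimum on unimodal likelihoods.
    """
    cfg = config or FitConfig(k2p_bounds=bounds)
    if step is None:
        step = cfg.k2p_step_init
    lo, hi = bounds
    cur = float(np.clip(current, lo, hi))
    cands = [max(cur / step, lo), min(cur * step, hi)]

    def ll(k2p):
        b = basis_for(k2p)
        return float(poisson_loglik(
            X, vb * b.Bp + k1p * b.Bexp + ki * b.Bi, b.w, epsilon))

    ll_cur = ll(cur)
    best, ll_best = cur, ll_cur
    for c in cands:
        llc = ll(c)
        if llc > ll_best:
            best, ll_best = c, llc
    moved = best != cur
    return best, float(cfg.next_k2p_step(step, moved))


def update_delay(current, X, vb, k1p, ki, basis_for, delay_grid,
                 epsilon: float = 1e-9):
    """One local 3-point delay search on the configured grid.

    Evaluates the current grid point and its immediate neighbors and moves
    only on strict improvement; among strictly better candidates ties break
    toward the smaller delay.  Never leaves the grid.
    """
    grid = np.asarray(delay_grid, dtype=float)
    idx = int(np.argmin(np.abs(grid - current)))

    def ll(delta):
        b = basis_for(delta)
        return float(poisson_loglik(
            X, vb * b.Bp + k1p * b.Bexp + ki * b.Bi, b.w, epsilon))

    ll_cur = ll(grid[idx])
    best_idx, ll_best = idx, ll_cur
    for j in (idx - 1, idx + 1):          # ascending: smaller delay first
        if 0 <= j < grid.size:
            llj = ll(grid[j])
            if llj > ll_best:
                best_idx, ll_best = j, llj
    return float(grid[best_idx])


# ---------------------------------------------------------------------------
# precomputed frame-averaged basis tables
# ---------------------------------------------------------------------------

class BasisTable:
    """Frame-averaged bases tabulated over the (k2', delay) search space.

    Bp and Bi depend only on the delay; Bexp additionally on k2', for which
    a dense log-spaced table is built and read by log-linear interpolation.
    Delaying Cp commutes with convolution and integration, so every entry is
    a frame average of an undelayed fine-grid curve over shifted frame
    windows, evaluated from one cumulative integral per curve.
    """

    def __init__(self, cp: SampledCurve, schedule: FrameSchedule,
                 delay_grid, k2p_bounds=(0.01, 3.0), k2p_table_size=128,
                 pad_s: float = 60.0):
        dt = cp.dt
        n_pad = int(np.ceil(pad_s / dt))
        t_ext = np.concatenate([cp.t, cp.t[-1] + dt * np.arange(1, n_pad + 1)])
        v_ext = np.concatenate([cp.v, np.full(n_pad, cp.v[-1])])
        cpe = SampledCurve(t_ext, v_ext)

        self.schedule = schedule
        self.delay_grid = np.asarray(delay_grid, dtype=float)
        self.log_k2p = np.linspace(np.log(k2p_bounds[0]),
                                   np.log(k2p_bounds[1]), k2p_table_size)
        self.k2p_grid = np.exp(self.log_k2p)
        self.w = schedule.durations / schedule.durations.max()

        self.TBp = self._avg_all_deltas(cpe)
        self.TBi = self._avg_all_deltas(cumint(cpe))
        self.TBexp = np.stack([self._avg_all_deltas(expconv(cpe, k))
                               for k in self.k2p_grid])     # (K, D, F)

    def _avg_all_deltas(self, curve: SampledCurve) -> np.ndarray:
        """Frame averages of ``curve(t - delta)`` for every grid delay."""
        from scipy.integrate import cumulative_trapezoid
        t, v = curve.t, curve.v
        ct = cumulative_trapezoid(v, t, initial=0.0)
        s = self.schedule.frame_starts
        e = self.schedule.frame_ends
        out = np.empty((self.delay_grid.size, s.size))
        for i, d in enumerate(self.delay_grid):
            a = np.interp(s - d, t, ct)   # clamps: zero before, flat after
            b = np.interp(e - d, t, ct)
            out[i] = (b - a) / (e - s)
        return out

    # -- gathers ---------------------------------------------------------

    def delay_index(self, delta) -> np.ndarray:
        g = self.delay_grid
        return np.argmin(np.abs(np.subtract.outer(
            np.atleast_1d(np.asarray(delta, float)), g)), axis=1)

    def bp(self, didx):
        return self.TBp[didx]

    def bi(self, didx):
        return self.TBi[didx]

    def bexp(self, k2p, didx):
        """Bexp rows at per-voxel (k2', delay index), log-linear in k2'."""
        lg = np.log(np.clip(np.atleast_1d(np.asarray(k2p, float)),
                            self.k2p_grid[0], self.k2p_grid[-1]))
        pos = ((lg - self.log_k2p[0])
               / (self.log_k2p[1] - self.log_k2p[0]))
        i0 = np.clip(pos.astype(int), 0, self.log_k2p.size - 2)
        frac = (pos - i0)[:, None]
        didx = np.atleast_1d(didx)
        return ((1.0 - frac) * self.TBexp[i0, didx]
                + frac * self.TBexp[i0 + 1, didx])


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

class KineticFitResults:
    """Results of a voxelwise joint ML fit.

    Attributes
    ----------
    maps : ParamMaps
        The five parameter maps plus per-voxel flags.
    loglik_trace : ndarray
        Aggregate weighted Poisson log-likelihood after each main iteration
        (summed over fitted voxels); non-decreasing.
    counters : dict
        Instrumented per-voxel iteration counts actually executed.
    """

    def __init__(self, maps, loglik_trace, counters, config, mask,
                 n_flagged, schedule):
        self.maps = maps
        self.loglik_trace = np.asarray(loglik_trace)
        self.counters = counters
        self.config = config
        self.mask = mask
        self.n_flagged = n_flagged
        self.schedule = schedule

    def summary(self) -> pd.DataFrame:
        """Per-parameter statistics over cleanly fitted voxels."""
        ok = (self.maps.flags == 0)
        rows = []
        for name, arr in self.maps.as_dict().items():
            vals = arr[ok]
            rows.append({"parameter": name,
                         "mean": vals.mean() if vals.size else np.nan,
                         "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                         "min": vals.min() if vals.size else np.nan,
                         "max": vals.max() if vals.size else np.nan})
        df = pd.DataFrame(rows).set_index("parameter")
        df.attrs["counters"] = dict(self.counters)
        df.attrs["n_voxels"] = int(ok.sum())
        df.attrs["n_flagged"] = int(self.n_flagged)
        return df

    def report(self) -> dict:
        """JSON-serializable run report (config echo, counters, trace)."""
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self.config).items()}
        return {"config": cfg,
                "counters": dict(self.counters),
                "loglik_trace": self.loglik_trace.tolist(),
                "n_flagged_voxels": int(self.n_flagged)}


class PatlakResults:
    """Patlak graphical-fit results: slope (Ki) and intercept maps."""

    def __init__(self, ki, intercept, t_star, mask, flags):
        self.ki = ki
        self.intercept = intercept
        self.t_star = t_star
        self.mask = mask
        self.flags = flags

    @property
    def maps(self):
        return {"Ki": self.ki, "intercept": self.intercept}

    def summary(self) -> pd.DataFrame:
        ok = self.flags == 0
        rows = []
        for name, arr in self.maps.items():
            vals = arr[ok]
            rows.append({"parameter": name, "mean": vals.mean(),
                         "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                         "min": vals.min(), "max": vals.max()})
        return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class NonlinearKineticModel:
    """Joint voxelwise ML model for the irreversible FDG compartment model.

    Parameters
    ----------
    image : DynamicImage
        Dynamic frames (any protocol) in kBq/mL.
    input_function : SampledCurve
        Plasma input on a fine grid covering the schedule (plus delay
        headroom; the table pads the tail as needed).
    mask : ndarray of bool, optional
        Voxels to fit; default all.
    config : FitConfig, optional

    ``fit()`` returns a :class:`KineticFitResults`.  Voxels are fitted
    independently; results do not depend on processing order or chunking.
    """

    def __init__(self, image: DynamicImage, input_function: SampledCurve,
                 mask: np.ndarray | None = None,
                 config: FitConfig | None = None):
        self.image = image
        self.cp = input_function
        if mask is None:
            mask = np.ones(image.spatial_shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.spatial_shape:
            raise MaskError("mask shape does not match the image grid")
        self.mask = mask
        self.config = config or FitConfig()

    # -- fitting ---------------------------------------------------------

    def fit(self, config: FitConfig | None = None) -> KineticFitResults:
        cfg = config or self.config
        sched = self.image.schedule
        delay_grid = (np.asarray(cfg.delay_grid, float)
                      if cfg.estimate_delay
                      else np.asarray([cfg.init_delay], float))
        table = BasisTable(self.cp, sched, delay_grid,
                           cfg.k2p_bounds, cfg.k2p_table_size)

        F = sched.n_frames
        X_all = self.image.values.reshape(F, -1).T  # (Nvox, F)
        flat_mask = self.mask.ravel()
        Xm = X_all[flat_mask]

        finite = np.all(np.isfinite(Xm), axis=1)
        nonzero = np.any(Xm > 0, axis=1)
        fit_sel = finite & nonzero

        V = int(fit_sel.sum())
        shape = self.image.spatial_shape
        n = flat_mask.size
        ki = np.zeros(n)
        k1p = np.zeros(n)
        k2p = np.zeros(n)
        vb = np.zeros(n)
        delta = np.zeros(n)
        flags = np.full(n, -1, dtype=np.int8)

        midx = np.flatnonzero(flat_mask)
        flags[midx] = 0
        flags[midx[~finite]] = 1
        flags[midx[finite & ~nonzero]] = 2
        # flagged-but-masked voxels keep their initialization (all-zero
        # TACs) or zeros (non-finite, excluded)
        keep_init = midx[finite & ~nonzero]
        ki[keep_init] = cfg.init_ki
        k1p[keep_init] = cfg.init_k1p
        k2p[keep_init] = cfg.init_k2p
        vb[keep_init] = cfg.init_vb
        delta[keep_init] = cfg.init_delay

        trace = np.zeros(cfg.n_main)
        counters = None
        good = midx[fit_sel]
        Xg = Xm[fit_sel]
        for lo in range(0, V, cfg.chunk_size):
            hi = min(lo + cfg.chunk_size, V)
            res = self._fit_chunk(Xg[lo:hi], table, cfg)
            cki, ck1p, ck2p, cvb, cdel, ctrace, ccount = res
            sel = good[lo:hi]
            ki[sel], k1p[sel], k2p[sel] = cki, ck1p, ck2p
            vb[sel], delta[sel] = cvb, cdel
            trace += ctrace
            if counters is None:
                counters = ccount
        if counters is None:
            counters = {"main_iterations": 0, "ki_updates": 0,
                        "k1p_updates": 0, "vb_updates": 0,
                        "delay_updates": 0, "k2p_updates": 0}

        maps = ParamMaps(ki.reshape(shape), k1p.reshape(shape),
                         k2p.reshape(shape), vb.reshape(shape),
                         delta.reshape(shape), flags.reshape(shape))
        n_flagged = int(((flags == 1) | (flags == 2)).sum())
        return KineticFitResults(maps, trace, counters, cfg, self.mask,
                                 n_flagged, sched)

    def _fit_chunk(self, X, table: BasisTable, cfg: FitConfig):
        """Run the alternating schedule on a (V, F) block of voxel TACs."""
        V = X.shape[0]
        w = table.w
        eps = cfg.epsilon
        D = table.delay_grid.size

        ki = np.full(V, cfg.init_ki)
        k1p = np.full(V, cfg.init_k1p)
        vb = np.full(V, cfg.init_vb)
        k2p = np.full(V, float(np.clip(cfg.init_k2p, *cfg.k2p_bounds)))
        k2p_step = np.full(V, cfg.k2p_step_init)
        did = np.full(V, int(np.argmin(np.abs(table.delay_grid
                                              - cfg.init_delay))))

        counters = {"main_iterations": 0, "ki_updates": 0, "k1p_updates": 0,
                    "vb_updates": 0, "delay_updates": 0, "k2p_updates": 0}
        trace = np.zeros(cfg.n_main)

        def loglik_at(k2p_v, didx):
            Bp, Bi = table.bp(didx), table.bi(didx)
            Bexp = table.bexp(k2p_v, didx)
            Xh = vb[:, None] * Bp + k1p[:, None] * Bexp + ki[:, None] * Bi
            return poisson_loglik(X, Xh, w, eps)

        def sweep_at(k2p_v, didx):
            # candidate evaluation for the nonlinear parameters: one linear
            # sweep re-adapts (Ki, K1', vb) to the candidate basis so the
            # search can follow the curved (k2', K1') likelihood valley
            Bp, Bi = table.bp(didx), table.bi(didx)
            Bexp = table.bexp(k2p_v, didx)
            basis = _ChunkBasis(Bp, Bexp, Bi, w)
            vb2, k1p2, ki2 = vb, k1p, ki
            for _ in range(cfg.candidate_sweeps):
                vb2, k1p2, ki2 = update_linear(vb2, k1p2, ki2, X, basis, eps)
            Xh = (vb2[:, None] * Bp + k1p2[:, None] * Bexp
                  + ki2[:, None] * Bi)
            return vb2, k1p2, ki2, poisson_loglik(X, Xh, w, eps)

        def accept(res_lo, res_hi, res_cur):
            # symmetric comparison: the incumbent is re-adapted with the
            # same number of sweeps as the candidates, so a move reflects a
            # genuine profile-likelihood preference; when no candidate wins
            # strictly, the incumbent keeps its adapted coefficients (free
            # monotone progress).  Ties prefer the low candidate.
            vb_lo, k1p_lo, ki_lo, ll_lo = res_lo
            vb_hi, k1p_hi, ki_hi, ll_hi = res_hi
            vb_c, k1p_c, ki_c, ll_c = res_cur
            take_lo = (ll_lo > ll_c) & (ll_lo >= ll_hi)
            take_hi = (ll_hi > ll_c) & ~take_lo
            nonlocal vb, k1p, ki
            vb = np.where(take_lo, vb_lo, np.where(take_hi, vb_hi, vb_c))
            k1p = np.where(take_lo, k1p_lo,
                           np.where(take_hi, k1p_hi, k1p_c))
            ki = np.where(take_lo, ki_lo, np.where(take_hi, ki_hi, ki_c))
            return take_lo, take_hi

        for it in range(cfg.n_main):
            Bp, Bi = table.bp(did), table.bi(did)
            Bexp = table.bexp(k2p, did)
            basis = _ChunkBasis(Bp, Bexp, Bi, w)

            for _ in range(cfg.sub_linear):
                vb, k1p, ki = update_linear(vb, k1p, ki, X, basis, eps)
                counters["ki_updates"] += 1
                counters["k1p_updates"] += 1
                counters["vb_updates"] += 1

            if cfg.estimate_delay and D > 1:
                for _ in range(cfg.sub_delay):
                    lo_j = np.maximum(did - 1, 0)
                    hi_j = np.minimum(did + 1, D - 1)
                    res_cur = sweep_at(k2p, did)
                    res_lo = sweep_at(k2p, lo_j)
                    res_hi = sweep_at(k2p, hi_j)
                    # edge voxels: a clipped neighbor equals the current
                    # point; mask it out so the search never leaves the grid
                    res_lo = res_lo[:3] + (np.where(lo_j != did, res_lo[3],
                                                    -np.inf),)
                    res_hi = res_hi[:3] + (np.where(hi_j != did, res_hi[3],
                                                    -np.inf),)
                    take_lo, take_hi = accept(res_lo, res_hi, res_cur)
                    did = np.where(take_lo, lo_j,
                                   np.where(take_hi, hi_j, did))
                    counters["delay_updates"] += 1

            lo_b, hi_b = cfg.k2p_bounds
            for _ in range(cfg.sub_k2p):
                c_lo = np.maximum(k2p / k2p_step, lo_b)
                c_hi = np.minimum(k2p * k2p_step, hi_b)
                res_cur = sweep_at(k2p, did)
                res_lo = sweep_at(c_lo, did)
                res_hi = sweep_at(c_hi, did)
                take_lo, take_hi = accept(res_lo, res_hi, res_cur)
                move = take_lo | take_hi
                k2p = np.where(take_lo, c_lo, np.where(take_hi, c_hi, k2p))
                k2p_step = cfg.next_k2p_step(k2p_step, move)
                counters["k2p_updates"] += 1

            counters["main_iterations"] += 1
            ll_now = float(loglik_at(k2p, did).sum())
            trace[it] = ll_now
            logger.info("main iteration %d/%d: aggregate loglik %.6g",
                        it + 1, cfg.n_main, ll_now)

        delta = table.delay_grid[did]
        return ki, k1p, k2p, vb, delta, trace, counters


@dataclass(frozen=True)
class _ChunkBasis:
    """Duck-typed BasisSet over a voxel chunk (arrays broadcast as (V, F))."""

    Bp: np.ndarray
    Bexp: np.ndarray
    Bi: np.ndarray
    w: np.ndarray


class PatlakModel:
    """Patlak graphical model: OLS of X/Cp against Ci/Cp after t*.

    The slope is the net influx rate Ki; the intercept lumps the blood
    fraction with the (assumed equilibrated) convolution term.  Uses frames
    with ``frame_start >= t_star``; unweighted least squares.
    """

    def __init__(self, image: DynamicImage, input_function: SampledCurve,
                 t_star: float = 1200.0, mask: np.ndarray | None = None):
        if t_star < 0:
            raise ConfigError("t_star must be nonnegative")
        self.image = image
        self.cp = input_function
        self.t_star = float(t_star)
        if mask is None:
            mask = np.ones(image.spatial_shape, dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != image.spatial_shape:
            raise MaskError("mask shape does not match the image grid")

    def fit(self) -> PatlakResults:
        sched = self.image.schedule
        sel = sched.frame_starts >= self.t_star
        if sel.sum() < 2:
            raise InsufficientDataError(
                f"need >= 2 frames with start >= t* = {self.t_star} s")
        sub = FrameSchedule(sched.frame_starts[sel], sched.frame_ends[sel],
                            sched.injection_times, sched.protocol_id)
        bp = frame_averages(self.cp, sub)
        bi = frame_averages(cumint(self.cp), sub)
        if np.any(bp <= 0):
            raise InsufficientDataError("Cp must be positive on used frames")
        x = bi / bp                                   # (F',) same all voxels
        F = sched.n_frames
        X_all = self.image.values.reshape(F, -1).T[:, sel]
        y = X_all / bp                                # (Nvox, F')
        xc = x - x.mean()
        ssx = float((xc ** 2).sum())
        slope = (y @ xc) / ssx
        intercept = y.mean(axis=1) - slope * x.mean()
        shape = self.image.spatial_shape
        flat_mask = self.mask.ravel()
        bad = ~np.all(np.isfinite(X_all), axis=1)
        slope[bad] = 0.0
        intercept[bad] = 0.0
        flags = np.where(flat_mask, np.where(bad, 1, 0), -1).astype(np.int8)
        slope = np.where(flat_mask, slope, 0.0)
        intercept = np.where(flat_mask, intercept, 0.0)
        return PatlakResults(slope.reshape(shape), intercept.reshape(shape),
                             self.t_star, self.mask, flags.reshape(shape))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_image(dyn: DynamicImage, cp: SampledCurve,
              cfg: FitConfig | None = None,
              mask: np.ndarray | None = None) -> KineticFitResults:
    """Voxelwise joint ML fit of a dynamic image (convenience wrapper)."""
    return NonlinearKineticModel(dyn, cp, mask=mask, config=cfg).fit()


def patlak_fit(dyn: DynamicImage, cp: SampledCurve, t_star: float = 1200.0,
               mask: np.ndarray | None = None) -> PatlakResults:
    """Voxelwise Patlak fit (convenience wrapper)."""
    return PatlakModel(dyn, cp, t_star=t_star, mask=mask).fit()
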