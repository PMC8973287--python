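"""Frame schedules for the three scanning protocols and image transforms.

Three acquisition protocols are supported:

* **P1** — the conventional 60-min dynamic scan (5 s x 30, 30 s x 15,
  120 s x 25), the gold standard.
* **P2** — dual-time-point scanning: 0-4 min and 54-60 min post-injection
  (5 s x 30, 30 s x 3, a 50-min gap with no acquisition, 120 s x 3).
* **P3** — dual-injection scanning: a single 50-60 min window
  (120 s x 3, then 5 s x 30 and 30 s x 3) with a second tracer injection
  56 min after the first, so early-phase kinetics of the second bolus are
  superimposed on the late phase of the first.

Both reduced protocols are *simulated* from a full P1 acquisition, exactly as
they would be derived from a 60-min scan: P2 by dropping the 4-54 min
interval, P3 by summing the early-phase frames (shifted to the second
injection time) onto the late-phase activity.

Frame intervals are half-open ``[start, end)``; all times are seconds with
the first injection at t = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import (FramingIncompatibilityError, ProtocolError,
                     ScheduleMismatchError)

PROTOCOLS = ("P1", "P2", "P3")

#: second-injection time for protocol 3, seconds (56 min after the first).
SECOND_INJECTION_S = 3360.0


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition frames plus injection event times.

    frame_starts/frame_ends are seconds from the first injection; frames are
    half-open ``[start, end)``, non-overlapping, possibly with gaps.
    """

    frame_starts: np.ndarray
    frame_ends: np.ndarray
    injection_times: tuple
    protocol_id: str

    def __post_init__(self) -> None:
        s = np.asarray(self.frame_starts, dtype=float)
        e = np.asarray(self.frame_ends, dtype=float)
        object.__setattr__(self, "frame_starts", s)
        object.__setattr__(self, "frame_ends", e)
        object.__setattr__(self, "injection_times",
                           tuple(float(x) for x in self.injection_times))
        if self.protocol_id not in PROTOCOLS:
            raise ProtocolError(f"unknown protocol_id {self.protocol_id!r}")
        if s.shape != e.shape or s.ndim != 1 or s.size == 0:
            raise ProtocolError("frame_starts/frame_ends must be matching 1-D arrays")
        if np.any(np.diff(s) <= 0):
            raise ProtocolError("frame_starts must be strictly increasing")
        if np.any(e <= s):
            raise ProtocolError("each frame_end must exceed its frame_start")
        if np.any(s[1:] < e[:-1] - 1e-9):
            raise ProtocolError("frames must not overlap")
        if not self.injection_times or self.injection_times[0] != 0.0:
            raise ProtocolError("injection_times[0] must be 0 by convention")
        if self.protocol_id == "P3" and len(self.injection_times) != 2:
            raise ProtocolError("P3 requires exactly two injections")

    @property
    def n_frames(self) -> int:
        return int(self.frame_starts.size)

    @property
    def durations(self) -> np.ndarray:
        """Frame durations, seconds."""
        return self.frame_ends - self.frame_starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)

    @property
    def total_acquired(self) -> float:
        """Total acquired (scanned) time, seconds — gaps excluded."""
        return float(self.durations.sum())

    def same_framing(self, other: "FrameSchedule") -> bool:
        return (self.n_frames == other.n_frames
                and np.allclose(self.frame_starts, other.frame_starts)
                and np.allclose(self.frame_ends, other.frame_ends))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol_id,
            "frame_starts_s": self.frame_starts.tolist(),
            "frame_ends_s": self.frame_ends.tolist(),
            "injection_times_s": list(self.injection_times),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["frame_starts_s"], dtype=float),
                   np.asarray(d["frame_ends_s"], dtype=float),
                   tuple(d["injection_times_s"]),
                   d["protocol"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class DynamicImage:
    """A 4-D dynamic image: frame-major voxel array bound to a schedule.

    ``values`` has shape ``(n_frames, nx, ny, nz)`` in kBq/mL (decay-corrected
    activity concentration, the convention of clinical reconstructions).
    """

    values: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple = (3.125, 3.125, 2.89)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "voxel_size_mm",
                           tuple(float(x) for x in self.voxel_size_mm))
        if v.ndim != 4:
            raise ScheduleMismatchError("values must be 4-D (frames, x, y, z)")
        if v.shape[0] != self.schedule.n_frames:
            raise ScheduleMismatchError(
                f"{v.shape[0]} frames in image vs "
                f"{self.schedule.n_frames} in schedule")

    @property
    def spatial_shape(self) -> tuple:
        return self.values.shape[1:]

    def frame_means(self, mask: np.ndarray) -> np.ndarray:
        """Per-frame mean voxel value within a boolean mask."""
        from .errors import MaskError
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.spatial_shape:
            raise MaskError("mask shape does not match the image grid")
        if not mask.any():
            raise MaskError("mask is empty")
        return self.values[:, mask].mean(axis=1)


def _framing(blocks, t0=0.0):
    """Expand ``[(dur_s, count), ...]`` into start/end arrays from t0."""
    durs = np.concatenate([np.full(n, d, dtype=float) for d, n in blocks])
    ends = t0 + np.cumsum(durs)
    starts = ends - durs
    return starts, ends


def build_schedule(protocol_id: str) -> FrameSchedule:
    """Build the frame schedule of one of the three protocols.

    P1: 5 s x 30, 30 s x 15, 120 s x 25 (70 frames, 0-3600 s).
    P2: 5 s x 30, 30 s x 3 (0-240 s), no scan until 3240 s, 120 s x 3.
    P3: from 3000 s, 120 s x 3, 5 s x 30, 30 s x 3; injections at 0 and
    3360 s.
    """
    if protocol_id == "P1":
        s, e = _framing([(5, 30), (30, 15), (120, 25)])
        return FrameSchedule(s, e, (0.0,), "P1")
    if protocol_id == "P2":
        s1, e1 = _framing([(5, 30), (30, 3)])
        s2, e2 = _framing([(120, 3)], t0=3240.0)
        return FrameSchedule(np.concatenate([s1, s2]),
                             np.concatenate([e1, e2]), (0.0,), "P2")
    if protocol_id == "P3":
        s, e = _framing([(120, 3), (5, 30), (30, 3)], t0=3000.0)
        return FrameSchedule(s, e, (0.0, SECOND_INJECTION_S), "P3")
    raise ProtocolError(f"unknown protocol_id {protocol_id!r}")


def _match_frames(sub: FrameSchedule, full: FrameSchedule) -> np.ndarray:
    """Indices in ``full`` whose (start, end) equal each frame of ``sub``."""
    idx = np.empty(sub.n_frames, dtype=int)
    for i, (a, b) in enumerate(zip(sub.frame_starts, sub.frame_ends)):
        hit = np.flatnonzero(np.isclose(full.frame_starts, a)
                             & np.isclose(full.frame_ends, b))
        if hit.size != 1:
            raise FramingIncompatibilityError(
                f"frame [{a}, {b}) has no exact match in the source framing")
        idx[i] = hit[0]
    return idx


def subset_protocol2(full: DynamicImage) -> DynamicImage:
    """Reduce a full P1 acquisition to the dual-time-point protocol.

    Keeps exactly the frames whose ``[start, end)`` lies within
    ``[0, 240)`` s or ``[3240, 3600)`` s and binds them to the P2 schedule;
    voxel values are untouched.
    """
    if full.schedule.protocol_id != "P1":
        raise ScheduleMismatchError("subset_protocol2 expects a P1 image")
    p2 = build_schedule("P2")
    idx = _match_frames(p2, full.schedule)
    return DynamicImage(full.values[idx], p2, full.voxel_size_mm)


def combine_protocol3(full: DynamicImage) -> DynamicImage:
    """Simulate the dual-injection protocol from a full P1 acquisition.

    The 3000-3360 s frames are the P1 late frames unchanged (first-injection
    activity only).  The 3360-3600 s fine frames are the P1 late activity,
    resampled assuming the activity is constant within each original 120-s
    frame, plus the P1 early-frame activity at ``t - 3360`` s (the second
    bolus, identical shape and dose to the first), added voxelwise.
    """
    if full.schedule.protocol_id != "P1":
        raise ScheduleMismatchError("combine_protocol3 expects a P1 image")
    p3 = build_schedule("P3")
    t0 = SECOND_INJECTION_S
    fs, fe = full.schedule.frame_starts, full.schedule.frame_ends
    out = np.empty((p3.n_frames,) + full.spatial_shape, dtype=float)
    for i, (a, b) in enumerate(zip(p3.frame_starts, p3.frame_ends)):
        if b <= t0:
            # late window before the second injection: exact frame match
            hit = np.flatnonzero(np.isclose(fs, a) & np.isclose(fe, b))
            if hit.size != 1:
                raise FramingIncompatibilityError(
                    f"P1 framing does not tile [{a}, {b}) exactly")
            out[i] = full.values[hit[0]]
        else:
            # containing 120-s late frame (piecewise-constant resampling)
            cont = np.flatnonzero((fs <= a + 1e-9) & (fe >= b - 1e-9))
            if cont.size != 1:
                raise FramingIncompatibilityError(
                    f"no single P1 late frame contains [{a}, {b})")
            # matching early frame at t - t0
            hit = np.flatnonzero(np.isclose(fs, a - t0)
                                 & np.isclose(fe, b - t0))
            if hit.size != 1:
                raise FramingIncompatibilityError(
                    "P1 early framing does not tile the post-injection "
                    f"window at [{a - t0}, {b - t0})")
            out[i] = full.values[cont[0]] + full.values[hit[0]]
    return DynamicImage(out, p3, full.voxel_size_mm)
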