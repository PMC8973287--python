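"""Digital whole-body-like phantom with known kinetics.

The phantom is the synthetic stand-in for a dynamic whole-body FDG cohort:
a small 3-D label volume (default 32 x 32 x 48 voxels at 3.125 mm in-plane /
2.89 mm slice, echoing a total-body PET reconstruction grid scaled down)
whose labels map to known two-tissue-compartment parameters.  It contains a
muscle background, liver, kidneys, a blood pool (vb = 1, used for IDIF
extraction) and spherical lesions (default equivalent diameter 13.8 mm).

Simulation is exact for piecewise-constant phantoms: the noiseless TAC is
computed once per label by integrating the compartment ODE, frame-averaged,
and broadcast to the label's voxels.  Noise follows the scaled-Poisson model
of reconstructed PET frames: a frame value v (kBq/mL) acquired over d
seconds becomes ``Poisson(v * count_scale * d) / (count_scale * d)``, so the
variance scales as 1/(count_scale * duration).

Default kinetic values are generator choices in the physiological range for
FDG, not measured constants; ground truth for every voxel is returned
alongside the simulated data, which is what parameter-recovery tests rest
on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import SampledCurve, uniform_grid
from .errors import ConfigError
from .estimation import ParamMaps
from .input_functions import FengParams, assemble_composite_if, population_if
from .kinetics import TissueParams, frame_averages, solve_2tc
from .protocols import (SECOND_INJECTION_S, DynamicImage, FrameSchedule,
                        build_schedule, combine_protocol3, subset_protocol2)

DEFAULT_SHAPE = (32, 32, 48)
DEFAULT_VOXEL_MM = (3.125, 3.125, 2.89)
#: default lesion equivalent diameter, mm
DEFAULT_LESION_DIAMETER_MM = 13.8

#: generator default kinetics (K1 mL/min/mL, k2..k4 1/min, vb fraction)
TISSUE_DEFAULTS = {
    "air": TissueParams(0.0, 0.0, 0.0, 0.0, 0.0),
    "muscle": TissueParams(0.03, 0.3, 0.01, 0.0, 0.03),
    "liver": TissueParams(0.6, 0.5, 0.005, 0.0, 0.10),
    "kidney": TissueParams(0.3, 0.6, 0.02, 0.0, 0.15),
    "blood": TissueParams(0.0, 0.0, 0.0, 0.0, 1.0),
    "lesion": TissueParams(0.1, 0.4, 0.1, 0.0, 0.05),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Label volume plus per-label kinetic parameters (the ground truth)."""

    labels: np.ndarray
    tissues: dict            # label -> TissueParams
    names: dict              # label -> tissue name
    lesion_labels: tuple
    blood_label: int
    voxel_size_mm: tuple = DEFAULT_VOXEL_MM

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        for v in np.unique(lab):
            if v != 0 and int(v) not in self.tissues:
                raise ConfigError(f"label {v} has no tissue parameters")
        if self.blood_label not in self.tissues:
            raise ConfigError("blood label missing from tissue table")
        if not np.any(lab == self.blood_label):
            raise ConfigError("blood region is empty")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def blood_mask(self) -> np.ndarray:
        return self.mask(self.blood_label)

    @property
    def lesion_mask(self) -> np.ndarray:
        m = np.zeros(self.labels.shape, dtype=bool)
        for lab in self.lesion_labels:
            m |= self.mask(lab)
        return m

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels > 0

    def true_maps(self) -> ParamMaps:
        """Ground-truth parameter maps (macroparameters of each tissue)."""
        shape = self.labels.shape
        ki = np.zeros(shape)
        k1p = np.zeros(shape)
        k2p = np.zeros(shape)
        vb = np.zeros(shape)
        for lab, par in self.tissues.items():
            m = self.labels == lab
            ki[m], k1p[m], k2p[m], vb[m] = par.Ki, par.K1p, par.k2p, par.vb
        flags = np.where(self.labels > 0, 0, -1).astype(np.int8)
        return ParamMaps(ki, k1p, k2p, vb, np.zeros(shape), flags)


def _sphere_mask(shape, voxel_mm, center_vox, radius_mm) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d2 = sum(((idx[a] - center_vox[a]) * voxel_mm[a]) ** 2 for a in range(3))
    return d2 <= radius_mm ** 2


def build_phantom(config: dict | None = None) -> PhantomSpec:
    """Build the default (or configured) multi-region phantom.

    ``config`` keys (all optional): ``shape``, ``voxel_size_mm``,
    ``tissues`` (per-name parameter overrides, e.g.
    ``{"liver": {"k4": 0.01}}``), ``lesions`` (list of
    ``{"center": [i,j,k], "diameter_mm": float}``; an empty list removes
    lesions), ``organs`` (bool, include liver/kidneys; default True).
    User-supplied lesions may not overlap each other or the blood pool.
    """
    cfg = dict(config or {})
    shape = tuple(cfg.get("shape", DEFAULT_SHAPE))
    vox = tuple(cfg.get("voxel_size_mm", DEFAULT_VOXEL_MM))
    if len(shape) != 3 or min(shape) < 4:
        raise ConfigError("phantom shape must be 3-D with >= 4 voxels/axis")

    tissues = dict(TISSUE_DEFAULTS)
    for name, over in cfg.get("tissues", {}).items():
        if name not in tissues:
            raise ConfigError(f"unknown tissue {name!r}")
        base = tissues[name]
        tissues[name] = TissueParams(**{**vars(base), **over})

    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rx, ry = 0.42 * nx, 0.42 * ny
    ii, jj, _ = np.indices(shape, dtype=float)
    body = ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    labels[body] = 1  # muscle background

    organs = bool(cfg.get("organs", True))
    if organs:
        liver_c = (0.33 * nx, cy, 0.70 * nz)
        liver = _sphere_mask(shape, vox, liver_c,
                             0.18 * nx * vox[0]) & body
        labels[liver] = 2
        for ky in (0.32 * ny, 0.68 * ny):
            kid = _sphere_mask(shape, vox, (0.30 * nx, ky, 0.5 * nz),
                               0.09 * nx * vox[0]) & body
            labels[kid] = 3

    # blood pool: axial cylinder (descending-aorta-like), vb = 1
    bx, by = 0.70 * nx, cy
    blood = ((ii - bx) * vox[0]) ** 2 + ((jj - by) * vox[1]) ** 2 \
        <= (1.9 * vox[0]) ** 2
    blood &= body
    labels[blood] = 4

    default_lesions = [
        {"center": (0.50 * nx, 0.26 * ny, 0.22 * nz)},
        {"center": (0.34 * nx, 0.52 * ny, 0.72 * nz)},   # in the liver
        {"center": (0.62 * nx, 0.70 * ny, 0.85 * nz)},
    ]
    lesions = cfg.get("lesions", default_lesions)
    lesion_labels = []
    taken = np.zeros(shape, dtype=bool)
    for n, les in enumerate(lesions):
        r = 0.5 * float(les.get("diameter_mm", DEFAULT_LESION_DIAMETER_MM))
        m = _sphere_mask(shape, vox, tuple(les["center"]), r) & body
        if not m.any():
            raise ConfigError(f"lesion {n} lies outside the body")
        if (m & taken).any() or (m & blood).any():
            raise ConfigError(f"lesion {n} overlaps another region")
        taken |= m
        lab = 5 + n
        labels[m] = lab
        lesion_labels.append(lab)

    names = {1: "muscle", 2: "liver", 3: "kidney", 4: "blood"}
    names.update({lab: f"lesion_{i}" for i, lab in enumerate(lesion_labels)})
    tissue_map = {}
    for lab, name in names.items():
        key = "lesion" if name.startswith("lesion") else name
        if np.any(labels == lab):
            tissue_map[lab] = tissues[key]
    names = {lab: n for lab, n in names.items() if lab in tissue_map}
    return PhantomSpec(labels, tissue_map, names, tuple(lesion_labels), 4, vox)


@dataclass(frozen=True)
class NoiseModel:
    """Scaled-Poisson frame noise: counts per (kBq/mL * s) and a seed."""

    count_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.count_scale <= 0:
            raise ConfigError("count_scale must be positive")


def apply_noise(dyn: DynamicImage, noise: NoiseModel,
                rng: np.random.Generator | None = None) -> DynamicImage:
    """Scaled-Poisson noise realization of a (noiseless) dynamic image."""
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    dur = dyn.schedule.durations.reshape((-1,) + (1,) * 3)
    lam = np.clip(dyn.values, 0.0, None) * noise.count_scale * dur
    noisy = rng.poisson(lam) / (noise.count_scale * dur)
    return DynamicImage(noisy, dyn.schedule, dyn.voxel_size_mm)


def simulate_dynamic(phantom: PhantomSpec, cp: SampledCurve,
                     schedule: FrameSchedule,
                     noise: NoiseModel | None = None,
                     rng: np.random.Generator | None = None) -> DynamicImage:
    """Forward-simulate the phantom under a schedule and input function.

    The noiseless frame value is the frame-averaged ODE solution of each
    label's kinetics, broadcast to the label's voxels; noise (optional) is
    scaled-Poisson per :func:`apply_noise`.  For the dual-injection protocol
    pass the composite two-bolus Cp.
    """
    vals = np.zeros((schedule.n_frames,) + phantom.labels.shape)
    for lab in np.unique(phantom.labels):
        if lab == 0:
            continue
        par = phantom.tissues.get(int(lab))
        if par is None:
            raise ConfigError(f"label {lab} has no tissue parameters")
        tac = solve_2tc(par, cp)
        vals[:, phantom.labels == lab] = \
            frame_averages(tac, schedule)[:, None]
    dyn = DynamicImage(vals, schedule, phantom.voxel_size_mm)
    if noise is not None:
        dyn = apply_noise(dyn, noise, rng)
    return dyn


@dataclass(frozen=True)
class PhantomDataset:
    """One simulated study: image, truths and masks for one protocol."""

    protocol_id: str
    image: DynamicImage
    phantom: PhantomSpec
    cp_true: SampledCurve                 # first-injection input function
    cp_model: SampledCurve                # input driving the fitted model
    true_maps: ParamMaps
    p1_image: DynamicImage                # the source 60-min acquisition


def make_dataset(protocol_id: str, phantom: PhantomSpec | None = None,
                 noise: NoiseModel | None = None,
                 seed: int | None = None,
                 if_params: FengParams | None = None) -> PhantomDataset:
    """Simulate one study under a protocol, with ground truth attached.

    The full 60-min P1 acquisition is always simulated first; P2 subsets
    it and P3 combines it, exactly as the reduced protocols are derived
    from a standard scan.  ``cp_model`` is the input function the protocol's
    model should be driven with: the first-injection input for P1/P2 and
    the exact two-bolus composite for P3.
    """
    phantom = phantom or build_phantom()
    rng = np.random.default_rng(seed)
    cp = population_if(if_params or FengParams(),
                       uniform_grid(3660.0))
    p1 = simulate_dynamic(phantom, cp, build_schedule("P1"),
                          noise=noise, rng=rng)
    if protocol_id == "P1":
        image, cp_model = p1, cp
    elif protocol_id == "P2":
        image, cp_model = subset_protocol2(p1), cp
    elif protocol_id == "P3":
        image = combine_protocol3(p1)
        bolus = cp.restrict(0.0, 240.0)
        cp_model = assemble_composite_if(cp, bolus, SECOND_INJECTION_S, 1.0)
    else:
        raise ConfigError(f"unknown protocol {protocol_id!r}")
    return PhantomDataset(protocol_id, image, phantom, cp, cp_model,
                          phantom.true_maps(), p1)
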