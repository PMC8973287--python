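"""Minimal plot helpers for curves and parameter-map slices."""

from __future__ import annotations

import numpy as np


def plot_curves(curves: dict, ax=None, **kwargs):
    """Overlay named :class:`~petki.curves.SampledCurve` objects."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for name, c in curves.items():
        ax.plot(c.t / 60.0, c.v, label=name, **kwargs)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("activity (kBq/mL)")
    ax.legend()
    return ax


def plot_map_slice(values: np.ndarray, z: int | None = None, ax=None,
                   **imshow_kwargs):
    """Show one axial slice of a 3-D parameter map."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    z = values.shape[2] // 2 if z is None else z
    im = ax.imshow(values[:, :, z].T, origin="lower", **imshow_kwargs)
    ax.figure.colorbar(im, ax=ax)
    return ax
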