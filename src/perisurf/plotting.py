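"""Plot helpers: height maps, material ratio curves, feature labels."""

from __future__ import annotations

import numpy as np

from .heightmap import HeightMap
from .parameters import MaterialRatioCurve


def plot_heightmap(hm: HeightMap, ax=None, cmap="viridis", colorbar=True):
    """Heat map of a height grid (μm), axes in mm."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [0, hm.shape[1] * hm.step_x / 1000.0,
              0, hm.shape[0] * hm.step_y / 1000.0]
    im = ax.imshow(hm.heights, origin="lower", extent=extent, cmap=cmap)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if colorbar:
        ax.figure.colorbar(im, ax=ax, label="height (μm)")
    return ax


def plot_material_ratio(curve: MaterialRatioCurve, ax=None):
    """Abbott-Firestone curve: material ratio (%) vs section height (μm)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.ratios, curve.levels)
    ax.axhline(curve.mean_height, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("material ratio (%)")
    ax.set_ylabel("section height (μm)")
    return ax


def plot_features(labels: np.ndarray, ax=None):
    """Label image of segmented features, randomly recoloured."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    rng = np.random.default_rng(0)
    perm = rng.permutation(labels.max() + 1)
    ax.imshow(perm[labels], origin="lower", cmap="tab20", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
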