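"""Trunk extraction by a growing vertical pipe.

The cloud is sliced into horizontal layers; starting from the lowest
occupied layer, layers are accumulated as trunk while their horizontal
extent stays within the base layer's extent plus a bend tolerance λ.
The pipe stops at the first layer that widens beyond the tolerance —
in an orchard tree, the first scaffold bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud
from .exceptions import EmptyCloudError

__all__ = ["LayerStack", "TrunkResult", "slice_layers", "layer_extent", "extract_trunk"]

DEFAULT_THICKNESS = 0.02  # m per layer
DEFAULT_LAMBDA = 0.05     # m of allowed widening over the base extent


@dataclass
class LayerStack:
    """Horizontal slicing of a cloud: ordered point-position sets per layer."""

    layers: list[np.ndarray]      # positional indices into the cloud, bottom→top
    thickness: float
    z_breaks: np.ndarray          # layer boundary z values, len = n_layers + 1

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class TrunkResult:
    """Outcome of the pipe-growing trunk search."""

    trunk_ids: np.ndarray         # point ids classified as trunk
    stop_layer: int               # first layer failing the width test (== n if none)
    base_extent: tuple[float, float]
    reached_top: bool             # True when the pipe never stopped (whole tree)


def slice_layers(cloud: PointCloud, thickness: float = DEFAULT_THICKNESS) -> LayerStack:
    """Partition the cloud into half-open horizontal bins of given thickness.

    Layer j covers [z_min + j*t, z_min + (j+1)*t); the topmost point falls
    in the last bin.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    cloud.require_nonempty("slice_layers")
    z = cloud.z
    z0 = z.min()
    idx = np.floor((z - z0) / thickness).astype(np.int64)
    # the maximum z lands exactly on the upper boundary: close the top bin
    n_layers = int(idx.max()) + 1
    top = idx == n_layers  # cannot happen for max via floor, kept for clarity
    idx[top] = n_layers - 1
    layers = [np.nonzero(idx == j)[0] for j in range(n_layers)]
    z_breaks = z0 + thickness * np.arange(n_layers + 1)
    return LayerStack(layers=layers, thickness=thickness, z_breaks=z_breaks)


def layer_extent(layer: np.ndarray, cloud: PointCloud) -> tuple[float, float]:
    """(x width, y width) = coordinate ranges of the layer's points."""
    if len(layer) == 0:
        return (0.0, 0.0)
    pts = cloud.points[layer]
    x_width = float(pts[:, 0].max() - pts[:, 0].min())
    y_width = float(pts[:, 1].max() - pts[:, 1].min())
    return (x_width, y_width)


def extract_trunk(cloud: PointCloud, thickness: float = DEFAULT_THICKNESS,
                  lam: float = DEFAULT_LAMBDA) -> TrunkResult:
    """Grow the trunk pipe upward from the base layer.

    Starting from the lowest non-empty layer s, layer i joins the trunk
    while ``x_i <= x_s + lam`` and ``y_i <= y_s + lam``; the first
    violating layer stops the pipe.  Empty intermediate layers (occlusion
    gaps) are skipped without stopping.
    """
    if lam <= 0 or thickness <= 0:
        raise ValueError("thickness and lam must be positive")
    stack = slice_layers(cloud, thickness)
    s = next((j for j, lay in enumerate(stack.layers) if len(lay)), None)
    if s is None:
        raise EmptyCloudError("extract_trunk: no occupied base layer")
    x_s, y_s = layer_extent(stack.layers[s], cloud)
    trunk_positions = [stack.layers[s]]
    stop_layer = stack.n_layers
    reached_top = True
    for i in range(s + 1, stack.n_layers):
        layer = stack.layers[i]
        if len(layer) == 0:
            continue
        x_i, y_i = layer_extent(layer, cloud)
        if x_i <= x_s + lam and y_i <= y_s + lam:
            trunk_positions.append(layer)
        else:
            stop_layer = i
            reached_top = False
            break
    trunk_ids = cloud.ids[np.concatenate(trunk_positions)]
    return TrunkResult(
        trunk_ids=np.sort(trunk_ids),
        stop_layer=stop_layer,
        base_extent=(x_s, y_s),
        reached_top=reached_top,
    )
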