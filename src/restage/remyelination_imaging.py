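"""Confocal co-localization quantification of remyelination.

Two-channel z-stacks (green = MBP myelin staining, red = NFH axonal
staining, 1 um z-spacing) are quantified layer by layer: a pixel belongs to
the co-localization mask when both channels exceed their intensity
thresholds, and the layer's remyelination index is the co-localized pixel
count divided by the NFH-positive pixel count. Layer indices are averaged
into a stack index, stack indices into a per-condition mean +/- SEM, and a
relative index against the untreated control condition.

Thresholds are either fixed or computed per channel and layer by Otsu's
method. Because the co-localization mask is the intersection of the two
channel masks, the index is guaranteed to lie in [0, 1]; layers with no
NFH-positive pixels are flagged undefined and excluded from the stack mean
rather than being counted as zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

from .errors import ComputationError, ValidationError

__all__ = [
    "ImageStack",
    "ColocParams",
    "LayerColoc",
    "StackIndex",
    "ConditionIndex",
    "split_channels",
    "coloc_mask",
    "layer_remyelination_index",
    "stack_index",
    "condition_index",
    "read_stack",
    "write_stack",
]


@dataclass
class ImageStack:
    """A confocal z-stack: ``voxels[layer, y, x, channel]`` plus channel roles."""

    voxels: np.ndarray
    channels: dict = field(default_factory=lambda: {"red": 0, "green": 1})
    z_spacing_um: float = 1.0

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"stack must be 4-D (layers, height, width, channels), got {self.voxels.ndim}-D"
            )

    @property
    def n_layers(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class ColocParams:
    """Thresholding parameters for the co-localization mask."""

    green_threshold: float = 100.0
    red_threshold: float = 100.0
    threshold_mode: str = "fixed"  # "fixed" | "otsu_per_channel"

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "otsu_per_channel"):
            raise ValidationError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass(frozen=True)
class LayerColoc:
    layer_index: int
    coloc_pixels: int
    nfh_pixels: int
    index: Optional[float]  # None when nfh_pixels == 0 (undefined)


@dataclass(frozen=True)
class StackIndex:
    per_layer: tuple[LayerColoc, ...]
    stack_index: float
    n_layers_used: int


@dataclass(frozen=True)
class ConditionIndex:
    condition: str
    stack_indices: tuple[float, ...]
    mean: float
    sem: float
    relative_index: Optional[float] = None


def split_channels(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Return the (green, red) 3-D intensity arrays; any extra channel is
    ignored. Channel roles come from metadata, never from pixel statistics."""
    for role in ("green", "red"):
        if role not in stack.channels:
            raise ValidationError(f"stack metadata lacks the '{role}' channel role")
    n_channels = stack.voxels.shape[-1]
    if n_channels < 2:
        raise ValidationError("co-localization requires at least 2 channels")
    green = stack.voxels[..., stack.channels["green"]]
    red = stack.voxels[..., stack.channels["red"]]
    return green, red


def _thresholds(green_layer: np.ndarray, red_layer: np.ndarray, params: ColocParams):
    if params.threshold_mode == "fixed":
        return params.green_threshold, params.red_threshold
    return threshold_otsu(green_layer), threshold_otsu(red_layer)


def coloc_mask(
    green_layer: np.ndarray, red_layer: np.ndarray, params: ColocParams = ColocParams()
) -> np.ndarray:
    """Boolean mask, true exactly where both channels exceed their thresholds."""
    if green_layer.shape != red_layer.shape:
        raise ValidationError("channel layers must have the same shape")
    gt, rt = _thresholds(green_layer, red_layer, params)
    return (green_layer > gt) & (red_layer > rt)


def layer_remyelination_index(
    green_layer: np.ndarray,
    red_layer: np.ndarray,
    params: ColocParams = ColocParams(),
    layer_index: int = 0,
) -> LayerColoc:
    """Per-layer index: co-localized pixels / NFH-positive pixels.

    A layer with no NFH signal gets ``index=None`` (undefined), not zero.
    """
    if green_layer.shape != red_layer.shape:
        raise ValidationError("channel layers must have the same shape")
    gt, rt = _thresholds(green_layer, red_layer, params)
    red_mask = red_layer > rt
    mask = (green_layer > gt) & red_mask
    nfh = int(red_mask.sum())
    coloc = int(mask.sum())
    return LayerColoc(
        layer_index=layer_index,
        coloc_pixels=coloc,
        nfh_pixels=nfh,
        index=(coloc / nfh) if nfh > 0 else None,
    )


def stack_index(stack: ImageStack, params: ColocParams = ColocParams()) -> StackIndex:
    """Unweighted mean of the defined per-layer indices of one z-stack."""
    green, red = split_channels(stack)
    layers = tuple(
        layer_remyelination_index(green[i], red[i], params, layer_index=i)
        for i in range(stack.n_layers)
    )
    defined = [lc.index for lc in layers if lc.index is not None]
    if not defined:
        raise ComputationError("all layers have zero NFH signal; stack index undefined")
    return StackIndex(
        per_layer=layers,
        stack_index=float(np.mean(defined)),
        n_layers_used=len(defined),
    )


def condition_index(
    condition: str,
    stacks: Sequence[StackIndex | float],
    control: Optional[ConditionIndex] = None,
) -> ConditionIndex:
    """Aggregate stack indices of one experimental condition (typically 3
    stacks per point); optionally express the mean relative to a control
    condition's mean."""
    values = [s.stack_index if isinstance(s, StackIndex) else float(s) for s in stacks]
    if not values:
        raise ComputationError(f"condition '{condition}' has no stacks")
    arr = np.asarray(values, float)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    relative = None
    if control is not None:
        relative = float(arr.mean() / control.mean) if control.mean != 0 else None
    return ConditionIndex(
        condition=condition,
        stack_indices=tuple(values),
        mean=float(arr.mean()),
        sem=sem,
        relative_index=relative,
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF, one page per z-layer, channels last."""
    tifffile.imwrite(path, stack.voxels, photometric="rgb" if stack.voxels.shape[-1] == 3 else None)


def read_stack(path, green_channel: int = 1, red_channel: int = 0, z_spacing_um: float = 1.0) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Accepts (layers, H, W, C) or single-layer (H, W, C) data; channel roles
    are declared by the caller.
    """
    voxels = tifffile.imread(path)
    if voxels.ndim == 3:
        voxels = voxels[np.newaxis, ...]
    if voxels.ndim != 4:
        raise ValidationError(f"unsupported TIFF shape {voxels.shape}")
    return ImageStack(
        voxels=voxels,
        channels={"green": green_channel, "red": red_channel},
        z_spacing_um=z_spacing_um,
    )
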