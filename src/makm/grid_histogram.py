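"""Multi-channel images and joint histograms over the feature space.

The segmentation method operates on the *joint histogram* of a multi-channel
image ``I : Omega -> Y`` — here typically two channels, an equivolumetric
cortical depth in [0, 1] and a normalized stain intensity.  The histogram
``q`` is a probability density on a regular bin grid over the feature space
``Y = [0, 1]^N`` (unit integral), and every downstream field (mixture density,
filtered kernel estimate, error field) lives on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MultiChannelImage",
    "BinGrid",
    "JointHistogram",
    "GridField",
    "normalize_channels",
    "joint_histogram",
    "eval_image_features",
]


@dataclass
class MultiChannelImage:
    """A multi-channel image on one voxel grid plus a foreground mask.

    Parameters
    ----------
    data : ndarray, shape (n_channels, \\*spatial)
        Channel-first stack; all channels share the spatial grid.
    spacing : tuple of float
        Physical voxel size per spatial axis, in mm.
    mask : ndarray of bool, shape (\\*spatial)
        Foreground (cortex) mask; voxels outside never enter the histogram.
    channel_names : tuple of str
        One name per channel.  The depth channel is identified by
        ``depth_channel`` (index 0 by convention).
    norms : dict, optional
        Per-channel affine normalization records ``name -> (offset, scale)``
        such that ``normalized = (raw - offset) * scale``.
    """

    data: np.ndarray
    spacing: tuple
    mask: np.ndarray
    channel_names: tuple
    depth_channel: int = 0
    norms: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != self.mask.ndim + 1:
            raise ValueError("data must be (channel, *spatial) matching mask")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError(
                f"channel grid {self.data.shape[1:]} != mask grid {self.mask.shape}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name required per channel")
        if len(self.spacing) != self.mask.ndim:
            raise ValueError("one spacing entry required per spatial axis")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        d = self.data[self.depth_channel][self.mask]
        if d.min() < -1e-9 or d.max() > 1 + 1e-9:
            raise ValueError("depth channel must lie in [0, 1] inside the mask")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.mask.shape

    def masked_features(self) -> np.ndarray:
        """Feature vectors of all masked voxels, shape (n_voxels, n_channels)."""
        return self.data[:, self.mask].T


@dataclass(frozen=True)
class BinGrid:
    """Regular bin grid discretizing the feature space.

    ``edges[n]`` are the ``n_bins + 1`` evenly spaced edges of channel ``n``;
    centers are edge midpoints and ``bin_volume`` is the product of per-channel
    bin widths.
    """

    edges: tuple  # tuple of 1-D ndarrays, one per channel

    def __post_init__(self):
        object.__setattr__(
            self, "edges", tuple(np.asarray(e, dtype=float) for e in self.edges)
        )
        for e in self.edges:
            if e.ndim != 1 or len(e) < 3 or not np.all(np.diff(e) > 0):
                raise ValueError("edges must be strictly increasing with >=2 bins")

    @classmethod
    def regular(cls, n_channels: int, n_bins: int, lo: float = 0.0, hi: float = 1.0):
        if n_bins < 2:
            raise ValueError("need at least 2 bins per channel")
        e = np.linspace(lo, hi, n_bins + 1)
        return cls(edges=tuple(e.copy() for _ in range(n_channels)))

    @property
    def n_channels(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple:
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def widths(self) -> np.ndarray:
        return np.array([e[1] - e[0] for e in self.edges])

    @property
    def bin_volume(self) -> float:
        return float(np.prod(self.widths))

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    def center_points(self) -> np.ndarray:
        """All bin centers as points, shape (n_bins_total, n_channels), C order."""
        mesh = np.meshgrid(*self.centers, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)


@dataclass
class GridField:
    """A real scalar field sampled on a bin grid (may be negative)."""

    grid: BinGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.bin_volume)


@dataclass
class JointHistogram(GridField):
    """Nonnegative density on a bin grid with unit integral."""

    def __post_init__(self):
        super().__post_init__()
        if self.values.min() < 0:
            raise ValueError("histogram values must be nonnegative")
        if abs(self.mass - 1.0) > 1e-9:
            raise ValueError(f"histogram mass {self.mass} != 1")


def normalize_channels(image: MultiChannelImage) -> MultiChannelImage:
    """Affinely rescale each non-depth channel to [0, 1] over the mask.

    The depth channel is left untouched (it is defined on [0, 1] already).
    The affine parameters are recorded in ``norms`` for inversion.
    """
    data = image.data.copy()
    norms = dict(image.norms)
    for c, name in enumerate(image.channel_names):
        if c == image.depth_channel:
            continue
        vals = data[c][image.mask]
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            raise ValueError(f"constant channel {name!r}: cannot normalize")
        data[c] = (data[c] - lo) / (hi - lo)
        norms[name] = (lo, 1.0 / (hi - lo))
    return replace(image, data=data, norms=norms)


def joint_histogram(
    image: MultiChannelImage, bins_per_channel: int = 50
) -> JointHistogram:
    """Build the normalized joint histogram of the masked voxels.

    Bins are half-open ``[lo, hi)`` on ``[0, 1]`` per channel, with the top
    edge closed so that feature value 1.0 (the gray-white boundary in depth)
    lands in the last bin.  The counts are divided by
    ``n_voxels * bin_volume`` so the result integrates to one.
    """
    if bins_per_channel < 2:
        raise ValueError("bins_per_channel must be >= 2")
    grid = BinGrid.regular(image.n_channels, bins_per_channel)
    feats = image.masked_features()
    if feats.min() < -1e-9 or feats.max() > 1 + 1e-9:
        raise ValueError("features outside [0,1]; call normalize_channels first")
    # np.clip keeps exact 1.0 in the closed top bin.
    idx = np.clip(
        np.floor(feats * bins_per_channel).astype(int), 0, bins_per_channel - 1
    )
    counts = np.zeros(grid.shape, dtype=float)
    np.add.at(counts, tuple(idx.T), 1.0)
    assert counts.sum() == feats.shape[0]  # every voxel in exactly one bin
    values = counts / (feats.shape[0] * grid.bin_volume)
    return JointHistogram(grid=grid, values=values)


def eval_image_features(image: MultiChannelImage, x: tuple) -> np.ndarray:
    """Return the channel value vector ``I(x)`` at voxel index ``x``."""
    x = tuple(int(i) for i in x)
    if not image.mask[x]:
        raise ValueError(f"voxel {x} is outside the mask")
    return image.data[(slice(None),) + x].copy()
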