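"""Gaussian mixtures, filter functions, and the filtered kernel estimate.

The density model is an M-component multivariate Gaussian mixture

    g_theta(y) = sum_m  w_m * psi_{K_m}(y - mu_m),     sum_m w_m = 1,

where ``psi_K`` is the zero-centered normal density with covariance ``K``.
Each component's *filter function* (posterior responsibility)

    rho_m(y) = w_m * psi_{K_m}(y - mu_m) / g_theta(y)

partitions unity wherever the mixture density is above a small floor.  The
*filtered kernel estimate* (FKE) re-smooths the joint histogram ``q``
component by component,

    f_theta(y) = sum_m ((rho_m * q) conv psi_{h K_m})(y),

with a per-component kernel whose covariance is the component covariance
scaled by the diagonal bandwidth matrix ``h``.  The alternating fit minimizes
the discrete squared L2 distance between the FKE of the previous model and
the mixture currently being refined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .grid_histogram import BinGrid, GridField, JointHistogram

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "Bandwidth",
    "gaussian_pdf",
    "mixture_pdf",
    "responsibilities",
    "filtered_kernel_estimate",
    "l2_distance_sq",
]

#: Relative density floor: responsibilities are zeroed where the mixture
#: density falls below DENSITY_FLOOR_REL times its peak value.
DENSITY_FLOOR_REL = 1e-12

#: Covariance eigenvalue floor applied after symmetrization.
SPD_JITTER = 1e-10


def _ensure_spd(K: np.ndarray) -> np.ndarray:
    """Symmetrize and floor the eigenvalues of a covariance matrix."""
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    if w.min() <= SPD_JITTER:
        w = np.maximum(w, SPD_JITTER)
        K = (V * w) @ V.T
        K = 0.5 * (K + K.T)
    return K


@dataclass
class GaussianComponent:
    """One mixture component: weight, mean and SPD covariance."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.weight = float(self.weight)
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.weight < 0:
            raise ValueError("component weight must be nonnegative")
        n = self.mean.shape[0]
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape must match mean dimension")
        self.covariance = _ensure_spd(self.covariance)

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]


@dataclass
class MixtureModel:
    """An ordered list of Gaussian components with weights on the simplex."""

    components: list

    def __post_init__(self):
        if len(self.components) < 1:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_features(self) -> int:
        return self.components[0].n_features

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([c.covariance for c in self.components])

    # -- serialization ----------------------------------------------------

    def to_dict(self, channel_names=None, bandwidth=None) -> dict:
        doc = {
            "components": [
                {
                    "weight": c.weight,
                    "mean": c.mean.tolist(),
                    "covariance": c.covariance.tolist(),
                }
                for c in self.components
            ]
        }
        if channel_names is not None:
            doc["channel_names"] = list(channel_names)
        if bandwidth is not None:
            doc["bandwidth"] = list(np.asarray(bandwidth.diagonal, dtype=float))
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "MixtureModel":
        comps = [
            GaussianComponent(c["weight"], np.array(c["mean"]), np.array(c["covariance"]))
            for c in doc["components"]
        ]
        return cls(components=comps)

    def to_json(self, path, channel_names=None, bandwidth=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(channel_names, bandwidth), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MixtureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Bandwidth:
    """Diagonal bandwidth matrix h = diag(h_1, ..., h_N), entries > 0.

    The all-zero bandwidth is accepted as the delta-kernel limit (the FKE
    then reproduces the filtered histogram bin for bin).
    """

    diagonal: np.ndarray

    def __post_init__(self):
        self.diagonal = np.asarray(self.diagonal, dtype=float)
        if np.any(self.diagonal < 0):
            raise ValueError("bandwidth entries must be nonnegative")
        if np.any(self.diagonal == 0) and not np.all(self.diagonal == 0):
            raise ValueError("bandwidth entries must be all zero or all positive")

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.diagonal == 0))

    @classmethod
    def auto(cls, grid: BinGrid, scale: float = 2.0) -> "Bandwidth":
        """Default bandwidth: ``scale`` bin widths per channel."""
        return cls(diagonal=scale * grid.widths)


# ---------------------------------------------------------------------------
# densities


def gaussian_pdf(y: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Zero-centered multivariate normal density psi_K evaluated at y.

    ``y`` may be a single N-vector or an array of shape (..., N).
    """
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance is singular or not positive")
    Kinv = np.linalg.inv(K)
    maha = np.einsum("...i,ij,...j->...", y, Kinv, y)
    return np.exp(-0.5 * maha - 0.5 * (n * np.log(2 * np.pi) + logdet))


def _component_densities(model: MixtureModel, y: np.ndarray) -> np.ndarray:
    """w_m * psi_{K_m}(y - mu_m) for all m; shape (..., M)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    parts = [
        c.weight * gaussian_pdf(y - c.mean, c.covariance) for c in model.components
    ]
    return np.stack(parts, axis=-1)


def mixture_pdf(model: MixtureModel, y: np.ndarray) -> np.ndarray:
    """Mixture density g_theta(y); vectorized over leading axes of y."""
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 1
    out = _component_densities(model, y).sum(axis=-1)
    return float(out[0]) if scalar else out


def mixture_on_grid(model: MixtureModel, grid: BinGrid) -> GridField:
    """Evaluate the mixture density at every bin center of ``grid``."""
    pts = grid.center_points()
    vals = mixture_pdf(model, pts).reshape(grid.shape)
    return GridField(grid=grid, values=vals)


def responsibilities(model: MixtureModel, y: np.ndarray) -> np.ndarray:
    """Filter functions rho_m(y) = w_m psi_m(y - mu_m) / g(y); shape (..., M).

    The division is floored: wherever the mixture density falls below
    ``DENSITY_FLOOR_REL`` times the largest density in the evaluated batch
    (the grid maximum when evaluating on a bin grid), the whole
    responsibility vector is zero — these are empty histogram corners whose
    posteriors are numerically meaningless.  Degenerate voxels are handled
    downstream (nearest-mean labeling).
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 1
    num = _component_densities(model, y)
    den = num.sum(axis=-1, keepdims=True)
    floor = max(DENSITY_FLOOR_REL * float(den.max()), 1e-300)
    safe = den > floor
    rho = np.where(safe, num / np.where(safe, den, 1.0), 0.0)
    return rho[0] if scalar else rho


# ---------------------------------------------------------------------------
# filtered kernel estimate


def kernel_covariance(h: Bandwidth, K: np.ndarray) -> np.ndarray:
    """Smoothing-kernel covariance for bandwidth h and component covariance K.

    The bandwidth sets the kernel's *scale* — the kernel's standard
    deviation along channel n is exactly h_n — while the component
    covariance contributes only its correlation structure (orientation):

        S = diag(h) . corr(K) . diag(h).

    Scaling K by the bandwidth on the raw covariance instead would make the
    smoothing length proportional to each component's own spread, so
    already-narrow components would leave their share of the histogram
    essentially unsmoothed; the target field then has region-dependent
    sharpness and the residual-driven insertion piles new components onto
    the sharpest region instead of the worst-covered one.
    """
    s = np.sqrt(np.diag(K))
    R = K / np.outer(s, s)
    D = np.diag(h.diagonal)
    return _ensure_spd(D @ R @ D)


def _discrete_kernel(grid: BinGrid, S: np.ndarray, truncate: float = 4.0):
    """Sample a zero-centered Gaussian of covariance S at bin-center offsets.

    Truncated at ``truncate`` standard deviations per axis and renormalized
    to unit discrete sum so convolution conserves mass.  Returns None for a
    single-bin (delta) kernel.
    """
    widths = grid.widths
    sig = np.sqrt(np.diag(S))
    half = np.ceil(truncate * sig / widths).astype(int)
    extent = np.array(grid.shape)
    if np.any(half > 10 * extent):
        raise ValueError(
            f"kernel support {2 * half + 1} exceeds 10x grid extent {extent}: "
            "bandwidth implausible for this grid"
        )
    if np.all(half == 0):
        return None
    offsets = [w * np.arange(-h, h + 1) for w, h in zip(widths, half)]
    mesh = np.meshgrid(*offsets, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    ker = gaussian_pdf(pts, S).reshape([2 * h + 1 for h in half])
    return ker / ker.sum()


def filtered_kernel_estimate(
    model: MixtureModel, q: JointHistogram, h: Bandwidth
) -> GridField:
    """FKE: f(y) = sum_m ((rho_m q) conv psi_{hK_m})(y) on q's bin grid.

    Kernels are discretized at bin centers, truncated at 4 sigma, and
    renormalized to unit discrete mass; the convolution is "same"-sized with
    zero-padded boundaries, so total mass equals the mass of sum_m rho_m q
    up to boundary truncation.  A zero bandwidth is the delta-kernel limit:
    the result is the rho-filtered histogram itself.
    """
    grid = q.grid
    pts = grid.center_points()
    rho = responsibilities(model, pts).reshape(grid.shape + (model.n_components,))
    out = np.zeros(grid.shape)
    for m, comp in enumerate(model.components):
        filtered = rho[..., m] * q.values
        if h.is_zero:
            out += filtered
            continue
        ker = _discrete_kernel(grid, kernel_covariance(h, comp.covariance))
        if ker is None:
            out += filtered
        else:
            out += signal.fftconvolve(filtered, ker, mode="same")
    return GridField(grid=grid, values=out)


def l2_distance_sq(a: GridField, b: GridField) -> float:
    """Discrete squared L2 distance: sum((a-b)^2) * bin_volume."""
    if a.grid.shape != b.grid.shape or not all(
        np.array_equal(ea, eb) for ea, eb in zip(a.grid.edges, b.grid.edges)
    ):
        raise ValueError("fields live on different grids")
    d = a.values - b.values
    return float((d * d).sum() * a.grid.bin_volume)
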