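"""Incremental alternating-kernel mixture fitting.

Components are added one at a time.  At stage M the previous model's
filtered kernel estimate becomes the fixed target field (the histogram
itself at M=1), a new component is seeded by the multidimensional "smart
start" — placed where the box-smoothed residual error is largest, weighted
to cancel that error, with a covariance from the error-weighted second
moments around the peak — and all M components are then refined jointly by
gradient descent on the discrete squared L2 distance between target and
mixture.

Constraints are enforced by reparameterization: weights through a softmax
(simplex), covariances through Cholesky factors with log-diagonals (SPD).
Gradients are analytic; the line search is Armijo backtracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid_histogram import GridField, JointHistogram
from .mixture import (
    Bandwidth,
    GaussianComponent,
    MixtureModel,
    filtered_kernel_estimate,
    mixture_on_grid,
)

__all__ = [
    "FitConfig",
    "FitTrace",
    "NoUnderfitRegion",
    "smart_start",
    "fit_single_component",
    "akm_step",
    "fit_makm",
]

#: Clamp range for a freshly inserted component's weight: never negligible,
#: never enough to wipe out the weights of the components already fitted.
W_MIN = 1e-3
W_MAX = 0.5


class NoUnderfitRegion(Exception):
    """Raised when the box-smoothed error field is nowhere positive.

    The model already covers the histogram everywhere; inserting another
    component would carry zero or negative weight, so the incremental loop
    stops early.
    """


@dataclass
class FitConfig:
    """Tunable parameters of the incremental fit.

    mmax : int
        Final number of mixture components (12 in the original application).
    bins_per_channel : int
        Joint-histogram resolution (50 by default).
    bandwidth : Bandwidth or "auto"
        FKE smoothing bandwidth; "auto" means two bin widths per channel.
    box_halfwidth : int
        Half-width, in bins, of the smart-start box kernel (1 -> 3 bins/axis).
    max_iter, tol : optimization loop controls; tol is the relative change
        in objective between accepted steps.
    step_init, armijo : initial step and Armijo constant for backtracking.
    seed : recorded for provenance; the fit itself is deterministic.
    """

    mmax: int = 12
    bins_per_channel: int = 50
    bandwidth: object = "auto"
    box_halfwidth: int = 1
    max_iter: int = 2000
    tol: float = 1e-8
    step_init: float = 0.25
    armijo: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.mmax < 1:
            raise ValueError("mmax must be >= 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tolerances and iteration counts must be positive")

    def resolve_bandwidth(self, grid) -> Bandwidth:
        if isinstance(self.bandwidth, Bandwidth):
            return self.bandwidth
        if self.bandwidth == "auto":
            return Bandwidth.auto(grid)
        return Bandwidth(diagonal=np.asarray(self.bandwidth, dtype=float))


@dataclass
class FitTrace:
    """Objective and initialization bookkeeping across the incremental fit."""

    final_objectives: list = field(default_factory=list)  # one per M
    iteration_objectives: dict = field(default_factory=dict)  # M -> [J...]
    initializations: dict = field(default_factory=dict)  # M -> dict

    def record(self, M: int, objectives: list, init: dict | None = None) -> None:
        self.iteration_objectives[M] = list(objectives)
        self.final_objectives.append(objectives[-1])
        if init is not None:
            self.initializations[M] = init


# ---------------------------------------------------------------------------
# smart start


def smart_start(
    error: GridField, box_halfwidth: int = 1, bandwidth: Bandwidth | None = None
):
    """Seed a new component from the residual error field.

    The error is smoothed with a centered unit-sum box kernel of
    ``(2*box_halfwidth+1)^N`` bins (zero-padded at the grid boundary).  The
    new mean is the bin center maximizing the smoothed error (ties broken by
    lowest C-order index).  The weight is the error *mass* the new component
    must absorb — the smoothed error density at the peak times the box's
    feature-space volume — clamped to [1e-3, 0.5] so the insertion can never
    wipe out the weights of the components already fitted.  The covariance
    is the error-weighted second moment of the box neighborhood around the
    peak; if that matrix is not positive definite (the error may be negative
    within the box), a diagonal fallback sized to the box extent is used.

    Returns ``(mean, weight, covariance)``; raises :class:`NoUnderfitRegion`
    when the smoothed error is nowhere positive.
    """
    grid = error.grid
    size = 2 * int(box_halfwidth) + 1
    if box_halfwidth == 0:
        smoothed = error.values
    else:
        smoothed = ndimage.uniform_filter(error.values, size=size, mode="constant")
    flat_idx = int(np.argmax(smoothed))
    peak = smoothed.flat[flat_idx]
    if peak <= 0:
        raise NoUnderfitRegion("box-smoothed error is nowhere positive")
    idx = np.unravel_index(flat_idx, smoothed.shape)
    centers = grid.centers
    mu = np.array([centers[n][idx[n]] for n in range(grid.n_channels)])
    box_volume = size**grid.n_channels * grid.bin_volume
    w = float(np.clip(peak * box_volume, W_MIN, W_MAX))

    # error-weighted second moment over the box window around the peak;
    # zero padding means out-of-grid bins contribute nothing.
    n = grid.n_channels
    lo = [max(0, idx[d] - box_halfwidth) for d in range(n)]
    hi = [min(grid.shape[d], idx[d] + box_halfwidth + 1) for d in range(n)]
    window = tuple(slice(l, h) for l, h in zip(lo, hi))
    e_win = error.values[window]
    axes = np.meshgrid(*(centers[d][window[d]] for d in range(n)), indexing="ij")
    d_pts = np.stack([a.ravel() for a in axes], axis=-1) - mu  # (nbox, N)
    c = e_win.ravel() / size**n  # e(y) * b(y - mu)
    K = (d_pts * c[:, None]).T @ d_pts / peak
    K = 0.5 * (K + K.T)
    if np.linalg.eigvalsh(K).min() > 1e-10:
        return mu, w, K
    # fallback: diagonal covariance sized to the box extent
    if bandwidth is not None and not bandwidth.is_zero:
        sig = bandwidth.diagonal * size / 2.0
    else:
        sig = grid.widths * size / 2.0
    return mu, w, np.diag(sig**2)


# ---------------------------------------------------------------------------
# parameter (un)packing: logits | means | Cholesky factors (log-diagonal)


def _tril_ix(n):
    return np.tril_indices(n)


def _pack(model: MixtureModel) -> np.ndarray:
    M, N = model.n_components, model.n_features
    logits = np.log(np.maximum(model.weights, 1e-300))
    means = model.means.ravel()
    ix = _tril_ix(N)
    chols = []
    for c in model.components:
        L = np.linalg.cholesky(c.covariance)
        L = L.copy()
        diag = np.arange(N)
        L[diag, diag] = np.log(L[diag, diag])
        chols.append(L[ix])
    return np.concatenate([logits, means, np.concatenate(chols)])


def _unpack(theta: np.ndarray, M: int, N: int):
    """Return (weights, means, Ls) with L the lower-tri Cholesky factors."""
    ix = _tril_ix(N)
    ntri = len(ix[0])
    logits = theta[:M]
    means = theta[M : M + M * N].reshape(M, N)
    tri = theta[M + M * N :].reshape(M, ntri)
    z = logits - logits.max()
    w = np.exp(z)
    w = w / w.sum()
    Ls = np.zeros((M, N, N))
    diag = np.arange(N)
    for m in range(M):
        Ls[m][ix] = tri[m]
        Ls[m, diag, diag] = np.exp(Ls[m, diag, diag])
    return w, means, Ls


def _to_model(theta: np.ndarray, M: int, N: int) -> MixtureModel:
    w, means, Ls = _unpack(theta, M, N)
    w = w / w.sum()
    comps = [
        GaussianComponent(w[m], means[m], Ls[m] @ Ls[m].T) for m in range(M)
    ]
    return MixtureModel(components=comps)


def _objective_and_grad(theta, M, N, pts, target, bin_volume):
    """Discrete L2 objective and its analytic gradient in packed coordinates."""
    w, means, Ls = _unpack(theta, M, N)
    B = pts.shape[0]
    psi = np.empty((B, M))
    Kinvs = np.empty((M, N, N))
    diffs = np.empty((M, B, N))
    for m in range(M):
        L = Ls[m]
        d = pts - means[m]
        sol = np.linalg.solve(L, d.T)  # L z = d  ->  maha = |z|^2
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        psi[:, m] = np.exp(-0.5 * maha - 0.5 * (N * np.log(2 * np.pi) + logdet))
        Kinvs[m] = np.linalg.inv(L @ L.T)
        diffs[m] = d
    g = psi @ w
    r = g - target
    J = float((r * r).sum() * bin_volume)

    grad = np.zeros_like(theta)
    ix = _tril_ix(N)
    ntri = len(ix[0])
    diag = np.arange(N)
    # weights via softmax chain rule
    u = 2.0 * bin_volume * (psi * r[:, None]).sum(axis=0)  # dJ/dw_m
    grad[:M] = w * (u - float(u @ w))
    for m in range(M):
        p = w[m] * psi[:, m]
        rp = r * p
        d = diffs[m]
        Kinv = Kinvs[m]
        s0 = rp.sum()
        s1 = rp @ d
        S2 = (d * rp[:, None]).T @ d
        grad[M + m * N : M + (m + 1) * N] = 2.0 * bin_volume * (Kinv @ s1)
        G = bin_volume * (Kinv @ S2 @ Kinv - s0 * Kinv)  # dJ/dK (symmetric)
        gL = 2.0 * G @ Ls[m]
        gL[diag, diag] *= np.diag(Ls[m])  # chain rule for log-diagonal
        grad[M + M * N + m * ntri : M + M * N + (m + 1) * ntri] = gL[ix]
    return J, grad


def _chol_diag_lower_bounds(M: int, N: int, widths: np.ndarray) -> np.ndarray:
    """Packed-coordinate lower bounds keeping Cholesky diagonals resolvable.

    A component narrower than about half a bin along any channel cannot be
    represented on the discrete grid (and lets the density spike without
    bound), so the log-diagonal entries are bounded below at
    ``log(width/2)``; all other coordinates are unbounded.
    """
    ix = _tril_ix(N)
    ntri = len(ix[0])
    lower = np.full(M + M * N + M * ntri, -np.inf)
    for m in range(M):
        for t, (i, j) in enumerate(zip(*ix)):
            if i == j:
                lower[M + M * N + m * ntri + t] = np.log(widths[i] / 2.0)
    return lower


def _gradient_descent(theta, M, N, pts, target, bin_volume, cfg: FitConfig, lower=None):
    """Projected gradient descent with Barzilai-Borwein steps; (theta, [J...]).

    The trial step length is the spectral (BB1) estimate s.s / s.y from the
    previous accepted iterate, safeguarded by Armijo backtracking (halving),
    and each candidate is projected onto the box given by ``lower``.  Plain
    fixed-step descent crawls on this objective — the parameter blocks
    (logits, means, log-Cholesky factors) have very different curvatures —
    while the BB step adapts to the local scale at no extra cost per
    iteration.  The recorded objective is non-increasing across accepted
    steps by construction.
    """
    J, grad = _objective_and_grad(theta, M, N, pts, target, bin_volume)
    trace = [J]
    step = cfg.step_init
    theta_prev = grad_prev = None
    for _ in range(cfg.max_iter):
        gnorm2 = float(grad @ grad)
        if gnorm2 == 0.0:
            break
        if theta_prev is not None:
            s = theta - theta_prev
            ygrad = grad - grad_prev
            sy = float(s @ ygrad)
            if sy > 1e-30:
                step = float(s @ s) / sy
            step = float(np.clip(step, 1e-12, 1e3))
        accepted = False
        t = step
        for _ in range(60):
            cand = theta - t * grad
            if lower is not None:
                cand = np.maximum(cand, lower)
            Jc, gc = _objective_and_grad(cand, M, N, pts, target, bin_volume)
            if Jc <= J - cfg.armijo * t * gnorm2:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        rel = (J - Jc) / max(J, 1e-300)
        theta_prev, grad_prev = theta, grad
        theta, J, grad = cand, Jc, gc
        trace.append(J)
        if rel < cfg.tol:
            break
    return theta, trace


# ---------------------------------------------------------------------------
# incremental fit


def _refine(model: MixtureModel, target: GridField, cfg: FitConfig):
    grid = target.grid
    pts = grid.center_points()
    M, N = model.n_components, model.n_features
    lower = _chol_diag_lower_bounds(M, N, grid.widths)
    theta = np.maximum(_pack(model), lower)
    theta, trace = _gradient_descent(
        theta, M, N, pts, target.values.ravel(), grid.bin_volume, cfg, lower=lower
    )
    return _to_model(theta, M, N), trace


def fit_single_component(
    q: JointHistogram, h: Bandwidth, cfg: FitConfig,
    trace: FitTrace | None = None,
) -> MixtureModel:
    """Fit the M=1 model: moment initialization, then L2 refinement against q.

    The single weight is pinned to 1 by the softmax parameterization.
    """
    grid = q.grid
    pts = grid.center_points()
    p = (q.values * grid.bin_volume).ravel()  # bin probabilities, sum 1
    mu = p @ pts
    d = pts - mu
    K = (d * p[:, None]).T @ d
    K += np.diag(grid.widths**2 / 12.0)  # binning (Sheppard) floor
    model = MixtureModel([GaussianComponent(1.0, mu, K)])
    model, iters = _refine(model, q, cfg)
    if trace is not None:
        trace.record(
            1, iters, init={"mean": mu.tolist(), "weight": 1.0, "covariance": K.tolist()}
        )
    return model


def akm_step(
    model: MixtureModel, q: JointHistogram, h: Bandwidth, cfg: FitConfig,
    trace: FitTrace | None = None,
) -> MixtureModel:
    """Insert one component into a fitted (M-1)-model and refine jointly.

    The target field is the FKE of the incoming model; the new component is
    seeded by :func:`smart_start` on the error (target minus current
    mixture), existing weights are rescaled by (1 - w_new) to restore the
    simplex, and all parameters are then optimized together.
    """
    target = filtered_kernel_estimate(model, q, h)
    g_prev = mixture_on_grid(model, q.grid)
    err = GridField(grid=q.grid, values=target.values - g_prev.values)
    mu, w, K = smart_start(err, cfg.box_halfwidth, bandwidth=h)
    comps = [
        GaussianComponent(c.weight * (1.0 - w), c.mean, c.covariance)
        for c in model.components
    ]
    comps.append(GaussianComponent(w, mu, K))
    grown = MixtureModel(components=comps)
    refined, iters = _refine(grown, target, cfg)
    if trace is not None:
        trace.record(
            grown.n_components,
            iters,
            init={"mean": mu.tolist(), "weight": w, "covariance": K.tolist()},
        )
    return refined


def fit_makm(q: JointHistogram, cfg: FitConfig):
    """Run the full incremental fit from M=1 up to ``cfg.mmax``.

    Returns ``(model, trace)``.  Stops early if the smoothed error is
    nowhere positive (nothing left to explain).
    """
    h = cfg.resolve_bandwidth(q.grid)
    trace = FitTrace()
    model = fit_single_component(q, h, cfg, trace=trace)
    for _ in range(2, cfg.mmax + 1):
        try:
            model = akm_step(model, q, h, cfg, trace=trace)
        except NoUnderfitRegion:
            break
    return model, trace
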