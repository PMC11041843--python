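"""scikit-learn style front end for the full pipeline.

:class:`MAKMSegmenter` wires the modules together: normalize channels,
build the joint histogram, fit the mixture incrementally, sort components
by depth, and label voxels.  It follows the scikit-learn estimator
contract (``get_params``/``set_params``, fitted attributes with trailing
underscores, ``fit``/``predict``) so it composes with sklearn tooling,
although its samples are images rather than feature matrices.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .fit import FitConfig, fit_makm
from .grid_histogram import MultiChannelImage, joint_histogram, normalize_channels
from .labeling import LabelImage, label_argmax, label_contiguous, sort_components_by_depth

__all__ = ["MAKMSegmenter"]


class MAKMSegmenter(BaseEstimator):
    """Cortical-layer segmentation by alternating-kernel mixture fitting.

    Parameters
    ----------
    mmax : int
        Number of mixture components to fit.
    bins_per_channel : int
        Joint-histogram resolution per channel.
    bandwidth : "auto", Bandwidth, or sequence of float
        FKE smoothing bandwidth ("auto": two bin widths per channel).
    box_halfwidth : int
        Smart-start box-kernel half-width in bins.
    max_iter, tol : gradient-descent controls per incremental stage.
    rule : {"contiguous", "argmax"}
        Labeling rule used by :meth:`predict`.
    normalize : bool
        Rescale non-depth channels to [0, 1] over the mask before fitting.
    random_state : int
        Recorded seed (the fit itself is deterministic).

    Attributes
    ----------
    model_ : MixtureModel
        Fitted mixture, sorted by increasing mean depth.
    trace_ : FitTrace
        Per-stage objective and initialization history.
    histogram_ : JointHistogram
        The joint histogram the mixture was fitted to.
    """

    def __init__(
        self,
        mmax: int = 12,
        bins_per_channel: int = 50,
        bandwidth="auto",
        box_halfwidth: int = 1,
        max_iter: int = 2000,
        tol: float = 1e-8,
        rule: str = "contiguous",
        normalize: bool = True,
        random_state: int = 0,
    ):
        self.mmax = mmax
        self.bins_per_channel = bins_per_channel
        self.bandwidth = bandwidth
        self.box_halfwidth = box_halfwidth
        self.max_iter = max_iter
        self.tol = tol
        self.rule = rule
        self.normalize = normalize
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            mmax=self.mmax,
            bins_per_channel=self.bins_per_channel,
            bandwidth=self.bandwidth,
            box_halfwidth=self.box_halfwidth,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )

    def _prepare(self, X: MultiChannelImage) -> MultiChannelImage:
        if not isinstance(X, MultiChannelImage):
            raise TypeError("X must be a MultiChannelImage")
        return normalize_channels(X) if self.normalize else X

    def fit(self, X: MultiChannelImage, y=None) -> "MAKMSegmenter":
        """Fit the mixture to the image's joint histogram."""
        image = self._prepare(X)
        self.histogram_ = joint_histogram(image, self.bins_per_channel)
        model, trace = fit_makm(self.histogram_, self._config())
        self.model_ = sort_components_by_depth(model, image.depth_channel)
        self.trace_ = trace
        self.n_features_in_ = image.n_channels
        return self

    def predict(self, X: MultiChannelImage) -> LabelImage:
        """Segment an image with the fitted, depth-sorted mixture."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        image = self._prepare(X)
        if self.rule == "contiguous":
            return label_contiguous(self.model_, image)
        if self.rule == "argmax":
            return label_argmax(self.model_, image)
        raise ValueError(f"unknown rule {self.rule!r}")

    def fit_predict(self, X: MultiChannelImage, y=None) -> LabelImage:
        return self.fit(X).predict(X)
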