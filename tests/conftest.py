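import numpy as np
import pytest

from makm import (
    FitConfig,
    fit_makm,
    joint_histogram,
    label_contiguous,
    normalize_channels,
    sort_components_by_depth,
)
from makm.phantom import default_smi32_spec, generate_phantom


def random_mixture(rng, n_components, n_features=2):
    """A random valid mixture with well-conditioned covariances."""
    from makm.mixture import GaussianComponent, MixtureModel

    w = rng.dirichlet(np.ones(n_components))
    comps = []
    for m in range(n_components):
        mu = rng.uniform(0.1, 0.9, size=n_features)
        A = rng.normal(0, 0.1, size=(n_features, n_features))
        K = A @ A.T + 0.01 * np.eye(n_features)
        comps.append(GaussianComponent(w[m], mu, K))
    return MixtureModel(components=comps)


def sample_image(rng, means, weights, sigma, n):
    """1-D 'image' whose voxels are draws from a 2-feature Gaussian mixture."""
    from makm.grid_histogram import MultiChannelImage

    means = np.asarray(means, dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights)
    pts = means[comp] + rng.normal(0.0, sigma, size=(n, means.shape[1]))
    pts = np.clip(pts, 0.0, 1.0)
    return MultiChannelImage(
        data=pts.T.copy(),
        spacing=(1.0,),
        mask=np.ones(n, dtype=bool),
        channel_names=tuple(f"f{i}" for i in range(means.shape[1])),
    )


@pytest.fixture(scope="session")
def smi32_noiseless():
    """Noiseless 6-layer gyral phantom fitted end to end (shared, ~10 s)."""
    out = generate_phantom(default_smi32_spec())
    q = joint_histogram(out.image, 50)
    model, trace = fit_makm(q, FitConfig(mmax=6))
    model = sort_components_by_depth(model)
    pred = label_contiguous(model, out.image)
    return {"phantom": out, "histogram": q, "model": model, "trace": trace, "pred": pred}


@pytest.fixture(scope="session")
def smi32_noisy():
    """Same phantom with intensity noise sd 0.05, fitted end to end."""
    out = generate_phantom(default_smi32_spec(noise_sd=0.05, seed=1))
    image = normalize_channels(out.image)
    q = joint_histogram(image, 50)
    model, trace = fit_makm(q, FitConfig(mmax=6))
    model = sort_components_by_depth(model)
    pred = label_contiguous(model, image)
    return {"phantom": out, "histogram": q, "model": model, "trace": trace, "pred": pred}
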