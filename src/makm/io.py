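"""Reading and writing volumes: NIfTI for 3D, (multi-page) TIFF for 2D.

Channels are supplied as separate single-channel files sharing one grid and
paired into a :class:`~makm.grid_histogram.MultiChannelImage`; labels are
written as unsigned 8-bit volumes.
"""

from __future__ import annotations

import numpy as np

from .grid_histogram import MultiChannelImage
from .labeling import LabelImage


def _is_nifti(path) -> bool:
    s = str(path)
    return s.endswith(".nii") or s.endswith(".nii.gz")


def read_volume(path):
    """Read a single-channel volume; returns ``(array, spacing_or_None)``."""
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return data, spacing
    import tifffile

    return np.asarray(tifffile.imread(str(path)), dtype=float), None


def write_volume(path, array: np.ndarray, spacing=None) -> None:
    """Write a single-channel volume in the format implied by the suffix."""
    array = np.asarray(array)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.eye(4)
        if spacing is not None:
            for i, s in enumerate(spacing[:3]):
                affine[i, i] = s
        img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine)
        if spacing is not None:
            img.header.set_zooms(tuple(spacing) + (1.0,) * (3 - len(spacing)))
        nib.save(img, str(path))
    else:
        import tifffile

        tifffile.imwrite(str(path), array)


def write_labels(path, labels: LabelImage) -> None:
    if labels.labels.max() > 255:
        raise ValueError("more than 255 labels cannot be stored as uint8")
    write_volume(path, labels.labels.astype(np.uint8), spacing=labels.spacing)


def read_labels(path) -> LabelImage:
    data, spacing = read_volume(path)
    if spacing is None:
        spacing = (1.0,) * data.ndim
    return LabelImage(labels=np.rint(data).astype(np.int32), spacing=spacing)


def load_image(
    channel_paths,
    mask_path,
    channel_names=None,
    spacing=None,
    depth_channel: int = 0,
) -> MultiChannelImage:
    """Pair separate channel files and a mask into one multi-channel image.

    ``spacing`` overrides any header spacing; TIFF inputs require it (or
    default to 1 mm isotropic).
    """
    arrays, spacings = [], []
    for p in channel_paths:
        a, s = read_volume(p)
        arrays.append(a)
        spacings.append(s)
    mask, mask_spacing = read_volume(mask_path)
    if spacing is None:
        found = [s for s in spacings + [mask_spacing] if s is not None]
        spacing = found[0] if found else (1.0,) * arrays[0].ndim
    if channel_names is None:
        channel_names = ["depth"] + [f"ch{i}" for i in range(1, len(arrays))]
    return MultiChannelImage(
        data=np.stack(arrays),
        spacing=spacing,
        mask=mask > 0.5,
        channel_names=tuple(channel_names),
        depth_channel=depth_channel,
    )
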