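"""Pre-processing chain feeding both segmenters.

Three steps, in this order: subtract the background-ROI mean from every voxel
(clamping negatives to zero), cap all values at the thyroid-ROI mean, and
linearly quantize [0, cap] to 8-bit integers (0-255, half-up rounding). The
cap prevents a hotspot from being segmented as a separate object; the
subtraction equates background tissue with non-radioactive surroundings.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import PreprocessingError, RoiError
from .phantoms import Label, LabelPhantom

__all__ = ["RoiPair", "QuantizedVolume", "derive_rois", "preprocess_volume"]


@dataclass(frozen=True)
class RoiPair:
    """Disjoint background and representative-thyroid voxel masks."""

    background_roi: np.ndarray
    thyroid_roi: np.ndarray

    def __post_init__(self):
        if self.background_roi.shape != self.thyroid_roi.shape:
            raise ValueError("ROI grids differ")
        if not self.background_roi.any() or not self.thyroid_roi.any():
            raise RoiError("both ROIs must be non-empty")
        if (self.background_roi & self.thyroid_roi).any():
            raise RoiError("background and thyroid ROIs overlap")


@dataclass(frozen=True)
class QuantizedVolume:
    """8-bit volume consumed by the segmenters, with its scaling record."""

    values: np.ndarray  # uint8
    voxel_size: float
    offset: float  # background mean subtracted, original intensity units
    gain: float  # grey levels per original intensity unit (255 / cap)

    def to_nifti(self, path) -> None:
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), affine), str(path))


def _values_of(recon) -> np.ndarray:
    return recon.values if hasattr(recon, "values") else np.asarray(recon)


def derive_rois(recon, truth: LabelPhantom | None = None, margin_vox: int = 3) -> RoiPair:
    """Automatic (or label-derived) background and thyroid ROIs.

    In validation mode (``truth`` given) the thyroid ROI is a 1-voxel erosion
    of the true gland and the background ROI is the water compartment at
    least ``margin_vox`` voxels away from it — isolating segmentation
    behaviour from ROI placement, as an operator outlining ROIs would.

    Automatically, the gland blob is the largest connected component of the
    top decile of the (robust) intensity range; the thyroid ROI is its
    1-voxel erosion and the background ROI collects voxels below the median
    positive intensity, at least ``margin_vox`` voxels away from the blob.
    """
    values = _values_of(recon)
    if not np.isfinite(values).all():
        raise ValueError("reconstruction contains non-finite values")

    if truth is not None:
        gland = truth.gland_mask
        thy = ndimage.binary_erosion(gland)
        if not thy.any():
            raise RoiError("gland too small: empty thyroid ROI after erosion")
        water = truth.labels == Label.WATER
        bg = water & ~ndimage.binary_dilation(gland, iterations=margin_vox)
        if not bg.any():
            raise RoiError("empty background ROI")
        return RoiPair(background_roi=bg, thyroid_roi=thy)

    positive = values > 0
    if not positive.any():
        raise RoiError("image has no positive voxels")
    vmax = np.percentile(values[positive], 99.5)
    # restrict to the reconstructed support: the faint blur fringe around the
    # object would otherwise dominate the percentiles
    support = values > 0.05 * vmax
    if not support.any():
        raise RoiError("image has no usable support")
    pos_vals = values[support]
    vmin = pos_vals.min()
    if vmax <= vmin:
        raise RoiError("uniform image: no separable gland")
    top = values >= vmin + 0.9 * (vmax - vmin)
    lab, n_cc = ndimage.label(top)
    if n_cc == 0:
        raise RoiError("no high-intensity blob found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_cc + 1))
    blob = lab == (1 + int(np.argmax(sizes)))
    thy = ndimage.binary_erosion(blob)
    if not thy.any():
        raise RoiError("gland blob too small: empty thyroid ROI after erosion")
    med = np.median(pos_vals)
    bg = support & (values <= med) & ~ndimage.binary_dilation(blob, iterations=margin_vox)
    if not bg.any():
        raise RoiError("empty background ROI")
    return RoiPair(background_roi=bg, thyroid_roi=thy)


def preprocess_volume(recon, rois: RoiPair) -> QuantizedVolume:
    """Background subtraction, hotspot capping and 8-bit quantization."""
    values = _values_of(recon).astype(np.float64)
    if rois.background_roi.shape != values.shape:
        raise ValueError("ROI grid does not match the volume")
    offset = float(values[rois.background_roi].mean())
    shifted = np.clip(values - offset, 0.0, None)
    cap = float(shifted[rois.thyroid_roi].mean())
    if cap <= 0:
        raise PreprocessingError(
            "thyroid ROI mean is not above the background level"
        )
    q = np.floor(np.minimum(shifted, cap) / cap * 255.0 + 0.5).astype(np.uint8)
    voxel = getattr(recon, "voxel_size", 1.0)
    return QuantizedVolume(values=q, voxel_size=float(voxel), offset=offset, gain=255.0 / cap)
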