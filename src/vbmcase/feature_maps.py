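"""The four statistical input maps of the post-processing pipeline.

Two processing streams feed the single-case statistics:

* T1 stream — gray-matter concentration (GMC, unmodulated GM probability),
  gray-matter volume (GMV, GM probability times the Jacobian determinant of
  the normalizing deformation, preserving absolute volume), and the junction
  map (JM, binary image of voxels with intensity intermediate between gray
  and white matter, highlighting gray-white blurring).
* FLAIR stream — normalized FLAIR signal intensity (nFSI), the bias-corrected
  FLAIR z-scored against the subject's white-matter reference region
  (WM probability > 0.5).

Every map is brain-masked and then smoothed with an isotropic Gaussian
kernel (default 8-mm FWHM) and re-masked, so values outside the brain are
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi

from .segmentation import TissueSegmentation
from .volume import Volume

__all__ = [
    "FeatureMap",
    "DegenerateContrastError",
    "FWHM_TO_SIGMA",
    "gaussian_smooth",
    "brain_mask",
    "gmc_map",
    "gmv_map",
    "junction_map",
    "nfsi_map",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

KINDS = ("GMC", "GMV", "JM", "NFSI")


class DegenerateContrastError(ValueError):
    """Gray and white matter intensity distributions leave no junction zone."""


@dataclass
class FeatureMap:
    kind: str
    data: Volume                 # smoothed, masked
    source: Volume               # pre-smoothing masked source
    mask: Volume
    fwhm_mm: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be > 0")


def gaussian_smooth(volume: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing; sigma = FWHM / sqrt(8 ln 2) per axis in mm.

    Anisotropic voxels are handled by per-axis sigma in voxel units;
    zero-padded (constant) boundaries preserve the total sum of interior
    impulses.
    """
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / volume.voxel_size
    return volume.like(ndi.gaussian_filter(volume.data.astype(float), sigma=sigma_vox, mode="constant"))


def brain_mask(seg: TissueSegmentation, threshold: float = 0.5) -> Volume:
    """Binary brain mask: GM+WM+CSF probability above threshold, hole-filled,
    largest connected component retained."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p = seg.brain_probability()
    m = p.data > threshold
    if not m.any():
        raise ValueError("brain mask is empty at this threshold")
    m = ndi.binary_fill_holes(m)
    lab, n = ndi.label(m, structure=np.ones((3, 3, 3), int))
    if n > 1:
        sizes = ndi.sum_labels(m, lab, index=np.arange(1, n + 1))
        m = lab == (1 + int(np.argmax(sizes)))
    return p.like(m.astype(np.uint8))


def _finish(kind: str, source: np.ndarray, mask: Volume, fwhm_mm: float, prov: dict) -> FeatureMap:
    mk = mask.data.astype(bool)
    src = np.where(mk, source, 0.0)
    smoothed = gaussian_smooth(mask.like(src), fwhm_mm).data
    smoothed[~mk] = 0.0
    return FeatureMap(
        kind=kind,
        data=mask.like(smoothed),
        source=mask.like(src),
        mask=mask,
        fwhm_mm=fwhm_mm,
        provenance=prov,
    )


def gmc_map(seg: TissueSegmentation | Volume, fwhm_mm: float = 8.0, mask: Volume | None = None) -> FeatureMap:
    """Gray-matter concentration: smoothed unmodulated GM probability."""
    gm = seg.probabilities["gm"] if isinstance(seg, TissueSegmentation) else seg
    if mask is None:
        raise ValueError("gmc_map requires a brain mask")
    return _finish("GMC", gm.data.astype(float), mask, fwhm_mm, {"modulated": False})


def gmv_map(
    seg: TissueSegmentation | Volume,
    jacobian_det: Volume,
    fwhm_mm: float = 8.0,
    mask: Volume | None = None,
) -> FeatureMap:
    """Gray-matter volume: GM probability modulated by the Jacobian determinant
    of the template-to-native mapping, preserving absolute gray-matter volume."""
    gm = seg.probabilities["gm"] if isinstance(seg, TissueSegmentation) else seg
    jac = jacobian_det.data.astype(float)
    if np.any(jac <= 0):
        raise ValueError("Jacobian determinant must be strictly positive")
    if mask is None:
        raise ValueError("gmv_map requires a brain mask")
    return _finish("GMV", gm.data.astype(float) * jac, mask, fwhm_mm, {"modulated": True})


def junction_map(
    bias_corrected_t1: Volume,
    seg: TissueSegmentation,
    fwhm_mm: float = 8.0,
    mask: Volume | None = None,
    band_sds: float = 0.5,
) -> FeatureMap:
    """Junction map: binary image of the gray-white transition zone.

    A voxel belongs to the zone when its bias-corrected T1 intensity lies in
    [mu_GM + 0.5 sigma_GM, mu_WM - 0.5 sigma_WM], with class statistics taken
    over voxels whose class probability exceeds 0.5; the binary image is
    masked and then smoothed.
    """
    if mask is None:
        raise ValueError("junction_map requires a brain mask")
    t1 = bias_corrected_t1.data.astype(float)
    stats = {}
    for cls in ("gm", "wm"):
        sel = seg.probabilities[cls].data > 0.5
        if sel.sum() < 10:
            raise DegenerateContrastError(f"fewer than 10 voxels with {cls} probability > 0.5")
        stats[cls] = (float(t1[sel].mean()), float(t1[sel].std(ddof=1)))
    lo = stats["gm"][0] + band_sds * stats["gm"][1]
    hi = stats["wm"][0] - band_sds * stats["wm"][1]
    if lo >= hi:
        raise DegenerateContrastError(
            f"junction zone empty: GM mean+{band_sds}SD = {lo:.4f} >= WM mean-{band_sds}SD = {hi:.4f}"
        )
    binary = ((t1 >= lo) & (t1 <= hi)).astype(float)
    prov = {"zone": (lo, hi), "gm_stats": stats["gm"], "wm_stats": stats["wm"]}
    return _finish("JM", binary, mask, fwhm_mm, prov)


def nfsi_map(
    flair_bias_corrected: Volume,
    seg: TissueSegmentation,
    fwhm_mm: float = 8.0,
    mask: Volume | None = None,
    wm_threshold: float = 0.5,
    form: str = "zscore",
    min_reference: int = 100,
) -> FeatureMap:
    """Normalized FLAIR signal intensity, referenced to whole-brain white matter.

    The reference region R is all voxels with WM probability > ``wm_threshold``.
    ``form='zscore'`` gives (I - mean(R)) / sd(R); ``form='ratio'`` gives
    I / mean(R).
    """
    if mask is None:
        raise ValueError("nfsi_map requires a brain mask")
    flair = flair_bias_corrected.data.astype(float)
    ref = seg.probabilities["wm"].data > wm_threshold
    if ref.sum() < min_reference:
        raise ValueError(f"white-matter reference region has {int(ref.sum())} < {min_reference} voxels")
    m, s = float(flair[ref].mean()), float(flair[ref].std(ddof=1))
    if form == "zscore":
        norm = (flair - m) / s
    elif form == "ratio":
        norm = flair / m
    else:
        raise ValueError(f"unknown nFSI form {form!r}")
    prov = {"reference_mean": m, "reference_sd": s, "n_reference": int(ref.sum()), "form": form}
    return _finish("NFSI", norm, mask, fwhm_mm, prov)
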