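"""Myocardial non-compaction index from mid-ventricular section images.

The index is the free-space area fraction inside the ventricular-wall
region of interest: pixels between muscle lamellae that carry no
tissue stain, divided by all ROI pixels. Because absolute staining
intensity varies between sessions, raw indices are only comparable
within a staining/imaging batch and are normalised to the batch's
wild-type mean (WT mean maps to exactly 1). Each section is measured in
triplicate with deterministically jittered thresholds to expose the
sensitivity of the segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import color, filters, measure, morphology

__all__ = [
    "SectionImage",
    "CompactionResult",
    "SegmentationError",
    "segment_tissue",
    "ventricular_roi",
    "noncompaction_index",
    "analyze_section",
    "normalize_to_wt",
]


class SegmentationError(ValueError):
    pass


@dataclass
class SectionImage:
    image: np.ndarray  # RGB uint8 or grayscale
    subject_id: str
    genotype: str  # "WT" / "MFS"
    age_months: int
    batch_id: str  # staining/imaging session; cross-batch comparison forbidden
    roi_mask: np.ndarray | None = None  # optional provided ROI, overrides

    def __post_init__(self) -> None:
        if self.image is None or np.asarray(self.image).size == 0:
            raise ValueError("section image is empty")
        if not self.batch_id:
            raise ValueError("batch_id is required: indices are batch-relative")


@dataclass
class CompactionResult:
    subject_id: str
    genotype: str
    age_months: int
    batch_id: str
    raw_index: float  # mean of triplicates, in [0, 1)
    triplicate: list[float] = field(default_factory=list)
    normalized_index: float = np.nan

    @property
    def triplicate_sd(self) -> float:
        return float(np.std(self.triplicate, ddof=1)) if len(self.triplicate) > 1 else 0.0


def _stain_channel(image: np.ndarray) -> np.ndarray:
    """Stain strength per pixel on a 0-255 scale (saturation for RGB)."""
    img = np.asarray(image)
    if img.ndim == 3:
        sat = color.rgb2hsv(img)[..., 1]
        return sat * 255.0
    # grayscale: stained tissue is darker; invert so tissue scores high
    g = img.astype(float)
    return 255.0 - (g / g.max() * 255.0 if g.max() > 1 else g * 255.0)


def segment_tissue(
    image: np.ndarray,
    despeckle_radius: int = 2,
    threshold_offset: float = 0.0,
) -> np.ndarray:
    """Boolean tissue mask via a histogram-valley (bimodal) threshold.

    The stain channel is median-despeckled (``despeckle_radius`` px, 0
    disables) and thresholded at the valley between the two histogram
    modes; ``threshold_offset`` shifts the cut by that many intensity
    levels (used for triplicate jitter). A unimodal histogram — e.g. a
    blank, all-background image — raises :class:`SegmentationError`.
    """
    ch = _stain_channel(image)
    if despeckle_radius > 0:
        ch = filters.median(ch, morphology.disk(despeckle_radius))
    lo, hi = ch.min(), ch.max()
    if hi - lo < 1.0:
        raise SegmentationError("image histogram is unimodal (flat); cannot segment")
    try:
        thr = float(filters.threshold_minimum(ch.astype(np.uint8)))
    except RuntimeError:
        # valley search fails on near-noiseless (two-spike) histograms:
        # fall back to the midpoint between the Otsu class means, but
        # refuse genuinely unimodal content (classes not separated)
        u = ch.astype(np.uint8)
        split = filters.threshold_otsu(u)
        lo_m, hi_m = ch[u <= split].mean(), ch[u > split].mean()
        if hi_m - lo_m < 30.0:
            raise SegmentationError(
                "no histogram valley and Otsu classes are not separated; "
                "image appears unimodal") from None
        thr = 0.5 * (lo_m + hi_m)
    return ch > (thr + threshold_offset)


def ventricular_roi(
    tissue_mask: np.ndarray,
    closing_radius: int | None = None,
    lumen_area_frac: float = 0.05,
    provided: np.ndarray | None = None,
) -> np.ndarray:
    """Ventricular-wall ROI: closed tissue outline minus chamber lumens.

    The tissue mask is morphologically closed (default radius 2% of the
    image width — enough to bridge inter-lamellar gaps), interior holes
    are filled, and connected background components larger than
    ``lumen_area_frac`` of the ROI are removed as chamber lumens, so
    that free space between lamellae counts while the cavity does not.
    A caller-provided ROI mask overrides the whole procedure.
    """
    if provided is not None:
        return np.asarray(provided, dtype=bool)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not tissue.any():
        raise SegmentationError("tissue mask is empty; no ROI")
    r = closing_radius if closing_radius is not None else max(1, round(0.02 * tissue.shape[1]))
    closed = morphology.closing(tissue, morphology.disk(r))
    roi = ndi.binary_fill_holes(closed)
    # chamber lumens are the large holes of the *closed* outline (the
    # closing seals inter-lamellar gaps into small holes, while a
    # chamber cavity stays a single large one)
    labels = measure.label(roi & ~closed, connectivity=1)
    roi_px = roi.sum()
    for reg in measure.regionprops(labels):
        if reg.area > lumen_area_frac * roi_px:
            roi[labels == reg.label] = False
    if not (roi & tissue).any() or roi.sum() == 0:
        raise SegmentationError("ROI empty after lumen removal")
    return roi


def noncompaction_index(tissue_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """Free-space fraction: ROI pixels not covered by tissue / ROI pixels."""
    tissue = np.asarray(tissue_mask, dtype=bool)
    roi = np.asarray(roi_mask, dtype=bool)
    if tissue.shape != roi.shape:
        raise ValueError("masks must be aligned")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI: index undefined")
    return float((roi & ~tissue).sum() / n_roi)


def analyze_section(
    section: SectionImage,
    jitter_levels: tuple[float, ...] = (-2.0, 0.0, 2.0),
    despeckle_radius: int = 2,
) -> CompactionResult:
    """Triplicate non-compaction measurement of one section.

    Three segmentations with the threshold jittered by ``jitter_levels``
    intensity steps; the mean is reported and the spread retained.
    """
    vals = []
    for off in jitter_levels:
        tissue = segment_tissue(section.image, despeckle_radius=despeckle_radius,
                                threshold_offset=off)
        roi = ventricular_roi(tissue, provided=section.roi_mask)
        vals.append(noncompaction_index(tissue, roi))
    return CompactionResult(section.subject_id, section.genotype,
                            section.age_months, section.batch_id,
                            raw_index=float(np.mean(vals)), triplicate=vals)


def normalize_to_wt(results: list[CompactionResult]) -> pd.DataFrame:
    """Normalise raw indices to the wild-type mean within each batch.

    Every batch must contain at least one WT section; a batch without
    one cannot be normalised and raises. The WT batch mean maps to
    exactly 1 by construction.
    """
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in results],
            "genotype": [r.genotype for r in results],
            "age_months": [r.age_months for r in results],
            "batch": [r.batch_id for r in results],
            "raw_index": [r.raw_index for r in results],
            "triplicate_sd": [r.triplicate_sd for r in results],
        }
    )
    out = []
    for batch, grp in df.groupby("batch"):
        wt = grp.loc[grp["genotype"] == "WT", "raw_index"]
        if wt.empty:
            raise ValueError(f"batch {batch!r} has no WT section; normalization refused")
        ref = wt.mean()
        g = grp.copy()
        g["normalized_index"] = g["raw_index"] / ref
        out.append(g)
    res = pd.concat(out).sort_index()
    for r, norm in zip(results, res["normalized_index"]):
        r.normalized_index = float(norm)
    return res
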