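"""Biopsy tissue detection and physical-area measurement.

Every burden metric in the pipeline is normalised to the tissue area
actually present on the slide, so the tissue mask is the denominator of
the whole analysis.  Tissue is separated from the near-white slide
background by thresholding the HSV saturation channel after estimating
the background white point from a high luminance percentile, followed by
morphological closing and small-object removal.  Masking runs at a
moderate downsample (default 4x) — tissue-scale structure does not need
full 20x resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color, measure, morphology, transform

from .slide_io import SlideImage

logger = logging.getLogger(__name__)

#: Biopsy adequacy rule used by the source cohort: cores shorter than
#: 12 mm (or with <10 portal tracts, which needs pathologist metadata)
#: are inadequate.
MIN_SPECIMEN_LENGTH_MM = 12.0
MIN_PORTAL_TRACTS = 10


@dataclass(frozen=True)
class TissueParams:
    """Tissue masking parameters (all physical units)."""

    saturation_threshold: float = 0.08
    background_luminance_percentile: float = 95.0
    min_object_area_mm2: float = 0.005
    closing_radius_um: float = 20.0
    edge_margin_um: float = 0.0
    working_downsample: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.saturation_threshold <= 1:
            raise ValueError("saturation_threshold must be in [0, 1]")
        if not 0 < self.background_luminance_percentile <= 100:
            raise ValueError("background percentile must be in (0, 100]")
        for name in ("min_object_area_mm2", "closing_radius_um",
                     "edge_margin_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.working_downsample < 1:
            raise ValueError("working_downsample must be >= 1")


@dataclass
class TissueMask:
    """Binary tissue map at a working downsample with physical area."""

    mask: np.ndarray  # bool, (H, W) at working downsample
    downsample: float  # relative to slide level 0
    mpp: float  # level-0 microns per pixel
    qc_warnings: list[str] = field(default_factory=list)

    @property
    def tissue_px(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def mpp_at_mask(self) -> float:
        return self.mpp * self.downsample

    @property
    def tissue_area_mm2(self) -> float:
        # px * (um/px)^2 -> um^2; 1 mm^2 = 1e6 um^2
        return self.tissue_px * self.mpp_at_mask**2 / 1e6

    def resample_to(self, shape: tuple[int, int], offset_l0: tuple[int, int] = (0, 0),
                    downsample: float = 1.0) -> np.ndarray:
        """Nearest-neighbour view of the mask for a tile.

        ``shape`` is the tile's (H, W) at resolution ``downsample``
        relative to level 0; ``offset_l0`` is the tile origin (x, y) in
        level-0 pixels.
        """
        h, w = shape
        ys = ((offset_l0[1] + np.arange(h) * downsample) / self.downsample)
        xs = ((offset_l0[0] + np.arange(w) * downsample) / self.downsample)
        yi = np.clip(ys.astype(int), 0, self.mask.shape[0] - 1)
        xi = np.clip(xs.astype(int), 0, self.mask.shape[1] - 1)
        return self.mask[np.ix_(yi, xi)]

    def specimen_length_mm(self) -> float:
        """Major-axis length of the largest connected component, in mm."""
        labels = measure.label(self.mask, connectivity=2)
        if labels.max() == 0:
            return 0.0
        props = measure.regionprops(labels)
        largest = max(props, key=lambda p: p.area)
        return largest.axis_major_length * self.mpp_at_mask / 1000.0


def detect_tissue(
    slide: SlideImage, params: TissueParams | None = None
) -> TissueMask:
    """Segment stained tissue from the near-white slide background.

    Deterministic for fixed input and parameters.  An all-background
    slide returns a valid zero-area mask carrying a QC warning rather
    than raising.
    """
    params = params or TissueParams()
    ds = params.working_downsample
    # pick the deepest pyramid level not past the working downsample,
    # then rescale the remainder
    level = 0
    for k, lds in enumerate(slide.level_downsamples):
        if lds <= ds:
            level = k
    base = slide.levels[level]
    level_ds = slide.level_downsamples[level]
    remaining = ds / level_ds
    if remaining > 1:
        out_shape = (
            max(1, int(round(base.shape[0] / remaining))),
            max(1, int(round(base.shape[1] / remaining))),
        )
        img = transform.resize(
            base, out_shape, order=1, anti_aliasing=True, preserve_range=True
        )
    else:
        img = base.astype(float)
    img = img / 255.0

    hsv = color.rgb2hsv(img)
    saturation = hsv[..., 1]
    luminance = hsv[..., 2]
    white = np.percentile(luminance, params.background_luminance_percentile)

    # tissue = chromatic pixels, or clearly darker than the background
    mask = (saturation > params.saturation_threshold) | (
        luminance < 0.75 * max(white, 1e-6)
    )

    mpp_eff = slide.mpp * ds
    close_r = int(round(params.closing_radius_um / mpp_eff))
    if close_r > 0:
        mask = morphology.closing(mask, morphology.disk(close_r))
        mask = ndi.binary_fill_holes(mask)
    min_px = int(round(params.min_object_area_mm2 * 1e6 / mpp_eff**2))
    if min_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)

    tm = TissueMask(mask=mask, downsample=float(ds), mpp=slide.mpp)
    if tm.tissue_px == 0:
        tm.qc_warnings.append("no tissue detected (empty slide?)")
        logger.warning("%s: no tissue detected", slide.name)
    if params.edge_margin_um > 0:
        tm = erode_margin(tm, params.edge_margin_um)
    return tm


def erode_margin(mask: TissueMask, margin_um: float) -> TissueMask:
    """Shrink the tissue mask by a physical margin from its boundary.

    Every retained pixel lies at least ``margin_um`` from the original
    boundary (Euclidean distance transform); margin 0 returns the input
    unchanged.  A margin larger than the object empties the mask and
    sets a QC warning.
    """
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    if margin_um == 0:
        return mask
    margin_px = margin_um / mask.mpp_at_mask
    padded = np.pad(mask.mask, 1, constant_values=False)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    eroded = dist > margin_px
    out = TissueMask(
        mask=eroded,
        downsample=mask.downsample,
        mpp=mask.mpp,
        qc_warnings=list(mask.qc_warnings),
    )
    if mask.tissue_px > 0 and out.tissue_px == 0:
        out.qc_warnings.append(
            f"edge margin {margin_um} um removed all tissue"
        )
        logger.warning("edge margin %.1f um removed all tissue", margin_um)
    return out


def adequacy_flags(
    mask: TissueMask, n_portal_tracts: int | None = None
) -> list[str]:
    """QC flags for the cohort's specimen-adequacy rule.

    Specimen length is the mask's largest-component major axis; the
    portal-tract count cannot be measured automatically and is consumed
    as optional pathologist metadata.  Inadequate specimens are flagged,
    never dropped.
    """
    flags = []
    length = mask.specimen_length_mm()
    if length < MIN_SPECIMEN_LENGTH_MM:
        flags.append(
            f"specimen length {length:.1f} mm < {MIN_SPECIMEN_LENGTH_MM:.0f} mm"
        )
    if n_portal_tracts is not None and n_portal_tracts < MIN_PORTAL_TRACTS:
        flags.append(
            f"{n_portal_tracts} portal tracts < {MIN_PORTAL_TRACTS}"
        )
    return flags
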