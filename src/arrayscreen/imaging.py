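"""Image-based phenotype quantification.

Reimplements the high-content readouts of the screen: nuclear segmentation
from the DNA-stain channel (median filtering, automated thresholding, and a
watershed to split touching nuclei), per-nucleus mean intensity and area
measurements, per-cell quantification of punctate perinuclear (Golgi)
signal via top-hat filtering, rule-based object QC, and scrambled-versus-
target group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import filters, measure, morphology, segmentation

from arrayscreen.errors import InsufficientDataError, NoForegroundError

OBJECT_COLUMNS = [
    "label", "area_px", "centroid_r", "centroid_c",
    "mean_nuclear", "total_nuclear", "mean_signal", "total_signal",
    "solidity", "touches_border",
]


@dataclass
class ImageField:
    """One two-channel microscopy field (nuclear stain + signal)."""

    nuclear_channel: np.ndarray
    signal_channel: np.ndarray
    pixel_size: float | None = None  # microns per pixel
    field_id: str = ""

    def __post_init__(self) -> None:
        self.nuclear_channel = np.asarray(self.nuclear_channel, dtype=float)
        self.signal_channel = np.asarray(self.signal_channel, dtype=float)
        if self.nuclear_channel.shape != self.signal_channel.shape:
            raise ValueError("channel shapes differ")
        if self.nuclear_channel.ndim != 2:
            raise ValueError("channels must be 2-D")


@dataclass
class SegmentationResult:
    """Label map plus the per-object measurement table.

    Labels are contiguous 1..K; 0 is background. The table follows
    :data:`OBJECT_COLUMNS`.
    """

    label_map: np.ndarray
    objects: pd.DataFrame
    pixel_size: float | None = None
    field_id: str = ""
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["label", "reason"])
    )

    @property
    def n_objects(self) -> int:
        return int(self.objects.shape[0])


def _measure_objects(
    label_map: np.ndarray,
    nuclear: np.ndarray,
    signal: np.ndarray,
) -> pd.DataFrame:
    props = measure.regionprops(label_map, intensity_image=None)
    rows = []
    h, w = label_map.shape
    for p in props:
        mask_idx = tuple(p.coords.T)
        nuc = nuclear[mask_idx]
        sig = signal[mask_idx]
        minr, minc, maxr, maxc = p.bbox
        rows.append(
            {
                "label": p.label,
                "area_px": int(p.area),
                "centroid_r": p.centroid[0],
                "centroid_c": p.centroid[1],
                "mean_nuclear": float(nuc.mean()),
                "total_nuclear": float(nuc.sum()),
                "mean_signal": float(sig.mean()),
                "total_signal": float(sig.sum()),
                "solidity": float(p.solidity),
                "touches_border": bool(
                    minr == 0 or minc == 0 or maxr == h or maxc == w
                ),
            }
        )
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def _relabel(label_map: np.ndarray) -> np.ndarray:
    """Renumber labels to contiguous 1..K preserving order."""
    out, _, _ = segmentation.relabel_sequential(label_map)
    return out


def segment_nuclei(
    fld: ImageField,
    smooth_radius: int = 2,
    min_area_px: int = 40,
    max_area_px: int | None = None,
    min_seed_distance: int = 5,
    dist_smooth_sigma: float = 0.5,
    exclude_border: bool = True,
) -> SegmentationResult:
    """Segment nuclei from the nuclear channel.

    Pipeline: median filter (disk of ``smooth_radius``) for noise
    suppression, Otsu global threshold, hole filling, then a watershed on
    the negated distance transform seeded at local distance maxima (minimum
    seed separation ``min_seed_distance``) to split touching nuclei.
    Objects outside ``[min_area_px, max_area_px]`` or touching the image
    border (when ``exclude_border``) are discarded.
    """
    nuc = fld.nuclear_channel
    if float(nuc.max()) == float(nuc.min()):
        raise NoForegroundError(
            f"field {fld.field_id!r}: constant nuclear channel"
        )
    smoothed = filters.median(nuc, morphology.disk(smooth_radius))
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    if not mask.any():
        raise NoForegroundError(
            f"field {fld.field_id!r}: empty foreground after thresholding"
        )
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    smooth_dist = ndi.gaussian_filter(distance, sigma=dist_smooth_sigma)
    # peak_local_max scans row-major, so coordinate ties already resolve to
    # the lower (row, col) pixel — deterministic seeding.
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        smooth_dist,
        min_distance=min_seed_distance,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        raise NoForegroundError(
            f"field {fld.field_id!r}: no watershed seeds found"
        )
    labels = segmentation.watershed(-smooth_dist, markers, mask=mask)

    # size / border filters
    for p in measure.regionprops(labels):
        too_small = p.area < min_area_px
        too_big = max_area_px is not None and p.area > max_area_px
        minr, minc, maxr, maxc = p.bbox
        on_border = exclude_border and (
            minr == 0 or minc == 0
            or maxr == labels.shape[0] or maxc == labels.shape[1]
        )
        if too_small or too_big or on_border:
            labels[labels == p.label] = 0
    labels = _relabel(labels)
    objects = _measure_objects(labels, fld.nuclear_channel, fld.signal_channel)
    return SegmentationResult(
        label_map=labels,
        objects=objects,
        pixel_size=fld.pixel_size,
        field_id=fld.field_id,
    )


def measure_nuclear_intensity(
    seg: SegmentationResult, channel: str = "signal"
) -> pd.Series:
    """Per-object mean intensity in the chosen channel ('nuclear' or
    'signal'), indexed by label."""
    col = {"nuclear": "mean_nuclear", "signal": "mean_signal"}[channel]
    return seg.objects.set_index("label")[col]


def measure_nuclear_area(seg: SegmentationResult) -> pd.DataFrame:
    """Per-object area in pixels, and in square microns when the pixel
    size is known."""
    out = seg.objects[["label", "area_px"]].copy()
    if seg.pixel_size is not None:
        out["area_um2"] = out["area_px"] * seg.pixel_size**2
    return out


def segment_golgi(
    fld: ImageField,
    nuclei: SegmentationResult,
    cell_dilation_px: int = 25,
    tophat_radius_px: int = 6,
    fragment_dilation_px: int = 3,
) -> pd.DataFrame:
    """Per-cell total intensity of punctate (Golgi-like) signal.

    Cell regions are a nearest-nucleus assignment clipped at
    ``cell_dilation_px`` from each nucleus. The signal channel is white
    top-hat filtered (disk of ``tophat_radius_px``) to remove local
    background, Otsu-thresholded into fragments, and each cell's fragment
    intensity is summed and corrected by fragment-pixel-count times the
    median intensity of pixels outside all cell regions.

    Returns a DataFrame (label, total_golgi, n_fragment_px, background).
    """
    if nuclei.n_objects == 0:
        raise NoForegroundError(
            f"field {fld.field_id!r}: no nuclei to anchor cell regions"
        )
    labels = nuclei.label_map
    distance, (ir, ic) = ndi.distance_transform_edt(
        labels == 0, return_indices=True
    )
    cells = labels[ir, ic]
    cells[distance > cell_dilation_px] = 0

    tophat = morphology.white_tophat(
        fld.signal_channel, morphology.disk(tophat_radius_px)
    )
    if float(tophat.max()) > 0:
        th = filters.threshold_otsu(tophat)
        fragments = tophat > th
        if fragment_dilation_px > 0:
            # grow the fragment cores to capture the dim tails of puncta;
            # the per-pixel background correction cancels what the growth
            # adds in background signal
            fragments = morphology.dilation(
                fragments, morphology.disk(fragment_dilation_px)
            )
    else:
        fragments = np.zeros_like(tophat, dtype=bool)

    outside = cells == 0
    background = float(np.median(fld.signal_channel[outside])) if outside.any() else 0.0

    rows = []
    for lab in nuclei.objects["label"]:
        cell_frag = fragments & (cells == lab)
        n_px = int(cell_frag.sum())
        total = float(fld.signal_channel[cell_frag].sum()) - n_px * background
        rows.append(
            {
                "label": int(lab),
                "total_golgi": total,
                "n_fragment_px": n_px,
                "background": background,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    target,
    scrambled,
    test: str = "mann_whitney",
) -> dict:
    """Two-sided comparison of target vs scrambled per-object measurements.

    ``test`` is "mann_whitney" or "ks". The normalized effect is the
    target median divided by the scrambled median.
    """
    target = np.asarray(target, dtype=float)
    scrambled = np.asarray(scrambled, dtype=float)
    if target.size < 3 or scrambled.size < 3:
        raise InsufficientDataError("each group needs >= 3 values")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(target, scrambled, alternative="two-sided")
    elif test == "ks":
        res = stats.ks_2samp(target, scrambled, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    med_t = float(np.median(target))
    med_s = float(np.median(scrambled))
    return {
        "test": test,
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "median_target": med_t,
        "median_scrambled": med_s,
        "normalized_effect": med_t / med_s if med_s != 0 else float("nan"),
        "n_target": int(target.size),
        "n_scrambled": int(scrambled.size),
    }


def object_qc_filter(
    seg: SegmentationResult,
    max_intensity_percentile: float | None = None,
    solidity_min: float | None = None,
    border_exclusion: bool = False,
) -> SegmentationResult:
    """Deterministic rule-based object exclusion.

    Automated surrogate for interactive QC of high-content images: very
    bright objects (mitotic/condensed chromatin), low-solidity objects
    (debris, out-of-focus blobs) and border objects can be excluded.
    ``max_intensity_percentile`` excludes objects whose mean nuclear
    intensity exceeds that percentile of the per-object means. Excluded
    labels are zeroed in the label map and listed with reasons.
    """
    obj = seg.objects
    reasons: dict[int, list[str]] = {}
    if max_intensity_percentile is not None and len(obj) > 0:
        cutoff = np.percentile(
            obj["mean_nuclear"], max_intensity_percentile
        )
        for lab in obj.loc[obj["mean_nuclear"] > cutoff, "label"]:
            reasons.setdefault(int(lab), []).append("bright")
    if solidity_min is not None:
        for lab in obj.loc[obj["solidity"] < solidity_min, "label"]:
            reasons.setdefault(int(lab), []).append("low_solidity")
    if border_exclusion:
        for lab in obj.loc[obj["touches_border"], "label"]:
            reasons.setdefault(int(lab), []).append("border")

    if not reasons:
        return SegmentationResult(
            label_map=seg.label_map.copy(),
            objects=obj.copy(),
            pixel_size=seg.pixel_size,
            field_id=seg.field_id,
        )
    excluded_labels = set(reasons)
    labels = seg.label_map.copy()
    labels[np.isin(labels, list(excluded_labels))] = 0
    labels = _relabel(labels)
    kept = obj.loc[~obj["label"].isin(excluded_labels)].copy()
    kept["label"] = np.arange(1, len(kept) + 1)
    excluded = pd.DataFrame(
        [
            {"label": lab, "reason": ";".join(rs)}
            for lab, rs in sorted(reasons.items())
        ]
    )
    return SegmentationResult(
        label_map=labels,
        objects=kept.reset_index(drop=True),
        pixel_size=seg.pixel_size,
        field_id=seg.field_id,
        excluded=excluded,
    )
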