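"""Phototoxicity quantification from two-channel Ca2+ / cell-death movies.

High-pulse-energy infrared scanning can stress or kill cells; the readouts
are a cytosolic Ca2+ indicator (GCaMP, green channel) that rises on stress
and a membrane-impermeant DNA stain (Sytox) whose nuclear signal reports
membrane damage with a delay. Two complementary analyses are provided:

* **Per-cell trace analysis** — intensity-time traces are extracted at
  manually tracked coordinates; a cell is a responder when its trace crosses
  ``mean_baseline + 3 * SD_baseline`` computed from the unsmoothed
  pre-exposure baseline (one-tailed 3-sigma exceedance, p ~ 0.00135 per
  sample under a Gaussian null). The Sytox trace is the nucleus/cytosol
  ratio after background subtraction, which cancels GCaMP crosstalk.
* **Image-area analysis** — a threshold ``t = mean + 3*SD`` over the 95%
  dimmest pre-exposure ROI pixels classifies responding area per frame;
  pixels already positive before exposure are removed via a dilated
  pre-exposure mask, and the responding fraction is the remaining positive
  area over the correspondingly corrected ROI area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import mannwhitneyu

from ._exceptions import DegenerateInputError, InputError
from .core_io import ImageStack, Roi, mean_filter_disk, median_filter_disk

__all__ = [
    "IntensityTrace",
    "ResponderCall",
    "AreaResponse",
    "GroupComparison",
    "extract_traces",
    "sytox_trace",
    "smooth_normalize",
    "classify_responder",
    "area_response_fraction",
    "gcamp_fraction_summary",
    "compare_exposure_groups",
]


@dataclass
class IntensityTrace:
    """Per-cell, per-compartment intensity time series.

    ``baseline_window`` is a half-open frame range ``(start, stop)`` that
    must precede the exposure onset; masked samples are NaN.
    """

    times_s: np.ndarray
    values: np.ndarray
    compartment: str = "cytosol"
    cell_id: str | int = ""
    baseline_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise InputError("times and values must have equal length")
        if self.compartment not in ("nucleus", "cytosol", "ratio"):
            raise InputError(f"unknown compartment {self.compartment!r}")
        if self.baseline_window is not None:
            b0, b1 = self.baseline_window
            if not 0 <= b0 < b1 <= len(self.values):
                raise InputError("baseline_window must be a non-empty frame range")

    def baseline_values(self) -> np.ndarray:
        if self.baseline_window is None:
            raise InputError("trace has no baseline window")
        b0, b1 = self.baseline_window
        vals = self.values[b0:b1]
        return vals[np.isfinite(vals)]

    def with_values(self, values: np.ndarray) -> "IntensityTrace":
        return IntensityTrace(
            times_s=self.times_s,
            values=np.asarray(values, float),
            compartment=self.compartment,
            cell_id=self.cell_id,
            baseline_window=self.baseline_window,
        )


@dataclass
class ResponderCall:
    cell_id: str | int
    responder: bool
    threshold: float
    first_crossing_frame: int | None


@dataclass
class AreaResponse:
    """Per-frame responding-area fraction within a drift-corrected ROI."""

    per_frame_fraction: np.ndarray
    roi: Roi
    pre_mask: np.ndarray  # dilated pre-exposure positive mask
    threshold_t: float

    def __post_init__(self) -> None:
        f = np.asarray(self.per_frame_fraction, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise InputError("fractions must lie in [0, 1]")
        self.per_frame_fraction = f


@dataclass
class GroupComparison:
    p_value: float
    statistic: float
    summary_a: dict
    summary_b: dict


# ---------------------------------------------------------------------------


def extract_traces(
    movie: ImageStack,
    channel: int | str,
    tracks: pd.DataFrame,
    neighborhood_radius_px: int = 2,
    baseline_window: tuple[int, int] | None = None,
) -> dict[tuple, IntensityTrace]:
    """Intensity-time traces at tracked cell coordinates.

    ``tracks`` columns: frame, cell_id, compartment, y_px, x_px. Each trace
    value is the mean over a disk of radius ``neighborhood_radius_px``
    centred on the tracked coordinate (display-scaling factors applied by
    acquisition software are irrelevant here: every downstream statistic is
    scale-invariant). Coordinates outside the frame give a masked (NaN)
    sample and a warning.
    """
    required = {"frame", "cell_id", "compartment", "y_px", "x_px"}
    if not required <= set(tracks.columns):
        raise InputError(f"tracks table needs columns {sorted(required)}")
    ci = movie.channel_index(channel)
    h, w = movie.frame_shape
    n_frames = movie.n_planes
    filtered = {
        k: mean_filter_disk(movie.pixels[ci, k], neighborhood_radius_px)
        for k in sorted(tracks["frame"].unique())
    }

    traces: dict[tuple, IntensityTrace] = {}
    times = movie.plane_coords()
    for (cell_id, comp), grp in tracks.groupby(["cell_id", "compartment"], sort=False):
        values = np.full(n_frames, np.nan)
        for _, row in grp.iterrows():
            k, y, x = int(row["frame"]), int(round(row["y_px"])), int(round(row["x_px"]))
            if not (0 <= k < n_frames):
                raise InputError(f"track frame {k} outside movie")
            if not (0 <= y < h and 0 <= x < w):
                warnings.warn(
                    f"cell {cell_id} frame {k}: coordinate ({y},{x}) outside frame; masked",
                    stacklevel=2,
                )
                continue
            values[k] = filtered[k][y, x]
        traces[(cell_id, comp)] = IntensityTrace(
            times_s=times,
            values=values,
            compartment=comp,
            cell_id=cell_id,
            baseline_window=baseline_window,
        )
    return traces


def sytox_trace(
    nucleus: IntensityTrace,
    cytosol: IntensityTrace,
    background: np.ndarray | float = 0.0,
) -> IntensityTrace:
    """Crosstalk-corrected Sytox trace: (nucleus - bg) / (cytosol - bg).

    The green channel contains both GCaMP (cytosolic) and Sytox (nuclear)
    emission; dividing by the cytosol trace removes the shared GCaMP
    component. Frames with non-positive denominator are masked with a
    warning.
    """
    if nucleus.values.shape != cytosol.values.shape:
        raise InputError("nucleus and cytosol traces must be frame-aligned")
    bg = np.broadcast_to(np.asarray(background, dtype=float), nucleus.values.shape)
    denom = cytosol.values - bg
    bad = denom <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} frames with non-positive cytosol signal masked", stacklevel=2)
    ratio = np.where(bad, np.nan, (nucleus.values - bg) / np.where(bad, 1.0, denom))
    return IntensityTrace(
        times_s=nucleus.times_s,
        values=ratio,
        compartment="ratio",
        cell_id=nucleus.cell_id,
        baseline_window=nucleus.baseline_window,
    )


def smooth_normalize(
    trace: IntensityTrace,
    window_pts: int = 10,
    poly_order: int = 2,
    norm_ref: IntensityTrace | None = None,
    background: np.ndarray | float = 0.0,
) -> IntensityTrace:
    """Background-subtract, Savitzky-Golay smooth, normalise to reference max.

    The smoother (window 10 points, polynomial order 2 by default)
    reproduces polynomials up to the fit order exactly. The trace is divided
    by the maximum of the identically processed reference trace (typically
    the cell's cytosol trace), or by its own maximum when no reference is
    given.
    """
    if window_pts >= len(trace.values):
        raise InputError("smoothing window must be shorter than the trace")
    if poly_order >= window_pts:
        raise InputError("poly_order must be < window_pts")

    def _process(t: IntensityTrace) -> np.ndarray:
        vals = t.values - np.broadcast_to(np.asarray(background, float), t.values.shape)
        return savgol_filter(vals, window_pts, poly_order)

    smoothed = _process(trace)
    ref = _process(norm_ref) if norm_ref is not None else smoothed
    peak = np.nanmax(ref)
    if peak <= 0:
        raise DegenerateInputError("normalisation reference has non-positive maximum")
    return trace.with_values(smoothed / peak)


def classify_responder(
    trace: IntensityTrace,
    response: IntensityTrace | None = None,
) -> ResponderCall:
    """Call a cell responsive when its trace crosses baseline mean + 3 SD.

    The threshold always comes from the *unsmoothed* pre-exposure baseline
    of ``trace``. The crossing is checked on ``response`` when given
    (typically the Savitzky-Golay smoothed trace, which suppresses
    single-frame noise excursions), otherwise on ``trace`` itself. Under a
    Gaussian null the per-sample exceedance probability of the 3-sigma
    threshold is the one-tailed level (~0.00135), so a crossing rejects the
    quiescence null at about p = 0.0015 per sample.
    """
    base = trace.baseline_values()
    if len(base) < 5:
        raise InputError("baseline window must contain at least 5 usable frames")
    sd = float(base.std())
    if sd == 0:
        raise DegenerateInputError("zero baseline SD; threshold undefined")
    threshold = float(base.mean()) + 3.0 * sd
    b1 = trace.baseline_window[1]
    check = trace if response is None else response
    if check.values.shape != trace.values.shape:
        raise InputError("response trace must be frame-aligned with trace")
    post = check.values[b1:]
    exceed = np.flatnonzero(np.isfinite(post) & (post > threshold))
    if len(exceed):
        return ResponderCall(trace.cell_id, True, threshold, int(b1 + exceed[0]))
    return ResponderCall(trace.cell_id, False, threshold, None)


def _positive_mask(frame: np.ndarray, t: float, roi: Roi, median_radius_px: int) -> np.ndarray:
    return (median_filter_disk(frame, median_radius_px) > t) & roi.mask


def area_response_fraction(
    stack: ImageStack,
    channel: int | str,
    roi: Roi,
    pre_exposure: tuple[int, int],
    dilate_steps: int = 6,
    median_radius_px: int = 1,
) -> AreaResponse:
    """Responding-area fraction per frame (time-lapse) or plane (z-stack).

    1. Threshold ``t = mean + 3*SD`` over the 95% dimmest ROI pixels of the
       last pre-exposure frame (pixels at or below the 95th percentile).
    2. Per frame: median filter (radius 1), mask = pixels > t inside ROI.
    3. Pre-exposure positive mask — last pre-exposure frame for time lapses,
       union over all pre-exposure planes for z-stacks — dilated
       ``dilate_steps`` times (3x3 square) to absorb drift/expansion.
    4. The dilated pre-mask is subtracted from each frame mask; the fraction
       is the remaining positive area over the ROI area corrected for the
       pixels already positive before exposure (the undilated pre-mask, so
       the fraction is non-increasing in the dilation margin).
    """
    from scipy import ndimage

    ci = stack.channel_index(channel)
    if roi.mask.shape != stack.frame_shape:
        raise InputError("roi does not match frame shape")
    p0, p1 = pre_exposure
    if not 0 <= p0 < p1 <= stack.n_planes:
        raise InputError("pre_exposure must be a non-empty frame range")

    ref_frame = stack.pixels[ci, p1 - 1]
    roi_vals = ref_frame[roi.mask].astype(float)
    cut = np.percentile(roi_vals, 95)
    dim = roi_vals[roi_vals <= cut]
    t = float(dim.mean() + 3.0 * dim.std())

    if stack.axis_kind == "t":
        pre_positive = _positive_mask(ref_frame, t, roi, median_radius_px)
    else:
        pre_positive = np.zeros(stack.frame_shape, dtype=bool)
        for k in range(p0, p1):
            pre_positive |= _positive_mask(stack.pixels[ci, k], t, roi, median_radius_px)
    pre_mask = pre_positive
    if dilate_steps > 0 and pre_positive.any():
        pre_mask = ndimage.binary_dilation(
            pre_positive, structure=np.ones((3, 3), bool), iterations=dilate_steps
        )

    denom = int(roi.mask.sum()) - int((pre_positive & roi.mask).sum())
    if denom <= 0:
        raise DegenerateInputError("dilated pre-exposure mask covers the entire ROI")

    fractions = []
    for k in range(stack.n_planes):
        mask_k = _positive_mask(stack.pixels[ci, k], t, roi, median_radius_px)
        new = mask_k & ~pre_mask
        fractions.append(new.sum() / denom)
    return AreaResponse(
        per_frame_fraction=np.asarray(fractions, dtype=float),
        roi=roi,
        pre_mask=pre_mask,
        threshold_t=t,
    )


def gcamp_fraction_summary(
    response: AreaResponse, exposure_window: tuple[int, int]
) -> float:
    """Exposure-induced responding fraction: the maximum per-frame fraction
    reached inside the exposure window."""
    e0, e1 = exposure_window
    n = len(response.per_frame_fraction)
    if not 0 <= e0 < e1 <= n:
        raise InputError("exposure_window must be a non-empty frame range")
    return float(response.per_frame_fraction[e0:e1].max())


def _box_summary(x: np.ndarray) -> dict:
    return {
        "n": int(len(x)),
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
        "p5": float(np.percentile(x, 5)),
        "p95": float(np.percentile(x, 95)),
    }


def compare_exposure_groups(group_a, group_b) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum test between exposure conditions,
    with box-plot summaries (median, quartiles, 5/95 percentiles)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InputError("each group needs n >= 3")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        summary_a=_box_summary(a),
        summary_b=_box_summary(b),
    )
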