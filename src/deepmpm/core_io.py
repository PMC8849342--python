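"""Image-stack containers, TIFF I/O and the shared pixel-statistics primitives.

Every analysis stage in the package consumes the same in-memory container,
:class:`ImageStack`: a non-negative grayscale array with axes normalised to
``(channel, plane, y, x)`` where the plane axis is either depth (z) or time
(t), plus the acquisition metadata needed downstream (pixel size, plane step,
per-plane excitation pulse energy).

Statistical conventions used package-wide:

* standard deviations are population SDs (``ddof=0``);
* "brightest fraction" selection takes ``ceil(fraction * N)`` pixels, ties at
  the cut intensity broken by raster order;
* median/mean filters are parameterised by a disk radius in pixels;
* binary erosion/dilation uses a 3x3 square (8-connected) structuring element.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.morphology import disk

from ._exceptions import ConfigError, DegenerateInputError, InputError

__all__ = [
    "AcquisitionMeta",
    "ImageStack",
    "Roi",
    "RegionStats",
    "read_stack",
    "write_stack",
    "median_filter_disk",
    "mean_filter_disk",
    "select_bright_pixels",
    "background_stats",
    "auto_threshold_mask",
    "huang_threshold",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class AcquisitionMeta:
    """Acquisition metadata attached to a stack.

    ``per_plane_energy_nj`` is the excitation pulse energy at the sample
    surface for each plane; ``objective_energy_nj`` is the energy under the
    objective before immersion-medium absorption.
    """

    wavelength_nm: float | None = None
    rep_rate_hz: float | None = None
    per_plane_energy_nj: np.ndarray | None = None
    immersion_path_mm: float | None = None
    objective_energy_nj: float | None = None

    def __post_init__(self) -> None:
        if self.per_plane_energy_nj is not None:
            e = np.asarray(self.per_plane_energy_nj, dtype=float)
            if e.ndim != 1 or np.any(~np.isfinite(e)) or np.any(e <= 0):
                raise InputError("per_plane_energy_nj must be 1-D, finite and > 0")
            self.per_plane_energy_nj = e


@dataclass
class ImageStack:
    """N-D grayscale stack with axes ``(channel, plane, y, x)``.

    ``axis_kind`` declares what the plane axis means: ``"z"`` (depth stack,
    ``plane_step`` in um, plane 0 nearest the surface) or ``"t"`` (time
    lapse, ``plane_step`` in seconds, plane 0 earliest).
    """

    pixels: np.ndarray
    axis_kind: str
    pixel_size_um: float
    plane_step: float
    channel_names: list[str] = field(default_factory=list)
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 4:
            raise InputError(f"pixels must be 4-D (channel, plane, y, x), got {px.ndim}-D")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise InputError("pixel intensities must be finite and non-negative")
        if self.axis_kind not in ("z", "t"):
            raise InputError(f"axis_kind must be 'z' or 't', got {self.axis_kind!r}")
        if not (self.plane_step > 0 and self.pixel_size_um > 0):
            raise InputError("plane_step and pixel_size_um must be > 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(px.shape[0])]
        if len(self.channel_names) != px.shape[0]:
            raise InputError("channel_names length must equal the channel-axis length")
        if (
            self.meta.per_plane_energy_nj is not None
            and len(self.meta.per_plane_energy_nj) != px.shape[1]
        ):
            raise InputError("per_plane_energy_nj must have one value per plane")
        self.pixels = px

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2:]

    def plane_coords(self) -> np.ndarray:
        """Depth (um) or time (s) coordinate of each plane."""
        return np.arange(self.n_planes) * float(self.plane_step)

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise InputError(f"unknown channel {channel!r}") from None
        if not 0 <= channel < self.n_channels:
            raise InputError(f"channel index {channel} out of range")
        return channel

    def plane(self, channel: int | str, index: int) -> np.ndarray:
        return self.pixels[self.channel_index(channel), index]

    def with_pixels(self, pixels: np.ndarray) -> "ImageStack":
        return replace(self, pixels=pixels)


@dataclass
class Roi:
    """Boolean pixel mask over the (y, x) frame.

    ``degenerate`` marks masks that became empty through processing (e.g.
    over-erosion); such ROIs are not valid selection inputs.
    """

    mask: np.ndarray
    label: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InputError("Roi mask must be 2-D")
        if not self.degenerate and not self.mask.any():
            raise InputError(f"Roi {self.label!r} selects no pixels")

    @classmethod
    def from_rect(cls, y0: int, y1: int, x0: int, x1: int, shape: tuple[int, int], label: str = "") -> "Roi":
        mask = np.zeros(shape, dtype=bool)
        mask[y0:y1, x0:x1] = True
        return cls(mask=mask, label=label)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionStats:
    """Summary statistics of a pixel selection (population SD convention)."""

    i_mean: float = math.nan
    sigma_i: float = math.nan
    b_mean: float = math.nan
    sigma_b: float = math.nan
    area_px: int = 0


# ---------------------------------------------------------------------------
# TIFF / sidecar I/O


_SIDECAR_KEYS = {
    "axis_kind",
    "pixel_size_um",
    "plane_step",
    "channel_names",
    "channel_axis",
    "wavelength_nm",
    "rep_rate_hz",
    "per_plane_energy_nj",
    "immersion_path_mm",
    "objective_energy_nj",
}


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".yaml"


def _load_sidecar(path: str, sidecar: str | dict | None) -> dict:
    if isinstance(sidecar, dict):
        cfg = dict(sidecar)
    else:
        sc_path = sidecar or _sidecar_path(path)
        if os.path.exists(sc_path):
            with open(sc_path) as fh:
                cfg = yaml.safe_load(fh) or {}
        else:
            cfg = {}
    unknown = set(cfg) - _SIDECAR_KEYS
    if unknown:
        raise ConfigError(f"unknown sidecar keys: {sorted(unknown)}")
    return cfg


def read_stack(path: str, axis_kind: str = "z", sidecar: str | dict | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack and normalise axes to (channel, plane, y, x).

    Metadata absent from the TIFF tags is supplied through a YAML sidecar
    (``<stem>.yaml`` next to the file, or passed explicitly as a path/dict).
    A 3-D array is interpreted as (plane, y, x) unless ``channel_axis: 0``
    is declared in the sidecar; 4-D arrays are (channel, plane, y, x) unless
    ``channel_axis: 1`` requests the transposed layout.
    """
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read TIFF {path!r}: {exc}") from exc

    cfg = _load_sidecar(path, sidecar)
    axis_kind = cfg.get("axis_kind", axis_kind)
    channel_axis = cfg.get("channel_axis")

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None] if channel_axis != 0 else arr[:, None]
    elif arr.ndim == 4:
        if channel_axis == 1:
            arr = np.swapaxes(arr, 0, 1)
    else:
        raise ConfigError(f"cannot resolve axes of a {arr.ndim}-D TIFF {path!r}")

    names = cfg.get("channel_names") or []
    if names and len(names) != arr.shape[0]:
        raise ConfigError(
            f"sidecar lists {len(names)} channel names but stack has {arr.shape[0]} channels"
        )
    energies = cfg.get("per_plane_energy_nj")
    meta = AcquisitionMeta(
        wavelength_nm=cfg.get("wavelength_nm"),
        rep_rate_hz=cfg.get("rep_rate_hz"),
        per_plane_energy_nj=None if energies is None else np.asarray(energies, float),
        immersion_path_mm=cfg.get("immersion_path_mm"),
        objective_energy_nj=cfg.get("objective_energy_nj"),
    )
    return ImageStack(
        pixels=arr,
        axis_kind=axis_kind,
        pixel_size_um=float(cfg.get("pixel_size_um", 1.0)),
        plane_step=float(cfg.get("plane_step", 1.0)),
        channel_names=list(names),
        meta=meta,
    )


def write_stack(stack: ImageStack, path: str) -> str:
    """Write a stack as TIFF plus a YAML sidecar; returns the sidecar path."""
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    cfg: dict = {
        "axis_kind": stack.axis_kind,
        "pixel_size_um": stack.pixel_size_um,
        "plane_step": stack.plane_step,
        "channel_names": list(stack.channel_names),
    }
    m = stack.meta
    if m.wavelength_nm is not None:
        cfg["wavelength_nm"] = float(m.wavelength_nm)
    if m.rep_rate_hz is not None:
        cfg["rep_rate_hz"] = float(m.rep_rate_hz)
    if m.per_plane_energy_nj is not None:
        cfg["per_plane_energy_nj"] = [float(v) for v in m.per_plane_energy_nj]
    if m.immersion_path_mm is not None:
        cfg["immersion_path_mm"] = float(m.immersion_path_mm)
    if m.objective_energy_nj is not None:
        cfg["objective_energy_nj"] = float(m.objective_energy_nj)
    sc = _sidecar_path(path)
    with open(sc, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return sc


# ---------------------------------------------------------------------------
# Filters


def median_filter_disk(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Median filter over a disk neighbourhood; radius 0 is the identity."""
    if radius_px < 0:
        raise InputError("median radius must be >= 0")
    if radius_px == 0:
        return np.asarray(image, dtype=float)
    return ndimage.median_filter(np.asarray(image, float), footprint=disk(radius_px))


def mean_filter_disk(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Mean filter over a disk neighbourhood; radius 0 is the identity."""
    if radius_px < 0:
        raise InputError("mean radius must be >= 0")
    img = np.asarray(image, dtype=float)
    if radius_px == 0:
        return img
    fp = disk(radius_px).astype(float)
    return ndimage.convolve(img, fp / fp.sum(), mode="nearest")


# ---------------------------------------------------------------------------
# Pixel statistics


def select_bright_pixels(
    image: np.ndarray,
    top_fraction: float,
    median_radius_px: int = 0,
    roi: Roi | None = None,
) -> RegionStats:
    """Mean/SD over the brightest fraction of (median-filtered) pixels.

    ``ceil(top_fraction * N)`` pixels are taken from the filtered image
    (restricted to ``roi`` when given); ties at the cut intensity are broken
    by raster order, making the selection deterministic.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InputError("empty image")
    if not 0 < top_fraction <= 1:
        raise InputError("top_fraction must lie in (0, 1]")
    filtered = median_filter_disk(img, median_radius_px)
    if roi is not None:
        if roi.mask.shape != img.shape:
            raise InputError("roi shape does not match image")
        values = filtered[roi.mask]
    else:
        values = filtered.ravel()
    count = math.ceil(top_fraction * values.size)
    # stable sort on negated values keeps raster order among ties
    order = np.argsort(-values, kind="stable")[:count]
    sel = values[order]
    return RegionStats(
        i_mean=float(sel.mean()),
        sigma_i=float(sel.std()),
        area_px=int(count),
    )


def background_stats(
    stack: ImageStack,
    channel: int | str,
    roi: Roi,
    per_plane: bool = True,
) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
    """Background mean/SD over an ROI of the *unfiltered* stack.

    With ``per_plane=True`` returns arrays of (B_mean, sigma_B) per plane,
    otherwise scalars pooled over every plane.
    """
    ci = stack.channel_index(channel)
    if roi.mask.shape != stack.frame_shape:
        raise InputError("background roi does not match frame shape")
    data = stack.pixels[ci][:, roi.mask]  # (planes, roi_px)
    if per_plane:
        return data.mean(axis=1), data.std(axis=1)
    return float(data.mean()), float(data.std())


# ---------------------------------------------------------------------------
# Auto-thresholding


def huang_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Huang's fuzzy-entropy threshold.

    Minimises Shannon fuzzy entropy with membership
    ``mu(g) = 1 / (1 + |g - m_class| / C)`` where ``m_class`` is the mean of
    the pixel's class and ``C`` the intensity range. Not provided by
    scikit-image, hence implemented here over a 256-bin histogram.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise DegenerateInputError("constant image cannot be thresholded")
    hist, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    c_range = hi - lo

    w = hist.astype(float)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * centers)
    total_w, total_wx = cw[-1], cwx[-1]

    best_t, best_s = centers[0], np.inf
    for k in range(nbins - 1):
        w0, w1 = cw[k], total_w - cw[k]
        if w0 == 0 or w1 == 0:
            continue
        m0 = cwx[k] / w0
        m1 = (total_wx - cwx[k]) / w1
        mu = np.empty(nbins)
        mu[: k + 1] = 1.0 / (1.0 + np.abs(centers[: k + 1] - m0) / c_range)
        mu[k + 1 :] = 1.0 / (1.0 + np.abs(centers[k + 1 :] - m1) / c_range)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ent = -(mu * np.log(mu) + (1 - mu) * np.log(1 - mu))
        s = float(np.sum(w * ent))
        if s < best_s:
            best_s, best_t = s, centers[k]
    return float(best_t)


_THRESHOLDERS = {
    "otsu": threshold_otsu,
    "isodata": threshold_isodata,
    "huang": huang_threshold,
}


def auto_threshold_mask(image: np.ndarray, method: str = "otsu", erode_steps: int = 0) -> Roi:
    """Threshold an image and erode the resulting mask.

    Pixels strictly above the method's threshold are selected, then eroded
    ``erode_steps`` times with the 3x3 square element. A mask emptied by
    erosion is returned with ``degenerate=True`` rather than raising.
    """
    img = np.asarray(image, dtype=float)
    if img.min() == img.max():
        raise DegenerateInputError("constant image has no threshold")
    try:
        thresh = _THRESHOLDERS[method](img)
    except KeyError:
        raise ConfigError(f"unknown threshold method {method!r}") from None
    mask = img > thresh
    if erode_steps > 0 and mask.any():
        mask = ndimage.binary_erosion(mask, structure=_SQUARE3, iterations=erode_steps)
    if not mask.any():
        return Roi(mask=mask, label=f"{method}-empty", degenerate=True)
    return Roi(mask=mask, label=method)
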