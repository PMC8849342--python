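"""Ground-truthed synthetic data with the statistical structure the
analyses assume.

Three generators cover the package's input kinds:

* :func:`make_depth_stack` — a z-stack through scattering tissue. The focal
  signal of an order-``n`` process driven at surface pulse energy ``P(z)``
  decays as ``P(z)**n * exp(-n * z / l_e)`` (optionally with layered
  ``l_e``); features are Gaussian blobs blurred by the lateral/axial PSF
  widths, on a constant background, with mean-preserving shot noise and
  additive Gaussian read noise.
* :func:`make_power_series` — the excitation-order measurement protocol:
  frames at stepwise-varied pulse energy, each followed by a fixed-energy
  bleach-reference frame, with mono-exponential photobleaching applied per
  scan.
* :func:`make_viability_movie` — a two-channel cell movie (green:
  GCaMP with Sytox crosstalk in the nucleus; red: nuclear mCherry with
  optional bleach fade) over a quiet / spontaneous-transient / steep
  responder / gradual responder population mixture, with delayed nuclear
  Sytox uptake in dying cells.

Every generator takes an explicit seed, echoes its generative parameters in
a :class:`GroundTruth` record sufficient to predict estimator outputs, and
produces bit-identical output for identical seeds. With noise disabled the
expected images are exact, which makes every downstream estimator testable
against closed-form values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .calibration import PowerSchedule
from .core_io import AcquisitionMeta, ImageStack, Roi
from .excitation_order import PowerSeries

__all__ = [
    "SceneConfig",
    "ViabilityConfig",
    "GroundTruth",
    "make_depth_stack",
    "make_power_series",
    "make_viability_movie",
    "default_feature_grid",
]


@dataclass
class GroundTruth:
    """Generative parameters echoed verbatim, plus derived per-plane or
    per-cell quantities needed to predict estimator outputs."""

    params: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.params[key]

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            return v

        return _clean(self.params)


# ---------------------------------------------------------------------------
# Noise model


def _apply_noise(
    expected: np.ndarray,
    rng: np.random.Generator,
    shot: bool = True,
    read_sd: float = 2.0,
) -> np.ndarray:
    """Shot + read noise around an expected image.

    Shot noise is Poisson below 20 expected counts and its Gaussian
    (variance = mean) approximation above, which is indistinguishable at
    those count rates and much faster. Read noise is additive Gaussian.
    Output is clipped at zero (a detector reports no negative counts).
    """
    out = expected.astype(float)
    if shot:
        low = expected < 20
        out = np.where(
            low,
            rng.poisson(np.clip(expected, 0, None)).astype(float),
            expected + np.sqrt(np.clip(expected, 0, None)) * rng.standard_normal(expected.shape),
        )
    if read_sd > 0:
        out = out + read_sd * rng.standard_normal(expected.shape)
    return np.clip(out, 0, None)


# ---------------------------------------------------------------------------
# Depth stacks


def default_feature_grid(
    shape: tuple[int, int] = (96, 96),
    spacing_px: int = 24,
    amplitude: float = 240.0,  # yields surface SNR ~50 with the default noise model
    sigma_um: float = 1.0,
) -> list[dict]:
    """A regular grid of identical blob features.

    The grid starts one spacing in from the frame origin, leaving a dark
    corner margin suitable for a background ROI.
    """
    h, w = shape
    feats = []
    for y in range(spacing_px, h, spacing_px):
        for x in range(spacing_px, w, spacing_px):
            feats.append({"y_px": y, "x_px": x, "amplitude": amplitude, "sigma_um": sigma_um})
    return feats


@dataclass
class SceneConfig:
    """Generative description of a synthetic tissue z-stack.

    ``l_e_um`` may be a single value or one per layer with
    ``layer_boundaries_um`` giving the depths separating consecutive
    layers. The default power schedule ramps the surface pulse energy
    exponentially from 4.6 to 32 nJ across the stack, the typical
    compensation applied when imaging deep. Default PSF widths correspond
    to sub-micron lateral and ~3 um axial resolution.
    """

    order_n: int = 3
    l_e_um: float | list[float] = 220.0
    layer_boundaries_um: list[float] | None = None
    n_planes: int = 40
    z_step_um: float = 10.0
    shape: tuple[int, int] = (96, 96)
    pixel_size_um: float = 0.5
    power_schedule: PowerSchedule | None = None
    feature_layout: list[dict] | None = None
    psf_sigma_um: tuple[float, float] = (0.35, 1.3)
    shot_noise: bool = True
    read_sd: float = 2.0
    background: float = 10.0
    bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order_n not in (2, 3, 4):
            raise InputError("order_n must be one of {2, 3, 4}")
        les = np.atleast_1d(np.asarray(self.l_e_um, dtype=float))
        if np.any(les <= 0):
            raise InputError("l_e_um must be > 0")
        if les.size > 1:
            if self.layer_boundaries_um is None or len(self.layer_boundaries_um) != les.size - 1:
                raise InputError("layered l_e needs len(l_e)-1 layer boundaries")
        if self.read_sd < 0 or not 0 <= self.bleach_rate < 1:
            raise InputError("read_sd must be >= 0 and bleach_rate in [0, 1)")

    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_planes) * self.z_step_um

    def schedule(self) -> PowerSchedule:
        if self.power_schedule is not None:
            return self.power_schedule
        z = self.depths_um()
        z_max = max(z[-1], 1.0)
        e = 4.6 * (32.0 / 4.6) ** (z / z_max)
        return PowerSchedule(z, e)

    def optical_thickness(self, z: np.ndarray) -> np.ndarray:
        """Cumulative attenuation integral tau(z) = int_0^z dz'/l_e(z')."""
        les = np.atleast_1d(np.asarray(self.l_e_um, dtype=float))
        if les.size == 1:
            return z / les[0]
        bounds = [0.0, *self.layer_boundaries_um, np.inf]
        tau = np.zeros_like(z, dtype=float)
        for i, le in enumerate(les):
            lo, hi = bounds[i], bounds[i + 1]
            seg = np.clip(z, lo, hi) - lo
            tau += seg / le
        return tau


def make_depth_stack(cfg: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic z-stack and its ground truth.

    The expected plane at depth ``z`` is ``background + sum_of_blobs *
    depth_factor(z)`` with ``depth_factor = (P(z)/P(0))**n * exp(-n*tau(z))``
    (so the surface plane carries the nominal feature amplitudes). Features
    without a ``z_um`` key span all depths (columns through tissue); a
    feature with ``z_um`` is axially confined with the axial PSF width,
    which is what the axial-resolution scorer measures.
    """
    rng = np.random.default_rng(cfg.seed)
    z = cfg.depths_um()
    sched = cfg.schedule()
    p = np.array([np.interp(zz, sched.depths_um, sched.e_surface_nj) for zz in z])
    tau = cfg.optical_thickness(z)
    depth_factor = (p / p[0]) ** cfg.order_n * np.exp(-cfg.order_n * tau)

    feats = cfg.feature_layout
    if feats is None:
        feats = default_feature_grid(cfg.shape)
    h, w = cfg.shape
    yy, xx = np.mgrid[0:h, 0:w]

    # lateral blob field shared by all depths (per-feature axial weights vary)
    blobs = []
    for f in feats:
        sigma_px = np.hypot(f.get("sigma_um", 1.0), cfg.psf_sigma_um[0]) / cfg.pixel_size_um
        field2d = f["amplitude"] * np.exp(
            -((yy - f["y_px"]) ** 2 + (xx - f["x_px"]) ** 2) / (2 * sigma_px**2)
        )
        blobs.append((field2d, f.get("z_um")))

    planes = np.empty((cfg.n_planes, h, w))
    expected = np.empty_like(planes)
    sigma_ax = cfg.psf_sigma_um[1]
    for k, zk in enumerate(z):
        img = np.full((h, w), cfg.background, dtype=float)
        for field2d, z0 in blobs:
            ax_w = 1.0 if z0 is None else np.exp(-((zk - z0) ** 2) / (2 * sigma_ax**2))
            img = img + field2d * (depth_factor[k] * ax_w)
        expected[k] = img
        planes[k] = _apply_noise(img, rng, cfg.shot_noise, cfg.read_sd)

    stack = ImageStack(
        pixels=planes[None],
        axis_kind="z",
        pixel_size_um=cfg.pixel_size_um,
        plane_step=cfg.z_step_um,
        channel_names=["synthetic"],
        meta=AcquisitionMeta(per_plane_energy_nj=p),
    )
    gt = GroundTruth(
        params={
            "order_n": cfg.order_n,
            "l_e_um": cfg.l_e_um,
            "layer_boundaries_um": cfg.layer_boundaries_um,
            "depths_um": z,
            "energy_nj": p,
            "depth_factor": depth_factor,
            "background": cfg.background,
            "features": feats,
            "psf_sigma_um": list(cfg.psf_sigma_um),
            "expected_planes": expected,
            "seed": cfg.seed,
        }
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Power series


def make_power_series(
    a: float,
    n: int,
    energies_nj: np.ndarray,
    bleach_rate: float = 0.0,
    bleach_energy_nj: float = 1.0,
    shot_noise: bool = False,
    read_sd: float = 0.0,
    rel_noise: float = 0.0,
    background: float = 5.0,
    shape: tuple[int, int] = (48, 48),
    seed: int = 0,
) -> tuple[PowerSeries, GroundTruth]:
    """Simulate the excitation-order protocol on a uniform bright disk.

    Scans alternate measurement frame / reference frame; each scan removes
    a ``bleach_rate`` fraction of the remaining fluorophore, so frame ``k``
    (0-based) sees residual ``(1-r)**(2k)`` and its reference
    ``(1-r)**(2k+1)``. The in-disk expected intensity of frame ``k`` is
    ``background + a * residual * P_k**n``. ``rel_noise`` adds a
    multiplicative Gaussian perturbation of that relative SD to the signal
    term (a simple stand-in for laser and detection fluctuations).
    """
    energies = np.asarray(energies_nj, dtype=float)
    if np.any(energies <= 0) or bleach_energy_nj <= 0:
        raise InputError("all energies must be > 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    disk_mask = (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= (min(h, w) / 4) ** 2

    def render(signal: float) -> np.ndarray:
        img = np.full((h, w), background, dtype=float)
        img[disk_mask] += signal
        return _apply_noise(img, rng, shot_noise, read_sd)

    frames, refs, true_signal = [], [], []
    for k, e in enumerate(energies):
        resid_f = (1.0 - bleach_rate) ** (2 * k)
        resid_r = (1.0 - bleach_rate) ** (2 * k + 1)
        sig = a * resid_f * e**n
        if rel_noise > 0:
            sig *= 1.0 + rel_noise * rng.standard_normal()
        ref_sig = a * resid_r * bleach_energy_nj**n
        if rel_noise > 0:
            ref_sig *= 1.0 + rel_noise * rng.standard_normal()
        frames.append(render(sig))
        refs.append(render(ref_sig))
        true_signal.append(sig)

    roi = Roi(mask=disk_mask, label="disk")
    bg_roi = Roi.from_rect(0, h // 6, 0, w // 6, shape, label="background")
    series = PowerSeries(
        frames=frames,
        energies_nj=energies,
        bleach_frames=refs,
        bleach_energy_nj=float(bleach_energy_nj),
        roi=roi,
        background_roi=bg_roi,
    )
    gt = GroundTruth(
        params={
            "a": a,
            "n": n,
            "energies_nj": energies,
            "bleach_rate": bleach_rate,
            "bleach_energy_nj": bleach_energy_nj,
            "background": background,
            "true_signal": np.asarray(true_signal),
            "seed": seed,
        }
    )
    return series, gt


# ---------------------------------------------------------------------------
# Viability movies


@dataclass
class ViabilityConfig:
    """Generative description of a two-channel GCaMP/Sytox cell movie.

    Population weights follow the phenomenology of exposure experiments:
    most cells stay quiet, a minority shows spontaneous reversible
    transients, and exposure above threshold produces steep (dying,
    Sytox-positive with delayed uptake) and gradual responders.
    ``response_amplitude_sd`` is the Ca2+ response amplitude in units of
    the baseline fluctuation SD; 3 SD is the detection threshold, so the
    default of 5 SD models a clear supra-threshold response.
    """

    n_cells: int = 60
    populations: dict[str, float] = field(
        default_factory=lambda: {
            "quiet": 0.55,
            "spontaneous": 0.20,
            "steep": 0.15,
            "gradual": 0.10,
        }
    )
    response_amplitude_sd: float = 5.0
    sytox_delay_mean_frames: float = 20.0
    sytox_delay_sd_frames: float = 5.0
    n_frames: int = 150
    frame_time_s: float = 2.0
    baseline_end: int = 50
    exposure_window: tuple[int, int] = (50, 100)
    baseline_level: float = 100.0
    baseline_sd: float = 4.0
    baseline_corr: float = 0.4
    crosstalk: float = 0.6
    sytox_amplitude: float = 150.0
    mcherry_level: float = 120.0
    mcherry_bleach_rate: float = 0.0
    background: float = 10.0
    shot_noise: bool = True
    read_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InputError("n_cells must be >= 1")
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"population weights must sum to 1 (got {total})")
        unknown = set(self.populations) - {"quiet", "spontaneous", "steep", "gradual"}
        if unknown:
            raise InputError(f"unknown populations: {sorted(unknown)}")
        e0, e1 = self.exposure_window
        if not 0 < self.baseline_end <= e0 < e1 <= self.n_frames:
            raise InputError("need baseline_end <= exposure start < end <= n_frames")
        if not 0 <= self.baseline_corr < 1:
            raise InputError("baseline_corr must lie in [0, 1)")


# Cell geometry chosen so that a 2-px sampling disk at the nucleus centre
# covers exactly the nucleus, and one at the cytosol track point (5 px off
# centre) lies entirely inside the cytosol shell.
_CELL_SPACING_PX = 16
_NUCLEUS_R = 2
_CYTO_R_OUT = 7
_CYTO_TRACK_OFFSET = 5


def _cell_grid(n_cells: int) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    centers = []
    for i in range(n_cells):
        r, c = divmod(i, cols)
        centers.append((_CELL_SPACING_PX // 2 + r * _CELL_SPACING_PX,
                        _CELL_SPACING_PX // 2 + c * _CELL_SPACING_PX))
    shape = (rows * _CELL_SPACING_PX, cols * _CELL_SPACING_PX)
    return centers, shape


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_viability_movie(
    cfg: ViabilityConfig,
) -> tuple[ImageStack, pd.DataFrame, GroundTruth]:
    """Render a two-channel viability movie plus tracks and ground truth.

    Cells are static disks (nucleus) with an annular cytosol. The green
    cytosol series is baseline + Gaussian fluctuation, plus the cell's
    Ca2+ response; the green nucleus series is crosstalk times the cytosol
    series plus a delayed Sytox ramp for dying (steep) cells. The red
    channel holds nuclear mCherry with optional per-frame mono-exponential
    bleaching during exposure. Tracks (frame, cell_id, compartment, y_px,
    x_px) point at the nucleus centre and a fixed cytosol offset.
    """
    rng = np.random.default_rng(cfg.seed)
    n, t = cfg.n_cells, cfg.n_frames
    frames_idx = np.arange(t)
    e0, e1 = cfg.exposure_window

    kinds = list(cfg.populations)
    weights = np.array([cfg.populations[k] for k in kinds])
    labels = rng.choice(kinds, size=n, p=weights)

    amp = cfg.response_amplitude_sd * cfg.baseline_sd
    cyto_series = np.empty((n, t))
    nucgreen_series = np.empty((n, t))
    red_series = np.empty((n, t))
    onset = np.full(n, -1)
    sytox_onset = np.full(n, -1)

    bleach = np.ones(t)
    if cfg.mcherry_bleach_rate > 0:
        scans = np.clip(frames_idx - e0, 0, e1 - e0)
        bleach = (1.0 - cfg.mcherry_bleach_rate) ** scans

    rho = cfg.baseline_corr
    burn = 50
    for i in range(n):
        base = cfg.baseline_level * (1.0 + 0.1 * rng.standard_normal())
        # baseline Ca2+ fluctuation: stationary AR(1) -- calcium dynamics
        # are slow relative to the frame time, so successive samples are
        # strongly correlated rather than white
        eps = rng.standard_normal(t + burn)
        fluct = np.empty(t + burn)
        fluct[0] = eps[0]
        for k in range(1, t + burn):
            fluct[k] = rho * fluct[k - 1] + np.sqrt(1.0 - rho**2) * eps[k]
        trace = base + cfg.baseline_sd * fluct[burn:]
        kind = labels[i]
        if kind == "spontaneous":
            for _ in range(rng.integers(1, 4)):
                t0 = rng.integers(0, t - 10)
                width = rng.integers(4, 10)
                bump = 4.0 * cfg.baseline_sd * np.exp(
                    -((frames_idx - t0 - width / 2) ** 2) / (2 * (width / 3) ** 2)
                )
                trace = trace + bump
        elif kind == "steep":
            # rise is near-instantaneous with exposure onset
            onset[i] = e0 + rng.integers(0, 3)
            trace = trace + amp * _sigmoid((frames_idx - onset[i]) / 0.5)
            delay = max(
                1.0,
                rng.normal(cfg.sytox_delay_mean_frames, cfg.sytox_delay_sd_frames),
            )
            sytox_onset[i] = int(round(onset[i] + delay))
        elif kind == "gradual":
            onset[i] = e0 + rng.integers(0, 5)
            ramp = np.clip((frames_idx - onset[i]) / max(e1 - onset[i], 1), 0, 1)
            trace = trace + amp * ramp
        cyto_series[i] = trace

        nuc = cfg.crosstalk * trace
        if sytox_onset[i] >= 0:
            # dye influx starts at the onset frame and saturates exponentially
            dt = frames_idx - sytox_onset[i]
            uptake = np.where(dt >= 0, 1.0 - np.exp(-np.clip(dt, 0, None) / 6.0), 0.0)
            nuc = nuc + cfg.sytox_amplitude * uptake
        nucgreen_series[i] = nuc
        red_series[i] = cfg.mcherry_level * bleach

    centers, shape = _cell_grid(n)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    nuc_masks, cyto_masks = [], []
    for cy, cx in centers:
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuc_masks.append(r2 <= _NUCLEUS_R**2)
        cyto_masks.append((r2 > _NUCLEUS_R**2) & (r2 <= _CYTO_R_OUT**2))

    green = np.empty((t, h, w))
    red = np.empty((t, h, w))
    for k in range(t):
        g = np.full((h, w), cfg.background, dtype=float)
        r = np.full((h, w), cfg.background, dtype=float)
        for i in range(n):
            g[cyto_masks[i]] = cfg.background + cyto_series[i, k]
            g[nuc_masks[i]] = cfg.background + nucgreen_series[i, k]
            r[nuc_masks[i]] = cfg.background + red_series[i, k]
        green[k] = _apply_noise(g, rng, cfg.shot_noise, cfg.read_sd)
        red[k] = _apply_noise(r, rng, cfg.shot_noise, cfg.read_sd)

    movie = ImageStack(
        pixels=np.stack([green, red]),
        axis_kind="t",
        pixel_size_um=1.0,
        plane_step=cfg.frame_time_s,
        channel_names=["green", "red"],
    )

    rows = []
    for k in range(t):
        for i, (cy, cx) in enumerate(centers):
            rows.append((k, i, "nucleus", cy, cx))
            rows.append((k, i, "cytosol", cy, cx + _CYTO_TRACK_OFFSET))
    tracks = pd.DataFrame(rows, columns=["frame", "cell_id", "compartment", "y_px", "x_px"])

    gt = GroundTruth(
        params={
            "labels": labels.tolist(),
            "onset_frame": onset,
            "sytox_onset_frame": sytox_onset,
            "cyto_series": cyto_series,
            "nucleus_green_series": nucgreen_series,
            "red_series": red_series,
            "baseline_window": (0, cfg.baseline_end),
            "exposure_window": cfg.exposure_window,
            "baseline_sd": cfg.baseline_sd,
            "response_amplitude": amp,
            "centers": centers,
            "background": cfg.background,
            "seed": cfg.seed,
        }
    )
    return movie, tracks, gt
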