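"""Determination of the nonlinear excitation-process order.

The order ``n`` of a multiphoton process (2 for 2P/SHG, 3 for 3P/THG, 4 for
4P) is recovered from an image series acquired at stepwise-varied excitation
pulse energy ``P``. Because repeated scanning bleaches the fluorophore, each
measurement frame is paired with a reference frame taken at a fixed low
energy ``P_bleach``; dividing by the reference cancels the bleaching trend.

Per frame the normalised, bleaching-corrected, background-subtracted signal is

    S(P) = F_norm * [I_mean(P) - B_mean(P)] / [I_mean(P_bleach) - B_mean(P_bleach)]

and the order is obtained by fitting ``S(P) = A * P**n`` with orthogonal
distance regression, weighting both the energy uncertainty (a configurable
relative error; the measurement inaccuracy of the attenuator calibration)
and the propagated signal uncertainty. Fits are quality-gated on reduced
chi-square < 2 and adjusted R-square > 0.995.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import odr

from ._exceptions import BleachCorrectionError, FitError, InputError
from .core_io import Roi, auto_threshold_mask, median_filter_disk

__all__ = [
    "PowerSeries",
    "NormalizedSeries",
    "PowerLawFit",
    "normalize_power_series",
    "fit_power_law",
    "qc_fit",
    "DEFAULT_REL_P_ERROR",
]

# Relative uncertainty assumed on the excitation pulse energy. The attenuator
# calibration error is not quantified upstream, so this is an explicit,
# reported configuration value rather than a measured one.
DEFAULT_REL_P_ERROR = 0.03


@dataclass
class PowerSeries:
    """Measurement frames at varied energy, interleaved with fixed-energy
    bleach-reference frames (one reference acquired after each measurement)."""

    frames: list[np.ndarray]
    energies_nj: np.ndarray
    bleach_frames: list[np.ndarray]
    bleach_energy_nj: float
    roi: Roi
    background_roi: Roi
    mask_params: dict | None = None

    def __post_init__(self) -> None:
        self.energies_nj = np.asarray(self.energies_nj, dtype=float)
        if not (len(self.frames) == len(self.energies_nj) == len(self.bleach_frames)):
            raise InputError("frames, energies and bleach_frames must have equal length")
        if np.any(self.energies_nj <= 0) or self.bleach_energy_nj <= 0:
            raise InputError("all excitation energies must be > 0")


@dataclass
class NormalizedSeries:
    """Bleach-corrected signal S per retained energy, with propagated errors."""

    energies_nj: np.ndarray
    s_values: np.ndarray
    s_errors: np.ndarray
    p_errors: np.ndarray
    f_norm: float

    def __post_init__(self) -> None:
        n = len(self.energies_nj)
        for name in ("s_values", "s_errors", "p_errors"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise InputError(f"{name} length mismatch")
            setattr(self, name, arr)
        if np.any(self.s_errors < 0) or np.any(self.p_errors < 0):
            raise InputError("errors must be >= 0")


@dataclass
class PowerLawFit:
    a: float
    a_se: float
    n: float
    n_se: float
    red_chisq: float
    adj_r2: float
    fit_range_nj: tuple[float, float]
    points_used: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise FitError(f"fitted order n = {self.n:.3g} is not positive")

    def to_dict(self) -> dict:
        return {
            "A": self.a,
            "A_se": self.a_se,
            "n": self.n,
            "n_se": self.n_se,
            "red_chisq": self.red_chisq,
            "adj_r2": self.adj_r2,
            "fit_range_nj": list(self.fit_range_nj),
            "points_used": self.points_used,
        }


def _region_signal(frame: np.ndarray, bright: np.ndarray, background: Roi):
    sel = np.asarray(frame, float)[bright]
    bg = np.asarray(frame, float)[background.mask]
    return sel.mean(), sel.std(), sel.size, bg.mean(), bg.std()


def _bright_mask(frame: np.ndarray, series: PowerSeries) -> np.ndarray:
    mask = series.roi.mask
    if series.mask_params:
        mp = series.mask_params
        filtered = median_filter_disk(frame, int(mp.get("median_radius_px", 0)))
        auto = auto_threshold_mask(
            filtered, mp.get("method", "otsu"), int(mp.get("erode_steps", 0))
        )
        mask = mask & auto.mask
    if not mask.any():
        raise InputError("bright-pixel mask selects no pixels")
    return mask


def normalize_power_series(
    series: PowerSeries,
    rel_p_error: float = DEFAULT_REL_P_ERROR,
    f_norm: float | None = None,
) -> NormalizedSeries:
    """Bleach-correct, background-subtract and normalise a power series.

    Each measurement frame is divided by its paired reference frame
    (background-subtracted in both cases). Signal errors are propagated in
    quadrature from the standard errors of the numerator and denominator
    means; energy errors are ``rel_p_error * P``. Unless ``f_norm`` is
    given, the normalisation constant is chosen so that max(S) = 1.
    """
    raw, raw_err = [], []
    for k, (frame, ref) in enumerate(zip(series.frames, series.bleach_frames)):
        bright = _bright_mask(frame, series)
        i_m, s_i, area, b_m, _ = _region_signal(frame, bright, series.background_roi)
        ri_m, rs_i, rarea, rb_m, _ = _region_signal(ref, bright, series.background_roi)
        denom = ri_m - rb_m
        if denom <= 0:
            raise BleachCorrectionError(
                f"reference frame {k} has non-positive background-subtracted signal"
            )
        num = i_m - b_m
        s = num / denom
        rel = 0.0
        if num != 0:
            rel = np.hypot((s_i / np.sqrt(area)) / num, (rs_i / np.sqrt(rarea)) / denom)
        raw.append(s)
        raw_err.append(abs(s) * rel)

    raw = np.asarray(raw)
    raw_err = np.asarray(raw_err)
    if f_norm is None:
        peak = np.max(raw)
        f_norm = 1.0 / peak if peak > 0 else 1.0
    return NormalizedSeries(
        energies_nj=series.energies_nj.copy(),
        s_values=f_norm * raw,
        s_errors=f_norm * raw_err,
        p_errors=rel_p_error * series.energies_nj,
        f_norm=float(f_norm),
    )


def _loglog_init(p: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Log-log least-squares starting point for the ODR iteration."""
    slope, intercept = np.polyfit(np.log(p), np.log(s), 1)
    return float(np.exp(intercept)), float(slope)


def fit_power_law(
    ns: NormalizedSeries,
    fit_range_nj: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit ``S(P) = A * P**n`` by orthogonal distance regression.

    Points outside ``fit_range_nj`` (energies beyond a damage threshold or
    above the fluorophore's saturation limit) are excluded before fitting.
    Both energy and signal uncertainties weight the regression; the starting
    point comes from a log-log ordinary least-squares fit.
    """
    p, s = ns.energies_nj, ns.s_values
    sp, ss = ns.p_errors, ns.s_errors
    if fit_range_nj is None:
        keep = np.ones(len(p), dtype=bool)
        fit_range_nj = (float(p.min()), float(p.max()))
    else:
        lo, hi = fit_range_nj
        keep = (p >= lo) & (p <= hi)
    keep &= (p > 0) & (s > 0)
    if keep.sum() < 4:
        raise FitError(f"only {int(keep.sum())} usable points inside fit range; need >= 4")
    p, s, sp, ss = p[keep], s[keep], sp[keep], ss[keep]

    a0, n0 = _loglog_init(p, s)
    model = odr.Model(lambda beta, x: beta[0] * x ** beta[1])
    # ODR needs strictly positive errors; an axis with no stated uncertainty
    # is left unweighted, and isolated zeros are floored to the smallest
    # positive error on that axis.
    sx = sp if np.any(sp > 0) else None
    sy = ss if np.any(ss > 0) else None
    if sx is not None:
        sx = np.where(sx > 0, sx, sx[sx > 0].min())
    if sy is not None:
        sy = np.where(sy > 0, sy, sy[sy > 0].min())
    weighted = sx is not None or sy is not None
    data = odr.RealData(p, s, sx=sx, sy=sy)
    out = odr.ODR(data, model, beta0=[a0, n0], maxit=200).run()
    if out.info >= 5:
        raise FitError(f"ODR failed: {out.stopreason}")

    a, n = out.beta
    a_se, n_se = out.sd_beta
    pred = a * p**n
    ss_res = float(np.sum((s - pred) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    n_pts, n_par = len(p), 2
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = (
        1.0 - (1.0 - r2) * (n_pts - 1) / (n_pts - n_par - 1)
        if n_pts > n_par + 1
        else r2
    )
    return PowerLawFit(
        a=float(a),
        a_se=float(a_se),
        n=float(n),
        n_se=float(n_se),
        red_chisq=float(out.res_var) if weighted else ss_res / max(n_pts - n_par, 1),
        adj_r2=float(adj_r2),
        fit_range_nj=(float(fit_range_nj[0]), float(fit_range_nj[1])),
        points_used=int(n_pts),
    )


def qc_fit(
    fit: PowerLawFit,
    max_red_chisq: float = 2.0,
    min_adj_r2: float = 0.995,
) -> tuple[bool, list[str]]:
    """Quality gate: reduced chi-square below 2 and adjusted R^2 above 0.995."""
    if not (np.isfinite(fit.red_chisq) and np.isfinite(fit.adj_r2)):
        raise InputError("fit statistics must be finite")
    reasons = []
    if not fit.red_chisq < max_red_chisq:
        reasons.append("red_chisq")
    if not fit.adj_r2 > min_adj_r2:
        reasons.append("adj_r2")
    return (not reasons), reasons
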