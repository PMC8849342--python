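"""Excitation calibration: pulse energy at the sample surface and power schedules.

The pulse energy delivered under the objective (``E_obj``) is partially
absorbed by the immersion medium before reaching the sample. The energy at
the sample surface ``E`` is the package's reference quantity for every
excitation-dependent analysis and follows a single Beer-Lambert factor::

    E = E_obj * exp(-absorption_per_mm * immersion_path_mm)

The absorption coefficient is wavelength-dependent and instrument-specific,
so it is configuration (a YAML table per wavelength), not hard-coded physics.
Average power relates to pulse energy through the repetition rate:
nJ x MHz = mW (e.g. 17 nJ at 1 MHz = 17 mW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from ._exceptions import InputError

__all__ = [
    "ExcitationSetting",
    "PowerSchedule",
    "surface_pulse_energy",
    "average_power",
    "schedule_at",
    "load_absorption_table",
    "load_schedule_csv",
]


@dataclass(frozen=True)
class ExcitationSetting:
    """One excitation configuration: wavelength, repetition rate, energy
    under the objective and the immersion path it traverses."""

    wavelength_nm: float
    rep_rate_hz: float
    e_obj_nj: float
    immersion_path_mm: float = 0.0
    absorption_per_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.rep_rate_hz <= 0:
            raise InputError("rep_rate_hz must be > 0")
        if self.e_obj_nj < 0 or self.immersion_path_mm < 0 or self.absorption_per_mm < 0:
            raise InputError("energies, path lengths and absorption must be >= 0")


@dataclass
class PowerSchedule:
    """Depth-dependent excitation ramp: surface pulse energy per depth."""

    depths_um: np.ndarray
    e_surface_nj: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_um, dtype=float)
        e = np.asarray(self.e_surface_nj, dtype=float)
        if d.shape != e.shape or d.ndim != 1:
            raise InputError("depths and energies must be 1-D with equal length")
        if len(d) == 0 or np.any(np.diff(d) <= 0):
            raise InputError("depths must be non-empty and strictly increasing")
        if np.any(e <= 0):
            raise InputError("all schedule energies must be > 0")
        self.depths_um, self.e_surface_nj = d, e

    @classmethod
    def constant(cls, depths_um: np.ndarray, energy_nj: float) -> "PowerSchedule":
        d = np.asarray(depths_um, dtype=float)
        return cls(d, np.full_like(d, float(energy_nj)))


def surface_pulse_energy(setting: ExcitationSetting) -> float:
    """Pulse energy at the sample surface (nJ) after immersion absorption."""
    return setting.e_obj_nj * float(
        np.exp(-setting.absorption_per_mm * setting.immersion_path_mm)
    )


def average_power(e_surface_nj: float, rep_rate_hz: float) -> float:
    """Average power in mW from pulse energy (nJ) and repetition rate (Hz)."""
    if e_surface_nj <= 0 or rep_rate_hz <= 0:
        raise InputError("pulse energy and repetition rate must be > 0")
    return e_surface_nj * rep_rate_hz * 1e-6  # nJ * MHz = mW


def schedule_at(schedule: PowerSchedule, z_um: float) -> float:
    """Surface pulse energy at depth ``z_um``, linearly interpolated.

    Exact at grid points; depths outside the grid raise rather than
    extrapolating.
    """
    d = schedule.depths_um
    if not d[0] <= z_um <= d[-1]:
        raise InputError(f"depth {z_um} um outside schedule range [{d[0]}, {d[-1]}]")
    return float(np.interp(z_um, d, schedule.e_surface_nj))


# Wavelengths for which an immersion-absorption coefficient is expected.
# Values must come from the user's own instrument calibration; the shipped
# defaults are deliberately unset.
KNOWN_WAVELENGTHS_NM = (910, 1180, 1270, 1300, 1650, 1700)


def load_absorption_table(path: str) -> dict[float, float]:
    """Load a wavelength -> absorption_per_mm (natural-log units/mm) YAML table."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = {float(k): float(v) for k, v in raw.items()}
    for wl, coeff in table.items():
        if coeff < 0:
            raise InputError(f"absorption coefficient for {wl} nm must be >= 0")
    return table


def load_schedule_csv(path: str) -> PowerSchedule:
    """Read a 2-column CSV (depth_um, e_surface_nj) into a schedule."""
    df = pd.read_csv(path)
    if not {"depth_um", "e_surface_nj"} <= set(df.columns):
        raise InputError("schedule CSV needs columns depth_um, e_surface_nj")
    return PowerSchedule(df["depth_um"].to_numpy(), df["e_surface_nj"].to_numpy())
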