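"""Closed-form Transwell barrier-physiology calculators.

Four small computations accompany the imaging pipeline:

* **orbital shear stress** — the classic estimate of the maximal fluid
  shear stress at the bottom of a well swirled on an orbital shaker,
  ``tau_max = a * sqrt(rho * eta * (2*pi*f)**3)``, with ``a`` the orbital
  radius (half the orbital diameter), ``rho`` the medium density, ``eta``
  its dynamic viscosity and ``f`` the rotation frequency.  With a 25 mm
  orbital diameter at 55 rpm and culture medium at 37 °C this gives
  0.17 Pa (1.7 dynes/cm²).
* **TEER** — blank-corrected, area-normalized transepithelial electrical
  resistance: ``(R_measured - R_blank) * A`` in Ω·cm².
* **P_app** — apparent permeability coefficient of a tracer,
  ``P_app = K * Vr / A`` (cm/s), where ``K`` (s⁻¹) is the steady-state
  rate of change of the receiver concentration expressed as a fraction of
  the donor concentration, ``Vr`` the receiver volume (mL = cm³) and ``A``
  the membrane area (cm²).  When the receiver is periodically sampled and
  the withdrawn volume replaced with fresh buffer, the measured
  concentrations are first corrected by cumulative mass accounting:
  omitting the correction biases K low.
* **flux AUC** — trapezoidal area under a transepithelial flux time
  series, the scalar used to compare permeability across differentiation
  time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

DYNES_PER_CM2_PER_PA = 10.0


class ShearParams(BaseModel):
    """Orbital-shaker operating point and medium properties (SI units)."""

    orbital_diameter_m: float = Field(default=0.025, gt=0)
    rotation_rate_hz: float = Field(default=55.0 / 60.0, ge=0)
    medium_density: float = Field(default=1000.0, gt=0, description="kg/m^3")
    medium_viscosity: float = Field(default=9.5e-4, gt=0, description="Pa*s at 37 C")

    @classmethod
    def from_rpm(cls, orbital_diameter_mm: float, rpm: float, **kw) -> "ShearParams":
        return cls(
            orbital_diameter_m=orbital_diameter_mm / 1000.0,
            rotation_rate_hz=rpm / 60.0,
            **kw,
        )


class PermeabilityParams(BaseModel):
    """Transwell permeability assay constants and measured time series.

    ``times_s`` / ``receiver_conc`` describe the receiver-compartment
    tracer concentration over time (any concentration unit, as long as
    ``donor_conc`` matches); ``sample_volume_ml`` is withdrawn and replaced
    with blank buffer at each sampling time after the first.
    """

    receiver_volume_ml: float = Field(default=1.5, gt=0)
    membrane_area_cm2: float = Field(default=1.12, gt=0)
    donor_conc: float = Field(default=1.0, gt=0)
    sample_volume_ml: float = Field(default=0.1, ge=0)
    times_s: list[float] = Field(default_factory=list)
    receiver_conc: list[float] = Field(default_factory=list)
    steady_state_fraction: float = Field(
        default=2.0 / 3.0,
        gt=0,
        le=1,
        description="final fraction of time points used for the K fit",
    )


@dataclass
class TeerRecord:
    """One TEER reading with its cell-free blank."""

    measured_ohm: float
    blank_ohm: float
    area_cm2: float = 1.12

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ValueError("membrane area must be positive")


@dataclass
class PappResult:
    papp_cm_per_s: float
    k_per_s: float
    corrected_fraction: np.ndarray
    warning: str | None = None


def orbital_shear_stress(params: ShearParams) -> float:
    """Maximal bottom shear stress in Pa: a * sqrt(rho * eta * (2*pi*f)^3)."""
    a = params.orbital_diameter_m / 2.0
    omega = 2.0 * math.pi * params.rotation_rate_hz
    return a * math.sqrt(params.medium_density * params.medium_viscosity * omega**3)


def shear_stress_dynes(params: ShearParams) -> float:
    """Same estimate in dynes/cm² (1 Pa = 10 dynes/cm²)."""
    return orbital_shear_stress(params) * DYNES_PER_CM2_PER_PA


def correct_sampling_dilution(
    receiver_conc: Sequence[float],
    receiver_volume_ml: float,
    sample_volume_ml: float,
) -> np.ndarray:
    """Undo the dilution caused by sampling with volume replacement.

    Each withdrawal removes ``sample_volume * C_k`` of tracer mass from the
    receiver; the corrected concentration is what would have accumulated in
    an unsampled receiver:

        C_corr[n] = C_meas[n] + (s / Vr) * sum_{k<n} C_meas[k]
    """
    c = np.asarray(receiver_conc, dtype=float)
    ratio = sample_volume_ml / receiver_volume_ml
    removed = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    return c + ratio * removed


def papp(params: PermeabilityParams, k: float | None = None) -> PappResult:
    """Apparent permeability P_app = K * Vr / A in cm/s.

    If ``k`` is given it is used directly; otherwise K is the least-squares
    slope of the dilution-corrected receiver concentration fraction
    (C_receiver / C_donor) versus time over the steady-state window (the
    final ``steady_state_fraction`` of time points).
    """
    if k is None:
        t = np.asarray(params.times_s, dtype=float)
        if t.size < 3:
            raise ValueError("need at least 3 time points to fit K")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time vector must be strictly increasing")
        c = np.asarray(params.receiver_conc, dtype=float)
        if c.shape != t.shape:
            raise ValueError("times and concentrations must align")
        corrected = correct_sampling_dilution(
            c, params.receiver_volume_ml, params.sample_volume_ml
        )
        frac = corrected / params.donor_conc
        n_fit = max(2, int(math.ceil(params.steady_state_fraction * t.size)))
        k = float(np.polyfit(t[-n_fit:], frac[-n_fit:], 1)[0])
    else:
        corrected = np.asarray(params.receiver_conc, dtype=float)
        frac = corrected / params.donor_conc
    p = k * params.receiver_volume_ml / params.membrane_area_cm2
    warning = "fitted K is negative" if k < 0 else None
    return PappResult(
        papp_cm_per_s=p, k_per_s=k, corrected_fraction=frac, warning=warning
    )


def simulate_transport(
    papp_cm_per_s: float,
    params: PermeabilityParams,
    times_s: Sequence[float],
) -> np.ndarray:
    """Forward-simulate receiver concentrations under periodic sampling.

    Sink-condition transport: between samplings the receiver gains tracer
    at rate ``dC/dt = P_app * A * C_donor / Vr``; at each sampling time
    (after recording the concentration) ``sample_volume`` is withdrawn and
    replaced with blank buffer, diluting the receiver by
    ``1 - s/Vr``.  This is the independent ground-truth generator used to
    validate the dilution correction and the K fit.
    """
    t = np.asarray(times_s, dtype=float)
    rate = papp_cm_per_s * params.membrane_area_cm2 * params.donor_conc / params.receiver_volume_ml
    keep = 1.0 - params.sample_volume_ml / params.receiver_volume_ml
    c = 0.0
    out = np.empty(t.size)
    prev = 0.0
    for i, ti in enumerate(t):
        c += rate * (ti - prev)
        out[i] = c
        c *= keep  # sample withdrawn and replaced after the reading
        prev = ti
    return out


def flux_auc(times: Sequence[float], flux: Sequence[float]) -> float:
    """Trapezoidal area under a flux time series (flux x time units)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(flux, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points for an AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def teer(record: TeerRecord) -> tuple[float, str | None]:
    """Blank-corrected, area-normalized TEER in Ω·cm²."""
    value = (record.measured_ohm - record.blank_ohm) * record.area_cm2
    warning = "corrected TEER is negative" if value < 0 else None
    return value, warning


def dilution_nominal(concentration: float, dilution_factor: float) -> float:
    """Nominal concentration after an n-fold dilution: c / factor."""
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    return concentration / dilution_factor
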