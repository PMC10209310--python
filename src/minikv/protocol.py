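"""Manufacturer dose-rate protocol and GUM uncertainty combination.

The absorbed dose rate to water at depth r is computed from an ionisation
chamber reading as

    D_w(r) = N_k * Q(r) * (T/T0) * (P0/P) * k_Q * k_{kA->Dw}

with N_k the air-kerma calibration factor (Gy/C), Q the collected charge,
T/P the measurement temperature and pressure against the calibration
reference T0/P0, k_Q the beam-quality factor (unity for this source, whose
quality matches a T30 reference beam, HVL 0.37 mm Al) and k_{kA->Dw} the
air-kerma-to-water-dose conversion for the parallel-plate chamber.

Relative uncertainties combine in quadrature (GUM):

    sigma = sqrt(sigma_rep^2 + sigma_pos^2 + sigma_kQkA^2 + sigma_P^2 + sigma_T^2)

after rescaling every component to coverage k = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

T0_DEFAULT_K = 293.15
P0_DEFAULT_HPA = 1013.25


@dataclass(frozen=True)
class CalibrationFactors:
    """Chamber calibration data from the calibration certificate."""

    n_k: float  # Gy/C
    k_q: float = 1.0
    k_ka_to_dw: float = 1.0
    t0_k: float = T0_DEFAULT_K
    p0_hpa: float = P0_DEFAULT_HPA

    def __post_init__(self):
        for name in ("n_k", "k_q", "k_ka_to_dw", "t0_k", "p0_hpa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ChamberMeasurement:
    """Charge readings collected at one depth."""

    readings_c: tuple[float, ...]  # repeat charge readings, C
    interval_s: float
    temperature_k: float
    pressure_hpa: float
    depth_cm: float = float("nan")

    def __post_init__(self):
        if len(self.readings_c) < 1:
            raise ValueError("need at least one reading")
        if any(q <= 0 for q in self.readings_c):
            raise ValueError("charge readings must be positive")
        if self.interval_s <= 0 or self.temperature_k <= 0 or self.pressure_hpa <= 0:
            raise ValueError("interval, temperature and pressure must be positive")

    @property
    def mean_charge_c(self) -> float:
        return float(np.mean(self.readings_c))

    @property
    def sigma_rep_percent(self) -> float:
        """Standard deviation of the mean of the readings, % (k = 1)."""
        q = np.asarray(self.readings_c, float)
        if len(q) < 2:
            return 0.0
        sem = q.std(ddof=1) / math.sqrt(len(q))
        return float(100.0 * sem / q.mean())


def temperature_pressure_factor(t_k: float, t0_k: float,
                                p_hpa: float, p0_hpa: float) -> float:
    """Air-density correction (T/T0) * (P0/P)."""
    if min(t_k, t0_k, p_hpa, p0_hpa) <= 0:
        raise ValueError("temperatures and pressures must be positive")
    return (t_k / t0_k) * (p0_hpa / p_hpa)


def dose_rate(measurement: ChamberMeasurement,
              cal: CalibrationFactors) -> tuple[float, float]:
    """(dose over the interval in Gy, dose rate in Gy/min).

    Uses the mean of the repeat readings; the product follows the protocol
    equation exactly.
    """
    ktp = temperature_pressure_factor(
        measurement.temperature_k, cal.t0_k, measurement.pressure_hpa, cal.p0_hpa
    )
    dose = cal.n_k * measurement.mean_charge_c * ktp * cal.k_q * cal.k_ka_to_dw
    return dose, dose / (measurement.interval_s / 60.0)


@dataclass
class UncertaintyBudget:
    """Relative uncertainty components in %, each with its coverage factor."""

    sigma_rep: float = 0.0
    sigma_pos: float = 0.0
    sigma_kq_ka: float = 2.0  # calibration-certificate value at k = 1
    sigma_p: float = 0.0
    sigma_t: float = 0.0
    coverage: dict = field(default_factory=dict)  # component name -> k

    def components_k1(self) -> list[float]:
        out = []
        for name in ("sigma_rep", "sigma_pos", "sigma_kq_ka", "sigma_p", "sigma_t"):
            val = getattr(self, name)
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
            k = self.coverage.get(name, 1.0)
            if k < 1.0:
                raise ValueError("coverage factors must be >= 1")
            out.append(val / k)
        return out


def combine_uncertainty(budget: UncertaintyBudget, k: float = 1.0) -> float:
    """Root-sum-square of the k=1 components, expanded by coverage ``k``."""
    comps = budget.components_k1()
    return k * math.sqrt(sum(c * c for c in comps))


def positioning_uncertainty_percent(pdd_fit, depth_cm: float,
                                    delta_r_cm: float = 0.01) -> float:
    """Convert a positioning bound into a relative dose uncertainty via the
    local PDD gradient: sigma_pos = |d ln D / dr| * delta_r * 100 %.

    ``pdd_fit`` is an :class:`minikv.analysis.PDDFit`; the derivative is
    evaluated at ``depth_cm`` (from the device surface) by central
    differences on the fitted curve.
    """
    from .analysis import evaluate_model

    x = depth_cm + pdd_fit.origin_offset_cm
    h = 1e-4
    d0 = evaluate_model(pdd_fit, x - h)
    d1 = evaluate_model(pdd_fit, x + h)
    grad = (math.log(d1) - math.log(d0)) / (2 * h)
    return abs(grad) * delta_r_cm * 100.0
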