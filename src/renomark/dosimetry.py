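"""Kidney self-dose dosimetry via the MIRD formalism.

The mean absorbed dose to a target region equals the time-integrated
activity in the source region times the mean electron energy emitted per
decay (Delta = sum_i E_i * Y_i), times the absorbed fraction phi, divided by
the target mass; source and target are both the whole kidney (self-dose
only, electrons only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: 177Lu physical half-life, hours (6.647 d).
LU177_HALF_LIFE_H = 159.528
#: Joules per keV.
KEV_TO_J = 1.602176634e-16
#: Decays per MBq * hour.
DECAYS_PER_MBQ_H = 3.6e9


@dataclass
class TimeActivityCurve:
    """Sampled organ activity vs time for one injected activity."""

    times_h: np.ndarray
    activities_MBq: np.ndarray
    organ: str = "kidney"

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activities_MBq = np.asarray(self.activities_MBq, dtype=float)
        if self.times_h.size == 0:
            raise ValueError("time-activity curve needs at least one sample")
        if self.times_h.size != self.activities_MBq.size:
            raise ValueError("times and activities must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.times_h[0] <= 0:
            raise ValueError("sample times must start after t=0")
        if np.any(self.activities_MBq < 0):
            raise ValueError("activities must be non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_h": self.times_h, "activity_MBq": self.activities_MBq}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, organ: str = "kidney") -> "TimeActivityCurve":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["activity_MBq"].to_numpy(), organ)


@dataclass
class DoseParameters:
    """MIRD constants for the kidney self-dose calculation.

    delta_keV is the mean electron energy per decay, phi the absorbed
    fraction, mass_g the whole-kidney mass (both kidneys are dosed
    independently; the default 0.3 g is a typical adult-mouse kidney).
    """

    delta_keV: float = 147.0
    phi: float = 0.93
    mass_g: float = 0.3
    phys_half_life_h: float = LU177_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.delta_keV <= 0:
            raise ValueError("delta_keV must be positive")
        if not 0 < self.phi <= 1:
            raise ValueError("phi must be in (0, 1]")
        if self.mass_g <= 0:
            raise ValueError("mass_g must be positive")
        if self.phys_half_life_h <= 0:
            raise ValueError("phys_half_life_h must be positive")


@dataclass
class AbsorbedDose:
    dose_Gy: float
    tia_MBq_h: float


def integrate_tac(tac: TimeActivityCurve, phys_half_life_h: float = LU177_HALF_LIFE_H) -> float:
    """Time-integrated activity (MBq*h) of a sampled curve.

    Trapezoid rule over the samples, a linear rise from (0, 0) to the first
    sample, and an analytic tail A_last / lambda beyond the last sample that
    decays with the physical half-life only.
    """
    if phys_half_life_h <= 0:
        raise ValueError("phys_half_life_h must be positive")
    lam = np.log(2.0) / phys_half_life_h
    t, a = tac.times_h, tac.activities_MBq
    rise = 0.5 * t[0] * a[0]
    body = float(np.trapezoid(a, t)) if t.size > 1 else 0.0
    tail = a[-1] / lam
    return float(rise + body + tail)


def absorbed_dose(tia_MBq_h: float, params: DoseParameters | None = None) -> AbsorbedDose:
    """Mean absorbed dose (Gy) from a time-integrated activity (MBq*h)."""
    if params is None:
        params = DoseParameters()
    if tia_MBq_h < 0:
        raise ValueError("time-integrated activity must be non-negative")
    energy_j = tia_MBq_h * DECAYS_PER_MBQ_H * params.delta_keV * KEV_TO_J * params.phi
    dose = energy_j / (params.mass_g * 1e-3)
    return AbsorbedDose(dose_Gy=float(dose), tia_MBq_h=float(tia_MBq_h))


def dose_table(
    activities_MBq,
    model,
    params: DoseParameters | None = None,
    grid_h: np.ndarray | None = None,
) -> dict[float, AbsorbedDose]:
    """Absorbed dose per injected activity for a saturable-uptake model.

    For each activity the kidney time-activity curve is generated from the
    uptake model, integrated, and converted to dose.
    """
    from .synthetic import gen_biodistribution  # deferred: avoids import cycle

    if params is None:
        params = DoseParameters()
    if grid_h is None:
        grid_h = default_grid_h(params.phys_half_life_h)
    out: dict[float, AbsorbedDose] = {}
    for act in activities_MBq:
        tac = gen_biodistribution(act, model, grid_h)
        out[float(act)] = absorbed_dose(integrate_tac(tac, params.phys_half_life_h), params)
    return out


def default_grid_h(phys_half_life_h: float = LU177_HALF_LIFE_H, n: int = 400) -> np.ndarray:
    """Sampling grid spanning ten physical half-lives, denser early on."""
    return np.geomspace(0.1, 10 * phys_half_life_h, n)


def calibrate_uptake_model(
    anchors: dict[float, float],
    params: DoseParameters | None = None,
    template=None,
) -> "object":
    """Fit u0 and k_sat of a saturable UptakeModel to printed dose anchors.

    ``anchors`` maps injected activity (MBq) to absorbed dose (Gy). The dose
    is linear in u0 for fixed k_sat, so u0 is solved by least squares inside
    a 1-D golden-section search over log k_sat. Clearance half-lives are
    taken from ``template`` (package defaults when None).
    """
    from dataclasses import replace

    from scipy.optimize import minimize_scalar

    from .synthetic import UptakeModel, gen_biodistribution

    if params is None:
        params = DoseParameters()
    if template is None:
        template = UptakeModel()
    acts = np.array(sorted(anchors), dtype=float)
    target = np.array([anchors[a] for a in acts])
    grid = default_grid_h(params.phys_half_life_h)

    def doses_for(k_sat: float, u0: float) -> np.ndarray:
        m = replace(template, u0=u0, k_sat_MBq=k_sat)
        return np.array(
            [
                absorbed_dose(
                    integrate_tac(gen_biodistribution(a, m, grid), params.phys_half_life_h),
                    params,
                ).dose_Gy
                for a in acts
            ]
        )

    def loss(log_k: float) -> float:
        k = float(np.exp(log_k))
        base = doses_for(k, 1.0)
        u0 = float(base @ target / (base @ base))
        return float(np.sum((u0 * base - target) ** 2))

    res = minimize_scalar(loss, bounds=(np.log(1.0), np.log(1e4)), method="bounded")
    k_sat = float(np.exp(res.x))
    base = doses_for(k_sat, 1.0)
    u0 = float(base @ target / (base @ base))
    return replace(template, u0=u0, k_sat_MBq=k_sat)
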