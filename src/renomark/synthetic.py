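"""Synthetic inputs for every pipeline stage.

Generates expression studies with the 5-activity x 3-timepoint x 2-tissue
x n=3 design, saturable-uptake biodistribution curves for dosimetry,
Poisson-noise planar gamma-camera frame series, and blood panels with
fixture-driven effect sizes. All randomness flows through explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .diffexpr import ExpressionSet
from .dosimetry import LU177_HALF_LIFE_H, TimeActivityCurve
from .scintigraphy import TC99M_HALF_LIFE_H, PlanarFrame

#: Printed kidney absorbed dose (Gy) per injected activity (MBq) in the
#: reference study design; used to map design activities onto effect doses.
DOSE_BY_ACTIVITY_GY = {30.0: 16.0, 60.0: 29.0, 90.0: 40.0, 120.0: 48.0, 150.0: 54.0}


class GeometryError(ValueError):
    """Scene objects overlap or fall outside the image."""


# ---------------------------------------------------------------------------
# study design


@dataclass
class StudyDesign:
    """Exposure design: activities + control, timepoints, tissues, replicates."""

    activities_MBq: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0, 150.0)
    timepoints_months: tuple[float, ...] = (4.0, 8.0, 12.0)
    tissues: tuple[str, ...] = ("cortex", "medulla")
    replicates_per_group: int = 3
    controls_per_timepoint: int = 3

    def __post_init__(self) -> None:
        acts = np.asarray(self.activities_MBq, float)
        if np.any(acts < 0) or np.any(np.diff(acts) <= 0):
            raise ValueError("activities must be strictly increasing and non-negative")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if self.controls_per_timepoint < 2:
            raise ValueError("controls_per_timepoint must be >= 2")

    @property
    def exposure_groups(self) -> list[tuple[float, float]]:
        """(activity, timepoint) pairs; 15 for the reference design."""
        return [
            (a, t)
            for t in self.timepoints_months
            for a in self.activities_MBq
            if a > 0
        ]


# ---------------------------------------------------------------------------
# expression effects

EffectFn = Callable[[float, float], float]  # (dose_Gy, timepoint_months) -> log2 ratio

GENE_CLASSES = ("null", "monotone_dose", "late_responder", "recurrent_marker")


@dataclass
class GeneEffect:
    klass: str
    effect: EffectFn

    def __post_init__(self) -> None:
        if self.klass not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.klass!r}")


@dataclass
class EffectModel:
    """Per-gene true effect functions plus the log2 noise level."""

    genes: dict[str, GeneEffect]
    noise_sd: float = 0.2
    baseline_range: tuple[float, float] = (6.0, 12.0)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.genes) == 0:
            raise ValueError("effect model needs at least one gene")

    # -- builders ---------------------------------------------------------
    @staticmethod
    def null_effect() -> GeneEffect:
        return GeneEffect("null", lambda dose, tp: 0.0)

    @staticmethod
    def monotone_effect(slope_per_gy: float) -> GeneEffect:
        """log2 ratio rising linearly with absorbed dose at every timepoint."""
        return GeneEffect("monotone_dose", lambda dose, tp: slope_per_gy * dose)

    @staticmethod
    def late_effect(amplitude: float, onset_months: float = 12.0) -> GeneEffect:
        """Effect switched on only at late timepoints (>= onset)."""
        return GeneEffect(
            "late_responder",
            lambda dose, tp: amplitude if tp >= onset_months and dose > 0 else 0.0,
        )

    @staticmethod
    def table_effect(table: dict[tuple[float, float], float]) -> GeneEffect:
        """Marker-style effect from a {(dose_Gy, timepoint): log2 ratio} table."""
        lut = dict(table)
        return GeneEffect(
            "recurrent_marker", lambda dose, tp: lut.get((dose, tp), 0.0)
        )

    @classmethod
    def build(
        cls,
        n_null: int = 0,
        monotone: dict[str, float] | None = None,
        late: dict[str, float] | None = None,
        markers: dict[str, dict[tuple[float, float], float]] | None = None,
        noise_sd: float = 0.2,
    ) -> "EffectModel":
        genes: dict[str, GeneEffect] = {}
        for i in range(n_null):
            genes[f"null_{i:05d}"] = cls.null_effect()
        for name, slope in (monotone or {}).items():
            genes[name] = cls.monotone_effect(slope)
        for name, amp in (late or {}).items():
            genes[name] = cls.late_effect(amp)
        for name, table in (markers or {}).items():
            genes[name] = cls.table_effect(table)
        return cls(genes=genes, noise_sd=noise_sd)


def gen_expression_set(
    design: StudyDesign,
    effects: EffectModel,
    seed: int,
    dose_by_activity: dict[float, float] | None = None,
) -> dict[str, ExpressionSet]:
    """Simulate the expression study; returns one ExpressionSet per tissue.

    Controls (activity 0) are drawn per timepoint, age-matched. Each value is
    gene baseline + true effect (exposed samples only) + Gaussian log2 noise.
    """
    if dose_by_activity is None:
        dose_by_activity = DOSE_BY_ACTIVITY_GY
    gene_ids = sorted(effects.genes)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene identifiers")
    rng = np.random.default_rng(seed)
    lo, hi = effects.baseline_range
    baselines = rng.uniform(lo, hi, size=len(gene_ids))

    out: dict[str, ExpressionSet] = {}
    for tissue in design.tissues:
        cols: list[np.ndarray] = []
        meta_rows: list[dict] = []
        for tp in design.timepoints_months:
            for r in range(design.controls_per_timepoint):
                cols.append(baselines + rng.normal(0, effects.noise_sd, len(gene_ids)))
                meta_rows.append(
                    {
                        "sample_id": f"{tissue}_t{tp:g}_ctl_{r}",
                        "tissue": tissue,
                        "timepoint_months": tp,
                        "activity_MBq": 0.0,
                        "replicate": r,
                    }
                )
            for act in design.activities_MBq:
                if act == 0:
                    continue
                dose = dose_by_activity.get(float(act), float(act))
                true = np.array(
                    [effects.genes[g].effect(dose, tp) for g in gene_ids]
                )
                for r in range(design.replicates_per_group):
                    cols.append(
                        baselines + true + rng.normal(0, effects.noise_sd, len(gene_ids))
                    )
                    meta_rows.append(
                        {
                            "sample_id": f"{tissue}_t{tp:g}_a{act:g}_{r}",
                            "tissue": tissue,
                            "timepoint_months": tp,
                            "activity_MBq": float(act),
                            "replicate": r,
                        }
                    )
        out[tissue] = ExpressionSet(
            gene_ids, np.column_stack(cols), pd.DataFrame(meta_rows)
        )
    return out


# ---------------------------------------------------------------------------
# biodistribution


@dataclass
class UptakeModel:
    """Saturable kidney uptake with biexponential biological clearance.

    The plateau uptake fraction falls with injected activity as
    u(A) = u0 * k_sat / (k_sat + A) (one-site receptor saturation); retained
    activity then clears biexponentially on top of physical decay.
    """

    u0: float = 0.05
    k_sat_MBq: float = 200.0
    half_life_fast_h: float = 12.0
    half_life_slow_h: float = 90.0
    fraction_fast: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.u0 <= 1:
            raise ValueError("u0 must be in (0, 1]")
        if self.k_sat_MBq <= 0:
            raise ValueError("k_sat_MBq must be positive")
        if self.half_life_fast_h <= 0 or self.half_life_slow_h <= 0:
            raise ValueError("half-lives must be positive")
        if not 0 <= self.fraction_fast <= 1:
            raise ValueError("fraction_fast must be in [0, 1]")

    def uptake_fraction(self, injected_MBq: float) -> float:
        return self.u0 * self.k_sat_MBq / (self.k_sat_MBq + injected_MBq)


def gen_biodistribution(
    injected_MBq: float,
    model: UptakeModel,
    grid_h,
    phys_half_life_h: float = LU177_HALF_LIFE_H,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
) -> TimeActivityCurve:
    """Kidney time-activity curve for one injected activity (deterministic
    unless ``noise_sd_frac`` > 0)."""
    grid = np.asarray(grid_h, dtype=float)
    if grid.size == 0:
        raise ValueError("sampling grid must not be empty")
    if injected_MBq < 0:
        raise ValueError("injected activity must be non-negative")
    lam_p = math.log(2.0) / phys_half_life_h
    lam_f = math.log(2.0) / model.half_life_fast_h
    lam_s = math.log(2.0) / model.half_life_slow_h
    a0 = model.uptake_fraction(injected_MBq) * injected_MBq
    bio = model.fraction_fast * np.exp(-lam_f * grid) + (
        1 - model.fraction_fast
    ) * np.exp(-lam_s * grid)
    act = a0 * bio * np.exp(-lam_p * grid)
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        act = np.clip(act * (1 + rng.normal(0, noise_sd_frac, act.shape)), 0, None)
    return TimeActivityCurve(grid, act, organ="kidney")


# ---------------------------------------------------------------------------
# renal kinetics and planar frames


@dataclass
class RenalKinetics:
    """Three-compartment DTPA kinetics: blood/remainder -> kidneys -> bladder.

    impairment_factor scales the kidney-to-bladder excretion rate
    (1 = normal, 0 = full obstruction). Physical decay of 99mTc multiplies
    every compartment, so decay-corrected amounts conserve injected activity.
    """

    uptake_rate_per_min: float = 0.03
    excretion_rate_per_min: float = 0.2
    impairment_factor: float = 1.0
    injected_MBq: float = 55.0

    def __post_init__(self) -> None:
        if self.uptake_rate_per_min <= 0 or self.excretion_rate_per_min <= 0:
            raise ValueError("rate constants must be positive")
        if not 0 <= self.impairment_factor <= 1:
            raise ValueError("impairment_factor must be in [0, 1]")
        if self.injected_MBq < 0:
            raise ValueError("injected activity must be non-negative")

    def activities(self, t_min: float) -> tuple[float, float, float]:
        """(kidneys, bladder, remainder) activity in MBq at ``t_min``."""
        ku = self.uptake_rate_per_min
        ke = self.excretion_rate_per_min * self.impairment_factor
        a = self.injected_MBq
        r = a * math.exp(-ku * t_min)
        if ke == 0:
            k = a * (1 - math.exp(-ku * t_min))
        elif math.isclose(ke, ku):
            k = a * ku * t_min * math.exp(-ku * t_min)
        else:
            k = a * ku / (ke - ku) * (math.exp(-ku * t_min) - math.exp(-ke * t_min))
        b = max(a - r - k, 0.0)  # guard float round-off at full obstruction
        decay = 2.0 ** (-t_min / (TC99M_HALF_LIFE_H * 60.0))
        return (k * decay, b * decay, r * decay)


@dataclass
class FrameGeometry:
    """Minimal planar scene: two Gaussian kidneys, a bladder disc, a syringe
    rectangle in a corner, and the remainder activity spread over a body
    ellipse."""

    shape: tuple[int, int] = (256, 256)
    kidney_centers: tuple[tuple[float, float], ...] = ((100.0, 96.0), (100.0, 160.0))
    kidney_sigma_px: float = 3.0
    bladder_center: tuple[float, float] = (190.0, 128.0)
    bladder_radius_px: float = 12.0
    syringe_rows: tuple[int, int] = (8, 24)
    syringe_cols: tuple[int, int] = (8, 16)
    body_center: tuple[float, float] = (140.0, 128.0)
    body_semi_axes: tuple[float, float] = (105.0, 70.0)
    syringe_activity_MBq: float = 5.0
    sensitivity_counts_per_MBq_min: float = 1800.0
    background_rate_per_px: float = 0.0

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return rr.astype(float), cc.astype(float)

    def kidney_profiles(self) -> list[np.ndarray]:
        rr, cc = self.grids()
        out = []
        for (r0, c0) in self.kidney_centers:
            g = np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * self.kidney_sigma_px**2)
            )
            out.append(g / g.sum())
        return out

    def bladder_mask(self) -> np.ndarray:
        rr, cc = self.grids()
        r0, c0 = self.bladder_center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.bladder_radius_px**2

    def syringe_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.syringe_rows[0] : self.syringe_rows[1], self.syringe_cols[0] : self.syringe_cols[1]] = True
        return m

    def body_mask(self) -> np.ndarray:
        rr, cc = self.grids()
        r0, c0 = self.body_center
        ar, ac = self.body_semi_axes
        return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0

    def validate(self) -> None:
        """Kidney cores (3 sigma), bladder and syringe must not overlap."""
        rr, cc = self.grids()
        masks = []
        for (r0, c0) in self.kidney_centers:
            masks.append(
                (rr - r0) ** 2 + (cc - c0) ** 2 <= (3 * self.kidney_sigma_px) ** 2
            )
        masks.append(self.bladder_mask())
        masks.append(self.syringe_mask())
        total = np.zeros(self.shape, dtype=int)
        for m in masks:
            total += m.astype(int)
        if (total > 1).any():
            raise GeometryError("scene objects overlap")


def gen_scintigraphy_series(
    kinetics: RenalKinetics,
    geometry: FrameGeometry,
    frame_times_min,
    seed: int,
    duration_min: float = 1.0,
    noise: bool = True,
) -> list[PlanarFrame]:
    """Poisson-noise planar frames of the kinetic scene at the given times.

    Expected counts per object = sensitivity x activity x frame duration,
    spread over the object's spatial profile; the kidney total is split
    evenly between left and right. The syringe holds a fixed calibration
    activity decaying physically; its truth at each frame time is recorded
    in the frame metadata. ``noise=False`` returns the expected (float)
    count images for mass-balance checks.
    """
    geometry.validate()
    rng = np.random.default_rng(seed)
    profiles = geometry.kidney_profiles()
    bladder = geometry.bladder_mask()
    syringe = geometry.syringe_mask()
    body = geometry.body_mask()
    organ = np.zeros(geometry.shape, dtype=bool)
    for (r0, c0) in geometry.kidney_centers:
        rr, cc = geometry.grids()
        organ |= (rr - r0) ** 2 + (cc - c0) ** 2 <= (3 * geometry.kidney_sigma_px) ** 2
    remainder_mask = body & ~organ & ~bladder & ~syringe
    sens = geometry.sensitivity_counts_per_MBq_min

    frames: list[PlanarFrame] = []
    for t in frame_times_min:
        k_act, b_act, r_act = kinetics.activities(float(t))
        expected = np.full(geometry.shape, geometry.background_rate_per_px, float)
        for prof in profiles:
            expected += sens * (k_act / 2.0) * duration_min * prof
        if bladder.sum():
            expected[bladder] += sens * b_act * duration_min / bladder.sum()
        if remainder_mask.sum():
            expected[remainder_mask] += sens * r_act * duration_min / remainder_mask.sum()
        syr_act = geometry.syringe_activity_MBq * 2.0 ** (
            -float(t) / (TC99M_HALF_LIFE_H * 60.0)
        )
        expected[syringe] += sens * syr_act * duration_min / syringe.sum()
        counts = rng.poisson(expected).astype(np.uint32) if noise else expected
        frames.append(
            PlanarFrame(
                counts=counts,
                frame_time_min=float(t),
                duration_min=duration_min,
                syringe_activity_MBq=float(syr_act),
                injected_MBq=kinetics.injected_MBq,
            )
        )
    return frames


def gen_static_frame(
    kidney_percent_ia: float,
    geometry: FrameGeometry,
    seed: int,
    frame_time_min: float = 180.0,
    duration_min: float = 3.0,
    injected_MBq: float = 40.0,
    bladder_percent_ia: float = 15.0,
    remainder_percent_ia: float = 30.0,
    noise: bool = True,
) -> PlanarFrame:
    """Single static frame (DMSA-style) with a prescribed kidney uptake.

    ``kidney_percent_ia`` is the decay-corrected percent of injected
    activity retained by both kidneys together at the frame time.
    """
    geometry.validate()
    rng = np.random.default_rng(seed)
    decay = 2.0 ** (-frame_time_min / (TC99M_HALF_LIFE_H * 60.0))
    k_act = kidney_percent_ia / 100.0 * injected_MBq * decay
    b_act = bladder_percent_ia / 100.0 * injected_MBq * decay
    r_act = remainder_percent_ia / 100.0 * injected_MBq * decay
    sens = geometry.sensitivity_counts_per_MBq_min
    bladder = geometry.bladder_mask()
    syringe = geometry.syringe_mask()
    rr, cc = geometry.grids()
    organ = np.zeros(geometry.shape, dtype=bool)
    for (r0, c0) in geometry.kidney_centers:
        organ |= (rr - r0) ** 2 + (cc - c0) ** 2 <= (3 * geometry.kidney_sigma_px) ** 2
    remainder_mask = geometry.body_mask() & ~organ & ~bladder & ~syringe
    expected = np.full(geometry.shape, geometry.background_rate_per_px, float)
    for prof in geometry.kidney_profiles():
        expected += sens * (k_act / 2.0) * duration_min * prof
    expected[bladder] += sens * b_act * duration_min / bladder.sum()
    expected[remainder_mask] += sens * r_act * duration_min / remainder_mask.sum()
    syr_act = geometry.syringe_activity_MBq * decay
    expected[syringe] += sens * syr_act * duration_min / syringe.sum()
    counts = rng.poisson(expected).astype(np.uint32) if noise else expected
    return PlanarFrame(
        counts=counts,
        frame_time_min=frame_time_min,
        duration_min=duration_min,
        syringe_activity_MBq=float(syr_act),
        injected_MBq=injected_MBq,
    )


# ---------------------------------------------------------------------------
# blood panels

#: Control baselines per analyte (units in comments).
BLOOD_BASELINES = {
    "wbc": 6.0,  # 1e9 cells/L
    "rbc": 9.0,  # 1e12 cells/L
    "urea": 8.0,  # mmol/L
    "creatinine": 20.0,  # umol/L
}


@dataclass
class BloodPanel:
    """One animal's blood analyte values with group metadata."""

    values: dict[str, float]
    activity_MBq: float
    timepoint_months: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("analyte values must be non-negative")


def gen_blood_panel(
    dose_Gy: float,
    timepoint_months: float,
    effect_table: pd.DataFrame,
    seed: int,
    noise_sd_log: float = 0.05,
    n: int = 3,
) -> tuple[list[BloodPanel], list[BloodPanel]]:
    """Synthetic test and control blood panels for one dose/time cell.

    The expected test/control ratio of each analyte equals the fixture cell
    (percent_of_control / 100) at the nearest design dose; values carry
    multiplicative log-normal noise. Returns (test_panels, control_panels).
    """
    if dose_Gy < 0:
        raise ValueError("dose must be non-negative")
    rng = np.random.default_rng(seed)
    # nearest design cell by dose, then by timepoint
    acts = sorted(DOSE_BY_ACTIVITY_GY, key=lambda a: abs(DOSE_BY_ACTIVITY_GY[a] - dose_Gy))
    activity = acts[0] if dose_Gy > 0 else 0.0
    tps = sorted(
        effect_table["timepoint_months"].unique(), key=lambda t: abs(t - timepoint_months)
    )
    cell = effect_table[
        (effect_table["timepoint_months"] == tps[0])
        & (effect_table["activity_MBq"] == activity)
    ]

    def ratio_for(analyte: str) -> float:
        if dose_Gy == 0:
            return 1.0
        row = cell[cell["analyte"] == analyte]
        if row.empty:
            return 1.0
        return float(row["percent_of_control"].iloc[0]) / 100.0

    # log-normal with mean exactly the target ratio
    adj = -0.5 * noise_sd_log**2

    def draw(mean_value: float) -> float:
        return mean_value * math.exp(adj + rng.normal(0, noise_sd_log))

    test = [
        BloodPanel(
            {a: draw(BLOOD_BASELINES[a] * ratio_for(a)) for a in BLOOD_BASELINES},
            activity_MBq=activity,
            timepoint_months=timepoint_months,
        )
        for _ in range(n)
    ]
    control = [
        BloodPanel(
            {a: draw(BLOOD_BASELINES[a]) for a in BLOOD_BASELINES},
            activity_MBq=0.0,
            timepoint_months=timepoint_months,
            is_control=True,
        )
        for _ in range(n)
    ]
    return test, control
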