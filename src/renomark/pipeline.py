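"""End-to-end orchestration: dosimetry, simulated expression + DE,
biomarker fixtures, scintigraphy and blood ratios, consolidated into a
machine-readable summary plus TSV artifacts."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker, blood, diffexpr, dosimetry, scintigraphy, synthetic

log = logging.getLogger("renomark")

#: Printed dose anchors (MBq -> Gy) used to calibrate the uptake model.
DOSE_ANCHORS_GY = {30.0: 16.0, 60.0: 29.0, 90.0: 40.0}

#: Excretion impairment per injected activity used for the simulated DTPA
#: renograms (1 = normal clearance, near 0 = obstruction at high dose).
IMPAIRMENT_BY_ACTIVITY = {0.0: 1.0, 30.0: 1.0, 90.0: 0.4, 150.0: 0.05}


@dataclass
class PipelineConfig:
    """Flat, serializable run configuration; unknown keys are rejected."""

    activities_MBq: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0, 150.0)
    timepoints_months: tuple[float, ...] = (4.0, 8.0, 12.0)
    tissues: tuple[str, ...] = ("cortex", "medulla")
    replicates_per_group: int = 3
    n_null_genes: int = 300
    monotone_slope_per_gy: float = 0.03
    noise_sd: float = 0.2
    q_max: float = 0.01
    lfc_min: float = 0.58
    roi_frac: float = 0.10
    alpha: float = 0.05
    kidney_mass_g: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("q_max", "lfc_min", "roi_frac", "alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


# ---------------------------------------------------------------------------
# stages


def stage_dosimetry(config: PipelineConfig) -> dict:
    params = dosimetry.DoseParameters(mass_g=config.kidney_mass_g)
    model = dosimetry.calibrate_uptake_model(DOSE_ANCHORS_GY, params)
    table = dosimetry.dose_table(config.activities_MBq, model, params)
    log.info("dosimetry: calibrated u0=%.4g k_sat=%.4g MBq", model.u0, model.k_sat_MBq)
    return {
        "model": model,
        "params": params,
        "dose_Gy": {a: d.dose_Gy for a, d in table.items()},
        "tia_MBq_h": {a: d.tia_MBq_h for a, d in table.items()},
    }


def default_effect_model(config: PipelineConfig, cat: biomarker.MarkerCatalogue) -> synthetic.EffectModel:
    """Null genes, one planted monotone gene, one late responder, and a
    Cdkn1a-like marker whose effect table is read off the packaged panel."""
    panel = cat.panel("cortex")
    cdkn1a = panel[panel["gene"] == "Cdkn1a"]
    table = {
        (synthetic.DOSE_BY_ACTIVITY_GY[row.activity_MBq], row.timepoint_months): row.log2_ratio
        for row in cdkn1a.itertuples(index=False)
    }
    return synthetic.EffectModel.build(
        n_null=config.n_null_genes,
        monotone={"mono_planted": config.monotone_slope_per_gy},
        late={"late_planted": 1.0},
        markers={"Cdkn1a_like": table},
        noise_sd=config.noise_sd,
    )


def stage_expression(config: PipelineConfig, cat: biomarker.MarkerCatalogue) -> dict:
    design = synthetic.StudyDesign(
        activities_MBq=config.activities_MBq,
        timepoints_months=config.timepoints_months,
        tissues=config.tissues,
        replicates_per_group=config.replicates_per_group,
    )
    effects = default_effect_model(config, cat)
    sets = synthetic.gen_expression_set(design, effects, seed=config.seed)
    de_results: dict[tuple[str, float, float], pd.DataFrame] = {}
    for tissue, es in sets.items():
        es = diffexpr.preprocess(es, variance_quantile=0.0)
        de_results.update(
            diffexpr.de_all_groups(es, q_max=config.q_max, lfc_min=config.lfc_min)
        )
    sig_counts = {
        f"{t}_{tp:g}mo_{a:g}MBq": int(df["significant"].sum())
        for (t, tp, a), df in sorted(de_results.items())
    }
    rec = {
        t: biomarker.build_recurrence(
            de_results, t, expected_groups=[(tp, a) for a, tp in design.exposure_groups]
        )
        for t in design.tissues
    }
    mono = {}
    for t in design.tissues:
        # dose-response of the planted monotone gene at the last timepoint
        tp = config.timepoints_months[-1]
        lfcs = [
            de_results[(t, tp, a)]
            .set_index("gene")
            .loc["mono_planted", "log2_ratio"]
            for a in config.activities_MBq
        ]
        score = biomarker.dose_response_score(lfcs)
        mono[t] = {"rho": score.rho, "monotone": score.monotone}
    return {
        "design": design,
        "effects": effects,
        "de_results": de_results,
        "recurrence": rec,
        "significant_counts": sig_counts,
        "monotone_gene_dose_response": mono,
    }


def stage_fixture_biomarkers(config: PipelineConfig, cat: biomarker.MarkerCatalogue) -> dict:
    out: dict = {"marker_unique_count": {}, "cdkn1a_recurrence": {}, "top_regulator": {}}
    regmap = biomarker.RegulatorMap.load()
    for tissue in ("cortex", "medulla"):
        m = biomarker.recurrence_from_catalogue(cat, tissue)
        _, unique = biomarker.marker_overlap(m, cat, tissue)
        out["marker_unique_count"][tissue] = unique
        out["cdkn1a_recurrence"][tissue] = {
            "count": biomarker.recurrence_count(m, "Cdkn1a"),
            "of": m.n_groups,
        }
        recurrent = set(m.table.index[m.table.notna().sum(axis=1) >= 2])
        enr = biomarker.regulator_enrichment(
            recurrent | {"C3", "Dbp", "Per2", "Actb"},
            regmap,
            tissue,
            universe_size=max(1000, config.n_null_genes),
        )
        out["top_regulator"][tissue] = str(enr["regulator"].iloc[0])
    panel = cat.panel("cortex")
    row = panel[(panel["gene"] == "Cdkn1a") & (panel["timepoint_months"] == 12)]
    lfcs = row.sort_values("activity_MBq")["log2_ratio"].tolist()
    out["cdkn1a_cortex_12mo_spearman_rho"] = biomarker.dose_response_score(lfcs).rho
    return out


def stage_scintigraphy(config: PipelineConfig) -> dict:
    geometry = synthetic.FrameGeometry()
    seeds = {
        "kidneys": tuple(
            (int(r), int(c)) for r, c in geometry.kidney_centers
        ),
        "bladder": (
            int(geometry.bladder_center[0]),
            int(geometry.bladder_center[1]),
        ),
        "syringe": (
            (geometry.syringe_rows[0] + geometry.syringe_rows[1]) // 2,
            (geometry.syringe_cols[0] + geometry.syringe_cols[1]) // 2,
        ),
    }
    out = {"bladder_at_27_5": {}, "kidney_renogram": {}}
    for i, (act, imp) in enumerate(sorted(IMPAIRMENT_BY_ACTIVITY.items())):
        kin = synthetic.RenalKinetics(impairment_factor=imp)
        frames = synthetic.gen_scintigraphy_series(
            kin, geometry, scintigraphy.DTPA_PROTOCOL_TIMES_MIN, seed=config.seed + 101 + i
        )
        ren = scintigraphy.build_renogram(
            frames,
            seeds["kidneys"],
            seeds["bladder"],
            seeds["syringe"],
            threshold_frac=config.roi_frac,
        )
        key = f"{act:g}MBq"
        out["bladder_at_27_5"][key] = float(ren.bladder_at_27_5)
        out["kidney_renogram"][key] = [float(x) for x in ren.kidney_percent_ia]
    out["frame_times_min"] = list(scintigraphy.DTPA_PROTOCOL_TIMES_MIN)
    return out


def stage_blood(config: PipelineConfig) -> dict:
    table = biomarker.load_blood_effect_table()
    cells = {
        "wbc_30MBq_4mo": (16.0, 4.0, "wbc"),
        "wbc_90MBq_4mo": (40.0, 4.0, "wbc"),
        "wbc_150MBq_4mo": (54.0, 4.0, "wbc"),
        "urea_150MBq_12mo": (54.0, 12.0, "urea"),
    }
    out = {}
    for i, (key, (dose, tp, analyte)) in enumerate(sorted(cells.items())):
        test, ctrl = synthetic.gen_blood_panel(
            dose, tp, table, seed=config.seed + 211 + i, n=50
        )
        ratios = blood.derive_ratios(test, ctrl).set_index("analyte")
        out[key] = {
            "percent_of_control": float(ratios.loc[analyte, "percent_of_control"]),
            "reduction_factor": float(ratios.loc[analyte, "reduction_factor"]),
            "fold_int": int(ratios.loc[analyte, "fold_int"]),
        }
    return out


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report bundle (no files written)."""
    cat = biomarker.MarkerCatalogue.load()
    bundle: dict = {"config": dataclasses.asdict(config)}
    log.info("stage: dosimetry")
    dose = stage_dosimetry(config)
    log.info("stage: expression + differential expression")
    expr = stage_expression(config, cat)
    log.info("stage: fixture biomarkers")
    fixture = stage_fixture_biomarkers(config, cat)
    log.info("stage: scintigraphy")
    scinti = stage_scintigraphy(config)
    log.info("stage: blood")
    blood_out = stage_blood(config)
    bundle.update(
        dose={"dose_Gy": dose["dose_Gy"], "tia_MBq_h": dose["tia_MBq_h"]},
        expression=expr,
        fixture=fixture,
        scintigraphy=scinti,
        blood=blood_out,
    )
    bundle["summary"] = make_summary(bundle)
    return bundle


def make_summary(bundle: dict) -> dict:
    """Headline numbers with provenance pointers to stage outputs."""
    fx = bundle["fixture"]
    return {
        "marker_unique_count_cortex": fx["marker_unique_count"]["cortex"],
        "marker_unique_count_medulla": fx["marker_unique_count"]["medulla"],
        "cdkn1a_recurrence_cortex": fx["cdkn1a_recurrence"]["cortex"]["count"],
        "cdkn1a_recurrence_medulla": fx["cdkn1a_recurrence"]["medulla"]["count"],
        "cdkn1a_cortex_12mo_spearman_rho": fx["cdkn1a_cortex_12mo_spearman_rho"],
        "dose_Gy": bundle["dose"]["dose_Gy"],
        "bladder_percent_ia_at_27_5_min": bundle["scintigraphy"]["bladder_at_27_5"],
        "blood": bundle["blood"],
        "provenance": {
            "marker_unique_count_*": "fixture stage / table1_markers.tsv",
            "cdkn1a_recurrence_*": "fixture stage / table1_markers.tsv",
            "dose_Gy": "dosimetry stage (calibrated uptake model)",
            "bladder_percent_ia_at_27_5_min": "scintigraphy stage renograms",
            "blood": "blood stage synthetic panels / table3_ratios.tsv",
        },
    }


def write_report(bundle: dict, outdir) -> list[Path]:
    """Write summary JSON, markdown report, and TSV artifacts; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(bundle["summary"], indent=1, sort_keys=True))
    written.append(summary_path)

    dose_df = pd.DataFrame(
        {
            "activity_MBq": list(bundle["dose"]["dose_Gy"]),
            "dose_Gy": list(bundle["dose"]["dose_Gy"].values()),
            "tia_MBq_h": list(bundle["dose"]["tia_MBq_h"].values()),
        }
    )
    p = outdir / "dose_table.tsv"
    dose_df.to_csv(p, sep="\t", index=False)
    written.append(p)

    if "expression" in bundle:
        de = pd.concat(
            {
                f"{t}|{tp:g}|{a:g}": df
                for (t, tp, a), df in bundle["expression"]["de_results"].items()
            },
            names=["group"],
        ).reset_index(level=0)
        p = outdir / "de_results.tsv"
        de.to_csv(p, sep="\t", index=False)
        written.append(p)

    cfg = bundle["config"]
    lines = [
        "# renomark pipeline report",
        "",
        "## Run parameters",
        f"- seed: {cfg['seed']}",
        f"- thresholds: q_max={cfg['q_max']}, lfc_min={cfg['lfc_min']}, "
        f"roi_frac={cfg['roi_frac']}, alpha={cfg['alpha']}",
        "",
        "## Dosimetry",
        *(
            f"- {a:g} MBq -> {d:.1f} Gy"
            for a, d in bundle["dose"]["dose_Gy"].items()
        ),
        "",
        "## Transcripts (fixture panel)",
        f"- unique marker genes: cortex {bundle['summary']['marker_unique_count_cortex']}, "
        f"medulla {bundle['summary']['marker_unique_count_medulla']}",
        f"- Cdkn1a recurrence: cortex {bundle['summary']['cdkn1a_recurrence_cortex']}/15, "
        f"medulla {bundle['summary']['cdkn1a_recurrence_medulla']}/15",
        "",
        "## Scintigraphy",
        *(
            f"- bladder %IA at 27.5 min, {k}: {v:.2f}"
            for k, v in bundle["summary"]["bladder_percent_ia_at_27_5_min"].items()
        ),
        "",
        "## Blood",
        *(
            f"- {k}: {v['percent_of_control']:.0f}% of control "
            f"(reduction factor {v['reduction_factor']:.1f}, {v['fold_int']}-fold)"
            for k, v in bundle["summary"]["blood"].items()
        ),
        "",
    ]
    p = outdir / "report.md"
    p.write_text("\n".join(lines))
    written.append(p)
    return written
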