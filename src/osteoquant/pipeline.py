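"""End-to-end orchestration: simulate raw data, run each analysis stage,
merge the cohort table, and produce the study report.

The inter-stage contract is a set of CSV files under one output directory;
the merged long-format cohort table feeds the statistics stage.  Every stage
is deterministic given the config seed, and every output carries the config
hash in the report provenance block.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import flexural as FX
from . import geometry as G
from . import indentation as IN
from . import io as qio
from . import raman as RM
from . import stats as ST
from .config import PipelineConfig, config_hash, dump_config
from .synthetic import (
    BendingTruth,
    CohortSpec,
    GeometryTruth,
    IndentationTruth,
    SpectrumTruth,
    gen_bending_curve,
    gen_cohort,
    gen_cross_section,
    gen_indentation_curve,
    gen_raman_spectrum,
)
from .synthetic.raman import default_bands

log = logging.getLogger("osteoquant")

MOUSE_OUTCOMES = [
    "Tt_Ar", "Ct_Ar", "Ma_Ar", "Ct_Th", "I_min", "I_max", "c", "Ct_Po", "Ct_TMD",
]
FLEX_OUTCOMES = ["stiffness", "max_moment", "post_yield_displacement", "work_to_fracture"]


def _indenter_constants(cfg: PipelineConfig) -> IN.IndenterConstants:
    s = cfg.indenter
    return IN.IndenterConstants(
        epsilon=s.epsilon, beta=s.beta, E_indenter=s.E_indenter_GPa,
        nu_indenter=s.nu_indenter, nu_sample=s.nu_sample,
    )


def _bending_config(cfg: PipelineConfig) -> FX.BendingConfig:
    s = cfg.bending
    return FX.BendingConfig(
        span=s.span_mm, preload=s.preload_N,
        failure_drop_fraction=s.failure_drop_fraction,
        yield_secant_fraction=s.yield_secant_fraction,
        stiffness_window_fraction=s.stiffness_window_fraction,
    )


def _es_to_er(e_s: float, cfg: PipelineConfig) -> float:
    s = cfg.indenter
    return 1.0 / (
        (1.0 - s.nu_sample**2) / e_s
        + (1.0 - s.nu_indenter**2) / s.E_indenter_GPa
    )


# ------------------------------------------------------------------ simulate

def run_simulate(cfg: PipelineConfig, outdir) -> Path:
    """Generate the full synthetic dataset under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config_used.yaml")
    rng_base = cfg.seed

    spec = CohortSpec(
        n_per_group={
            "C57Bl/6J": cfg.simulate.n_control,
            "TallyHO": cfg.simulate.n_diabetic,
        },
        points_per_region=cfg.simulate.points_per_region,
        seed=cfg.seed,
    )
    cohort = gen_cohort(spec)
    cdir = out / "cohort"
    cdir.mkdir(exist_ok=True)
    cohort.mice.to_csv(cdir / "mice.csv", index=False)
    cohort.glucose.to_csv(cdir / "glucose.csv", index=False)
    cohort.points.to_csv(cdir / "points.csv", index=False)

    gdir = out / "geometry"
    bdir = out / "bending"
    idir = out / "indent"
    rdir = out / "raman"
    for d in (gdir, bdir, idir, rdir):
        d.mkdir(exist_ok=True)

    base_metrics = SpectrumTruth().true_metrics
    indent_manifest = []
    raman_manifest = []
    for mi, row in cohort.mice.iterrows():
        mouse = row["mouse"]
        seed_m = rng_base * 100_003 + mi

        # --- geometry: elliptical annulus matching the drawn areas
        rho = 0.85
        a = float(np.sqrt(row["Tt_Ar"] / (np.pi * rho)))
        ai = float(np.sqrt(row["Ma_Ar"] / (np.pi * rho)))
        gt = GeometryTruth(
            outer_semi_axes=(a, rho * a),
            inner_semi_axes=(ai, rho * ai),
            pore_fraction=max(0.0, row["Ct_Po"] / 100.0),
            voxel_size=cfg.simulate.voxel_size,
        )
        grid, labels, gt = gen_cross_section(gt, seed=seed_m, n_slices=cfg.simulate.n_slices)
        qio.write_voxel_tiff(gdir / f"{mouse}.tif", grid)
        qio.write_truth_json(
            gdir / f"{mouse}.truth.json",
            {
                "outer_semi_axes": gt.outer_semi_axes,
                "inner_semi_axes": gt.inner_semi_axes,
                "pore_fraction": gt.pore_fraction,
                "voxel_size": gt.voxel_size,
                "true_areas": gt.true_areas,
                "true_moments": gt.true_moments,
                "true_c": gt.true_c,
            },
        )

        # --- bending
        f_ult = 4.0 * row["max_moment"] / cfg.bending.span_mm
        bt = BendingTruth(
            stiffness=row["stiffness"],
            yield_force=0.92 * f_ult,
            ultimate_force=f_ult,
            post_yield_displacement=max(row["post_yield_displacement"], 0.01),
            span=cfg.bending.span_mm,
            noise_sd=cfg.simulate.bending_noise_sd,
        )
        curve, bt = gen_bending_curve(bt, seed=seed_m)
        qio.write_curve_csv(bdir / f"{mouse}.csv", curve.displacement, curve.force)
        qio.write_truth_json(
            bdir / f"{mouse}.truth.json",
            {
                "stiffness": bt.stiffness,
                "ultimate_force": bt.ultimate_force,
                "post_yield_displacement": bt.post_yield_displacement,
                "yield_displacement": bt.yield_displacement,
                "work_to_fracture": bt.work_to_fracture,
            },
        )

        # --- per-point modalities
        points = cohort.points[cohort.points["mouse"] == mouse]
        for pi, prow in points.reset_index(drop=True).iterrows():
            tag = f"{mouse}_{prow['quadrant']}_{prow['region']}_{pi}"
            it = IndentationTruth(
                reduced_modulus=_es_to_er(prow["E_s"], cfg),
                hardness=prow["H"],
                noise_sd=cfg.simulate.indent_noise_sd,
            )
            icurve, irec = gen_indentation_curve(it, seed=seed_m * 1009 + pi)
            qio.write_indent_csv(idir / f"{tag}.csv", icurve.time, icurve.depth, icurve.load)
            indent_manifest.append(
                {
                    "file": f"{tag}.csv", "mouse": mouse,
                    "quadrant": prow["quadrant"], "region": prow["region"],
                    "point": prow["point"], "microstructure": prow["microstructure"],
                    "true_E_s": prow["E_s"], "true_H": prow["H"],
                }
            )

            bands = default_bands(
                nu1_sigma=(1.0 / prow["crystallinity"]) / (2.0 * np.sqrt(2.0 * np.log(2.0))),
                mineral_scale=prow["mineral_matrix"] / base_metrics["mineral_matrix"],
            )
            st = SpectrumTruth(
                bands=bands,
                baseline_coeffs=(100.0, -80.0, 60.0, 300.0),
                noise_sd=cfg.simulate.raman_noise_sd,
            )
            spec_r, st = gen_raman_spectrum(st, step=1.0, seed=seed_m * 2003 + pi)
            qio.write_spectrum_txt(rdir / f"{tag}.txt", spec_r.wavenumber, spec_r.intensity)
            raman_manifest.append(
                {
                    "file": f"{tag}.txt", "mouse": mouse,
                    "quadrant": prow["quadrant"], "region": prow["region"],
                    "point": prow["point"], "microstructure": prow["microstructure"],
                    **{f"true_{k}": v for k, v in st.true_metrics.items()},
                }
            )
    pd.DataFrame(indent_manifest).to_csv(idir / "manifest.csv", index=False)
    pd.DataFrame(raman_manifest).to_csv(rdir / "manifest.csv", index=False)
    log.info("simulated dataset written to %s", out)
    return out


# -------------------------------------------------------------------- stages

def run_geometry(cfg: PipelineConfig, outdir) -> pd.DataFrame:
    out = Path(outdir)
    gdir = out / "geometry"
    rows = []
    for tif in sorted(gdir.glob("*.tif")):
        grid = qio.read_voxel_tiff(tif)
        mask = G.segment(grid, sigma=cfg.geometry.sigma, threshold=cfg.geometry.threshold)
        labels = G.label_compartments(mask)
        morph = G.cortical_morphometry(
            labels,
            grid.voxel_size,
            calibration=(cfg.geometry.tmd_slope, cfg.geometry.tmd_intercept),
            values=grid.values,
        )
        rows.append(
            {
                "mouse": tif.stem,
                "Tt_Ar": morph.Tt_Ar, "Ct_Ar": morph.Ct_Ar, "Ma_Ar": morph.Ma_Ar,
                "Ct_Th": morph.Ct_Th, "I_min": morph.I_min, "I_max": morph.I_max,
                "c": morph.c, "Ct_Po": morph.Ct_Po, "Ct_TMD": morph.Ct_TMD,
            }
        )
    if not rows:
        raise FileNotFoundError(f"no voxel grids found under {gdir}")
    df = pd.DataFrame(rows)
    df.to_csv(out / "morphometry.csv", index=False)
    return df


def run_bending(cfg: PipelineConfig, outdir) -> pd.DataFrame:
    out = Path(outdir)
    bdir = out / "bending"
    bc = _bending_config(cfg)
    morph_path = out / "morphometry.csv"
    imin = {}
    if morph_path.exists():
        m = pd.read_csv(morph_path)
        imin = dict(zip(m["mouse"], m["I_min"]))
    rows = []
    for csv in sorted(bdir.glob("*.csv")):
        df = qio.read_curve_csv(csv)
        curve = FX.ForceDisplacementCurve(
            df["displacement_mm"].to_numpy(), df["force_N"].to_numpy()
        )
        props = FX.extract_properties(curve, bc, i_min=imin.get(csv.stem))
        rows.append(
            {
                "mouse": csv.stem,
                "stiffness": props.stiffness,
                "max_force": props.max_force,
                "max_moment": props.max_moment,
                "yield_displacement": props.yield_displacement,
                "failure_displacement": props.failure_displacement,
                "post_yield_displacement": props.post_yield_displacement,
                "work_to_fracture": props.work_to_fracture,
                "tissue_modulus": props.tissue_modulus,
                "irregular": props.irregular,
            }
        )
    if not rows:
        raise FileNotFoundError(f"no bending curves found under {bdir}")
    df = pd.DataFrame(rows)
    df.to_csv(out / "flexural.csv", index=False)
    return df


def run_indent(cfg: PipelineConfig, outdir) -> pd.DataFrame:
    out = Path(outdir)
    idir = out / "indent"
    manifest = pd.read_csv(idir / "manifest.csv")
    constants = _indenter_constants(cfg)
    af = IN.AreaFunction()
    fit_range = (cfg.indenter.fit_range_hi, cfg.indenter.fit_range_lo)
    rows = []
    for _, mrow in manifest.iterrows():
        df = qio.read_indent_csv(idir / mrow["file"])
        res = IN.analyze_curve(
            df["time_s"].to_numpy(), df["depth_nm"].to_numpy(),
            df["load_uN"].to_numpy(), af, constants, fit_range=fit_range,
        )
        rows.append(
            {
                "mouse": mrow["mouse"], "quadrant": mrow["quadrant"],
                "region": mrow["region"], "point": mrow["point"],
                "microstructure": mrow["microstructure"],
                "E_r_GPa": res.E_r, "E_s_GPa": res.E_s, "H_GPa": res.H,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "indent_results.csv", index=False)
    return df


def run_raman(cfg: PipelineConfig, outdir) -> pd.DataFrame:
    out = Path(outdir)
    rdir = out / "raman"
    manifest = pd.read_csv(rdir / "manifest.csv")
    rows = []
    for _, mrow in manifest.iterrows():
        wn, inten = qio.read_spectrum_txt(rdir / mrow["file"])
        spec = RM.RamanSpectrum(wn, inten)
        spec = RM.truncate(spec, cfg.raman.truncate_lo, cfg.raman.truncate_hi)
        corrected, _ = RM.rcf_baseline(
            spec,
            radius=cfg.raman.rcf_radius,
            iterations=cfg.raman.rcf_iterations,
            intensity_fraction=cfg.raman.rcf_intensity_fraction,
            smooth_sigma=cfg.raman.rcf_smooth_sigma,
        )
        metrics = RM.compute_metrics(corrected)
        rows.append(
            {
                "mouse": mrow["mouse"], "quadrant": mrow["quadrant"],
                "region": mrow["region"], "point": mrow["point"],
                "microstructure": mrow["microstructure"],
                "mineral_matrix": metrics.mineral_matrix,
                "carbonate_phosphate": metrics.carbonate_phosphate,
                "crystallinity": metrics.crystallinity,
                "collagen_maturity": metrics.collagen_maturity,
                "pen_ratio": metrics.pen_ratio,
                "pen_snr_flag": metrics.pen_snr_flag,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "raman_metrics.csv", index=False)
    return df


# --------------------------------------------------------------------- stats

def build_mouse_table(outdir) -> pd.DataFrame:
    """Merge per-mouse outputs of every stage with the cohort covariates."""
    out = Path(outdir)
    mice = pd.read_csv(out / "cohort" / "mice.csv")[
        ["mouse", "genotype", "body_mass", "HbA1c"]
    ]
    glucose = pd.read_csv(out / "cohort" / "glucose.csv")
    avg = (
        glucose.groupby("mouse")["glucose"]
        .mean()
        .rename("lifetime_avg_glucose")
        .reset_index()
    )
    gmin = glucose.groupby("mouse")["glucose"].min().rename("min_glucose").reset_index()
    table = mice.merge(avg, on="mouse").merge(gmin, on="mouse")
    for name in ("morphometry.csv", "flexural.csv"):
        p = out / name
        if p.exists():
            table = table.merge(pd.read_csv(p), on="mouse", how="left")
    for name, cols in (
        ("indent_results.csv", ["E_r_GPa", "E_s_GPa", "H_GPa"]),
        (
            "raman_metrics.csv",
            ["mineral_matrix", "carbonate_phosphate", "crystallinity",
             "collagen_maturity", "pen_ratio"],
        ),
    ):
        p = out / name
        if p.exists():
            per_mouse = pd.read_csv(p).groupby("mouse")[cols].mean().reset_index()
            table = table.merge(per_mouse, on="mouse", how="left")
    return table


def run_stats(cfg: PipelineConfig, outdir) -> dict:
    out = Path(outdir)
    table = build_mouse_table(out)

    # diabetic inclusion: drop TallyHO mice that lost hyperglycemia
    glucose = pd.read_csv(out / "cohort" / "glucose.csv")
    keep = ST.diabetic_inclusion_filter(
        glucose, threshold=cfg.stats.diabetic_glucose_threshold
    )
    table = table[table["mouse"].isin(keep)].reset_index(drop=True)

    # body-mass adjustment of structural outcomes (not tissue properties)
    adjustable = [c for c in MOUSE_OUTCOMES + FLEX_OUTCOMES if c in table.columns]
    adjusted = table.copy()
    for col in adjustable:
        ok = table[col].notna()
        try:
            sub = table[ok]
            adjusted.loc[ok, col] = FX.mass_adjust(
                sub[col].to_numpy(), sub["body_mass"].to_numpy(),
                sub["genotype"].to_numpy(),
            )
        except ValueError:
            log.warning("body-mass adjustment skipped for %s (too few mice)", col)

    comparisons = []
    for col in adjustable + ["HbA1c", "lifetime_avg_glucose"]:
        if col not in adjusted.columns:
            continue
        try:
            gc = ST.compare_groups(adjusted, col)
        except ValueError:
            continue
        comparisons.append(
            {
                "outcome": col,
                "mean_C57Bl6J": gc.mean_control, "sd_C57Bl6J": gc.sd_control,
                "mean_TallyHO": gc.mean_treated, "sd_TallyHO": gc.sd_treated,
                "pct_difference": gc.percent_difference_rounded,
                "U": gc.U, "p": gc.p,
            }
        )
    comp_df = pd.DataFrame(comparisons)
    comp_df.to_csv(out / "group_comparisons.csv", index=False)

    # mixed models on the unaggregated point data
    points_results = {}
    merged_points = None
    ipath, rpath = out / "indent_results.csv", out / "raman_metrics.csv"
    if ipath.exists() and rpath.exists():
        ind = pd.read_csv(ipath)
        ram = pd.read_csv(rpath)
        merged_points = ind.merge(
            ram, on=["mouse", "quadrant", "region", "point", "microstructure"]
        ).merge(table[["mouse", "genotype"]], on="mouse")
        for outcome in ("E_s_GPa", "H_GPa", "mineral_matrix", "crystallinity"):
            try:
                fit = ST.fit_lmm(merged_points, outcome)
                points_results[outcome] = {
                    "fixed_effects": fit.fixed_effects.to_dict(orient="index"),
                    "variance_components": fit.variance_components,
                    "qq_correlation": fit.qq_correlation,
                    "levene_p": fit.levene_p,
                    "converged": fit.converged,
                    "singular": fit.singular,
                }
            except Exception as exc:  # singular fits on tiny demo cohorts
                points_results[outcome] = {"error": str(exc)}

    # glucose-metric regressions (Table-4-like)
    regressions = []
    for outcome in (
        "max_moment", "stiffness", "post_yield_displacement", "work_to_fracture",
        "E_s_GPa", "H_GPa", "mineral_matrix", "carbonate_phosphate",
        "crystallinity", "collagen_maturity",
    ):
        if outcome not in table.columns:
            continue
        for xvar in ("lifetime_avg_glucose", "HbA1c"):
            sub = table.dropna(subset=[outcome, xvar])
            if len(sub) < 3:
                continue
            res = ST.linreg(sub[xvar], sub[outcome])
            regressions.append({"outcome": outcome, "predictor": xvar, **{
                k: res[k] for k in ("r", "R2", "p", "slope")
            }})
    reg_df = pd.DataFrame(regressions)
    reg_df.to_csv(out / "regressions.csv", index=False)

    # backward-AICc: ductility vs tissue composition
    selection = None
    need = ["post_yield_displacement", "crystallinity", "collagen_maturity",
            "mineral_matrix", "carbonate_phosphate"]
    if all(c in table.columns for c in need):
        sub = table.dropna(subset=need)
        if len(sub) >= 8:
            sel = ST.stepwise_aicc(
                sub, "post_yield_displacement",
                ["crystallinity", "collagen_maturity", "mineral_matrix",
                 "carbonate_phosphate"],
            )
            selection = {
                "selected": sel.selected,
                "coefficients": sel.coefficients,
                "R2": sel.R2,
                "AICc": sel.aicc,
            }

    results = {
        "group_comparisons": comparisons,
        "mixed_models": points_results,
        "regressions": regressions,
        "model_selection": selection,
        "n_mice": int(len(table)),
    }
    qio.write_truth_json(out / "stats_results.json", results)
    return results


def run_report(cfg: PipelineConfig, outdir) -> dict:
    out = Path(outdir)
    stats_path = out / "stats_results.json"
    if not stats_path.exists():
        raise FileNotFoundError(f"{stats_path} missing: run the stats stage first")
    report = qio.read_truth_json(stats_path)
    import osteoquant

    report["provenance"] = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "package_version": osteoquant.__version__,
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    qio.write_truth_json(out / "report.json", report)
    return report


STAGES = {
    "simulate": run_simulate,
    "geometry": run_geometry,
    "bending": run_bending,
    "indent": run_indent,
    "raman": run_raman,
    "stats": run_stats,
    "report": run_report,
}


def run_full(cfg: PipelineConfig, outdir) -> dict:
    run_simulate(cfg, outdir)
    run_geometry(cfg, outdir)
    run_bending(cfg, outdir)
    run_indent(cfg, outdir)
    run_raman(cfg, outdir)
    run_stats(cfg, outdir)
    return run_report(cfg, outdir)
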