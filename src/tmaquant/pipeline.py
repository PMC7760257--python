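"""End-to-end orchestration: simulate -> segment -> quantify -> stratify -> report.

The pipeline reproduces, on synthetic data with known ground truth, the
analysis structure of an epithelial-restricted TMA immunofluorescence
study: per-marker paired tumor/normal comparisons, ROC- or median-based
high/low stratification with Kaplan-Meier / log-rank / Cox survival
analysis in the epithelial and stromal compartments, stage-adjusted Cox
models for the profile markers, stage and immune-infiltrate associations,
the combined two-marker protein profile, and a cohort summary table.
Everything is seeded and deterministic given the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantify as tq
from . import segment as tseg
from . import simulate as tsim
from . import stats as tst

__all__ = [
    "SegmentationConfig",
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "write_report",
    "analyze_cohort",
    "measure_cohort",
    "latent_values",
    "config_hash",
    "load_config",
    "save_config",
    "STAGE_GROUPS",
    "TABLE_NAMES",
]

logger = logging.getLogger("tmaquant")

# markers stratified by ROC-derived cutoffs in the epithelium; the rest use
# the median split.  Stromal stratification defaults to ROC.
ROC_EPITHELIAL_MARKERS = ("NLRP6", "CASP1", "IL18")

TABLE_NAMES = (
    "paired_tests",
    "survival_by_marker",
    "adjusted_cox",
    "stage_assoc",
    "infiltrate_assoc",
    "profile",
    "cohort_summary",
)


def stage_group(stage: str) -> str:
    """Collapse TNM stage to I-II (local), III (regional), IV (metastatic)."""
    return "I-II" if stage in ("I", "II") else stage


STAGE_GROUPS = ("I-II", "III", "IV")


@dataclass
class SegmentationConfig:
    threshold_method: str | float = "otsu"
    min_area_px: int = 15
    smoothing_sigma: float = 0.5
    min_peak_distance: int = 2
    expansion_radius_px: float = 6.0


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``use_images`` selects whether per-patient marker values come from the
    imaging path (render spots, segment, quantify, aggregate) or directly
    from the generator's latent values (fast path for cohort-scale
    statistics).  ``segmentation_source="ground_truth"`` runs the imaging
    path but injects the ground-truth nuclei and epithelial mask, isolating
    quantification from segmentation error.
    """

    sim: tsim.SimulationParams = field(default_factory=tsim.SimulationParams)
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    seed: int = 0
    use_images: bool = True
    segmentation_source: str = "image"  # "image" | "ground_truth"
    cutoff_methods: dict = field(default_factory=dict)  # (marker, compartment) -> method
    horizon_months: float = 60.0
    make_plots: bool = False

    def cutoff_method(self, marker: str, compartment: str) -> str:
        if (marker, compartment) in self.cutoff_methods:
            return self.cutoff_methods[(marker, compartment)]
        if compartment == "epithelial":
            return "roc_youden" if marker in ROC_EPITHELIAL_MARKERS else "median"
        return "roc_youden"

    def validate(self) -> None:
        self.sim.validate()
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.segmentation_source not in ("image", "ground_truth"):
            raise ValueError("segmentation_source must be 'image' or 'ground_truth'")
        m1, m2 = self.sim.profile_markers
        for m in (m1, m2):
            if m not in self.sim.markers:
                raise ValueError(f"profile marker {m!r} not in simulated markers")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    manifest: dict
    cohort: pd.DataFrame | None = None
    values: pd.DataFrame | None = None
    km_curves: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# marker-value acquisition


def latent_values(cohort: pd.DataFrame, markers) -> pd.DataFrame:
    """Patient marker values straight from the generator's latent columns."""
    rows = []
    for m in markers:
        for _, r in cohort.iterrows():
            rows.append(
                {
                    "patient_id": r["patient_id"],
                    "marker": m,
                    "tumor_epithelial": r[f"{m}_tumor_epithelial"],
                    "normal_epithelial": r[f"{m}_normal_epithelial"],
                    "tumor_stromal": r[f"{m}_tumor_stromal"],
                }
            )
    return pd.DataFrame(rows)


def _segment_spot(spot: tsim.SpotImage, seg: SegmentationConfig,
                  source: str, params: tsim.SimulationParams):
    tissue = tsim.spot_tissue_mask(params)
    if source == "ground_truth":
        nuclei = tseg.nuclei_from_centers(
            spot.ground_truth.nuclei_centers, spot.shape, params.nucleus_radius_px
        )
        cells = tseg.segment_cells(nuclei, seg.expansion_radius_px)
        cells = np.where(tissue, cells, 0)
        ck_mask = spot.ground_truth.epithelial_mask
    else:
        nuclei = tseg.segment_nuclei(
            spot.channels["dapi"],
            min_area_px=seg.min_area_px,
            threshold_method=seg.threshold_method,
            smoothing_sigma=seg.smoothing_sigma,
            min_peak_distance=seg.min_peak_distance,
        )
        cells = tseg.segment_cells(nuclei, seg.expansion_radius_px)
        cells = np.where(tissue, cells, 0)
        ck_mask = tseg.make_cytokeratin_mask(spot.channels["ck"], cells)
    return nuclei, cells, ck_mask


def measure_cohort(
    cohort: pd.DataFrame,
    params: tsim.SimulationParams,
    seg: SegmentationConfig,
    master_seed: int,
    segmentation_source: str = "image",
    markers=None,
) -> pd.DataFrame:
    """Render, segment and quantify every spot of every patient.

    Returns the tidy patient-marker-value table (one row per patient and
    marker) measured from images; per-spot seeds derive from
    ``master_seed`` via the documented counter scheme.
    """
    markers = tuple(markers) if markers is not None else params.markers
    rows = []
    n_done = 0
    for pi, pid in enumerate(cohort["patient_id"]):
        record = tsim.patient_record(cohort, pid)
        for mi, marker in enumerate(markers):
            spots = []
            for kind, count in (("tumor", params.n_tumor_spots),
                                ("normal", params.n_normal_spots)):
                for si in range(count):
                    seed = tsim.spot_seed(master_seed, pi, mi, kind, si)
                    spot = tsim.generate_spot_image(record, marker, kind, si, params, seed)
                    nuclei, cells, ck_mask = _segment_spot(
                        spot, seg, segmentation_source, params
                    )
                    summary, _ = tq.quantify_spot(
                        spot.channels["marker"], nuclei, cells, ck_mask,
                        patient_id=pid, tissue_kind=kind, spot_index=si, marker=marker,
                    )
                    spots.append(summary)
                    n_done += 1
                    if n_done % 100 == 0:
                        logger.info("quantified %d spots", n_done)
            agg = tq.aggregate_patient(spots)
            rows.append(
                {
                    "patient_id": pid,
                    "marker": marker,
                    "tumor_epithelial": agg.tumor_epithelial,
                    "normal_epithelial": agg.normal_epithelial,
                    "tumor_stromal": agg.tumor_stromal,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistical report


def _safe_assoc(values, labels, kind: str) -> tst.TestResult:
    """Group association that degrades to a NaN result (with a warning) when
    the grouping is degenerate, e.g. one level only in a tiny cohort."""
    try:
        return tst.group_assoc(values, labels, kind=kind)
    except ValueError as exc:
        logger.warning("association skipped: %s", exc)
        return tst.TestResult(float("nan"), float("nan"), "degenerate",
                              len(values), degenerate=True)


def _values_wide(values: pd.DataFrame) -> pd.DataFrame:
    wide = values.pivot(index="patient_id", columns="marker")
    wide.columns = [f"{marker}_{col}" for col, marker in wide.columns]
    return wide.reset_index()


def _survival_row(config: RunConfig, data: pd.DataFrame, marker: str,
                  compartment: str, km_store: dict) -> dict:
    col = "tumor_epithelial" if compartment == "epithelial" else "tumor_stromal"
    sub = data.dropna(subset=[f"{marker}_{col}"])
    vals = sub[f"{marker}_{col}"].to_numpy(dtype=float)
    times = sub["time_months"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=bool)

    method = config.cutoff_method(marker, compartment)
    if method == "roc_youden":
        model = tst.roc_cutoff(vals, events, marker=marker, compartment=compartment)
    elif method == "median":
        model = tst.median_cutoff(vals, marker=marker, compartment=compartment)
    else:
        raise ValueError(f"unknown cutoff method {method!r}")
    groups = model.stratify(vals)
    row = {
        "marker": marker,
        "compartment": compartment,
        "cutoff_method": model.method,
        "cutoff": model.cutoff,
        "auc": model.auc if model.auc is not None else np.nan,
        "n_low": int((groups == "low").sum()),
        "n_high": int((groups == "high").sum()),
    }
    if len(np.unique(groups)) < 2:
        logger.warning("degenerate stratification for %s/%s", marker, compartment)
        row.update(
            logrank_chi2=np.nan, logrank_p=np.nan, hr_low_vs_high=np.nan,
            hr_ci_low=np.nan, hr_ci_high=np.nan, cox_p=np.nan,
            surv_horizon_low=np.nan, surv_horizon_high=np.nan, degenerate=True,
        )
        return row
    lr = tst.logrank_test(times, events, groups)
    low = (groups == "low").astype(float)
    cox = tst.cox_fit(times, events, pd.DataFrame({"low": low}))
    curves = {
        g: tst.km_estimate(times[groups == g], events[groups == g])
        for g in ("low", "high")
    }
    km_store[(marker, compartment)] = curves
    row.update(
        logrank_chi2=lr.statistic,
        logrank_p=lr.p_value,
        hr_low_vs_high=cox.hazard_ratio,
        hr_ci_low=cox.ci95[0],
        hr_ci_high=cox.ci95[1],
        cox_p=cox.p_value,
        surv_horizon_low=curves["low"].survival_at(config.horizon_months),
        surv_horizon_high=curves["high"].survival_at(config.horizon_months),
        degenerate=False,
    )
    return row


def analyze_cohort(cohort: pd.DataFrame, values: pd.DataFrame,
                   config: RunConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Produce the seven report tables from a cohort and its marker values."""
    markers = config.sim.markers
    m1, m2 = config.sim.profile_markers
    data = cohort.merge(_values_wide(values), on="patient_id", suffixes=("_latent", ""))
    km_store: dict = {}

    # (1) paired tumor vs normal epithelial intensity, per marker
    paired_rows = []
    for m in markers:
        sub = data.dropna(subset=[f"{m}_tumor_epithelial", f"{m}_normal_epithelial"])
        t = sub[f"{m}_tumor_epithelial"].to_numpy(dtype=float)
        nrm = sub[f"{m}_normal_epithelial"].to_numpy(dtype=float)
        res = tst.paired_compare(t, nrm, method="auto")
        paired_rows.append(
            {
                "marker": m,
                "n_pairs": t.size,
                "mean_tumor": t.mean(),
                "mean_normal": nrm.mean(),
                "direction": "tumor<normal" if t.mean() < nrm.mean() else "tumor>=normal",
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )

    # (2) per-marker stratified survival, epithelial and stromal
    survival_rows = [
        _survival_row(config, data, m, "epithelial", km_store) for m in markers
    ]
    survival_rows += [
        _survival_row(config, data, m, "stromal", km_store) for m in (m1, m2)
    ]
    survival = pd.DataFrame(survival_rows)

    # strata reused below: epithelial high/low per marker from the fitted cutoffs
    strata: dict[str, np.ndarray] = {}
    for m in markers:
        row = survival[(survival["marker"] == m) & (survival["compartment"] == "epithelial")]
        cutoff = float(row["cutoff"].iloc[0])
        strata[m] = np.where(
            data[f"{m}_tumor_epithelial"].to_numpy(dtype=float) > cutoff, "high", "low"
        )

    # (3) stage-adjusted Cox for the profile markers
    times = data["time_months"].to_numpy(dtype=float)
    events = data["event"].to_numpy(dtype=bool)
    sgroups = data["stage"].map(stage_group)
    adj_rows = []
    for m in (m1, m2):
        cov = pd.DataFrame(
            {
                f"{m}_low": (strata[m] == "low").astype(float),
                "stage_III": (sgroups == "III").astype(float).to_numpy(),
                "stage_IV": (sgroups == "IV").astype(float).to_numpy(),
            }
        )
        fit = tst.cox_fit(times, events, cov, focus=f"{m}_low")
        adj_rows.append(
            {
                "marker": m,
                "hr_low_vs_high": fit.hazard_ratio,
                "hr_ci_low": fit.ci95[0],
                "hr_ci_high": fit.ci95[1],
                "p_value": fit.p_value,
                "adjustment": "stage I-II/III/IV",
                "n": fit.n,
                "n_events": fit.n_events,
            }
        )

    # (4) marker intensity vs stage group
    stage_rows = []
    for m in markers:
        comps = ("epithelial", "stromal") if m in (m1, m2) else ("epithelial",)
        for comp in comps:
            col = "tumor_epithelial" if comp == "epithelial" else "tumor_stromal"
            vals = data[f"{m}_{col}"].to_numpy(dtype=float)
            res = _safe_assoc(vals, sgroups.to_numpy(), "multi_group")
            stage_rows.append(
                {"marker": m, "compartment": comp, "method": res.method,
                 "statistic": res.statistic, "p_value": res.p_value, "n": res.n}
            )

    # (5) marker intensity vs immune infiltrates and checkpoint status
    infil_rows = []
    for m in markers:
        vals = data[f"{m}_tumor_epithelial"].to_numpy(dtype=float)
        for cell in tsim.INFILTRATE_TYPES:
            res = _safe_assoc(vals, data[cell].to_numpy(), "multi_group")
            infil_rows.append(
                {"marker": m, "covariate": cell, "method": res.method,
                 "statistic": res.statistic, "p_value": res.p_value, "n": res.n}
            )
        for flag in ("pd1_positive", "pdl1_positive"):
            res = _safe_assoc(vals, data[flag].to_numpy(), "two_group")
            infil_rows.append(
                {"marker": m, "covariate": flag, "method": res.method,
                 "statistic": res.statistic, "p_value": res.p_value, "n": res.n}
            )

    # (6) combined protein profile: survival, stage, infiltrates
    profile = tst.combine_profiles(strata[m1], strata[m2])
    concordant = (profile == "high/high") | (profile == "low/low")
    prof_row: dict = {
        "marker_pair": f"{m1}/{m2}",
        "n_high_high": int((profile == "high/high").sum()),
        "n_low_low": int((profile == "low/low").sum()),
        "n_mixed": int((profile == "mixed").sum()),
    }
    if prof_row["n_high_high"] and prof_row["n_low_low"]:
        pt, pe, pg = times[concordant], events[concordant], profile[concordant]
        lr = tst.logrank_test(pt, pe, pg.astype(str))
        cox = tst.cox_fit(
            pt, pe, pd.DataFrame({"low_low": (pg == "low/low").astype(float)})
        )
        curves = {
            g: tst.km_estimate(pt[pg == g], pe[pg == g])
            for g in ("high/high", "low/low")
        }
        km_store[("profile", "epithelial")] = curves
        stage_tab = pd.crosstab(pg, sgroups[concordant]).reindex(
            index=["high/high", "low/low"], columns=list(STAGE_GROUPS), fill_value=0
        )
        stage_test = tst.categorical_assoc(stage_tab.to_numpy())
        prof_row.update(
            logrank_chi2=lr.statistic,
            logrank_p=lr.p_value,
            hr_low_low=cox.hazard_ratio,
            hr_ci_low=cox.ci95[0],
            hr_ci_high=cox.ci95[1],
            cox_p=cox.p_value,
            surv_horizon_high_high=curves["high/high"].survival_at(config.horizon_months),
            surv_horizon_low_low=curves["low/low"].survival_at(config.horizon_months),
            stage_chi2=stage_test.statistic,
            stage_p=stage_test.p_value,
        )
        for cell in tsim.INFILTRATE_TYPES:
            tab = pd.crosstab(pg, data.loc[concordant, cell]).reindex(
                index=["high/high", "low/low"],
                columns=list(tsim.INFILTRATE_GRADES),
                fill_value=0,
            )
            res = tst.categorical_assoc(tab.to_numpy())
            prof_row[f"{cell.lower()}_chi2"] = res.statistic
            prof_row[f"{cell.lower()}_p"] = res.p_value

    # (7) cohort summary (counts and one-decimal percentages)
    n = len(data)
    summary_rows = []

    def _cat(characteristic: str, series: pd.Series, levels) -> None:
        for lv in levels:
            c = int((series == lv).sum())
            summary_rows.append(
                {"characteristic": characteristic, "level": str(lv),
                 "count": c, "percent": tst.percent_summary(c, n)}
            )

    _cat("sex", data["sex"], ("M", "F"))
    _cat("stage", data["stage"], tsim.STAGES)
    _cat("grade", data["grade"], sorted(data["grade"].unique()))
    _cat("msi", data["msi"], ("MSS", "MSI"))
    _cat("kras", data["kras"], (True,))
    _cat("braf", data["braf"], (True,))
    km_all = tst.km_estimate(times, events)
    summary_rows.append(
        {
            "characteristic": f"survival_at_{config.horizon_months:g}_months",
            "level": "all",
            "count": n,
            "percent": round(100.0 * km_all.survival_at(config.horizon_months), 1),
        }
    )

    tables = {
        "paired_tests": pd.DataFrame(paired_rows),
        "survival_by_marker": survival,
        "adjusted_cox": pd.DataFrame(adj_rows),
        "stage_assoc": pd.DataFrame(stage_rows),
        "infiltrate_assoc": pd.DataFrame(infil_rows),
        "profile": pd.DataFrame([prof_row]),
        "cohort_summary": pd.DataFrame(summary_rows),
    }
    return tables, km_store


# ---------------------------------------------------------------------------
# configuration plumbing and reporting


def _config_payload(config: RunConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["sim"]["markers"] = list(config.sim.markers)
    payload["sim"]["profile_markers"] = list(config.sim.profile_markers)
    payload["sim"]["infiltrate_probs_by_group"] = {
        g: {c: list(p) for c, p in by_cell.items()}
        for g, by_cell in config.sim.infiltrate_probs_by_group.items()
    }
    payload["cutoff_methods"] = {
        f"{m}:{c}": v for (m, c), v in config.cutoff_methods.items()
    }
    return tsim._to_builtin(payload)


def config_hash(config: RunConfig) -> str:
    text = yaml.safe_dump(_config_payload(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_config_payload(config), sort_keys=True))
    return path


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    sim_payload = payload.pop("sim", {})
    if "intensity_models" in sim_payload:
        sim_payload["intensity_models"] = {
            m: tsim.MarkerModel(**mod)
            for m, mod in sim_payload["intensity_models"].items()
        }
    if "infiltrate_probs_by_group" in sim_payload:
        sim_payload["infiltrate_probs_by_group"] = {
            g: {c: tuple(p) for c, p in by_cell.items()}
            for g, by_cell in sim_payload["infiltrate_probs_by_group"].items()
        }
    for key in ("markers", "profile_markers"):
        if key in sim_payload:
            sim_payload[key] = tuple(sim_payload[key])
    seg_payload = payload.pop("seg", {})
    cutoffs = {
        tuple(k.split(":", 1)): v
        for k, v in payload.pop("cutoff_methods", {}).items()
    }
    return RunConfig(
        sim=tsim.SimulationParams(**sim_payload),
        seg=SegmentationConfig(**seg_payload),
        cutoff_methods=cutoffs,
        **payload,
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and return a :class:`ReportBundle`.

    Stage failures surface as exceptions naming the stage; outputs are a
    pure function of the configuration (including its seed).
    """
    config.validate()
    timings: dict[str, float] = {}
    sim_params = dataclasses.replace(config.sim, seed=config.seed)

    t0 = time.perf_counter()
    logger.info("stage simulate: cohort of %d patients", sim_params.n_patients)
    try:
        cohort = tsim.generate_cohort(sim_params)
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    timings["simulate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.use_images:
        logger.info("stage segment+quantify: imaging path (%s)",
                    config.segmentation_source)
        try:
            values = measure_cohort(
                cohort, sim_params, config.seg, config.seed,
                segmentation_source=config.segmentation_source,
            )
        except Exception as exc:
            raise RuntimeError(f"stage quantify failed: {exc}") from exc
    else:
        logger.info("stage quantify: latent-value path")
        values = latent_values(cohort, sim_params.markers)
    timings["quantify_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    logger.info("stage stratify+report: statistical tables")
    try:
        tables, km_store = analyze_cohort(cohort, values, config)
    except Exception as exc:
        raise RuntimeError(f"stage report failed: {exc}") from exc
    timings["report_s"] = time.perf_counter() - t0

    import tmaquant

    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_patients": sim_params.n_patients,
        "markers": ",".join(sim_params.markers),
        "tmaquant_version": tmaquant.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        **{k: round(v, 3) for k, v in timings.items()},
        **{f"rows_{name}": len(df) for name, df in tables.items()},
    }
    return ReportBundle(tables=tables, manifest=manifest, cohort=cohort,
                        values=values, km_curves=km_store)


def _plot_km(curves, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, km in curves.items():
        t = np.concatenate([[0.0], np.repeat(km.event_times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)[:-1]])
        ax.plot(t, s, drawstyle="default", label=f"{label} (n={km.n})")
        if km.censor_times.size:
            ax.plot(km.censor_times,
                    [km.survival_at(t_) for t_ in km.censor_times],
                    "|", color=ax.lines[-1].get_color())
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(bundle: ReportBundle, outdir: str | Path,
                 make_plots: bool = False) -> list[Path]:
    """Write one CSV per analysis table plus a plain-text run manifest.

    Table CSVs are byte-stable for identical bundles; the manifest carries
    the config hash, seed, versions and timings (timings vary run to run
    and live only here).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in sorted(bundle.tables.items()):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    if bundle.cohort is not None:
        written.append(tsim.write_cohort(bundle.cohort, outdir / "cohort.csv"))
    if bundle.values is not None:
        path = outdir / "patient_marker_values.csv"
        bundle.values.to_csv(path, index=False)
        written.append(path)
    if make_plots and bundle.km_curves:
        plot_dir = outdir / "plots"
        plot_dir.mkdir(exist_ok=True)
        for (marker, compartment), curves in bundle.km_curves.items():
            path = plot_dir / f"km_{marker.replace('/', '_')}_{compartment}.png"
            _plot_km(curves, f"{marker} ({compartment})", path)
            written.append(path)
    manifest_path = outdir / "manifest.txt"
    lines = [f"{k}: {v}" for k, v in bundle.manifest.items()]
    manifest_path.write_text("\n".join(lines) + "\n")
    written.append(manifest_path)
    return written
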