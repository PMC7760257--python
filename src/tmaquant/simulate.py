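"""Synthetic tissue-microarray cohorts and spot images with known ground truth.

This module emulates the data-generating process behind a multiplexed
immunofluorescence TMA study of colorectal cancer: each patient contributes
three tumor cores and two matched normal-mucosa cores; each core ("spot") is
imaged in three channels (DAPI nuclei, cytokeratin epithelium, one
inflammasome marker); per-patient latent marker intensities follow a
lognormal model with a configurable tumor-epithelium downregulation; and
overall survival follows an exponential hazard whose log-hazard depends on
marker-low group membership.  Every generated object carries its ground
truth so that downstream segmentation, quantification and survival fits can
be validated against known values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "MarkerModel",
    "SimulationParams",
    "GroundTruth",
    "SpotImage",
    "PatientRecord",
    "generate_cohort",
    "generate_spot_image",
    "spot_tissue_mask",
    "patient_record",
    "spot_seed",
    "write_spot",
    "read_spot",
    "write_cohort",
    "read_cohort",
    "params_to_yaml",
    "params_from_yaml",
    "DEFAULT_MARKERS",
    "INFILTRATE_TYPES",
    "STAGES",
]

DEFAULT_MARKERS = ("NLRP1", "NLRP3", "NLRP6", "AIM2", "ASC", "CASP1", "IL1B", "IL18")
INFILTRATE_TYPES = ("CD3", "CD8", "CD68", "CD163")
INFILTRATE_GRADES = ("low", "mild", "high")
STAGES = ("I", "II", "III", "IV")

# fixed rendering levels for the structural channels (16-bit scale)
DAPI_LEVEL = 20000.0
CK_EPITHELIAL_LEVEL = 15000.0
CK_STROMAL_LEVEL = 800.0
IMAGE_MARGIN_PX = 4
INTENSITY_MAX = 65535.0

# marginal probabilities for clinical covariates (cohort composition of a
# surgical colorectal series: predominantly male, elderly, MSS)
_P_MALE = 0.577
_P_MSI = 0.154
_P_KRAS = 0.183
_P_BRAF = 0.038
_GRADE_LEVELS = ("1", "1-2", "2", "3")
_GRADE_PROBS = (0.077, 0.087, 0.731, 0.077)  # renormalized at draw time
_AGE_MEAN, _AGE_SD, _AGE_MIN, _AGE_MAX = 70.0, 10.0, 38.0, 89.0
# checkpoint positivity: PD-1 tracks epithelial IL-18-high status
_P_PD1_IL18_HIGH, _P_PD1_IL18_LOW = 0.45, 0.20
_P_PDL1 = 0.30


def _default_stage_probs() -> dict[str, dict[str, float]]:
    # combined NLRP6/IL-18 profile drives stage: low/low concentrates in IV
    return {
        "high_high": {"I": 0.15, "II": 0.45, "III": 0.35, "IV": 0.05},
        "mixed": {"I": 0.08, "II": 0.35, "III": 0.36, "IV": 0.21},
        "low_low": {"I": 0.02, "II": 0.13, "III": 0.35, "IV": 0.50},
    }


def _default_infiltrate_probs() -> dict[str, dict[str, tuple[float, float, float]]]:
    # lymphoid infiltrate (CD3/CD8) is depressed in the low/low profile;
    # macrophage infiltrate (CD68/CD163) does not depend on the profile
    flat = (0.33, 0.34, 0.33)
    return {
        "high_high": {"CD3": (0.15, 0.40, 0.45), "CD8": (0.20, 0.40, 0.40),
                      "CD68": flat, "CD163": flat},
        "mixed": {"CD3": (0.30, 0.40, 0.30), "CD8": (0.33, 0.40, 0.27),
                  "CD68": flat, "CD163": flat},
        "low_low": {"CD3": (0.55, 0.30, 0.15), "CD8": (0.50, 0.35, 0.15),
                    "CD68": flat, "CD163": flat},
    }


def _default_log_hazard_ratios() -> dict[str, float]:
    # hazard-ratio effects of epithelial marker-low status
    return {
        "NLRP6_low": math.log(1.72),
        "CASP1_low": math.log(1.58),
        "IL18_low": math.log(1.68),
    }


@dataclass
class MarkerModel:
    """Lognormal intensity model for one marker, on the 16-bit scale.

    A patient-level baseline ``location * exp(N(0, between_patient_scale))``
    is shared between the tumor and normal epithelium of that patient; each
    compartment then receives an independent ``exp(N(0, within_patient_scale))``
    deviation, and the tumor epithelium is additionally multiplied by
    ``tumor_downregulation`` (a factor in (0, 1]; 1 disables the effect).
    """

    epithelial_location: float = 3000.0
    stromal_location: float = 1200.0
    between_patient_scale: float = 0.35
    within_patient_scale: float = 0.12
    tumor_downregulation: float = 0.6

    def validate(self, name: str = "marker") -> None:
        if not (0.0 < self.tumor_downregulation <= 1.0):
            raise ValueError(f"{name}: tumor_downregulation must be in (0, 1]")
        if self.epithelial_location <= 0 or self.stromal_location <= 0:
            raise ValueError(f"{name}: intensity locations must be positive")
        if self.between_patient_scale < 0 or self.within_patient_scale < 0:
            raise ValueError(f"{name}: scales must be nonnegative")


@dataclass
class SimulationParams:
    """All knobs of the synthetic cohort and spot-image generator."""

    n_patients: int = 104
    markers: tuple[str, ...] = DEFAULT_MARKERS
    n_tumor_spots: int = 3
    n_normal_spots: int = 2
    spot_radius_px: int = 80
    n_nuclei_per_spot: int = 280
    nucleus_radius_px: int = 3
    epithelial_fraction: float = 0.5
    intensity_models: dict[str, MarkerModel] = field(default_factory=dict)
    noise_sd: float = 100.0
    baseline_hazard: float = 0.003  # events per month
    log_hazard_ratios: dict[str, float] = field(default_factory=_default_log_hazard_ratios)
    censoring_time_months: float | None = 120.0
    stage_probs_by_group: dict[str, dict[str, float]] = field(default_factory=_default_stage_probs)
    infiltrate_probs_by_group: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=_default_infiltrate_probs
    )
    profile_markers: tuple[str, str] = ("NLRP6", "IL18")
    seed: int = 0

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        for m in self.markers:
            self.intensity_models.setdefault(m, MarkerModel())

    def model_for(self, marker: str) -> MarkerModel:
        return self.intensity_models[marker]

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.markers:
            raise ValueError("markers must be a non-empty list")
        if self.n_tumor_spots <= 0 or self.n_normal_spots <= 0:
            raise ValueError("spot counts must be positive")
        if self.spot_radius_px <= 0 or self.nucleus_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.spot_radius_px <= self.nucleus_radius_px:
            raise ValueError("spot_radius_px must exceed nucleus_radius_px")
        if self.n_nuclei_per_spot <= 0:
            raise ValueError("n_nuclei_per_spot must be positive")
        if not (0.0 < self.epithelial_fraction < 1.0):
            raise ValueError("epithelial_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_time_months is not None and self.censoring_time_months <= 0:
            raise ValueError("censoring_time_months must be positive (or None)")
        for name, model in self.intensity_models.items():
            model.validate(name)
        for group, probs in self.stage_probs_by_group.items():
            total = sum(probs.get(s, 0.0) for s in STAGES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"stage probabilities for group {group!r} must sum to 1")
        for group, by_cell in self.infiltrate_probs_by_group.items():
            for cell, probs in by_cell.items():
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(
                        f"infiltrate probabilities for {group!r}/{cell} must sum to 1"
                    )


@dataclass
class GroundTruth:
    """Per-spot ground truth: epithelial mask, nuclei centers, true means.

    ``nuclei_centers`` are 0-based (row, col) pixel coordinates, origin at
    the image top-left.  ``true_compartment_mean`` maps ``epithelial`` and
    ``stromal`` to the latent intensity rendered into the marker channel.
    """

    epithelial_mask: np.ndarray
    nuclei_centers: np.ndarray
    true_compartment_mean: dict[str, float]


@dataclass
class SpotImage:
    """One TMA core: three co-registered channels plus optional ground truth."""

    patient_id: str
    tissue_kind: str  # "tumor" | "normal"
    spot_index: int
    marker: str
    channels: dict[str, np.ndarray]  # keys: dapi, ck, marker (float64 images)
    ground_truth: GroundTruth | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["dapi"].shape


@dataclass
class PatientRecord:
    patient_id: str
    age_years: float
    sex: str
    stage: str
    grade: str
    msi: str
    kras: bool
    braf: bool
    infiltrates: dict[str, str]
    pd1_positive: bool
    pdl1_positive: bool
    time_months: float
    event: bool
    marker_values: dict[str, dict[str, float]]


def _draw_categorical(rng: np.random.Generator, levels, probs, size: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(levels, dtype=object), size=size, p=p)


def _resolve_hazard_groups(key: str, cohort: pd.DataFrame) -> np.ndarray | None:
    """Map a hazard-group label to a boolean membership vector.

    Recognized labels: ``{MARKER}_low`` (epithelial latent low status),
    ``{MARKER}_stromal_low`` and the combined-profile label ``low_low``.
    A well-formed label whose marker is not simulated resolves to None
    (the effect is skipped with a warning); malformed labels raise.
    """
    if key == "low_low":
        return (cohort["profile_group"] == "low_low").to_numpy()
    if key in cohort.columns:
        return cohort[key].to_numpy(dtype=bool)
    if key.endswith("_low"):
        return None
    raise ValueError(f"unknown hazard group label: {key!r}")


def generate_cohort(params: SimulationParams) -> pd.DataFrame:
    """Generate a synthetic patient cohort as a tidy DataFrame.

    One row per patient.  Columns:

    - ``patient_id``, ``age_years``, ``sex`` (M/F), ``stage`` (I..IV),
      ``grade``, ``msi`` (MSS/MSI), ``kras``, ``braf``
    - ``CD3``/``CD8``/``CD68``/``CD163`` — ordinal infiltrate grades
      (low/mild/high), ``pd1_positive``, ``pdl1_positive``
    - ``time_months``, ``event`` — overall survival with administrative
      censoring at ``censoring_time_months``
    - per marker ``{m}_tumor_epithelial``, ``{m}_normal_epithelial``,
      ``{m}_tumor_stromal`` — latent (noise-free) intensities
    - per marker ``{m}_low``, ``{m}_stromal_low`` — ground-truth low status
      (latent value strictly below the cohort median), and ``profile_group``
      (high_high / mixed / low_low from the two profile markers)

    Fully reproducible given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    width = max(3, len(str(n)))
    cohort = pd.DataFrame(
        {"patient_id": [f"P{i + 1:0{width}d}" for i in range(n)]}
    )
    age = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
    cohort["age_years"] = np.clip(age, _AGE_MIN, _AGE_MAX).round(1)
    cohort["sex"] = np.where(rng.random(n) < _P_MALE, "M", "F")
    cohort["grade"] = _draw_categorical(rng, _GRADE_LEVELS, _GRADE_PROBS, n)
    cohort["msi"] = np.where(rng.random(n) < _P_MSI, "MSI", "MSS")
    cohort["kras"] = rng.random(n) < _P_KRAS
    cohort["braf"] = rng.random(n) < _P_BRAF

    # latent marker intensities: shared patient baseline, compartment noise,
    # multiplicative downregulation of the tumor epithelium
    for m in params.markers:
        model = params.model_for(m)
        base = model.epithelial_location * np.exp(
            rng.normal(0.0, model.between_patient_scale, size=n)
        )
        sbase = model.stromal_location * np.exp(
            rng.normal(0.0, model.between_patient_scale, size=n)
        )
        w = model.within_patient_scale
        cohort[f"{m}_normal_epithelial"] = base * np.exp(rng.normal(0.0, w, size=n))
        cohort[f"{m}_tumor_epithelial"] = (
            base * model.tumor_downregulation * np.exp(rng.normal(0.0, w, size=n))
        )
        cohort[f"{m}_tumor_stromal"] = sbase * np.exp(rng.normal(0.0, w, size=n))

    for m in params.markers:
        te = cohort[f"{m}_tumor_epithelial"]
        ts = cohort[f"{m}_tumor_stromal"]
        cohort[f"{m}_low"] = (te < te.median()).to_numpy()
        cohort[f"{m}_stromal_low"] = (ts < ts.median()).to_numpy()

    m1, m2 = params.profile_markers
    if m1 in params.markers and m2 in params.markers:
        low1 = cohort[f"{m1}_low"].to_numpy()
        low2 = cohort[f"{m2}_low"].to_numpy()
        cohort["profile_group"] = np.where(
            low1 & low2, "low_low", np.where(~low1 & ~low2, "high_high", "mixed")
        )
    else:
        cohort["profile_group"] = "mixed"

    # stage and infiltrates conditional on the profile group
    stage = np.empty(n, dtype=object)
    infil = {c: np.empty(n, dtype=object) for c in INFILTRATE_TYPES}
    for group in ("high_high", "mixed", "low_low"):
        idx = np.flatnonzero(cohort["profile_group"].to_numpy() == group)
        if idx.size == 0:
            continue
        sp = params.stage_probs_by_group[group]
        stage[idx] = _draw_categorical(rng, STAGES, [sp[s] for s in STAGES], idx.size)
        for cell in INFILTRATE_TYPES:
            probs = params.infiltrate_probs_by_group[group][cell]
            infil[cell][idx] = _draw_categorical(rng, INFILTRATE_GRADES, probs, idx.size)
    cohort["stage"] = stage
    for cell in INFILTRATE_TYPES:
        cohort[cell] = infil[cell]

    if "IL18" in params.markers:
        p_pd1 = np.where(cohort["IL18_low"], _P_PD1_IL18_LOW, _P_PD1_IL18_HIGH)
    else:
        p_pd1 = np.full(n, _P_PD1_IL18_LOW)
    cohort["pd1_positive"] = rng.random(n) < p_pd1
    cohort["pdl1_positive"] = rng.random(n) < _P_PDL1

    # exponential survival: h_i = h0 * exp(sum of group betas)
    log_h = np.full(n, math.log(params.baseline_hazard))
    for key, beta in params.log_hazard_ratios.items():
        member = _resolve_hazard_groups(key, cohort)
        if member is None:
            warnings.warn(
                f"hazard group {key!r} refers to a marker that is not "
                "simulated; effect skipped",
                stacklevel=2,
            )
            continue
        log_h += beta * member.astype(float)
    latent_time = rng.exponential(1.0 / np.exp(log_h))
    if params.censoring_time_months is None:
        cohort["time_months"] = latent_time
        cohort["event"] = True
    else:
        c = float(params.censoring_time_months)
        cohort["time_months"] = np.minimum(latent_time, c)
        cohort["event"] = latent_time <= c

    return cohort


def patient_record(cohort: pd.DataFrame, patient_id: str) -> PatientRecord:
    """Materialize one cohort row as a :class:`PatientRecord`."""
    row = cohort.loc[cohort["patient_id"] == patient_id]
    if row.empty:
        raise KeyError(f"no patient {patient_id!r} in cohort")
    row = row.iloc[0]
    markers = sorted(
        c[: -len("_tumor_epithelial")]
        for c in cohort.columns
        if c.endswith("_tumor_epithelial")
    )
    marker_values = {
        m: {
            "tumor_epithelial": float(row[f"{m}_tumor_epithelial"]),
            "normal_epithelial": float(row[f"{m}_normal_epithelial"]),
            "tumor_stromal": float(row[f"{m}_tumor_stromal"]),
        }
        for m in markers
    }
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age_years=float(row["age_years"]),
        sex=str(row["sex"]),
        stage=str(row["stage"]),
        grade=str(row["grade"]),
        msi=str(row["msi"]),
        kras=bool(row["kras"]),
        braf=bool(row["braf"]),
        infiltrates={c: str(row[c]) for c in INFILTRATE_TYPES},
        pd1_positive=bool(row["pd1_positive"]),
        pdl1_positive=bool(row["pdl1_positive"]),
        time_months=float(row["time_months"]),
        event=bool(row["event"]),
        marker_values=marker_values,
    )


def spot_seed(master_seed: int, patient_index: int, marker_index: int,
              tissue_kind: str, spot_index: int) -> np.random.SeedSequence:
    """Stated per-spot seeding scheme: a SeedSequence spawned from the master
    seed and the (patient, marker, tissue, spot) counters."""
    tissue_code = 0 if tissue_kind == "tumor" else 1
    return np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(patient_index, marker_index, tissue_code, spot_index),
    )


def spot_tissue_mask(params: SimulationParams) -> np.ndarray:
    """Boolean mask of the tissue core (the spot disk) on the image grid.

    Cell regions grown by segmentation are clipped to this mask so that
    edge cells do not accumulate empty background pixels."""
    side = 2 * (params.spot_radius_px + IMAGE_MARGIN_PX)
    center = (side - 1) / 2.0
    rows, cols = np.mgrid[0:side, 0:side]
    return np.hypot(rows - center, cols - center) <= params.spot_radius_px


def _gland_mask(rng: np.random.Generator, dist: np.ndarray, radius: float,
                target_fraction: float) -> np.ndarray:
    """Epithelium as 3-8 random annuli ("crypts") clipped to the spot disk."""
    shape = dist.shape
    center = (shape[0] - 1) / 2.0
    disk = dist <= radius
    disk_px = int(disk.sum())
    mask = np.zeros(shape, dtype=bool)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    n_annuli = 0
    while n_annuli < 8:
        # annulus center uniform in a concentric disk of 0.8 * radius
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = radius * 0.8 * math.sqrt(rng.uniform())
        cy = center + rad * math.sin(ang)
        cx = center + rad * math.cos(ang)
        ro = rng.uniform(0.4, 0.6) * radius
        ri = ro * rng.uniform(0.1, 0.35)
        d = np.hypot(rows - cy, cols - cx)
        mask |= (d >= ri) & (d <= ro) & disk
        n_annuli += 1
        if n_annuli >= 3 and mask.sum() >= target_fraction * disk_px:
            break
    return mask


def _place_nuclei(rng: np.random.Generator, center: float, spot_radius: int,
                  nucleus_radius: int, n: int) -> np.ndarray:
    """Poisson-disk-like rejection sampling: centers inside the spot disk with
    pairwise distance >= 2 * nucleus_radius."""
    min_d2 = (2 * nucleus_radius) ** 2
    rmax = spot_radius - nucleus_radius - 1
    placed = np.empty((0, 2), dtype=float)
    attempts = 0
    limit = 2000 * n
    while len(placed) < n:
        if attempts >= limit:
            raise RuntimeError(
                f"could not place {n} nuclei of radius {nucleus_radius} in a "
                f"spot of radius {spot_radius}; reduce density"
            )
        attempts += 1
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = rmax * math.sqrt(rng.uniform())
        cand = np.array([center + rad * math.sin(ang), center + rad * math.cos(ang)])
        if len(placed) and (((placed - cand) ** 2).sum(axis=1) < min_d2).any():
            continue
        placed = np.vstack([placed, cand])
    return np.round(placed).astype(int)


def generate_spot_image(
    patient: PatientRecord,
    marker: str,
    tissue_kind: str,
    spot_index: int,
    params: SimulationParams,
    seed: int | np.random.SeedSequence,
) -> SpotImage:
    """Render one synthetic spot (DAPI + cytokeratin + marker channel).

    The marker channel is piecewise constant at the patient's latent
    epithelial / stromal value for ``tissue_kind``, plus additive Gaussian
    noise of sd ``params.noise_sd`` (clipped to the 16-bit range).  Channels
    are float64; :func:`write_spot` rounds to uint16 on disk.  Identical
    seeds produce identical pixels.
    """
    params.validate()
    if tissue_kind not in ("tumor", "normal"):
        raise ValueError("tissue_kind must be 'tumor' or 'normal'")
    if marker not in patient.marker_values:
        raise ValueError(f"marker {marker!r} not present in patient.marker_values")

    rng = np.random.default_rng(seed)
    r = params.spot_radius_px
    side = 2 * (r + IMAGE_MARGIN_PX)
    center = (side - 1) / 2.0
    rows, cols = np.mgrid[0:side, 0:side]
    dist = np.hypot(rows - center, cols - center)
    disk = dist <= r

    epi_mask = _gland_mask(rng, dist, r, params.epithelial_fraction)
    centers = _place_nuclei(rng, center, r, params.nucleus_radius_px,
                            params.n_nuclei_per_spot)

    values = patient.marker_values[marker]
    if tissue_kind == "tumor":
        epi_value = values["tumor_epithelial"]
    else:
        epi_value = values["normal_epithelial"]
    # stroma is modeled as unaffected by tumor status; normal spots reuse the
    # patient's stromal latent value
    stromal_value = values["tumor_stromal"]

    dapi = np.zeros((side, side))
    nd2 = params.nucleus_radius_px**2
    for cy, cx in centers:
        lo_r, hi_r = cy - params.nucleus_radius_px, cy + params.nucleus_radius_px + 1
        lo_c, hi_c = cx - params.nucleus_radius_px, cx + params.nucleus_radius_px + 1
        sub_r, sub_c = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        hit = (sub_r - cy) ** 2 + (sub_c - cx) ** 2 <= nd2
        dapi[sub_r[hit], sub_c[hit]] = DAPI_LEVEL

    ck = np.where(epi_mask, CK_EPITHELIAL_LEVEL, np.where(disk, CK_STROMAL_LEVEL, 0.0))
    marker_img = np.where(epi_mask, epi_value, np.where(disk, stromal_value, 0.0))

    channels = {"dapi": dapi, "ck": ck, "marker": marker_img}
    if params.noise_sd > 0:
        for name in channels:
            noisy = channels[name] + rng.normal(0.0, params.noise_sd,
                                                size=channels[name].shape)
            channels[name] = np.clip(noisy, 0.0, INTENSITY_MAX)

    truth = GroundTruth(
        epithelial_mask=epi_mask,
        nuclei_centers=centers,
        true_compartment_mean={"epithelial": float(epi_value),
                               "stromal": float(stromal_value)},
    )
    return SpotImage(
        patient_id=patient.patient_id,
        tissue_kind=tissue_kind,
        spot_index=spot_index,
        marker=marker,
        channels=channels,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# file interfaces: 16-bit TIFF channels, 8-bit TIFF masks, CSV sidecars


def _spot_stem(spot: SpotImage) -> str:
    return f"{spot.patient_id}_{spot.tissue_kind}_{spot.spot_index}_{spot.marker}"


def write_spot(spot: SpotImage, outdir: str | Path) -> list[Path]:
    """Write one spot: one uint16 TIFF per channel, ground-truth mask as
    8-bit TIFF, sidecar CSVs with nuclei centers and true compartment means."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = _spot_stem(spot)
    written: list[Path] = []
    for name, img in spot.channels.items():
        path = outdir / f"{stem}_{name}.tif"
        tifffile.imwrite(path, np.clip(np.round(img), 0, INTENSITY_MAX).astype(np.uint16))
        written.append(path)
    if spot.ground_truth is not None:
        gt = spot.ground_truth
        mpath = outdir / f"{stem}_gtmask.tif"
        tifffile.imwrite(mpath, (gt.epithelial_mask.astype(np.uint8) * 255))
        written.append(mpath)
        npath = outdir / f"{stem}_nuclei.csv"
        pd.DataFrame(gt.nuclei_centers, columns=["row", "col"]).to_csv(npath, index=False)
        written.append(npath)
        tpath = outdir / f"{stem}_truth.csv"
        pd.DataFrame(
            {"compartment": list(gt.true_compartment_mean),
             "true_mean": list(gt.true_compartment_mean.values())}
        ).to_csv(tpath, index=False)
        written.append(tpath)
    return written


def read_spot(outdir: str | Path, patient_id: str, tissue_kind: str,
              spot_index: int, marker: str) -> SpotImage:
    """Read a spot written by :func:`write_spot` (channels become float64)."""
    outdir = Path(outdir)
    stem = f"{patient_id}_{tissue_kind}_{spot_index}_{marker}"
    channels = {
        name: tifffile.imread(outdir / f"{stem}_{name}.tif").astype(np.float64)
        for name in ("dapi", "ck", "marker")
    }
    truth = None
    mpath = outdir / f"{stem}_gtmask.tif"
    if mpath.exists():
        mask = tifffile.imread(mpath) > 0
        centers = pd.read_csv(outdir / f"{stem}_nuclei.csv")[["row", "col"]].to_numpy()
        tdf = pd.read_csv(outdir / f"{stem}_truth.csv")
        truth = GroundTruth(
            epithelial_mask=mask,
            nuclei_centers=centers,
            true_compartment_mean=dict(zip(tdf["compartment"], tdf["true_mean"])),
        )
    return SpotImage(patient_id, tissue_kind, spot_index, marker, channels, truth)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in df.columns:
        if col in ("kras", "braf", "pd1_positive", "pdl1_positive", "event") or (
            col.endswith("_low")
        ):
            df[col] = df[col].astype(bool)
    return df


def _to_builtin(obj):
    """Recursively convert numpy scalars/arrays for yaml.safe_dump."""
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def params_to_yaml(params: SimulationParams, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = asdict(params)
    payload["markers"] = list(params.markers)
    payload["profile_markers"] = list(params.profile_markers)
    payload["intensity_models"] = {m: asdict(mod) for m, mod in params.intensity_models.items()}
    payload["infiltrate_probs_by_group"] = {
        g: {c: list(p) for c, p in by_cell.items()}
        for g, by_cell in params.infiltrate_probs_by_group.items()
    }
    path.write_text(yaml.safe_dump(_to_builtin(payload), sort_keys=True))
    return path


def params_from_yaml(path: str | Path) -> SimulationParams:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if "intensity_models" in payload:
        payload["intensity_models"] = {
            m: MarkerModel(**mod) for m, mod in payload["intensity_models"].items()
        }
    if "infiltrate_probs_by_group" in payload:
        payload["infiltrate_probs_by_group"] = {
            g: {c: tuple(p) for c, p in by_cell.items()}
            for g, by_cell in payload["infiltrate_probs_by_group"].items()
        }
    for key in ("markers", "profile_markers"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SimulationParams(**payload)
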