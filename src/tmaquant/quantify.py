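"""Per-cell, per-spot and per-patient marker quantification.

The per-cell statistic is the median marker intensity over the cell region
(whole cell by default, nucleus-only as an option).  A cell enters the
tally only if it is DAPI-positive, i.e. its nucleus label exists in the
nuclei segmentation; the compartment is epithelial when the cell lies in
the cytokeratin mask and stromal otherwise.  Spot values are arithmetic
means of per-cell medians per compartment, and patient values are means
over the available spots of each tissue kind.  Missing compartments
propagate as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellMeasurement",
    "SpotSummary",
    "PatientMarkerValue",
    "quantify_spot",
    "aggregate_patient",
    "cells_to_frame",
    "spots_to_frame",
]


@dataclass
class CellMeasurement:
    cell_id: int
    compartment: str  # "epithelial" | "stromal"
    median_marker_intensity: float
    dapi_positive: bool


@dataclass
class SpotSummary:
    patient_id: str
    tissue_kind: str
    spot_index: int
    marker: str
    n_epithelial_cells: int
    n_stromal_cells: int
    epithelial_value: float  # NaN when no epithelial cells
    stromal_value: float  # NaN when no stromal cells


@dataclass
class PatientMarkerValue:
    patient_id: str
    marker: str
    tumor_epithelial: float
    normal_epithelial: float
    tumor_stromal: float
    n_tumor_spots: int
    n_normal_spots: int


def quantify_spot(
    marker_img: np.ndarray,
    nuclei: np.ndarray,
    cells: np.ndarray,
    ck_mask: np.ndarray,
    *,
    patient_id: str = "",
    tissue_kind: str = "",
    spot_index: int = 0,
    marker: str = "",
    region: str = "cell",
) -> tuple[SpotSummary, list[CellMeasurement]]:
    """Measure one spot: per-cell medians and compartment means.

    ``region="cell"`` takes the median over the cell region;
    ``region="nucleus"`` restricts to the nucleus pixels.  A cell is
    epithelial iff the majority of its pixels fall inside ``ck_mask``, and
    its median is computed over the pixels lying in its own compartment
    (inside the mask for epithelial cells, outside for stromal) — the
    intensity of the cell *in* the mask.  With segmentation-derived masks
    the mask is a union of whole cells, so membership is all-or-nothing
    and the restriction is a no-op; with ground-truth masks that cut
    across cells it keeps boundary cells from mixing compartments.
    """
    marker_img = np.asarray(marker_img, dtype=float)
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    ck_mask = np.asarray(ck_mask, dtype=bool)
    if not (marker_img.shape == nuclei.shape == cells.shape == ck_mask.shape):
        raise ValueError("all inputs must share one shape")
    if region not in ("cell", "nucleus"):
        raise ValueError("region must be 'cell' or 'nucleus'")

    src = cells if region == "cell" else nuclei
    flat_labels = src.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    start = np.searchsorted(sorted_labels, 1)  # skip background
    sorted_labels = sorted_labels[start:]
    order = order[start:]
    ids, first = np.unique(sorted_labels, return_index=True)
    bounds = np.append(first, sorted_labels.size)

    nucleus_ids = set(np.unique(nuclei[nuclei > 0]).tolist())
    flat_marker = marker_img.ravel()[order]
    flat_mask = ck_mask.ravel()[order]

    measurements: list[CellMeasurement] = []
    epi_vals: list[float] = []
    str_vals: list[float] = []
    for k, cid in enumerate(ids):
        if int(cid) not in nucleus_ids:
            continue  # not DAPI-positive: excluded from quantification
        sl = slice(bounds[k], bounds[k + 1])
        in_mask = flat_mask[sl]
        epithelial = bool(in_mask.mean() > 0.5)
        pixels = flat_marker[sl][in_mask if epithelial else ~in_mask]
        med = float(np.median(pixels))
        measurements.append(
            CellMeasurement(int(cid), "epithelial" if epithelial else "stromal",
                            med, True)
        )
        (epi_vals if epithelial else str_vals).append(med)

    summary = SpotSummary(
        patient_id=patient_id,
        tissue_kind=tissue_kind,
        spot_index=spot_index,
        marker=marker,
        n_epithelial_cells=len(epi_vals),
        n_stromal_cells=len(str_vals),
        epithelial_value=float(np.mean(epi_vals)) if epi_vals else float("nan"),
        stromal_value=float(np.mean(str_vals)) if str_vals else float("nan"),
    )
    return summary, measurements


def aggregate_patient(spots: list[SpotSummary]) -> PatientMarkerValue:
    """Average spot values into one record per patient and marker.

    Tumor values are means over the available tumor spots (at most the
    punch count, normally 3), normal values over the normal spots (2);
    spots with a missing compartment are skipped and the contributing spot
    counts are recorded.  With no tumor (normal) spots the corresponding
    values are NaN.
    """
    if not spots:
        raise ValueError("no spots to aggregate")
    pids = {s.patient_id for s in spots}
    markers = {s.marker for s in spots}
    if len(pids) != 1 or len(markers) != 1:
        raise ValueError("all spots must share patient_id and marker")

    tumor = [s for s in spots if s.tissue_kind == "tumor"]
    normal = [s for s in spots if s.tissue_kind == "normal"]

    def _mean(values: list[float]) -> float:
        values = [v for v in values if not np.isnan(v)]
        return float(np.mean(values)) if values else float("nan")

    return PatientMarkerValue(
        patient_id=spots[0].patient_id,
        marker=spots[0].marker,
        tumor_epithelial=_mean([s.epithelial_value for s in tumor]),
        normal_epithelial=_mean([s.epithelial_value for s in normal]),
        tumor_stromal=_mean([s.stromal_value for s in tumor]),
        n_tumor_spots=len(tumor),
        n_normal_spots=len(normal),
    )


def cells_to_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in measurements])


def spots_to_frame(spots: list[SpotSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in spots])
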