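"""Single-cell quality control and normalization.

Applies, in order: exposure-time normalization, per-wavelength
autofluorescence subtraction, quantile outlier filtering (high
autofluorescence, extreme nuclear sizes), epithelial gating on CK8 and
E-Cadherin, and z-scoring of every biomarker (and DTA) against the untreated
control cohort.

Conventions (documented because the source protocol leaves them open):
quantile thresholds use linear interpolation between order statistics (the
numpy default); the outlier comparisons are strict (> the high quantile,
< the low quantile); z-score scale is the sample standard deviation
(ddof = 1) of the control cohort, centered on the control median; negative
values after autofluorescence subtraction are retained, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "NormalizationSpec",
    "QCError",
    "normalize_exposure",
    "subtract_autofluorescence",
    "filter_outliers",
    "gate_epithelial",
    "zscore_to_control",
    "run_qc_chain",
]


class QCError(ValueError):
    """Raised when a QC/normalization step cannot be applied."""


@dataclass
class NormalizationSpec:
    """Parameters of the QC/normalization chain.

    Defaults follow the workflow this package reimplements: Cy3
    autofluorescence above its 95th quantile flags tissue artifacts; nuclear
    sizes outside the 5th-95th quantiles flag mis-segmented nuclei; cells
    must be positive for both CK8 and E-Cadherin to count as tumor
    epithelium; z-scores are anchored to the untreated control cohort.
    """

    af_channel_for_outliers: str = "Cy3"
    af_quantile: float = 0.95
    size_quantiles: tuple[float, float] = (0.05, 0.95)
    epithelial_markers: tuple[str, ...] = ("CK8", "ECad")
    gate_method: str = "otsu"  # or "fixed"
    gate_thresholds: dict[str, float] = field(default_factory=dict)
    control_label: str = "control"

    def __post_init__(self) -> None:
        lo, hi = self.size_quantiles
        if not (0.0 < lo < hi < 1.0):
            raise QCError("size quantiles must satisfy 0 < low < high < 1")
        if not 0.0 < self.af_quantile < 1.0:
            raise QCError("af_quantile must lie in (0, 1)")
        if self.gate_method not in ("otsu", "fixed"):
            raise QCError("gate_method must be 'otsu' or 'fixed'")


def _intensity_columns(cells: pd.DataFrame) -> list[str]:
    return [c for c in cells.columns if c.startswith("mean_") or c.startswith("af_")]


def normalize_exposure(cells: pd.DataFrame, exposures: dict[str, float]) -> pd.DataFrame:
    """Divide every marker and autofluorescence mean by its exposure time.

    ``exposures`` maps column names (``mean_<marker>`` / ``af_<wavelength>``,
    or bare marker/wavelength names) to exposure times in ms. Every intensity
    column must have a positive exposure.
    """
    out = cells.copy()
    for col in _intensity_columns(out):
        bare = col.split("_", 1)[1]
        exp = exposures.get(col, exposures.get(bare))
        if exp is None:
            raise QCError(f"no exposure time for intensity column {col!r}")
        if not exp > 0:
            raise QCError(f"exposure for {col!r} must be positive, got {exp}")
        out[col] = out[col] / float(exp)
    return out


def subtract_autofluorescence(
    cells: pd.DataFrame, channel_wavelength_map: dict[str, str]
) -> pd.DataFrame:
    """Subtract each cell's same-wavelength autofluorescence from its markers.

    ``channel_wavelength_map`` maps marker name -> wavelength tag; the table
    must carry an ``af_<wavelength>`` column for every mapped wavelength.
    Negative corrected values are retained.
    """
    out = cells.copy()
    for col in out.columns:
        if not col.startswith("mean_"):
            continue
        marker = col[len("mean_") :]
        wl = channel_wavelength_map.get(marker)
        if wl is None:
            raise QCError(f"marker {marker!r} has no wavelength mapping")
        af_col = f"af_{wl}"
        if af_col not in out.columns:
            raise QCError(f"missing autofluorescence column {af_col!r} for marker {marker!r}")
        out[col] = out[col] - out[af_col]
    return out


def filter_outliers(
    cells: pd.DataFrame, spec: NormalizationSpec
) -> tuple[pd.DataFrame, dict]:
    """Remove autofluorescence and nuclear-size outliers.

    Thresholds are computed once on the input table with linear-interpolation
    quantiles. Cells strictly above the autofluorescence quantile are
    removed; cells strictly below the low or strictly above the high nuclear-
    size quantile are removed. Returns the filtered table and a QC report
    (thresholds used, counts removed per rule). Removal flags
    (``af_outlier``, ``size_outlier``) are recorded on the returned table's
    complement via the report's flagged id lists.
    """
    if len(cells) == 0:
        raise QCError("cannot filter an empty cell table")
    af_col = f"af_{spec.af_channel_for_outliers}"
    if af_col not in cells.columns:
        raise QCError(f"missing autofluorescence column {af_col!r}")
    if "nuclear_size" not in cells.columns:
        raise QCError("missing nuclear_size column")

    af_thr = float(np.quantile(cells[af_col].to_numpy(), spec.af_quantile))
    lo_q, hi_q = spec.size_quantiles
    size = cells["nuclear_size"].to_numpy()
    size_lo = float(np.quantile(size, lo_q))
    size_hi = float(np.quantile(size, hi_q))

    af_outlier = cells[af_col].to_numpy() > af_thr
    size_outlier = (size < size_lo) | (size > size_hi)
    keep = ~(af_outlier | size_outlier)

    out = cells.loc[keep].copy()
    report = {
        "n_input": int(len(cells)),
        "n_kept": int(keep.sum()),
        "af_threshold": af_thr,
        "size_thresholds": [size_lo, size_hi],
        "n_af_removed": int(af_outlier.sum()),
        "n_size_removed": int(size_outlier.sum()),
        "af_outlier_ids": cells.loc[af_outlier, "cell_id"].tolist(),
        "size_outlier_ids": cells.loc[size_outlier, "cell_id"].tolist(),
    }
    return out, report


def _gate_threshold(values: np.ndarray, spec: NormalizationSpec, marker: str) -> float:
    if spec.gate_method == "fixed":
        if marker not in spec.gate_thresholds:
            raise QCError(f"fixed gate requested but no threshold for {marker!r}")
        return float(spec.gate_thresholds[marker])
    finite = values[np.isfinite(values)]
    if finite.size < 2 or np.ptp(finite) == 0:
        raise QCError(f"cannot Otsu-gate constant marker {marker!r}")
    # Otsu on log1p compresses the right tail; shift so the minimum sits at 0
    shifted = np.log1p(finite - finite.min())
    thr = threshold_otsu(shifted)
    return float(np.expm1(thr) + finite.min())


def gate_epithelial(
    cells: pd.DataFrame, spec: NormalizationSpec
) -> tuple[pd.DataFrame, dict]:
    """Retain cells positive for *both* epithelial markers.

    Positivity per marker is value strictly above a threshold chosen by
    ``spec.gate_method``: Otsu on log1p-transformed values across the cohort
    (default), or a fixed per-marker threshold.

    Raises
    ------
    QCError
        If the gate would retain zero cells (reported with the thresholds
        used, to aid diagnosis).
    """
    thresholds: dict[str, float] = {}
    positive = np.ones(len(cells), dtype=bool)
    for marker in spec.epithelial_markers:
        col = f"mean_{marker}"
        if col not in cells.columns:
            raise QCError(f"missing epithelial marker column {col!r}")
        thr = _gate_threshold(cells[col].to_numpy(dtype=float), spec, marker)
        thresholds[marker] = thr
        positive &= cells[col].to_numpy(dtype=float) > thr
    if not positive.any():
        raise QCError(f"epithelial gate retained zero cells (thresholds: {thresholds})")
    out = cells.loc[positive].copy()
    report = {
        "n_input": int(len(cells)),
        "n_kept": int(positive.sum()),
        "gate_method": spec.gate_method,
        "thresholds": thresholds,
    }
    return out, report


def zscore_to_control(
    cells: pd.DataFrame,
    spec: NormalizationSpec,
    columns: list[str] | None = None,
    cohort_column: str = "cohort",
) -> tuple[pd.DataFrame, dict]:
    """Z-score biomarker (and DTA) columns against the untreated controls.

    For each column, ``z = (value - control_median) / control_SD`` where the
    median and sample SD (ddof = 1) are taken across all cells of the control
    cohort (``spec.control_label``). The control statistics are returned for
    reporting.

    Raises
    ------
    QCError
        If the control cohort is empty or any column has zero control SD.
    """
    if cohort_column not in cells.columns:
        raise QCError(f"missing cohort column {cohort_column!r}")
    control = cells[cells[cohort_column] == spec.control_label]
    if len(control) == 0:
        raise QCError(
            f"control cohort {spec.control_label!r} is empty; z-scoring requires "
            "untreated control cells"
        )
    if columns is None:
        columns = [c for c in cells.columns if c.startswith("mean_")]
        if "dta_mean" in cells.columns:
            columns = columns + ["dta_mean"]

    out = cells.copy()
    stats: dict[str, dict[str, float]] = {}
    for col in columns:
        ctrl = control[col].to_numpy(dtype=float)
        ctrl = ctrl[np.isfinite(ctrl)]
        if ctrl.size < 2:
            raise QCError(f"control cohort has fewer than 2 finite values for {col!r}")
        med = float(np.median(ctrl))
        sd = float(np.std(ctrl, ddof=1))
        if sd == 0:
            raise QCError(f"control SD is zero for column {col!r}; cannot z-score")
        out[col] = (out[col] - med) / sd
        stats[col] = {"control_median": med, "control_sd": sd, "n_control": int(ctrl.size)}
    return out, stats


def run_qc_chain(
    cells: pd.DataFrame,
    spec: NormalizationSpec,
    exposures: dict[str, float],
    channel_wavelength_map: dict[str, str],
    zscore: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full chain: exposure → AF subtraction → outlier filter → gate → z-score.

    Returns the processed table and a combined QC report. The z-score step is
    skipped when ``zscore=False`` (e.g. single-cohort runs without controls).
    """
    report: dict = {}
    out = normalize_exposure(cells, exposures)
    out = subtract_autofluorescence(out, channel_wavelength_map)
    out, report["outlier_filter"] = filter_outliers(out, spec)
    out, report["epithelial_gate"] = gate_epithelial(out, spec)
    if zscore:
        out, report["zscore"] = zscore_to_control(out, spec)
    return out, report
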