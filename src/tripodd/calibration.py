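"""Titration calibration and the probe scaling factor (SF).

Paired-agent imaging corrects for nonspecific probe uptake by dividing the
targeted-probe image by the untargeted-probe image. Because the two probes
carry different fluorophores (and are imaged in different channels), equal
concentrations do not produce equal intensities. The scaling factor SF
equalises the two channels: each probe is imaged at a series of known
concentrations, a linear trend line is fitted per probe, and

    SF = slope_untargeted / slope_targeted

so that ``SF * I_T`` and ``I_UnT`` are on a common concentration-equivalent
scale. SF is dimensionless and must be positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TitrationSeries",
    "LineFit",
    "ScalingFactor",
    "CalibrationError",
    "fit_titration",
    "compute_scaling_factor",
    "read_titration_csv",
]


class CalibrationError(ValueError):
    """Raised when a titration series cannot yield a valid calibration."""


@dataclass(frozen=True)
class TitrationSeries:
    """Mean image intensity measured at each probe concentration.

    Parameters
    ----------
    probe
        ``"targeted"`` or ``"untargeted"``.
    concentrations
        Probe concentrations (any consistent amount unit), >= 2 distinct.
    mean_intensities
        Mean fluorescence intensity (a.u.) of the image at each concentration.
    """

    probe: str
    concentrations: tuple[float, ...]
    mean_intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        inten = np.asarray(self.mean_intensities, dtype=float)
        if conc.size != inten.size:
            raise CalibrationError("concentrations and intensities differ in length")
        if np.unique(conc).size < 2:
            raise CalibrationError("titration needs >= 2 distinct concentrations")
        if np.any(conc < 0):
            raise CalibrationError("concentrations must be nonnegative")
        if np.any(inten < 0):
            raise CalibrationError("mean intensities must be nonnegative")


@dataclass(frozen=True)
class LineFit:
    """Ordinary least-squares line ``intensity = slope * concentration + intercept``."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class ScalingFactor:
    """SF with the two titration line fits it derives from.

    ``sf == slope_unt / slope_t`` within floating tolerance; both slopes > 0.
    """

    sf: float
    slope_t: float
    slope_unt: float
    intercept_t: float = 0.0
    intercept_unt: float = 0.0
    r_squared_t: float = float("nan")
    r_squared_unt: float = float("nan")

    def __post_init__(self) -> None:
        if not self.sf > 0:
            raise CalibrationError(f"scaling factor must be positive, got {self.sf}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingFactor":
        return cls(**json.loads(Path(path).read_text()))


def fit_titration(series: TitrationSeries) -> LineFit:
    """Fit the linear calibration trend line for one probe.

    Ordinary least squares of mean intensity on concentration. The intercept
    is fitted, not forced through zero; SF uses slopes only.

    Raises
    ------
    CalibrationError
        If fewer than 2 distinct concentrations (zero variance in x).
    """
    x = np.asarray(series.concentrations, dtype=float)
    y = np.asarray(series.mean_intensities, dtype=float)
    res = _sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # zero variance in y -> flat line, r^2 undefined; report 1 for exact fit
        r2 = 1.0 if np.allclose(y, res.intercept + res.slope * x) else 0.0
    return LineFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def compute_scaling_factor(fit_t: LineFit, fit_unt: LineFit) -> ScalingFactor:
    """SF = slope of the untargeted trend line / slope of the targeted trend line.

    Raises
    ------
    CalibrationError
        If either slope is non-positive (failed calibration).
    """
    if fit_t.slope <= 0 or fit_unt.slope <= 0:
        raise CalibrationError(
            f"both titration slopes must be positive "
            f"(targeted={fit_t.slope:g}, untargeted={fit_unt.slope:g})"
        )
    return ScalingFactor(
        sf=fit_unt.slope / fit_t.slope,
        slope_t=fit_t.slope,
        slope_unt=fit_unt.slope,
        intercept_t=fit_t.intercept,
        intercept_unt=fit_unt.intercept,
        r_squared_t=fit_t.r_squared,
        r_squared_unt=fit_unt.r_squared,
    )


def read_titration_csv(path: str | Path) -> dict[str, TitrationSeries]:
    """Read a titration table (columns: probe, concentration, mean_intensity).

    Returns one :class:`TitrationSeries` per probe label found.
    """
    df = pd.read_csv(path)
    required = {"probe", "concentration", "mean_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise CalibrationError(f"titration CSV missing columns: {sorted(missing)}")
    out: dict[str, TitrationSeries] = {}
    for probe, sub in df.groupby("probe"):
        out[str(probe)] = TitrationSeries(
            probe=str(probe),
            concentrations=tuple(sub["concentration"].astype(float)),
            mean_intensities=tuple(sub["mean_intensity"].astype(float)),
        )
    return out


def calibrate_from_series(
    targeted: TitrationSeries, untargeted: TitrationSeries
) -> ScalingFactor:
    """Convenience: fit both trend lines and form SF in one call."""
    return compute_scaling_factor(fit_titration(targeted), fit_titration(untargeted))
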