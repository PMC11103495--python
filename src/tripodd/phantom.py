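"""Synthetic tissue phantom with known ground truth.

Generates multi-round fluorescence image stacks that emulate a xenograft
tissue section imaged through a paired-agent + cyclic-immunofluorescence
workflow, so every downstream stage (calibration, DTA mapping, registration,
segmentation, QC, statistics) is testable without any external data.

Forward model
-------------
The tissue is a disk of autofluorescent background containing ``n_cells``
non-overlapping cells. Each cell is a nuclear disk (radius drawn from a
truncated normal) plus a fixed-width cytoplasmic annulus. Per cell we draw a
receptor density ``R`` (log-normal) and a nonspecific probe accumulation
``N`` (log-normal). With a fraction ``f`` of target sites occupied by the
unlabeled parent drug and binding gain ``B``, the probe channels inside the
cell region are::

    targeted   = slope_T   * (B * (1 - f) * R + N)
    untargeted = slope_UnT * N

so the true per-cell drug-target availability is ``DTA = B * (1 - f) * R / N``
and the true scaling factor is ``SF = slope_UnT / slope_T``. Wavelength-
specific autofluorescence is added over the whole tissue disk, channels are
scaled by their exposure time, and additive Gaussian noise (truncated at
zero) or Poisson noise is applied. Each imaging round is the base scene
displaced by that round's rigid shift, with fresh acquisition noise.

Marker channels (CK8, E-Cad, Ki67, CC3 by default) carry per-cell expression
levels; CK8/E-Cad are high only in the epithelial subpopulation, and CC3 is
bimodal (mostly zero with a punctate-positive subset), mimicking the binary
viable-to-apoptotic switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .dta import ChannelImage

__all__ = [
    "MarkerSpec",
    "PhantomConfig",
    "PhantomTruth",
    "TitrationImageSet",
    "generate_phantom",
    "generate_titration",
]

#: Width of the cytoplasmic annulus around each nucleus, in pixels.
CYTOPLASM_WIDTH_PX = 4

#: Channel layout per imaging round. Round 0 is the paired-agent round
#: (probes + Cy2 tissue autofluorescence), rounds 1-2 carry markers, and the
#: final round images residual autofluorescence per wavelength after signal
#: removal. Every round includes DAPI for registration.
ROUND_PLAN: tuple[tuple[str, ...], ...] = (
    ("DAPI", "AF_Cy2", "probe_UnT", "probe_T"),
    ("DAPI", "CK8", "ECad"),
    ("DAPI", "Ki67", "CC3"),
    ("DAPI", "AF_Cy3", "AF_Cy5"),
)

CHANNEL_WAVELENGTHS: dict[str, str] = {
    "DAPI": "DAPI",
    "AF_Cy2": "Cy2",
    "AF_Cy3": "Cy3",
    "AF_Cy5": "Cy5",
    "probe_UnT": "Cy3",
    "probe_T": "Cy5",
    "CK8": "Cy3",
    "ECad": "Cy5",
    "Ki67": "Cy3",
    "CC3": "Cy5",
}

DEFAULT_EXPOSURES_MS: dict[str, float] = {
    "DAPI": 10.0,
    "AF_Cy2": 50.0,
    "AF_Cy3": 50.0,
    "AF_Cy5": 50.0,
    "probe_UnT": 1.0,
    "probe_T": 1.0,
    "CK8": 100.0,
    "ECad": 150.0,
    "Ki67": 100.0,
    "CC3": 200.0,
}


@dataclass(frozen=True)
class MarkerSpec:
    """Per-cell expression model for one immunofluorescence marker.

    Expression is log-normal(log_mean, log_sigma) in expressing cells. With
    ``positive_fraction < 1`` only that fraction expresses (the rest are 0),
    giving a bimodal, punctate-style marker. ``epithelial`` markers are drawn
    from a low-expression log-normal in non-epithelial cells instead.
    """

    name: str
    round_index: int
    wavelength: str
    log_mean: float
    log_sigma: float
    positive_fraction: float = 1.0
    epithelial: bool = False
    negative_log_mean: float = float(np.log(0.5))


def _default_markers() -> tuple[MarkerSpec, ...]:
    return (
        MarkerSpec("CK8", 1, "Cy3", float(np.log(20.0)), 0.3, epithelial=True),
        MarkerSpec("ECad", 1, "Cy5", float(np.log(20.0)), 0.3, epithelial=True),
        MarkerSpec("Ki67", 2, "Cy3", float(np.log(10.0)), 0.4),
        MarkerSpec("CC3", 2, "Cy5", float(np.log(25.0)), 0.3, positive_fraction=0.15),
    )


@dataclass
class PhantomConfig:
    """Parameters of the synthetic tissue scene.

    Defaults describe a moderately dense xenograft-like section: ~200 nuclei
    of radius ~6 px, log-normal receptor density (median 50 a.u.) and
    nonspecific uptake (median 10 a.u.), probe gains 3 and 6 fluorescence
    units per concentration unit, low per-wavelength autofluorescence and
    additive Gaussian noise of 1 a.u.
    """

    n_cells: int = 200
    field_size: tuple[int, int] = (768, 768)
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 1.0
    receptor_log_mean: float = float(np.log(50.0))
    receptor_log_sigma: float = 0.4
    occupancy_f: float = 0.0
    nonspecific_log_mean: float = float(np.log(10.0))
    nonspecific_log_sigma: float = 0.3
    binding_gain: float = 1.0
    slope_t: float = 3.0
    slope_unt: float = 6.0
    autofluorescence_levels: dict[str, float] = field(
        default_factory=lambda: {"DAPI": 0.0, "Cy2": 2.0, "Cy3": 1.0, "Cy5": 0.5, "Cy7": 0.5}
    )
    dapi_level: float = 50.0
    noise_sigma: float = 1.0
    noise_model: str = "gaussian"  # or "poisson"
    round_shifts: tuple[tuple[float, float], ...] = ((0.0, 0.0), (6.0, -4.0), (-5.0, 3.0), (4.0, 5.0))
    exposure_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPOSURES_MS))
    markers: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    epithelial_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_f <= 1.0:
            raise ValueError("occupancy_f must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.slope_t <= 0 or self.slope_unt <= 0:
            raise ValueError("probe gains must be positive")
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if len(self.round_shifts) != len(ROUND_PLAN):
            raise ValueError(f"round_shifts must list {len(ROUND_PLAN)} rounds")
        rows, cols = self.field_size
        for dy, dx in self.round_shifts:
            if abs(dy) >= rows or abs(dx) >= cols:
                raise ValueError("round shift exceeds field size")
        for name, exp in self.exposure_ms.items():
            if exp <= 0:
                raise ValueError(f"exposure for {name} must be positive")
        if not 0.0 <= self.epithelial_fraction <= 1.0:
            raise ValueError("epithelial_fraction must lie in [0, 1]")

    @property
    def sf_true(self) -> float:
        return self.slope_unt / self.slope_t


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom.

    ``cells`` has one row per cell: cell_id, centroid (row, col), nucleus
    radius and rendered nuclear area, receptor density R, nonspecific
    accumulation N, epithelial flag, per-marker true expression and the true
    per-cell DTA = B * (1 - f) * R / N.
    """

    cells: pd.DataFrame
    round_shifts: tuple[tuple[float, float], ...]
    sf_true: float
    tissue_mask: np.ndarray
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray


def _place_nuclei(config: PhantomConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping nuclei inside the tissue disk.

    Cell regions (nucleus + cytoplasm) are kept pairwise disjoint with at
    least a 1 px gap, and fully inside the tissue disk.
    """
    rows, cols = config.field_size
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    tissue_radius = 0.46 * min(rows, cols)

    radii = rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd, size=config.n_cells)
    radii = np.clip(radii, max(2.0, config.nucleus_radius_mean / 2), None)

    placed = np.empty((config.n_cells, 2))
    max_attempts = 20000 + 400 * config.n_cells
    attempts = 0
    n_placed = 0
    while n_placed < config.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_cells} non-overlapping cells in "
                f"field {config.field_size}; reduce n_cells or enlarge the field"
            )
        r = radii[n_placed]
        reach = tissue_radius - (r + CYTOPLASM_WIDTH_PX + 2)
        if reach <= 0:
            raise ValueError("field too small for a single cell")
        # uniform over the admissible disk
        u = rng.uniform(0, 1)
        theta = rng.uniform(0, 2 * np.pi)
        pos = center + np.sqrt(u) * reach * np.array([np.cos(theta), np.sin(theta)])
        if n_placed:
            d = np.hypot(*(placed[:n_placed] - pos).T)
            min_sep = radii[:n_placed] + r + 2 * CYTOPLASM_WIDTH_PX + 1
            if np.any(d < min_sep):
                continue
        placed[n_placed] = pos
        n_placed += 1
    return placed, radii, center, tissue_radius


def _render_labels(config: PhantomConfig, centers: np.ndarray, radii: np.ndarray):
    """Paint nucleus and whole-cell (nucleus + annulus) label images."""
    rows, cols = config.field_size
    nucleus = np.zeros((rows, cols), dtype=np.int32)
    cell = np.zeros((rows, cols), dtype=np.int32)
    for k in range(len(radii)):
        cy, cx = centers[k]
        r_cell = radii[k] + CYTOPLASM_WIDTH_PX
        r0, r1 = int(np.floor(cy - r_cell)) - 1, int(np.ceil(cy + r_cell)) + 2
        c0, c1 = int(np.floor(cx - r_cell)) - 1, int(np.ceil(cx + r_cell)) + 2
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell[r0:r1, c0:c1][d2 <= r_cell**2] = k + 1
        nucleus[r0:r1, c0:c1][d2 <= radii[k] ** 2] = k + 1
    return nucleus, cell


def _per_cell_map(values: np.ndarray, cell_labels: np.ndarray) -> np.ndarray:
    """Broadcast a per-cell value vector onto the cell-region label image."""
    out = np.zeros(cell_labels.shape, dtype=np.float64)
    m = cell_labels > 0
    out[m] = values[cell_labels[m] - 1]
    return out


def _acquire(
    rate: np.ndarray,
    shift: tuple[float, float],
    exposure: float,
    noise_sigma: float,
    noise_model: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Displace the clean scene, scale by exposure and add acquisition noise."""
    if shift != (0.0, 0.0):
        rate = ndi.shift(rate, shift, order=1, mode="constant", cval=0.0)
        rate = np.clip(rate, 0.0, None)
    img = exposure * rate
    if noise_model == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    elif noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, None)


def generate_phantom(config: PhantomConfig) -> tuple[list[dict[str, ChannelImage]], PhantomTruth]:
    """Generate the multi-round image stack and its ground truth.

    Returns
    -------
    rounds
        One dict per imaging round mapping channel name to
        :class:`~tripodd.dta.ChannelImage`; every round contains DAPI.
    truth
        :class:`PhantomTruth` with the per-cell table, true round shifts,
        true SF and the noise-free label images.

    Deterministic: the same config (including seed) yields bit-identical
    stacks and truth.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.field_size

    if config.n_cells > 0:
        centers, radii, field_center, tissue_radius = _place_nuclei(config, rng)
        nucleus_labels, cell_labels = _render_labels(config, centers, radii)
    else:
        centers = np.empty((0, 2))
        radii = np.empty(0)
        field_center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
        tissue_radius = 0.46 * min(rows, cols)
        nucleus_labels = np.zeros((rows, cols), dtype=np.int32)
        cell_labels = np.zeros((rows, cols), dtype=np.int32)

    yy, xx = np.mgrid[0:rows, 0:cols]
    tissue = (yy - field_center[0]) ** 2 + (xx - field_center[1]) ** 2 <= tissue_radius**2

    n = config.n_cells
    receptor = rng.lognormal(config.receptor_log_mean, config.receptor_log_sigma, size=n)
    nonspecific = rng.lognormal(config.nonspecific_log_mean, config.nonspecific_log_sigma, size=n)
    epithelial = rng.uniform(size=n) < config.epithelial_fraction
    dta_true = config.binding_gain * (1.0 - config.occupancy_f) * receptor / nonspecific

    marker_levels: dict[str, np.ndarray] = {}
    for spec in config.markers:
        level = rng.lognormal(spec.log_mean, spec.log_sigma, size=n)
        if spec.epithelial:
            neg = rng.lognormal(spec.negative_log_mean, spec.log_sigma, size=n)
            level = np.where(epithelial, level, neg)
        if spec.positive_fraction < 1.0:
            positive = rng.uniform(size=n) < spec.positive_fraction
            level = np.where(positive, level, 0.0)
        marker_levels[spec.name] = level

    # clean per-channel signal rates (fluorescence per ms, before AF/noise)
    af = config.autofluorescence_levels
    specific = config.binding_gain * (1.0 - config.occupancy_f) * receptor
    rates: dict[str, np.ndarray] = {
        "DAPI": np.where(nucleus_labels > 0, config.dapi_level, 0.0),
        "probe_T": config.slope_t * _per_cell_map(specific + nonspecific, cell_labels),
        "probe_UnT": config.slope_unt * _per_cell_map(nonspecific, cell_labels),
        "AF_Cy2": np.zeros((rows, cols)),
        "AF_Cy3": np.zeros((rows, cols)),
        "AF_Cy5": np.zeros((rows, cols)),
    }
    for spec in config.markers:
        rates[spec.name] = _per_cell_map(marker_levels[spec.name], cell_labels)
    # wavelength-specific autofluorescence over the tissue disk
    for name in list(rates):
        wl = CHANNEL_WAVELENGTHS[name]
        level = af.get(wl, 0.0)
        if level > 0:
            rates[name] = rates[name] + np.where(tissue, level, 0.0)

    stack: list[dict[str, ChannelImage]] = []
    for round_idx, channels in enumerate(ROUND_PLAN):
        shift = tuple(config.round_shifts[round_idx])
        round_images: dict[str, ChannelImage] = {}
        for name in channels:
            exposure = config.exposure_ms[name]
            pixels = _acquire(
                rates[name], shift, exposure, config.noise_sigma, config.noise_model, rng
            )
            round_images[name] = ChannelImage(
                pixels=pixels,
                wavelength=CHANNEL_WAVELENGTHS[name],
                label=name,
                exposure_ms=exposure,
            )
        stack.append(round_images)

    nuclear_area = (
        ndi.sum_labels(np.ones_like(nucleus_labels), nucleus_labels, index=np.arange(1, n + 1))
        if n
        else np.empty(0)
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=np.int64),
            "row": centers[:, 0],
            "col": centers[:, 1],
            "radius_px": radii,
            "nuclear_area_px": nuclear_area.astype(np.int64) if n else nuclear_area,
            "receptor_density": receptor,
            "nonspecific": nonspecific,
            "epithelial": epithelial,
            "dta_true": dta_true,
        }
    )
    for name, level in marker_levels.items():
        cells[f"marker_{name}"] = level

    truth = PhantomTruth(
        cells=cells,
        round_shifts=tuple(tuple(s) for s in config.round_shifts),
        sf_true=config.sf_true,
        tissue_mask=tissue,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
    )
    return stack, truth


@dataclass
class TitrationImageSet:
    """Images of each probe at titrated concentrations (plus metadata)."""

    concentrations: tuple[float, ...]
    targeted: list[np.ndarray]
    untargeted: list[np.ndarray]

    def mean_intensities(self) -> "pd.DataFrame":
        """Per-image mean intensity table (columns: probe, concentration, mean_intensity)."""
        records = []
        for probe, images in (("targeted", self.targeted), ("untargeted", self.untargeted)):
            for c, img in zip(self.concentrations, images):
                records.append(
                    {"probe": probe, "concentration": c, "mean_intensity": float(img.mean())}
                )
        return pd.DataFrame.from_records(records)


def generate_titration(
    slope_t: float,
    slope_unt: float,
    concentrations,
    noise_sigma: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] = (64, 64),
) -> TitrationImageSet:
    """Simulate the titration imaging series used to calibrate SF.

    Each image is a uniform field of ``slope * concentration`` plus additive
    Gaussian noise truncated at zero, so the mean intensity of the image at
    concentration ``c`` equals ``slope * c`` up to noise. Deterministic for a
    fixed seed.

    Raises
    ------
    ValueError
        With fewer than 2 distinct concentrations, a negative concentration
        or non-positive slopes.
    """
    conc = tuple(float(c) for c in concentrations)
    if len(set(conc)) < 2:
        raise ValueError("titration needs >= 2 distinct concentrations")
    if any(c < 0 for c in conc):
        raise ValueError("concentrations must be nonnegative")
    if slope_t <= 0 or slope_unt <= 0:
        raise ValueError("probe gains must be positive")
    rng = np.random.default_rng(seed)
    targeted, untargeted = [], []
    for slope, out in ((slope_t, targeted), (slope_unt, untargeted)):
        for c in conc:
            img = np.full(image_size, slope * c, dtype=np.float64)
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, size=image_size)
            out.append(np.clip(img, 0.0, None))
    return TitrationImageSet(concentrations=conc, targeted=targeted, untargeted=untargeted)
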