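"""Readers, writers and run configuration.

Images travel as TIFF (one file per channel, or multi-page per round);
channel metadata (marker name, wavelength, exposure) is manifest-driven —
a YAML run configuration names every file explicitly rather than relying on
filename conventions. Tables are CSV, results and provenance JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dta import ChannelImage, DTAMap, TissueMask
from .qc import NormalizationSpec

__all__ = [
    "ChannelSpec",
    "TissueEntry",
    "RunConfig",
    "load_run_config",
    "load_stack",
    "read_channel_tiff",
    "write_channel_tiff",
    "write_dta_map",
    "read_dta_map",
    "write_mask",
    "read_mask",
    "write_labels",
    "read_labels",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Manifest entry for one acquired channel."""

    path: str
    name: str
    wavelength: str
    exposure_ms: float
    round_index: int = 0

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError(f"channel {self.name!r}: exposure must be positive")


@dataclass(frozen=True)
class TissueEntry:
    """One tissue section: its channels plus cohort/treatment label."""

    tissue_id: str
    cohort: str
    channels: tuple[ChannelSpec, ...]


@dataclass
class RunConfig:
    """Validated end-to-end pipeline configuration.

    ``sf_source`` is either a ScalingFactor JSON file or a titration CSV
    (columns probe, concentration, mean_intensity) from which SF is fitted.
    ``channel_wavelength_map`` maps marker names to the wavelength whose
    autofluorescence is subtracted from them.
    """

    tissues: tuple[TissueEntry, ...]
    sf_source: str
    out_dir: str
    spec: NormalizationSpec = field(default_factory=NormalizationSpec)
    channel_wavelength_map: dict[str, str] = field(default_factory=dict)
    af_channels: dict[str, str] = field(default_factory=dict)
    targeted_channel: str = "probe_T"
    untargeted_channel: str = "probe_UnT"
    tissue_reference_channel: str = "AF_Cy2"
    floor_eps: float = 1e-3
    cell_expansion_px: int = 3
    min_nucleus_area_px: int = 15
    zscore: bool = True
    seed: int = 0

    def validate(self, base_dir: Path | None = None) -> None:
        """Check every referenced file exists and metadata is complete."""
        base = Path(base_dir) if base_dir else Path(".")
        missing = []
        for tissue in self.tissues:
            for ch in tissue.channels:
                p = Path(ch.path)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    missing.append(str(p))
        sf = Path(self.sf_source)
        if not sf.is_absolute():
            sf = base / sf
        if not sf.exists():
            missing.append(str(sf))
        if missing:
            raise FileNotFoundError(f"run config references missing files: {missing}")
        for tissue in self.tissues:
            markers = {
                ch.name
                for ch in tissue.channels
                if ch.name not in self.af_channels
                and ch.name not in (self.targeted_channel, self.untargeted_channel)
                and ch.wavelength != "DAPI"
            }
            unmapped = markers - set(self.channel_wavelength_map)
            if unmapped:
                raise ValueError(
                    f"tissue {tissue.tissue_id!r}: markers without a wavelength "
                    f"mapping: {sorted(unmapped)}"
                )

    def config_hash(self) -> str:
        """Stable digest of the configuration, stamped into outputs."""
        payload = json.dumps(_config_to_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_to_dict(config: RunConfig) -> dict:
    return {
        "tissues": [
            {
                "tissue_id": t.tissue_id,
                "cohort": t.cohort,
                "channels": [vars(c) for c in t.channels],
            }
            for t in config.tissues
        ],
        "sf_source": config.sf_source,
        "out_dir": config.out_dir,
        "spec": vars(config.spec),
        "channel_wavelength_map": config.channel_wavelength_map,
        "af_channels": config.af_channels,
        "targeted_channel": config.targeted_channel,
        "untargeted_channel": config.untargeted_channel,
        "tissue_reference_channel": config.tissue_reference_channel,
        "floor_eps": config.floor_eps,
        "cell_expansion_px": config.cell_expansion_px,
        "min_nucleus_area_px": config.min_nucleus_area_px,
        "zscore": config.zscore,
        "seed": config.seed,
    }


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    tissues = tuple(
        TissueEntry(
            tissue_id=t["tissue_id"],
            cohort=t["cohort"],
            channels=tuple(ChannelSpec(**c) for c in t["channels"]),
        )
        for t in raw["tissues"]
    )
    spec_raw = raw.get("normalization", {})
    if "size_quantiles" in spec_raw:
        spec_raw["size_quantiles"] = tuple(spec_raw["size_quantiles"])
    if "epithelial_markers" in spec_raw:
        spec_raw["epithelial_markers"] = tuple(spec_raw["epithelial_markers"])
    config = RunConfig(
        tissues=tissues,
        sf_source=raw["sf_source"],
        out_dir=raw.get("out_dir", "tripodd_run"),
        spec=NormalizationSpec(**spec_raw),
        channel_wavelength_map=raw.get("channel_wavelength_map", {}),
        af_channels=raw.get("af_channels", {}),
        targeted_channel=raw.get("targeted_channel", "probe_T"),
        untargeted_channel=raw.get("untargeted_channel", "probe_UnT"),
        tissue_reference_channel=raw.get("tissue_reference_channel", "AF_Cy2"),
        floor_eps=float(raw.get("floor_eps", 1e-3)),
        cell_expansion_px=int(raw.get("cell_expansion_px", 3)),
        min_nucleus_area_px=int(raw.get("min_nucleus_area_px", 15)),
        zscore=bool(raw.get("zscore", True)),
        seed=int(raw.get("seed", 0)),
    )
    config.validate(base_dir=path.parent)
    return config


# ---------------------------------------------------------------------------
# image I/O


def read_channel_tiff(
    path: str | Path, name: str, wavelength: str, exposure_ms: float
) -> ChannelImage:
    pixels = tifffile.imread(str(path))
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D TIFF, got shape {pixels.shape}")
    return ChannelImage(
        pixels=np.asarray(pixels, dtype=np.float64),
        wavelength=wavelength,
        label=name,
        exposure_ms=exposure_ms,
    )


def write_channel_tiff(path: str | Path, image: ChannelImage) -> None:
    tifffile.imwrite(
        str(path),
        image.pixels.astype(np.float32),
        metadata={
            "axes": "YX",
            "name": image.label,
            "wavelength": image.wavelength,
            "exposure_ms": image.exposure_ms,
        },
    )


def load_stack(
    tissue: TissueEntry, base_dir: str | Path = "."
) -> dict[int, dict[str, ChannelImage]]:
    """Load one tissue's channels grouped by round, shape-checked.

    Raises on unreadable files or a shape mismatch across channels.
    """
    base = Path(base_dir)
    rounds: dict[int, dict[str, ChannelImage]] = {}
    shape = None
    for ch in tissue.channels:
        p = Path(ch.path)
        if not p.is_absolute():
            p = base / p
        img = read_channel_tiff(p, ch.name, ch.wavelength, ch.exposure_ms)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"tissue {tissue.tissue_id!r}: channel {ch.name!r} shape "
                f"{img.shape} != {shape}"
            )
        rounds.setdefault(ch.round_index, {})[ch.name] = img
    return rounds


def write_dta_map(path: str | Path, dta_map: DTAMap, provenance: dict | None = None) -> None:
    """DTA map as 32-bit float TIFF (NaN at invalid pixels) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(str(path), dta_map.dta.astype(np.float32))
    sidecar = {
        "sf_used": dta_map.sf_used,
        "floor_eps": dta_map.floor_eps,
        "n_valid": int(dta_map.valid.sum()),
    }
    if provenance:
        sidecar.update(provenance)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_dta_map(path: str | Path) -> DTAMap:
    path = Path(path)
    dta = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return DTAMap(
        dta=dta,
        valid=np.isfinite(dta),
        sf_used=float(sidecar["sf_used"]),
        floor_eps=float(sidecar["floor_eps"]),
    )


def write_mask(path: str | Path, mask: TissueMask) -> None:
    tifffile.imwrite(str(path), mask.mask.astype(np.uint8) * 255)


def read_mask(path: str | Path, provenance: str = "imported") -> TissueMask:
    arr = tifffile.imread(str(path))
    return TissueMask(mask=arr > 0, provenance=provenance)  # type: ignore[arg-type]


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    dtype = np.uint16 if arr.max() < 2**16 else np.uint32
    tifffile.imwrite(str(path), arr.astype(dtype))


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.int32)


def write_phantom(
    stack: list[dict[str, ChannelImage]],
    truth,
    out_dir: str | Path,
    cohort: str = "control",
    tissue_id: str = "phantom",
) -> Path:
    """Write a generated phantom as TIFFs + truth CSV + a run-ready manifest.

    Returns the path of the manifest fragment (YAML) describing the tissue.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channels = []
    for round_idx, round_images in enumerate(stack):
        for name, img in round_images.items():
            fname = f"{tissue_id}_r{round_idx}_{name}.tif"
            write_channel_tiff(out / fname, img)
            channels.append(
                {
                    "path": fname,
                    "name": name,
                    "wavelength": img.wavelength,
                    "exposure_ms": img.exposure_ms,
                    "round_index": round_idx,
                }
            )
    truth.cells.to_csv(out / f"{tissue_id}_truth.csv", index=False)
    manifest = {
        "tissue_id": tissue_id,
        "cohort": cohort,
        "channels": channels,
    }
    manifest_path = out / f"{tissue_id}_manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
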