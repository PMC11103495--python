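"""Per-pixel drug-target-availability (DTA) maps.

DTA is a ratiometric binding-potential metric computed per pixel from the
targeted and untargeted probe channels:

    DTA = SF * (I_T / I_UnT) - 1

where ``I_T`` is the targeted-probe intensity, ``I_UnT`` the untargeted-probe
intensity and SF the titration-derived scaling factor that converts both
channels to a common concentration-equivalent scale (see
:mod:`tripodd.calibration`). With this form, a pixel where the targeted probe
shows only the same nonspecific accumulation as the untargeted probe has
DTA = 0, and DTA rises with the density of unoccupied target sites. DTA falls
toward 0 when the unlabeled parent drug occupies the target.

The alternative placement of SF on the denominator,
``DTA = I_T / (SF * I_UnT) - 1`` with the reciprocal SF convention, is
available via ``sf_on_untargeted=True`` for compatibility with scripts that
define SF as slope_T/slope_UnT.

DTA is undefined where the untargeted channel is at or below a small floor
(autofluorescence-level denominators make the ratio unstable); such pixels
are marked invalid and excluded from every summary. Negative DTA values are
retained, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .calibration import ScalingFactor

__all__ = [
    "ChannelImage",
    "TissueMask",
    "DTAMap",
    "RegionSummary",
    "compute_dta_map",
    "make_tissue_mask",
    "summarize_region",
]

#: Fallback denominator floor when no autofluorescence reference is supplied.
DEFAULT_FLOOR_EPS = 1e-6


def _pixels(image: "ChannelImage | np.ndarray") -> np.ndarray:
    return image.pixels if isinstance(image, ChannelImage) else np.asarray(image, dtype=float)


@dataclass
class ChannelImage:
    """One 2D fluorescence channel with acquisition metadata.

    Attributes
    ----------
    pixels
        2D array of nonnegative, finite intensities (a.u.).
    wavelength
        Filter-set tag: DAPI, Cy2, Cy3, Cy5 or Cy7.
    label
        Marker or probe name carried by this channel (e.g. ``probe_T``,
        ``CK8``, ``AF``).
    exposure_ms
        Camera exposure; must be positive. Intensities are per-exposure a.u.
        until exposure normalization divides them out.
    pixel_size_um
        Physical pixel pitch, for area conversions.
    """

    pixels: np.ndarray
    wavelength: str
    label: str = ""
    exposure_ms: float = 1.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ChannelImage pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("ChannelImage pixels must be nonnegative")
        if not self.exposure_ms > 0:
            raise ValueError("exposure_ms must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class TissueMask:
    """Boolean foreground mask delimiting the tissue section."""

    mask: np.ndarray
    provenance: Literal["automatic", "imported"] = "automatic"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("tissue mask must be 2D")
        if not self.mask.any():
            raise ValueError("tissue mask has no foreground pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


@dataclass
class DTAMap:
    """Per-pixel DTA values with a validity mask and provenance.

    ``dta`` is finite wherever ``valid``; invalid pixels hold NaN. ``valid``
    is a subset of the tissue mask used at computation time.
    """

    dta: np.ndarray
    valid: np.ndarray
    sf_used: float
    floor_eps: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.dta.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RegionSummary:
    mean: float
    median: float
    lower_quartile: float
    upper_quartile: float
    n_pixels: int


def compute_dta_map(
    targeted: ChannelImage | np.ndarray,
    untargeted: ChannelImage | np.ndarray,
    sf: ScalingFactor | float,
    mask: TissueMask | np.ndarray | None = None,
    floor_eps: float | None = None,
    af_reference: ChannelImage | np.ndarray | None = None,
    sf_on_untargeted: bool = False,
) -> DTAMap:
    """Compute the per-pixel DTA map from paired probe channels.

    For each masked pixel with untargeted intensity strictly above
    ``floor_eps``::

        dta = sf * (I_T / I_UnT) - 1          (default)
        dta = I_T / (sf * I_UnT) - 1          (sf_on_untargeted=True)

    Parameters
    ----------
    floor_eps
        Denominator floor. If None and ``af_reference`` is given, the 95th
        percentile of the reference (autofluorescence / vehicle) image within
        the mask is used; otherwise a small positive constant.
    af_reference
        Optional autofluorescence or vehicle-control image in the untargeted
        probe's channel, used only to derive ``floor_eps``.

    Raises
    ------
    ValueError
        On shape mismatch or non-positive SF.
    """
    i_t = _pixels(targeted)
    i_unt = _pixels(untargeted)
    if i_t.shape != i_unt.shape:
        raise ValueError(f"channel shapes differ: {i_t.shape} vs {i_unt.shape}")
    sf_value = float(sf.sf if isinstance(sf, ScalingFactor) else sf)
    if not sf_value > 0:
        raise ValueError("scaling factor must be positive")

    if mask is None:
        mask_arr = np.ones(i_t.shape, dtype=bool)
    else:
        mask_arr = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != i_t.shape:
        raise ValueError("mask shape does not match images")

    if floor_eps is None:
        if af_reference is not None:
            ref = _pixels(af_reference)
            floor_eps = float(np.percentile(ref[mask_arr], 95))
        else:
            floor_eps = DEFAULT_FLOOR_EPS
    if floor_eps < 0:
        raise ValueError("floor_eps must be nonnegative")

    valid = mask_arr & (i_unt > floor_eps)
    dta = np.full(i_t.shape, np.nan, dtype=np.float64)
    if sf_on_untargeted:
        np.divide(i_t, sf_value * i_unt, out=dta, where=valid)
        dta[valid] -= 1.0
    else:
        np.divide(i_t, i_unt, out=dta, where=valid)
        dta[valid] = sf_value * dta[valid] - 1.0
    return DTAMap(dta=dta, valid=valid, sf_used=sf_value, floor_eps=float(floor_eps))


def make_tissue_mask(
    reference: ChannelImage | np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> TissueMask:
    """Segment the tissue section from a reference channel.

    Replaces manual tissue outlining: threshold the reference image (tissue
    autofluorescence, typically the Cy2 channel), fill holes and keep the
    largest connected foreground component.

    Parameters
    ----------
    method
        ``"otsu"`` (default) or ``"threshold"`` with an explicit ``threshold``.

    Raises
    ------
    ValueError
        If the result has no foreground (empty slide).
    """
    img = _pixels(reference)
    if img.size == 0:
        raise ValueError("reference image is empty")
    if method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("reference image is constant; no tissue found")
        thr = threshold_otsu(img)
    elif method == "threshold":
        if threshold is None:
            raise ValueError("method='threshold' requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown masking method: {method!r}")

    fg = img > thr
    if not fg.any():
        raise ValueError("thresholding found no tissue foreground")
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return TissueMask(mask=fg, provenance="automatic")


def import_tissue_mask(mask: np.ndarray) -> TissueMask:
    """Wrap an externally drawn mask; returned unchanged with provenance."""
    return TissueMask(mask=np.asarray(mask, dtype=bool), provenance="imported")


def summarize_region(
    image_or_map: ChannelImage | DTAMap | np.ndarray,
    mask: TissueMask | np.ndarray,
) -> RegionSummary:
    """Mean, median and quartiles of the masked region.

    For a :class:`DTAMap`, only pixels that are both masked and valid enter
    the summary and ``n_pixels`` counts exactly those.

    Raises
    ------
    ValueError
        If the mask is empty or no valid pixels remain.
    """
    mask_arr = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if isinstance(image_or_map, DTAMap):
        if mask_arr.shape != image_or_map.shape:
            raise ValueError("mask shape does not match map")
        sel = mask_arr & image_or_map.valid
        values = image_or_map.dta[sel]
    else:
        img = _pixels(image_or_map)
        if mask_arr.shape != img.shape:
            raise ValueError("mask shape does not match image")
        values = img[mask_arr]
    if values.size == 0:
        raise ValueError("no valid pixels to summarize")
    lq, med, uq = np.percentile(values, [25, 50, 75])
    return RegionSummary(
        mean=float(values.mean()),
        median=float(med),
        lower_quartile=float(lq),
        upper_quartile=float(uq),
        n_pixels=int(values.size),
    )
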