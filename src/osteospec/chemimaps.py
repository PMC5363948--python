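"""Univariate chemical maps: band integration, detection statistics, rendering.

A chemi-map is the per-pixel trapezoidal integral of intensity over a
band's wavenumber window, optionally after subtracting the straight chord
between the window endpoints (a two-point local baseline).  Detection is a
signal-to-noise criterion: the integral divided by the standard error that
the *same* estimator would produce on pure white noise of known sigma —
including the variance contributed by the chord anchors when a local
baseline is used.  A sample-level verdict requires a minimum fraction of
mineralized-tissue pixels to pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from matplotlib import colormaps

from .errors import ParameterError, SpectralDomainError
from .spectral_core import HyperspectralCube, Spectrum
from .synthetic_data import BandDefinition

DEFAULT_SNR_THRESHOLD = 3.0
DEFAULT_MIN_TISSUE_FRACTION = 0.05


@dataclass(frozen=True)
class ChemiMap:
    """2-D band-integral field with its own noise-propagation factor.

    ``se_factor`` is the standard error of one pixel's integral per unit of
    per-channel noise sigma: multiply by sigma to get the integral's noise
    standard deviation.  ``snr``/``detection``/``sample_detected`` are
    filled in by :func:`detect`.
    """

    values: np.ndarray
    band: BandDefinition
    cube_ref: str
    se_factor: float
    snr: Optional[np.ndarray] = None
    detection: Optional[np.ndarray] = None
    sample_detected: Optional[bool] = None
    threshold: Optional[float] = None

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


class PeakReading(NamedTuple):
    height: float
    wavenumber: float


def _window_weights(x: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights on a (possibly non-uniform) grid."""
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    if len(x) > 2:
        w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return w


def integrate_band(
    cube: HyperspectralCube,
    band: BandDefinition,
    local_baseline: bool = False,
    endpoint_channels: int = 1,
) -> ChemiMap:
    """Per-pixel trapezoidal area under the band window.

    With ``local_baseline`` the chord between the window's endpoint
    anchors is subtracted first.  Anchors are the means of the first and
    last ``endpoint_channels`` channels of the window (1 = the classic
    two-point chord; a few channels makes the anchor noise-robust while
    still exactly annihilating any straight-line segment).
    """
    lo, hi = band.window
    idx = cube.axis.window_indices(lo, hi)
    if idx.size < 3:
        raise SpectralDomainError(
            f"band {band.name}: window [{lo}, {hi}] overlaps axis by "
            f"{idx.size} channels (< 3)"
        )
    if endpoint_channels < 1 or 2 * endpoint_channels > idx.size:
        raise ParameterError("endpoint_channels must be >= 1 and fit inside the window")
    x = cube.axis.values[idx]
    block = cube.data[:, :, idx]  # (H, W, n)
    w = _window_weights(x)
    values = np.tensordot(block, w, axes=([2], [0]))
    var_factor = float(np.sum(w**2))
    if local_baseline:
        m = endpoint_channels
        x_lo, x_hi = x[:m].mean(), x[-m:].mean()
        y_lo = block[:, :, :m].mean(axis=2)
        y_hi = block[:, :, -m:].mean(axis=2)
        # trapezoid integral of the chord through (x_lo, y_lo), (x_hi, y_hi):
        # sum_i w_i * (y_lo + slope*(x_i - x_lo)) = c_lo*y_lo + c_hi*y_hi
        s0 = float(np.sum(w))
        s1 = float(np.sum(w * (x - x_lo)))
        dx = x_hi - x_lo
        c_lo = s0 - s1 / dx
        c_hi = s1 / dx
        values = values - (c_lo * y_lo + c_hi * y_hi)
        # anchor means carry var sigma^2/m each; add their propagated variance
        var_factor += (c_lo**2 + c_hi**2) / m
    se_factor = float(np.sqrt(var_factor))
    ref = f"{cube.sample_id}:{cube.modality}"
    if not np.all(np.isfinite(values)):
        raise SpectralDomainError("non-finite band integrals")
    return ChemiMap(values=values, band=band, cube_ref=ref, se_factor=se_factor)


def peak_height(
    spectrum: Spectrum,
    center: float,
    search_halfwidth: float,
    local_baseline: bool = False,
) -> PeakReading:
    """Maximum intensity in [center ± halfwidth], optionally chord-corrected.

    Returns the height and the wavenumber where it occurs.  The window is
    clipped to the axis; reading a windowed maximum rather than the value
    at a fixed channel makes the result robust to small calibration shifts.
    """
    idx = spectrum.axis.window_indices(center - search_halfwidth, center + search_halfwidth)
    if idx.size == 0:
        raise SpectralDomainError(
            f"peak window [{center - search_halfwidth}, {center + search_halfwidth}] "
            "does not overlap the axis"
        )
    x = spectrum.axis.values[idx]
    y = spectrum.intensities[idx].copy()
    if local_baseline and idx.size >= 2:
        chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / max(x[-1] - x[0], np.finfo(float).tiny)
        y = y - chord
    k = int(np.argmax(y))
    return PeakReading(height=float(y[k]), wavenumber=float(x[k]))


def detect(
    cmap: ChemiMap,
    noise_sigma: float,
    threshold: float = DEFAULT_SNR_THRESHOLD,
    tissue_mask: Optional[np.ndarray] = None,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
) -> ChemiMap:
    """Attach per-pixel SNR/detection fields and a sample-level verdict.

    SNR = integral / (noise_sigma * se_factor) where se_factor is the exact
    standard error of this map's integral estimator per unit sigma.  The
    sample is 'detected' iff at least ``min_tissue_fraction`` of tissue
    pixels (all pixels when no mask is given) pass the threshold.
    """
    if not noise_sigma > 0:
        raise ParameterError("noise_sigma must be > 0")
    snr = np.clip(cmap.values / (noise_sigma * cmap.se_factor), 0.0, None)
    detection = snr >= threshold
    if tissue_mask is None:
        frac = detection.mean()
    else:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
        if tissue_mask.shape != cmap.values.shape:
            raise ParameterError("tissue mask shape does not match map")
        if not tissue_mask.any():
            raise ParameterError("tissue mask selects no pixels")
        frac = detection[tissue_mask].mean()
    return replace(
        cmap,
        snr=snr,
        detection=detection,
        sample_detected=bool(frac >= min_tissue_fraction),
        threshold=float(threshold),
    )


def render_map(
    cmap: ChemiMap,
    out_path,
    colormap_name: str = "inferno",
    percentile_clip: Sequence[float] = (2.0, 98.0),
) -> None:
    """Write a false-colour PNG, one image pixel per map pixel (no resampling)."""
    p_lo, p_hi = percentile_clip
    if not (0 <= p_lo < p_hi <= 100):
        raise ParameterError("percentile_clip must satisfy 0 <= p_lo < p_hi <= 100")
    v = cmap.values
    lo = np.percentile(v, p_lo)
    hi = np.percentile(v, p_hi)
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((v - lo) / span, 0.0, 1.0)
    rgba = (colormaps[colormap_name](norm) * 255).astype(np.uint8)
    Image.fromarray(rgba, mode="RGBA").save(out_path)


def chemimap_to_csv(cmap: ChemiMap, path) -> None:
    """Long-format CSV export: x, y, value, snr, detected."""
    h, w = cmap.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x,y,value,snr,detected\n")
        for r in range(h):
            for c in range(w):
                snr = cmap.snr[r, c] if cmap.snr is not None else ""
                det = int(cmap.detection[r, c]) if cmap.detection is not None else ""
                fh.write(f"{c},{r},{cmap.values[r, c]!r},{snr},{det}\n")
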