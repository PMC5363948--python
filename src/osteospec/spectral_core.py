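"""Spectra, hyperspectral cubes, file I/O and spectral pretreatment.

The data model is deliberately small: a :class:`WavenumberAxis` (strictly
monotonic cm⁻¹ grid, stored ascending), a :class:`Spectrum` (axis +
intensities + modality) and a :class:`HyperspectralCube`
(height × width × n_channels block with acquisition metadata).  All
pretreatment operations are pure functions returning new objects; nothing
mutates in place.

Modalities
----------
``reflection`` and ``atr`` are FTIR absorbance-like modes acquired between
600 and 4000 cm⁻¹; ``raman`` is a 785 nm Raman-shift axis between 0 and
1776 cm⁻¹.  Axis-range legality is enforced on cube construction.

Cube container format (version 1)
---------------------------------
A self-describing header of UTF-8 ``key=value`` lines followed by a dense
little-endian float64 payload in C order (row, column, channel):

    line 1:  ``OSTEOSPEC-CUBE 1 <n_header_lines>``
    lines 2..n: ``key=value`` — required keys ``height``, ``width``,
        ``n_channels``, ``pixel_pitch_um``, ``modality``, ``axis``
        (comma-separated cm⁻¹ values); optional ``sample_id``, ``pmi_days``.
    payload: ``8 * height * width * n_channels`` bytes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateSpectrumError,
    FormatError,
    IntegrityError,
    ParameterError,
    SpectralDomainError,
    SuspiciousSpectrumError,
)

MODALITIES = ("reflection", "atr", "raman")

#: legal axis range per modality, with a small tolerance at the edges
_MODALITY_RANGE = {
    "reflection": (600.0 - 1.0, 4000.0 + 1.0),
    "atr": (600.0 - 1.0, 4000.0 + 1.0),
    "raman": (0.0 - 1e-9, 1776.0 + 1.0),
}

_MAGIC = "OSTEOSPEC-CUBE"
_FORMAT_VERSION = 1


def _check_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise ParameterError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return modality


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotonic wavenumber grid in cm⁻¹, stored ascending.

    Descending input (the native storage order of many FTIR instruments)
    is accepted and flipped; the original direction is recorded so writers
    can round-trip it.
    """

    values: np.ndarray
    resolution_hint: Optional[float] = None
    descending_input: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ParameterError("axis needs at least 2 wavenumbers")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ParameterError("axis values must be finite and >= 0")
        d = np.diff(v)
        if np.all(d > 0):
            desc = False
        elif np.all(d < 0):
            v = v[::-1].copy()
            desc = True
        else:
            raise ParameterError("axis must be strictly monotonic")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "descending_input", bool(self.descending_input or desc))
        if self.resolution_hint is None:
            object.__setattr__(self, "resolution_hint", float(np.median(np.diff(v))))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of channels with lo <= wavenumber <= hi (closed interval)."""
        if not lo < hi:
            raise ParameterError(f"window requires lo < hi, got [{lo}, {hi}]")
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: intensities (a.u.) on a wavenumber axis."""

    axis: WavenumberAxis
    intensities: np.ndarray
    modality: str = "atr"

    def __post_init__(self):
        _check_modality(self.modality)
        y = np.asarray(self.intensities, dtype=float)
        if self.axis.descending_input and y.ndim == 1 and len(y) == len(self.axis):
            # caller supplied intensities in the original (descending) order
            pass
        if y.shape != (len(self.axis),):
            raise ParameterError(
                f"intensities shape {y.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ParameterError("intensities must be finite")
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class SpectralMask:
    """Wavenumber windows flagged for exclusion (e.g. atmospheric bands)."""

    windows: Sequence[tuple] = field(default_factory=tuple)

    def __post_init__(self):
        ws = []
        for lo, hi in self.windows:
            if not lo < hi:
                raise ParameterError(f"mask window requires lo < hi, got [{lo}, {hi}]")
            ws.append((float(lo), float(hi)))
        object.__setattr__(self, "windows", tuple(ws))


#: default atmospheric-interferent masks: CO2 asymmetric stretch and the
#: strongest water-vapour rotational band region. Raman needs none.
DEFAULT_ATMOSPHERIC_MASK = {
    "reflection": SpectralMask(((2300.0, 2400.0), (1800.0, 1900.0))),
    "atr": SpectralMask(((2300.0, 2400.0), (1800.0, 1900.0))),
    "raman": SpectralMask(()),
}


@dataclass(frozen=True)
class HyperspectralCube:
    """(height × width × n_channels) intensity block plus acquisition metadata.

    ``pixel_pitch`` is the lateral scan-point spacing in μm; ``pmi_days``
    is the known post-mortem interval of the sample when available.
    """

    axis: WavenumberAxis
    data: np.ndarray
    modality: str
    pixel_pitch: float
    sample_id: str = ""
    pmi_days: Optional[float] = None

    def __post_init__(self):
        _check_modality(self.modality)
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ParameterError("cube data must be 3-D (height, width, channels)")
        if d.shape[2] != len(self.axis):
            raise IntegrityError(
                f"cube has {d.shape[2]} channels but axis has {len(self.axis)}"
            )
        if not self.pixel_pitch > 0:
            raise ParameterError("pixel_pitch must be > 0")
        lo, hi = _MODALITY_RANGE[self.modality]
        if self.axis.lo < lo or self.axis.hi > hi:
            raise ParameterError(
                f"{self.modality} axis [{self.axis.lo}, {self.axis.hi}] outside "
                f"legal range [{lo}, {hi}]"
            )
        if self.pmi_days is not None and self.pmi_days < 0:
            raise ParameterError("pmi_days must be nonnegative")
        object.__setattr__(self, "data", d)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.data[row, col], self.modality)

    def as_matrix(self) -> np.ndarray:
        """Pixels flattened to (height*width, n_channels), C order."""
        return self.data.reshape(-1, self.n_channels)


# ---------------------------------------------------------------------------
# cube container I/O


def write_cube(cube: HyperspectralCube, path) -> None:
    """Write a cube to the self-describing container format (see module docs)."""
    fields = {
        "height": cube.height,
        "width": cube.width,
        "n_channels": cube.n_channels,
        "pixel_pitch_um": repr(float(cube.pixel_pitch)),
        "modality": cube.modality,
        "sample_id": cube.sample_id,
        "axis_descending_input": int(cube.axis.descending_input),
        "axis": ",".join(repr(float(v)) for v in cube.axis.values),
    }
    if cube.pmi_days is not None:
        fields["pmi_days"] = repr(float(cube.pmi_days))
    lines = [f"{k}={v}" for k, v in fields.items()]
    header = f"{_MAGIC} {_FORMAT_VERSION} {len(lines) + 1}\n" + "\n".join(lines) + "\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("utf-8"))
        fh.write(np.ascontiguousarray(cube.data, dtype="<f8").tobytes())


def read_cube(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`; exact inverse."""
    with open(path, "rb") as fh:
        first = fh.readline().decode("utf-8").rstrip("\n")
        parts = first.split()
        if len(parts) != 3 or parts[0] != _MAGIC:
            raise FormatError(f"not an {_MAGIC} container: bad magic line {first!r}")
        n_header = int(parts[2])
        fields = {}
        for _ in range(n_header - 1):
            line = fh.readline().decode("utf-8").rstrip("\n")
            if "=" not in line:
                raise FormatError(f"malformed header line {line!r}")
            k, _, v = line.partition("=")
            fields[k] = v
        for req in ("height", "width", "n_channels", "pixel_pitch_um", "modality", "axis"):
            if req not in fields:
                raise FormatError(f"header missing required field {req!r}")
        h = int(fields["height"])
        w = int(fields["width"])
        n = int(fields["n_channels"])
        payload = fh.read()
    expected = 8 * h * w * n
    if len(payload) != expected:
        raise IntegrityError(
            f"payload is {len(payload)} bytes; header declares {h}x{w}x{n} "
            f"({expected} bytes)"
        )
    data = np.frombuffer(payload, dtype="<f8").reshape(h, w, n)
    axis_vals = np.array([float(x) for x in fields["axis"].split(",")])
    if len(axis_vals) != n:
        raise IntegrityError("axis length disagrees with declared n_channels")
    axis = WavenumberAxis(
        axis_vals, descending_input=bool(int(fields.get("axis_descending_input", "0")))
    )
    pmi = fields.get("pmi_days")
    return HyperspectralCube(
        axis=axis,
        data=data.copy(),
        modality=fields["modality"],
        pixel_pitch=float(fields["pixel_pitch_um"]),
        sample_id=fields.get("sample_id", ""),
        pmi_days=float(pmi) if pmi not in (None, "") else None,
    )


def spectrum_to_csv(spectrum: Spectrum, path) -> None:
    """Plain two-column CSV exporter: ``wavenumber_cm-1,intensity``."""
    buf = io.StringIO()
    buf.write("wavenumber_cm-1,intensity\n")
    for x, y in zip(spectrum.axis.values, spectrum.intensities):
        buf.write(f"{x!r},{y!r}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# pretreatment


def crop_spectral(
    obj: Union[Spectrum, HyperspectralCube], lo: float, hi: float
) -> Union[Spectrum, HyperspectralCube]:
    """Keep only channels with lo <= wavenumber <= hi. No interpolation."""
    if not lo < hi:
        raise ParameterError(f"crop requires lo < hi, got [{lo}, {hi}]")
    idx = obj.axis.window_indices(lo, hi)
    if idx.size == 0:
        raise SpectralDomainError(f"crop window [{lo}, {hi}] does not overlap the axis")
    return _take_channels(obj, idx)


def _take_channels(obj, idx):
    axis = WavenumberAxis(
        obj.axis.values[idx],
        resolution_hint=obj.axis.resolution_hint,
        descending_input=obj.axis.descending_input,
    )
    if isinstance(obj, Spectrum):
        return Spectrum(axis, obj.intensities[idx], obj.modality)
    return replace(obj, axis=axis, data=obj.data[:, :, idx])


def vector_normalize(
    spectrum: Spectrum, lo: Optional[float] = None, hi: Optional[float] = None
) -> Spectrum:
    """Scale so the Euclidean norm over channels in [lo, hi] equals 1.

    Channels outside the window are scaled by the same factor, preserving
    shape and relative intensities.  Defaults to the full axis range.
    """
    lo = spectrum.axis.lo if lo is None else lo
    hi = spectrum.axis.hi if hi is None else hi
    idx = spectrum.axis.window_indices(lo, hi)
    if idx.size == 0:
        raise SpectralDomainError(f"normalization window [{lo}, {hi}] is empty")
    norm = float(np.linalg.norm(spectrum.intensities[idx]))
    if norm <= 0.0:
        raise DegenerateSpectrumError("zero-norm spectrum (dead pixel?)")
    return Spectrum(spectrum.axis, spectrum.intensities / norm, spectrum.modality)


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (x, y) evaluated at every x (Andrew monotone chain)."""
    n = len(x)
    hull = [0]
    for i in range(1, n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on/above the segment j->i (non-left turn)
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    hx = x[hull]
    hy = y[hull]
    return np.interp(x, hx, hy)


def rubberband_baseline(spectrum: Spectrum) -> Spectrum:
    """Subtract the lower convex hull of the (wavenumber, intensity) points.

    The classic parameter-free 'rubberband' correction: the baseline is the
    hull stretched beneath the spectrum, so the output is ~0 at every hull
    contact point, nonnegative (up to rounding), and invariant to adding
    any affine function of wavenumber.
    """
    if len(spectrum.axis) < 3:
        raise ParameterError("rubberband baseline needs at least 3 channels")
    base = _lower_hull_baseline(spectrum.axis.values, spectrum.intensities)
    return Spectrum(spectrum.axis, spectrum.intensities - base, spectrum.modality)


def rubberband_baseline_matrix(axis: WavenumberAxis, matrix: np.ndarray) -> np.ndarray:
    """Rubberband correction of each row of a (spectra × channels) matrix."""
    x = axis.values
    out = np.empty_like(matrix, dtype=float)
    for i in range(matrix.shape[0]):
        out[i] = matrix[i] - _lower_hull_baseline(x, matrix[i])
    return out


def smooth(spectrum: Spectrum, window_channels: int = 9, polyorder: int = 2) -> Spectrum:
    """Savitzky–Golay local polynomial smoothing.

    Reproduces any polynomial of degree <= polyorder exactly, which is the
    defining property of the filter.
    """
    n = len(spectrum.axis)
    if window_channels % 2 != 1:
        raise ParameterError("window_channels must be odd")
    if not (polyorder < window_channels <= n):
        raise ParameterError(
            f"need polyorder < window_channels <= n_channels "
            f"({polyorder}, {window_channels}, {n})"
        )
    y = savgol_filter(spectrum.intensities, window_channels, polyorder)
    return Spectrum(spectrum.axis, y, spectrum.modality)


def apply_mask(
    obj: Union[Spectrum, HyperspectralCube], mask: SpectralMask
) -> Union[Spectrum, HyperspectralCube]:
    """Remove masked channels entirely (not zero-fill).

    Downstream norms and integrals then run over retained channels only,
    which is the point of removing rather than zeroing.
    """
    keep = np.ones(len(obj.axis), dtype=bool)
    for lo, hi in mask.windows:
        keep &= ~((obj.axis.values >= lo) & (obj.axis.values <= hi))
    if not keep.any():
        raise DegenerateSpectrumError("mask removes every channel")
    if keep.all():
        return obj
    return _take_channels(obj, np.nonzero(keep)[0])


def despike(spectrum: Spectrum, z_threshold: float = 8.0) -> Spectrum:
    """Remove cosmic-ray spikes from a Raman spectrum.

    Channels whose modified z-score of the first difference exceeds
    ``z_threshold`` are replaced by linear interpolation of the nearest
    clean neighbours (Whitaker–Hayes style).  Refuses to alter more than
    5% of channels — that is not a cosmic-ray pattern.
    """
    if not z_threshold > 0:
        raise ParameterError("z_threshold must be > 0")
    if spectrum.modality != "raman":
        raise ParameterError("despike applies to Raman spectra only")
    y = spectrum.intensities
    d = np.diff(y)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0.0:
        mad = np.finfo(float).tiny
    with np.errstate(over="ignore"):
        z = 0.6745 * (d - med) / mad
    bad_diff = np.abs(z) > z_threshold
    # a spike at channel i makes both diffs i-1 and i large; flag channels
    # adjacent to any flagged difference
    bad = np.zeros(len(y), dtype=bool)
    bad[:-1] |= bad_diff
    bad[1:] |= bad_diff
    if not bad.any():
        return spectrum
    if bad.sum() > 0.05 * len(y):
        raise SuspiciousSpectrumError(
            f"{bad.sum()}/{len(y)} channels flagged (> 5%); not treating as spikes"
        )
    x = spectrum.axis.values
    out = y.copy()
    out[bad] = np.interp(x[bad], x[~bad], y[~bad])
    return Spectrum(spectrum.axis, out, spectrum.modality)


def mean_spectrum(
    cube: HyperspectralCube, pixel_mask: Optional[np.ndarray] = None
) -> Spectrum:
    """Channel-wise arithmetic mean over selected pixels (all by default)."""
    if pixel_mask is None:
        m = cube.data.reshape(-1, cube.n_channels).mean(axis=0)
    else:
        pixel_mask = np.asarray(pixel_mask, dtype=bool)
        if pixel_mask.shape != (cube.height, cube.width):
            raise ParameterError(
                f"pixel mask shape {pixel_mask.shape} does not match cube "
                f"({cube.height}, {cube.width})"
            )
        if not pixel_mask.any():
            raise SpectralDomainError("pixel mask selects no pixels")
        m = cube.data[pixel_mask].mean(axis=0)
    return Spectrum(cube.axis, m, cube.modality)


def estimate_noise_sigma(
    cube: HyperspectralCube, quiet_window: Optional[tuple] = None
) -> float:
    """Robust per-channel noise estimate from first differences.

    For white additive noise the channel-to-channel first difference has
    standard deviation σ√2; a MAD-based scale estimate over all pixels is
    insensitive to the (sparse) band structure.  Restricting to a
    band-free ``quiet_window`` removes the upward bias that band slopes
    and signal-proportional noise add to the differences.
    """
    data = cube.data
    if quiet_window is not None:
        idx = cube.axis.window_indices(*quiet_window)
        if idx.size < 3:
            raise SpectralDomainError("quiet window retains fewer than 3 channels")
        data = data[:, :, idx]
    d = np.diff(data, axis=2)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))
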