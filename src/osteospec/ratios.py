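"""Scalar degradation statistics: MINCON, organic-to-mineral ratio, PMI trends.

MINCON (mineral content ratio) is the ν₄ phosphate peak height divided by
the amide I peak height; the organic-to-mineral ratio (OMR) is the
CH-aliphatic peak height divided by the phosphate peak height.  Both are
dimensionless, invariant under global intensity scaling, and move in
opposite directions as bone ages: mineral enriches, organics decay.

Peak windows come from the modality's band library and peaks are read as
windowed maxima after a two-point chord baseline.  On FTIR axes the ν₄
phosphate window (550–610 cm⁻¹) is clipped by the 600 cm⁻¹ detector
cutoff, so only the high-wavenumber tail of the band is visible; a convex
decaying tail lies on any chord or lower envelope drawn beneath it, so a
local baseline would read it as exactly zero.  For edge-clipped windows
the raw windowed maximum is used instead (logged): the residual background
under it does not depend on PMI, so ratio *trends* are unaffected.
Cohort ratios are computed on the mean mineralized-tissue spectrum.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateRatioError, ParameterError, SpectralDomainError
from .chemimaps import peak_height
from .spectral_core import Spectrum, mean_spectrum
from .synthetic_data import PmiCohort, get_band

logger = logging.getLogger(__name__)

#: band-library names of the peaks entering each ratio, per modality
_MINCON_NUM = "nu4 PO4"
_MINCON_DEN = "amide I"
_OMR_NUM = {"reflection": "CH stretch", "atr": "CH stretch", "raman": "CH2 deformation"}
_OMR_DEN = {"reflection": "nu3 PO4", "atr": "nu3 PO4", "raman": "nu1 PO4"}


@dataclass(frozen=True)
class RatioResult:
    sample_id: str
    modality: str
    pmi_days: float
    mincon: Optional[float]
    omr: Optional[float]
    n_pixels_used: int
    flags: str = ""


def _band_peak(spectrum: Spectrum, band_name: str, local_baseline: bool) -> float:
    band = get_band(spectrum.modality, band_name)
    lo, hi = band.window
    # peak_height clips the window to the axis internally; when a band is
    # substantially cut by the detector edge, a chord baseline would zero
    # out its convex tail, so fall back to the raw windowed maximum
    if lo < spectrum.axis.lo or hi > spectrum.axis.hi:
        clipped_lo = max(lo, spectrum.axis.lo)
        clipped_hi = min(hi, spectrum.axis.hi)
        if clipped_hi <= clipped_lo:
            raise SpectralDomainError(
                f"band {band_name} window [{lo}, {hi}] entirely outside axis"
            )
        lost = 1.0 - (clipped_hi - clipped_lo) / (hi - lo)
        if lost > 0.05 and local_baseline:
            logger.warning(
                "band %s window [%.0f, %.0f] clipped to [%.0f, %.0f] by the axis "
                "edge; reading raw maximum (no chord baseline)",
                band_name, lo, hi, clipped_lo, clipped_hi,
            )
            local_baseline = False
    center = (lo + hi) / 2.0
    halfwidth = (hi - lo) / 2.0
    return peak_height(spectrum, center, halfwidth, local_baseline=local_baseline).height


def mincon(spectrum: Spectrum, local_baseline: bool = True) -> float:
    """Mineral content ratio: ν₄ phosphate peak / amide I peak."""
    num = _band_peak(spectrum, _MINCON_NUM, local_baseline)
    den = _band_peak(spectrum, _MINCON_DEN, local_baseline)
    if den <= 0:
        raise DegenerateRatioError(
            "amide I peak height <= 0 (fully degraded organic phase)"
        )
    return num / den


def organic_mineral_ratio(spectrum: Spectrum, local_baseline: bool = True) -> float:
    """Organic-to-mineral ratio: CH-aliphatic peak / phosphate peak."""
    num = _band_peak(spectrum, _OMR_NUM[spectrum.modality], local_baseline)
    den = _band_peak(spectrum, _OMR_DEN[spectrum.modality], local_baseline)
    if den <= 0:
        raise DegenerateRatioError("phosphate peak height <= 0")
    return num / den


def cohort_ratio_table(
    cohort: PmiCohort,
    raman_omr: bool = False,
    modalities=("reflection", "atr", "raman"),
) -> List[RatioResult]:
    """Per sample × modality ratios on the baseline-corrected mean tissue spectrum.

    Haversian-canal pixels are excluded via the generator's template.  Raman
    rows carry MINCON only unless ``raman_omr`` is set.  Degenerate ratios
    are recorded as flagged rows, never raised.
    """
    if len(cohort) == 0:
        raise ParameterError("empty cohort")
    rows: List[RatioResult] = []
    for sample in cohort:
        tissue = sample.template.tissue_mask()
        for mod in modalities:
            cube = sample.cubes[mod]
            spec = mean_spectrum(cube, tissue)
            flags = []
            try:
                mc = mincon(spec)
            except DegenerateRatioError:
                mc = None
                flags.append("degenerate_mincon")
            omr: Optional[float]
            if mod == "raman" and not raman_omr:
                omr = None
            else:
                try:
                    omr = organic_mineral_ratio(spec)
                except DegenerateRatioError:
                    omr = None
                    flags.append("degenerate_omr")
            rows.append(
                RatioResult(
                    sample_id=sample.sample_id,
                    modality=mod,
                    pmi_days=sample.pmi_days,
                    mincon=mc,
                    omr=omr,
                    n_pixels_used=int(tissue.sum()),
                    flags=";".join(flags),
                )
            )
    return rows


@dataclass(frozen=True)
class TrendReport:
    statistic_name: str
    modality: str
    n: int
    rho: Optional[float]
    p_value: Optional[float]
    direction: str  # increasing | decreasing | none
    notes: str = ""


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2) * np.sum(ry**2)))
    if denom == 0:
        return float("nan")
    return float(np.sum(rx * ry) / denom)


def pmi_trend(
    table: List[RatioResult],
    statistic_name: str,
    modality: str,
    alpha: float = 0.05,
    max_exact_n: int = 8,
) -> TrendReport:
    """Spearman rank trend of a ratio against PMI.

    For n <= ``max_exact_n`` the two-sided p-value is exact: the null
    distribution of rho is enumerated over all n! permutations of the PMI
    ranks.  A perfectly monotone series of 6 distinct PMIs gives
    p = 2/720.  Ties in PMI take midranks (noted in the report).
    """
    if statistic_name not in ("mincon", "omr"):
        raise ParameterError("statistic_name must be 'mincon' or 'omr'")
    rows = [
        r for r in table
        if r.modality == modality and getattr(r, statistic_name) is not None
    ]
    pmi = np.array([r.pmi_days for r in rows], dtype=float)
    val = np.array([getattr(r, statistic_name) for r in rows], dtype=float)
    if len(np.unique(pmi)) < 3:
        raise ParameterError("need >= 3 rows with distinct pmi_days")
    notes = []
    if len(np.unique(pmi)) < len(pmi):
        notes.append("ties in pmi_days handled with midranks")
    if np.ptp(val) == 0:
        return TrendReport(statistic_name, modality, len(rows), None, None, "none",
                           "; ".join(notes + ["constant series: rho undefined"]))
    rho = _spearman_rho(pmi, val)
    n = len(rows)
    if n <= max_exact_n:
        ry = rankdata(val)
        count = 0
        total = 0
        for perm in itertools.permutations(rankdata(pmi)):
            r = _spearman_rho(np.array(perm), ry)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        from scipy.stats import spearmanr

        p = float(spearmanr(pmi, val).pvalue)
    if p <= alpha:
        direction = "increasing" if rho > 0 else "decreasing"
    else:
        direction = "none"
    return TrendReport(statistic_name, modality, n, rho, p, direction, "; ".join(notes))
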