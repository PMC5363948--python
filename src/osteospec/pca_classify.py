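"""ROI selection, pretreatment, PCA and forensic/archaeological separation.

Thirty spectra (five tissue pixels from each of the six cohort samples) are
selected per modality, cropped to the informative region (1700–750 cm⁻¹ for
reflection/ATR, 1700–300 cm⁻¹ for Raman), rubberband-baseline corrected and
vector normalized, then decomposed by PCA.  Separation between the forensic
and archaeological groups is quantified as the silhouette coefficient of
the two-label partition in the first two score dimensions — a bounded,
scale-free analogue of "the clusters in the score plot are well separated".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import silhouette_score

from .errors import ParameterError, SelectionError
from .chemimaps import integrate_band
from .spectral_core import (
    HyperspectralCube,
    Spectrum,
    WavenumberAxis,
    estimate_noise_sigma,
    rubberband_baseline_matrix,
)
from .synthetic_data import PmiCohort, get_band

#: informative spectral region per modality (lo, hi) in cm⁻¹
DEFAULT_REGIONS = {
    "reflection": (750.0, 1700.0),
    "atr": (750.0, 1700.0),
    "raman": (300.0, 1700.0),
}

_MINERAL_BAND = {"reflection": "nu3 PO4", "atr": "nu3 PO4", "raman": "nu1 PO4"}


@dataclass(frozen=True)
class RoiSelection:
    sample_id: str
    modality: str
    pixel_coords: Tuple[Tuple[int, int], ...]
    spectra: Tuple[Spectrum, ...]

    @property
    def n_per_sample(self) -> int:
        return len(self.spectra)


def select_rois(
    cube: HyperspectralCube,
    n_per_sample: int = 5,
    strategy: str = "tissue_random",
    seed: int = 0,
    template=None,
    snr_threshold: float = 3.0,
) -> RoiSelection:
    """Pick tissue pixels and extract their spectra.

    ``tissue_random``: uniform over pixels whose mineral-band SNR passes
    the threshold (noise sigma estimated from the cube itself), i.e.
    mineralized tissue rather than canal space.  ``template``: uniform over
    the ground-truth lamellae when a template is supplied.
    """
    if n_per_sample < 1:
        raise ParameterError("n_per_sample must be >= 1")
    if strategy == "tissue_random":
        band = get_band(cube.modality, _MINERAL_BAND[cube.modality])
        cmap = integrate_band(cube, band, local_baseline=True, endpoint_channels=3)
        sigma = estimate_noise_sigma(cube)
        snr = cmap.values / (max(sigma, np.finfo(float).tiny) * cmap.se_factor)
        eligible = np.argwhere(snr >= snr_threshold)
    elif strategy == "template":
        if template is None:
            raise ParameterError("template strategy requires a template")
        eligible = np.argwhere(template.class_mask("osteonal_lamellae"))
    else:
        raise ParameterError(f"unknown ROI strategy {strategy!r}")
    if len(eligible) < n_per_sample:
        raise SelectionError(
            f"only {len(eligible)} eligible pixels for {n_per_sample} ROIs"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=n_per_sample, replace=False)
    coords = tuple(tuple(map(int, eligible[i])) for i in sorted(pick))
    spectra = tuple(cube.pixel(r, c) for r, c in coords)
    return RoiSelection(cube.sample_id, cube.modality, coords, spectra)


def pretreat_for_pca(
    spectra: Sequence[Spectrum], region: Tuple[float, float]
) -> Tuple[WavenumberAxis, np.ndarray]:
    """Crop → rubberband baseline → vector normalize, per spectrum.

    Returns the cropped axis and a (spectra × channels) matrix with
    unit-norm rows, row order preserved.
    """
    lo, hi = region
    axis0 = spectra[0].axis
    idx = axis0.window_indices(lo, hi)
    if idx.size < 3:
        raise ParameterError(f"region [{lo}, {hi}] retains {idx.size} channels (< 3)")
    axis = WavenumberAxis(axis0.values[idx])
    X = np.stack([s.intensities[idx] for s in spectra])
    X = rubberband_baseline_matrix(axis, X)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ParameterError("degenerate (zero-norm) spectrum after baseline correction")
    return axis, X / norms


@dataclass(frozen=True)
class PcaModel:
    region: Tuple[float, float]
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (components × channels), orthonormal rows
    explained_variance_fraction: np.ndarray
    scores: np.ndarray  # (spectra × components)
    labels: Tuple[str, ...]
    sample_ids: Tuple[str, ...] = ()


def pca_fit(
    X: np.ndarray,
    labels: Sequence[str],
    n_components: int = 2,
    region: Tuple[float, float] = (0.0, 0.0),
    sample_ids: Sequence[str] = (),
) -> PcaModel:
    """Mean-centered PCA with canonical sign fixing.

    SVD of the centered matrix; components ordered by variance; each
    loading's sign is fixed so its largest-magnitude coefficient is
    positive, making scores reproducible across linear-algebra backends.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ParameterError(
            f"{X.shape[0]} rows cannot support {n_components} components"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    loadings = vt[:n_components].copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = Xc @ loadings.T
    evf = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PcaModel(
        region=region,
        mean_spectrum=mean,
        loadings=loadings,
        explained_variance_fraction=evf,
        scores=scores,
        labels=tuple(labels),
        sample_ids=tuple(sample_ids),
    )


def separation_score(
    model: PcaModel, label_a: str, label_b: str, n_components: int = 2
) -> float:
    """Silhouette coefficient of the two-label partition in score space."""
    labels = np.array(model.labels)
    sel = (labels == label_a) | (labels == label_b)
    for lab in (label_a, label_b):
        if np.sum(labels == lab) < 2:
            raise ParameterError(f"label {lab!r} needs >= 2 spectra")
    pts = model.scores[sel, :n_components]
    return float(silhouette_score(pts, labels[sel]))


def pca_per_modality(
    cohort: PmiCohort,
    modality: str,
    n_per_sample: int = 5,
    seed: int = 0,
    region: Optional[Tuple[float, float]] = None,
    strategy: str = "tissue_random",
) -> PcaModel:
    """ROI selection + pretreatment + PCA for one modality of a cohort."""
    region = region or DEFAULT_REGIONS[modality]
    ss = np.random.SeedSequence(seed)
    spectra: List[Spectrum] = []
    labels: List[str] = []
    sample_ids: List[str] = []
    for sample, child in zip(cohort, ss.spawn(len(cohort))):
        roi_seed = int(child.generate_state(1)[0] % (2**31))
        roi = select_rois(
            sample.cubes[modality],
            n_per_sample=n_per_sample,
            strategy=strategy,
            seed=roi_seed,
            template=sample.template,
        )
        spectra.extend(roi.spectra)
        labels.extend([sample.cohort_label] * len(roi.spectra))
        sample_ids.extend([sample.sample_id] * len(roi.spectra))
    _, X = pretreat_for_pca(spectra, region)
    return pca_fit(X, labels, n_components=2, region=region, sample_ids=sample_ids)


def score_plot(model: PcaModel, out_path) -> None:
    """Deterministic PC1-vs-PC2 scatter: colour per sample, marker per cohort."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if model.scores.shape[1] < 2:
        raise ParameterError("score plot needs >= 2 components")
    fig, ax = plt.subplots(figsize=(5, 4))
    samples = sorted(set(model.sample_ids)) or ["?"]
    cmap = matplotlib.colormaps["tab10"]
    markers = {"forensic": "o", "archaeological": "s"}
    sids = np.array(model.sample_ids) if model.sample_ids else np.array(["?"] * len(model.labels))
    labs = np.array(model.labels)
    for i, sid in enumerate(samples):
        sel = sids == sid
        lab = labs[sel][0] if sel.any() else "forensic"
        ax.scatter(
            model.scores[sel, 0],
            model.scores[sel, 1],
            color=cmap(i % 10),
            marker=markers.get(lab, "o"),
            label=f"{sid} ({lab})",
            s=30,
        )
    ev = model.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}% var)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}% var)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100, metadata={"Software": None})
    plt.close(fig)
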