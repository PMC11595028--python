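"""Compartment segmentation of preprocessed cubes.

Raman cubes are clustered by k-means (KMCA) on the per-pixel spectra;
FTIR cubes by unsupervised hierarchical cluster analysis (UHCA) with
Ward linkage on D-values, D = (1 - r) * 1000 with r the Pearson correlation
between spectra concatenated over the configured spectral regions.

Cluster labels are anonymous; :func:`assign_compartments` names them from
marker bands (CH stretching for lipid droplets, the 780-800 cm^-1 nucleic
acid band for the nucleus in Raman, the amide-I-to-lipid ratio for
cytoplasm, the remaining class as the perilipidic area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans

from .core import (
    BandWindow,
    HyperspectralCube,
    Modality,
    Spectrum,
    ValidationError,
    integrate_band,
)

__all__ = [
    "SegmentationResult",
    "kmca",
    "uhca",
    "assign_compartments",
    "class_mean_spectra",
    "ld_instances",
]

UNASSIGNED = "unassigned"


@dataclass
class SegmentationResult:
    """Integer label map (-1 outside the mask) with per-class mean spectra."""

    label_map: np.ndarray
    class_mean_spectra: dict[int, Spectrum]
    method: str
    class_names: dict[int, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.labels
        if labels.size and not np.array_equal(labels, np.arange(labels.size)):
            raise ValidationError("class labels must be contiguous from 0")
        if set(self.class_mean_spectra) != set(labels.tolist()):
            raise ValidationError("one mean spectrum required per label")

    @property
    def labels(self) -> np.ndarray:
        present = np.unique(self.label_map)
        return present[present >= 0]

    @property
    def n_classes(self) -> int:
        return self.labels.size

    def class_sizes(self) -> dict[int, int]:
        return {
            int(lab): int((self.label_map == lab).sum()) for lab in self.labels
        }

    def mask_for(self, name: str) -> np.ndarray:
        labels = [lab for lab, n in self.class_names.items() if n == name]
        mask = np.zeros(self.label_map.shape, dtype=bool)
        for lab in labels:
            mask |= self.label_map == lab
        return mask

    def spectrum_for(self, name: str) -> Spectrum:
        for lab, n in self.class_names.items():
            if n == name:
                return self.class_mean_spectra[lab]
        raise KeyError(f"no class named {name!r}")


def _relabel_by_size(labels_flat: np.ndarray) -> np.ndarray:
    """Relabel so that 0 is the largest class (deterministic tie-break)."""
    present, counts = np.unique(labels_flat, return_counts=True)
    order = np.lexsort((present, -counts))
    mapping = np.empty(present.max() + 1, dtype=int)
    for new, idx in enumerate(order):
        mapping[present[idx]] = new
    return mapping[labels_flat]


def _build_result(
    cube: HyperspectralCube,
    keep: np.ndarray,
    labels_flat: np.ndarray,
    method: str,
    params: dict,
) -> SegmentationResult:
    labels_flat = _relabel_by_size(labels_flat)
    label_map = np.full((cube.height, cube.width), -1, dtype=int)
    label_map.reshape(-1)[keep] = labels_flat
    means = class_mean_spectra(cube, label_map)
    return SegmentationResult(label_map, means, method, params=params)


def _region_matrix(
    cube: HyperspectralCube, regions: Sequence[tuple[float, float]] | None
) -> np.ndarray:
    flat = cube.flat()
    if regions is None:
        return flat
    mask = cube.axis.region_mask(regions)
    return flat[:, mask]


def kmca(
    cube: HyperspectralCube,
    k: int = 4,
    seed: int = 0,
    region: Sequence[tuple[float, float]] | None = None,
    mask: np.ndarray | None = None,
) -> SegmentationResult:
    """K-means cluster analysis of per-pixel spectra.

    Euclidean distance, k-means++ initialization from ``seed``, at most 300
    iterations at relative inertia tolerance 1e-6.  Classes are relabelled
    in decreasing size so a fixed seed yields identical labels.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    keep = (
        np.ones(cube.n_pixels, dtype=bool)
        if mask is None
        else np.asarray(mask, dtype=bool).reshape(-1)
    )
    X = _region_matrix(cube, region)[keep]
    if X.shape[0] < k:
        raise ValidationError("fewer in-mask pixels than clusters")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10, max_iter=300, tol=1e-6,
        random_state=seed,
    )
    labels = km.fit_predict(X)
    params = {"k": k, "seed": seed, "region": region,
              "inertia": float(km.inertia_), "n_iter": int(km.n_iter_)}
    return _build_result(cube, keep, labels, "kmca", params)


def d_values(X: np.ndarray) -> np.ndarray:
    """Condensed D-value distance matrix: (1 - Pearson r) * 1000.

    Constant spectra have undefined correlation; their distance to every
    partner is set to 1000 (r treated as 0) and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    D = pdist(X, metric="correlation")
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant spectra in UHCA; "
                      "assigning D = 1000 to their pairs")
        n = X.shape[0]
        idx = np.nonzero(degenerate)[0]
        cond = np.zeros((n, n))
        cond[np.triu_indices(n, 1)] = D
        cond += cond.T
        cond[idx, :] = 1.0
        cond[:, idx] = 1.0
        np.fill_diagonal(cond, 0.0)
        D = cond[np.triu_indices(n, 1)]
    return D * 1000.0


def uhca(
    cube: HyperspectralCube,
    regions: Sequence[tuple[float, float]] = ((900.0, 1800.0), (2800.0, 3050.0)),
    n_classes: int = 3,
    mask: np.ndarray | None = None,
    max_pixels: int = 5000,
    seed: int = 0,
) -> SegmentationResult:
    """Ward-linkage hierarchical clustering on D-values.

    Cubes with more in-mask pixels than ``max_pixels`` are subsampled for the
    linkage; remaining pixels are assigned to the nearest class by
    correlation distance to the class mean.
    """
    keep = (
        np.ones(cube.n_pixels, dtype=bool)
        if mask is None
        else np.asarray(mask, dtype=bool).reshape(-1)
    )
    X = _region_matrix(cube, regions)[keep]
    n = X.shape[0]
    if n < n_classes:
        raise ValidationError("fewer in-mask pixels than classes")
    rng = np.random.default_rng(seed)
    if n > max_pixels:
        subset = np.sort(rng.choice(n, size=max_pixels, replace=False))
    else:
        subset = np.arange(n)
    Z = linkage(d_values(X[subset]), method="ward")
    sub_labels = fcluster(Z, t=n_classes, criterion="maxclust") - 1
    labels = np.empty(n, dtype=int)
    labels[subset] = sub_labels
    rest = np.setdiff1d(np.arange(n), subset, assume_unique=True)
    if rest.size:
        centroids = np.vstack(
            [X[subset][sub_labels == c].mean(axis=0) for c in range(n_classes)]
        )
        labels[rest] = np.argmin(
            cdist(X[rest], centroids, metric="correlation"), axis=1
        )
    params = {"regions": tuple(regions), "n_classes": n_classes, "seed": seed,
              "linkage": "ward", "subsampled": int(subset.size) if n > max_pixels else 0}
    return _build_result(cube, keep, labels, "uhca", params)


# ------------------------------------------------------- compartment naming

_LIPID_WINDOWS = {
    Modality.RAMAN: BandWindow("lipid", 2830.0, 2900.0),
    Modality.FTIR: BandWindow("lipid", 1720.0, 1770.0),
}
_AMIDE_WINDOWS = {
    Modality.RAMAN: BandWindow("amide_I", 1640.0, 1680.0),
    Modality.FTIR: BandWindow("amide_I", 1620.0, 1680.0),
}
_NUCLEUS_WINDOW = BandWindow("nucleic", 780.0, 800.0)


def _argmax_with_size_tiebreak(
    scores: dict[int, float], sizes: dict[int, int]
) -> int:
    return max(scores, key=lambda lab: (scores[lab], sizes[lab], -lab))


def assign_compartments(result: SegmentationResult) -> SegmentationResult:
    """Name clusters from marker-band scores (deterministic rule).

    lipid_droplet: largest CH-stretch (Raman) / ester (FTIR) integral;
    nucleus: largest 780-800 cm^-1 integral (Raman only); cytoplasm: largest
    amide-I-to-lipid ratio; perilipidic_area: the remaining class.  Ties are
    broken by class size (larger first).  With fewer classes than names, the
    names are dropped in the order nucleus, then perilipidic_area.
    """
    spectra = result.class_mean_spectra
    if not spectra:
        raise ValidationError("no class mean spectra available")
    modality = next(iter(spectra.values())).modality
    sizes = result.class_sizes()
    lipid = {
        lab: integrate_band(s, _LIPID_WINDOWS[modality])
        for lab, s in spectra.items()
    }
    amide = {
        lab: integrate_band(s, _AMIDE_WINDOWS[modality])
        for lab, s in spectra.items()
    }
    names: dict[int, str] = {}
    remaining = set(spectra)

    ld = _argmax_with_size_tiebreak({lab: lipid[lab] for lab in remaining}, sizes)
    names[ld] = "lipid_droplet"
    remaining.discard(ld)

    want_nucleus = modality is Modality.RAMAN and len(remaining) >= 3
    if want_nucleus:
        nuc_scores = {
            lab: integrate_band(spectra[lab], _NUCLEUS_WINDOW) for lab in remaining
        }
        nuc = _argmax_with_size_tiebreak(nuc_scores, sizes)
        names[nuc] = "nucleus"
        remaining.discard(nuc)

    if remaining:
        ratios = {
            lab: amide[lab] / lipid[lab] if lipid[lab] > 0 else np.inf
            for lab in remaining
        }
        cyto = _argmax_with_size_tiebreak(ratios, sizes)
        names[cyto] = "cytoplasm"
        remaining.discard(cyto)

    if remaining:
        pa = _argmax_with_size_tiebreak({lab: sizes[lab] for lab in remaining},
                                        sizes)
        names[pa] = "perilipidic_area"
        remaining.discard(pa)
    for lab in remaining:
        names[lab] = UNASSIGNED
    return replace(result, class_names=names)


def class_mean_spectra(
    cube: HyperspectralCube, label_map: np.ndarray
) -> dict[int, Spectrum]:
    """Arithmetic mean spectrum of each nonnegative label."""
    label_map = np.asarray(label_map)
    means: dict[int, Spectrum] = {}
    for lab in np.unique(label_map):
        if lab < 0:
            continue
        members = cube.data[label_map == lab]
        if members.size == 0:
            warnings.warn(f"label {lab} has no member pixels; omitted")
            continue
        means[int(lab)] = Spectrum(cube.axis, members.mean(axis=0),
                                   cube.modality)
    return means


def ld_instances(
    ld_mask: np.ndarray, pixel_size: float
) -> pd.DataFrame:
    """Connected-component table of lipid-droplet instances.

    8-connected labeling; one row per instance with pixel count, area in
    um^2 and centroid (row, col).  An empty mask yields an empty table.
    """
    ld_mask = np.asarray(ld_mask, dtype=bool)
    labels, n = ndimage.label(ld_mask, structure=np.ones((3, 3), dtype=bool))
    rows = []
    if n:
        counts = ndimage.sum_labels(ld_mask, labels, index=range(1, n + 1))
        centroids = ndimage.center_of_mass(ld_mask, labels, range(1, n + 1))
        for i in range(n):
            rows.append(
                {
                    "instance": i + 1,
                    "pixels": int(counts[i]),
                    "area_um2": float(counts[i]) * pixel_size**2,
                    "centroid_row": centroids[i][0],
                    "centroid_col": centroids[i][1],
                }
            )
    return pd.DataFrame(
        rows, columns=["instance", "pixels", "area_um2",
                       "centroid_row", "centroid_col"]
    )
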