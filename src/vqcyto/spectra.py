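"""Codebook-index feature spectra: construction, ordering, and prediction.

A protein's *feature spectrum* is the histogram, over all of its images, of
which local-codebook indices appear in the quantized latent.  Stacking the
spectra of P proteins gives a P x K count matrix (K = codebook size).  The
columns ("feature profiles") are correlated pairwise and ordered by
hierarchical biclustering so related features sit together; correlating a
protein's spectrum against per-organelle consensus spectra predicts its
localization, and nearest-neighbor spectrum correlation flags likely shared
protein-complex membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .embed import AnnotationTable


class InputError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class SpectrumMatrix:
    counts: np.ndarray  # (P, K) non-negative integers
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.protein_ids) != len(self.counts):
            raise InputError("one protein id per row required")
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def row(self, protein_id: str) -> np.ndarray:
        return self.counts[self.protein_ids.index(protein_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.protein_ids)


def index_histogram(index_maps: np.ndarray, n_codes: int) -> np.ndarray:
    """Count occurrences of each codebook index over all positions of all
    images (additive across images)."""
    idx = np.asarray(index_maps)
    if idx.size and (idx.min() < 0 or idx.max() >= n_codes):
        raise DataError("index out of codebook range")
    return np.bincount(idx.ravel(), minlength=n_codes)


def spectra_from_index_maps(
    index_maps: np.ndarray, protein_ids: list[str], n_codes: int
) -> SpectrumMatrix:
    """Per-protein spectra from per-image local index maps."""
    pids = sorted(set(protein_ids))
    arr = np.asarray(protein_ids)
    rows = [
        index_histogram(np.asarray(index_maps)[arr == pid], n_codes)
        for pid in pids
    ]
    return SpectrumMatrix(np.stack(rows), pids)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _pearson_matrix(columns: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; constant columns correlate 0
    off-diagonal and 1 with themselves."""
    x = np.asarray(columns, np.float64)
    centered = x - x.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe
    corr = unit.T @ unit
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def feature_correlation(matrix: SpectrumMatrix) -> np.ndarray:
    """K x K Pearson correlations between feature-index profiles (columns)."""
    if len(matrix.counts) < 3:
        raise InputError("need at least 3 proteins to correlate profiles")
    return _pearson_matrix(matrix.counts)


def pairwise_spectrum_correlation(matrix: SpectrumMatrix) -> np.ndarray:
    """P x P Pearson correlations between protein spectra (rows)."""
    if len(matrix.counts) < 2:
        raise InputError("need at least 2 proteins")
    if (np.ptp(matrix.counts, axis=1) == 0).any():
        warnings.warn("constant spectrum row; correlations set to 0")
    return _pearson_matrix(matrix.counts.T)


@dataclass
class FeatureOrdering:
    order: np.ndarray  # permutation of 0..K-1 (dendrogram leaf order)
    linkage: np.ndarray


def bicluster_order(corr: np.ndarray) -> FeatureOrdering:
    """Order features by agglomerative clustering of correlation-matrix rows
    (average linkage, Euclidean); the ordering is the dendrogram leaf order."""
    corr = np.asarray(corr, np.float64)
    if not np.isfinite(corr).all():
        raise InputError("non-finite correlation entries")
    k = corr.shape[0]
    if k == 1:
        return FeatureOrdering(np.array([0]), np.empty((0, 4)))
    link = hierarchy.linkage(corr, method="average", metric="euclidean")
    order = np.asarray(hierarchy.leaves_list(link))
    return FeatureOrdering(order, link)


# ---------------------------------------------------------------------------
# consensus spectra and leave-one-out localization prediction
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, np.float64)
    b = np.asarray(b, np.float64)
    ac, bc = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


@dataclass
class PredictionResult:
    ranking: list[tuple[str, float]]  # (category, r), descending r
    true_rank: int | None = None  # 1-based rank of the true label

    @property
    def top(self) -> str:
        return self.ranking[0][0]


def consensus_spectra(
    matrix: SpectrumMatrix,
    annotations: AnnotationTable,
    leave_out: str | None = None,
) -> dict[str, np.ndarray]:
    """Mean spectrum per localization category, optionally excluding one
    protein; categories emptied by the leave-out are dropped with a warning."""
    groups: dict[str, list[np.ndarray]] = {}
    for i, pid in enumerate(matrix.protein_ids):
        if pid == leave_out or pid not in annotations.organelle_of:
            continue
        groups.setdefault(annotations.organelle_of[pid], []).append(
            matrix.counts[i]
        )
    dropped = {
        annotations.organelle_of[p]
        for p in ([leave_out] if leave_out else [])
        if p in annotations.organelle_of
    } - set(groups)
    for cat in dropped:
        warnings.warn(f"category {cat!r} emptied by leave-out; excluded")
    if not groups:
        raise InputError("no annotated proteins available for consensus")
    return {
        cat: np.mean(np.stack(rows), axis=0) for cat, rows in groups.items()
    }


def consensus_and_predict(
    spectrum: np.ndarray,
    matrix: SpectrumMatrix,
    annotations: AnnotationTable,
    leave_out: str | None = None,
) -> PredictionResult:
    """Rank localization categories by Pearson correlation between the query
    spectrum and each category's consensus spectrum."""
    consensus = consensus_spectra(matrix, annotations, leave_out)
    ranking = sorted(
        ((cat, _pearson(spectrum, ref)) for cat, ref in consensus.items()),
        key=lambda t: -t[1],
    )
    true_rank = None
    if leave_out is not None and leave_out in annotations.organelle_of:
        true_label = annotations.organelle_of[leave_out]
        for r, (cat, _) in enumerate(ranking, start=1):
            if cat == true_label:
                true_rank = r
                break
    return PredictionResult(ranking, true_rank)


def leave_one_out_accuracy(
    matrix: SpectrumMatrix, annotations: AnnotationTable, top_k: int = 1
) -> float:
    """Full leave-one-out localization prediction; fraction of proteins whose
    true category ranks within ``top_k``."""
    hits, n = 0, 0
    for pid in matrix.protein_ids:
        if pid not in annotations.organelle_of:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = consensus_and_predict(
                matrix.row(pid), matrix, annotations, leave_out=pid
            )
        if res.true_rank is not None and res.true_rank <= top_k:
            hits += 1
        n += 1
    if n == 0:
        raise InputError("no annotated proteins")
    return hits / n


# ---------------------------------------------------------------------------
# protein-complex neighbor analysis
# ---------------------------------------------------------------------------


def neighbor_complex_fraction(
    matrix: SpectrumMatrix,
    annotations: AnnotationTable,
    thresholds,
) -> dict[float, float | None]:
    """For each correlation threshold t: among proteins whose best-correlated
    neighbor exceeds t, the fraction sharing at least one complex with that
    neighbor.  Thresholds that no protein passes map to ``None``."""
    pids = [p for p in matrix.protein_ids if annotations.complexes_of.get(p)]
    if len(pids) < 2:
        raise InputError("need >= 2 proteins with complex annotations")
    sub_idx = [matrix.protein_ids.index(p) for p in pids]
    corr = _pearson_matrix(matrix.counts[sub_idx].T)
    np.fill_diagonal(corr, -np.inf)
    best = corr.argmax(axis=1)
    best_r = corr[np.arange(len(pids)), best]
    shares = np.array(
        [
            bool(
                annotations.complexes_of[pids[i]]
                & annotations.complexes_of[pids[j]]
            )
            for i, j in enumerate(best)
        ]
    )
    out: dict[float, float | None] = {}
    for t in thresholds:
        passing = best_r > t
        out[float(t)] = (
            float(shares[passing].mean()) if passing.any() else None
        )
    return out


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------


def save_spectra(matrix: SpectrumMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index_label="protein_id")


def load_spectra(path) -> SpectrumMatrix:
    df = pd.read_csv(path, index_col="protein_id")
    return SpectrumMatrix(df.to_numpy(), list(df.index))
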