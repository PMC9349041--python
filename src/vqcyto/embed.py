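"""Representation extraction, UMAP projection, and the robust clustering score.

The separation of annotated classes in an embedding is summarized by the
statistic

    Gamma = sigma*({mu*(C_j)}_j) / mu*({sigma*(C_j)}_j)

where mu* is the coordinate-wise median and sigma* a median-based robust
standard deviation.  The numerator is the robust spread of the class
centroids; the denominator the median within-class robust spread.  Gamma is
translation- and scale-invariant: higher means tighter classes that sit
farther apart.

For point sets in R^m, sigma* is defined here as 1.4826 times the median
Euclidean distance to the coordinate-wise median — the standard consistency
constant that makes the 1D case agree with the MAD-based estimate of a
normal standard deviation.  The constant cancels in Gamma but keeps sigma*
interpretable on its own; the definition used is recorded in every report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imgprep import CropSet
from .vqmodel import Model

SIGMA_STAR_DEFINITION = (
    "1.4826 * median Euclidean distance to the coordinate-wise median"
)


class InputError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class EmbeddingSet:
    matrix: np.ndarray  # (n points, m features)
    protein_ids: list[str]
    level: str = "global"
    index_maps: np.ndarray | None = None  # (n, h, w[, splits]) integer maps

    def __post_init__(self) -> None:
        if len(self.protein_ids) != len(self.matrix):
            raise InputError("one protein id per row required")
        if not np.isfinite(self.matrix).all():
            raise InputError("non-finite embedding values")


@dataclass(frozen=True)
class UMAPParams:
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise InputError("n_neighbors must be >= 2")


def extract_representations(
    model: Model,
    crops: CropSet,
    level: str = "global",
    batch_size: int = 64,
    pre_quantization: bool = False,
) -> EmbeddingSet:
    """Run the trained model over crops and collect representations.

    ``level='global'`` returns the quantized (default) or pre-quantization
    global latent flattened per crop; ``level='local'`` additionally retains
    the per-crop local codebook index maps used for feature spectra.
    """
    if level not in ("global", "local"):
        raise InputError("level must be 'global' or 'local'")
    x = crops.stack().astype(np.float32)
    if not model.config.use_nuclear_channel:
        x = x[:, :1]
    rows, maps = [], []
    for i in range(0, len(x), batch_size):
        out = model.forward(x[i : i + batch_size])
        if level == "global":
            q = out.quant_global
            tensor = out.global_latent if pre_quantization else q.quantized
            rows.append(tensor.reshape(len(tensor), -1))
        else:
            q = out.quant_local
            tensor = out.local_latent if pre_quantization else q.quantized
            rows.append(tensor.reshape(len(tensor), -1))
            maps.append(q.indices)
    return EmbeddingSet(
        matrix=np.concatenate(rows),
        protein_ids=list(crops.protein_ids),
        level=level,
        index_maps=np.concatenate(maps) if maps else None,
    )


def reduce_umap(
    embeddings: EmbeddingSet | np.ndarray, params: UMAPParams = UMAPParams()
) -> np.ndarray:
    """Project to 2D with UMAP (Euclidean, 15 neighbors, min_dist 0.1)."""
    import umap

    matrix = (
        embeddings.matrix
        if isinstance(embeddings, EmbeddingSet)
        else np.asarray(embeddings)
    )
    if len(matrix) <= params.n_neighbors:
        raise InputError("need more points than n_neighbors")
    reducer = umap.UMAP(
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        random_state=params.seed,
        n_components=2,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(matrix), np.float64)


# ---------------------------------------------------------------------------
# robust statistics and the clustering score
# ---------------------------------------------------------------------------


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, np.float64)
    return pts[:, None] if pts.ndim == 1 else pts


def robust_center(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise median (the robust mean mu*)."""
    pts = _as_points(points)
    if pts.size == 0:
        raise InputError("empty point set")
    return np.median(pts, axis=0)


def robust_spread(points: np.ndarray) -> float:
    """Median-based robust standard deviation sigma* of a point set."""
    pts = _as_points(points)
    if pts.size == 0:
        raise InputError("empty point set")
    center = np.median(pts, axis=0)
    dists = np.sqrt(((pts - center) ** 2).sum(axis=1))
    return float(1.4826 * np.median(dists))


@dataclass
class ClusteringInput:
    points: np.ndarray  # (n, m)
    labels: np.ndarray  # (n,) class of each point

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.points):
            raise InputError("one label per point required")


@dataclass
class ScoreReport:
    gamma: float
    centroid_spread: float
    within_spreads: dict
    sigma_star_definition: str = SIGMA_STAR_DEFINITION


def clustering_score(data: ClusteringInput) -> ScoreReport:
    """Robust clustering score Gamma over a labeled point set.

    Raises :class:`DegenerateInputError` when every class has zero spread
    (the ratio would be infinite and is meaningless for comparisons).
    """
    classes = sorted(set(data.labels.tolist()))
    if len(classes) < 2:
        raise InputError("need at least 2 classes")
    centers, withins = [], {}
    for c in classes:
        pts = data.points[data.labels == c]
        centers.append(robust_center(pts))
        withins[c] = robust_spread(pts)
    denom = float(np.median(list(withins.values())))
    if denom == 0.0:
        raise DegenerateInputError("all classes degenerate: zero within-spread")
    numer = robust_spread(np.stack(centers))
    return ScoreReport(
        gamma=numer / denom, centroid_spread=numer, within_spreads=withins
    )


def gamma_with_labels(points: np.ndarray, labels) -> float:
    return clustering_score(ClusteringInput(points, np.asarray(labels))).gamma


def rank_sum_separation(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of separation between two point groups.

    Multivariate inputs are reduced to 1D by projecting onto the axis that
    joins the two groups' robust centers; 1D inputs are used as-is.  Returns
    (U statistic for group A, two-sided p value).  Fully tied data yields
    p = 1 with a warning.
    """
    a = np.asarray(group_a, np.float64)
    b = np.asarray(group_b, np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise InputError("both groups must be non-empty")
    if a.shape[1] == 1:
        av, bv = a[:, 0], b[:, 0]
    else:
        axis = robust_center(b) - robust_center(a)
        norm = np.linalg.norm(axis)
        if norm == 0:
            axis = np.zeros_like(axis)
            axis[0] = 1.0
        else:
            axis = axis / norm
        av, bv = a @ axis, b @ axis
    if np.ptp(np.concatenate([av, bv])) == 0:
        warnings.warn("all values tied; p = 1")
        return float(len(av) * len(bv) / 2.0), 1.0
    method = "exact" if min(len(av), len(bv)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(av, bv, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# annotations and CSV round trips
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Protein -> organelle label and protein -> complex memberships."""

    organelle_of: dict = field(default_factory=dict)
    complexes_of: dict = field(default_factory=dict)  # pid -> frozenset

    @classmethod
    def from_csv(cls, path) -> "AnnotationTable":
        import pandas as pd

        df = pd.read_csv(path)
        org = dict(zip(df["protein_id"], df["organelle"]))
        comp = {}
        if "complex_ids" in df:
            for pid, raw in zip(df["protein_id"], df["complex_ids"]):
                comp[pid] = frozenset(
                    s for s in str(raw).split(";") if s and s != "nan"
                )
        return cls(org, comp)


def write_embeddings_csv(points: np.ndarray, ids: list[str], path) -> None:
    import pandas as pd

    cols = {f"dim{i}": points[:, i] for i in range(points.shape[1])}
    pd.DataFrame({"protein_id": ids, **cols}).to_csv(path, index=False)
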