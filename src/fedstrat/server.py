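"""Server-side aggregation, cluster-number selection, k-means, and scoring.

The server concatenates the researchers' noisy PCA payloads into one point
cloud, chooses the number of population clusters with the elbow of the
within-cluster-sum-of-squares (WCSS) curve, runs k-means, and reports per
pseudonym the cluster label and per cluster its size. Utility is scored
against either the generator's population labels or a centralized benchmark
(PCA + k-means on the pooled raw data), with one-to-one cluster matching by
the Hungarian algorithm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .genotypes import GenotypeMatrix
from .pca import FactorScores, NoisyMetadata, fit_pca_model, project_samples

log = logging.getLogger(__name__)

#: k-means restarts / iteration cap / convergence tolerance
KMEANS_RESTARTS = 10
KMEANS_MAX_ITER = 300
KMEANS_TOL = 1e-6


@dataclass
class CombinedPoints:
    """The server's combined PCA: all researchers' payloads stacked."""

    coordinates: np.ndarray
    hashed_ids: list[str]
    sources: list[str]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = self.coordinates.shape[0]
        if len(self.hashed_ids) != n or len(self.sources) != n:
            raise ValueError("ids/sources must match coordinate rows")
        pairs = list(zip(self.hashed_ids, self.sources))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(hashed_id, source) pairs must be unique")

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusterReport:
    """Clustering outcome returned to the researchers."""

    labels: np.ndarray
    cluster_sizes: dict[int, int]
    chosen_k: int
    wcss_curve: dict[int, float] | None
    ids: list[str]
    sources: list[str] | None = None
    inertia: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != self.labels.shape[0]:
            raise ValueError("ids must match labels")
        if sum(self.cluster_sizes.values()) != self.labels.shape[0]:
            raise ValueError("cluster sizes must sum to the number of points")
        if self.labels.size and not (
            (self.labels >= 0).all() and (self.labels < self.chosen_k).all()
        ):
            raise ValueError("labels must lie in [0, chosen_k)")

    def save(self, path: str | Path) -> None:
        payload = {
            "chosen_k": self.chosen_k,
            "wcss_curve": (
                {str(k): v for k, v in self.wcss_curve.items()}
                if self.wcss_curve is not None
                else None
            ),
            "clusters": [
                {"label": int(c), "size": int(s)}
                for c, s in sorted(self.cluster_sizes.items())
            ],
            "assignments": [
                {
                    "hashed_id": i,
                    "source": (self.sources[j] if self.sources else None),
                    "cluster": int(self.labels[j]),
                }
                for j, i in enumerate(self.ids)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterReport":
        payload = json.loads(Path(path).read_text())
        labels = np.asarray([a["cluster"] for a in payload["assignments"]], dtype=int)
        sources = [a["source"] for a in payload["assignments"]]
        return cls(
            labels=labels,
            cluster_sizes={c["label"]: c["size"] for c in payload["clusters"]},
            chosen_k=payload["chosen_k"],
            wcss_curve=(
                {int(k): v for k, v in payload["wcss_curve"].items()}
                if payload["wcss_curve"] is not None
                else None
            ),
            ids=[a["hashed_id"] for a in payload["assignments"]],
            sources=None if all(s is None for s in sources) else sources,
        )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_metadata(
    payloads: Sequence[NoisyMetadata], sources: Sequence[str] | None = None
) -> CombinedPoints:
    """Row-concatenate researchers' payloads, tagging each row by source."""
    if len(payloads) == 0:
        raise ValueError("no payloads to aggregate")
    d = payloads[0].n_components
    for p in payloads[1:]:
        if p.n_components != d:
            raise ValueError(
                f"payload dimensionality mismatch: {p.n_components} vs {d}"
            )
    if sources is None:
        sources = [f"researcher_{i + 1}" for i in range(len(payloads))]
    if len(sources) != len(payloads):
        raise ValueError("one source tag per payload required")
    coords = np.vstack([p.coordinates for p in payloads])
    hashed = [h for p in payloads for h in p.hashed_ids]
    tags = [s for s, p in zip(sources, payloads) for _ in range(p.n_samples)]
    return CombinedPoints(coords, hashed, tags)


# ---------------------------------------------------------------------------
# k selection and clustering
# ---------------------------------------------------------------------------

def _kmeans_fit(
    x: np.ndarray, k: int, seed: int, init: np.ndarray | None = None
) -> KMeans:
    if init is not None:
        km = KMeans(
            n_clusters=k, init=init, n_init=1,
            max_iter=KMEANS_MAX_ITER, tol=KMEANS_TOL, random_state=seed,
        )
    else:
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=KMEANS_RESTARTS,
            max_iter=KMEANS_MAX_ITER, tol=KMEANS_TOL, random_state=seed,
        )
    return km.fit(x)


def wcss_curve(
    points: CombinedPoints, k_min: int = 1, k_max: int | None = None, seed: int = 0
) -> dict[int, float]:
    """Best-of-restarts WCSS for each k in [k_min, k_max].

    Besides the k-means++ restarts, each k is also warm-started from the
    previous k's centroids plus the point farthest from them, which makes
    the curve non-increasing in k by construction.
    """
    n = points.n_points
    if k_max is None:
        k_max = min(10, n)
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of points ({n})")
    x = points.coordinates
    curve: dict[int, float] = {}
    prev_centers: np.ndarray | None = None
    for k in range(k_min, k_max + 1):
        best = _kmeans_fit(x, k, seed)
        if prev_centers is not None and prev_centers.shape[0] == k - 1:
            dist2 = ((x[:, None, :] - prev_centers[None, :, :]) ** 2).sum(-1).min(1)
            init = np.vstack([prev_centers, x[int(dist2.argmax())]])
            warm = _kmeans_fit(x, k, seed, init=init)
            if warm.inertia_ < best.inertia_:
                best = warm
        curve[k] = float(best.inertia_)
        prev_centers = best.cluster_centers_
    return curve


def choose_k_elbow(curve: Mapping[int, float]) -> int:
    """Pick k at the elbow of the WCSS curve.

    Both axes are normalized to [0, 1]; the chosen k maximizes the
    perpendicular distance from (k, WCSS_k) to the chord joining the first
    and last points of the curve. Ties break toward smaller k; a flat or
    strictly linear curve yields k_min with a warning.
    """
    if len(curve) < 3:
        raise ValueError("elbow selection needs at least three curve points")
    ks = np.array(sorted(curve))
    ws = np.array([curve[int(k)] for k in ks], dtype=float)
    k_min = int(ks[0])
    if ws.max() == ws.min():
        log.warning("flat WCSS curve: returning k_min=%d", k_min)
        return k_min
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (ws - ws.min()) / (ws.max() - ws.min())
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    dist /= np.hypot(y1 - y0, x1 - x0)
    if dist.max() < 1e-9:
        log.warning("no elbow (linear WCSS curve): returning k_min=%d", k_min)
        return k_min
    return int(ks[int(dist.argmax())])


def _canonicalize_labels(labels: np.ndarray, k: int) -> tuple[np.ndarray, dict[int, int]]:
    """Reindex cluster labels by decreasing size (ties by original index)."""
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    new_labels = np.array([remap[int(l)] for l in labels], dtype=int)
    return new_labels, {remap[c]: int(sizes[c]) for c in range(k)}


def cluster_kmeans(points: CombinedPoints, k: int, seed: int = 0) -> ClusterReport:
    """k-means (k-means++ init, restarts) with size-canonical labels."""
    if not 1 <= k <= points.n_points:
        raise ValueError(f"k={k} must lie in [1, {points.n_points}]")
    km = _kmeans_fit(points.coordinates, k, seed)
    labels, sizes = _canonicalize_labels(km.labels_, k)
    return ClusterReport(
        labels=labels,
        cluster_sizes=sizes,
        chosen_k=k,
        wcss_curve=None,
        ids=list(points.hashed_ids),
        sources=list(points.sources),
        inertia=float(km.inertia_),
    )


def stratify(
    points: CombinedPoints,
    k: int | str = "auto",
    k_min: int = 1,
    k_max: int | None = None,
    seed: int = 0,
) -> ClusterReport:
    """Full server step: elbow-select k (unless fixed) and cluster.

    The WCSS curve spans k_min..k_max (default 1..min(10, n_t − 1)); the
    curve must start at k=1 for a two-cluster elbow to be selectable, since
    the chord rule cannot pick an endpoint. The selected k is floored at 2,
    the smallest admissible number of population clusters.
    """
    curve = None
    if k == "auto":
        if k_max is None:
            k_max = min(10, points.n_points - 1)
        curve = wcss_curve(points, k_min, k_max, seed)
        k = max(choose_k_elbow(curve), 2)
    report = cluster_kmeans(points, int(k), seed)
    report.wcss_curve = curve
    return report


# ---------------------------------------------------------------------------
# centralized benchmark and scoring
# ---------------------------------------------------------------------------

def pool_matrices(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack sample rows of SNP-aligned matrices into one cohort."""
    first = matrices[0]
    for g in matrices[1:]:
        if list(g.snp_ids) != list(first.snp_ids):
            raise ValueError("matrices must be SNP-aligned before pooling")
    values = np.vstack([g.values for g in matrices])
    ids = [s for g in matrices for s in g.sample_ids]
    labels = None
    if all(g.population_labels is not None for g in matrices):
        labels = [p for g in matrices for p in g.population_labels]
    return GenotypeMatrix(values, ids, list(first.snp_ids), labels)


def centralized_benchmark(
    locals_: Sequence[GenotypeMatrix],
    public: GenotypeMatrix,
    n_components: int,
    k: int | str = "auto",
    seed: int = 0,
) -> ClusterReport:
    """Ground-truth pipeline: PCA + k-means on the pooled raw data.

    Pools every local dataset with the public panel, fits PCA on the pooled
    standardized matrix, and clusters the factor scores. Used only to score
    the federated protocol; report ids are the raw sample ids.
    """
    pooled = pool_matrices([*locals_, public])
    model = fit_pca_model(pooled, n_components)
    scores = project_samples(model, pooled)
    points = CombinedPoints(
        scores.coordinates, list(pooled.sample_ids), ["centralized"] * pooled.n_samples
    )
    return stratify(points, k=k, seed=seed)


def _as_labels(predicted: ClusterReport | np.ndarray | Sequence[int]) -> np.ndarray:
    if isinstance(predicted, ClusterReport):
        return predicted.labels
    return np.asarray(predicted)


def _contingency(pred: np.ndarray, truth: np.ndarray):
    pred_vals = sorted(set(pred.tolist()))
    truth_vals = sorted(set(truth.tolist()))
    table = np.zeros((len(pred_vals), len(truth_vals)), dtype=int)
    p_idx = {v: i for i, v in enumerate(pred_vals)}
    t_idx = {v: i for i, v in enumerate(truth_vals)}
    for p, t in zip(pred, truth):
        table[p_idx[p], t_idx[t]] += 1
    return table, pred_vals, truth_vals


def match_cluster_labels(
    predicted: ClusterReport | np.ndarray | Sequence[int],
    truth: np.ndarray | Sequence,
) -> dict:
    """One-to-one predicted→truth cluster mapping maximizing total overlap.

    Solved with the Hungarian algorithm on the contingency table; when the
    partitions have different cluster counts the unmatched clusters map to
    None. Inputs must cover the same samples in the same order.
    """
    pred = _as_labels(predicted)
    truth = np.asarray(truth)
    if pred.shape[0] != truth.shape[0]:
        raise ValueError("predicted and truth labels must cover the same samples")
    if pred.shape[0] == 0:
        raise ValueError("cannot match empty partitions")
    table, pred_vals, truth_vals = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(-table)
    mapping: dict = {pred_vals[r]: truth_vals[c] for r, c in zip(rows, cols)}
    for v in pred_vals:
        mapping.setdefault(v, None)
    return mapping


def score_accuracy(
    predicted: ClusterReport | np.ndarray | Sequence[int],
    truth: np.ndarray | Sequence,
) -> float:
    """Fraction of samples whose matched predicted cluster equals the truth."""
    pred = _as_labels(predicted)
    truth = np.asarray(truth)
    mapping = match_cluster_labels(pred, truth)
    mapped = np.array([mapping[p] for p in pred.tolist()], dtype=object)
    return float(np.mean(mapped == truth.astype(object)))


def score_precision_recall(
    predicted: ClusterReport | np.ndarray | Sequence[int],
    truth: np.ndarray | Sequence,
) -> tuple[float, float]:
    """Cluster precision and recall, weighted by true cluster size.

    After Hungarian matching, a truth cluster matched to predicted cluster c
    scores precision = overlap / |c| (fraction of samples assigned to c that
    belong there) and recall = overlap / |truth cluster|; a truth cluster
    left unmatched scores 0 on both. An empty matched predicted cluster
    scores precision 1 if the truth cluster is empty too, else 0.
    """
    pred = _as_labels(predicted)
    truth = np.asarray(truth)
    if pred.shape[0] != truth.shape[0]:
        raise ValueError("predicted and truth labels must cover the same samples")
    table, pred_vals, truth_vals = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(-table)
    match_for_truth = {truth_vals[c]: pred_vals[r] for r, c in zip(rows, cols)}
    pred_sizes = dict(zip(pred_vals, table.sum(axis=1)))
    truth_sizes = dict(zip(truth_vals, table.sum(axis=0)))
    p_idx = {v: i for i, v in enumerate(pred_vals)}
    t_idx = {v: i for i, v in enumerate(truth_vals)}
    n = truth.shape[0]
    precision = recall = 0.0
    for t in truth_vals:
        w = truth_sizes[t] / n
        c = match_for_truth.get(t)
        if c is None:
            continue  # unmatched truth cluster contributes 0 to both
        overlap = table[p_idx[c], t_idx[t]]
        if pred_sizes[c] == 0:
            prec_t = 1.0 if truth_sizes[t] == 0 else 0.0
        else:
            prec_t = overlap / pred_sizes[c]
        rec_t = overlap / truth_sizes[t] if truth_sizes[t] else 1.0
        precision += w * prec_t
        recall += w * rec_t
    return float(precision), float(recall)
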