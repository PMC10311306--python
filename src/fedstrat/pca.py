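"""Shared-model PCA with local differential privacy for the clients.

The server trains a PCA model on a public genotype panel: the panel is
standardized per SNP (mean 0, variance 1), decomposed as Z = P Δ Qᵀ, and the
top-d right singular vectors Q are shipped to every researcher together with
the standardization parameters and one sensitivity per component. Each
researcher standardizes its own samples with the *model's* parameters,
projects them to factor scores F = Z Q, adds Laplace noise calibrated to
ε-local differential privacy, pseudonymizes sample identifiers with SHA-256,
and shares only the resulting metadata.

Sensitivity of component j is estimated as the range (max − min) of that
component's factor scores over the public panel. With the total budget ε
split evenly over d components, the per-entry Laplace scale is

    λ_j = s_j / (ε / d) = s_j · d / ε.

``epsilon = math.inf`` is the no-noise sentinel: the projection is shared
exactly (used for utility benchmarking only).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix

#: accepted spelling of the no-noise privacy budget in files and CLIs
INF_EPSILON_TOKENS = ("inf", "infinity", "Infinity")


class DegenerateModelError(ValueError):
    """A principal component is constant on the public panel (zero range)."""


@dataclass
class FactorScores:
    """PCA coordinates of a set of samples (n × d)."""

    coordinates: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be 2-D")
        if len(self.sample_ids) != self.coordinates.shape[0]:
            raise ValueError("sample_ids length must match coordinate rows")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class PCAModel:
    """The trained model shipped from the server to every researcher."""

    q_matrix: np.ndarray          # m × d right singular vectors
    n_components: int
    snp_ids: list[str]
    means: np.ndarray             # per-SNP standardization means
    scales: np.ndarray            # per-SNP standardization std deviations
    sensitivities: np.ndarray     # per-component score range on the panel

    def __post_init__(self) -> None:
        self.q_matrix = np.asarray(self.q_matrix, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        m, d = self.q_matrix.shape
        if d != self.n_components:
            raise ValueError("q_matrix width must equal n_components")
        if len(self.snp_ids) != m or self.means.shape != (m,) or self.scales.shape != (m,):
            raise ValueError("snp_ids/means/scales must all have one entry per SNP")
        if self.sensitivities.shape != (d,):
            raise ValueError("one sensitivity per component required")
        gram = self.q_matrix.T @ self.q_matrix
        if not np.allclose(gram, np.eye(d), atol=1e-8):
            raise ValueError("q_matrix columns must be orthonormal")
        if not (self.sensitivities > 0).all():
            raise DegenerateModelError("all sensitivities must be positive")

    # -- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "snp_ids": self.snp_ids,
            "n_components": self.n_components,
            "q_matrix": self.q_matrix.ravel(order="C").tolist(),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "sensitivities": self.sensitivities.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        payload = json.loads(Path(path).read_text())
        m = len(payload["snp_ids"])
        d = payload["n_components"]
        return cls(
            q_matrix=np.asarray(payload["q_matrix"], dtype=float).reshape(m, d),
            n_components=d,
            snp_ids=list(payload["snp_ids"]),
            means=np.asarray(payload["means"], dtype=float),
            scales=np.asarray(payload["scales"], dtype=float),
            sensitivities=np.asarray(payload["sensitivities"], dtype=float),
        )


@dataclass
class NoisyMetadata:
    """One researcher's shared payload: hashed IDs plus noisy coordinates."""

    hashed_ids: list[str]
    coordinates: np.ndarray
    epsilon: float
    n_components: int

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != self.n_components:
            raise ValueError("coordinates must be n x n_components")
        if len(self.hashed_ids) != self.coordinates.shape[0]:
            raise ValueError("hashed_ids length must match coordinate rows")
        if len(set(self.hashed_ids)) != len(self.hashed_ids):
            raise ValueError("hashed_ids must be unique within a payload")
        if not (self.epsilon > 0):  # also rejects NaN; inf passes
            raise ValueError("epsilon must be positive (math.inf = no noise)")

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]

    def save(self, path: str | Path) -> None:
        """Write coordinates as CSV plus a small JSON sidecar (``<path>.json``).

        Floats are serialized with ``repr`` (17 significant digits) so the
        round trip is bit exact.
        """
        path = Path(path)
        header = "hashed_id," + ",".join(
            f"coord_{j + 1}" for j in range(self.n_components)
        )
        lines = [header]
        for hid, row in zip(self.hashed_ids, self.coordinates):
            lines.append(hid + "," + ",".join(repr(float(v)) for v in row))
        path.write_text("\n".join(lines) + "\n")
        sidecar = {
            "epsilon": "inf" if math.isinf(self.epsilon) else self.epsilon,
            "n_components": self.n_components,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "NoisyMetadata":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        eps = sidecar["epsilon"]
        eps = math.inf if isinstance(eps, str) and eps in INF_EPSILON_TOKENS else float(eps)
        hashed: list[str] = []
        rows: list[list[float]] = []
        lines = path.read_text().strip().splitlines()
        for line in lines[1:]:
            cells = line.split(",")
            hashed.append(cells[0])
            rows.append([float(c) for c in cells[1:]])
        coords = np.asarray(rows, dtype=float).reshape(len(hashed), sidecar["n_components"])
        return cls(hashed, coords, eps, sidecar["n_components"])


# ---------------------------------------------------------------------------
# server side: training
# ---------------------------------------------------------------------------

def _standardize_fit(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-fill missing entries, return (standardized, means, scales)."""
    filled = values.copy()
    if np.isnan(filled).any():
        col_means = np.nanmean(filled, axis=0)
        idx = np.where(np.isnan(filled))
        filled[idx] = col_means[idx[1]]
    means = filled.mean(axis=0)
    scales = filled.std(axis=0)  # population sd, matching StandardScaler
    if (scales == 0).any():
        j = int(np.flatnonzero(scales == 0)[0])
        raise ValueError(
            f"SNP column {j} has zero variance on the training panel; "
            "apply qc_filter before fitting"
        )
    return (filled - means) / scales, means, scales


def compute_sensitivity(public_scores: FactorScores) -> np.ndarray:
    """Per-component sensitivity: score range (max − min) on the public panel."""
    if public_scores.coordinates.shape[0] == 0:
        raise ValueError("cannot compute sensitivities from empty scores")
    s = np.ptp(public_scores.coordinates, axis=0)
    if not (s > 0).all():
        j = int(np.flatnonzero(~(s > 0))[0])
        raise DegenerateModelError(f"component {j + 1} is constant on the public panel")
    return s


def fit_pca_model(public: GenotypeMatrix, n_components: int) -> PCAModel:
    """Train the shared PCA model on the server's public panel.

    The panel is standardized per SNP; the top-``n_components`` right
    singular vectors form the projection matrix Q. Each column's sign is
    fixed so its largest-magnitude entry is positive, making the model (and
    its serialization) deterministic. Sensitivities are the per-component
    factor-score ranges of the panel itself.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if public.n_samples < n_components + 1:
        raise ValueError("need at least n_components + 1 training samples")
    if public.n_snps < n_components:
        raise ValueError("need at least n_components SNPs")
    z, means, scales = _standardize_fit(public.values)
    _, svals, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((svals > svals[0] * max(z.shape) * np.finfo(float).eps).sum())
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but the panel has rank {rank}"
        )
    q = vt[:n_components].T
    flip = np.sign(q[np.abs(q).argmax(axis=0), np.arange(n_components)])
    q = q * flip
    # same row-wise kernel as project_samples so the panel's own projection
    # (and hence the sensitivities) is bit-reproducible at the clients
    scores = FactorScores(_project_rows(z, q), list(public.sample_ids))
    sens = compute_sensitivity(scores)
    return PCAModel(q, n_components, list(public.snp_ids), means, scales, sens)


# ---------------------------------------------------------------------------
# client side: projection, perturbation, pseudonymization
# ---------------------------------------------------------------------------

def _project_rows(z: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-by-row projection: a sample's coordinates must not depend on the
    batch it is projected with, and blocked matrix-matrix products round
    differently for different batch sizes."""
    coords = np.empty((z.shape[0], q.shape[1]))
    for i in range(z.shape[0]):
        coords[i] = z[i] @ q
    return coords


def project_samples(model: PCAModel, local: GenotypeMatrix) -> FactorScores:
    """Project supplementary samples through the trained model: F = Z_std Q.

    Rows are standardized with the model's means/scales; a missing dosage is
    imputed with the model's training mean, i.e. contributes 0 after
    standardization.
    """
    if list(local.snp_ids) != list(model.snp_ids):
        for j, (a, b) in enumerate(zip(local.snp_ids, model.snp_ids)):
            if a != b:
                raise ValueError(
                    f"SNP mismatch at column {j}: local {a!r} vs model {b!r}"
                )
        raise ValueError(
            f"SNP count mismatch: local has {local.n_snps}, model expects "
            f"{len(model.snp_ids)} (run align_snp_sets first)"
        )
    z = (local.values - model.means) / model.scales
    z = np.nan_to_num(z, nan=0.0)
    return FactorScores(_project_rows(z, model.q_matrix), list(local.sample_ids))


def laplace_scales(
    sensitivities: np.ndarray | Sequence[float], epsilon: float, n_components: int | None = None
) -> np.ndarray:
    """Per-component Laplace scale λ_j = s_j · d / ε (budget ε split over d)."""
    s = np.asarray(sensitivities, dtype=float)
    d = len(s) if n_components is None else n_components
    return s * d / epsilon


def perturb_projection(
    scores: FactorScores,
    epsilon: float,
    sensitivities: np.ndarray | Sequence[float],
    rng_seed: int | np.random.Generator | None = None,
) -> FactorScores:
    """Add ε-LDP Laplace noise to factor scores.

    Component j receives i.i.d. Laplace(0, s_j·d/ε) noise, d being the
    number of shared components, so the per-dimension budget is ε/d and the
    total budget ε. ``epsilon = math.inf`` returns the scores unchanged
    (bit exact). By default the noise stream is seeded from fresh OS
    entropy; pass ``rng_seed`` only for reproducible experiments.
    """
    if math.isnan(epsilon) or epsilon <= 0:
        raise ValueError("epsilon must be positive")
    sens = np.asarray(sensitivities, dtype=float)
    if sens.shape != (scores.n_components,):
        raise ValueError("need one sensitivity per component")
    if math.isinf(epsilon):
        return FactorScores(scores.coordinates.copy(), list(scores.sample_ids))
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lam = laplace_scales(sens, epsilon)
    noise = rng.laplace(0.0, lam, size=scores.coordinates.shape)
    return FactorScores(scores.coordinates + noise, list(scores.sample_ids))


def hash_sample_ids(sample_ids: Sequence[str], salt: str | None = None) -> list[str]:
    """SHA-256 pseudonyms (64-char lowercase hex) of UTF-8 encoded IDs.

    ``salt``, when given, is prepended before hashing; the default (no salt)
    is a plain digest of the identifier. Duplicate inputs are rejected
    because the shared payload requires unique pseudonyms.
    """
    ids = [str(s) for s in sample_ids]
    if any(not s for s in ids):
        raise ValueError("sample ids must be non-empty strings")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids cannot be pseudonymized")
    prefix = salt or ""
    return [hashlib.sha256((prefix + s).encode("utf-8")).hexdigest() for s in ids]


def build_metadata(
    noisy: FactorScores, epsilon: float, salt: str | None = None
) -> NoisyMetadata:
    """Couple SHA-256 pseudonyms with noisy coordinates into the payload."""
    if noisy.coordinates.shape[0] == 0:
        raise ValueError("cannot build metadata from empty scores")
    return NoisyMetadata(
        hashed_ids=hash_sample_ids(noisy.sample_ids, salt=salt),
        coordinates=noisy.coordinates.copy(),
        epsilon=epsilon,
        n_components=noisy.n_components,
    )


def researcher_payload(
    model: PCAModel,
    local: GenotypeMatrix,
    epsilon: float,
    rng_seed: int | np.random.Generator | None = None,
    salt: str | None = None,
) -> NoisyMetadata:
    """Convenience: project, perturb, and pseudonymize one local dataset."""
    scores = project_samples(model, local)
    noisy = perturb_projection(scores, epsilon, model.sensitivities, rng_seed)
    return build_metadata(noisy, epsilon, salt=salt)
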