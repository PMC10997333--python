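"""Interpretation geometry over parse-depth vectors, and model RDMs.

The incremental parse-depth vector of the first three words (determiner,
subject noun, first verb) locates each sentence in a 3-D model space whose
fixed landmarks are the context-free depth vectors of the passive and
active parses.  A sentence's *interpretative mismatch* with a reading is
the cosine distance between its estimated depth vector and that reading's
landmark; its trajectory is the sequence of per-prefix distances to both
landmarks.  Any scalar or vector measure over the stimulus set can be
turned into a model representational dissimilarity matrix (RDM) for RSA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

METRICS = ("absolute_difference", "cosine_distance",
           "pearson_correlation_distance", "euclidean")


@dataclass
class RDM:
    """Symmetric zero-diagonal dissimilarity matrix over conditions."""

    matrix: np.ndarray
    label: str = ""
    metric: str = "absolute_difference"
    condition_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("RDM entries must be finite")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = 0.5 * (m + m.T)
        np.fill_diagonal(self.matrix, 0.0)
        if self.condition_ids and len(self.condition_ids) != m.shape[0]:
            raise ValueError("condition_ids length mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (diagonal excluded), row-major."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.matrix[i, j]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.matrix, delimiter="\t")
        sidecar = {"label": self.label, "metric": self.metric,
                   "condition_ids": list(self.condition_ids)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RDM":
        path = Path(path)
        matrix = np.loadtxt(path, delimiter="\t")
        meta = {}
        if path.with_suffix(".json").exists():
            meta = json.loads(path.with_suffix(".json").read_text())
        return cls(matrix=matrix, label=meta.get("label", ""),
                   metric=meta.get("metric", "absolute_difference"),
                   condition_ids=tuple(meta.get("condition_ids", ())))


@dataclass
class TrajectoryRecord:
    """Per-prefix distances of one sentence to both landmarks."""

    sentence_id: str
    vectors: np.ndarray                     # (n_steps, 3)
    distance_to_passive: np.ndarray         # (n_steps,)
    distance_to_active: np.ndarray
    step_delta_passive: np.ndarray = field(init=False)   # (n_steps,), first 0
    step_delta_active: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for d in (self.distance_to_passive, self.distance_to_active):
            if np.any(np.asarray(d) < 0):
                raise ValueError("distances must be non-negative")
        self.step_delta_passive = np.diff(self.distance_to_passive, prepend=self.distance_to_passive[:1])
        self.step_delta_active = np.diff(self.distance_to_active, prepend=self.distance_to_active[:1])


def interpretative_mismatch(
    probe_depths: Sequence[float], context_free_depths: Sequence[float]
) -> float:
    """Cosine distance (1 − cosine similarity) between an estimated
    incremental depth vector and a landmark; smaller = stronger
    preference for that interpretation."""
    v = np.asarray(probe_depths, dtype=float)
    u = np.asarray(context_free_depths, dtype=float)
    if v.shape != u.shape or v.ndim != 1:
        raise ValueError("prefix lengths differ")
    nv, nu = np.linalg.norm(v), np.linalg.norm(u)
    if nv == 0 or nu == 0:
        raise ValueError("cosine distance undefined for zero-norm vector")
    return float(1.0 - np.dot(v, u) / (nv * nu))


def _distance(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "cosine_distance":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("cosine distance undefined for zero vector")
        return float(1.0 - np.dot(a, b) / (na * nb))
    raise ValueError(f"unsupported trajectory metric {metric!r}")


def landmark_trajectory(
    per_prefix_vectors: np.ndarray,
    passive_landmark: Sequence[float],
    active_landmark: Sequence[float],
    *,
    sentence_id: str = "",
    metric: str = "euclidean",
) -> TrajectoryRecord:
    """Distances of a sentence's evolving 3-D depth vector to the two
    interpretation landmarks, plus consecutive-step deltas (negative delta
    = movement toward that landmark)."""
    vecs = np.atleast_2d(np.asarray(per_prefix_vectors, dtype=float))
    if vecs.shape[0] < 1:
        raise ValueError("need at least one prefix step")
    pas = np.asarray(passive_landmark, dtype=float)
    act = np.asarray(active_landmark, dtype=float)
    d_pas = np.array([_distance(v, pas, metric) for v in vecs])
    d_act = np.array([_distance(v, act, metric) for v in vecs])
    return TrajectoryRecord(sentence_id=sentence_id, vectors=vecs,
                            distance_to_passive=d_pas, distance_to_active=d_act)


def v1_depth_change(v1_depth_at_mv: float, v1_depth_at_v1: float) -> float:
    """Updated-minus-initial change of the first verb's estimated depth.

    Positive values (toward the passive landmark depth 2) indicate growing
    preference for the passive reading by the time the actual main verb
    arrives; negative values indicate movement toward the active depth 0.
    """
    for v in (v1_depth_at_mv, v1_depth_at_v1):
        if v is None or not np.isfinite(v):
            raise ValueError("missing prefix record for V1 depth")
    return float(v1_depth_at_mv - v1_depth_at_v1)


def pca_scores(depth_matrix: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centered principal-component scores of a sentences x positions
    depth matrix; returns (scores, explained_variance_ratio).

    Component signs follow the convention that each component's
    largest-magnitude loading is positive.  If the matrix rank falls below
    ``n_components`` the surplus components are dropped with a warning.
    """
    X = np.asarray(depth_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("depth matrix must be 2-D")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, rank, *X.shape)
    if k < n_components:
        warnings.warn(
            f"rank {rank} below requested {n_components}; returning {k} components"
        )
    if k == 0:
        return np.zeros((X.shape[0], 0)), np.zeros(0)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(k):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    return scores, pca.explained_variance_ratio_


def model_rdm(
    values: np.ndarray,
    metric: str,
    *,
    label: str = "",
    condition_ids: Sequence[str] = (),
) -> RDM:
    """Model RDM from per-condition scalars or vectors.

    ``absolute_difference`` applies to scalar measures; ``cosine_distance``
    and ``pearson_correlation_distance`` to equal-length vectors.
    """
    vals = np.asarray(values, dtype=float)
    if metric == "absolute_difference":
        if vals.ndim != 1:
            raise ValueError("absolute_difference expects scalar values")
        mat = np.abs(vals[:, None] - vals[None, :])
    elif metric == "cosine_distance":
        if vals.ndim != 2:
            raise ValueError("cosine_distance expects a conditions x dim matrix")
        norms = np.linalg.norm(vals, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm condition vector")
        unit = vals / norms[:, None]
        mat = 1.0 - unit @ unit.T
        np.fill_diagonal(mat, 0.0)
        mat = np.clip(0.5 * (mat + mat.T), 0.0, 2.0)
    elif metric == "pearson_correlation_distance":
        if vals.ndim != 2:
            raise ValueError("correlation distance expects a matrix")
        if np.any(np.std(vals, axis=1) == 0):
            raise ValueError("constant condition vector: correlation undefined")
        mat = 1.0 - np.corrcoef(vals)
        np.fill_diagonal(mat, 0.0)
        mat = np.clip(0.5 * (mat + mat.T), 0.0, 2.0)
    else:
        raise ValueError(f"unsupported RDM metric {metric!r}")
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    return RDM(matrix=mat, label=label, metric=metric,
               condition_ids=tuple(condition_ids))
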