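"""Linear structural probing of contextual word embeddings.

A structural probe is a linear map ``B`` (k x d) on contextual word
embeddings ``h`` chosen so that the squared L2 norm of the transformed
embedding, ``||B h||^2``, estimates the word's parse depth in the
sentence's dependency tree.  Probes are trained by minimising the mean
absolute error between predicted and gold depths, normalised per sentence
by sentence length, with several random restarts; downstream analyses use
the parse depths averaged over restarts.

Probe quality is summarised by *root accuracy*: the fraction of sentences
in which the smallest predicted depth falls on the main verb (the root of
the dependency tree, whose parse depth is 0) when the whole sentence is
input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy.stats import spearmanr


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class EmbeddingSet:
    """Word embeddings keyed by (sentence_id, prefix_len).

    Each entry is a (prefix_len, d) array: one d-dimensional vector per
    word of the incremental prefix.  ``d`` is constant across entries.
    """

    def __init__(self, layer_tag: str = "layer") -> None:
        self.layer_tag = layer_tag
        self._entries: dict[tuple[str, int], np.ndarray] = {}
        self.d: int | None = None

    def add(self, sentence_id: str, prefix_len: int, vectors: np.ndarray) -> None:
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[0] != prefix_len:
            raise ValueError(
                f"expected ({prefix_len}, d) array, got shape {vectors.shape}"
            )
        if not np.all(np.isfinite(vectors)):
            raise ValueError("non-finite embedding values")
        if self.d is None:
            self.d = vectors.shape[1]
        elif vectors.shape[1] != self.d:
            raise ValueError(f"dimension {vectors.shape[1]} != {self.d}")
        self._entries[(str(sentence_id), int(prefix_len))] = vectors

    def get(self, sentence_id: str, prefix_len: int) -> np.ndarray:
        return self._entries[(str(sentence_id), int(prefix_len))]

    def keys(self):
        return self._entries.keys()

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key) -> bool:
        return (str(key[0]), int(key[1])) in self._entries


@dataclass
class ProbeModel:
    """A trained structural probe: predicted depth = ||transform @ h||^2."""

    transform: np.ndarray  # (k, d)
    training_meta: dict = field(default_factory=dict)
    restart_transforms: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.transform = np.asarray(self.transform, dtype=float)
        if self.transform.ndim != 2 or self.transform.shape[0] < 1:
            raise ValueError("transform must be a k x d matrix with k >= 1")
        if not np.all(np.isfinite(self.transform)):
            raise ValueError("non-finite probe transform")

    @property
    def d(self) -> int:
        return self.transform.shape[1]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _probe_loss_and_grad(B: np.ndarray, X: np.ndarray, y: np.ndarray,
                         w: np.ndarray) -> tuple[float, np.ndarray]:
    # loss = sum_w w_i |‖B x_i‖² − y_i| ; w holds 1/(n_sent · len(sent))
    Z = X @ B.T                     # (N, k)
    pred = np.einsum("ij,ij->i", Z, Z)
    err = pred - y
    loss = float(np.sum(w * np.abs(err)))
    s = w * np.sign(err)
    grad = 2.0 * (Z * s[:, None]).T @ X
    return loss, grad


def train_probe(
    train_set: EmbeddingSet,
    gold_depths: Mapping[tuple[str, int], Sequence[float]],
    *,
    k: int | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    learning_rate: float = 0.02,
) -> ProbeModel:
    """Train the probe with ``n_restarts`` random initialisations.

    The loss is the per-sentence length-normalised L1 error between
    ``||B h||^2`` and the gold parse depth, minimised by full-batch Adam
    with plateau-halved learning rate; iteration stops when the relative
    improvement of the best loss falls below ``tol``.  The returned model
    is the restart with the lowest final training loss; all restart
    transforms are retained so depth predictions can be averaged across
    restarts.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    keys = sorted(train_set.keys())
    X_parts, y_parts, w_parts = [], [], []
    for key in keys:
        emb = train_set.get(*key)
        gold = np.asarray(gold_depths[key], dtype=float)
        if gold.shape[0] != emb.shape[0]:
            raise ValueError(f"gold depth length mismatch for {key}")
        X_parts.append(emb)
        y_parts.append(gold)
        w_parts.append(np.full(emb.shape[0], 1.0 / emb.shape[0]))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    w = np.concatenate(w_parts) / len(keys)
    d = X.shape[1]
    k = d if k is None else int(k)
    if k < 1:
        raise ValueError("probe rank k must be >= 1")

    rng = np.random.default_rng(seed)
    restart_losses: list[float] = []
    restart_curves: list[list[float]] = []
    transforms: list[np.ndarray] = []
    for restart in range(n_restarts):
        B = rng.normal(scale=1.0 / np.sqrt(d), size=(k, d))
        m = np.zeros_like(B)
        v = np.zeros_like(B)
        lr = learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss = np.inf
        best_B = B.copy()
        since_improve = 0
        curve: list[float] = []
        for it in range(1, max_iter + 1):
            loss, grad = _probe_loss_and_grad(B, X, y, w)
            curve.append(loss)
            if loss < best_loss * (1.0 - tol):
                since_improve = 0
            else:
                since_improve += 1
            if loss < best_loss:
                best_loss = loss
                best_B = B.copy()
            if since_improve >= 200:
                break
            if since_improve and since_improve % 50 == 0:
                lr *= 0.5
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad ** 2
            mhat = m / (1 - beta1 ** it)
            vhat = v / (1 - beta2 ** it)
            B = B - lr * mhat / (np.sqrt(vhat) + eps)
        restart_losses.append(best_loss)
        restart_curves.append(curve)
        transforms.append(best_B)

    best = int(np.argmin(restart_losses))
    meta = {
        "restart_losses": [float(l) for l in restart_losses],
        "best_restart": best,
        "seed": seed,
        "k": k,
        "n_restarts": n_restarts,
        "loss_curve": [float(l) for l in restart_curves[best]],
    }
    return ProbeModel(transform=transforms[best], training_meta=meta,
                      restart_transforms=transforms)


def predict_depths(probe: ProbeModel, embeddings: np.ndarray) -> np.ndarray:
    """Predicted parse depths ``||B h||^2`` for one (sentence, prefix)."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[1] != probe.d:
        raise ValueError(
            f"embedding dimension {embeddings.shape} incompatible with probe d={probe.d}"
        )
    Z = embeddings @ probe.transform.T
    return np.einsum("ij,ij->i", Z, Z)


def predict_depths_averaged(probe: ProbeModel, embeddings: np.ndarray) -> np.ndarray:
    """Depth predictions averaged over all training restarts (depth space)."""
    if not probe.restart_transforms:
        return predict_depths(probe, embeddings)
    preds = [
        predict_depths(ProbeModel(transform=B), embeddings)
        for B in probe.restart_transforms
    ]
    return average_restarts(preds)


def average_restarts(depth_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of per-restart depth predictions."""
    if len(depth_vectors) == 0:
        raise ValueError("no restart predictions")
    arrs = [np.asarray(v, dtype=float) for v in depth_vectors]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("restart predictions differ in shape")
    return np.mean(arrs, axis=0)


def root_accuracy(
    probe: ProbeModel,
    eval_set: EmbeddingSet,
    main_verb_positions: Mapping[str, int],
    *,
    use_restart_average: bool = True,
) -> float:
    """Fraction of sentences whose minimum predicted depth is the main verb.

    Whole-sentence embeddings are used (the entry with the largest
    prefix_len per sentence).  A non-unique minimum counts as incorrect.
    """
    by_sentence: dict[str, int] = {}
    for sid, plen in eval_set.keys():
        by_sentence[sid] = max(by_sentence.get(sid, 0), plen)
    if not by_sentence:
        raise ValueError("empty evaluation set")
    n_correct = 0
    for sid, plen in sorted(by_sentence.items()):
        if sid not in main_verb_positions:
            raise KeyError(f"missing main-verb annotation for sentence {sid!r}")
        emb = eval_set.get(sid, plen)
        depths = (predict_depths_averaged(probe, emb) if use_restart_average
                  else predict_depths(probe, emb))
        mv = int(main_verb_positions[sid])  # 1-based
        mins = np.flatnonzero(depths == depths.min())
        if mins.size == 1 and mins[0] == mv - 1:
            n_correct += 1
    return n_correct / len(by_sentence)


def position_contribution(
    depth_vectors: np.ndarray,
    position_to_shuffle: int,
    *,
    n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """Contribution of one word position to parse-depth vector variance.

    The depths at ``position_to_shuffle`` (1-based) are permuted across
    sentences; the statistic is the mean, over shuffles and sentences, of
    the Spearman distance (1 − rho) between each original vector and its
    shuffled counterpart.  Higher values mean the position carries more of
    the cross-sentence variance.  Returns NaN (with a warning) if every
    per-sentence correlation is undefined (constant vectors).
    """
    mat = np.asarray(depth_vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 3:
        raise ValueError("need a (n_sentences >= 3, prefix_len) depth matrix")
    n_sent, prefix_len = mat.shape
    if not 1 <= position_to_shuffle <= prefix_len:
        raise ValueError(f"position {position_to_shuffle} out of range")
    col = position_to_shuffle - 1
    rng = np.random.default_rng(seed)
    dists: list[float] = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n_sent)
        shuffled = mat.copy()
        shuffled[:, col] = mat[perm, col]
        for s in range(n_sent):
            if np.ptp(mat[s]) == 0 or np.ptp(shuffled[s]) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearmanr(mat[s], shuffled[s]).statistic
            if np.isfinite(rho):
                dists.append(1.0 - rho)
    if not dists:
        warnings.warn("all vectors constant; position contribution undefined")
        return float("nan")
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_embedding_set(es: EmbeddingSet, h5_path: str | Path,
                       index_path: str | Path | None = None) -> None:
    """Write embeddings to HDF5 plus a delimited-text row index."""
    h5_path = Path(h5_path)
    keys = sorted(es.keys())
    rows = np.concatenate([es.get(*k) for k in keys]) if keys else np.empty((0, 0))
    index_lines = ["sentence_id\tprefix_len\tposition\trow_offset"]
    offset = 0
    for sid, plen in keys:
        for pos in range(1, plen + 1):
            index_lines.append(f"{sid}\t{plen}\t{pos}\t{offset}")
            offset += 1
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("embeddings", data=rows)
        f.attrs["layer_tag"] = es.layer_tag
    if index_path is None:
        index_path = h5_path.with_suffix(".index.tsv")
    Path(index_path).write_text("\n".join(index_lines) + "\n")


def load_embedding_set(h5_path: str | Path,
                       index_path: str | Path | None = None) -> EmbeddingSet:
    h5_path = Path(h5_path)
    if index_path is None:
        index_path = h5_path.with_suffix(".index.tsv")
    with h5py.File(h5_path, "r") as f:
        rows = f["embeddings"][()]
        layer_tag = str(f.attrs.get("layer_tag", "layer"))
    es = EmbeddingSet(layer_tag=layer_tag)
    groups: dict[tuple[str, int], list[int]] = {}
    lines = Path(index_path).read_text().splitlines()
    for line in lines[1:]:
        sid, plen, _pos, off = line.split("\t")
        groups.setdefault((sid, int(plen)), []).append(int(off))
    for (sid, plen), offs in groups.items():
        es.add(sid, plen, rows[np.asarray(offs)])
    return es


def save_probe(probe: ProbeModel, path: str | Path) -> None:
    """Probe transform(s) as .npz with a JSON metadata sidecar."""
    path = Path(path)
    arrays = {"transform": probe.transform}
    for i, B in enumerate(probe.restart_transforms):
        arrays[f"restart_{i}"] = B
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(probe.training_meta, indent=1))


def load_probe(path: str | Path) -> ProbeModel:
    path = Path(path)
    with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
        transform = data["transform"]
        restarts = [data[k] for k in sorted(
            (k for k in data.files if k.startswith("restart_")),
            key=lambda s: int(s.split("_")[1]))]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ProbeModel(transform=transform, training_meta=meta,
                      restart_transforms=restarts)


def select_best_layer(
    probes_by_layer: Mapping[str, ProbeModel],
    eval_set: EmbeddingSet,
    main_verb_positions: Mapping[str, int],
) -> tuple[str, dict[str, float]]:
    """Compare candidate representation layers by root accuracy."""
    scores = {
        tag: root_accuracy(p, eval_set, main_verb_positions)
        for tag, p in probes_by_layer.items()
    }
    best = max(scores, key=lambda t: (scores[t], t))
    return best, scores
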