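"""Spatiotemporal searchlight representational similarity analysis (ssRSA).

A searchlight is a sphere of mesh vertices (default radius 10 mm) crossed
with a sliding time window (default +-30 ms, i.e. 60 ms).  Within each
searchlight the per-sentence source patterns are vectorised, optionally
whitened by a shrinkage-estimated noise covariance, and turned into a data
RDM of pairwise Pearson correlation distances.  Model RDMs are fitted to
data RDMs by Spearman rank correlation over the lower triangle, giving a
participant x vertex x time map of model fits.  Group inference uses a
one-tailed one-sample t-test per vertex/time with cluster-based sign-flip
permutation correction (suprathreshold clusters scored by t-mass against
the max-cluster-mass permutation null).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import rankdata, t as t_dist

from .geometry import RDM


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Source-space vertex table: ids, 3-D coordinates in mm, optional
    region labels."""

    vertex_ids: np.ndarray
    coordinates: np.ndarray  # (n, 3) mm
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(np.unique(self.vertex_ids)) != len(self.vertex_ids):
            raise ValueError("duplicate vertex ids")
        if self.coordinates.shape != (len(self.vertex_ids), 3):
            raise ValueError("coordinates must be (n_vertices, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite vertex coordinates")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "vertex_id": self.vertex_ids,
            "x_mm": self.coordinates[:, 0],
            "y_mm": self.coordinates[:, 1],
            "z_mm": self.coordinates[:, 2],
        })
        if self.region_labels is not None:
            df["region"] = self.region_labels
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "Mesh":
        df = pd.read_csv(path, sep="\t")
        labels = df["region"].to_numpy() if "region" in df.columns else None
        return cls(df["vertex_id"].to_numpy(),
                   df[["x_mm", "y_mm", "z_mm"]].to_numpy(), labels)


@dataclass
class SourceEpochs:
    """Source-space epochs: (participant, sentence, vertex, time sample)."""

    data: np.ndarray
    sampling_rate: float
    epoch_label: str = "V1"       # one of V1 / PP1 / MV
    sentence_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                "epochs must be (participant, sentence, vertex, time)")
        if self.sentence_ids and len(self.sentence_ids) != self.data.shape[1]:
            raise ValueError("sentence_ids length mismatch")

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.data.shape[3]) * 1000.0 / self.sampling_rate

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("data", data=self.data)
            d.attrs["dims"] = "participant,sentence,vertex,time"
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["epoch_label"] = self.epoch_label
            f.attrs["sentence_ids"] = json.dumps(list(self.sentence_ids))

    @classmethod
    def load(cls, path: str | Path) -> "SourceEpochs":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                epoch_label=str(f.attrs["epoch_label"]),
                sentence_ids=tuple(json.loads(f.attrs["sentence_ids"])),
            )


@dataclass
class SearchlightSpec:
    """Searchlight geometry: 10 mm spatial and 30 ms temporal radius by
    default (a 60 ms sliding window); ``time_stride`` sets the spacing of
    window centers in samples."""

    spatial_radius_mm: float = 10.0
    temporal_radius_ms: float = 30.0
    time_stride: int = 1

    def __post_init__(self) -> None:
        if self.spatial_radius_mm <= 0 or self.temporal_radius_ms <= 0:
            raise ValueError("searchlight radii must be positive")
        if self.time_stride < 1:
            raise ValueError("time_stride must be >= 1")


@dataclass
class Neighborhoods:
    """Searchlight index: per vertex its in-radius vertex set; per time
    center its clipped sample window."""

    vertex_neighbors: list[np.ndarray]
    window_centers: np.ndarray          # sample indices
    window_slices: list[tuple[int, int]]  # [start, stop) samples


@dataclass
class FitMap:
    """Spearman model fits: (participant, vertex, window center)."""

    rho: np.ndarray
    window_centers: np.ndarray
    model_label: str = ""
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 3:
            raise ValueError("rho must be (participant, vertex, center)")
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("rho outside [-1, 1]")

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("rho", data=self.rho)
            d.attrs["dims"] = "participant,vertex,window_center"
            f.create_dataset("window_centers", data=self.window_centers)
            f.attrs["model_label"] = self.model_label
            if self.sampling_rate is not None:
                f.attrs["sampling_rate"] = self.sampling_rate

    @classmethod
    def load(cls, path: str | Path) -> "FitMap":
        with h5py.File(path, "r") as f:
            sr = f.attrs.get("sampling_rate")
            return cls(rho=f["rho"][()],
                       window_centers=f["window_centers"][()],
                       model_label=str(f.attrs["model_label"]),
                       sampling_rate=float(sr) if sr is not None else None)


@dataclass
class ClusterResult:
    """Suprathreshold spatiotemporal clusters with permutation p-values."""

    t_map: np.ndarray                 # (vertex, center)
    threshold: float
    clusters: list[dict]              # {"nodes": [(v, c), ...], "mass": .., "p": ..}
    significant_mask: np.ndarray      # (vertex, center) bool
    null_max_mass: np.ndarray
    cluster_alpha: float

    def save(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "cluster_alpha": self.cluster_alpha,
            "clusters": [
                {"nodes": [[int(v), int(c)] for v, c in cl["nodes"]],
                 "mass": float(cl["mass"]), "p": float(cl["p"])}
                for cl in self.clusters
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        np.savetxt(path.with_suffix(".mask.tsv"),
                   self.significant_mask.astype(int), fmt="%d", delimiter="\t")


# ---------------------------------------------------------------------------
# searchlight construction
# ---------------------------------------------------------------------------

def searchlight_index(
    mesh: Mesh,
    times_ms: Sequence[float],
    spec: SearchlightSpec,
    *,
    distance_matrix: np.ndarray | None = None,
) -> Neighborhoods:
    """Vertex neighborhoods and clipped time windows for every center.

    Distances are Euclidean in source coordinates unless a precomputed
    ``distance_matrix`` is supplied.  Every center vertex is in its own
    neighborhood; windows span [t − r, t + r] clipped to the epoch.
    """
    times = np.asarray(times_ms, dtype=float)
    if times.size == 0:
        raise ValueError("empty time axis")
    if distance_matrix is not None:
        dm = np.asarray(distance_matrix, dtype=float)
        neighbors = [np.flatnonzero(dm[i] <= spec.spatial_radius_mm)
                     for i in range(mesh.n_vertices)]
    else:
        tree = cKDTree(mesh.coordinates)
        neighbors = [np.asarray(idx, dtype=int) for idx in
                     tree.query_ball_point(mesh.coordinates,
                                           spec.spatial_radius_mm)]
    centers = np.arange(0, times.size, spec.time_stride)
    dt = times[1] - times[0] if times.size > 1 else 1.0
    r_samples = int(round(spec.temporal_radius_ms / dt)) if times.size > 1 else 0
    slices = [(max(0, c - r_samples), min(times.size, c + r_samples + 1))
              for c in centers]
    return Neighborhoods(vertex_neighbors=neighbors, window_centers=centers,
                         window_slices=slices)


# ---------------------------------------------------------------------------
# pattern normalization and data RDMs
# ---------------------------------------------------------------------------

def shrinkage_covariance(residuals: np.ndarray, shrinkage: float = 0.4) -> np.ndarray:
    """Sample covariance shrunk toward its own diagonal."""
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need >= 2 residual samples")
    S = np.cov(R, rowvar=False)
    S = np.atleast_2d(S)
    return (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))


def multivariate_normalize(
    patterns: np.ndarray,
    residuals: np.ndarray,
    *,
    shrinkage: float = 0.4,
) -> np.ndarray:
    """Whiten patterns by the inverse square root of the shrinkage noise
    covariance estimated from residuals (channels on the last axis)."""
    X = np.asarray(patterns, dtype=float)
    C = shrinkage_covariance(residuals, shrinkage)
    vals, vecs = np.linalg.eigh(C)
    vals = np.maximum(vals, 1e-12 * vals.max() if vals.max() > 0 else 1e-12)
    W = vecs @ np.diag(vals ** -0.5) @ vecs.T
    return X @ W.T


def data_rdm(
    patterns: np.ndarray,
    *,
    normalize: bool = False,
    shrinkage: float = 0.4,
    condition_ids: Sequence[str] = (),
    label: str = "data",
) -> RDM:
    """Pearson-correlation-distance RDM over per-sentence patterns.

    ``patterns`` is (n_sentences, n_channels); with ``normalize`` the
    channels are whitened by the shrinkage noise covariance of the
    trial-mean-removed patterns before distances are taken.
    """
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 sentences of patterns")
    if normalize and X.shape[0] > 2:
        X = multivariate_normalize(X, X - X.mean(axis=0), shrinkage=shrinkage)
    stds = X.std(axis=1)
    if np.any(stds == 0):
        bad = np.flatnonzero(stds == 0).tolist()
        raise ValueError(f"constant pattern for sentences {bad}: "
                         "correlation distance undefined")
    mat = 1.0 - np.corrcoef(X)
    np.fill_diagonal(mat, 0.0)
    mat = np.clip(0.5 * (mat + mat.T), 0.0, 2.0)
    return RDM(matrix=mat, label=label, metric="pearson_correlation_distance",
               condition_ids=tuple(condition_ids))


def fit_model(model: RDM, data: RDM) -> float:
    """Spearman rho between model and data RDM lower triangles."""
    if model.n != data.n:
        raise ValueError("RDM sizes differ")
    if model.condition_ids and data.condition_ids \
            and model.condition_ids != data.condition_ids:
        raise ValueError("condition order mismatch between model and data RDM")
    a = rankdata(model.condensed())
    b = rankdata(data.condensed())
    return float(np.corrcoef(a, b)[0, 1])


def run_ssrsa(
    epochs: SourceEpochs,
    model: RDM,
    mesh: Mesh,
    spec: SearchlightSpec,
    *,
    normalize: bool = False,
    shrinkage: float = 0.4,
) -> FitMap:
    """Model fit for every (participant, vertex, window center)."""
    if epochs.data.shape[1] != model.n:
        raise ValueError("sentence count differs from model RDM size")
    if model.condition_ids and epochs.sentence_ids \
            and tuple(model.condition_ids) != tuple(epochs.sentence_ids):
        raise ValueError("condition order mismatch between model RDM and epochs")
    nb = searchlight_index(mesh, epochs.times_ms, spec)
    n_part, n_sent, n_vert, _ = epochs.data.shape
    n_centers = len(nb.window_centers)
    model_ranks = rankdata(model.condensed())
    mrc = model_ranks - model_ranks.mean()
    mnorm = np.sqrt(np.sum(mrc ** 2))
    il, jl = np.tril_indices(n_sent, k=-1)
    rho = np.full((n_part, n_vert, n_centers), np.nan)
    for p in range(n_part):
        part = epochs.data[p]
        for v in range(n_vert):
            verts = nb.vertex_neighbors[v]
            block_all = part[:, verts, :]          # (sent, |verts|, time)
            for ci, (lo, hi) in enumerate(nb.window_slices):
                X = block_all[:, :, lo:hi].reshape(n_sent, -1)
                if normalize and X.shape[0] > 2:
                    X = multivariate_normalize(X, X - X.mean(axis=0),
                                               shrinkage=shrinkage)
                stds = X.std(axis=1)
                if np.any(stds == 0):
                    continue
                dmat = 1.0 - np.corrcoef(X)
                dr = rankdata(dmat[il, jl])
                drc = dr - dr.mean()
                denom = mnorm * np.sqrt(np.sum(drc ** 2))
                rho[p, v, ci] = float(np.dot(mrc, drc) / denom) if denom > 0 else np.nan
    return FitMap(rho=rho, window_centers=nb.window_centers,
                  model_label=model.label, sampling_rate=epochs.sampling_rate)


# ---------------------------------------------------------------------------
# group-level cluster permutation inference
# ---------------------------------------------------------------------------

def _spatiotemporal_adjacency(mesh: Mesh, n_centers: int,
                              cluster_radius_mm: float) -> sparse.csr_matrix:
    """Adjacency over (vertex, center) nodes: spatially in-radius vertices
    at the same center, and the same vertex at consecutive centers."""
    tree = cKDTree(mesh.coordinates)
    pairs = tree.query_pairs(cluster_radius_mm, output_type="ndarray")
    V = mesh.n_vertices
    rows, cols = [], []
    for c in range(n_centers):
        base = c * V
        if pairs.size:
            rows.append(pairs[:, 0] + base)
            cols.append(pairs[:, 1] + base)
        if c + 1 < n_centers:
            v = np.arange(V)
            rows.append(v + base)
            cols.append(v + base + V)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    else:
        rows = np.empty(0, dtype=int)
        cols = np.empty(0, dtype=int)
    n = V * n_centers
    A = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return (A + A.T).tocsr()


def _max_cluster_mass(t_flat: np.ndarray, threshold: float,
                      adjacency: sparse.csr_matrix) -> float:
    nodes = np.flatnonzero(t_flat > threshold)
    if nodes.size == 0:
        return 0.0
    sub = adjacency[nodes][:, nodes]
    n_comp, labels = connected_components(sub, directed=False)
    masses = np.bincount(labels, weights=t_flat[nodes], minlength=n_comp)
    return float(masses.max())


def group_cluster_test(
    fitmap: FitMap,
    mesh: Mesh,
    *,
    n_perm: int = 5000,
    vertex_p: float = 0.01,
    cluster_p: float = 0.05,
    seed: int = 0,
    cluster_radius_mm: float | None = None,
    spec: SearchlightSpec | None = None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test on participant fit maps.

    A one-tailed one-sample t-test (fits > 0) is run at every
    vertex/time; suprathreshold nodes (t above the one-tailed t quantile
    at ``vertex_p``, df = n_participants − 1) form spatiotemporally
    connected clusters scored by summed t.  The null distribution of the
    maximum cluster mass is built by randomly sign-flipping each
    participant's whole fit map; a cluster is significant if its mass
    exceeds the (1 − cluster_p) null quantile.
    """
    X = fitmap.rho
    n_part, V, C = X.shape
    if n_part < 2:
        raise ValueError("need >= 2 participants")
    radius = cluster_radius_mm if cluster_radius_mm is not None else (
        spec.spatial_radius_mm if spec is not None else 10.0)
    # flatten center-major (node index = center * V + vertex) to match the
    # spatiotemporal adjacency layout
    Xf = np.nan_to_num(X.transpose(0, 2, 1).reshape(n_part, C * V), nan=0.0)
    threshold = float(t_dist.ppf(1.0 - vertex_p, df=n_part - 1))
    adjacency = _spatiotemporal_adjacency(mesh, C, radius)

    meansq = np.mean(Xf ** 2, axis=0)
    if n_perm >= 2 ** n_part:
        warnings.warn("n_perm exceeds 2^n_participants; using exhaustive sign flips")
        flips = np.array(list(product((1.0, -1.0), repeat=n_part)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice((1.0, -1.0), size=(n_perm, n_part))
        flips[0] = 1.0  # include identity in the null per convention
    means = flips @ Xf / n_part                       # (n_perm, V*C)
    var = (meansq[None, :] - means ** 2) * n_part / (n_part - 1)
    var = np.maximum(var, 1e-30)
    t_perm = means / np.sqrt(var / n_part)

    t_obs = Xf.mean(axis=0) / np.sqrt(
        np.maximum((meansq - Xf.mean(axis=0) ** 2) * n_part / (n_part - 1), 1e-30)
        / n_part)
    null_max = np.array([
        _max_cluster_mass(t_perm[i], threshold, adjacency)
        for i in range(flips.shape[0])
    ])

    nodes = np.flatnonzero(t_obs > threshold)
    clusters: list[dict] = []
    mask = np.zeros(V * C, dtype=bool)
    if nodes.size:
        sub = adjacency[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = nodes[labels == comp]
            mass = float(t_obs[members].sum())
            p = float((1 + np.sum(null_max >= mass)) / (len(null_max) + 1))
            cl = {
                "nodes": [(int(m % V), int(m // V)) for m in members],
                "mass": mass,
                "p": p,
            }
            clusters.append(cl)
            if p < cluster_p:
                mask[members] = True
    clusters.sort(key=lambda cl: -cl["mass"])
    return ClusterResult(
        t_map=t_obs.reshape(C, V).T,
        threshold=threshold,
        clusters=clusters,
        significant_mask=mask.reshape(C, V).T,
        null_max_mass=null_max,
        cluster_alpha=cluster_p,
    )


def summary_maps(
    result: ClusterResult,
    *,
    region_labels: np.ndarray | None = None,
) -> dict:
    """Summary statistics of a cluster result.

    Returns vertex t-mass (summed t over each vertex's significant
    samples), per-cluster t-mass time series (summed t over a cluster's
    significant vertices at each time), and, when region labels are
    given, ROI peak-t series (max t in each ROI at each time).
    """
    t_map = result.t_map
    mask = result.significant_mask
    V, C = t_map.shape
    vertex_t_mass = np.where(mask, t_map, 0.0).sum(axis=1)
    cluster_series = []
    for cl in result.clusters:
        if cl["p"] >= result.cluster_alpha:
            continue
        series = np.zeros(C)
        for v, c in cl["nodes"]:
            series[c] += t_map[v, c]
        cluster_series.append({"mass": cl["mass"], "p": cl["p"],
                               "t_mass_series": series})
    out = {"vertex_t_mass": vertex_t_mass, "cluster_t_mass_series": cluster_series}
    if region_labels is not None:
        labels = np.asarray(region_labels)
        rois = {}
        for roi in np.unique(labels):
            rois[str(roi)] = t_map[labels == roi].max(axis=0)
        out["roi_peak_t"] = rois
    return out
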