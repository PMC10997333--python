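"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study design end to end with no external data:

* **Stimuli** — 60 sets of six sentences (360 in all).  The two *target*
  sentences per set differ only in the subcategorization bias of their
  first verb (high- vs low-transitivity) and are temporarily ambiguous
  between a passive parse (Verb1 heads a reduced relative clause) and an
  active parse (Verb1 is the main verb); both parses are generated for
  each target.  The remaining four sentences are structural fillers.
* **Embeddings** — word vectors in which parse depth is a planted
  squared-norm linear function ``||B0 h||^2``, following a schedule that
  blends the active parse's depths toward the passive parse's as the
  sentence unfolds (earlier and more strongly for high-transitivity
  targets, with both types converging on the passive parse at the main
  verb).
* **Corpus counts and continuations** — count tables whose derived
  direct-object probability is calibrated to means of 0.71 (high
  transitivity) and 0.44 (low transitivity), with condition-correlated
  thematic-role biases and continuation tables correlated with them.
* **Mesh and source epochs** — a random cortical-like vertex cloud and
  participant x sentence x vertex x time epochs of spatially correlated
  Gaussian noise, plus planted effects whose local pattern geometry
  inside chosen vertex/time windows matches a target model RDM (via a
  classical-MDS embedding mapped onto random orthonormal spatiotemporal
  patterns).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import RDM
from .probe import EmbeddingSet
from .rsa import Mesh, SourceEpochs
from .trees import DependencyTree, build_tree, node_depths

import pandas as pd

TARGET_CONDITIONS = ("HiTrans", "LoTrans")
FILLER_CONDITIONS = ("UNA", "PAS", "DO1", "DO2")
# 1-based positions in the 9-token target template
POSITIONS = {"Det": 1, "SN": 2, "V1": 3, "PP1": 4, "PP2": 5, "PP3": 6,
             "MV": 7, "END": 9}


@dataclass
class EffectSpec:
    """A planted representational effect: a target model RDM realised in
    the pattern geometry of a vertex set over a time-sample window."""

    vertex_indices: np.ndarray
    window: tuple[int, int]       # [start, stop) samples
    rdm: RDM
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=int)
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")


@dataclass
class SyntheticConfig:
    """Generator defaults mirror the study conditions.

    60 sentence sets with two target conditions each; 16 participants;
    600 ms epochs at 200 Hz; continuation pre-tests with 30 (after-V1)
    and 18 (after-PP) respondents; corpus-count biases calibrated so the
    direct-object probability averages 0.71 (HiTrans) vs 0.44 (LoTrans).
    """

    n_sets: int = 60
    embedding_dim: int = 32
    probe_rank: int = 16
    embedding_noise_sd: float = 0.0
    # log-transitivity means per condition: log(p/(1-p)) at p = 0.71 / 0.44
    log_transitivity_mean: dict = field(default_factory=lambda: {
        "HiTrans": 0.8954, "LoTrans": -0.2412})
    log_transitivity_sd: float = 0.78
    depth_jitter_sd: float = 0.15
    role_coherence_slope: float = 0.6   # log-patienthood tracks log-transitivity
    role_noise_sd: float = 0.6
    n_corpus_min: int = 150
    n_corpus_max: int = 400
    n_continuation_v1: int = 30
    n_continuation_pp: int = 18
    n_vertices: int = 200
    mesh_extent_mm: float = 35.0
    spatial_length_scale_mm: float = 15.0
    n_participants: int = 16
    sampling_rate: float = 200.0
    epoch_ms: float = 600.0
    noise_sd: float = 1.0
    master_seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_ms / 1000.0 * self.sampling_rate))

    def to_manifest(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, default=str))


@dataclass
class SentenceRecord:
    sentence_id: str
    set_id: int
    condition: str
    tokens: tuple[str, ...]
    is_target: bool
    positions: dict
    trees: dict                      # interpretation label -> DependencyTree
    word_timing_ms: list = field(default_factory=list)
    # latent stimulus-design variables for targets: the first verb's
    # log-transitivity (drives every downstream bias) and per-word
    # idiosyncratic depth offsets (sentences converge on the passive parse
    # but spread around its context-free depths)
    log_transitivity: float = 0.0
    depth_jitter: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

# 9-token target template: The SN V1 in the PLACE MV in NOUN2
_PASSIVE_HEADS = (2, 7, 2, 3, 6, 4, 0, 7, 8)
_ACTIVE_HEADS = (2, 3, 0, 3, 6, 4, 3, 7, 8)
_FILLER_HEADS = (2, 3, 0, 3, 6, 4, 8, 3, 8)  # simple coordinated parse


def _target_tokens(set_id: int, condition: str) -> tuple[str, ...]:
    verb = f"hiverb{set_id:02d}" if condition == "HiTrans" else f"loverb{set_id:02d}"
    return ("The", f"noun{set_id:02d}", verb, "in", "the",
            f"place{set_id:02d}", f"mverb{set_id:02d}", "in", f"goal{set_id:02d}")


def _filler_tokens(set_id: int, condition: str) -> tuple[str, ...]:
    return ("The", f"fnoun{set_id:02d}{condition}", f"fverb{set_id:02d}",
            "near", "the", f"fplace{set_id:02d}", "and", "went",
            f"fgoal{set_id:02d}")


def generate_stimuli(config: SyntheticConfig, seed: int | None = None
                     ) -> list[SentenceRecord]:
    """Sentence records for every set: two ambiguous targets with dual
    parses plus four structural fillers, with word-position labels and
    word timing metadata."""
    rng = np.random.default_rng(config.master_seed if seed is None else seed)
    records: list[SentenceRecord] = []
    for set_id in range(config.n_sets):
        for condition in TARGET_CONDITIONS + FILLER_CONDITIONS:
            is_target = condition in TARGET_CONDITIONS
            tokens = (_target_tokens(set_id, condition) if is_target
                      else _filler_tokens(set_id, condition))
            sid = f"s{set_id:02d}_{condition}"
            if is_target:
                trees = {
                    "passive": build_tree(tokens, _PASSIVE_HEADS,
                                          interpretation_label="passive",
                                          sentence_id=sid),
                    "active": build_tree(tokens, _ACTIVE_HEADS,
                                         interpretation_label="active",
                                         sentence_id=sid),
                }
            else:
                trees = {"other": build_tree(tokens, _FILLER_HEADS,
                                             interpretation_label="other",
                                             sentence_id=sid)}
            # word timing: onset, uniqueness point, offset per word (ms)
            timing = []
            t = 0.0
            for tok in tokens:
                dur = 180.0 + 40.0 * len(tok) + rng.uniform(-30.0, 30.0)
                up = t + 0.7 * dur + rng.uniform(-20.0, 20.0)
                timing.append({"onset": t, "uniqueness_point": up,
                               "offset": t + dur})
                t += dur
            log_t = 0.0
            jitter = np.zeros(len(tokens))
            if is_target:
                log_t = float(rng.normal(
                    config.log_transitivity_mean[condition],
                    config.log_transitivity_sd))
                jitter = rng.normal(0.0, config.depth_jitter_sd,
                                    size=len(tokens))
            records.append(SentenceRecord(
                sentence_id=sid, set_id=set_id, condition=condition,
                tokens=tokens, is_target=is_target,
                positions=dict(POSITIONS), trees=trees,
                word_timing_ms=timing, log_transitivity=log_t,
                depth_jitter=tuple(jitter)))
    return records


def target_records(records: Sequence[SentenceRecord]) -> list[SentenceRecord]:
    """The target sentences in canonical stimulus order."""
    return [r for r in records if r.is_target]


# ---------------------------------------------------------------------------
# embeddings with a planted squared-norm depth code
# ---------------------------------------------------------------------------

def planted_probe_matrix(config: SyntheticConfig, seed: int | None = None
                         ) -> np.ndarray:
    """A full-row-rank k x d planted probe matrix."""
    rng = np.random.default_rng(
        config.master_seed + 1 if seed is None else seed)
    while True:
        B0 = rng.normal(size=(config.probe_rank, config.embedding_dim))
        if np.linalg.matrix_rank(B0) == config.probe_rank:
            return B0


def interpretation_weight(log_transitivity: float, prefix_len: int) -> float:
    """Blend weight toward the passive parse for a given prefix.

    All targets start biased to the active reading; during the
    prepositional phrase the weight tracks the first verb's transitivity
    (a highly transitive verb left without its direct object pushes
    toward the passive parse, an intransitive one sustains the active
    parse); the actual main verb forces the passive parse in every
    sentence.
    """
    mv = POSITIONS["MV"]
    if prefix_len >= mv:
        return 1.0
    if prefix_len <= POSITIONS["V1"]:
        return 0.15 + 0.25 / (1.0 + np.exp(-1.5 * log_transitivity))
    return 0.15 + 0.7 / (1.0 + np.exp(-1.5 * log_transitivity))


def depth_schedule(record: SentenceRecord, prefix_len: int) -> np.ndarray:
    """Scheduled (real-valued) depths of the first ``prefix_len`` words."""
    if record.is_target:
        pas = node_depths(record.trees["passive"]).as_array()
        act = node_depths(record.trees["active"]).as_array()
        w = interpretation_weight(record.log_transitivity, prefix_len)
        sched = (1 - w) * act + w * pas
        jitter = np.asarray(record.depth_jitter, dtype=float)
        if jitter.size == sched.size:
            sched = np.maximum(sched + jitter, 0.0)
    else:
        sched = node_depths(record.trees["other"]).as_array()
    return sched[:prefix_len]


def generate_embeddings(
    records: Sequence[SentenceRecord],
    B0: np.ndarray,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    prefixes: str = "all",
    layer_tag: str = "synthetic",
) -> EmbeddingSet:
    """Embeddings whose planted squared-norm depth follows the schedule.

    For each word a vector ``h`` is built so that ``||B0 h||^2`` equals the
    scheduled depth exactly, then Gaussian noise of sd ``noise_sd`` is
    added.  ``prefixes`` is "all" (every incremental prefix) or "full"
    (whole-sentence input only).
    """
    B0 = np.asarray(B0, dtype=float)
    k, d = B0.shape
    if np.linalg.matrix_rank(B0) < k:
        raise ValueError("planted probe matrix must have full row rank")
    pinv = np.linalg.pinv(B0)
    # null-space directions add probe-invisible variance
    _, _, vt = np.linalg.svd(B0)
    null_basis = vt[k:].T if d > k else np.zeros((d, 0))
    rng = np.random.default_rng(seed)
    es = EmbeddingSet(layer_tag=layer_tag)
    for record in records:
        n = len(record.tokens)
        plens = range(1, n + 1) if prefixes == "all" else [n]
        for plen in plens:
            sched = depth_schedule(record, plen)
            if np.any(sched < 0):
                raise ValueError("infeasible schedule: negative target depth")
            H = np.empty((plen, d))
            for i, depth in enumerate(sched):
                u = rng.normal(size=k)
                u /= np.linalg.norm(u)
                h = pinv @ (np.sqrt(depth) * u)
                if null_basis.shape[1]:
                    h = h + null_basis @ rng.normal(
                        scale=0.5, size=null_basis.shape[1])
                H[i] = h
            if noise_sd > 0:
                H = H + rng.normal(scale=noise_sd, size=H.shape)
            es.add(record.sentence_id, plen, H)
    return es


def gold_depths(records: Sequence[SentenceRecord], prefixes: str = "all"
                ) -> dict[tuple[str, int], np.ndarray]:
    """Scheduled depths keyed like the embedding set, for probe training."""
    out: dict[tuple[str, int], np.ndarray] = {}
    for record in records:
        n = len(record.tokens)
        plens = range(1, n + 1) if prefixes == "all" else [n]
        for plen in plens:
            out[(record.sentence_id, plen)] = depth_schedule(record, plen)
    return out


def main_verb_positions(records: Sequence[SentenceRecord]) -> dict[str, int]:
    """1-based root position per sentence (the actual main verb)."""
    out = {}
    for record in records:
        tree = record.trees.get("passive") or record.trees["other"]
        out[record.sentence_id] = tree.root_position
    return out


# ---------------------------------------------------------------------------
# corpus counts and continuations
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_corpus_counts(
    config: SyntheticConfig,
    records: Sequence[SentenceRecord],
    seed: int | None = None,
) -> pd.DataFrame:
    """Raw agent/patient and subcategorization-frame counts per target.

    Log-transitivity is drawn per condition around the calibrated means;
    log-patienthood tracks it (coherence between thematic-role and
    subcategorization biases) with independent noise.  All counts >= 1.
    """
    rng = np.random.default_rng(
        config.master_seed + 2 if seed is None else seed)
    rows = []
    for record in target_records(records):
        log_t = record.log_transitivity
        p_do = _sigmoid(log_t)
        n_scf = int(rng.integers(config.n_corpus_min, config.n_corpus_max))
        do = int(np.clip(round(n_scf * p_do), 1, n_scf - 1))
        log_pat = (config.role_coherence_slope * log_t
                   + rng.normal(0.0, config.role_noise_sd))
        p_pat = _sigmoid(log_pat)
        n_role = int(rng.integers(config.n_corpus_min, config.n_corpus_max))
        patient = int(np.clip(round(n_role * p_pat), 1, n_role - 1))
        rows.append({
            "sentence_id": record.sentence_id,
            "condition": record.condition,
            "agent_count": n_role - patient,
            "patient_count": patient,
            "do_count": do,
            "other_scf_count": n_scf - do,
            "log_transitivity_true": log_t,
        })
    return pd.DataFrame(rows).set_index("sentence_id")


def generate_continuations(
    config: SyntheticConfig,
    records: Sequence[SentenceRecord],
    seed: int | None = None,
) -> pd.DataFrame:
    """Raw continuation counts at the after-V1 and after-PP gates.

    The direct-object continuation probability is tied to the sentence's
    (true) log-transitivity, so contextual and corpus transitivity
    correlate; main-verb continuations after the prepositional phrase are
    likelier for high-transitivity targets (the passive parse needs a
    main verb to complete).
    """
    rng = np.random.default_rng(
        config.master_seed + 3 if seed is None else seed)
    rows = []
    for record in target_records(records):
        log_t = record.log_transitivity
        p_do = float(np.clip(_sigmoid(log_t + rng.normal(0, 0.3)),
                             1 / config.n_continuation_v1,
                             1 - 1 / config.n_continuation_v1))
        n_v1 = config.n_continuation_v1
        n_do = int(rng.binomial(n_v1, p_do))
        n_pp = int(rng.binomial(n_v1 - n_do, 0.8))
        rows.append({"sentence_id": record.sentence_id, "gate": "afterV1",
                     "n_responses": n_v1, "n_direct_object": n_do,
                     "n_prepositional_phrase": n_pp, "n_main_verb": 0})
        p_mv = float(np.clip(_sigmoid(0.8 * log_t + rng.normal(0, 0.4)),
                             0.02, 0.98))
        n_pp_gate = config.n_continuation_pp
        n_mv = int(rng.binomial(n_pp_gate, p_mv))
        rows.append({"sentence_id": record.sentence_id, "gate": "afterPP",
                     "n_responses": n_pp_gate, "n_direct_object": 0,
                     "n_prepositional_phrase": 0, "n_main_verb": n_mv})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mesh and source epochs
# ---------------------------------------------------------------------------

def generate_mesh(n_vertices: int, seed: int = 0,
                  extent_mm: float = 35.0) -> Mesh:
    """A random vertex cloud standing in for a cortical mesh, with
    hemisphere-by-lobe region labels derived from coordinates."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-extent_mm, extent_mm, size=(n_vertices, 3))
    hemi = np.where(coords[:, 0] < 0, "LH", "RH")
    lobe = np.where(coords[:, 1] < 0, "posterior", "anterior")
    labels = np.array([f"{h}_{l}" for h, l in zip(hemi, lobe)])
    return Mesh(vertex_ids=np.arange(n_vertices), coordinates=coords,
                region_labels=labels)


def _mds_embedding(rdm: RDM, rank: int = 10) -> np.ndarray:
    """Classical MDS configuration of an RDM (top positive dimensions)."""
    D = rdm.matrix
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(rank, int(np.sum(vals > 1e-10 * max(vals.max(), 1e-30))))
    if keep == 0:
        raise ValueError("RDM has no positive MDS dimensions")
    S = vecs[:, :keep] * np.sqrt(vals[:keep])
    return S


def generate_epochs(
    config: SyntheticConfig,
    mesh: Mesh,
    sentence_ids: Sequence[str],
    effects: Sequence[EffectSpec] = (),
    seed: int | None = None,
    epoch_label: str = "MV",
) -> SourceEpochs:
    """Noise epochs plus planted representational effects.

    Noise is Gaussian with an exponential spatial covariance
    (length scale ``config.spatial_length_scale_mm``) and white in time,
    drawn independently per participant.  Each effect adds, inside its
    vertex set and time window, a signal whose across-sentence pattern
    geometry realises the target RDM: the RDM's classical-MDS embedding
    (rank <= 10) is mapped onto random orthonormal spatiotemporal
    patterns and scaled by ``effect_size`` times the noise sd.
    """
    rng = np.random.default_rng(
        config.master_seed + 4 if seed is None else seed)
    n_sent = len(sentence_ids)
    V = mesh.n_vertices
    T = config.n_samples
    # overlapping effects with contradictory geometry are rejected
    for i, e1 in enumerate(effects):
        for e2 in effects[i + 1:]:
            t_olap = not (e1.window[1] <= e2.window[0]
                          or e2.window[1] <= e1.window[0])
            v_olap = np.intersect1d(e1.vertex_indices, e2.vertex_indices).size
            if t_olap and v_olap and not np.allclose(e1.rdm.matrix,
                                                     e2.rdm.matrix):
                raise ValueError("overlapping effects with contradictory RDMs")
    dist = np.linalg.norm(
        mesh.coordinates[:, None, :] - mesh.coordinates[None, :, :], axis=-1)
    cov = np.exp(-dist / config.spatial_length_scale_mm)
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(V))
    signal = np.zeros((n_sent, V, T))
    for effect in effects:
        if effect.rdm.n != n_sent:
            raise ValueError("effect RDM size differs from sentence count")
        if effect.effect_size == 0:
            continue
        S = _mds_embedding(effect.rdm)
        S = S - S.mean(axis=0)
        S /= max(np.sqrt(np.mean(S ** 2)), 1e-12)
        verts = effect.vertex_indices
        lo, hi = effect.window
        p = len(verts) * (hi - lo)
        M = rng.normal(size=(S.shape[1], p))
        # orthonormal rows: independent spatial patterns per MDS dimension
        M = np.linalg.qr(M.T)[0].T * np.sqrt(p)
        pat = (S @ M).reshape(n_sent, len(verts), hi - lo)
        signal[:, verts[:, None], np.arange(lo, hi)[None, :]] += (
            effect.effect_size * config.noise_sd * pat)
    data = np.empty((config.n_participants, n_sent, V, T))
    for pnum in range(config.n_participants):
        noise = L @ rng.normal(size=(n_sent, V, T)) * config.noise_sd
        data[pnum] = noise + signal
    return SourceEpochs(data=data, sampling_rate=config.sampling_rate,
                        epoch_label=epoch_label,
                        sentence_ids=tuple(sentence_ids))
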