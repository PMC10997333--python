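"""End-to-end orchestration: generate -> probe -> measures -> geometry ->
ssRSA -> clusters -> NMF/GCA, from one declarative YAML config.

Each stage writes its artifacts into the run directory and records a
checksum in ``manifest.json``; a rerun with an unchanged config reuses
stages whose outputs are already present and whose config hash matches.
All randomness derives from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import constraints, gca, geometry, probe, rsa, synth, trees

log = logging.getLogger("sentstruct.pipeline")

STAGES = ("generate", "probe", "measures", "geometry", "rsa", "cluster", "gca")


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML-serialisable)."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_jobs: int = 1
    # synthetic generation (defaults are the study conditions; the demo
    # config shipped with the package scales them down)
    synthetic: dict = field(default_factory=dict)
    epochs_path: str | None = None       # real epochs instead of synthetic
    use_synthetic: bool = True
    # probing
    probe_n_restarts: int = 10
    probe_max_iter: int = 2000
    probe_rank: int | None = None
    # searchlight
    spatial_radius_mm: float = 10.0
    temporal_radius_ms: float = 30.0
    time_stride: int = 1
    normalize_patterns: bool = False
    # statistics
    n_perm_cluster: int = 5000
    vertex_p: float = 0.01
    cluster_p: float = 0.05
    n_perm_spearman: int = 10000
    # planted effect (synthetic epochs)
    effect_size: float = 1.0
    effect_n_vertices: int = 10
    effect_window_ms: tuple[float, float] = (200.0, 400.0)
    # GCA
    nmf_k_max: int = 6
    nmf_restarts: int = 5
    gc_max_order: int = 5
    gc_surrogates: int = 200

    def synthetic_config(self) -> synth.SyntheticConfig:
        return synth.SyntheticConfig(master_seed=self.seed, **self.synthetic)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"unparseable config {path}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        cfg.effect_window_ms = tuple(cfg.effect_window_ms)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Static violations (bad radii, impossible permutation counts,
    missing inputs) without running anything."""
    violations: list[str] = []
    if config.spatial_radius_mm <= 0:
        violations.append("spatial_radius_mm must be positive")
    if config.temporal_radius_ms <= 0:
        violations.append("temporal_radius_ms must be positive")
    if config.time_stride < 1:
        violations.append("time_stride must be >= 1")
    if config.n_perm_cluster < 1:
        violations.append("n_perm_cluster must be >= 1")
    if not (0 < config.vertex_p < 1) or not (0 < config.cluster_p < 1):
        violations.append("vertex_p and cluster_p must be in (0, 1)")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        violations.append(f"unknown stages: {sorted(unknown)}")
    if not config.use_synthetic and not config.epochs_path:
        violations.append("synthetic generation disabled but no epochs_path given")
    if config.epochs_path and not Path(config.epochs_path).exists():
        violations.append(f"epochs_path does not exist: {config.epochs_path}")
    try:
        scfg = config.synthetic_config()
        if config.effect_n_vertices > scfg.n_vertices:
            violations.append("effect_n_vertices exceeds mesh size")
        lo, hi = config.effect_window_ms
        if not (0 <= lo < hi <= scfg.epoch_ms):
            violations.append("effect window outside the epoch")
    except TypeError as exc:
        violations.append(f"bad synthetic config: {exc}")
    if config.epochs_path and Path(config.epochs_path).exists():
        try:
            ep = rsa.SourceEpochs.load(config.epochs_path)
            rdm_path = Path(config.out_dir) / "geometry" / "rdm_depth_vector.tsv"
            if rdm_path.exists():
                model = geometry.RDM.load(rdm_path)
                if model.condition_ids and tuple(model.condition_ids) != tuple(
                        ep.sentence_ids):
                    violations.append(
                        "model RDM condition order differs from epoch sentence order")
        except Exception as exc:  # malformed container
            violations.append(f"cannot read epochs: {exc}")
    return violations


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class PipelineRun:
    """Stateful single-run driver; stage methods read predecessors'
    artifacts from the run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else
                         {"config_hash": config.config_hash(), "stages": {}})
        if self.manifest.get("config_hash") != config.config_hash():
            self.manifest = {"config_hash": config.config_hash(), "stages": {}}

    # -- helpers ----------------------------------------------------------
    def _dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def _done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry:
            return False
        return all(Path(p).exists() and _checksum(Path(p)) == c
                   for p, c in entry["outputs"].items())

    def _record(self, stage: str, outputs: Sequence[Path],
                elapsed: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {str(p): _checksum(p) for p in outputs},
            "elapsed_s": round(elapsed, 3),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    # -- stages -----------------------------------------------------------
    def run(self, stages: Sequence[str] | None = None) -> Path:
        violations = validate_config(self.config)
        if violations:
            raise ValueError("invalid config: " + "; ".join(violations))
        for stage in (stages or self.config.stages):
            if self._done(stage):
                log.info("stage %s: cached, skipping", stage)
                continue
            t0 = time.monotonic()
            log.info("stage %s: running", stage)
            try:
                outputs = getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            self._record(stage, outputs, time.monotonic() - t0)
            log.info("stage %s: done (%.1f s)", stage,
                     time.monotonic() - t0)
        return self.out

    def stage_generate(self) -> list[Path]:
        cfg = self.config
        scfg = cfg.synthetic_config()
        d = self._dir("generate")
        records = synth.generate_stimuli(scfg, seed=cfg.seed)
        targets = synth.target_records(records)
        all_trees = [t for r in records for t in r.trees.values()]
        trees.write_conllu(all_trees, d / "stimuli.conllu")
        meta = pd.DataFrame([
            {"sentence_id": r.sentence_id, "set_id": r.set_id,
             "condition": r.condition, "is_target": r.is_target,
             "n_tokens": len(r.tokens),
             **{f"pos_{k}": v for k, v in r.positions.items()}}
            for r in records])
        meta.to_csv(d / "stimuli.tsv", sep="\t", index=False)
        B0 = synth.planted_probe_matrix(scfg, seed=cfg.seed + 1)
        np.savetxt(d / "planted_probe.tsv", B0, delimiter="\t")
        es = synth.generate_embeddings(
            records, B0, noise_sd=scfg.embedding_noise_sd, seed=cfg.seed + 2)
        probe.save_embedding_set(es, d / "embeddings.h5")
        counts = synth.generate_corpus_counts(scfg, records, seed=cfg.seed + 3)
        counts.to_csv(d / "corpus_counts.tsv", sep="\t")
        cont = synth.generate_continuations(scfg, records, seed=cfg.seed + 4)
        cont.to_csv(d / "continuations.tsv", sep="\t", index=False)
        mesh = synth.generate_mesh(scfg.n_vertices, seed=cfg.seed + 5,
                                   extent_mm=scfg.mesh_extent_mm)
        mesh.save(d / "mesh.tsv")
        # planted effect: geometry of the scheduled full-prefix depth vectors
        sched = np.stack([synth.depth_schedule(r, len(r.tokens))
                          for r in targets])
        target_ids = [r.sentence_id for r in targets]
        planted = geometry.model_rdm(sched, "cosine_distance",
                                     label="planted_depth_vector",
                                     condition_ids=target_ids)
        planted.save(d / "rdm_planted.tsv")
        rng = np.random.default_rng(cfg.seed + 6)
        verts = rng.choice(scfg.n_vertices, size=cfg.effect_n_vertices,
                           replace=False)
        dt_ms = 1000.0 / scfg.sampling_rate
        window = (int(cfg.effect_window_ms[0] / dt_ms),
                  int(cfg.effect_window_ms[1] / dt_ms))
        effect = synth.EffectSpec(vertex_indices=verts, window=window,
                                  rdm=planted, effect_size=cfg.effect_size)
        epochs = synth.generate_epochs(scfg, mesh, target_ids, [effect],
                                       seed=cfg.seed + 7)
        epochs.save(d / "epochs.h5")
        json.dump({"effect_vertices": verts.tolist(),
                   "effect_window_samples": list(window)},
                  (d / "effect.json").open("w"), indent=1)
        scfg.to_manifest(d / "synthetic_config.json")
        return [d / "stimuli.conllu", d / "stimuli.tsv", d / "embeddings.h5",
                d / "corpus_counts.tsv", d / "continuations.tsv",
                d / "mesh.tsv", d / "rdm_planted.tsv", d / "epochs.h5",
                d / "effect.json", d / "synthetic_config.json",
                d / "planted_probe.tsv"]

    def stage_probe(self) -> list[Path]:
        cfg = self.config
        scfg = cfg.synthetic_config()
        d = self._dir("probe")
        gdir = self.out / "generate"
        es = probe.load_embedding_set(gdir / "embeddings.h5")
        records = synth.generate_stimuli(scfg, seed=cfg.seed)
        gold = synth.gold_depths(records)
        # train on whole-sentence prefixes; evaluate incrementally
        full_keys = {}
        for sid, plen in es.keys():
            full_keys[sid] = max(full_keys.get(sid, 0), plen)
        train = probe.EmbeddingSet(layer_tag=es.layer_tag)
        for sid, plen in full_keys.items():
            train.add(sid, plen, es.get(sid, plen))
        model = probe.train_probe(
            train, gold, k=cfg.probe_rank or scfg.probe_rank,
            n_restarts=cfg.probe_n_restarts, seed=cfg.seed + 10,
            max_iter=cfg.probe_max_iter)
        probe.save_probe(model, d / "probe.npz")
        mv = synth.main_verb_positions(records)
        acc = probe.root_accuracy(model, es, mv)
        rows = []
        for r in synth.target_records(records):
            for plen in range(1, len(r.tokens) + 1):
                depths = probe.predict_depths_averaged(
                    model, es.get(r.sentence_id, plen))
                for pos, dep in enumerate(depths, 1):
                    rows.append({"sentence_id": r.sentence_id,
                                 "prefix_len": plen, "position": pos,
                                 "depth": dep})
        pd.DataFrame(rows).to_csv(d / "probe_depths.tsv", sep="\t",
                                  index=False)
        json.dump({"root_accuracy": acc,
                   "restart_losses": model.training_meta["restart_losses"]},
                  (d / "probe_report.json").open("w"), indent=1)
        return [d / "probe.npz", d / "probe.json", d / "probe_depths.tsv",
                d / "probe_report.json"]

    def stage_measures(self) -> list[Path]:
        cfg = self.config
        d = self._dir("measures")
        gdir = self.out / "generate"
        counts = pd.read_csv(gdir / "corpus_counts.tsv", sep="\t",
                             index_col="sentence_id")
        table = constraints.interpretation_indices(
            constraints.ratio_measures(counts))
        table.to_csv(d / "constraint_table.tsv", sep="\t")
        cont = constraints.continuation_probabilities(
            pd.read_csv(gdir / "continuations.tsv", sep="\t"))
        cont.to_csv(d / "continuation_table.tsv", sep="\t", index=False)
        # correlate constraint indices with the contextual DO probability
        at_v1 = cont[cont["gate"] == "afterV1"].set_index("sentence_id")
        joined = table.join(at_v1[["DO_prob"]], how="inner")
        report = constraints.correlation_report(
            joined[["agenthood", "patienthood", "transitivity",
                    "intransitivity", "passive_index", "active_index",
                    "nondirectional_index"]],
            joined["DO_prob"].to_numpy(),
            n_perm=cfg.n_perm_spearman, seed=cfg.seed + 20)
        report.to_csv(d / "correlation_report.tsv", sep="\t", index=False)
        return [d / "constraint_table.tsv", d / "continuation_table.tsv",
                d / "correlation_report.tsv"]

    def stage_geometry(self) -> list[Path]:
        cfg = self.config
        scfg = cfg.synthetic_config()
        d = self._dir("geometry")
        depths = pd.read_csv(self.out / "probe" / "probe_depths.tsv",
                             sep="\t")
        records = synth.generate_stimuli(scfg, seed=cfg.seed)
        targets = synth.target_records(records)
        target_ids = [r.sentence_id for r in targets]
        n_tok = len(targets[0].tokens)
        pos = targets[0].positions
        pivot = depths.set_index(["sentence_id", "prefix_len", "position"])[
            "depth"]
        # full-prefix depth vectors and V1 depth trajectory
        full_vecs = np.array([
            [pivot[(sid, n_tok, p)] for p in range(1, n_tok + 1)]
            for sid in target_ids])
        v1_series = {
            sid: {plen: pivot[(sid, plen, pos["V1"])]
                  for plen in range(pos["V1"], n_tok + 1)}
            for sid in target_ids}
        rows = []
        for r in targets:
            sid = r.sentence_id
            lm_pas = trees.landmark_vector(r.trees["passive"], 3).as_array()
            lm_act = trees.landmark_vector(r.trees["active"], 3).as_array()
            vecs3 = np.array([
                [pivot[(sid, plen, p)] for p in (1, 2, 3)]
                for plen in range(3, n_tok + 1)])
            traj = geometry.landmark_trajectory(vecs3, lm_pas, lm_act,
                                                sentence_id=sid)
            mism_pas = geometry.interpretative_mismatch(vecs3[-1], lm_pas)
            mism_act = geometry.interpretative_mismatch(vecs3[-1], lm_act)
            dchange = geometry.v1_depth_change(
                v1_series[sid][pos["MV"]], v1_series[sid][pos["V1"]])
            rows.append({
                "sentence_id": sid, "condition": r.condition,
                "dist_passive_final": traj.distance_to_passive[-1],
                "dist_active_final": traj.distance_to_active[-1],
                "mismatch_passive": mism_pas, "mismatch_active": mism_act,
                "v1_depth_change": dchange,
                "v1_depth_final": v1_series[sid][n_tok],
            })
        gtable = pd.DataFrame(rows)
        gtable.to_csv(d / "geometry_table.tsv", sep="\t", index=False)
        scores, evr = geometry.pca_scores(full_vecs, n_components=2)
        pd.DataFrame({"sentence_id": target_ids, "PC1": scores[:, 0],
                      "PC2": scores[:, 1] if scores.shape[1] > 1 else np.nan}
                     ).to_csv(d / "pca_scores.tsv", sep="\t", index=False)
        rdm_vec = geometry.model_rdm(full_vecs, "cosine_distance",
                                     label="depth_vector",
                                     condition_ids=target_ids)
        rdm_vec.save(d / "rdm_depth_vector.tsv")
        rdm_v1 = geometry.model_rdm(
            gtable["v1_depth_final"].to_numpy(), "absolute_difference",
            label="v1_depth", condition_ids=target_ids)
        rdm_v1.save(d / "rdm_v1_depth.tsv")
        ctable = pd.read_csv(self.out / "measures" / "constraint_table.tsv",
                             sep="\t", index_col="sentence_id")
        rdm_pass = geometry.model_rdm(
            ctable.loc[target_ids, "passive_index"].to_numpy(),
            "absolute_difference", label="passive_index",
            condition_ids=target_ids)
        rdm_pass.save(d / "rdm_passive_index.tsv")
        return [d / "geometry_table.tsv", d / "pca_scores.tsv",
                d / "rdm_depth_vector.tsv", d / "rdm_v1_depth.tsv",
                d / "rdm_passive_index.tsv"]

    def _load_epochs(self) -> rsa.SourceEpochs:
        if self.config.epochs_path:
            return rsa.SourceEpochs.load(self.config.epochs_path)
        return rsa.SourceEpochs.load(self.out / "generate" / "epochs.h5")

    def stage_rsa(self) -> list[Path]:
        cfg = self.config
        d = self._dir("rsa")
        epochs = self._load_epochs()
        mesh = rsa.Mesh.load(self.out / "generate" / "mesh.tsv")
        spec = rsa.SearchlightSpec(cfg.spatial_radius_mm,
                                   cfg.temporal_radius_ms, cfg.time_stride)
        outputs = []
        for name in ("rdm_depth_vector", "rdm_passive_index"):
            model = geometry.RDM.load(self.out / "geometry" / f"{name}.tsv")
            fitmap = run_ssrsa_parallel(epochs, model, mesh, spec,
                                        normalize=cfg.normalize_patterns,
                                        n_jobs=cfg.n_jobs)
            path = d / f"fitmap_{name}.h5"
            fitmap.save(path)
            outputs.append(path)
        return outputs

    def stage_cluster(self) -> list[Path]:
        cfg = self.config
        d = self._dir("cluster")
        mesh = rsa.Mesh.load(self.out / "generate" / "mesh.tsv")
        outputs = []
        for name in ("rdm_depth_vector", "rdm_passive_index"):
            fitmap = rsa.FitMap.load(self.out / "rsa" / f"fitmap_{name}.h5")
            result = rsa.group_cluster_test(
                fitmap, mesh, n_perm=cfg.n_perm_cluster,
                vertex_p=cfg.vertex_p, cluster_p=cfg.cluster_p,
                seed=cfg.seed + 30,
                cluster_radius_mm=cfg.spatial_radius_mm)
            path = d / f"clusters_{name}.json"
            result.save(path)
            summaries = rsa.summary_maps(
                result, region_labels=mesh.region_labels)
            np.savetxt(d / f"vertex_t_mass_{name}.tsv",
                       summaries["vertex_t_mass"], delimiter="\t")
            fig_path = d / f"cluster_summary_{name}.png"
            _cluster_figure(result, summaries, fig_path)
            outputs += [path, d / f"vertex_t_mass_{name}.tsv", fig_path]
        return outputs

    def stage_gca(self) -> list[Path]:
        cfg = self.config
        d = self._dir("gca")
        factor_sets = []
        for name in ("rdm_depth_vector", "rdm_passive_index"):
            fitmap = rsa.FitMap.load(self.out / "rsa" / f"fitmap_{name}.h5")
            maps = [fitmap.rho[p] for p in range(fitmap.rho.shape[0])]
            fs = gca.nmf_decompose(
                maps, k_range=range(2, cfg.nmf_k_max + 1),
                n_restarts=cfg.nmf_restarts, seed=cfg.seed + 40,
                label=name)
            factor_sets.append(fs)
            json.dump({"k": fs.k, "rms": fs.rms,
                       "rms_by_k": {str(k): v for k, v in fs.rms_by_k.items()}},
                      (d / f"nmf_{name}.json").open("w"), indent=1)
            np.savetxt(d / f"nmf_bases_{name}.tsv", fs.bases, delimiter="\t")
        A, B = factor_sets[0].time_series, factor_sets[1].time_series
        results = gca.gc_pairwise(A, B, max_order=cfg.gc_max_order)
        results = gca.gc_significance(A, B, results,
                                      n_surrogates=cfg.gc_surrogates,
                                      seed=cfg.seed + 41)
        gca.gc_report(results).to_csv(d / "gc_connections.tsv", sep="\t",
                                      index=False)
        return [d / "gc_connections.tsv",
                d / "nmf_rdm_depth_vector.json",
                d / "nmf_rdm_passive_index.json"]


def _cluster_figure(result, summaries, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3))
    axes[0].bar(np.arange(len(summaries["vertex_t_mass"])),
                summaries["vertex_t_mass"], color="tab:blue")
    axes[0].set_xlabel("vertex")
    axes[0].set_ylabel("t-mass")
    axes[0].set_title("vertex t-mass (significant samples)")
    for cl in summaries["cluster_t_mass_series"]:
        axes[1].plot(cl["t_mass_series"], label=f"p={cl['p']:.3f}")
    axes[1].set_xlabel("window center")
    axes[1].set_ylabel("cluster t-mass")
    axes[1].set_title("significant cluster t-mass over time")
    if summaries["cluster_t_mass_series"]:
        axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_ssrsa_parallel(epochs, model, mesh, spec, *, normalize=False,
                       n_jobs=1) -> rsa.FitMap:
    """run_ssrsa split over participants with joblib when n_jobs > 1."""
    if n_jobs == 1 or epochs.n_participants == 1:
        return rsa.run_ssrsa(epochs, model, mesh, spec, normalize=normalize)
    parts = Parallel(n_jobs=n_jobs)(
        delayed(rsa.run_ssrsa)(
            rsa.SourceEpochs(epochs.data[p:p + 1], epochs.sampling_rate,
                             epochs.epoch_label, epochs.sentence_ids),
            model, mesh, spec, normalize=normalize)
        for p in range(epochs.n_participants))
    return rsa.FitMap(rho=np.concatenate([f.rho for f in parts]),
                      window_centers=parts[0].window_centers,
                      model_label=model.label,
                      sampling_rate=epochs.sampling_rate)


def run_pipeline(config: RunConfig,
                 stages: Sequence[str] | None = None) -> Path:
    """Run the configured stages; returns the run directory."""
    return PipelineRun(config).run(stages)
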