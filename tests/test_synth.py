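"""The synthetic-data generators: stimulus design, planted embeddings,
condition-biased count tables, and source epochs with planted geometry."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, ttest_ind

from sentstruct import constraints, synth, trees
from sentstruct.geometry import model_rdm
from sentstruct.probe import predict_depths, ProbeModel
from sentstruct.rsa import data_rdm


def _hash(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


class TestStimuli:
    def test_paper_scale_counts(self):
        cfg = synth.SyntheticConfig()
        recs = synth.generate_stimuli(cfg)
        assert len(recs) == 360
        assert sum(r.is_target for r in recs) == 120

    def test_unit_scale(self):
        cfg = synth.SyntheticConfig(n_sets=1)
        recs = synth.generate_stimuli(cfg)
        assert len(recs) == 6
        targets = [r for r in recs if r.is_target]
        assert len(targets) == 2
        for r in targets:
            assert set(r.trees) == {"passive", "active"}
            assert r.trees["passive"].tokens == r.trees["active"].tokens

    def test_target_parses_have_canonical_landmarks(self, small_records):
        for r in synth.target_records(small_records):
            pas = trees.landmark_vector(r.trees["passive"], 3).depths
            act = trees.landmark_vector(r.trees["active"], 3).depths
            assert pas == (2.0, 1.0, 2.0)
            assert act == (2.0, 1.0, 0.0)

    def test_determinism(self, small_config):
        a = synth.generate_stimuli(small_config, seed=4)
        b = synth.generate_stimuli(small_config, seed=4)
        assert [r.tokens for r in a] == [r.tokens for r in b]
        assert [r.log_transitivity for r in a] == [r.log_transitivity for r in b]
        assert [r.depth_jitter for r in a] == [r.depth_jitter for r in b]


class TestEmbeddings:
    def test_noiseless_construction_oracle(self, planted_embeddings,
                                           small_records):
        B0, es, gold = planted_embeddings
        model = ProbeModel(transform=B0)
        for key in list(es.keys())[:20]:
            pred = predict_depths(model, es.get(*key))
            assert np.max(np.abs(pred - gold[key])) < 1e-6

    def test_lotrans_v1_depth_change_positive(self, small_records):
        pos = synth.POSITIONS
        for r in synth.target_records(small_records):
            if r.condition != "LoTrans":
                continue
            initial = synth.depth_schedule(r, pos["V1"])[pos["V1"] - 1]
            updated = synth.depth_schedule(r, pos["MV"])[pos["V1"] - 1]
            assert updated - initial > 0

    def test_noise_degrades_eval_correlation_monotonically(
            self, small_config, small_records):
        B0 = synth.planted_probe_matrix(small_config, seed=0)
        model = ProbeModel(transform=B0)
        gold = synth.gold_depths(small_records, prefixes="full")
        corrs = []
        for noise in (0.0, 0.3, 1.5):
            es = synth.generate_embeddings(small_records, B0,
                                           noise_sd=noise, seed=9,
                                           prefixes="full")
            preds, golds = [], []
            for key in es.keys():
                preds.extend(predict_depths(model, es.get(*key)))
                golds.extend(gold[key])
            corrs.append(spearmanr(preds, golds).statistic)
        assert corrs[0] > corrs[1] > corrs[2]

    def test_determinism(self, small_config, small_records):
        B0 = synth.planted_probe_matrix(small_config, seed=0)
        a = synth.generate_embeddings(small_records, B0, seed=5,
                                      prefixes="full")
        b = synth.generate_embeddings(small_records, B0, seed=5,
                                      prefixes="full")
        key = next(iter(a.keys()))
        assert _hash(a.get(*key)) == _hash(b.get(*key))


class TestCountTables:
    def test_calibrated_do_probability_means(self):
        # generator targets: mean DO probability 0.71 (HiTrans) / 0.44
        # (LoTrans); check within sampling error at 60 sets
        cfg = synth.SyntheticConfig(master_seed=21)
        recs = synth.generate_stimuli(cfg)
        counts = synth.generate_corpus_counts(cfg, recs)
        table = constraints.ratio_measures(counts)
        do_p = table["transitivity"] / (1 + table["transitivity"])
        means = do_p.groupby(table["condition"]).mean()
        assert means["HiTrans"] == pytest.approx(0.71, abs=0.07)
        assert means["LoTrans"] == pytest.approx(0.44, abs=0.08)

    def test_zero_gap_conditions_indistinguishable(self):
        rejections = 0
        n_reps, alpha = 40, 0.1
        for rep in range(n_reps):
            cfg = synth.SyntheticConfig(
                n_sets=20, master_seed=1000 + rep,
                log_transitivity_mean={"HiTrans": 0.3, "LoTrans": 0.3})
            recs = synth.generate_stimuli(cfg)
            counts = synth.generate_corpus_counts(cfg, recs)
            logt = np.log(constraints.ratio_measures(counts)["transitivity"])
            cond = counts["condition"]
            p = ttest_ind(logt[cond == "HiTrans"],
                          logt[cond == "LoTrans"]).pvalue
            rejections += p < alpha
        # binomial 95% CI around 0.1 with 40 repeats: [1, 9]
        assert rejections <= 9

    def test_counts_positive_and_consistent(self, small_config,
                                            small_records):
        counts = synth.generate_corpus_counts(small_config, small_records)
        assert (counts[["agent_count", "patient_count", "do_count",
                        "other_scf_count"]] >= 1).all().all()
        cont = synth.generate_continuations(small_config, small_records)
        derived = constraints.continuation_probabilities(cont)
        assert derived["DO_prob"].between(0, 1).all()

    def test_do_prob_correlates_with_transitivity(self):
        cfg = synth.SyntheticConfig(master_seed=31)
        recs = synth.generate_stimuli(cfg)
        counts = synth.generate_corpus_counts(cfg, recs)
        cont = synth.generate_continuations(cfg, recs)
        v1 = cont[cont["gate"] == "afterV1"].set_index("sentence_id")
        do_prob = (v1["n_direct_object"] / v1["n_responses"]).loc[counts.index]
        logt = np.log(constraints.ratio_measures(counts)["transitivity"])
        rho = spearmanr(do_prob, logt).statistic
        assert rho > 0.5

    def test_determinism(self, small_config, small_records):
        a = synth.generate_corpus_counts(small_config, small_records, seed=2)
        b = synth.generate_corpus_counts(small_config, small_records, seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestMeshAndEpochs:
    def test_epoch_dimensions(self, small_config):
        # 600 ms at 200 Hz = 120 samples
        assert small_config.n_samples == 120
        mesh = synth.generate_mesh(10, seed=0)
        ep = synth.generate_epochs(small_config, mesh, ["a", "b", "c"],
                                   seed=1)
        assert ep.data.shape == (small_config.n_participants, 3, 10, 120)

    def test_mesh_labels_and_ids(self):
        mesh = synth.generate_mesh(25, seed=3)
        assert len(np.unique(mesh.vertex_ids)) == 25
        assert set(np.unique(mesh.region_labels)) <= {
            "LH_anterior", "LH_posterior", "RH_anterior", "RH_posterior"}

    def test_zero_effect_size_is_pure_noise(self, rng):
        cfg = synth.SyntheticConfig(n_participants=2, n_vertices=8,
                                    master_seed=1)
        mesh = synth.generate_mesh(8, seed=1)
        rdm = model_rdm(rng.normal(size=10), "absolute_difference")
        eff = synth.EffectSpec(np.arange(4), (10, 40), rdm, effect_size=0.0)
        a = synth.generate_epochs(cfg, mesh, [f"s{i}" for i in range(10)],
                                  [eff], seed=2)
        b = synth.generate_epochs(cfg, mesh, [f"s{i}" for i in range(10)],
                                  [], seed=2)
        assert np.allclose(a.data, b.data)

    def test_planted_geometry_recovered_in_data_rdm(self, rng):
        cfg = synth.SyntheticConfig(n_participants=1, n_vertices=12,
                                    master_seed=5)
        mesh = synth.generate_mesh(12, seed=5)
        target = model_rdm(rng.normal(size=(40, 4)), "cosine_distance")
        verts = np.arange(6)
        eff = synth.EffectSpec(verts, (20, 60), target, effect_size=2.0)
        ep = synth.generate_epochs(cfg, mesh, [f"s{i}" for i in range(40)],
                                   [eff], seed=6)
        patterns = ep.data[0][:, verts, 20:60].reshape(40, -1)
        empirical = data_rdm(patterns)
        rho = spearmanr(empirical.condensed(), target.condensed()).statistic
        assert rho > 0.5

    def test_contradictory_overlapping_effects_rejected(self, rng):
        cfg = synth.SyntheticConfig(n_participants=1, n_vertices=6)
        mesh = synth.generate_mesh(6, seed=0)
        r1 = model_rdm(rng.normal(size=5), "absolute_difference")
        r2 = model_rdm(rng.normal(size=5), "absolute_difference")
        effs = [synth.EffectSpec(np.arange(3), (0, 50), r1),
                synth.EffectSpec(np.arange(2, 5), (30, 80), r2)]
        with pytest.raises(ValueError, match="contradictory"):
            synth.generate_epochs(cfg, mesh, [f"s{i}" for i in range(5)],
                                  effs)

    def test_negative_effect_size_rejected(self, rng):
        rdm = model_rdm(rng.normal(size=4), "absolute_difference")
        with pytest.raises(ValueError):
            synth.EffectSpec(np.arange(2), (0, 10), rdm, effect_size=-1.0)

    def test_determinism(self):
        cfg = synth.SyntheticConfig(n_participants=2, n_vertices=6,
                                    master_seed=9)
        mesh = synth.generate_mesh(6, seed=9)
        a = synth.generate_epochs(cfg, mesh, ["x", "y", "z"], seed=3)
        b = synth.generate_epochs(cfg, mesh, ["x", "y", "z"], seed=3)
        assert _hash(a.data) == _hash(b.data)
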