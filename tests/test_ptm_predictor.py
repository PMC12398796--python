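"""Predictor model, PR-AUC evaluation, and PR-AUC-weighted ensembling."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from ptm_crosstalk.ptm_predictor import (EnsembleSpec, PredictorConfig,
                                         PredictorModel, compute_pr_auc,
                                         ensemble_predict, pretrain)
from ptm_crosstalk.schema import DEFAULT_SCHEMA
from ptm_crosstalk.sequence_io import ProteinRecord
from ptm_crosstalk.synthetic_data import (MotifRule, SyntheticCorpus,
                                          gen_corpus, gen_labels,
                                          gen_sequences)


class TestPredict:
    def test_one_row_per_residue_and_unit_interval(self, tiny_model, short_record):
        pm = tiny_model.predict(short_record)
        assert pm.values.shape == (len(short_record), 13)
        assert pm.values.min() >= 0.0 and pm.values.max() <= 1.0

    def test_eval_determinism(self, tiny_model, short_record):
        a = tiny_model.predict(short_record).values
        b = tiny_model.predict(short_record).values
        assert np.array_equal(a, b)

    def test_eligibility_masking_zeroes_incompatible_residues(self, tiny_model,
                                                              short_record):
        pm = tiny_model.predict(short_record, mask_eligibility=True)
        j = DEFAULT_SCHEMA.index("acetyl_K")
        for pos0, aa in enumerate(short_record.sequence):
            if aa != "K":
                assert pm.values[pos0, j] == 0.0
        raw = tiny_model.predict(short_record, mask_eligibility=False)
        k_rows = [i for i, aa in enumerate(short_record.sequence) if aa == "K"]
        assert (raw.values[k_rows, j] > 0).all()

    def test_padding_invariance_across_batch_layouts(self, tiny_model):
        # the same sequence must score identically alone and batched with a
        # longer partner (pads are masked out of attention)
        rng = np.random.default_rng(0)
        s1 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        s2 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        from ptm_crosstalk import encoder_prep as enc
        w1 = enc.tokenize(ProteinRecord(id="a", sequence=s1))[0]
        w2 = enc.tokenize(ProteinRecord(id="b", sequence=s2))[0]
        alone = tiny_model._forward_windows([w1]).data[0]
        batched = tiny_model._forward_windows([w1, w2]).data[0]
        assert np.allclose(alone[:42], batched[:42], atol=1e-5)

    def test_long_protein_predictions_cover_all_residues(self, tiny_model,
                                                         hsp90_pair):
        alpha, _ = hsp90_pair
        pm = tiny_model.predict(alpha)
        assert pm.values.shape == (732, 13)


class TestPretrain:
    def test_seed_determinism(self, tiny_config):
        corpus = gen_corpus(6, (30, 50), seed=4)
        m1 = pretrain(corpus, tiny_config, seed=9)
        m2 = pretrain(corpus, tiny_config, seed=9)
        for k, v in m1.net.state_dict().items():
            assert np.array_equal(v, m2.net.state_dict()[k]), k

    def test_different_seeds_differ(self, tiny_config):
        corpus = gen_corpus(6, (30, 50), seed=4)
        m1 = pretrain(corpus, tiny_config, seed=9)
        m2 = pretrain(corpus, tiny_config, seed=10)
        assert any(not np.array_equal(v, m2.net.state_dict()[k])
                   for k, v in m1.net.state_dict().items())

    def test_empty_corpus_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            pretrain(SyntheticCorpus(records=[]), tiny_config, seed=0)

    def test_motif_class_beats_prevalence_baseline(self):
        # strong motif (boost 0.9 / base 0.05): held-out PR-AUC must exceed
        # the class-prevalence baseline of a label-independent ranker
        rules = [MotifRule("phospho_S", frozenset("S"), context="RR?S",
                           base_rate=0.1, boosted_rate=0.9)]
        records = gen_sequences(32, (120, 160), seed=1)
        corpus = SyntheticCorpus(
            [(r, gen_labels(r, rules, seed=100 + i)) for i, r in
             enumerate(records)])
        train, val = corpus.split(8)
        config = PredictorConfig(d_model=32, n_layers=2, n_heads=2, d_ff=64,
                                 pretrain_epochs=150, pretrain_lr=3e-3,
                                 batch_size=4)
        model = pretrain(train, config, seed=2)
        aucs = compute_pr_auc(model, val)
        labels = np.concatenate([l for _r, l in val.records])
        j = DEFAULT_SCHEMA.index("phospho_S")
        prevalence = labels[:, j].mean()
        assert aucs["phospho_S"] is not None
        assert aucs["phospho_S"] > prevalence


class TestPrAuc:
    def _corpus_with_scores(self, labels):
        rec = ProteinRecord(id="r", sequence="S" * len(labels))
        lab = np.zeros((len(labels), 13), dtype=np.int8)
        lab[:, 0] = labels
        return SyntheticCorpus([(rec, lab)])

    def test_degenerate_class_flagged_absent(self, tiny_model, short_record):
        lab = np.zeros((len(short_record), 13), dtype=np.int8)
        corpus = SyntheticCorpus([(short_record, lab)])
        aucs = compute_pr_auc(tiny_model, corpus)
        assert all(v is None for v in aucs.values())

    def test_random_scores_near_prevalence(self):
        # permutation oracle: label-independent scores give AP ~ prevalence;
        # the empirical 3-SD band comes from resampled permutations
        rng = np.random.default_rng(12)
        n, prevalence = 600, 0.15
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        resampled = [average_precision_score(rng.permutation(labels), scores)
                     for _ in range(200)]
        ap = average_precision_score(labels, scores)
        assert abs(ap - np.mean(resampled)) < 3 * np.std(resampled)

    def test_perfect_separation_gives_one(self, tiny_config):
        # single positive ranked first among n -> average precision 1.0
        assert average_precision_score([0, 0, 1], [0.1, 0.2, 0.9]) == 1.0


class TestEnsemble:
    @pytest.fixture()
    def members(self, tiny_config):
        return [PredictorModel(tiny_config, seed=s, model_id=f"m{s}")
                for s in (0, 1, 2)]

    def test_single_member_identity(self, members, short_record):
        spec = EnsembleSpec(members=[members[0]], weights=np.ones((1, 13)))
        ens = ensemble_predict(spec, short_record)
        solo = members[0].predict(short_record)
        assert np.allclose(ens.values, solo.values)

    def test_equal_weights_reduce_to_arithmetic_mean(self, members, short_record):
        spec = EnsembleSpec(members=members, weights=np.ones((3, 13)))
        ens = ensemble_predict(spec, short_record)
        brute = np.mean([m.predict(short_record).values for m in members],
                        axis=0)
        assert np.allclose(ens.values, brute, atol=1e-12)

    def test_weighted_mean_matches_bruteforce_oracle(self, members, short_record):
        rng = np.random.default_rng(8)
        w = rng.random((3, 13))
        spec = EnsembleSpec(members=members, weights=w.copy())
        ens = ensemble_predict(spec, short_record)
        preds = [m.predict(short_record).values for m in members]
        wn = w / w.sum(axis=0)
        expected = np.zeros_like(preds[0])
        for pos in range(expected.shape[0]):       # explicit per-cell oracle
            for cls in range(13):
                expected[pos, cls] = sum(wn[m, cls] * preds[m][pos, cls]
                                         for m in range(3))
        assert np.allclose(ens.values, expected, atol=1e-10)

    def test_two_members_halfway(self, tiny_config, short_record):
        # weights 3:1 on probabilities p and q give 0.75 p + 0.25 q
        m1 = PredictorModel(tiny_config, seed=3)
        m2 = PredictorModel(tiny_config, seed=4)
        spec = EnsembleSpec(members=[m1, m2],
                            weights=np.array([[3.0] * 13, [1.0] * 13]))
        ens = ensemble_predict(spec, short_record)
        expected = 0.75 * m1.predict(short_record).values \
            + 0.25 * m2.predict(short_record).values
        assert np.allclose(ens.values, expected, atol=1e-12)

    def test_output_bounded_by_member_envelope(self, members, short_record):
        rng = np.random.default_rng(9)
        spec = EnsembleSpec(members=members, weights=rng.random((3, 13)))
        ens = ensemble_predict(spec, short_record)
        stack = np.stack([m.predict(short_record).values for m in members])
        assert (ens.values <= stack.max(axis=0) + 1e-12).all()
        assert (ens.values >= stack.min(axis=0) - 1e-12).all()

    def test_zero_total_weight_rejected(self, members):
        w = np.ones((3, 13))
        w[:, 4] = 0.0
        with pytest.raises(ValueError, match="zero total weight"):
            EnsembleSpec(members=members, weights=w)

    def test_pr_auc_weights_fall_back_to_equal_for_absent_classes(self, members):
        aucs = [{c: (0.5 if c == "phospho_S" else None)
                 for c in DEFAULT_SCHEMA.classes} for _ in members]
        spec = EnsembleSpec.from_pr_auc(members, aucs)
        j = DEFAULT_SCHEMA.index("acetyl_K")
        assert np.allclose(spec.weights[:, j], 1 / 3)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model, short_record, tmp_path):
        tiny_model.save(tmp_path / "ckpt")
        back = PredictorModel.load(tmp_path / "ckpt")
        assert np.array_equal(back.predict(short_record).values,
                              tiny_model.predict(short_record).values)
        assert back.model_id == tiny_model.model_id
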