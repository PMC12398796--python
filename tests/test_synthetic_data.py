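"""Generators: determinism, eligibility, planted-effect arithmetic."""

import math

import numpy as np
import pytest

from ptm_crosstalk.ms_quant import normalize_and_lfc
from ptm_crosstalk.schema import DEFAULT_SCHEMA
from ptm_crosstalk.sequence_io import ProteinRecord
from ptm_crosstalk.synthetic_data import (ALPHA_ID, BETA_ID, CrosstalkRule,
                                          EffectSpec, MotifRule,
                                          gen_binder_table, gen_corpus,
                                          gen_intensity_table, gen_labels,
                                          gen_sequences, hsp90_site_panel,
                                          synthesize_hsp90_standins)


class TestGenSequences:
    def test_zero_count_gives_empty_list(self):
        assert gen_sequences(0, (10, 20), seed=1) == []

    def test_seed_determinism(self):
        a = gen_sequences(5, (30, 60), seed=7)
        b = gen_sequences(5, (30, 60), seed=7)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        c = gen_sequences(5, (30, 60), seed=8)
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_letter_frequencies_within_binomial_bounds(self):
        # 200 sequences x 300 residues: each letter is Binomial(n, 1/20)
        records = gen_sequences(200, (300, 300), seed=3)
        joined = "".join(r.sequence for r in records)
        n = len(joined)
        p = 1 / 20
        sd = math.sqrt(n * p * (1 - p))
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert abs(joined.count(aa) - n * p) < 3 * sd, aa

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            gen_sequences(3, (10, 5), seed=0)
        with pytest.raises(ValueError):
            gen_sequences(-1, (5, 10), seed=0)

    def test_motif_insertion_fraction(self):
        records = gen_sequences(400, (50, 80), seed=4, insert_motif="GKG",
                                insert_fraction=0.5)
        n_with = sum("GKG" in r.sequence for r in records)
        # Binomial(400, ~0.5) plus rare spontaneous occurrences
        assert abs(n_with - 200) < 3 * math.sqrt(400 * 0.25) + 10


class TestGenLabels:
    def test_deterministic_context_rates(self):
        rule = MotifRule("phospho_S", frozenset("ST"), context="RR?S",
                         base_rate=0.0, boosted_rate=1.0)
        rec = ProteinRecord(id="r", sequence="AARRKSAA")
        labels = gen_labels(rec, [rule], seed=0)
        j = DEFAULT_SCHEMA.index("phospho_S")
        assert labels[5, j] == 1                      # position 6, 1-based
        assert labels[:, j].sum() == 1

    def test_eligibility_never_violated(self):
        rec = gen_sequences(1, (400, 400), seed=9)[0]
        rules = [MotifRule("acetyl_K", frozenset("K"), context=None,
                           base_rate=1.0, boosted_rate=1.0)]
        for seed in range(5):
            labels = gen_labels(rec, rules, seed=seed)
            j = DEFAULT_SCHEMA.index("acetyl_K")
            labeled = np.flatnonzero(labels[:, j])
            assert all(rec.sequence[i] == "K" for i in labeled)
            # every K labeled at rate 1
            assert len(labeled) == rec.sequence.count("K")

    def test_base_rate_count_within_binomial_bounds(self):
        # ~1000 eligible positions at rate 0.1 -> count within 3 SD of 100
        seq = "S" * 1000
        rec = ProteinRecord(id="r", sequence=seq)
        rule = MotifRule("phospho_S", frozenset("S"), context=None,
                         base_rate=0.1, boosted_rate=0.1)
        labels = gen_labels(rec, [rule], seed=21)
        count = labels[:, DEFAULT_SCHEMA.index("phospho_S")].sum()
        assert abs(count - 100) < 3 * math.sqrt(1000 * 0.1 * 0.9)

    def test_crosstalk_rule_conditions_on_trigger(self):
        rule = CrosstalkRule("phospho_S", frozenset("S"), trigger="GKG",
                             base_rate=0.0, boosted_rate=1.0)
        with_trigger = ProteinRecord(id="a", sequence="SSSAGKGASSS")
        without = ProteinRecord(id="b", sequence="SSSAAKAASSS")
        j = DEFAULT_SCHEMA.index("phospho_S")
        assert gen_labels(with_trigger, [rule], seed=0)[:, j].sum() == 6
        assert gen_labels(without, [rule], seed=0)[:, j].sum() == 0

    def test_unknown_class_rejected(self):
        rule = MotifRule("nosuch_ptm", frozenset("S"))
        with pytest.raises(ValueError):
            gen_labels(ProteinRecord(id="r", sequence="SSS"), [rule], seed=0)


class TestIntensityTable:
    def sites_effects(self, lfc=1.0):
        sites = [("P1", "10", "S", "phospho_S"), ("P1", "20", "S", "phospho_S")]
        effects = [EffectSpec("P1", "10", "phospho_S", lfc)]
        return sites, effects

    def test_noiseless_recovery_is_exact(self):
        sites, effects = self.sites_effects(lfc=1.0)
        table = gen_intensity_table(sites, effects, noise_sd=0.0,
                                    abundance_factors={"WT": 1.0, "KO": 1.0},
                                    seed=5)
        by_pos = {f.position: f for f in normalize_and_lfc(table, "KO")}
        assert by_pos["10"].x == pytest.approx(1.0, abs=1e-12)
        assert by_pos["20"].x == pytest.approx(0.0, abs=1e-12)

    def test_abundance_scaling_cancels(self):
        sites, _ = self.sites_effects()
        table = gen_intensity_table(sites, [], noise_sd=0.0,
                                    abundance_factors={"WT": 1.0, "KO": 2.0},
                                    seed=5)
        for fc in normalize_and_lfc(table, "KO"):
            assert fc.x == pytest.approx(0.0, abs=1e-12)

    def test_noisy_mean_recovery_within_gaussian_bounds(self):
        # 50 replicate sites, lfc +1, multiplicative noise sd 0.2 in both
        # conditions: recovered mean within 3 * sqrt(2) * (0.2/ln2) / sqrt(50)
        sites = [("P1", str(i), "S", "phospho_S") for i in range(1, 51)]
        effects = [EffectSpec("P1", str(i), "phospho_S", 1.0)
                   for i in range(1, 51)]
        table = gen_intensity_table(sites, effects, noise_sd=0.2,
                                    abundance_factors={"WT": 1.0, "KO": 1.0},
                                    seed=17)
        xs = [f.x for f in normalize_and_lfc(table, "KO")]
        tol = 3 * math.sqrt(2) * (0.2 / math.log(2)) / math.sqrt(50)
        assert abs(np.mean(xs) - 1.0) < tol

    def test_effect_on_unknown_site_rejected(self):
        sites, _ = self.sites_effects()
        bad = [EffectSpec("P1", "99", "phospho_S", 1.0)]
        with pytest.raises(ValueError, match="unknown site"):
            gen_intensity_table(sites, bad, 0.0, {"WT": 1.0, "KO": 1.0}, seed=0)

    def test_seed_determinism(self):
        sites, effects = self.sites_effects()
        t1 = gen_intensity_table(sites, effects, 0.3, {"WT": 1.0, "KO": 1.0}, 9)
        t2 = gen_intensity_table(sites, effects, 0.3, {"WT": 1.0, "KO": 1.0}, 9)
        assert t1.frame.equals(t2.frame)


class TestBinderTable:
    def test_seed_determinism(self):
        s1 = gen_binder_table(10, 2, 1, 1, 1, 2.0, seed=3, noise_sd=0.1)
        s2 = gen_binder_table(10, 2, 1, 1, 1, 2.0, seed=3, noise_sd=0.1)
        assert s1.table.equals(s2.table)

    def test_truth_matches_planted_groups(self):
        sim = gen_binder_table(5, 3, 2, 1, 4, 2.0, seed=1)
        counts = {"decreased_both": 0, "increased_both": 0,
                  "only_a": 0, "only_b": 0}
        for dir_a, dir_b in sim.truth.values():
            if dir_a == dir_b == "decreased":
                counts["decreased_both"] += 1
            elif dir_a == dir_b == "increased":
                counts["increased_both"] += 1
            elif dir_a == "decreased":
                counts["only_a"] += 1
            elif dir_b == "decreased":
                counts["only_b"] += 1
        assert counts == {"decreased_both": 3, "increased_both": 2,
                          "only_a": 1, "only_b": 4}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gen_binder_table(-1, 0, 0, 0, 0, 1.0, seed=0)


class TestHsp90Panel:
    def test_panel_covers_named_sites(self):
        sites, effects = hsp90_site_panel()
        positions = {(p, pos) for p, pos, _r, _t in sites}
        assert (f"{ALPHA_ID};{BETA_ID}", "283;275") in positions
        assert (f"{ALPHA_ID};{BETA_ID}", "362;354") in positions
        assert (f"{ALPHA_ID};{BETA_ID}", "615;607") in positions
        assert (ALPHA_ID, "231") in positions and (BETA_ID, "532") in positions
        directions = {e.position: e.direction for e in effects}
        assert directions["283;275"] == "hyper"
        assert directions["362;354"] == directions["615;607"] == "hypo"
        assert all(e.direction == "hyper" for e in effects
                   if e.ptm_type == "phospho_S")

    def test_every_effect_targets_a_listed_site(self):
        sites, effects = hsp90_site_panel()
        keys = {(p, pos, t) for p, pos, _r, t in sites}
        assert all((e.protein_id, e.position, e.ptm_type) in keys
                   for e in effects)

    def test_standins_deterministic_and_match_packaged(self, hsp90_pair):
        alpha, beta = synthesize_hsp90_standins()
        packaged_alpha, packaged_beta = hsp90_pair
        assert alpha.sequence == packaged_alpha.sequence
        assert beta.sequence == packaged_beta.sequence

    def test_trigger_context_unique_at_acetyl_site(self):
        alpha, beta = synthesize_hsp90_standins()
        for rec, site in ((alpha, 283), (beta, 275)):
            s = rec.sequence
            assert s[site - 2:site + 1] == "GKG"
            assert sum(s[i:i + 3] == "GKG" for i in range(len(s))) == 1


def test_corpus_split_and_label_shapes():
    corpus = gen_corpus(8, (40, 60), seed=2)
    train, val = corpus.split(2)
    assert len(train.records) == 6 and len(val.records) == 2
    for rec, lab in corpus.records:
        assert lab.shape == (len(rec), 13)
        assert set(np.unique(lab)) <= {0, 1}
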