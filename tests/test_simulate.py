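"""Synthetic-data generator: PWM structure, sampling, variant design."""

from __future__ import annotations

import numpy as np
import pytest

import splicevar as sv
from splicevar.metrics import auroc
from splicevar.simulate import background_distribution


class TestDefaultMotif:
    def test_rows_sum_to_one(self):
        for site in ("donor", "acceptor"):
            for strength in (0.0, 0.4, 1.0):
                motif = sv.default_motif(site, "DLAI40", strength)
                assert np.allclose(motif.pwm.sum(axis=1), 1.0, atol=1e-9)

    def test_dimer_columns_degenerate_at_any_strength(self):
        for strength in (0.0, 0.5, 1.0):
            motif = sv.default_motif("donor", "DLAI40", strength)
            d0 = motif.convention.dimer_start - 1
            assert motif.pwm[d0].tolist() == [0, 0, 1, 0]      # G
            assert motif.pwm[d0 + 1].tolist() == [0, 0, 0, 1]  # T

    def test_strength_zero_is_pure_background(self):
        motif = sv.default_motif("donor", "DLAI40", 0.0, background_gc=0.42)
        bg = background_distribution(0.42)
        d0 = motif.convention.dimer_start - 1
        for j in range(40):
            if j in (d0, d0 + 1):
                continue
            assert np.allclose(motif.pwm[j], bg)

    def test_full_strength_consensus_purine_after_dimer(self):
        motif = sv.default_motif("donor", "DLAI40", 1.0)
        d0 = motif.convention.dimer_start - 1
        col = motif.pwm[d0 + 2]  # first base after GT: purine-rich
        assert col[0] + col[2] > 0.9
        assert col.argmax() in (0, 2)

    def test_gwh398_places_motif_at_gwh_positions(self):
        motif = sv.default_motif("donor", "GWH398", 1.0)
        assert motif.pwm[200].tolist() == [0, 0, 1, 0]
        assert motif.pwm[201].tolist() == [0, 0, 0, 1]

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError):
            sv.default_motif("donor", "DLAI40", 1.5)


class TestSampling:
    def test_empty_draw(self):
        motif = sv.default_motif("donor", "DLAI40", 1.0)
        assert sv.sample_positive(motif, 0, 1) == []

    def test_same_seed_identical_output(self):
        motif = sv.default_motif("donor", "DLAI40", 1.0)
        a = sv.sample_positive(motif, 50, 42)
        b = sv.sample_positive(motif, 50, 42)
        assert [r.seq for r in a] == [r.seq for r in b]
        cfg = sv.GeneratorConfig("donor", "DLAI40", 0, 50, seed=42)
        assert [r.seq for r in sv.sample_negative(cfg)] == \
               [r.seq for r in sv.sample_negative(cfg)]

    def test_positive_frequencies_match_pwm(self):
        motif = sv.default_motif("donor", "DLAI40", 1.0)
        records = sv.sample_positive(motif, 10_000, 7)
        counts = np.zeros((40, 4))
        index = {b: i for i, b in enumerate("ACGT")}
        for r in records:
            for j, base in enumerate(r.seq):
                counts[j, index[base]] += 1
        freqs = counts / len(records)
        assert np.abs(freqs - motif.pwm).max() < 0.02

    def test_negative_dimer_positions(self):
        donor = sv.sample_negative(
            sv.GeneratorConfig("donor", "DLAI40", 0, 200, seed=1))
        assert all(r.seq[19:21] == "GT" for r in donor)
        acceptor = sv.sample_negative(
            sv.GeneratorConfig("acceptor", "DLAI40", 0, 200, seed=2))
        assert all(r.seq[18:20] == "AG" for r in acceptor)

    def test_negative_gc_concentrates(self):
        cfg = sv.GeneratorConfig("donor", "DLAI40", 0, 10_000,
                                 background_gc=0.5, seed=3)
        records = sv.sample_negative(cfg)
        non_dimer = [r.seq[:19] + r.seq[21:] for r in records]
        gc = np.mean([(s.count("G") + s.count("C")) / len(s)
                      for s in non_dimer])
        assert abs(gc - 0.5) < 0.02

    def test_generate_dataset_deterministic_and_valid(self):
        cfg = sv.GeneratorConfig("acceptor", "DLAI40", 30, 40, seed=5)
        a = sv.generate_dataset(cfg)
        b = sv.generate_dataset(cfg)
        assert [r.seq for r in a] == [r.seq for r in b]
        assert sum(r.label is sv.Label.POSITIVE for r in a) == 30
        assert sum(r.label is sv.Label.NEGATIVE for r in a) == 40


class TestSeparabilityControl:
    def test_pwm_scorer_separates_at_full_strength(self):
        for site in ("donor", "acceptor"):
            motif = sv.default_motif(site, "DLAI40", 1.0)
            pos = sv.sample_positive(motif, 2000, 11)
            neg = sv.sample_negative(
                sv.GeneratorConfig(site, "DLAI40", 0, 2000, seed=12))
            scores = [motif.log_odds(r.seq) for r in pos + neg]
            labels = [1] * 2000 + [0] * 2000
            assert auroc(scores, labels) >= 0.95

    def test_pwm_scorer_chance_at_zero_strength(self):
        motif = sv.default_motif("donor", "DLAI40", 0.0)
        pos = sv.sample_positive(motif, 2000, 13)
        neg = sv.sample_negative(
            sv.GeneratorConfig("donor", "DLAI40", 0, 2000, seed=14))
        scores = [motif.log_odds(r.seq) for r in pos + neg]
        labels = [1] * 2000 + [0] * 2000
        assert abs(auroc(scores, labels) - 0.5) <= 0.05


class TestGenerateVariants:
    @pytest.fixture()
    def setup(self):
        motif = sv.default_motif("donor", "DLAI40", 1.0)
        positives = sv.sample_positive(motif, 100, 21)
        return motif, positives

    def test_ref_allele_matches_window(self, setup):
        motif, positives = setup
        vset = sv.generate_variants(positives, 50, 50, 1, motif)
        assert len(vset.records) == 100
        for rec in vset.records:
            assert rec.window[rec.position - 1] == rec.ref_allele
            assert rec.ref_allele != rec.alt_allele

    def test_dimer_hit_breaks_dimer(self, setup):
        motif, positives = setup
        vset = sv.generate_variants(positives, 200, 10, 2, motif)
        dimer_hits = [r for r in vset.records
                      if r.position in motif.dimer_positions]
        assert dimer_hits, "dimer positions should be eligible by default"
        for rec in dimer_hits:
            mutated = sv.apply_variant(rec)
            assert mutated[19:21] != "GT"

    def test_neutral_positions_exclude_dimer(self, setup):
        motif, positives = setup
        vset = sv.generate_variants(positives, 10, 200, 3, motif)
        for rec in vset.records:
            if rec.clinical_class is sv.ClinicalClass.BENIGN:
                assert rec.position not in motif.dimer_positions

    def test_disruptive_drop_exceeds_neutral_drop(self, setup):
        """PWM log-likelihood falls more for disruptive than neutral alts."""
        motif, positives = setup
        vset = sv.generate_variants(positives, 150, 150, 4, motif)
        drops = {"pathogenic": [], "benign": []}
        for rec in vset.records:
            drop = (motif.log_likelihood(rec.window)
                    - motif.log_likelihood(sv.apply_variant(rec)))
            drops[rec.clinical_class.value].append(drop)
        assert np.mean(drops["pathogenic"]) > np.mean(drops["benign"])

    def test_requesting_too_many_raises(self, setup):
        motif, positives = setup
        with pytest.raises(ValueError, match="available"):
            sv.generate_variants(positives[:1], 100, 0, 5, motif)

    def test_deterministic(self, setup):
        motif, positives = setup
        a = sv.generate_variants(positives, 20, 20, 6, motif)
        b = sv.generate_variants(positives, 20, 20, 6, motif)
        assert a.records == b.records

    def test_class_design_reported(self, setup):
        motif, positives = setup
        vset = sv.generate_variants(positives, 5, 5, 7, motif)
        assert set(vset.class_design) == {"disruptive", "neutral"}
        assert 20 in vset.class_design["disruptive"]  # G of the GT dimer
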