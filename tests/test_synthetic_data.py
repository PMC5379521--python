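import numpy as np
import pytest

from mirsnp.core_io import SequenceRecord, reverse_complement
from mirsnp.mirna_discovery import evaluate_hairpin, fold_nussinov
from mirsnp.synthetic_data import (
    GenerationError,
    ScenarioConfig,
    make_degradome,
    make_hairpin,
    make_scenario,
    plant_binding_site,
    plant_impact_event,
    write_scenario,
)
from mirsnp.target_engine import ScoreParams, find_sites, score_duplex

from conftest import random_seq

P = ScoreParams()


class TestMakeHairpin:
    def test_zero_mismatch_hairpin_fully_paired(self):
        rng = np.random.default_rng(1)
        prec, mat, star = make_hairpin(rng, 21, 12, 0)
        ev = evaluate_hairpin(prec, mat, fold_nussinov(prec))
        assert ev.passed and ev.unpaired_mature == 0

    def test_five_mismatches_fail_default_criteria(self):
        rng = np.random.default_rng(2)
        prec, mat, star = make_hairpin(rng, 21, 12, 5)
        assert not evaluate_hairpin(prec, mat, fold_nussinov(prec)).passed

    def test_same_seed_identical_output(self):
        a = make_hairpin(np.random.default_rng(5), 21, 12, 1)
        b = make_hairpin(np.random.default_rng(5), 21, 12, 1)
        assert a == b

    def test_excessive_mismatches_rejected(self):
        with pytest.raises(ValueError):
            make_hairpin(np.random.default_rng(1), 21, 12, 22)


class TestPlantBindingSite:
    def test_score_zero_plants_exact_reverse_complement(self):
        rng = np.random.default_rng(3)
        mirna = random_seq(rng, 21)
        tx = plant_binding_site(rng, random_seq(rng, 200), mirna, 0.0, 80, P)
        assert tx[80:101] == reverse_complement(mirna)

    @pytest.mark.parametrize("target", [0.5, 1.0, 2.0, 3.0, 3.5])
    def test_planted_score_rescored_exactly(self, target):
        rng = np.random.default_rng(int(target * 10))
        mirna = random_seq(rng, 21)
        tx = plant_binding_site(rng, random_seq(rng, 200), mirna, target, 80, P)
        score, _ = score_duplex(mirna, tx[80:101], P)
        assert score == pytest.approx(target, abs=1e-12)
        hits = find_sites(SequenceRecord("m", mirna), SequenceRecord("t", tx), P)
        planted = [h for h in hits if h.site_start == 81]
        assert len(planted) == 1 and planted[0].score == pytest.approx(target)

    def test_unreachable_quarter_point_score_raises(self):
        rng = np.random.default_rng(4)
        mirna = random_seq(rng, 21)
        with pytest.raises(ValueError, match="0.25|reachable|step"):
            plant_binding_site(rng, random_seq(rng, 200), mirna, 0.25, 80, P)


class TestPlantImpactEvent:
    def _setup(self, seed, score=3.0):
        rng = np.random.default_rng(seed)
        mirna = random_seq(rng, 21)
        tx = plant_binding_site(rng, random_seq(rng, 200), mirna, score, 80, P)
        return rng, mirna, tx

    def test_a_unique_edit_crosses_cutoff_with_margin(self):
        rng, mirna, tx = self._setup(11)
        ref_tx, pos0, ref_b, alt_b = plant_impact_event(
            rng, "a_unique", mirna, tx, 80, P, margin=1.0
        )
        assert ref_tx == tx  # reference keeps the working site
        alt_tx = tx[:pos0] + alt_b + tx[pos0 + 1 :]
        alt_score, _ = score_duplex(mirna, alt_tx[80:101], P)
        assert alt_score >= P.cutoff + 1.0 - 1e-9
        hits = find_sites(SequenceRecord("m", mirna), SequenceRecord("t", alt_tx), P)
        assert not [h for h in hits if h.site_start - 1 < 101 and 80 < h.site_end]

    def test_b_unique_reference_is_broken_alt_works(self):
        rng, mirna, tx = self._setup(12)
        ref_tx, pos0, ref_b, alt_b = plant_impact_event(
            rng, "b_unique", mirna, tx, 80, P, margin=1.0
        )
        assert ref_tx != tx
        hits_ref = find_sites(SequenceRecord("m", mirna), SequenceRecord("t", ref_tx), P)
        assert not [h for h in hits_ref if h.site_start - 1 < 101 and 80 < h.site_end]
        alt_tx = ref_tx[:pos0] + alt_b + ref_tx[pos0 + 1 :]
        assert alt_tx == tx

    def test_neutral_edit_keeps_a_reported_site(self):
        rng, mirna, tx = self._setup(13, score=1.0)
        ref_tx, pos0, ref_b, alt_b = plant_impact_event(
            rng, "neutral", mirna, tx, 80, P, margin=1.0
        )
        alt_tx = tx[:pos0] + alt_b + tx[pos0 + 1 :]
        hits = find_sites(SequenceRecord("m", mirna), SequenceRecord("t", alt_tx), P)
        assert [h for h in hits if h.site_start - 1 < 101 and 80 < h.site_end]


class TestMakeDegradome:
    def test_full_peak_gives_category_zero(self):
        from mirsnp.degradome import classify_site, map_tags

        rng = np.random.default_rng(6)
        tx = random_seq(rng, 200)
        tags = make_degradome(rng, 90, tx, total_tags=10, peak_fraction=1.0)
        assert sum(c for _, c in tags) == 10
        profiles, _ = map_tags(tags, [SequenceRecord("t", tx)])
        assert classify_site(profiles[0], 90) == 0

    def test_zero_peak_fraction_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            make_degradome(rng, 50, random_seq(rng, 200), 10, 0.0)

    def test_tags_are_verbatim_substrings(self):
        rng = np.random.default_rng(8)
        tx = random_seq(rng, 200)
        for seq, count in make_degradome(rng, 90, tx, 40, 0.5):
            assert seq in tx and len(seq) == 20

    def test_seeded_runs_identical(self):
        tx = random_seq(np.random.default_rng(0), 200)
        a = make_degradome(np.random.default_rng(9), 90, tx, 40, 0.5)
        b = make_degradome(np.random.default_rng(9), 90, tx, 40, 0.5)
        assert a == b


class TestMakeScenario:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_scenario(make_scenario(ScenarioConfig(seed=3)), d1)
        write_scenario(make_scenario(ScenarioConfig(seed=3)), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_planted_sites=20, n_transcripts=5)
        with pytest.raises(ValueError):
            ScenarioConfig(n_a_unique=8, n_b_unique=8, n_planted_sites=10)

    def test_all_planted_sites_rescore_exactly(self, bundle):
        mat_of = {l.id: l.mature_seq for l in bundle.loci}
        tx = {t.id: t for t in bundle.transcripts_a}
        for s in bundle.truth_sites:
            if s["kind"] == "b_unique":
                continue  # reference carries the broken allele by design
            hits = find_sites(
                SequenceRecord(s["mirna_id"], mat_of[s["mirna_id"]]),
                tx[s["transcript_id"]],
                bundle.config.params,
            )
            match = [h for h in hits if h.site_start == s["site_start"]]
            assert len(match) == 1
            assert match[0].score == pytest.approx(s["score"], abs=1e-12)

    def test_reads_derive_from_hairpins(self, bundle):
        matures = {l.mature_seq for l in bundle.loci}
        stars = {l.star_seq for l in bundle.loci if l.star_seq}
        for lib, reads in bundle.reads_by_library.items():
            seqs = {r.seq for r in reads}
            assert matures <= seqs
            assert stars <= seqs

    def test_group_b_transcripts_carry_b_alleles(self, bundle):
        b_by_id = {t.id: t for t in bundle.transcripts_b}
        for e in bundle.truth_events:
            b_tx = b_by_id[f"hwk_{e.transcript_id}"]
            assert b_tx.seq[e.transcript_pos - 1] == e.alt_base

    def test_no_event_scenario_reports_zero_deltas(self):
        from mirsnp.snp_impact import compare_groups

        cfg = ScenarioConfig(
            seed=4, n_a_unique=0, n_b_unique=0, n_neutral=0,
            background_snp_rate=0.0, n_mature_snp_mirnas=0,
        )
        b = make_scenario(cfg)
        comp = compare_groups(
            b.loci, b.transcripts_a, b.gene_models, b.variant_records,
            cfg.group_a, cfg.group_b, cfg.params,
        )
        assert not comp.a_unique and not comp.b_unique
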