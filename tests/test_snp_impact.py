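import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsnp.core_io import SequenceRecord, reverse_complement
from mirsnp.snp_impact import (
    align_global,
    apply_variants,
    build_snp_mirna,
    call_group_unique_targets,
    compare_groups,
    diff_targets,
    ortholog_validate,
)
from mirsnp.target_engine import ScoreParams, TargetInteraction, find_sites

from conftest import oracle_nw_score, random_seq


class TestApplyVariants:
    def test_substitution(self):
        assert apply_variants("AAAA", [(2, "A", "G")]).variant_seq == "AGAA"

    def test_identity_on_empty_list(self):
        s = apply_variants("AAAA", [])
        assert s.variant_seq == "AAAA" and s.is_reference

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            apply_variants("AAAA", [(2, "C", "G")])

    def test_out_of_range_position(self):
        with pytest.raises(ValueError):
            apply_variants("AAAA", [(5, "A", "G")])

    @settings(max_examples=40, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=30), st.data())
    def test_inverse_substitutions_recover_original(self, seq, data):
        pos = data.draw(st.integers(1, len(seq)))
        alt = data.draw(st.sampled_from("ACGT"))
        if alt == seq[pos - 1]:
            return
        fwd = apply_variants(seq, [(pos, seq[pos - 1], alt)])
        back = apply_variants(fwd.variant_seq, [(pos, alt, seq[pos - 1])])
        assert back.variant_seq == seq


class TestBuildSnpMirna:
    def test_mature_position_14_substitution(self, bundle):
        # a planted fixed difference inside a mature sequence (Table-3 style)
        row = bundle.truth_mature_snps[0]
        locus = next(l for l in bundle.loci if l.id == row["mirna_id"])
        haps = build_snp_mirna(locus, bundle.variant_records, bundle.config.group_b)
        assert len(haps) == 1
        hap = haps[0]
        assert hap.variant_seq != locus.mature_seq
        pos = row["mature_pos"]
        assert hap.variant_seq[pos - 1] == row["alt"]
        assert locus.mature_seq[pos - 1] == row["ref"]
        # only that base differs
        diffs = [
            i
            for i, (a, b) in enumerate(zip(locus.mature_seq, hap.variant_seq))
            if a != b
        ]
        assert diffs == [pos - 1]

    def test_reference_group_keeps_mature(self, bundle):
        for locus in bundle.loci:
            haps = build_snp_mirna(locus, bundle.variant_records, bundle.config.group_a)
            assert haps[0].variant_seq == locus.mature_seq

    def test_minus_strand_allele_complemented(self):
        from mirsnp.core_io import GenomicInterval, VariantRecord
        from mirsnp.mirna_discovery import MiRNALocus

        mature = "TGACAGAAGAGAGTGAGCACA"
        genome_fwd = reverse_complement(mature)
        locus = MiRNALocus(
            id="m",
            precursor_interval=GenomicInterval("c", 0, 21, "-"),
            mature_interval=GenomicInterval("c", 0, 21, "-"),
            precursor_seq=mature,
            mature_seq=mature,
            star_seq=None,
            arm="5p",
            class_label="conserved",
        )
        # genomic A->G at fwd position 1 = mature local position 21 (T->C)
        assert genome_fwd[0] == "T"
        v = VariantRecord(
            "c", 1, "T", ["C"], {"B": {"C": 1.0}}, {"B": {"C": 10}}
        )
        hap = build_snp_mirna(locus, [v], "B")[0]
        assert hap.variant_seq[20] == "G"  # revcomp of C


class TestDiffTargets:
    def _site(self, tid, start, end, score=1.0):
        return TargetInteraction("m", tid, start, end, (), score)

    def test_ref_only_is_disrupted(self):
        d = diff_targets([self._site("T1", 10, 30)], [])
        assert [x.status for x in d] == ["disrupted"]

    def test_alt_only_is_created(self):
        d = diff_targets([], [self._site("T2", 5, 25)])
        assert [x.status for x in d] == ["created"]

    def test_identical_lists_all_conserved(self):
        sites = [self._site("T1", 10, 30), self._site("T2", 40, 60)]
        d = diff_targets(sites, sites)
        assert all(x.status == "conserved" for x in d)
        assert len(d) == 2

    def test_overlap_within_one_base_still_matches(self):
        d = diff_targets([self._site("T1", 10, 30)], [self._site("T1", 11, 31)])
        assert [x.status for x in d] == ["conserved"]

    def test_counts_stable_under_order_permutation(self):
        rng = np.random.default_rng(2)
        ref = [self._site(f"T{i}", 10, 30) for i in range(6)]
        alt = [self._site(f"T{i}", 12, 32) for i in range(3, 9)]
        base = diff_targets(ref, alt)
        perm = diff_targets(
            [ref[i] for i in rng.permutation(6)], [alt[i] for i in rng.permutation(6)]
        )
        count = lambda ds: sorted((d.transcript_id, d.status) for d in ds)
        assert count(base) == count(perm)


class TestAlignGlobal:
    def test_identical_sequences(self):
        _, identity = align_global("ACGTACGTAC", "ACGTACGTAC")
        assert identity == 1.0

    def test_one_substitution_in_ten(self):
        _, identity = align_global("ACGTACGTAC", "ACGTACGTAA")
        assert identity == pytest.approx(0.9)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")

    def test_score_matches_dp_oracle_on_small_instances(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            a = random_seq(rng, int(rng.integers(4, 13)))
            b = random_seq(rng, int(rng.integers(4, 13)))
            alignment, _ = align_global(a, b)
            assert alignment.score == pytest.approx(oracle_nw_score(a, b))


class TestOrthologValidate:
    P = ScoreParams()

    def _setup(self, rng, n_diffs, L=1000):
        mirna = random_seq(rng, 21)
        tx = random_seq(rng, L)
        pos = 400
        tx = tx[:pos] + reverse_complement(mirna) + tx[pos + 21 :]
        snp_mrna = SequenceRecord("q", tx)
        inter = find_sites(SequenceRecord("m", mirna), snp_mrna, self.P)
        site = next(h for h in inter if h.site_start == pos + 1)
        # ortholog: n_diffs evenly spaced substitutions outside the site
        # (spacing keeps the optimal global alignment gap-free)
        chars = list(tx)
        free = [i for i in range(L) if not (pos <= i < pos + 21)]
        if n_diffs:
            step = len(free) // n_diffs
            for i in [free[k * step] for k in range(n_diffs)]:
                chars[i] = next(b for b in "ACGT" if b != chars[i])
        ortho = SequenceRecord("o", "".join(chars))
        return snp_mrna, ortho, site

    def test_verbatim_ortholog_accepted(self):
        rng = np.random.default_rng(3)
        snp_mrna, _, site = self._setup(rng, 0)
        match = ortholog_validate(
            snp_mrna, [SequenceRecord("o", snp_mrna.seq)], site
        )
        assert match.identity == 1.0 and match.site_contained and match.accepted

    def test_identity_exactly_090_rejected(self):
        rng = np.random.default_rng(4)
        snp_mrna, ortho, site = self._setup(rng, 100, L=1000)
        match = ortholog_validate(snp_mrna, [ortho], site)
        assert match.identity == pytest.approx(0.90)
        assert match.site_contained
        assert not match.accepted  # "higher than 90%" is strict

    def test_identity_0901_accepted(self):
        rng = np.random.default_rng(5)
        snp_mrna, ortho, site = self._setup(rng, 99, L=1000)
        match = ortholog_validate(snp_mrna, [ortho], site)
        assert match.identity == pytest.approx(0.901)
        assert match.accepted

    def test_site_deleted_in_ortholog_rejected(self):
        rng = np.random.default_rng(6)
        snp_mrna, ortho, site = self._setup(rng, 10, L=1000)
        # excise the site region from the ortholog
        chars = ortho.seq[: site.site_start - 1] + ortho.seq[site.site_end :]
        gutted = SequenceRecord("o", chars)
        match = ortholog_validate(snp_mrna, [gutted], site)
        assert match.identity > 0.90
        assert not match.site_contained
        assert not match.accepted

    def test_empty_ortholog_set_raises(self):
        rng = np.random.default_rng(7)
        snp_mrna, _, site = self._setup(rng, 0)
        with pytest.raises(ValueError):
            ortholog_validate(snp_mrna, [], site)


class TestGroupComparison:
    def test_planted_events_called_exactly(self, bundle):
        comp = compare_groups(
            bundle.loci,
            bundle.transcripts_a,
            bundle.gene_models,
            bundle.variant_records,
            bundle.config.group_a,
            bundle.config.group_b,
            bundle.config.params,
            ortholog_transcripts=bundle.transcripts_b,
        )
        table = call_group_unique_targets(comp)
        truth_a = {
            (e.mirna_id, e.transcript_id)
            for e in bundle.truth_events
            if e.kind == "a_unique"
        }
        truth_b = {
            (e.mirna_id, e.transcript_id)
            for e in bundle.truth_events
            if e.kind == "b_unique"
        }
        called_a = {
            (r["mirna_id"], r["transcript_id"])
            for r in table["rows"]
            if r["unique_to"] == bundle.config.group_a
        }
        called_b = {
            (r["mirna_id"], r["transcript_id"])
            for r in table["rows"]
            if r["unique_to"] == bundle.config.group_b
        }
        assert called_a == truth_a
        assert called_b == truth_b

    def test_neutral_events_stay_conserved(self, bundle):
        comp = compare_groups(
            bundle.loci,
            bundle.transcripts_a,
            bundle.gene_models,
            bundle.variant_records,
            bundle.config.group_a,
            bundle.config.group_b,
            bundle.config.params,
        )
        neutral = {
            (e.mirna_id, e.transcript_id)
            for e in bundle.truth_events
            if e.kind == "neutral"
        }
        conserved = {
            (d.mirna_id, d.transcript_id)
            for d in comp.deltas
            if d.status == "conserved"
        }
        assert neutral <= conserved

    def test_created_sites_are_ortholog_validated(self, bundle):
        comp = compare_groups(
            bundle.loci,
            bundle.transcripts_a,
            bundle.gene_models,
            bundle.variant_records,
            bundle.config.group_a,
            bundle.config.group_b,
            bundle.config.params,
            ortholog_transcripts=bundle.transcripts_b,
        )
        for d in comp.b_unique:
            assert d.ortholog is not None
            assert d.ortholog.accepted  # group-B transcript carries the site

    def test_swapping_groups_swaps_unique_counts(self, bundle):
        kwargs = dict(params=bundle.config.params)
        ab = compare_groups(
            bundle.loci, bundle.transcripts_a, bundle.gene_models,
            bundle.variant_records, bundle.config.group_a, bundle.config.group_b,
            **kwargs,
        )
        ba = compare_groups(
            bundle.loci, bundle.transcripts_a, bundle.gene_models,
            bundle.variant_records, bundle.config.group_b, bundle.config.group_a,
            **kwargs,
        )
        assert len(ab.a_unique) == len(ba.b_unique)
        assert len(ab.b_unique) == len(ba.a_unique)

    def test_rescoring_reported_deltas_reproduces_scores(self, bundle):
        from mirsnp.snp_impact import build_snp_transcript

        comp = compare_groups(
            bundle.loci, bundle.transcripts_a, bundle.gene_models,
            bundle.variant_records, bundle.config.group_a, bundle.config.group_b,
            bundle.config.params,
        )
        tx_a = {t.id: t for t in bundle.transcripts_a}
        for d in comp.deltas:
            locus = next(l for l in bundle.loci if l.id == d.mirna_id)
            if d.ref_score is not None:
                mir = build_snp_mirna(
                    locus, bundle.variant_records, bundle.config.group_a
                )[0]
                tx = build_snp_transcript(
                    tx_a[d.transcript_id],
                    bundle.gene_models[d.transcript_id],
                    bundle.variant_records,
                    bundle.config.group_a,
                )[0]
                hits = find_sites(
                    SequenceRecord(d.mirna_id, mir.variant_seq),
                    SequenceRecord(d.transcript_id, tx.variant_seq),
                    bundle.config.params,
                )
                assert any(
                    h.site_start == d.ref_site[0] and h.score == pytest.approx(d.ref_score)
                    for h in hits
                )
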