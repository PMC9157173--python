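"""Amplicon decoder: read assignment, pattern calling, NA logic,
per-line genotyping, and dereplication."""

from collections import Counter

import pytest

from ampmux import (Allele, LocusModel, PrimerPair, assign_reads,
                    build_default_locus, call_indel_patterns, call_na,
                    dereplicate, expected_calls, genotype_line, revcomp)
from ampmux.decode import (AMBIGUOUS, InsufficientDepthError, orient_read)
from ampmux.simulate import (EditSpectrumConfig, EditedGenotype, apply_indel,
                             simulate_amplicon_reads, simulate_line_edits)

from oracles import cluster_oracle


def _wt(model, line="ctl"):
    return EditedGenotype(line, [], {a.id: a.seq for a in model.alleles},
                          {}, 0)


def _wt_reads(model, depth=100, error_rate=0.0, seed=1):
    return list(simulate_amplicon_reads(_wt(model), model, depth=depth,
                                        error_rate=error_rate, seed=seed))


class TestAssign:
    def test_exact_reads_assigned_to_their_allele(self, resolvable_locus,
                                                  resolvable_snps):
        res = assign_reads(_wt_reads(resolvable_locus), resolvable_locus,
                           snps=resolvable_snps)
        for a in res.assignments:
            true_allele = a.read_id.split("|")[1]
            assert a.allele == true_allele
            assert a.distances[true_allele] == 0

    def test_conservation(self, resolvable_locus):
        reads = _wt_reads(resolvable_locus, depth=50) + \
            [("junk1", "A" * 270), ("junk2", "C" * 270)]
        res = assign_reads(reads, resolvable_locus)
        assert len(res.assignments) + res.unmatched == len(reads)
        assert res.unmatched == 2

    def test_planted_minus_two_read_distance(self, resolvable_locus,
                                             resolvable_guide,
                                             resolvable_snps):
        aid = "MYB138m2"
        cut = resolvable_guide.cut_site(aid)
        edited = apply_indel(resolvable_locus.allele(aid).seq, cut, -2)
        gt = EditedGenotype("l", [], {a.id: (edited if a.id == aid
                                             else a.seq)
                                      for a in resolvable_locus.alleles},
                            {}, 0)
        reads = list(simulate_amplicon_reads(gt, resolvable_locus, depth=20,
                                             error_rate=0.0, seed=2))
        res = assign_reads(reads, resolvable_locus, snps=resolvable_snps)
        mine = [a for a in res.assignments if aid in a.read_id]
        assert all(a.allele == aid for a in mine)
        assert all(a.distances[aid] == 2 for a in mine)

    def test_repeat_only_pair_naive_vs_normalized(self, default_locus,
                                                  default_snps,
                                                  default_guide):
        """Reads of the longer-repeat sibling are absorbed by the earlier
        allele in naive mode (surfacing a repeat-length indel away from the
        cut), but go ambiguous under repeat normalization."""
        reads = [(rid, s) for rid, s in _wt_reads(default_locus, depth=40)
                 if "MYB186a" in rid]
        naive = assign_reads(reads, default_locus, snps=default_snps,
                             mode="naive")
        assert {a.allele for a in naive.assignments} == {"MYB186m1"}
        pats = call_indel_patterns(naive, "MYB186m1", default_locus,
                                   default_guide)
        cut = 81  # amplicon-relative cut
        assert all(p.size % 2 == 0 and p.size != 0 for p in pats)
        assert all(abs(p.position - cut) > 10 for p in pats)

        norm = assign_reads(reads, default_locus, snps=default_snps,
                            mode="repeat_normalized")
        assert {a.allele for a in norm.assignments} == {AMBIGUOUS}

    def test_one_repeat_unit_sibling_artifact(self):
        """A sibling differing by a single GT unit produces the classic
        apparent +/-2 under naive assignment."""
        stem = "ATGCCGTTAGCATCCTGGACTT"
        core = ("GATTACCAGGATCTTGCAAGCTTCGGCATAATCCGGATTACA"
                "CCTGATCATGCAAGGTTACG")
        def seq(units):
            return stem + core + "CA" + "GT" * units + "AC" + \
                "TTGACCATGGATCCGTTACAGGCATCAAGGTACCATGGTTAA"
        fwd = seq(5)[:18]
        rev = revcomp(seq(5)[-18:])
        a = Allele(id="sib8", gene="G", chrom="c1", copy_index=0,
                   seq=seq(5), start=0, exons=[(0, len(seq(5)))])
        b = Allele(id="sib9", gene="G", chrom="c2", copy_index=0,
                   seq=seq(6), start=0, exons=[(0, len(seq(6)))])
        model = LocusModel(alleles=[a, b],
                           chrom_layouts={"c1": ["sib8"], "c2": ["sib9"]},
                           primer_pairs=[PrimerPair(fwd, rev,
                                                    ("sib8", "sib9"))],
                           amplicon_len_range=(1, 500))
        reads = [(f"r{i}", seq(6)) for i in range(10)]
        naive = assign_reads(reads, model, mode="naive")
        assert all(x.allele == "sib8" for x in naive.assignments)
        assert all(x.distances["sib8"] == 2 for x in naive.assignments)
        norm = assign_reads(reads, model, mode="repeat_normalized")
        assert all(x.allele == AMBIGUOUS for x in norm.assignments)

    def test_empty_stream_errors(self, resolvable_locus):
        with pytest.raises(ValueError, match="empty"):
            assign_reads([], resolvable_locus)
        with pytest.raises(ValueError, match="primer"):
            assign_reads([("r", "A" * 100)], resolvable_locus)


class TestPatterns:
    def test_all_wt_reads_single_zero_pattern(self, resolvable_locus,
                                              resolvable_guide,
                                              resolvable_snps):
        res = assign_reads(_wt_reads(resolvable_locus, depth=50),
                           resolvable_locus, snps=resolvable_snps)
        pats = call_indel_patterns(res, "MYB186m1", resolvable_locus,
                                   resolvable_guide)
        assert len(pats) == 1
        assert pats[0].size == 0
        assert pats[0].frequency == 1.0

    def test_planted_minus_two_dominant_with_errors(self, resolvable_locus,
                                                    resolvable_guide,
                                                    resolvable_snps):
        aid = "MYB38m"
        cut = resolvable_guide.cut_site(aid)
        realized = {a.id: a.seq for a in resolvable_locus.alleles}
        realized[aid] = apply_indel(realized[aid], cut, -2)
        gt = EditedGenotype("l", [], realized, {}, 0)
        reads = list(simulate_amplicon_reads(gt, resolvable_locus, depth=500,
                                             error_rate=0.001, seed=5))
        res = assign_reads(reads, resolvable_locus, snps=resolvable_snps)
        pats = call_indel_patterns(res, aid, resolvable_locus,
                                   resolvable_guide)
        assert pats[0].size == -2
        assert pats[0].frequency >= 0.95

    def test_fused_allele_reads_show_junction_indel(self, resolvable_locus,
                                                    resolvable_guide,
                                                    resolvable_snps):
        """A fusion's amplicon decodes as the upstream donor carrying the
        junction indel (-2 here), the read-level signature of a dropout."""
        u, d = "MYB186m1", "MYB138m1"
        cut = resolvable_guide.cut_site(u)
        fused = resolvable_locus.allele(u).seq[:cut] + \
            resolvable_locus.allele(d).seq[resolvable_guide.cut_site(d):]
        fused = apply_indel(fused, cut, -2)
        realized = {a.id: a.seq for a in resolvable_locus.alleles}
        realized[u] = fused
        realized[d] = None
        gt = EditedGenotype("ko5", [], realized, {}, 0)
        reads = list(simulate_amplicon_reads(gt, resolvable_locus, depth=100,
                                             error_rate=0.0, seed=6))
        res = assign_reads(reads, resolvable_locus, snps=resolvable_snps)
        assert not any(a.allele == d for a in res.assignments)
        pats = call_indel_patterns(res, u, resolvable_locus,
                                   resolvable_guide)
        assert pats[0].size == -2
        cut_amp = 81
        assert abs(pats[0].position - cut_amp) <= 10

    def test_zero_assigned_reads_is_an_error(self, resolvable_locus,
                                             resolvable_guide):
        with pytest.raises(ValueError, match="NA"):
            call_indel_patterns([], "MYB186m1", resolvable_locus,
                                resolvable_guide)


class TestNa:
    CONTROL = {f"a{i}": 100 for i in range(8)}

    def test_control_proportions_give_empty_set(self):
        assert call_na(dict(self.CONTROL), self.CONTROL) == set()

    def test_missing_allele_flagged(self):
        sample = dict(self.CONTROL)
        sample["a3"] = 0
        assert call_na(sample, self.CONTROL) == {"a3"}

    def test_zero_depth_is_no_call(self):
        with pytest.raises(InsufficientDepthError):
            call_na({}, self.CONTROL)

    def test_monotone_in_depth(self):
        """Decreasing an allele's depth never un-flags it."""
        sample = dict(self.CONTROL)
        flagged_at = None
        for depth in range(40, -1, -5):
            sample["a0"] = depth
            na = call_na(sample, self.CONTROL)
            if flagged_at is None and "a0" in na:
                flagged_at = depth
            if flagged_at is not None:
                assert "a0" in na


class TestGenotypeLine:
    def test_unedited_control_all_wt(self, resolvable_locus,
                                     resolvable_guide, resolvable_snps,
                                     control_profile):
        calls = genotype_line(_wt_reads(resolvable_locus, depth=60, seed=9),
                              resolvable_locus, resolvable_guide,
                              control_profile, snps=resolvable_snps)
        assert [c.call for c in calls] == ["WT"] * 8

    def test_six_edited_two_wt_line(self, resolvable_locus,
                                    resolvable_guide, resolvable_snps,
                                    control_profile):
        """A line with six indel alleles and unedited MYB38 copies decodes
        to exactly the planted classes."""
        realized = {}
        sizes = {"MYB186m1": -3, "MYB138m1": -1, "MYB186m2": -2,
                 "MYB138m2": -1, "MYB186a": -2, "MYB138a": -4}
        for a in resolvable_locus.alleles:
            realized[a.id] = apply_indel(
                a.seq, resolvable_guide.cut_site(a.id),
                sizes.get(a.id, 0)) if a.id in sizes else a.seq
        gt = EditedGenotype("ko27", [], realized, {}, 0)
        reads = list(simulate_amplicon_reads(gt, resolvable_locus, depth=200,
                                             error_rate=0.001, seed=12))
        calls = genotype_line(reads, resolvable_locus, resolvable_guide,
                              control_profile, snps=resolvable_snps)
        for c in calls:
            if c.allele_id in sizes:
                assert c.call == "indel"
                assert c.patterns[0].size == sizes[c.allele_id]
            else:
                assert c.call == "WT"

    def test_dropout_line_flags_na(self, resolvable_locus, resolvable_guide,
                                   resolvable_snps, control_profile):
        cfg = EditSpectrumConfig(dropout_prob=1.0, junction_indel_prob=1.0,
                                 p_edit=1.0, p_chimera=0.0)
        gt = simulate_line_edits(resolvable_locus, resolvable_guide, cfg, 21)
        truth = expected_calls(gt, resolvable_locus, resolvable_guide)
        reads = list(simulate_amplicon_reads(gt, resolvable_locus, depth=200,
                                             error_rate=0.0, seed=13))
        calls = genotype_line(reads, resolvable_locus, resolvable_guide,
                              control_profile, snps=resolvable_snps)
        assert any(t == ("NA", None) for t in truth.values())
        for c in calls:
            assert c.call == truth[c.allele_id][0]


class TestDereplicate:
    def test_identical_reads_one_tag(self):
        tags = dereplicate([(f"r{i}", "ACGT" * 40) for i in range(1000)])
        assert tags == [("ACGT" * 40, 1000)]

    def test_default_locus_yields_seven_tags(self, default_locus):
        """Eight alleles, one amplicon-identical pair: seven distinct
        control sequences."""
        pair = default_locus.primer_pairs[0]
        reads = [("r", orient_read(s, pair))
                 for _, s in _wt_reads(default_locus, depth=50, seed=3)]
        assert len(dereplicate(reads)) == 7

    def test_error_reads_collapse_to_error_free_tags(self, default_locus):
        pair = default_locus.primer_pairs[0]
        clean = [("r", orient_read(s, pair))
                 for _, s in _wt_reads(default_locus, depth=60, seed=4)]
        noisy = [("r", orient_read(s, pair))
                 for _, s in _wt_reads(default_locus, depth=60,
                                       error_rate=0.001, seed=4)]
        assert {t for t, _ in dereplicate(noisy)} == \
            {t for t, _ in dereplicate(clean)}

    def test_matches_connected_components_oracle(self, default_locus):
        pair = default_locus.primer_pairs[0]
        seqs = [orient_read(s, pair)
                for _, s in _wt_reads(default_locus, depth=30,
                                      error_rate=0.002, seed=8)]
        tags = dereplicate([("r", s) for s in seqs], min_group_size=1,
                           min_unique_depth=1)
        oracle = cluster_oracle(seqs, max_mm=2)
        assert len(tags) == len(oracle)
        assert sorted(c for _, c in tags) == \
            sorted(sum(g.values()) for g in oracle)
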