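"""Mapping, precursor excision, folding and hairpin criteria."""

import random

import pytest

from mircold import hairpin as hp
from mircold._seq import revcomp


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMapTags:
    def test_planted_tag_single_hit(self, small_refs):
        refs, truth = small_refs
        p = truth.by_class("novel")[0]
        hits = hp.map_tags([p.mature], refs.contigs)
        assert any(h.contig_id == p.contig_id and h.start == p.mature_start
                   and h.strand == "+" for h in hits)

    def test_absent_tag_no_hits(self):
        assert hp.map_tags(["A" * 21], {"c1": "CGTACGTACG" * 30}) == []

    def test_revcomp_hit_on_minus_strand(self):
        rng = random.Random(6)
        contig = _random_seq(rng, 300)
        tag = revcomp(contig[100:121])
        hits = hp.map_tags([tag], {"c1": contig})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (100, 121, "-")

    def test_repeat_tags_discarded(self):
        tag = "ACGTACGTACGTACGTACGTA"
        contig = ("T" * 10).join([tag] * 25)
        assert hp.map_tags([tag], {"c1": contig}, max_hits=20) == []


class TestExtractPrecursor:
    def test_interior_hit_arithmetic(self):
        rng = random.Random(7)
        contig = _random_seq(rng, 1000)
        hit = hp.TagHit(contig[200:221], "c1", 200, 221, "+")
        cand = hp.extract_precursor(hit, {"c1": contig}, flank=150)
        assert (cand.window_start, cand.window_end) == (50, 371)
        assert cand.mature_offset == 150

    def test_left_clipped_window(self):
        rng = random.Random(8)
        contig = _random_seq(rng, 1000)
        hit = hp.TagHit(contig[10:31], "c1", 10, 31, "+")
        cand = hp.extract_precursor(hit, {"c1": contig}, flank=150)
        assert (cand.window_start, cand.window_end) == (0, 181)
        assert cand.mature_offset == 10

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_mature_round_trip(self, strand):
        """precursor[mature_offset : +L] equals the tag, strand-aware."""
        rng = random.Random(9)
        contig = _random_seq(rng, 600)
        tag = contig[250:271] if strand == "+" else revcomp(contig[250:271])
        hit = hp.TagHit(tag, "c1", 250, 271, strand)
        cand = hp.extract_precursor(hit, {"c1": contig})
        assert cand.seq[cand.mature_offset:cand.mature_offset + 21] == tag


class TestFold:
    def test_inverted_repeat_forms_hairpin(self):
        seq = "GGGGGGGGGGAAAACCCCCCCCCC"
        fr = hp.fold(seq)
        assert "(" in fr.structure and ")" in fr.structure
        assert fr.mfe < 0

    def test_homopolymer_unpaired(self):
        fr = hp.fold("A" * 60)
        assert fr.structure == "." * 60
        assert fr.mfe == 0.0

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            hp.fold("ACGTXACGT")

    def test_deterministic(self):
        seq = "GCGCGCAAAGUUUGCGCGCAAAAGGGCCCAAAGGGCCC"
        assert hp.fold(seq) == hp.fold(seq)


def _stub_backend(structure, mfe):
    def backend(seq):
        assert len(seq) == len(structure)
        return hp.FoldResult(structure=structure, mfe=mfe)
    return backend


def _perfect_hairpin_candidate():
    """100-nt stem-loop with GC exactly 50%, mature on the 5' arm."""
    arm = "G" * 25 + "A" * 20          # 45 nt, 25 GC
    loop = "T" * 10                    # 0 GC -> 50 GC / 100 nt
    seq = arm + loop + revcomp(arm)
    assert len(seq) == 100
    structure = "(" * 45 + "." * 10 + ")" * 45
    cand = hp.PrecursorCandidate(
        contig_id="c", window_start=0, window_end=100, strand="+",
        seq=seq, mature_offset=0, tag_seq=seq[:21])
    return cand, structure


class TestEvaluateHairpin:
    @pytest.mark.parametrize("mfe,amfe,mfei,passes", [
        (-40.0, -40.0, -0.8, False),   # |MFEI| below 0.85
        (-50.0, -50.0, -1.0, True),
    ])
    def test_mfei_arithmetic(self, mfe, amfe, mfei, passes):
        cand, structure = _perfect_hairpin_candidate()
        backend = _stub_backend(structure, mfe)
        ev = hp.evaluate_hairpin(cand, hp.FoldResult(structure, mfe), backend=backend)
        assert ev.precursor_len == 100
        assert ev.gc_percent == pytest.approx(50.0)
        assert ev.amfe == pytest.approx(amfe)
        assert ev.mfei == pytest.approx(mfei)
        assert ev.flags["mfei"] is passes
        assert ev.arm == "5p" and ev.duplex_mismatches == 0
        assert ev.passed is passes

    def test_mature_spanning_loop_fails_one_arm(self):
        cand, structure = _perfect_hairpin_candidate()
        cand.mature_offset = 40          # bases 40-61 cross the 45-55 loop
        cand.tag_seq = cand.seq[40:61]
        backend = _stub_backend(structure, -50.0)
        ev = hp.evaluate_hairpin(cand, hp.FoldResult(structure, -50.0), backend=backend)
        assert ev.arm == "loop-spanning"
        assert not ev.flags["one_arm"] and not ev.passed

    def test_mfei_closed_form_on_real_candidates(self, small_refs):
        """mfei * gc% * length / 100 reproduces mfe for every evaluation."""
        refs, truth = small_refs
        for p in truth.by_class("novel"):
            hits = hp.map_tags([p.mature], refs.contigs)
            for h in hits:
                cand = hp.extract_precursor(h, refs.contigs)
                ev = hp.evaluate_hairpin(cand, hp.fold(cand.seq))
                if ev.gc_percent > 0:
                    assert ev.mfei * ev.gc_percent * ev.precursor_len / 100 == \
                        pytest.approx(ev.mfe, rel=1e-9)

    def test_threshold_monotonicity(self, small_refs):
        """Lowering the |MFEI| threshold never shrinks the passing set."""
        refs, truth = small_refs
        evs_strict, evs_loose = [], []
        for p in truth.by_class("novel"):
            for h in hp.map_tags([p.mature], refs.contigs):
                cand = hp.extract_precursor(h, refs.contigs)
                fr = hp.fold(cand.seq)
                evs_strict.append(hp.evaluate_hairpin(
                    cand, fr, hp.HairpinConfig(min_abs_mfei=0.85)))
                evs_loose.append(hp.evaluate_hairpin(
                    cand, fr, hp.HairpinConfig(min_abs_mfei=0.5)))
        strict = {e.candidate.tag_seq for e in evs_strict if e.passed}
        loose = {e.candidate.tag_seq for e in evs_loose if e.passed}
        assert strict <= loose


class TestSelectNovel:
    def _ev(self, mature, mfei, contig="c1"):
        cand = hp.PrecursorCandidate(contig, 0, 100, "+", "A" * 100, 0, mature)
        return hp.HairpinEvaluation(
            candidate=cand, arm="5p", duplex_mismatches=0, max_bulge=0,
            precursor_seq="A" * 80, precursor_len=80, structure="." * 80,
            mfe=mfei * 40, amfe=mfei * 50, mfei=mfei, gc_percent=50.0,
            flags={}, passed=True)

    def test_best_mfei_locus_wins(self):
        m = "ACGTACGTACGTACGTACGTA"
        novel = hp.select_novel([self._ev(m, -0.9, "c1"), self._ev(m, -1.1, "c2")])
        assert len(novel) == 1
        assert novel.iloc[0]["contig_id"] == "c2"

    def test_empty_input(self):
        assert hp.select_novel([]).empty


def test_planted_precursors_pass_and_decoys_mostly_fail(small_refs):
    """All planted hairpins pass in contig context; shuffled decoys rarely do."""
    refs, truth = small_refs
    rng = random.Random(11)
    n_pass = 0
    novel = truth.by_class("novel")
    for p in novel:
        hits = hp.map_tags([p.mature], refs.contigs)
        if any(hp.evaluate_hairpin(
                c := hp.extract_precursor(h, refs.contigs), hp.fold(c.seq)).passed
               for h in hits):
            n_pass += 1
    assert n_pass == len(novel)

    decoy_pass = 0
    n_decoys = 15
    for i in range(n_decoys):
        p = novel[i % len(novel)]
        hit = hp.map_tags([p.mature], refs.contigs)[0]
        cand = hp.extract_precursor(hit, refs.contigs)
        shuffled = list(cand.seq)
        rng.shuffle(shuffled)
        decoy = "".join(shuffled)
        dc = hp.PrecursorCandidate(
            "decoy", 0, len(decoy), "+", decoy, cand.mature_offset,
            decoy[cand.mature_offset:cand.mature_offset + len(p.mature)])
        if hp.evaluate_hairpin(dc, hp.fold(decoy)).passed:
            decoy_pass += 1
    assert decoy_pass / n_decoys < 0.2
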