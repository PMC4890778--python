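"""Contaminant filtering, catalog matching, family analytics."""

import itertools
import random
import warnings

import numpy as np
import pandas as pd
import pytest

from mircold import annotate
from mircold._seq import hamming, revcomp


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFilterContaminants:
    def test_substring_removed(self):
        rng = random.Random(1)
        contam = {"rRNA_1": _random_seq(rng, 120)}
        tag = contam["rRNA_1"][30:51]
        removed, retained = annotate.filter_contaminants([tag], contam)
        assert removed == [tag] and retained == []

    def test_revcomp_substring_removed(self):
        rng = random.Random(2)
        contam = {"tRNA_1": _random_seq(rng, 100)}
        tag = revcomp(contam["tRNA_1"][10:31])
        removed, _ = annotate.filter_contaminants([tag], contam)
        assert removed == [tag]

    def test_unrelated_tag_retained(self):
        contam = {"rRNA_1": "A" * 100}
        tag = "CGTACGTACGTACGTACGTAC"
        removed, retained = annotate.filter_contaminants([tag], contam)
        assert retained == [tag] and removed == []

    def test_empty_set_warns_and_retains_all(self):
        with pytest.warns(UserWarning):
            removed, retained = annotate.filter_contaminants(["A" * 21], {})
        assert removed == [] and retained == ["A" * 21]

    def test_partition_is_exhaustive(self, small_refs):
        refs, truth = small_refs
        tags = [p.mature for p in truth.planted] + [
            refs.contaminants[n][: 21] for n in truth.contaminant_names]
        removed, retained = annotate.filter_contaminants(tags, refs.contaminants)
        assert sorted(removed + retained) == sorted(tags)
        assert set(removed).isdisjoint(retained)


def _brute_force_best(tag, catalog, max_len_diff=2):
    """Exhaustive search over entries x offsets, mirroring the stated
    tie-break (mismatches, |length difference|, name)."""
    best = None
    for e in catalog:
        ldiff = abs(len(tag) - len(e.mature_seq))
        if ldiff > max_len_diff:
            continue
        short, long_ = (tag, e.mature_seq) if len(tag) <= len(e.mature_seq) \
            else (e.mature_seq, tag)
        mm = min(hamming(short, long_[o:o + len(short)])
                 for o in range(len(long_) - len(short) + 1))
        key = (mm, ldiff, e.name)
        if best is None or key < best:
            best = key
    return best


class TestMatchConserved:
    def test_identity_assigns_zero_mismatches(self):
        cat = [annotate.CatalogEntry("pdu-miR1a", "ACGTACGTACGTACGTACGTA")]
        assigned, un = annotate.match_conserved(["ACGTACGTACGTACGTACGTA"], cat)
        assert not un and assigned[0].mismatches == 0

    def test_three_mismatches_unassigned(self):
        cat = [annotate.CatalogEntry("pdu-miR1a", "A" * 21)]
        tag = "A" * 18 + "CCC"
        assigned, un = annotate.match_conserved([tag], cat)
        assert not assigned and un == [tag]

    def test_catalog_order_invariance(self):
        rng = random.Random(3)
        cat = [annotate.CatalogEntry(f"pdu-miR{i}", _random_seq(rng, 21))
               for i in range(10)]
        tags = [_random_seq(rng, 21) for _ in range(20)] + [cat[3].mature_seq]
        a1, u1 = annotate.match_conserved(tags, cat)
        a2, u2 = annotate.match_conserved(tags, list(reversed(cat)))
        assert [(a.tag_seq, a.entry.name, a.mismatches) for a in a1] == \
               [(a.tag_seq, a.entry.name, a.mismatches) for a in a2]
        assert u1 == u2

    def test_agrees_with_brute_force_on_random_tags(self):
        rng = random.Random(4)
        cat = [annotate.CatalogEntry(f"pdu-miR{i}a", _random_seq(rng, rng.choice([20, 21, 22])))
               for i in range(12)]
        tags = [_random_seq(rng, rng.choice([19, 20, 21, 22, 23])) for _ in range(60)]
        # spike in near-misses so assignment actually happens
        for e in cat[:5]:
            s = list(e.mature_seq)
            s[5] = "A" if s[5] != "A" else "C"
            tags.append("".join(s))
        assigned, unassigned = annotate.match_conserved(tags, cat)
        by_tag = {a.tag_seq: a for a in assigned}
        for tag in tags:
            best = _brute_force_best(tag, cat)
            if best is None or best[0] > 2:
                assert tag in unassigned or tag not in by_tag
            else:
                a = by_tag[tag]
                assert (a.mismatches, abs(len(tag) - len(a.entry.mature_seq)),
                        a.entry.name) == best


class TestFamilyOf:
    @pytest.mark.parametrize("name,family", [
        ("pdu-miR482b-5p", "miR482"),
        ("miR7122a-3p", "miR7122"),
        ("miR159", "miR159"),
        ("ath-miR156a", "miR156"),
        ("pdu-miRn01-5p", "pdu-miRn01-5p"),  # novel-style name, no digits after miR
    ])
    def test_parsing(self, name, family):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert annotate.family_of(name) == family

    def test_unparseable_warns(self):
        with pytest.warns(UserWarning):
            assert annotate.family_of("weird-name") == "weird-name"


def test_family_distribution_counts_distinct_entries():
    cat = {
        "pdu-miR482f": "ACGTACGTACGTACGTACGTA",
        "pdu-miR482b-5p": "TTGTACGTACGTACGTACGAA",
        "pdu-miR159": "CCGTACGTACGTACGTACGCC",
    }
    assignments = [
        annotate.ConservedAssignment(seq, annotate.CatalogEntry(n, seq), 0, 0)
        for n, seq in cat.items()]
    dist = annotate.family_distribution(assignments)
    assert dist.loc["miR482", "pooled"] == 2
    assert dist.loc["miR159", "pooled"] == 1


def test_family_distribution_empty():
    assert annotate.family_distribution([]).empty


META = {"HCA": ("anther", "control"), "HSA": ("anther", "stress"),
        "HCO": ("ovary", "control"), "HSO": ("ovary", "stress")}


class TestSpecificitySets:
    def test_family_only_in_hca(self):
        presence = pd.DataFrame(
            [[True, False, False, False]], index=["miR1"],
            columns=["HCA", "HSA", "HCO", "HSO"])
        s = annotate.specificity_sets(presence, META)
        assert "miR1" in s.anther_only and "miR1" in s.control_only

    def test_family_everywhere_is_shared(self):
        presence = pd.DataFrame(
            [[True] * 4], index=["miR1"], columns=["HCA", "HSA", "HCO", "HSO"])
        s = annotate.specificity_sets(presence, META)
        assert s.shared == {"miR1"}

    def test_matches_truth_table_on_random_matrices(self):
        rng = np.random.default_rng(5)
        libs = ["HCA", "HSA", "HCO", "HSO"]
        for _ in range(20):
            mat = rng.random((15, 4)) < 0.5
            presence = pd.DataFrame(mat, index=[f"miR{i}" for i in range(15)],
                                    columns=libs)
            s = annotate.specificity_sets(presence, META)
            for fam, row in presence.iterrows():
                a = row["HCA"] or row["HSA"]
                o = row["HCO"] or row["HSO"]
                c = row["HCA"] or row["HCO"]
                t = row["HSA"] or row["HSO"]
                assert (fam in s.anther_only) == (a and not o)
                assert (fam in s.ovary_only) == (o and not a)
                assert (fam in s.control_only) == (c and not t)
                assert (fam in s.stress_only) == (t and not c)
                in_any = a or o
                specific = (a and not o) or (o and not a) or (c and not t) or (t and not c)
                assert (fam in s.shared) == (in_any and not specific)
            assert s.anther_only.isdisjoint(s.ovary_only)
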