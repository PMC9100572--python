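"""Allele-defining variant classification and putative-allele construction."""

import numpy as np
import pandas as pd
import pytest

from latscan.alleles import (
    DEFAULT_GROUPING,
    AnnotatedVariant,
    EffectClass,
    build_gene_alleles,
    filter_testable_genes,
    is_nonconservative,
    qualifies,
)


def _mk_variant(pos=100, effect=EffectClass.MISSENSE, aa=("M", "T", 37), gene="G1", chrom="01"):
    aa_ref, aa_alt, aa_pos = aa if aa else (None, None, None)
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref="A", alt="T", gene_id=gene,
        effect_class=effect, aa_ref=aa_ref, aa_alt=aa_alt, aa_pos=aa_pos,
    )


class TestNonconservative:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("M", "T", True),   # hydrophobic -> polar (the M37T-style call)
            ("L", "L", False),  # identity
            ("L", "I", False),  # both aliphatic (so I->V style changes don't define alleles)
            ("K", "R", False),  # both positive
            ("Q", "P", True),   # polar -> special
            ("W", "C", True),   # aromatic -> polar
            ("D", "E", False),
        ],
    )
    def test_default_grouping_calls(self, a, b, expected):
        assert is_nonconservative(a, b) is expected

    def test_symmetric(self):
        for a, b in [("M", "T"), ("L", "I"), ("D", "K")]:
            assert is_nonconservative(a, b) == is_nonconservative(b, a)

    def test_nonstandard_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            is_nonconservative("B", "T")

    def test_grouping_is_total_over_standard_residues(self):
        assert set(DEFAULT_GROUPING) == set("ACDEFGHIKLMNPQRSTVWY")


class TestQualifies:
    @pytest.mark.parametrize(
        "effect",
        [
            EffectClass.STOP_GAINED,
            EffectClass.STOP_LOST,
            EffectClass.START_LOST,
            EffectClass.SPLICE_SITE,
            EffectClass.INFRAME_INDEL,
            EffectClass.FRAMESHIFT,
        ],
    )
    def test_structural_classes_always_qualify(self, effect):
        aa = ("K", "*", 528) if effect in (EffectClass.STOP_GAINED,) else None
        assert qualifies(_mk_variant(effect=effect, aa=aa)) is True

    def test_synonymous_never_qualifies(self):
        assert qualifies(_mk_variant(effect=EffectClass.SYNONYMOUS, aa=None)) is False

    def test_conservative_missense_does_not_qualify(self):
        assert qualifies(_mk_variant(aa=("I", "V", 220))) is False

    def test_nonconservative_missense_qualifies(self):
        assert qualifies(_mk_variant(aa=("M", "T", 37))) is True

    def test_exclusion_list_drops_artifact_frameshift(self):
        v = _mk_variant(effect=EffectClass.FRAMESHIFT, aa=None, chrom="04", pos=123)
        assert qualifies(v) is True
        assert qualifies(v, exclude_sites={"04:123"}) is False

    def test_nonprimary_transcript_ignored(self):
        v = AnnotatedVariant(
            chrom="01", pos=5, ref="A", alt="T", gene_id="G",
            effect_class=EffectClass.STOP_GAINED, transcript_rank="other",
        )
        assert qualifies(v) is False


def _brute_force_partition(geno: pd.DataFrame) -> dict[frozenset, int]:
    """Oracle: group accessions by their exact genotype tuple."""
    groups: dict[tuple, set] = {}
    for acc, row in geno.iterrows():
        groups.setdefault(tuple(row), set()).add(acc)
    return {frozenset(v): len(v) for v in groups.values()}


class TestBuildGeneAlleles:
    def test_single_site_forced_partition(self):
        geno = pd.DataFrame({"01:100": [0, 2, 2]}, index=["A", "B", "C"])
        cat = build_gene_alleles("G1", [_mk_variant()], geno)
        assert cat.assignments == {"A": "Ref", "B": "Alt1", "C": "Alt1"}
        assert cat.carrier_counts == {"Ref": 1, "Alt1": 2}

    def test_distinct_tuples_distinct_alleles(self):
        geno = pd.DataFrame(
            {"01:100": [0, 2, 2], "01:200": [0, 0, 2]}, index=["A", "B", "C"]
        )
        vs = [_mk_variant(pos=100), _mk_variant(pos=200)]
        cat = build_gene_alleles("G1", vs, geno)
        assert len(cat.allele_states) == 3
        assert cat.assignments["A"] == "Ref"
        assert cat.assignments["B"] != cat.assignments["C"]

    def test_labels_ordered_by_descending_carrier_count(self):
        geno = pd.DataFrame({"01:100": [2, 2, 2], "01:200": [0, 2, 2]},
                            index=["A", "B", "C"])
        vs = [_mk_variant(pos=100), _mk_variant(pos=200)]
        cat = build_gene_alleles("G1", vs, geno)
        assert cat.carrier_counts["Alt1"] == 2  # (1,1) carried twice
        assert cat.carrier_counts["Alt2"] == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_tuple_grouping(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_acc = rng.integers(1, 11), rng.integers(2, 51)
        accs = [f"a{i}" for i in range(n_acc)]
        sites = [f"01:{100 + i}" for i in range(n_sites)]
        geno = pd.DataFrame(
            rng.choice([0, 2], size=(n_acc, n_sites)), index=accs, columns=sites
        )
        vs = [_mk_variant(pos=100 + i) for i in range(n_sites)]
        cat = build_gene_alleles("G1", vs, geno)
        got = {
            frozenset(a for a, l in cat.assignments.items() if l == lab): n
            for lab, n in cat.carrier_counts.items()
        }
        assert got == _brute_force_partition(geno)
        assert sum(cat.carrier_counts.values()) == n_acc  # partition

    def test_site_order_invariance(self, rng):
        accs = [f"a{i}" for i in range(20)]
        sites = [f"01:{100 + i}" for i in range(4)]
        geno = pd.DataFrame(rng.choice([0, 2], (20, 4)), index=accs, columns=sites)
        vs = [_mk_variant(pos=100 + i) for i in range(4)]
        cat1 = build_gene_alleles("G1", vs, geno)
        cat2 = build_gene_alleles("G1", vs[::-1], geno[sites[::-1]])
        assert cat1.assignments == cat2.assignments
        assert cat1.allele_states == cat2.allele_states

    def test_missing_site_errors(self):
        geno = pd.DataFrame({"01:100": [0, 2]}, index=["A", "B"])
        with pytest.raises(ValueError, match="lacks sites"):
            build_gene_alleles("G1", [_mk_variant(pos=999)], geno)

    def test_missing_genotypes_rejected(self):
        geno = pd.DataFrame({"01:100": [0.0, np.nan]}, index=["A", "B"])
        with pytest.raises(ValueError, match="missing"):
            build_gene_alleles("G1", [_mk_variant()], geno)


class TestFilterTestableGenes:
    @staticmethod
    def _catalog_with_carriers(n_alt: int, n_total: int = 200):
        accs = [f"a{i}" for i in range(n_total)]
        geno = pd.DataFrame(
            {"01:100": [2] * n_alt + [0] * (n_total - n_alt)}, index=accs
        )
        return build_gene_alleles("G", [_mk_variant()], geno)

    def test_threshold_inclusive_at_ten(self):
        cats = {
            "keep": self._catalog_with_carriers(12),
            "edge": self._catalog_with_carriers(10),
            "drop": self._catalog_with_carriers(9),
        }
        assert filter_testable_genes(cats, ["keep", "edge", "drop"]) == ["keep", "edge"]

    def test_gene_without_qualifying_variants_excluded(self):
        from latscan.alleles import GeneAlleleCatalog

        empty = GeneAlleleCatalog("G0", [], {"Ref": ()}, {"a": "Ref"})
        cats = {"G0": empty, "G1": self._catalog_with_carriers(20)}
        assert filter_testable_genes(cats, ["G0", "G1"]) == ["G1"]

    def test_absent_candidate_warned_and_excluded(self):
        cats = {"G1": self._catalog_with_carriers(20)}
        with pytest.warns(UserWarning, match="absent"):
            out = filter_testable_genes(cats, ["missing", "G1"])
        assert out == ["G1"]

    def test_input_order_preserved(self):
        cats = {g: self._catalog_with_carriers(30) for g in "ABC"}
        assert filter_testable_genes(cats, ["C", "A", "B"]) == ["C", "A", "B"]
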