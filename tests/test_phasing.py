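import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triohap3d import phasing, simulate


SITE = ("chr1", 100, "A", "G")


def _table(father=(), mother=(), child=()):
    return phasing.classify_snps(set(father), set(mother), set(child))


class TestClassifySNPs:
    @pytest.mark.parametrize(
        "in_father,in_mother,in_child,expected",
        [
            (True, False, True, "paternal_specific"),
            (False, True, True, "maternal_specific"),
            (True, True, True, "shared"),
            (False, False, True, "excluded"),
            (True, False, False, "paternal_specific"),  # non-transmitted
            (False, True, False, "maternal_specific"),
        ],
    )
    def test_trio_rule_table(self, in_father, in_mother, in_child, expected):
        table = _table(
            father=[SITE] if in_father else [],
            mother=[SITE] if in_mother else [],
            child=[SITE] if in_child else [],
        )
        assert table.df.category.iloc[0] == expected
        assert bool(table.df.transmitted.iloc[0]) is in_child

    def test_conflicting_alts_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            table = phasing.classify_snps(
                {("chr1", 100, "A", "G")}, set(), {("chr1", 100, "A", "T")}
            )
        assert (table.df.category == "excluded").all()

    def test_empty_child_means_no_shared(self):
        table = _table(father=[SITE], mother=[("chr1", 200, "C", "T")])
        assert set(table.df.category) == {"paternal_specific", "maternal_specific"}
        assert not table.df.transmitted.any()

    @given(st.lists(st.tuples(st.integers(0, 50), st.booleans(), st.booleans(), st.booleans())))
    @settings(deadline=None, max_examples=50)
    def test_parent_swap_symmetry(self, sites):
        father, mother, child = set(), set(), set()
        for pos, f, m, c in sites:
            site = ("chr1", pos * 10, "A", "G")
            if f:
                father.add(site)
            if m:
                mother.add(site)
            if c:
                child.add(site)
        direct = phasing.classify_snps(father, mother, child).df
        swapped = phasing.classify_snps(mother, father, child).df
        rename = {"paternal_specific": "maternal_specific", "maternal_specific": "paternal_specific"}
        assert list(swapped.category) == [rename.get(c, c) for c in direct.category]


class TestAssignFragment:
    @pytest.fixture
    def rule_lookup(self):
        # one informative site per parent, one shared site
        df = pd.DataFrame(
            [
                ("chr1", 100, "A", "G", "paternal_specific", True),
                ("chr1", 200, "C", "T", "maternal_specific", True),
                ("chr1", 300, "G", "A", "shared", True),
                ("chr1", 400, "T", "C", "paternal_specific", False),  # non-transmitted
            ],
            columns=["chrom", "pos", "ref", "alt", "category", "transmitted"],
        )
        return phasing.PhasedSNPTable(df)

    def test_rule_table_matches_exhaustive_oracle(self, rule_lookup):
        """Enumerate all (has paternal alt, has maternal alt) combinations."""
        for has_pat, has_mat in itertools.product([False, True], repeat=2):
            alleles = []
            alleles.append((100, "G" if has_pat else "A"))
            alleles.append((200, "T" if has_mat else "C"))
            label = phasing.assign_fragment({"chrom": "chr1", "alleles": tuple(alleles)}, rule_lookup)
            if has_pat and has_mat:
                expected = "conflict"
            elif has_pat:
                expected = "paternal"
            elif has_mat:
                expected = "maternal"
            else:
                expected = "unassigned"
            assert label == expected

    def test_shared_and_nontransmitted_sites_never_assign(self, rule_lookup):
        frag = {"chrom": "chr1", "alleles": ((300, "A"), (400, "C"))}
        assert phasing.assign_fragment(frag, rule_lookup) == "unassigned"

    def test_no_covered_sites_unassigned(self, rule_lookup):
        assert phasing.assign_fragment({"chrom": "chr1", "alleles": ()}, rule_lookup) == "unassigned"


class TestSplitLibrary:
    def test_error_free_assignment_matches_truth(self, small_fragments, phase_table):
        pat, mat, report = phasing.split_library(small_fragments, phase_table)
        assert report["conflict"] == 0
        assert (pat.true_hap == "paternal").all()
        assert (mat.true_hap == "maternal").all()
        assert report["paternal"] + report["maternal"] + report["unassigned"] == len(small_fragments)

    def test_empty_input(self, phase_table):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "frag_id", "true_hap", "alleles"])
        pat, mat, report = phasing.split_library(empty, phase_table)
        assert pat.empty and mat.empty
        assert all(v == 0 for v in report.values())

    def test_contact_conflict_rule(self, phase_table):
        # build one pair whose ends vote for different parents
        informative = {v[1]: (k, v[0]) for k, v in phase_table.lookup.items()}
        (chrom_p, pos_p), alt_p = informative["paternal"]
        (chrom_m, pos_m), alt_m = informative["maternal"]
        pairs = pd.DataFrame(
            {
                "chromA": [chrom_p], "posA": [pos_p],
                "chromB": [chrom_m], "posB": [pos_m],
                "allelesA": [((pos_p, alt_p),)], "allelesB": [((pos_m, alt_m),)],
            }
        )
        tagged = phasing.assign_contacts(pairs, phase_table)
        assert tagged.label.iloc[0] == "conflict"


class TestSNPDensity:
    def test_identical_lists_zero(self):
        score = phasing.snp_density_difference([10, 20], [10, 20], ("chr1", 0, 100), 50)
        assert score.total == 0

    @pytest.mark.parametrize(
        "pat,mat,bins,expected",
        [
            ([0, 1, 2, 3, 4], [60, 61, 62, 63, 64], 50, 10),  # [5,0] vs [0,5]
            ([1, 2, 3], [4], 100, 2),  # single bin, 3 vs 1
        ],
    )
    def test_hand_sums(self, pat, mat, bins, expected):
        score = phasing.snp_density_difference(pat, mat, ("chr1", 0, 100), bins)
        assert score.total == expected
        assert score.total == score.bins.difference.sum()

    def test_invalid_region_or_bin(self):
        with pytest.raises(ValueError):
            phasing.snp_density_difference([], [], ("chr1", 100, 50), 10)
        with pytest.raises(ValueError):
            phasing.snp_density_difference([], [], ("chr1", 0, 100), 0)
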