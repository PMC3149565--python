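import numpy as np
import pytest

from empaiq.annotation import (
    DEFAULT_CATEGORIES,
    EMBOSS_PK,
    UNMAPPED_CATEGORY,
    assign_category,
    category_fold_change,
    category_profile,
    distribution_bins,
    net_charge,
    protein_mw,
    protein_pi,
)
from oracles import charge_oracle, pi_oracle
from conftest import random_protein


class TestCategories:
    def test_unmapped_accession_gets_no_description(self):
        assert assign_category("ghost", {"p1": "translation"}) == UNMAPPED_CATEGORY

    def test_mapped_accessions_stay_in_configured_set(self, rng):
        go_map = {f"p{i}": DEFAULT_CATEGORIES[int(rng.integers(10))] for i in range(50)}
        for acc in go_map:
            assert assign_category(acc, go_map) in DEFAULT_CATEGORIES

    def test_profile_counts_match_construction(self, rng):
        go_map = {}
        planted = {c: 0 for c in DEFAULT_CATEGORIES}
        for i in range(120):
            c = DEFAULT_CATEGORIES[int(rng.integers(10))]
            go_map[f"p{i}"] = c
            planted[c] += 1
        prof = category_profile(list(go_map), go_map)
        for c in DEFAULT_CATEGORIES:
            assert prof.counts[c] == planted[c]
        assert sum(prof.counts.values()) == prof.n_total == 120

    def test_rounded_percentage_matches_reported_style(self):
        go_map = {f"p{i}": "biosynthetic process" for i in range(34)}
        accs = [f"p{i}" for i in range(224)]  # 190 unmapped
        prof = category_profile(accs, go_map)
        assert round(prof.percentages["biosynthetic process"]) == 15

    def test_single_category_set(self):
        prof = category_profile(["a", "b"], {"a": "glycolysis", "b": "glycolysis"})
        assert prof.percentages["glycolysis"] == 100.0
        assert all(v == 0.0 for c, v in prof.percentages.items() if c != "glycolysis")

    def test_percentages_sum_to_100(self, rng):
        go_map = {f"p{i}": DEFAULT_CATEGORIES[int(rng.integers(10))] for i in range(77)}
        prof = category_profile(list(go_map), go_map)
        assert sum(prof.percentages.values()) == pytest.approx(100.0, abs=0.1)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            category_profile([], {})

    def test_profile_invariant_under_relabeling(self, rng):
        cats = [DEFAULT_CATEGORIES[int(rng.integers(10))] for _ in range(40)]
        m1 = {f"x{i}": c for i, c in enumerate(cats)}
        m2 = {f"y{i}": c for i, c in enumerate(cats)}
        p1 = category_profile(list(m1), m1)
        p2 = category_profile(list(m2), m2)
        assert p1.counts == p2.counts


class TestFoldChange:
    def _profile(self, pct_map, n=100):
        go_map, accs = {}, []
        i = 0
        for cat, pct in pct_map.items():
            for _ in range(int(pct * n / 100)):
                go_map[f"p{i}"] = cat
                accs.append(f"p{i}")
                i += 1
        return category_profile(accs, go_map)

    def test_identical_profiles_give_unit_ratios(self):
        p = self._profile({"translation": 50, "transport": 50})
        fc = category_fold_change(p, p)
        assert fc["translation"] == pytest.approx(1.0)
        assert fc["transport"] == pytest.approx(1.0)

    def test_doubled_percentage_gives_ratio_two(self):
        pb = self._profile({"translation": 20, "other": 80})
        pa = self._profile({"translation": 10, "other": 90})
        assert category_fold_change(pb, pa)["translation"] == pytest.approx(2.0)

    def test_reciprocity(self):
        pb = self._profile({"translation": 30, "transport": 70})
        pa = self._profile({"translation": 60, "transport": 40})
        fab = category_fold_change(pa, pb)
        fba = category_fold_change(pb, pa)
        for c in ("translation", "transport"):
            assert fab[c] == pytest.approx(1.0 / fba[c])

    def test_zero_denominator_flagged_not_infinite(self):
        pb = self._profile({"translation": 100})
        pa = self._profile({"transport": 100})
        fc = category_fold_change(pb, pa)
        assert fc["translation"] is None


class TestIsoelectricPoint:
    def test_basic_exceeds_acidic(self):
        assert protein_pi("KKKKKKKK") > protein_pi("DDDDDDDD")

    def test_charge_at_pi_is_zero(self):
        seq = "MKTAYIAKQRDE"
        pi = protein_pi(seq, tol=1e-6)
        assert abs(net_charge(seq, pi)) < 1e-3

    def test_twentymer_matches_independent_root_finder(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert protein_pi(seq) == pytest.approx(pi_oracle(seq, EMBOSS_PK), abs=0.02)

    def test_oracle_equivalence_on_random_proteins(self, rng):
        for _ in range(100):
            seq = random_protein(rng, int(rng.integers(30, 120)))
            assert protein_pi(seq) == pytest.approx(pi_oracle(seq, EMBOSS_PK), abs=0.02)

    def test_charge_equation_agrees_with_oracle(self, rng):
        for _ in range(20):
            seq = random_protein(rng, 50)
            ph = float(rng.uniform(1, 13))
            assert net_charge(seq, ph) == pytest.approx(charge_oracle(seq, ph, EMBOSS_PK), rel=1e-12)


class TestMolecularWeight:
    def test_diglycine(self):
        assert protein_mw("GG") == pytest.approx(132.12, abs=0.05)

    def test_strictly_increasing_with_length(self, rng):
        seq = random_protein(rng, 30)
        grown = seq
        for aa in "AGW":
            longer = grown + aa
            assert protein_mw(longer) > protein_mw(grown)
            grown = longer

    def test_matches_biopython_calculator(self, rng):
        from Bio.SeqUtils import molecular_weight

        for _ in range(100):
            seq = random_protein(rng, 100)
            assert protein_mw(seq) == pytest.approx(
                molecular_weight(seq, seq_type="protein"), abs=0.1
            )


class TestDistributionBins:
    def test_all_in_one_bin(self):
        counts, pct = distribution_bins([1.1, 1.2, 1.3], [0, 1, 2, 3])
        assert list(counts) == [0, 3, 0]
        assert pct[1] == pytest.approx(100.0)

    def test_counts_conserved(self, rng):
        vals = rng.uniform(0, 10, 200)
        counts, _ = distribution_bins(vals, np.linspace(0, 10, 11))
        assert counts.sum() == 200

    def test_matches_brute_force_tally(self, rng):
        vals = rng.uniform(0, 5, 300)
        edges = [0.0, 1.0, 2.5, 4.0, 5.0]
        counts, _ = distribution_bins(vals, edges)
        for k in range(len(edges) - 1):
            lo, hi = edges[k], edges[k + 1]
            if k == len(edges) - 2:
                brute = sum(1 for v in vals if lo <= v <= hi)
            else:
                brute = sum(1 for v in vals if lo <= v < hi)
            assert counts[k] == brute

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            distribution_bins([1.0], [0, 2, 1])
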