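"""Region definition and credible-set construction (CS1/CS2, purity)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blrfine as bf
from blrfine.assoc import LDMatrix
from blrfine.credsets import write_credsets_tsv, write_regions_tsv
from blrfine.phenosim import CausalSpec


def toy_truth(indices):
    k = len(indices)
    return CausalSpec(np.array(indices), np.ones(k), np.array(["x"] * k, dtype=object))


def ld_from(matrix, ids=None):
    vals = np.asarray(matrix, dtype=float)
    if ids is None:
        ids = np.array([f"v{i}" for i in range(len(vals))], dtype=object)
    return LDMatrix(ids=ids, values=vals)


class TestRegionsFromCausals:
    def test_interior_causal_gets_1001_snps(self):
        regs = bf.regions_from_causals(toy_truth([600]), m_total=1500)
        assert (regs[0].start_idx, regs[0].end_idx) == (100, 1100)
        assert regs[0].size == 1001

    def test_boundary_clipping(self):
        regs = bf.regions_from_causals(toy_truth([0]), m_total=1500)
        assert (regs[0].start_idx, regs[0].end_idx) == (0, 500)

    def test_two_causal_width(self):
        regs = bf.regions_from_causals(toy_truth([1200]), m_total=3000,
                                       half_width=1000)
        assert regs[0].size == 2001

    def test_region_records_contained_causals(self):
        regs = bf.regions_from_causals(toy_truth([100, 150]), m_total=1500,
                                       half_width=60)
        assert regs[0].causal_idx == (100, 150)
        assert regs[1].causal_idx == (100, 150)


class TestRegionsFromLeads:
    def _ss(self, pos, p, chrom=None):
        m = len(pos)
        return bf.SummaryStats(
            ids=np.array([f"v{i}" for i in range(m)], dtype=object),
            chrom=np.array(chrom or ["1"] * m, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            a1=np.array(["A"] * m, dtype=object), a2=np.array(["G"] * m, dtype=object),
            freq=np.full(m, 0.3), beta=np.zeros(m), se=np.ones(m),
            n=np.full(m, 100.0), p=np.array(p, dtype=float))

    def test_single_lead_window(self):
        ss = self._ss([100, 2_000_000, 3_000_000], [0.5, 1e-9, 0.5])
        regs = bf.regions_from_leads(ss)
        assert len(regs) == 1
        assert regs[0].start_bp == 1_500_000
        assert regs[0].end_bp == 2_500_000
        assert regs[0].lead_idx == 1

    def test_nearby_leads_merge(self):
        # 400 kb apart: 1 Mb windows share 600 kb > 500 kb -> merged
        ss = self._ss([2_000_000, 2_400_000, 9_000_000],
                      [1e-9, 1e-10, 0.5])
        regs = bf.regions_from_leads(ss)
        assert len(regs) == 1
        assert regs[0].lead_idx == 1  # most significant lead kept

    def test_distant_leads_stay_separate(self):
        ss = self._ss([2_000_000, 4_000_000], [1e-9, 1e-9])
        regs = bf.regions_from_leads(ss)
        # clumping keeps both leads (2 Mb apart); windows do not overlap
        assert len(regs) == 2

    def test_no_significant_snps_empty(self):
        ss = self._ss([1000, 2000], [0.5, 0.2])
        assert bf.regions_from_leads(ss) == []


class TestCS1:
    def test_first_element_suffices(self):
        s = bf.cs1(np.array([0.95, 0.03, 0.02]))
        assert list(s.variant_idx) == [0]
        assert s.cum_pip == pytest.approx(0.95)

    def test_greedy_accumulation(self):
        s = bf.cs1(np.array([0.5, 0.3, 0.15, 0.05]))
        assert list(s.variant_idx) == [0, 1, 2]
        assert s.cum_pip == pytest.approx(0.95)

    def test_insufficient_mass_returns_none(self):
        assert bf.cs1(np.array([0.3, 0.2, 0.1])) is None

    def test_tie_break_by_index(self):
        s = bf.cs1(np.array([0.45, 0.45, 0.45]))
        assert list(s.variant_idx) == [0, 1]

    def test_invalid_pips_rejected(self):
        with pytest.raises(ValueError):
            bf.cs1(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
           st.floats(0.1, 0.99))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_minimality(self, pips, coverage):
        # removing the lowest-PIP member must drop below coverage
        pips = np.array(pips)
        s = bf.cs1(pips, coverage=coverage)
        if s is None:
            assert pips.sum() < coverage
        else:
            assert s.cum_pip >= coverage
            assert s.cum_pip - s.pips.min() < coverage


class TestCS2:
    def test_high_pip_singleton(self):
        B = ld_from(np.eye(3))
        sets = bf.cs2(np.array([0.92, 0.01, 0.01]), B)
        assert len(sets) == 1
        assert sets[0].size == 1
        assert list(sets[0].variant_idx) == [0]

    def test_ld_partner_grouped(self):
        # seed 0.5 with an r2=0.6 partner at 0.45 -> one set of two
        r = np.sqrt(0.6)
        B = ld_from([[1, r, 0], [r, 1, 0], [0, 0, 1]])
        sets = bf.cs2(np.array([0.5, 0.45, 0.01]), B)
        assert len(sets) == 1
        assert sorted(sets[0].variant_idx) == [0, 1]
        assert sets[0].cum_pip == pytest.approx(0.95)

    def test_weak_ld_partner_not_groupable(self):
        r = np.sqrt(0.3)
        B = ld_from([[1, r, 0], [r, 1, 0], [0, 0, 1]])
        sets = bf.cs2(np.array([0.5, 0.45, 0.01]), B)
        assert sets == []

    def test_singleton_emission_precedes_grouping(self):
        # the 0.91 variant must come out as a singleton even though it is in
        # perfect LD with the 0.5 variant
        B = ld_from([[1, 0.9, 0], [0.9, 1, 0], [0, 0, 1]])
        sets = bf.cs2(np.array([0.91, 0.5, 0.01]), B)
        assert sets[0].size == 1 and sets[0].variant_idx[0] == 0

    def test_pip_floor_drops_variants(self):
        B = ld_from(np.eye(2))
        sets = bf.cs2(np.array([0.95, 0.0005]), B, pip_floor=0.001)
        assert len(sets) == 1
        assert list(sets[0].variant_idx) == [0]

    def test_sets_disjoint_and_covering(self):
        rng = np.random.default_rng(31)
        G = bf.simulate_genotypes(2000, 30, ld_rho=0.8, seed=32)
        W = bf.scale_genotypes(G)
        B = bf.compute_ld(W)
        pips = rng.beta(0.2, 1.0, size=30)
        sets = bf.cs2(pips, B)
        seen = set()
        for s in sets:
            assert s.cum_pip >= 0.9
            members = set(int(v) for v in s.variant_idx)
            assert not (members & seen)
            seen |= members


class TestPurity:
    def test_singleton_absent(self):
        B = ld_from(np.eye(2))
        cs = bf.CredibleSet(variant_idx=np.array([0]), pips=np.array([0.95]),
                            cum_pip=0.95)
        assert bf.purity(cs, B) is None

    def test_absolute_value_of_negative_correlation(self):
        B = ld_from([[1, -0.9], [-0.9, 1]])
        cs = bf.CredibleSet(variant_idx=np.array([0, 1]),
                            pips=np.array([0.5, 0.45]), cum_pip=0.95)
        assert bf.purity(cs, B) == pytest.approx(0.9)
        assert cs.purity_r2 == pytest.approx(0.81)

    def test_duplicated_variants_perfect_purity(self):
        B = ld_from(np.ones((3, 3)))
        cs = bf.CredibleSet(variant_idx=np.array([0, 1, 2]),
                            pips=np.array([0.4, 0.3, 0.25]), cum_pip=0.95)
        assert bf.purity(cs, B) == pytest.approx(1.0)

    def test_large_set_subsample_is_seeded(self):
        m = 150
        G = bf.simulate_genotypes(500, m, ld_rho=0.9, seed=33)
        B = bf.compute_ld(bf.scale_genotypes(G))
        cs = bf.CredibleSet(variant_idx=np.arange(m),
                            pips=np.full(m, 1.0 / m), cum_pip=1.0)
        a = bf.purity(cs, B, max_snps=100, seed=5)
        b = bf.purity(cs, B, max_snps=100, seed=5)
        assert a == b


def test_region_and_credset_tables_roundtrip(tmp_path):
    regs = bf.regions_from_causals(toy_truth([10]), m_total=100, half_width=5)
    write_regions_tsv(regs, tmp_path / "regions.tsv")
    sets = [bf.CredibleSet(variant_idx=np.array([1, 2]),
                           pips=np.array([0.6, 0.35]), cum_pip=0.95,
                           region_id="region0")]
    write_credsets_tsv(sets, tmp_path / "cs.tsv")
    import pandas as pd
    cs = pd.read_csv(tmp_path / "cs.tsv", sep="\t")
    assert list(cs["variant"]) == [1, 2]
    assert cs["cum_pip"].iloc[-1] == pytest.approx(0.95)
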