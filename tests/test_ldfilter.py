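import numpy as np
import pytest
from scipy import stats

from hapforge.ibd import AnchorMap
from hapforge.ldfilter import (
    PASS_LLD,
    PASS_UNASSESSED,
    REJECT,
    fisher_exact_2x2,
    ld_filter,
    ld_pvalue,
)

from .conftest import make_site


def _hom(v):
    return np.stack([v, v], axis=-1).astype(np.int8)


class TestFisherExact:
    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            t = rng.integers(0, 15, size=(2, 2))
            expected = stats.fisher_exact(t)[1]
            got = fisher_exact_2x2(t[0, 0], t[0, 1], t[1, 0], t[1, 1])
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_vectorized_matches_scalar(self, rng):
        t = rng.integers(0, 12, size=(50, 4))
        got = fisher_exact_2x2(t[:, 0], t[:, 1], t[:, 2], t[:, 3])
        for i in range(50):
            exp = stats.fisher_exact(t[i].reshape(2, 2))[1]
            assert got[i] == pytest.approx(exp, rel=1e-6, abs=1e-12)

    def test_perfect_association_closed_form(self):
        # AB=20, ab=20: two-sided P = 2 / C(40,20)
        p = fisher_exact_2x2(20, 0, 0, 20)
        assert p == pytest.approx(2 / 137846528820, rel=1e-9)


class TestLdPvalue:
    def _vectors(self, n=50, match=True, rng=None):
        rng = rng or np.random.default_rng(0)
        a = rng.integers(0, 2, size=n)
        b = a.copy() if match else rng.integers(0, 2, size=n)
        return _hom(a), _hom(b)

    def test_too_close_untestable(self):
        g1, g2 = self._vectors()
        assert ld_pvalue(g1, g2, ("1", 1000), ("1", 3000)) is None

    def test_different_chromosomes_always_far_enough(self):
        g1, g2 = self._vectors()
        assert ld_pvalue(g1, g2, ("1", 1000), ("2", 1000)) is not None

    def test_too_few_common_taxa_untestable(self):
        g1, g2 = self._vectors(n=50)
        g2[:11] = -1  # only 39 common nonmissing
        assert ld_pvalue(g1, g2, ("1", 1000), ("1", 10_000)) is None

    def test_too_few_minor_carriers_untestable(self):
        g1 = _hom(np.zeros(50, dtype=int))
        g1[0] = (1, 1)  # single minor carrier
        g2 = _hom(np.r_[np.ones(25, dtype=int), np.zeros(25, dtype=int)])
        assert ld_pvalue(g1, g2, ("1", 1000), ("1", 10_000)) is None

    def test_symmetric_and_label_swap_invariant(self, rng):
        g1 = _hom(rng.integers(0, 2, size=60))
        g2 = _hom(rng.integers(0, 2, size=60))
        args = (("1", 1000), ("1", 500_000))
        p12 = ld_pvalue(g1, g2, *args)
        p21 = ld_pvalue(g2, g1, args[1], args[0])
        assert p12 == pytest.approx(p21, rel=1e-9)
        # swapping allele labels at one site flips rows of the 2x2 table
        p_swap = ld_pvalue(_hom(1 - g1[..., 0]), g2, *args)
        assert p_swap == pytest.approx(p12, rel=1e-9)

    def test_heterozygotes_count_as_minor_homozygotes(self):
        v = np.r_[np.ones(20, dtype=int), np.zeros(30, dtype=int)]
        g1, g2 = _hom(v), _hom(v)
        g1_het = g1.copy()
        g1_het[:20] = (0, 1)  # hets instead of minor homs
        args = (("1", 1000), ("1", 10_000))
        assert ld_pvalue(g1_het, g2, *args) == pytest.approx(
            ld_pvalue(g1, g2, *args), rel=1e-9
        )


def _anchor(genos, positions, chroms=None):
    n_sites, n_taxa = genos.shape[:2]
    if chroms is None:
        chroms = ["1"] * n_sites
    return AnchorMap(
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        taxa=[f"t{i}" for i in range(n_taxa)],
        genotypes=genos.astype(np.int8),
    )


class TestLdFilter:
    def test_low_maf_site_passes_unassessed(self, rng):
        n = 50
        site_g = [(0, 0)] * (n - 1) + [(1, 1)]  # 1 minor carrier < min_minor
        site = make_site(site_g, pos=500_000)
        anchor = _anchor(_hom(rng.integers(0, 2, size=(30, n))), np.arange(30) * 20_000 + 1)
        verdict, hits = ld_filter(site, anchor)
        assert verdict == PASS_UNASSESSED
        assert hits == []

    def test_weak_best_hit_rejected(self, rng):
        n = 50
        v = rng.integers(0, 2, size=n)
        site = make_site([(int(x), int(x)) for x in v], pos=500_000)
        # uncorrelated anchor: best P will be far above 1e-6
        anchor = _anchor(_hom(rng.integers(0, 2, size=(40, n))), np.arange(40) * 20_000 + 1)
        verdict, hits = ld_filter(site, anchor)
        assert verdict == REJECT
        assert hits[0].pvalue > 1e-6

    def test_local_perfect_ld_flagged_lld(self, rng):
        n = 60
        v = rng.integers(0, 2, size=n)
        site = make_site([(int(x), int(x)) for x in v], pos=500_000)
        genos = _hom(rng.integers(0, 2, size=(40, n)))
        genos[10] = _hom(v)  # perfect local hit at 10*20kb+1 = 200_001
        anchor = _anchor(genos, np.arange(40) * 20_000 + 1)
        verdict, hits = ld_filter(site, anchor)
        assert verdict == PASS_LLD
        assert hits[0].anchor_pos == 200_001

    def test_nonlocal_only_ld_rejected(self, rng):
        n = 60
        v = rng.integers(0, 2, size=n)
        site = make_site([(int(x), int(x)) for x in v], chrom="1", pos=500_000)
        genos = _hom(rng.integers(0, 2, size=(40, n)))
        genos[10] = _hom(v)  # perfect hit, but on another chromosome
        anchor = _anchor(genos, np.arange(40) * 20_000 + 1, chroms=["2"] * 40)
        verdict, _ = ld_filter(site, anchor)
        assert verdict == REJECT

    def test_local_hit_within_factor_of_nonlocal_best(self, rng):
        n = 60
        v = rng.integers(0, 2, size=n)
        w = v.copy()
        w[:2] = 1 - w[:2]  # near-perfect local correlate
        site = make_site([(int(x), int(x)) for x in v], chrom="1", pos=500_000)
        genos = _hom(rng.integers(0, 2, size=(40, n)))
        genos[5] = _hom(v)  # perfect nonlocal hit (chrom 2)
        genos[20] = _hom(w)  # strong local hit
        chroms = ["2"] * 10 + ["1"] * 30
        anchor = _anchor(genos, np.arange(40) * 20_000 + 1, chroms=chroms)
        verdict, hits = ld_filter(site, anchor)
        best = hits[0]
        assert best.anchor_chrom == "2"
        local = [h for h in hits if h.anchor_chrom == "1"]
        if local and local[0].pvalue < 10 * best.pvalue:
            assert verdict == PASS_LLD

    def test_lld_implies_testable_local_hit(self, rng):
        from hapforge.ldfilter import DEFAULT_LOCAL_RADIUS

        n = 60
        for seed in range(5):
            r = np.random.default_rng(seed)
            v = r.integers(0, 2, size=n)
            site = make_site([(int(x), int(x)) for x in v], pos=400_000)
            genos = _hom(r.integers(0, 2, size=(50, n)))
            genos[7] = _hom(v)
            anchor = _anchor(genos, np.arange(50) * 15_000 + 1)
            verdict, hits = ld_filter(site, anchor)
            if verdict == PASS_LLD:
                assert any(
                    h.is_local(site.chrom, site.pos, DEFAULT_LOCAL_RADIUS) for h in hits
                )
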