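import itertools

import numpy as np
import pandas as pd
import pytest

from demres.popgen import (
    GenotypeMatrix,
    dxy,
    great_circle_km,
    maf_filter,
    pop_site_pi,
    site_pi,
    wc_fst,
    window_average,
)


def _matrix(geno, pops, positions=None):
    geno = np.asarray(geno, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, geno.shape[0] + 1) * 100
    samples = [f"s{i}" for i in range(geno.shape[1])]
    return GenotypeMatrix(
        chrom="chr1",
        positions=np.asarray(positions),
        genotypes=geno,
        samples=samples,
        pops=np.asarray(pops, dtype=object),
    )


class TestSitePi:
    def test_exhaustive_enumeration_oracle(self):
        # brute force: fraction of differing haplotype pairs among all C(n,2)
        for n in range(2, 9):
            for a in range(0, n + 1):
                hap = [1] * a + [0] * (n - a)
                pairs = list(itertools.combinations(hap, 2))
                brute = sum(x != y for x, y in pairs) / len(pairs)
                assert site_pi(a, n - a) == pytest.approx(brute)

    def test_boundary_values(self):
        assert site_pi(0, 4) == 0.0
        assert site_pi(1, 1) == 1.0
        assert np.isnan(site_pi(1, 0))

    def test_vectorised_matches_scalar(self):
        G = _matrix([[0, 1, 2], [2, 2, 2], [0, 0, 1]], ["p1"] * 3)
        pi = pop_site_pi(G, "p1")
        # alt counts: 3/6, 6/6, 1/6
        np.testing.assert_allclose(
            pi, [site_pi(3, 3), site_pi(6, 0), site_pi(1, 5)]
        )


class TestMafFilter:
    def test_boundary_convention(self):
        # 100 chromosomes; 1 alt (MAF .01) removed, 2 alt (MAF .02) kept
        g1 = np.zeros((2, 50), dtype=np.int8)
        g1[0, 0] = 1  # singleton
        g1[1, 0] = 2  # doubleton
        G = _matrix(g1, ["p1"] * 50)
        kept = maf_filter(G, 0.02)
        assert list(kept.positions) == [200]

    def test_monomorphic_removed(self):
        G = _matrix([[0, 0, 0], [2, 2, 2], [1, 0, 0]], ["p1"] * 3)
        kept = maf_filter(G, 0.02)
        assert kept.n_sites == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        G = _matrix(rng.integers(0, 3, (50, 20)), ["p1"] * 20)
        once = maf_filter(G, 0.05)
        twice = maf_filter(once, 0.05)
        np.testing.assert_array_equal(once.positions, twice.positions)


class TestWindowAverage:
    def test_mean_in_single_window(self):
        w = window_average(np.array([5000, 9999]), np.array([0.2, 0.4]), 10_000)
        assert w.loc[0, "value"] == pytest.approx(0.3)
        assert w.loc[0, "n_sites"] == 2

    def test_half_open_boundary(self):
        w = window_average(np.array([10_000]), np.array([1.0]), 10_000)
        assert w.loc[0, "n_sites"] == 0 and w.loc[1, "n_sites"] == 1

    def test_empty_window_is_missing(self):
        w = window_average(
            np.array([25_000]), np.array([0.5]), 10_000, chrom_length=30_000
        )
        assert np.isnan(w.loc[0, "value"]) and w.loc[2, "value"] == 0.5


class TestWcFst:
    def test_complete_fixation_is_one(self):
        g = np.vstack([np.concatenate([np.full(10, 2), np.full(10, 0)])] * 5)
        G = _matrix(g, ["A"] * 10 + ["B"] * 10)
        _, theta = wc_fst(G, "A", "B")
        assert theta == pytest.approx(1.0)

    def test_pooled_then_split_population_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 3000)
        g = rng.binomial(2, p[:, None], size=(3000, 40)).astype(np.int8)
        G = _matrix(g, ["A"] * 20 + ["B"] * 20)
        _, theta = wc_fst(G, "A", "B")
        assert abs(theta) < 0.01

    def test_matches_loop_reference_implementation(self):
        # independent per-site evaluation of the 1984 variance components
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, (40, 12)).astype(np.int8)
        g[rng.random((40, 12)) < 0.1] = -1
        G = _matrix(g, ["A"] * 6 + ["B"] * 6)
        per_site, theta = wc_fst(G, "A", "B")
        num = den = 0.0
        for i in range(40):
            comps = []
            for cols in (range(6), range(6, 12)):
                gi = [g[i, j] for j in cols if g[i, j] >= 0]
                if len(gi) < 2:
                    comps = None
                    break
                n = len(gi)
                p = sum(gi) / (2 * n)
                h = sum(1 for x in gi if x == 1) / n
                comps.append((n, p, h))
            if comps is None:
                assert not per_site.loc[i, "used"]
                continue
            (n1, p1, h1), (n2, p2, h2) = comps
            r = 2
            nbar = (n1 + n2) / r
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            if pbar in (0.0, 1.0):
                assert not per_site.loc[i, "used"]
                continue
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = nbar / nc * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
            b = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2
            num += a
            den += a + b + c
            assert per_site.loc[i, "a"] == pytest.approx(a)
        assert theta == pytest.approx(num / den)


class TestDxy:
    def test_fixed_difference(self):
        G = _matrix([[2, 2, 0, 0]], ["A", "A", "B", "B"])
        d, _ = dxy(G, "A", "B")
        assert d[0] == pytest.approx(1.0)

    def test_half_half(self):
        G = _matrix([[1, 1, 1, 1]], ["A", "A", "B", "B"])
        d, _ = dxy(G, "A", "B")
        assert d[0] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        G = _matrix([[0, 0, 0, 0]], ["A", "A", "B", "B"])
        d, _ = dxy(G, "A", "B")
        assert d[0] == 0.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        G = _matrix(rng.integers(0, 3, (200, 10)), ["A"] * 5 + ["B"] * 5)
        d1, _ = dxy(G, "A", "B")
        d2, _ = dxy(G, "B", "A")
        np.testing.assert_allclose(d1, d2)
        assert np.nanmin(d1) >= 0.0 and np.nanmax(d1) <= 1.0


class TestGreatCircle:
    def test_quarter_circumference(self):
        assert great_circle_km(0, 0, 0, 90) == pytest.approx(np.pi * 6371 / 2, rel=1e-6)

    def test_identity_and_symmetry(self):
        assert great_circle_km(12.5, 100.0, 12.5, 100.0) == 0.0
        assert great_circle_km(5, 10, -40, 170) == pytest.approx(
            great_circle_km(-40, 170, 5, 10)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_km(95.0, 0.0, 0.0, 0.0)
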