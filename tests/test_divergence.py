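"""FST/DXY estimators against textbook oracles; window makers; p-distances."""

import numpy as np
import pandas as pd
import pytest

from popgenscan import (
    GenomeLayout,
    genome_fst,
    nonoverlapping_windows,
    p_distance_matrix,
    site_fst,
    site_variance_components,
    sliding_windows,
    window_divergence,
)
from popgenscan.divergence import mean_nonnegative_fst

from conftest import make_gm


def wc84_oracle(n1, p1, h1, n2, p2, h2):
    """Scalar Weir-Cockerham (1984) two-population components, written
    straight from the published estimator definitions (independent of the
    vectorised implementation)."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestSiteComponents:
    def test_fixed_difference_gives_fst_one(self):
        # p=1 vs p=0, 10 diploids each, no hets
        a, b, c = site_variance_components(10, 1.0, 0.0, 10, 0.0, 0.0)
        assert a / (a + b + c) == pytest.approx(1.0, abs=1e-6)

    def test_identical_populations_nonpositive(self):
        a, b, c = site_variance_components(10, 0.4, 0.48, 10, 0.4, 0.48)
        assert a <= 0
        assert a / (a + b + c) <= 0

    def test_matches_textbook_oracle_on_spec_counts(self):
        # pop1: 12 ref / 8 alt alleles of 10 diploids; pop2: 4 ref / 16 alt
        # with explicit genotype configurations fixing the het proportions
        pop1 = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0])  # 8 alt, 8 hets
        pop2 = np.array([2, 2, 2, 2, 2, 2, 1, 1, 1, 1])  # 16 alt, 4 hets
        n1, p1, h1 = 10, pop1.sum() / 20, (pop1 == 1).mean()
        n2, p2, h2 = 10, pop2.sum() / 20, (pop2 == 1).mean()
        a, b, c = site_variance_components(n1, p1, h1, n2, p2, h2)
        oa, ob, oc = wc84_oracle(n1, p1, h1, n2, p2, h2)
        assert (a, b, c) == pytest.approx((oa, ob, oc), rel=1e-12)

    def test_matches_oracle_on_random_sites(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n1, n2 = rng.integers(2, 30, size=2)
            p1, p2 = rng.uniform(0, 1, size=2)
            h1 = rng.uniform(0, min(2 * p1 * (1 - p1) + 0.2, 1.0))
            h2 = rng.uniform(0, min(2 * p2 * (1 - p2) + 0.2, 1.0))
            got = site_variance_components(n1, p1, h1, n2, p2, h2)
            want = wc84_oracle(n1, p1, h1, n2, p2, h2)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_underpowered_site_skipped(self):
        a, _, _ = site_variance_components(1, 1.0, 0.0, 10, 0.0, 0.0)
        assert np.isnan(a)


class TestWindowDivergence:
    def test_window_equals_sitewise_accumulation(self, two_pop_gm):
        """Ratio-of-sums window FST equals brute-force accumulation of the
        per-site components; DXY equals the per-site mean."""
        gm, layout = two_pop_gm
        windows = sliding_windows(layout, size=2_000_000, step=2_000_000, min_sites=1)
        stats = window_divergence(gm, "A", "B", windows)
        per_site = site_fst(gm, "A", "B")
        lg = gm.sites["lg"].to_numpy()
        pos0 = gm.sites["pos"].to_numpy() - 1
        row = stats.iloc[3]
        sel = (lg == row.lg) & (pos0 >= row.start) & (pos0 < row.end)
        sel &= ~np.isnan(per_site["a"].to_numpy()) & ~np.isnan(per_site["dxy"].to_numpy())
        a = per_site["a"][sel].sum()
        den = (per_site["a"] + per_site["b"] + per_site["c"])[sel].sum()
        assert row.fst == pytest.approx(a / den, rel=1e-12)
        assert row.dxy == pytest.approx(per_site["dxy"][sel].mean(), rel=1e-12)
        assert row.n_sites == int(sel.sum())

    def test_symmetry_in_population_order(self, two_pop_gm):
        gm, layout = two_pop_gm
        windows = sliding_windows(layout, size=5_000_000, step=5_000_000, min_sites=1)
        ab = window_divergence(gm, "A", "B", windows)
        ba = window_divergence(gm, "B", "A", windows)
        assert np.allclose(ab["fst"], ba["fst"])
        assert np.allclose(ab["dxy"], ba["dxy"])

    def test_monomorphic_window_dxy_zero(self):
        d = np.zeros((8, 5), dtype=np.int8)
        gm = make_gm(d, populations=["A"] * 4 + ["B"] * 4)
        windows = pd.DataFrame({"lg": ["LG01"], "start": [0], "end": [10_000]})
        stats = window_divergence(gm, "A", "B", windows, min_sites=1)
        assert stats["dxy"].iat[0] == 0.0

    def test_single_fixed_difference_dxy(self):
        d = np.zeros((8, 5), dtype=np.int8)
        d[4:, 0] = 2  # one fixed difference among 5 sites
        gm = make_gm(d, populations=["A"] * 4 + ["B"] * 4)
        windows = pd.DataFrame({"lg": ["LG01"], "start": [0], "end": [10_000]})
        stats = window_divergence(gm, "A", "B", windows, min_sites=1)
        assert stats["dxy"].iat[0] == pytest.approx(1 / 5)
        assert stats["n_sites"].iat[0] == 5

    def test_min_sites_omits_sparse_windows(self, two_pop_gm):
        gm, layout = two_pop_gm
        windows = sliding_windows(layout, size=100_000, step=100_000, min_sites=10_000)
        stats = window_divergence(gm, "A", "B", windows)
        assert len(stats) == 0


class TestWindowMakers:
    def test_sliding_hand_enumeration(self):
        layout = GenomeLayout(("LG1",), (1_500_000,))
        w = sliding_windows(layout, size=1_000_000, step=100_000)
        assert len(w) == 6
        assert w["start"].tolist() == [0, 100_000, 200_000, 300_000, 400_000, 500_000]
        assert (w["end"] - w["start"] == 1_000_000).all()

    def test_short_lg_yields_single_truncated_window(self):
        layout = GenomeLayout(("LG1",), (400_000,))
        w = sliding_windows(layout, size=1_000_000, step=100_000)
        assert len(w) == 1
        assert (w["start"].iat[0], w["end"].iat[0]) == (0, 400_000)

    def test_step_equals_size_tiles(self):
        layout = GenomeLayout(("LG1",), (1_000_000,))
        w = sliding_windows(layout, size=100_000, step=100_000)
        assert len(w) == 10
        assert w["start"].tolist() == list(range(0, 1_000_000, 100_000))

    def test_nonoverlapping_bins(self):
        layout = GenomeLayout(("LG1",), (1_000_000,))
        w = nonoverlapping_windows(layout, size=100_000)
        assert w["bin"].tolist() == list(range(10))

    def test_min_sites_zero_retains_all_tiles(self, two_pop_gm):
        gm, layout = two_pop_gm
        w = nonoverlapping_windows(layout, size=100_000, min_sites=0)
        stats = window_divergence(gm, "A", "B", w, min_sites=0)
        # every tile containing at least one usable site is reported
        assert (stats["n_sites"] >= 1).all()

    def test_size_smaller_than_step_rejected(self):
        layout = GenomeLayout(("LG1",), (1_000_000,))
        with pytest.raises(ValueError):
            sliding_windows(layout, size=50_000, step=100_000)


class TestGenomeFst:
    def test_negative_window_removal_arithmetic(self):
        assert mean_nonnegative_fst(np.array([0.2, 0.4, -0.1])) == pytest.approx(0.3)

    def test_single_window(self):
        assert mean_nonnegative_fst(np.array([0.25])) == pytest.approx(0.25)

    def test_all_negative_is_undefined(self):
        assert np.isnan(mean_nonnegative_fst(np.array([-0.2, -0.01])))

    def test_identical_populations_undefined_or_zero(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(6, 400)).astype(np.int8)
        dup = np.vstack([d, d])  # population B duplicates population A
        layout = GenomeLayout(("LG01",), (400_000,))
        gm = make_gm(dup, populations=["A"] * 6 + ["B"] * 6,
                     pos=1 + 1000 * np.arange(400))
        result = genome_fst(gm, "A", "B", layout, size=100_000, min_sites=1)
        assert np.isnan(result) or result == 0.0


class TestPDistance:
    def test_identical_samples_zero(self):
        gm = make_gm([[0, 1, 2], [0, 1, 2]])
        mat = p_distance_matrix(gm)
        assert mat.iloc[0, 1] == 0.0

    def test_opposite_homozygotes_unit_distance(self):
        gm = make_gm([[0, 0, 0], [2, 2, 2]])
        assert p_distance_matrix(gm).iloc[0, 1] == 1.0
        assert p_distance_matrix(gm, percent=True).iloc[0, 1] == 100.0

    def test_hand_computed_mixture(self):
        gm = make_gm([[0, 1, 2, 1], [0, 2, 2, 0]])
        # (0 + 0.5 + 0 + 0.5)/4
        assert p_distance_matrix(gm).iloc[0, 1] == pytest.approx(0.25)

    def test_missing_sites_excluded_pairwise(self):
        gm = make_gm([[0, -1, 2, 1], [0, 2, -1, 0]])
        # only sites 0 and 3 shared: (0 + 0.5)/2
        assert p_distance_matrix(gm).iloc[0, 1] == pytest.approx(0.25)

    def test_matrix_structure(self, two_pop_gm):
        gm, _ = two_pop_gm
        sub = gm.subset_samples(gm.sample_ids()[:5])
        mat = p_distance_matrix(sub)
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)

    def test_single_sample_rejected(self):
        gm = make_gm([[0, 1]])
        with pytest.raises(ValueError):
            p_distance_matrix(gm)
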