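"""VCF round-trips, quality masks, site filters, thinning and SNAPP arithmetic."""

import numpy as np
import pandas as pd
import pytest

from popgenscan import (
    DegeneratePanelError,
    apply_quality_masks,
    filter_sites,
    merge_genotype_matrices,
    read_vcf,
    snapp_prepare,
    snapp_rates,
    thin_by_distance,
    write_vcf,
)
from popgenscan.synthetic_data import simulate_dataset
from popgenscan.variant_io import MISSING

from conftest import make_gm


@pytest.fixture(scope="module")
def vcf_roundtrip(tmp_path_factory):
    gm, _ = simulate_dataset(n_sites=400, n_per_pop=3, missing_rate=0.1, seed=31)
    path = tmp_path_factory.mktemp("vcf") / "sim.vcf"
    write_vcf(gm, path)
    pop_map = dict(zip(gm.samples["id"], gm.samples["population"]))
    return gm, path, pop_map


class TestVcfRoundTrip:
    def test_dosages_depth_quality_survive(self, vcf_roundtrip):
        gm, path, pop_map = vcf_roundtrip
        back = read_vcf(path, pop_map=pop_map)
        assert np.array_equal(gm.dosages, back.dosages)
        assert np.array_equal(gm.depth, back.depth)
        assert np.array_equal(gm.geno_qual, back.geno_qual)
        assert back.sites["pos"].equals(gm.sites["pos"])

    def test_second_write_identical(self, vcf_roundtrip, tmp_path):
        gm, path, pop_map = vcf_roundtrip
        back = read_vcf(path, pop_map=pop_map)
        again = tmp_path / "again.vcf"
        write_vcf(back, again)
        assert again.read_text() == path.read_text()

    def test_sample_subset(self, vcf_roundtrip):
        gm, path, pop_map = vcf_roundtrip
        two = gm.sample_ids()[:2]
        back = read_vcf(path, sample_subset=two, pop_map=pop_map)
        assert back.sample_ids() == two
        assert back.n_sites == gm.n_sites

    def test_missing_genotype_written_as_no_call(self, tmp_path):
        gm = make_gm([[0, MISSING], [2, 1]], depth=[[9, 0], [9, 9]],
                     geno_qual=[[99, 0], [99, 99]])
        path = tmp_path / "m.vcf"
        write_vcf(gm, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 2
        assert "./." in body[1]
        back = read_vcf(path, pop_map={"s00": "p", "s01": "p"})
        assert back.dosages[0, 1] == MISSING

    def test_single_sample_single_site_one_data_line(self, tmp_path):
        gm = make_gm([[1]], depth=[[10]], geno_qual=[[99]])
        path = tmp_path / "one.vcf"
        write_vcf(gm, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 1

    def test_unmapped_sample_errors(self, vcf_roundtrip):
        _, path, _ = vcf_roundtrip
        with pytest.raises(KeyError, match="population map"):
            read_vcf(path, pop_map={"nobody": "p"})

    def test_missing_file_errors(self):
        with pytest.raises(FileNotFoundError):
            read_vcf("/nonexistent/never.vcf")


class TestQualityMasks:
    def base(self):
        # 3 samples x 3 sites, everything passing
        return dict(
            dosages=[[0, 1, 2], [1, 1, 0], [2, 0, 1]],
            depth=[[30, 30, 30], [30, 30, 30], [30, 30, 30]],
            geno_qual=[[99, 99, 99], [99, 99, 99], [99, 99, 99]],
        )

    def test_all_passing_unchanged(self):
        gm = make_gm(**self.base())
        out = apply_quality_masks(gm)
        assert np.array_equal(out.dosages, gm.dosages)
        assert out.n_sites == 3

    def test_low_depth_masks_genotype_but_keeps_site(self):
        kw = self.base()
        kw["depth"][1][1] = 4  # below the 5-read floor
        gm = make_gm(**kw)
        out = apply_quality_masks(gm)
        assert out.n_sites == 3
        assert out.dosages[1, 1] == MISSING
        assert (np.delete(out.dosages.ravel(), 4) != MISSING).all()

    def test_low_genotype_quality_masks_cell(self):
        kw = self.base()
        kw["geno_qual"][2][0] = 19  # threshold is pass-if->=20
        gm = make_gm(**kw)
        out = apply_quality_masks(gm)
        assert out.dosages[2, 0] == MISSING

    def test_threshold_is_inclusive(self):
        kw = self.base()
        kw["geno_qual"][2][0] = 20
        kw["depth"][1][1] = 5
        gm = make_gm(**kw)
        out = apply_quality_masks(gm)
        assert (out.dosages != MISSING).all()

    def test_site_quality_drops_site(self):
        kw = self.base()
        gm = make_gm(**kw, qual=[50.0, 19.9, 50.0])
        out = apply_quality_masks(gm)
        assert out.n_sites == 2

    def test_mapping_quality_drops_site(self):
        kw = self.base()
        gm = make_gm(**kw, mq=[50.0, 50.0, 10.0])
        out = apply_quality_masks(gm)
        assert out.n_sites == 2

    def test_high_depth_percentile_nearest_rank(self):
        """One 10000x outlier among 1000 per-site depths is masked by the
        99.5th-percentile rule (nearest-rank cutoff on the sample's own DP)."""
        rng = np.random.default_rng(0)
        n = 1000
        depth = rng.integers(20, 40, size=(2, n))
        depth[0, 123] = 10_000
        gm = make_gm(
            np.ones((2, n), dtype=np.int8),
            depth=depth,
            geno_qual=np.full((2, n), 99),
        )
        out = apply_quality_masks(gm)
        assert out.dosages[0, 123] == MISSING
        # nearest-rank oracle: cutoff is the ceil(0.995*1000)=995th smallest
        cutoff = np.sort(depth[0])[994]
        masked = out.dosages[0] == MISSING
        assert np.array_equal(masked, depth[0] > cutoff)

    def test_missing_layer_errors(self):
        gm = make_gm([[0, 1]], depth=[[9, 9]])
        with pytest.raises(ValueError, match="GQ"):
            apply_quality_masks(gm)
        gm = make_gm([[0, 1]], geno_qual=[[99, 99]])
        with pytest.raises(ValueError, match="DP"):
            apply_quality_masks(gm)


class TestFilterSites:
    def test_missingness_fraction_threshold(self):
        # 8 samples; site 0 has 3 missing (0.375 > 0.25 -> dropped)
        d = np.ones((8, 2), dtype=np.int8)
        d[:3, 0] = MISSING
        d[0, 1] = 0  # keep site 1 polymorphic
        gm = make_gm(d)
        out = filter_sites(gm, max_missing_frac=0.25, min_maf=0.0)
        assert out.n_sites == 1
        assert out.sites["pos"].iat[0] == gm.sites["pos"].iat[1]

    def test_monomorphic_dropped_by_maf(self):
        d = np.column_stack([np.zeros(8), np.tile([0, 1], 4)]).astype(np.int8)
        gm = make_gm(d)
        out = filter_sites(gm, min_maf=0.1)
        assert out.n_sites == 1

    def test_thresholds_off_is_identity(self):
        gm, _ = simulate_dataset(n_sites=300, n_per_pop=4, missing_rate=0.2, seed=41)
        out = filter_sites(gm, biallelic_only=False, max_missing_frac=1.0, min_maf=0.0)
        assert out.n_sites == gm.n_sites
        assert np.array_equal(out.dosages, gm.dosages)

    def test_idempotent(self):
        gm, _ = simulate_dataset(n_sites=500, n_per_pop=4, missing_rate=0.2, seed=42)
        once = filter_sites(gm, max_missing_frac=0.25, min_maf=0.1)
        twice = filter_sites(once, max_missing_frac=0.25, min_maf=0.1)
        assert twice.n_sites == once.n_sites
        assert np.array_equal(twice.dosages, once.dosages)

    def test_empty_result_warns_not_raises(self):
        gm = make_gm(np.zeros((4, 3), dtype=np.int8))  # all monomorphic
        with pytest.warns(UserWarning):
            out = filter_sites(gm, min_maf=0.1)
        assert out.n_sites == 0


class TestThinByDistance:
    def test_greedy_hand_trace(self):
        pos = [1, 100_001, 600_001, 1_000_001, 1_200_001]
        gm = make_gm(np.tile([0, 1], (2, 1))[:, [0, 1, 0, 1, 0]][:2], pos=pos)
        out = thin_by_distance(gm, min_bp=500_000)
        assert out.sites["pos"].tolist() == [1, 600_001, 1_200_001]

    def test_single_site_kept(self):
        gm = make_gm([[1], [0]])
        assert thin_by_distance(gm).n_sites == 1

    def test_rule_is_per_linkage_group(self):
        gm = make_gm([[1, 1], [0, 0]], lg=["LG01", "LG02"], pos=[100, 150])
        assert thin_by_distance(gm, min_bp=500_000).n_sites == 2

    def test_pairwise_spacing_postcondition(self):
        gm, _ = simulate_dataset(n_sites=2000, n_per_pop=2, seed=43)
        out = thin_by_distance(gm, min_bp=500_000)
        df = out.sites
        for _, grp in df.groupby("lg"):
            assert (np.diff(grp["pos"].to_numpy()) >= 500_000).all()

    def test_idempotent_at_same_spacing(self):
        gm, _ = simulate_dataset(n_sites=2000, n_per_pop=2, seed=44)
        once = thin_by_distance(gm, min_bp=500_000)
        twice = thin_by_distance(once, min_bp=500_000)
        assert once.sites["pos"].tolist() == twice.sites["pos"].tolist()


class TestSnappPreparation:
    def test_printed_rates_from_mean_frequency(self):
        """u = 1.3420 corresponds to pi1 = 1/(2u); v then equals 0.7969 to 4 dp."""
        pi1 = 1.0 / (2.0 * 1.3420)
        u, v = snapp_rates(pi1)
        assert round(u, 4) == 1.3420
        assert round(v, 4) == 0.7969

    def test_symmetric_frequency_gives_unit_rates(self):
        u, v = snapp_rates(0.5)
        assert u == v == 1.0

    def test_gamma_prior_mean(self, two_pop_gm):
        gm, _ = two_pop_gm
        panel = snapp_prepare(gm, min_bp=500_000, alpha=2, beta=2000)
        assert panel.theta == pytest.approx(0.001)

    def test_stationarity_and_normalisation_invariants(self, two_pop_gm):
        gm, _ = two_pop_gm
        panel = snapp_prepare(gm)
        assert panel.pi1 * panel.u + panel.pi0 * panel.v == pytest.approx(1.0, abs=1e-9)
        assert panel.pi1 == pytest.approx(panel.v / (panel.u + panel.v), abs=1e-9)

    def test_panel_sites_complete_and_spaced(self):
        gm, _ = simulate_dataset(n_sites=3000, n_per_pop=4, missing_rate=0.05, seed=45)
        panel = snapp_prepare(gm, min_bp=500_000)
        sub = gm.subset_sites(panel.site_index)
        assert (sub.dosages != MISSING).all()
        for _, grp in sub.sites.groupby("lg"):
            assert (np.diff(grp["pos"].to_numpy()) >= 500_000).all()

    def test_degenerate_panel_errors(self):
        gm = make_gm(np.zeros((4, 3), dtype=np.int8), pos=[1, 600_000, 1_200_000])
        with pytest.raises(DegeneratePanelError):
            snapp_prepare(gm, min_bp=1)


class TestMerge:
    def test_positional_intersection_with_conflict_drop(self):
        a = make_gm([[0, 1, 2]], pos=[10, 20, 30])
        b = make_gm([[2, 0]], pos=[10, 20])
        b.samples.loc[0, "id"] = "other"
        b.sites.loc[1, "alt"] = "G"  # allele conflict at pos 20
        merged = merge_genotype_matrices([a, b])
        assert merged.n_samples == 2
        assert merged.sites["pos"].tolist() == [10]
        assert merged.dosages[:, 0].tolist() == [0, 2]
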