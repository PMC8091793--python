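"""Cohort orchestration: battery, filters, power grid, binned/gene-set/feature screens."""

import numpy as np
import pandas as pd
import pytest

from sitemut import (
    CohortConfig,
    compare_binned_downsampled,
    compute_pga,
    filter_outlier_tumours,
    geneset_analysis,
    group_sites_by_value,
    power_analysis,
    read_gmt,
    run_cohort_analysis,
    screen_genetic_features,
    simulate_cohort,
    simulate_genome,
    simulate_sites,
)
from sitemut.workflows import filter_features
from sitemut.mutations import MutationSet

from conftest import small_spec


def _cfg(**kw):
    kw.setdefault("min_cohort_size", 5)
    kw.setdefault("n_draws", 0)
    return CohortConfig(**kw)


@pytest.fixture(scope="module")
def cohort20():
    spec = small_spec(seed=21, n_tumours=20, site_fold_change=1.4)
    g = simulate_genome(spec)
    s = simulate_sites(spec, g)
    ms, truth = simulate_cohort(spec, g, s)
    return spec, g, s, ms, truth


class TestBattery:
    def test_default_subset_enumeration(self, cohort20):
        _, g, s, ms, _ = cohort20
        res = run_cohort_analysis(s, ms, g, config=_cfg(seed=21))
        # 1 total + 6 refalt + 2 strands + 1 indel
        assert list(res["subset"]) == [
            "total", "C>A", "C>G", "C>T", "T>A", "T>C", "T>G", "w", "c", "indel"
        ]
        assert res["q"].between(0, 1).all()

    def test_signature_subsets_appended(self, cohort20):
        _, g, s, ms, _ = cohort20
        from sitemut import SignatureCatalog
        from sitemut.trinuc import CLASS_LABELS

        prof = np.full((96, 5), 1 / 96)
        rng = np.random.default_rng(0)
        expo = rng.random((20, 5)) + 0.1
        cat = SignatureCatalog(
            profiles=pd.DataFrame(prof, index=list(CLASS_LABELS[:96]),
                                  columns=[f"SBS{i}" for i in range(1, 6)]),
            exposures=pd.DataFrame(expo, index=sorted(ms.tumours),
                                   columns=[f"SBS{i}" for i in range(1, 6)]),
        )
        res = run_cohort_analysis(s, ms, g, config=_cfg(seed=21), catalog=cat)
        assert len(res) == 15  # 10 + 5 signatures

    def test_single_subset_q_equals_p(self, cohort20):
        _, g, s, ms, _ = cohort20
        res = run_cohort_analysis(s, ms, g, subsets=["total"], config=_cfg(seed=21))
        assert len(res) == 1 and res["q"].iloc[0] == res["p"].iloc[0]
        assert res["p"].iloc[0] < 1e-10  # the injected enrichment is found

    def test_deterministic_outputs(self, cohort20):
        _, g, s, ms, _ = cohort20
        a = run_cohort_analysis(s, ms, g, subsets=["total", "indel"], config=_cfg(seed=3))
        b = run_cohort_analysis(s, ms, g, subsets=["total", "indel"], config=_cfg(seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_small_cohort_refused(self, cohort20):
        _, g, s, ms, _ = cohort20
        with pytest.raises(ValueError, match="meta-cohort"):
            run_cohort_analysis(s, ms, g, config=CohortConfig(min_cohort_size=25, n_draws=0))


class TestOutlierFilter:
    def test_homogeneous_null_cohort_keeps_everyone(self):
        spec = small_spec(seed=31, n_tumours=20)
        g = simulate_genome(spec)
        s = simulate_sites(spec, g)
        ms, _ = simulate_cohort(spec, g, s)
        kept, outliers = filter_outlier_tumours(s, ms, g, _cfg())
        assert outliers == {}
        assert sorted(kept.tumours) == sorted(ms.tumours)

    def test_spiked_tumour_removed(self):
        spec = small_spec(seed=22, n_tumours=15)
        g = simulate_genome(spec)
        s = simulate_sites(spec, g)
        ms, _ = simulate_cohort(spec, g, s)
        spike_spec = small_spec(seed=99, n_tumours=1, site_fold_change=20.0,
                                mean_rate=4000.0)
        spiked, _ = simulate_cohort(spike_spec, g, s)
        sdf = spiked.df.copy()
        sdf["tumour"] = "spiked"
        both = MutationSet(df=pd.concat(
            [ms.df, sdf], ignore_index=True
        ).astype({"tumour": str}))
        kept, outliers = filter_outlier_tumours(s, both, g, _cfg())
        assert "spiked" in outliers
        assert "spiked" not in kept.tumours
        # partition: removed and kept tumours cover the roster disjointly
        assert set(kept.tumours) | set(outliers) == set(both.tumours)
        assert set(kept.tumours).isdisjoint(outliers)


class TestPowerAnalysis:
    def test_alpha_one_gives_full_power(self, cohort20):
        _, g, s, ms, _ = cohort20
        res = power_analysis(s, ms, g, [100], [5], n_reps=3,
                             config=_cfg(seed=1, alpha=1.0))
        assert (res["frac_significant"] == 1.0).all()

    def test_grid_shape_and_bounds(self, cohort20):
        _, g, s, ms, _ = cohort20
        res = power_analysis(s, ms, g, [50, 100], [5, 10], n_reps=2, config=_cfg(seed=1))
        assert len(res) == 4 and res["frac_significant"].between(0, 1).all()
        assert (res["n_reps"] == 2).all()
        with pytest.raises(ValueError):
            power_analysis(s, ms, g, [10**7], [5], n_reps=1, config=_cfg())

    def test_power_increases_with_data(self):
        spec = small_spec(seed=23, n_tumours=24, site_fold_change=1.25)
        g = simulate_genome(spec)
        s = simulate_sites(spec, g)
        ms, _ = simulate_cohort(spec, g, s)
        res = power_analysis(s, ms, g, [100, 800], [4, 24], n_reps=8, config=_cfg(seed=5))
        small = res[(res.n_sites == 100) & (res.n_genomes == 4)]["median_p"].iloc[0]
        big = res[(res.n_sites == 800) & (res.n_genomes == 24)]["median_p"].iloc[0]
        assert big < small


class TestValueBins:
    def test_exact_quintiles(self, cohort20):
        _, _, s, _, _ = cohort20
        vals = np.arange(s.n_sites, dtype=float)
        out = group_sites_by_value(s.subset(np.arange(10)), vals[:10], n_bins=5)
        assert [list(b.site_id) for b in out.values()] == [
            [0, 1], [2, 3], [4, 5], [6, 7], [8, 9]
        ]

    def test_constant_values_stable_tiebreak(self, cohort20):
        _, _, s, _, _ = cohort20
        out = group_sites_by_value(s, np.zeros(s.n_sites), n_bins=5)
        sizes = [b.n_sites for b in out.values()]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == s.n_sites

    def test_downsampled_bin_comparison_flags_enriched_bin(self):
        # half the sites carry the enrichment; value-binning separates them
        spec = small_spec(seed=24, n_tumours=20, n_sites=400)
        g = simulate_genome(spec)
        s = simulate_sites(spec, g)
        enriched = small_spec(seed=24, n_tumours=20, n_sites=400, site_fold_change=1.6)
        # rebuild the cohort with fold change over a site subset: simulate the
        # enriched cohort over the first half of sites only
        half = s.subset(np.arange(200))
        ms_bg, _ = simulate_cohort(spec, g, s.subset(np.arange(200, 400)))
        ms_fg, _ = simulate_cohort(enriched, g, half)
        both = MutationSet(df=pd.concat([
            ms_bg.df.assign(tumour=ms_bg.df.tumour.astype(str)),
            ms_fg.df.assign(tumour=ms_fg.df.tumour.astype(str) + "x"),
        ], ignore_index=True))
        binned = {1: half, 2: s.subset(np.arange(200, 400))}
        res = compare_binned_downsampled(binned, both, g, n_sample=150, n_iter=5,
                                         config=_cfg(seed=7))
        res = res.set_index("bin")
        assert res.loc[1, "q"] < 0.05 and res.loc[1, "coef"] > 0

    def test_bin_smaller_than_sample_rejected(self, cohort20):
        _, g, s, ms, _ = cohort20
        with pytest.raises(ValueError, match="n_sample"):
            compare_binned_downsampled({1: s.subset(np.arange(10))}, ms, g,
                                       n_sample=100, n_iter=2, config=_cfg())

    def test_reported_p_is_lower_median_iteration(self, cohort20):
        _, g, s, ms, _ = cohort20
        res = compare_binned_downsampled({1: s}, ms, g, n_sample=100, n_iter=4,
                                         config=_cfg(seed=11))
        assert res["median_iteration"].iloc[0] in range(4)


class TestGeneSets:
    def test_size_bounds_inclusive_and_ranking(self, cohort20, tmp_path):
        _, g, s, ms, _ = cohort20
        genes = np.array([f"G{i}" for i in range(s.n_sites)], dtype=object)
        s.names = genes
        sets = {
            "tiny": set(genes[:50]),
            "lo": set(genes[:100]),
            "hi": set(genes[:400]),
            "toobig": set(genes) | {f"X{i}" for i in range(700)},
        }
        gmt = tmp_path / "sets.gmt"
        with open(gmt, "w") as fh:
            for name, gg in sets.items():
                fh.write("\t".join([name, "desc"] + sorted(gg)) + "\n")
        loaded = read_gmt(gmt)
        assert loaded.keys() == sets.keys()
        res = geneset_analysis(s, loaded, ms, g, min_size=100, max_size=400,
                               config=_cfg(seed=2))
        assert sorted(res["gene_set"]) == ["hi", "lo"]  # inclusive bounds
        assert (res["n_genes"] <= 400).all()

    def test_duplicate_genes_counted_once(self, cohort20):
        _, g, s, ms, _ = cohort20
        s.names = np.array(["G0"] * s.n_sites, dtype=object)
        res = geneset_analysis(s, {"dup": {"G0"}}, ms, g, min_size=1, max_size=10,
                               config=_cfg(seed=2))
        assert res["n_genes"].iloc[0] == 1


class TestFeatureScreen:
    def test_frequency_filters_strict_bounds(self):
        idx = [f"T{i:04d}" for i in range(99)]
        f = pd.DataFrame(0, index=idx, columns=["rare", "ok", "common"])
        f.iloc[:14, 0] = 1   # 14 carriers: excluded (< 15)
        f.iloc[:20, 1] = 1   # kept
        f.iloc[:67, 2] = 1   # 67 > 2/3 of 99 = 66: excluded
        keep = filter_features(f, 99)
        assert keep == ["ok"]
        f.iloc[14, 0] = 1    # 15 carriers: kept now
        f.iloc[66, 2] = 0    # 66 == 2/3: kept (bound is strict)
        assert filter_features(f, 99) == ["rare", "ok", "common"]

    def test_carrier_only_enrichment_is_sole_hit(self):
        spec = small_spec(seed=27, n_tumours=40, carrier_fraction=0.5,
                          carrier_fold_change=1.5)
        g = simulate_genome(spec)
        s = simulate_sites(spec, g)
        ms, truth = simulate_cohort(spec, g, s)
        carriers = set(truth.carriers)
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({
            "driver": [int(t in carriers) for t in ms.tumours],
            "noise": rng.integers(0, 2, size=len(ms.tumours)),
        }, index=ms.tumours)
        res, details = screen_genetic_features(feats, s, ms, g, config=_cfg(seed=8))
        res = res.set_index("feature")
        assert bool(res.loc["driver", "hit"])
        assert not bool(res.loc["noise", "hit"])


class TestPGA:
    AUTO = {"chr1": 1000, "chr2": 1000}

    def _seg(self, rows):
        return pd.DataFrame(rows, columns=["tumour", "chrom", "start", "end", "total_cn"])

    def test_no_deviating_segments(self):
        seg = self._seg([("t1", "chr1", 0, 500, 2)])
        out = compute_pga(seg, {}, self.AUTO).set_index("tumour")
        assert out.loc["t1", "pga"] == 0.0

    def test_ten_percent_gain(self):
        seg = self._seg([("t1", "chr1", 0, 200, 3), ("t2", "chr1", 0, 1, 2)])
        out = compute_pga(seg, {}, self.AUTO).set_index("tumour")
        assert out.loc["t1", "pga"] == pytest.approx(10.0)

    def test_wgd_baseline_four(self):
        seg = self._seg([("t1", "chr1", 0, 1000, 4), ("t1", "chr2", 0, 1000, 4)])
        out = compute_pga(seg, {"t1": True}, self.AUTO).set_index("tumour")
        assert out.loc["t1", "pga"] == 0.0

    def test_sex_chromosomes_ignored_and_median_split(self):
        seg = self._seg([
            ("t1", "chrX", 0, 1000, 5),
            ("t1", "chr1", 0, 100, 1),
            ("t2", "chr1", 0, 400, 3),
            ("t3", "chr1", 0, 900, 0),
        ])
        out = compute_pga(seg, {}, self.AUTO).set_index("tumour")
        assert out.loc["t1", "pga"] == pytest.approx(5.0)  # chrX did not count
        assert out.attrs["n_sex_segments_ignored"] == 1
        assert list(out["pga_high"]) == [0, 0, 1]  # strictly above median
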