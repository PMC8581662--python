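"""Window construction and the DMR filter cascade against brute force."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methmark as mm
from methmark.errors import (CoverageError, InputError, OrderingError,
                             StratumError)
from methmark.regions import validate_manifest
from _oracles import bh_step_up, brute_force_regions, random_manifest


def _manifest(positions, chrom="1", genes=None):
    n = len(positions)
    return pd.DataFrame({
        "site_id": [f"cg{i:04d}" for i in range(n)],
        "chrom": [chrom] * n,
        "pos": list(positions),
        "strand": ["+"] * n,
        "gene": genes or [""] * n,
    })


class TestFindRegions:
    def test_below_min_sites_yields_nothing(self):
        assert mm.find_methylation_regions(
            _manifest([100, 120, 140, 160, 180])) == []

    def test_single_maximal_window(self):
        regions = mm.find_methylation_regions(
            _manifest([100, 150, 200, 250, 300, 350]))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_sites) == (100, 350, 6)

    def test_empty_manifest(self):
        assert mm.find_methylation_regions(_manifest([])) == []

    def test_unsorted_manifest_rejected(self):
        bad = _manifest([100, 50, 200, 250, 300, 350])
        with pytest.raises(OrderingError):
            mm.find_methylation_regions(bad)

    def test_duplicate_site_ids_rejected(self):
        man = _manifest([100, 150, 200, 250, 300, 350])
        man.loc[1, "site_id"] = man.loc[0, "site_id"]
        with pytest.raises(OrderingError):
            validate_manifest(man)

    def test_matches_brute_force_on_random_manifests(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            man = random_manifest(rng, int(rng.integers(10, 120)))
            got = {
                (r.chrom, r.start, r.end, r.site_ids)
                for r in mm.find_methylation_regions(man)
            }
            assert got == brute_force_regions(man)

    def test_gene_filter_restricts_substrate(self):
        genes = ["A"] * 6 + ["B"] * 6
        man = _manifest(list(range(100, 700, 100)) * 2, genes=genes)
        man["pos"] = list(range(100, 700, 100)) + list(range(5000, 5600, 100))
        only_a = mm.find_methylation_regions(man, gene_filter={"A"})
        assert len(only_a) == 1 and only_a[0].gene == "A"

    def test_every_region_satisfies_the_mr_invariant(self, cascade):
        for r in cascade["regions"]:
            assert r.n_sites >= 6
            assert r.end - r.start < 1000
            assert r.start <= r.end


class TestRegionMean:
    def _region(self, ids):
        return mm.MethylationRegion(chrom="1", start=1, end=10,
                                    site_ids=tuple(ids))

    def test_constant_block(self):
        values = pd.DataFrame(0.5, index=["a", "b", "c"], columns=["s1", "s2"])
        out = mm.region_mean(values, self._region(["a", "b", "c"]))
        assert (out == 0.5).all()

    def test_missing_values_excluded(self):
        values = pd.DataFrame({"s1": [0.2, 0.4, np.nan]},
                              index=["a", "b", "c"])
        out = mm.region_mean(values, self._region(["a", "b", "c"]))
        assert out["s1"] == pytest.approx(0.3)

    def test_all_missing_sample_is_nan(self):
        values = pd.DataFrame({"s1": [np.nan, np.nan]}, index=["a", "b"])
        assert np.isnan(mm.region_mean(values, self._region(["a", "b"]))["s1"])

    def test_no_member_sites_raises(self):
        values = pd.DataFrame({"s1": [0.1]}, index=["z"])
        with pytest.raises(CoverageError):
            mm.region_mean(values, self._region(["a", "b"]))

    def test_matches_row_wise_brute_force(self):
        rng = np.random.default_rng(5)
        block = rng.random((8, 10))
        block[rng.random((8, 10)) < 0.2] = np.nan
        values = pd.DataFrame(block, index=[f"s{i}" for i in range(8)],
                              columns=[f"c{j}" for j in range(10)])
        out = mm.region_mean(values, self._region([f"s{i}" for i in range(8)]))
        for j, col in enumerate(values.columns):
            vals = block[:, j]
            expected = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
            assert out[col] == pytest.approx(expected, nan_ok=True)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert mm.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_most_extreme_small_case(self):
        # most extreme of the C(6,3)=20 rank assignments: p = 2/20
        assert mm.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mm.wilcoxon_rank_sum([], [1.0])

    def test_null_p_values_are_uniform(self):
        """Under the null the asymptotic p is ~ Uniform(0,1)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(6)
        ps = [mm.wilcoxon_rank_sum(rng.normal(size=40), rng.normal(size=40))
              for _ in range(400)]
        assert kstest(ps, "uniform").pvalue > 0.01


class TestBH:
    def test_single_p_unchanged(self):
        assert mm.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_case(self):
        out = mm.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            mm.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_matches_hand_rolled_step_up_and_dominates(self, ps):
        out = mm.bh_adjust(ps)
        assert np.allclose(out, bh_step_up(ps))
        assert (out >= np.asarray(ps) - 1e-12).all()


class TestDifferential:
    def test_planted_regions_rank_below_background(self, array_cohort,
                                                   cascade):
        _, _, truth = array_cohort
        planted = {(r["chrom"], r["start"], r["end"])
                   for _, r in truth.planted().iterrows()}
        records = cascade["records"]
        fp = [r.fdr for r in records
              if (r.region.chrom, r.region.start, r.region.end) in planted]
        fb = [r.fdr for r in records
              if (r.region.chrom, r.region.start, r.region.end) not in planted]
        assert max(fp) < np.median(fb)

    def test_fdr_dominates_p(self, cascade):
        for rec in cascade["records"]:
            assert rec.fdr >= rec.p_value - 1e-12

    def test_small_stratum_rejected(self, array_cohort):
        manifest, betas, _ = array_cohort
        one_case = mm.BetaMatrix(
            values=betas.values,
            groups=betas.groups[
                (betas.groups == "para-tumor")
                | (betas.groups.index == betas.samples_in("tumor")[0])],
        )
        regions = mm.find_methylation_regions(manifest)
        with pytest.raises(StratumError):
            mm.test_differential(regions[:2], one_case)

    def test_threshold_flag_needs_adenomas(self, array_cohort):
        manifest, betas, _ = array_cohort
        no_adenoma = mm.BetaMatrix(
            values=betas.values,
            groups=betas.groups[betas.groups != "adenoma"])
        regions = mm.find_methylation_regions(manifest)
        records = mm.test_differential(regions, no_adenoma)
        survivors = mm.filter_thresholds(records)
        assert survivors == []
        assert not any(r.passes_thresholds for r in records)

    def test_type_one_error_calibration(self, array_cohort):
        """With permuted group labels ~5% of regions reach p < 0.05."""
        manifest, betas, _ = array_cohort
        rng = np.random.default_rng(8)
        permuted = mm.BetaMatrix(
            values=betas.values,
            groups=pd.Series(rng.permutation(betas.groups.to_numpy()),
                             index=betas.groups.index))
        regions = mm.find_methylation_regions(manifest)
        records = mm.test_differential(regions, permuted)
        frac = np.mean([r.p_value < 0.05 for r in records])
        assert 0.01 <= frac <= 0.10


def _record(mcam, madm, mcom, fdr=0.01, chrom="1", start=100, gene="G"):
    region = mm.MethylationRegion(
        chrom=chrom, start=start, end=start + 500,
        site_ids=tuple(f"x{start}_{i}" for i in range(6)), gene=gene)
    return mm.DMRRecord(region=region, mcam=mcam, madm=madm, mcom=mcom,
                        p_value=fdr, fdr=fdr)


class TestThresholdFilter:
    @pytest.mark.parametrize(
        "means, expected",
        [
            ((0.51, 0.51, 0.29), True),
            ((0.50, 0.60, 0.10), False),   # strict >
            ((0.60, 0.50, 0.10), False),   # strict >
            ((0.60, 0.60, 0.30), False),   # strict <
            ((0.60, np.nan, 0.10), False),  # no adenoma mean
        ],
    )
    def test_strict_inequalities(self, means, expected):
        out = mm.filter_thresholds([_record(*means)])
        assert (len(out) == 1) is expected

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(9)
        records = [_record(*rng.random(3), start=100 + 10 * i)
                   for i in range(200)]
        got = {r.region.start for r in mm.filter_thresholds(records)}
        want = {r.region.start for r in records
                if r.mcam > 0.5 and r.madm > 0.5 and r.mcom < 0.3}
        assert got == want


class TestBloodFilter:
    def _blood(self, means_by_region):
        """Blood matrix over two 6-site regions with given means."""
        rows, index = [], []
        for start, comp_means in means_by_region.items():
            for i in range(6):
                index.append(f"x{start}_{i}")
                rows.append([comp_means["WB"]] * 4 + [comp_means["PBMC"]] * 4
                            + [comp_means["PBL"]] * 4)
        cols = ([f"WB_{i}" for i in range(4)] + [f"PBMC_{i}" for i in range(4)]
                + [f"PBL_{i}" for i in range(4)])
        return mm.BetaMatrix(
            values=pd.DataFrame(rows, index=index, columns=cols),
            groups=pd.Series(["WB"] * 4 + ["PBMC"] * 4 + ["PBL"] * 4,
                             index=cols))

    def test_all_compartments_rule(self):
        rec = _record(0.6, 0.6, 0.1, start=100)
        blood = self._blood({100: {"WB": 0.05, "PBMC": 0.04, "PBL": 0.06}})
        assert mm.filter_blood([rec], blood) == [rec]
        blood = self._blood({100: {"WB": 0.05, "PBMC": 0.15, "PBL": 0.04}})
        assert mm.filter_blood([rec], blood) == []
        # disjunctive mode keeps it
        assert mm.filter_blood([rec], blood, mode="any") == [rec]

    def test_missing_compartment_rejected(self):
        rec = _record(0.6, 0.6, 0.1, start=100)
        blood = self._blood({100: {"WB": 0.05, "PBMC": 0.05, "PBL": 0.05}})
        wb_only = mm.BetaMatrix(values=blood.values,
                                groups=blood.groups[blood.groups == "WB"])
        with pytest.raises(InputError):
            mm.filter_blood([rec], wb_only)

    def test_contaminated_planted_region_removed(self, array_cohort,
                                                 blood_reference, cascade):
        dirty = [r for r in cascade["after_thresholds"]
                 if r.region.gene == "ZFGBLD"]
        assert dirty, "contaminated region should pass the mean thresholds"
        survivors = mm.filter_blood(dirty, blood_reference)
        assert survivors == []


class TestPerGeneSelection:
    def test_minimum_fdr_kept(self):
        a = _record(0.6, 0.6, 0.1, fdr=1e-8, start=100, gene="G")
        b = _record(0.6, 0.6, 0.1, fdr=1e-5, start=900, gene="G")
        assert mm.select_per_gene([a, b]) == [a]

    def test_fdr_tie_broken_by_case_control_delta(self):
        a = _record(0.6, 0.6, 0.1, fdr=1e-5, start=100, gene="G")   # delta 0.5
        b = _record(0.6, 0.6, 0.3, fdr=1e-5, start=900, gene="G")   # delta 0.3
        assert mm.select_per_gene([b, a]) == [a]

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(10)
        records = []
        for i in range(120):
            records.append(_record(
                rng.random(), rng.random(), rng.random(),
                fdr=float(rng.choice([1e-6, 1e-4, 1e-2])),
                start=100 + 1000 * i, gene=f"G{int(rng.integers(0, 20))}"))
        got = mm.select_per_gene(records)
        by_gene = {}
        for r in records:
            by_gene.setdefault(r.region.gene, []).append(r)
        want = {
            min(group, key=lambda r: (r.fdr, -(r.mcam - r.mcom),
                                      r.region.start)).region.start
            for group in by_gene.values()
        }
        assert {r.region.start for r in got} == want
        assert len(got) == len(by_gene)


class TestExpressionFilter:
    def _setup(self, slope, n=60, seed=12):
        rng = np.random.default_rng(seed)
        region = mm.MethylationRegion(
            chrom="1", start=100, end=600,
            site_ids=tuple(f"e{i}" for i in range(6)), gene="G1")
        meth = rng.random(n)
        values = pd.DataFrame(
            np.tile(meth, (6, 1)) + rng.normal(0, 0.01, (6, n)),
            index=region.site_ids, columns=[f"s{j}" for j in range(n)])
        expr = pd.DataFrame(
            [slope * meth + rng.normal(0, 0.1, n)],
            index=pd.Index(["G1"], name="gene"), columns=values.columns)
        betas = mm.BetaMatrix(values=values.clip(0, 1),
                              groups=pd.Series("tumor", index=values.columns))
        rec = mm.DMRRecord(region=region, mcam=0.6, madm=0.6, mcom=0.1,
                           p_value=1e-6, fdr=1e-6)
        return rec, betas, expr

    def test_anticorrelated_gene_passes(self):
        rec, betas, expr = self._setup(slope=-1.0)
        assert mm.filter_expression_correlation([rec], betas, expr) == [rec]

    def test_positively_correlated_gene_fails(self):
        rec, betas, expr = self._setup(slope=+1.0)
        assert mm.filter_expression_correlation([rec], betas, expr) == []

    def test_absent_gene_warns(self):
        rec, betas, expr = self._setup(slope=-1.0)
        expr = expr.rename(index={"G1": "OTHER"})
        with pytest.warns(UserWarning, match="absent"):
            out = mm.filter_expression_correlation([rec], betas, expr)
        assert out == []

    def test_null_calibration(self):
        """Independent expression passes at ~ the nominal FDR level."""
        rng = np.random.default_rng(13)
        passes = 0
        reps = 400
        for i in range(reps):
            rec, betas, expr = self._setup(slope=0.0, n=40, seed=1000 + i)
            expr.loc["G1"] = rng.normal(size=expr.shape[1])
            passes += len(
                mm.filter_expression_correlation([rec], betas, expr))
        rate = passes / reps
        assert 0.02 <= rate <= 0.09


class TestCascade:
    def test_counts_monotone_and_flags_consistent(self, cascade):
        c = cascade["counts"]
        assert (c["tested"] >= c["after_thresholds"] >= c["after_blood"]
                >= c["after_gene"] >= c["survivors"])
        order = ["passes_thresholds", "passes_blood", "selected_per_gene",
                 "passes_expression"]
        for rec in cascade["records"]:
            flags = [getattr(rec, f) for f in order]
            # once a flag is False, all later flags must be False
            seen_false = False
            for f in flags:
                if seen_false:
                    assert not f
                if not f:
                    seen_false = True

    def test_permuted_labels_yield_no_survivors(self, array_cohort,
                                                blood_reference):
        manifest, betas, _ = array_cohort
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            permuted = mm.BetaMatrix(
                values=betas.values,
                groups=pd.Series(rng.permutation(betas.groups.to_numpy()),
                                 index=betas.groups.index))
            res = mm.run_cascade(manifest, permuted, blood_reference)
            assert res["counts"]["survivors"] == 0
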