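"""Scan mechanics: FDR, candidate selection, LD r², clumping, output."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_bh
from triadpoo import (
    ClumpSpec,
    SnpRecord,
    TriadDataset,
    TriadPooModel,
    annotate_genes,
    bh_adjust,
    clump,
    ld_r2,
    run_scan,
    select_candidates,
    simulate_case_families,
    SimConfig,
    write_ped_map,
    write_results,
)
from triadpoo.scan import format_pvalue


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_textbook_definition(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_bh(pvals), atol=1e-12)


def _rows(**overrides):
    base = {
        "snp_id": ["s1", "s2", "s3"],
        "chrom": ["1", "1", "2"],
        "pos": [1000, 2000, 1000],
        "rr_cm_p": [1.71e-5, 0.5, 0.2],
        "rr_cf_p": [0.3, 8.99e-6, 0.4],
        "ratio_p": [1.13e-8, 0.01, 0.9],
        "fdr_q": [3e-8, 0.2, 0.9],
        "converged": [True, True, True],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestSelectCandidates:
    def test_ratio_fdr_and_one_parent_rules(self):
        sel = select_candidates(_rows(), fdr=0.05, one_parent_p=1e-5)
        # s1: rr_cm_p=1.71e-5 misses the one-parent threshold but its ratio FDR selects it
        # s2: rr_cf_p=8.99e-6 passes the one-parent rule
        assert list(sel["snp_id"]) == ["s1", "s2"]
        assert list(sel["selection_reason"]) == ["ratio_fdr", "one_parent"]

    def test_empty_scan(self):
        sel = select_candidates(_rows().iloc[0:0])
        assert sel.empty and "selection_reason" in sel.columns


class TestLdR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self, rng):
        g1 = rng.integers(0, 3, 10000).astype(float)
        g2 = rng.integers(0, 3, 10000).astype(float)
        assert ld_r2(g1, g2) < 0.01

    def test_missing_pairs_dropped(self):
        g1 = np.array([0, 1, 2, np.nan, 1])
        g2 = np.array([0, 1, 2, 0, np.nan])
        assert ld_r2(g1, g2) == pytest.approx(1.0)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            ld_r2([1, 1, 1, 1], [0, 1, 2, 1])


class TestClump:
    def _dosages(self, rng, rho=0.999, n=400):
        g1 = rng.integers(0, 3, n).astype(float)
        g2 = np.where(rng.random(n) < rho, g1, rng.integers(0, 3, n))
        g3 = rng.integers(0, 3, n).astype(float)
        return {"s1": g1, "s2": g2, "s3": g3}

    def test_perfect_ld_pair_keeps_smaller_p(self, rng):
        rows = _rows(ratio_p=[1e-8, 1e-6, 1e-7])
        dos = self._dosages(rng, rho=1.0)
        kept = clump(rows, dos, ClumpSpec(p_threshold=1e-5))
        assert list(kept["snp_id"]) == ["s1", "s3"]

    def test_unlinked_snps_all_retained(self, rng):
        rows = _rows(ratio_p=[1e-8, 1e-6, 1e-7])
        dos = {k: rng.integers(0, 3, 500).astype(float) for k in ("s1", "s2", "s3")}
        kept = clump(rows, dos, ClumpSpec(p_threshold=1e-5))
        assert set(kept["snp_id"]) == {"s1", "s2", "s3"}

    def test_threshold_excludes_weak_rows(self, rng):
        rows = _rows(ratio_p=[1e-8, 0.5, 1e-7])
        kept = clump(rows, self._dosages(rng), ClumpSpec(p_threshold=1e-5))
        assert "s2" not in set(kept["snp_id"])

    def test_output_is_antichain(self, rng):
        # a dense block of correlated SNPs: no retained pair may exceed the r2 cap
        n, m = 300, 12
        base = rng.integers(0, 3, n).astype(float)
        dosages, rows = {}, []
        for j in range(m):
            g = np.where(rng.random(n) < 0.85, base, rng.integers(0, 3, n))
            dosages[f"s{j}"] = g
            rows.append({"snp_id": f"s{j}", "chrom": "1", "pos": 1000 + j * 5000,
                         "rr_cm_p": 1.0, "rr_cf_p": 1.0,
                         "ratio_p": 10 ** -rng.uniform(5.1, 9), "fdr_q": 0.01,
                         "converged": True})
        spec = ClumpSpec(p_threshold=1e-5, r2_threshold=0.1, window_kb=500)
        kept = clump(pd.DataFrame(rows), dosages, spec)
        ids = list(kept["snp_id"])
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                assert ld_r2(dosages[a], dosages[b]) <= spec.r2_threshold

    def test_high_ld_neighbours_collapse_to_one_index(self, rng):
        # two SNPs ~8 kb apart in near-perfect LD, like the reported top pair
        rows = _rows(pos=[244605036, 244612984, 1000], chrom=["1", "1", "2"],
                     ratio_p=[1.13e-8, 1.09e-8, 0.5])
        dos = self._dosages(rng, rho=0.999)
        kept = clump(rows, dos, ClumpSpec(p_threshold=1e-5))
        assert list(kept["snp_id"]) == ["s2"]  # marginally smaller p wins


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("scan")
    rng_units = []
    snps = []
    for j, (p, rcm) in enumerate([(0.3, 1.0), (0.4, 1.6), (0.2, 1.0)]):
        units, _ = simulate_case_families(
            SimConfig(p=p, rr_cm=rcm, n_case_families=400, seed=100 + j)
        )
        rng_units.append(units)
        snps.append(SnpRecord(f"rs{j}", "1", 1000 * (j + 1), "A", "G"))
    # write one SNP at a time, then merge into a 3-SNP panel by family id
    from triadpoo import HaploFamily

    merged = [
        HaploFamily(
            u0.family_id,
            (u0.child, u1.child, u2.child),
            (u0.mother, u1.mother, u2.mother),
            (u0.father, u1.father, u2.father),
        )
        for u0, u1, u2 in zip(*rng_units)
    ]
    write_ped_map(merged, snps, tmp / "panel.ped", tmp / "panel.map")
    return TriadDataset.from_ped_map(tmp / "panel.ped", tmp / "panel.map",
                                     effect_allele_rule={s.snp_id: "G" for s in snps})


class TestScanDriver:
    def test_one_row_per_retained_snp(self, dataset):
        rows = run_scan(dataset)
        assert len(rows) == 3
        assert rows["converged"].all()
        assert (rows["fdr_q"] >= rows["ratio_p"]).all()

    def test_driver_matches_independent_fits(self, dataset):
        rows = run_scan(dataset)
        for j in range(3):
            res = TriadPooModel(dataset.units(j)).fit()
            assert rows.iloc[j]["rr_cm"] == res.params.rr_cm
            assert rows.iloc[j]["ratio_p"] == res.ratio_test().p_value

    def test_cis_bracket_estimates(self, dataset):
        rows = run_scan(dataset)
        assert ((rows["rr_cm_low"] <= rows["rr_cm"]) & (rows["rr_cm"] <= rows["rr_cm_high"])).all()
        assert ((rows["ratio_low"] <= rows["ratio"]) & (rows["ratio"] <= rows["ratio_high"])).all()

    def test_all_snps_filtered_is_error(self, dataset):
        with pytest.raises(ValueError):
            run_scan(dataset, maf_min=0.5)

    def test_annotation_passthrough(self, dataset, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t0\t1500\tGENEA\n1\t2400\t5000\tGENEB\n")
        rows = annotate_genes(run_scan(dataset), bed)
        assert list(rows["nearest_gene"]) == ["GENEA", "GENEB", "GENEB"]


class TestWriteResults:
    def test_pvalue_formatting(self):
        assert format_pvalue(0.0000113) == "1.13E-05"
        assert format_pvalue(float("nan")) == "NA"

    def test_round_trip_to_printed_precision(self, tmp_path):
        rows = _rows()
        out = tmp_path / "scan.tsv"
        write_results(rows, out, manhattan_path=tmp_path / "man.tsv")
        back = pd.read_csv(out, sep="\t")
        for col in ("ratio_p", "rr_cm_p"):
            np.testing.assert_allclose(back[col], rows[col], rtol=5e-3)
        man = pd.read_csv(tmp_path / "man.tsv", sep="\t")
        np.testing.assert_allclose(man["neg_log10_ratio_p"], -np.log10(rows["ratio_p"]))

    def test_empty_rows_give_header_only(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_results(_rows().iloc[0:0], out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("snp_id")
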