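"""CGI methylation scoring and allele-specific methylation calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diplomethyl import (
    ASMParams,
    CGIRecord,
    CpGCall,
    METHYLATED,
    NOCALL,
    UNMETHYLATED,
    asm_scan,
    cgi_methylation_score,
    swap_alleles,
)


def cgi_calls(states, hap, start=1000, step=10, cov=20):
    return [
        CpGCall("chr1", start + step * i, hap, s, cov)
        for i, s in enumerate(states)
    ]


def uniform_cgi(n_cpg=40, start=1000, step=10, id="cgi1"):
    return CGIRecord("chr1", start, start + step * n_cpg, n_cpg, id)


class TestScore:
    def test_direct_mean(self):
        states = [METHYLATED] * 3 + [UNMETHYLATED]
        assert cgi_methylation_score(cgi_calls(states, "A")) == 0.75

    def test_all_unmethylated(self):
        assert cgi_methylation_score(cgi_calls([UNMETHYLATED] * 5, "A")) == 0.0

    def test_all_nocall_undefined(self):
        assert math.isnan(cgi_methylation_score(cgi_calls([NOCALL] * 5, "A")))

    def test_nocall_excluded_from_mean(self):
        states = [METHYLATED, NOCALL, UNMETHYLATED, NOCALL]
        assert cgi_methylation_score(cgi_calls(states, "A")) == 0.5


class TestScan:
    def test_full_contrast_is_asm(self):
        n = 40
        a = cgi_calls([METHYLATED] * 36 + [UNMETHYLATED] * 4, "A")
        b = cgi_calls([UNMETHYLATED] * 36 + [METHYLATED] * 4, "B")
        (rec,) = asm_scan(a, b, [uniform_cgi(n)])
        assert rec.score_a == 0.9 and rec.score_b == pytest.approx(0.1)
        assert rec.abs_diff == pytest.approx(0.8)
        assert rec.is_asm

    def test_equal_scores_not_asm(self):
        a = cgi_calls([METHYLATED] * 40, "A")
        b = cgi_calls([METHYLATED] * 40, "B")
        (rec,) = asm_scan(a, b, [uniform_cgi()])
        assert rec.abs_diff == 0.0 and not rec.is_asm

    def test_small_cgi_excluded(self):
        a = cgi_calls([METHYLATED] * 20, "A")
        b = cgi_calls([UNMETHYLATED] * 20, "B")
        assert asm_scan(a, b, [uniform_cgi(n_cpg=20)]) == []

    def test_threshold_boundary(self):
        # 0.68 difference is ASM, just below is not
        n = 50
        a = cgi_calls([METHYLATED] * 34 + [UNMETHYLATED] * 16, "A")
        b = cgi_calls([UNMETHYLATED] * 50, "B")
        (rec,) = asm_scan(a, b, [uniform_cgi(n)])
        assert rec.abs_diff == pytest.approx(0.68)
        assert rec.is_asm
        a2 = cgi_calls([METHYLATED] * 33 + [UNMETHYLATED] * 17, "A")
        (rec2,) = asm_scan(a2, b, [uniform_cgi(n)])
        assert not rec2.is_asm

    def test_low_coverage_blocks_asm(self):
        a = cgi_calls([METHYLATED] * 40, "A", cov=10)
        b = cgi_calls([UNMETHYLATED] * 40, "B", cov=10)
        (rec,) = asm_scan(a, b, [uniform_cgi()])
        assert rec.abs_diff == 1.0
        assert not rec.coverage_ok and not rec.is_asm

    def test_min_coverage_rule_selectable(self):
        covs = [10] + [30] * 39  # mean passes 16x, min does not
        a = [
            CpGCall("chr1", 1000 + 10 * i, "A", METHYLATED, c)
            for i, c in enumerate(covs)
        ]
        b = [
            CpGCall("chr1", 1000 + 10 * i, "B", UNMETHYLATED, c)
            for i, c in enumerate(covs)
        ]
        (rec_mean,) = asm_scan(a, b, [uniform_cgi()], ASMParams())
        (rec_min,) = asm_scan(
            a, b, [uniform_cgi()], ASMParams(coverage_rule="min")
        )
        assert rec_mean.coverage_ok and rec_mean.is_asm
        assert not rec_min.coverage_ok

    def test_quantile_mode_selects_ceil_fraction(self):
        cgis, calls_a, calls_b = [], [], []
        rng = np.random.default_rng(13)
        for i in range(30):
            start = 1000 + i * 1000
            n_meth_a = int(rng.integers(0, 41))
            a_states = [METHYLATED] * n_meth_a + [UNMETHYLATED] * (40 - n_meth_a)
            calls_a += cgi_calls(a_states, "A", start=start)
            calls_b += cgi_calls([UNMETHYLATED] * 40, "B", start=start)
            cgis.append(CGIRecord("chr1", start, start + 400, 40, f"cgi{i:02d}"))
        records = asm_scan(
            calls_a, calls_b, cgis, ASMParams(top_quantile=0.1)
        )
        assert sum(r.is_asm for r in records) == math.ceil(0.1 * 30)
        chosen = sorted(r.abs_diff for r in records if r.is_asm)
        others = [r.abs_diff for r in records if not r.is_asm]
        assert all(c >= max(others) - 1e-12 for c in chosen)

    def test_nearest_phv_distance_from_center(self):
        a = cgi_calls([METHYLATED] * 40, "A")
        b = cgi_calls([METHYLATED] * 40, "B")
        cgi = uniform_cgi()  # spans 1000..1400, center 1200
        (rec,) = asm_scan(a, b, [cgi], phv_positions=[900, 1250])
        assert rec.nearest_phv_distance == 50


class TestSwapSymmetry:
    def test_swap_preserves_diff_and_verdict(self):
        a = cgi_calls([METHYLATED] * 40, "A")
        b = cgi_calls([UNMETHYLATED] * 40, "B")
        records = asm_scan(a, b, [uniform_cgi()])
        swapped = swap_alleles(records)
        assert swapped[0].score_a == records[0].score_b
        assert swapped[0].abs_diff == records[0].abs_diff
        assert swapped[0].is_asm == records[0].is_asm
        assert swap_alleles([]) == []

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**16), quantile=st.booleans())
    def test_scan_commutes_with_allele_swap(self, seed, quantile):
        """scan(B, A) equals swap(scan(A, B)) record by record."""
        rng = np.random.default_rng(seed)
        cgis, calls_a, calls_b = [], [], []
        for i in range(6):
            start = 1000 + i * 1000
            states = [METHYLATED, UNMETHYLATED, NOCALL]
            a_states = [states[j] for j in rng.integers(0, 3, size=40)]
            b_states = [states[j] for j in rng.integers(0, 3, size=40)]
            calls_a += cgi_calls(a_states, "A", start=start)
            calls_b += cgi_calls(b_states, "B", start=start)
            cgis.append(CGIRecord("chr1", start, start + 400, 40, f"c{i}"))
        params = ASMParams(top_quantile=0.5 if quantile else None)
        fwd = asm_scan(calls_a, calls_b, cgis, params)
        rev = asm_scan(calls_b, calls_a, cgis, params)
        for f, r in zip(fwd, rev):
            assert r.score_a == f.score_b or (
                math.isnan(r.score_a) and math.isnan(f.score_b)
            )
            assert r.is_asm == f.is_asm
            if not math.isnan(f.abs_diff):
                assert r.abs_diff == pytest.approx(f.abs_diff, abs=1e-12)

    def test_scores_and_diff_in_unit_interval(self):
        rng = np.random.default_rng(4)
        states = [METHYLATED, UNMETHYLATED]
        a = cgi_calls([states[j] for j in rng.integers(0, 2, 40)], "A")
        b = cgi_calls([states[j] for j in rng.integers(0, 2, 40)], "B")
        (rec,) = asm_scan(a, b, [uniform_cgi()])
        assert 0.0 <= rec.score_a <= 1.0
        assert 0.0 <= rec.score_b <= 1.0
        assert 0.0 <= rec.abs_diff <= 1.0


class TestPlantedRecovery:
    def test_planted_asm_recovered_end_to_end(self, mini_dataset):
        """Fully contrastive planted ASM islands are recovered; balanced
        fully-covered islands yield no false ASM."""
        from diplomethyl import VariantIndex, assign_readset, SegmentationParams
        from diplomethyl.methylation import segment_methylation, summarize_ipd

        ds = mini_dataset
        idx = VariantIndex(ds.variants)
        calls_df, _ = assign_readset(ds.reads, idx)
        assignments = dict(zip(calls_df["read_id"], calls_df["verdict"]))
        cpgs = ds.cpg_positions
        by_hap = {}
        for hap in ("A", "B"):
            summaries = summarize_ipd(ds.reads, assignments, cpgs, hap)
            by_hap[hap] = segment_methylation(summaries)
        cgis = [
            CGIRecord(r.chrom, int(r.start), int(r.end), int(r.n_cpg), str(r.cgi_id))
            for r in ds.cgis.itertuples()
        ]
        records = asm_scan(by_hap["A"], by_hap["B"], cgis)
        truth = dict(zip(ds.truth.cgi_asm["cgi_id"], ds.truth.cgi_asm["is_asm"]))
        for rec in records:
            if rec.coverage_ok:
                assert rec.is_asm == truth[rec.cgi.id], rec.cgi.id
            else:
                assert not rec.is_asm
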