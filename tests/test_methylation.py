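"""IPD summarization and two-state regional segmentation."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diplomethyl import (
    METHYLATED,
    NOCALL,
    UNMETHYLATED,
    CpGSiteSummary,
    SegmentationParams,
    segment_methylation,
    summarize_ipd,
)
from conftest import make_read

STATE_OF = {0: UNMETHYLATED, 1: METHYLATED}


def brute_force_segment(x, cov, params):
    """Exhaustive minimum over all 2^n state sequences.

    Ranking mirrors the documented tie-break: total cost, then switch
    count, then lexicographic with unmethylated first.
    """
    n = len(x)
    scale = [c / (2.0 * params.sigma**2) for c in cov]
    best = None
    for bits in itertools.product((0, 1), repeat=n):
        cost = sum(
            scale[i]
            * (x[i] - (params.mu_unmeth if b == 0 else params.mu_meth)) ** 2
            for i, b in enumerate(bits)
        )
        switches = sum(a != b for a, b in zip(bits, bits[1:]))
        key = (cost + params.switch_penalty * switches, switches, bits)
        if best is None or key < best:
            best = key
    return list(best[2])


def exact_cost(bits, x, cov, params):
    """Order-independent (rational-arithmetic) cost of a state sequence."""
    total = Fraction(0)
    for i, b in enumerate(bits):
        mu = params.mu_unmeth if b == 0 else params.mu_meth
        total += (
            Fraction(float(cov[i]))
            / (2 * Fraction(params.sigma) ** 2)
            * (Fraction(float(x[i])) - Fraction(float(mu))) ** 2
        )
    switches = sum(a != b for a, b in zip(bits, bits[1:]))
    return total + Fraction(params.switch_penalty) * switches


def summaries_from(x, cov, chrom="chr1", hap="A"):
    return [
        CpGSiteSummary(chrom, 100 + 10 * i, hap, int(c), float(v))
        for i, (v, c) in enumerate(zip(x, cov))
    ]


class TestSummarizeIpd:
    def test_single_value_log_identity(self):
        read = make_read(cpg_ipd={500: [1.0]})
        (s,) = summarize_ipd([read], {"r1": "A"}, [500], "A")
        assert s.coverage == 1
        assert s.mean_log_ipd == 0.0

    def test_symmetric_values_cancel(self):
        reads = [
            make_read(read_id="r1", cpg_ipd={500: [math.e]}),
            make_read(read_id="r2", cpg_ipd={500: [1 / math.e]}),
        ]
        (s,) = summarize_ipd(reads, {"r1": "A", "r2": "A"}, [500], "A")
        assert s.coverage == 2
        assert s.mean_log_ipd == pytest.approx(0.0, abs=1e-12)

    def test_only_matching_haplotype_contributes(self):
        reads = [
            make_read(read_id="r1", cpg_ipd={500: [2.0]}),
            make_read(read_id="r2", cpg_ipd={500: [8.0]}),
        ]
        (s,) = summarize_ipd(reads, {"r1": "A", "r2": "B"}, [500], "A")
        assert s.coverage == 1
        assert s.mean_log_ipd == pytest.approx(math.log(2.0))

    def test_sampling_distribution_of_mean(self):
        rng = np.random.default_rng(3)
        mu, sigma, n = math.log(1.3), 0.6, 20
        values = np.exp(rng.normal(mu, sigma, size=n))
        reads = [
            make_read(read_id=f"r{i}", cpg_ipd={500: [float(v)]})
            for i, v in enumerate(values)
        ]
        (s,) = summarize_ipd(
            reads, {f"r{i}": "A" for i in range(n)}, [500], "A"
        )
        assert abs(s.mean_log_ipd - mu) <= 3 * sigma / math.sqrt(n)


class TestSegmentation:
    def test_uniform_methylated_block(self):
        s = summaries_from([math.log(1.3)] * 30, [20] * 30)
        calls = segment_methylation(s)
        assert all(c.state == METHYLATED for c in calls)

    def test_uniform_unmethylated_block(self):
        s = summaries_from([0.0] * 30, [20] * 30)
        calls = segment_methylation(s)
        assert all(c.state == UNMETHYLATED for c in calls)

    def test_empty_and_all_nocall(self):
        assert segment_methylation([]) == []
        s = summaries_from([0.0] * 5, [2] * 5)  # below default min_coverage
        calls = segment_methylation(s)
        assert all(c.state == NOCALL for c in calls)

    def test_single_switch_at_boundary(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [
                rng.normal(math.log(1.3), 0.6 / math.sqrt(20), 30),
                rng.normal(0.0, 0.6 / math.sqrt(20), 30),
            ]
        )
        calls = segment_methylation(summaries_from(x, [20] * 60))
        states = [c.state for c in calls]
        switches = sum(a != b for a, b in zip(states, states[1:]))
        assert switches == 1
        boundary = states.index(UNMETHYLATED)
        assert abs(boundary - 30) <= 1

    def test_zero_penalty_is_nearest_mean(self):
        params = SegmentationParams(switch_penalty=0.0, min_coverage=1)
        rng = np.random.default_rng(21)
        x = rng.normal(0.13, 0.3, size=40)
        calls = segment_methylation(summaries_from(x, [20] * 40), params)
        mid = (params.mu_meth + params.mu_unmeth) / 2
        for xi, c in zip(x, calls):
            expected = METHYLATED if xi > mid else UNMETHYLATED
            assert c.state == expected

    def test_nocall_sites_do_not_influence_neighbors(self):
        params = SegmentationParams(min_coverage=16)
        x = [math.log(1.3)] * 10 + [0.0] * 10
        cov = [20] * 20
        base = segment_methylation(summaries_from(x, cov), params)
        # splice three low-coverage sites with extreme values into the middle
        spiked = summaries_from(x[:10], cov[:10])
        spiked += [
            CpGSiteSummary("chr1", 100 + 10 * 10 + j, "A", 2, 5.0)
            for j in range(3)
        ]
        spiked += [
            CpGSiteSummary("chr1", 100 + 10 * (13 + i), "A", 20, v)
            for i, v in enumerate(x[10:])
        ]
        out = segment_methylation(spiked, params)
        called = [c.state for c in out if c.state != NOCALL]
        assert called == [c.state for c in base]
        assert [c.state for c in out[10:13]] == [NOCALL] * 3

    def test_deterministic_tie_prefers_fewer_switches_then_unmethylated(self):
        # exactly representable arithmetic: mu 0/2, values at the midpoint
        params = SegmentationParams(
            mu_meth=2.0, mu_unmeth=0.0, sigma=1.0, switch_penalty=3.0,
            min_coverage=1,
        )
        calls = segment_methylation(summaries_from([1.0] * 4, [2] * 4), params)
        assert [c.state for c in calls] == [UNMETHYLATED] * 4

    @pytest.mark.parametrize("n", [1, 2, 5, 8, 12])
    def test_dp_equals_brute_force_random_inputs(self, n):
        params = SegmentationParams(min_coverage=1)
        rng = np.random.default_rng(n)
        for _ in range(30):
            x = rng.normal(0.13, 0.5, size=n)
            cov = rng.integers(1, 40, size=n)
            calls = segment_methylation(summaries_from(x, cov), params)
            expected = brute_force_segment(list(x), list(cov), params)
            assert [c.state for c in calls] == [STATE_OF[b] for b in expected]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        x=st.lists(st.floats(-2, 2), min_size=1, max_size=10),
        penalty=st.floats(0, 10),
    )
    def test_dp_cost_optimal_any_input(self, x, penalty):
        """DP cost never exceeds the exhaustive minimum (rational arithmetic)."""
        params = SegmentationParams(switch_penalty=penalty, min_coverage=1)
        cov = [20] * len(x)
        calls = segment_methylation(summaries_from(x, cov), params)
        bits = [0 if c.state == UNMETHYLATED else 1 for c in calls]
        dp_cost = exact_cost(bits, x, cov, params)
        best = min(
            exact_cost(b, x, cov, params)
            for b in itertools.product((0, 1), repeat=len(x))
        )
        assert float(dp_cost - best) <= 1e-9

    def test_unsorted_input_rejected(self):
        s = summaries_from([0.0, 0.0], [20, 20])
        with pytest.raises(ValueError):
            segment_methylation(list(reversed(s)))
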