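"""Spike-in calibration algebra and SES background scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikechip as sc
from spikechip.normalization import (
    DegenerateEnrichmentError,
    UndefinedStatisticError,
    compute_eip,
    n_factor_ip_vs_input,
    n_factor_mut_vs_wt,
    ses_scale,
)

counts_st = st.builds(
    sc.SpikeInCounts,
    ip_exp=st.integers(1, 10**7),
    input_exp=st.integers(1, 10**7),
    ip_spike=st.integers(1, 10**6),
    input_spike=st.integers(1, 10**6),
)


class TestEip:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((100, 100, 10, 10), 1.0),
            ((800, 400, 100, 200), 4.0),
            ((90, 30, 30, 30), 3.0),
        ],
    )
    def test_direct_evaluation(self, counts, expected):
        assert compute_eip(sc.SpikeInCounts(*counts)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_ip_depth_invariance(self):
        c = sc.SpikeInCounts(800, 400, 100, 200)
        c3 = sc.SpikeInCounts(2400, 400, 300, 200)
        assert compute_eip(c) == compute_eip(c3)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedStatisticError):
            compute_eip(sc.SpikeInCounts(100, 100, 0, 10))

    @settings(max_examples=200, deadline=None)
    @given(counts_st, st.integers(2, 9), st.integers(2, 9))
    def test_depth_invariance_and_recovery_equivariance(self, c, a, b):
        """E^IP is invariant under uniform IP-library and input-library
        rescaling and scales linearly with exp-genome IP recovery."""
        e = compute_eip(c)
        scaled = sc.SpikeInCounts(
            c.ip_exp * a, c.input_exp * b, c.ip_spike * a, c.input_spike * b
        )
        assert compute_eip(scaled) == pytest.approx(e, rel=1e-12)
        boosted = sc.SpikeInCounts(
            c.ip_exp * a, c.input_exp, c.ip_spike, c.input_spike
        )
        assert compute_eip(boosted) == pytest.approx(a * e, rel=1e-12)


class TestNFactors:
    def test_calibrated_sample_has_unit_n(self):
        c = sc.SpikeInCounts(100, 100, 10, 10)
        r = n_factor_ip_vs_input(c)
        assert r.e_ip == 1.0 and r.n_factor == 1.0

    def test_worked_example(self):
        r = n_factor_ip_vs_input(sc.SpikeInCounts(800, 400, 100, 200))
        assert r.e_ip == pytest.approx(4.0)
        assert r.n_factor == pytest.approx(2.0)

    def test_doubling_input_halves_eip_keeps_calibration(self):
        """Doubling input_exp halves E^IP while N = E^IP x input/IP is
        unchanged (the two factors of two cancel); the defining product
        N x IP/input = E^IP holds either way."""
        c = sc.SpikeInCounts(800, 400, 100, 200)
        c2 = sc.SpikeInCounts(800, 800, 100, 200)
        r, r2 = n_factor_ip_vs_input(c), n_factor_ip_vs_input(c2)
        assert r2.e_ip == pytest.approx(r.e_ip / 2)
        assert r2.n_factor == pytest.approx(r.n_factor)
        assert r2.n_factor * c2.ip_exp / c2.input_exp == pytest.approx(
            r2.e_ip, abs=1e-12
        )

    def test_self_comparison_mut_vs_wt(self):
        c = sc.SpikeInCounts(800, 400, 100, 200)
        r = n_factor_mut_vs_wt(c, c)
        assert r.e_ip == pytest.approx(1.0) and r.n_factor == pytest.approx(1.0)

    def test_mut_vs_wt_worked_example(self):
        # E^IP_mut = 1.5, E^IP_wt = 3, ip_mut = 600, ip_wt = 300 -> N = 0.25
        c_mut = sc.SpikeInCounts(600, 400, 100, 100)   # E = 1.5
        c_wt = sc.SpikeInCounts(300, 100, 100, 100)    # E = 3
        r = n_factor_mut_vs_wt(c_mut, c_wt)
        assert r.e_ip == pytest.approx(0.5)
        assert r.n_factor == pytest.approx(0.25)

    @settings(max_examples=200, deadline=None)
    @given(counts_st, counts_st)
    def test_algebraic_invariants(self, c_mut, c_wt):
        """N x (IP/input) = E^IP and N x (IP_mut/IP_wt) = E ratio, both
        to 1e-12 relative error."""
        r = n_factor_ip_vs_input(c_mut)
        assert r.n_factor * c_mut.ip_exp / c_mut.input_exp == pytest.approx(
            r.e_ip, rel=1e-12
        )
        r2 = n_factor_mut_vs_wt(c_mut, c_wt)
        assert r2.n_factor * c_mut.ip_exp / c_wt.ip_exp == pytest.approx(
            compute_eip(c_mut) / compute_eip(c_wt), rel=1e-12
        )


def ses_bruteforce(ip_v, in_v):
    """Independent cut-point search: for every k, compute the cumulative
    fraction gap from scratch; first maximum wins."""
    order = np.argsort(ip_v, kind="stable")
    best_k, best_gap = None, -np.inf
    for k in range(1, len(ip_v) + 1):
        sel = order[:k]
        gap = in_v[sel].sum() / in_v.sum() - ip_v[sel].sum() / ip_v.sum()
        if gap > best_gap + 1e-15:
            best_gap, best_k = gap, k
    sel = order[:best_k]
    return (ip_v[sel].sum() / ip_v.sum()) / (in_v[sel].sum() / in_v.sum())


def _tracks_from(ip_v, in_v):
    n = len(ip_v)
    layout = sc.GenomeLayout(chromosomes=[("chrA", 50 * n)])
    ip = sc.BinnedTrack(layout, 50, {"chrA": np.asarray(ip_v, float)})
    inp = sc.BinnedTrack(layout, 50, {"chrA": np.asarray(in_v, float)})
    return ip, inp


class TestSesScale:
    def test_no_enrichment_gives_unit_scale(self):
        ip, inp = _tracks_from([2, 3, 5, 1], [2, 3, 5, 1])
        assert ses_scale(ip, inp) == pytest.approx(1.0)

    def test_worked_example(self):
        ip, inp = _tracks_from([1, 1, 8], [4, 4, 4])
        assert ses_scale(ip, inp) == pytest.approx((2 / 10) / (8 / 12))

    def test_matches_bruteforce_on_small_random_tracks(self, rng):
        for n in range(2, 13):
            for _ in range(30):
                ip_v = rng.integers(0, 20, n).astype(float)
                in_v = rng.integers(1, 20, n).astype(float)
                if ip_v.sum() == 0:
                    continue
                ip, inp = _tracks_from(ip_v, in_v)
                try:
                    got = ses_scale(ip, inp)
                except DegenerateEnrichmentError:
                    continue
                assert got == pytest.approx(
                    ses_bruteforce(ip_v, in_v), abs=1e-12
                )

    def test_matches_bruteforce_on_larger_tracks(self, rng):
        for _ in range(20):
            ip_v = rng.gamma(2.0, 5.0, 50)
            in_v = rng.gamma(2.0, 5.0, 50) + 0.1
            ip, inp = _tracks_from(ip_v, in_v)
            assert ses_scale(ip, inp) == pytest.approx(
                ses_bruteforce(ip_v, in_v), abs=1e-12
            )

    def test_degenerate_background_raises(self):
        ip, inp = _tracks_from([0, 0, 10], [0, 0, 10])
        with pytest.raises(DegenerateEnrichmentError):
            ses_scale(ip, inp)


class TestFoldChangeRecovery:
    @pytest.mark.parametrize("f", [0.5, 1.0, 1.5, 2.0])
    def test_spike_normalized_recovery(self, f):
        """Simulated wt/mutant pairs at 1e6 reads recover the true H3
        fold change on bound bins within 0.1."""
        design = sc.build_study_model(h3_fold_change=f)
        cfg = sc.SimulationConfig(
            seed=100 + int(f * 10), total_ip_reads=10**6,
            total_input_reads=10**6,
        )
        wt = sc.simulate_chip(design.model, cfg, "wt", "H3")
        mut = sc.simulate_chip(design.model, cfg, "ies6D", "H3")
        r = n_factor_mut_vs_wt(mut.counts, wt.counts)
        tr = sc.mutant_vs_wt_track(
            mut.ip_exp, wt.ip_exp, n_factor=r.n_factor, pseudocount=1.0
        )
        bound = np.concatenate(
            [tr.values[c][i] for c, i in design.bound_bins.items() if i.size]
        )
        unbound = np.concatenate(
            [tr.values[c][i] for c, i in design.unbound_bins.items() if i.size]
        )
        assert abs(bound.mean() - f) < 0.1
        assert abs(unbound.mean() - 1.0) < 0.05
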