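"""Hemizygous X copy-number calling: segmentation, calibration, state fit, CCF."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gctevo import xcn
from gctevo.genome import build_genome
from gctevo.simcohort import simulate_window_depths, logr_track

from conftest import TEST_GENOME_BP


def windows(n, w=10):
    return [(i * w, (i + 1) * w) for i in range(n)]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_constant_signal_single_segment():
    segs = xcn.segment_logr_pcf([0.3] * 15, windows(15), gamma=1.0)
    assert len(segs) == 1
    assert segs[0].mean_logr == pytest.approx(0.3)


def test_step_signal_breakpoint_at_step():
    x = [0.0] * 8 + [1.0] * 12
    segs = xcn.segment_logr_pcf(x, windows(20), gamma=0.1)
    assert len(segs) == 2
    assert (segs[0].end_idx, segs[1].start_idx) == (7, 8)
    assert segs[0].mean_logr == pytest.approx(0.0)
    assert segs[1].mean_logr == pytest.approx(1.0)


def test_forced_sv_breakpoint_splits_constant_region():
    segs = xcn.segment_logr_pcf([0.2] * 20, windows(20), gamma=5.0,
                                sv_breakpoints=[100])
    assert len(segs) == 2
    assert segs[0].end_idx == 9 and segs[1].start_idx == 10
    assert segs[0].mean_logr == pytest.approx(segs[1].mean_logr)


def _exhaustive_pcf_cost(x, gamma):
    """Best penalized cost over every breakpoint subset (oracle)."""
    n = len(x)
    best = np.inf
    for k in range(n):
        for cuts in itertools.combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            cost = gamma * k
            for a, b in zip(bounds[:-1], bounds[1:]):
                seg = np.asarray(x[a:b])
                cost += float(((seg - seg.mean()) ** 2).sum())
            best = min(best, cost)
    return best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dp_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(0, 0.2, 4), rng.normal(1, 0.2, 4),
                        rng.normal(0.3, 0.2, 4)])
    gamma = 0.3
    segs = xcn.segment_logr_pcf(x, windows(12), gamma=gamma)
    dp_cost = gamma * (len(segs) - 1)
    for s in segs:
        seg = x[s.start_idx:s.end_idx + 1]
        dp_cost += float(((seg - seg.mean()) ** 2).sum())
    assert dp_cost == pytest.approx(_exhaustive_pcf_cost(list(x), gamma), abs=1e-9)


def test_empty_track_rejected():
    with pytest.raises(ValueError):
        xcn.segment_logr_pcf([], [], gamma=1.0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _track(chrom, values, w=10):
    return pd.DataFrame({"chrom": chrom, "start": [i * w for i in range(len(values))],
                         "end": [(i + 1) * w for i in range(len(values))],
                         "logr": values})


def test_calibration_shift_from_diploid_regions():
    track = _track("1", [0.3] * 10)
    regions = pd.DataFrame([{"chrom": "1", "start": 0, "end": 100, "n": 2,
                             "n_normal": 2}])
    shifted, delta = xcn.calibrate_logr(track, regions, purity=1.0, tumor_ploidy=2.0)
    assert delta == pytest.approx(-0.3)
    assert shifted["logr"].median() == pytest.approx(0.0)

    already, delta0 = xcn.calibrate_logr(shifted, regions, 1.0, 2.0)
    assert delta0 == pytest.approx(0.0)


def test_calibration_pools_diploid_and_gained_classes():
    """Delta equals the median of pooled (expected - observed) offsets."""
    rho, psi = 0.8, 2.0
    e2 = xcn.expected_logr(2, rho, psi)
    e3 = xcn.expected_logr(3, rho, psi)
    off = 0.17
    vals2 = [e2 + off + d for d in (-0.02, 0.0, 0.01)]
    vals3 = [e3 + off + d for d in (-0.01, 0.0, 0.03)]
    track = pd.concat([_track("1", vals2), _track("2", vals3)], ignore_index=True)
    regions = pd.DataFrame([
        {"chrom": "1", "start": 0, "end": 30, "n": 2, "n_normal": 2},
        {"chrom": "2", "start": 0, "end": 30, "n": 3, "n_normal": 2},
    ])
    pooled = [e2 - v for v in vals2] + [e3 - v for v in vals3]
    _, delta = xcn.calibrate_logr(track, regions, rho, psi)
    assert delta == pytest.approx(np.median(pooled), abs=1e-12)


def test_calibration_without_coverage_errors():
    with pytest.raises(ValueError):
        xcn.calibrate_logr(_track("1", [0.0]), pd.DataFrame(
            [{"chrom": "5", "start": 0, "end": 10, "n": 2, "n_normal": 2}]),
            1.0, 2.0)


# ---------------------------------------------------------------------------
# expected LogR and state fitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n, rho, psi, n_norm, expected", [
    (2, 0.37, 2.0, 2, 0.0),           # diploid autosome: 0 at any purity
    (2, 1.0, 2.0, 1, 1.0),            # hemizygous locus doubled in pure tumor
    (3, 0.5, 4.0, 1, np.log2(4 / 3)),
])
def test_expected_logr_values(n, rho, psi, n_norm, expected):
    assert xcn.expected_logr(n, rho, psi, n_norm) == pytest.approx(expected, abs=5e-4)


def test_fit_copy_state_examples():
    c = xcn.fit_copy_state(0.0, purity=0.6, tumor_ploidy=2.0, n_normal=2)
    assert c.n_eff == pytest.approx(2.0) and c.n_hat == 2 and c.clonal

    c = xcn.fit_copy_state(1.0, purity=1.0, tumor_ploidy=2.0, n_normal=1)
    assert c.n_hat == 2 and c.clonal

    logr_half = xcn.expected_logr(2.5, 0.8, 3.0, 1)
    c = xcn.fit_copy_state(logr_half, 0.8, 3.0, n_normal=1, tau=0.2)
    assert not c.clonal
    assert c.ccf_high == pytest.approx(0.5, abs=1e-9)


def test_subclonal_ccf_is_fractional_part():
    call = xcn.XStateCall(0, 0, 0.0, n_eff=3.25, n_hat=3, clonal=False, ccf_high=None)
    assert xcn.estimate_subclonal_ccf(call) == pytest.approx(0.25)
    clonal = xcn.XStateCall(0, 0, 0.0, n_eff=3.0, n_hat=3, clonal=True, ccf_high=None)
    with pytest.raises(ValueError):
        xcn.estimate_subclonal_ccf(clonal)


def test_round_trip_state_recovery_grid():
    """expected_logr -> fit_copy_state is exact for n in 0..8 over a
    purity/ploidy grid (both hemizygous and diploid normals)."""
    for n_norm in (1, 2):
        for n in range(0, 9):
            for rho in np.linspace(0.3, 1.0, 8):
                for psi in (2.0, 3.5, 4.0):
                    L = xcn.expected_logr(n, float(rho), psi, n_norm)
                    call = xcn.fit_copy_state(L, float(rho), psi, n_norm)
                    assert call.n_hat == n and call.clonal, (n, rho, psi, n_norm)


def test_simulated_subclonal_mixture_ccf_recovery(test_genome):
    """60% of tumor cells at 3 X copies, 40% at 2, purity 0.8: the fitted
    fractional state recovers ccf_high ~= 0.60."""
    from gctevo.simcohort import _SegState

    rng = np.random.default_rng(77)
    recovered = []
    for _ in range(20):
        states = [_SegState("X", r.start, r.end, 2, 0, False, 0.6, 0.0, r.normal_copies)
                  if r.name == "nonPAR" else
                  _SegState("X", r.start, r.end, 1, 1, True, 1.0, 0.0, 2)
                  for r in test_genome.chrom_regions("X")]
        win = simulate_window_depths(test_genome, states, 0.8, 2.0, 80.0, 32.0,
                                     10_000, rng)
        track = logr_track(win, test_genome)
        xtrack = track[track["chrom"] == "X"]
        x_body = xtrack[(xtrack["start"] >= states[1].start) &
                        (xtrack["end"] <= states[1].end)]
        calls = xcn.call_x_segments(x_body, 0.8, 2.0, gamma=20.0)
        main = calls.loc[(calls["end"] - calls["start"]).idxmax()]
        if main["clonal_flag"] == 0:
            recovered.append(main["ccf_high"])
    assert len(recovered) >= 15
    assert np.mean(recovered) == pytest.approx(0.60, abs=0.05)
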