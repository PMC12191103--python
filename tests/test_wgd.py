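"""WGD detection thresholds, timing-ratio arithmetic, division clock, utilities."""

import numpy as np
import pandas as pd
import pytest

from gctevo import wgd
from gctevo.genome import AUTOSOMES
from gctevo.simcohort import expected_vaf

from conftest import make_segments, make_variants


# ---------------------------------------------------------------------------
# multiplicity / clonality / NRPCC
# ---------------------------------------------------------------------------

def test_multiplicity_inversion_examples():
    m_raw, m_hat, ccf = wgd.estimate_multiplicity(0.5, 1.0, 2, 1)
    assert (m_hat, ccf) == (1, 1.0)

    m_raw, m_hat, _ = wgd.estimate_multiplicity(1 / 3, 0.5, 4, 2)
    assert m_raw == pytest.approx(2.0)
    assert m_hat == 2

    vaf = expected_vaf(0.8, 2, 1, 1.0, 1)  # non-PAR X round trip
    m_raw, m_hat, ccf = wgd.estimate_multiplicity(vaf, 0.8, 2, 2, n_normal=1)
    assert m_hat == 1 and ccf == pytest.approx(1.0)

    with pytest.raises(ValueError):
        wgd.estimate_multiplicity(0.5, 0.0, 2, 1)


def test_clonality_threshold():
    assert wgd.classify_clonality(1.0) == "clonal"
    assert wgd.classify_clonality(0.4) == "subclonal"
    assert wgd.classify_clonality(0.9) == "clonal"  # inclusive boundary


def test_subclone_variants_labeled_subclonal_by_readcount_model():
    """A CCF-0.5 subclone at 80x, purity 0.8: >= 95% of its variants get a
    subclonal label after multiplicity inversion."""
    rng = np.random.default_rng(4)
    rho, n_tot, ccf = 0.8, 2.0, 0.5
    ev = expected_vaf(rho, n_tot, 1, ccf, 2)
    n = 2000
    dp = rng.poisson(80, n)
    ad = rng.binomial(np.maximum(dp, 1), ev)
    labels = []
    for a, d in zip(ad, dp):
        if d == 0:
            continue
        _, _, c = wgd.estimate_multiplicity(a / d, rho, int(n_tot), 1)
        labels.append(wgd.classify_clonality(c))
    assert np.mean([l == "subclonal" for l in labels]) >= 0.95


@pytest.mark.parametrize("depth, rho, psi, expected", [
    (20.0, 1.0, 2.0, 10.0),
    (82.0, 0.7, 3.5, 57.4 / 3.05),
    (100.0, 1e-9, 2.0, 100.0 * 1e-9 / 2.0),  # -> 0 as purity -> 0
])
def test_nrpcc_values(depth, rho, psi, expected):
    assert wgd.compute_nrpcc(depth, rho, psi) == pytest.approx(expected, rel=1e-6)


# ---------------------------------------------------------------------------
# WGD classification
# ---------------------------------------------------------------------------

def uniform_cohort(mcn_states):
    """One equal-length segment per autosome with given (n_major, n_minor)."""
    rows = [(c, 0, 1_000_000, *mcn_states[i]) for i, c in enumerate(AUTOSOMES)]
    return make_segments(rows)


def test_all_tetraploid_is_single_wgd():
    call = wgd.classify_wgd(uniform_cohort([(2, 2)] * 22))
    assert call.status == "single"
    assert call.frac_mcn_ge2 == pytest.approx(1.0)
    assert call.n_chroms_majority_mcn2 == 22


def test_all_diploid_is_not_wgd():
    assert wgd.classify_wgd(uniform_cohort([(1, 1)] * 22)).status == "none"


def test_boundary_both_criteria_required():
    # 12 of 22 equal-length autosomes at MCN 2: frac = 0.545 > 0.5, 12 >= 11
    call12 = wgd.classify_wgd(uniform_cohort([(2, 1)] * 12 + [(1, 1)] * 10))
    assert call12.status == "single"
    assert call12.frac_mcn_ge2 == pytest.approx(12 / 22)

    # 10 qualifying chromosomes: chromosome criterion fails even with the
    # genome fraction pushed past 0.5 by making those segments longer
    rows = [(c, 0, 3_000_000, 2, 1) for c in AUTOSOMES[:10]]
    rows += [(c, 0, 1_000_000, 1, 1) for c in AUTOSOMES[10:]]
    call10 = wgd.classify_wgd(make_segments(rows))
    assert call10.frac_mcn_ge2 > 0.5
    assert call10.n_chroms_majority_mcn2 == 10
    assert call10.status == "none"


def test_multi_wgd_detected_and_never_none():
    call = wgd.classify_wgd(uniform_cohort([(3, 3)] * 22))
    assert call.status == "multi"
    assert call.frac_mcn_ge3 == pytest.approx(1.0)


def test_classification_invariant_to_segment_subdivision():
    base = uniform_cohort([(2, 2)] * 12 + [(1, 1)] * 10)
    split_rows = []
    for _, s in base.iterrows():
        mid = (s["start"] + s["end"]) // 3
        split_rows.append((s["chrom"], s["start"], mid, s["n_major"], s["n_minor"]))
        split_rows.append((s["chrom"], mid, s["end"], s["n_major"], s["n_minor"]))
    split = make_segments(split_rows)
    a, b = wgd.classify_wgd(base), wgd.classify_wgd(split)
    assert (a.status, a.frac_mcn_ge2, a.n_chroms_majority_mcn2) == \
           (b.status, b.frac_mcn_ge2, b.n_chroms_majority_mcn2)


def test_no_autosomes_is_an_error():
    with pytest.raises(ValueError):
        wgd.classify_wgd(make_segments([("X", 0, 100, 2, 0)]))


# ---------------------------------------------------------------------------
# timing ratio
# ---------------------------------------------------------------------------

def test_timing_ratio_density_arithmetic():
    segs = make_segments([("1", 0, 100_000_000, 2, 2), ("2", 0, 100_000_000, 1, 1)])
    vrows = [{"chrom": "1", "pos": p} for p in range(1, 41)]
    vrows += [{"chrom": "2", "pos": p} for p in range(1, 21)]
    ratio, ok = wgd.wgd_timing_ratio(segs, make_variants(vrows))
    assert ok and ratio == pytest.approx(2.0)


def test_timing_ratio_undefined_without_denominator():
    segs = make_segments([("1", 0, 100, 2, 2), ("2", 0, 100, 1, 1)])
    only_high = make_variants([{"chrom": "1", "pos": 5}])
    ratio, ok = wgd.wgd_timing_ratio(segs, only_high)
    assert not ok and ratio is None

    no_low_stratum = make_segments([("1", 0, 100, 2, 2)])
    ratio, ok = wgd.wgd_timing_ratio(no_low_stratum, only_high)
    assert not ok


def test_timing_ratio_ignores_subclonal_and_nonclock_variants():
    segs = make_segments([("1", 0, 1000, 2, 2), ("2", 0, 1000, 1, 1)])
    v = make_variants(
        [{"chrom": "1", "pos": 10}, {"chrom": "2", "pos": 10},
         {"chrom": "2", "pos": 20, "clonality": "subclonal"},
         {"chrom": "2", "pos": 30, "clock_flag": False}])
    ratio, ok = wgd.wgd_timing_ratio(segs, v)
    assert ok and ratio == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# pre-WGD divisions
# ---------------------------------------------------------------------------

def test_divisions_clock_arithmetic():
    # M_obs = 30 in 1.5 Gb of 2+2 out of a 3 Gb genome -> M_pre = 60;
    # divisions = 60 / (2 * 0.6) = 50, bounds 60/1.4 and 60/1.0
    segs = make_segments([("1", 0, 1_500_000_000, 2, 2)])
    v = make_variants([{"chrom": "1", "pos": i + 1, "multiplicity": 2}
                       for i in range(30)])
    res = wgd.pre_wgd_divisions(segs, v, autosome_length=3_000_000_000)
    assert res["defined"]
    assert res["pre_wgd_burden"] == pytest.approx(60.0)
    assert res["divisions"] == pytest.approx(50.0)
    assert res["divisions_low"] == pytest.approx(60 / 1.4)
    assert res["divisions_high"] == pytest.approx(60.0)


def test_divisions_zero_burden_and_missing_segments():
    segs = make_segments([("1", 0, 1_000_000, 2, 2)])
    res = wgd.pre_wgd_divisions(segs, make_variants([]), 3_000_000)
    assert res["defined"] and res["divisions"] == 0.0

    no22 = make_segments([("1", 0, 1_000_000, 2, 1)])
    res = wgd.pre_wgd_divisions(no22, make_variants([]), 3_000_000)
    assert not res["defined"]


def test_divisions_counts_only_multiplicity_two_clonal_in_22():
    segs = make_segments([("1", 0, 1_000_000, 2, 2), ("2", 0, 1_000_000, 2, 1)])
    v = make_variants([
        {"chrom": "1", "pos": 10, "multiplicity": 2},                       # counted
        {"chrom": "1", "pos": 20, "multiplicity": 1},                       # m=1
        {"chrom": "1", "pos": 30, "multiplicity": 2, "clonality": "subclonal"},
        {"chrom": "2", "pos": 10, "multiplicity": 2},                       # not 2+2
    ])
    res = wgd.pre_wgd_divisions(segs, v, 2_000_000)
    assert res["m_obs"] == 1
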