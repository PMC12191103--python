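"""Whole-genome doubling: detection, molecular timing, pre-WGD cell divisions.

Detection follows the major-copy-number (MCN) criteria of Bielski-style
classifiers: a tumor is WGD-positive when more than half of the autosomal
genome (base-pair weighted) has MCN >= 2 and at least 11 autosomes each
carry MCN >= 2 over more than half of their covered length; evidence of
multiple doublings requires more than half the autosomal genome at
MCN >= 3.

Timing uses the density of clock-like mutations: segments duplicated by an
early WGD carry pre-WGD mutations on both copies, so the per-bp density of
distinct clock-mutation loci in MCN = 2 segments approaches twice that of
MCN = 1 segments when WGD is early, and parity when WGD is late.

The number of cell divisions preceding WGD converts the pre-WGD mutation
burden (clonal multiplicity-2 substitutions in balanced 2+2 segments,
extrapolated to the whole autosomal genome) with a germline-like rate of
r = 0.5-0.7 substitutions per haploid genome per division: d = M / (2 r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AUTOSOMES
from .simcohort import expected_vaf  # noqa: F401  (inverse model documented here)


@dataclass
class WGDCall:
    status: str                      # none | single | multi
    frac_mcn_ge2: float
    frac_mcn_ge3: float
    n_chroms_majority_mcn2: int
    timing_ratio: float | None = None
    timing_defined: bool = False
    pre_wgd_burden: float | None = None      # mutations per diploid genome
    pre_wgd_divisions: float | None = None
    divisions_low: float | None = None       # at r = 0.7
    divisions_high: float | None = None      # at r = 0.5
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-variant utilities
# ---------------------------------------------------------------------------

def estimate_multiplicity(vaf: float, purity: float, n_tot: int,
                          n_major: int, n_normal: int = 2,
                          ccf_cap: float = 1.25) -> tuple[float, int, float]:
    """Invert the VAF mixture to mutation multiplicity and CCF.

    m_raw = VAF * ((1 - rho) * N + rho * n_tot) / rho;  the integer
    multiplicity is m_raw rounded and clamped to [1, n_major]; CCF is
    m_raw / m_hat, capped at ``ccf_cap`` (read-support noise) and clipped
    to <= 1 for classification.

    Returns (m_raw, m_hat, ccf).
    """
    if purity <= 0:
        raise ValueError("purity must be > 0")
    m_raw = vaf * ((1 - purity) * n_normal + purity * n_tot) / purity
    m_hat = int(np.clip(round(m_raw), 1, max(n_major, 1)))
    ccf = min(m_raw / m_hat, ccf_cap)
    return m_raw, m_hat, min(ccf, 1.0)


def classify_clonality(ccf: float, threshold: float = 0.9) -> str:
    """Clonal iff CCF >= threshold (default 0.9)."""
    if ccf < 0:
        raise ValueError("ccf must be >= 0")
    return "clonal" if ccf >= threshold else "subclonal"


def compute_nrpcc(tumor_depth: float, purity: float, ploidy: float) -> float:
    """Number of reads per chromosome copy.

    NRPCC = depth * rho / (rho * psi + 2 * (1 - rho)); the sequencing power
    available to resolve a single tumor chromosome copy (subclone detection
    is considered adequately powered above 10).
    """
    if tumor_depth <= 0:
        raise ValueError("depth must be > 0")
    if purity == 0:
        return 0.0
    return tumor_depth * purity / (purity * ploidy + 2.0 * (1.0 - purity))


def annotate_variants(variants: pd.DataFrame, segments: pd.DataFrame,
                      purity: float, n_normal_by_chrom: dict[str, int] | None = None,
                      clonal_threshold: float = 0.9) -> pd.DataFrame:
    """Attach segment state, multiplicity, CCF and clonality to variants.

    Variants outside any segment are dropped.  ``segments`` uses 0-based
    half-open coordinates; variant ``pos`` is 1-based.
    """
    out_rows = []
    seg_by_chrom = {c: g.sort_values("start") for c, g in segments.groupby("chrom")}
    for _, v in variants.iterrows():
        segs = seg_by_chrom.get(v["chrom"])
        if segs is None:
            continue
        hit = segs[(segs["start"] < v["pos"]) & (v["pos"] <= segs["end"])]
        if hit.empty:
            continue
        seg = hit.iloc[0]
        n_tot = int(seg["n_major"] + seg["n_minor"])
        if n_tot == 0 or v["total_reads"] <= 0:
            continue
        n_norm = 2
        if n_normal_by_chrom and v["chrom"] in n_normal_by_chrom:
            n_norm = n_normal_by_chrom[v["chrom"]]
        vaf = v["alt_reads"] / v["total_reads"]
        m_raw, m_hat, ccf = estimate_multiplicity(vaf, purity, n_tot,
                                                  int(seg["n_major"]), n_norm)
        row = dict(v)
        row.update({"n_tot": n_tot, "n_major_seg": int(seg["n_major"]),
                    "seg_clonal": int(seg["clonal_flag"]),
                    "m_raw": m_raw, "m_hat": m_hat, "ccf_hat": ccf,
                    "clonality_hat": classify_clonality(ccf, clonal_threshold)})
        out_rows.append(row)
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# WGD classification
# ---------------------------------------------------------------------------

def classify_wgd(segments: pd.DataFrame, min_chroms: int = 11) -> WGDCall:
    """WGD status from bp-weighted major-copy-number fractions.

    single: frac(MCN >= 2) > 0.5 AND >= ``min_chroms`` autosomes each with
    > 50% of covered bp at MCN >= 2.  multi: frac(MCN >= 3) > 0.5 (the
    single criteria are evaluated and reported alongside).  Inequalities
    are strict.
    """
    auto = segments[segments["chrom"].isin(AUTOSOMES)].copy()
    if auto.empty:
        raise ValueError("no autosomal segments")
    auto["len"] = auto["end"] - auto["start"]
    total = auto["len"].sum()
    frac2 = auto.loc[auto["n_major"] >= 2, "len"].sum() / total
    frac3 = auto.loc[auto["n_major"] >= 3, "len"].sum() / total

    n_majority = 0
    for _, grp in auto.groupby("chrom"):
        covered = grp["len"].sum()
        if covered > 0 and grp.loc[grp["n_major"] >= 2, "len"].sum() / covered > 0.5:
            n_majority += 1

    single_ok = frac2 > 0.5 and n_majority >= min_chroms
    if frac3 > 0.5:
        status = "multi"
    elif single_ok:
        status = "single"
    else:
        status = "none"
    return WGDCall(status=status, frac_mcn_ge2=float(frac2),
                   frac_mcn_ge3=float(frac3),
                   n_chroms_majority_mcn2=n_majority)


# ---------------------------------------------------------------------------
# WGD timing
# ---------------------------------------------------------------------------

def wgd_timing_ratio(segments: pd.DataFrame, variants: pd.DataFrame,
                     mcn_high: int = 2, mcn_low: int = 1,
                     per_bp: bool = True) -> tuple[float | None, bool]:
    """Clock-mutation density ratio between duplicated and unduplicated MCN strata.

    Default compares MCN = 2 against MCN = 1 (single WGD); pass 3 vs 2 for
    multiple WGD.  Only clonal segments and clonal, clock-flagged variants
    count (subclonal mutations post-date any WGD and carry no timing
    signal); each distinct variant locus counts once (density reading).
    With ``per_bp=False`` raw locus counts are compared instead
    (multiplicity-class reading).  Returns (ratio, defined).
    """
    auto = segments[(segments["chrom"].isin(AUTOSOMES)) &
                    (segments["clonal_flag"] == 1)].copy()
    auto["len"] = auto["end"] - auto["start"]
    clock = variants[variants["clock_flag"].astype(bool)]
    for col in ("clonality_hat", "clonality"):
        if col in clock.columns:
            clock = clock[clock[col] == "clonal"]
            break
    strata = {}
    for label, mcn in (("high", mcn_high), ("low", mcn_low)):
        sel = auto[auto["n_major"] == mcn]
        bp = sel["len"].sum()
        count = 0
        for _, seg in sel.iterrows():
            count += ((clock["chrom"] == seg["chrom"]) &
                      (clock["pos"] > seg["start"]) &
                      (clock["pos"] <= seg["end"])).sum()
        strata[label] = (bp, count)
    (bp_h, n_h), (bp_l, n_l) = strata["high"], strata["low"]
    if bp_h == 0 or bp_l == 0 or n_l == 0:
        return None, False
    if per_bp:
        return float((n_h / bp_h) / (n_l / bp_l)), True
    return float(n_h / n_l), True


def pre_wgd_divisions(segments: pd.DataFrame, variants: pd.DataFrame,
                      autosome_length: int, rate_r: float = 0.6,
                      r_low: float = 0.5, r_high: float = 0.7,
                      clonal_threshold: float = 0.9) -> WGDCall | dict:
    """Cell divisions before WGD from the duplicated mutation burden.

    M_obs counts clonal substitutions (all contexts) at multiplicity 2
    inside clonal balanced 2+2 autosomal segments; extrapolated to the
    whole autosomal genome, M_pre = M_obs / (L_22 / L_auto), and
    divisions = M_pre / (2 r) with bounds at r = 0.7 (low) and 0.5 (high).

    ``variants`` must carry ``m_hat`` and ``clonality_hat`` (or
    ``multiplicity``/``clonality``) annotations.
    """
    auto = segments[(segments["chrom"].isin(AUTOSOMES)) &
                    (segments["clonal_flag"] == 1) &
                    (segments["n_major"] == 2) & (segments["n_minor"] == 2)].copy()
    auto["len"] = auto["end"] - auto["start"]
    l22 = auto["len"].sum()
    if l22 == 0:
        return {"defined": False, "divisions": None}

    m_obs = 0
    if not variants.empty:
        mcol = "m_hat" if "m_hat" in variants.columns else "multiplicity"
        ccol = "clonality_hat" if "clonality_hat" in variants.columns else "clonality"
        cand = variants[(variants[mcol] == 2) & (variants[ccol] == "clonal")]
        for _, seg in auto.iterrows():
            m_obs += ((cand["chrom"] == seg["chrom"]) &
                      (cand["pos"] > seg["start"]) &
                      (cand["pos"] <= seg["end"])).sum()

    m_pre = m_obs / (l22 / autosome_length)
    return {
        "defined": True,
        "m_obs": int(m_obs),
        "l22": int(l22),
        "pre_wgd_burden": float(m_pre),
        "divisions": m_pre / (2.0 * rate_r),
        "divisions_low": m_pre / (2.0 * r_high),
        "divisions_high": m_pre / (2.0 * r_low),
    }


def analyze_sample(segments: pd.DataFrame, variants: pd.DataFrame,
                   autosome_length: int, rate_r: float = 0.6) -> WGDCall:
    """Full WGD analysis of one sample (detection + timing + divisions)."""
    call = classify_wgd(segments)
    high, low = (3, 2) if call.status == "multi" else (2, 1)
    ratio, defined = wgd_timing_ratio(segments, variants, high, low)
    call.timing_ratio, call.timing_defined = ratio, defined
    if call.status != "none":
        div = pre_wgd_divisions(segments, variants, autosome_length, rate_r)
        if div["defined"]:
            call.pre_wgd_burden = div["pre_wgd_burden"]
            call.pre_wgd_divisions = div["divisions"]
            call.divisions_low = div["divisions_low"]
            call.divisions_high = div["divisions_high"]
        else:
            call.notes.append("no clonal 2+2 segments; divisions undefined")
    return call
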