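"""Isochromosome 12p classification and WGD-aware arm/focal event calling.

i(12p) — the germ-cell-tumor hallmark of extra 12p copies relative to
12q — is called from allele-specific segments: the representative copy
number of each arm is the total copy number of its longest clonal segment
(ties broken toward the higher total), and a tumor is i(12p)-positive
under the lenient rule when 12p exceeds 12q by at least one copy, under
the stringent rule by at least two.

Arm-level gains and losses are scored against a WGD-aware baseline
(2 copies for non-WGD tumors, 4 after doubling): an arm is gained/lost
when more than half its covered length lies at least one copy above/below
baseline; copy-neutral LOH requires the minor allele lost at or above
baseline total.  Focal queries report segments whose baseline-relative
copy number reaches +2 (high-level amplification) or -2 (deep deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class I12pCall:
    sample: str
    rep_cn_12p: int | None
    rep_cn_12q: int | None
    lenient: bool
    stringent: bool
    defined: bool = True


@dataclass
class ArmEvent:
    sample: str
    chrom: str
    arm: str
    baseline: int
    weighted_median_cn: float
    frac_bp_gain: float
    frac_bp_loss: float
    call: str             # gain | loss | neutral
    cn_loh: bool
    defined: bool = True


def _rep_cn(arm_segs: pd.DataFrame) -> int | None:
    """Total CN of the longest clonal segment (ties -> higher total CN)."""
    clonal = arm_segs[arm_segs["clonal_flag"] == 1].copy()
    if clonal.empty:
        return None
    clonal["len"] = clonal["end"] - clonal["start"]
    clonal["n_tot"] = clonal["n_major"] + clonal["n_minor"]
    best = clonal.sort_values(["len", "n_tot"], ascending=False).iloc[0]
    return int(best["n_tot"])


def classify_i12p(segments: pd.DataFrame, arms: pd.DataFrame,
                  sample: str = "") -> I12pCall:
    """i(12p) call from chromosome 12 segments.

    ``arms`` holds arm boundaries (chrom, arm, start, end).  Lenient:
    rep_cn(12p) >= rep_cn(12q) + 1; stringent: >= + 2.  Missing clonal
    coverage of either arm yields an undefined call.
    """
    chr12 = segments[segments["chrom"] == "12"]
    bounds = arms[arms["chrom"] == "12"].set_index("arm")
    reps: dict[str, int | None] = {}
    for arm in ("p", "q"):
        s, e = int(bounds.loc[arm, "start"]), int(bounds.loc[arm, "end"])
        mids = (chr12["start"] + chr12["end"]) // 2
        reps[arm] = _rep_cn(chr12[(mids >= s) & (mids < e)])
    if reps["p"] is None or reps["q"] is None:
        return I12pCall(sample, reps["p"], reps["q"], False, False, defined=False)
    lenient = reps["p"] >= reps["q"] + 1
    stringent = reps["p"] >= reps["q"] + 2
    return I12pCall(sample, reps["p"], reps["q"], lenient, stringent)


def call_arm_events(segments: pd.DataFrame, arms: pd.DataFrame,
                    wgd_positive: bool, sample: str = "") -> list[ArmEvent]:
    """Arm-level gain/loss/CN-LOH calls against the WGD-aware baseline."""
    b = 4 if wgd_positive else 2
    out = []
    for _, arm in arms.iterrows():
        chrom, name = arm["chrom"], arm["arm"]
        segs = segments[segments["chrom"] == chrom].copy()
        mids = (segs["start"] + segs["end"]) // 2
        segs = segs[(mids >= arm["start"]) & (mids < arm["end"])]
        if segs.empty:
            out.append(ArmEvent(sample, chrom, name, b, float("nan"), 0.0, 0.0,
                                "neutral", False, defined=False))
            continue
        segs["len"] = segs["end"] - segs["start"]
        segs["n_tot"] = segs["n_major"] + segs["n_minor"]
        total = segs["len"].sum()
        fg = segs.loc[segs["n_tot"] >= b + 1, "len"].sum() / total
        fl = segs.loc[segs["n_tot"] <= b - 1, "len"].sum() / total
        floh = segs.loc[(segs["n_minor"] == 0) & (segs["n_tot"] >= b),
                        "len"].sum() / total
        srt = segs.sort_values("n_tot")
        cum = srt["len"].cumsum() / total
        med = float(srt.loc[cum >= 0.5, "n_tot"].iloc[0])
        call = "gain" if fg > 0.5 else ("loss" if fl > 0.5 else "neutral")
        out.append(ArmEvent(sample, chrom, name, b, med, float(fg), float(fl),
                            call, bool(floh > 0.5)))
    return out


def focal_event_overlap(segments: pd.DataFrame, region: tuple[str, int, int],
                        wgd_positive: bool, min_len: int = 0) -> pd.DataFrame:
    """Clonal segments overlapping a query region, on the baseline-relative scale.

    Reports relative CN = n_tot - baseline (baseline 4 if WGD else 2),
    flags high-level amplification (relative >= +2) and deep deletion
    (relative <= -2), and optionally drops segments shorter than
    ``min_len`` bp (e.g. 10 Mb for large arm-level Y deletions).
    """
    chrom, start, end = region
    b = 4 if wgd_positive else 2
    sel = segments[(segments["chrom"] == chrom) &
                   (segments["clonal_flag"] == 1) &
                   (segments["end"] > start) & (segments["start"] < end)].copy()
    sel["len"] = sel["end"] - sel["start"]
    sel = sel[sel["len"] >= min_len]
    sel["n_tot"] = sel["n_major"] + sel["n_minor"]
    sel["relative_cn"] = sel["n_tot"] - b
    sel["high_amp"] = sel["relative_cn"] >= 2
    sel["deep_del"] = sel["relative_cn"] <= -2
    return sel.reset_index(drop=True)
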