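"""Purity-adjusted sex-chromosome to autosome sequencing-depth ratios.

In a normal male genome the chromosome X (or Y) to autosome depth ratio
centers on 0.5 (one copy versus two).  In tumors, contaminating normal
cells dilute the signal; the adjusted ratio removes the normal-cell
contribution from both numerator and denominator:

    R = (TD_chr - (1 - rho) * ND_chr) / (TD_auto - (1 - rho) * ND_auto)

where TD/ND are mean tumor/normal depths and rho is tumor purity.  This
"literal" form is unbiased only when tumor and normal per-copy coverages
match.  The default "per_copy" mode first rescales tumor depths by the
tumor per-copy coverage  c_t = TD_auto / ((1 - rho) * 2 + rho * psi)  and
normal depths by  c_n = ND_auto / 2, after which the same subtraction
yields R = n_chr / psi for ideal data — the 0.5 baseline is then exact for
a WGD tumor without sex-chromosome gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, Genome, build_genome


@dataclass
class DosageResult:
    sample: str
    chrom: str
    raw_ratio: float        # unadjusted TD_chr / TD_auto
    adjusted_ratio: float
    mode: str               # literal | per_copy
    call: str               # loss | baseline | gain
    clamped: bool = False   # negative adjusted numerator clamped to 0


def _auto_means(depths: pd.DataFrame, genome: Genome | None) -> tuple[float, float]:
    """Length-weighted mean autosomal tumor and normal depth."""
    auto = depths[depths["chrom"].isin(AUTOSOMES)]
    if auto.empty or (auto[["tumor_depth", "normal_depth"]] <= 0).any().any():
        raise ValueError("autosomal depths must be present and positive")
    if genome is not None:
        w = np.array([genome.chrom_lengths[c] for c in auto["chrom"]], dtype=float)
    else:
        w = np.ones(len(auto))
    return (float(np.average(auto["tumor_depth"], weights=w)),
            float(np.average(auto["normal_depth"], weights=w)))


def adjusted_depth_ratio(depths: pd.DataFrame, purity: float, ploidy: float,
                         chrom: str = "X", mode: str = "per_copy",
                         sample: str = "", genome: Genome | None = None,
                         tol: float = 0.05) -> DosageResult:
    """Purity-adjusted chromosome-to-autosome depth ratio for one sample.

    Parameters
    ----------
    depths
        Per-chromosome mean depths: columns chrom, tumor_depth, normal_depth.
    purity, ploidy
        Tumor purity rho in (0, 1] and mean tumor ploidy psi (per_copy mode).
    chrom
        "X" or "Y".
    mode
        "literal" applies the printed subtraction to raw depths; "per_copy"
        (default) rescales to per-copy coverage first so R = n_chr / psi.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]; the adjusted ratio is "
                         "undefined at purity 0")
    if mode not in ("literal", "per_copy"):
        raise ValueError(f"unknown mode {mode!r}")
    genome = genome or build_genome()

    row = depths[depths["chrom"] == chrom]
    if row.empty:
        raise ValueError(f"no depth entry for chromosome {chrom}")
    td_chr = float(row["tumor_depth"].iloc[0])
    nd_chr = float(row["normal_depth"].iloc[0])
    td_auto, nd_auto = _auto_means(depths, genome)
    raw = td_chr / td_auto

    if mode == "per_copy":
        c_t = td_auto / ((1 - purity) * 2 + purity * ploidy)
        c_n = nd_auto / 2.0
        td_chr, td_auto = td_chr / c_t, td_auto / c_t
        nd_chr, nd_auto = nd_chr / c_n, nd_auto / c_n

    num = td_chr - (1 - purity) * nd_chr
    den = td_auto - (1 - purity) * nd_auto
    if den <= 0:
        raise ValueError("non-positive adjusted autosomal depth; check purity")
    clamped = num < 0
    ratio = max(num, 0.0) / den
    return DosageResult(sample=sample, chrom=chrom, raw_ratio=raw,
                        adjusted_ratio=ratio, mode=mode,
                        call=classify_sex_chrom_dosage(ratio, tol),
                        clamped=clamped)


def classify_sex_chrom_dosage(ratio: float, tol: float = 0.05) -> str:
    """Gain/loss/baseline call around the single-copy baseline of 0.5."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio > 0.5 + tol:
        return "gain"
    if ratio < 0.5 - tol:
        return "loss"
    return "baseline"


def cohort_dosage(depths: pd.DataFrame, samples: pd.DataFrame, chrom: str = "X",
                  mode: str = "per_copy", genome: Genome | None = None,
                  tol: float = 0.05) -> pd.DataFrame:
    """Adjusted ratios for every sample in a cohort depth table."""
    meta = samples.set_index("sample")
    out = []
    for sid, grp in depths.groupby("sample", sort=False):
        res = adjusted_depth_ratio(grp, float(meta.loc[sid, "purity"]),
                                   float(meta.loc[sid, "ploidy"]), chrom=chrom,
                                   mode=mode, sample=str(sid), genome=genome,
                                   tol=tol)
        out.append(vars(res))
    return pd.DataFrame(out)
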