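"""Hemizygous-aware copy-number calling for male chromosome X.

The non-pseudoautosomal region of X in males has a single germline copy
and therefore no heterozygous SNPs, so allele-specific (BAF-based) callers
cannot phase it.  This module works from total coverage only: GC-corrected
LogR windows are segmented by penalized piecewise-constant fitting (with
structural-variant breakpoints forced where available), the LogR baseline
is calibrated against autosomal regions of known state, and each segment's
mean LogR is inverted to a real-valued copy number under a purity/ploidy
model with germline copy number N = 1 (non-PAR) or 2 (PAR / autosomes).
Segments near an integer state are called clonal; the fractional part of
intermediate states is read as the cancer cell fraction carrying the
higher state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

NORMAL_PLOIDY = 2.0  # psi_n: genome-average ploidy of the normal genome


@dataclass
class Segment:
    start_idx: int   # first window index (inclusive)
    end_idx: int     # last window index (inclusive)
    start: int       # bp
    end: int         # bp
    mean_logr: float
    n_windows: int


@dataclass
class XStateCall:
    start: int
    end: int
    mean_logr: float
    n_eff: float            # real-valued copies
    n_hat: int              # integer state, clipped to [0, n_max]
    clonal: bool
    ccf_high: float | None  # fraction of tumor cells at n_hat_low + 1, if subclonal
    artifact: bool = False  # n_eff below -tau


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_logr_pcf(logr: Sequence[float], positions: Sequence[tuple[int, int]],
                     gamma: float = 10.0, min_windows: int = 1,
                     sv_breakpoints: Sequence[int] | None = None) -> list[Segment]:
    """Penalized least-squares piecewise-constant segmentation.

    Minimizes  sum of squared residuals + gamma * (number of breakpoints)
    by exact dynamic programming (O(n^2)).  ``positions`` gives each
    window's (start, end) in bp.  SV breakpoint positions are forced: the
    signal is cut there and each block is segmented independently.

    Parameters
    ----------
    gamma
        Breakpoint penalty in squared-LogR units; larger values yield
        fewer segments.
    min_windows
        Minimum windows per segment.
    """
    x = np.asarray(logr, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty LogR track")
    if n < min_windows:
        raise ValueError(f"need at least min_windows={min_windows} windows")
    pos = list(positions)

    # split window indices at forced SV breakpoints
    cuts = {0, n}
    for bp in (sv_breakpoints or []):
        for i, (s, e) in enumerate(pos):
            if s >= bp:
                if 0 < i < n:
                    cuts.add(i)
                break
    bounds = sorted(cuts)

    segments: list[Segment] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        segments.extend(_pcf_block(x, pos, b0, b1, gamma, min_windows))
    return segments


def _pcf_block(x: np.ndarray, pos: list[tuple[int, int]], lo: int, hi: int,
               gamma: float, min_windows: int) -> list[Segment]:
    """Exact DP over x[lo:hi]."""
    y = x[lo:hi]
    m = len(y)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csq = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(i: int, j: int) -> float:  # cost of one segment over y[i:j]
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / (j - i)

    best = np.full(m + 1, np.inf)
    back = np.zeros(m + 1, dtype=int)
    best[0] = -gamma  # first segment incurs no breakpoint penalty
    for j in range(1, m + 1):
        for i in range(0, j - min_windows + 1):
            if j - i < min_windows:
                continue
            c = best[i] + gamma + sse(i, j)
            if c < best[j]:
                best[j], back[j] = c, i
    if not np.isfinite(best[m]):  # block shorter than min_windows
        best[m], back[m] = sse(0, m), 0

    cuts = []
    j = m
    while j > 0:
        i = back[j]
        cuts.append((i, j))
        j = i
    cuts.reverse()
    out = []
    for i, j in cuts:
        a, b = lo + i, lo + j - 1
        mean = float((csum[j] - csum[i]) / (j - i))
        out.append(Segment(a, b, pos[a][0], pos[b][1], mean, j - i))
    return out


def segment_track(track: pd.DataFrame, gamma: float = 10.0, min_windows: int = 1,
                  sv_breakpoints: Sequence[int] | None = None) -> list[Segment]:
    """Segment a (chrom, start, end, logr) window table (single chromosome)."""
    return segment_logr_pcf(track["logr"].to_numpy(float),
                            list(zip(track["start"], track["end"])),
                            gamma=gamma, min_windows=min_windows,
                            sv_breakpoints=sv_breakpoints)


# ---------------------------------------------------------------------------
# calibration and state model
# ---------------------------------------------------------------------------

def expected_logr(n: float, purity: float, tumor_ploidy: float,
                  n_normal: int = 2) -> float:
    """Expected LogR of a region at tumor copy number ``n``.

    log2( psi_n * ((1-rho) * N + rho * n) / (N * ((1-rho) * psi_n + rho * psi_t)) )
    with normal genome ploidy psi_n = 2.  Hemizygous male X/Y enters via
    N = 1, not via psi_n, so autosomes, PAR and non-PAR share one formula.
    """
    if n < 0:
        raise ValueError("copy number must be >= 0")
    if n_normal not in (1, 2):
        raise ValueError("n_normal must be 1 or 2")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    num = NORMAL_PLOIDY * ((1 - purity) * n_normal + purity * n)
    den = n_normal * ((1 - purity) * NORMAL_PLOIDY + purity * tumor_ploidy)
    if num <= 0:
        return -np.inf  # pure tumor at n = 0: no signal
    return float(math.log2(num / den))


def calibrate_logr(track: pd.DataFrame, calibration_regions: pd.DataFrame,
                   purity: float, tumor_ploidy: float) -> tuple[pd.DataFrame, float]:
    """Additive LogR shift from autosomal regions of known copy state.

    ``calibration_regions`` columns: chrom, start, end, n (tumor copies),
    n_normal.  The shift delta is the median, over all calibration windows,
    of expected - observed LogR (pooling diploid and gained classes), so
    that after shifting the median observed value matches the state model.
    Returns the shifted track and delta.
    """
    diffs = []
    for _, reg in calibration_regions.iterrows():
        exp = expected_logr(float(reg["n"]), purity, tumor_ploidy,
                            int(reg.get("n_normal", 2)))
        sel = track[(track["chrom"] == reg["chrom"]) &
                    (track["start"] >= reg["start"]) &
                    (track["end"] <= reg["end"])]
        diffs.extend((exp - sel["logr"]).tolist())
    if not diffs:
        raise ValueError("calibration regions do not overlap the LogR track")
    delta = float(np.median(diffs))
    out = track.copy()
    out["logr"] = out["logr"] + delta
    return out, delta


def fit_copy_state(mean_logr: float, purity: float, tumor_ploidy: float,
                   n_normal: int = 1, tau: float = 0.2, n_max: int = 8,
                   start: int = 0, end: int = 0) -> XStateCall:
    """Invert the expected-LogR model to an integer copy-number call.

    n_eff = (N * ((1-rho) * psi_n + rho * psi_t) * 2^L / psi_n - (1-rho) * N) / rho

    The segment is clonal iff |n_eff - round(n_eff)| <= tau copies
    (default 0.2); otherwise it is subclonal and the fractional part of
    n_eff is the fraction of tumor cells carrying the next-higher state.
    """
    if purity <= 0:
        raise ValueError("purity must be > 0 to invert the LogR model")
    rho = purity
    n_eff = (n_normal * ((1 - rho) * NORMAL_PLOIDY + rho * tumor_ploidy)
             * 2.0 ** mean_logr / NORMAL_PLOIDY - (1 - rho) * n_normal) / rho
    artifact = n_eff < -tau
    n_hat = int(np.clip(round(n_eff), 0, n_max))
    clonal = abs(n_eff - round(n_eff)) <= tau
    call = XStateCall(start=start, end=end, mean_logr=mean_logr, n_eff=n_eff,
                      n_hat=n_hat, clonal=clonal, ccf_high=None,
                      artifact=artifact)
    if not clonal:
        call.ccf_high = estimate_subclonal_ccf(call)
    return call


def estimate_subclonal_ccf(call: XStateCall) -> float:
    """CCF of the higher state for a subclonal segment.

    A real-valued state n_eff between integers k and k+1 is read as a
    mixture: a fraction  n_eff - k  of tumor cells carry k+1 copies.
    """
    if call.clonal:
        raise ValueError("CCF of the higher state is defined only for "
                         "subclonal segments")
    return float(call.n_eff - math.floor(call.n_eff))


def call_x_segments(track: pd.DataFrame, purity: float, tumor_ploidy: float,
                    gamma: float = 10.0, min_windows: int = 1,
                    sv_breakpoints: Sequence[int] | None = None,
                    n_normal: int = 1, tau: float = 0.2, n_max: int = 8
                    ) -> pd.DataFrame:
    """Segment + fit pipeline for one calibrated chromosome X LogR track."""
    segs = segment_track(track, gamma=gamma, min_windows=min_windows,
                         sv_breakpoints=sv_breakpoints)
    rows = []
    for s in segs:
        c = fit_copy_state(s.mean_logr, purity, tumor_ploidy, n_normal=n_normal,
                           tau=tau, n_max=n_max, start=s.start, end=s.end)
        rows.append({
            "start": c.start, "end": c.end, "mean_logr": c.mean_logr,
            "n_eff": c.n_eff, "n_major": c.n_hat, "n_minor": 0 if n_normal == 1 else None,
            "clonal_flag": int(c.clonal), "ccf_high": c.ccf_high,
            "artifact": c.artifact,
        })
    return pd.DataFrame(rows)
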