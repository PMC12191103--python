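"""Synthetic germ-cell-tumor cohort generator with known ground truth.

Emulates the statistical structure of tumor/normal WGS-derived inputs for
the downstream analyses in this package: purity-diluted sequencing depths,
copy-number-consistent variant allele fractions, clock-like mutation
accrual before and after whole-genome doubling (WGD), pre-WGD cell-division
burden, subclonal mutation clusters, chromosome X amplification up to eight
copies, isochromosome 12p, and expression/methylation matrices.

Generative model
----------------
Each tumor has an age at diagnosis, purity, WGD status, a most recent
common ancestor (MRCA) age, and a WGD time.  Clock-like mutations accrue
per base pair per chromosome copy at a constant rate ``mu / (2 * L_auto)``
per year (``mu`` = clock mutations per diploid autosomal genome per year),
so a copy present since conception carries ``mu * t / 2`` expected clock
mutations per haploid autosomal genome at time ``t``.  Mutations acquired
before a duplication are carried by every descendant copy (multiplicity =
copies of that allele); mutations after it have multiplicity one.  Pre-WGD
cell divisions add substitutions at ``r`` per haploid genome per division
(``r`` in 0.5-0.7).  Subclonal mutations accrue on the sampled lineage
after the MRCA; each subclone's locus count is scaled by 1/CCF so that the
CCF-weighted per-cell burden matches the clock expectation.  Read support
is binomial around the expected VAF and depths are Poisson at the window
level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, Genome, Region, build_genome

READ_LENGTH = 151  # bp, matches 2x151 paired-end sequencing

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults reflect the cohort structure the package targets: deep tumor
    (80x) and normal (32x) WGS, adolescent/young-adult ages, near-ubiquitous
    WGD of fetal origin, frequent chromosome X amplification and i(12p).
    """

    n_samples: int = 20
    seed: int = 0
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_tumor: float = 80.0
    depth_normal: float = 32.0
    age_range: tuple[float, float] = (15.0, 45.0)
    clock_rate_mu: float = 3.0        # clock mutations / diploid genome / year
    nonclock_rate: float = 3.0        # non-clock mutations / diploid genome / year
    pre_wgd_rate_r: float = 0.6       # substitutions / haploid genome / cell division
    pre_wgd_divisions_range: tuple[int, int] = (30, 70)
    p_wgd: float = 0.917
    p_multi_wgd: float = 0.0635       # conditional on WGD
    wgd_time_fraction_range: tuple[float, float] = (0.0, 0.05)  # fraction of age
    mrca_fraction_range: tuple[float, float] = (0.5, 1.0)       # fraction of age
    x_copy_distribution: tuple[float, ...] = (0.06, 0.22, 0.30, 0.22, 0.10, 0.05, 0.03, 0.02)
    p_x_subclonal: float = 0.177
    p_i12p: float = 0.88
    p_i12p_two_extra: float = 0.5     # of i(12p) tumors, fraction with >=2 extra 12p copies
    p_y_loss: float = 0.234
    p_seminoma: float = 0.567
    max_subclones: int = 2
    subclone_ccf_range: tuple[float, float] = (0.2, 0.8)
    wgd_arm_loss_fraction: float = 0.25  # arms reverting to MCN=1 after WGD
    segment_mean_length: int = 10_000_000
    window_size: int = 100_000
    total_autosome_bp: int = 3_000_000_000
    min_alt_reads: int = 1

    def validate(self) -> None:
        for name in ("p_wgd", "p_multi_wgd", "p_x_subclonal", "p_i12p",
                     "p_i12p_two_extra", "p_y_loss", "p_seminoma",
                     "wgd_arm_loss_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("purity_range", "age_range", "wgd_time_fraction_range",
                     "mrca_fraction_range", "subclone_ccf_range",
                     "pre_wgd_divisions_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} not ordered: {lo} > {hi}")
        if self.clock_rate_mu <= 0:
            raise ConfigError("clock_rate_mu must be positive")
        if self.pre_wgd_rate_r <= 0:
            raise ConfigError("pre_wgd_rate_r must be positive")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if len(self.x_copy_distribution) != 8:
            raise ConfigError("x_copy_distribution needs weights for 1..8 copies")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class SampleTruth:
    """Per-sample generative ground truth."""

    sample: str
    subtype: str
    age: float
    purity: float
    ploidy: float
    wgd_status: str              # none | single | multi
    wgd_time: float              # years (0 if no WGD)
    pre_wgd_divisions: int
    mrca_age: float
    latency: float
    x_total_copies: int
    x_subclonal_ccf: float | None
    i12p_flag: bool
    i12p_extra_copies: int
    subclone_ccfs: list[float]
    latent_expr_score: float = 0.0


@dataclass
class GroundTruth:
    """Truth ledger for an entire simulated cohort."""

    samples: list[SampleTruth] = field(default_factory=list)

    def by_sample(self) -> dict[str, SampleTruth]:
        return {t.sample: t for t in self.samples}

    def to_json(self, path: str | Path) -> None:
        payload = [asdict(t) for t in self.samples]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class Cohort:
    """In-memory simulated cohort: the tables every downstream stage consumes."""

    samples: pd.DataFrame
    segments: pd.DataFrame
    variants: pd.DataFrame
    depths: pd.DataFrame
    expression: pd.DataFrame | None
    methylation: pd.DataFrame | None
    probe_map: pd.DataFrame | None
    truth: GroundTruth
    genome: Genome

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        seg = self.segments.copy()
        seg["start"] = seg["start"] + 1  # 1-based inclusive on disk
        seg.to_csv(out / "segments.tsv", sep="\t", index=False)
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.depths.to_csv(out / "depths.tsv", sep="\t", index=False)
        if self.expression is not None:
            self.expression.to_csv(out / "expr.tsv", sep="\t")
        if self.methylation is not None:
            self.methylation.to_csv(out / "meth.tsv", sep="\t")
        if self.probe_map is not None:
            self.probe_map.to_csv(out / "probes.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# expected VAF
# ---------------------------------------------------------------------------

def expected_vaf(purity: float, n_tot: float, multiplicity: float,
                 ccf: float, n_normal: int) -> float:
    """Expected variant allele fraction under the purity/copy-number mixture.

    VAF = rho * f * m / ((1 - rho) * N + rho * n_tot), where ``rho`` is
    purity, ``f`` the cancer cell fraction, ``m`` the number of tumor copies
    carrying the variant, ``n_tot`` the tumor total copy number and ``N``
    the normal copy number at the locus (1 on male non-PAR X/Y, else 2).
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity {purity} outside (0, 1]")
    if not 0 < ccf <= 1:
        raise ValueError(f"ccf {ccf} outside (0, 1]")
    if multiplicity < 1 or multiplicity > n_tot:
        raise ValueError(f"multiplicity {multiplicity} outside [1, n_tot={n_tot}]")
    if n_normal not in (1, 2):
        raise ValueError("n_normal must be 1 or 2")
    return purity * ccf * multiplicity / ((1 - purity) * n_normal + purity * n_tot)


# ---------------------------------------------------------------------------
# per-sample copy-number state construction
# ---------------------------------------------------------------------------

@dataclass
class _SegState:
    """Internal true segment state (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int
    clonal: bool
    ccf: float              # 1.0 for clonal; fraction at n+1 for subclonal gain
    gain_time: float        # years at which the allele reached multi-copy state
    n_normal: int

    @property
    def n_tot(self) -> int:
        return self.n_major + self.n_minor

    @property
    def length(self) -> int:
        return self.end - self.start


def _subdivide(start: int, end: int, mean_len: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split [start, end) into exponential-length pieces (>=1 piece)."""
    pieces = []
    pos = start
    while pos < end:
        ln = max(int(rng.exponential(mean_len)), mean_len // 10 + 1)
        nxt = min(pos + ln, end)
        pieces.append((pos, nxt))
        pos = nxt
    return pieces


def _draw_sample_truth(cfg: SimConfig, idx: int, rng: np.random.Generator) -> SampleTruth:
    age = rng.uniform(*cfg.age_range)
    purity = rng.uniform(*cfg.purity_range)
    subtype = "seminoma" if rng.random() < cfg.p_seminoma else "non-seminoma"
    mrca_age = age * rng.uniform(*cfg.mrca_fraction_range)
    latency = age - mrca_age

    if rng.random() < cfg.p_wgd:
        status = "multi" if rng.random() < cfg.p_multi_wgd else "single"
        wgd_time = min(age * rng.uniform(*cfg.wgd_time_fraction_range), mrca_age)
    else:
        status, wgd_time = "none", 0.0
    divisions = int(rng.integers(cfg.pre_wgd_divisions_range[0],
                                 cfg.pre_wgd_divisions_range[1] + 1))

    weights = np.asarray(cfg.x_copy_distribution, dtype=float)
    x_copies = int(rng.choice(np.arange(1, 9), p=weights / weights.sum()))
    x_sub = float(rng.uniform(*cfg.subclone_ccf_range)) if rng.random() < cfg.p_x_subclonal else None

    i12p = rng.random() < cfg.p_i12p
    extra = 0
    if i12p:
        extra = 2 if rng.random() < cfg.p_i12p_two_extra else 1

    # positive latency implies detectable post-MRCA lineages (>= 1 subclone);
    # an MRCA strictly before diagnosis is unidentifiable without them
    if latency == 0.0:
        ccfs: list[float] = []
    else:
        n_sub = int(rng.integers(1, max(cfg.max_subclones, 1) + 1))
        ccfs = sorted(float(rng.uniform(*cfg.subclone_ccf_range)) for _ in range(n_sub))

    return SampleTruth(
        sample=f"S{idx:04d}", subtype=subtype, age=age, purity=purity,
        ploidy=0.0, wgd_status=status, wgd_time=wgd_time,
        pre_wgd_divisions=divisions, mrca_age=mrca_age, latency=latency,
        x_total_copies=x_copies, x_subclonal_ccf=x_sub, i12p_flag=i12p,
        i12p_extra_copies=extra, subclone_ccfs=ccfs,
    )


def _build_states(cfg: SimConfig, genome: Genome, truth: SampleTruth,
                  rng: np.random.Generator) -> list[_SegState]:
    """True copy-number states for one sample, arm by arm."""
    wgd = truth.wgd_status != "none"
    base_allele = {"none": 1, "single": 2, "multi": 3}[truth.wgd_status]
    states: list[_SegState] = []

    for chrom in AUTOSOMES:
        for arm, (s, e) in genome.arm_bounds(chrom).items():
            a = base_allele
            # chr12 is reserved for the controlled i(12p) state: random arm
            # losses elsewhere would mimic relative 12p excess
            if wgd and chrom != "12" and rng.random() < cfg.wgd_arm_loss_fraction:
                a = base_allele - 1  # post-WGD loss of one copy per allele
            n_major = n_minor = a
            if chrom == "12" and arm == "p" and truth.i12p_flag:
                n_major = a + truth.i12p_extra_copies
            gain_time = truth.wgd_time if max(n_major, n_minor) >= 2 else 0.0
            for ps, pe in _subdivide(s, e, cfg.segment_mean_length, rng):
                states.append(_SegState(chrom, ps, pe, n_major, n_minor,
                                        True, 1.0, gain_time, 2))

    # chromosome X: PARs behave like autosomes, non-PAR is hemizygous
    x_gain_time = truth.wgd_time if wgd else truth.mrca_age * float(rng.uniform(0.0, 0.3))
    for reg in genome.chrom_regions("X"):
        if reg.name in ("PAR1", "PAR2"):
            a = base_allele
            states.append(_SegState("X", reg.start, reg.end, a, a, True, 1.0,
                                    truth.wgd_time if wgd else 0.0, 2))
        else:
            n = truth.x_total_copies
            sub = truth.x_subclonal_ccf
            for ps, pe in _subdivide(reg.start, reg.end, cfg.segment_mean_length, rng):
                if sub is None:
                    states.append(_SegState("X", ps, pe, n, 0, True, 1.0,
                                            x_gain_time if n >= 2 else 0.0, 1))
                else:
                    states.append(_SegState("X", ps, pe, n, 0, False, sub,
                                            x_gain_time if n >= 2 else 0.0, 1))

    # chromosome Y: baseline 1, whole-chromosome loss with probability p_y_loss
    y_lost = rng.random() < cfg.p_y_loss
    ly = genome.chrom_lengths["Y"]
    states.append(_SegState("Y", 0, ly, 0 if y_lost else 1, 0, True, 1.0, 0.0, 1))
    return states


def _mean_ploidy(states: Sequence[_SegState]) -> float:
    """Length-weighted mean autosomal total copy number."""
    num = sum(s.n_tot * s.length for s in states if s.chrom in AUTOSOMES)
    den = sum(s.length for s in states if s.chrom in AUTOSOMES)
    return num / den


# ---------------------------------------------------------------------------
# mutation simulation
# ---------------------------------------------------------------------------

def _draw_contexts(n: int, clock: bool, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trinucleotide contexts (pyrimidine-strand) with ref/alt alleles.

    Clock mutations are C>T at NpCpG; others avoid that pattern.
    """
    if n == 0:
        empty = np.array([], dtype="<U3")
        return empty, empty.astype("<U1"), empty.astype("<U1")
    if clock:
        five = rng.choice(_BASES, size=n)
        ctx = np.char.add(five, "CG")
        return ctx, np.full(n, "C"), np.full(n, "T")
    five = rng.choice(_BASES, size=n)
    three = rng.choice(_BASES, size=n)
    ref = rng.choice(np.array(["C", "T"]), size=n)
    alts = np.empty(n, dtype="<U1")
    for i in range(n):
        if ref[i] == "C":
            choices = ["A", "G"] if three[i] == "G" else ["A", "G", "T"]
        else:
            choices = ["A", "C", "G"]
        alts[i] = choices[rng.integers(len(choices))]
    return np.char.add(np.char.add(five, ref), three), ref, alts


def _emit_variants_for_sample(cfg: SimConfig, genome: Genome, truth: SampleTruth,
                              states: Sequence[_SegState],
                              rng: np.random.Generator) -> pd.DataFrame:
    l_auto = genome.autosome_length
    lam_clock = cfg.clock_rate_mu / (2.0 * l_auto)      # per bp per copy per year
    lam_other = cfg.nonclock_rate / (2.0 * l_auto)
    div_rate = cfg.pre_wgd_rate_r * truth.pre_wgd_divisions / l_auto  # per bp per copy
    rho, age, t_mrca = truth.purity, truth.age, truth.mrca_age
    wgd = truth.wgd_status != "none"

    rows: list[dict] = []

    def emit(seg: _SegState, n_loci: int, mult: int, ccf: float, clonality: str,
             clock: bool) -> None:
        if n_loci == 0:
            return
        pos = rng.integers(seg.start, seg.end, size=n_loci)
        ctx, ref, alt = _draw_contexts(n_loci, clock, rng)
        c_t = cfg.depth_tumor / ((1 - rho) * 2 + rho * truth.ploidy)
        mean_dp = c_t * ((1 - rho) * seg.n_normal + rho * seg.n_tot)
        dp = rng.poisson(mean_dp, size=n_loci)
        ev = expected_vaf(rho, seg.n_tot, mult, ccf, seg.n_normal)
        ad = rng.binomial(np.maximum(dp, 1), min(ev, 1.0))
        for i in range(n_loci):
            if dp[i] < 1 or ad[i] < cfg.min_alt_reads:
                continue
            rows.append({
                "sample": truth.sample, "chrom": seg.chrom, "pos": int(pos[i]) + 1,
                "ref": ref[i], "alt": alt[i], "alt_reads": int(ad[i]),
                "total_reads": int(dp[i]), "context": ctx[i],
                "clock_flag": clock, "multiplicity": mult, "ccf": ccf,
                "clonality": clonality,
            })

    n_sub = len(truth.subclone_ccfs)
    for seg in states:
        if seg.n_tot == 0:
            continue
        for copies in (seg.n_major, seg.n_minor):
            if copies == 0:
                continue
            t_g = seg.gain_time if copies >= 2 else 0.0
            for lam, is_clock in ((lam_clock, True), (lam_other, False)):
                if copies >= 2:
                    pre = rng.poisson(lam * seg.length * t_g)
                    post = rng.poisson(lam * seg.length * (t_mrca - t_g) * copies)
                    emit(seg, pre, copies, 1.0, "clonal", is_clock)
                    emit(seg, post, 1, 1.0, "clonal", is_clock)
                else:
                    emit(seg, rng.poisson(lam * seg.length * t_mrca), 1, 1.0,
                         "clonal", is_clock)
            # pre-WGD cell-division burden (duplicated by later WGD)
            if wgd:
                emit(seg, rng.poisson(div_rate * seg.length), copies, 1.0,
                     "clonal", False)
            else:
                emit(seg, rng.poisson(div_rate * seg.length), 1, 1.0,
                     "clonal", False)
        # subclonal accrual on the sampled lineage after the MRCA
        if n_sub and age > t_mrca:
            for ccf in truth.subclone_ccfs:
                for lam, is_clock in ((lam_clock, True), (lam_other, False)):
                    mean = lam * seg.length * seg.n_tot * (age - t_mrca) / (n_sub * ccf)
                    emit(seg, rng.poisson(mean), 1, ccf, "subclonal", is_clock)

    cols = ["sample", "chrom", "pos", "ref", "alt", "alt_reads", "total_reads",
            "context", "clock_flag", "multiplicity", "ccf", "clonality"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------

def simulate_window_depths(genome: Genome, states: Sequence[_SegState] | None,
                           purity: float, ploidy: float, depth_tumor: float,
                           depth_normal: float, window_size: int,
                           rng: np.random.Generator,
                           chroms: Sequence[str] | None = None) -> pd.DataFrame:
    """Window-level tumor/normal depths with Poisson read-count noise.

    ``states=None`` simulates a normal male genome as "tumor" (copy-neutral,
    purity irrelevant).  Tumor window depth is Poisson around
    ``c_t * ((1-rho) * N + rho * n)`` where ``c_t`` is the per-copy tumor
    coverage implied by the configured mean autosomal depth; normal depth is
    Poisson around ``(depth_normal / 2) * N``.
    """
    chroms = list(chroms) if chroms is not None else list(AUTOSOMES) + ["X", "Y"]
    c_n = depth_normal / 2.0
    c_t = depth_tumor / ((1 - purity) * 2 + purity * ploidy) if states is not None else depth_tumor / 2.0

    lookup: list[_SegState] = sorted(states, key=lambda s: (s.chrom, s.start)) if states else []
    rows = []
    for chrom in chroms:
        length = genome.chrom_lengths[chrom]
        seg_iter = [s for s in lookup if s.chrom == chrom]
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            mid = (start + end) // 2
            n_norm = genome.normal_copies(chrom, mid)
            if states is None:
                n_tum_eff = float(n_norm)
            else:
                seg = next((s for s in seg_iter if s.start <= mid < s.end), None)
                n = float(seg.n_tot) if seg is not None else float(n_norm)
                if seg is not None and not seg.clonal:
                    n = seg.n_tot + seg.ccf  # mixture of n and n+1 states
                n_tum_eff = (1 - purity) * n_norm + purity * n
            w = end - start
            mean_t_reads = c_t * n_tum_eff * w / READ_LENGTH
            mean_n_reads = c_n * n_norm * w / READ_LENGTH
            t_reads = rng.poisson(mean_t_reads)
            n_reads = rng.poisson(mean_n_reads)
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "tumor_depth": t_reads * READ_LENGTH / w,
                "normal_depth": n_reads * READ_LENGTH / w,
            })
    return pd.DataFrame(rows)


def summarize_depths(windows: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Per-chromosome mean depths (length-weighted) from window depths."""
    win = windows.copy()
    win["w"] = win["end"] - win["start"]
    out = []
    for chrom, grp in win.groupby("chrom", sort=False):
        w = grp["w"].to_numpy(float)
        out.append({
            "chrom": chrom,
            "tumor_depth": float(np.average(grp["tumor_depth"], weights=w)),
            "normal_depth": float(np.average(grp["normal_depth"], weights=w)),
        })
    return pd.DataFrame(out)


def logr_track(windows: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """LogR = log2((tumor/mean autosomal tumor) / (normal/mean autosomal normal)).

    Mirrors standard coverage normalization; windows with zero counts are
    dropped.
    """
    auto = windows[windows["chrom"].isin(AUTOSOMES)]
    w = (auto["end"] - auto["start"]).to_numpy(float)
    mt = np.average(auto["tumor_depth"], weights=w)
    mn = np.average(auto["normal_depth"], weights=w)
    keep = (windows["tumor_depth"] > 0) & (windows["normal_depth"] > 0)
    track = windows[keep].copy()
    track["logr"] = np.log2((track["tumor_depth"] / mt) / (track["normal_depth"] / mn))
    return track[["chrom", "start", "end", "logr"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression / methylation
# ---------------------------------------------------------------------------

def simulate_expression(n_samples: int, gene_weights: pd.Series,
                        rng: np.random.Generator, noise_sd: float = 0.1
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression matrix (genes x samples) from a latent per-sample score.

    Each sample draws a standard-normal latent score; gene value =
    weight * score + Gaussian noise.  Returns the matrix and latent scores.
    """
    if n_samples < 2:
        raise ConfigError("need >= 2 samples for expression simulation")
    if len(gene_weights) < 1:
        raise ConfigError("need >= 1 weighted gene")
    latent = rng.standard_normal(n_samples)
    values = np.outer(gene_weights.to_numpy(float), latent)
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    cols = [f"S{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(values, index=gene_weights.index, columns=cols), latent


def default_gene_weights(rng: np.random.Generator | None = None) -> pd.Series:
    """Synthetic 17-gene replication-stress weight table.

    The published score uses weights from an external study that are not
    redistributed here; this synthetic stand-in preserves the structure
    (17 signed weights) for simulation and testing.
    """
    rng = rng or np.random.default_rng(170)
    genes = [f"RSG{i:02d}" for i in range(1, 18)]
    w = rng.normal(0.0, 1.0, size=17)
    w[np.abs(w) < 0.2] = 0.5  # keep every gene informative
    return pd.Series(w, index=genes, name="weight")


def simulate_methylation(n_samples: int, rng: np.random.Generator,
                         n_x: int = 60, n_auto: int = 140, n_flat: int = 50
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta-value matrix with hypomethylated X probes and low-MAD flat probes."""
    cols = [f"S{i:04d}" for i in range(n_samples)]
    sample_shift = rng.normal(0.0, 0.08, size=n_samples)

    def block(n, mean, spread, chrom_pool):
        base = rng.uniform(mean - spread, mean + spread, size=(n, 1))
        vals = np.clip(base + sample_shift + rng.normal(0, 0.05, (n, n_samples)), 0, 1)
        chroms = rng.choice(chrom_pool, size=n)
        return vals, chroms

    vx, cx = block(n_x, 0.25, 0.15, np.array(["X"]))
    va, ca = block(n_auto, 0.55, 0.2, np.asarray(AUTOSOMES))
    vf = np.clip(0.5 + rng.normal(0, 0.01, (n_flat, n_samples)), 0, 1)
    cf = rng.choice(np.asarray(AUTOSOMES), size=n_flat)

    values = np.vstack([vx, va, vf])
    chroms = np.concatenate([cx, ca, cf])
    probes = [f"cg{i:07d}" for i in range(values.shape[0])]
    beta = pd.DataFrame(values, index=probes, columns=cols)
    pmap = pd.DataFrame({"probe": probes, "chrom": chroms})
    return beta, pmap


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def build_cohort(cfg: SimConfig, outdir: str | Path | None = None,
                 with_depths: bool = True, with_omics: bool = True) -> Cohort:
    """Generate a full synthetic cohort.

    Deterministic for a fixed ``cfg.seed``.  Emits sample metadata,
    allele-specific segments, somatic variants with read support,
    per-chromosome depth summaries, and (optionally) expression/methylation
    matrices, alongside the ground-truth ledger.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = build_genome(cfg.total_autosome_bp)

    truth = GroundTruth()
    seg_rows, var_frames, depth_rows = [], [], []
    for i in range(cfg.n_samples):
        st = _draw_sample_truth(cfg, i, rng)
        states = _build_states(cfg, genome, st, rng)
        st.ploidy = _mean_ploidy(states)
        truth.samples.append(st)

        for s in states:
            seg_rows.append({
                "sample": st.sample, "chrom": s.chrom, "start": s.start,
                "end": s.end, "n_major": s.n_major, "n_minor": s.n_minor,
                "clonal_flag": int(s.clonal), "ccf": s.ccf,
            })
        var_frames.append(_emit_variants_for_sample(cfg, genome, st, states, rng))

        if with_depths:
            win = simulate_window_depths(genome, states, st.purity, st.ploidy,
                                         cfg.depth_tumor, cfg.depth_normal,
                                         cfg.window_size, rng)
            summ = summarize_depths(win, genome)
            summ.insert(0, "sample", st.sample)
            depth_rows.append(summ)

    samples = pd.DataFrame({
        "sample": [t.sample for t in truth.samples],
        "subtype": [t.subtype for t in truth.samples],
        "age_years": [t.age for t in truth.samples],
        "purity": [t.purity for t in truth.samples],
        "ploidy": [t.ploidy for t in truth.samples],
    })
    segments = pd.DataFrame(seg_rows)
    variants = pd.concat(var_frames, ignore_index=True) if var_frames else pd.DataFrame()
    depths = pd.concat(depth_rows, ignore_index=True) if depth_rows else pd.DataFrame()

    expression = methylation = probe_map = None
    if with_omics:
        weights = default_gene_weights()
        expression, latent = simulate_expression(cfg.n_samples, weights, rng)
        expression.columns = samples["sample"]
        for t, sc in zip(truth.samples, latent):
            t.latent_expr_score = float(sc)
        methylation, probe_map = simulate_methylation(cfg.n_samples, rng)
        methylation.columns = samples["sample"]

    cohort = Cohort(samples=samples, segments=segments, variants=variants,
                    depths=depths, expression=expression,
                    methylation=methylation, probe_map=probe_map,
                    truth=truth, genome=genome)
    if outdir is not None:
        cohort.write(outdir)
    return cohort
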