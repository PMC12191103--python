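import numpy as np
import pandas as pd
import pytest

from gctevo.genome import build_genome
from gctevo.simcohort import SimConfig

TEST_GENOME_BP = 30_000_000  # scaled autosomal length used throughout the suite


def small_config(**overrides) -> SimConfig:
    """SimConfig on the 30 Mb test genome with 10 kb windows."""
    base = dict(total_autosome_bp=TEST_GENOME_BP, window_size=10_000)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def test_genome():
    return build_genome(TEST_GENOME_BP)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A deterministic 6-sample cohort shared by read-only tests."""
    from gctevo.simcohort import build_cohort

    return build_cohort(small_config(n_samples=6, seed=42))


def make_segments(rows, sample="S"):
    """Segment table helper: rows of (chrom, start, end, n_major, n_minor[, clonal, ccf])."""
    recs = []
    for r in rows:
        chrom, start, end, nmaj, nmin = r[:5]
        clonal = r[5] if len(r) > 5 else 1
        ccf = r[6] if len(r) > 6 else 1.0
        recs.append({"sample": sample, "chrom": str(chrom), "start": start,
                     "end": end, "n_major": nmaj, "n_minor": nmin,
                     "clonal_flag": clonal, "ccf": ccf})
    return pd.DataFrame(recs)


def make_variants(rows, sample="S"):
    """Variant table helper: rows of dicts with defaults filled in."""
    defaults = {"sample": sample, "ref": "C", "alt": "T", "alt_reads": 10,
                "total_reads": 20, "context": "ACG", "clock_flag": True,
                "multiplicity": 1, "ccf": 1.0, "clonality": "clonal"}
    recs = []
    for r in rows:
        rec = dict(defaults)
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)
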