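"""Shared fixtures and table builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrmediation import HarmonizedSet


def make_table(
    ids,
    beta,
    se,
    pval=None,
    eaf=0.3,
    effect_allele="A",
    other_allele="G",
    n=100_000,
    chrom=None,
    pos=None,
):
    """Build a canonical summary-statistics DataFrame from per-variant arrays."""
    k = len(ids)

    def expand(x):
        return list(x) if np.ndim(x) else [x] * k

    from scipy import stats

    beta = np.asarray(expand(beta), dtype=float)
    se = np.asarray(expand(se), dtype=float)
    if pval is None:
        pval = 2 * stats.norm.sf(np.abs(beta) / se)
    df = pd.DataFrame(
        {
            "variant_id": list(ids),
            "effect_allele": expand(effect_allele),
            "other_allele": expand(other_allele),
            "eaf": expand(eaf),
            "beta": beta,
            "se": se,
            "pval": expand(pval),
            "n": expand(n),
        }
    )
    if chrom is not None:
        df["chrom"] = expand(chrom)
    if pos is not None:
        df["pos"] = expand(pos)
    return df


def make_harmonized(bx, by, sex=None, sey=None, ids=None, extras=None):
    """Build a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    n = bx.size
    sex = np.full(n, 0.01) if sex is None else np.asarray(sex, dtype=float)
    sey = np.full(n, 0.05) if sey is None else np.asarray(sey, dtype=float)
    ids = np.array([f"rs{i+1:04d}" for i in range(n)], dtype=object) if ids is None else np.asarray(ids, dtype=object)
    return HarmonizedSet(
        variants=ids,
        exposure_beta=bx,
        exposure_se=sex,
        outcome_beta=by,
        outcome_se=sey,
        extra_exposures=dict(extras or {}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def five_snp_set(rng):
    """Small noisy harmonized set with a common underlying slope of 0.4."""
    bx = rng.normal(0.08, 0.02, 5)
    sey = rng.uniform(0.02, 0.06, 5)
    by = 0.4 * bx + rng.normal(0, 1, 5) * sey
    return make_harmonized(bx, by, sex=np.full(5, 0.005), sey=sey)
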