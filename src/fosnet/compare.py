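"""Bootstrap comparison of per-region connectivity between two groups.

Networks built separately from two groups of animals (e.g. drug-exposed vs
saline) differ in their per-region connectivity k_r; this module tests
whether an observed difference Δk_r = k_r(A) − k_r(B) exceeds what random
group membership would produce.  The null is a group-relabeling resample:
the animals of both groups are pooled and repeatedly re-split *without
replacement* into two sets of the original sizes; Δk is recorded per region
for each re-split.  Under exchangeability this null is symmetric about
zero.  The observed difference is summarized by

    Z = (Δk_obs − null mean) / null sd

and by an add-one-corrected empirical two-sided p value,

    p = (1 + #{ |Δk_null| ≥ |Δk_obs| }) / (n_boot + 1),

which can never return exactly zero.  Raw per-region p values are primary;
Benjamini–Hochberg-adjusted values across regions are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectivity import _connectivity_kernel, _corr_kernel
from .errors import DegenerateDataError, InsufficientDataError
from .sample_table import region_columns

#: Smallest group size accepted for a network comparison.
MIN_GROUP = 4


@dataclass
class NetworkDifference:
    """Per-region connectivity difference with its relabeling-null summary."""

    delta: pd.Series  # observed k(A) - k(B)
    null_mean: pd.Series
    null_sd: pd.Series
    z: pd.Series
    p: pd.Series  # empirical two-sided, add-one corrected
    p_adjusted: pd.Series  # Benjamini-Hochberg across regions
    n_boot: int
    seed: int
    group_sizes: Tuple[int, int]
    group_labels: Tuple[str, str]
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_connectivity": self.delta,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
                "p": self.p,
                "p_bh": self.p_adjusted,
            }
        ).rename_axis("region")


def _group_matrices(
    table: pd.DataFrame, by: str, group_a: str, group_b: str
) -> Tuple[np.ndarray, np.ndarray, list]:
    if by not in table.columns:
        raise KeyError(f"grouping column {by!r} not in table")
    regions = region_columns(table)
    xa = table.loc[table[by] == group_a, regions].to_numpy(dtype=float)
    xb = table.loc[table[by] == group_b, regions].to_numpy(dtype=float)
    for label, x in ((group_a, xa), (group_b, xb)):
        if len(x) < MIN_GROUP:
            raise InsufficientDataError(
                f"group {label!r} has {len(x)} animals; at least {MIN_GROUP} are required"
            )
        if np.isnan(x).any():
            raise DegenerateDataError(
                f"group {label!r} contains missing values; the bootstrap requires complete data"
            )
    return xa, xb, regions


def connectivity_difference(
    table: pd.DataFrame,
    by: str = "treatment",
    group_a: str = "MA",
    group_b: str = "SAL",
    method: str = "pearson",
) -> pd.Series:
    """Observed Δk_r = k_r(A) − k_r(B) for every region."""
    xa, xb, regions = _group_matrices(table, by, group_a, group_b)
    dk = _connectivity_kernel(_corr_kernel(xa, method)) - _connectivity_kernel(
        _corr_kernel(xb, method)
    )
    return pd.Series(dk, index=pd.Index(regions, name="region"), name="delta_connectivity")


def bootstrap_compare(
    table: pd.DataFrame,
    by: str = "treatment",
    group_a: str = "MA",
    group_b: str = "SAL",
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "pearson",
) -> NetworkDifference:
    """Group-relabeling bootstrap test of per-region connectivity differences.

    The pooled animals are re-split ``n_boot`` times (without replacement,
    preserving the original group sizes); each replicate draws its own RNG
    substream from the master seed, so results are reproducible and
    parallel-safe.  Identical seeds give identical output.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100; got {n_boot}")
    xa, xb, regions = _group_matrices(table, by, group_a, group_b)
    na, nb = len(xa), len(xb)
    observed = _connectivity_kernel(_corr_kernel(xa, method)) - _connectivity_kernel(
        _corr_kernel(xb, method)
    )

    pooled = np.vstack([xa, xb])
    n = na + nb
    children = np.random.SeedSequence(seed).spawn(n_boot)
    null = np.empty((n_boot, len(regions)))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.permutation(n)
        ka = _connectivity_kernel(_corr_kernel(pooled[idx[:na]], method))
        kb = _connectivity_kernel(_corr_kernel(pooled[idx[na:]], method))
        null[i] = ka - kb

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = (observed - mean) / sd
    p = (1.0 + (np.abs(null) >= np.abs(observed)).sum(axis=0)) / (n_boot + 1.0)
    p_bh = multipletests(p, method="fdr_bh")[1]
    idx = pd.Index(regions, name="region")
    return NetworkDifference(
        delta=pd.Series(observed, index=idx, name="delta_connectivity"),
        null_mean=pd.Series(mean, index=idx, name="null_mean"),
        null_sd=pd.Series(sd, index=idx, name="null_sd"),
        z=pd.Series(z, index=idx, name="z"),
        p=pd.Series(p, index=idx, name="p"),
        p_adjusted=pd.Series(p_bh, index=idx, name="p_bh"),
        n_boot=n_boot,
        seed=seed,
        group_sizes=(na, nb),
        group_labels=(group_a, group_b),
        method=method,
    )
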