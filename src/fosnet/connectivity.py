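"""Inter-regional correlation networks, connectivity, and the permutation null.

Within one experimental group, regional activation counts are correlated
across animals; the resulting region × region correlation matrix is read as
a weighted, signed co-activation network.  A region's *connectivity* is the
sum of the absolute correlations with every other region,

    k_r = sum_{s != r} |corr(r, s)|,

an unthresholded node strength (edge display thresholds never feed back
into k).

Whether an observed k_r could arise by chance is assessed against a
permutation null: each region column's sample order is shuffled
independently, which destroys cross-region alignment while preserving every
marginal distribution, and connectivity is recomputed.  (A joint shuffle of
whole rows would leave all correlations unchanged, so independent
per-column shuffles are the only scheme that yields a nontrivial null.)
The observed value is expressed as Z = (k_obs − null mean) / null sd, with
the sample (n−1) standard deviation; Z > 2 is the conventional cutoff for
connectivity unlikely to arise by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateDataError, InsufficientDataError
from .sample_table import region_columns

#: Minimum pairwise-complete observations for a correlation to be computed.
MIN_PAIRS = 3


# ---------------------------------------------------------------------------
# fast internal kernels (no-NaN fast path shared with the bootstrap module)
# ---------------------------------------------------------------------------

def _corr_kernel(x: np.ndarray, method: str) -> np.ndarray:
    """Correlation matrix of the columns of ``x`` (no missing values)."""
    if method == "spearman":
        x = scipy.stats.rankdata(x, axis=0)
    xc = x - x.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    if (norm == 0).any():
        bad = int(np.flatnonzero(norm == 0)[0])
        raise DegenerateDataError(f"column {bad} has zero variance")
    z = xc / norm
    c = z.T @ z
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def _connectivity_kernel(corr: np.ndarray) -> np.ndarray:
    """Node strengths k_r = sum_{s != r} |corr(r, s)| (diagonal excluded)."""
    return np.abs(corr).sum(axis=0) - 1.0


# ---------------------------------------------------------------------------
# public containers
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Region × region correlation matrix with per-entry pair counts."""

    values: pd.DataFrame
    method: str
    n_pairs: pd.DataFrame

    @property
    def regions(self) -> List[str]:
        return list(self.values.index)


@dataclass
class ConnectivityProfile:
    """Per-region connectivity within one group."""

    connectivity: pd.Series  # index: region
    group: Optional[str]
    n_samples: int
    method: str


@dataclass
class PermutationResult:
    """Observed connectivity against the randomized-sample-order null."""

    observed: pd.Series
    null_mean: pd.Series
    null_sd: pd.Series
    z: pd.Series
    n_perm: int
    seed: int
    method: str
    group: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "connectivity": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
            }
        ).rename_axis("region")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def correlation_matrix(table: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """Correlate all region pairs across the animals of one group.

    ``table`` must already be restricted to a single group; factor columns
    are ignored.  Missing values are handled pairwise-complete; any pair
    with fewer than 3 complete observations raises
    :class:`InsufficientDataError` naming the pair, and a zero-variance
    region raises :class:`DegenerateDataError`.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    regions = region_columns(table)
    data = table[regions].astype(float)
    x = data.to_numpy()
    n = len(data)

    if not np.isnan(x).any():
        if n < MIN_PAIRS:
            raise InsufficientDataError(
                f"only {n} animals; at least {MIN_PAIRS} are required"
            )
        sd = x.std(axis=0)
        if (sd == 0).any():
            bad = regions[int(np.flatnonzero(sd == 0)[0])]
            raise DegenerateDataError(f"region {bad!r} has zero variance")
        values = pd.DataFrame(_corr_kernel(x, method), index=regions, columns=regions)
        pairs = pd.DataFrame(n, index=regions, columns=regions)
        return CorrelationMatrix(values=values, method=method, n_pairs=pairs)

    mask = data.notna().to_numpy().astype(int)
    pairs = pd.DataFrame(mask.T @ mask, index=regions, columns=regions)
    low = np.argwhere(pairs.to_numpy() < MIN_PAIRS)
    if len(low):
        i, j = low[0]
        raise InsufficientDataError(
            f"region pair ({regions[i]!r}, {regions[j]!r}) has "
            f"{int(pairs.iloc[i, j])} complete pairs; at least {MIN_PAIRS} are required"
        )
    values = data.corr(method=method, min_periods=MIN_PAIRS)
    nan_entries = np.argwhere(values.isna().to_numpy())
    if len(nan_entries):
        i, j = nan_entries[0]
        raise DegenerateDataError(
            f"correlation undefined for pair ({regions[i]!r}, {regions[j]!r}) "
            "(zero variance over complete pairs)"
        )
    np.fill_diagonal(values.to_numpy(), 1.0)
    return CorrelationMatrix(values=values, method=method, n_pairs=pairs)


def connectivity_profile(
    corr: CorrelationMatrix, group: Optional[str] = None, n_samples: Optional[int] = None
) -> ConnectivityProfile:
    """Per-region connectivity k_r from a correlation matrix."""
    k = _connectivity_kernel(corr.values.to_numpy())
    n = n_samples if n_samples is not None else int(corr.n_pairs.to_numpy().min())
    return ConnectivityProfile(
        connectivity=pd.Series(k, index=corr.values.index, name="connectivity"),
        group=group,
        n_samples=n,
        method=corr.method,
    )


def permutation_null(
    table: pd.DataFrame,
    n_perm: int = 10_000,
    method: str = "pearson",
    seed: int = 0,
    group: Optional[str] = None,
) -> PermutationResult:
    """Permutation Z-scores for per-region connectivity within one group.

    For each of ``n_perm`` replicates every region column is shuffled
    independently and connectivity recomputed; the observed k_r is reduced
    to Z = (k_obs − null mean) / null sd.  Identical seeds give identical
    results.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be at least 100; got {n_perm}")
    regions = region_columns(table)
    x = table[regions].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DegenerateDataError("permutation null requires a complete table (no NaN)")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = regions[int(np.flatnonzero(sd == 0)[0])]
        raise DegenerateDataError(f"region {bad!r} has zero variance")
    observed = _connectivity_kernel(_corr_kernel(x, method))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null = np.empty((n_perm, len(regions)))
    for i in range(n_perm):
        null[i] = _connectivity_kernel(_corr_kernel(rng.permuted(x, axis=0), method))
    mean = null.mean(axis=0)
    sd_null = null.std(axis=0, ddof=1)
    idx = pd.Index(regions, name="region")
    return PermutationResult(
        observed=pd.Series(observed, index=idx, name="connectivity"),
        null_mean=pd.Series(mean, index=idx, name="null_mean"),
        null_sd=pd.Series(sd_null, index=idx, name="null_sd"),
        z=pd.Series((observed - mean) / sd_null, index=idx, name="z"),
        n_perm=n_perm,
        seed=seed,
        method=method,
        group=group,
    )


def edge_list(corr: CorrelationMatrix, min_abs_r: float = 0.0) -> pd.DataFrame:
    """Signed, weighted edges with |r| at or above a display threshold.

    The threshold affects display/export only; connectivity k_r always uses
    every off-diagonal correlation.
    """
    if not 0.0 <= min_abs_r <= 1.0:
        raise ValueError(f"min_abs_r must lie in [0, 1]; got {min_abs_r}")
    regions = corr.regions
    m = corr.values.to_numpy()
    rows = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            r = m[i, j]
            if abs(r) >= min_abs_r:
                rows.append({"region_a": regions[i], "region_b": regions[j], "r": r})
    return pd.DataFrame(rows, columns=["region_a", "region_b", "r"])


def to_graph(corr: CorrelationMatrix, min_abs_r: float = 0.0):
    """Thresholded signed network as a networkx graph (weight = r)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(corr.regions)
    for _, row in edge_list(corr, min_abs_r).iterrows():
        g.add_edge(
            row["region_a"], row["region_b"],
            weight=float(row["r"]),
            sign="positive" if row["r"] >= 0 else "negative",
        )
    return g


def write_graphml(corr: CorrelationMatrix, path, min_abs_r: float = 0.0) -> None:
    """Export the thresholded signed network as GraphML."""
    import networkx as nx

    nx.write_graphml(to_graph(corr, min_abs_r), path)
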