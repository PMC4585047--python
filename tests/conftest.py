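import numpy as np
import pandas as pd
import pytest

from fosnet.sample_table import PHASES, TREATMENTS


def make_balanced_table(
    cell_means, n_per_cell=5, sd=8.0, seed=0, regions=("R1",)
):
    """Balanced 2x2 factorial table with Gaussian noise, clipped at zero.

    ``cell_means`` is either a 2x2 array (same for all regions) or a dict
    region -> 2x2 array indexed [treatment, phase] = (MA, SAL) x (light, dark).
    """
    rng = np.random.default_rng(seed)
    if not isinstance(cell_means, dict):
        cell_means = {r: np.asarray(cell_means, float) for r in regions}
    rows = []
    for ti, t in enumerate(TREATMENTS):
        for pi, p in enumerate(PHASES):
            for i in range(n_per_cell):
                row = {"animal_id": f"{t}_{p}_{i}", "treatment": t, "phase": p}
                for r in regions:
                    row[r] = max(0.0, cell_means[r][ti, pi] + rng.normal(0.0, sd))
                rows.append(row)
    return pd.DataFrame(rows)


def anova_oracle(table, region):
    """Independent cell-means regression oracle for the two-way ANOVA.

    Sum-coded design [1, t, p, t*p]; each effect's F is the partial
    (Type-III) F from the SSR increase when its column is dropped.
    """
    y = table[region].to_numpy(dtype=float)
    t = np.where(table["treatment"].to_numpy() == "MA", 1.0, -1.0)
    p = np.where(table["phase"].to_numpy() == "light", 1.0, -1.0)
    x = np.column_stack([np.ones_like(y), t, p, t * p])

    def ssr(xm):
        beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
        resid = y - xm @ beta
        return float(resid @ resid)

    full = ssr(x)
    df_den = len(y) - x.shape[1]
    mse = full / df_den
    fs = {
        name: (ssr(np.delete(x, col, axis=1)) - full) / mse
        for name, col in (("treatment", 1), ("time", 2), ("interaction", 3))
    }
    return fs, df_den


def pearson_oracle(a, b):
    """Textbook product-moment correlation, written out longhand."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a) ** 0.5
    db = sum((y - mb) ** 2 for y in b) ** 0.5
    return num / (da * db)


@pytest.fixture
def toy_table_5x3():
    """Frozen 5-animal, 3-region single-group table for exact-value checks."""
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(5)],
            "treatment": ["MA"] * 5,
            "phase": ["light", "light", "light", "dark", "dark"],
            "A": [12.0, 7.5, 3.0, 9.0, 15.5],
            "B": [4.0, 11.0, 8.5, 2.0, 6.0],
            "C": [20.0, 14.0, 17.5, 25.0, 9.0],
        }
    )
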