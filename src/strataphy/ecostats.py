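"""Rank correlation of phylotype abundance with environmental gradients.

Spearman's rho is computed exactly as rank-then-Pearson: both vectors are
ranked (ties get mean ranks) and a Pearson product-moment correlation is
taken of the rank vectors. Significance comes from the ANOVA F-test of
the simple linear regression of rank(y) on rank(x) — for one predictor
this F equals the squared t of the slope, so P is identical to the
slope t-test.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ENV_VARIABLES = ("depth_m", "salinity", "DO", "temperature")
PHYLOTYPE_COLUMNS = ("depth_A", "depth_B")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mean-tie ranks.

    Returns NaN (flagged undefined) when either rank vector has zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def regression_p(x, y) -> float:
    """P-value from the regression ANOVA F-test on the rank vectors.

    F = rho^2 (n-2) / (1 - rho^2) on (1, n-2) degrees of freedom.
    Returns NaN for degenerate (zero-variance) ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    rho = spearman_rho(x, y)
    if np.isnan(rho):
        return float("nan")
    n = x.size
    if abs(rho) >= 1.0:
        return 0.0
    f = rho * rho * (n - 2) / (1.0 - rho * rho)
    return float(stats.f.sf(f, 1, n - 2))


def correlate_abundance_env(
    table: pd.DataFrame,
    env_variables: tuple[str, ...] = ENV_VARIABLES,
    phylotype_columns: tuple[str, ...] = PHYLOTYPE_COLUMNS,
) -> pd.DataFrame:
    """(rho, P) for each environmental variable x phylotype depth pair.

    Only complete rows enter the correlation; at least 4 are required.
    Degenerate (constant) columns are flagged undefined rather than
    dropped.
    """
    cols = list(env_variables) + list(phylotype_columns)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    complete = table[cols].dropna()
    if len(complete) < 4:
        raise ValueError("need at least 4 complete rows")
    rows = []
    for var in env_variables:
        for phylo in phylotype_columns:
            x = complete[var].to_numpy(float)
            y = complete[phylo].to_numpy(float)
            rho = spearman_rho(x, y)
            p = regression_p(x, y) if not np.isnan(rho) else float("nan")
            rows.append({
                "variable": var, "phylotype": phylo, "rho": rho, "P": p,
                "n": len(complete), "defined": not np.isnan(rho),
            })
    return pd.DataFrame(rows)
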