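"""Vectorized two-sample t statistics with explicit degenerate handling.

All group-vs-complement machinery in the package funnels through
:func:`ttest_groups`, so the Bonferroni family, degenerate-variance
conventions and pooled/Welch choice are defined in exactly one place.

Degenerate conventions (sparse toy matrices hit these constantly):

* both samples constant with equal values -> t = 0, p = 1;
* both samples constant with different values -> t = +/-inf, p = 0.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def ttest_matrix(
    x: np.ndarray,
    y: np.ndarray,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test for every column of ``x`` vs ``y``.

    Parameters
    ----------
    x, y
        Dense arrays of shape (n_x, features) and (n_y, features).
    equal_var
        Pooled-variance Student test (default) or Welch.

    Returns
    -------
    (t, p) arrays of length ``features``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[0], y.shape[0]
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    diff = mx - my

    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
            se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
            dof = np.full_like(se, nx + ny - 2.0)
        else:
            se = np.sqrt(vx / nx + vy / ny)
            num = (vx / nx + vy / ny) ** 2
            den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            dof = np.where(den > 0, num / den, nx + ny - 2.0)
        t = diff / se
        p = 2.0 * sps.t.sf(np.abs(t), dof)

    degenerate = se == 0
    equal = degenerate & (diff == 0)
    unequal = degenerate & (diff != 0)
    t[equal] = 0.0
    p[equal] = 1.0
    t[unequal] = np.sign(diff[unequal]) * np.inf
    p[unequal] = 0.0
    return t, p


def bonferroni(p_raw: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * family size)."""
    p_raw = np.asarray(p_raw, dtype=float)
    m = len(p_raw) if family_size is None else int(family_size)
    return np.minimum(1.0, p_raw * m)


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two 1-D vectors (NaN if either is constant)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.std() == 0 or v.std() == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])
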