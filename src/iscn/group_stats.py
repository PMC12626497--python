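"""Group comparisons of abnormality strengths (SF vs NSF).

Two-sample pooled-variance Student t-tests with Benjamini-Hochberg
step-up FDR control across units (regions, modules or edges), plus the
top-fraction edge report used to display the strongest group differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_model import ValidationError


@dataclass(frozen=True)
class GroupTestResult:
    unit: str
    t: float
    p: float
    q: float = float("nan")
    significant: bool = False


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Pooled-variance Student t (Welch via ``equal_var=False``).

    Degenerate zero-variance cases: equal means give t=0, p=1; unequal
    means with zero pooled variance are an error (infinite statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValidationError("zero variance with unequal means: t undefined")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, boolean rejection set)."""
    pvals = np.asarray(pvals, dtype=float)
    reject, q, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return q, reject


def compare_groups(
    values: pd.DataFrame,
    labels,
    group_a: str = "NSF",
    group_b: str = "SF",
    alpha: float = 0.05,
    correct: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-test every column of *values* between two label groups.

    Returns a table of (unit, t, p, q, significant); t > 0 means
    *group_a* (default NSF) exceeds *group_b*.
    """
    labels = np.asarray(labels)
    a = values.loc[labels == group_a]
    b = values.loc[labels == group_b]
    rows = []
    for col in values.columns:
        t, p = two_sample_t(a[col], b[col], equal_var=equal_var)
        rows.append({"unit": str(col), "t": t, "p": p})
    out = pd.DataFrame(rows)
    if correct:
        q, rej = bh_fdr(out["p"].to_numpy(), alpha)
        out["q"] = q
        out["significant"] = rej
    else:
        out["q"] = np.nan
        out["significant"] = out["p"] < alpha
    return out


def edgewise_t(
    z_stack: np.ndarray, labels, group_a: str = "NSF", group_b: str = "SF"
) -> np.ndarray:
    """Edge-by-edge t map over a patients x regions x regions |Z| stack."""
    labels = np.asarray(labels)
    a = z_stack[labels == group_a]
    b = z_stack[labels == group_b]
    p = z_stack.shape[1]
    tmap = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            try:
                t, _ = two_sample_t(a[:, i, j], b[:, i, j])
            except ValidationError:
                t = np.inf if a[:, i, j].mean() > b[:, i, j].mean() else -np.inf
            tmap[i, j] = tmap[j, i] = t
    return tmap


def top_fraction_edges(
    t_map: np.ndarray, fraction: float = 0.01
) -> list[tuple[int, int]]:
    """The ceil(fraction * #edges) edges with the largest signed t.

    Ties are broken by (i, j) lexicographic order so the report is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    p = t_map.shape[0]
    edges = [(t_map[i, j], i, j) for i in range(p) for j in range(i + 1, p)]
    k = math.ceil(fraction * len(edges))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return [(i, j) for _, i, j in edges[:k]]
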