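"""Group-level tests and multiple-comparison corrections.

Only the simple, fully specified procedures live here: Welch's t-test (in
:mod:`hyperbrain.behavior`), paired t-tests over all condition contrasts
with Holm step-down adjustment, and Bonferroni correction. Holm is
implemented directly (it is a sort plus a running maximum) so that
simulation studies can call it tens of thousands of times cheaply.
Mixed-effects group models are intentionally out of scope; the tidy
results table is exported for external modeling tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sstats


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class PairedContrast:
    condition_a: str
    condition_b: str
    t: float
    df: float
    p_raw: float
    p_adjusted: float


def paired_t_holm(
    values: np.ndarray, condition_names: list[str] | None = None
) -> list[PairedContrast]:
    """All pairwise paired t contrasts between conditions, Holm-adjusted.

    ``values`` is (n_subjects, n_conditions), complete (no NaN rows are
    used; subjects with any missing cell are dropped with that caveat in
    the caller's hands). Returns one contrast per unordered condition pair,
    ``t`` computed on (a - b) differences, two-sided p, Holm step-down
    adjusted across the family of contrasts.
    """
    mat = np.asarray(values, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("values must be (n_subjects, n_conditions>=2)")
    complete = ~np.isnan(mat).any(axis=1)
    mat = mat[complete]
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 complete subjects")
    n_cond = mat.shape[1]
    names = condition_names or [f"c{i}" for i in range(n_cond)]
    pairs = list(combinations(range(n_cond), 2))

    diffs = np.stack([mat[:, a] - mat[:, b] for a, b in pairs], axis=1)
    n = mat.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0.0, np.where(mean == 0.0, 0.0, np.sign(mean) * np.inf), t)
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    p = np.clip(p, 0.0, 1.0)
    p_adj = holm_adjust(p)
    return [
        PairedContrast(
            condition_a=names[a],
            condition_b=names[b],
            t=float(t[k]),
            df=float(n - 1),
            p_raw=float(p[k]),
            p_adjusted=float(p_adj[k]),
        )
        for k, (a, b) in enumerate(pairs)
    ]


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, p * m)``; ``m`` defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)
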