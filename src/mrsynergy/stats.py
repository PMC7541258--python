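"""Shared two-sample rank statistics.

Every Wilcoxon rank-sum comparison in the package (validation of selected
regulators, the regulon synergy test, the clinical and mutation association
battery) goes through :func:`rank_sum_p` so that tie handling and the
exact-vs-asymptotic switch are identical everywhere.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

Alternative = Literal["two-sided", "greater", "less"]

#: largest per-group size for which the exact null distribution is used
EXACT_MAX_N = 12


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def rank_sum_p(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "two-sided",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value comparing ``x`` against ``y``.

    The exact null distribution is enumerated when both groups have at most
    :data:`EXACT_MAX_N` observations and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity correction is
    used. Deterministic: no randomisation of ties.

    Parameters
    ----------
    x, y:
        The two samples. Both must be nonempty and finite.
    alternative:
        ``"greater"`` tests whether ``x`` is stochastically larger than ``y``.

    Returns
    -------
    float
        The p-value in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_p requires two nonempty samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("rank_sum_p requires finite values")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")

    exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))
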