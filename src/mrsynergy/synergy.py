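"""Synergy testing of MR pairs via the Expression Contribution to Activity (ECA).

Two regulators act synergistically when the targets they share respond more
extremely than the targets unique to either. For each MR of a pair and each
DE dataset, the ECA of a target is DE * MOR (using that MR's own MOR, so a
shared target can contribute different ECA values to the two tests), and a
one-tailed rank-sum test compares the common targets against that MR's
unique targets — alternative "greater" when the MR is activated in the
dataset (positive DA) and "less" when suppressed. A pair is eligible only
when the shared-target count is > 10 and exceeds 10% of both regulon sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import DATable
from .network import RegulatoryNetwork, RegulonPartition, partition_regulons
from .signatures import DESignature
from .stats import rank_sum_p

DEFAULT_MIN_COMMON = 10
DEFAULT_MIN_FRAC = 0.10


@dataclass(frozen=True)
class SynergyResult:
    """Per-dataset synergy p-values for one eligible MR pair.

    ``per_dataset`` maps dataset_id -> (p_vs_unique1, p_vs_unique2, da_sign1,
    da_sign2); p entries are NaN when a comparison group is empty after
    dropping unscored targets or when the MR's DA is undefined.
    """

    mr1: str
    mr2: str
    size1: int
    size2: int
    common_size: int
    per_dataset: dict

    def worst_p(self) -> float:
        """Largest per-dataset p over both tests, with NaN treated as 1.0."""
        worst = 0.0
        for p1, p2, _, _ in self.per_dataset.values():
            for p in (p1, p2):
                worst = max(worst, 1.0 if (p is None or np.isnan(p)) else p)
        return worst


def eligible_pair(
    size1: int,
    size2: int,
    common_size: int,
    min_common: int = DEFAULT_MIN_COMMON,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> bool:
    """Strict eligibility rule: common count > 10 and > 10% of both regulons."""
    if min(size1, size2, common_size) < 0:
        raise ValueError("sizes must be non-negative")
    if common_size > min(size1, size2):
        raise ValueError(
            f"inconsistent partition: common {common_size} exceeds min regulon size"
        )
    return (
        common_size > min_common
        and common_size / size1 > min_frac
        and common_size / size2 > min_frac
    )


def eca(de: float, mor: float) -> float:
    """Expression Contribution to Activity of one target: DE * MOR."""
    if not -1.0 <= mor <= 1.0:
        raise ValueError(f"mor outside [-1, 1]: {mor}")
    return de * mor


def synergy_test(
    partition: RegulonPartition,
    sig: DESignature,
    da_sign1: int,
    da_sign2: int,
) -> tuple[float, float]:
    """One-tailed common-vs-unique ECA rank-sum tests for both MRs of a pair.

    Returns (p1, p2); a p is NaN when either comparison group is empty after
    dropping targets unscored in the signature. Likelihood weights are not
    used: the ECA depends on DE and MOR only.
    """
    for sign in (da_sign1, da_sign2):
        if sign not in (1, -1):
            raise ValueError(f"DA sign must be +1 or -1, got {sign!r}")
    scores = sig.scores

    def group_eca(frame: pd.DataFrame, mor_col: str) -> np.ndarray:
        sub = frame[frame["target"].isin(scores.index)]
        if sub.empty:
            return np.empty(0)
        de = scores.reindex(sub["target"]).to_numpy()
        return de * sub[mor_col].to_numpy()

    common1 = group_eca(partition.common, "mor1")
    common2 = group_eca(partition.common, "mor2")
    uniq1 = group_eca(partition.unique1, "mor")
    uniq2 = group_eca(partition.unique2, "mor")

    def one_test(common: np.ndarray, unique: np.ndarray, sign: int) -> float:
        if common.size == 0 or unique.size == 0:
            return float("nan")
        alt = "greater" if sign > 0 else "less"
        return rank_sum_p(common, unique, alt)

    return one_test(common1, uniq1, da_sign1), one_test(common2, uniq2, da_sign2)


def synergy_screen(
    net: RegulatoryNetwork,
    candidate_mrs: set[str],
    sigs: Sequence[DESignature],
    das: Sequence[DATable],
    min_common: int = DEFAULT_MIN_COMMON,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[SynergyResult]:
    """Test every eligible unordered pair of candidate MRs in every dataset.

    DA signs are taken per MR per dataset from the matching DA table; a
    dataset whose DA is undefined for an MR contributes NaN for that MR's
    test. Results are ordered by (mr1, mr2) with mr1 < mr2 lexicographically.
    """
    das_by_id = {da.dataset_id: da for da in das}
    for sig in sigs:
        if sig.dataset_id not in das_by_id:
            raise ValueError(f"no DA table for dataset {sig.dataset_id!r}")
    results: list[SynergyResult] = []
    target_sets = {mr: {t for t, _, _ in net.regulon_of(mr)} for mr in candidate_mrs}
    for mr1, mr2 in itertools.combinations(sorted(candidate_mrs), 2):
        # cheap set-overlap eligibility check before building the partition
        n_common = len(target_sets[mr1] & target_sets[mr2])
        if not eligible_pair(
            len(target_sets[mr1]), len(target_sets[mr2]), n_common, min_common, min_frac
        ):
            continue
        part = partition_regulons(net, mr1, mr2)
        per_dataset: dict = {}
        for sig in sigs:
            da = das_by_id[sig.dataset_id]
            s1 = da.nes_sign(mr1)
            s2 = da.nes_sign(mr2)
            p1 = p2 = float("nan")
            if s1 is not None and s2 is not None:
                p1, p2 = synergy_test(part, sig, s1, s2)
            elif s1 is not None:
                p1, _ = synergy_test(part, sig, s1, 1)
                p2 = float("nan")
            elif s2 is not None:
                _, p2 = synergy_test(part, sig, 1, s2)
                p1 = float("nan")
            per_dataset[sig.dataset_id] = (p1, p2, s1, s2)
        results.append(
            SynergyResult(
                mr1=mr1,
                mr2=mr2,
                size1=part.size1,
                size2=part.size2,
                common_size=part.common_size,
                per_dataset=per_dataset,
            )
        )
    return results


def write_synergy_report(
    results: Sequence[SynergyResult], dataset_ids: Sequence[str], path: str | Path
) -> None:
    """TSV: mr1, mr2, sizes, then two p columns per dataset (NaN as 'NA')."""

    def fmt(p: float) -> str:
        return "NA" if (p is None or np.isnan(p)) else repr(float(p))

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        cols = ["mr1", "mr2", "size1", "size2", "common_size"]
        for d in dataset_ids:
            cols += [f"p1_{d}", f"p2_{d}"]
        fh.write("\t".join(cols) + "\n")
        for res in results:
            row = [res.mr1, res.mr2, str(res.size1), str(res.size2), str(res.common_size)]
            for d in dataset_ids:
                p1, p2, _, _ = res.per_dataset.get(d, (np.nan, np.nan, None, None))
                row += [fmt(p1), fmt(p2)]
            fh.write("\t".join(row) + "\n")
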