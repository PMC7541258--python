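"""Discovery/validation selection of common top MRs and DA-DE consistency.

The discovery datasets each contribute a ranked DA table; the common top
regulators are the intersection of the per-dataset top-N lists (separately
for the activated and suppressed direction). The validation datasets check,
by rank-sum test, that the selected set sits at the extreme of their DA
distributions, and the consistency filter keeps only regulators whose own
expression change agrees in sign with their inferred activity and exceeds
|DE| > 3 in every discovery dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .activity import DATable
from .signatures import DESignature
from .stats import rank_sum_p

logger = logging.getLogger(__name__)

Direction = Literal["activated", "suppressed"]

DEFAULT_DE_THRESHOLD = 3.0


@dataclass(frozen=True)
class TopMRSelection:
    """Outcome of the discovery/validation selection at one N."""

    n: int
    activated: frozenset[str]
    suppressed: frozenset[str]
    validation_p: dict  # (dataset_id, direction) -> p-value

    def __post_init__(self) -> None:
        if set(self.activated) & set(self.suppressed):
            raise ValueError("activated and suppressed sets overlap")


def top_n(da: DATable, n: int, direction: Direction) -> set[str]:
    """The n most activated (largest NES) or suppressed (smallest NES) regulators.

    NES ties at the boundary are broken by lexicographic regulator id, so the
    returned set is deterministic. Raises if fewer than n rows have a NES.
    """
    if direction not in ("activated", "suppressed"):
        raise ValueError(f"unknown direction: {direction!r}")
    defined = da.defined()
    if len(defined) < n:
        raise ValueError(
            f"{da.dataset_id}: only {len(defined)} regulators with defined NES, need {n}"
        )
    ascending = direction == "suppressed"
    # mergesort is stable; pre-sorting the index makes the NES tie-break lexicographic
    ordered = defined.loc[sorted(defined.index)].sort_values(
        "nes", ascending=ascending, kind="mergesort"
    )
    return set(ordered.index[:n])


def common_top(das: Sequence[DATable], n: int) -> tuple[set[str], set[str]]:
    """Intersection of the per-dataset top-n sets, per direction."""
    if len(das) < 2:
        raise ValueError("common_top requires at least 2 discovery DA tables")
    activated: set[str] | None = None
    suppressed: set[str] | None = None
    for da in das:
        a = top_n(da, n, "activated")
        s = top_n(da, n, "suppressed")
        activated = a if activated is None else activated & a
        suppressed = s if suppressed is None else suppressed & s
    return activated, suppressed


def validate_common(da: DATable, mrs: set[str]) -> float:
    """Two-sided rank-sum p of the selected MRs' NES against all other MRs."""
    if not mrs:
        raise ValueError("validate_common requires a nonempty MR set")
    defined = da.defined()
    missing = set(mrs) - set(defined.index)
    if missing:
        raise ValueError(f"MRs without defined NES in {da.dataset_id}: {sorted(missing)}")
    others = defined.index.difference(list(mrs))
    if len(others) == 0:
        raise ValueError("MR set must be a strict subset of the regulators")
    return rank_sum_p(
        defined.loc[sorted(mrs), "nes"].to_numpy(),
        defined.loc[others, "nes"].to_numpy(),
        "two-sided",
    )


def da_de_consistent(
    mrs: set[str],
    das: Sequence[DATable],
    sigs: Sequence[DESignature],
    de_threshold: float = DEFAULT_DE_THRESHOLD,
) -> set[str]:
    """Keep MRs whose own DE agrees with their DA in every discovery dataset.

    An MR is kept iff in each dataset sign(DE) == sign(NES) and |DE| is
    strictly greater than ``de_threshold``. MRs missing a DA or DE value in
    any dataset are dropped with a logged warning.
    """
    by_id = {da.dataset_id: da for da in das}
    kept: set[str] = set()
    for mr in sorted(mrs):
        ok = True
        for sig in sigs:
            da = by_id.get(sig.dataset_id)
            if da is None:
                raise ValueError(f"no DA table for dataset {sig.dataset_id!r}")
            sign = da.nes_sign(mr) if mr in da.table.index else None
            if sign is None or mr not in sig.scores.index:
                logger.warning(
                    "dropping %s: missing DA or DE in dataset %s", mr, sig.dataset_id
                )
                ok = False
                break
            de = float(sig.scores[mr])
            if not (abs(de) > de_threshold and np.sign(de) == sign):
                ok = False
                break
        if ok:
            kept.add(mr)
    return kept


def select_top_mrs(
    discovery_das: Sequence[DATable],
    validation_das: Sequence[DATable],
    discovery_sigs: Sequence[DESignature],
    n: int,
    de_threshold: float = DEFAULT_DE_THRESHOLD,
) -> tuple[TopMRSelection, set[str]]:
    """Full selection stage: common top MRs, validation p-values, consistency.

    Returns the selection object and the DA-DE consistent subset of the
    union of both directions.
    """
    activated, suppressed = common_top(discovery_das, n)
    validation_p: dict = {}
    for da in validation_das:
        if activated:
            validation_p[(da.dataset_id, "activated")] = validate_common(da, activated)
        if suppressed:
            validation_p[(da.dataset_id, "suppressed")] = validate_common(da, suppressed)
    selection = TopMRSelection(
        n=n,
        activated=frozenset(activated),
        suppressed=frozenset(suppressed),
        validation_p=validation_p,
    )
    consistent = da_de_consistent(
        set(activated) | set(suppressed), discovery_das, discovery_sigs, de_threshold
    )
    return selection, consistent


def write_selection_report(
    selection: TopMRSelection,
    consistent: set[str],
    discovery_das: Sequence[DATable],
    path: str | Path,
) -> None:
    """TSV report: regulator, direction, per-discovery rank, consistency verdict."""
    ranks: dict[str, pd.Series] = {}
    for da in discovery_das:
        defined = da.defined().loc[lambda d: sorted(d.index)]
        ranks[da.dataset_id] = (
            defined["nes"].rank(ascending=False, method="first").astype(int)
        )
    dataset_ids = [da.dataset_id for da in discovery_das]
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        cols = ["regulator", "direction"] + [f"rank_{d}" for d in dataset_ids] + [
            "consistent"
        ]
        fh.write("\t".join(cols) + "\n")
        for direction, mrs in (
            ("activated", selection.activated),
            ("suppressed", selection.suppressed),
        ):
            for mr in sorted(mrs):
                row = [mr, direction]
                for d in dataset_ids:
                    row.append(str(int(ranks[d].get(mr, -1))))
                row.append("yes" if mr in consistent else "no")
                fh.write("\t".join(row) + "\n")
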