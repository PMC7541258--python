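"""Differential-activity (DA) inference: DE signature + interactome -> NES per MR.

The normalised enrichment score (NES) of a regulator is a likelihood-weighted,
MOR-signed mean of the normal scores of its targets' DE ranks,

    nes = sum_t w_t * mor_t * z_t / sqrt(sum_t w_t^2 * mor_t^2),

which is N(0, 1) under the null of an exchangeable signature, so
p = 2 * Phi(-|nes|). A positive NES means the regulator's programme is
activated in the contrast. This is a deliberately transparent analytic
rank-enrichment: it plays the role of the aREA/msVIPER step (NES sign =
direction, magnitude = evidence) without shadow/pleiotropy machinery; see
docs/methods.md for the exact relationship and its limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .network import RegulatoryNetwork
from .signatures import DESignature

#: regulators with fewer scoreable targets than this carry no NES
DEFAULT_MIN_TARGETS = 2


@dataclass(frozen=True)
class DATable:
    """Per-regulator differential activity for one dataset.

    ``table`` is indexed by regulator with float columns ``nes`` and ``p``
    (NaN where undefined) and integer column ``n_targets_used``.
    """

    dataset_id: str
    table: pd.DataFrame

    def defined(self) -> pd.DataFrame:
        """Rows with a defined NES."""
        return self.table[self.table["nes"].notna()]

    def nes_sign(self, mr: str) -> int | None:
        """+1/-1 for the activation direction of ``mr``; None if undefined.

        A NES of exactly 0 is treated as activation (+1); it cannot occur for
        continuous signatures.
        """
        nes = self.table.at[mr, "nes"] if mr in self.table.index else np.nan
        if np.isnan(nes):
            return None
        return 1 if nes >= 0 else -1


def signed_normal_scores(sig: DESignature) -> pd.Series:
    """Map DE scores to standard-normal scores via their (tie-averaged) ranks.

    With G genes and ascending average ranks r, z = Phi^-1((r - 0.5) / G):
    strictly monotone in the score for untied inputs, mean approximately 0.
    """
    if len(sig) < 2:
        raise ValueError("signed_normal_scores requires at least 2 genes")
    vals = sig.scores.to_numpy()
    ranks = _sps.rankdata(vals, method="average")
    z = _sps.norm.ppf((ranks - 0.5) / len(vals))
    return pd.Series(z, index=sig.scores.index)


def mr_nes(
    net: RegulatoryNetwork,
    z: pd.Series,
    mr: str,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> tuple[float, float, int]:
    """NES, two-sided p and contributing-target count for one regulator.

    Targets absent from ``z`` or with mor == 0 are dropped; with fewer than
    ``min_targets`` contributing targets the NES and p are NaN.
    """
    regulon = net.regulon_of(mr)  # raises KeyError for unknown regulators
    zmap = z
    num = 0.0
    den = 0.0
    n_used = 0
    for target, mor, w in regulon:
        if mor == 0.0 or target not in zmap.index:
            continue
        zt = float(zmap[target])
        num += w * mor * zt
        den += (w * mor) ** 2
        n_used += 1
    if n_used < min_targets:
        return (float("nan"), float("nan"), n_used)
    nes = num / np.sqrt(den)
    p = 2.0 * _sps.norm.sf(abs(nes))
    return (float(nes), float(max(p, np.nextafter(0, 1))), n_used)


def da_signature(
    net: RegulatoryNetwork,
    sig: DESignature,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> DATable:
    """Full DA table: one row per regulator of ``net`` against ``sig``.

    Vectorised equivalent of calling :func:`mr_nes` per regulator.
    """
    z = signed_normal_scores(sig)
    edges = net.edges
    regs, reg_codes, tgt_uniques, tgt_codes = net.coded_edges()

    zvals = z.reindex(tgt_uniques).to_numpy()[tgt_codes]
    mor = edges["mor"].to_numpy()
    w = edges["likelihood"].to_numpy()
    usable = np.isfinite(zvals) & (mor != 0.0)

    a = np.where(usable, w * mor, 0.0)
    num = np.bincount(reg_codes, weights=np.where(usable, a * np.nan_to_num(zvals), 0.0),
                      minlength=len(regs))
    den = np.bincount(reg_codes, weights=a * a, minlength=len(regs))
    n_used = np.bincount(reg_codes, weights=usable.astype(float), minlength=len(regs)).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        nes = num / np.sqrt(den)
    nes = np.where(n_used >= min_targets, nes, np.nan)
    p = np.where(np.isnan(nes), np.nan, 2.0 * _sps.norm.sf(np.abs(nes)))
    p = np.where(p == 0.0, np.nextafter(0, 1), p)

    table = pd.DataFrame(
        {"nes": nes, "p": p, "n_targets_used": n_used}, index=regs
    )
    table.index.name = "regulator"
    return DATable(dataset_id=sig.dataset_id, table=table)


# -- TSV I/O ---------------------------------------------------------------


def write_da_table(da: DATable, path: str | Path) -> None:
    """Write regulator, nes, p, n_targets_used, dataset_id; NaN as 'NA'."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("regulator\tnes\tp\tn_targets_used\tdataset_id\n")
        for reg, row in da.table.sort_index().iterrows():
            nes = "NA" if np.isnan(row["nes"]) else repr(float(row["nes"]))
            p = "NA" if np.isnan(row["p"]) else repr(float(row["p"]))
            fh.write(f"{reg}\t{nes}\t{p}\t{int(row['n_targets_used'])}\t{da.dataset_id}\n")


def read_da_table(path: str | Path) -> DATable:
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str}, na_values=["NA"])
    expected = ["regulator", "nes", "p", "n_targets_used", "dataset_id"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    ids = df["dataset_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"{path}: expected a single dataset_id, got {list(ids)}")
    table = df.set_index("regulator")[["nes", "p", "n_targets_used"]]
    table["n_targets_used"] = table["n_targets_used"].astype(int)
    return DATable(dataset_id=str(ids[0]), table=table)
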