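"""Gene-level differential-expression (DE) signatures.

A DE signature is one number per gene contrasting tumour against normal
tissue in one dataset: the moderated t-statistic for microarray platforms,
or the signed -log10(adjusted P) score for RNA-seq. The statistics
themselves come from upstream tools; this module handles probe collapsing,
the RNA-seq score transform, cross-dataset averaging and gene selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PLATFORMS = ("microarray", "rnaseq")

#: floor applied to adjusted P-values before the log (DESeq2 can emit 0)
MIN_ADJ_P = 1e-300


@dataclass(frozen=True)
class DESignature:
    """Per-gene DE scores for one dataset."""

    dataset_id: str
    platform: str
    scores: pd.Series  # index: gene id, values: float

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform: {self.platform!r}")
        s = pd.Series(self.scores, dtype=float)
        s.index = s.index.astype(str)
        s.index.name = "gene"
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise ValueError(f"duplicate gene in signature: {dup!r}")
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("DE scores must be finite")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ProbeRecord:
    """One microarray probe: its moderated t and (possibly absent) gene id."""

    probe_id: str
    gene: str | None
    t: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError(f"probe {self.probe_id}: non-finite t")


def collapse_probes(records: Iterable[ProbeRecord]) -> dict[str, float]:
    """Collapse probe-level t-statistics to one score per gene.

    Probes without an assigned gene are discarded. Among a gene's probes the
    one with the largest |t| wins; a |t| tie is broken toward the larger
    signed t, and a residual tie toward the lexicographically smallest
    probe_id, so the result is independent of input order.
    """
    best: dict[str, tuple[float, float, str]] = {}
    for rec in records:
        if rec.gene is None or rec.gene == "":
            continue
        key = (abs(rec.t), rec.t, rec.probe_id)
        cur = best.get(rec.gene)
        # higher |t| wins, then higher signed t, then smaller probe_id
        if cur is None or (key[0], key[1], _neg_str(key[2])) > (
            cur[0],
            cur[1],
            _neg_str(cur[2]),
        ):
            best[rec.gene] = key
    return {gene: t for gene, (_, t, _) in best.items()}


class _neg_str(str):
    """str wrapper with reversed ordering, for min-probe_id tie-breaks."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def rnaseq_de_score(direction: int, adj_p: float) -> float:
    """Signed RNA-seq DE score: -S * log10(adjusted P).

    ``direction`` is +1 for up-regulation in tumour and -1 for
    down-regulation; the score's sign equals the direction and its magnitude
    grows as the adjusted P shrinks. P-values of 0 are floored to 1e-300.
    """
    if direction not in (1, -1):
        raise ValueError(f"direction must be +1 or -1, got {direction!r}")
    if not 0.0 <= adj_p <= 1.0:
        raise ValueError(f"adjusted P outside [0, 1]: {adj_p}")
    adj_p = max(adj_p, MIN_ADJ_P)
    return -direction * math.log10(adj_p)


def average_de(signatures: Sequence[DESignature], gene: str) -> float:
    """Arithmetic mean DE score of ``gene`` over the datasets that contain it."""
    vals = [float(sig.scores[gene]) for sig in signatures if gene in sig.scores.index]
    if not vals:
        raise KeyError(f"gene {gene!r} absent from all signatures")
    return float(np.mean(vals))


def select_by_average_de(
    signatures: Sequence[DESignature], genes: Iterable[str], threshold: float
) -> set[str]:
    """Genes whose average DE across datasets is strictly above ``threshold``."""
    return {g for g in genes if average_de(signatures, g) > threshold}


# -- TSV I/O ---------------------------------------------------------------


def read_signature(path: str | Path) -> DESignature:
    """Read a signature TSV: '#' header comments with dataset_id and platform,
    then columns gene, score."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", dtype={"gene": str, "score": float})
    if list(df.columns) != ["gene", "score"]:
        raise ValueError(f"{path}: expected columns ['gene', 'score']")
    if "dataset_id" not in meta or "platform" not in meta:
        raise ValueError(f"{path}: missing '# dataset_id:' or '# platform:' header")
    return DESignature(
        dataset_id=meta["dataset_id"],
        platform=meta["platform"],
        scores=pd.Series(df["score"].to_numpy(), index=df["gene"]),
    )


def write_signature(sig: DESignature, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# dataset_id: {sig.dataset_id}\n")
        fh.write(f"# platform: {sig.platform}\n")
        fh.write("gene\tscore\n")
        for gene, score in sig.scores.sort_index().items():
            fh.write(f"{gene}\t{score!r}\n")


def read_probe_table(path: str | Path) -> list[ProbeRecord]:
    """Read a probe TSV with columns probe_id, gene (empty allowed), t."""
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "gene": str}, keep_default_na=False
    )
    if list(df.columns) != ["probe_id", "gene", "t"]:
        raise ValueError(f"{path}: expected columns ['probe_id', 'gene', 't']")
    return [
        ProbeRecord(probe_id=p, gene=(g or None), t=float(t))
        for p, g, t in df.itertuples(index=False)
    ]
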