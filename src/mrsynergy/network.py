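"""Regulon interactome model, TSV I/O, and GO-based regulator categories.

The interactome is the edge list of a context-specific regulatory network:
one row per (regulator, target) pair with a mode of regulation (MOR, signed
association strength in [-1, +1]) and a likelihood (edge confidence in
(0, 1]). It is the fixed substrate of every downstream step, so the reader
is strict: malformed or out-of-range rows are rejected, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EDGE_COLUMNS = ("regulator", "target", "mor", "likelihood")


class NetworkFormatError(ValueError):
    """A malformed or invariant-violating interactome row."""


@dataclass
class RegulatoryNetwork:
    """An interactome: unique (regulator, target) edges with MOR and likelihood.

    Invariants (enforced on construction): no self-edges, no duplicate
    (regulator, target) pairs, mor in [-1, +1], likelihood in (0, 1], and
    every regulator has at least one target (trivially true for an edge list).
    """

    edges: pd.DataFrame

    _by_regulator: dict | None = field(default=None, repr=False, compare=False)
    _coded: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.edges, columns=list(EDGE_COLUMNS)).reset_index(drop=True)
        df["regulator"] = df["regulator"].astype(str)
        df["target"] = df["target"].astype(str)
        df["mor"] = df["mor"].astype(float)
        df["likelihood"] = df["likelihood"].astype(float)
        if df[["mor", "likelihood"]].isna().any().any():
            raise NetworkFormatError("mor/likelihood must be numeric and present")
        if (df["regulator"] == df["target"]).any():
            bad = df.index[df["regulator"] == df["target"]][0]
            raise NetworkFormatError(f"self-edge at row {bad}: {df.at[bad, 'regulator']}")
        reg_codes, _ = pd.factorize(df["regulator"], sort=False)
        tgt_codes, tgt_uniques = pd.factorize(df["target"], sort=False)
        key = reg_codes.astype(np.int64) * (len(tgt_uniques) + 1) + tgt_codes
        if np.unique(key).size < len(df):
            dup = pd.Series(key).duplicated()
            bad = int(dup.idxmax())
            raise NetworkFormatError(
                f"duplicate edge at row {bad}: "
                f"({df.at[bad, 'regulator']}, {df.at[bad, 'target']})"
            )
        if ((df["mor"] < -1) | (df["mor"] > 1)).any():
            bad = df.index[(df["mor"] < -1) | (df["mor"] > 1)][0]
            raise NetworkFormatError(f"mor outside [-1, 1] at row {bad}")
        if ((df["likelihood"] <= 0) | (df["likelihood"] > 1)).any():
            bad = df.index[(df["likelihood"] <= 0) | (df["likelihood"] > 1)][0]
            raise NetworkFormatError(f"likelihood outside (0, 1] at row {bad}")
        object.__setattr__(self, "edges", df)

    # -- accessors ---------------------------------------------------------

    @property
    def regulators(self) -> list[str]:
        return sorted(self.edges["regulator"].unique())

    def __len__(self) -> int:
        return len(self.edges)

    def _index(self) -> dict:
        """regulator -> (targets, mors, likelihoods) arrays, built lazily."""
        if self._by_regulator is None:
            idx: dict[str, tuple] = {}
            for reg, sub in self.edges.groupby("regulator", sort=False):
                idx[reg] = (
                    sub["target"].to_numpy(),
                    sub["mor"].to_numpy(),
                    sub["likelihood"].to_numpy(),
                )
            object.__setattr__(self, "_by_regulator", idx)
        return self._by_regulator

    def coded_edges(self) -> tuple[pd.Index, np.ndarray, pd.Index, np.ndarray]:
        """(regulators, regulator codes, target uniques, target codes), cached.

        Integer-coded view of the edge list for vectorised per-regulator
        aggregation; regulators are sorted, target uniques are in first-seen
        order.
        """
        if self._coded is None:
            regs = pd.Index(sorted(self.edges["regulator"].unique()))
            reg_codes = regs.get_indexer(self.edges["regulator"].to_numpy())
            tgt_codes, tgt_uniques = pd.factorize(self.edges["target"], sort=False)
            object.__setattr__(
                self, "_coded", (regs, reg_codes, pd.Index(tgt_uniques), tgt_codes)
            )
        return self._coded

    def regulon_of(self, mr: str) -> list[tuple[str, float, float]]:
        """All (target, mor, likelihood) edges of ``mr``.

        Raises ``KeyError`` naming the gene if it is not a regulator.
        """
        idx = self._index()
        if mr not in idx:
            raise KeyError(f"unknown regulator: {mr!r}")
        targets, mors, liks = idx[mr]
        return list(zip(targets.tolist(), mors.tolist(), liks.tolist()))

    def regulon_size(self, mr: str) -> int:
        idx = self._index()
        if mr not in idx:
            raise KeyError(f"unknown regulator: {mr!r}")
        return len(idx[mr][0])


@dataclass(frozen=True)
class RegulonPartition:
    """Targets of an MR pair split into common / MR1-unique / MR2-unique.

    ``common`` has columns target, mor1, mor2, w1, w2; the unique frames have
    target, mor, w. The three target sets are pairwise disjoint.
    """

    mr1: str
    mr2: str
    common: pd.DataFrame
    unique1: pd.DataFrame
    unique2: pd.DataFrame

    @property
    def size1(self) -> int:
        return len(self.common) + len(self.unique1)

    @property
    def size2(self) -> int:
        return len(self.common) + len(self.unique2)

    @property
    def common_size(self) -> int:
        return len(self.common)


def partition_regulons(net: RegulatoryNetwork, mr1: str, mr2: str) -> RegulonPartition:
    """Split the regulons of two MRs into common and unique target groups.

    The common group carries both MRs' MORs and likelihoods for each shared
    target; when ``mr1 == mr2`` the whole regulon is common.
    """
    t1, m1, w1 = net._index().get(mr1, (None,) * 3)
    if t1 is None:
        raise KeyError(f"unknown regulator: {mr1!r}")
    t2, m2, w2 = net._index().get(mr2, (None,) * 3)
    if t2 is None:
        raise KeyError(f"unknown regulator: {mr2!r}")

    d1 = {t: (mo, w) for t, mo, w in zip(t1, m1, w1)}
    d2 = {t: (mo, w) for t, mo, w in zip(t2, m2, w2)}
    shared = sorted(set(d1) & set(d2))
    common = pd.DataFrame(
        {
            "target": shared,
            "mor1": [d1[t][0] for t in shared],
            "mor2": [d2[t][0] for t in shared],
            "w1": [d1[t][1] for t in shared],
            "w2": [d2[t][1] for t in shared],
        }
    )
    only1 = sorted(set(d1) - set(d2))
    only2 = sorted(set(d2) - set(d1))
    unique1 = pd.DataFrame(
        {"target": only1, "mor": [d1[t][0] for t in only1], "w": [d1[t][1] for t in only1]}
    )
    unique2 = pd.DataFrame(
        {"target": only2, "mor": [d2[t][0] for t in only2], "w": [d2[t][1] for t in only2]}
    )
    return RegulonPartition(mr1=mr1, mr2=mr2, common=common, unique1=unique1, unique2=unique2)


# -- TSV I/O ---------------------------------------------------------------


def read_interactome(path: str | Path) -> RegulatoryNetwork:
    """Read a tab-separated interactome (regulator, target, mor, likelihood).

    UTF-8, header required, no missing values permitted. Violations of the
    network invariants are reported with the offending (1-based, header
    included) file row number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(EDGE_COLUMNS):
            raise NetworkFormatError(
                f"{path}: expected header {list(EDGE_COLUMNS)}, got {header}"
            )
        rows = []
        seen: set[tuple[str, str]] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4 or "" in parts or "." in parts[2:]:
                raise NetworkFormatError(f"{path}:{lineno}: malformed row {line!r}")
            reg, tgt, mor_s, lik_s = parts
            try:
                mor = float(mor_s)
                lik = float(lik_s)
            except ValueError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: non-numeric value") from exc
            if not -1.0 <= mor <= 1.0:
                raise NetworkFormatError(f"{path}:{lineno}: mor {mor} outside [-1, 1]")
            if not 0.0 < lik <= 1.0:
                raise NetworkFormatError(
                    f"{path}:{lineno}: likelihood {lik} outside (0, 1]"
                )
            if reg == tgt:
                raise NetworkFormatError(f"{path}:{lineno}: self-edge {reg}")
            if (reg, tgt) in seen:
                raise NetworkFormatError(f"{path}:{lineno}: duplicate edge ({reg}, {tgt})")
            seen.add((reg, tgt))
            rows.append((reg, tgt, mor, lik))
    return RegulatoryNetwork(pd.DataFrame(rows, columns=list(EDGE_COLUMNS)))


def write_interactome(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the interactome as TSV, edges sorted by (regulator, target)."""
    df = net.edges.sort_values(["regulator", "target"], kind="mergesort")
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for reg, tgt, mor, lik in df.itertuples(index=False):
            fh.write(f"{reg}\t{tgt}\t{mor!r}\t{lik!r}\n")


# -- GO-based MR categories -------------------------------------------------

TF = "TF"
TF_COFACTOR = "TFcoFac"
SIG_PATHWAY = "SigPathway"
UNANNOTATED = "Unannotated"

MR_CATEGORIES = (TF, TF_COFACTOR, SIG_PATHWAY, UNANNOTATED)

_GO_TF_ACTIVITY = "GO:0003700"  # DNA-binding transcription factor activity
_GO_DNA_BINDING = "GO:0003677"
_GO_TX_REGULATOR = "GO:0030528"  # transcription regulator activity
_GO_REG_OF_TX = "GO:0045449"  # regulation of transcription
_GO_TX_COFACTOR = "GO:0003712"
_GO_SIGNAL_TRANSDUCTION = "GO:0007165"
_GO_INTRACELLULAR = "GO:0005622"
_GO_PLASMA_MEMBRANE = "GO:0005886"


@dataclass(frozen=True)
class GOAnnotation:
    """GO term ids annotated to one gene (terms matched literally)."""

    gene: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        for t in self.terms:
            if not (t.startswith("GO:") and len(t) == 10 and t[3:].isdigit()):
                raise ValueError(f"invalid GO term id: {t!r}")
        object.__setattr__(self, "terms", frozenset(self.terms))


def classify_mr(ann: GOAnnotation) -> str:
    """Assign a regulator to TF, TF cofactor, signalling pathway, or unannotated.

    Precedence TF > TFcoFac > SigPathway: a transcription factor is a gene
    with DNA-binding transcription factor activity, or DNA binding combined
    with transcription-regulator activity or regulation of transcription;
    cofactors and signalling genes are matched only among the remainder.
    """
    t = ann.terms
    if _GO_TF_ACTIVITY in t or (
        _GO_DNA_BINDING in t and (_GO_TX_REGULATOR in t or _GO_REG_OF_TX in t)
    ):
        return TF
    if _GO_TX_COFACTOR in t or _GO_TX_REGULATOR in t or _GO_REG_OF_TX in t:
        return TF_COFACTOR
    if _GO_SIGNAL_TRANSDUCTION in t or _GO_INTRACELLULAR in t or _GO_PLASMA_MEMBRANE in t:
        return SIG_PATHWAY
    return UNANNOTATED


def read_go_annotations(path: str | Path) -> dict[str, GOAnnotation]:
    """Read a TSV with columns gene, go_terms (comma-separated term ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ["gene", "go_terms"]:
        raise ValueError(f"{path}: expected columns ['gene', 'go_terms']")
    out: dict[str, GOAnnotation] = {}
    for gene, terms in df.itertuples(index=False):
        ids = frozenset(t for t in terms.split(",") if t)
        out[gene] = GOAnnotation(gene=gene, terms=ids)
    return out
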