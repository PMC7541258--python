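"""End-to-end orchestration: DE signatures -> DA -> selection -> synergy -> cohort.

`analyze` is the in-memory core (used by tests and the acceptance script);
`run_full_analysis` wraps it with file I/O, stage logging and TSV/JSON
exports. Outputs are deterministic functions of the inputs: rerunning on the
same bundle yields byte-identical files. Timings and the config hash go to
the logging stream, never into output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from .activity import da_signature, write_da_table, DEFAULT_MIN_TARGETS
from .network import RegulatoryNetwork, read_interactome
from .selection import (
    DEFAULT_DE_THRESHOLD,
    TopMRSelection,
    select_top_mrs,
    write_selection_report,
)
from .signatures import DESignature, average_de, read_signature
from .synergy import (
    DEFAULT_MIN_COMMON,
    DEFAULT_MIN_FRAC,
    synergy_screen,
    write_synergy_report,
)

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 100


class ConfigError(ValueError):
    """An invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """File-level configuration of a full pipeline run.

    ``signature_dir`` holds one signature TSV per dataset; ``cohort_dir`` is
    optional and enables the association battery. All thresholds default to
    the analysis' standard values (top-N 100, |DE| > 3, > 10 common targets
    and > 10% overlap, mutation alpha 0.1, survival split at the 80th
    percentile).
    """

    interactome: Path
    signature_dir: Path
    out_dir: Path
    discovery_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    n: int = DEFAULT_TOP_N
    de_threshold: float = DEFAULT_DE_THRESHOLD
    min_targets: int = DEFAULT_MIN_TARGETS
    min_common: int = DEFAULT_MIN_COMMON
    min_frac: float = DEFAULT_MIN_FRAC
    alpha_mutation: float = assoc.DEFAULT_MUTATION_ALPHA
    survival_percentile: float = assoc.DEFAULT_SURVIVAL_PERCENTILE
    cohort_dir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.discovery_ids or not self.validation_ids:
            raise ConfigError("discovery_ids and validation_ids must be nonempty")
        if set(self.discovery_ids) & set(self.validation_ids):
            raise ConfigError("discovery and validation dataset ids overlap")
        for p in (self.interactome, self.signature_dir):
            if not Path(p).exists():
                raise ConfigError(f"missing input path: {p}")
        if self.cohort_dir is not None and not Path(self.cohort_dir).exists():
            raise ConfigError(f"missing cohort directory: {self.cohort_dir}")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat YAML config; keyword overrides win over file values."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    base = Path(path).parent
    for key in ("interactome", "signature_dir", "out_dir", "cohort_dir"):
        if raw.get(key) is not None:
            p = Path(raw[key])
            raw[key] = p if p.is_absolute() else base / p
    for key in ("discovery_ids", "validation_ids"):
        if isinstance(raw.get(key), str):
            raw[key] = tuple(s.strip() for s in raw[key].split(",") if s.strip())
        elif raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


@dataclass(frozen=True)
class AnalysisResult:
    """In-memory result of the core pipeline stages."""

    da_tables: dict  # dataset_id -> DATable
    selection: TopMRSelection
    consistent: frozenset[str]
    synergy: list
    top_pair: tuple[str, str] | None

    def summary(self) -> dict:
        """JSON-serialisable machine-readable summary."""
        pairs = []
        for res in self.synergy:
            per_ds = {
                ds: {
                    "p1": _none_if_nan(p1),
                    "p2": _none_if_nan(p2),
                    "da_sign1": s1,
                    "da_sign2": s2,
                }
                for ds, (p1, p2, s1, s2) in sorted(res.per_dataset.items())
            }
            pairs.append(
                {
                    "mr1": res.mr1,
                    "mr2": res.mr2,
                    "size1": res.size1,
                    "size2": res.size2,
                    "common_size": res.common_size,
                    "worst_p": res.worst_p(),
                    "per_dataset": per_ds,
                }
            )
        return {
            "n": self.selection.n,
            "activated": sorted(self.selection.activated),
            "suppressed": sorted(self.selection.suppressed),
            "validation_p": {
                f"{ds}:{direction}": p
                for (ds, direction), p in sorted(self.selection.validation_p.items())
            },
            "consistent": sorted(self.consistent),
            "eligible_pairs": pairs,
            "top_pair": list(self.top_pair) if self.top_pair else None,
        }


def _none_if_nan(x):
    return None if (x is None or (isinstance(x, float) and np.isnan(x))) else x


def analyze(
    net: RegulatoryNetwork,
    sigs: Sequence[DESignature],
    discovery_ids: Sequence[str],
    validation_ids: Sequence[str],
    n: int = DEFAULT_TOP_N,
    de_threshold: float = DEFAULT_DE_THRESHOLD,
    min_targets: int = DEFAULT_MIN_TARGETS,
    min_common: int = DEFAULT_MIN_COMMON,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> AnalysisResult:
    """DA inference, top-MR selection, consistency filter and synergy screen.

    The synergy screen runs over the DA-DE consistent MRs using every dataset
    (discovery and validation). The "top pair" convention is the eligible
    pair minimising its worst (largest) per-dataset p, undefined p counting
    as 1; ties break lexicographically.
    """
    by_id = {sig.dataset_id: sig for sig in sigs}
    missing = (set(discovery_ids) | set(validation_ids)) - set(by_id)
    if missing:
        raise ConfigError(f"datasets without signatures: {sorted(missing)}")

    t0 = time.perf_counter()
    da_tables = {ds: da_signature(net, by_id[ds], min_targets) for ds in sorted(by_id)}
    logger.info("stage activity: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    selection, consistent = select_top_mrs(
        [da_tables[d] for d in discovery_ids],
        [da_tables[d] for d in validation_ids],
        [by_id[d] for d in discovery_ids],
        n=n,
        de_threshold=de_threshold,
    )
    logger.info("stage selection: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    all_ids = list(discovery_ids) + list(validation_ids)
    synergy = synergy_screen(
        net,
        set(consistent),
        [by_id[d] for d in all_ids],
        [da_tables[d] for d in all_ids],
        min_common=min_common,
        min_frac=min_frac,
    )
    logger.info("stage synergy: %.2fs", time.perf_counter() - t0)

    top_pair = None
    if synergy:
        best = min(synergy, key=lambda r: (r.worst_p(), r.mr1, r.mr2))
        top_pair = (best.mr1, best.mr2)
    return AnalysisResult(
        da_tables=da_tables,
        selection=selection,
        consistent=frozenset(consistent),
        synergy=synergy,
        top_pair=top_pair,
    )


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the configured pipeline and write all stage outputs.

    Writes per-dataset DA tables, the selection report, the synergy report,
    Cytoscape node/edge tables for the top pair, the association battery
    (when a cohort is configured) and summary.json under ``cfg.out_dir``.
    Returns the summary dict. Inputs are never mutated; a stage failure
    raises with the stage name while earlier outputs are retained.
    """
    cfg_text = repr(cfg).encode()
    logger.info(
        "run config hash %s seed %d", hashlib.sha256(cfg_text).hexdigest()[:12], cfg.seed
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = read_interactome(cfg.interactome)
    sigs = [
        read_signature(p) for p in sorted(Path(cfg.signature_dir).glob("*.tsv"))
    ]
    result = analyze(
        net,
        sigs,
        cfg.discovery_ids,
        cfg.validation_ids,
        n=cfg.n,
        de_threshold=cfg.de_threshold,
        min_targets=cfg.min_targets,
        min_common=cfg.min_common,
        min_frac=cfg.min_frac,
    )

    for ds, da in sorted(result.da_tables.items()):
        write_da_table(da, out / f"da_{ds}.tsv")
    write_selection_report(
        result.selection,
        set(result.consistent),
        [result.da_tables[d] for d in cfg.discovery_ids],
        out / "selection.tsv",
    )
    all_ids = list(cfg.discovery_ids) + list(cfg.validation_ids)
    write_synergy_report(result.synergy, all_ids, out / "synergy.tsv")

    if result.top_pair is not None:
        nodes, edges = export_cytoscape_tables(net, set(result.top_pair), sigs)
        _write_tsv(nodes, out / "network_nodes.tsv")
        _write_tsv(edges, out / "network_edges.tsv")

    summary = result.summary()
    if cfg.cohort_dir is not None and result.top_pair is not None:
        t0 = time.perf_counter()
        cohort = assoc.read_cohort(cfg.cohort_dir)
        summary["associations"] = _association_battery(
            cohort, result.top_pair, cfg, out
        )
        logger.info("stage associations: %.2fs", time.perf_counter() - t0)

    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    return summary


def _association_battery(
    cohort: assoc.CohortTable,
    pair: tuple[str, str],
    cfg: RunConfig,
    out: Path,
) -> dict:
    """Clinical/mutation/survival battery for the top pair's genes."""
    genes = [g for g in pair if g in cohort.expression.index]
    battery: dict = {}
    rows = []
    for gene in genes:
        for feature in sorted(cohort.categorical.columns):
            res = assoc.categorical_association(cohort, gene, feature)
            rows.append(
                (gene, feature, res.low_group or "NA", res.high_group or "NA",
                 "NA" if res.p is None else repr(res.p))
            )
            battery[f"categorical:{gene}:{feature}"] = res.p
    _write_rows(
        ["gene", "feature", "low_group", "high_group", "p"], rows,
        out / "categorical_associations.tsv",
    )

    rows = []
    mut_genes = sorted(cohort.mutations["gene"].unique())
    selected_for_combined: set[str] = set()
    for gene in genes:
        for mg in mut_genes:
            for m in assoc.mutation_association(cohort, gene, mg, cfg.alpha_mutation):
                rows.append(
                    (gene, mg, m.mutation_class.value, str(m.n),
                     repr(m.delta_median), m.direction, repr(m.p),
                     "yes" if m.selected else "no")
                )
                if (
                    m.selected
                    and m.mutation_class is assoc.MutationClass.MISSENSE
                    and m.direction == "higher"
                ):
                    selected_for_combined.add(mg)
    _write_rows(
        ["gene", "mutated_gene", "class", "n", "delta_median", "direction", "p",
         "selected"],
        rows,
        out / "mutation_associations.tsv",
    )

    if selected_for_combined:
        for gene in genes:
            n_mut, n_none, p = assoc.combined_mutation_test(
                cohort, gene, selected_for_combined
            )
            battery[f"combined_missense:{gene}"] = {
                "n_mutated": n_mut, "n_unmutated": n_none, "p": p,
                "gene_set": sorted(selected_for_combined),
            }

    for gene in genes:
        for feature in sorted(cohort.numerical.columns):
            rho, p = assoc.numerical_association(cohort, gene, feature)
            battery[f"numerical:{gene}:{feature}"] = {"rho": rho, "p": p}
        res = assoc.survival_split_logrank(cohort, gene, cfg.survival_percentile)
        battery[f"survival:{gene}"] = {
            "n_high": res.n_high, "n_low": res.n_low,
            "chi_sq": res.chi_sq, "p": res.p, "reason": res.reason,
        }
    return battery


def export_cytoscape_tables(
    net: RegulatoryNetwork, mrs: set[str], sigs: Sequence[DESignature]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for network visualisation of selected MRs.

    Nodes are the MRs plus every regulon target scored in at least one
    signature, annotated with the cross-dataset average DE (NA when the gene
    is unscored, e.g. an MR absent from the signatures). Edges are the
    regulator->target pairs restricted to scored targets, annotated with MOR.
    """
    scored: set[str] = set()
    for sig in sigs:
        scored.update(sig.scores.index)
    edge_rows = []
    node_ids: set[str] = set(mrs)
    for mr in sorted(mrs):
        for target, mor, _ in net.regulon_of(mr):
            if target in scored:
                edge_rows.append((mr, target, mor))
                node_ids.add(target)
    node_rows = []
    for gene in sorted(node_ids):
        try:
            avg = average_de(sigs, gene)
        except KeyError:
            avg = float("nan")
        node_rows.append((gene, avg))
    nodes = pd.DataFrame(node_rows, columns=["gene", "average_de"])
    edges = pd.DataFrame(edge_rows, columns=["regulator", "target", "mor"])
    return nodes, edges


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            cells = [
                "NA" if (isinstance(v, float) and np.isnan(v)) else
                (repr(v) if isinstance(v, float) else str(v))
                for v in row
            ]
            fh.write("\t".join(cells) + "\n")


def _write_rows(header: list[str], rows: list[tuple], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
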