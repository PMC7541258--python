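"""Association of regulator expression with clinical features, mutations, survival.

Works on a cohort of tumour/normal samples with per-gene expression,
categorical and numerical sample features, per-gene somatic mutation events
and overall-survival follow-up. Tests mirror common practice for such
cohorts: rank-sum comparisons between extreme categorical groups, rank-sum
comparisons of mutated vs unmutated samples (with missense and
loss-of-function classes kept apart), Spearman correlation for numerical
features, and a log-rank test after splitting expression at a percentile.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats as _sps

from .stats import rank_sum_p

#: categorical groups with at most this many samples are dropped (strict '>')
DEFAULT_MIN_GROUP = 5
DEFAULT_MUTATION_ALPHA = 0.1
DEFAULT_SURVIVAL_PERCENTILE = 80.0

MUTATION_EVENTS = ("missense", "nonsense", "frameshift", "splice")
LOF_EVENTS = frozenset({"nonsense", "frameshift", "splice"})


class MutationClass(enum.Enum):
    """Per-sample, per-gene mutation class; LOF dominates missense."""

    NONE = "None"
    MISSENSE = "missense"
    LOF = "LOF"


def classify_mutation(events: Iterable[str]) -> MutationClass:
    """Collapse a sample's mutation events in one gene to a single class.

    Loss-of-function events (nonsense, frameshift, splice) dominate: a sample
    carrying both a missense and a LOF mutation is classified LOF.
    """
    events = set(events)
    unknown = events - set(MUTATION_EVENTS)
    if unknown:
        raise ValueError(f"unknown mutation event kind(s): {sorted(unknown)}")
    if not events:
        return MutationClass.NONE
    if events & LOF_EVENTS:
        return MutationClass.LOF
    return MutationClass.MISSENSE


@dataclass
class CohortTable:
    """Samples with expression, features, mutation events and survival.

    ``expression`` is genes x samples; ``categorical`` and ``numerical`` are
    samples x features; ``mutations`` is a long frame with columns sample,
    gene, event; ``survival`` is indexed by sample with columns os_time,
    os_event (0/1). Samples present in ``survival`` with an event must carry
    a time.
    """

    expression: pd.DataFrame
    categorical: pd.DataFrame
    numerical: pd.DataFrame
    mutations: pd.DataFrame
    survival: pd.DataFrame

    def __post_init__(self) -> None:
        self.expression = pd.DataFrame(self.expression, dtype=float)
        if self.expression.isna().any().any():
            raise ValueError("expression values must be present for all samples")
        for col in ("sample", "gene", "event"):
            if col not in self.mutations.columns:
                raise ValueError(f"mutations frame missing column {col!r}")
        bad = set(self.mutations["event"]) - set(MUTATION_EVENTS)
        if bad:
            raise ValueError(f"unknown mutation event kind(s): {sorted(bad)}")
        if not self.survival.empty:
            if not set(self.survival.columns) >= {"os_time", "os_event"}:
                raise ValueError("survival frame needs os_time and os_event")
            ev = self.survival["os_event"].astype(int)
            if not ev.isin([0, 1]).all():
                raise ValueError("os_event must be 0/1")
            if self.survival.loc[ev == 1, "os_time"].isna().any():
                raise ValueError("os_event=1 requires os_time")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def mutation_classes(self, gene: str) -> pd.Series:
        """Per-sample MutationClass for one gene, over all cohort samples."""
        sub = self.mutations[self.mutations["gene"] == gene]
        by_sample = sub.groupby("sample")["event"].agg(set)
        return pd.Series(
            {
                s: classify_mutation(by_sample.get(s, set()))
                for s in self.samples
            }
        )


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a two-group comparison; ``p`` is None when undefined."""

    low_group: str | None
    high_group: str | None
    p: float | None
    reason: str | None = None


def categorical_association(
    cohort: CohortTable,
    gene: str,
    feature: str,
    min_group: int = DEFAULT_MIN_GROUP,
) -> AssociationResult:
    """Compare the lowest- against the highest-median expression group.

    Groups with at most ``min_group`` samples are dropped (strict '>'); with
    fewer than two groups left the result is undefined with a reason. Median
    ties between groups are broken by lexicographic group label.
    """
    if gene not in cohort.expression.index:
        raise KeyError(f"gene {gene!r} not in expression table")
    labels = cohort.categorical[feature].dropna()
    expr = cohort.expression.loc[gene]
    groups: dict[str, np.ndarray] = {}
    for label in sorted(labels.unique()):
        members = labels.index[labels == label]
        members = [s for s in members if s in expr.index]
        if len(members) > min_group:
            groups[str(label)] = expr[members].to_numpy()
    if len(groups) < 2:
        return AssociationResult(
            None, None, None, reason=f"fewer than 2 groups with > {min_group} samples"
        )
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    low = min(sorted(medians), key=lambda g: medians[g])
    high = max(sorted(medians), key=lambda g: medians[g])
    p = rank_sum_p(groups[low], groups[high], "two-sided")
    return AssociationResult(low_group=low, high_group=high, p=p)


@dataclass(frozen=True)
class MutationAssociation:
    """One mutation-class vs no-mutation comparison for one gene pair."""

    mutation_class: MutationClass
    n: int
    delta_median: float
    direction: str  # "higher" / "lower" / "equal"
    p: float
    selected: bool


def mutation_association(
    cohort: CohortTable,
    mr_gene: str,
    mutated_gene: str,
    alpha: float = DEFAULT_MUTATION_ALPHA,
) -> list[MutationAssociation]:
    """Compare MR expression in missense / LOF samples against unmutated ones.

    For each mutation class with at least one sample: two-sided rank-sum p
    against the None group, the median expression difference (mutated minus
    unmutated), its direction, and whether p < alpha (strict). Classes with
    no samples are omitted.
    """
    classes = cohort.mutation_classes(mutated_gene)
    expr = cohort.expression.loc[mr_gene]
    none_samples = classes.index[classes == MutationClass.NONE]
    if len(none_samples) == 0:
        raise ValueError(f"no unmutated samples for gene {mutated_gene!r}")
    none_expr = expr[none_samples].to_numpy()
    out: list[MutationAssociation] = []
    for cls in (MutationClass.MISSENSE, MutationClass.LOF):
        members = classes.index[classes == cls]
        if len(members) == 0:
            continue
        vals = expr[members].to_numpy()
        p = rank_sum_p(vals, none_expr, "two-sided")
        delta = float(np.median(vals) - np.median(none_expr))
        direction = "higher" if delta > 0 else ("lower" if delta < 0 else "equal")
        out.append(
            MutationAssociation(
                mutation_class=cls,
                n=len(members),
                delta_median=delta,
                direction=direction,
                p=p,
                selected=p < alpha,
            )
        )
    return out


def combined_mutation_test(
    cohort: CohortTable, mr_gene: str, gene_set: set[str]
) -> tuple[int, int, float | None]:
    """Missense-in-any vs unmutated-in-all comparison over a gene set.

    Group A: samples with a missense class for at least one gene of the set.
    Group B: samples whose class is None for every gene of the set. Samples
    that only carry LOF mutations in the set fall in neither group, keeping
    both definitions simultaneously satisfiable. Returns (n_A, n_B, p);
    p is None with empty groups.
    """
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    class_by_gene = {g: cohort.mutation_classes(g) for g in sorted(gene_set)}
    expr = cohort.expression.loc[mr_gene]
    group_a: list[str] = []
    group_b: list[str] = []
    for s in cohort.samples:
        classes = {class_by_gene[g][s] for g in class_by_gene}
        if MutationClass.MISSENSE in classes:
            group_a.append(s)
        elif classes == {MutationClass.NONE}:
            group_b.append(s)
    if not group_a or not group_b:
        return (len(group_a), len(group_b), None)
    p = rank_sum_p(expr[group_a].to_numpy(), expr[group_b].to_numpy(), "two-sided")
    return (len(group_a), len(group_b), p)


def numerical_association(
    cohort: CohortTable, gene: str, feature: str
) -> tuple[float, float]:
    """Spearman correlation (rho, p) of expression against a numerical feature."""
    expr = cohort.expression.loc[gene]
    vals = cohort.numerical[feature]
    paired = pd.concat([expr, vals], axis=1, join="inner").dropna()
    if len(paired) < 4:
        raise ValueError(
            f"numerical_association needs >= 4 paired observations, got {len(paired)}"
        )
    rho, p = _sps.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
    return float(rho), float(p)


@dataclass(frozen=True)
class LogrankResult:
    n_high: int
    n_low: int
    chi_sq: float | None
    p: float | None
    reason: str | None = None


def survival_split_logrank(
    cohort: CohortTable,
    gene: str,
    percentile: float = DEFAULT_SURVIVAL_PERCENTILE,
) -> LogrankResult:
    """Log-rank test between high- and low-expression survival groups.

    The threshold is the linear-interpolation percentile of the expression
    values of samples with survival data; the high group is strictly above it
    (ties at the threshold go low). Undefined with a reason when either group
    has fewer than 2 samples or no event occurred.
    """
    surv = cohort.survival.dropna(subset=["os_time"])
    samples = [s for s in surv.index if s in cohort.expression.columns]
    if not samples:
        return LogrankResult(0, 0, None, None, reason="no samples with survival data")
    expr = cohort.expression.loc[gene, samples]
    thr = float(np.percentile(expr.to_numpy(), percentile))
    high = expr.index[expr > thr]
    low = expr.index[expr <= thr]
    if len(high) < 2 or len(low) < 2:
        return LogrankResult(
            len(high), len(low), None, None, reason="a group has fewer than 2 samples"
        )
    events = surv["os_event"].astype(int)
    if events[samples].sum() == 0:
        return LogrankResult(len(high), len(low), None, None, reason="no events")
    res = logrank_test(
        surv.loc[high, "os_time"],
        surv.loc[low, "os_time"],
        event_observed_A=events[high],
        event_observed_B=events[low],
    )
    return LogrankResult(
        n_high=len(high),
        n_low=len(low),
        chi_sq=float(res.test_statistic),
        p=float(res.p_value),
    )


# -- reference-cohort reproduction ------------------------------------------


def reference_cohort_checks(path: str | Path) -> dict[str, float]:
    """Checks on a published cervical-cohort expression table of CENPF/TOP2A.

    Expects a TSV with columns sample, sample_type (N/C/M), CENPF, TOP2A.
    Returns the Pearson correlation of the two genes over all samples and the
    rank-sum p-values for the M-vs-C (CENPF) and C-vs-N (both genes)
    contrasts. The table is external published data and must be supplied by
    the user; it is not bundled.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "sample_type", "CENPF", "TOP2A"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    r, _ = _sps.pearsonr(df["CENPF"], df["TOP2A"])
    by = {t: sub for t, sub in df.groupby("sample_type")}
    out = {"pearson_r": float(r)}
    out["p_cenpf_m_vs_c"] = rank_sum_p(by["M"]["CENPF"], by["C"]["CENPF"], "two-sided")
    out["p_cenpf_c_vs_n"] = rank_sum_p(by["C"]["CENPF"], by["N"]["CENPF"], "two-sided")
    out["p_top2a_c_vs_n"] = rank_sum_p(by["C"]["TOP2A"], by["N"]["TOP2A"], "two-sided")
    return out


# -- cohort TSV I/O ----------------------------------------------------------


def read_cohort(directory: str | Path) -> CohortTable:
    """Read a cohort bundle: expression.tsv (genes x samples), samples.tsv,
    numerical.tsv, mutations.tsv (sample, gene, event), survival.tsv."""
    d = Path(directory)
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    categorical = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0, dtype=str)
    numerical = pd.read_csv(d / "numerical.tsv", sep="\t", index_col=0)
    mutations = pd.read_csv(d / "mutations.tsv", sep="\t", dtype=str)
    survival = pd.read_csv(d / "survival.tsv", sep="\t", index_col=0)
    return CohortTable(
        expression=expression,
        categorical=categorical,
        numerical=numerical,
        mutations=mutations,
        survival=survival,
    )


def write_cohort(cohort: CohortTable, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(d / "expression.tsv", sep="\t", lineterminator="\n")
    cohort.categorical.to_csv(d / "samples.tsv", sep="\t", lineterminator="\n")
    cohort.numerical.to_csv(d / "numerical.tsv", sep="\t", lineterminator="\n")
    cohort.mutations.to_csv(d / "mutations.tsv", sep="\t", index=False, lineterminator="\n")
    cohort.survival.to_csv(d / "survival.tsv", sep="\t", lineterminator="\n")
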