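"""Synthetic benchmark generators with planted ground truth.

The generators emit the three inputs the pipeline consumes — an interactome,
a panel of DE signatures, and a clinical cohort — with a known planted
structure: a set of activated/suppressed master regulators whose targets are
shifted through mor*likelihood weighting (so the NES model is correctly
specified at defaults), one synergistic MR pair whose shared targets carry an
extra shift, a correlated designated gene pair with ordered N < C < M group
means, missense-mutation-linked expression shifts, and survival hazard tied
to high expression. Defaults state a fixed world (sizes and effects mirroring
a ten-dataset cervical-cancer style analysis); they are documented in
docs/methods.md and are not tuning knobs.

All generators are pure functions of (config, seed): one integer seed drives
named substreams (network / DE / cohort), so e.g. changing cohort sizes never
perturbs the generated network.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork, write_interactome
from .associations import CohortTable, write_cohort
from .signatures import DESignature, write_signature
from .synergy import eligible_pair

# substream tags: one per generator
_STREAM_NETWORK = 1
_STREAM_DE = 2
_STREAM_COHORT = 3


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the synthetic benchmark.

    Network: ``n_mrs`` regulators over ``n_target_genes`` potential targets,
    regulon sizes uniform over ``regulon_size_range`` (inclusive), MOR signs
    positive with probability ``mor_positive_fraction``, magnitudes U(0.3, 1),
    likelihoods U(0.1, 1). Signatures: planted shifts plus per-dataset
    N(0, sqrt(1 + dataset_noise_sd^2)) noise (unit biological baseline plus
    inter-dataset heterogeneity). Cohort: normal/tumour/metastatic groups of
    sizes ``n_n``/``n_c``/``n_m`` with designated-gene group means
    ``group_means`` and unit within-group spread.
    """

    n_mrs: int = 5000
    n_target_genes: int = 20000
    regulon_size_range: tuple[int, int] = (100, 200)
    mor_positive_fraction: float = 0.7
    n_discovery: int = 5
    n_validation: int = 5
    dataset_noise_sd: float = 0.5
    n_n: int = 10
    n_c: int = 30
    n_m: int = 20
    seed: int = 0

    # planted-effect structure
    n_activated: int = 18
    n_suppressed: int = 3
    effect: float = 2.0
    extra_effect: float = 2.0
    pair_common_size: int = 34
    mr_self_de_shift: float = 8.0
    planted_r: float = 0.8
    group_means: tuple[float, float, float] = (0.0, 1.0, 2.0)
    mutation_shift: float = 2.0
    missense_prob: float = 0.25
    lof_prob: float = 0.10
    survival_hazard_ratio: float = 2.0
    survival_scale: float = 50.0
    followup_time: float = 60.0

    def __post_init__(self) -> None:
        lo, hi = self.regulon_size_range
        if min(self.n_mrs, self.n_target_genes, self.n_discovery, self.n_validation,
               self.n_n, self.n_c, self.n_m) <= 0:
            raise ValueError("all counts must be positive")
        if lo < 2 or hi < lo:
            raise ValueError("regulon sizes must be >= 2 with lo <= hi")
        if self.n_target_genes < hi:
            raise ValueError("n_target_genes must be at least the max regulon size")
        if self.n_activated + self.n_suppressed > self.n_mrs:
            raise ValueError("more planted MRs than regulators")
        if not 0.0 <= self.mor_positive_fraction <= 1.0:
            raise ValueError("mor_positive_fraction must be in [0, 1]")
        if self.pair_common_size >= lo:
            raise ValueError("pair_common_size must be below the minimum regulon size")
        if self.n_activated < 2:
            raise ValueError("need at least 2 activated MRs for the synergistic pair")
        if not -1.0 < self.planted_r < 1.0:
            raise ValueError("planted_r must be in (-1, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Planted parameters the recovery tests check against."""

    active_mrs: dict  # regulator -> signed effect
    synergistic_pair: tuple[str, str, float]  # (mr1, mr2, extra_effect)
    planted_correlation: tuple[str, str, float]  # (geneA, geneB, r)
    mutation_effects: dict  # gene -> expression shift
    survival_hazard_ratio: float
    seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["synergistic_pair"] = list(d["synergistic_pair"])
        d["planted_correlation"] = list(d["planted_correlation"])
        return json.dumps(d, sort_keys=True, indent=1)


def _mr_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_mrs))
    return [f"MR{i + 1:0{width}d}" for i in range(cfg.n_mrs)]


def _gene_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_target_genes))
    return [f"G{i + 1:0{width}d}" for i in range(cfg.n_target_genes)]


def _sample_distinct(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    """k distinct draws from pool (order irrelevant downstream)."""
    return rng.choice(pool, size=k, replace=False)


def _draw_mor(rng: np.random.Generator, k: int, pos_frac: float) -> np.ndarray:
    sign = np.where(rng.random(k) < pos_frac, 1.0, -1.0)
    return sign * rng.uniform(0.3, 1.0, k)


def simulate_interactome(cfg: SimConfig) -> tuple[RegulatoryNetwork, SimTruth]:
    """Generate the regulon network and the planted truth.

    The first ``n_activated`` regulators are planted activated (effect
    +``effect``), the next ``n_suppressed`` suppressed; the first two
    activated regulators form the synergistic pair and share a block of
    ``pair_common_size`` targets that both regulate positively. The block is
    sized by config to pass the synergy eligibility rule; an infeasible
    configuration raises.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_NETWORK])
    mrs = _mr_ids(cfg)
    genes = np.array(_gene_ids(cfg))
    lo, hi = cfg.regulon_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_mrs)

    mr1, mr2 = mrs[0], mrs[1]
    c = cfg.pair_common_size
    if not eligible_pair(int(sizes[0]), int(sizes[1]), c):
        raise ValueError(
            f"infeasible config: common block {c} fails eligibility for regulon "
            f"sizes {int(sizes[0])}, {int(sizes[1])}"
        )

    regs: list[np.ndarray] = []
    tgts: list[np.ndarray] = []
    mors: list[np.ndarray] = []
    liks: list[np.ndarray] = []

    # pair: shared positive-MOR block plus mutually disjoint unique targets
    block_and_unique = _sample_distinct(
        rng, genes, c + (int(sizes[0]) - c) + (int(sizes[1]) - c)
    )
    common_block = block_and_unique[:c]
    uniq1 = block_and_unique[c : c + int(sizes[0]) - c]
    uniq2 = block_and_unique[c + int(sizes[0]) - c :]
    for mr, uniq, size in ((mr1, uniq1, sizes[0]), (mr2, uniq2, sizes[1])):
        t = np.concatenate([common_block, uniq])
        m = np.concatenate(
            [rng.uniform(0.3, 1.0, c), _draw_mor(rng, int(size) - c, cfg.mor_positive_fraction)]
        )
        regs.append(np.repeat(mr, size))
        tgts.append(t)
        mors.append(m)
        liks.append(rng.uniform(0.1, 1.0, int(size)))

    for i in range(2, cfg.n_mrs):
        k = int(sizes[i])
        regs.append(np.repeat(mrs[i], k))
        tgts.append(_sample_distinct(rng, genes, k))
        mors.append(_draw_mor(rng, k, cfg.mor_positive_fraction))
        liks.append(rng.uniform(0.1, 1.0, k))

    edges = pd.DataFrame(
        {
            "regulator": np.concatenate(regs),
            "target": np.concatenate(tgts),
            "mor": np.concatenate(mors),
            "likelihood": np.concatenate(liks),
        }
    )
    net = RegulatoryNetwork(edges)

    active: dict[str, float] = {}
    for i in range(cfg.n_activated):
        active[mrs[i]] = cfg.effect
    for i in range(cfg.n_activated, cfg.n_activated + cfg.n_suppressed):
        active[mrs[i]] = -cfg.effect
    truth = SimTruth(
        active_mrs=active,
        synergistic_pair=(mr1, mr2, cfg.extra_effect),
        planted_correlation=(mr1, mr2, cfg.planted_r),
        mutation_effects={"MUTA": cfg.mutation_shift, "MUTB": cfg.mutation_shift},
        survival_hazard_ratio=cfg.survival_hazard_ratio,
        seed=cfg.seed,
    )
    return net, truth


def simulate_de_datasets(
    net: RegulatoryNetwork, truth: SimTruth, cfg: SimConfig
) -> list[DESignature]:
    """Discovery + validation DE signatures sharing the planted biology.

    Every gene's score is its planted shift plus independent per-dataset
    N(0, sqrt(1 + dataset_noise_sd^2)) noise; at zero effects the signatures
    are i.i.d. noise across datasets. Targets of an active MR are shifted by
    effect * mor * likelihood (so the activity model is correctly specified),
    shared targets of the synergistic pair gain an extra extra_effect * mor
    per pair member, and each active MR's own gene is shifted by
    ``mr_self_de_shift`` in the direction of its effect so the DA-DE
    consistency rule is exercisable.
    """
    all_genes = pd.Index(_gene_ids(cfg) + _mr_ids(cfg))
    shift = pd.Series(0.0, index=all_genes)

    edges = net.edges
    for mr, d in truth.active_mrs.items():
        sub = edges[edges["regulator"] == mr]
        shift[sub["target"].to_numpy()] += (
            d * sub["mor"].to_numpy() * sub["likelihood"].to_numpy()
        )
        shift[mr] += np.sign(d) * cfg.mr_self_de_shift
    mr1, mr2, extra = truth.synergistic_pair
    sub1 = edges[edges["regulator"] == mr1]
    sub2 = edges[edges["regulator"] == mr2]
    common = np.intersect1d(sub1["target"].to_numpy(), sub2["target"].to_numpy())
    for sub in (sub1, sub2):
        mask = sub["target"].isin(common).to_numpy()
        shift[sub["target"].to_numpy()[mask]] += extra * sub["mor"].to_numpy()[mask]

    total_sd = float(np.sqrt(1.0 + cfg.dataset_noise_sd**2))
    shift_vals = shift.to_numpy()
    sigs: list[DESignature] = []
    n_total = cfg.n_discovery + cfg.n_validation
    for d_idx in range(n_total):
        rng = np.random.default_rng([cfg.seed, _STREAM_DE, d_idx])
        scores = shift_vals + rng.normal(0.0, total_sd, len(all_genes))
        if d_idx < cfg.n_discovery:
            ds_id = f"disc_{d_idx + 1:02d}"
            platform = "microarray"
        else:
            ds_id = f"valid_{d_idx - cfg.n_discovery + 1:02d}"
            platform = "rnaseq" if d_idx == cfg.n_discovery else "microarray"
        sigs.append(
            DESignature(
                dataset_id=ds_id,
                platform=platform,
                scores=pd.Series(scores, index=all_genes),
            )
        )
    return sigs


def simulate_expression_cohort(cfg: SimConfig, truth: SimTruth) -> CohortTable:
    """Cohort with N/C/M groups, a correlated designated gene pair, mutation
    shifts, and expression-linked survival.

    Within each sample group the two designated genes (the synergistic pair's
    own genes) are bivariate normal with the planted correlation and unit
    spread around ordered group means N < C < M. Tumour samples acquire
    missense or LOF mutations in the truth's mutation genes; missense
    carriers have both designated genes shifted by the gene's planted effect
    (LOF carriers are left unshifted and act as a built-in null). Survival is
    exponential, with the hazard multiplied by the planted ratio for samples
    in the top 20% of the first designated gene's expression, censored at the
    follow-up horizon.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_COHORT])
    geneA, geneB, r = truth.planted_correlation
    groups = (["N"] * cfg.n_n) + (["C"] * cfg.n_c) + (["M"] * cfg.n_m)
    samples = [f"{g}{i + 1:03d}" for g, i in zip(groups, _within_group_counter(groups))]
    n = len(samples)

    means = {"N": cfg.group_means[0], "C": cfg.group_means[1], "M": cfg.group_means[2]}
    cov = np.array([[1.0, r], [r, 1.0]])
    ab = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    mu = np.array([means[g] for g in groups])
    exprA = mu + ab[:, 0]
    exprB = mu + ab[:, 1]

    # somatic mutations: tumour samples only; missense shifts both genes
    mut_rows: list[tuple[str, str, str]] = []
    lof_kinds = ("nonsense", "frameshift", "splice")
    is_tumour = np.array([g != "N" for g in groups])
    for gene, eff in sorted(truth.mutation_effects.items()):
        u = rng.random(n)
        missense = is_tumour & (u < cfg.missense_prob)
        lof = is_tumour & (u >= cfg.missense_prob) & (u < cfg.missense_prob + cfg.lof_prob)
        exprA = exprA + np.where(missense, eff, 0.0)
        exprB = exprB + np.where(missense, eff, 0.0)
        kinds = rng.integers(0, len(lof_kinds), size=n)
        for i, s in enumerate(samples):
            if missense[i]:
                mut_rows.append((s, gene, "missense"))
            elif lof[i]:
                mut_rows.append((s, gene, lof_kinds[kinds[i]]))

    expression = pd.DataFrame(
        [exprA, exprB], index=[geneA, geneB], columns=samples
    )

    categorical = pd.DataFrame({"sample_type": groups}, index=samples)
    purity = 0.5 * (exprA - exprA.mean()) / exprA.std() + rng.normal(0, 1, n)
    numerical = pd.DataFrame({"purity": purity}, index=samples)

    thr = np.percentile(exprA, 80.0)
    hazard = np.where(exprA > thr, truth.survival_hazard_ratio, 1.0) / cfg.survival_scale
    t = rng.exponential(1.0, n) / hazard
    os_event = (t <= cfg.followup_time).astype(int)
    os_time = np.minimum(t, cfg.followup_time)
    survival = pd.DataFrame({"os_time": os_time, "os_event": os_event}, index=samples)

    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "event"])
    return CohortTable(
        expression=expression,
        categorical=categorical,
        numerical=numerical,
        mutations=mutations,
        survival=survival,
    )


def _within_group_counter(groups: list[str]) -> list[int]:
    seen: dict[str, int] = {}
    out = []
    for g in groups:
        seen[g] = seen.get(g, 0) + 1
        out.append(seen[g] - 1)
    return out


def write_bundle(cfg: SimConfig, directory: str | Path) -> SimTruth:
    """Generate and write the full input bundle for a pipeline run.

    Layout: interactome.tsv, signatures/<dataset>.tsv, cohort/*.tsv,
    truth.json, and a datasets.tsv listing dataset ids and their
    discovery/validation roles.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    net, truth = simulate_interactome(cfg)
    sigs = simulate_de_datasets(net, truth, cfg)
    cohort = simulate_expression_cohort(cfg, truth)

    write_interactome(net, d / "interactome.tsv")
    sig_dir = d / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for sig in sigs:
        write_signature(sig, sig_dir / f"{sig.dataset_id}.tsv")
    write_cohort(cohort, d / "cohort")
    (d / "truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")
    with (d / "datasets.tsv").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("dataset_id\trole\n")
        for sig in sigs:
            role = "discovery" if sig.dataset_id.startswith("disc") else "validation"
            fh.write(f"{sig.dataset_id}\t{role}\n")
    return truth
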