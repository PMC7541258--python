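import numpy as np
import pandas as pd
import pytest

from mrsynergy.network import partition_regulons
from mrsynergy.selection import common_top
from mrsynergy.activity import da_signature
from mrsynergy.simulate import (
    SimConfig,
    simulate_de_datasets,
    simulate_expression_cohort,
    simulate_interactome,
    write_bundle,
)
from mrsynergy.synergy import eligible_pair

SMALL = dict(
    n_mrs=20, n_target_genes=400, regulon_size_range=(60, 60), pair_common_size=12,
    n_activated=4, n_suppressed=2, n_discovery=2, n_validation=2,
    n_n=4, n_c=6, n_m=5,
)


class TestInteractome:
    def test_pair_eligible_by_construction(self):
        net, truth = simulate_interactome(SimConfig(**SMALL, seed=0))
        mr1, mr2, _ = truth.synergistic_pair
        part = partition_regulons(net, mr1, mr2)
        assert part.common_size == 12
        assert eligible_pair(part.size1, part.size2, part.common_size)
        assert (part.common[["mor1", "mor2"]] > 0).all().all()

    def test_regulon_sizes_within_range(self):
        cfg = SimConfig(**{**SMALL, "regulon_size_range": (20, 40)}, seed=1)
        net, _ = simulate_interactome(cfg)
        sizes = [net.regulon_size(r) for r in net.regulators]
        assert min(sizes) >= 20 and max(sizes) <= 40

    def test_same_seed_identical_bytes(self, tmp_path):
        cfg = SimConfig(**SMALL, seed=7)
        t1 = write_bundle(cfg, tmp_path / "a")
        t2 = write_bundle(cfg, tmp_path / "b")
        assert t1 == t2
        for rel in ("interactome.tsv", "signatures/disc_01.tsv", "truth.json",
                    "cohort/expression.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_different_seeds_differ(self):
        net1, _ = simulate_interactome(SimConfig(**SMALL, seed=1))
        net2, _ = simulate_interactome(SimConfig(**SMALL, seed=2))
        assert not net1.edges.equals(net2.edges)

    def test_mor_sign_fraction_matches_config(self):
        cfg = SimConfig(
            n_mrs=150, n_target_genes=2000, regulon_size_range=(60, 80),
            pair_common_size=12, mor_positive_fraction=0.7, seed=3,
        )
        net, _ = simulate_interactome(cfg)
        # the pair's always-positive common block is negligible at this size
        mors = net.edges["mor"].to_numpy()
        assert len(mors) > 10000
        assert abs((mors > 0).mean() - 0.7) < 0.02

    def test_infeasible_common_block_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(**{**SMALL, "pair_common_size": 60}, seed=0)

    def test_cohort_size_change_does_not_perturb_network(self):
        base = simulate_interactome(SimConfig(**SMALL, seed=4))[0]
        other = simulate_interactome(SimConfig(**{**SMALL, "n_c": 50}, seed=4))[0]
        pd.testing.assert_frame_equal(base.edges, other.edges)


class TestDeDatasets:
    def test_null_world_is_noise(self):
        cfg = SimConfig(
            **{**SMALL, "n_mrs": 400, "n_target_genes": 3000,
               "regulon_size_range": (20, 40), "n_discovery": 5, "n_validation": 1},
            effect=0.0, extra_effect=0.0, mr_self_de_shift=0.0, seed=5,
        )
        net, truth = simulate_interactome(cfg)
        sigs = simulate_de_datasets(net, truth, cfg)
        das = [da_signature(net, s) for s in sigs[:5]]
        act, sup = common_top(das, 20)
        assert len(act) + len(sup) <= 1  # pure noise: no shared top regulators

    def test_datasets_differ_but_share_planted_shift(self):
        cfg = SimConfig(**SMALL, seed=6)
        net, truth = simulate_interactome(cfg)
        s1, s2 = simulate_de_datasets(net, truth, cfg)[:2]
        assert not np.allclose(s1.scores.to_numpy(), s2.scores.to_numpy())
        mr = next(iter(truth.active_mrs))
        assert s1.scores[mr] > 3 and s2.scores[mr] > 3  # self-DE shift present

    def test_scores_cover_targets_and_mr_genes(self):
        cfg = SimConfig(**SMALL, seed=6)
        net, truth = simulate_interactome(cfg)
        sig = simulate_de_datasets(net, truth, cfg)[0]
        assert len(sig) == cfg.n_target_genes + cfg.n_mrs


class TestCohort:
    def test_group_means_ordered(self):
        cfg = SimConfig(**{**SMALL, "n_n": 40, "n_c": 40, "n_m": 40}, seed=8)
        _, truth = simulate_interactome(cfg)
        cohort = simulate_expression_cohort(cfg, truth)
        geneA = truth.planted_correlation[0]
        expr = cohort.expression.loc[geneA]
        types = cohort.categorical["sample_type"]
        means = {t: expr[types[types == t].index].mean() for t in ("N", "C", "M")}
        assert means["N"] < means["C"] < means["M"]

    def test_within_group_correlation_near_planted(self):
        # estimate within one group on unmutated samples: mutation shifts act
        # on both designated genes and would otherwise inflate the correlation
        cfg = SimConfig(**{**SMALL, "n_c": 300}, seed=9, planted_r=0.8)
        _, truth = simulate_interactome(cfg)
        cohort = simulate_expression_cohort(cfg, truth)
        geneA, geneB, r = truth.planted_correlation
        types = cohort.categorical["sample_type"]
        mutated = set(cohort.mutations["sample"])
        c_samples = [s for s in types[types == "C"].index if s not in mutated]
        assert len(c_samples) > 80
        sub = cohort.expression[c_samples]
        observed = np.corrcoef(sub.loc[geneA], sub.loc[geneB])[0, 1]
        assert observed == pytest.approx(0.8, abs=0.1)

    def test_normals_carry_no_mutations(self):
        cfg = SimConfig(**SMALL, seed=10)
        _, truth = simulate_interactome(cfg)
        cohort = simulate_expression_cohort(cfg, truth)
        mutated = set(cohort.mutations["sample"])
        assert all(not s.startswith("N") for s in mutated)

    def test_validators_pass_for_random_configs(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            lo = int(rng.integers(14, 20))
            cfg = SimConfig(
                n_mrs=int(rng.integers(8, 16)),
                n_target_genes=int(rng.integers(100, 200)),
                regulon_size_range=(lo, lo + int(rng.integers(0, 10))),
                pair_common_size=12,
                n_activated=2,
                n_suppressed=1,
                n_discovery=2,
                n_validation=1,
                n_n=int(rng.integers(2, 6)),
                n_c=int(rng.integers(2, 8)),
                n_m=int(rng.integers(2, 6)),
                seed=int(rng.integers(0, 2**20)),
            )
            net, truth = simulate_interactome(cfg)  # validates network invariants
            cohort = simulate_expression_cohort(cfg, truth)  # validates cohort
            sigs = simulate_de_datasets(net, truth, cfg)
            assert all(np.isfinite(s.scores).all() for s in sigs)
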