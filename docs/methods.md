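# Methods

This note documents the statistical model behind each stage, the defaults and
why they are set where they are, what the synthetic benchmark does and does
not emulate, and the numerical conventions that make runs reproducible.

## Activity inference (NES)

A DE signature assigns one finite score per gene. Scores are converted to
normal scores of their ranks, z = Φ⁻¹((r − ½)/G) with tie-averaged ranks, so
the downstream statistic depends on the signature only through its ordering —
moderated *t* (microarray) and signed −log₁₀(adjusted *P*) (RNA-seq) panels
can be mixed without rescaling.

For regulator R with regulon edges (t, morₜ, wₜ):

  NES(R) = Σₜ wₜ·morₜ·zₜ / √(Σₜ wₜ²·morₜ²),  p = 2·Φ(−|NES|),

summing over targets present in the signature with morₜ ≠ 0 (a zero MOR
carries no direction under this statistic). Regulators with fewer than
`min_targets` (default 2) scoreable targets get no NES: the normalisation is
degenerate below two targets.

**Relationship to three-tailed regulon enrichment.** This is a deliberately
transparent one-tail analytic statistic: the NES sign is the activation
direction and its magnitude the evidence, the roles the downstream stages
need. It does not model |MOR|-graded two-tail contributions, shadow effects,
or pleiotropy correction for overlapping regulons; where regulons overlap
heavily, NES values of different regulators are correlated, and the
discovery/validation intersection — not the per-dataset p — is the guard
against that.

**Null accuracy and its limits.** Under an exchangeable signature the
statistic is asymptotically N(0, 1) in the regulon size; with 10,000 random
regulons of 10–50 targets over a 5,000-gene signature the measured 5 %
rejection rate is 0.0525. On *very* small instances the approximation
degrades for a structural reason: the z-population of G genes has variance
(1/G)·Σ z² < 1 (0.879 at G = 10) and the permutation distribution over a
small signature is discrete. Exhaustive enumeration at G = 10 puts the
worst-case |analytic − permutation| p at 0.141 for 2-target regulons
(the two-target statistic has no achievable value near 0 — a spectral gap —
when the two weights are comparable), ≈ 0.05 at 3 targets, and ≤ 0.047 from
4 targets up. Practical regulons (tens to hundreds of targets over ≥ 10⁴
genes) are far inside the safe regime; p-values for regulons of 2–3 targets
on tiny signatures should not be taken at face value.

## Selection of common top regulators

Per discovery dataset, the top-N activated (largest NES) and suppressed
(smallest NES) regulators are taken, with NES ties at the boundary broken by
lexicographic regulator id so the sets are reproducible. The common sets are
plain intersections across discovery datasets. Validation is a two-sided
Wilcoxon rank-sum test of the selected regulators' NES against all other
regulators with defined NES, per validation dataset and direction.

DA–DE consistency keeps a regulator iff in *every* discovery dataset its own
gene's DE score satisfies |DE| > threshold (default 3, strict) with
sign(DE) = sign(NES). Regulators missing a DA or DE value in any dataset are
dropped with a logged warning rather than failing the run; the DE threshold
is applied to each dataset's native score scale.

## Synergy of a regulator pair (ECA)

The regulons of an eligible pair are partitioned into shared and pair-unique
targets; eligibility requires strictly more than `min_common` (10) shared
targets and a shared fraction strictly above `min_frac` (10 %) of *both*
regulon sizes. For each dataset and each member of the pair, the ECA of a
target is DE × MOR using that member's own MOR — a shared target therefore
contributes different ECA values to the two tests when the MORs differ — and
a one-tailed rank-sum test compares shared vs that member's unique targets,
alternative "greater" if the member's DA is positive in that dataset, "less"
if negative. Likelihood weights are carried in the partition but do not
enter the test. Shared targets with opposite-signed MORs are kept. The
screen's summary convention for the "top pair" is the eligible pair
minimising its largest per-dataset p, with an undefined p (empty comparison
group, undefined DA) counting as 1.0; ties break lexicographically.

## Rank-sum convention

All Wilcoxon rank-sum tests in the package share one routine: the exact null
distribution when both groups have ≤ 12 observations and the pooled sample
is tie-free, otherwise the normal approximation with tie and continuity
correction. This matches the exact small-sample arithmetic used in the test
suite's closed-form cases while remaining correct at cohort scale.

## Clinical association battery

* **Categorical features:** groups with ≤ 5 samples are dropped (strict
  "> 5"); the lowest- and highest-median expression groups are compared
  two-sided; median ties between groups break lexicographically by label.
* **Mutations:** per gene, a sample is None / missense / LOF; LOF (nonsense,
  frameshift, splice) dominates missense. Each non-empty mutated class is
  compared two-sided against the None group; `delta_median` (mutated minus
  unmutated medians) gives the direction; selection uses strict p < α
  (default 0.1), uncorrected. The combined test contrasts samples with a
  missense class in ≥ 1 gene of a set against samples with class None for
  *all* genes of the set; LOF-only samples belong to neither group, so both
  definitions hold simultaneously.
* **Numerical features:** Spearman correlation (t-approximation), requiring
  ≥ 4 pairs.
* **Survival:** samples with follow-up are split at the linear-interpolation
  80th percentile of expression; the high group is strictly above the
  threshold (ties go low). The two-group log-rank statistic (1 df) and
  chi-square p come from lifelines. Undefined with a recorded reason when a
  group has < 2 samples or no event occurred.

No multiple-testing correction is applied anywhere in the battery; reported
p-values are raw and thresholds (0.05 / 0.1) are used as-is.

## Synthetic benchmark: the stated world

The generators are pure functions of (config, seed); a single integer seed
drives named substreams (network / signatures / cohort), so changing cohort
sizes never perturbs the network. Defaults:

| parameter | default | rationale |
|---|---|---|
| regulators / target genes | 5,000 / 20,000 | interactome and transcriptome scale of a context-specific network |
| regulon size | U{100..200} | typical mutual-information regulon scale |
| MOR | ±U(0.3, 1), 70 % positive | mixed-mode regulation, activation-skewed |
| likelihood | U(0.1, 1) | full confidence range |
| planted regulators | 18 activated, 3 suppressed, effect ±2 | the discovery-set cardinalities the selection stage is designed to recover |
| target shift | effect·mor·likelihood | the NES model is correctly specified at defaults |
| regulator self-DE shift | ±8 | strong self-expression change typical of replicating top regulators; exercises the |DE| > 3 rule |
| pair common block | 34 shared, positive MORs both sides | the shared-regulon scale the synergy test targets |
| extra synergy effect | +2·mor per pair member | shared targets more extreme than unique ones |
| dataset noise | sd 0.5 on top of a per-dataset N(0, 1) baseline | inter-dataset heterogeneity at 25 % of baseline variance |
| cohort | N/C/M groups, means 0/1/2, unit spread, pair correlation 0.8 | ordered normal→tumour→metastatic expression with a correlated designated pair |
| mutations | 2 genes, missense 25 % / LOF 10 % of tumour samples, missense shift +2 | LOF carriers are left unshifted and act as a built-in null class |
| survival | exponential, scale 50, hazard ×2 above the 80th expression percentile, censor at 60 | expression-linked risk with ~70 % event rate |

DE scores are planted shift + independent per-dataset noise
N(0, √(1 + 0.5²)): signatures are i.i.d. across datasets at zero effect, so
a null world yields no common top regulators, while planted shifts are the
shared biology. The regulon size range and noise level were fixed by a
design-stage power study (per-regulator miss probability vs the top-100
cutoff, integrated over regulon size and weight draws: 0 misses in 5,775
planted-regulator trials over 55 design seeds) before the recovery tests
were frozen.

What the benchmark does **not** emulate: probe-level microarray structure,
batch effects, gene-gene correlation beyond the designated pair and the
planted regulons, HPV or other covariates, non-exponential survival, and
mutation classes with expression effects of their own (LOF is deliberately
null). A green recovery test therefore establishes that the pipeline's
inference chain is correct under its own model assumptions — not that those
assumptions hold in any particular public cohort.

Note for calibration experiments: the planted mutation shifts act on *both*
designated genes, so they confound a naive pooled correlation estimate; the
planted pair correlation is identified within a sample group restricted to
unmutated samples.

## Determinism and serialisation

All TSV writers emit `repr`-formatted floats with `\n` line endings and
undefined values as `NA`; `summary.json` is key-sorted. Stage timings and
the config hash go to the logging stream, never into output files, so two
runs on the same inputs are byte-identical. Probe collapse breaks |t| ties
toward the larger signed t, then the lexicographically smallest probe id;
top-N and median-group ties break lexicographically; adjusted P-values of 0
are floored at 1e-300 before the log.
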