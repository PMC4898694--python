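# Methods

## Model

Each run of the evolutionary model simulates a closed, strictly monogamous
mating market. Agents have a sex, one of seven preference-integration
algorithms (fixed at birth; algorithms and sex never mutate), T continuous
trait values confined to the 1–7 rating scale, four unbounded preference
parameters per trait, and a fitness score.

**Fitness landscape.** At the start of a run, each trait receives a lookup
table mapping the seven integer trait levels to 1–7 fitness points. In the
default `random` mode the table is a uniform permutation of (1..7), so
every level is distinguishable and each trait contributes the same 4
points in expectation; `linear`, `curvilinear` (a shifted tent), and
`unequal` (points scrambled across traits, unequalizing per-trait totals)
modes exercise alternative landscape shapes. A configurable subset of
traits (default: the first 5) is sexually dimorphic, with independent
tables per sex. Continuous trait values are scored at their nearest
integer level (ties at .5 round up), which makes the extreme summed scores
exactly 23·7 = 161 and 23·1 = 23 and hence the offspring extremes 8 and 1
at the default reproduction cost.

**Life cycle.** Per generation: (1) each agent computes raw attraction to
every opposite-sex agent under its algorithm; (2) raw values are linearly
rescaled *within algorithm* — pooling that algorithm's values from both
directed matrices — to mean 50, SD 15, so no algorithm gains an advantage
from the units of its outputs; for the three threshold-style algorithms
(threshold regression, threshold Euclidean, aspiration) the transform is
fitted on strictly positive values only and zeros (rejected mates) are
preserved exactly; (3) mutual attraction is the element-wise product of
the two matrices; (4) couples form greedily: the global maximum cell
pairs, its row and column leave the market, and every still-unpaired agent
of both sexes pays the search cost — so agents who pair late pay the most,
and the surplus of the larger sex never pairs and dies unmated; (5) each
couple produces ⌊(f₁+f₂)/cost⌋ offspring (clamped at 0: search costs can
erode fitness), which inherit values — same-sex parent for dimorphic
traits and their preference slots, an independent fair coin per value
otherwise — mutate with N(0, mutation_sd²) on every trait and preference
(traits re-clamped, preferences free), are scored on the landscape, and
are culled uniformly at random to the population cap.

## Parameters

| parameter | default | units / meaning |
|---|---|---|
| `n_agents` / `pop_cap` | 700 / 700 (small variant 100 / 200) | agents |
| `n_traits` | 23 | rating dimensions, scale 1–7 |
| `trait_init_mean`, `trait_init_sd` | 4, 1.5 | normal draw, clamped to bounds |
| `pref_init_mean`, `pref_init_sd` | 0, 1.5 | normal draw, unbounded |
| `n_dimorphic` | 5 | traits with per-sex fitness tables |
| `search_cost` | 0.25 | fitness points per pairing event while unpaired |
| `reproduction_cost` | 40 | fitness points per offspring unit |
| `mutation_sd` | 0.5 | SD of per-value offspring noise |
| `n_generations` | 200 | — |
| `scale_mean`, `scale_sd` | 50, 15 | within-algorithm attraction moments |
| `aspiration_exponent` | 15 | power on the satisfied-band count |
| `euclidean_epsilon` | 1e-6 | guard on the inverse squared distance |

The full model assigns 50 agents per sex to each of the seven algorithms;
the single-algorithm variants (used for couples-level analyses) start with
50 per sex of one algorithm.

## Ideal points and couples metrics

The couples analytics need one ideal value per trait per individual.
Euclidean agents carry it in preference slot 1. Polynomial agents' ideals
are inferred by per-trait argmax of their cubic attraction curve over a
candidate grid (default 1–7 in steps of 0.1; an integer grid is exposed —
with evolved coefficients the argmax sits overwhelmingly on the scale
boundaries, so both grids agree). Aspiration agents' ideals are the
centers of their acceptable bands (slot 3).

Absolute fulfillment is ‖ideal − partner traits‖. Relative fulfillment
counts, among opposite-sex individuals in the sample other than the own
partner, the share lying *strictly* further from the ideals (equidistant
alternatives do not count). In tabulated couples data every individual is
represented by the partner-description in their spouse's row, keeping the
rating source consistent across own partner and alternatives. Mate value
is the distance between own traits and the opposite sex's mean ideal,
negated by default; a reciprocal transform is available, and the two agree
on rankings. Correlations relate mate value to raw distance, so a
*negative* r means more desirable individuals hold partners closer to
their ideals. Distances measured on k₁ dimensions map to k₂ dimensions as
d·√(k₂/k₁), preserving the per-dimension expected squared deviation.
Bootstrap CIs resample whole couples with replacement and use the 2.5/97.5
percentiles. Across-run model summaries use mean ± 1.96·SD/√runs.

## Synthetic couples generator

The generator emulates the statistical structure the metrics assume:
per-sex ideal and self-trait points (clamped normal draws around
mid-scale), and partner descriptions equal to own ideals plus per-
dimension noise. A coupling parameter in [0, 1] scales the noise SD
linearly in the participant's mate-value rank (0 = independent, 1 = the
least desirable participants' partners scatter with twice the average SD),
planting a recoverable mate-value → match-quality gradient without
re-assigning partners. It does not emulate real-data features such as
rater disagreement, item-level missingness, sex-differentiated preference
means, or non-normal rating distributions — so passing recovery tests
demonstrates the correctness of the metric machinery, not realism of any
particular human sample.

## Numerical choices

- Initial traits are drawn then clamped (not rejection-sampled), producing
  small point masses at the bounds.
- Scaling uses the sample (n−1) SD; degenerate pools (fewer than two
  fitted values, or zero variance) map to the target mean. Values driven
  negative by the linear transform are clamped to 0, so the mutual
  product can never turn two strong rejections into a strong match (this
  clamp has no measurable effect on the evolutionary outcomes; see
  sensitivity notes below).
- Greedy pairing breaks ties at the argmax by smallest (row, column)
  index, making runs bit-reproducible under a fixed seed; pairing
  continues until a sex is exhausted, including zero-attraction pairs.
- Acceptable-range band checks take the range slot in absolute value
  (preferences may evolve negative) and are boundary-inclusive.
- Very large aspiration powers (23¹⁵ ≈ 9.3·10¹⁸) stay in floating point;
  only within-algorithm order and moments matter after scaling.
- Per-run generators are spawned from one seed sequence, so experiments
  are reproducible run by run.

## Replication scales

Simulation-backed checks run at desk scale, as the package's own choice of
problem size: 10–12 replicates of the full 700-agent model and 25
replicates of each 100-agent single-algorithm variant (each full-scale run
takes a few seconds on one CPU).

## Known limitations and sensitivity

- **Polynomial runaway.** In the single-algorithm polynomial variant the
  population reliably evolves a coherent directional equilibrium: inferred
  ideals concentrate on the upper scale boundary (the convex cubic makes
  "prefer high" raters discriminate far more sharply among high-trait
  mates), traits drift upward, and pairing becomes trait-assortative,
  which drags the mate-value × fulfillment correlation strongly negative
  (≈ −0.4) and shrinks mean ideal-to-partner distances. These statistics
  are sensitive to the attraction-scaling convention: rescaling within
  each *rater* instead of within algorithm removes the runaway for the
  polynomial variant but badly distorts the Euclidean variant, so the
  within-algorithm convention is kept. Polynomial-variant statistics
  should therefore be read as properties of this implementation's
  equilibrium, not as robust constants of the model family.
- The model omits assortative meeting constraints, kin influence,
  short-term and extra-pair mating, costs of information acquisition, and
  assessment error; agents appraise all potential mates perfectly.
- Fitness is frequency-independent and tabular; no continuous fitness
  functions.
- Relative fulfillment uses opposite-sex alternatives only, and couples
  tables require complete ideal/partner blocks (incomplete couples are
  dropped and logged, never imputed).
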