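# Methods

## Model and assumptions

The simulator iterates a deterministic allele-frequency recursion for a
single biallelic locus (wild-type W, drive D) under random mating,
non-overlapping generations and an infinite population.  Each generation:

1. zygotes form at Hardy–Weinberg proportions $(q_D^2,\; 2 q_W q_D,\; q_W^2)$;
2. drive action modifies genotypes (conversion, and in the self-cleaving
   variant excision/lethality);
3. viability selection reweights the surviving genotype classes by their
   relative fitness, and the next allele frequencies are the
   fitness-weighted allele counts divided by mean fitness.

Assumptions worth keeping in mind: no resistance alleles of any kind
(failed conversion leaves a clean heterozygote), no sex structure, no
spatial structure, no drift (see the Wright–Fisher check below), fitness
acting identically in both sexes, and conversion occurring before
reproduction so a converted heterozygote carries drive-homozygote fitness.

### Genotype bookkeeping for the self-cleaving variant

With population-averaged self-cleavage probability $E$ and conversion
probability $e_W$, the post-action genotype masses are

| pool | mass | fitness |
|---|---|---|
| DD | $q_D^2 (1 - E^2) + 2 q_W q_D (1-E)\, e_W$ | $f$ |
| DW | $2 q_W q_D (1-E)(1-e_W)$ | $(1-h)+f h$ |
| WW | $q_W^2 + 2 q_W q_D\, E (1-e_W)$ | $1$ |
| lethal | $q_D^2 E^2 + 2 q_W q_D\, E\, e_W$ | — |

In a heterozygote the two cleavage events (drive self-excision, prob. $E$;
target cleavage + conversion, prob. $e_W$) are independent: both → lethal;
drive only → the wild-type gene is copied over the excised drive,
restoring a wild-type homozygote; target only → drive homozygote; neither
→ heterozygote.  In a drive homozygote, excision of both copies
($E^2$) is lethal; with one or zero copies cleaved the genotype is
restored to DD by homology-directed repair (there is no wild-type template
in that individual).  The next drive frequency is
$(f\cdot\mathrm{DD} + w_{het}\cdot\mathrm{DW}/2)/\bar w$ with
$\bar w = f\cdot\mathrm{DD} + w_{het}\cdot\mathrm{DW} + \mathrm{WW}$.

This surviving-pool form conserves probability (the four masses always sum
to 1) and its denominator expands exactly to
$1 - (1-f)\,\mathrm{DD} - (h - f h)\,\mathrm{DW} - \mathrm{lethal}$.
We adopted it as the package's definition of the self-cleaving update:
it is the unique bookkeeping consistent with the scenario outcomes above,
and the independent enumeration oracle reproduces it to $10^{-12}$ by
construction-free re-derivation.  The repaired-back-to-DD choice for a
singly cleaved drive homozygote follows from keeping the surviving DD mass
at $q_D^2(1-E^2)$.

## Parameters

| symbol | meaning | range | default |
|---|---|---|---|
| $e_W$ | conversion efficiency (cleave target + copy drive) | [0, 1] | required |
| $f$ | drive-homozygote fitness relative to WT | [0, 1] | required |
| $h$ | dominance of the fitness effect | [0, 1] | 0.5 |
| $e_W'$ | post-induction conversion efficiency | [0, 1] | 0 |
| $f'$ | post-induction drive fitness | [0, 1] | 1 |
| $e_D$ | basal ("leaky") self-cleavage rate | [0, 1] | 0 |
| $e_D'$ | post-induction self-cleavage rate | [0, 1] | 0 |
| $\alpha$ | fraction responding to the signal per generation | [0, 1] | — |
| $q_{D,0}$ | initial drive frequency | (0, 1) | 0.001 |
| — | fixation threshold (strict) | (0.5, 1) | 0.99999 |
| — | generation cap | ≥ 1 | 1000 |

Induced parameters enter as population averages, e.g.
$e_\mathrm{eff} = \alpha e_W' + (1-\alpha) e_W$ and
$E = (1-\alpha) e_D + \alpha e_D'$ (note $E$ reduces to the leaky rate
$e_D$, not zero, before induction).

**Induction convention.**  "Signal at generation $g$" means generations
$\ge g$ are exposed: the transition producing generation $g+1$ is the
first induced one, and the signal stays on at the same level forever
after.  The fixation check runs after every update and also at generation
0; with the default threshold the ordering of check and switch cannot
change any outcome, but the convention is pinned by tests.

**Degenerate populations.**  Mean fitness $\le 10^{-12}$ raises a
dedicated error rather than returning 0/0.  The all-lethal corner (a
nearly drive-fixed population under certain self-cleavage) is biologically
extinction, which a frequency-only model cannot represent; sweeps record
such cells under their own `DEGENERATE` label.

## Numerical choices

- Updates are closed-form rational maps; results are clamped to [0, 1] to
  absorb a few ulp of round-off at exact boundaries.
- The self-cleaving step delegates to the standard-body expression when
  $E = 0$ so the reduction identity holds bit for bit.
- Bisection returns the midpoint of its final bracket (default tolerance
  $10^{-4}$) and reports the bracket, after an 11-point monotonicity
  pre-scan that warns on outcome reversals.
- Serialized frequencies carry 12 significant digits so oracle-level
  comparisons survive a CSV round trip; manifests omit timestamps so
  identical configurations produce byte-identical outputs.

## Validation layers

- **Enumeration oracle** — every variant's step is re-derived by explicit
  probability-tree enumeration of the six heterozygote/homozygote outcomes
  and compared to the closed form ($\le 10^{-12}$ over $10^4$ random
  parameter draws).
- **Closed-form limit** — at $e_W = 1, f = 1$ the recursion collapses to
  $1 - q_{n} = (1 - q_0)^{2^n}$, checked per generation; from $q_0 =
  0.001$ fixation lands at generation 14.
- **Wright–Fisher sampler** — binomial sampling of $2N$ alleles around the
  deterministic expectation; replicate means converge to the deterministic
  step as $N$ grows, quantifying what "infinite population" buys.
- **Linearization** — the invasion growth factor matches the simulated
  per-generation ratio at $q_D \le 10^{-3}$ to $10^{-3}$ relative error.

## Finite-horizon effect on thresholds

The invasion boundary at $e_W = 1,\ h = 0.5$ is $f = 0.5$ exactly
($\lambda = 2f$).  The *observable* boundary — drive fixation within the
1,000-generation cap — sits slightly higher, because trajectories with
$\lambda$ marginally above 1 cannot traverse from $q_D = 0.001$ to beyond
0.99999 before the cap.  The drive:WT allele ratio must grow by
$\ln(10^8) \approx 18.4$ in log units, so the cap-limited boundary is at
most $0.5\,e^{18.4/1000} \approx 0.5046$; the bisected value is
$\approx 0.5006$.  Threshold results therefore report their final bracket,
and "approximately 0.5"-style comparisons are made against the bracket
plus this horizon bound, not a point value.

## What the simulations do and do not show

All quantities here are deterministic consequences of the recursions; there
is no synthetic data beyond the parameter sets themselves.  Conclusions
about reversal (e.g. that reverting a population requires a very low
induced $e_W'$ but only a moderate $f'$ or $e_D'$, or that late fitness
induction fails once the drive is common) are statements about this
idealized model.  They do not account for drift in small populations
(except via the Wright–Fisher check), resistance-allele evolution, spatial
or mating structure, parameter heterogeneity between individuals, or any
molecular feasibility of the induction mechanisms.

## Known limitations

- Single effective conversion rate: dual-nuclease designs with distinct
  per-nuclease efficiencies are represented only through the single
  effective rates $e_W$ and $e_D/e_D'$.
- One step-change signal regime; no pulsed or time-varying $\alpha$.
- Outcome classification is frequency-based; "drive lost" and "population
  extinct" are distinguished only via the degenerate-population error.
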