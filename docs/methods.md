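# Methods

## Games and the correspondence-of-interests index

All games are symmetric 2×2 with fixed R = 1 and P = 0, so a game is the
point (S, T). Quadrants of the (S, T) plane give the four archetypes:
Harmony/Maximizing-Difference (S > 0, T < 1), Chicken (S > 0, T > 1), Stag
Hunt (S < 0, T < 1), Prisoner's Dilemma (S < 0, T > 1). `classify` labels
boundary games (S = 0 or T = 1, measure zero under any continuous ecology)
by grouping S = 0 with S > 0 and T = 1 with T > 1; the *strict* test
`is_cooperation_dominant` (T < 1 and S > 0) is what a type-of-game inferrer
acts on.

The degree of correspondence of interests is implemented as the Pearson
correlation between the actor's payoffs (1, S, T, 0) and the partner's
payoffs (1, T, S, 0) across the four outcomes — the standard
correspondence-of-outcomes index of interdependence theory:

DoC(S, T) = [(1 + 2ST)/4 − μ²] / [(1 + S² + T²)/4 − μ²],  μ = (1 + S + T)/4.

The denominator is the common variance of the four payoffs and is strictly
positive (R ≠ P), so the index is defined everywhere, symmetric in (S, T),
bounded in [−1, 1], and equal to 1 exactly when S = T. A DoC-inferring agent
cooperates when DoC ≥ 0 (ties cooperate); since the denominator is positive,
the decision reduces to the sign of the quadratic
3 + 6ST − S² − T² − 2S − 2T, which is what the vectorised statistics use.

## Ecologies and their summary statistics

An ecology displaces the average game (S₀, T₀) by independent uniform noise
on [−Δ/2, +Δ/2] in each coordinate. Because fitness is an expectation over
the ecology, the dynamics only see a few statistics: the cooperation
frequency of the adaptive type (α₊ = P(DoC ≥ 0) for DoC inference,
α_MD = P(S > 0)P(T < 1) for ToG inference) and *unconditional* split means
such as t₊ = E[T·1{DoC ≥ 0}]. The unconditional normalisation (divide by the
number of games, not by the split's frequency) is deliberate: it makes every
entry of the strategy payoff table an exact expectation, and the
decomposition t₊ + t₋ = E[T] holds to machine precision — a tested
invariant.

MD-split statistics are exact closed forms (rectangle probabilities and
truncated-uniform means). DoC-split statistics are Monte-Carlo estimates
from m seeded draws (default m = 10⁶); a Gauss–Legendre tensor-quadrature
backend exists for validation (its accuracy is limited to ~1/order by the
indicator's discontinuity). On (S₀, T₀) grids, one shared draw of noise
displacements is translated to every grid point (the uniform family is a
location family), so the whole map uses common random numbers and
between-point differences carry no sampling noise.

## Payoff table and finite-population dynamics

With strategies ordered (AA, AllC, AllD) and inference cost c paid in every
interaction, the ecology-averaged pairwise payoffs for DoC inference are

|            | AA             | AllC           | AllD     |
|------------|----------------|----------------|----------|
| **AA**     | α₊ − c         | α₊ + t₋ − c    | s₊ − c   |
| **AllC**   | α₊ + s₋        | 1              | E[S]     |
| **AllD**   | t₊             | E[T]           | 0        |

(ToG: replace α₊ and the ± splits by α_MD and the MD/non-MD splits.)
Fitness in state (X, Y, Z) averages the table over the N − 1 partners,
excluding self.

Evolution is the pairwise-comparison process: an ordered pair (role model k,
learner j) of distinct agents is drawn uniformly, and j adopts k's strategy
with probability p = 1/(1 + e^{−β(π_k−π_j)/w}). The state performs a random
walk on the simplex whose three vertices are absorbing; extinct strategies
never reappear. Fixation probabilities come from the standard absorbing-chain
solve (I − Q)B = R over the (N+1)(N+2)/2 − 3 transient states, using a
sparse LU factorisation (self-loops sit on Q's diagonal and cancel exactly
in I − Q; absorption probabilities are insensitive to lazy steps). At the
study size N = 60 one solve takes ~7 ms, so full 101×101 game-space maps
are exact rather than simulated. States are indexed lexicographically over
(X, Y), index = X(N+1) − X(X−1)/2 + Y, making result tables reproducible
bit for bit.

**Payoff scale of selection.** The Fermi argument divides payoff differences
by the ecology's payoff span w = max(1, T₀ + Δ/2) − min(0, S₀ − Δ/2). Raw
payoff differences vary several-fold across the (S₀, T₀) plane at Δ = 2, so
a fixed β would apply much stronger selection in high-temptation ecologies
than in harmony-like ones; normalising by the realisable payoff range keeps
β comparable across game space, which is what makes a single β = 1 produce
the study's game-space maps. `DynamicsParams(payoff_scale=1.0)` recovers the
raw-payoff rule. This normalisation is a reconstruction choice: it
reproduces the published favored-area fractions to within ~2.5 percentage
points on the published grid, with all qualitative response shapes intact;
the residual gap is uniform in sign and would correspond to a ~20% larger
scale constant, which we do not fit for lack of a mechanism.

**Cooperation level and increase.** P_c = φ_C + α·φ_A is the probability
that a post-fixation interaction is cooperative. The cooperation increase
compares P_c of the three-strategy chain with the φ_C of a fixed-behaviour
baseline — an AllC/AllD-only chain of the same N and β started from the even
split (N/2, N/2). The baseline composition is a convention (the source
analysis does not state one); because the baseline starts from 30 rather
than 40 cooperator-types, "strategy equivalence" cases (e.g. a cost-free
DoC inferrer in an all-harmony ecology) show a residual increase of order
10⁻⁷ rather than exactly zero.

## Agent-based model

The ABM samples agents directly per elementary step (role model ~
composition, learner ~ remaining agents, Fermi coin) with fitness computed
from the current composition — per-encounter payoff noise is deliberately
absent, since lifetimes span many interactions. `estimate_fixation` advances
all replicates in lock-step with vectorised updates, which is statistically
identical to independent runs; truncated (non-absorbed) replicates are
reported separately so truncation bias is visible. The suite checks the ABM
against the exact chain by chi-square on absorption counts and by 3-standard-
error agreement at 10⁴ replicates.

## ESS analysis

The adaptive resident is evolutionarily stable against invader
x ∈ {AllC, AllD} if π(AA,AA) > π(x,AA), or π(AA,AA) = π(x,AA) and
π(AA,x) > π(x,x). Payoff equality between Monte-Carlo floats is declared at
relative tolerance 10⁻⁹; this catches the structural ties (behavioural
clones, e.g. a cost-free inferrer that cooperates in every game vs AllC)
instead of letting sampling noise break them, and a clone is reported as
"neutral invasion" (not an ESS) rather than as strict invasion.

The published stable-area percentages are reproduced by the *cost-free*
stability boundaries (c = 0): with c = 0, a 201×201 endpoint grid over
T₀ ∈ [0, 2] × S₀ ∈ [−1, 1] matches both printed values to printed precision
(DoC 49.12% vs 49.13% with m = 10⁶; ToG 60.64% exactly, closed form), which
also validates the correlation form of the DoC index and the unconditional
split normalisation. At any c > 0 the stable areas shrink markedly and the
DoC/ToG ordering reverses, so the cost evidently does not enter the
published stability maps; `ess_map` keeps c as an explicit argument, and the
acceptance pipeline evaluates the maps at c = 0. The default acceptance grid
is 101×101 (values 49.0% / 59.9%).

## Problem sizes and defaults

* N = 60, β = 1, c = 0.1, initial (20, 20, 20); rare-mutant variant
  (2, 29, 29) with neutral reference 2/60.
* m = 10⁶ games per ecology for DoC statistics (α estimates have standard
  error ≤ 5·10⁻⁴); unit tests use 10⁵–2·10⁵ where only thresholds matter.
* Game-space maps: 41×41 grid by default, 101×101 for headline area
  fractions; heterogeneity sweep Δ ∈ {0.1, 0.25, 0.5, 1, 1.5, 2}; cost sweep
  c ∈ {0, 0.05, …, 0.5}.
* ABM: 10⁴ replicates for validation, max 10⁷ elementary updates per
  replicate.
* Linear solves: direct sparse LU; absorption rows are checked to sum to 1
  within 10⁻⁸ (typical residuals are ~10⁻¹³).

## What the synthetic ecologies do and do not capture

The generator realises exactly the model's premises: independent uniform
payoff noise around an average game, one-shot interactions, a well-mixed
population. It does not emulate correlated S/T displacements, asymmetric
(power-imbalanced) games, noisy or erroneous inference, structured
populations, or payoff distributions with heavier tails — passing tests
therefore certify the solvers and the model's internal consistency, not the
robustness of the biological conclusions to those extensions.

## Known limitations

* The transition rule's payoff normalisation is reconstructed (see above);
  the raw-payoff rule is available but does not reproduce the published
  finite-population maps.
* One published qualitative claim — that ToG inference tolerates a higher
  cost than DoC inference in Stag-Hunt ecologies — does not hold under this
  reconstruction (DoC tolerates slightly more there); all other response
  signatures reproduce.
* MD-split closed forms rely on the independence and uniformity of the
  payoff noise; other noise families would need the Monte-Carlo path.
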