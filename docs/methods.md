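# Methods

## Model

Two infinite, well-mixed populations of fishers with fixed strategies play
a symmetric, deterministic, repeated 2×2 game. Cooperators fish the legal
effort `f*`; cheaters (non-cooperators) fish to maximize individual season
profit. The stock is a single species in logistic growth; catchability `q`
is constant; one generation is one fishing season. Within a season,
removals follow the exponential-mortality harvest relation
`H = B(1 − e^(−qf))` — natural mortality is treated as constant background
and folded out, and season length is one time unit, so fishing mortality is
`F = q·f`.

All monetary quantities are normalized by carrying capacity `K`
(`B′ = B/K`, `c′ = c/K`), which makes every payoff scale-free: multiplying
`(c, B, K)` by a common factor leaves `(c′, B′)` and all normalized payoffs
unchanged (this homogeneity is property-tested against an independent
raw-unit evaluation of the same algebra).

### Encounter payoffs

With `ρ = c′/(B′Pq)` and `L = ln ρ` (negative when fishing is viable), the
profit-maximizing total effort is `f_T = −L/q`, the unique solution of the
first-order condition `B′Pq·e^(−qf) = c′`. Unpenalized payoffs per unit
carrying capacity:

* `Π_CC = B′(1 − e^(−qf*))P − c′f*`: both fish `f*`; each is evaluated at
  own effort `f*` (the combined depletion by two agents is not modelled —
  the printed formulation evaluates each cooperator independently, and we
  keep that reading).
* Mixed encounter: the cheater expands total effort to `f_T`, the
  cooperator contributes `f*`, the cheater `f_T − f*`, and the total
  revenue `B′(1 − ρ)P` is split in proportion to contributed effort. Hence
  `Π_CN = (f*/f_T)·B′(1 − ρ)P − c′f*` (algebraically
  `(c′ − B′Pq)f*/L − c′f*`) and
  `Π_NC = ((L + qf*)/L)·B′(1 − ρ)P − c′(f_T − f*)`.
  The two shares sum to one by construction; the conservation identity
  `Π_CN + Π_NC + c′f_T = B′(1 − ρ)P` holds to 1e−12 and is enforced by a
  10⁴-draw property test. The cheater-share factor `(L + qf*)/L` is the
  unique reading of the mixed-encounter algebra consistent with both the
  cooperator's proportional share and revenue conservation.
* `Π_NN = 0`: two cheaters race for the stock and dissipate the entire
  rent.

Degenerate case `f* ≥ f_T`: the cheater's residual effort would be
negative, which is meaningless; it is clipped to zero, the encounter is
evaluated at total effort `f*` (`Π_CN = Π_CC`, `Π_NC = 0`), a
`DegenerateEncounterWarning` is emitted and the payoffs are flagged. With
the default economics this can only occur for
`B′ ≤ ρ·e^(qf*) ≈ 5.7×10⁻⁵`, far below the default grid.

Viability: fishing is viable iff `c′ < B′Pq`, i.e. the marginal revenue of
the first effort unit exceeds its cost (equivalently `f_T > 0`). The
no-fishing outcome is decided *before* any payoff comparison because the
payoff logarithms are undefined outside viability.

### Behaviour penalty

`δ = α/(1 + b·r)` with control perception `α ∈ [0, 1]`, risk tolerance
`b ∈ [0, 1]` (b near 0 = high tolerance of stock uncertainty, favouring
cooperation) and growth rate `r ≥ 0` (fast turnover erodes the perceived
need for restraint). Cooperator payoffs are scaled by `δ`, cheater payoffs
by `1 − δ`. The two populations may hold different perceptions: cooperator
payoffs use `δ_C = δ(α₁, b₁, r)`, cheater payoffs `1 − δ_N` with
`δ_N = δ(α₂, b₂, r)`. This is the only reading that uses all four social
parameters while collapsing to the symmetric formulas when
`α₁ = α₂, b₁ = b₂` (the case of every reported scenario). A
`disable_penalty` switch fixes `δ ≡ 0.5` for both roles, removing the
control/risk effects; in that base state every viable cell of the default
grid classifies as non-cooperative coexistence.

### Classification and dynamics

Outcomes follow the strict sign pattern of `π′_CC − π′_NC` and
`π′_CN − π′_NN`; coexistence is sub-labelled cooperative when the interior
equilibrium `x̄ = (π′_NN − π′_CN)/(π′_CC − π′_CN − π′_NC + π′_NN)` exceeds
1/2 strictly (exactly 1/2 is classified non-cooperative and logged — the
cooperative label requires a strictly higher frequency). Comparisons use an
absolute tie tolerance of 1e−12; ties raise a degenerate-game error rather
than being silently binned, since they occur only on measure-zero parameter
boundaries.

Replicator dynamics `dx/dt = x(1 − x)(fit_C − fit_N)` are integrated with
a fixed-step classical Runge–Kutta (RK4) scheme, step 0.01 time units
(generations), default horizon 10⁴, stopping when `|dx/dt| < 1e−10` or
within 1e−12 of a boundary; frequencies are clipped to [0, 1] against
round-off. The dynamics are one-dimensional and smooth, so fixed-step RK4
is ample; halving the step changes terminal frequencies by far less than
1e−8. The inner loop is numba-JIT-compiled, which keeps long-horizon
integrations (slow near-degenerate games) in milliseconds. Whether the
original study iterated a discrete-generation map or the ODE is immaterial
for everything reported here: both share the same fixed points and
stability, which is all the results use.

## Sweeps and boundaries

Default grids: `r` from 0 to 2 in steps of 0.01 (201 points; `r = 0` is
included and gives `δ = α` exactly), `B′` from 0.01 to 1.00 in steps of
0.01 (100 points). The resolution is unstated in the source material; 0.01
localizes every reported threshold to better than the reporting precision.
Because base payoffs depend only on `B′` and the penalty only on `r`,
outcome boundaries along `r` solve closed-form sign conditions —
`δ_C Π_CC = (1 − δ_N) Π_NC` for the dominance edge, `x̄(r) = 0.5` for the
cooperative/non-cooperative coexistence split — refined by Brent's method
to 1e−6 rather than read off the grid.

Aggregating a boundary over the `B′` band supports two readings, both
exposed (`scope`):

* `"every"`: the largest `r` at which *every* viable column is still on
  the cooperative side (the minimum of per-column crossings — where the
  first non-cooperative cell appears anywhere);
* `"any"`: the largest `r` at which *any* column still is (the maximum).

The per-column crossings vary by roughly 0.06–0.2 in `r` across the band,
so the two readings differ materially. The reported band thresholds of the
case study are reproduced with `"every"` for the dominance bound and the
onset of non-cooperative coexistence (the phrasing "non-cooperative
coexistence appeared for r > X" denotes first appearance), and `"any"` for
the "any cooperative outcome below r" bound of the worst scenario. Columns
that never cross within `r ∈ [0, 2]` contribute the top of the range;
columns already past the transition at `r = 0` contribute the bottom.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `P` | market price | 23 | currency/kg |
| `q` | catchability | 0.023 | fraction per effort unit |
| `c′` | effort cost per unit K | 2×10⁻⁵ | currency/(effort·kg) |
| `f*` | regulated effort | 18 | effort units (nets) |
| `α` | control perception | scenario: 1.0 / 0.8 | — |
| `b` | risk tolerance | scenario: 0.3 / 0.7 | — (0 = high tolerance) |
| `r` | stock growth rate | swept 0–2 | per season |
| `B′` | relative stock size | swept 0.01–1 | — |

The economics are the empirical Laguna shrimp fyke-net values and ship as
the bundled `default` preset; the four `fig1*` presets cross high/low
control (`α = 1/0.8`) with high/low risk tolerance (`b = 0.3/0.7`), and
`fig3a`/`fig3b` fix the invasion-experiment state `B′ = 0.3, r = 1.0`.

## Random scenario generation

`random_scenarios(n, seed)` draws `α₁, α₂, b₁, b₂` uniform in [0, 1], `r`
uniform in [0, 2] and `B′` uniform in (0, 1] with fixed default economics,
using numpy's seeded `default_rng`; identical seeds give identical
sequences. These draws exist to stress the *structural* properties
(classifier–dynamics agreement, conservation, monotonicity); they do not
emulate empirical parameter distributions of any real fishery, so passing
property tests certifies internal consistency of the model, not ecological
realism. Real fisheries also violate model assumptions the generator
shares: single species, constant catchability, no within-season depletion
feedback, exogenous and static `α` and `b`, infinite well-mixed
populations.

In the classifier–dynamics agreement test the integration horizon is sized
per scenario from the slowest linearized rate of the matrix
(`min(|π′_CC − π′_NC|, |π′_CN − π′_NN|, x̄(1 − x̄)|denominator|)`), capped
at 2×10⁶ generations, so that near-degenerate random games are integrated
long enough to resolve their attractor.

## Known limitations and reconstruction uncertainty

The mixed-encounter payoff algebra is reconstructed from the printed
closed forms; the original derivation appendix is not public. The
reconstruction satisfies exact revenue conservation and reproduces every
printed formula, but the case study's own reported numbers differ mildly
from direct evaluation (e.g. failed-invasion equilibrium 5.9% here vs 4%
reported; dominance edge at `B′ = 0.3` at r ≈ 1.19 vs 1.1 reported). These
gaps are treated as reconstruction uncertainty: boundary checks carry
±0.15 in `r` and frequency checks ±2.5 percentage points. Whether the CC
encounter should deplete the stock with combined effort `2f*` is likewise
unstated; the printed per-agent form is used. Bistability is structurally
unreachable under model-generated matrices (`π′_CN > 0` whenever viable
and `δ_C > 0`) but fully supported by the classifier and integrator for
hand-built matrices.
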