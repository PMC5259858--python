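# Methods

## The formalism

`cgspn` implements colored generalized stochastic Petri nets: places typed
by finite product color sets, tokens carrying tuple values, arc
inscriptions of the form `k'(term, …)` whose terms are constants, variables
or tuple components with ±1 successor/predecessor arithmetic, and boolean
guards over bound components. A transition is enabled under a binding *b*
when every input place *p* covers the demanded multiset, `m(p) ≥ f(p,t)[b]`,
and the guard holds; firing is atomic,
`m'(p) = m(p) + f'(t,p)[b] − f(p,t)[b]`.

Four transition kinds coexist:

* **stochastic** — exponential waiting time with marking-dependent rate
  `λ_t(m) = k_t · W_t(m)`, where the total weight `W_t(m) = Σ_b w(b)` sums
  the combinatorial binding weights, `w(b) = Π C(n_c, k_c)` over demanded
  token values (k identical tokens from a stock of n contribute `C(n,k)`).
  This convention makes the colored race statistically identical to
  mass-action Gillespie dynamics on the unfolded low-level net, which the
  test suite verifies against an independently written unfolded simulator.
  A `rate_function` may override `λ_t(m)` entirely.
* **immediate** — zero delay, absolute priority; chained immediate firings
  beyond a configurable cap raise a livelock error.
* **delayed** — fires exactly `d` time units after an instance becomes
  enabled, or not at all: timers are cancelled as soon as enabling is lost
  (pre-emptive rule) and re-verified at the due instant. One timer exists
  per enabled *instance* (a binding enabled with weight w holds w
  concurrent timers; when enabling shrinks, the newest timers are cancelled
  first). A per-binding-value single timer would serialize identical
  tokens that enable together, distorting processing-delay semantics.
* **scheduled** — fires at absolute times `start, start+period, … ≤ end`
  when enabled; a disabled occurrence is skipped.

Tie-breaking at equal instants is immediate > scheduled > delayed >
stochastic, uniform within a class. Variables appearing only on output
arcs are drawn uniformly at random from their color set at fire time.
Integer color sets saturate under ± arithmetic unless declared circular
(toroidal grids wrap; a life counter must not).

## Simulation engine

The engine is a direct-method Gillespie loop extended with the
deterministic event classes. Per-transition total weights are kept exactly
synchronized with the marking through incremental integer indexes: a
matching-token count for single-input-arc transitions, and a hash-join
index keyed on guard equality atoms for two-place interactions (each side
maps join key → token counts; `W = Σ_k tot₁[k]·tot₂[k]`). Transition
shapes outside these classes fall back to full re-enumeration when an
input place changes. For the hot shapes the engine compiles, once per
transition, direct token-test, key-extraction and firing-delta functions;
the generic interpreted matcher remains the semantic reference and the
test suite asserts exact agreement between the two paths mid-simulation.
All weights are integers, so no floating-point drift can accumulate; the
total rate is re-summed from the per-transition weights every step.

Each replicate owns one seeded NumPy generator (replicate *i* uses
`base_seed + i`); identical seeds give bit-identical trajectories,
independent of whether event records are kept. Observables (token counts
per place, optionally filtered by component values) are sampled on the
integer time grid; events falling exactly on a grid time are applied
before that grid point is recorded, so a scheduled injection at t=100 is
visible in the t=100 sample.

## The humoral immune-response model

One time unit is 8 hours. Cells carry (STATE, POSITION, LIFE, RECEPTOR);
molecular entities (bacteria, IgM, IgG) carry (POSITION, LIFE, RECEPTOR).
STATE has five values (resting, active, presenting, memory, plasma), LIFE
is 0…10, POSITION has cardinality 1 (no spatial description; the component
is carried so that spatial variants only change the color set), and
RECEPTOR has 10 integer values — a repertoire coarse enough to simulate
and fine enough that cross-reactivity is impossible, since recognition is
strict integer equality. With these defaults the model unfolds to
6·550 + 3·110 = 3630 low-level places.

The 27 transitions: three stochastic sources (bursts of 10 resting cells
with full life and uniform random receptor into MP, TH, B), two scheduled
inoculations, four aging and four death transitions, three effector decays
(PB, IgM, IgG), bacterial replication, and the ten-step response chain —
a-specific phagocytosis into the MP processing buffer, delayed peptide
exposure (2 steps), specific B-cell recognition (IgM burst of 5,
activation), antigen internalization into the B processing buffer, delayed
B presentation (2 steps), TH priming by presenting macrophages, the
central TH–B interaction (TH duplication; asymmetric division into one
memory B cell and one plasma cell, all with renewed life), the memory
shortcut (memory B + matching bacterium → plasma cell directly), IgG
secretion by plasma cells, and IgG killing of receptor-matched bacteria.
The two processing buffers are internal places; the seven biological
populations plus the two buffers give the 9 places, wired by 55 arcs.

Two deliberate guard choices:

* `age_B` exempts memory cells (`c:1 != "memory"`). With LIFE capped at 10
  and one expected decrement per 8 h step, a memory cell would otherwise
  vanish ~4 days after creation; immunological memory must persist for the
  ~100 days separating the two inoculations.
* The macrophage stays "presenting" after priming a TH cell — an antigen-
  presenting cell is reusable.

## Parameters

All rates are per 8 h step; mass-action propensities are rate × number of
matching tokens (or token pairs).

| parameter | default | reading |
|---|---|---|
| source_rate / bursts | 1.0, 10 cells | ~10 new resting cells per type per step; homeostasis ≈ 110 cells/type, reached well inside the 100-step burn-in |
| aging_rate (cells) | 1.0 | one life decrement per step → ~3.7-day naive lifespan |
| bacteria_aging_rate | 0.2 | untreated bacterial cohort fades over ~2–3 weeks |
| death_rate | 2.0 | prompt removal once LIFE reaches 0 |
| bacteria_replication_rate | 0.02 | slow growth, roughly offsetting natural death during an infection |
| phagocytosis_rate | 1e-3 | resting-MP pool saturates within a step of an inoculation |
| b_recognition_rate | 2e-3 | a receptor-matched resting B cell activates within ~a step of a 2000-token inoculum |
| b_internalization_rate | 2e-3 | active B cells internalize antigen promptly |
| th_priming_rate | 0.01 | presenting MP × resting TH, receptor-matched |
| th_b_interaction_rate | 0.05 | the central duplication/differentiation event |
| memory_reencounter_rate | 2e-4 | memory→plasma conversion over a few steps at full inoculum |
| igg_production_rate | 0.5 | one IgG per plasma cell per ~2 steps |
| igg_kill_rate | 3e-5 | ~60 kills/step at 1000 IgG × 2000 bacteria |
| pb_decay_rate | 0.03 | plasma-cell lifetime ~11 days |
| igm_decay_rate | 0.05 | early antibody, fast turnover |
| igg_decay_rate | 0.002 | specific serum IgG persists between exposures (effective titer half-life of months, standing in for the long-lived plasma-cell output not modeled explicitly) |
| processing delays | 2 steps | 16 h of antigen processing (MP and B) |

The paper-style experiment protocol is fixed: horizon 600 steps (~28
weeks), empty initial marking with a 100-step burn-in, scheduled
inoculations at steps 100 and 400 (memory: 2000 tokens of epitope 3 twice;
specificity: 1000 of epitope 3, then 1000 of epitope 3 plus 1000 of a
novel epitope 8), clearance declared at 5% of the inoculum.

Rate constants were calibrated once against the qualitative targets —
homeostasis inside the burn-in, primary clearance roughly 40–90 steps
post-inoculation (2–4 weeks at 8 h per step), memory persistence to step
400, a larger and faster secondary response, and epitope specificity —
across several independent base seeds, not against any particular test
seed. Two couplings discovered during calibration are worth recording.
First, the memory-re-encounter rate constant ties memory survival through
the primary infection (integrated hazard ≈ rate × ∫bacteria dt) to recall
speed at re-infection, so the standing memory pool at step 400 is modest
(≈10–20 cells on average) rather than large. Second, the robust carrier of
the secondary advantage is the combination of that recall spike with the
persistence of specific serum IgG between injections: standing antibody
kills from the first step of re-infection and lifts the secondary peak,
giving a consistent ~10-step mean clearance advantage and a 10–25% higher
mean secondary IgG peak at 20 replicates.

## What the experiments do and do not show

The simulations are self-contained: no external data enters, and all
quantities are token counts. Passing the dynamic checks shows that the
formalism plus this 27-transition biology reproduces the qualitative
hallmarks of adaptive humoral immunity — memory (larger, faster secondary
response; standing memory-B population; the transient memory dip at
re-encounter as memory cells convert to plasma cells) and specificity (no
cross-epitope activation; a novel epitope at the second exposure behaves
like a first exposure). It does not show quantitative agreement with any
clinical or experimental dataset: receptor space, affinity (equality, not
a distance), spatial structure, the cytotoxic arm, cytokines and
immunocomplexes are all absent, and absolute token counts have no units of
cells/µl.

## Numerical and design notes

* Replicates default to 100 in the experiment configs (the documented full
  protocol); the test suite and the acceptance script run 20 replicates,
  with tolerances read accordingly. A 600-step replicate costs ~3 s.
* Clearance uses a 5% threshold rather than zero because stochastic
  straggler bacteria make hard-zero crossing times erratic.
* "Comparable" for the novel-epitope response is fixed as a factor-of-two
  band on peak IgG; "higher"/"faster" are strict inequalities of
  20-replicate means.
* The binding-enumeration DFS iterates token values in sorted order and the
  engine's per-replicate RNG is the only source of randomness, so runs are
  bit-reproducible per seed.
* Degenerate inputs: transitions with no input places are always enabled
  with a single weight-1 binding; an empty net yields an all-zero
  trajectory; firing a disabled binding, evaluating a guard with unbound
  variables, and shrinking the clock are hard errors; binding enumeration
  refuses color spaces beyond a configurable cap.
* Offsets on input arcs match by exact preimage (at a saturating boundary
  only the arithmetic preimage is accepted); offsets on output arcs
  saturate or wrap per the color set.

## Known limitations

* The printed arc inventory of the model is 55; alternative wirings of the
  same biology (e.g. splitting decay from aging differently) change that
  count without changing behavior.
* Memory longevity is modeled as exemption from aging rather than a longer
  life color set, to keep LIFE at 0…10 for every entity.
* The hash-join fast path covers transitions with at most two input arcs
  of multiplicity 1 and conjunctive guards; other shapes re-enumerate on
  every dependent marking change, which is correct but slow for large
  populations.
* IgM is produced but, by default, kills nothing (low-affinity binding);
  an optional IgM kill transition can be enabled by configuration.
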