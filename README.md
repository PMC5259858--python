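# cgspn — colored stochastic Petri nets for immune-system modeling

`cgspn` is a simulation kernel for **Colored Generalized Stochastic Petri
Nets** (CGSPN) — Petri nets whose tokens carry tuple-valued "colors" and
whose transitions may be stochastic (exponential races, Gillespie-style),
immediate (zero delay, priority), delayed (fixed delay with pre-emption)
or scheduled (absolute firing times) — together with a proof-of-concept
model of the humoral immune response built on that kernel.

It is written for computational/systems biologists who want agent-level
detail (per-cell internal state, receptor, life counter) without giving up
the compact rule-based description a Petri net gives: one aging transition
ages *every* cell type of a place, one guarded interaction rule covers all
receptor-matched cell pairs. A colored model with 9 places and 27
transitions stands in for an unfolded low-level net of ~3600 places.

## The formalism in one paragraph

A net is a tuple of color sets, typed places, transitions, inscribed arcs,
guards and an initial marking. An arc inscription like
`2'("active", p, l, 4)` demands (or produces) two tokens whose STATE is
`"active"` and RECEPTOR is `4`, binding the variables `p` and `l`; a guard
like `[b:1 = "presenting" & th:1 = "active" & b:4 = th:4]` gates a
transition on the bound components. A transition fires by atomically
consuming its input multiset and producing its outputs,
`m'(p) = m(p) + f'(t,p) − f(p,t)`. Stochastic transitions race with rate
λ_t(m) = k_t · Σ_b w(b), where a binding demanding k identical tokens from
a stock of n has weight C(n,k) — exactly mass-action kinetics on the
unfolded net, which the test suite verifies against an independent
low-level Gillespie simulation.

## The humoral model

Seven entity places — Bacteria, macrophages (MP), T helper cells (TH),
B cells (B), plasma cells (PB), IgM and IgG — plus two internal
antigen-processing buffers. Cells carry (STATE, POSITION, LIFE, RECEPTOR);
receptor recognition is integer equality, which is what makes the response
*specific*. Bacteria injected by scheduled transitions are phagocytosed
a-specifically by macrophages, which present the epitope after a 16 h
processing delay and prime receptor-matched TH cells; resting B cells that
recognize a bacterium release low-affinity IgM and, after internalizing
antigen, present it to primed TH cells; that interaction duplicates the TH
cell and splits the B cell into a long-lived *memory* B cell and a plasma
cell; plasma cells secrete IgG, which kills receptor-matched bacteria.
Memory cells convert directly to plasma cells on antigen re-encounter —
the shortcut behind the faster, stronger *secondary* response. One
simulation step is 8 h. See `docs/methods.md` for the full transition
inventory, parameters and assumptions.

## Worked example

The memory experiment: 2000 bacteria of epitope 3 injected at steps 100
and 400 of a 600-step simulation (~28 weeks), after a 100-step burn-in
that lets the cell populations reach homeostasis.

```python
from cgspn.experiments import memory_config, run_memory_experiment

result = run_memory_experiment(memory_config(replicates=5, seed=42))
for r in result.responses:
    print(f"injection t={r.injection_time:.0f}: peak IgG {r.peak_igg:.0f} "
          f"at t={r.peak_igg_time:.0f}, cleared {r.time_to_clearance:.0f} "
          f"steps after inoculation")
mem = result.summary.mean["memory_b_3"]
print(f"mean memory B cells just before re-infection: {mem[399]:.1f}")
```

prints

```
injection t=100: peak IgG 1055 at t=262, cleared 84 steps after inoculation
injection t=400: peak IgG 1133 at t=549, cleared 77 steps after inoculation
mean memory B cells just before re-infection: 10.6
```

The secondary response peaks higher and clears the same inoculum faster —
the memory hallmark — because specific IgG persists between exposures and
the standing memory-B pool converts straight into plasma cells. The
specificity experiment (`run_specificity_experiment`) injects a second,
novel epitope at step 400 and shows that only the recalled epitope enjoys
that advantage.

## Command line

```bash
cgspn validate humoral                     # structural diagnostics
cgspn unfold-report humoral                # unfolded low-level net size (3630 places)
cgspn simulate humoral --t-end 200 --seed 1 --observable TH --out th.csv
cgspn experiment memory --replicates 20 --seed 1 --out results/memory
cgspn export-pnml humoral --out humoral.pnml
```

Models round-trip through a JSON document format and through PNML (P/T
skeleton with colored annotations in `toolspecific` elements); experiment
outputs are tidy CSV plus a summary JSON, every artifact embedding the
seed, a config hash and the package version.

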