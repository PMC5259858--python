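"""Humoral immune-response model as a colored generalized stochastic net.

The model tracks seven biological populations — extracellular bacteria,
macrophages (MP), T helper cells (TH), B cells (B), plasma cells (PB) and
the two antibody classes IgM and IgG — plus two internal processing buffers
(MP_proc, B_proc) that feed the delayed antigen-processing transitions.
Tokens are colored tuples: cells carry (STATE, POSITION, LIFE, RECEPTOR)
and molecular entities (POSITION, LIFE, RECEPTOR).  Receptor recognition is
integer equality: a lymphocyte interacts with a bacterium only when their
RECEPTOR components match, which is what makes the response *specific*;
long-lived memory B cells created by TH–B interaction are what make the
secondary response faster and stronger (*memory*).

The causal chain: bacteria are phagocytosed a-specifically by resting
macrophages, which after a processing delay present the bacterial epitope;
presenting MP prime receptor-matched resting TH cells; resting B cells that
recognize a bacterium release low-affinity IgM and become active; active B
cells internalize antigen and, after a processing delay, present it; an
active TH meeting a presenting B with the same receptor duplicates and the
B cell differentiates asymmetrically into a memory B cell and a plasma
cell; plasma cells secrete IgG, and an IgG binding a matching bacterium
removes both.  Memory B cells convert directly to plasma cells on antigen
re-encounter, which is the shortcut that produces the secondary response.

One time unit is one simulation step of 8 hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

from .net import Net
from .scheduler import Observable

__all__ = [
    "STATES",
    "ENTITY_PLACES",
    "ImmuneParams",
    "Injection",
    "default_params",
    "build_model",
    "model_observables",
]

STATES = ("resting", "active", "presenting", "memory", "plasma")

#: The seven biological entity places (the processing buffers are internal).
ENTITY_PLACES = ("Bacteria", "MP", "TH", "B", "PB", "IgM", "IgG")


@dataclass(frozen=True)
class Injection:
    """One scheduled inoculation: ``doses`` is ((count, epitope), ...)."""

    time: float
    doses: Tuple[Tuple[int, int], ...]


@dataclass(frozen=True)
class ImmuneParams:
    """Rate constants (per 8 h time unit), bursts, delays and schedule.

    Defaults are calibrated so that the cell populations reach homeostasis
    well inside the 100-step burn-in, a primary infection of 2000 bacteria
    clears within roughly 40-90 steps of injection (the 2-4 weeks a typical
    adaptive response takes at 8 h per step), and memory B cells persist to
    the second injection at step 400.
    """

    # sources: each firing emits a burst of resting cells with life 10 and
    # uniformly random receptor
    source_rate: float = 1.0
    th_burst: int = 10  # fixed by the model description
    mp_burst: int = 10
    b_burst: int = 10

    # per-token aging (life decrement) and death-at-life-0 rates
    aging_rate: float = 1.0
    bacteria_aging_rate: float = 0.2
    death_rate: float = 2.0

    # unconditional exponential decay of effector entities; the slow IgG
    # decay models the months-long persistence of specific serum antibody
    pb_decay_rate: float = 0.03
    igm_decay_rate: float = 0.05
    igg_decay_rate: float = 0.002

    bacteria_replication_rate: float = 0.02

    # interaction rate constants (mass action on matching token pairs)
    phagocytosis_rate: float = 1e-3
    b_recognition_rate: float = 2e-3
    b_internalization_rate: float = 2e-3
    th_priming_rate: float = 0.01
    th_b_interaction_rate: float = 0.05
    memory_reencounter_rate: float = 2e-4
    igg_production_rate: float = 0.5
    igg_kill_rate: float = 3e-5
    igm_kill_rate: float = 0.0  # IgM binds with low affinity; off by default

    igm_burst: int = 5
    mp_processing_delay: float = 2.0
    b_processing_delay: float = 2.0

    max_life: int = 10
    receptor_values: int = 10
    positions: int = 1

    injections: Tuple[Injection, ...] = (
        Injection(100.0, ((2000, 3),)),
        Injection(400.0, ((2000, 3),)),
    )

    def validate(self) -> list[str]:
        """Named diagnostics; empty list when the parameters are coherent."""
        bad = []
        for name in (
            "source_rate",
            "aging_rate",
            "bacteria_aging_rate",
            "death_rate",
            "pb_decay_rate",
            "igm_decay_rate",
            "igg_decay_rate",
            "phagocytosis_rate",
            "b_recognition_rate",
            "b_internalization_rate",
            "th_priming_rate",
            "th_b_interaction_rate",
            "memory_reencounter_rate",
            "igg_production_rate",
            "igg_kill_rate",
        ):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be > 0")
        if self.bacteria_replication_rate < 0 or self.igm_kill_rate < 0:
            bad.append("replication and IgM kill rates must be >= 0")
        for name in ("th_burst", "mp_burst", "b_burst", "igm_burst"):
            if getattr(self, name) < 1:
                bad.append(f"{name} must be >= 1")
        if self.mp_processing_delay < 0 or self.b_processing_delay < 0:
            bad.append("processing delays must be >= 0")
        if self.max_life < 1:
            bad.append("max_life must be >= 1")
        if self.receptor_values < 1 or self.positions < 1:
            bad.append("receptor_values and positions must be >= 1")
        for inj in self.injections:
            if inj.time < 0:
                bad.append(f"injection time {inj.time} is negative")
            for count, epitope in inj.doses:
                if count < 1:
                    bad.append(f"injection at t={inj.time}: count must be >= 1")
                if not 0 <= epitope < self.receptor_values:
                    bad.append(
                        f"injection at t={inj.time}: epitope {epitope} outside "
                        f"[0, {self.receptor_values})"
                    )
        return bad

    def with_injections(self, injections: Sequence[Injection]) -> "ImmuneParams":
        return replace(self, injections=tuple(injections))


def default_params() -> ImmuneParams:
    """The documented default parameter set (see class docstring)."""
    return ImmuneParams()


def build_model(params: ImmuneParams | None = None) -> Net:
    """Assemble the humoral-response net for ``params``.

    With the default two-event injection schedule the net has exactly 9
    places and 27 transitions: 3 sources, 2 scheduled injections, 4 aging,
    4 death, 3 decay, bacterial replication, and the 10 interaction /
    processing transitions of the response chain.
    """
    p = params or default_params()
    problems = p.validate()
    if problems:
        raise ValueError("invalid immune parameters:\n  " + "\n  ".join(problems))

    net = Net("humoral_response")
    L = p.max_life
    net.add_colorset("STATE", STATES)
    net.add_colorset("POSITION", range(p.positions))
    net.add_colorset("LIFE", range(L + 1))
    net.add_colorset("RECEPTOR", range(p.receptor_values))
    CELL = net.add_product("CELL", ["STATE", "POSITION", "LIFE", "RECEPTOR"])
    MOL = net.add_product("MOL", ["POSITION", "LIFE", "RECEPTOR"])

    for name in ("MP", "TH", "B", "PB", "MP_proc", "B_proc"):
        net.add_place(name, CELL)
    for name in ("Bacteria", "IgM", "IgG"):
        net.add_place(name, MOL)

    # --- sources: bursts of resting cells, random position and receptor
    for place, burst in (("MP", p.mp_burst), ("TH", p.th_burst), ("B", p.b_burst)):
        t = f"gen_{place}"
        net.add_transition(t, "stochastic", rate=p.source_rate)
        net.add_output(t, place, f"{burst}'(\"resting\", pos, {L}, r)")

    # --- scheduled inoculations
    for i, inj in enumerate(p.injections, start=1):
        t = f"inject_{i}"
        net.add_transition(t, "scheduled", schedule=(inj.time, None, None))
        for count, epitope in inj.doses:
            net.add_output(t, "Bacteria", f"{count}'(0, {L}, {epitope})")

    # --- aging: life decrements by one; memory B cells are long-lived and
    # exempt (with LIFE capped at 10 they could otherwise never survive
    # from the primary response to a re-encounter hundreds of steps later)
    for place, rate, guard in (
        ("MP", p.aging_rate, "[c:3 > 0]"),
        ("TH", p.aging_rate, "[c:3 > 0]"),
        ("B", p.aging_rate, '[c:3 > 0 & c:1 != "memory"]'),
    ):
        t = f"age_{place}"
        net.add_transition(t, "stochastic", rate=rate, guard=guard)
        net.add_input(place, t, "1'(c)")
        net.add_output(t, place, "1'(c:1, c:2, c:3-1, c:4)")
    net.add_transition("age_Bact", "stochastic", rate=p.bacteria_aging_rate, guard="[x:2 > 0]")
    net.add_input("Bacteria", "age_Bact", "1'(x)")
    net.add_output("age_Bact", "Bacteria", "1'(x:1, x:2-1, x:3)")

    # --- death of exhausted entities (life counter at zero)
    for place in ("MP", "TH", "B"):
        t = f"die_{place}"
        net.add_transition(t, "stochastic", rate=p.death_rate, guard="[c:3 = 0]")
        net.add_input(place, t, "1'(c)")
    net.add_transition("die_Bact", "stochastic", rate=p.death_rate, guard="[x:2 = 0]")
    net.add_input("Bacteria", "die_Bact", "1'(x)")

    # --- unconditional decay of effectors
    for place, rate in (
        ("PB", p.pb_decay_rate),
        ("IgM", p.igm_decay_rate),
        ("IgG", p.igg_decay_rate),
    ):
        t = f"decay_{place}"
        net.add_transition(t, "stochastic", rate=rate)
        net.add_input(place, t, "1'(c)")

    # --- bacterial replication (fresh life, same epitope)
    net.add_transition("bact_replicate", "stochastic", rate=p.bacteria_replication_rate)
    net.add_input("Bacteria", "bact_replicate", "1'(x)")
    net.add_output("bact_replicate", "Bacteria", f"2'(x:1, {L}, x:3)")

    # --- a-specific phagocytosis: resting MP engulfs any bacterium and
    # starts processing its epitope (no receptor match required)
    net.add_transition(
        "MP_phagocytose", "stochastic", rate=p.phagocytosis_rate, guard='[m:1 = "resting"]'
    )
    net.add_input("MP", "MP_phagocytose", "1'(m)")
    net.add_input("Bacteria", "MP_phagocytose", "1'(x)")
    net.add_output("MP_phagocytose", "MP_proc", "1'(m:1, m:2, m:3, x:3)")

    # --- delayed processing: expose the peptide after a fixed time
    net.add_transition("MP_process", "delayed", delay=p.mp_processing_delay)
    net.add_input("MP_proc", "MP_process", "1'(q)")
    net.add_output("MP_process", "MP", "1'(\"presenting\", q:2, q:3, q:4)")

    # --- specific recognition by resting B cells: IgM release, activation,
    # bacterium returned
    net.add_transition(
        "B_recognize",
        "stochastic",
        rate=p.b_recognition_rate,
        guard='[b:1 = "resting" & b:4 = x:3]',
    )
    net.add_input("B", "B_recognize", "1'(b)")
    net.add_input("Bacteria", "B_recognize", "1'(x)")
    net.add_output("B_recognize", "B", f"1'(\"active\", b:2, {L}, b:4)")
    net.add_output("B_recognize", "Bacteria", "1'(x)")
    net.add_output("B_recognize", "IgM", f"{p.igm_burst}'(b:2, {L}, b:4)")

    # --- antigen internalization by an active B cell (bacterium consumed)
    net.add_transition(
        "AG_B",
        "stochastic",
        rate=p.b_internalization_rate,
        guard='[b:1 = "active" & b:4 = x:3]',
    )
    net.add_input("B", "AG_B", "1'(b)")
    net.add_input("Bacteria", "AG_B", "1'(x)")
    net.add_output("AG_B", "B_proc", "1'(b:1, b:2, b:3, b:4)")

    net.add_transition("B_process", "delayed", delay=p.b_processing_delay)
    net.add_input("B_proc", "B_process", "1'(q)")
    net.add_output("B_process", "B", "1'(\"presenting\", q:2, q:3, q:4)")

    # --- priming of TH by a presenting, receptor-matched MP (MP is a
    # reusable antigen-presenting cell: it stays presenting)
    net.add_transition(
        "TH_prime",
        "stochastic",
        rate=p.th_priming_rate,
        guard='[m:1 = "presenting" & th:1 = "resting" & m:4 = th:4]',
    )
    net.add_input("MP", "TH_prime", "1'(m)")
    net.add_input("TH", "TH_prime", "1'(th)")
    net.add_output("TH_prime", "TH", f"1'(\"active\", th:2, {L}, th:4)")
    net.add_output("TH_prime", "MP", "1'(m)")

    # --- the central TH-B interaction: TH duplication, asymmetric division
    # of the B cell into a memory B cell and a plasma cell, all with
    # renewed life
    net.add_transition(
        "TH_B_interact",
        "stochastic",
        rate=p.th_b_interaction_rate,
        guard='[b:1 = "presenting" & th:1 = "active" & b:4 = th:4]',
    )
    net.add_input("TH", "TH_B_interact", "1'(th)")
    net.add_input("B", "TH_B_interact", "1'(b)")
    net.add_output("TH_B_interact", "TH", f"2'(th:1, th:2, {L}, th:4)")
    net.add_output("TH_B_interact", "B", f"1'(\"memory\", b:2, {L}, b:4)")
    net.add_output("TH_B_interact", "PB", f"1'(\"plasma\", b:2, {L}, b:4)")

    # --- memory shortcut: a memory B cell re-encountering its antigen
    # differentiates directly into a plasma cell
    net.add_transition(
        "AG_MEM_B",
        "stochastic",
        rate=p.memory_reencounter_rate,
        guard='[b:1 = "memory" & b:4 = x:3]',
    )
    net.add_input("B", "AG_MEM_B", "1'(b)")
    net.add_input("Bacteria", "AG_MEM_B", "1'(x)")
    net.add_output("AG_MEM_B", "PB", f"1'(\"plasma\", b:2, {L}, b:4)")
    net.add_output("AG_MEM_B", "Bacteria", "1'(x)")

    # --- antibody secretion and killing
    net.add_transition("PB_IgG", "stochastic", rate=p.igg_production_rate)
    net.add_input("PB", "PB_IgG", "1'(q)")
    net.add_output("PB_IgG", "PB", "1'(q)")
    net.add_output("PB_IgG", "IgG", f"1'(q:2, {L}, q:4)")

    net.add_transition("IgG_kill", "stochastic", rate=p.igg_kill_rate, guard="[g:3 = x:3]")
    net.add_input("IgG", "IgG_kill", "1'(g)")
    net.add_input("Bacteria", "IgG_kill", "1'(x)")

    if p.igm_kill_rate > 0:
        net.add_transition("IgM_kill", "stochastic", rate=p.igm_kill_rate, guard="[g:3 = x:3]")
        net.add_input("IgM", "IgM_kill", "1'(g)")
        net.add_input("Bacteria", "IgM_kill", "1'(x)")

    return net


def model_observables(epitopes: Sequence[int] = (3,)) -> list[Observable]:
    """Standard experiment observables, stratified by epitope.

    Token components: CELL = (state, position, life, receptor) so receptor
    is index 3; MOL = (position, life, receptor) so receptor is index 2.
    """
    obs = [
        Observable("MP", "MP"),
        Observable("TH", "TH"),
        Observable("B", "B"),
        Observable("IgM", "IgM"),
    ]
    for e in epitopes:
        obs.extend(
            [
                Observable(f"bacteria_{e}", "Bacteria", {2: e}),
                Observable(f"igg_{e}", "IgG", {2: e}),
                Observable(f"pb_{e}", "PB", {3: e}),
                Observable(f"memory_b_{e}", "B", lambda v, e=e: v[0] == "memory" and v[3] == e),
            ]
        )
    return obs
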