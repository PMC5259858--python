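"""Small reference nets: known closed forms for engine verification.

Each builder returns a fresh :class:`~cgspn.net.Net`.  The birth-death net
is an M/M/inf queue per color (stationary count Poisson with mean
``birth_rate / (n_colors * death_rate)`` per color); the random-walk net is
the classic single-token walk on a toroidal square grid whose stationary
marginals are uniform.
"""

from __future__ import annotations

from .net import Net

__all__ = [
    "birth_death",
    "exponential_race",
    "preemption_net",
    "immediate_conflict",
    "scheduled_injection",
    "random_walk_2d",
    "fixture_nets",
]


def birth_death(birth_rate: float = 1.0, death_rate: float = 0.5, n_colors: int = 1) -> Net:
    """Colored M/M/inf: births at total rate ``birth_rate`` with uniform
    random color, deaths at ``death_rate`` per token."""
    net = Net("birth_death")
    net.add_colorset("C", [f"c{i}" for i in range(n_colors)])
    net.add_place("X", ["C"])
    net.add_transition("birth", "stochastic", rate=birth_rate)
    net.add_output("birth", "X", "1'(c)")
    net.add_transition("death", "stochastic", rate=death_rate)
    net.add_input("X", "death", "1'(c)")
    return net


def exponential_race(rate_a: float = 1.0, rate_b: float = 1.0) -> Net:
    """One token, two stochastic consumers racing for it."""
    net = Net("race")
    net.add_colorset("U", ["u"])
    net.add_place("X", ["U"])
    for name, rate in (("a", rate_a), ("b", rate_b)):
        net.add_transition(name, "stochastic", rate=rate)
        net.add_input("X", name, "1'(v)")
    net.set_initial("X", [("u",)])
    return net


def preemption_net(delay: float = 5.0, competitor_rate: float = 10.0) -> Net:
    """A delayed transition whose sole input token a fast competitor steals.

    With ``competitor_rate >> 1/delay`` the delayed transition should
    essentially never fire (pre-emptive rule)."""
    net = Net("preemption")
    net.add_colorset("U", ["u"])
    net.add_place("X", ["U"])
    net.add_place("Slow", ["U"])
    net.add_place("Fast", ["U"])
    net.add_transition("slow", "delayed", delay=delay)
    net.add_input("X", "slow", "1'(v)")
    net.add_output("slow", "Slow", "1'(v)")
    net.add_transition("fast", "stochastic", rate=competitor_rate)
    net.add_input("X", "fast", "1'(v)")
    net.add_output("fast", "Fast", "1'(v)")
    net.set_initial("X", [("u",)])
    return net


def immediate_conflict(stochastic_rate: float = 1e6) -> Net:
    """Immediate vs (very fast) stochastic transition in conflict for one
    token; the immediate one must always win."""
    net = Net("immediate_conflict")
    net.add_colorset("U", ["u"])
    net.add_place("X", ["U"])
    net.add_place("WonImmediate", ["U"])
    net.add_place("WonStochastic", ["U"])
    net.add_transition("imm", "immediate")
    net.add_input("X", "imm", "1'(v)")
    net.add_output("imm", "WonImmediate", "1'(v)")
    net.add_transition("sto", "stochastic", rate=stochastic_rate)
    net.add_input("X", "sto", "1'(v)")
    net.add_output("sto", "WonStochastic", "1'(v)")
    net.set_initial("X", [("u",)])
    return net


def scheduled_injection(start: float = 100.0, count: int = 2000, period=None, end=None) -> Net:
    """A scheduled source dropping ``count`` tokens at fixed absolute times."""
    net = Net("scheduled_injection")
    net.add_colorset("U", ["u"])
    net.add_place("X", ["U"])
    net.add_transition("inject", "scheduled", schedule=(start, period, end))
    net.add_output("inject", "X", f"{count}'(\"u\")")
    return net


def random_walk_2d(size: int = 5, move_rate: float = 1.0) -> Net:
    """Single-token 2D random walk on a toroidal ``size x size`` grid.

    Positions are integer color sets with wraparound; the four move
    transitions use successor/predecessor arithmetic on the X or Y
    component.
    """
    net = Net("random_walk_2d")
    net.add_colorset("X", range(size), circular=True)
    net.add_colorset("Y", range(size), circular=True)
    net.add_place("W", ["X", "Y"])
    for name, pattern in (
        ("x_inc", "1'(p:1+1, p:2)"),
        ("x_dec", "1'(p:1-1, p:2)"),
        ("y_inc", "1'(p:1, p:2+1)"),
        ("y_dec", "1'(p:1, p:2-1)"),
    ):
        net.add_transition(name, "stochastic", rate=move_rate)
        net.add_input("W", name, "1'(p)")
        net.add_output(name, "W", pattern)
    net.set_initial("W", [(0, 0)])
    return net


def fixture_nets() -> dict:
    """The named demo nets with their default parameters."""
    return {
        "birth_death": birth_death(),
        "exponential_race": exponential_race(),
        "preemption": preemption_net(),
        "immediate_conflict": immediate_conflict(),
        "scheduled_injection": scheduled_injection(),
        "random_walk_2d": random_walk_2d(),
    }
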