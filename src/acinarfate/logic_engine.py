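"""Multi-valued logical networks with a three-timescale update scheme.

The formalism is a Thomas-style generalization of Boolean networks: each
variable takes a small number of ordered levels (0..max_level) and is driven
by *level-targeted* rules.  A rule is a conjunction of threshold literals
(``A`` means A >= 1, ``2 A`` means A >= 2, ``!A`` means A = 0, ``2 !A`` means
A < 2) optionally including a negated conjunction ``!( ... )``, and assigns a
target level to one variable.  Disjunction is expressed by several rules with
the same (target, level).  When rules for several levels of a variable fire
simultaneously, the highest level wins; if no rule fires the variable falls
back to its default level 0.

Updates are block-synchronous on three timescales: *input* and *fast*
variables are recomputed every step, *slow* variables every fifth step and
*output* variables every 25th step.  All variables scheduled at step t read
the full state at step t-1.  Rate limits (at most +-1 per step) are encoded
in the rules themselves, never clipped by the engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TIMESCALES",
    "Variable",
    "Literal",
    "NegatedConjunction",
    "Rule",
    "LogicNetwork",
    "Trajectory",
    "RuleParseError",
    "FixedPointError",
    "parse_rules",
    "serialize_rules",
    "rule_fires",
    "target_level",
    "scheduled_classes",
    "advance",
    "simulate",
    "pre_stimulus_state",
    "settling_step",
    "trajectory_frame",
]

TIMESCALES = ("input", "fast", "slow", "output")

#: update periods per timescale class, in simulation steps
_PERIOD = {"input": 1, "fast": 1, "slow": 5, "output": 25}

# A state is a plain mapping variable name -> integer level.
State = dict


class RuleParseError(ValueError):
    """Malformed rule text; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FixedPointError(RuntimeError):
    """No pre-stimulus steady state found within the iteration guard."""


@dataclass(frozen=True)
class Variable:
    name: str
    max_level: int = 2
    timescale: str = "fast"

    def __post_init__(self):
        if self.max_level < 1:
            raise ValueError(f"{self.name}: max_level must be >= 1")
        if self.timescale not in TIMESCALES:
            raise ValueError(f"{self.name}: unknown timescale {self.timescale!r}")


@dataclass(frozen=True)
class Literal:
    """Threshold literal: ``at_least`` is value >= k, otherwise value < k."""

    variable: str
    threshold: int = 1
    at_least: bool = True

    def holds(self, state: Mapping[str, int]) -> bool:
        v = state[self.variable]
        return v >= self.threshold if self.at_least else v < self.threshold

    def text(self) -> str:
        prefix = "" if self.threshold == 1 else f"{self.threshold} "
        bang = "" if self.at_least else "!"
        return f"{prefix}{bang}{self.variable}"


@dataclass(frozen=True)
class NegatedConjunction:
    """``!( L1 + L2 + ... )`` — true iff at least one conjunct is false."""

    conjuncts: tuple[Literal, ...]

    def __post_init__(self):
        if not self.conjuncts:
            raise ValueError("negated conjunction needs at least one conjunct")

    def holds(self, state: Mapping[str, int]) -> bool:
        return not all(lit.holds(state) for lit in self.conjuncts)

    def text(self) -> str:
        return "!(" + " + ".join(lit.text() for lit in self.conjuncts) + ")"


@dataclass(frozen=True)
class Rule:
    id: str
    antecedent: tuple
    target: str
    target_level: int = 1

    def fires(self, state: Mapping[str, int]) -> bool:
        return all(term.holds(state) for term in self.antecedent)

    def text(self) -> str:
        lhs = " + ".join(term.text() for term in self.antecedent)
        rhs = self.target if self.target_level == 1 else f"{self.target_level} {self.target}"
        return f"{lhs} = {rhs}"


def rule_fires(state: Mapping[str, int], rule: Rule) -> bool:
    """True iff every antecedent element of ``rule`` holds in ``state``."""
    return rule.fires(state)


_LITERAL_RE = re.compile(r"^(?:(\d+)\s*)?(!?)\s*([A-Za-z_]\w*)$")


def _parse_literal(term: str, line: int) -> Literal:
    m = _LITERAL_RE.match(term.strip())
    if not m:
        raise RuleParseError(f"malformed literal {term!r}", line)
    k = int(m.group(1)) if m.group(1) else 1
    if k < 1:
        raise RuleParseError(f"threshold must be >= 1 in {term!r}", line)
    return Literal(m.group(3), k, at_least=(m.group(2) != "!"))


def _split_terms(lhs: str, line: int) -> list[str]:
    """Split on top-level '+', leaving '!( ... )' groups intact."""
    terms, depth, cur = [], 0, []
    for ch in lhs:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise RuleParseError("unbalanced ')'", line)
        if ch == "+" and depth == 0:
            terms.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise RuleParseError("unbalanced '('", line)
    terms.append("".join(cur))
    return [t.strip() for t in terms]


def _parse_term(term: str, line: int):
    if term.startswith("!("):
        if not term.endswith(")"):
            raise RuleParseError(f"malformed negated group {term!r}", line)
        inner = term[2:-1]
        lits = tuple(_parse_literal(t, line) for t in inner.split("+"))
        return NegatedConjunction(lits)
    return _parse_literal(term, line)


def parse_rules(
    text: str, variables: Mapping[str, Variable] | None = None
) -> list[Rule]:
    """Parse one rule per line (``#`` starts a comment).

    Rule ids are the 1-based position among non-comment lines, matching the
    numbering of the published rule table when rules are listed in table
    order.  If ``variables`` is given, variable names and thresholds are
    validated (threshold at most max_level + 1).
    """
    rules: list[Rule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise RuleParseError("missing '='", lineno)
        lhs, rhs = stripped.split("=", 1)
        m = _LITERAL_RE.match(rhs.strip())
        if not m or m.group(2) == "!":
            raise RuleParseError(f"malformed right-hand side {rhs!r}", lineno)
        target_level = int(m.group(1)) if m.group(1) else 1
        target = m.group(3)
        antecedent = tuple(_parse_term(t, lineno) for t in _split_terms(lhs, lineno))
        rule = Rule(str(len(rules) + 1), antecedent, target, target_level)
        if variables is not None:
            _validate_rule(rule, variables, lineno)
        rules.append(rule)
    return rules


def _validate_rule(rule: Rule, variables: Mapping[str, Variable], line: int) -> None:
    if rule.target not in variables:
        raise RuleParseError(f"unknown target variable {rule.target!r}", line)
    if rule.target_level > variables[rule.target].max_level:
        raise RuleParseError(
            f"target level {rule.target_level} exceeds max level of {rule.target}", line
        )
    for term in rule.antecedent:
        lits = term.conjuncts if isinstance(term, NegatedConjunction) else (term,)
        for lit in lits:
            if lit.variable not in variables:
                raise RuleParseError(f"unknown variable {lit.variable!r}", line)
            if lit.threshold > variables[lit.variable].max_level + 1:
                raise RuleParseError(
                    f"threshold {lit.threshold} exceeds max level + 1 of {lit.variable}",
                    line,
                )


def serialize_rules(rules: Iterable[Rule]) -> str:
    """Inverse of :func:`parse_rules` up to whitespace and comments."""
    return "\n".join(r.text() for r in rules) + "\n"


@dataclass(frozen=True)
class LogicNetwork:
    variables: tuple[Variable, ...]
    rules: tuple[Rule, ...]
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        vmap = self.variable_map
        for rule in self.rules:
            _validate_rule(rule, vmap, line=None)
        for name, level in self.clamps.items():
            if name not in vmap:
                raise ValueError(f"clamp on unknown variable {name!r}")
            if not 0 <= level <= vmap[name].max_level:
                raise ValueError(f"clamp level {level} out of range for {name}")

    @property
    def variable_map(self) -> dict[str, Variable]:
        return {v.name: v for v in self.variables}

    def names(self, timescale: str | None = None) -> tuple[str, ...]:
        return tuple(
            v.name for v in self.variables if timescale is None or v.timescale == timescale
        )

    def rules_for(self, name: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.target == name)

    def clamped(self, **levels: int) -> "LogicNetwork":
        """Copy of the network with additional clamped variables.

        Passing ``name=None`` removes an existing clamp.
        """
        clamps = dict(self.clamps)
        for name, level in levels.items():
            if level is None:
                clamps.pop(name, None)
            else:
                clamps[name] = level
        return replace(self, clamps=clamps)

    def check_state(self, state: Mapping[str, int]) -> None:
        for v in self.variables:
            if v.name not in state:
                raise ValueError(f"state missing variable {v.name}")
            if not 0 <= state[v.name] <= v.max_level:
                raise ValueError(f"{v.name}={state[v.name]} outside [0, {v.max_level}]")


def target_level(state: Mapping[str, int], var: Variable | str, network: LogicNetwork) -> int:
    """Level assigned to ``var`` when it is updated from ``state``.

    Clamped variables return their clamp.  Otherwise the highest target level
    among the firing rules wins; with no firing rule the default is 0.
    """
    name = var.name if isinstance(var, Variable) else var
    if name in network.clamps:
        return network.clamps[name]
    level = 0
    for rule in network.rules:
        if rule.target == name and rule.target_level > level and rule.fires(state):
            level = rule.target_level
    return level


def scheduled_classes(step: int) -> frozenset:
    """Timescale classes updated at a given step (step >= 1)."""
    return frozenset(ts for ts, period in _PERIOD.items() if step % period == 0)


def advance(state: Mapping[str, int], step: int, network: LogicNetwork) -> dict:
    """One block-synchronous update: every variable whose timescale is
    scheduled at ``step`` is recomputed from the full previous state."""
    classes = scheduled_classes(step)
    new = dict(state)
    for v in network.variables:
        if v.timescale in classes:
            new[v.name] = target_level(state, v, network)
    return new


@dataclass
class Trajectory:
    states: list
    schedule: dict
    condition: str = ""
    outputs: frozenset = frozenset()

    def __len__(self) -> int:
        return len(self.states)

    def levels(self, name: str) -> list[int]:
        return [s[name] for s in self.states]


def simulate(
    network: LogicNetwork,
    initial: Mapping[str, int],
    n_steps: int = 40,
    condition: str = "",
) -> Trajectory:
    """Deterministic simulation for ``n_steps`` updates (trajectory length
    n_steps + 1)."""
    network.check_state(initial)
    states = [dict(initial)]
    schedule: dict[int, frozenset] = {}
    for t in range(1, n_steps + 1):
        classes = scheduled_classes(t)
        schedule[t] = frozenset(
            name for ts in classes for name in network.names(ts)
        )
        states.append(advance(states[-1], t, network))
    return Trajectory(states, schedule, condition, frozenset(network.names("output")))


def _is_fixed_point(state: Mapping[str, int], network: LogicNetwork) -> bool:
    return all(target_level(state, v, network) == state[v.name] for v in network.variables)


def pre_stimulus_state(
    network: LogicNetwork,
    antiox_mode: str = "normal",
    guard: int = 200,
) -> dict:
    """Resting steady state before stimulation.

    Bile is clamped to 0; AntiOx is clamped to 0 (``inhibited``) or 2
    (``added``) or left free (``normal``).  The state is found by iterating
    the full update schedule from the all-zero state and is invariant under
    updates at every timescale.
    """
    clamps = {"Bile": 0}
    if antiox_mode == "inhibited":
        clamps["AntiOx"] = 0
    elif antiox_mode == "added":
        clamps["AntiOx"] = 2
    elif antiox_mode != "normal":
        raise ValueError(f"unknown antiox mode {antiox_mode!r}")
    net = network.clamped(**clamps)
    state = {v.name: 0 for v in net.variables}
    state.update(net.clamps)
    for t in range(1, guard + 1):
        if _is_fixed_point(state, net):
            return state
        state = advance(state, t, net)
    raise FixedPointError(
        f"no pre-stimulus fixed point within {guard} iterations "
        "(check the rule set for unresolved feedback)"
    )


def settling_step(traj: Trajectory, exclude: Iterable[str] | None = None) -> int | None:
    """Smallest step t* from which all non-excluded variables stay constant.

    ``exclude`` defaults to the trajectory's output variables.  Returns None
    when the tail still changes, or when the apparently constant tail is
    shorter than one slow period (5 steps) — too short to distinguish a
    settled state from an oscillation phase — unless the whole trajectory is
    constant.
    """
    excluded = frozenset(traj.outputs if exclude is None else exclude)
    keys = [k for k in traj.states[0] if k not in excluded]

    def restricted(i: int):
        return tuple(traj.states[i][k] for k in keys)

    n = len(traj.states) - 1
    last = restricted(n)
    t_star = n
    while t_star > 0 and restricted(t_star - 1) == last:
        t_star -= 1
    if t_star == 0:
        return 0
    if n - t_star < _PERIOD["slow"]:
        return None
    return t_star


def trajectory_frame(traj: Trajectory):
    """Trajectory as a pandas DataFrame: one row per step, one column per
    variable, plus an ``updated`` column listing the scheduled classes."""
    import pandas as pd

    rows = []
    for t, state in enumerate(traj.states):
        classes = sorted(scheduled_classes(t)) if t >= 1 else []
        rows.append({"step": t, **state, "updated": "+".join(classes)})
    return pd.DataFrame(rows)
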