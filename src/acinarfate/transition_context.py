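"""Transition contexts: from qualitative runs to binary FCA data tables.

A run of states (a simulation trajectory or a discretized experimental
series) is turned into *transitions*: every state paired with every later
state of the same run — the transitive closure of the step relation — so
that rules mined later can speak about what holds always, eventually or
never after a given situation.

Each transition becomes an object of a *formal context*; the attributes
scale the variable levels of its input and output state: ``Var.in.0`` /
``Var.out.0`` hold iff the value is 0, ``Var.in.k`` / ``Var.out.k`` (k >= 1)
hold iff the value is at least k.

Contexts over the same attribute set can be stacked (*subposition*) and are
read and written in the Burmeister ``.cxt`` dialect and as 0/1 CSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_VARIABLES",
    "Transition",
    "FormalContext",
    "scaled_attributes",
    "attribute_holds",
    "run_transitions",
    "series_to_states",
    "build_context",
    "subposition",
    "read_cxt",
    "write_cxt",
    "context_to_frame",
]

#: default variable selection E (chosen by data availability) with max levels
DEFAULT_VARIABLES = {
    "Bile": 2, "Ca": 2, "NADH": 2, "ROS": 3, "AntiOx": 2, "Apt": 2, "Necr": 2,
}


@dataclass(frozen=True)
class Transition:
    """A pair (input state, some later state) within one labelled run."""

    run: str
    i: int
    j: int
    s_in: Mapping[str, int]
    s_out: Mapping[str, int]

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("transition needs i < j")

    @property
    def label(self) -> str:
        return f"({self.run}.{self.i},{self.run}.{self.j})"


def run_transitions(
    states: Sequence[Mapping[str, int]],
    include_identity: bool = False,
    run: str = "run",
) -> list:
    """All pairs (i, j) with i < j of a run.

    Pairs whose two state vectors are equal are dropped unless
    ``include_identity`` — an identity transition cannot invalidate any
    implication (its in/out attribute rows coincide), matching the published
    convention of not showing transitions between identical states.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    out = []
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            if include_identity or states[i] != states[j]:
                out.append(Transition(run, i, j, dict(states[i]), dict(states[j])))
    return out


def series_to_states(series: Iterable) -> list:
    """Stack per-variable discretized series of one condition into states."""
    series = list(series)
    conditions = {s.condition for s in series}
    if len(conditions) != 1:
        raise ValueError(f"series from mixed conditions: {sorted(conditions)}")
    n = len(series[0].levels)
    return [{s.variable: s.levels[t] for s in series} for t in range(n)]


def scaled_attributes(variables: Mapping[str, int] | None = None) -> list:
    """Canonical attribute list: per variable, ``in`` before ``out``, level 0
    (the "value is 0" attribute) before the >= 1 .. >= max thresholds."""
    variables = DEFAULT_VARIABLES if variables is None else variables
    return [
        f"{var}.{role}.{k}"
        for var in variables
        for role in ("in", "out")
        for k in range(variables[var] + 1)
    ]


def attribute_holds(transition: Transition, attribute: str) -> bool:
    var, role, k = attribute.rsplit(".", 2)
    state = transition.s_in if role == "in" else transition.s_out
    if var not in state:
        raise KeyError(f"transition state lacks variable {var!r}")
    value, k = state[var], int(k)
    return value == 0 if k == 0 else value >= k


@dataclass(frozen=True)
class FormalContext:
    """Binary data table (G, M, I); incidence stored as per-object bitmasks
    over the attribute index order."""

    objects: tuple
    attributes: tuple
    rows: tuple  # int bitmask per object; bit i <-> attributes[i]

    def __post_init__(self):
        if len(self.objects) != len(self.rows):
            raise ValueError("one incidence row per object required")
        if len(set(self.objects)) != len(self.objects):
            raise ValueError("object labels must be unique")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("attribute names must be unique")

    @classmethod
    def from_incidence(cls, objects, attributes, incidence) -> "FormalContext":
        """Build from ``incidence(g, m) -> bool`` or a set of (g, m) pairs."""
        if not callable(incidence):
            pairs = set(incidence)
            incidence = lambda g, m: (g, m) in pairs  # noqa: E731
        rows = tuple(
            sum(1 << i for i, m in enumerate(attributes) if incidence(g, m))
            for g in objects
        )
        return cls(tuple(objects), tuple(attributes), rows)

    def has(self, obj, attribute) -> bool:
        g = self.objects.index(obj)
        return bool(self.rows[g] >> self.attributes.index(attribute) & 1)

    def object_intent(self, obj) -> frozenset:
        row = self.rows[self.objects.index(obj)]
        return frozenset(m for i, m in enumerate(self.attributes) if row >> i & 1)

    # --- internal bitmask helpers -----------------------------------------
    def attr_mask(self, attrs: Iterable[str]) -> int:
        mask = 0
        for m in attrs:
            mask |= 1 << self.attributes.index(m)
        return mask

    def mask_attrs(self, mask: int) -> frozenset:
        return frozenset(m for i, m in enumerate(self.attributes) if mask >> i & 1)

    def extent_of_mask(self, mask: int) -> list:
        return [g for g, row in enumerate(self.rows) if row & mask == mask]

    def intent_of_objects(self, indices: Iterable[int]) -> int:
        mask = (1 << len(self.attributes)) - 1
        for g in indices:
            mask &= self.rows[g]
        return mask

    def closure_mask(self, mask: int) -> int:
        return self.intent_of_objects(self.extent_of_mask(mask))


def build_context(
    transitions: Sequence[Transition],
    variables: Mapping[str, int] | None = None,
) -> FormalContext:
    """Transition context: objects are transitions, attributes the scaled
    input/output levels of the selected variables."""
    variables = DEFAULT_VARIABLES if variables is None else variables
    attrs = scaled_attributes(variables)
    objects = [t.label for t in transitions]
    rows = []
    for t in transitions:
        mask = 0
        for i, m in enumerate(attrs):
            if attribute_holds(t, m):
                mask |= 1 << i
        rows.append(mask)
    return FormalContext(tuple(objects), tuple(attrs), tuple(rows))


def subposition(contexts: Sequence[FormalContext]) -> FormalContext:
    """Stack contexts over the same attribute set (object/row union).

    Colliding object labels are disambiguated with a ``#k`` suffix.
    """
    contexts = list(contexts)
    if not contexts:
        raise ValueError("need at least one context")
    attrs = contexts[0].attributes
    for ctx in contexts[1:]:
        if ctx.attributes != attrs:
            raise ValueError("subposition requires identical attribute sets")
    objects, rows, seen = [], [], set()
    for ctx in contexts:
        for g, row in zip(ctx.objects, ctx.rows):
            label, k = g, 2
            while label in seen:
                label, k = f"{g}#{k}", k + 1
            seen.add(label)
            objects.append(label)
            rows.append(row)
    return FormalContext(tuple(objects), attrs, tuple(rows))


# ---------------------------------------------------------------------------
# Burmeister .cxt I/O

def write_cxt(context: FormalContext, path) -> None:
    lines = ["B", "", str(len(context.objects)), str(len(context.attributes)), ""]
    lines += list(context.objects)
    lines += list(context.attributes)
    for row in context.rows:
        lines.append(
            "".join("X" if row >> i & 1 else "." for i in range(len(context.attributes)))
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cxt(path) -> FormalContext:
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw or raw[0].strip() != "B":
        raise ValueError("not a Burmeister context: missing 'B' header")
    body = [ln for ln in raw[1:] if ln.strip() != ""]
    try:
        n_obj, n_attr = int(body[0]), int(body[1])
    except (IndexError, ValueError):
        raise ValueError("malformed header: expected object/attribute counts")
    names = body[2:]
    if len(names) != n_obj + n_attr + n_obj:
        raise ValueError("malformed body: name/row count mismatch")
    objects = tuple(names[:n_obj])
    attributes = tuple(names[n_obj:n_obj + n_attr])
    rows = []
    for line in names[n_obj + n_attr:]:
        if len(line) != n_attr or set(line) - {"X", ".", "x"}:
            raise ValueError(f"malformed incidence row {line!r}")
        rows.append(sum(1 << i for i, ch in enumerate(line) if ch in "Xx"))
    return FormalContext(objects, attributes, tuple(rows))


def context_to_frame(context: FormalContext):
    """Context as a pandas DataFrame of 0/1 (objects x attributes)."""
    import pandas as pd

    data = [
        [row >> i & 1 for i in range(len(context.attributes))]
        for row in context.rows
    ]
    return pd.DataFrame(data, index=list(context.objects), columns=list(context.attributes))
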