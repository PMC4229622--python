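"""Formal concept analysis kernel.

Implements the classical machinery on finite formal contexts (G, M, I):

* the two derivation operators A' (attributes common to a set of objects)
  and B' (objects sharing a set of attributes), and the closure B'';
* concept enumeration with Ganter's NextClosure algorithm, in the lectic
  order induced by the context's attribute order;
* the concept lattice (cover relation of the extent-inclusion order, with
  per-concept "own object" counts);
* attribute implications, their semantics and the forward-chaining closure
  under an implication set;
* the Duquenne-Guigues stem base, computed by the automatic variant of
  attribute exploration where the context itself answers every query and
  an optional set of valid background implications is taken as given.

Internally attribute sets are bitmasks over the context's attribute order;
the public API speaks frozensets of attribute names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .transition_context import FormalContext

__all__ = [
    "FormalConcept",
    "ConceptLattice",
    "Implication",
    "derive",
    "closure",
    "enumerate_concepts",
    "build_lattice",
    "implication_holds",
    "implication_closure",
    "stem_base",
    "counterexamples",
    "format_implication",
    "parse_implication",
    "read_implications",
    "write_implications",
    "lattice_to_dot",
    "lattice_to_json",
]


@dataclass(frozen=True)
class FormalConcept:
    extent: frozenset
    intent: frozenset


@dataclass(frozen=True)
class Implication:
    """Attribute implication: premise -> conclusion.

    Holds in a context iff every object with all premise attributes also has
    all conclusion attributes, i.e. conclusion is inside closure(premise).
    """

    premise: frozenset
    conclusion: frozenset

    def __init__(self, premise: Iterable[str], conclusion: Iterable[str]):
        object.__setattr__(self, "premise", frozenset(premise))
        object.__setattr__(self, "conclusion", frozenset(conclusion))


def derive(context: FormalContext, elements: Iterable, direction: str) -> frozenset:
    """Derivation operator: ``direction='objects'`` maps A to A' (common
    attributes), ``direction='attributes'`` maps B to B' (shared objects)."""
    elements = set(elements)
    if direction == "objects":
        unknown = elements - set(context.objects)
        if unknown:
            raise KeyError(f"unknown objects: {sorted(unknown)}")
        idx = [i for i, g in enumerate(context.objects) if g in elements]
        return context.mask_attrs(context.intent_of_objects(idx))
    if direction == "attributes":
        unknown = elements - set(context.attributes)
        if unknown:
            raise KeyError(f"unknown attributes: {sorted(unknown)}")
        mask = context.attr_mask(elements)
        return frozenset(context.objects[g] for g in context.extent_of_mask(mask))
    raise ValueError("direction must be 'objects' or 'attributes'")


def closure(context: FormalContext, attrs: Iterable[str]) -> frozenset:
    """Attribute closure B''."""
    return context.mask_attrs(context.closure_mask(context.attr_mask(attrs)))


def _next_closure(mask: int, n: int, close) -> int | None:
    """Lectically next set (as bitmask) closed under ``close``; None at end."""
    for i in range(n - 1, -1, -1):
        if mask >> i & 1:
            mask &= ~(1 << i)
        else:
            candidate = close(mask | (1 << i))
            if not (candidate & ~mask) & ((1 << i) - 1):
                return candidate
    return None


def enumerate_concepts(context: FormalContext) -> list:
    """All formal concepts, intents in lectic order (top concept first)."""
    n = len(context.attributes)
    close = context.closure_mask
    concepts = []
    mask = close(0)
    while mask is not None:
        extent = frozenset(context.objects[g] for g in context.extent_of_mask(mask))
        concepts.append(FormalConcept(extent, context.mask_attrs(mask)))
        mask = _next_closure(mask, n, close)
    return concepts


@dataclass(frozen=True)
class ConceptLattice:
    """Concepts ordered by extent inclusion with their cover relation.

    ``covers`` holds pairs (sub, sup) of concept indices where ``sub`` is an
    immediate subconcept of ``sup``; ``own_objects[i]`` are the objects whose
    object intent equals concept i's intent (so the counts partition G).
    """

    concepts: tuple
    covers: tuple
    own_objects: tuple

    def top(self) -> int:
        return max(range(len(self.concepts)), key=lambda i: len(self.concepts[i].extent))

    def bottom(self) -> int:
        return min(range(len(self.concepts)), key=lambda i: len(self.concepts[i].extent))


def build_lattice(concepts: Sequence[FormalConcept], context: FormalContext | None = None) -> ConceptLattice:
    """Cover relation of the extent-inclusion order plus own-object counts.

    ``context`` is only needed for own-object attribution; without it the
    objects are attributed by comparing concept extents (equivalent for a
    complete concept set of one context).
    """
    concepts = tuple(concepts)
    order = sorted(range(len(concepts)), key=lambda i: len(concepts[i].extent))
    covers = []
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            if concepts[i].extent < concepts[j].extent:
                # immediate unless some k sits strictly between
                if not any(
                    concepts[i].extent < concepts[k].extent < concepts[j].extent
                    for k in order
                ):
                    covers.append((i, j))
    by_intent = {c.intent: idx for idx, c in enumerate(concepts)}
    own: list[list] = [[] for _ in concepts]
    all_objects = set().union(*(c.extent for c in concepts)) if concepts else set()
    for g in all_objects:
        if context is not None:
            intent = context.object_intent(g)
        else:
            intent = frozenset().union(
                *[c.intent for c in concepts if g in c.extent]
            )
        own[by_intent[intent]].append(g)
    return ConceptLattice(concepts, tuple(covers), tuple(tuple(sorted(o)) for o in own))


# ---------------------------------------------------------------------------
# Implications

def implication_holds(context: FormalContext, imp: Implication) -> bool:
    for attrs in (imp.premise, imp.conclusion):
        unknown = attrs - set(context.attributes)
        if unknown:
            raise KeyError(f"unknown attributes: {sorted(unknown)}")
    return imp.conclusion <= closure(context, imp.premise)


def counterexamples(context: FormalContext, imp: Implication) -> list:
    """Objects having every premise attribute but missing a conclusion one."""
    p = context.attr_mask(imp.premise)
    c = context.attr_mask(imp.conclusion)
    return [
        g for g, row in zip(context.objects, context.rows)
        if row & p == p and row & c != c
    ]


def _lin_closure(imps: Sequence[tuple], mask: int) -> int:
    """Forward chaining over (premise_mask, conclusion_mask) pairs."""
    changed = True
    while changed:
        changed = False
        for p, c in imps:
            if mask & p == p and mask | c != mask:
                mask |= c
                changed = True
    return mask


def implication_closure(
    implications: Iterable[Implication], attrs: Iterable[str]
) -> frozenset:
    """Smallest superset of ``attrs`` closed under every implication."""
    implications = list(implications)
    universe = sorted(
        set(attrs).union(*[i.premise | i.conclusion for i in implications], set())
    )
    index = {m: i for i, m in enumerate(universe)}
    to_mask = lambda s: sum(1 << index[m] for m in s)  # noqa: E731
    imps = [(to_mask(i.premise), to_mask(i.conclusion)) for i in implications]
    out = _lin_closure(imps, to_mask(attrs))
    return frozenset(m for m, i in index.items() if out >> i & 1)


def stem_base(
    context: FormalContext, background: Iterable[Implication] = ()
) -> list:
    """Duquenne-Guigues basis of the context relative to background knowledge.

    This is the automatic variant of attribute exploration: candidate
    premises are enumerated in lectic order among the sets closed under the
    background plus previously accepted implications; the context acts as
    the oracle, accepting every implication that is valid (no expert, no new
    counterexample objects).  The result is sound (every implication holds),
    complete (together with the background it entails every implication
    valid in the context) and minimal (no member follows from the others
    plus the background).
    """
    n = len(context.attributes)
    full = (1 << n) - 1
    bg = []
    for imp in background:
        if not implication_holds(context, imp):
            raise ValueError(f"background implication not valid in context: {imp}")
        bg.append((context.attr_mask(imp.premise), context.attr_mask(imp.conclusion)))
    imps = list(bg)
    base_masks = []
    mask = _lin_closure(imps, 0)
    while mask is not None and mask != full:
        closed = context.closure_mask(mask)
        if closed != mask:
            base_masks.append((mask, closed))
            imps.append((mask, closed))
        mask = _next_closure(mask, n, lambda m: _lin_closure(imps, m))
    if mask == full and context.closure_mask(full) != full:  # pragma: no cover
        raise AssertionError("closure of M must be M")
    return [
        Implication(context.mask_attrs(p), context.mask_attrs(c))
        for p, c in base_masks
    ]


# ---------------------------------------------------------------------------
# Serialization

def _canonical(attrs: Iterable[str], order: Sequence[str] | None) -> list:
    attrs = set(attrs)
    if order is None:
        return sorted(attrs)
    rank = {m: i for i, m in enumerate(order)}
    return sorted(attrs, key=lambda m: rank.get(m, len(rank)))


def format_implication(imp: Implication, order: Sequence[str] | None = None) -> str:
    """``A1, A2 -> B1, B2`` with conclusions minus premises, canonical order."""
    premise = ", ".join(_canonical(imp.premise, order))
    conclusion = ", ".join(_canonical(imp.conclusion - imp.premise, order))
    return f"{premise} -> {conclusion}"


def parse_implication(text: str) -> Implication:
    if "->" not in text:
        raise ValueError(f"malformed implication {text!r}")
    lhs, rhs = text.split("->", 1)
    split = lambda s: frozenset(t.strip() for t in s.split(",") if t.strip())  # noqa: E731
    return Implication(split(lhs), split(rhs))


def write_implications(
    implications: Iterable[Implication], path, order: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for imp in implications:
            fh.write(format_implication(imp, order) + "\n")


def read_implications(path) -> list:
    with open(path) as fh:
        return [parse_implication(ln) for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# Lattice export

def _node_label(lattice: ConceptLattice, i: int) -> str:
    intent = ", ".join(sorted(lattice.concepts[i].intent))
    return f"{intent or '{}'}\\n|ext|={len(lattice.concepts[i].extent)} own={len(lattice.own_objects[i])}"


def lattice_to_dot(lattice: ConceptLattice) -> str:
    lines = ["digraph concept_lattice {", "  rankdir=BT;", "  node [shape=box];"]
    for i in range(len(lattice.concepts)):
        lines.append(f'  c{i} [label="{_node_label(lattice, i)}"];')
    for sub, sup in lattice.covers:
        lines.append(f"  c{sub} -> c{sup};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def lattice_to_json(lattice: ConceptLattice) -> dict:
    return {
        "nodes": [
            {
                "intent": sorted(c.intent),
                "extent_size": len(c.extent),
                "own_objects": list(lattice.own_objects[i]),
            }
            for i, c in enumerate(lattice.concepts)
        ],
        "edges": [{"sub": a, "sup": b} for a, b in lattice.covers],
    }
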