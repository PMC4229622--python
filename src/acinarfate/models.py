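"""Concrete rule tables and the scenario catalogue.

Three networks are provided:

* ``build_acinar`` — the 41-rule model of bile-acid (TLC-S) stimulated
  pancreatic acinar cells.  Bile 0/1/2 encodes 0/200/500 uM TLC-S.
* ``build_liver`` — liver-cell variant: mitochondrial pore rupture causes a
  ROS burst, pores are more ROS-sensitive, and necrosis is driven directly
  by ATP depletion instead of sustained Ca2+.
* ``build_no_atp`` — alternative acinar model without ATP depletion: the
  sustained Ca2+ rise needed for trypsin activation is produced by
  persistent plasma-membrane channel opening instead (rule 33 removed, PMCh
  persistence added).

A scenario fixes the stimulus level, the antioxidant condition (DMN
inhibition clamps AntiOx to 0, NAC addition clamps it to 2) and the network
variant; ``scenario_run`` simulates it from the matching resting state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .logic_engine import (
    LogicNetwork,
    Rule,
    Trajectory,
    Variable,
    parse_rules,
    pre_stimulus_state,
    simulate,
)

__all__ = [
    "VARIABLES",
    "ACINAR_RULES",
    "Scenario",
    "build_acinar",
    "build_liver",
    "build_no_atp",
    "build_variant",
    "scenario_run",
]

#: The 13 model variables: levels 0..2 throughout, except ROS (0..3, the top
#: level is reached only when antioxidants are inhibited) and the binary
#: plasma-membrane channels.  Timescales: the stimulus is an input; redox and
#: energy state react within seconds (fast); Ca2+ handling, channel/pore
#: gating and cytochrome-C release are slower (every 5th step); cell-fate
#: outputs are evaluated once the signalling layer has settled (every 25th).
VARIABLES = (
    Variable("Bile", 2, "input"),
    Variable("Ca", 2, "slow"),
    Variable("CaMem", 2, "slow"),
    Variable("PMCh", 1, "slow"),
    Variable("NADH", 2, "fast"),
    Variable("Pot", 2, "fast"),
    Variable("ATP", 2, "fast"),
    Variable("ROS", 3, "fast"),
    Variable("AntiOx", 2, "fast"),
    Variable("Pores", 2, "slow"),
    Variable("CytC", 2, "slow"),
    Variable("Apt", 2, "output"),
    Variable("Necr", 2, "output"),
)

#: Rule table in the text DSL, one rule per line in table order (ids 1-41).
ACINAR_RULES = """\
Bile = Bile
!Ca + Bile = Ca
PMCh = Ca
2 !ATP = Ca
2 Ca = Ca
!Ca + !CaMem + 2 Bile = 2 Ca
Ca = CaMem
2 Ca = 2 CaMem
2 Ca = PMCh
2 !ROS = NADH
2 NADH = NADH
NADH + 2 Ca = 2 NADH
2 !Pores = Pot
2 Pot = Pot
Pot + 2 NADH + 2 !Pores = 2 Pot
!Pot = ATP
2 ATP = ATP
ATP + Pot = 2 ATP
Pot = ROS
2 ROS = ROS
ROS + 2 Pot + 2 !AntiOx = 2 ROS
ROS + Pot + Ca + 2 !AntiOx = 2 ROS
ROS + CytC + 2 !AntiOx = 2 ROS
3 ROS = 2 ROS
2 ROS + Ca + CytC + !AntiOx = 3 ROS
2 !Ca = AntiOx
2 !Pores = AntiOx
2 AntiOx = AntiOx
AntiOx + 2 NADH + !Ca + 2 !Pores = 2 AntiOx
Ca = Pores
2 ROS = Pores
2 Pores = Pores
Pores + Ca + CaMem = 2 Pores
2 ROS = CytC
2 CytC = CytC
CytC + 3 ROS = 2 CytC
ATP + CytC + Pores = Apt
ATP + 2 CytC + Pores = 2 Apt
Ca + CaMem = Necr
2 Ca + !(ATP + 2 CytC + Pores) = 2 Necr
Ca + CaMem + !(ATP + 2 CytC + Pores) = 2 Necr
"""

#: liver variant: ROS burst after full pore opening, ROS-sensitive pores
LIVER_ROS_BURST = "2 ROS + 2 Pores + 2 !AntiOx = 3 ROS"
LIVER_PORE_SENSITIVITY = "Pores + 3 ROS = 2 Pores"
#: liver necrosis block: direct inhibitory influence of ATP on necrosis,
#: with the apoptosis condition keeping its prevalence over necrosis
LIVER_NECROSIS = "2 !ATP = Necr"
LIVER_NECROSIS_STRONG = "2 !ATP + !(ATP + 2 CytC + Pores) = 2 Necr"
#: no-ATP-depletion variant: plasma-membrane channels stay open once opened
PMCH_PERSISTENCE = "PMCh = PMCh"


def _parse_one(text: str, rule_id: str) -> Rule:
    (rule,) = parse_rules(text, {v.name: v for v in VARIABLES})
    return replace(rule, id=rule_id)


def build_acinar() -> LogicNetwork:
    """The 41-rule acinar-cell network."""
    vmap = {v.name: v for v in VARIABLES}
    return LogicNetwork(VARIABLES, tuple(parse_rules(ACINAR_RULES, vmap)))


def build_liver() -> LogicNetwork:
    """Liver-cell variant of the acinar network.

    Added: a ROS burst after complete pore opening and higher pore
    sensitivity to ROS.  The three Ca2+-driven necrosis rules (39-41) are
    replaced by two ATP-depletion-driven ones; everything else, including
    the cytochrome-C response to the ROS burst (rule 36), is unchanged.
    """
    acinar = build_acinar()
    kept = tuple(r for r in acinar.rules if r.target != "Necr")
    added = (
        _parse_one(LIVER_ROS_BURST, "L1"),
        _parse_one(LIVER_PORE_SENSITIVITY, "L2"),
        _parse_one(LIVER_NECROSIS, "L3"),
        _parse_one(LIVER_NECROSIS_STRONG, "L4"),
    )
    return replace(acinar, rules=kept + added)


def build_no_atp() -> LogicNetwork:
    """Acinar variant without the ATP-depletion route to sustained Ca2+.

    Rule 33 (full pore opening under sustained Ca2+) is deleted and a PMCh
    persistence rule is added, so the prolonged Ca2+ elevation required for
    trypsin activation comes from plasma-membrane channels staying open.
    """
    acinar = build_acinar()
    kept = tuple(r for r in acinar.rules if r.id != "33")
    return replace(acinar, rules=kept + (_parse_one(PMCH_PERSISTENCE, "A1"),))


_BUILDERS = {"acinar": build_acinar, "liver": build_liver, "no_atp": build_no_atp}

ANTIOX_MODES = ("inhibited", "normal", "added")


def build_variant(variant: str) -> LogicNetwork:
    try:
        return _BUILDERS[variant]()
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None


@dataclass(frozen=True)
class Scenario:
    """A simulation condition: stimulus level x antioxidant mode x variant."""

    bile_level: int = 0
    antiox_mode: str = "normal"
    variant: str = "acinar"

    def __post_init__(self):
        if self.bile_level not in (0, 1, 2):
            raise ValueError("bile_level must be 0, 1 or 2")
        if self.antiox_mode not in ANTIOX_MODES:
            raise ValueError(f"unknown antiox mode {self.antiox_mode!r}")
        if self.variant not in _BUILDERS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def label(self) -> str:
        suffix = {"inhibited": ".DMN", "added": ".NAC", "normal": ""}[self.antiox_mode]
        return f"Bile{self.bile_level}{suffix}"


def scenario_run(scenario: Scenario, n_steps: int = 40) -> Trajectory:
    """Simulate a scenario from its resting state.

    The initial state is the pre-stimulus fixed point under the scenario's
    antioxidant clamp; Bile is then clamped to the stimulus level.
    """
    network = build_variant(scenario.variant)
    resting = pre_stimulus_state(network, scenario.antiox_mode)
    clamps = {"Bile": scenario.bile_level}
    if scenario.antiox_mode == "inhibited":
        clamps["AntiOx"] = 0
    elif scenario.antiox_mode == "added":
        clamps["AntiOx"] = 2
    net = network.clamped(**clamps)
    initial = dict(resting)
    initial.update(net.clamps)
    return simulate(net, initial, n_steps, condition=scenario.label)
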