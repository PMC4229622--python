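"""End-to-end analysis: simulations and observations to rule sets.

The validation protocol mirrors the study design:

1. simulate the six shared conditions (bile 0/1/2, antioxidants normal or
   inhibited; antioxidant *addition* runs are not part of the comparison),
   down-sample each trajectory to the slow-step boundaries and build the
   simulation transition context K_sim;
2. build the observation context K_obs from the discretized fixtures (or a
   user-supplied CSV of real discretized series);
3. stack both into the combined context K_com (subposition);
4. compute the stem base of K_com — the rules common to model and data —
   and feed it as background knowledge into the exploration of K_sim and
   K_obs, yielding the implications specific to the simulations
   (``extra_sim``) and to the data (``extra_obs``);
5. verify the defining property of the extra rule sets (each extra_sim rule
   fails somewhere in K_obs and vice versa) and write all artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import fca
from .fca import Implication
from .models import Scenario, scenario_run
from .observations import fixture_conditions, fixture_observed, read_discretized_csv
from .transition_context import (
    DEFAULT_VARIABLES,
    FormalContext,
    build_context,
    run_transitions,
    series_to_states,
    subposition,
    write_cxt,
)

log = logging.getLogger("acinarfate")

__all__ = [
    "NAMED_RULES",
    "PipelineConfig",
    "RuleReport",
    "build_ksim",
    "build_kobs",
    "run_pipeline",
    "check_named_rules",
    "export_lattice",
]

#: Published named implications, grouped by the context they characterize.
#: "common" rules hold in the combined context (hence in both sides);
#: "sim_only" rules hold in K_sim but have counterexamples in the data;
#: "obs_only" rules hold in K_obs but not in the simulations.
NAMED_RULES: Mapping[str, Sequence[tuple]] = {
    "common": (
        ("strong necrosis entails medium apoptosis",
         Implication({"Necr.out.2"}, {"Apt.out.1"})),
        ("apoptosis is preceded by NADH decline and ROS >= 2",
         Implication({"Apt.out.1"}, {"NADH.out.0", "ROS.out.2"})),
        ("NADH depletion co-occurs with elevated ROS",
         Implication({"NADH.out.0"}, {"ROS.out.2"})),
        ("the NADH peak needs elevated ROS and high stimulation",
         Implication({"NADH.out.2"}, {"ROS.out.2", "Bile.in.2"})),
        ("after the strong Ca peak, Ca stays up and ROS rise",
         Implication({"Ca.in.2"}, {"Ca.out.1", "ROS.out.2"})),
        ("NADH not yet depleted means necrosis not yet initiated",
         Implication({"NADH.out.1"}, {"Necr.out.0"})),
    ),
    "sim_only": (
        ("necrosis only under high stimulation",
         Implication({"Necr.out.1"}, {"Bile.in.2"})),
        ("a Ca trough with elevated ROS fixes the NADH/necrosis future",
         Implication({"Ca.in.0", "ROS.in.2"}, {"NADH.out.0", "Necr.out.0"})),
        ("elevated ROS with NADH still medium implies Ca present",
         Implication({"ROS.in.2", "NADH.out.1"}, {"Ca.in.1"})),
    ),
    "obs_only": (
        ("maximal ROS during a Ca pulse depletes NADH",
         Implication({"Ca.in.1", "ROS.in.3"}, {"NADH.out.0"})),
        ("the NADH peak coincides with the strong Ca peak",
         Implication({"NADH.out.2"}, {"Ca.in.0", "Ca.out.2"})),
        ("the strong Ca peak coincides with the NADH peak",
         Implication({"Ca.out.2"}, {"NADH.out.2"})),
        ("a Ca minimum after NADH decline initiates apoptosis",
         Implication({"NADH.in.0", "Ca.out.0"}, {"Apt.out.1"})),
    ),
}

#: the six conditions common to simulations and data
COMPARISON_CONDITIONS = tuple(
    (bile, mode) for mode in ("normal", "inhibited") for bile in (0, 1, 2)
)


@dataclass(frozen=True)
class PipelineConfig:
    variant: str = "acinar"
    steps: int = 40
    downsample: int = 5
    include_identity: bool = False
    variables: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_VARIABLES))
    observed_csv: str | None = None
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.steps < 25:
            raise ValueError("steps must cover at least one output update (>= 25)")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


@dataclass
class RuleReport:
    ksim: FormalContext
    kobs: FormalContext
    kcom: FormalContext
    base_com: list
    extra_sim: list
    extra_obs: list
    named_verdicts: dict

    def summary(self) -> dict:
        return {
            "objects": {
                "K_sim": len(self.ksim.objects),
                "K_obs": len(self.kobs.objects),
                "K_com": len(self.kcom.objects),
            },
            "attributes": len(self.kcom.attributes),
            "rules": {
                "common": len(self.base_com),
                "extra_sim": len(self.extra_sim),
                "extra_obs": len(self.extra_obs),
            },
        }


def build_ksim(config: PipelineConfig = PipelineConfig()) -> FormalContext:
    """Simulation transition context over the six comparison conditions.

    Trajectories are down-sampled to the slow-step boundaries (every
    ``downsample``-th state) before the transitive transition closure, so
    simulated and observed runs have comparable granularity.
    """
    contexts = []
    for bile, mode in COMPARISON_CONDITIONS:
        traj = scenario_run(Scenario(bile, mode, config.variant), config.steps)
        states = traj.states[:: config.downsample]
        restricted = [
            {v: s[v] for v in config.variables} for s in states
        ]
        transitions = run_transitions(
            restricted, include_identity=config.include_identity, run=traj.condition
        )
        if transitions:
            contexts.append(build_context(transitions, config.variables))
        log.info("K_sim %s: %d states, %d transitions", traj.condition,
                 len(states), len(transitions))
    return subposition(contexts)


def build_kobs(config: PipelineConfig = PipelineConfig()) -> FormalContext:
    """Observation transition context from fixtures or a discretized CSV."""
    if config.observed_csv is not None:
        series = read_discretized_csv(config.observed_csv)
        by_condition: dict[str, list] = {}
        for s in series:
            by_condition.setdefault(s.condition, []).append(s)
        groups = [by_condition[c] for c in sorted(by_condition)]
    else:
        groups = [fixture_observed(b, m) for b, m in fixture_conditions()]
    contexts = []
    for group in groups:
        states = series_to_states(group)
        restricted = [{v: s[v] for v in config.variables} for s in states]
        transitions = run_transitions(
            restricted, include_identity=config.include_identity,
            run=group[0].condition,
        )
        if transitions:
            contexts.append(build_context(transitions, config.variables))
        log.info("K_obs %s: %d transitions", group[0].condition, len(transitions))
    return subposition(contexts)


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> RuleReport:
    """Full exploration; writes artifacts when ``config.outdir`` is set."""
    ksim = build_ksim(config)
    kobs = build_kobs(config)
    kcom = subposition([ksim, kobs])
    log.info("contexts: K_sim %dx%d, K_obs %dx%d", len(ksim.objects),
             len(ksim.attributes), len(kobs.objects), len(kobs.attributes))
    base_com = fca.stem_base(kcom)
    log.info("stem base of K_com: %d rules", len(base_com))
    extra_sim = fca.stem_base(ksim, background=base_com)
    extra_obs = fca.stem_base(kobs, background=base_com)
    log.info("extra rules: %d simulation-only, %d data-only",
             len(extra_sim), len(extra_obs))
    for imp in extra_sim:
        if not fca.counterexamples(kobs, imp):
            raise RuntimeError(
                f"simulation-only rule unexpectedly valid in the data: {imp}"
            )
    for imp in extra_obs:
        if not fca.counterexamples(ksim, imp):
            raise RuntimeError(
                f"data-only rule unexpectedly valid in the simulations: {imp}"
            )
    named = {
        "common@K_com": check_named_rules(kcom, [i for _, i in NAMED_RULES["common"]]),
        "sim_only@K_sim": check_named_rules(ksim, [i for _, i in NAMED_RULES["sim_only"]]),
        "sim_only@K_obs": check_named_rules(kobs, [i for _, i in NAMED_RULES["sim_only"]]),
        "obs_only@K_obs": check_named_rules(kobs, [i for _, i in NAMED_RULES["obs_only"]]),
    }
    report = RuleReport(ksim, kobs, kcom, base_com, extra_sim, extra_obs, named)
    if config.outdir is not None:
        _write_artifacts(report, config)
    return report


def check_named_rules(
    context: FormalContext, rules: Iterable[Implication]
) -> list:
    """Per-rule verdicts: holds or fails with a counterexample object."""
    verdicts = []
    for imp in rules:
        cex = fca.counterexamples(context, imp)
        verdicts.append({
            "rule": fca.format_implication(imp, context.attributes),
            "holds": not cex,
            "counterexample": cex[0] if cex else None,
        })
    return verdicts


def export_lattice(
    context: FormalContext, attribute_filter: Iterable[str] | None = None
) -> fca.ConceptLattice:
    """Concept lattice of the context restricted to selected attributes.

    ``attribute_filter`` may contain attribute names or ``Var.role.*``
    patterns (all levels of a variable/role).
    """
    if attribute_filter is None:
        sub = context
    else:
        keep = set()
        for pat in attribute_filter:
            if pat.endswith(".*"):
                matched = {m for m in context.attributes if m.startswith(pat[:-1])}
                if not matched:
                    raise KeyError(f"pattern {pat!r} matches no attribute")
                keep |= matched
            elif pat in context.attributes:
                keep.add(pat)
            else:
                raise KeyError(f"unknown attribute or pattern {pat!r}")
        idx = [i for i, m in enumerate(context.attributes) if m in keep]
        rows = tuple(
            sum(((row >> i) & 1) << k for k, i in enumerate(idx))
            for row in context.rows
        )
        sub = FormalContext(
            context.objects, tuple(context.attributes[i] for i in idx), rows
        )
    return fca.build_lattice(fca.enumerate_concepts(sub), sub)


def _write_artifacts(report: RuleReport, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = report.kcom.attributes
    write_cxt(report.ksim, outdir / "ksim.cxt")
    write_cxt(report.kobs, outdir / "kobs.cxt")
    write_cxt(report.kcom, outdir / "kcom.cxt")
    fca.write_implications(report.base_com, outdir / "base_com.imp", order)
    fca.write_implications(report.extra_sim, outdir / "extra_sim.imp", order)
    fca.write_implications(report.extra_obs, outdir / "extra_obs.imp", order)
    lattice = export_lattice(
        report.kcom, ["ROS.out.*", "NADH.out.*", "Apt.out.*", "Necr.out.*", "Bile.in.*"]
    )
    (outdir / "kcom_lattice.dot").write_text(fca.lattice_to_dot(lattice))
    (outdir / "kcom_lattice.json").write_text(
        json.dumps(fca.lattice_to_json(lattice), indent=1, sort_keys=True)
    )
    lines = ["# Rule report", "", "## Context sizes", ""]
    summary = report.summary()
    lines += [f"- {k}: {v} objects" for k, v in summary["objects"].items()]
    lines += ["", "## Rule counts", ""]
    lines += [f"- {k}: {v}" for k, v in summary["rules"].items()]
    lines += ["", "## Named rules", ""]
    for section, verdicts in report.named_verdicts.items():
        lines.append(f"### {section}")
        for v in verdicts:
            status = "holds" if v["holds"] else f"fails ({v['counterexample']})"
            lines.append(f"- `{v['rule']}` — {status}")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
    log.info("artifacts written to %s", outdir)
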