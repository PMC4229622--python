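# Methods

## The logical model

The network is a multi-valued logical system in the tradition of Thomas'
generalization of Boolean networks. Each of the 13 variables carries a small
ordered level set — 0–2 for most, 0–3 for ROS (the top level is only
reachable when antioxidants are inhibited and matters because it triggers
the strong cytochrome-C release), 0–1 for the plasma-membrane channels. A
rule is a conjunction of threshold literals, optionally with one negated
conjunction `!( ... )`, targeting one level of one variable. Disjunction is
spread over several rules for the same (variable, level); together the
left-hand sides form the disjunctive normal form of the level's condition.
Evaluation is by level priority: among the firing rules for a variable the
highest target level wins, and with no firing rule the variable falls to its
default 0 — which denotes a basal, not necessarily zero, quantity (basal ATP
for instance still supports apoptosis).

### Timescales and update semantics

Variables are partitioned into four classes updated with periods 1/1/5/25:

| class  | variables                     | period | rationale |
|--------|-------------------------------|--------|-----------|
| input  | Bile                          | 1      | clamped stimulus |
| fast   | NADH, Pot, ATP, ROS, AntiOx   | 1      | electro-chemical and redox processes, seconds |
| slow   | Ca, CaMem, PMCh, Pores, CytC  | 5      | Ca²⁺ transients, channel/pore gating, CytC diffusion, ~1 min |
| output | Apt, Necr                     | 25     | cell-fate initiation read from the settled signalling state |

Updates are block-synchronous: every variable scheduled at step t is
recomputed from the complete state at t−1. Two conventions are open in the
published description and fixed here once:

* *Phase.* Slow variables update at steps 5, 10, …; outputs at step 25 (and
  every further multiple). Slow updates thus always follow a run of fast
  updates, which is the stated intent ("after a stable value for the fast
  variables is reached"), and a 40-step run contains exactly one output
  update, so the alternative reading — outputs evaluated once on the steady
  state — coincides.
* *No engine-level ramp.* The ±1-per-step rate limit is carried entirely by
  the rules (self-guards like `ATP + Pot = 2 ATP`); the engine never clips.
  Consequently the rules *without* such a guard are exactly the places where
  jumps are intended: the phenomenological Ca²⁺ peak rule (6), its CaMem
  memory image (8), and the single-update level-2 output rules (38, 40, 41).

Clamped variables (Bile always; AntiOx under DMN inhibition → 0 or NAC
addition → 2) are never rule-updated, reflecting the continuous presence of
those compounds in the experiments.

### Initial condition

Simulations start from the pre-stimulus steady state: the fixed point of the
full schedule with Bile clamped to 0 and AntiOx clamped per condition. It is
found by iterating the schedule from the all-zero state with a guard of 200
steps; non-convergence (e.g. a negation loop) raises an error, signalling a
mis-specified rule set, rather than silently picking a state. For all three
antioxidant modes the fixed point is
`Ca=0, CaMem=0, PMCh=0, NADH=1, Pot=1, ATP=2, ROS=1, Pores=0, CytC=0,
Apt=0, Necr=0` with AntiOx = 1/0/2.

### Settling detection

`settling_step` reports the earliest step from which the non-output
variables stay constant. On a finite trajectory a tail of length zero is
vacuously constant, so a constant tail shorter than one slow period
(5 steps) is not accepted as settled (`None`), unless the run is constant
from step 0. With the default 40-step horizon this correctly classifies the
period-10 Ca²⁺ oscillation at 200 μM as non-settling.

## Model variants

*Liver*: adds `2 ROS + 2 Pores + 2 !AntiOx = 3 ROS` (ROS burst after outer
membrane rupture) and `Pores + 3 ROS = 2 Pores` (higher pore sensitivity),
and replaces the three Ca²⁺-driven necrosis rules by `2 !ATP = Necr` and
`2 !ATP + !(ATP + 2 CytC + Pores) = 2 Necr` — necrosis directly under ATP
control, apoptosis keeping its prevalence. Only these listed substitutions
are applied; all other acinar rules, including the partially-open-pore
rules, are kept verbatim.

*No ATP depletion*: removes rule 33 (full pore opening under sustained
Ca²⁺) and adds the persistence rule `PMCh = PMCh`. Open plasma-membrane
channels then maintain the prolonged Ca²⁺ elevation needed for trypsin
activation; the tests confirm the cell-fate outcomes are unchanged across
the basic and antioxidant conditions, and that deleting rule 33 *without*
the persistence rule loses necrosis — one prolonged slow step of channel
opening is the minimal addition.

The intermediate 200 μM behaviour (oscillations followed by a sustained
rise, seen in a quarter of the measured cells) is deliberately not
simulated; the model covers the pure-oscillation majority, and the
intermediate case enters the analysis only through the observation data.

## Synthetic observations

Measured traces are reduced to levels at the seven canonical time points 0,
100, 200, 300, 400, 600, 1200 s by linear interpolation followed by
per-variable ascending thresholds (the published material does not state
the sampling convention; interpolation is the package's choice). The
default scheme puts cuts at k − 0.5 on a normalized 0..max scale.

Only one discretized row is published verbatim: Ca²⁺ at 200 μM,
`0-1-0-1-0-1-1`. All other fixture rows are reconstructions (flagged
`approx=True`) chosen to satisfy, jointly, (i) the published qualitative
descriptions — initial Ca²⁺ peak and plateau at 500 μM, NAD(P)H peak then
decline, maximal ROS only under antioxidant inhibition, end-point
apoptosis/necrosis levels; (ii) every printed implication: the common rules
must hold on both sides, the data-only rules on the observation side, and
the simulation-only rules must fail there; and (iii) the concept-hierarchy
observation that reduced necrosis (level 1, never 2) co-occurs with the
maximal ROS level. Known tension: the fixtures let ROS reach level 2 late
in the 200 μM *normal* run, although the measured cytosolic ROS does not
rise there — forced by the printed rule `NADH.out.0 → ROS.out.2` once NADH
declines. Passing tests on these fixtures therefore demonstrate that the
pipeline reproduces the printed rule-level findings, not that the fixtures
equal the original supplementary tables; users holding those tables can
load them through the same CSV schema (`condition, variable, t_seconds,
level`) and rerun the pipeline unchanged.

`synth_raw` wraps the fixtures into continuous traces (piecewise-linear
template plus seeded uniform noise bounded strictly below half the
threshold gap) whose discretization provably recovers the fixture for any
seed — the only stochastic element in the package.

## Transition contexts

Runs become objects of a formal context by pairing every state with every
later state of the same run (the transitive closure of the step relation),
dropping pairs of identical states — an identity row has equal in/out
attributes and can invalidate no implication; a flag restores them.
Attributes scale the levels of the seven comparison variables (Bile, Ca,
NADH, ROS, AntiOx, Apt, Necr — those with data under all conditions) in
both roles: `Var.role.0` for "value is 0" and `Var.role.k` for "value ≥ k",
44 attributes in total. Simulated trajectories are down-sampled to the
slow-step boundaries (states 0, 5, …, 40) before pairing, giving both sides
comparable granularity; the exact sampling behind the original contexts is
not published, so rule *counts* computed here are not comparable to the
originally reported ones, while the named implications are. The six
comparison conditions are bile 0/1/2 with and without antioxidant
inhibition; NAC runs are excluded from the FCA stage.

## FCA kernel

Derivation operators and closures run on bitmask rows. Concepts are
enumerated with NextClosure in the lectic order of the canonical attribute
order (declared variable order, `in` before `out`, level 0 before the
ascending thresholds) — determinism makes artifact diffs stable. The
Duquenne–Guigues stem base is computed by the automatic variant of
attribute exploration: candidate premises are the lectically enumerated
sets closed under background-plus-accepted implications, and the context
itself answers every query, accepting valid implications. Soundness,
completeness and minimality, and exact agreement with a brute-force
pseudo-intent enumeration, are verified in the test suite on exhaustive
small instances (the kernel is exact at any size; the brute-force oracles
cap |G|, |M| at 8/6 to stay exhaustive). The pipeline additionally
hard-verifies the defining property of the relative bases: every
simulation-only rule has a counterexample in the data context and vice
versa.

Implications are serialized premise-sorted with conclusions minus premises;
lattices are exported as GraphViz dot and JSON with extent sizes and
own-object counts (objects whose object intent equals the concept intent,
partitioning G).

## Problem sizes and numerical choices

Everything is integer-valued and desk-scale: trajectories of 41 states over
13 variables, contexts of ≈200 objects × 44 attributes; the full pipeline,
including three stem-base computations, runs in well under a minute on one
CPU, and the default test suite in a few seconds. There is no floating-point
tolerance anywhere except the discretization thresholds, where ties resolve
upward (value ≥ cut).

## Limitations

* The observation fixtures are reconstructions, not data; see above.
* No stochastic or single-variable asynchronous semantics; the
  block-synchronous three-timescale scheme is the only update mode.
* No compartmental resolution (cytosol vs. mitochondria vs. ER) and no
  autophagy branch.
* Concept-lattice rendering is plain dot/JSON; no interactive exploration.
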