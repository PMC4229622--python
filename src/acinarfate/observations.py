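"""Synthetic observation stage: discretization and qualitative fixtures.

The experiments behind the model measure Ca2+, ROS and NAD(P)H continuously
for up to 20 minutes of bile-acid stimulation and score apoptosis/necrosis
as end points.  For the qualitative comparison, every trace is reduced to
discrete levels at seven canonical time points (0, 100, 200, 300, 400, 600
and 1200 s).

``fixture_observed`` returns deterministic discretized series per condition
that emulate the qualitative structure of those measurements: Ca2+
oscillation with a late sustained rise at 200 uM (the row 0-1-0-1-0-1-1),
an initial Ca2+ peak plus plateau at 500 uM, NAD(P)H decline, a ROS rise
that reaches the maximum level when antioxidants are inhibited, and the
end-point apoptosis/necrosis levels.  Only the 200 uM Ca2+ row is a
published discretization; all other rows are plausible reconstructions
(marked ``approx``) chosen to be consistent with the published qualitative
descriptions and temporal rules.  Users holding real discretized series can
load them from CSV with :func:`read_discretized_csv` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CANONICAL_TIMES",
    "OBSERVED_VARIABLES",
    "ContinuousSeries",
    "DiscretizedSeries",
    "ThresholdScheme",
    "discretize_series",
    "fixture_observed",
    "fixture_conditions",
    "synth_raw",
    "default_threshold_scheme",
    "read_discretized_csv",
    "write_discretized_csv",
    "write_raw_csv",
]

#: seconds after stimulation onset at which every series is sampled
CANONICAL_TIMES = (0, 100, 200, 300, 400, 600, 1200)

#: variables with data available under all conditions (max levels)
OBSERVED_VARIABLES = {
    "Bile": 2, "Ca": 2, "NADH": 2, "ROS": 3, "AntiOx": 2, "Apt": 2, "Necr": 2,
}


@dataclass(frozen=True)
class ContinuousSeries:
    """A raw trace in arbitrary units; times in seconds, strictly increasing."""

    variable: str
    condition: str
    times: tuple
    values: tuple

    def __post_init__(self):
        if len(self.times) != len(self.values) or len(self.times) < 2:
            raise ValueError("need >= 2 (time, value) samples")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class DiscretizedSeries:
    """Levels of one variable at the seven canonical time points."""

    variable: str
    condition: str
    levels: tuple
    approx: bool = False

    def __post_init__(self):
        if len(self.levels) != len(CANONICAL_TIMES):
            raise ValueError(f"need exactly {len(CANONICAL_TIMES)} levels")
        max_level = OBSERVED_VARIABLES.get(self.variable)
        if max_level is not None and not all(0 <= l <= max_level for l in self.levels):
            raise ValueError(f"{self.variable} levels outside [0, {max_level}]")


class ThresholdScheme(dict):
    """Per-variable ascending cut points; level = number of cuts <= value."""

    def level(self, variable: str, value: float) -> int:
        cuts = self[variable]
        return int(sum(value >= c for c in cuts))

    def validate(self) -> None:
        for var, cuts in self.items():
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"{var}: cuts must be strictly increasing")


def default_threshold_scheme() -> ThresholdScheme:
    """Cuts on a normalized 0..max_level scale: level k from value k - 0.5."""
    scheme = ThresholdScheme(
        {var: tuple(k - 0.5 for k in range(1, max_level + 1))
         for var, max_level in OBSERVED_VARIABLES.items()}
    )
    scheme.validate()
    return scheme


def discretize_series(
    series: ContinuousSeries, scheme: ThresholdScheme
) -> DiscretizedSeries:
    """Linear interpolation at the canonical time points, then thresholding."""
    if series.times[0] > CANONICAL_TIMES[0] or series.times[-1] < CANONICAL_TIMES[-1]:
        raise ValueError(
            f"{series.variable}/{series.condition}: samples must span "
            f"[{CANONICAL_TIMES[0]}, {CANONICAL_TIMES[-1]}] s"
        )
    sampled = np.interp(CANONICAL_TIMES, series.times, series.values)
    levels = tuple(scheme.level(series.variable, v) for v in sampled)
    return DiscretizedSeries(series.variable, series.condition, levels)


# ---------------------------------------------------------------------------
# Fixtures

#: resting levels of the observed variables (matches the model's pre-stimulus
#: fixed point restricted to the observed set; AntiOx depends on the condition)
_RESTING = {"Ca": 0, "NADH": 1, "ROS": 1, "Apt": 0, "Necr": 0}

# Level rows per (bile_level, antiox_mode), indexed by canonical time point.
# Ca at bile 1 is the published discretization; everything else is a
# reconstruction (approx) consistent with the published temporal rules:
# strong necrosis only with at least medium apoptosis, apoptosis preceded by
# NADH decline and ROS >= 2, the Ca/NADH peak equivalence at 500 uM, the
# maximal ROS level only under antioxidant inhibition, medium (reduced)
# necrosis co-occurring with that maximal ROS level, and medium necrosis at
# 200 uM appearing in the antioxidant-inhibited run — the intermediate
# oscillation-then-rise cells that the simulations deliberately exclude.
_FIXTURES = {
    (0, "normal"): {},
    (1, "normal"): {
        "Ca": ((0, 1, 0, 1, 0, 1, 1), False),
        "NADH": ((1, 1, 1, 1, 0, 0, 0), True),
        "ROS": ((1, 1, 1, 1, 2, 2, 2), True),
        "Apt": ((0, 0, 0, 0, 0, 0, 1), True),
    },
    (2, "normal"): {
        "Ca": ((0, 2, 1, 1, 1, 1, 1), True),
        "NADH": ((1, 2, 1, 0, 0, 0, 0), True),
        "ROS": ((1, 2, 2, 2, 2, 2, 2), True),
        "Apt": ((0, 0, 0, 0, 0, 0, 1), True),
        "Necr": ((0, 0, 0, 0, 0, 0, 2), True),
    },
    (0, "inhibited"): {},
    (1, "inhibited"): {
        # Ca and NADH are carried over from the normal condition (they are
        # not affected by antioxidant inhibition); ROS climbs to the maximum.
        "Ca": ((0, 1, 0, 1, 0, 1, 1), False),
        "NADH": ((1, 1, 1, 1, 0, 0, 0), True),
        "ROS": ((1, 2, 2, 3, 3, 3, 3), True),
        "Apt": ((0, 0, 0, 0, 0, 0, 1), True),
        "Necr": ((0, 0, 0, 0, 0, 0, 1), True),
    },
    (2, "inhibited"): {
        "Ca": ((0, 2, 1, 1, 1, 1, 1), True),
        "NADH": ((1, 2, 1, 0, 0, 0, 0), True),
        "ROS": ((1, 2, 3, 3, 3, 3, 3), True),
        "Apt": ((0, 0, 0, 0, 0, 0, 2), True),
        "Necr": ((0, 0, 0, 0, 0, 0, 1), True),
    },
}


def fixture_conditions() -> list:
    """The six observed conditions: bile 0/1/2 x normal/DMN-inhibited."""
    return sorted(_FIXTURES)


def condition_label(bile_level: int, antiox_mode: str) -> str:
    suffix = {"normal": "", "inhibited": ".DMN", "added": ".NAC"}[antiox_mode]
    return f"Bile{bile_level}{suffix}"


def fixture_observed(bile_level: int, antiox_mode: str = "normal") -> list:
    """Deterministic discretized series for one condition.

    Returns one :class:`DiscretizedSeries` per observed variable; rows not
    published in discretized form carry ``approx=True``.
    """
    key = (bile_level, antiox_mode)
    if key not in _FIXTURES:
        raise ValueError(f"unknown condition {key!r}")
    rows = _FIXTURES[key]
    label = condition_label(bile_level, antiox_mode)
    n = len(CANONICAL_TIMES)
    out = [DiscretizedSeries("Bile", label, (bile_level,) * n, approx=False)]
    antiox = 0 if antiox_mode == "inhibited" else 1
    out.append(DiscretizedSeries("AntiOx", label, (antiox,) * n, approx=False))
    for var, resting in _RESTING.items():
        if var in rows:
            levels, approx = rows[var]
        else:
            levels, approx = (resting,) * n, False
        out.append(DiscretizedSeries(var, label, levels, approx=approx))
    return out


def synth_raw(
    bile_level: int,
    antiox_mode: str = "normal",
    seed: int = 0,
    noise: float = 0.2,
) -> list:
    """Noisy continuous traces whose discretization equals the fixture.

    Each trace is a piecewise-linear template through the fixture levels
    (held constant in a window around each canonical time point so that
    interpolation at the time points stays on-level) plus bounded uniform
    noise strictly below half the threshold gap, so discretization with the
    default scheme recovers the fixture exactly for any seed.
    """
    if not 0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5) threshold-gap units")
    rng = np.random.default_rng(seed)
    out = []
    for ds in fixture_observed(bile_level, antiox_mode):
        times: list[float] = []
        values: list[float] = []
        for t, level in zip(CANONICAL_TIMES, ds.levels):
            lo = t if t == CANONICAL_TIMES[0] else t - 20.0
            hi = t if t == CANONICAL_TIMES[-1] else t + 20.0
            for tt in ([lo, hi] if lo < hi else [float(t)]):
                times.append(tt)
                values.append(level + rng.uniform(-noise, noise))
        out.append(ContinuousSeries(ds.variable, ds.condition, tuple(times), tuple(values)))
    return out


# ---------------------------------------------------------------------------
# CSV I/O (columns: condition, variable, t_seconds, level / value)

def write_discretized_csv(series: Iterable[DiscretizedSeries], path) -> None:
    import pandas as pd

    rows = [
        {"condition": s.condition, "variable": s.variable, "t_seconds": t, "level": l}
        for s in series
        for t, l in zip(CANONICAL_TIMES, s.levels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_discretized_csv(path) -> list:
    """Load discretized series (e.g. a real supplementary data table)."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for (cond, var), grp in df.groupby(["condition", "variable"], sort=True):
        grp = grp.sort_values("t_seconds")
        if tuple(grp["t_seconds"]) != CANONICAL_TIMES:
            raise ValueError(
                f"{cond}/{var}: expected time points {CANONICAL_TIMES}"
            )
        out.append(DiscretizedSeries(var, cond, tuple(int(l) for l in grp["level"])))
    return out


def write_raw_csv(series: Iterable[ContinuousSeries], path) -> None:
    import pandas as pd

    rows = [
        {"condition": s.condition, "variable": s.variable, "t_seconds": t, "value": v}
        for s in series
        for t, v in zip(s.times, s.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
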