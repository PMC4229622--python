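"""Independent reference interpreter used as a test oracle.

Deliberately naive and structurally unrelated to the package: rules are kept
as text and re-read with local regexes at every evaluation; the schedule and
the level-priority convention are re-implemented from scratch.  Any
agreement with the package is therefore meaningful.
"""

import re

PERIOD = {"input": 1, "fast": 1, "slow": 5, "output": 25}

MAX_LEVEL = {"ROS": 3, "PMCh": 1}  # all other variables: 2
TIMESCALE = {
    "Bile": "input",
    "NADH": "fast", "Pot": "fast", "ATP": "fast", "ROS": "fast", "AntiOx": "fast",
    "Ca": "slow", "CaMem": "slow", "PMCh": "slow", "Pores": "slow", "CytC": "slow",
    "Apt": "output", "Necr": "output",
}

_LIT = re.compile(r"^\s*(?:(\d+)\s*)?(!?)\s*(\w+)\s*$")


def _lit_true(text, state):
    m = _LIT.match(text)
    k = int(m.group(1) or 1)
    value = state[m.group(3)]
    return value < k if m.group(2) == "!" else value >= k


def _split_plus(text):
    parts, depth, cur = [], 0, ""
    for ch in text:
        depth += ch == "("
        depth -= ch == ")"
        if ch == "+" and depth == 0:
            parts.append(cur)
            cur = ""
        else:
            cur += ch
    return parts + [cur]


def _lhs_true(lhs, state):
    for term in _split_plus(lhs):
        term = term.strip()
        if term.startswith("!("):
            inner = term[2:].rstrip()[:-1]
            if all(_lit_true(p, state) for p in inner.split("+")):
                return False
        elif not _lit_true(term, state):
            return False
    return True


def _clean(rule_lines):
    out = []
    for line in rule_lines:
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def oracle_target(rule_lines, state, var, clamps):
    if var in clamps:
        return clamps[var]
    best = 0
    for line in _clean(rule_lines):
        lhs, rhs = line.split("=")
        m = _LIT.match(rhs)
        if m.group(3) != var:
            continue
        level = int(m.group(1) or 1)
        if level > best and _lhs_true(lhs, state):
            best = level
    return best


def oracle_step(rule_lines, state, t, clamps):
    new = dict(state)
    for var, scale in TIMESCALE.items():
        if t % PERIOD[scale] == 0:
            new[var] = oracle_target(rule_lines, state, var, clamps)
    return new


def oracle_simulate(rule_lines, initial, n_steps, clamps):
    states = [dict(initial)]
    for t in range(1, n_steps + 1):
        states.append(oracle_step(rule_lines, states[-1], t, clamps))
    return states


def oracle_fixed_point(rule_lines, clamps, guard=200):
    """Fixed-point search from all-zero; a state invariant at a step where
    every class updates (t = 25) is invariant at every step."""
    state = {v: 0 for v in TIMESCALE}
    state.update(clamps)
    for t in range(1, guard + 1):
        if oracle_step(rule_lines, state, 25, clamps) == state:
            return state
        state = oracle_step(rule_lines, state, t, clamps)
    raise RuntimeError("oracle found no fixed point")
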