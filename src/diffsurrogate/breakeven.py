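"""Break-even analysis: when does a surrogate pay for its construction?

Building a surrogate costs ``M * delta`` seconds of direct solves for the
training set plus ``E`` seconds of training; each use then costs ``epsilon``
seconds instead of ``delta``. Running N replicas directly takes
``t_direct = N * delta``; through the surrogate workflow it takes
``t_neuro = M * delta + E + N * epsilon``. Equating the two gives the
break-even evaluation count

    N_min = (M + E / delta) / (1 - epsilon / delta),

approximately ``M + E/delta`` when the surrogate speed-up is large. The
reference worked example (M = 20,000 training solves at delta = 1.16 s,
E = 12 h of training, epsilon = delta/1000) gives N_min of about 57,300.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["BreakevenInputs", "n_min", "workflow_times", "parse_duration"]


@dataclass(frozen=True)
class BreakevenInputs:
    """All times in seconds; M is the training-set size in replicas."""

    M: float
    E: float
    delta: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.M < 0 or self.E < 0:
            raise ValueError("M and E must be non-negative")
        if not (self.delta > 0) or self.epsilon < 0:
            raise ValueError("delta must be positive and epsilon non-negative")


def n_min(inputs: BreakevenInputs) -> float:
    """Replica count at which the surrogate workflow matches direct solving."""
    if inputs.epsilon >= inputs.delta:
        raise ValueError(
            f"no break-even: surrogate evaluation ({inputs.epsilon}s) is not "
            f"faster than the direct solve ({inputs.delta}s)"
        )
    return (inputs.M + inputs.E / inputs.delta) / (1.0 - inputs.epsilon / inputs.delta)


def workflow_times(inputs: BreakevenInputs, N: float) -> tuple[float, float]:
    """(t_direct, t_neuro) for N replica evaluations."""
    if N < 0:
        raise ValueError("N must be non-negative")
    t_direct = N * inputs.delta
    t_neuro = inputs.M * inputs.delta + inputs.E + N * inputs.epsilon
    return t_direct, t_neuro


_DURATION_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*(h|m|min|s|d)?\s*$", re.IGNORECASE)
_UNIT_SECONDS = {None: 1.0, "s": 1.0, "m": 60.0, "min": 60.0, "h": 3600.0, "d": 86400.0}


def parse_duration(text: str | float) -> float:
    """Parse '12h', '30min', '1.16s', or a bare number, into seconds."""
    if isinstance(text, (int, float)):
        return float(text)
    m = _DURATION_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse duration {text!r}")
    unit = m.group(2).lower() if m.group(2) else None
    return float(m.group(1)) * _UNIT_SECONDS[unit]
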