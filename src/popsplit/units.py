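"""Time-unit conversions between mutation-scaled and Ne-generation units.

Internally every time is mutation-scaled (expected substitutions per
site), the same scale as Theta = 4 Ne mu.  Figures in the divergence-time
literature are often labelled in Ne or 4 Ne generations; with Theta known
the conversions are

    t_mut = x * Theta / 4        for x in Ne generations,
    t_mut = x * Theta            for x in 4 Ne generations (the classic
                                 ms coalescent time unit).

Which Theta serves as the reference (per-deme or combined) must be stated;
these helpers take it explicitly.
"""

from __future__ import annotations

__all__ = [
    "mut_from_ne_generations",
    "mut_from_coalescent_units",
    "ne_generations_from_mut",
    "coalescent_units_from_mut",
]


def mut_from_ne_generations(x: float, theta: float) -> float:
    """Mutation-scaled time of ``x`` Ne generations (Ne from ``theta``)."""
    return x * theta / 4.0


def mut_from_coalescent_units(x: float, theta: float) -> float:
    """Mutation-scaled time of ``x`` coalescent units of 4 Ne generations."""
    return x * theta


def ne_generations_from_mut(t: float, theta: float) -> float:
    return 4.0 * t / theta


def coalescent_units_from_mut(t: float, theta: float) -> float:
    return t / theta
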