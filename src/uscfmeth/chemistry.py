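"""Bisulfite chemistry model: strand breakage and cytosine conversion.

Sodium bisulfite treatment deaminates unmethylated cytosines (read as T
after PCR) but also nicks the DNA backbone.  Breakage is modelled as an
independent Bernoulli event at each internal phosphodiester bond, so a
fragment of ``n`` bases (``n - 1`` internal bonds) survives intact with
probability ``(1 - lam)**(n - 1)``.  Published degradation figures for
bisulfite-treated DNA (about 10% loss at 62 bp and 20% at 131 bp) are
mutually consistent under this per-bond model, which is why a single
``lam`` calibrated on one anchor reproduces the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChemistryParams",
    "calibrate_breakage",
    "expected_loss_fraction",
    "simulate_loss_fraction",
]


@dataclass(frozen=True)
class ChemistryParams:
    """Parameters of the bisulfite reaction.

    Attributes
    ----------
    breakage_prob:
        Per internal-bond breakage probability ``lam``.  The default is
        calibrated so that 62 bp fragments sustain a 10% loss.
    c_cpg:
        Conversion efficiency for unmethylated cytosines in CpG context
        (probability an unmethylated C reads as T).
    c_non_cpg:
        Conversion efficiency for unmethylated cytosines in CHG/CHH context.
    over_conversion:
        Probability that a *methylated* cytosine is erroneously converted
        (reads as T).
    min_fragment_length:
        Shortest sub-fragment (bases) retained after breakage; smaller
        pieces are lost during cleanup.
    """

    breakage_prob: float = 1.0 - 0.9 ** (1.0 / 61.0)
    c_cpg: float = 0.995
    c_non_cpg: float = 0.99
    over_conversion: float = 0.01
    min_fragment_length: int = 20

    def __post_init__(self) -> None:
        for name in ("breakage_prob", "c_cpg", "c_non_cpg", "over_conversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_fragment_length < 1:
            raise ValueError("min_fragment_length must be >= 1")


def calibrate_breakage(loss_fraction: float, length: int) -> float:
    """Per-bond breakage probability reproducing a given loss at a given length.

    Solves ``1 - (1 - lam)**(length - 1) = loss_fraction`` for ``lam``; a
    fragment of ``length`` bases then has exactly the requested probability
    of sustaining at least one break.

    Parameters
    ----------
    loss_fraction:
        Fraction of fragments of ``length`` bases destroyed (0 < f < 1).
    length:
        Fragment length in bases; must be >= 2 (otherwise there is no
        internal bond to break).
    """
    if not 0.0 < loss_fraction < 1.0:
        raise ValueError(f"loss_fraction must be in (0, 1), got {loss_fraction}")
    if length < 2:
        raise ValueError(f"length must be >= 2 (no internal bond at {length})")
    return 1.0 - (1.0 - loss_fraction) ** (1.0 / (length - 1))


def expected_loss_fraction(lam: float, length: int) -> float:
    """Probability that a fragment of ``length`` bases sustains >= 1 break."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return 1.0 - (1.0 - lam) ** (length - 1)


def simulate_loss_fraction(
    lam: float, length: int, n: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo loss fraction: ``n`` fragments with per-bond Bernoulli breaks."""
    breaks = rng.binomial(length - 1, lam, size=n)
    return float(np.mean(breaks >= 1))
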