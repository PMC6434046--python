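"""Closed-form gel-based indel estimators.

Three pure functions convert band intensities or clone counts from
restriction-digest / mismatch-nuclease assays into an indel fraction:

* :func:`rflp_indels` — bulk restriction fragment length polymorphism.
* :func:`t7ei_indels` — T7 endonuclease I, assuming fully random
  re-annealing of amplicons before digestion.
* :func:`sc_rflp_indels` — single-clone RFLP scoring for a polyploid
  line (defaults assume triploidy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandIntensities",
    "CloneCounts",
    "rflp_indels",
    "t7ei_indels",
    "sc_rflp_indels",
    "sc_rflp_bootstrap_ci",
]


@dataclass(frozen=True)
class BandIntensities:
    """Summed gel band intensities from one RFLP digest lane."""

    cleaved: float
    uncleaved: float

    def __post_init__(self) -> None:
        if self.cleaved < 0 or self.uncleaved < 0:
            raise ValueError("band intensities must be non-negative")
        if self.cleaved + self.uncleaved == 0:
            raise ValueError("total band intensity must be positive")


@dataclass(frozen=True)
class CloneCounts:
    """Digest outcomes over single-cell clones.

    ``fully``   — clones whose amplicon digested completely (unedited on
                  all alleles, for an enzyme cutting the intact site);
    ``partial`` — partially digested clones (a strict subset of alleles
                  edited);
    ``none``    — undigested clones (all alleles edited).
    """

    fully: int
    partial: int
    none: int

    def __post_init__(self) -> None:
        if min(self.fully, self.partial, self.none) < 0:
            raise ValueError("clone counts must be non-negative")
        if self.fully + self.partial + self.none == 0:
            raise ValueError("at least one clone is required")


def rflp_indels(bands: BandIntensities) -> float:
    """Indel fraction from a bulk RFLP digest.

    The enzyme cuts only amplicons still carrying the intact target
    site, so the indel fraction is ``cleaved / (cleaved + uncleaved)``
    when the cleaved bands report edited molecules (the assay is set up
    so that editing *creates* the cut site) — the formula is symmetric
    either way and simply returns the cleaved share of total intensity.
    """
    return bands.cleaved / (bands.cleaved + bands.uncleaved)


def t7ei_indels(fraction_cleaved: float) -> float:
    """Indel fraction from a T7EI assay's fraction cleaved (FC).

    Under completely random re-annealing an amplicon pool with indel
    fraction ``p`` forms heteroduplexes with probability
    ``FC = 1 - (1 - p)**2``; inverting gives ``p = 1 - sqrt(1 - FC)``.
    """
    if not 0.0 <= fraction_cleaved <= 1.0:
        raise ValueError(f"fraction cleaved must be in [0, 1], got {fraction_cleaved}")
    return 1.0 - math.sqrt(1.0 - fraction_cleaved)


def heteroduplex_fraction(indel_fraction: float) -> float:
    """Forward model inverted by :func:`t7ei_indels`: FC(p) = 1 - (1-p)**2."""
    if not 0.0 <= indel_fraction <= 1.0:
        raise ValueError("indel fraction must be in [0, 1]")
    return 1.0 - (1.0 - indel_fraction) ** 2


def sc_rflp_indels(clones: CloneCounts, ploidy: float = 3.0) -> float:
    """Indel fraction from single-clone RFLP digest categories.

    Fully digested clones score ``ploidy`` edited alleles, undigested
    score 0, and partially digested clones score ``ploidy / 2`` (each
    intermediate allele count being equally likely a priori). The
    default ploidy of 3 reflects the near-triploid karyotype of the
    HEK293T line commonly used for such assays.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    total = clones.fully + clones.partial + clones.none
    return (ploidy * clones.fully + (ploidy / 2.0) * clones.partial) / (ploidy * total)


def sc_rflp_bootstrap_ci(
    clones: CloneCounts,
    ploidy: float = 3.0,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for :func:`sc_rflp_indels` over clones."""
    total = clones.fully + clones.partial + clones.none
    p = np.array([clones.fully, clones.partial, clones.none]) / total
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(total, p, size=n_boot)
    scores = (ploidy * draws[:, 0] + (ploidy / 2.0) * draws[:, 1]) / (ploidy * total)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(scores, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
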