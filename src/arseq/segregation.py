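"""Plasmid maintenance under binomial partitioning at cell division.

Each generation every cell replicates its n plasmid copies to 2n and the
copies segregate independently to the two daughters (the tracked daughter
receives Binomial(2n, 1/2) copies).  With selection on (antibiotic
present), plasmid-free cells are removed and the population renormalised
by resampling survivors; with selection off, plasmid-free cells accumulate
— faster for low-copy plasmids, since the single-generation loss
probability 2^(-2n) decays with copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SegregationTrajectory:
    initial_copies: int
    generations: int
    selection_on: bool
    fraction_plasmid_free: np.ndarray  # one entry per generation, 1..G
    seed: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction_plasmid_free, dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        self.fraction_plasmid_free = f


def simulate_segregation(
    initial_copies: int,
    generations: int,
    selection_on: bool,
    n_cells: int = 10_000,
    seed: int = 0,
) -> SegregationTrajectory:
    """Monte-Carlo population of cells dividing with random plasmid partition.

    Returns the fraction of plasmid-free cells after each generation.
    Without selection this fraction is non-decreasing (plasmid-free is an
    absorbing state); with selection it is recorded before the
    plasmid-free cells are purged, modelling growth on selective plates.
    """
    if initial_copies < 0:
        raise ValueError("initial_copies must be >= 0")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    copies = np.full(n_cells, initial_copies, dtype=np.int64)
    fractions = np.empty(generations, dtype=float)
    for g in range(generations):
        copies = rng.binomial(2 * copies, 0.5)
        fractions[g] = np.mean(copies == 0)
        if selection_on:
            alive = copies > 0
            if alive.any():
                # survivors regrow to constant population size
                copies = copies[alive][rng.integers(0, alive.sum(), size=n_cells)]
            # if every cell lost the plasmid the population is extinct;
            # keep the all-zero state so the fraction stays 1
    return SegregationTrajectory(
        initial_copies=initial_copies,
        generations=generations,
        selection_on=selection_on,
        fraction_plasmid_free=fractions,
        seed=seed,
    )
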