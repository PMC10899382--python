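"""Clone libraries and the two-bottleneck enrichment screen.

Stage A is a random fragment library: 1.5–2.5 kbp genomic fragments ligated
into a selectable vector, sampled across replicons in proportion to
per-cell copy weight times replicon length.  Stage B models transformation
into the screening host: clones whose insert fully contains an ARS locus
survive as replicating plasmids, while a configurable background fraction
of non-ARS material persists (chromosomally integrated clones plus genomic
carry-over in the extracted DNA).  Stage C models plasmid re-isolation in a
secondary host: only autonomously replicating (ARS-bearing) clones survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from arseq.genome import GenomeModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryConfig:
    """Fragmentation and bottleneck sizes for the three library stages.

    Defaults mirror the screen scale: 2.5e4 independent clones in the
    initial library, 6.3e3 surviving host transformation, 456 recovered
    after plasmid re-isolation.
    """

    fragment_min: int = 1500
    fragment_max: int = 2500
    n_clones_a: int = 25000
    n_clones_b: int = 6300
    n_clones_c: int = 456
    background_fraction_b: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_min > self.fragment_max:
            raise ValueError("fragment_min > fragment_max")
        if not (self.n_clones_a >= self.n_clones_b >= self.n_clones_c):
            raise ValueError("bottleneck sizes must satisfy n_a >= n_b >= n_c")
        if not (0.0 <= self.background_fraction_b <= 1.0):
            raise ValueError("background_fraction_b must lie in [0, 1]")


@dataclass(frozen=True)
class FragmentClone:
    """One vector-borne genomic fragment.

    Coordinates are 0-based half-open on the circular source replicon;
    ``end`` may exceed the replicon length when the fragment wraps the
    origin (interpret modulo length).
    """

    replicon: str
    start: int
    end: int
    carries_ars: bool
    stage: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CloneLibrary:
    stage: str
    clones: list[FragmentClone]
    genome: GenomeModel = field(repr=False)

    def __post_init__(self) -> None:
        if self.stage not in ("A", "B", "C"):
            raise ValueError(f"unknown stage {self.stage!r}")
        for c in self.clones:
            if c.stage != self.stage:
                raise ValueError("clone stage does not match library stage")

    def __len__(self) -> int:
        return len(self.clones)

    def ars_fraction(self) -> float:
        if not self.clones:
            return 0.0
        return sum(c.carries_ars for c in self.clones) / len(self.clones)


class EmptySelectionError(RuntimeError):
    """Raised when a selection stage has no eligible clones to sample."""


def _contains_ars(genome: GenomeModel, replicon: str, start: int, end: int) -> bool:
    """True iff some ARS locus is fully contained in the (circular) fragment."""
    rep = genome[replicon]
    L = rep.length
    for ars in rep.ars_loci:
        for shift in (0, L):  # ARS viewed on the unrolled circle
            s, e = ars.start + shift, ars.end + shift
            if start <= s and e <= end:
                return True
    return False


def make_library_a(genome: GenomeModel, config: LibraryConfig) -> CloneLibrary:
    """Draw the initial random fragment library (stage A).

    Source replicon is chosen proportional to copy_weight x length (a
    fragment of bulk DNA is more likely to come from an abundant, long
    replicon); fragment length is uniform on [fragment_min, fragment_max]
    and the start uniform on the circle.  Replicons shorter than
    fragment_min are excluded from sampling with a warning.
    """
    if not genome.replicons:
        raise ValueError("empty genome")
    rng = np.random.default_rng(config.seed)
    eligible = [r for r in genome.replicons if r.length >= config.fragment_min]
    for r in genome.replicons:
        if r.length < config.fragment_min:
            logger.warning(
                "replicon %s (%d bp) shorter than fragment_min; excluded from library",
                r.name, r.length,
            )
    if not eligible:
        raise ValueError("no replicon long enough to yield a fragment")
    w = np.array([genome.copy_weights[r.name] * r.length for r in eligible], dtype=float)
    w /= w.sum()
    idx = rng.choice(len(eligible), size=config.n_clones_a, p=w)
    lengths = rng.integers(config.fragment_min, config.fragment_max + 1, size=config.n_clones_a)
    clones = []
    for i, flen in zip(idx, lengths):
        rep = eligible[i]
        flen = int(min(flen, rep.length))  # fragment cannot exceed the replicon
        start = int(rng.integers(0, rep.length))
        end = start + flen
        clones.append(
            FragmentClone(
                replicon=rep.name,
                start=start,
                end=end,
                carries_ars=_contains_ars(genome, rep.name, start, end),
                stage="A",
            )
        )
    return CloneLibrary(stage="A", clones=clones, genome=genome)


def apply_selection(library: CloneLibrary, target_stage: str, config: LibraryConfig) -> CloneLibrary:
    """Pass a library through one selection bottleneck (A->B or B->C).

    A->B: ``n_clones_b`` survivors are drawn as a mixture — a
    ``background_fraction_b`` share comes from non-ARS clones (chromosomal
    integration and genomic carry-over), the rest from ARS-bearing clones
    that replicate as plasmids.  B->C: ``n_clones_c`` clones are drawn
    exclusively from ARS-bearing survivors (plasmid re-isolation).
    """
    transitions = {("A", "B"), ("B", "C")}
    if (library.stage, target_stage) not in transitions:
        raise ValueError(f"illegal stage transition {library.stage}->{target_stage}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, ord(target_stage)]))

    if target_stage == "B":
        n_out = config.n_clones_b
        ars = np.array([i for i, c in enumerate(library.clones) if c.carries_ars])
        non = np.array([i for i, c in enumerate(library.clones) if not c.carries_ars])
        n_bg = int(round(n_out * config.background_fraction_b)) if non.size else 0
        if ars.size == 0:
            n_bg = n_out
        if (n_out - n_bg > 0 and ars.size == 0) or (n_bg > 0 and non.size == 0):
            raise EmptySelectionError("no clone can survive host transformation")
        idx = np.concatenate([
            rng.choice(non, size=n_bg) if n_bg else np.array([], dtype=int),
            rng.choice(ars, size=n_out - n_bg) if n_out - n_bg else np.array([], dtype=int),
        ])
        rng.shuffle(idx)
    else:
        n_out = config.n_clones_c
        ars_idx = np.array([i for i, c in enumerate(library.clones) if c.carries_ars])
        if ars_idx.size == 0 and n_out > 0:
            raise EmptySelectionError("no ARS-bearing clone available for plasmid re-isolation")
        idx = rng.choice(ars_idx, size=n_out) if n_out else np.array([], dtype=int)

    clones = [replace(library.clones[i], stage=target_stage) for i in idx]
    return CloneLibrary(stage=target_stage, clones=clones, genome=library.genome)
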