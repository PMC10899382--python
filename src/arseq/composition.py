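"""Per-replicon read composition and per-base coverage tracks.

Composition counts concordantly mapped *pairs* per replicon and reports
percentages over the counted pairs.  Under the ``exclude_multimapped``
policy, pairs in which either mate has several co-optimal placements are
dropped from numerator and denominator (the non-specific reads ignored in
the composition view); under ``include_all`` every concordant pair counts
with weight 1/n_hits per placement so percentages still sum to 100.

Coverage tracks count every aligned mate interval (paired or not), so the
multi-mapping view of a duplicated plasmid segment is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from arseq.genome import GenomeModel
from arseq.mapping import AlignmentTable

POLICIES = ("exclude_multimapped", "include_all")


class EmptyCompositionError(RuntimeError):
    """No counted pairs under the requested policy."""


@dataclass
class CompositionTable:
    library_stage: str
    policy: str
    table: pd.DataFrame  # columns: replicon, mapped_pairs, percent

    def percent(self, replicon: str) -> float:
        row = self.table[self.table.replicon == replicon]
        return float(row.percent.iloc[0]) if len(row) else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stage={self.library_stage} policy={self.policy}\n")
            self.table.to_csv(fh, sep="\t", index=False)


@dataclass
class CoverageTrack:
    replicon: str
    depth: np.ndarray
    policy: str

    def mean_depth(self, start: int | None = None, end: int | None = None) -> float:
        return float(self.depth[slice(start, end)].mean())


def compute_composition(
    alignments: AlignmentTable,
    genome: GenomeModel,
    policy: str = "exclude_multimapped",
    stage: str = "?",
) -> CompositionTable:
    """Per-replicon composition of concordantly mapped pairs."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    pairs = alignments.pairs
    conc = pairs[pairs["concordant"].astype(bool)]
    if policy == "exclude_multimapped":
        counted = conc[~conc["multi_mapped"].astype(bool)]
        if len(counted) == 0:
            raise EmptyCompositionError(f"no counted pairs for stage {stage} ({policy})")
        counts = counted.groupby("replicon").size().astype(float)
    else:
        # each concordant pair spreads unit weight over its co-optimal
        # concordant placements, so the percentages remain conservative
        pl = alignments.pair_placements
        if len(pl) == 0:
            raise EmptyCompositionError(f"no counted pairs for stage {stage} ({policy})")
        counts = pl.groupby("replicon").weight.sum()
    rows = []
    total = counts.sum()
    for rep in genome.names:
        c = float(counts.get(rep, 0.0))
        rows.append((rep, c, 100.0 * c / total))
    return CompositionTable(
        library_stage=stage,
        policy=policy,
        table=pd.DataFrame(rows, columns=["replicon", "mapped_pairs", "percent"]),
    )


def compute_coverage(
    alignments: AlignmentTable,
    genome: GenomeModel,
    policy: str = "include_all",
) -> dict[str, CoverageTrack]:
    """Per-base depth per replicon from every aligned mate interval.

    ``include_all`` stacks all co-optimal placements of multi-mapped
    mates; ``exclude_multimapped`` keeps only uniquely placed mates.
    Intervals wrapping the circular origin contribute to both ends.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    recs = alignments.records
    if policy == "exclude_multimapped":
        recs = recs[recs.n_hits == 1]
    tracks = {}
    for rep in genome.replicons:
        depth = np.zeros(rep.length, dtype=np.int64)
        sub = recs[recs.replicon == rep.name]
        # difference-array accumulation, unrolling circular wrap
        diff = np.zeros(rep.length + 1, dtype=np.int64)
        for s, e in zip(sub.start.to_numpy(), sub.end.to_numpy()):
            if e <= rep.length:
                diff[s] += 1
                diff[e] -= 1
            else:
                diff[s] += 1
                diff[rep.length] -= 1
                diff[0] += 1
                diff[e - rep.length] -= 1
        depth = np.cumsum(diff[:-1])
        tracks[rep.name] = CoverageTrack(replicon=rep.name, depth=depth, policy=policy)
    return tracks


def write_bedgraph(track: CoverageTrack, path) -> None:
    """bedGraph with 0-based half-open intervals, runs of equal depth merged."""
    d = track.depth
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.replicon}"\n')
        if d.size == 0:
            return
        boundaries = np.nonzero(np.diff(d))[0] + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [d.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{track.replicon}\t{s}\t{e}\t{int(d[s])}\n")
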