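"""Candidate autonomous-replication regions from selected-vs-input coverage.

The screen enriches ARS-containing fragments, so regions required for
autonomous replication stand out as windows where the selected library's
(C) coverage exceeds the input library's (A) after depth normalisation.
Windows are scored as log2 ratios of per-million-normalised depth with a
pseudocount; runs of high-scoring windows are merged and reported only if
they contain at least one ORF fully covered in the selected library —
operationalising "a full-length gene present in the surviving clones".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from arseq.composition import CoverageTrack
from arseq.genome import Orf


@dataclass
class EnrichmentProfile:
    replicon: str
    window: int
    scores: np.ndarray  # log2((covC_norm + eps) / (covA_norm + eps)) per window
    epsilon: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite enrichment score")


@dataclass
class ArsCandidate:
    replicon: str
    start: int
    end: int
    mean_enrichment: float
    covered_orfs: list[str]
    fully_covered: bool = True


def enrichment_profile(
    covC: CoverageTrack,
    covA: CoverageTrack,
    window: int = 200,
    epsilon: float = 1.0,
) -> EnrichmentProfile:
    """Windowed log2 enrichment of selected over input coverage.

    Both tracks are normalised to depth per million aligned bases of
    their own library before comparison, so library size cancels;
    ``epsilon`` (in normalised depth units) keeps zero/zero windows at
    score 0.  The last window may be short.
    """
    if covC.replicon != covA.replicon:
        raise ValueError("coverage tracks come from different replicons")
    if len(covC.depth) != len(covA.depth):
        raise ValueError("track length mismatch")

    def norm(track: CoverageTrack) -> np.ndarray:
        total = track.depth.sum()
        if total == 0:
            return track.depth.astype(float)
        return track.depth * (1e6 / total)

    c, a = norm(covC), norm(covA)
    L = len(c)
    n_win = (L + window - 1) // window
    scores = np.empty(n_win)
    for i in range(n_win):
        sl = slice(i * window, min((i + 1) * window, L))
        scores[i] = np.log2((c[sl].mean() + epsilon) / (a[sl].mean() + epsilon))
    return EnrichmentProfile(replicon=covC.replicon, window=window,
                             scores=scores, epsilon=epsilon)


def call_candidates(
    profile: EnrichmentProfile,
    covC: CoverageTrack,
    orfs: list[Orf],
    min_depth: int = 5,
    threshold: float = 2.0,
    gap_windows: int = 1,
) -> list[ArsCandidate]:
    """Merge enriched windows into regions and keep those with a fully
    covered ORF.

    Maximal runs of windows scoring >= ``threshold`` are merged, tolerating
    gaps of up to ``gap_windows`` sub-threshold windows.  A merged region
    is reported only with the ORFs lying inside it whose every base has
    selected-library depth >= ``min_depth``; regions without such an ORF
    are dropped.
    """
    if covC.replicon != profile.replicon:
        raise ValueError("profile/coverage replicon mismatch")
    w = profile.window
    L = len(covC.depth)
    hot = np.nonzero(profile.scores >= threshold)[0]
    if hot.size == 0:
        return []
    # merge hot windows allowing small gaps
    runs: list[list[int]] = [[int(hot[0]), int(hot[0])]]
    for i in hot[1:]:
        if i - runs[-1][1] <= gap_windows + 1:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    out = []
    for a, b in runs:
        start, end = a * w, min((b + 1) * w, L)
        covered = [
            orf.id
            for orf in orfs
            if orf.start < end and orf.end > start  # ORF overlaps the region
            and np.all(covC.depth[orf.start:orf.end] >= min_depth)
        ]
        if not covered:
            continue
        out.append(
            ArsCandidate(
                replicon=profile.replicon,
                start=start,
                end=end,
                mean_enrichment=float(profile.scores[a:b + 1].mean()),
                covered_orfs=covered,
            )
        )
    return out


def write_candidates_bed(candidates: list[ArsCandidate], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates):
            name = f"ars_candidate_{i + 1}:{','.join(c.covered_orfs)}"
            fh.write(f"{c.replicon}\t{c.start}\t{c.end}\t{name}\t"
                     f"{c.mean_enrichment:.3f}\n")


def write_candidates_gff3(candidates: list[ArsCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(candidates):
            fh.write(
                f"{c.replicon}\tarseq\tregion\t{c.start + 1}\t{c.end}\t"
                f"{c.mean_enrichment:.3f}\t.\t.\t"
                f"ID=ars_candidate_{i + 1};orfs={','.join(c.covered_orfs)}\n"
            )
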