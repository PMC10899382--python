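"""Self-contained paired-end read mapper with identity/length filters.

Mapping semantics follow a reference-assembly style scoring scheme: match
score 1, mismatch cost 2, indel cost 3, and two read-level filters — at
least a fraction 0.8 of the read aligned (length fraction) and at least
0.9 identity over aligned columns (similarity fraction).  Alignment is
end-to-end on the read (no soft clipping), so the filters are defined on
the whole read.  All co-optimal placements are reported; reads with more
than one equally scoring placement are the multi-mapped reads that
downstream composition can exclude.

References are circular: k-mers spanning the origin are indexed via a
k-1 base wraparound extension and alignments crossing the origin are
reported modulo the replicon length (``end`` may exceed it).

The mapper is seed-and-extend: exact k-mer seeds at non-overlapping read
offsets locate candidate diagonals (pigeonhole: a read with fewer than
floor(len/k) substitutions always retains an exact seed); candidates are
scored by gapless comparison first, with banded dynamic programming as a
fallback when gapless alignment cannot reach the similarity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arseq.genome import GenomeModel, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappingParams:
    match_score: int = 1
    mismatch_cost: int = 2
    indel_cost: int = 3
    length_fraction: float = 0.8
    similarity_fraction: float = 0.9
    kmer_size: int = 15
    max_hits: int = 10
    band: int = 8  # half-width of the DP band in the gapped fallback

    def __post_init__(self) -> None:
        if not (0 < self.length_fraction <= 1 and 0 < self.similarity_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.kmer_size < 8:
            raise ValueError("kmer_size must be >= 8")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    replicon: str
    start: int  # 0-based, in [0, replicon length)
    end: int    # exclusive; > replicon length when the alignment wraps
    strand: str
    aligned_fraction: float
    identity: float
    n_hits: int
    mate_index: int
    score: int


@dataclass
class ReferenceIndex:
    genome: GenomeModel
    kmer_size: int
    table: dict[str, list[tuple[int, int]]] = field(repr=False)  # kmer -> [(rep_idx, pos)]

    @property
    def replicon_names(self) -> list[str]:
        return self.genome.names


def index_reference(genome: GenomeModel, params: MappingParams) -> ReferenceIndex:
    """Build the exact k-mer position table over all replicons.

    Every position 0..L-1 of each circular replicon contributes one k-mer
    (the last k-1 wrap the origin).  Replicons shorter than k are skipped
    with a warning.
    """
    if not genome.replicons:
        raise ValueError("empty genome")
    k = params.kmer_size
    table: dict[str, list[tuple[int, int]]] = {}
    for ri, rep in enumerate(genome.replicons):
        if rep.length < k:
            logger.warning("replicon %s shorter than k=%d; not indexed", rep.name, k)
            continue
        ext = rep.sequence + rep.sequence[:k - 1]
        for pos in range(rep.length):
            table.setdefault(ext[pos:pos + k], []).append((ri, pos))
    return ReferenceIndex(genome=genome, kmer_size=k, table=table)


def _gapless(query: np.ndarray, ref: np.ndarray, params: MappingParams) -> tuple[int, int]:
    """(score, matches) of the end-to-end gapless alignment of equal-length arrays."""
    m = int(np.count_nonzero(query == ref))
    mm = query.size - m
    return params.match_score * m - params.mismatch_cost * mm, m


def glocal_align(query: str, window: str, params: MappingParams) -> tuple[int, int, int, int, int]:
    """Best fit alignment of the full query inside ``window``.

    Global on the query, free start/end on the window.  Returns
    (score, ref_start, ref_end, matches, aligned_query_bases) for the
    highest-scoring alignment; ties resolved toward the smallest ref_end
    and, in the traceback, toward the diagonal.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    n, m = q.size, w.size
    NEG = -10**9
    # score[i, j]: best score of q[:i] aligned ending at window position j (exclusive)
    score = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    score[0, :] = 0  # free start in the window
    for i in range(1, n + 1):
        sub = np.where(w == q[i - 1], params.match_score, -params.mismatch_cost)
        diag = score[i - 1, :-1] + sub
        up = score[i - 1, 1:] - params.indel_cost  # query base inserted (not on ref)
        best = np.maximum(diag, up)
        # left moves (deletion on the query / gap consuming window base)
        row = score[i]
        row[1:] = best
        row[0] = score[i - 1, 0] - params.indel_cost
        # in-row prefix scan for left gaps
        for j in range(1, m + 1):
            if row[j - 1] - params.indel_cost > row[j]:
                row[j] = row[j - 1] - params.indel_cost
    j_end = int(np.argmax(score[n]))
    best_score = int(score[n, j_end])
    # traceback to recover matches / aligned query bases / ref_start
    i, j = n, j_end
    matches = 0
    aligned_q = 0
    while i > 0:
        if j > 0 and score[i, j] == score[i, j - 1] - params.indel_cost:
            j -= 1
        elif j > 0 and score[i, j] == score[i - 1, j - 1] + (
            params.match_score if w[j - 1] == q[i - 1] else -params.mismatch_cost
        ):
            matches += int(w[j - 1] == q[i - 1])
            aligned_q += 1
            i -= 1
            j -= 1
        else:
            i -= 1  # query base against a gap
    return best_score, j, j_end, matches, aligned_q


def map_read(seq: str, index: ReferenceIndex, params: MappingParams,
             read_id: str = "", mate_index: int = 1) -> list[AlignmentRecord]:
    """Map one read; return all co-optimal placements passing the filters."""
    k = index.kmer_size
    n = len(seq)
    if n < k:
        raise ValueError("read shorter than k")
    genome = index.genome
    qf = np.frombuffer(seq.encode(), dtype=np.uint8)
    qr_str = revcomp(seq)
    qr = np.frombuffer(qr_str.encode(), dtype=np.uint8)

    candidates: set[tuple[int, int, str]] = set()  # (rep_idx, start, strand)
    n_seeds = max(1, n // k)
    offsets = [i * k for i in range(n_seeds)]
    for strand, query in (("+", seq), ("-", qr_str)):
        for off in offsets:
            for ri, pos in index.table.get(query[off:off + k], ()):
                L = genome.replicons[ri].length
                candidates.add((ri, (pos - off) % L, strand))

    def passes(matches: int, aligned_cols: int, aligned_q: int) -> bool:
        if aligned_cols == 0:
            return False
        return (aligned_q / n >= params.length_fraction
                and matches / aligned_cols >= params.similarity_fraction)

    # gapless scoring of every candidate diagonal
    # tuples: (score, rep_idx, start, end, strand, matches, aligned_cols, aligned_q)
    scored: list[tuple[int, int, int, int, str, int, int, int]] = []
    for ri, start, strand in candidates:
        rep = genome.replicons[ri]
        ref = np.frombuffer(
            genome.fetch(rep.name, start, start + n).encode(), dtype=np.uint8
        )
        q = qf if strand == "+" else qr
        s, m = _gapless(q, ref, params)
        scored.append((s, ri, start, start + n, strand, m, n, n))

    best_pass = [t for t in scored if passes(t[5], t[6], t[7])]
    if not best_pass and candidates:
        # gapped fallback: banded DP around each candidate diagonal
        pad = params.band
        gapped = []
        for ri, start, strand in candidates:
            rep = genome.replicons[ri]
            wstart = (start - pad) % rep.length
            window = genome.fetch(rep.name, wstart, wstart + n + 2 * pad)
            query = seq if strand == "+" else qr_str
            s, ws, we, m, aq = glocal_align(query, window, params)
            a_start = (wstart + ws) % rep.length
            a_end = a_start + (we - ws)
            cols = n + (we - ws) - aq  # diag + insertions + deletions
            if passes(m, cols, aq):
                gapped.append((s, ri, a_start, a_end, strand, m, cols, aq))
        best_pass = gapped

    if not best_pass:
        return []
    top = max(t[0] for t in best_pass)
    winners = sorted(
        (t for t in best_pass if t[0] == top),
        key=lambda t: (t[1], t[2], t[4]),
    )
    n_hits = len(winners)
    out = []
    for s, ri, start, end, strand, m, cols, aq in winners[:params.max_hits]:
        out.append(
            AlignmentRecord(
                read_id=read_id,
                replicon=genome.replicons[ri].name,
                start=start,
                end=end,
                strand=strand,
                aligned_fraction=aq / n,
                identity=m / cols,
                n_hits=n_hits,
                mate_index=mate_index,
                score=s,
            )
        )
    return out


@dataclass
class AlignmentTable:
    """Per-record alignments plus the per-pair summary and run statistics.

    ``pair_placements`` carries one row per co-optimal concordant
    placement of each concordant pair with a fractional weight (1/number
    of co-optimal placements), enabling conservation-preserving
    composition under the include_all policy.
    """

    records: pd.DataFrame
    pairs: pd.DataFrame
    pair_placements: pd.DataFrame
    stats: dict

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# arseq alignment table; coordinates 0-based half-open\n")
            self.records.to_csv(fh, sep="\t", index=False)

    def save(self, directory) -> None:
        """Write records/pairs/placements TSVs and stats JSON to a directory."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(d / "records.tsv", sep="\t", index=False)
        self.pairs.to_csv(d / "pairs.tsv", sep="\t", index=False)
        self.pair_placements.to_csv(d / "placements.tsv", sep="\t", index=False)
        with open(d / "stats.json", "w") as fh:
            json.dump(self.stats, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "AlignmentTable":
        import json
        from pathlib import Path

        d = Path(directory)
        records = pd.read_csv(d / "records.tsv", sep="\t")
        pairs = pd.read_csv(d / "pairs.tsv", sep="\t")
        placements = pd.read_csv(d / "placements.tsv", sep="\t")
        with open(d / "stats.json") as fh:
            stats = json.load(fh)
        return cls(records=records, pairs=pairs,
                   pair_placements=placements, stats=stats)


_RECORD_COLS = ["read_id", "mate", "replicon", "start", "end", "strand",
                "aligned_fraction", "identity", "n_hits", "score"]
_PAIR_COLS = ["read_id", "mapped", "concordant", "multi_mapped", "replicon",
              "insert_start", "insert_end"]


def _concordant_insert(a: AlignmentRecord, b: AlignmentRecord, L: int) -> int | None:
    """Implied insert length for a (+,-) oriented placement pair on a circle."""
    fwd, rev = (a, b) if a.strand == "+" else (b, a)
    ins = (rev.end - fwd.start) % L
    if ins == 0:
        ins = L
    return ins


def map_library(
    reads,
    index: ReferenceIndex,
    params: MappingParams,
    insert_sd_factor: float = 4.0,
) -> AlignmentTable:
    """Map both mates of every pair and classify pairs.

    A pair is concordant when some placement of mate 1 and mate 2 lies on
    the same replicon, on opposite strands, with implied insert length
    within insert_mean +/- ``insert_sd_factor`` * insert_sd (taken from the
    read set's simulation metadata).  A pair is multi-mapped when either
    mate has more than one co-optimal placement.
    """
    lo = reads.insert_mean - insert_sd_factor * reads.insert_sd
    hi = reads.insert_mean + insert_sd_factor * reads.insert_sd
    rec_rows: list[tuple] = []
    pair_rows: list[tuple] = []
    placement_rows: list[tuple] = []
    genome = index.genome
    lengths = {r.name: r.length for r in genome.replicons}
    n_mapped = n_conc = n_multi = 0
    for pair in reads.pairs:
        recs1 = map_read(pair.seq1, index, params, read_id=pair.id, mate_index=1)
        recs2 = map_read(pair.seq2, index, params, read_id=pair.id, mate_index=2)
        for r in recs1 + recs2:
            rec_rows.append((r.read_id, r.mate_index, r.replicon, r.start, r.end,
                             r.strand, r.aligned_fraction, r.identity, r.n_hits, r.score))
        mapped = bool(recs1) and bool(recs2)
        multi = any(r.n_hits > 1 for r in recs1 + recs2)
        combos: list[tuple[int, AlignmentRecord, AlignmentRecord]] = []
        for r1 in recs1:
            for r2 in recs2:
                if r1.replicon != r2.replicon or r1.strand == r2.strand:
                    continue
                ins = _concordant_insert(r1, r2, lengths[r1.replicon])
                if lo <= ins <= hi:
                    combos.append((r1.score + r2.score, r1, r2))
        if combos:
            top = max(c[0] for c in combos)
            winners = [c for c in combos if c[0] == top]
            _, r1, r2 = winners[0]
            fwd = r1 if r1.strand == "+" else r2
            ins = _concordant_insert(r1, r2, lengths[r1.replicon])
            pair_rows.append((pair.id, True, True, multi, r1.replicon,
                              fwd.start, fwd.start + ins))
            w = 1.0 / len(winners)
            for _, w1, _w2 in winners:
                placement_rows.append((pair.id, w1.replicon, w))
            n_conc += 1
        else:
            pair_rows.append((pair.id, mapped, False, multi, None, -1, -1))
        n_mapped += mapped
        n_multi += multi
    records = pd.DataFrame(rec_rows, columns=_RECORD_COLS)
    pairs = pd.DataFrame(pair_rows, columns=_PAIR_COLS)
    placements = pd.DataFrame(placement_rows, columns=["read_id", "replicon", "weight"])
    stats = {
        "total_pairs": len(reads.pairs),
        "mapped_pairs": int(n_mapped),
        "concordant_pairs": int(n_conc),
        "multi_mapped_pairs": int(n_multi),
    }
    return AlignmentTable(records=records, pairs=pairs,
                          pair_placements=placements, stats=stats)
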