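"""Paired-end read simulation from clone libraries.

Reads come from the genomic insert only — the vector backbone is not
emitted, matching an analysis in which backbone reads are never mapped to
the reference.  Inserts are placed uniformly within a clone's fragment
(truncated-normal length), mate 2 is reverse-complemented, and per-base
substitution errors are applied at a configurable rate.  Truth records
(source clone and coordinates) are retained for mapper validation.
Qualities are a fixed character since downstream mapping is sequence-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from arseq.genome import revcomp
from arseq.library import CloneLibrary

_QUAL_CHAR = "I"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class ReadTruth:
    """Source of a read pair: clone and 0-based genome coordinates.

    ``insert_start``/``insert_end`` are on the unrolled circle of the
    source replicon (may exceed its length when wrapping the origin).
    """

    replicon: str
    insert_start: int
    insert_end: int
    clone_index: int
    mate1_start: int  # leftmost base of mate1 on the forward strand
    mate2_start: int  # leftmost base of mate2 on the forward strand


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str
    truth: ReadTruth


@dataclass
class ReadPairSet:
    pairs: list[ReadPair]
    read_length: int
    substitution_rate: float
    insert_mean: float
    insert_sd: float
    seed: int
    stage: str = "?"

    def __len__(self) -> int:
        return len(self.pairs)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply iid substitutions; the substituted base is one of the 3 others."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        cur = _BASE_INDEX[arr[hits]]
        shift = rng.integers(1, 4, size=hits.size)
        arr[hits] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def simulate_reads(
    library: CloneLibrary,
    n_pairs: int,
    read_length: int = 150,
    substitution_rate: float = 0.001,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    seed: int = 0,
) -> ReadPairSet:
    """Simulate paired-end reads from a clone library.

    Clones are sampled uniformly; the insert length is drawn from
    N(insert_mean, insert_sd) rounded and clipped to
    [read_length, fragment length], its position uniform within the
    fragment.  Mate 1 reads the insert 5' end on the forward strand of the
    fragment; mate 2 reads the 3' end reverse-complemented.
    """
    if read_length > min((c.length for c in library.clones), default=read_length):
        raise ValueError("read_length exceeds shortest fragment")
    if insert_mean < read_length:
        raise ValueError("insert_mean must be >= read_length")
    rng = np.random.default_rng(seed)
    genome = library.genome
    pairs: list[ReadPair] = []
    if n_pairs and not library.clones:
        raise ValueError("cannot simulate reads from an empty library")
    clone_idx = rng.integers(0, max(len(library.clones), 1), size=n_pairs)
    for i in range(n_pairs):
        ci = int(clone_idx[i])
        clone = library.clones[ci]
        flen = clone.length
        ins = int(np.rint(rng.normal(insert_mean, insert_sd)))
        ins = max(read_length, min(ins, flen))
        offset = int(rng.integers(0, flen - ins + 1))
        istart = clone.start + offset
        iend = istart + ins
        insert_seq = genome.fetch(clone.replicon, istart, iend)
        m1 = insert_seq[:read_length]
        m2 = revcomp(insert_seq[-read_length:])
        pairs.append(
            ReadPair(
                id=f"{library.stage}:{i}",
                seq1=_mutate(rng, m1, substitution_rate),
                seq2=_mutate(rng, m2, substitution_rate),
                truth=ReadTruth(
                    replicon=clone.replicon,
                    insert_start=istart,
                    insert_end=iend,
                    clone_index=ci,
                    mate1_start=istart,
                    mate2_start=iend - read_length,
                ),
            )
        )
    return ReadPairSet(
        pairs=pairs,
        read_length=read_length,
        substitution_rate=substitution_rate,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        seed=seed,
        stage=library.stage,
    )


def write_fastq(reads: ReadPairSet, path1: str | Path, path2: str | Path) -> None:
    qual = _QUAL_CHAR * reads.read_length
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in reads.pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{qual}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{qual}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[str, str, str]]:
    """Load mate sequences from a FASTQ pair as (id, seq1, seq2) tuples."""
    from Bio import SeqIO

    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("mate files differ in record count")
    out = []
    for a, b in zip(r1, r2):
        rid = a.id.rsplit("/", 1)[0]
        out.append((rid, str(a.seq), str(b.seq)))
    return out


def write_truth_json(reads: ReadPairSet, path: str | Path) -> None:
    import json

    payload = {
        "read_length": reads.read_length,
        "substitution_rate": reads.substitution_rate,
        "insert_mean": reads.insert_mean,
        "insert_sd": reads.insert_sd,
        "seed": reads.seed,
        "stage": reads.stage,
        "pairs": [
            {
                "id": p.id,
                "replicon": p.truth.replicon,
                "insert_start": p.truth.insert_start,
                "insert_end": p.truth.insert_end,
                "clone_index": p.truth.clone_index,
            }
            for p in reads.pairs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
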