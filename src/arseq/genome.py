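"""Synthetic multi-replicon genomes with designated ARS loci.

A genome here is a set of circular replicons (one chromosome plus plasmids),
each carrying annotated ORFs, zero or more autonomous-replication (ARS)
loci — intervals whose full inclusion in a cloned fragment confers
replication in the screening host — and optional byte-identical internal
duplications modelling tandem repeated plasmid segments that cause
read multi-mapping.

All intervals are 0-based, half-open.  Sequences are random under a fixed
seed, with duplications applied by copying the source bytes verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMPLEMENT[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMPLEMENT[arr][::-1].tobytes().decode()


@dataclass(frozen=True)
class Orf:
    id: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class ArsLocus:
    id: str
    start: int
    end: int


@dataclass(frozen=True)
class Duplication:
    """Segment [src_start, src_end) copied verbatim to dst_start."""

    src_start: int
    src_end: int
    dst_start: int

    @property
    def length(self) -> int:
        return self.src_end - self.src_start


@dataclass
class RepliconSpec:
    """One circular replicon: sequence, ORFs, ARS loci, duplications."""

    name: str
    length: int
    sequence: str
    is_chromosome: bool = False
    orfs: list[Orf] = field(default_factory=list)
    ars_loci: list[ArsLocus] = field(default_factory=list)
    duplications: list[Duplication] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != declared {self.length}"
            )
        for iv in [*self.orfs, *self.ars_loci]:
            if not (0 <= iv.start < iv.end <= self.length):
                raise ValueError(f"{self.name}: interval {iv} outside [0, {self.length})")
        for d in self.duplications:
            if not (0 <= d.src_start < d.src_end <= self.length):
                raise ValueError(f"{self.name}: duplication source {d} out of range")
            if not (0 <= d.dst_start and d.dst_start + d.length <= self.length):
                raise ValueError(f"{self.name}: duplication destination {d} out of range")
            src = self.sequence[d.src_start:d.src_end]
            dst = self.sequence[d.dst_start:d.dst_start + d.length]
            if src != dst:
                raise ValueError(f"{self.name}: duplication {d} not byte-identical")


@dataclass
class GenomeModel:
    """A set of uniquely named circular replicons with per-cell copy weights."""

    replicons: list[RepliconSpec]
    copy_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            raise ValueError("replicon names must be unique")
        if not self.copy_weights:
            self.copy_weights = {n: 1.0 for n in names}
        for n in names:
            w = self.copy_weights.get(n)
            if w is None or w <= 0:
                raise ValueError(f"copy weight for {n} must be strictly positive")

    def __getitem__(self, name: str) -> RepliconSpec:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.replicons]

    def fetch(self, replicon: str, start: int, end: int) -> str:
        """Sequence of the (possibly origin-wrapping) interval [start, end).

        ``end`` may exceed the replicon length; coordinates are taken modulo
        the length, so a fragment spanning the circular origin is returned
        contiguously.
        """
        rep = self[replicon]
        L = rep.length
        span = end - start
        if span < 0 or span > L:
            raise ValueError("interval longer than replicon or inverted")
        start %= L
        end = start + span
        if end <= L:
            return rep.sequence[start:end]
        return rep.sequence[start:] + rep.sequence[:end - L]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=length)]


def build_genome(spec: list[dict], seed: int) -> GenomeModel:
    """Build a genome from replicon descriptors with random sequences.

    Each descriptor is a mapping with keys ``name``, ``length``, and
    optionally ``is_chromosome``, ``copy_weight``, ``orfs`` (list of
    ``(id, start, end, strand)``), ``ars_loci`` (list of ``(id, start,
    end)``) and ``duplications`` (list of ``(src_start, src_end,
    dst_start)``).  Sequences are uniform random ACGT under the seed;
    duplications are then applied by copying source bytes, so the
    destination segment is byte-identical to its source.

    Overlapping duplication source/destination intervals are rejected, as
    are ARS/ORF intervals that leave the replicon.
    """
    rng = np.random.default_rng(seed)
    replicons = []
    weights: dict[str, float] = {}
    for d in spec:
        name = d["name"]
        length = int(d["length"])
        arr = _random_sequence(rng, length)
        dups = [Duplication(*t) for t in d.get("duplications", [])]
        for dup in dups:
            if dup.length <= 0:
                raise ValueError(f"{name}: empty duplication {dup}")
            src = range(dup.src_start, dup.src_end)
            dst = range(dup.dst_start, dup.dst_start + dup.length)
            if max(src.start, dst.start) < min(src.stop, dst.stop):
                raise ValueError(f"{name}: duplication source and destination overlap")
            arr[dst.start:dst.stop] = arr[src.start:src.stop]
        replicons.append(
            RepliconSpec(
                name=name,
                length=length,
                sequence=arr.tobytes().decode(),
                is_chromosome=bool(d.get("is_chromosome", False)),
                orfs=[Orf(*t) for t in d.get("orfs", [])],
                ars_loci=[ArsLocus(*t) for t in d.get("ars_loci", [])],
                duplications=dups,
            )
        )
        weights[name] = float(d.get("copy_weight", 1.0))
    return GenomeModel(replicons=replicons, copy_weights=weights)


# ---------------------------------------------------------------------------
# serialization

def write_fasta(genome: GenomeModel, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in genome.replicons:
            fh.write(f">{rep.name} length={rep.length} circular=true\n")
            for i in range(0, rep.length, width):
                fh.write(rep.sequence[i:i + width] + "\n")


def write_gff3(genome: GenomeModel, path: str | Path) -> None:
    """ORF annotations as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.name} 1 {rep.length}\n")
        for rep in genome.replicons:
            for orf in rep.orfs:
                fh.write(
                    f"{rep.name}\tarseq\tgene\t{orf.start + 1}\t{orf.end}\t.\t"
                    f"{orf.strand}\t.\tID={orf.id}\n"
                )


def write_ars_bed(genome: GenomeModel, path: str | Path) -> None:
    """ARS loci as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for rep in genome.replicons:
            for ars in rep.ars_loci:
                fh.write(f"{rep.name}\t{ars.start}\t{ars.end}\t{ars.id}\n")


def read_fasta(path: str | Path) -> GenomeModel:
    """Load a reference genome from FASTA (annotations not recovered)."""
    from Bio import SeqIO

    replicons = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        replicons.append(RepliconSpec(name=rec.id, length=len(seq), sequence=seq))
    if not replicons:
        raise ValueError(f"no sequences in {path}")
    return GenomeModel(replicons=replicons)


def read_orfs_gff3(path: str | Path) -> dict[str, list[Orf]]:
    """ORFs per replicon from a GFF3 file (1-based closed -> 0-based half-open)."""
    out: dict[str, list[Orf]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            oid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            out.setdefault(f[0], []).append(Orf(oid, int(f[3]) - 1, int(f[4]), f[6]))
    return out
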