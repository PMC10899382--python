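"""End-to-end in-silico screen: simulate -> map -> compose -> call ARS.

A single global seed fans out to per-stage seeds through a deterministic
derivation (SHA-256 of the stage name folded into numpy SeedSequence
entropy), so any stage can be re-run independently and seeded runs are
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from arseq import __version__
from arseq.genome import GenomeModel, build_genome, write_fasta, write_gff3, write_ars_bed
from arseq.library import LibraryConfig, make_library_a, apply_selection, EmptySelectionError
from arseq.reads import simulate_reads, write_fastq, write_truth_json
from arseq.mapping import MappingParams, index_reference, map_library
from arseq.composition import compute_composition, compute_coverage, write_bedgraph
from arseq.ars_caller import enrichment_profile, call_candidates, write_candidates_bed

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


DEFAULT_GENOME_SPEC = [
    {"name": "chromosome", "length": 60_000, "is_chromosome": True, "copy_weight": 1.0,
     "orfs": [("chr_orf1", 10_000, 11_200, "+"), ("chr_orf2", 30_000, 31_500, "-")]},
    {"name": "plasmid_P", "length": 15_000, "copy_weight": 3.0,
     "orfs": [("repX", 5_200, 6_100, "+"), ("pP_orf2", 9_000, 9_900, "+")],
     "ars_loci": [("ars1", 5_000, 6_300)]},
    {"name": "plasmid_Q", "length": 10_000, "copy_weight": 2.0,
     "orfs": [("pQ_orf1", 2_000, 2_900, "+")]},
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; CLI flags override file values."""

    outdir: str = "arseq_run"
    seed: int = 0
    genome_spec: list = field(default_factory=lambda: [dict(d) for d in DEFAULT_GENOME_SPEC])
    library: LibraryConfig = field(default_factory=LibraryConfig)
    mapping: MappingParams = field(default_factory=MappingParams)
    n_pairs_per_stage: int = 2000
    read_length: int = 150
    substitution_rate: float = 0.001
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    window: int = 200
    threshold: float = 2.0
    min_depth: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        lib = LibraryConfig(**raw.pop("library", {}))
        mp = MappingParams(**raw.pop("mapping", {}))
        return cls(library=lib, mapping=mp, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in self.__dict__.items()
                if k not in ("library", "mapping", "outdir")},
             "library": asdict(self.library), "mapping": asdict(self.mapping)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# arseq {__version__} config={cfg.config_hash()} seed={cfg.seed}\n"


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full in-silico screen; returns the machine-readable summary.

    Layout under cfg.outdir: genome/, libraries/, reads/, alignments/,
    composition/, candidates/, logs/.  Any stage error aborts with the
    stage name in the log and exception.
    """
    out = Path(cfg.outdir)
    for sub in ("genome", "libraries", "reads", "alignments", "composition",
                "candidates", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "logs" / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("arseq")
    root_logger.addHandler(fh)
    try:
        return _run(cfg, out)
    finally:
        root_logger.removeHandler(fh)
        fh.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    stage = "genome"
    try:
        genome = build_genome(cfg.genome_spec, seed=stage_seed(cfg.seed, "genome"))
        write_fasta(genome, out / "genome" / "genome.fasta")
        write_gff3(genome, out / "genome" / "orfs.gff3")
        write_ars_bed(genome, out / "genome" / "ars_loci.bed")

        stage = "libraries"
        libcfg = LibraryConfig(
            **{**asdict(cfg.library), "seed": stage_seed(cfg.seed, "libraries")}
        )
        lib_a = make_library_a(genome, libcfg)
        lib_b = apply_selection(lib_a, "B", libcfg)
        try:
            lib_c = apply_selection(lib_b, "C", libcfg)
        except EmptySelectionError:
            if libcfg.n_clones_c == 0:
                lib_c = None
            else:
                raise
        libraries = {"A": lib_a, "B": lib_b, "C": lib_c}
        for name, lib in libraries.items():
            if lib is None:
                continue
            with open(out / "libraries" / f"library_{name}.tsv", "w") as f:
                f.write(_header(cfg))
                f.write("replicon\tstart\tend\tcarries_ars\n")
                for c in lib.clones:
                    f.write(f"{c.replicon}\t{c.start}\t{c.end}\t{int(c.carries_ars)}\n")

        stage = "reads"
        readsets = {}
        for name, lib in libraries.items():
            if lib is None or len(lib) == 0:
                continue
            rs = simulate_reads(
                lib, cfg.n_pairs_per_stage,
                read_length=cfg.read_length,
                substitution_rate=cfg.substitution_rate,
                insert_mean=cfg.insert_mean,
                insert_sd=cfg.insert_sd,
                seed=stage_seed(cfg.seed, f"reads:{name}"),
            )
            readsets[name] = rs
            write_fastq(rs, out / "reads" / f"library_{name}_R1.fastq",
                        out / "reads" / f"library_{name}_R2.fastq")
            write_truth_json(rs, out / "reads" / f"library_{name}_truth.json")

        stage = "alignments"
        index = index_reference(genome, cfg.mapping)
        tables = {}
        for name, rs in readsets.items():
            t = map_library(rs, index, cfg.mapping)
            tables[name] = t
            t.to_tsv(out / "alignments" / f"library_{name}.tsv")
            with open(out / "alignments" / f"library_{name}_stats.json", "w") as f:
                json.dump(t.stats, f, indent=1)

        stage = "composition"
        compositions = {}
        for name, t in tables.items():
            comp = compute_composition(t, genome, policy="exclude_multimapped", stage=name)
            compositions[name] = comp
            comp.to_tsv(out / "composition" / f"library_{name}.tsv")

        stage = "candidates"
        candidates = []
        if "C" in tables and "A" in tables:
            covA = compute_coverage(tables["A"], genome, policy="include_all")
            covC = compute_coverage(tables["C"], genome, policy="include_all")
            orfs_by_rep = {r.name: r.orfs for r in genome.replicons}
            for rep in genome.names:
                write_bedgraph(covC[rep], out / "candidates" / f"coverage_C_{rep}.bedgraph")
                prof = enrichment_profile(covC[rep], covA[rep], window=cfg.window)
                candidates.extend(
                    call_candidates(prof, covC[rep], orfs_by_rep[rep],
                                    min_depth=cfg.min_depth, threshold=cfg.threshold)
                )
            write_candidates_bed(candidates, out / "candidates" / "ars_candidates.bed")
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "composition": {
            name: {row.replicon: round(row.percent, 6) for row in comp.table.itertuples()}
            for name, comp in compositions.items()
        },
        "mapping_stats": {name: t.stats for name, t in tables.items()},
        "candidates": [
            {"replicon": c.replicon, "start": c.start, "end": c.end,
             "mean_enrichment": round(c.mean_enrichment, 4),
             "covered_orfs": c.covered_orfs}
            for c in candidates
        ],
    }
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True)
    return summary
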