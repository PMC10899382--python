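# arseq

Simulation and analysis toolkit for **AR-seq** (Autonomous Replication
sequencing) — a functional screen that identifies the genomic regions
enabling a plasmid to replicate on its own.  The motivating system is a
multi-replicon cyanobacterium: a chromosome plus several plasmids, some of
which carry unknown replication (Rep) genes.  In the screen, random 1.5–2.5
kbp genomic fragments are cloned onto a selectable vector (library A),
passed through a host-transformation bottleneck (library B), and
re-isolated as plasmids in a secondary host (library C), so only clones
whose insert contains an autonomous replication sequence (ARS) persist.
Sequencing the three libraries and mapping reads back to the genome reveals
which replicons and which loci confer replication.

The package provides, as importable modules and an `arseq` command line:

- **synthetic data** — multi-replicon circular genomes with planted ARS
  loci and byte-identical duplications; clone libraries with the two
  selection bottlenecks; paired-end reads with substitution errors; ddPCR
  droplet counts; fluorescence histograms; plasmid segregation trajectories;
- **mapping** — a self-contained paired-end mapper (match +1, mismatch −2,
  indel −3) that discards alignments below 0.8 length fraction or 0.9
  identity and reports all co-optimal placements (multi-mapping);
- **composition & coverage** — per-replicon percentages of concordantly
  mapped pairs (with or without multi-mapped pairs) and per-base depth;
- **ARS calling** — windowed log2 enrichment of the selected over the input
  library, merged into candidate regions that must contain a fully covered
  ORF;
- **copy number** — Poisson partition statistics for droplet digital PCR
  (λ = −ln(1 − p)), flow-cytometry ploidy calibration against a
  one-copy standard, and per-cell plasmid copy ranges
  `floor(ratio × ploidy)`;
- **phylogeny** — Poisson-corrected protein distances
  (d = −ln(1 − p), pairwise deletion) and Saitou–Nei neighbor joining
  with Newick output.

## Worked example

Run the full in-silico screen at desk scale (three replicons, one ARS locus
on `plasmid_P` containing the ORF `repX`):

```bash
arseq run --seed 1 --out screen_run
```

which prints the per-replicon composition of each library stage and the
candidate count:

```
{
 "A": {
  "chromosome": 48.15,
  "plasmid_P": 35.6,
  "plasmid_Q": 16.25
 },
 "B": {
  "chromosome": 25.162581,
  "plasmid_P": 67.533767,
  "plasmid_Q": 7.303652
 },
 "C": {
  "chromosome": 0.0,
  "plasmid_P": 100.0,
  "plasmid_Q": 0.0
 }
}
candidates: 1 -> screen_run/candidates/
```

Reading: in the unselected library A the three replicons contribute reads
roughly in proportion to copy weight × length; after the two bottlenecks
(library C) essentially all reads come from the ARS-bearing plasmid, and the
caller reports exactly one candidate region — the planted locus, covering
`repX` (see `screen_run/candidates/ars_candidates.bed`).

Copy-number arithmetic from a measured ddPCR ratio and a ploidy range:

```bash
$ arseq copynum --ratio 34.1 --ploidy-min 2 --ploidy-max 6
68-204
```

i.e. a plasmid measured at 34.1 copies per chromosome in cells carrying 2–6
chromosome copies is present at 68–204 copies per cell.

A neighbor-joining tree from an aligned protein FASTA:

```bash
arseq nj --alignment proteins.faa
```

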