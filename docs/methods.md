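# Methods

## The screen being simulated

AR-seq identifies autonomous replication sequences (ARS) by attrition: a
random fragment library passes through a transformation bottleneck into the
screening host and a plasmid re-isolation bottleneck in a secondary host.
A clone survives the second bottleneck only if its insert replicates on its
own, which in this model means the insert fully contains an ARS locus.
Sequencing the libraries before and after selection and mapping the reads
back to the genome shows the enrichment.

The simulator encodes that causal chain explicitly:

- **Genome.** Circular replicons with uniform random ACGT sequence under a
  fixed seed; ORFs, ARS loci and duplications are annotations on top.
  Duplications are applied by copying source bytes, so duplicated segments
  are exactly identical — the strongest possible multi-mapping challenge,
  matching a tandem-duplicated plasmid where reads cannot be placed
  uniquely.  All intervals are 0-based half-open; fragments and alignments
  may wrap the origin and are reported modulo the replicon length.
- **Library A** draws fragments with replicon probability proportional to
  copy weight × length (a bulk-DNA extraction samples abundant, long
  replicons more often), fragment length uniform on [1500, 2500] bp and
  start uniform on the circle.  Restriction-site preferences are not
  modelled; fragmentation is uniform.
- **Library B** is a mixture: a fraction `background_fraction_b` (default
  0.5) of the bottleneck survivors are non-ARS clones — standing in for
  chromosomally integrated material and genomic carry-over in the
  extracted DNA — and the rest are ARS-bearing clones replicating as
  plasmids.  The real screen does not quantify library B's composition, so
  this is a free parameter of the model, chosen at 0.5 so that stage B is
  visibly but incompletely enriched.
- **Library C** resamples exclusively from ARS-bearing survivors.
  Requesting stage C from a library with no ARS clones raises an explicit
  empty-selection error rather than returning an empty library.
- Default bottleneck sizes are 25 000 / 6 300 / 456 clones (the scale of
  the real screen); tests and the acceptance script run a 10× reduction
  (2 500 / 630 / 46) to keep runs in seconds without changing the
  selection structure.

**Reads.** Clones are sampled uniformly; insert length is
N(400, 40²) rounded, clipped to [read length, fragment length]; the insert
position is uniform within the fragment.  Mate 2 is the reverse complement
of the insert's 3' end.  Errors are iid substitutions only (no indels, no
quality model — qualities are written as a constant 'I' since the mapper is
sequence-only).  The vector backbone is never emitted: backbone reads would
not map to the genomic reference and would only dilute counts.  Truth
records (source clone, coordinates) ride along for mapper validation.

## Mapper

Scoring is match +1, mismatch −2, indel −3, end-to-end on the read (no
soft-clipping), with two filters applied to every emitted record: aligned
fraction of the read ≥ 0.8 and identity over aligned columns ≥ 0.9.
End-to-end alignment makes the filters well-defined on the whole read.

Candidate placements come from exact k-mer seeds (k = 15) at
non-overlapping read offsets, looked up in a position table that includes
origin-spanning k-mers (the reference is indexed with a k−1 base wraparound
extension).  By the pigeonhole principle a read with fewer than
⌊len/k⌋ substitutions always retains one exact seed at its true locus.
Each candidate diagonal is scored gaplessly first; only if no gapless
candidate passes the filters does a banded dynamic program (band ±8) run
around each candidate.  Under this scoring a gapless alignment is optimal
whenever one achieving the identity threshold exists, and the simulator
emits substitutions only, so the fallback is rarely exercised — but it is
required for mapping real reads with indels.  All co-optimal placements
are reported with `n_hits` set; enumeration stops at `max_hits` (10)
placements.  Tests check equivalence against an exhaustive
all-positions/both-strands scan on short reads and small references.

**Pairing.** Mates are mapped independently; a pair is concordant when some
placement combination lies on one replicon, on opposite strands, with
implied (circular) insert length within the simulated mean ± 4 SD.  The
4-SD window accepts essentially all true inserts (±4 SD of a normal) while
rejecting cross-locus artefacts.  The exact pairing rule of commercial
mappers is unpublished; this is the package's own definition.  A pair is
multi-mapped if either mate has several co-optimal placements.

## Composition and coverage

Composition counts concordant **pairs** per replicon (a pair is one clone
observation; mate-level counting would double-weight).  The
`exclude_multimapped` policy drops multi-mapped pairs from numerator and
denominator — the view used for per-replicon percentages; `include_all`
spreads each pair's unit weight over its co-optimal concordant placements
(weight 1/n), so percentages sum to 100 under both policies.  Coverage
counts every aligned mate interval and is the input to candidate calling
under `include_all`, because a duplicated ARS would otherwise lose all its
coverage to the multi-mapping filter.

## ARS candidate calling

The real analysis identified candidate regions by inspecting mapped reads;
this package operationalises that judgement so it is reproducible and
parameterised: coverage tracks are normalised to depth per million aligned
bases, compared per 200 bp window as log2((C + ε)/(A + ε)) with ε = 1
(normalised-depth units, i.e. one read-base per million), windows scoring
≥ 2 (4-fold enrichment) are merged tolerating a single-window gap, and a
merged region is reported only if it overlaps an ORF whose every base has
selected-library depth ≥ 5.  The full-ORF-coverage rule encodes
"a full-length gene present in the surviving clones"; the depth floor of 5
rejects single stray clones.  These defaults are package choices, not
measured constants; raising the threshold can only shrink the candidate
list (tested as a monotonicity property).

## Copy number

ddPCR: with template distributed Poisson across droplets, the positive
fraction p̂ estimates λ = −ln(1 − p̂) copies per droplet; the delta-method
SE is √(p̂/((1−p̂)n)).  A saturated assay (p̂ = 1) is an explicit error.
The plasmid-per-chromosome ratio is λ_t/λ_r with independent error
propagation; channels are treated as independent (two-probe design,
no dual-positive modelling).

Ploidy: the one-copy standard's histogram mode calibrates the fluorescence
of a single chromosome copy; the sample's 5 %/95 % quantiles divided by
that unit, rounded to integers and clamped to ≥ 1, give the copies-per-cell
range.  Ploidy may also be asserted directly (e.g. 2–6 or 3–10) when it
was measured elsewhere.

Per-cell plasmid copies: floor(ratio × ploidy bound) at each end.
Truncation reproduces the published arithmetic for nine of ten table cells;
the remaining cell (ratio 6.3, ploidy 6) prints 36 where floor gives 37 —
the package reports 37 and documents the discrepancy rather than special-
casing it.

## Phylogeny

Pairwise p-distances use pairwise deletion: for each sequence pair, columns
with a gap or ambiguity ('X', and also B, Z, U, O — anything outside the
20 canonical residues) in either sequence are excluded for that pair only.
The Poisson correction d = −ln(1 − p) converts the observed different-site
fraction to expected substitutions per site (equal rates across sites, no
rate matrix).  Neighbor joining follows Saitou–Nei with the Q-criterion;
negative branch-length estimates are clamped to 0; ties on Q break toward
the smallest index pair (tie behaviour differs between implementations and
is stated here as this package's rule).  NJ is exact on additive matrices,
which the tests exploit: random trees' path-length matrices must be
reproduced to 1e-9, and at five leaves the NJ topology must match the
least-squares-best of all 15 unrooted topologies.

## Segregation

Each generation every cell's n plasmid copies double to 2n and partition
binomially between daughters; the model tracks one daughter per cell,
n_cells cells in parallel.  The single-generation loss probability from n
copies is 2^(−2n), so low-copy plasmids are lost much faster — the
qualitative behaviour seen when selection is removed.  With selection on,
plasmid-free cells are purged and survivors resampled to constant
population size.  Copy-number regulation (replication control toward a set
point) is deliberately absent: without it the contrast between an 8-copy
and a 68-copy plasmid is purely segregational, which is the effect under
study.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on
— proportional sampling, containment-based selection, substitution noise,
Poisson partitioning, lognormal fluorescence spread — with uniform random
sequences.  It does not model restriction-biased fragmentation, PCR
duplicates, chimeras, indel errors, GC or mappability bias, or real
sequence composition; passing tests therefore demonstrate the correctness
of the pipeline's logic and estimators under the stated model, not mapper
performance on real cyanobacterial reads.  The mapper accepts real
FASTA/FASTQ input through `arseq map` for that purpose.

## Problem sizes and numerical choices

Tests and the acceptance script use 2–3 replicons of 10–60 kbp, libraries
of 10³–10⁴ clones scaled 10× below the real screen, 2 000 read pairs per
stage (≈ 100–200× local depth over an ARS locus), 10⁶ droplets × 20
replicates for the ddPCR recovery, and 10⁴ cells × 20 generations for
segregation — sizes chosen so each property is measured with comfortable
statistical margin while the whole suite runs in seconds.  All simulators
are bit-reproducible under a fixed seed; the pipeline derives per-stage
seeds from the global seed by hashing the stage name, so stages can be
re-run independently and a rerun is byte-identical.
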