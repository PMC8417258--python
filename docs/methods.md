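# Methods

## Scope and model

`nanovdj` determines the somatic-hypermutation (SHM) status of clonotypic
IGHV genes from noisy long-read IGH amplicon data. The object of inference
is, per sample, the set of clonal VDJ rearrangements, each summarised by a
polished consensus sequence, its germline V/D/J assignment, its V-region
identity to germline, its productivity, and the binary SHM status derived
from the 2% rule (identity ≥ 98.00% → unmutated). The pipeline assumes
already base-called, demultiplexed FASTQ input of FR1→J amplicons; quality
scores are ignored throughout (upstream quality filtering is assumed).

## Germline reference

Analysis runs against a single-contig germline bundle: a FASTA contig and a
BED of gene intervals (`GENE|SEGMENT` name field, frame offset in the score
column). The same database serves both read mapping and germline
interrogation; using one reference for both steps removes a known source of
inconsistency between coverage-based clonality calls and annotation calls
made against a separate germline directory. Coordinates are 0-based
half-open internally; all genes must be plus-strand (minus-strand records
are rejected at load rather than silently mishandled). Allele-level
(`*01`-style) resolution is out of scope.

The synthetic mini-locus generator (`build_fixture_db`) emulates the one
property of the real locus that matters for clonality calling: V genes that
resemble each other enough to scatter noisy reads across genes. V genes
(295 nt) are derived from a common ancestor with per-gene divergence chosen
so that every distinct pair sits at 70–92% identity, including one ~90%
"sibling" pair mimicking within-family similarity; all V genes are
stop-free in frame 0 and the J gene (48 nt, frame offset 1) is stop-free in
its own frame, so productivity is decided by junction geometry as in real
rearrangements. D genes are 10–30 nt of random sequence. The generator is
deterministic per seed; the bundled `data/fixture_locus.{fasta,bed}`
(8 V / 3 D / 1 J on a ~21 kb contig) is the output of seed 42 and is a
synthetic stand-in, not real locus sequence.

## Simulator

Rearrangement: amplicon = V[frame_offset : end−v_trim] + n1 + trimmed D +
n2 + J[j_trim:], with exact junction coordinates recorded as truth.
`random_clone_spec` draws trims (V ≤ 5, J ≤ 6, D up to a third per side)
and N-additions (0–8 nt) and rejection-samples until the template has the
requested productivity.

SHM is substitution-only, i.i.d. uniform over the V region at the
configured rate (0–20%), never back to the same base, and never creating an
in-frame stop codon — the assay sequences expressed rearrangements whose
SHM was under functional selection, and without this constraint a large
fraction of simulated "productive mutated" clones would be spuriously
unproductive. Real SHM hotspots, indels and junction mutations are not
modelled; they are unnecessary for exercising a coverage/consensus/identity
pipeline. True V-region identity is recorded as
`100·(1 − mutations/V-length)` and is exactly recomputable from the stored
mutation positions.

Sequencing errors are i.i.d. per base: deletion (default 4%), substitution
(3%, never to the same base), and insertion of a uniform random base in
each of the n+1 inter-base slots (3%) — 10% total, matching the error
budget of the targeted instrument generation. About half of the reads are
emitted reverse-complemented. Homopolymer-conditioned errors, chimeras,
truncations and quality-score structure are deliberately not simulated, so
green tests demonstrate correctness under context-free noise, not
robustness to systematic instrument artifacts. Per-clone read counts are
largest-remainder rounded abundance shares; everything is byte-reproducible
per seed.

## Alignment engine

All scored alignments use one affine-gap Smith–Waterman implementation
(numba-compiled Gotoh DP with full traceback): match +2, mismatch −4, gap
open −4, gap extend −2 (a gap of length L costs 4+2L), score floor 40, all
configurable. These values keep a ~300 nt germline gene alignable across a
10%-error read while penalising spurious extensions. On references longer
than 3 kb the scored DP is restricted to the best edit-distance window
(edlib infix scan, ±80 nt margin) on the competitive strand(s); on shorter
references the full matrix is used, so small instances are exactly the
textbook optimum (asserted against an independent pure-Python DP oracle in
the tests). A window could in principle miss a distant higher-scoring local
alignment, but for amplicon reads the edit-distance optimum and the score
optimum coincide.

## Clonality stage

Depth per V gene is mean per-base coverage: aligned (match/mismatch) bases
inside the gene interval divided by gene length; one best alignment per
read prevents double counting, and the overlapping-read count is reported
but never used for calling. A V gene is clonotypic when depth ≥ threshold
(default 500X, inclusive — the boundary convention is pinned by tests).
Reads whose alignment covers ≥ 50% of the gene length are selected for
consensus building, reverse-complemented to locus orientation. D and J
genes are never depth-called: J is shared by all rearrangements of a sample
and D segments are too short to accumulate specific coverage.

## Consensus stage

Subclustering is greedy centroid clustering on normalised edit distance
(distance/longer length, edlib with an early-exit cutoff): reads in
deterministic order (length descending, then id) join the closest centroid
within 2·tolerance or seed a new partition, capped at 64 centroids (later
non-matchers become inert singletons; relevant only below the support
filter anyway).

Assembly escalates through the tolerance schedule (default 0.05, 0.10,
0.15, 0.20): at each level, partitions under `min_support` (default 20
reads — a consensus from fewer nanopore reads is not trustworthy; the value
is configurable and logged) are dropped, and the first level yielding at
least one draft wins (earliest-success rule). At ~10% read error the low
levels shatter the cluster, so assembly typically succeeds at 0.10–0.15;
this is how the pipeline adapts to an unknown error rate. When every level
fails, a single non-ok record carries a machine-readable `failure_reason`
(largest observed partition vs `min_support`), making consensus-building
failures auditable rather than silent.

A draft is a star alignment to the partition's medoid (computed over the
first 40 reads, all-pairs edit distance): per-column plurality base with
alphabetical tie-break, column deleted when gaps strictly outnumber the
best base, plus insertion columns emitted where more than half of the
covering reads insert (plurality string). Insertion columns are essential
already at the draft stage — the medoid itself carries ~4% deletions that
only read-insertion evidence can restore.

Polishing iterates the same re-call against the current consensus (≤ 5
rounds, default) until byte-identical. Plain majority calling has one blind
spot: a missing or extra unit of a short tandem repeat, where the reads'
compensating indels left-align to different junctions and no single
insertion key reaches a majority. When the re-call is a fixed point, a
repeat-aware refinement therefore proposes candidate edits at junctions
with ≥ 30% aggregate insertion pressure (insert the plurality string) and
at columns with ≥ 30% gap pressure (delete the column), and applies the
candidate that most decreases the summed edit distance of the supporting
reads — only if it strictly decreases it. This is a deterministic steepest
descent on the cluster's edit-distance objective; at i.i.d. error rates
≤ 15% a spurious candidate cannot reach the trigger, and the
distance-decrease test protects mixed partitions. Voting and refinement use
at most the first 500 / 150 reads (deterministic order) per partition.

After polishing, records for the same V gene within edit distance 3 of a
better-supported record are merged (supports summed): greedy subclustering
routinely splits one rearrangement into several partitions that converge to
nearly the same sequence, and without the merge each would be reported as a
separate clone carrying its small-partition polish noise. Distinct
co-amplified rearrangements differ by far more than 3 edits in junction
alone; `merge_max_dist` is configurable.

## Annotation stage

V assignment aligns every germline V gene against the consensus under the
pipeline scoring; the best score wins (ties: higher identity, then
lexicographic name). V-region identity is
`100·matches/(matches+mismatches+inserted+deleted bases)` over the winning
alignment, reported to two decimals; counting each indel base once is a
deliberate, configurable convention (`identity_mode =
substitutions_only` ignores indels). J is the best-scoring J gene
downstream of the V span (floor 30); without a J the clone is excluded from
SHM reporting with an explicit reason. D is called only when ≥ 10 nt of a D
gene align at ≥ 80% identity between V and J — junctional trimming
routinely destroys the D signal, and a D call never affects SHM status.
The junction spans from the last V-aligned base through the first J-aligned
base, inclusive.

Productivity: the V frame offset is projected through the alignment onto
the consensus; `frame_ok` requires the first codon start inside the aligned
J to land on that frame (junction-induced offset ≡ 0 mod 3), `stop_free`
requires no in-frame TAA/TAG/TGA from the V frame anchor through the
aligned J, and `productive = frame_ok AND stop_free`.

SHM classification: identity ≥ 98.00 → unmutated; < 98.00 → mutated;
identities in [97.00, 98.00) are flagged borderline (least reliable band)
while still classed mutated. Both boundaries are inclusive-lower by
convention and pinned by unit tests at 97.00, 97.99 and 98.00.

## Reporting

Sample-level status aggregates over productive reported clones only:
unanimous → that status; disagreement → `discordant-multiclonal`, which is
deliberately never auto-resolved (multi-clonal discordance needs human
review or orthogonal validation); no productive reportable clone →
`no result`; no gene above the coverage threshold → `no clonal
rearrangement`. Exit codes: 0 status call, 2 structured no-result, 1 crash.
The analysis path contains no randomness — all tie-breaks are
deterministic — so re-running a sample reproduces every TSV byte for byte.

## Problem sizes

Simulation-backed tests and the acceptance script use 1000 reads per clone
for sweep-style runs (comfortably above the 500X calling threshold), 2000
reads for two-clone samples, and 500-read replicates for consensus
exactness; the identity sweep covers SHM rates 0/1/2/3/5% with 10 seeds per
rate in the test suite and 6 in the acceptance script. These sizes put
depth well into the regime where majority voting is near-deterministic
while keeping a full run to a few seconds.

## Known limitations

- The aligner windows long references through an edit-distance scan; exact
  optimality is guaranteed only ≤ 3 kb (covered by the DP-oracle tests).
- SHM and read errors are context-free; systematic homopolymer errors
  could defeat majority voting in ways the simulator cannot expose.
- Star alignment to a medoid is a deliberate substitution for full
  MSA/POA assembly; a POA backend is a natural extension point.
- The D-assignment rule (≥10 nt at ≥80%) is a pragmatic approximation of
  annotation-service behaviour; stereotypic subset assignment is out of
  scope.
- Minus-strand germline genes and allele-level resolution are unsupported
  by design.
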