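# Methods

## The measurement being modelled

A plasmid library whose members differ only in a 15-nt uniform-random barcode
is injected into 1-cell embryos of a landing-site (AttP) line together with
integrase mRNA. Integration is delayed and mosaic: during early cleavage,
individual cells recombine exactly one randomly drawn plasmid into the
landing site (the site is consumed by recombination, so a founder cell
carries exactly one barcode). Founders divide, so by the time genomic DNA is
extracted, each barcode's abundance reflects its clone's size. Barcodes are
PCR-amplified from the integration junction with a sample-specific 5-nt
multiplexing barcode, pooled, and sequenced. The analysis must then answer:
how many *distinct* integration events does each animal carry, and is the
abundance distribution consistent with clonal expansion of independent
events?

## Pipeline

Stages run in the order of the wet-lab data flow; all counts are integers
until RPM normalization, and every stage boundary is recorded in a manifest
whose totals must reconcile.

1. **Demultiplex** on the raw read orientation: the 5-nt region at the
   template-defined offset (default: read start) is compared to every sample
   sheet entry; a read is assigned iff *exactly one* entry is within Hamming
   distance 1. Reads matching zero or several entries are set aside as
   unassigned rather than guessed. Sheets whose barcodes are closer than
   twice the mismatch budget trigger a warning at construction (the bundled
   default pool is a pairwise-Hamming-≥3 code of 16 barcodes).
2. **Orient**: reads are reverse-complemented into template orientation
   (configurable off, for library samples sequenced in forward orientation).
3. **Extract**: the 12-nt upstream anchor is located by a progressive ladder
   — exact substring, then minimal Hamming distance ≤ 2, then minimal
   Levenshtein distance ≤ 2 over windows of the anchor length ± 2 — each
   stage restricted to the expected anchor position ± 5 nt (the Levenshtein
   stage widens the window by the indel budget). Ties break toward the
   smaller distance, then the leftmost start, then the window length nearest
   the anchor length. The 15 bases after the matched anchor are the candidate
   barcode; the next 5 bases must equal the downstream anchor exactly.
   Candidates containing `N`, and reads failing any step, are counted as
   unextractable — extraction failures are never fatal. The slot is always
   exactly 15 nt; indels *inside* the barcode are left to the collapse stage.
4. **Collapse**: barcodes are visited in decreasing cross-sample total count
   (ties lexicographic). A barcode becomes a parent if no finalized parent is
   within Levenshtein distance 1, else it merges into the most abundant such
   parent (children never become parents, so distance-2 chains are not
   transitively merged). Per-sample counts are added to the parent's; the
   grand total is conserved exactly. The implementation enumerates each
   parent's distance-1 neighborhood (~124 strings for a 15-mer) into a hash
   map, making collapse O(barcodes) rather than all-pairs; tests verify it
   against an exhaustive trace of the rule using an independent DP edit
   distance. Collapse is idempotent (surviving parents are pairwise ≥ 2
   apart).
5. **Filter**: fish samples keep a barcode in a given fish only with ≥ 3
   reads there (cells below threshold are zeroed independently per fish);
   source-library samples drop barcodes with < 2 reads. All-zero rows are
   dropped. Then barcodes within Levenshtein distance ≤ 2 of any conserved
   (non-barcode) template region are removed as likely mis-extraction
   artifacts, computed by infix (substring) alignment of the barcode against
   each region — equivalent to scanning all windows of length 15 ± 2.
6. **Report**: reads-per-million per sample (zero-depth columns are flagged,
   never divided); per-sample unique-barcode counts with mean/median/sample
   SD (n−1)/range; CV (population SD / mean of nonzero abundances), Shannon
   index in bits over nonzero relative abundances (0·log 0 := 0), quartile
   ratio Q3/Q1 with linear interpolation; positional nucleotide composition;
   mean pairwise Hamming distance over sampled pairs.

## Estimators from imaging tallies

- **Mutual exclusivity**: with counts (green-only, red-only, double-positive),
  `pct_double = 100·double/total` and `pct_exclusive = 100 − pct_double`.
  Because a 50:50 colour mix hides same-colour double integrants half the
  time, the multi-transgene rate is bounded above by `2 × pct_double`.
  Report formatting (2 decimals for percentages, 1 for the bound,
  round-half-up) is applied only at output; full precision is kept
  internally.
- **Brain coverage**: the arithmetic mean of per-fish fluorescent-neuron
  counts, and that mean as a percentage of a region-total estimate (default
  25,000 hindbrain neurons at 5 dpf). The formatted mean truncates toward
  zero and the percentage rounds to the nearest integer, matching the common
  reporting convention; internal values are full precision.

## Simulator: what it emulates and what it does not

`LibrarySpec` draws i.i.d. uniform-random barcodes (duplicates permitted —
the collision probability is the birthday bound n²/(2·4¹⁵)); a lognormal
abundance option models cloning-bottleneck skew. `MosaicSimConfig` draws
`n_integrations` independent events per fish from the library abundance
distribution (default 1,600, on the scale of observed per-animal barcode
counts) and assigns each founder a clone size. `ReadSimConfig` samples reads
multinomially in proportion to clone size, embeds each barcode in the
conserved template (synthetic fixed flanks stand in for the real amplicon
context, which is not specified as sequence; they contain no secondary
anchor near-match), prepends the 5-nt sample barcode, emits the read as the
reverse complement of template orientation, and applies independent per-base
substitutions (to a uniformly chosen different base), deletions and
insertions. `TwoColorSimConfig` gives each cell at most one landing-site
integration (probability `p_landing_integration`, colour green with
probability `color_mix`) and at most one spontaneous enzyme-independent
integration (`p_spontaneous`); double positives arise only from spontaneous
co-integration of the opposite colour, so among fluorescent cells
E[double] ≈ p_spont·2·mix·(1−mix) and the ×2 bound is unbiased at a 50:50
mix.

**Clone-size default**: lognormal with μ = ln 32, σ = 0.8 (median clone 32
cells, CV ≈ 0.95). Rationale: integration during early cleavage spread over
roughly ±1 cell cycle multiplies final clone sizes by ≈ 2^±1 ≈ e^±0.69,
and the resulting distribution keeps sub-3-read barcodes rare at ~50 reads
mean clone coverage, consistent with rare-barcode reads being a small
fraction of a real fish sample. Fixed-size and geometric options exist for
testing (the exact zero-error round-trip uses fixed(1), since multinomial
sampling at finite depth can otherwise miss small clones entirely).

The simulator deliberately omits: spatial embryo geometry and lineage trees,
PCR-cycle chimeras and quality-score-dependent errors (only run-level
uniform rates), paired-end structure (a single read spans the barcode
region). Passing tests therefore demonstrate correctness of the *analysis*
under a clean generative model of mosaic integration — they do not certify
robustness to PCR chimeras or quality-correlated error bursts in real data.

## Numerical and design choices

- Edit distances use edlib (infix mode for artifact scanning); tests
  cross-check every distance-dependent behaviour against a hand-rolled DP
  oracle and exhaustive window scans.
- Pair sampling for mean pairwise Hamming: uniform over unordered
  distinct-index pairs, without replacement when the pair space exceeds the
  request (rejection sampling with a seen-set), else with replacement; a
  seed is always required. Fewer than two barcodes → NaN, not 0.
- Degenerate inputs: empty count tables pass through every stage; samples
  with no nonzero barcode report NaN metrics; an empty conserved-region list
  makes the artifact filter warn and no-op.
- Determinism: a single integer seed fixes library, fish, reads and tallies
  bit-identically; the pipeline itself is deterministic. The implementation
  is single-threaded by design — there is no threads option because no stage
  would reorder results.
- Test problem sizes: the end-to-end recovery test runs 12 fish × 1,600
  integrations from a 10⁶-member library at 50 reads mean clone coverage
  (960,000 reads total, ~30 s), the scale at which per-fish recovery within
  ±2% of truth is a meaningful claim; unit tests use hundreds of reads.

## Known limitations

- The ±2% end-to-end recovery holds under the default clone-size model; a
  heavier-tailed model (σ ≳ 1.5) pushes more clones under the 3-read
  threshold at the same mean coverage, and recovery then degrades honestly.
- The artifact filter depends on the conserved regions supplied in the
  template; with the synthetic default flanks it demonstrates the mechanism,
  not the real amplicon's artifact spectrum.
- Demultiplexing discards ambiguous reads rather than assigning to the
  nearest barcode; with well-separated sheets this only affects reads with
  ≥ 2 index errors.
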