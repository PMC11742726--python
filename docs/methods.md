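# Methods

## Pseudo-matching lengths as exact matching statistics

The scoring layer consumes, for each read position `i`, the length of the
longest prefix of `read[i:]` that occurs in any indexed reference on either
strand. Run-length-compressed full-text indexes report *pseudo*-matching
lengths that approximate this quantity from below (the backward walk can
reset before the true longest match is found). `hostscrub` computes the
exact matching statistics instead: they are deterministic, backend-free,
and reproduce the three published score thresholds from the same idealized
read. The practical consequence is that per-position values against any
realistically sized index hover near `log4(index size)` for unrelated
reads, which is precisely why the custom metric keys on *contiguous runs*
rather than raw values (below).

The backend is a suffix automaton over the concatenation of all references
and their reverse complements, with sentinels between segments so matches
never bridge reference or strand boundaries. Construction is online and
linear in total reference length; matching statistics for a read of length
`L` take `O(L)` via the longest-suffix walk plus a monotone two-pointer
conversion. The exactness is enforced by tests comparing against an
exhaustive substring-scan oracle, position by position, on random and
host-segment-bearing reads.

`N` handling: an `N` (or any non-ACGT symbol) in a read matches nothing and
resets the walk; non-ACGT stretches in references become sentinels. This is
deliberately conservative — N runs can never inflate a host score.

Serialization stores the source sequences plus a format-version tag and
rebuilds the automaton on load; loading a mismatched version is an error.

## Per-read scores and the run decomposition

Three metrics condense a PML vector (read length `L`):

- **maximum** `max(PML)`, threshold 31;
- **average** `mean(PML)` over all positions including zeros, threshold
  3.306;
- **custom** `(1/2L)(max(PML) + (Σ_{r∈R} r)·ln(|R|+1))`, threshold 0.175
  with minimum run length `w = 5`.

A *matching run* is a maximal stretch of positions over which the value
decays by exactly 1 per step while staying positive — the signature of one
contiguous exact match being consumed base by base. The quantity `r`
entering the custom score is the run's length (number of positions in the
stretch); for an isolated match of `m` bases decaying to zero the run
length equals the match length, which is the regime the thresholds were
derived in. Counting run *length* rather than the value at the run's entry
point is essential: against a multi-kilobase index every position of an
unrelated read carries a chance match of 6–10 bases, so entry values would
qualify almost everywhere and the score would saturate for all reads.
Contiguous decay-by-1 stretches longer than 5, by contrast, are
vanishingly rare in unrelated reads and ubiquitous in true host reads.
Membership is strict (`len(r) > w`), so `w = 5` admits runs of length ≥ 6.

All three thresholds follow from the idealized 150 bp read with one
matching run of 31: max = 31; mean = 496/150 ≈ 3.3067 (the default
constant is stored as the conventionally printed 3.306); custom =
(31 + 31·ln 2)/300 ≈ 0.175. The natural logarithm is forced: base-10 gives
0.134, not 0.175. Classification uses `score ≥ threshold` so the defining
boundary read is itself caught. For reads shorter or longer than 150 bp
the `1/2L` normalization uses the actual read length while thresholds stay
fixed, matching how a single threshold is applied across real data whose
read lengths vary after trimming.

The validation grid sweeps thresholds 0.145–0.200 in steps of 0.005 (12
values) against minimum run lengths 2–12 (11 values), 132 combinations,
reporting human recall, human precision and microbial loss per point.

## Filtration stages and pair semantics

An alignment stage keeps a pair only if *both* mates fail to align
(`-f 12 -F 256` semantics; `-f 4 -F 256` single-end). An index stage
removes a pair if *either* mate classifies host — the symmetric,
privacy-conservative rule. Because each stage decides per pair
independently of the surviving set, plans whose stage sets nest produce
nested survivor sets; Method 2 ⊆ Method 1 ⊆ Method 3 holds on every input,
and re-running a plan on its own survivors removes nothing further.

Two aligners satisfy one contract. The hermetic default is seed-and-extend:
21-mer exact seeds probed every 4 read positions, ungapped extension, a
mate maps when some anchor achieves ≥ 90% identity over ≥ 60 aligned bases
on either strand. These defaults make reads from held-out haplotypes
(≈ 0.2% divergence from an indexed assembly) map essentially always while
unrelated reads essentially never share a 21-mer with a multi-kilobase
reference. An adapter invoking `minimap2 -2 -ax sr` and parsing the SAM
unmapped flags is provided for production-scale use; tests exercise it only
when the binary is present.

Pre-filtration mirrors standard quality control: 3' adapter read-through is
clipped by exact suffix-overlap (≥ 8 bp) against an explicit adapter list
(TruSeq/Nextera defaults), and a pair is dropped whole when either mate
falls below 45 bp after trimming. Quality-window trimming is out of scope;
only length and adapter clipping are applied, which keeps the step
deterministic and idempotent.

## Synthetic study design

The simulator's defaults are the study conditions used throughout the
tests: 150 bp paired reads, 50% human / 50% microbial pairs, i.i.d.
substitution errors at 0.001 (a typical Illumina-scale error rate; indel
errors and empirical quality models are out of scope since classification
uses sequence only), insert length 350 ± 50, genome GC 0.41 (human-like).
Haplotypes derive from a base genome at snp_rate 0.001 and indel_rate 1e-4,
approximating human pairwise diversity; every edit is logged and the log
reconstructs the haplotype exactly. Constant Phred-35 quality strings are
attached so downstream base-quality filters are exercised.

The benchmark fixture uses 10 kb genomes, 12 haplotypes of which 2 source
the human reads and are excluded from every filtration reference
(held-out design), 8 microbial genomes, and 10⁴ read pairs. At this scale
the index stage with default custom scoring removes ≥ 99% of human-labeled
pairs while losing ≤ 1% of microbial pairs, and the three methods display
the expected ordering of human-remaining and microbial-lost. These are
property bounds on synthetic data: real-data absolute counts depend on
full-size references, real pangenome diversity, and external aligners, so
passing them demonstrates the mechanism, not field performance. Features
of real data the simulator does not emulate include repeat structure and
low-complexity regions (except when deliberately embedded), indels in
sequencing (only in haplotypes), quality-score variation, and contaminant
or chimeric reads.

The coverage diagnostic flags artifactual mismapping when reads pile onto
a tiny fraction of a genome: breadth < 1% combined with the densest 1 kb
window exceeding 10× the genome-wide mean depth. Both cutoffs are
configurable; with no reads the flag is reported as not evaluable rather
than false.

## Re-identification model

Per site `i` with `n_i` covering reads of which `k_i` show the reference
allele, the likelihood that a genotype with `g` alternative alleles
produced the reads is
`2^-n [(2−g)ε + g(1−ε)]^(n−k) [gε + (2−g)(1−ε)]^k`, with read error
`ε = 1e-6` and error independence assumed. Scores are natural-log sums over
sites, computed entirely in log space (finite up to depths of at least
10⁴). The population background takes Hardy-Weinberg genotype frequencies
at each site's alternative-allele frequency; per-site means and variances
of the log likelihood are summed under site independence, which is why
sites are first LD-pruned: greedy within 100-site windows advanced by 30,
dropping the lower-minor-allele-frequency member of any pair with dosage
`r² > 0.1` (ties drop the later position) until stable. Monomorphic sites
are uninformative and dropped up front. Site selection is
cover-then-clump: the pileup defines covered sites, pruning runs on that
subset.

Standardized scores `z = (LS − E)/√V` convert to two-sided normal
p-values. A *match* additionally requires `z > 0`: a candidate must be
more likely than a random population member, not merely unusual. Pileups
honor mapping-quality ≥ 40 and base-quality ≥ 20 cutoffs; reads showing a
third allele count toward coverage `n` but not toward `k`. Allele
frequencies default to panel-derived values and can be supplied externally.
Sites are biallelic SNPs only; multi-allelic records are skipped on VCF
import. A read set with no usable sites, or a degenerate zero-variance
background, is reported not-evaluable rather than scored.

The audit's self-identification property is validated on a 500-sample HWE
panel with 1000 SNPs spaced 50 bp apart on a 50 kb genome: ten read pairs
(3000 bases) leaked from one donor's haplotypes suffice to rank the donor
first with `p < 0.05/500`, while filtering those reads with a Method-1
plan whose references include the donor's haplotypes leaves no sample
significant — the qualitative before/after of the privacy claim.

## Numerical and design choices

- Coordinates are 0-based half-open throughout.
- All simulator randomness flows from one seed through `SeedSequence`
  spawning; identical seeds give byte-identical outputs.
- Classification boundaries use `≥`; grid thresholds are generated as
  exact multiples of 0.005 to avoid float drift.
- The per-read audit trail of removal stages is off by default (memory)
  and enabled by flag.
- The command-line layer is a thin veneer over the library; every run
  writes a resolved-config snapshot next to its outputs so a run can be
  reproduced from the snapshot alone.

## Known limitations

- Exact matching statistics are an idealization of compressed-index PMLs;
  absolute score distributions (not the thresholds' derivation) can differ
  from tools that approximate them.
- The internal aligner is ungapped; indel-divergent host reads rely on the
  index stage or the external minimap2 adapter.
- The LD-pruning tie-break and window mechanics follow the documented
  greedy rule, not any specific external implementation's byte-exact
  behavior.
- Desk-scale synthetic genomes cannot reproduce absolute read counts
  reported for full human references; only orderings, rates and bounds are
  asserted.
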