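"""Labeled synthetic read mixtures, genotype panels, and benchmark scoring.

This module generates the entire synthetic study design used to validate
the filtration pipeline at desk scale:

* a base "human" genome plus derived pangenome haplotypes (SNPs + short
  indels, with a complete variant log);
* unrelated "microbial" genomes;
* paired-end read mixtures (default 50% human / 50% microbial, 150 bp
  reads, i.i.d. substitution errors) with ground-truth origin labels;
* held-out reference sets (haplotypes whose reads are in the mixture are
  excluded from filtration, mimicking filtration against references that do
  not include the sequenced individuals);
* Hardy-Weinberg genotype panels with a designated true donor whose leaked
  reads are generated from the donor's own haplotypes, for the
  re-identification audit;
* the coverage depth/breadth diagnostic that flags artifactual mismapping
  (a sharp coverage peak with low mean depth and tiny breadth).

All randomness flows from one explicit seed through ``numpy``
``SeedSequence`` spawning, so sub-streams are independent and every output
is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import ReadPair, ReadRecord

__all__ = [
    "SyntheticGenome",
    "MixtureSpec",
    "BenchmarkResult",
    "CoverageProfile",
    "make_genome",
    "make_haplotypes",
    "reconstruct_from_log",
    "simulate_reads",
    "make_mixture",
    "holdout_references",
    "benchmark",
    "coverage_profile",
    "make_genotype_panel",
    "plant_snp_sites",
    "donor_haplotype_sequences",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SyntheticGenome:
    """A generated genome with provenance.

    ``variant_log`` records ``(position, ref_allele, alt_allele)`` edits on
    the parent's coordinates, in left-to-right order, and is sufficient to
    reconstruct the haplotype from its parent.
    """

    id: str
    sequence: str
    kind: str  # human_base | human_haplotype | microbial
    parent: Optional[str] = None
    variant_log: list[tuple[int, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MixtureSpec:
    """Study conditions for one simulated mixture."""

    n_reads: int
    seed: int
    frac_human: float = 0.5
    read_length: int = 150
    error_rate: float = 0.001
    insert_mean: float = 350.0
    insert_sd: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_human <= 1.0):
            raise ValueError("frac_human must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class BenchmarkResult:
    """Filtration outcome against ground truth for one run."""

    human_remaining: int
    microbial_lost: int
    total_human: int
    total_microbial: int

    @property
    def microbial_remaining(self) -> int:
        return self.total_microbial - self.microbial_lost

    @property
    def human_removed(self) -> int:
        return self.total_human - self.human_remaining


@dataclass(frozen=True)
class CoverageProfile:
    """Depth/breadth diagnostic for reads placed on one genome.

    ``artifact`` is True when coverage is both extremely narrow
    (breadth below ``breadth_max``) and extremely peaked (the densest 1 kb
    window exceeds ``peak_min`` times the genome-wide mean depth) — the
    signature of reads piling onto one low-complexity locus rather than
    deriving from the genome at large.  ``None`` when not evaluable
    (no reads).
    """

    breadth: float
    mean_depth: float
    peak_ratio: float
    artifact: Optional[bool]


def _rng(seed: int | np.random.Generator, *spawn_key: int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    ss = np.random.SeedSequence(seed)
    if spawn_key:
        ss = np.random.SeedSequence(seed, spawn_key=spawn_key)
    return np.random.default_rng(ss)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[arr]


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def make_genome(
    length: int,
    gc: float = 0.41,
    seed: int | np.random.Generator = 0,
    genome_id: str = "genome",
    kind: str = "microbial",
) -> SyntheticGenome:
    """I.i.d. random genome at the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = _rng(seed)
    return SyntheticGenome(
        id=genome_id,
        sequence=_to_str(_random_bases(rng, length, gc)),
        kind=kind,
    )


def make_haplotypes(
    base: SyntheticGenome,
    n: int,
    snp_rate: float = 0.001,
    indel_rate: float = 0.0001,
    seed: int | np.random.Generator = 0,
    max_indel: int = 3,
) -> list[SyntheticGenome]:
    """Independently mutated haplotypes of ``base`` with full variant logs.

    SNPs substitute a single base; indels delete or insert 1–``max_indel``
    bases.  The log records edits on base coordinates, left to right, so
    :func:`reconstruct_from_log` reproduces each haplotype exactly.
    """
    for rate in (snp_rate, indel_rate):
        if not (0.0 <= rate <= 0.05):
            raise ValueError("mutation rates must be in [0, 0.05]")
    rng = _rng(seed)
    base_codes = _to_codes(base.sequence)
    L = base_codes.size
    haplotypes = []
    for h in range(n):
        log: list[tuple[int, str, str]] = []
        draws = rng.random(L)
        snp_pos = np.nonzero(draws < snp_rate)[0]
        indel_pos = np.nonzero((draws >= snp_rate) & (draws < snp_rate + indel_rate))[0]
        events: dict[int, tuple[str, str]] = {}
        for pos in snp_pos:
            ref = base.sequence[pos]
            alt = "ACGT"[(base_codes[pos] + rng.integers(1, 4)) % 4]
            events[int(pos)] = (ref, alt)
        for pos in indel_pos:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5 and pos + size <= L:  # deletion
                ref = base.sequence[pos : pos + size]
                alt = ""
            else:  # insertion after pos of random bases
                ref = base.sequence[pos]
                alt = ref + _to_str(rng.integers(0, 4, size))
            events[int(pos)] = (ref, alt)
        pieces: list[str] = []
        cursor = 0
        for pos in sorted(events):
            ref, alt = events[pos]
            if pos < cursor:  # overlapping a prior deletion; skip
                continue
            pieces.append(base.sequence[cursor:pos])
            pieces.append(alt)
            cursor = pos + len(ref)
            log.append((pos, ref, alt))
        pieces.append(base.sequence[cursor:])
        haplotypes.append(
            SyntheticGenome(
                id=f"{base.id}_hap{h}",
                sequence="".join(pieces),
                kind="human_haplotype",
                parent=base.id,
                variant_log=log,
            )
        )
    return haplotypes


def reconstruct_from_log(base: SyntheticGenome, haplotype: SyntheticGenome) -> str:
    """Replay a haplotype's variant log against its parent sequence."""
    if haplotype.parent != base.id:
        raise ValueError("haplotype does not derive from the given base")
    pieces: list[str] = []
    cursor = 0
    for pos, ref, alt in haplotype.variant_log:
        pieces.append(base.sequence[cursor:pos])
        pieces.append(alt)
        cursor = pos + len(ref)
    pieces.append(base.sequence[cursor:])
    return "".join(pieces)


def _apply_errors(
    codes: np.ndarray, rng: np.random.Generator, error_rate: float
) -> np.ndarray:
    if error_rate <= 0:
        return codes
    err = rng.random(codes.size) < error_rate
    n_err = int(err.sum())
    if n_err:
        codes = codes.copy()
        codes[err] = (codes[err] + rng.integers(1, 4, n_err)) % 4
    return codes


def simulate_reads(
    genome: SyntheticGenome,
    n_pairs: int,
    spec: MixtureSpec,
    rng: Optional[np.random.Generator] = None,
    quality_char: str = "D",  # constant Phred 35
) -> list[ReadPair]:
    """Paired-end reads from uniformly placed fragments on either strand.

    Mate 1 reads the fragment's 5' end on the drawn strand; mate 2 is the
    reverse complement of the fragment's other end.  Substitution errors are
    i.i.d. at ``spec.error_rate``.  Each mate carries a ``placement``
    ``(genome_id, start, end, strand, mapq)`` in forward-genome coordinates.
    """
    L = spec.read_length
    codes = _to_codes(genome.sequence)
    G = codes.size
    min_insert = L
    if G < spec.insert_mean + 4 * spec.insert_sd:
        raise ValueError(
            f"genome {genome.id!r} ({G} bp) too short for insert "
            f"{spec.insert_mean}±{spec.insert_sd}"
        )
    rng = rng if rng is not None else _rng(spec.seed)
    label = "human" if genome.kind.startswith("human") else "microbial"
    qual = quality_char * L
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        insert = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
        insert = max(min_insert, min(insert, G))
        start = int(rng.integers(0, G - insert + 1))
        frag = codes[start : start + insert]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = (3 - frag)[::-1]
        fwd = _apply_errors(frag[:L], rng, spec.error_rate)
        rev = _apply_errors((3 - frag[-L:])[::-1], rng, spec.error_rate)
        rid = f"{genome.id}:{i}"
        # genome-forward coordinates of each mate
        if strand == "+":
            p1 = (genome.id, start, start + L, "+", 60)
            p2 = (genome.id, start + insert - L, start + insert, "-", 60)
        else:
            p1 = (genome.id, start + insert - L, start + insert, "-", 60)
            p2 = (genome.id, start, start + L, "+", 60)
        r1 = ReadRecord(rid, _to_str(fwd), qual, mate=1, origin_label=label, placement=p1)
        r2 = ReadRecord(rid, _to_str(rev), qual, mate=2, origin_label=label, placement=p2)
        pairs.append(ReadPair(r1, r2))
    return pairs


def make_mixture(
    human_haplotypes: Sequence[SyntheticGenome],
    microbial_genomes: Sequence[SyntheticGenome],
    spec: MixtureSpec,
) -> tuple[list[ReadPair], dict[str, tuple[str, str]]]:
    """A labeled 50/50 (by default) human/microbial read-pair mixture.

    Pair counts are balanced to ``frac_human`` within rounding, spread
    round-robin across the genomes of each class, and the combined list is
    shuffled deterministically by the mixture seed.  The truth table maps
    read id to ``(origin, source_genome)``.
    """
    if not human_haplotypes or not microbial_genomes:
        raise ValueError("both genome lists must be non-empty")
    rng = _rng(spec.seed)
    n_human = int(round(spec.n_reads * spec.frac_human))
    n_microbial = spec.n_reads - n_human
    pairs: list[ReadPair] = []
    truth: dict[str, tuple[str, str]] = {}
    for genomes, total in ((human_haplotypes, n_human), (microbial_genomes, n_microbial)):
        counts = [total // len(genomes)] * len(genomes)
        for j in range(total % len(genomes)):
            counts[j] += 1
        for genome, count in zip(genomes, counts):
            sub = simulate_reads(genome, count, spec, rng=rng)
            pairs.extend(sub)
            for pair in sub:
                truth[pair.read_id] = (pair.r1.origin_label, genome.id)
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    return pairs, truth


def holdout_references(
    haplotypes: Sequence[SyntheticGenome],
    used_for_simulation: Iterable[str],
) -> list[SyntheticGenome]:
    """Drop every genome whose reads are in the mixture from the reference
    set used for filtration; the rest (base included) is retained."""
    used = set(used_for_simulation)
    ids = {g.id for g in haplotypes}
    unknown = used - ids
    if unknown:
        raise ValueError(f"unknown genome ids in holdout request: {sorted(unknown)}")
    kept = [g for g in haplotypes if g.id not in used]
    if not kept:
        raise ValueError("holdout would empty the reference set")
    return kept


def benchmark(
    survivor_ids: Iterable[str],
    truth: dict[str, tuple[str, str]],
) -> BenchmarkResult:
    """Count human reads remaining and microbial reads lost after a run."""
    survivors = set(survivor_ids)
    unknown = survivors - truth.keys()
    if unknown:
        raise ValueError(f"survivor ids absent from truth table: {sorted(unknown)[:5]}")
    total_human = sum(1 for origin, _ in truth.values() if origin == "human")
    total_microbial = len(truth) - total_human
    human_remaining = sum(
        1 for rid in survivors if truth[rid][0] == "human"
    )
    microbial_remaining = len(survivors) - human_remaining
    return BenchmarkResult(
        human_remaining=human_remaining,
        microbial_lost=total_microbial - microbial_remaining,
        total_human=total_human,
        total_microbial=total_microbial,
    )


def coverage_profile(
    placements: Sequence[tuple[str, int, int]],
    genome_length: int,
    window: int = 1000,
    breadth_max: float = 0.01,
    peak_min: float = 10.0,
) -> CoverageProfile:
    """Depth/breadth diagnostic from ``(genome_id, start, end)`` intervals.

    Per-base depth comes from a difference array; ``peak_ratio`` is the
    densest ``window``-sized mean depth over the genome-wide mean depth.
    """
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    for _, start, end in placements:
        if not (0 <= start < end <= genome_length):
            raise ValueError(f"invalid interval [{start}, {end})")
        diff[start] += 1
        diff[end] -= 1
    depth = np.cumsum(diff[:-1])
    mean_depth = float(depth.mean())
    if not placements:
        return CoverageProfile(0.0, 0.0, 0.0, artifact=None)
    breadth = float((depth > 0).mean())
    window = min(window, genome_length)
    csum = np.concatenate([[0], np.cumsum(depth)])
    window_means = (csum[window:] - csum[:-window]) / window
    peak = float(window_means.max()) if window_means.size else mean_depth
    peak_ratio = peak / mean_depth if mean_depth > 0 else 0.0
    return CoverageProfile(
        breadth=breadth,
        mean_depth=mean_depth,
        peak_ratio=peak_ratio,
        artifact=(breadth < breadth_max and peak_ratio > peak_min),
    )


# ---------------------------------------------------------------------------
# Genotype-panel synthesis for the re-identification audit
# ---------------------------------------------------------------------------


def make_genotype_panel(
    n_samples: int,
    n_sites: int,
    seed: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
    positions: Optional[np.ndarray] = None,
):
    """Hardy-Weinberg genotype panel over independent biallelic SNPs.

    Allele frequencies are Uniform over ``freq_range``; genotypes are drawn
    per sample as Binomial(2, p).  Returns a
    :class:`hostscrub.reident.GenotypePanel`.
    """
    from .reident import GenotypePanel

    rng = _rng(seed)
    p = rng.uniform(*freq_range, size=n_sites)
    genotypes = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(np.int8)
    if positions is None:
        positions = np.arange(n_sites, dtype=np.int64)
    ref_alt = [
        tuple(rng.choice(list("ACGT"), size=2, replace=False)) for _ in range(n_sites)
    ]
    return GenotypePanel(
        site_ids=[f"site{i}" for i in range(n_sites)],
        positions=np.asarray(positions, dtype=np.int64),
        ref_alleles=[ra[0] for ra in ref_alt],
        alt_alleles=[ra[1] for ra in ref_alt],
        genotypes=genotypes,
        sample_ids=[f"sample{j}" for j in range(n_samples)],
        freqs=p,
    )


def plant_snp_sites(genome: SyntheticGenome, panel) -> SyntheticGenome:
    """Rewrite the genome so every panel site carries its reference allele.

    Keeps genome coordinates aligned with panel positions so simulated read
    placements map directly onto SNP sites.
    """
    seq = list(genome.sequence)
    for pos, ref in zip(panel.positions, panel.ref_alleles):
        seq[pos] = ref
    return SyntheticGenome(
        id=genome.id, sequence="".join(seq), kind=genome.kind, parent=genome.parent
    )


def donor_haplotype_sequences(
    base: SyntheticGenome, panel, sample: str
) -> list[SyntheticGenome]:
    """The two SNP-substituted haplotypes of one panel sample.

    Heterozygous sites place the alternative allele on the first haplotype.
    Substitution-only, so coordinates stay aligned with the base genome and
    with panel positions.
    """
    j = panel.sample_ids.index(sample)
    g = panel.genotypes[:, j]
    haps = []
    for h in range(2):
        seq = list(base.sequence)
        for i, pos in enumerate(panel.positions):
            n_alt = int(g[i])
            has_alt = n_alt == 2 or (n_alt == 1 and h == 0)
            seq[pos] = panel.alt_alleles[i] if has_alt else panel.ref_alleles[i]
        haps.append(
            SyntheticGenome(
                id=f"{base.id}_{sample}_h{h}",
                sequence="".join(seq),
                kind="human_haplotype",
                parent=base.id,
            )
        )
    return haps
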