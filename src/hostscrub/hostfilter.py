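"""Sequential host-filtration plans: alignment stages + index stages.

Three preset plans combine the two complementary removal mechanisms:

* Method 1 — align to the primary reference, align to the secondary
  reference, then index-based matching against the aggregated reference set.
* Method 2 — align to primary, secondary, and each pangenome assembly in
  turn, then the same index stage.
* Method 3 — the index stage alone.

At an alignment stage a pair survives only if *both* mates fail to align
(the samtools ``-f 12 -F 256`` convention for paired data; ``-f 4 -F 256``
for single-end).  At an index stage a pair is removed if *either* mate is
classified host — the symmetric, privacy-conservative rule.  Because every
stage makes an independent per-pair decision, plans whose stage sets nest
produce nested survivor sets: survivors(Method 2) ⊆ survivors(Method 1) ⊆
survivors(Method 3).

Two aligner backends satisfy the same contract: a hermetic seed-and-extend
aligner (k-mer seeds, ungapped extension, a read maps when it achieves
>= ``min_identity`` over >= ``min_span`` aligned bases), and an adapter that
shells out to minimap2 with short-read presets and parses the SAM output.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, Union

from .msindex import HostIndex, matching_lengths, reverse_complement
from .pmlscore import ScoreConfig, classify_read
from .seqio import ReadPair, write_fastq

__all__ = [
    "AlignerContract",
    "SeedExtendAligner",
    "Minimap2Aligner",
    "AlignStage",
    "IndexStage",
    "FiltrationPlan",
    "FiltrationReport",
    "align_filter_stage",
    "index_filter_stage",
    "run_plan",
    "preset_method",
]

Reference = Sequence[tuple[str, str]]


class AlignerContract(Protocol):
    """Deterministic per-pair mapped/unmapped status against a reference."""

    name: str

    def align(self, pairs: Sequence[ReadPair], reference: Reference) -> list[bool]:
        """Return one flag per pair: True when the pair is *mapped*
        (either mate aligns)."""
        ...


class SeedExtendAligner:
    """Hermetic k-mer seed + ungapped extension aligner.

    A mate maps when some seed anchors an ungapped overlap of at least
    ``min_span`` bases with identity at least ``min_identity`` on either
    strand.  Deterministic and dependency-free; intended as the internal
    stand-in for an external short-read aligner.
    """

    def __init__(self, k: int = 21, min_span: int = 60, min_identity: float = 0.9):
        if not (0 < min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        self.name = f"seed-extend(k={k},span>={min_span},id>={min_identity})"
        self.k = k
        self.min_span = min_span
        self.min_identity = min_identity

    def _build_seed_table(self, reference: Reference) -> list[tuple[str, dict[str, list[int]]]]:
        tables = []
        for _, seq in reference:
            table: dict[str, list[int]] = {}
            k = self.k
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i : i + k], []).append(i)
            tables.append((seq, table))
        return tables

    def _maps(self, read_seq: str, tables) -> bool:
        k = self.k
        for query in (read_seq, reverse_complement(read_seq)):
            L = len(query)
            if L < k:
                continue
            for seq, table in tables:
                n = len(seq)
                seen_offsets: set[int] = set()
                for i in range(0, L - k + 1, 4):
                    for pos in table.get(query[i : i + k], ()):
                        offset = pos - i
                        if offset in seen_offsets:
                            continue
                        seen_offsets.add(offset)
                        lo = max(0, -offset)
                        hi = min(L, n - offset)
                        span = hi - lo
                        if span < self.min_span:
                            continue
                        matches = sum(
                            1
                            for j in range(lo, hi)
                            if query[j] == seq[j + offset]
                        )
                        if matches / span >= self.min_identity:
                            return True
        return False

    def align(self, pairs: Sequence[ReadPair], reference: Reference) -> list[bool]:
        tables = self._build_seed_table(reference)
        return [
            any(self._maps(mate.sequence, tables) for mate in pair.mates())
            for pair in pairs
        ]


class Minimap2Aligner:
    """Adapter around an external ``minimap2`` binary (short-read preset).

    Invokes ``minimap2 -2 -ax sr`` and derives per-pair status from the SAM
    unmapped flag, matching the samtools ``-f 12 -F 256`` / ``-f 4 -F 256``
    survivor semantics used by the alignment stages.
    """

    name = "minimap2 -2 -ax sr"

    def __init__(self, executable: str = "minimap2"):
        if shutil.which(executable) is None:
            raise RuntimeError(f"aligner executable not found: {executable}")
        self.executable = executable

    def align(self, pairs: Sequence[ReadPair], reference: Reference) -> list[bool]:
        import pysam

        with tempfile.TemporaryDirectory(prefix="hostscrub-mm2-") as tmp:
            tmp_path = Path(tmp)
            ref_fa = tmp_path / "ref.fa"
            with open(ref_fa, "w") as handle:
                for rid, seq in reference:
                    handle.write(f">{rid}\n{seq}\n")
            paired = pairs and pairs[0].r2 is not None
            fq1 = tmp_path / "r1.fq"
            if paired:
                fq2 = tmp_path / "r2.fq"
                write_fastq(pairs, fq1, fq2)
                cmd = [self.executable, "-2", "-ax", "sr", str(ref_fa), str(fq1), str(fq2)]
            else:
                write_fastq(pairs, fq1)
                cmd = [self.executable, "-2", "-ax", "sr", str(ref_fa), str(fq1)]
            sam_path = tmp_path / "out.sam"
            with open(sam_path, "w") as out:
                subprocess.run(cmd, stdout=out, stderr=subprocess.DEVNULL, check=True)
            mapped_ids: set[str] = set()
            with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
                for aln in sam:
                    if aln.is_secondary:  # -F 256
                        continue
                    if not aln.is_unmapped:
                        mapped_ids.add(aln.query_name)
        return [pair.read_id in mapped_ids for pair in pairs]


@dataclass(frozen=True)
class AlignStage:
    """Alignment-based removal against one named reference."""

    reference_id: str
    reference: Reference
    aligner: AlignerContract

    @property
    def description(self) -> str:
        return f"align({self.reference_id})"


@dataclass(frozen=True)
class IndexStage:
    """Index-based removal: either mate classified host drops the pair."""

    index: HostIndex
    config: ScoreConfig

    @property
    def description(self) -> str:
        return f"index({self.index.name},{self.config.metric}>={self.config.threshold})"


Stage = Union[AlignStage, IndexStage]


@dataclass(frozen=True)
class FiltrationPlan:
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("a filtration plan requires at least one stage")


@dataclass
class FiltrationReport:
    """Per-stage telescoping counts, with an optional per-read audit trail."""

    stages: list[dict] = field(default_factory=list)
    removal_stage: Optional[dict[str, str]] = None

    def add(self, description: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {
                "stage": description,
                "input": n_in,
                "removed": n_removed,
                "survivors": n_in - n_removed,
            }
        )

    @property
    def total_input(self) -> int:
        return self.stages[0]["input"] if self.stages else 0

    @property
    def total_survivors(self) -> int:
        return self.stages[-1]["survivors"] if self.stages else 0

    def as_dict(self) -> dict:
        return {
            "stages": self.stages,
            "input": self.total_input,
            "survivors": self.total_survivors,
        }


def align_filter_stage(
    pairs: Iterable[ReadPair],
    reference: Reference,
    aligner: AlignerContract,
) -> list[ReadPair]:
    """Keep only pairs in which no mate aligns to the reference."""
    pairs = list(pairs)
    if not pairs:
        return []
    mapped = aligner.align(pairs, reference)
    return [pair for pair, is_mapped in zip(pairs, mapped) if not is_mapped]


def index_filter_stage(
    pairs: Iterable[ReadPair],
    index: HostIndex,
    config: ScoreConfig,
) -> list[ReadPair]:
    """Remove pairs in which either mate scores as host against the index."""
    survivors = []
    for pair in pairs:
        is_host = any(
            classify_read(matching_lengths(mate, index), config) == "host"
            for mate in pair.mates()
        )
        if not is_host:
            survivors.append(pair)
    return survivors


def run_plan(
    pairs: Iterable[ReadPair],
    plan: FiltrationPlan,
    audit: bool = False,
) -> tuple[list[ReadPair], FiltrationReport]:
    """Apply plan stages in order; counts telescope stage to stage."""
    current = list(pairs)
    report = FiltrationReport(removal_stage={} if audit else None)
    for stage_idx, stage in enumerate(plan.stages):
        n_in = len(current)
        try:
            if isinstance(stage, AlignStage):
                survivors = align_filter_stage(current, stage.reference, stage.aligner)
            else:
                survivors = index_filter_stage(current, stage.index, stage.config)
        except Exception as exc:  # tag failures with the offending stage
            raise RuntimeError(
                f"stage {stage_idx} ({stage.description}) failed: {exc}"
            ) from exc
        if audit:
            survivor_ids = {p.read_id for p in survivors}
            for pair in current:
                if pair.read_id not in survivor_ids:
                    report.removal_stage[pair.read_id] = stage.description
        report.add(stage.description, n_in, n_in - len(survivors))
        current = survivors
    return current, report


def preset_method(
    n: int,
    refs: dict[str, object],
    config: Optional[ScoreConfig] = None,
    aligner: Optional[AlignerContract] = None,
) -> FiltrationPlan:
    """Build the stage list for preset Method 1, 2 or 3.

    ``refs`` maps ``primary_ref`` / ``secondary_ref`` to ``(id, seq)`` lists
    and ``pangenome_set`` to a list of such lists (one per assembly).  The
    index stage always covers the aggregate of all provided references.
    """
    if n not in (1, 2, 3):
        raise ValueError("method must be 1, 2 or 3")
    config = config or ScoreConfig()
    aligner = aligner or SeedExtendAligner()

    def need(key: str):
        if key not in refs or refs[key] is None:
            raise ValueError(f"method {n} requires reference set {key!r}")
        return refs[key]

    pangenomes: Sequence[Reference] = refs.get("pangenome_set") or []
    aggregate: list[tuple[str, str]] = []
    for key in ("primary_ref", "secondary_ref"):
        if refs.get(key):
            aggregate.extend(refs[key])  # type: ignore[arg-type]
    for pan in pangenomes:
        aggregate.extend(pan)
    if not aggregate:
        raise ValueError("no references provided")
    index = refs.get("index")
    if not isinstance(index, HostIndex):
        index = HostIndex(aggregate, name="aggregate")

    stages: list[Stage] = []
    if n in (1, 2):
        primary = need("primary_ref")
        secondary = need("secondary_ref")
        stages.append(AlignStage("primary", primary, aligner))
        stages.append(AlignStage("secondary", secondary, aligner))
    if n == 2:
        if not pangenomes:
            raise ValueError("method 2 requires a pangenome_set")
        for i, pan in enumerate(pangenomes):
            stages.append(AlignStage(f"pangenome_{i}", pan, aligner))
    stages.append(IndexStage(index, config))
    return FiltrationPlan(tuple(stages))
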