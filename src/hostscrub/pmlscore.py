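"""Per-read scores over pseudo-matching-length vectors and host calls.

Three metrics condense a PML vector into one number:

* ``maximum`` — the largest matching length anywhere in the read.
* ``average`` — the mean matching length over all read positions (zeros
  included).
* ``custom`` — a run-aware score that magnifies reads containing long
  contiguous stretches of matches::

      score = (1 / 2L) * ( max(PML) + (sum of run lengths r in R) * ln(|R| + 1) )

  where ``R`` is the set of matching runs longer than the minimum run
  length ``w`` (strictly: ``len(r) > w``), and ``L`` is the read length.

A *matching run* is a maximal stretch of positions over which the matching
length decays by exactly 1 per step — the signature of one contiguous exact
match being consumed left to right.  Its length (the number of positions in
the stretch) is the quantity ``r`` entering the custom score; for an
isolated match of ``m`` bases that decays all the way to zero, the run
length equals the match length ``m``.  Zero values belong to no run.

The default thresholds (maximum 31, average 3.306, custom 0.175 with
``w = 5``) all derive from the same idealized 150 bp read containing a
single contiguous matching run of 31 bases: max = 31; mean = 496/150 ≈
3.306; custom = (31 + 31·ln 2)/300 ≈ 0.175.  The logarithm is natural —
the only base that reproduces 0.175 from that read.  Classification uses
``score >= threshold`` so the idealized boundary read is itself caught.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .msindex import PMLVector

__all__ = [
    "MatchRun",
    "ScoreConfig",
    "DEFAULT_THRESHOLDS",
    "decompose_runs",
    "score_maximum",
    "score_average",
    "score_custom",
    "score",
    "classify_read",
    "grid_search",
]

Metric = Literal["maximum", "average", "custom"]

#: Printed default threshold per metric, all derived from the idealized
#: 150 bp read with one matching run of 31 bases.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "maximum": 31.0,
    "average": 3.306,
    "custom": 0.175,
}


@dataclass(frozen=True)
class MatchRun:
    """A maximal decay-by-1 stretch of positive matching lengths."""

    start: int  # 0-based read position of the run entry
    length: int  # number of positions in the run (the r of the custom score)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("run length must be >= 1")


@dataclass(frozen=True)
class ScoreConfig:
    """Metric, decision threshold and minimum run length for host calls."""

    metric: Metric = "custom"
    threshold: Optional[float] = None
    w: int = 5

    def __post_init__(self) -> None:
        if self.metric not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.threshold is None:
            object.__setattr__(self, "threshold", DEFAULT_THRESHOLDS[self.metric])
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.w < 0:
            raise ValueError("minimum run length w must be >= 0")


def _values(pml: PMLVector | Sequence[int] | np.ndarray) -> np.ndarray:
    if isinstance(pml, PMLVector):
        return pml.values
    return np.asarray(pml, dtype=np.int64)


def decompose_runs(pml: PMLVector | Sequence[int]) -> list[MatchRun]:
    """Split a PML vector into maximal decay-by-1 runs of positive values.

    A run starts at position 0 or wherever the value is not the exact
    decrement of its predecessor, and extends while each successive value
    decreases by exactly 1 and stays positive.
    """
    v = _values(pml)
    runs: list[MatchRun] = []
    i, L = 0, v.size
    while i < L:
        if v[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < L and v[j + 1] == v[j] - 1 and v[j + 1] > 0:
            j += 1
        runs.append(MatchRun(start=i, length=j - i + 1))
        i = j + 1
    return runs


def score_maximum(pml: PMLVector | Sequence[int]) -> float:
    """Largest matching length in the read (0 for an all-zero vector)."""
    v = _values(pml)
    return float(v.max(initial=0))


def score_average(pml: PMLVector | Sequence[int]) -> float:
    """Mean matching length over all read positions, zeros included."""
    v = _values(pml)
    return float(v.mean())


def score_custom(pml: PMLVector | Sequence[int], w: int = 5) -> float:
    """Run-aware score; only runs strictly longer than ``w`` contribute.

    An empty qualifying-run set contributes nothing (ln 1 = 0), leaving
    ``max(PML) / 2L`` as the floor.
    """
    v = _values(pml)
    L = v.size
    if L < 1:
        raise ValueError("read length must be >= 1")
    qualifying = [r.length for r in decompose_runs(v) if r.length > w]
    total = float(v.max(initial=0))
    if qualifying:
        total += sum(qualifying) * math.log(len(qualifying) + 1)
    return total / (2.0 * L)


def score(pml: PMLVector | Sequence[int], config: ScoreConfig) -> float:
    """Apply the configured metric to a PML vector."""
    if config.metric == "maximum":
        return score_maximum(pml)
    if config.metric == "average":
        return score_average(pml)
    return score_custom(pml, w=config.w)


def classify_read(pml: PMLVector | Sequence[int], config: ScoreConfig) -> str:
    """Call ``"host"`` iff the configured score reaches the threshold."""
    return "host" if score(pml, config) >= config.threshold else "nonhost"


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """Grid used to validate the custom metric: thresholds 0.145–0.200 by
    0.005 (12 values) crossed with minimum run lengths 2–12 (11 values)."""
    thresholds = np.round(np.arange(29, 41) * 0.005, 3)
    w_values = np.arange(2, 13)
    return thresholds, w_values


def grid_search(
    labeled_reads: Iterable[tuple[PMLVector | Sequence[int], str]],
    thresholds: Optional[Sequence[float]] = None,
    w_values: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Sweep (threshold, w) over labeled PML vectors with the custom metric.

    Returns one row per combination with human recall, human precision and
    the microbial loss rate (fraction of microbial reads called host).
    Labels must be ``"human"`` or ``"microbial"``.
    """
    if thresholds is None or w_values is None:
        dflt_t, dflt_w = default_grid()
        thresholds = dflt_t if thresholds is None else thresholds
        w_values = dflt_w if w_values is None else w_values
    reads = [( _values(pml), label) for pml, label in labeled_reads]
    if not reads:
        raise ValueError("labeled read set is empty")
    bad = {label for _, label in reads} - {"human", "microbial"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    labels = np.array([label for _, label in reads])
    is_human = labels == "human"
    n_human = int(is_human.sum())
    n_microbial = int((~is_human).sum())

    # run decomposition is w-independent; do it once per read
    decomposed = [
        (float(v.max(initial=0)), [r.length for r in decompose_runs(v)], v.size)
        for v, _ in reads
    ]
    rows = []
    for w in w_values:
        scores = np.array(
            [
                (
                    mx
                    + (
                        sum(q) * math.log(len(q) + 1)
                        if (q := [r for r in run_lengths if r > w])
                        else 0.0
                    )
                )
                / (2.0 * L)
                for mx, run_lengths, L in decomposed
            ]
        )
        for thr in thresholds:
            host = scores >= thr
            tp = int((host & is_human).sum())
            fp = int((host & ~is_human).sum())
            rows.append(
                {
                    "threshold": float(thr),
                    "w": int(w),
                    "recall_human": tp / n_human if n_human else np.nan,
                    "precision_human": tp / (tp + fp) if (tp + fp) else np.nan,
                    "microbial_loss_rate": fp / n_microbial if n_microbial else np.nan,
                }
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["threshold", "w"], ignore_index=True)
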