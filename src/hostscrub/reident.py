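"""Re-identification likelihood audit for leaked human reads.

Given (i) per-SNP-site read counts from the putatively microbial fraction
of a metagenome and (ii) a genotype panel with allele frequencies, this
module scores how likely each panel sample is to be the read donor.

Model (error probability ``eps``, independent errors).  At site ``i``
covered by ``n_i`` reads of which ``k_i`` carry the reference allele, the
likelihood that a diploid genotype with ``g`` alternative alleles produced
the reads is::

    L_i(g, n, k) = (1/2^n) * [(2-g)*eps + g*(1-eps)]^(n-k)
                           * [g*eps + (2-g)*(1-eps)]^k

The per-sample likelihood score is the natural-log sum over the retained
independent sites, ``LS_j = sum_i log L_i(g_ij, n_i, k_i)``.  The
population background assumes Hardy-Weinberg genotype frequencies
``{(1-p)^2, 2p(1-p), p^2}`` at each site; the background mean ``E`` and
variance ``V`` are per-site moments of ``log L_i`` under that distribution,
summed over sites (site independence).  Each sample is then standardized,
``z_j = (LS_j - E)/sqrt(V)``, and converted to a two-sided p-value from the
standard normal.  A *match* additionally requires ``z > 0``: the donor must
be more likely than a random member of the population, not less.

Approximately independent sites are obtained by greedy LD pruning in
sliding windows (defaults: window 100 sites, step 30, r^2 threshold 0.1,
with r^2 the squared Pearson correlation of genotype dosages); the
lower-minor-allele-frequency member of a correlated pair is dropped.

All products are computed in log space; scores stay finite for per-site
depths up to at least 1e4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import ReadRecord

__all__ = [
    "GenotypePanel",
    "PileupCounts",
    "ReidentConfig",
    "ReidentResult",
    "site_likelihood",
    "log_site_likelihood",
    "likelihood_score",
    "likelihood_scores_all_samples",
    "background_moments",
    "standardize_and_test",
    "ld_prune",
    "pileup_from_reads",
    "all_vs_all",
    "bonferroni_lines",
    "read_genotype_table",
    "write_genotype_table",
    "read_pileup_table",
    "write_pileup_table",
]


@dataclass
class GenotypePanel:
    """Site × sample genotype matrix with per-site allele frequencies.

    ``genotypes[i, j]`` counts alternative alleles (0/1/2) for sample ``j``
    at biallelic SNP site ``i``.  ``freqs`` holds the alternative-allele
    frequency per site; when not supplied it is derived from the panel
    itself (mean dosage / 2).
    """

    site_ids: list[str]
    positions: np.ndarray
    ref_alleles: list[str]
    alt_alleles: list[str]
    genotypes: np.ndarray
    sample_ids: list[str]
    freqs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n_sites, n_samples = self.genotypes.shape
        if len(self.site_ids) != n_sites or len(self.sample_ids) != n_samples:
            raise ValueError("genotype matrix shape does not match id lists")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0, 1 or 2 (no missing values)")
        if self.freqs is None:
            self.freqs = self.genotypes.mean(axis=1) / 2.0
        self.freqs = np.asarray(self.freqs, dtype=float)
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def subset_sites(self, keep: Sequence[int]) -> "GenotypePanel":
        keep = np.asarray(keep, dtype=np.int64)
        return GenotypePanel(
            site_ids=[self.site_ids[i] for i in keep],
            positions=self.positions[keep],
            ref_alleles=[self.ref_alleles[i] for i in keep],
            alt_alleles=[self.alt_alleles[i] for i in keep],
            genotypes=self.genotypes[keep],
            sample_ids=list(self.sample_ids),
            freqs=self.freqs[keep],
        )


@dataclass
class PileupCounts:
    """Per-site covering-read counts: ``n`` total, ``k`` reference-allele."""

    site_ids: list[str]
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        if not (len(self.site_ids) == self.n.size == self.k.size):
            raise ValueError("pileup arrays must share one length")
        if (self.n < 1).any():
            raise ValueError("sites with zero coverage must be excluded")
        if ((self.k < 0) | (self.k > self.n)).any():
            raise ValueError("need 0 <= k <= n at every site")

    @property
    def n_sites(self) -> int:
        return self.n.size

    @property
    def bases_used(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class ReidentConfig:
    """Audit parameters (sequencing error, pruning, significance policy)."""

    epsilon: float = 1e-6
    prune_window: int = 100
    prune_step: int = 30
    r2_max: float = 0.1
    min_mapq: int = 40
    min_baseq: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must be in (0, 0.5)")


@dataclass
class ReidentResult:
    """Scores for every panel sample against one metagenome read set."""

    sample_ids: list[str]
    ls: np.ndarray
    e_background: float
    v_background: float
    z: np.ndarray
    p: np.ndarray
    bases_used: int
    n_sites: int

    def best_match(self) -> tuple[str, float, float]:
        """(sample_id, z, p) of the top positive-z candidate."""
        order = int(np.argmax(self.z))
        return self.sample_ids[order], float(self.z[order]), float(self.p[order])


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def log_site_likelihood(
    g: int | np.ndarray, n: int | np.ndarray, k: int | np.ndarray, eps: float
) -> np.ndarray:
    """Natural log of the per-site read likelihood; vectorized over inputs."""
    g = np.asarray(g, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype g must be 0, 1 or 2")
    alt_factor = (2.0 - g) * eps + g * (1.0 - eps)  # weight of each alt read
    ref_factor = g * eps + (2.0 - g) * (1.0 - eps)  # weight of each ref read
    return (
        -n * math.log(2.0)
        + (n - k) * np.log(alt_factor)
        + k * np.log(ref_factor)
    )


def site_likelihood(g: int, n: int, k: int, eps: float) -> float:
    """Per-site likelihood on the linear scale (log space internally)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(np.exp(log_site_likelihood(g, n, k, eps)))


def likelihood_score(
    genotypes: Sequence[int] | np.ndarray,
    pileup: PileupCounts,
    eps: float = 1e-6,
) -> float:
    """``LS_j``: summed log likelihood of one sample over pileup sites."""
    g = np.asarray(genotypes)
    if g.size != pileup.n_sites:
        raise ValueError("genotype vector does not match pileup sites")
    if g.size == 0:
        return 0.0
    return float(log_site_likelihood(g, pileup.n, pileup.k, eps).sum())


def _loglik_table(pileup: PileupCounts, eps: float) -> np.ndarray:
    """Per-site log likelihoods for g = 0, 1, 2; shape (n_sites, 3)."""
    return np.stack(
        [log_site_likelihood(g, pileup.n, pileup.k, eps) for g in (0, 1, 2)],
        axis=1,
    )


def likelihood_scores_all_samples(
    panel: GenotypePanel, pileup: PileupCounts, eps: float = 1e-6
) -> np.ndarray:
    """``LS_j`` for every panel sample at once (table lookup per site)."""
    table = _loglik_table(pileup, eps)
    rows = np.arange(panel.n_sites)[:, None]
    return table[rows, panel.genotypes].sum(axis=0)


def background_moments(
    p: np.ndarray,
    pileup: PileupCounts,
    eps: float = 1e-6,
) -> tuple[float, float]:
    """Population mean and variance of the likelihood score under HWE.

    Per site, the genotype is distributed ``{(1-p)^2, 2p(1-p), p^2}``; the
    totals sum per-site moments (independent sites).
    """
    p = np.asarray(p, dtype=float)
    if p.size != pileup.n_sites:
        raise ValueError("frequency vector does not match pileup sites")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    weights = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
    table = _loglik_table(pileup, eps)
    e_site = (weights * table).sum(axis=1)
    v_site = (weights * (table - e_site[:, None]) ** 2).sum(axis=1)
    return float(e_site.sum()), float(v_site.sum())


def standardize_and_test(
    ls: float | np.ndarray, e: float, v: float
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize likelihood scores and compute two-sided normal p-values."""
    if v <= 0:
        raise ValueError("background variance must be positive (got V <= 0)")
    z = (np.asarray(ls, dtype=float) - e) / math.sqrt(v)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return z, p


# ---------------------------------------------------------------------------
# Site selection
# ---------------------------------------------------------------------------


def _minor_allele_freq(p: np.ndarray) -> np.ndarray:
    return np.minimum(p, 1 - p)


def ld_prune(
    panel: GenotypePanel,
    window: int = 100,
    step: int = 30,
    r2_max: float = 0.1,
) -> list[int]:
    """Greedy sliding-window LD pruning; returns retained site indices.

    Within each window of ``window`` sites (advanced by ``step``), any pair
    of retained sites with dosage ``r^2 > r2_max`` loses its lower-MAF
    member (ties drop the later position); this repeats until the window is
    stable.  Monomorphic sites (zero variance) are uninformative and are
    dropped up front.
    """
    if panel.n_sites == 0:
        raise ValueError("panel has no sites")
    G = panel.genotypes.astype(float)
    variances = G.var(axis=1)
    retained = set(np.nonzero(variances > 0)[0].tolist())
    maf = _minor_allele_freq(panel.freqs)
    n_sites = panel.n_sites
    starts = range(0, max(1, n_sites - 1), step) if n_sites > window else [0]
    for w0 in starts:
        window_idx = [i for i in range(w0, min(w0 + window, n_sites)) if i in retained]
        changed = True
        while changed and len(window_idx) > 1:
            changed = False
            sub = G[window_idx]
            corr = np.corrcoef(sub)
            r2 = corr**2
            np.fill_diagonal(r2, 0.0)
            hit = np.argwhere(r2 > r2_max)
            if hit.size:
                a, b = (window_idx[int(hit[0][0])], window_idx[int(hit[0][1])])
                if maf[a] < maf[b]:
                    drop = a
                elif maf[b] < maf[a]:
                    drop = b
                else:
                    drop = max(a, b)  # tie: later position
                retained.discard(drop)
                window_idx.remove(drop)
                changed = True
        if w0 + window >= n_sites:
            break
    return sorted(retained)


def pileup_from_reads(
    reads: Iterable[ReadRecord],
    panel: GenotypePanel,
    min_mapq: int = 40,
    min_baseq: int = 20,
) -> PileupCounts:
    """Per-site (n, k) counts from placed reads.

    Each read must carry a ``placement`` ``(genome_id, start, end, strand,
    mapq)``; reads below ``min_mapq`` are skipped and bases below
    ``min_baseq`` do not count.  ``k`` counts reference-allele bases; reads
    showing any other allele still count in ``n``.  Sites covered by no
    passing read are excluded.
    """
    positions = panel.positions
    order = np.argsort(positions)
    sorted_pos = positions[order]
    n = np.zeros(panel.n_sites, dtype=np.int64)
    k = np.zeros(panel.n_sites, dtype=np.int64)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for read in reads:
        if read.placement is None:
            raise ValueError(f"read {read.read_id!r} has no placement")
        _, start, end, strand, mapq = read.placement
        if mapq < min_mapq:
            continue
        lo = int(np.searchsorted(sorted_pos, start, side="left"))
        hi = int(np.searchsorted(sorted_pos, end, side="left"))
        for idx in order[lo:hi]:
            pos = int(positions[idx])
            if strand == "+":
                off = pos - start
                base = read.sequence[off]
                q = read.qualities[off] if read.qualities else "I"
            else:
                off = end - 1 - pos
                base = comp.get(read.sequence[off], "N")
                q = read.qualities[off] if read.qualities else "I"
            if ord(q) - 33 < min_baseq:
                continue
            n[idx] += 1
            if base == panel.ref_alleles[idx]:
                k[idx] += 1
    covered = np.nonzero(n > 0)[0]
    return PileupCounts(
        site_ids=[panel.site_ids[i] for i in covered],
        n=n[covered],
        k=k[covered],
    )


# ---------------------------------------------------------------------------
# All-vs-all audit
# ---------------------------------------------------------------------------


def bonferroni_lines(n_samples: int, n_metagenomes: int, alpha: float = 0.05) -> dict:
    """Study-wide and per-metagenome Bonferroni significance thresholds."""
    n_tests = n_samples * n_metagenomes
    return {
        "n_tests": n_tests,
        "study_wide": alpha / n_tests,
        "per_metagenome": alpha / n_samples,
    }


def score_metagenome(
    pileup: PileupCounts,
    panel: GenotypePanel,
    config: ReidentConfig = ReidentConfig(),
    prune: bool = True,
) -> Optional[ReidentResult]:
    """Full audit of one metagenome: site selection, LS, z, p per sample.

    Site selection is cover-then-clump: the pileup defines the covered
    sites, then LD pruning runs on that covered subset.  Returns ``None``
    when the read set is not evaluable (no usable sites, or a degenerate
    background with zero variance).
    """
    id_to_idx = {sid: i for i, sid in enumerate(panel.site_ids)}
    covered_idx = [id_to_idx[sid] for sid in pileup.site_ids if sid in id_to_idx]
    if not covered_idx:
        return None
    sub_panel = panel.subset_sites(covered_idx)
    pile_by_id = dict(zip(pileup.site_ids, zip(pileup.n, pileup.k)))
    if prune:
        keep_local = ld_prune(
            sub_panel, config.prune_window, config.prune_step, config.r2_max
        )
        if not keep_local:
            return None
        sub_panel = sub_panel.subset_sites(keep_local)
    counts = [pile_by_id[sid] for sid in sub_panel.site_ids]
    sub_pile = PileupCounts(
        site_ids=list(sub_panel.site_ids),
        n=[c[0] for c in counts],
        k=[c[1] for c in counts],
    )
    e, v = background_moments(sub_panel.freqs, sub_pile, config.epsilon)
    if v <= 0:
        return None
    ls = likelihood_scores_all_samples(sub_panel, sub_pile, config.epsilon)
    z, p = standardize_and_test(ls, e, v)
    return ReidentResult(
        sample_ids=list(panel.sample_ids),
        ls=ls,
        e_background=e,
        v_background=v,
        z=z,
        p=p,
        bases_used=sub_pile.bases_used,
        n_sites=sub_pile.n_sites,
    )


def all_vs_all(
    pileups: Sequence[Optional[PileupCounts]],
    panel: GenotypePanel,
    config: ReidentConfig = ReidentConfig(),
    metagenome_ids: Optional[Sequence[str]] = None,
) -> dict:
    """Score every panel sample against every metagenome read set.

    Returns p-value and z matrices (samples × metagenomes; NaN where a read
    set is not evaluable), the Bonferroni lines for the full test count, and
    the matches significant at the study-wide line (z > 0 required).
    """
    if panel.n_samples == 0:
        raise ValueError("empty genotype panel")
    if not pileups:
        raise ValueError("need at least one metagenome read set")
    J, M = panel.n_samples, len(pileups)
    if metagenome_ids is None:
        metagenome_ids = [f"metagenome{m}" for m in range(M)]
    pmat = np.full((J, M), np.nan)
    zmat = np.full((J, M), np.nan)
    bases = np.zeros(M, dtype=np.int64)
    for m, pile in enumerate(pileups):
        result = score_metagenome(pile, panel, config) if pile is not None else None
        if result is None:
            continue
        pmat[:, m] = result.p
        zmat[:, m] = result.z
        bases[m] = result.bases_used
    lines = bonferroni_lines(J, M)
    sig = np.argwhere((zmat > 0) & (pmat < lines["study_wide"]))
    return {
        "p": pd.DataFrame(pmat, index=list(panel.sample_ids), columns=list(metagenome_ids)),
        "z": pd.DataFrame(zmat, index=list(panel.sample_ids), columns=list(metagenome_ids)),
        "bases_used": dict(zip(metagenome_ids, bases.tolist())),
        "n_tests": lines["n_tests"],
        "bonferroni_study_wide": lines["study_wide"],
        "bonferroni_per_metagenome": lines["per_metagenome"],
        "significant_pairs": [
            (panel.sample_ids[i], metagenome_ids[m]) for i, m in sig
        ],
    }


# ---------------------------------------------------------------------------
# Plain-text interchange
# ---------------------------------------------------------------------------


def write_genotype_table(panel: GenotypePanel, path: str | Path) -> None:
    """TSV: site, pos, ref, alt, p, then one 0/1/2 column per sample."""
    frame = pd.DataFrame(
        {
            "site": panel.site_ids,
            "pos": panel.positions,
            "ref": panel.ref_alleles,
            "alt": panel.alt_alleles,
            "p": panel.freqs,
        }
    )
    for j, sid in enumerate(panel.sample_ids):
        frame[sid] = panel.genotypes[:, j]
    frame.to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path) -> GenotypePanel:
    frame = pd.read_csv(path, sep="\t")
    meta = ["site", "pos", "ref", "alt", "p"]
    sample_ids = [c for c in frame.columns if c not in meta]
    return GenotypePanel(
        site_ids=frame["site"].astype(str).tolist(),
        positions=frame["pos"].to_numpy(),
        ref_alleles=frame["ref"].astype(str).tolist(),
        alt_alleles=frame["alt"].astype(str).tolist(),
        genotypes=frame[sample_ids].to_numpy(),
        sample_ids=sample_ids,
        freqs=frame["p"].to_numpy(),
    )


def write_pileup_table(pileup: PileupCounts, path: str | Path) -> None:
    """TSV: site, n, k."""
    pd.DataFrame({"site": pileup.site_ids, "n": pileup.n, "k": pileup.k}).to_csv(
        path, sep="\t", index=False
    )


def read_pileup_table(path: str | Path) -> PileupCounts:
    frame = pd.read_csv(path, sep="\t")
    return PileupCounts(
        site_ids=frame["site"].astype(str).tolist(),
        n=frame["n"].to_numpy(),
        k=frame["k"].to_numpy(),
    )


def read_genotype_vcf(path: str | Path) -> GenotypePanel:
    """Load a biallelic-SNP genotype panel from a (text) VCF with GT fields.

    Multi-allelic and non-SNP records are skipped; allele frequencies are
    derived from the panel genotypes.
    """
    import pysam

    site_ids, positions, refs, alts, rows = [], [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            dosages = []
            ok = True
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    ok = False
                    break
                dosages.append(sum(gt))
            if not ok:
                continue
            site_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            positions.append(rec.pos - 1)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            rows.append(dosages)
    return GenotypePanel(
        site_ids=site_ids,
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=refs,
        alt_alleles=alts,
        genotypes=np.array(rows, dtype=np.int8),
        sample_ids=sample_ids,
    )
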