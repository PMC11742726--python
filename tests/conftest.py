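"""Shared fixtures: small deterministic genomes, mixtures and panels.

Everything is generated programmatically from fixed seeds; nothing is read
from disk.  The heavier benchmark mixture used by the end-to-end filtration
tests is session-scoped so the index and alignments are built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from hostscrub import hostfilter, msindex, pmlscore, simulate


@pytest.fixture(scope="session")
def small_genomes():
    """A 10 kb base genome, 12 haplotypes, and 8 microbial genomes."""
    base = simulate.make_genome(
        10_000, gc=0.41, seed=11, genome_id="human_base", kind="human_base"
    )
    haplotypes = simulate.make_haplotypes(
        base, 12, snp_rate=0.001, indel_rate=0.0001, seed=12
    )
    microbes = [
        simulate.make_genome(10_000, gc=0.45, seed=100 + i, genome_id=f"microbe{i}")
        for i in range(8)
    ]
    return base, haplotypes, microbes


@pytest.fixture(scope="session")
def benchmark_mixture(small_genomes):
    """Seeded 10^4-pair 50/50 mixture with two held-out source haplotypes.

    Returns (pairs, truth, refs) where refs is the named reference mapping
    consumed by :func:`hostscrub.hostfilter.preset_method`: the base genome
    as primary, one reserved haplotype as the secondary assembly, and the
    remaining non-source haplotypes as the pangenome set.
    """
    base, haplotypes, microbes = small_genomes
    spec = simulate.MixtureSpec(n_reads=10_000, seed=2024, frac_human=0.5)
    sources = haplotypes[:2]
    pairs, truth = simulate.make_mixture(sources, microbes, spec)
    kept = simulate.holdout_references(haplotypes, [g.id for g in sources])
    secondary, *pangenomes = kept
    refs = {
        "primary_ref": [(base.id, base.sequence)],
        "secondary_ref": [(secondary.id, secondary.sequence)],
        "pangenome_set": [[(g.id, g.sequence)] for g in pangenomes],
    }
    return pairs, truth, refs


@pytest.fixture(scope="session")
def method_survivors(benchmark_mixture):
    """Survivor sets for preset Methods 1-3 on the benchmark mixture."""
    pairs, truth, refs = benchmark_mixture
    config = pmlscore.ScoreConfig()
    aligner = hostfilter.SeedExtendAligner()
    aggregate = list(refs["primary_ref"]) + list(refs["secondary_ref"])
    for pan in refs["pangenome_set"]:
        aggregate.extend(pan)
    shared = dict(refs, index=msindex.build_index(aggregate, name="aggregate"))
    out = {}
    for n in (1, 2, 3):
        plan = hostfilter.preset_method(n, shared, config, aligner)
        survivors, report = hostfilter.run_plan(pairs, plan)
        out[n] = (survivors, report)
    return out, truth


@pytest.fixture
def theoretical_pml():
    """The idealized 150 bp read: one contiguous matching run of 31."""
    return np.concatenate([np.arange(31, 0, -1), np.zeros(119, dtype=np.int64)])
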