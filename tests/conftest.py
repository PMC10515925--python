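"""Shared fixtures: every dataset is generated in-process from seeds."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from biasbench.assignment import AlignmentIndex, assign_reads, build_all_contexts
from biasbench.fixtures import (
    TruthTable,
    build_diploid_consensus,
    perfect_align,
    random_phased_variants,
    random_reference,
    simulate_reads,
)
from biasbench.variants import PhasedVariant, remove_overlapping_variants


@dataclass
class World:
    """A complete small simulation universe."""

    chrom: str
    reference: str
    variants: list[PhasedVariant]
    hap1: object
    hap2: object
    reads: list
    truth: TruthTable
    alignments: list
    index: AlignmentIndex


def make_world(
    length: int = 120_000,
    n_snv: int = 150,
    n_indel: int = 50,
    seed: int = 7,
    coverage: float = 15.0,
    error_rate: float = 0.0,
    min_spacing: int = 150,
) -> World:
    chrom, ref = random_reference(length, seed=seed)
    raw = random_phased_variants(
        ref, chrom, n_snv=n_snv, n_indel=n_indel, seed=seed + 1, min_spacing=min_spacing
    )
    kept, _ = remove_overlapping_variants(raw)
    hap1, hap2 = build_diploid_consensus(ref, chrom, kept)
    reads, rows = simulate_reads(
        hap1,
        hap2,
        coverage_per_hap=coverage,
        error_rate=error_rate,
        seed_hap1=seed + 10,
        seed_hap2=seed + 11,
    )
    truth = TruthTable(rows)
    alignments = perfect_align(reads, truth, hap1, hap2)
    return World(
        chrom, ref, kept, hap1, hap2, reads, truth, alignments, AlignmentIndex(alignments)
    )


@pytest.fixture(scope="session")
def world() -> World:
    """120 kbp diploid universe with error-free reads, perfectly aligned."""
    return make_world()


@pytest.fixture(scope="session")
def world_assignments(world):
    """(context, naive) per-site assignments on the shared world."""
    ctx = assign_reads(world.index, world.variants, world.reference, "context")
    naive = assign_reads(world.index, world.variants, world.reference, "naive")
    return ctx, naive


@pytest.fixture(scope="session")
def world_contexts(world):
    return build_all_contexts(world.variants, world.reference)
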