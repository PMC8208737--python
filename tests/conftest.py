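"""Shared fixtures: the two-allele four-site toy community and helpers.

The toy encodes the classic worked example — three reads 0011, 0001, 0100
over four SNV sites, written with alleles 0 → A and 1 → C — for which every
marginal, conditional, edge score and traversal step has been hand-derived
and cross-checked by brute-force enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from mihap import (
    CommunitySpec,
    CooccurrenceMatrix,
    ReadObservation,
    build_matrix,
    evenly_spaced_positions,
    extract_observations,
    generate_community,
    simulate_reads,
    write_community,
    write_sam,
)

# 0 -> A, 1 -> C
TOY_READS = ("AACC", "AAAC", "ACAA")  # 0011, 0001, 0100
TOY_CHIMERAS = ("AAAA", "ACAC")  # 0000 and 0101: unsupported by any read


def toy_observations() -> list[ReadObservation]:
    return [
        ReadObservation(f"toy{k}", 1, 4, tuple(r)) for k, r in enumerate(TOY_READS)
    ]


@pytest.fixture
def toy_matrix() -> CooccurrenceMatrix:
    return build_matrix(toy_observations(), 4)


@pytest.fixture
def toy_community_spec() -> CommunitySpec:
    # one full-length read per "haplotype": the three toy reads, pre-aligned
    return CommunitySpec(
        region_length=12,
        n_haplotypes=3,
        snv_positions=(2, 5, 8, 11),
        alleles=TOY_READS,
        read_length=12,
        coverage=1.0,
        error_rate=0.0,
        seed=0,
        contig="toy",
    )


@pytest.fixture
def toy_sam(tmp_path, toy_community_spec):
    """The toy serialized as a SAM fixture through the simulator."""
    community = generate_community(toy_community_spec)
    reads = simulate_reads(community)
    path = tmp_path / "toy.sam"
    write_sam(reads, community, str(path))
    return path, community


def community_matrix(spec: CommunitySpec, tmp_path):
    """simulate → SAM → ingest → matrix, against the planted panel."""
    community = generate_community(spec)
    reads = simulate_reads(community)
    tmp_path.mkdir(parents=True, exist_ok=True)
    sam = tmp_path / "reads.sam"
    write_sam(reads, community, str(sam))
    observations, stats = extract_observations(str(sam), community.panel)
    H = build_matrix(observations, community.panel)
    return community, H, observations, stats


def random_matrix(
    rng: np.random.Generator,
    n: int,
    n_reads: int,
    symbols: str = "ACG",
) -> CooccurrenceMatrix:
    """A matrix built from random contiguous read observations."""
    H = CooccurrenceMatrix(n)
    for k in range(n_reads):
        first = int(rng.integers(1, n + 1))
        last = int(rng.integers(first, n + 1))
        syms = tuple(rng.choice(list(symbols), size=last - first + 1))
        H.observe_read(ReadObservation(f"r{k}", first, last, syms))
    return H
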