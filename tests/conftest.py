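"""Shared fixtures: a small simulated genome and datasets built from it."""

from __future__ import annotations

import numpy as np
import pytest

from nonsenseq import pipeline
from nonsenseq.genome_io import GeneRecord, GenomicInterval, RegionKind
from nonsenseq.synthetic_genome import GenomeSimParams, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """30-gene simulated genome used across module tests."""
    return simulate_genome(GenomeSimParams(n_genes=30, seed=7))


@pytest.fixture(scope="session")
def small_built(small_sim):
    """Labeled residue dataset built from the 30-gene genome."""
    return pipeline.build_residue_dataset(small_sim.genes)


@pytest.fixture(scope="session")
def small_cv(small_built):
    """A cheap grouped cross-validation run (5 folds, 2-member ensembles)."""
    from nonsenseq import evaluation

    cv = evaluation.run_cross_validation(
        small_built.dataset, k=5, seed=3, n_members=2
    )
    return cv


def make_gene(
    coding_parts: list[str],
    introns: list[str] | None = None,
    utr5: str = "",
    utr3: str = "",
    gene_id: str = "toy",
    isoforms: list[list[int]] | None = None,
) -> GeneRecord:
    """Assemble a GeneRecord from explicit sequence pieces.

    ``isoforms`` selects coding parts by index per isoform (default: one
    isoform using all parts).
    """
    introns = introns or [""] * max(len(coding_parts) - 1, 0)
    assert len(introns) == max(len(coding_parts) - 1, 0)
    seq = utr5
    regions: list[GenomicInterval] = []
    exon_ivs: list[GenomicInterval] = []
    if utr5:
        regions.append(GenomicInterval(0, len(utr5), RegionKind.UTR5))
    pos = len(utr5)
    for i, part in enumerate(coding_parts):
        iv = GenomicInterval(pos, pos + len(part), RegionKind.EXON)
        exon_ivs.append(iv)
        regions.append(iv)
        seq += part
        pos += len(part)
        if i < len(coding_parts) - 1 and introns[i]:
            regions.append(GenomicInterval(pos, pos + len(introns[i]), RegionKind.INTRON))
            seq += introns[i]
            pos += len(introns[i])
    if utr3:
        regions.append(GenomicInterval(pos, pos + len(utr3), RegionKind.UTR3))
        seq += utr3
    iso_lists = (
        [[exon_ivs[i] for i in sel] for sel in isoforms]
        if isoforms is not None else [exon_ivs]
    )
    return GeneRecord(gene_id, "NP", seq, iso_lists, regions)


def random_nt(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def random_protein(rng: np.random.Generator, n: int) -> str:
    from nonsenseq.genome_io import STANDARD_AA

    return "".join(rng.choice(list(STANDARD_AA), size=n))
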