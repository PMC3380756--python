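"""Synthetic annotated genomes for end-to-end offline testing.

The generator emulates the statistical structure the nonsense detector
exploits in real genomes, without mimicking any particular organism:

* genes with exon/intron/UTR architecture (coding length a multiple of 3),
* proteins composed of ordered and disordered segments drawn from two
  composition regimes (order-promoting residues up-weighted in ordered
  segments, disorder-promoting residues in disordered ones),
* coding sequence obtained by reverse translation with uniform synonymous
  codon choice (stop-free in frame 0 by construction),
* non-coding sequence (introns, UTRs) from an order-0 GC-biased model.

Frame-shifted and non-coding translations of such genes differ from the
true proteins in windowed composition — the contrast the predictor must
learn.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    STANDARD_AA,
    GeneRecord,
    GenomicInterval,
    RegionKind,
    _CODON_TABLE,
    write_annotated_genes,
)

DISORDER_PROMOTING = "RQSEKGP"
ORDER_PROMOTING = "WYFILVCN"


def _regime_weights(promoted: str, factor: float = 2.5) -> np.ndarray:
    w = np.array([factor if a in promoted else 1.0 for a in STANDARD_AA])
    return w / w.sum()


@dataclass
class GenomeSimParams:
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (1, 8)
    exon_length_range: tuple[int, int] = (60, 300)   # nt; totals forced to %3 == 0
    intron_length_range: tuple[int, int] = (60, 2000)
    utr_length_range: tuple[int, int] = (0, 300)
    ordered_aa_weights: np.ndarray = field(
        default_factory=lambda: _regime_weights(ORDER_PROMOTING)
    )
    disordered_aa_weights: np.ndarray = field(
        default_factory=lambda: _regime_weights(DISORDER_PROMOTING)
    )
    disordered_segment_fraction: float = 0.3
    disordered_segment_mean_length: int = 60  # aa; geometric block lengths
    noncoding_gc: float = 0.55
    alt_splice_fraction: float = 0.3  # genes given a second, exon-skipping isoform
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_length_range",
                     "intron_length_range", "utr_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        for name in ("ordered_aa_weights", "disordered_aa_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (20,) or np.any(w <= 0) or abs(w.sum() - 1) > 1e-9:
                raise ValueError(f"{name} must be 20 positive weights summing to 1")
            setattr(self, name, w)
        if not 0 <= self.disordered_segment_fraction <= 1:
            raise ValueError("disordered_segment_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "exon_count_range": list(self.exon_count_range),
            "exon_length_range": list(self.exon_length_range),
            "intron_length_range": list(self.intron_length_range),
            "utr_length_range": list(self.utr_length_range),
            "ordered_aa_weights": self.ordered_aa_weights.tolist(),
            "disordered_aa_weights": self.disordered_aa_weights.tolist(),
            "disordered_segment_fraction": self.disordered_segment_fraction,
            "disordered_segment_mean_length": self.disordered_segment_mean_length,
            "noncoding_gc": self.noncoding_gc,
            "alt_splice_fraction": self.alt_splice_fraction,
            "seed": self.seed,
        }


@dataclass
class SimulatedGenome:
    genes: list[GeneRecord]
    strands: list[str]
    proteins: dict[str, str]               # gene_id -> truth protein
    region_labels: dict[str, np.ndarray]   # gene_id -> per-nt kind strings
    params: GenomeSimParams


# one uniform-synonymous reverse-translation table
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.items():
    if aa != "*":
        _SYNONYMS.setdefault(aa, []).append(codon)
for codons in _SYNONYMS.values():
    codons.sort()


def _sample_protein(n_aa: int, params: GenomeSimParams, rng: np.random.Generator) -> str:
    """Protein as alternating ordered/disordered blocks; block lengths are
    geometric with means chosen so the expected disordered fraction matches
    the requested one."""
    frac = params.disordered_segment_fraction
    mean_dis = params.disordered_segment_mean_length
    aa_list = list(STANDARD_AA)
    if frac == 0:
        return "".join(rng.choice(aa_list, size=n_aa, p=params.ordered_aa_weights))
    if frac == 1:
        return "".join(rng.choice(aa_list, size=n_aa, p=params.disordered_aa_weights))
    mean_ord = max(1.0, mean_dis * (1 - frac) / frac)
    out: list[str] = []
    disordered = rng.random() < frac
    while len(out) < n_aa:
        mean = mean_dis if disordered else mean_ord
        block = 1 + rng.geometric(1.0 / mean)
        w = params.disordered_aa_weights if disordered else params.ordered_aa_weights
        out.extend(rng.choice(aa_list, size=min(block, n_aa - len(out)), p=w))
        disordered = not disordered
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _SYNONYMS[a][rng.integers(len(_SYNONYMS[a]))] for a in protein
    )


def _sample_noncoding(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def simulate_genome(params: GenomeSimParams) -> SimulatedGenome:
    """Generate ``params.n_genes`` annotated genes with truth tables."""
    rng = np.random.default_rng(params.seed)
    genes: list[GeneRecord] = []
    strands: list[str] = []
    proteins: dict[str, str] = {}
    region_labels: dict[str, np.ndarray] = {}

    for g in range(params.n_genes):
        gene_id = f"gene{g + 1:04d}"
        n_exons = int(rng.integers(params.exon_count_range[0],
                                   params.exon_count_range[1] + 1))
        exon_lens = rng.integers(params.exon_length_range[0],
                                 params.exon_length_range[1] + 1, size=n_exons)
        # force total coding length to a codon multiple by trimming the last exon
        excess = int(exon_lens.sum()) % 3
        exon_lens[-1] -= excess
        total_aa = int(exon_lens.sum()) // 3

        protein = _sample_protein(total_aa, params, rng)
        cds = _reverse_translate(protein, rng)

        intron_lens = rng.integers(params.intron_length_range[0],
                                   params.intron_length_range[1] + 1,
                                   size=max(n_exons - 1, 0))
        utr5_len = int(rng.integers(params.utr_length_range[0],
                                    params.utr_length_range[1] + 1))
        utr3_len = int(rng.integers(params.utr_length_range[0],
                                    params.utr_length_range[1] + 1))

        parts: list[str] = []
        regions: list[GenomicInterval] = []
        exons: list[GenomicInterval] = []
        pos = 0
        if utr5_len:
            parts.append(_sample_noncoding(utr5_len, params.noncoding_gc, rng))
            regions.append(GenomicInterval(pos, pos + utr5_len, RegionKind.UTR5))
            pos += utr5_len
        cds_off = 0
        for e, elen in enumerate(exon_lens):
            elen = int(elen)
            parts.append(cds[cds_off : cds_off + elen])
            exons.append(GenomicInterval(pos, pos + elen, RegionKind.EXON))
            regions.append(exons[-1])
            pos += elen
            cds_off += elen
            if e < n_exons - 1:
                ilen = int(intron_lens[e])
                parts.append(_sample_noncoding(ilen, params.noncoding_gc, rng))
                regions.append(GenomicInterval(pos, pos + ilen, RegionKind.INTRON))
                pos += ilen
        if utr3_len:
            parts.append(_sample_noncoding(utr3_len, params.noncoding_gc, rng))
            regions.append(GenomicInterval(pos, pos + utr3_len, RegionKind.UTR3))
            pos += utr3_len

        sequence = "".join(parts)
        isoforms = [exons]
        # optionally add an isoform skipping one internal, frame-preserving exon
        if n_exons >= 3 and rng.random() < params.alt_splice_fraction:
            skippable = [i for i in range(1, n_exons - 1) if len(exons[i]) % 3 == 0]
            if skippable:
                skip = skippable[int(rng.integers(len(skippable)))]
                isoforms.append([iv for i, iv in enumerate(exons) if i != skip])

        gene = GeneRecord(gene_id, "NP", sequence, isoforms, regions)
        genes.append(gene)
        strands.append("+" if rng.random() < 0.5 else "-")
        proteins[gene_id] = protein
        labels = np.empty(len(sequence), dtype=object)
        for iv in regions:
            labels[iv.start : iv.end] = iv.kind.value
        region_labels[gene_id] = labels

    return SimulatedGenome(genes, strands, proteins, region_labels, params)


def make_benchmark(params: GenomeSimParams, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated genome as FASTA + GFF3 + truth tables + manifest.

    The default parameters (200 genes, seed 42) define the repository's
    standard benchmark profile.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_genome(params)
    paths = {
        "fasta": out / "genome.fasta",
        "gff3": out / "genome.gff3",
        "proteins": out / "truth_proteins.tsv",
        "regions": out / "truth_regions.tsv",
        "manifest": out / "manifest.json",
    }
    write_annotated_genes(sim.genes, paths["gff3"], paths["fasta"], strands=sim.strands)
    pd.DataFrame(
        [{"gene_id": gid, "protein": prot} for gid, prot in sim.proteins.items()]
    ).to_csv(paths["proteins"], sep="\t", index=False)
    with open(paths["regions"], "w") as fh:
        fh.write("gene_id\tstart\tend\tkind\n")
        for gene in sim.genes:
            for iv in gene.merged_regions:
                fh.write(f"{gene.gene_id}\t{iv.start}\t{iv.end}\t{iv.kind.value}\n")
    paths["manifest"].write_text(json.dumps(
        {"generator": "nonsenseq.synthetic_genome", "params": params.to_dict()},
        indent=2,
    ))
    return paths


def default_benchmark_params(n_genes: int = 200, seed: int = 42) -> GenomeSimParams:
    return GenomeSimParams(n_genes=n_genes, seed=seed)
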