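"""Synthesis of nonsense peptide sequences from annotated gene structures.

A gene's nucleotide sequence is cropped so that no non-coding nucleotide
lies more than ``max_flank`` (default 120) nt from the closest coding exon,
then translated in all three reading frames with stop codons skipped.
Stretches of a candidate translation that match the gene's true protein
verbatim for at least ``min_match`` (default 10) residues are the correctly
translated exons and are masked out; the remaining runs — translations of
non-coding sequence or of coding sequence in the wrong codon alignment —
are emitted as labeled nonsense segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome_io import (
    GeneRecord,
    ProteinSequence,
    SourceClass,
    border_distance_map,
    translate_with_positions,
)

logger = logging.getLogger(__name__)


@dataclass
class CroppedGene:
    gene_id: str
    sequence: str
    nt_origin: np.ndarray  # bool, True = coding
    nt_border_distance: np.ndarray  # int, nt to nearest exon/non-coding border

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.nt_origin) == len(self.nt_border_distance)):
            raise ValueError("label arrays must match sequence length")


@dataclass
class CandidateTranslation:
    gene_id: str
    frame: int
    residues: str
    res_origin: np.ndarray  # bool, True = coding (codon's central nucleotide)
    res_border_distance: np.ndarray
    matched_mask: np.ndarray  # True = inside an exact >=min_match match to the true protein

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class NonsenseSegment:
    gene_id: str
    frame: int
    start: int  # residue index in the candidate
    end: int
    residues: str
    res_origin: np.ndarray
    res_border_distance: np.ndarray

    @property
    def segment_id(self) -> str:
        return f"{self.gene_id}|frame{self.frame}|{self.start}-{self.end}"

    def to_protein(self) -> ProteinSequence:
        return ProteinSequence(
            id=self.segment_id,
            residues=self.residues,
            source_class=SourceClass.NONSENSE,
            border_distances=self.res_border_distance,
        )


def crop_gene(gene: GeneRecord, max_flank: int = 120) -> CroppedGene:
    """Remove non-coding nucleotides further than ``max_flank`` nt from an exon.

    Origin and border-distance labels are computed on the original gene and
    carried through the splice, so a retained nucleotide keeps the distance
    it had in the full gene model.
    """
    if not gene.exon_intervals:
        raise ValueError(f"{gene.gene_id}: gene has no coding exons")
    coding = gene.coding_mask
    dist = border_distance_map(gene)
    keep = coding | (dist <= max_flank)
    idx = np.flatnonzero(keep)
    seq = "".join(gene.sequence[i] for i in idx)
    return CroppedGene(gene.gene_id, seq, coding[idx], dist[idx])


def mask_true_matches(
    candidate: str, true_protein: str, min_match: int = 10
) -> np.ndarray:
    """Mark candidate residues inside exact common substrings of length
    >= ``min_match`` with the true protein.

    A residue lies inside some common substring of length >= k iff it lies
    inside a common substring of length exactly k, so marking every shared
    k-mer occurrence is exhaustive (no mismatches or gaps within a match).
    """
    if not candidate or not true_protein:
        raise ValueError("sequences must be non-empty")
    n = len(candidate)
    mask = np.zeros(n, dtype=bool)
    if len(true_protein) < min_match or n < min_match:
        return mask
    kmers = {true_protein[i : i + min_match] for i in range(len(true_protein) - min_match + 1)}
    for j in range(n - min_match + 1):
        if candidate[j : j + min_match] in kmers:
            mask[j : j + min_match] = True
    return mask


def synthesize_candidates(
    cropped: CroppedGene, true_protein: ProteinSequence, min_match: int = 10
) -> list[CandidateTranslation]:
    """Translate the cropped gene in frames 0..2 and mask true-protein matches.

    Per-residue origin is the coding status of the codon's central
    nucleotide; the border distance is likewise the central nucleotide's.
    Always returns exactly three candidates (one per frame), possibly empty
    for very short inputs.
    """
    if len(cropped.sequence) < 3:
        raise ValueError(f"{cropped.gene_id}: cropped sequence shorter than one codon")
    out = []
    for frame in range(3):
        residues, centers = translate_with_positions(cropped.sequence, frame)
        if residues:
            origin = cropped.nt_origin[centers]
            border = cropped.nt_border_distance[centers]
            matched = mask_true_matches(residues, true_protein.residues, min_match)
        else:
            origin = np.zeros(0, dtype=bool)
            border = np.zeros(0, dtype=np.int64)
            matched = np.zeros(0, dtype=bool)
        out.append(
            CandidateTranslation(
                cropped.gene_id, frame, residues, origin, border, matched
            )
        )
    return out


def extract_nonsense_segments(
    candidate: CandidateTranslation, min_segment_length: int = 30
) -> list[NonsenseSegment]:
    """Maximal runs of unmatched residues, filtered to a minimum length.

    Very short leftovers cannot carry an informative composition window and
    are discarded.
    """
    mask = candidate.matched_mask
    segments: list[NonsenseSegment] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        if j - i >= min_segment_length:
            segments.append(
                NonsenseSegment(
                    gene_id=candidate.gene_id,
                    frame=candidate.frame,
                    start=i,
                    end=j,
                    residues=candidate.residues[i:j],
                    res_origin=candidate.res_origin[i:j],
                    res_border_distance=candidate.res_border_distance[i:j],
                )
            )
        i = j
    return segments


def synthesize_gene_nonsense(
    gene: GeneRecord,
    true_protein: ProteinSequence,
    max_flank: int = 120,
    min_match: int = 10,
    min_segment_length: int = 30,
) -> list[NonsenseSegment]:
    """Full synthesis for one gene: crop, translate in three frames, mask,
    and extract segments."""
    cropped = crop_gene(gene, max_flank)
    segments: list[NonsenseSegment] = []
    for cand in synthesize_candidates(cropped, true_protein, min_match):
        segments.extend(extract_nonsense_segments(cand, min_segment_length))
    return segments


def write_nonsense_fasta(segments: Iterable[NonsenseSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.segment_id}\n")
            for i in range(0, len(seg.residues), 70):
                fh.write(seg.residues[i : i + 70] + "\n")


def write_segment_labels(segments: Iterable[NonsenseSegment], path: str | Path) -> None:
    """Per-residue origin/border labels as TSV (segment_id, position, origin,
    border_distance)."""
    with open(path, "w") as fh:
        fh.write("segment_id\tposition\torigin\tborder_distance\n")
        for seg in segments:
            for k in range(len(seg.residues)):
                origin = "coding" if seg.res_origin[k] else "noncoding"
                fh.write(
                    f"{seg.segment_id}\t{k}\t{origin}\t{seg.res_border_distance[k]}\n"
                )
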