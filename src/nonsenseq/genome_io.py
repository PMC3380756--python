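"""Reading and writing annotated gene models.

Gene structures come in as GFF3 (gene / mRNA / exon / CDS / UTR features)
plus a genomic FASTA.  Internally every gene is represented in *gene-local,
transcription-orientation* coordinates: minus-strand genes are
reverse-complemented on read, all intervals are 0-based half-open, and
downstream code never sees a strand.

Throughout this package "exon" intervals denote *coding* exon regions
(CDS); untranslated leaders/trailers are classified ``utr5``/``utr3`` and,
together with introns, count as non-coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Standard genetic code, '*' marking stops.  Built once from Biopython's
#: table so the translation loop below can skip stops and N-codons itself.
_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


_CODON_TABLE = _build_codon_table()


class RegionKind(str, Enum):
    EXON = "exon"          # coding exon (CDS)
    INTRON = "intron"
    UTR5 = "utr5"
    UTR3 = "utr3"


class SourceClass(str, Enum):
    TRUE_NP = "TRUE_NP"
    TRUE_XP = "TRUE_XP"
    NONSENSE = "NONSENSE"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) in gene-local coordinates."""

    start: int
    end: int
    kind: RegionKind

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneRecord:
    """One gene in transcription orientation.

    ``isoforms`` holds, per annotated mRNA, the sorted list of coding-exon
    intervals.  ``merged_regions`` tiles the full sequence with
    exon/intron/UTR labels (exon = union of CDS across isoforms).
    """

    gene_id: str
    status: str  # "NP" or "XP"
    sequence: str
    isoforms: list[list[GenomicInterval]]
    merged_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.merged_regions:
            pos = 0
            for iv in self.merged_regions:
                if iv.start != pos:
                    raise ValueError(
                        f"{self.gene_id}: merged_regions do not tile the sequence"
                    )
                pos = iv.end
            if pos != len(self.sequence):
                raise ValueError(f"{self.gene_id}: merged_regions end at {pos}")

    @property
    def coding_mask(self) -> np.ndarray:
        """Boolean array, True where the nucleotide is in a coding exon."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for iv in self.merged_regions:
            if iv.kind is RegionKind.EXON:
                mask[iv.start : iv.end] = True
        return mask

    @property
    def exon_intervals(self) -> list[GenomicInterval]:
        return [iv for iv in self.merged_regions if iv.kind is RegionKind.EXON]


@dataclass
class ProteinSequence:
    id: str
    residues: str
    source_class: SourceClass
    #: per-residue distance (nt) of the codon to the nearest exon/non-coding
    #: border in the source gene; None for proteins without a gene model
    border_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(STANDARD_AA)
        if bad:
            raise ValueError(f"{self.id}: non-standard residues {sorted(bad)}")


class FrameConflictError(Exception):
    """Isoforms translate a shared exon in different codon alignments."""


EXCLUDED = None  # sentinel returned by compile_representative_protein


# ---------------------------------------------------------------------------
# translation

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` in the given frame, skipping stop and N codons.

    Stops are dropped rather than truncating the product, the rule used
    when synthesizing nonsense candidates; a trailing partial codon is
    discarded.  Returns the translated residues.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    residues, skipped_n, skipped_stop = _translate_codons(nt, frame)
    if skipped_n:
        logger.debug("translate: skipped %d codons containing N", skipped_n)
    if skipped_stop:
        logger.debug("translate: skipped %d stop codons", skipped_stop)
    return residues


def _translate_codons(nt: str, frame: int) -> tuple[str, int, int]:
    out = []
    skipped_n = skipped_stop = 0
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            skipped_n += 1
            continue
        aa = _CODON_TABLE[codon]
        if aa == "*":
            skipped_stop += 1
            continue
        out.append(aa)
    return "".join(out), skipped_n, skipped_stop


def translate_with_positions(nt: str, frame: int = 0) -> tuple[str, np.ndarray]:
    """Like :func:`translate` but also returns, per residue, the index of
    the codon's central nucleotide in ``nt``."""
    out: list[str] = []
    centers: list[int] = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            continue
        aa = _CODON_TABLE[codon]
        if aa == "*":
            continue
        out.append(aa)
        centers.append(i + 1)
    return "".join(out), np.asarray(centers, dtype=np.int64)


# ---------------------------------------------------------------------------
# border distances

def border_distance_map(gene: GeneRecord) -> np.ndarray:
    """Per-nucleotide distance (in nt) to the nearest exon/non-coding border.

    A border sits between two adjacent nucleotides with different coding
    status; the nucleotide adjacent to a border has distance 1.  For a gene
    that is entirely coding (or entirely non-coding) there is no such
    border and the distance to the nearer sequence end is used instead.
    """
    mask = gene.coding_mask
    L = len(mask)
    changes = np.flatnonzero(mask[1:] != mask[:-1]) + 1  # border before index b
    pos = np.arange(L)
    if changes.size == 0:
        return np.minimum(pos + 1, L - pos)
    # distance to border at b: positions < b are (b - p), positions >= b are (p - b + 1)
    dists = np.full(L, np.iinfo(np.int64).max, dtype=np.int64)
    for b in changes:
        d = np.where(pos < b, b - pos, pos - b + 1)
        np.minimum(dists, d, out=dists)
    return dists


# ---------------------------------------------------------------------------
# representative proteins

def _isoform_phase_map(isoform: Sequence[GenomicInterval], length: int) -> np.ndarray:
    """Codon phase (0/1/2) of every coding position; -1 where non-coding."""
    phases = np.full(length, -1, dtype=np.int8)
    offset = 0
    for iv in isoform:
        idx = np.arange(iv.start, iv.end)
        phases[idx] = (offset + idx - iv.start) % 3
        offset += len(iv)
    return phases


def compile_representative_protein(
    gene: GeneRecord, status: str | None = None
) -> ProteinSequence | None:
    """Translate the union of a gene's coding exons into one representative.

    Single-isoform genes translate their concatenated CDS.  Multi-isoform
    genes translate the exon union, provided every shared position keeps
    one codon alignment across isoforms; otherwise the gene is excluded
    (returns ``None``).  Internal stop codons are skipped with a warning,
    consistent with the nonsense-synthesis translation rule.
    """
    if not gene.isoforms:
        raise ValueError(f"{gene.gene_id}: no isoforms")
    L = len(gene.sequence)

    phases = _isoform_phase_map(gene.isoforms[0], L)
    for isoform in gene.isoforms[1:]:
        other = _isoform_phase_map(isoform, L)
        both = (phases >= 0) & (other >= 0)
        if np.any(phases[both] != other[both]):
            logger.info("%s: isoform codon-alignment conflict, excluded", gene.gene_id)
            return EXCLUDED
        phases = np.where(other >= 0, other, phases)

    union = gene.exon_intervals  # merged CDS across isoforms, sorted
    coding_pos = np.concatenate(
        [np.arange(iv.start, iv.end) for iv in union]
    ) if union else np.array([], dtype=np.int64)
    if coding_pos.size == 0:
        raise ValueError(f"{gene.gene_id}: no coding exons")
    # union concatenation must itself read in one frame
    if np.any(phases[coding_pos] != np.arange(coding_pos.size) % 3):
        logger.info("%s: exon union has no consistent codon alignment, excluded",
                    gene.gene_id)
        return EXCLUDED

    cds = "".join(gene.sequence[iv.start : iv.end] for iv in union)
    residues, centers = translate_with_positions(cds, frame=0)
    n_stops = (len(cds) // 3) - len(residues) - sum(
        1 for i in range(0, len(cds) - 2, 3) if "N" in cds[i : i + 3]
    )
    if n_stops > 0:
        logger.warning("%s: %d internal stop codon(s) skipped in CDS",
                       gene.gene_id, n_stops)
    if not residues:
        raise ValueError(f"{gene.gene_id}: CDS translates to nothing")
    dist_map = border_distance_map(gene)
    border = dist_map[coding_pos[centers]]
    return ProteinSequence(
        id=gene.gene_id,
        residues=residues,
        source_class=SourceClass.TRUE_XP if (status or gene.status) == "XP"
        else SourceClass.TRUE_NP,
        border_distances=border,
    )


# ---------------------------------------------------------------------------
# GFF3 + FASTA I/O

def read_annotated_genes(gff3_path: str | Path, fasta_path: str | Path) -> list[GeneRecord]:
    """Read gene models from GFF3 + genomic FASTA into :class:`GeneRecord`.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open,
    minus-strand genes are reverse-complemented, and every position of the
    gene span is classified exon (CDS union) / UTR (annotated) / intron.
    Genes without CDS features are skipped; genes whose features fall
    outside the FASTA sequence are skipped with a warning.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneRecord] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        if gf.seqid not in seqs:
            raise ValueError(f"sequence {gf.seqid!r} referenced by {gf.id} not in FASTA")
        chrom = seqs[gf.seqid]
        g_start, g_end = gf.start - 1, gf.end  # to 0-based half-open
        if g_start < 0 or g_end > len(chrom):
            logger.warning("%s: outside sequence bounds, skipped", gf.id)
            continue
        strand = gf.strand

        def to_local(start1: int, end1: int) -> tuple[int, int]:
            s, e = start1 - 1, end1
            if strand == "-":
                return g_end - e, g_end - s
            return s - g_start, e - g_start

        gene_len = g_end - g_start
        isoforms: list[list[GenomicInterval]] = []
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        ok = True
        for mrna in db.children(gf, featuretype="mRNA", order_by="start"):
            cds_ivs = []
            for c in db.children(mrna, featuretype="CDS", order_by="start"):
                s, e = to_local(c.start, c.end)
                if s < 0 or e > gene_len:
                    logger.warning("%s: CDS outside gene span, gene skipped", gf.id)
                    ok = False
                    break
                cds_ivs.append(GenomicInterval(s, e, RegionKind.EXON))
            if not ok:
                break
            for kind, store in (("five_prime_UTR", utr5), ("three_prime_UTR", utr3)):
                for u in db.children(mrna, featuretype=kind, order_by="start"):
                    store.append(to_local(u.start, u.end))
            if cds_ivs:
                isoforms.append(sorted(cds_ivs, key=lambda iv: iv.start))
        if not ok:
            continue
        if not isoforms:
            logger.info("%s: no CDS features, skipped", gf.id)
            continue

        seq = chrom[g_start:g_end]
        if strand == "-":
            seq = reverse_complement(seq)
        seq = _sanitize_nt(seq)

        status = gf.attributes.get("status", ["NP"])[0]
        merged = _merge_regions(gene_len, isoforms, utr5, utr3)
        genes.append(GeneRecord(gf.id, status, seq, isoforms, merged))
    return genes


def _sanitize_nt(seq: str) -> str:
    """Map non-ACGT IUPAC codes to N."""
    return "".join(c if c in "ACGT" else "N" for c in seq)


def _merge_regions(
    length: int,
    isoforms: list[list[GenomicInterval]],
    utr5: list[tuple[int, int]],
    utr3: list[tuple[int, int]],
) -> list[GenomicInterval]:
    coding = np.zeros(length, dtype=bool)
    for iso in isoforms:
        for iv in iso:
            coding[iv.start : iv.end] = True
    kind5 = np.zeros(length, dtype=bool)
    for s, e in utr5:
        kind5[s:e] = True
    kind3 = np.zeros(length, dtype=bool)
    for s, e in utr3:
        kind3[s:e] = True

    regions: list[GenomicInterval] = []
    i = 0
    while i < length:
        if coding[i]:
            kind = RegionKind.EXON
            j = i
            while j < length and coding[j]:
                j += 1
        else:
            if kind5[i]:
                kind = RegionKind.UTR5
            elif kind3[i]:
                kind = RegionKind.UTR3
            else:
                kind = RegionKind.INTRON
            j = i
            while j < length and not coding[j] and (
                kind5[j] == kind5[i] and kind3[j] == kind3[i]
            ):
                j += 1
        regions.append(GenomicInterval(i, j, kind))
        i = j
    return regions


def write_annotated_genes(
    genes: Iterable[GeneRecord],
    gff3_path: str | Path,
    fasta_path: str | Path,
    spacer: int = 50,
    strands: Sequence[str] | None = None,
) -> None:
    """Write gene records as a single-chromosome GFF3 + FASTA pair.

    Genes are laid out head-to-tail separated by ``spacer`` N's.  GeneRecord
    is strand-normalized, so ``strands`` (default all ``+``) only chooses the
    genomic orientation each gene is *stored* in; re-reading with
    :func:`read_annotated_genes` reproduces sequences and intervals exactly
    either way (round-trip property used by the test suite).
    """
    genes = list(genes)
    if strands is None:
        strands = ["+"] * len(genes)
    chrom_parts: list[str] = []
    lines = ["##gff-version 3"]
    offset = 0
    for gene, strand in zip(genes, strands):
        L = len(gene.sequence)
        g1, g2 = offset + 1, offset + L  # 1-based inclusive

        def to_chrom(s: int, e: int) -> tuple[int, int]:
            if strand == "-":
                return offset + (L - e) + 1, offset + (L - s)
            return offset + s + 1, offset + e

        lines.append(
            f"chr1\tnonsenseq\tgene\t{g1}\t{g2}\t.\t{strand}\t.\t"
            f"ID={gene.gene_id};status={gene.status}"
        )
        for k, iso in enumerate(gene.isoforms):
            mid = f"{gene.gene_id}.t{k + 1}"
            lines.append(
                f"chr1\tnonsenseq\tmRNA\t{g1}\t{g2}\t.\t{strand}\t.\t"
                f"ID={mid};Parent={gene.gene_id}"
            )
            for iv in iso:
                c1, c2 = to_chrom(iv.start, iv.end)
                lines.append(
                    f"chr1\tnonsenseq\tCDS\t{c1}\t{c2}\t.\t{strand}\t0\tParent={mid}"
                )
            if k == 0:
                for iv in gene.merged_regions:
                    if iv.kind in (RegionKind.UTR5, RegionKind.UTR3):
                        ft = ("five_prime_UTR" if iv.kind is RegionKind.UTR5
                              else "three_prime_UTR")
                        c1, c2 = to_chrom(iv.start, iv.end)
                        lines.append(
                            f"chr1\tnonsenseq\t{ft}\t{c1}\t{c2}\t.\t{strand}\t.\t"
                            f"Parent={mid}"
                        )
        chrom_parts.append(
            reverse_complement(gene.sequence) if strand == "-" else gene.sequence
        )
        chrom_parts.append("N" * spacer)
        offset += L + spacer
    chrom = "".join(chrom_parts)
    with open(fasta_path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(chrom), 70):
            fh.write(chrom[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_protein_fasta(proteins: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id} class={p.source_class.value}\n")
            for i in range(0, len(p.residues), 70):
                fh.write(p.residues[i : i + 70] + "\n")


def read_protein_fasta(
    path: str | Path, source_class: SourceClass = SourceClass.TRUE_NP
) -> list[ProteinSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ProteinSequence(rec.id, str(rec.seq).upper(), source_class))
    return out
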