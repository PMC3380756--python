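"""End-to-end orchestration: genes -> nonsense sets -> features -> dataset.

Thin glue over the stage modules so the CLI, the test suite and the
reproduction script all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import (
    dataset_builder,
    evaluation,
    genome_io,
    nonsense_synthesis,
    sequence_features,
)
from .dataset_builder import ResidueDataset
from .genome_io import GeneRecord, ProteinSequence
from .nonsense_predictor import TrainConfig
from .nonsense_synthesis import NonsenseSegment


@dataclass
class RunConfig:
    """All tunables of the pipeline, with the method's default values."""

    window: int = 41
    max_flank: int = 120
    min_match: int = 10
    min_segment_length: int = 30
    near_border_nt: int = 50
    train_frac: float = 0.08
    val_frac: float = 0.02
    hidden: int = 20
    n_members: int = 10
    folds: int = 10
    eps: float = 0.01
    thresholds: tuple[float, ...] = (0.4, 0.5, 0.6)
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "train"}
        d["thresholds"] = list(self.thresholds)
        d["train"] = self.train.to_dict()
        return d


@dataclass
class BuiltDataset:
    dataset: ResidueDataset
    true_proteins: list[ProteinSequence]
    segments: list[NonsenseSegment]
    excluded: list[tuple[str, str]]  # (gene_id, reason)


def compile_proteins(
    genes: list[GeneRecord],
) -> tuple[list[ProteinSequence], list[tuple[str, str]]]:
    """Representative protein per gene; frame-conflicted genes are excluded
    from both classes."""
    proteins, excluded = [], []
    for gene in genes:
        prot = genome_io.compile_representative_protein(gene)
        if prot is genome_io.EXCLUDED:
            excluded.append((gene.gene_id, "isoform codon-alignment conflict"))
        else:
            proteins.append(prot)
    return proteins, excluded


def build_residue_dataset(
    genes: list[GeneRecord], config: RunConfig | None = None
) -> BuiltDataset:
    """Synthesize nonsense segments, featurize everything and label residues."""
    cfg = config or RunConfig()
    proteins, excluded = compile_proteins(genes)
    by_id = {g.gene_id: g for g in genes}

    segments: list[NonsenseSegment] = []
    kept_proteins: list[ProteinSequence] = []
    for prot in proteins:
        segs = nonsense_synthesis.synthesize_gene_nonsense(
            by_id[prot.id], prot,
            max_flank=cfg.max_flank,
            min_match=cfg.min_match,
            min_segment_length=cfg.min_segment_length,
        )
        if len(prot.residues) >= cfg.min_segment_length:
            kept_proteins.append(prot)
            segments.extend(segs)
        else:
            excluded.append((prot.id, "true protein shorter than minimum length"))

    features: dict[str, sequence_features.FeatureMatrix] = {}
    profiles: dict[str, sequence_features.DisorderProfile] = {}
    for prot in kept_proteins:
        features[prot.id] = sequence_features.featurize_sequence(
            prot.residues, prot.id, window=cfg.window
        )
        profiles[prot.id] = sequence_features.disorder_scores(prot.residues, prot.id)
    for seg in segments:
        sid = seg.segment_id
        features[sid] = sequence_features.featurize_sequence(
            seg.residues, sid, window=cfg.window
        )
        profiles[sid] = sequence_features.disorder_scores(seg.residues, sid)

    dataset = dataset_builder.label_residues(
        kept_proteins, segments, features, profiles
    )
    return BuiltDataset(dataset, kept_proteins, segments, excluded)


@dataclass
class BenchmarkResult:
    built: BuiltDataset
    cv: evaluation.CrossValResult
    report: evaluation.EvalReport
    per_protein: evaluation.MetricRow
    content: "object"  # per-sequence content DataFrame

    def summary(self) -> dict:
        return {
            "per_residue": self.report.as_dict(),
            "per_protein": self.per_protein.as_dict(),
            "n_residues": len(self.built.dataset),
            "n_sequences": int(self.built.dataset.frame["sequence_id"].nunique()),
        }


def run_benchmark_cv(
    genes: list[GeneRecord], config: RunConfig | None = None
) -> BenchmarkResult:
    """Build the dataset from ``genes`` and evaluate with grouped k-fold CV."""
    cfg = config or RunConfig()
    built = build_residue_dataset(genes, cfg)
    cv = evaluation.run_cross_validation(
        built.dataset,
        k=cfg.folds,
        seed=cfg.seed,
        n_members=cfg.n_members,
        train_frac=cfg.train_frac,
        val_frac=cfg.val_frac,
        config=cfg.train,
    )
    report = evaluation.stratified_evaluation(cv.oof_scores, built.dataset.frame)
    content = evaluation.per_sequence_content(built.dataset.frame, cv.oof_scores)
    per_protein = evaluation.per_protein_metrics(content)
    return BenchmarkResult(built, cv, report, per_protein, content)


def disorder_content_by_sequence(built: BuiltDataset) -> dict[str, float]:
    """Disorder content per sequence, from the same provider used in labeling."""
    out = {}
    for prot in built.true_proteins:
        out[prot.id] = sequence_features.disorder_scores(
            prot.residues, prot.id
        ).disorder_content
    for seg in built.segments:
        out[seg.segment_id] = sequence_features.disorder_scores(
            seg.residues, seg.segment_id
        ).disorder_content
    return out
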