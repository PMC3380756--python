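"""Residue labeling and balanced train/validation sampling.

Every residue of every true protein and nonsense segment becomes one row
carrying its class (TRUE / NONSENSE), its predicted-disorder bin at the 0.5
threshold, its genomic origin (coding / non-coding; nonsense class only),
and whether its codon lies near (<= 50 nt) or far from the closest
exon/non-coding border.  Training and validation samples equalize, by
downsampling without replacement:

* residues per class,
* ordered vs. disordered residues within each class,
* coding- vs. non-coding-origin residues within the nonsense class,
* near- vs. far-border residues within each class,

then cap at the requested fractions of the available data (8% train, 2%
validation by default).  Equalization runs on the cross-product of the
applicable bins — 8 nonsense cells, 4 true cells, true cells at twice the
nonsense cell count — which satisfies all four marginal equalities at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import ProteinSequence, SourceClass
from .nonsense_synthesis import NonsenseSegment
from .sequence_features import DisorderProfile, FeatureMatrix

TARGET_TRUE = 0.1
TARGET_NONSENSE = 0.9
NEAR_BORDER_NT = 50

META_COLUMNS = [
    "sequence_id", "gene_id", "position", "klass",
    "disorder_bin", "origin_bin", "border_bin", "target",
]


@dataclass
class ResidueDataset:
    """Aligned per-residue metadata (``frame``) and 23-column features."""

    frame: pd.DataFrame
    features: np.ndarray

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.features):
            raise ValueError("metadata and feature row counts differ")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def targets(self) -> np.ndarray:
        return self.frame["target"].to_numpy()

    def strata_table(self) -> pd.DataFrame:
        return (
            self.frame.groupby(
                ["klass", "disorder_bin", "origin_bin", "border_bin"],
                dropna=False, observed=True,
            )
            .size()
            .rename("count")
            .reset_index()
        )


def label_residues(
    true_proteins: list[ProteinSequence],
    nonsense_segments: list[NonsenseSegment],
    features: dict[str, FeatureMatrix],
    profiles: dict[str, DisorderProfile],
) -> ResidueDataset:
    """Assemble the labeled residue table for both classes.

    Every sequence needs a feature matrix and a disorder profile; true
    proteins need per-residue border distances from their gene model.
    """
    blocks: list[pd.DataFrame] = []
    feats: list[np.ndarray] = []

    def _get(store: dict, sid: str, what: str):
        if sid not in store:
            raise KeyError(f"missing {what} for sequence {sid!r}")
        return store[sid]

    for prot in true_proteins:
        if prot.border_distances is None:
            raise ValueError(f"{prot.id}: true protein lacks border distances")
        fm = _get(features, prot.id, "features")
        profile = _get(profiles, prot.id, "disorder profile")
        L = len(prot.residues)
        if len(fm.rows) != L or len(profile.scores) != L:
            raise ValueError(f"{prot.id}: feature/profile length mismatch")
        blocks.append(pd.DataFrame({
            "sequence_id": prot.id,
            "gene_id": prot.id,
            "position": np.arange(L),
            "klass": "TRUE",
            "disorder_bin": np.where(profile.binary, "disordered", "ordered"),
            "origin_bin": pd.NA,
            "border_bin": np.where(
                prot.border_distances <= NEAR_BORDER_NT, "near", "far"
            ),
            "target": TARGET_TRUE,
        }))
        feats.append(fm.rows)

    for seg in nonsense_segments:
        sid = seg.segment_id
        fm = _get(features, sid, "features")
        profile = _get(profiles, sid, "disorder profile")
        L = len(seg.residues)
        if len(fm.rows) != L or len(profile.scores) != L:
            raise ValueError(f"{sid}: feature/profile length mismatch")
        blocks.append(pd.DataFrame({
            "sequence_id": sid,
            "gene_id": seg.gene_id,
            "position": np.arange(L),
            "klass": "NONSENSE",
            "disorder_bin": np.where(profile.binary, "disordered", "ordered"),
            "origin_bin": np.where(seg.res_origin, "coding", "noncoding"),
            "border_bin": np.where(
                seg.res_border_distance <= NEAR_BORDER_NT, "near", "far"
            ),
            "target": TARGET_NONSENSE,
        }))
        feats.append(fm.rows)

    if not blocks:
        raise ValueError("no sequences to label")
    frame = pd.concat(blocks, ignore_index=True)
    return ResidueDataset(frame, np.vstack(feats))


class EmptyStratumError(ValueError):
    """A balancing cell required by the sampling scheme has no residues."""


@dataclass
class BalancedSample:
    """Row indices (into a ResidueDataset) of one balanced train/val draw."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    strata_counts: pd.DataFrame
    seed: int

    def manifest(self, dataset: ResidueDataset) -> pd.DataFrame:
        """Audit table: every sampled residue with its strata keys and split."""
        parts = []
        for split, idx in (("train", self.train_idx), ("validation", self.val_idx)):
            part = dataset.frame.iloc[idx][
                ["sequence_id", "position", "klass",
                 "disorder_bin", "origin_bin", "border_bin"]
            ].copy()
            part["split"] = split
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


_NONSENSE_CELLS = [
    (d, o, b)
    for d in ("ordered", "disordered")
    for o in ("coding", "noncoding")
    for b in ("near", "far")
]
_TRUE_CELLS = [(d, b) for d in ("ordered", "disordered") for b in ("near", "far")]


def balance_sample(
    dataset: ResidueDataset,
    train_frac: float = 0.08,
    val_frac: float = 0.02,
    seed: int = 0,
    indices: np.ndarray | None = None,
) -> BalancedSample:
    """Draw one balanced, seeded train/validation sample.

    ``indices`` restricts the available pool (e.g. to a cross-validation
    training split).  Cells are downsampled to the limiting cell, the
    fraction caps are applied afterwards, and validation rows never overlap
    training rows.
    """
    pool = np.arange(len(dataset)) if indices is None else np.asarray(indices)
    frame = dataset.frame.iloc[pool]
    rng = np.random.default_rng(seed)

    cells: dict[tuple, np.ndarray] = {}
    empty: list[tuple] = []
    is_true = (frame["klass"] == "TRUE").to_numpy()
    dis = frame["disorder_bin"].to_numpy()
    orig = frame["origin_bin"].fillna("").to_numpy(dtype=object)
    bord = frame["border_bin"].to_numpy()
    for d, o, b in _NONSENSE_CELLS:
        rows = pool[(~is_true) & (dis == d) & (orig == o) & (bord == b)]
        key = ("NONSENSE", d, o, b)
        cells[key] = rng.permutation(rows)
        if rows.size == 0:
            empty.append(key)
    for d, b in _TRUE_CELLS:
        rows = pool[is_true & (dis == d) & (bord == b)]
        key = ("TRUE", d, None, b)
        cells[key] = rng.permutation(rows)
        if rows.size == 0:
            empty.append(key)
    if empty:
        raise EmptyStratumError(f"empty balancing strata: {empty}")

    min_nons = min(cells[k].size for k in cells if k[0] == "NONSENSE")
    min_true = min(cells[k].size for k in cells if k[0] == "TRUE")

    def cell_sizes(budget_rows: int, avail_nons: int, avail_true: int) -> tuple[int, int]:
        # n_true cells = 4 at 2c each, n_nonsense cells = 8 at c each -> 16c total
        c = min(avail_nons, avail_true // 2, budget_rows // 16)
        return c, 2 * c

    n_avail = pool.size
    c_train, ct_train = cell_sizes(int(train_frac * n_avail), min_nons, min_true)
    c_val, ct_val = cell_sizes(
        int(val_frac * n_avail), min_nons - c_train, min_true - ct_train
    )
    if c_train == 0:
        raise EmptyStratumError(
            "balancing yields an empty training sample "
            f"(limiting cell sizes: nonsense {min_nons}, true {min_true})"
        )

    train_parts, val_parts, count_rows = [], [], []
    for key, rows in cells.items():
        c, cv = (c_train, c_val) if key[0] == "NONSENSE" else (ct_train, ct_val)
        train_parts.append(rows[:c])
        val_parts.append(rows[c : c + cv])
        count_rows.append(
            {"klass": key[0], "disorder_bin": key[1], "origin_bin": key[2],
             "border_bin": key[3], "available": rows.size,
             "train": c, "validation": cv}
        )
    return BalancedSample(
        train_idx=np.concatenate(train_parts),
        val_idx=np.concatenate(val_parts),
        strata_counts=pd.DataFrame(count_rows),
        seed=seed,
    )


def write_sample_manifest(
    sample: BalancedSample, dataset: ResidueDataset, path: str | Path
) -> None:
    sample.manifest(dataset).to_csv(path, sep="\t", index=False)
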