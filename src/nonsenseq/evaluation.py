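"""Evaluation of nonsense predictors.

Cross-validation is grouped at the sequence level (all residues of a
sequence share a fold) and, when gene identifiers are supplied, at the gene
level, so a gene's true protein and the nonsense segments synthesized from
it can never straddle a training/test boundary.  The nonsense class is the
positive class throughout: sensitivity is accuracy on nonsense residues,
specificity accuracy on true-protein residues, and balanced accuracy their
mean.  Per-sequence summaries use nonsense content (fraction of residues
scored above threshold) and the mean residue score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .dataset_builder import ResidueDataset
from .nonsense_predictor import Ensemble, TrainConfig, train_ensemble

POSITIVE_CLASS = "NONSENSE"
NEGATIVE_CLASS = "TRUE"


# ---------------------------------------------------------------------------
# fold assignment

@dataclass
class FoldAssignment:
    folds: dict[str, int]  # sequence_id -> fold index
    k: int
    seed: int

    def fold_of(self, sequence_id: str) -> int:
        return self.folds[sequence_id]


def grouped_kfold(
    sequence_ids: list[str],
    k: int = 10,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> FoldAssignment:
    """Assign sequences to ``k`` folds of near-equal size, deterministically.

    ``groups`` maps sequence id -> group key (e.g. source gene); all
    sequences of a group land in the same fold.  Groups are shuffled with
    the seed and dealt greedily to the currently smallest fold, keeping
    fold sizes within one group of each other.
    """
    ids = list(dict.fromkeys(sequence_ids))
    if groups is None:
        groups = {s: s for s in ids}
    by_group: dict[str, list[str]] = {}
    for s in ids:
        by_group.setdefault(groups[s], []).append(s)
    keys = sorted(by_group)
    if len(keys) < k:
        raise ValueError(f"need at least {k} groups, got {len(keys)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    sizes = np.zeros(k, dtype=np.int64)
    folds: dict[str, int] = {}
    for gi in order:
        f = int(np.argmin(sizes))
        for s in by_group[keys[gi]]:
            folds[s] = f
        sizes[f] += 1
    return FoldAssignment(folds, k, seed)


# ---------------------------------------------------------------------------
# core metrics

@dataclass
class MetricRow:
    specificity: float
    sensitivity: float
    balanced_accuracy: float
    auc: float | None
    n_negative: int
    n_positive: int

    def as_dict(self) -> dict:
        return {
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "n_negative": self.n_negative,
            "n_positive": self.n_positive,
        }


def balanced_accuracy(specificity: float, sensitivity: float) -> float:
    """The accuracy measure used for the heavily imbalanced residue classes:
    the mean of per-class accuracies."""
    return (specificity + sensitivity) / 2.0


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5,
    with_auc: bool = True,
) -> MetricRow:
    """Specificity / sensitivity / balanced accuracy (and AUC) at a threshold.

    ``labels`` holds class names; NONSENSE is positive.  Raises if either
    class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE_CLASS
    neg = labels == NEGATIVE_CLASS
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    pred_pos = scores > threshold
    sens = float(np.count_nonzero(pred_pos & pos)) / int(pos.sum())
    spec = float(np.count_nonzero(~pred_pos & neg)) / int(neg.sum())
    return MetricRow(
        specificity=spec,
        sensitivity=sens,
        balanced_accuracy=balanced_accuracy(spec, sens),
        auc=auc(scores, labels) if with_auc else None,
        n_negative=int(neg.sum()),
        n_positive=int(pos.sum()),
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, ties counted half."""
    labels = np.asarray(labels)
    y = (labels == POSITIVE_CLASS).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class EvalReport:
    overall: MetricRow
    strata: dict[str, MetricRow] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "strata": {k: v.as_dict() for k, v in self.strata.items()},
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stratum": "overall", **self.overall.as_dict()}]
        rows += [{"stratum": k, **v.as_dict()} for k, v in self.strata.items()]
        return pd.DataFrame(rows)


def stratified_evaluation(
    scores: np.ndarray,
    frame: pd.DataFrame,
    threshold: float = 0.5,
) -> EvalReport:
    """Overall metrics plus the four strata: ordered/disordered regions and
    nonsense origin (coding exons vs. non-coding regions).

    Disorder strata restrict both classes; origin strata restrict only the
    positive class, so the two origin rows share one specificity — the
    negative class is always the full true-protein set.
    """
    labels = frame["klass"].to_numpy()
    report = EvalReport(overall=confusion_metrics(scores, labels, threshold))
    dis = frame["disorder_bin"].to_numpy()
    for value in ("ordered", "disordered"):
        sel = dis == value
        try:
            report.strata[value] = confusion_metrics(scores[sel], labels[sel], threshold)
        except ValueError:
            import logging
            logging.getLogger(__name__).warning("stratum %s empty, omitted", value)
    orig = frame["origin_bin"].fillna("").to_numpy(dtype=object)
    neg = labels == NEGATIVE_CLASS
    for value, name in (("noncoding", "nonsense_from_noncoding"),
                        ("coding", "nonsense_from_exons")):
        sel = neg | ((labels == POSITIVE_CLASS) & (orig == value))
        try:
            report.strata[name] = confusion_metrics(scores[sel], labels[sel], threshold)
        except ValueError:
            import logging
            logging.getLogger(__name__).warning("stratum %s empty, omitted", name)
    return report


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CrossValResult:
    assignment: FoldAssignment
    oof_scores: np.ndarray          # one out-of-fold score per dataset row
    fold_models: list[Ensemble]

    def predict_unseen(self, X: np.ndarray) -> np.ndarray:
        """Score sequences never used in training with the full bank of fold
        models (mean over all folds' ensembles)."""
        return np.mean([m.predict(X) for m in self.fold_models], axis=0)


def run_cross_validation(
    dataset: ResidueDataset,
    k: int = 10,
    seed: int = 0,
    n_members: int = 10,
    train_frac: float = 0.08,
    val_frac: float = 0.02,
    config: TrainConfig | None = None,
    group_by_gene: bool = True,
) -> CrossValResult:
    """Sequence-grouped k-fold cross-validation.

    Each fold's ensemble trains only on the other k-1 folds; every residue
    receives exactly one out-of-fold score.  The fold models are retained as
    the predictor bank for unseen sequences.
    """
    seq_ids = dataset.frame["sequence_id"].tolist()
    groups = (
        dict(zip(dataset.frame["sequence_id"], dataset.frame["gene_id"]))
        if group_by_gene else None
    )
    assignment = grouped_kfold(seq_ids, k=k, seed=seed, groups=groups)
    fold_of_row = dataset.frame["sequence_id"].map(assignment.folds).to_numpy()

    oof = np.full(len(dataset), np.nan)
    models: list[Ensemble] = []
    for fold in range(k):
        test_rows = np.flatnonzero(fold_of_row == fold)
        train_rows = np.flatnonzero(fold_of_row != fold)
        model = train_ensemble(
            dataset,
            n_members=n_members,
            base_seed=seed * 1000 + fold * 100,
            indices=train_rows,
            train_frac=train_frac,
            val_frac=val_frac,
            config=config,
        )
        oof[test_rows] = model.predict(dataset.features[test_rows])
        models.append(model)
    assert not np.isnan(oof).any()
    return CrossValResult(assignment, oof, models)


# ---------------------------------------------------------------------------
# per-sequence summaries

def per_sequence_content(
    frame: pd.DataFrame, scores: np.ndarray, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-sequence nonsense content and mean score (class carried along)."""
    df = pd.DataFrame({
        "sequence_id": frame["sequence_id"].to_numpy(),
        "klass": frame["klass"].to_numpy(),
        "score": np.asarray(scores, dtype=float),
    })
    g = df.groupby("sequence_id", sort=False)
    out = g.agg(
        klass=("klass", "first"),
        mean_score=("score", "mean"),
        n_residues=("score", "size"),
    )
    out["nonsense_content"] = g["score"].apply(
        lambda s: float((s > threshold).sum()) / len(s)
    )
    return out.reset_index()


def per_protein_metrics(
    content: pd.DataFrame, threshold: float = 0.5
) -> MetricRow:
    """Whole-sequence classification from mean residue scores."""
    return confusion_metrics(
        content["mean_score"].to_numpy(), content["klass"].to_numpy(), threshold
    )


def threshold_sweep(
    per_sequence_nc: dict[str, np.ndarray],
    thresholds: tuple[float, ...] = (0.4, 0.5, 0.6),
) -> pd.DataFrame:
    """Fraction of 'mostly nonsense' sequences (NC strictly above threshold)
    per sequence set."""
    rows = []
    for name, nc in per_sequence_nc.items():
        nc = np.asarray(nc, dtype=float)
        for t in thresholds:
            rows.append({
                "set": name, "threshold": t,
                "fraction_above": float(np.count_nonzero(nc > t)) / nc.size,
            })
    return pd.DataFrame(rows)


def total_content_margins(
    residue_scores: dict[str, np.ndarray], threshold: float = 0.5
) -> pd.DataFrame:
    """Total nonsense content per residue set and all pairwise margins.

    At the classification threshold the margin between the nonsense and
    true sets equals sensitivity + specificity - 1 on the same residues.
    """
    totals = {
        name: float(np.count_nonzero(np.asarray(s) > threshold)) / len(s)
        for name, s in residue_scores.items()
    }
    rows = [{"set": n, "total_nonsense_content": v} for n, v in totals.items()]
    names = list(totals)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append({
                "set": f"{a} - {b}",
                "total_nonsense_content": totals[a] - totals[b],
            })
    return pd.DataFrame(rows)


@dataclass
class CorrelationReport:
    pearson_rho: float
    r_squared: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "pearson_rho": self.pearson_rho, "r_squared": self.r_squared,
            "p_value": self.p_value, "n": self.n,
        }


def correlate_dc_nc(dc: np.ndarray, nc: np.ndarray) -> CorrelationReport:
    """Pearson correlation and simple linear regression of nonsense content
    on disorder content over sequences."""
    dc = np.asarray(dc, dtype=float)
    nc = np.asarray(nc, dtype=float)
    if dc.size != nc.size or dc.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(dc) == 0 or np.ptp(nc) == 0:
        raise ValueError("zero variance in disorder or nonsense content")
    res = stats.linregress(dc, nc)
    return CorrelationReport(
        pearson_rho=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=dc.size,
    )


def composition_logratio(
    set_a: list[str], set_b: list[str]
) -> pd.DataFrame:
    """Per-amino-acid log2 ratio of pooled frequencies between two sequence
    sets, plus the relative difference (freq_a - freq_b) / freq_b used to
    order residues by enrichment."""
    from .genome_io import STANDARD_AA

    def pooled(seqs: list[str]) -> np.ndarray:
        if not seqs:
            raise ValueError("empty sequence set")
        counts = np.zeros(20)
        for s in seqs:
            for a in s:
                counts[STANDARD_AA.index(a)] += 1
        return counts / counts.sum()

    fa, fb = pooled(set_a), pooled(set_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.where((fa > 0) & (fb > 0), np.log2(fa / np.where(fb > 0, fb, 1)), np.nan)
        reldiff = np.where(fb > 0, (fa - fb) / np.where(fb > 0, fb, 1), np.nan)
    return pd.DataFrame({
        "amino_acid": list(STANDARD_AA),
        "freq_a": fa, "freq_b": fb,
        "log2_ratio": log2r, "relative_difference": reldiff,
    })


def content_histogram(values: np.ndarray, bins: int = 10) -> pd.DataFrame:
    """Tabular histogram of content values on [0, 1], right-closed bins."""
    values = np.asarray(values, dtype=float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    # right-closed: (lo, hi]; first bin includes 0
    idx = np.clip(np.ceil(values * bins).astype(int) - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:],
        "count": counts, "fraction": counts / values.size,
    })
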