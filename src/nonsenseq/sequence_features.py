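"""Per-residue sequence features and intrinsic-disorder scores.

Each residue is described by 23 features computed over a sliding window of
41 residues centered on it (truncated at sequence ends, no padding):

* 20 amino-acid frequencies (alphabetical: A C D E F G H I K L M N P Q R S T V W Y),
* Shannon entropy of those frequencies (bits, local sequence complexity),
* mean chain flexibility (dot product with a normalized B-factor-derived scale),
* |net charge| / mean hydropathy (Kyte–Doolittle rescaled to [0, 1]).

Disorder scores come from a pluggable provider.  The built-in surrogate is a
deterministic composition contrast — disorder-promoting {R,Q,S,E,K,G,P} minus
order-promoting {W,Y,F,I,L,V,C,N} window frequency, squashed through a
logistic — standing in for an external per-residue disorder predictor whose
scores can instead be supplied as a TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .genome_io import STANDARD_AA

AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}

FEATURE_NAMES = [f"freq_{a}" for a in STANDARD_AA] + [
    "entropy",
    "flexibility",
    "charge_hydropathy_ratio",
]

#: Normalized average chain flexibility (B-factor derived), per residue.
FLEXIBILITY_SCALE = {
    "A": 0.984, "C": 0.906, "D": 1.068, "E": 1.094, "F": 0.915,
    "G": 1.031, "H": 0.950, "I": 0.927, "K": 1.102, "L": 0.935,
    "M": 0.952, "N": 1.048, "P": 1.049, "Q": 1.037, "R": 1.008,
    "S": 1.046, "T": 0.997, "V": 0.931, "W": 0.904, "Y": 0.929,
}

#: Kyte–Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

CHARGE = {a: 0.0 for a in STANDARD_AA}
CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})  # H neutral

DISORDER_PROMOTING = set("RQSEKGP")
ORDER_PROMOTING = set("WYFILVCN")

_RATIO_DELTA = 1e-6

DEFAULT_WINDOW = 41


def _scale_vector(scale: dict[str, float]) -> np.ndarray:
    return np.array([scale[a] for a in STANDARD_AA])

_FLEX_VEC = _scale_vector(FLEXIBILITY_SCALE)
_HYDRO_VEC = (_scale_vector(KYTE_DOOLITTLE) + 4.5) / 9.0  # rescaled to [0, 1]
_CHARGE_VEC = _scale_vector(CHARGE)


def load_scale_tsv(path: str | Path) -> np.ndarray:
    """Read a per-amino-acid scale (columns: amino_acid, value) so alternative
    flexibility/hydropathy parameterizations can be dropped in."""
    df = pd.read_csv(path, sep="\t")
    values = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    missing = set(STANDARD_AA) - set(values)
    if missing:
        raise ValueError(f"scale file missing amino acids: {sorted(missing)}")
    return np.array([values[a] for a in STANDARD_AA])


@dataclass
class FeatureMatrix:
    sequence_id: str
    rows: np.ndarray  # L x 23

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected L x {len(FEATURE_NAMES)} matrix")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=FEATURE_NAMES)
        df.insert(0, "position", np.arange(len(df)))
        df.insert(0, "sequence_id", self.sequence_id)
        return df


@dataclass
class DisorderProfile:
    sequence_id: str
    scores: np.ndarray  # per-residue, in [0, 1]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")

    @property
    def binary(self) -> np.ndarray:
        return self.scores > 0.5

    @property
    def disorder_content(self) -> float:
        return float(np.count_nonzero(self.binary)) / len(self.scores)


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int64)
    for a, i in AA_INDEX.items():
        lut[ord(a)] = i
    enc = lut[codes]
    if np.any(enc < 0):
        pos = int(np.flatnonzero(enc < 0)[0])
        raise ValueError(f"non-standard residue {seq[pos]!r} at position {pos}")
    return enc


def _window_counts(seq: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts of each amino acid in the truncated window around every
    position, plus the actual window lengths.  O(L) via cumulative sums."""
    enc = _encode(seq)
    L = len(enc)
    half = window // 2
    onehot = np.zeros((L + 1, 20), dtype=np.int64)
    onehot[np.arange(1, L + 1), enc] = 1
    cum = np.cumsum(onehot, axis=0)
    lo = np.maximum(np.arange(L) - half, 0)
    hi = np.minimum(np.arange(L) + half + 1, L)
    counts = cum[hi] - cum[lo]
    return counts, (hi - lo)


def window_composition(seq: str, center: int, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Amino-acid frequencies in the window centered at ``center``,
    truncated at sequence ends and normalized by the actual window size."""
    if not 0 <= center < len(seq):
        raise IndexError(f"center {center} outside sequence of length {len(seq)}")
    counts, sizes = _window_counts(seq, window)
    return counts[center] / sizes[center]


def window_entropy(freqs: np.ndarray) -> float:
    """Shannon entropy (bits) of a 20-frequency vector; 0 log 0 := 0."""
    f = np.asarray(freqs, dtype=float)
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def window_flexibility(freqs: np.ndarray, scale: np.ndarray | None = None) -> float:
    scale = _FLEX_VEC if scale is None else np.asarray(scale, dtype=float)
    return float(np.dot(freqs, scale))


def charge_hydropathy_ratio(freqs: np.ndarray, hydro_scale: np.ndarray | None = None) -> float:
    """|net charge| over mean hydropathy (rescaled KD), with a small delta
    guarding the division."""
    f = np.asarray(freqs, dtype=float)
    hydro = _HYDRO_VEC if hydro_scale is None else np.asarray(hydro_scale, dtype=float)
    net_charge = abs(float(np.dot(f, _CHARGE_VEC)))
    mean_hydro = float(np.dot(f, hydro))
    return net_charge / (mean_hydro + _RATIO_DELTA)


def featurize_sequence(
    seq: str,
    sequence_id: str = "",
    window: int = DEFAULT_WINDOW,
    flex_scale: np.ndarray | None = None,
    hydro_scale: np.ndarray | None = None,
) -> FeatureMatrix:
    """All 23 features for every residue of ``seq`` (vectorized)."""
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    counts, sizes = _window_counts(seq, window)
    freqs = counts / sizes[:, None]

    logs = np.zeros_like(freqs)
    np.log2(freqs, out=logs, where=freqs > 0)
    entropy = -(freqs * logs).sum(axis=1)

    flex_vec = _FLEX_VEC if flex_scale is None else np.asarray(flex_scale, dtype=float)
    hydro_vec = _HYDRO_VEC if hydro_scale is None else np.asarray(hydro_scale, dtype=float)
    flexibility = freqs @ flex_vec
    net_charge = np.abs(freqs @ _CHARGE_VEC)
    mean_hydro = freqs @ hydro_vec
    ratio = net_charge / (mean_hydro + _RATIO_DELTA)

    rows = np.column_stack([freqs, entropy, flexibility, ratio])
    return FeatureMatrix(sequence_id, rows)


# ---------------------------------------------------------------------------
# disorder scores

_DIS_VEC = np.array([1.0 if a in DISORDER_PROMOTING else 0.0 for a in STANDARD_AA])
_ORD_VEC = np.array([1.0 if a in ORDER_PROMOTING else 0.0 for a in STANDARD_AA])


def surrogate_disorder(seq: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Composition-contrast disorder score per residue.

    d = (window frequency of disorder-promoting residues) minus (window
    frequency of order-promoting residues); score = logistic(6 d), so a
    window with equal content of the two groups scores exactly 0.5.
    """
    counts, sizes = _window_counts(seq, window)
    freqs = counts / sizes[:, None]
    d = freqs @ _DIS_VEC - freqs @ _ORD_VEC
    return 1.0 / (1.0 + np.exp(-6.0 * d))


def disorder_scores(
    seq: str,
    sequence_id: str = "",
    predictor: Callable[[str], np.ndarray] | None = None,
) -> DisorderProfile:
    """Disorder profile from the given provider (default: the surrogate).

    An external provider must return one score per residue; a length
    mismatch is an error.
    """
    fn = predictor if predictor is not None else surrogate_disorder
    scores = np.asarray(fn(seq), dtype=float)
    if scores.shape != (len(seq),):
        raise ValueError(
            f"{sequence_id}: predictor returned {scores.shape[0] if scores.ndim else 0}"
            f" scores for {len(seq)} residues"
        )
    return DisorderProfile(sequence_id, scores)


def read_disorder_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Externally computed per-residue disorder scores
    (columns: sequence_id, position, score)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, np.ndarray] = {}
    for sid, grp in df.groupby("sequence_id", sort=False):
        grp = grp.sort_values("position")
        if not np.array_equal(grp["position"].to_numpy(), np.arange(len(grp))):
            raise ValueError(f"{sid}: positions must be contiguous from 0")
        out[str(sid)] = grp["score"].to_numpy(dtype=float)
    return out


def tsv_disorder_provider(path: str | Path) -> Callable[[str, str], DisorderProfile]:
    """Provider backed by a score TSV; raises if a sequence is missing or
    its score vector length mismatches."""
    table = read_disorder_tsv(path)

    def provide(seq: str, sequence_id: str) -> DisorderProfile:
        if sequence_id not in table:
            raise KeyError(f"no disorder scores for {sequence_id}")
        scores = table[sequence_id]
        if len(scores) != len(seq):
            raise ValueError(
                f"{sequence_id}: {len(scores)} scores for {len(seq)} residues"
            )
        return DisorderProfile(sequence_id, scores)

    return provide


def write_feature_tsv(matrices: list[FeatureMatrix], path: str | Path) -> None:
    pd.concat([fm.to_frame() for fm in matrices], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
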