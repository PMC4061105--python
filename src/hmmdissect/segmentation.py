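"""Partitioning domain-model positions into fold-critical vs remnant segments.

Three segmentation schemes are supported:

* **dssp** — positions whose aligned residue carries a DSSP secondary
  structure code (H, B, E, G, I, T, S) are fold-critical; loop residues
  and alignment gaps are remnant.
* **quality** — a CLUSTALX-style per-column conservation score computed
  from BLOSUM62 distances to a column consensus vector.  Columns at or
  above a cutoff (0.06 for SMART-like seed alignments, 0.14 for
  Pfam-like) are fold-critical.
* **seg** — per-column probabilities derived from external SEG
  low-complexity masks via a binomial column test; columns with
  probability >= 0.8 count as high-complexity (fold-critical surrogate).

All schemes produce the same :class:`Segmentation` container: a
per-position FOLD/REMNANT class and the maximal-run 1-based closed
intervals of each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .alignment_io import (
    GAP,
    STRUCTURAL_LABELS,
    UNSTRUCTURED_LABELS,
    MultipleAlignment,
    ResidueAnnotation,
)
from .model_io import AMINO_ALPHABET

FOLD = "FOLD"
REMNANT = "REMNANT"

#: quality-score cutoffs calibrated at a 5% column false-positive rate
DEFAULT_CUTOFF_SMART = 0.06
DEFAULT_CUTOFF_PFAM = 0.14

#: minimum non-gap residues per column for the binomial column test to
#: have power at alpha = 0.05
MIN_SEQUENCES = 5


def blosum62() -> np.ndarray:
    """BLOSUM62 as a symmetric 20x20 array over the amino alphabet."""
    mat = substitution_matrices.load("BLOSUM62")
    idx = [mat.alphabet.index(a) for a in AMINO_ALPHABET]
    return np.asarray(mat)[np.ix_(idx, idx)].astype(float)


def load_substitution_matrix(path: str) -> np.ndarray:
    """Read an NCBI-format substitution matrix file (e.g. BLOSUM62)."""
    with open(path) as fh:
        mat = substitution_matrices.read(fh)
    idx = [mat.alphabet.index(a) for a in AMINO_ALPHABET]
    return np.asarray(mat)[np.ix_(idx, idx)].astype(float)


# ---------------------------------------------------------------------------
# quality profile
# ---------------------------------------------------------------------------

@dataclass
class QualityProfile:
    """Per-column conservation profile of a seed alignment.

    ``consensus[j]`` is the consensus vector X_j (length 20),
    ``distances[i, j]`` the per-sequence distance D_ij (NaN at gaps),
    ``raw[j]`` the quality Q_j, ``inverted[j]`` the min-max inverted
    Q-hat in [0, 1] and ``normalized[j]`` the gap-downweighted Q-tilde =
    (k_j / M) * Q-hat_j.
    """

    consensus: np.ndarray
    distances: np.ndarray
    raw: np.ndarray
    inverted: np.ndarray
    normalized: np.ndarray
    valid_count: np.ndarray
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return self.raw.shape[0]


def quality_profile(
    aln: MultipleAlignment,
    substitution_matrix: np.ndarray | None = None,
    distance: str = "euclidean",
) -> QualityProfile:
    """CLUSTALX-style column quality profile of a multiple alignment.

    For column j, the consensus vector is X_j = F_j^T C / M where F_j
    counts residues in the column and C is the substitution matrix.  Each
    non-gap residue contributes the distance between X_j and its own
    score vector C[:, a_ij]; the column quality Q_j averages these over
    all M sequences (gap rows contribute zero to the sum but stay in the
    divisor).  Q is then min-max inverted across columns to Q-hat in
    [0, 1] (so the most conserved column scores 1) and down-weighted by
    the non-gap fraction to Q-tilde.

    ``distance`` selects the Euclidean norm (default) or the plain signed
    sum of componentwise differences (``"signed_sum"``).
    """
    if substitution_matrix is None:
        substitution_matrix = blosum62()
    C = np.asarray(substitution_matrix, dtype=float)
    if C.shape != (20, 20) or not np.allclose(C, C.T):
        raise ValueError("substitution matrix must be a symmetric 20x20 table")
    if distance not in ("euclidean", "signed_sum"):
        raise ValueError(f"unknown distance {distance!r}")

    M, N = aln.n_sequences, aln.n_columns
    index = {a: i for i, a in enumerate(AMINO_ALPHABET)}
    codes = np.full((M, N), -1, dtype=int)
    for i, row in enumerate(aln.rows):
        for j, a in enumerate(row):
            if a == GAP:
                continue
            try:
                codes[i, j] = index[a]
            except KeyError:
                raise ValueError(f"residue {a!r} outside the amino alphabet") from None

    valid = codes >= 0
    k = valid.sum(axis=0)

    # F: (20, N) residue counts per column; X: (N, 20) consensus vectors
    F = np.zeros((20, N))
    for r in range(20):
        F[r] = (codes == r).sum(axis=0)
    X = (F.T @ C) / M

    D = np.full((M, N), np.nan)
    for i in range(M):
        cols = np.nonzero(valid[i])[0]
        if cols.size == 0:
            continue
        S = C[:, codes[i, cols]].T  # (n_valid, 20) score vectors
        diff = X[cols] - S
        if distance == "euclidean":
            D[i, cols] = np.sqrt((diff**2).sum(axis=1))
        else:
            D[i, cols] = diff.sum(axis=1)

    Q = np.nansum(D, axis=0) / M
    qmin, qmax = Q.min(), Q.max()
    if qmax > qmin:
        qhat = 1.0 - (Q - qmin) / (qmax - qmin)
    else:
        # perfectly homogeneous alignment: maximal consensus everywhere
        qhat = np.ones_like(Q)
    qtilde = (k / M) * qhat
    return QualityProfile(
        consensus=X,
        distances=D,
        raw=Q,
        inverted=qhat,
        normalized=qtilde,
        valid_count=k,
        n_sequences=M,
    )


def min_sequence_pvalue(M: int, k: int, p: float = 0.5) -> float:
    """Exact binomial tail P(X >= k) for k positives among M trials.

    Used both for the minimum-sequences power argument (columns with
    fewer than 5 residues cannot reach significance at alpha = 0.05) and
    for the per-column SEG test.
    """
    if not 0 <= k <= M:
        raise ValueError(f"need 0 <= k <= M, got k={k}, M={M}")
    if M == 0:
        raise ValueError("column must contain at least one sequence")
    return float(stats.binom.sf(k - 1, M, p))


# ---------------------------------------------------------------------------
# segmentation container
# ---------------------------------------------------------------------------

@dataclass
class Segmentation:
    """FOLD/REMNANT partition of model positions 1..K."""

    classes: list[str]
    scheme: str = "manual"
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("segmentation must cover at least one position")
        for c in self.classes:
            if c not in (FOLD, REMNANT):
                raise ValueError(f"unknown segment class {c!r}")

    @property
    def model_length(self) -> int:
        return len(self.classes)

    def class_of(self, k: int) -> str:
        return self.classes[k - 1]

    @property
    def intervals(self) -> list[tuple[int, int, str]]:
        """Maximal runs of one class as (start, end, class), 1-based closed."""
        out: list[tuple[int, int, str]] = []
        start = 1
        for k in range(2, self.model_length + 1):
            if self.classes[k - 1] != self.classes[start - 1]:
                out.append((start, k - 1, self.classes[start - 1]))
                start = k
        out.append((start, self.model_length, self.classes[start - 1]))
        return out

    def intervals_of(self, cls: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, c in self.intervals if c == cls]

    def label_string(self) -> str:
        return "".join("F" if c == FOLD else "R" for c in self.classes)

    def to_tsv(self) -> str:
        rows = ["model_start\tmodel_end\tclass"]
        rows += [f"{s}\t{e}\t{c}" for s, e, c in self.intervals]
        return "\n".join(rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str, scheme: str = "manual") -> "Segmentation":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        ivals = []
        for ln in lines[1:]:
            s, e, c = ln.split("\t")
            ivals.append((int(s), int(e), c))
        ivals.sort()
        K = max(e for _, e, _ in ivals)
        classes = [None] * K
        for s, e, c in ivals:
            for k in range(s, e + 1):
                if classes[k - 1] is not None:
                    raise ValueError(f"overlapping intervals at position {k}")
                classes[k - 1] = c
        if any(c is None for c in classes):
            raise ValueError("intervals do not tile 1..K")
        return cls(classes=classes, scheme=scheme)


def segment_by_quality(
    profile: QualityProfile | Sequence[float],
    cutoff: float = DEFAULT_CUTOFF_SMART,
    model_length: int | None = None,
) -> Segmentation:
    """Threshold the normalized quality score into FOLD/REMNANT segments.

    Positions with Q-tilde >= cutoff are fold-critical (high quality);
    the rest are remnant.  Profile columns are assumed to map 1:1 onto
    model positions.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    qtilde = profile.normalized if isinstance(profile, QualityProfile) else np.asarray(profile, float)
    if model_length is not None and len(qtilde) != model_length:
        raise ValueError(
            f"profile covers {len(qtilde)} columns but model length is {model_length}"
        )
    classes = [FOLD if q >= cutoff else REMNANT for q in qtilde]
    return Segmentation(classes=classes, scheme="quality", cutoff=cutoff)


def segment_by_dssp(ann: ResidueAnnotation) -> Segmentation:
    """DSSP-based segmentation: structural labels -> FOLD, loop/gap -> REMNANT."""
    classes = []
    for lab in ann.labels:
        if lab in STRUCTURAL_LABELS:
            classes.append(FOLD)
        elif lab in UNSTRUCTURED_LABELS:
            classes.append(REMNANT)
        else:  # pragma: no cover - ResidueAnnotation already validates
            raise ValueError(f"unknown label {lab!r}")
    return Segmentation(classes=classes, scheme="dssp")


# ---------------------------------------------------------------------------
# SEG-derived column probabilities
# ---------------------------------------------------------------------------

@dataclass
class SegColumnProbability:
    """Binomial evaluation of one alignment column of SEG indicators."""

    k: int
    M: int
    p_value: float
    k_exp: float
    p_exp: float
    high_complexity: bool


def seg_column_probability(
    flags: Sequence[int],
    alpha: float = 0.05,
    cutoff: float = 0.8,
    literal: bool = True,
) -> SegColumnProbability:
    """Per-column high-complexity probability from SEG indicator flags.

    ``flags`` holds one indicator per sequence with a residue in the
    column: 1 for a high-complexity (positive) residue, 0 for a
    SEG-flagged low-complexity one.  The binomial tail P(X >= k) at
    p = 0.5 is tested at ``alpha``; on rejection the expected positive
    count is k_exp = P(X >= k) * k, otherwise k_exp = 0.  The column
    probability is p_exp = k_exp / M, floored at 0.01 when k_exp = 0,
    and the column counts as high-complexity iff p_exp >= ``cutoff``.

    With ``literal=False`` the complement weighting
    k_exp = (1 - P(X >= k)) * k is used instead, which makes confidently
    positive columns score high rather than low.
    """
    flags = list(flags)
    if not flags:
        raise ValueError("empty column")
    if any(f not in (0, 1) for f in flags):
        raise ValueError("flags must be 0/1 indicators")
    M = len(flags)
    k = sum(flags)
    p = min_sequence_pvalue(M, k)
    if p < alpha:
        k_exp = (p if literal else 1.0 - p) * k
    else:
        k_exp = 0.0
    p_exp = 0.01 if k_exp == 0 else k_exp / M
    return SegColumnProbability(
        k=k, M=M, p_value=p, k_exp=k_exp, p_exp=p_exp, high_complexity=p_exp >= cutoff
    )


def seg_masks_to_columns(
    aln: MultipleAlignment, masks: dict[str, Sequence[int]]
) -> list[list[int]]:
    """Project per-sequence ungapped SEG masks back to alignment columns.

    ``masks[seq_id][r]`` is the 0/1 indicator of the r-th ungapped
    residue of that sequence (1 = high-complexity).  Returns, per column,
    the indicator list over the sequences with a residue there.
    """
    cols: list[list[int]] = [[] for _ in range(aln.n_columns)]
    for sid, row in zip(aln.sequence_ids, aln.rows):
        mask = masks[sid]
        r = 0
        n_res = sum(1 for a in row if a != GAP)
        if len(mask) != n_res:
            raise ValueError(
                f"mask length {len(mask)} != {n_res} residues for sequence {sid!r}"
            )
        for j, a in enumerate(row):
            if a == GAP:
                continue
            cols[j].append(int(mask[r]))
            r += 1
    return cols


def segment_by_seg(
    columns: Iterable[Sequence[int]],
    alpha: float = 0.05,
    cutoff: float = 0.8,
    literal: bool = True,
) -> Segmentation:
    """Segment from per-column SEG indicators: high-complexity -> FOLD."""
    classes = []
    for col in columns:
        prob = seg_column_probability(col, alpha=alpha, cutoff=cutoff, literal=literal)
        classes.append(FOLD if prob.high_complexity else REMNANT)
    return Segmentation(classes=classes, scheme="seg", cutoff=cutoff)


# ---------------------------------------------------------------------------
# cutoff calibration
# ---------------------------------------------------------------------------

def confusion_rates(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """(FPR, TPR) from confusion counts: TPR = TP/(TP+FN), FPR = FP/(FP+TN)."""
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return fpr, tpr


def calibrate_cutoff(
    qt_scores_ge5: Sequence[float],
    qt_scores_lt5: Sequence[float],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Confusion table of quality-score cutoffs against the column classes.

    Columns with at least 5 non-gap residues form the positive class,
    columns with fewer the negative (null) class.  At each grid cutoff a
    score >= cutoff is called positive, giving TP/FN/FP/TN and the rates
    TPR = TP/(TP+FN), FPR = FP/(FP+TN).
    """
    pos = np.asarray(qt_scores_ge5, dtype=float)
    neg = np.asarray(qt_scores_lt5, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score classes must be non-empty")
    rows = []
    for c in grid:
        tp = int((pos >= c).sum())
        fn = int(pos.size - tp)
        fp = int((neg >= c).sum())
        tn = int(neg.size - fp)
        fpr, tpr = confusion_rates(tp, fn, fp, tn)
        rows.append(
            {"cutoff": c, "TP": tp, "FN": fn, "FP": fp, "TN": tn, "FPR": fpr, "TPR": tpr}
        )
    return pd.DataFrame(rows)
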