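"""Score reconstruction and dissection into segment-class contributions.

The total log2-odds score of a model-to-sequence alignment is the sum of
per-step emission scores, per-step transition scores (including the
B -> M entry and M -> E exit), and a position-invariant fixed score f
taken from the model's XT line.  Every positional term is anchored to a
model coordinate, so the total can be apportioned exactly between the
fold-critical and remnant segment classes: fold + remnant + f = total by
construction, under any segmentation.

E-values follow the maximum Gumbel extreme value distribution,
E = N * (1 - exp(-exp(-lambda * (v - mu)))), with the model's calibrated
(mu, lambda) and a database size N.  The fold and remnant sub-scores are
evaluated with the same calibration; their E-value ratio E1/E2 is the
diagnostic: << 1 supports homology, >> 1 flags a spurious similarity
carried by non-globular segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .alignment_io import AlignmentPath, State, Step
from .model_io import NEG_INF, HmmModel
from .segmentation import FOLD, REMNANT, Segmentation

#: UniProt/SwissProt sequence count used as the standard database size
DEFAULT_DB_SIZE = 540261

#: E-value significance threshold for homology calls
DEFAULT_SIGNIFICANCE = 0.1

#: verdict bands on the E1/E2 ratio
RATIO_SUPPORTING = 0.1
RATIO_SPURIOUS = 10.0


class PathModelError(ValueError):
    """Raised when a path is inconsistent with the model it is scored on."""


def _entry_term(first: Step, model: HmmModel) -> float:
    """Entry transition score into a fragment's first state.

    Entries into interior states of a converted (originally local) model
    have no stored parameter; those contribute 0 bits, which is the
    approximation inherent to rebuilding local-fragment scores from a
    glocal parameter file.
    """
    k = first.model_pos
    if first.state is State.MATCH:
        if k == 1:
            return model.b_to_m1
        s = model.transition_score(k, "BM")
        return 0.0 if s == NEG_INF else s
    if first.state is State.DELETE:
        return model.b_to_d1 if k == 1 else 0.0
    raise PathModelError("fragment cannot start in an INSERT state")


def _exit_term(last: Step, model: HmmModel) -> float:
    """Exit transition score out of a fragment's last state (to E)."""
    k = last.model_pos
    if last.state is State.MATCH:
        s = model.transition_score(k, "ME")
        if k == model.length_K:
            return s
        return 0.0 if s == NEG_INF else s
    # D_k -> E carries no parameter in the save format
    return 0.0


_PAIR_TRANSITION = {
    (State.MATCH, State.MATCH): "MM",
    (State.MATCH, State.INSERT): "MI",
    (State.MATCH, State.DELETE): "MD",
    (State.INSERT, State.MATCH): "IM",
    (State.INSERT, State.INSERT): "II",
    (State.DELETE, State.MATCH): "DM",
    (State.DELETE, State.DELETE): "DD",
}


def iter_score_terms(
    path: AlignmentPath, model: HmmModel
) -> Iterator[tuple[int, float]]:
    """Yield (anchor model position, score in bits) for every positional term.

    Anchoring rule: an emission at model position k belongs to k; a
    transition into position k belongs to k; insert emissions and I -> I
    self-transitions belong to the last match/delete position visited;
    the exit transition belongs to the fragment's last position.  The
    fixed score f is *not* yielded.
    """
    K = model.length_K
    for frag in path.fragments:
        for step in frag:
            if not 1 <= step.model_pos <= K:
                raise PathModelError(
                    f"path visits model position {step.model_pos} outside 1..{K}"
                )
        first, last = frag[0], frag[-1]
        yield first.model_pos, _entry_term(first, model)
        prev: Step | None = None
        for step in frag:
            if prev is not None:
                kind = _PAIR_TRANSITION.get((prev.state, step.state))
                if kind is None:
                    raise PathModelError(
                        f"illegal transition {prev.state.name} -> {step.state.name}"
                    )
                yield step.model_pos, model.transition_score(prev.model_pos, kind)
            if step.state is State.MATCH:
                yield step.model_pos, model.match_score(step.model_pos, step.residue)
            elif step.state is State.INSERT:
                yield step.model_pos, model.insert_score(step.model_pos, step.residue)
            prev = step
        yield last.model_pos, _exit_term(last, model)


def reconstruct_score(path: AlignmentPath, model: HmmModel) -> float:
    """Total reconstructed log2-odds score of a hit, in bits.

    Sum of all positional terms plus the fixed score f.  An empty path
    (no fragments) scores f alone.  Any impossible (-inf) emission or
    interior transition makes the total -inf.
    """
    total = model.fixed_score
    for _, term in iter_score_terms(path, model):
        total += term
    return total


def evalue(
    score: float,
    model: HmmModel | None = None,
    db_size: int = DEFAULT_DB_SIZE,
    mu: float | None = None,
    lam: float | None = None,
) -> float:
    """Gumbel E-value of a bit score: E = N * (1 - exp(-exp(-lambda*(v-mu)))).

    (mu, lambda) default to the model's EVD calibration; explicit values
    override.  The computation is numerically stable at both tails: for
    large scores the survival probability collapses to exp(-lambda*(v-mu))
    without premature underflow.
    """
    if mu is None or lam is None:
        if model is None or not model.calibrated:
            raise ValueError(
                "uncalibrated model: supply explicit (mu, lambda) for E-values"
            )
        mu = model.evd_mu if mu is None else mu
        lam = model.evd_lambda if lam is None else lam
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if db_size < 1:
        raise ValueError("database size must be at least 1")
    if score == NEG_INF:
        return float(db_size)
    t = lam * (score - mu)
    if t < -30.0:
        # survival probability is 1 to double precision
        return float(db_size)
    if t > 30.0:
        # 1 - exp(-x) == x to double precision for x = e^-t < 1e-13
        return db_size * math.exp(-t)
    return db_size * (-math.expm1(-math.exp(-t)))


def evalue_ratio(fold_evalue: float, remnant_evalue: float) -> float:
    """Diagnostic ratio E1/E2 of the fold-critical vs remnant E-values."""
    if remnant_evalue <= 0:
        raise ValueError("remnant E-value must be positive")
    if fold_evalue < 0:
        raise ValueError("E-values cannot be negative")
    return fold_evalue / remnant_evalue


def ratio_verdict(ratio: float) -> str:
    """Verbal band for an E1/E2 ratio: supporting / on-par / spurious."""
    if ratio < RATIO_SUPPORTING:
        return "homology-supporting"
    if ratio > RATIO_SPURIOUS:
        return "spurious"
    return "on-par"


@dataclass
class DissectedScore:
    """Total and per-segment-class score sums with their E-values."""

    hit_id: str
    total_score: float
    fold_score: float
    remnant_score: float
    fixed_score: float
    total_evalue: float
    fold_evalue: float
    remnant_evalue: float
    ratio: float
    db_size: int
    fragment_scores: list[float]

    @property
    def verdict(self) -> str:
        return ratio_verdict(self.ratio)


def dissect(
    path: AlignmentPath,
    model: HmmModel,
    seg: Segmentation,
    db_size: int = DEFAULT_DB_SIZE,
    mu: float | None = None,
    lam: float | None = None,
) -> DissectedScore:
    """Apportion a hit's reconstructed score between segment classes.

    Every positional term goes to the class of its anchor position; the
    fixed score f enters the total (and its E-value) but neither class
    sum.  For multi-fragment hits the per-class sums run over all
    fragments before E-values are computed; per-fragment raw sums are
    reported as well (without f).
    """
    if seg.model_length != model.length_K:
        raise ValueError(
            f"segmentation covers {seg.model_length} positions, model has {model.length_K}"
        )
    fold = 0.0
    remnant = 0.0
    fragment_scores = []
    for frag in path.fragments:
        frag_path = AlignmentPath(path.hit_id, [frag], engine_tag=path.engine_tag)
        frag_sum = 0.0
        for anchor, term in iter_score_terms(frag_path, model):
            frag_sum += term
            if seg.class_of(anchor) == FOLD:
                fold += term
            else:
                remnant += term
        fragment_scores.append(frag_sum)
    f = model.fixed_score
    total = fold + remnant + f
    kwargs = dict(model=model, db_size=db_size, mu=mu, lam=lam)
    e_total = evalue(total, **kwargs)
    e_fold = evalue(fold, **kwargs)
    e_rem = evalue(remnant, **kwargs)
    return DissectedScore(
        hit_id=path.hit_id,
        total_score=total,
        fold_score=fold,
        remnant_score=remnant,
        fixed_score=f,
        total_evalue=e_total,
        fold_evalue=e_fold,
        remnant_evalue=e_rem,
        ratio=evalue_ratio(e_fold, e_rem),
        db_size=db_size,
        fragment_scores=fragment_scores,
    )
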