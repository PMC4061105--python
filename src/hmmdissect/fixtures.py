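"""Synthetic models, alignments, annotations and hit sets with known truth.

Everything the other modules consume can be generated here from a seeded
:class:`FixtureSpec`, so the whole pipeline is testable without any
external downloads.  The generators emulate the statistical structure
each consumer assumes — integer 1/1000-bit model scores, glocal or local
alignment paths, seed alignments with planted conserved (fold-critical)
and noisy (remnant) column blocks, DSSP-style annotations and SEG-style
masks, and labelled hit populations mirroring a seed-space search where
nearly every hit is a true one.

The naive scoring oracle (:func:`oracle_score`) lives here, away from
the production scoring path, and sums the exact integer file scores with
rational arithmetic so oracle-vs-implementation comparisons are
genuinely independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .alignment_io import AlignmentPath, MultipleAlignment, State, Step
from .hit_classification import Hit
from .model_io import (
    AMINO_ALPHABET,
    NEG_INF,
    TRANSITION_FIELDS,
    XT_FIELDS,
    HmmModel,
    parse_hmmer2_model,
    write_hmmer2_model,
)
from .segmentation import FOLD, REMNANT

STRUCT_CODES = "HEGTSBI"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic test universe.

    The same seed and spec always produce identical artifacts.  Defaults
    describe a small but typical domain: 8 match states, 8 seed
    sequences, strongly conserved fold blocks (per-column consensus
    probability 0.9) against uniform-noise remnant blocks with 20% gaps.
    """

    seed: int = 0
    model_length: int = 8
    n_sequences: int = 8
    conservation: float = 0.9
    gap_fraction: float = 0.2
    fold_blocks: list[tuple[int, int]] | None = None
    local_entries: bool = False
    label_noise: float = 0.05
    n_hits: int = 200
    p_false_hit: float = 0.01
    p_obscured: float = 0.05

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def planted_classes(self) -> list[str]:
        """Per-position FOLD/REMNANT truth (default: first half FOLD)."""
        K = self.model_length
        blocks = self.fold_blocks
        if blocks is None:
            blocks = [(1, max(1, K // 2))]
        classes = [REMNANT] * K
        for s, e in blocks:
            for k in range(s, e + 1):
                classes[k - 1] = FOLD
        return classes


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _milli(rng: np.random.Generator, lo: int, hi: int, shape=None) -> np.ndarray | float:
    """Integer 1/1000-bit scores as exact floats."""
    v = rng.integers(lo, hi, size=shape, endpoint=True)
    return v / 1000.0 if shape is not None else float(v) / 1000.0


def make_model(spec: FixtureSpec) -> tuple[HmmModel, str]:
    """A random calibrated model plus its save-file text.

    All scores are integer multiples of 1/1000 bit, so the written file
    round-trips bit-exactly.  By default the model is glocal-style: no
    interior entry/exit scores (``*`` in the b->m / m->e columns);
    ``local_entries=True`` fills them in, emulating a model whose local
    parameters survived conversion.
    """
    rng = spec.rng(salt=1)
    K = spec.model_length
    match = _milli(rng, -5000, 5000, (K, 20))
    insert = _milli(rng, -2000, 1000, (K, 20))
    trans = np.empty((K, 9))
    trans[:, :7] = _milli(rng, -3000, -1, (K, 7))  # MM..DD
    if spec.local_entries:
        trans[:, 7] = _milli(rng, -6000, -1000, (K,))  # BM
        trans[:, 8] = _milli(rng, -6000, -1000, (K,))  # ME
    else:
        trans[:, 7] = NEG_INF
        trans[:, 8] = NEG_INF
        trans[K - 1, 8] = 0.0  # glocal exit M_K -> E
    xt = {f: _milli(rng, -2000, -1) for f in XT_FIELDS}
    model = HmmModel(
        name=f"fixture{spec.seed}",
        match_emission=match,
        insert_emission=insert,
        transition=trans,
        xt=xt,
        null_transition=(_milli(rng, -10, -1), _milli(rng, -9000, -8000)),
        null_emission=_milli(rng, -2000, 1000, (20,)),
        b_to_m1=_milli(rng, -500, -1),
        b_to_d1=_milli(rng, -8000, -4000),
        evd_mu=round(float(rng.uniform(-60.0, -10.0)), 6),
        evd_lambda=round(float(rng.uniform(0.2, 0.7)), 6),
    )
    return model, write_hmmer2_model(model)


# ---------------------------------------------------------------------------
# alignment paths and the naive score oracle
# ---------------------------------------------------------------------------

def make_path(spec: FixtureSpec, model: HmmModel) -> AlignmentPath:
    """A random single-fragment glocal path through the whole model."""
    rng = spec.rng(salt=2)
    steps: list[Step] = []
    seq_pos = 1
    for k in range(1, model.length_K + 1):
        # no I->D edge exists, so a delete may not follow an insert run
        after_insert = bool(steps) and steps[-1].state is State.INSERT
        if rng.random() < 0.15 and 1 < k < model.length_K and not after_insert:
            steps.append(Step(State.DELETE, k))
            continue
        res = AMINO_ALPHABET[rng.integers(0, 20)]
        steps.append(Step(State.MATCH, k, seq_pos, res))
        seq_pos += 1
        while k < model.length_K and rng.random() < 0.1:
            res = AMINO_ALPHABET[rng.integers(0, 20)]
            steps.append(Step(State.INSERT, k, seq_pos, res))
            seq_pos += 1
    return AlignmentPath(hit_id=f"hit{spec.seed}", fragments=[steps])


def make_alignment_with_truth(
    spec: FixtureSpec, model: HmmModel
) -> tuple[AlignmentPath, Fraction]:
    """A random path plus its independently hand-summed score in bits."""
    path = make_path(spec, model)
    return path, oracle_score(path, model)


def _frac(bits: float) -> Fraction:
    """Exact rational value of an integer-milli-bit score."""
    if bits == NEG_INF:
        raise OverflowError("-inf score")
    return Fraction(int(round(bits * 1000)), 1000)


def oracle_score(path: AlignmentPath, model: HmmModel) -> Fraction | float:
    """Naive per-term reference scorer, exact over the file's integers.

    Walks the path term by term, looking every score up afresh and
    summing with rational arithmetic; returns -inf if any interior term
    is impossible.  Deliberately written without reference to the
    production scorer.
    """
    tcol = {name: i for i, name in enumerate(TRANSITION_FIELDS)}
    aidx = {a: i for i, a in enumerate(model.alphabet)}
    try:
        total = _frac(model.xt["NB"]) + _frac(model.xt["EC"]) + _frac(model.xt["CT"])
        for frag in path.fragments:
            # entry
            first = frag[0]
            if first.state is State.MATCH and first.model_pos == 1:
                total += _frac(model.b_to_m1)
            elif first.state is State.MATCH:
                bm = model.transition[first.model_pos - 1, tcol["BM"]]
                if bm != NEG_INF:
                    total += _frac(bm)
            elif first.state is State.DELETE and first.model_pos == 1:
                total += _frac(model.b_to_d1)
            # emissions and transitions
            for n, step in enumerate(frag):
                if step.state is State.MATCH:
                    total += _frac(model.match_emission[step.model_pos - 1, aidx[step.residue]])
                elif step.state is State.INSERT:
                    total += _frac(model.insert_emission[step.model_pos - 1, aidx[step.residue]])
                if n > 0:
                    prev = frag[n - 1]
                    key = prev.state.value.lower() + step.state.value.lower()
                    name = {"mm": "MM", "mi": "MI", "md": "MD", "im": "IM",
                            "ii": "II", "dm": "DM", "dd": "DD"}[key]
                    total += _frac(model.transition[prev.model_pos - 1, tcol[name]])
            # exit
            last = frag[-1]
            if last.state is State.MATCH:
                me = model.transition[last.model_pos - 1, tcol["ME"]]
                if last.model_pos == model.length_K:
                    total += _frac(me)
                elif me != NEG_INF:
                    total += _frac(me)
        return total
    except OverflowError:
        return NEG_INF


# ---------------------------------------------------------------------------
# rendered hmmsearch-style text
# ---------------------------------------------------------------------------

def _columns_of(frag: list[Step]) -> tuple[str, str]:
    cons = []
    target = []
    for s in frag:
        if s.state is State.INSERT:
            cons.append(".")
            target.append(s.residue.lower())
        elif s.state is State.DELETE:
            cons.append("x")
            target.append("-")
        else:
            cons.append("x")
            target.append(s.residue)
    return "".join(cons), "".join(target)


def render_hmmsearch_text(
    path: AlignmentPath, model: HmmModel, style: str = "hmmer2"
) -> str:
    """Render a path as an hmmsearch-like plain-text alignment block."""
    if style == "hmmer2":
        out = []
        for frag in path.fragments:
            cons, target = _columns_of(frag)
            sf, st = (
                min(s.seq_pos for s in frag if s.seq_pos),
                max(s.seq_pos for s in frag if s.seq_pos),
            )
            lead = max(7, len(f"{path.hit_id} {sf} ") + 1)
            out.append(
                f"{path.hit_id}: domain 1 of 1, from {sf} to {st}: score 0.0, E = 1"
            )
            out.append(" " * (lead - 3) + "*->" + cons + "<-*")
            out.append(" " * lead + "+" * len(cons))
            out.append(f"{path.hit_id} {sf}".ljust(lead) + target + f" {st}")
            out.append("")
        return "\n".join(out) + "\n"
    if style == "hmmer3":
        out = [f">> {path.hit_id}  synthetic hit"]
        for d, frag in enumerate(path.fragments, start=1):
            cons, target = _columns_of(frag)
            mstart = next(s.model_pos for s in frag if s.state is not State.INSERT)
            mend = max(s.model_pos for s in frag)
            sf = min(s.seq_pos for s in frag if s.seq_pos)
            st = max(s.seq_pos for s in frag if s.seq_pos)
            out.append(f"  == domain {d}  score: 0.0 bits;  conditional E-value: 1")
            out.append(f"  {model.name} {mstart} {cons} {mend}")
            out.append("  " + " " * (len(model.name) + len(str(mstart)) + 2) + "+" * len(cons))
            out.append(f"  {path.hit_id} {sf} {target} {st}")
            out.append("")
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown style {style!r}")


# ---------------------------------------------------------------------------
# seed alignments with planted segmentation truth
# ---------------------------------------------------------------------------

def make_seed_alignment(spec: FixtureSpec) -> tuple[MultipleAlignment, list[str]]:
    """Seed alignment with planted conserved (FOLD) / noisy (REMNANT) columns.

    Conserved columns draw one consensus residue with probability
    ``conservation`` and a uniform residue otherwise; noisy columns draw
    uniformly and contain gaps at rate ``gap_fraction``.  The planted
    per-column truth is returned alongside.
    """
    rng = spec.rng(salt=3)
    M, N = spec.n_sequences, spec.model_length
    truth = spec.planted_classes()
    cols: list[str] = []
    for j in range(N):
        if truth[j] == FOLD:
            consensus = AMINO_ALPHABET[rng.integers(0, 20)]
            col = [
                consensus
                if rng.random() < spec.conservation
                else AMINO_ALPHABET[rng.integers(0, 20)]
                for _ in range(M)
            ]
        else:
            col = [
                "-" if rng.random() < spec.gap_fraction else AMINO_ALPHABET[rng.integers(0, 20)]
                for _ in range(M)
            ]
        cols.append("".join(col))
    rows = ["".join(cols[j][i] for j in range(N)) for i in range(M)]
    aln = MultipleAlignment(
        sequence_ids=[f"seq{i + 1}" for i in range(M)], rows=rows
    )
    return aln, truth


def make_dssp_labels(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    """Per-model-position DSSP-style labels consistent with planted truth.

    FOLD positions receive a structural code, REMNANT positions the loop
    marker, with ``label_noise`` of positions flipped.  Returns
    (labels, truth).
    """
    rng = spec.rng(salt=4)
    truth = spec.planted_classes()
    labels = []
    for cls in truth:
        fold = cls == FOLD
        if rng.random() < spec.label_noise:
            fold = not fold
        labels.append(STRUCT_CODES[rng.integers(0, len(STRUCT_CODES))] if fold else " ")
    return labels, truth


def make_hit_dssp_labels(spec: FixtureSpec, path: AlignmentPath) -> list[str]:
    """Per-hit-residue DSSP-style labels consistent with planted truth.

    Residues matched to a planted FOLD model position get a structural
    code; everything else (remnant matches, inserts) is loop.  Indexed by
    the hit's 1-based residue numbering, covering 1..max(seq_pos).
    """
    rng = spec.rng(salt=7)
    truth = spec.planted_classes()
    n = max(s.seq_pos for s in path.steps if s.seq_pos is not None)
    labels = [" "] * n
    for step in path.steps:
        if step.seq_pos is None or step.state is not State.MATCH:
            continue
        if truth[step.model_pos - 1] == FOLD:
            labels[step.seq_pos - 1] = STRUCT_CODES[rng.integers(0, len(STRUCT_CODES))]
    return labels


def render_dssp_text(labels: list[str], chain: str = "A") -> str:
    """Render residue labels 1..n as a parseable DSSP file.

    Synthetic: carries only the fields a DSSP reader needs (residue
    number, chain, amino acid, structure code) with zeroed energies and
    angles at their fixed columns.
    """
    out = [
        "==== Secondary Structure Definition, synthetic fixture ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    for i, ss in enumerate(labels, start=1):
        line = [" "] * 116
        line[0:5] = f"{i:5d}"
        line[5:10] = f"{i:5d}"
        line[11] = chain
        line[13] = "A"
        line[16] = ss if ss != " " else " "
        line[34:38] = f"{0:4d}"
        line[38:45] = f"{0:7d}"
        line[45] = ","
        line[46:50] = f"{0.0:4.1f}"
        line[50:56] = f"{0:6d}"
        line[56] = ","
        line[57:61] = f"{0.0:4.1f}"
        line[61:67] = f"{0:6d}"
        line[67] = ","
        line[68:72] = f"{0.0:4.1f}"
        line[72:78] = f"{0:6d}"
        line[78] = ","
        line[79:83] = f"{0.0:4.1f}"
        line[103:109] = f"{0.0:6.1f}"
        line[109:115] = f"{0.0:6.1f}"
        out.append("".join(line))
    return "\n".join(out) + "\n"


def make_seg_masks(
    spec: FixtureSpec, aln: MultipleAlignment, truth: list[str]
) -> dict[str, list[int]]:
    """Per-sequence ungapped 0/1 SEG-style masks consistent with truth.

    Residues in FOLD columns are high-complexity (1) and residues in
    REMNANT columns SEG-flagged (0), each with ``label_noise`` flips.
    """
    rng = spec.rng(salt=5)
    masks: dict[str, list[int]] = {}
    for sid, row in zip(aln.sequence_ids, aln.rows):
        mask = []
        for j, a in enumerate(row):
            if a == "-":
                continue
            bit = 1 if truth[j] == FOLD else 0
            if rng.random() < spec.label_noise:
                bit = 1 - bit
            mask.append(bit)
        masks[sid] = mask
    return masks


# ---------------------------------------------------------------------------
# labelled hit populations
# ---------------------------------------------------------------------------

def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))


def make_paired_hit_population(spec: FixtureSpec) -> tuple[list[Hit], list[Hit]]:
    """Two engines' hit lists over a common seed-like search space.

    Emulates the seed-space condition: a fraction ``1 - p_false_hit`` of
    hits are genuinely true (significant fold-critical E-value), of
    which ``p_obscured`` have an insignificant total E-value (obscured,
    i.e. FN); false hits owe their total significance to the remnant
    segments.  Each engine assesses the same segment with independent
    E-value noise; a small number of engine-A-only orphans is appended.
    """
    rng = spec.rng(salt=6)

    def engine_evalues(true_hit: bool) -> tuple[float, float, float]:
        if true_hit:
            high = _log_uniform(rng, 1e-9, 1e-2)
            low = _log_uniform(rng, 0.5, 1e3)
            total = (
                _log_uniform(rng, 0.2, 10.0)
                if rng.random() < spec.p_obscured
                else _log_uniform(rng, 1e-9, 0.05)
            )
        else:
            high = _log_uniform(rng, 0.5, 1e4)
            low = _log_uniform(rng, 1e-7, 1e-2)
            total = (
                _log_uniform(rng, 1e-4, 0.05)
                if rng.random() < 0.5
                else _log_uniform(rng, 0.2, 10.0)
            )
        return total, high, low

    hits_a: list[Hit] = []
    hits_b: list[Hit] = []
    for n in range(spec.n_hits):
        true_hit = rng.random() >= spec.p_false_hit
        seq_id = f"seq{n}"
        start = int(rng.integers(1, 200))
        end = start + int(rng.integers(30, 120))
        jitter = int(rng.integers(-5, 6))
        ta, ha, la = engine_evalues(true_hit)
        tb, hb, lb = engine_evalues(true_hit)
        hits_a.append(Hit(f"a{n}", seq_id, start, end, ta, ha, la, engine="engineA"))
        hits_b.append(
            Hit(f"b{n}", seq_id, max(1, start + jitter), end + jitter, tb, hb, lb, engine="engineB")
        )
    for n in range(max(1, spec.n_hits // 50)):
        ta, ha, la = engine_evalues(True)
        hits_a.append(Hit(f"orph{n}", f"orphan{n}", 1, 60, ta, ha, la, engine="engineA"))
    return hits_a, hits_b


def verify_roundtrip(spec: FixtureSpec) -> bool:
    """Convenience check: the written model file parses back identically."""
    from .model_io import models_equal

    model, text = make_model(spec)
    return models_equal(model, parse_hmmer2_model(text))
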