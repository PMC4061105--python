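"""Reading and writing HMMER2-format ASCII profile-HMM save files.

The HMMER2 (Plan 7) save format stores all scores as integers in units of
1/1000 bit, with ``*`` denoting an impossible transition or emission.  A
parsed :class:`HmmModel` therefore carries plain ``float`` bit scores, with
``-inf`` as the impossible-score sentinel.

Only the HMMER2 dialect is handled.  HMMER3 models are expected in
converted form (``hmmconvert -2`` output), which is itself a valid HMMER2
file; the conversion drops local entry/exit scores for interior states,
which show up here as ``*`` columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

#: canonical amino-acid ordering used by HMMER2 save files
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: per-state transition score columns, in file order
TRANSITION_FIELDS = ("MM", "MI", "MD", "IM", "II", "DM", "DD", "BM", "ME")

#: special (position-invariant) transition scores on the XT line, in file order
XT_FIELDS = ("NB", "NN", "EC", "EJ", "CT", "CC", "JB", "JJ")

NEG_INF = float("-inf")


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


class IncompleteModelError(ModelParseError):
    """Raised when a mandatory section (e.g. the XT line) is missing."""


def _score_from_field(tok: str) -> float:
    if tok == "*":
        return NEG_INF
    return int(tok) / 1000.0


def _field_from_score(x: float) -> str:
    if x == NEG_INF:
        return "*"
    if not math.isfinite(x):
        raise ValueError(f"score {x!r} is neither finite nor the -inf sentinel")
    return str(int(round(x * 1000.0)))


@dataclass
class HmmModel:
    """Complete parameter set of one profile-HMM domain model.

    All scores are log2-odds in bits.  ``match_emission`` and
    ``insert_emission`` have shape ``(K, 20)`` over :data:`AMINO_ALPHABET`;
    ``transition`` has shape ``(K, 9)`` over :data:`TRANSITION_FIELDS`,
    where row ``k-1`` holds the transitions out of state ``k`` (``MM`` =
    ``M_k -> M_{k+1}`` etc.), plus the entry column ``BM`` (``B -> M_k``)
    and the exit column ``ME`` (``M_k -> E``).
    """

    name: str
    match_emission: np.ndarray
    insert_emission: np.ndarray
    transition: np.ndarray
    xt: dict[str, float]
    null_transition: tuple[float, float]
    null_emission: np.ndarray
    b_to_m1: float = 0.0
    b_to_d1: float = NEG_INF
    evd_mu: float | None = None
    evd_lambda: float | None = None
    alphabet: str = AMINO_ALPHABET

    def __post_init__(self) -> None:
        self.match_emission = np.asarray(self.match_emission, dtype=float)
        self.insert_emission = np.asarray(self.insert_emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        K = self.match_emission.shape[0]
        if K < 1:
            raise ValueError("model must have at least one match state")
        if self.match_emission.shape != (K, 20) or self.insert_emission.shape != (K, 20):
            raise ValueError("emission tables must have shape (K, 20)")
        if self.transition.shape != (K, len(TRANSITION_FIELDS)):
            raise ValueError("transition table must have shape (K, 9)")
        if set(self.xt) != set(XT_FIELDS):
            raise ValueError("xt must provide exactly the 8 special transition scores")
        if self.evd_lambda is not None and self.evd_lambda <= 0:
            raise ValueError("EVD lambda must be positive")

    @property
    def length_K(self) -> int:
        return self.match_emission.shape[0]

    @property
    def calibrated(self) -> bool:
        """Whether the model carries EVD statistics (mu, lambda)."""
        return self.evd_mu is not None and self.evd_lambda is not None

    @property
    def fixed_score(self) -> float:
        """Position-invariant score f for a single-domain hit.

        Sum of the N->B entry, E->C and C->T exit special transitions; the
        J loop and the per-residue N->N / C->C flank terms are not part of a
        single-domain alignment.
        """
        return self.xt["NB"] + self.xt["EC"] + self.xt["CT"]

    def transition_score(self, k: int, kind: str) -> float:
        """Score of transition ``kind`` out of / into state ``k`` (1-based)."""
        return float(self.transition[k - 1, TRANSITION_FIELDS.index(kind)])

    def match_score(self, k: int, residue: str) -> float:
        return float(self.match_emission[k - 1, self.alphabet.index(residue)])

    def insert_score(self, k: int, residue: str) -> float:
        return float(self.insert_emission[k - 1, self.alphabet.index(residue)])


def parse_hmmer2_model(source: str | TextIO) -> HmmModel:
    """Parse an HMMER2 ASCII save file into an :class:`HmmModel`.

    Integer score fields are converted to bits (divide by 1000); ``*``
    becomes the ``-inf`` sentinel.  A missing XT or NULT/NULE section is an
    :class:`IncompleteModelError`; a missing EVD line yields an
    uncalibrated model (``calibrated`` is False) rather than an error, so
    that E-value computations can be given explicit (mu, lambda) later.
    """
    text = source if isinstance(source, str) else source.read()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("HMMER2.0"):
        raise ModelParseError("not an HMMER2.0 save file (missing header)")

    name = "unnamed"
    length = None
    xt: dict[str, float] | None = None
    nult: tuple[float, float] | None = None
    nule: np.ndarray | None = None
    evd_mu = evd_lambda = None
    alphabet = AMINO_ALPHABET

    i = 1
    while i < len(lines):
        line = lines[i]
        tok = line.split()
        key = tok[0] if tok else ""
        if key == "NAME":
            name = line[4:].strip()
        elif key == "LENG":
            length = int(tok[1])
        elif key == "ALPH":
            if tok[1].lower() != "amino":
                raise ModelParseError(f"unsupported alphabet {tok[1]!r}")
        elif key == "XT":
            if len(tok) != 9:
                raise ModelParseError("XT line must carry 8 scores")
            xt = dict(zip(XT_FIELDS, (_score_from_field(t) for t in tok[1:])))
        elif key == "NULT":
            nult = (_score_from_field(tok[1]), _score_from_field(tok[2]))
        elif key == "NULE":
            nule = np.array([_score_from_field(t) for t in tok[1:]], dtype=float)
        elif key == "EVD":
            evd_mu, evd_lambda = float(tok[1]), float(tok[2])
        elif key == "HMM":
            break
        i += 1
    else:
        raise ModelParseError("no HMM main section found")

    if xt is None:
        raise IncompleteModelError("incomplete model: missing XT line")
    if nult is None or nule is None:
        raise IncompleteModelError("incomplete model: missing NULT/NULE lines")
    if length is None:
        raise ModelParseError("missing LENG line")

    # skip the alphabet header and the transition-order header
    i += 2
    if i >= len(lines):
        raise ModelParseError("truncated main model section")

    # optional begin line: B->M1, B->I0 (always '*'), B->D1
    b_to_m1, b_to_d1 = 0.0, NEG_INF
    tok = lines[i].split()
    if len(tok) == 3:  # state lines carry 21 fields, so 3 fields => begin line
        b_to_m1 = _score_from_field(tok[0])
        b_to_d1 = _score_from_field(tok[2])
        i += 1

    match_emission = np.empty((length, 20))
    insert_emission = np.empty((length, 20))
    transition = np.empty((length, 9))
    for k in range(1, length + 1):
        if i + 2 >= len(lines):
            raise ModelParseError(f"truncated emission block at state {k}")
        mtok = lines[i].split()
        itok = lines[i + 1].split()
        ttok = lines[i + 2].split()
        if len(mtok) < 21 or mtok[0] != str(k):
            raise ModelParseError(f"malformed match-emission line at state {k}")
        if len(itok) < 21 or len(ttok) < 10:
            raise ModelParseError(f"truncated emission block at state {k}")
        match_emission[k - 1] = [_score_from_field(t) for t in mtok[1:21]]
        insert_emission[k - 1] = [_score_from_field(t) for t in itok[1:21]]
        transition[k - 1] = [_score_from_field(t) for t in ttok[1:10]]
        i += 3

    return HmmModel(
        name=name,
        match_emission=match_emission,
        insert_emission=insert_emission,
        transition=transition,
        xt=xt,
        null_transition=nult,
        null_emission=nule,
        b_to_m1=b_to_m1,
        b_to_d1=b_to_d1,
        evd_mu=evd_mu,
        evd_lambda=evd_lambda,
        alphabet=alphabet,
    )


def _row(values: Iterable[float], width: int = 7) -> str:
    return " ".join(f"{_field_from_score(v):>{width}}" for v in values)


def write_hmmer2_model(model: HmmModel) -> str:
    """Render a model back to HMMER2 ASCII save-file text.

    ``parse_hmmer2_model(write_hmmer2_model(m))`` reproduces ``m``
    bit-exactly as long as every score is an integer multiple of 1/1000
    bit (which holds for anything read from a file).
    """
    out: list[str] = []
    out.append("HMMER2.0  [hmmdissect]")
    out.append(f"NAME  {model.name}")
    out.append(f"LENG  {model.length_K}")
    out.append("ALPH  Amino")
    out.append("RF    no")
    out.append("CS    no")
    out.append("MAP   no")
    out.append("XT    " + _row(model.xt[f] for f in XT_FIELDS))
    out.append("NULT  " + _row(model.null_transition))
    out.append("NULE  " + _row(model.null_emission))
    if model.calibrated:
        out.append(f"EVD   {model.evd_mu:.6f}  {model.evd_lambda:.6f}")
    out.append("HMM        " + "      ".join(model.alphabet))
    out.append("         " + "   ".join(f"{t.lower()[0]}->{t.lower()[1]}" for t in TRANSITION_FIELDS))
    out.append("      " + _row([model.b_to_m1, NEG_INF, model.b_to_d1]))
    for k in range(1, model.length_K + 1):
        out.append(f"{k:>6} " + _row(model.match_emission[k - 1]))
        out.append("     - " + _row(model.insert_emission[k - 1]))
        out.append("     - " + _row(model.transition[k - 1]))
    out.append("//")
    return "\n".join(out) + "\n"


def models_equal(a: HmmModel, b: HmmModel) -> bool:
    """Field-by-field equality of two models (scores compared exactly)."""
    return (
        a.name == b.name
        and a.alphabet == b.alphabet
        and np.array_equal(a.match_emission, b.match_emission)
        and np.array_equal(a.insert_emission, b.insert_emission)
        and np.array_equal(a.transition, b.transition)
        and a.xt == b.xt
        and a.null_transition == b.null_transition
        and np.array_equal(a.null_emission, b.null_emission)
        and a.b_to_m1 == b.b_to_m1
        and a.b_to_d1 == b.b_to_d1
        and a.evd_mu == b.evd_mu
        and a.evd_lambda == b.evd_lambda
    )
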