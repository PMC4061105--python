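"""Alignments, alignment paths and per-residue structural annotations.

Everything downstream works in *model coordinates*: match states of a
domain model are numbered 1..K, and intervals are 1-based and closed.
This module reads seed multiple alignments (Stockholm / aligned FASTA),
model-to-sequence alignment paths (from hmmsearch plain-text output, or
an explicit TSV), and DSSP annotations, and projects the latter onto
model coordinates.
"""

from __future__ import annotations

import enum
import io
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import AlignIO
from Bio.PDB.DSSP import make_dssp_dict

GAP = "-"

#: DSSP codes counted as structural (R_S)
STRUCTURAL_LABELS = frozenset("HBEGITS")
#: loop marker (DSSP blank structure code)
LOOP = " "

UNSTRUCTURED_LABELS = frozenset({LOOP, GAP})


class AlignmentError(ValueError):
    """Raised on malformed alignment input."""


@dataclass
class MultipleAlignment:
    """A seed multiple alignment of M sequences by N columns."""

    sequence_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment must contain at least one sequence")
        n = len(self.rows[0])
        for sid, row in zip(self.sequence_ids, self.rows):
            if len(row) != n:
                raise AlignmentError(f"ragged alignment row for sequence {sid!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        """Residues of 0-based column ``j``."""
        return "".join(row[j] for row in self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_stockholm(text: str) -> MultipleAlignment:
    """Read a Stockholm or aligned-FASTA alignment.

    Rows are uppercased and both ``.`` and ``-`` are unified to ``-``.
    """
    fmt = "stockholm" if text.lstrip().startswith("# STOCKHOLM") else "fasta"
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot read alignment: {exc}") from exc
    return MultipleAlignment(
        sequence_ids=[rec.id for rec in aln],
        rows=[_normalize(str(rec.seq)) for rec in aln],
    )


def write_stockholm(aln: MultipleAlignment) -> str:
    out = ["# STOCKHOLM 1.0"]
    width = max(len(s) for s in aln.sequence_ids) + 2
    for sid, row in zip(aln.sequence_ids, aln.rows):
        out.append(f"{sid:<{width}}{row}")
    out.append("//")
    return "\n".join(out) + "\n"


class State(enum.Enum):
    MATCH = "M"
    INSERT = "I"
    DELETE = "D"


@dataclass(frozen=True)
class Step:
    """One step of an alignment path.

    ``model_pos`` is the governing match-state coordinate: the state's own
    position for MATCH/DELETE, and the position of the insert state I_k
    (the last match/delete position visited) for INSERT.  ``seq_pos`` is
    the 1-based hit-sequence residue for MATCH/INSERT and None for DELETE;
    ``residue`` is the aligned amino acid for emitting steps.
    """

    state: State
    model_pos: int
    seq_pos: int | None = None
    residue: str | None = None


@dataclass
class AlignmentPath:
    """Ordered model-state/sequence-position pairs for one hit.

    A hit may consist of several fragments (HMMER3-style local
    alignments); each fragment is an independent entry/exit through the
    model.
    """

    hit_id: str
    fragments: list[list[Step]]
    engine_tag: str = ""

    def __post_init__(self) -> None:
        for frag in self.fragments:
            if not frag:
                raise AlignmentError("empty alignment fragment")
            last = None
            for step in frag:
                if step.state is State.DELETE and step.seq_pos is not None:
                    raise AlignmentError("DELETE steps carry no sequence position")
                if step.state in (State.MATCH, State.INSERT) and step.seq_pos is None:
                    raise AlignmentError(f"{step.state.name} steps need a sequence position")
                if step.state in (State.MATCH, State.DELETE):
                    if last is not None and step.model_pos <= last:
                        raise AlignmentError("model position must strictly increase")
                    last = step.model_pos

    @property
    def steps(self) -> list[Step]:
        return [s for frag in self.fragments for s in frag]

    def match_positions(self) -> list[int]:
        return [s.model_pos for s in self.steps if s.state is State.MATCH]

    def seq_span(self) -> tuple[int, int]:
        pos = [s.seq_pos for s in self.steps if s.seq_pos is not None]
        return (min(pos), max(pos))


# ---------------------------------------------------------------------------
# hmmsearch plain-text output
# ---------------------------------------------------------------------------

def _walk_columns(
    consensus: str, target: str, model_pos: int, seq_pos: int
) -> tuple[list[Step], int, int]:
    """Convert one aligned text chunk into steps.

    Column semantics shared by both engine layouts: a ``.`` in the model
    consensus marks an inserted target residue (no model advance); a ``-``
    in the target marks a deletion (no sequence advance); anything else is
    a match column.
    """
    if len(consensus) != len(target):
        raise AlignmentError("consensus/target line length mismatch")
    steps: list[Step] = []
    for c, t in zip(consensus, target):
        if c == ".":
            if t in (GAP, "."):
                raise AlignmentError("insert column with gapped target residue")
            steps.append(Step(State.INSERT, model_pos, seq_pos, t.upper()))
            seq_pos += 1
        elif t in (GAP, "."):
            model_pos += 1
            steps.append(Step(State.DELETE, model_pos))
        else:
            model_pos += 1
            steps.append(Step(State.MATCH, model_pos, seq_pos, t.upper()))
            seq_pos += 1
    return steps, model_pos, seq_pos


def _parse_hmmer2_blocks(lines: list[str]) -> list[tuple[str, list[Step]]]:
    import re

    header = re.compile(
        r"^(?P<hit>\S+):\s+domain\s+\d+\s+of\s+\d+,\s+from\s+(?P<sf>\d+)\s+to\s+\d+"
    )
    results: list[tuple[str, list[Step]]] = []
    i = 0
    while i < len(lines):
        m = header.match(lines[i].strip())
        if not m:
            i += 1
            continue
        hit_id = m.group("hit")
        seq_pos = int(m.group("sf"))
        i += 1
        steps: list[Step] = []
        model_pos = 0
        done = False
        while i < len(lines) and not done:
            cons_line = lines[i]
            if "*->" in cons_line:
                cons = cons_line.split("*->", 1)[1]
                lead = len(cons_line) - len(cons)
            else:
                cons = cons_line.lstrip()
                lead = len(cons_line) - len(cons)
            if "<-*" in cons:
                cons = cons.split("<-*", 1)[0]
                done = True
            # model start coordinate for the first chunk comes from the
            # glocal convention: consensus starts at model position 1
            target_line = lines[i + 2]
            tok = target_line.split()
            if tok[0] != hit_id:
                raise AlignmentError(
                    f"expected target line for {hit_id!r}, got {target_line!r}"
                )
            target = target_line[lead : lead + len(cons)]
            # target rows are padded with the start/end coordinates; strip
            # them by aligning on the consensus window
            chunk, model_pos, seq_pos = _walk_columns(cons, target, model_pos, seq_pos)
            steps.extend(chunk)
            i += 3
        results.append((hit_id, steps))
    return results


def _parse_hmmer3_blocks(lines: list[str], model_name: str) -> list[list[tuple[str, list[Step]]]]:
    hits: list[list[tuple[str, list[Step]]]] = []
    current_hit: str | None = None
    i = 0
    frag: list[Step] | None = None

    def close_fragment() -> None:
        nonlocal frag
        if frag:
            hits[-1].append((current_hit, frag))
        frag = None

    while i < len(lines):
        line = lines[i]
        strip = line.strip()
        if strip.startswith(">> "):
            close_fragment()
            current_hit = strip.split()[1]
            hits.append([])
        elif strip.startswith("== domain"):
            close_fragment()
            frag = []
        elif frag is not None:
            tok = strip.split()
            if len(tok) == 4 and tok[0] == model_name:
                model_pos = int(tok[1]) - 1
                cons = tok[2]
                target_line = lines[i + 2]
                ttok = target_line.split()
                if len(ttok) != 4 or ttok[0] != current_hit:
                    raise AlignmentError(
                        f"expected target line for {current_hit!r}, got {target_line!r}"
                    )
                seq_pos = int(ttok[1])
                target = ttok[2]
                if len(target) != len(cons):
                    raise AlignmentError("consensus/target line length mismatch")
                chunk, _, _ = _walk_columns(cons, target, model_pos, seq_pos)
                frag.extend(chunk)
                i += 2
        i += 1
    close_fragment()
    return hits


def parse_hmmsearch_alignment(text: str, model) -> list[AlignmentPath]:
    """Parse hmmsearch plain-text domain alignments into alignment paths.

    Both engine layouts are recognized: the HMMER2 layout (``*->`` /
    ``<-*`` consensus delimiters, one path per domain header) and the
    HMMER3 layout (``>>`` hits with ``== domain`` blocks).  HMMER3
    multi-domain hits yield one fragment per domain grouped under a single
    hit_id, so per-hit score sums can be formed downstream.
    """
    lines = text.splitlines()
    if any("*->" in ln for ln in lines):
        paths = []
        for hit_id, steps in _parse_hmmer2_blocks(lines):
            paths.append(AlignmentPath(hit_id, [steps], engine_tag="hmmer2"))
        return paths
    grouped = _parse_hmmer3_blocks(lines, model.name)
    paths = []
    for frags in grouped:
        if not frags:
            continue
        hit_id = frags[0][0]
        paths.append(
            AlignmentPath(hit_id, [steps for _, steps in frags], engine_tag="hmmer3")
        )
    return paths


# ---------------------------------------------------------------------------
# explicit path TSV (hit_id, fragment, state, model_pos, seq_pos, residue)
# ---------------------------------------------------------------------------

def write_path_tsv(paths: Iterable[AlignmentPath]) -> str:
    out = ["hit_id\tfragment\tstate\tmodel_pos\tseq_pos\tresidue"]
    for path in paths:
        for fi, frag in enumerate(path.fragments):
            for s in frag:
                out.append(
                    f"{path.hit_id}\t{fi}\t{s.state.value}\t{s.model_pos}\t"
                    f"{'' if s.seq_pos is None else s.seq_pos}\t{s.residue or ''}"
                )
    return "\n".join(out) + "\n"


def read_path_tsv(text: str) -> list[AlignmentPath]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("hit_id"):
        raise AlignmentError("path TSV must start with a header line")
    by_hit: dict[str, dict[int, list[Step]]] = {}
    order: list[str] = []
    for ln in lines[1:]:
        hit_id, frag, state, model_pos, seq_pos, residue = (ln.split("\t") + [""])[:6]
        if hit_id not in by_hit:
            by_hit[hit_id] = {}
            order.append(hit_id)
        by_hit[hit_id].setdefault(int(frag), []).append(
            Step(
                State(state),
                int(model_pos),
                int(seq_pos) if seq_pos else None,
                residue or None,
            )
        )
    return [
        AlignmentPath(hid, [by_hit[hid][k] for k in sorted(by_hit[hid])])
        for hid in order
    ]


# ---------------------------------------------------------------------------
# DSSP annotations
# ---------------------------------------------------------------------------

@dataclass
class ResidueAnnotation:
    """Per-model-position structural labels.

    ``labels[k-1]`` is the DSSP code of the residue aligned to match state
    k, the loop marker ``' '`` for an unstructured residue, or ``'-'`` for
    a gap (deletion / position not covered by the alignment).
    """

    labels: list[str]
    source: str = "dssp"

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in STRUCTURAL_LABELS and lab not in UNSTRUCTURED_LABELS:
                raise AlignmentError(f"unknown structural label {lab!r}")

    @property
    def model_length(self) -> int:
        return len(self.labels)

    def n_structural(self) -> int:
        return sum(1 for lab in self.labels if lab in STRUCTURAL_LABELS)


def read_dssp_labels(path: str, chain: str | None = None) -> dict[int, str]:
    """Residue-number -> structure label from a DSSP file.

    Biopython's DSSP-file reader does the column parsing; its ``'-'`` loop
    placeholder is mapped back to the blank loop marker so labels stay in
    R_S + {' '}.
    """
    parsed, _keys = make_dssp_dict(path)
    out: dict[int, str] = {}
    for (chain_id, res_id), values in parsed.items():
        if chain is not None and chain_id != chain:
            continue
        ss = values[1]
        out[res_id[1]] = LOOP if ss == "-" else ss
    return out


def project_dssp_to_model(
    dssp_labels: Mapping[int, str], path: AlignmentPath, model_length: int
) -> ResidueAnnotation:
    """Project per-hit-residue DSSP labels onto model coordinates.

    Each MATCH position receives the label of its aligned residue; DELETE
    positions and positions outside the alignment receive the gap marker.
    INSERT steps have no model position of their own and are dropped.
    """
    labels = [GAP] * model_length
    for step in path.steps:
        if step.model_pos > model_length:
            raise AlignmentError(
                f"path visits model position {step.model_pos} > K={model_length}"
            )
        if step.state is State.MATCH:
            if step.seq_pos not in dssp_labels:
                raise AlignmentError(
                    f"residue {step.seq_pos} missing from DSSP annotation"
                )
            labels[step.model_pos - 1] = dssp_labels[step.seq_pos]
    return ResidueAnnotation(labels=labels, source="dssp")
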