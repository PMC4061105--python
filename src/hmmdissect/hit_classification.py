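"""Hit labelling, cross-engine pairing and concordance/error rates.

Each hit carries three E-values — for the total score, the high-quality
(fold-critical) segment score and the low-quality (remnant) segment
score — and is labelled TP/FN/FP/TN from their significance pattern at a
threshold (default 0.1):

* total and high-quality both significant -> TP (a true hit, confirmed);
* both insignificant -> TN;
* total significant but only through the low-quality segments -> FP
  (score inflated by non-globular similarity);
* total insignificant although the fold-critical part is significant on
  its own -> FN (an obscured true homology).

The two remaining patterns, where the fixed score alone flips the
total's significance, are undefined ("?") and practically nonexistent.

Hits from two search engines over the same database are paired whenever
they share a sequence segment; paired hits fall into positive/negative
concordance or one of two discordance types, and per-domain rates
summarize them.  Engine tags are free-form: nothing here is specific to
any particular HMMER version.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

TP, FN, FP, TN, UNDEF = "TP", "FN", "FP", "TN", "UNDEF"

#: labels counting as a positive (true) call
TRUE_LABELS = frozenset({TP, FN})
#: labels counting as a negative (false) call
FALSE_LABELS = frozenset({TN, FP})

POSITIVE_CONCORDANCE = "positive_concordance"
NEGATIVE_CONCORDANCE = "negative_concordance"
DISCORDANCE_1 = "discordance_1"  # engine A true, engine B false
DISCORDANCE_2 = "discordance_2"  # engine A false, engine B true
UNDEFINED = "undefined"

DEFAULT_SIGNIFICANCE = 0.1


def label_hit(
    total_E: float,
    high_E: float,
    low_E: float,
    significance: float = DEFAULT_SIGNIFICANCE,
) -> str:
    """Label one hit TP/FN/FP/TN/UNDEF from its three E-values."""
    t = total_E <= significance
    h = high_E <= significance
    l = low_E <= significance
    if t and h:
        return TP
    if not t and not h:
        return TN
    if t and not h:
        return FP if l else UNDEF
    # not t and h
    return FN if not l else UNDEF


@dataclass
class Hit:
    """One labelled hit: a sequence segment with its three E-values."""

    hit_id: str
    seq_id: str
    start: int
    end: int
    total_E: float
    high_E: float
    low_E: float
    engine: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"hit {self.hit_id!r}: end < start")

    def label(self, significance: float = DEFAULT_SIGNIFICANCE) -> str:
        return label_hit(self.total_E, self.high_E, self.low_E, significance)

    def overlap(self, other: "Hit") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def pair_class(label_a: str, label_b: str) -> str:
    """Concordance class of a labelled pair (engine A, engine B)."""
    if label_a == UNDEF or label_b == UNDEF:
        return UNDEFINED
    a_true = label_a in TRUE_LABELS
    b_true = label_b in TRUE_LABELS
    if a_true and b_true:
        return POSITIVE_CONCORDANCE
    if not a_true and not b_true:
        return NEGATIVE_CONCORDANCE
    return DISCORDANCE_1 if a_true else DISCORDANCE_2


@dataclass
class PairedHit:
    hit_a: Hit
    hit_b: Hit
    label_a: str
    label_b: str

    @property
    def pair_class(self) -> str:
        return pair_class(self.label_a, self.label_b)

    @property
    def combo(self) -> str:
        return self.label_a + self.label_b


def pair_hits(
    hits_a: Sequence[Hit],
    hits_b: Sequence[Hit],
    significance: float = DEFAULT_SIGNIFICANCE,
    min_overlap_fraction: float = 0.0,
) -> tuple[list[PairedHit], list[Hit], list[Hit]]:
    """Pair hits across two engines by shared sequence segments.

    A pair requires the same sequence id and at least one shared
    position (optionally at least ``min_overlap_fraction`` of the
    shorter hit).  Many-to-many overlaps are resolved greedily by
    longest overlap, with ties broken on smaller start coordinates and
    input order, so the matching is deterministic.  Hits left unmatched
    are returned as orphans.
    """
    candidates = []
    for ia, a in enumerate(hits_a):
        for ib, b in enumerate(hits_b):
            ov = a.overlap(b)
            if ov < 1:
                continue
            shorter = min(a.end - a.start + 1, b.end - b.start + 1)
            if ov / shorter < min_overlap_fraction:
                continue
            candidates.append((-ov, min(a.start, b.start), ia, ib))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[PairedHit] = []
    for _negov, _start, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        a, b = hits_a[ia], hits_b[ib]
        pairs.append(PairedHit(a, b, a.label(significance), b.label(significance)))
    orphans_a = [h for i, h in enumerate(hits_a) if i not in used_a]
    orphans_b = [h for i, h in enumerate(hits_b) if i not in used_b]
    return pairs, orphans_a, orphans_b


#: paired-label combinations entering the FN rate numerator
FN_COMBOS = frozenset({"TPFN", "FNTP", "FNFN"})
#: paired-label combinations entering the FP rate numerator
FP_COMBOS = frozenset({"FPTN", "TNFP", "FPFP"})


@dataclass
class DomainRates:
    """Per-domain concordance and error rates over paired hits.

    Percentages are over the count of (defined) paired hits; orphaned
    hits never enter any denominator.  The three concordance/discordance
    percentages sum to exactly 100.
    """

    n_paired: int
    n_positive_concordance: int
    n_negative_concordance: int
    n_discordance_1: int
    n_discordance_2: int
    n_fn: int
    n_fp: int

    @property
    def positive_concordance_pct(self) -> float:
        return 100.0 * self.n_positive_concordance / self.n_paired

    @property
    def negative_concordance_pct(self) -> float:
        return 100.0 * self.n_negative_concordance / self.n_paired

    @property
    def total_discordance_pct(self) -> float:
        return 100.0 * (self.n_discordance_1 + self.n_discordance_2) / self.n_paired

    @property
    def fn_rate_pct(self) -> float:
        return 100.0 * self.n_fn / self.n_paired

    @property
    def fp_rate_pct(self) -> float:
        return 100.0 * self.n_fp / self.n_paired


def domain_rates(pairs: Iterable[PairedHit]) -> DomainRates:
    """Concordance, discordance and FN/FP rates for one domain's pairs.

    The FN rate counts the TPFN, FNTP and FNFN combinations (true pairs
    containing a false negative); the FP rate counts FPTN, TNFP and FPFP
    (false pairs containing a false positive).  Pairs involving an
    undefined label are excluded.
    """
    counts = {
        POSITIVE_CONCORDANCE: 0,
        NEGATIVE_CONCORDANCE: 0,
        DISCORDANCE_1: 0,
        DISCORDANCE_2: 0,
    }
    n_fn = n_fp = 0
    n = 0
    for p in pairs:
        cls = p.pair_class
        if cls == UNDEFINED:
            continue
        n += 1
        counts[cls] += 1
        if p.combo in FN_COMBOS:
            n_fn += 1
        if p.combo in FP_COMBOS:
            n_fp += 1
    if n == 0:
        raise ValueError("no defined paired hits")
    return DomainRates(
        n_paired=n,
        n_positive_concordance=counts[POSITIVE_CONCORDANCE],
        n_negative_concordance=counts[NEGATIVE_CONCORDANCE],
        n_discordance_1=counts[DISCORDANCE_1],
        n_discordance_2=counts[DISCORDANCE_2],
        n_fn=n_fn,
        n_fp=n_fp,
    )


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

HIT_TSV_HEADER = "hit_id\tseq_id\tstart\tend\ttotal_E\thigh_E\tlow_E\tengine"


def write_hit_tsv(hits: Iterable[Hit]) -> str:
    rows = [HIT_TSV_HEADER]
    for h in hits:
        rows.append(
            f"{h.hit_id}\t{h.seq_id}\t{h.start}\t{h.end}\t"
            f"{h.total_E:g}\t{h.high_E:g}\t{h.low_E:g}\t{h.engine}"
        )
    return "\n".join(rows) + "\n"


def read_hit_tsv(text: str) -> list[Hit]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("hit_id"):
        raise ValueError("hit TSV must start with a header line")
    hits = []
    for ln in lines[1:]:
        hit_id, seq_id, start, end, te, he, le, engine = (ln.split("\t") + [""])[:8]
        hits.append(
            Hit(hit_id, seq_id, int(start), int(end), float(te), float(he), float(le), engine)
        )
    return hits
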