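"""Statistical support for the dissection framework.

Three independent pieces live here: the no-intercept regression used to
check that reconstructed scores reproduce engine-reported ones, the
additive error model summarizing reconstruction error per domain, and
the one-tailed Fisher's exact test for enrichment of structural residues
in high-quality segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .alignment_io import STRUCTURAL_LABELS, ResidueAnnotation
from .segmentation import FOLD, Segmentation


@dataclass
class RegressionResult:
    """No-intercept fit of reconstructed against original scores."""

    slope: float
    r_squared: float
    n_points: int


def regress_no_intercept(
    original: Sequence[float], reconstructed: Sequence[float]
) -> RegressionResult:
    """Regression through the origin of reconstructed (w) on original (v) scores.

    Scores of one domain's hits cluster tightly, which biases both the
    slope and r^2 toward whatever the cluster does; an extra point at the
    origin is therefore added before fitting.  The slope is
    sum(w*v)/sum(v^2) and r^2 is the squared product-moment correlation
    of the augmented point set, clamped into [0, 1].
    """
    v = np.asarray(original, dtype=float)
    w = np.asarray(reconstructed, dtype=float)
    if v.size == 0 or v.shape != w.shape:
        raise ValueError("score vectors must be equal-length and non-empty")
    v = np.append(v, 0.0)
    w = np.append(w, 0.0)
    denom = float(np.sum(v * v))
    if denom == 0.0:
        raise ValueError("all-zero original scores: slope undefined")
    slope = float(np.sum(w * v)) / denom
    P = v.size
    sxy = np.sum(v * w) - np.sum(v) * np.sum(w) / P
    sxx = np.sum(v * v) - np.sum(v) ** 2 / P
    syy = np.sum(w * w) - np.sum(w) ** 2 / P
    if sxx <= 0 or syy <= 0:
        r2 = 1.0 if np.allclose(v * slope, w) else 0.0
    else:
        r2 = float(sxy**2 / (sxx * syy))
    return RegressionResult(slope=slope, r_squared=min(max(r2, 0.0), 1.0), n_points=P)


@dataclass
class ErrorEstimate:
    """Additive-error summary W = v + eps over one domain's score pairs."""

    mean_error: float
    error_variance: float
    relative_error: float
    representative_score: float


def error_estimate(
    original: Sequence[float], reconstructed: Sequence[float]
) -> ErrorEstimate:
    """Mean, variance (population form) and relative size of the
    reconstruction error eps = w - v; the relative error is the mean
    error over the mean original score."""
    v = np.asarray(original, dtype=float)
    w = np.asarray(reconstructed, dtype=float)
    if v.size == 0 or v.shape != w.shape:
        raise ValueError("score vectors must be equal-length and non-empty")
    eps = w - v
    mu_eps = float(eps.mean())
    var_eps = float(((eps - mu_eps) ** 2).mean())
    mu_v = float(v.mean())
    if mu_v == 0.0:
        raise ValueError("mean original score is zero: relative error undefined")
    return ErrorEstimate(
        mean_error=mu_eps,
        error_variance=var_eps,
        relative_error=mu_eps / mu_v,
        representative_score=mu_v,
    )


@dataclass
class ContingencyTable:
    """2x2 cross-tabulation of segment class against structural label.

    Rows: high-quality (fold-critical) vs low-quality (remnant)
    positions; columns: structural (DSSP H/B/E/G/I/T/S) vs unstructured
    (loop or gap) residues.
    """

    f11: int
    f12: int
    f21: int
    f22: int

    def __post_init__(self) -> None:
        if min(self.f11, self.f12, self.f21, self.f22) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def R1(self) -> int:
        return self.f11 + self.f12

    @property
    def R2(self) -> int:
        return self.f21 + self.f22

    @property
    def C1(self) -> int:
        return self.f11 + self.f21

    @property
    def C2(self) -> int:
        return self.f12 + self.f22

    @property
    def N(self) -> int:
        return self.R1 + self.R2


def fisher_enrichment(table: ContingencyTable, inclusive: bool = False) -> float:
    """One-tailed hypergeometric enrichment p-value P(X > f11).

    The tail is strictly greater than the observed count, i.e.
    1 - P(X <= f11); with ``inclusive=True`` the conventional Fisher
    tail P(X >= f11) is returned instead.  Computed through the
    hypergeometric survival function, which is stable in log space for
    large margins.
    """
    k = table.f11 if not inclusive else table.f11 - 1
    return float(stats.hypergeom.sf(k, table.N, table.C1, table.R1))


def enrichment_test(
    seg: Segmentation,
    ann: ResidueAnnotation,
    alpha: float = 0.05,
    direction: str = "structural",
    inclusive: bool = False,
) -> tuple[ContingencyTable, float, bool]:
    """Test for enrichment of structural residues in fold-critical segments.

    Cross-tabulates the FOLD/REMNANT class of each model position against
    its structural/unstructured label and evaluates the one-tailed test.
    ``direction="unstructured"`` runs the control in the opposite
    direction (enrichment of non-structural residues in FOLD segments).
    Returns (table, p-value, enriched-at-alpha).
    """
    if seg.model_length != ann.model_length:
        raise ValueError(
            f"segmentation covers {seg.model_length} positions, "
            f"annotation {ann.model_length}"
        )
    if direction not in ("structural", "unstructured"):
        raise ValueError(f"unknown direction {direction!r}")
    f11 = f12 = f21 = f22 = 0
    for cls, lab in zip(seg.classes, ann.labels):
        structural = lab in STRUCTURAL_LABELS
        if direction == "unstructured":
            structural = not structural
        if cls == FOLD:
            if structural:
                f11 += 1
            else:
                f12 += 1
        else:
            if structural:
                f21 += 1
            else:
                f22 += 1
    table = ContingencyTable(f11, f12, f21, f22)
    p = fisher_enrichment(table, inclusive=inclusive)
    return table, p, p < alpha
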