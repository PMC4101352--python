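"""Validation benchmarks for predicted therapeutic targets.

Benchmark 1 — search-space classification.  Every gene in a phenotype's
search space is labelled four ways: TP (predicted, druggable and already a
known target for the phenotype), FP (predicted and druggable but not a known
target, i.e. the novel predictions), FN (known target present in the space
but not predicted) and TN (the partition-completing remainder).  One
confusion matrix per search space yields one ROC operating point per space;
the six spaces act as thresholds of prediction stringency.

Benchmark 2 — literature support.  A gene is "supported" at threshold t when
it is co-cited with the phenotype in at least t articles; the four citation
thresholds give four operating points.

AUC is the trapezoidal area over the empirical points (with (0,0) and (1,1)
anchors); significance against the uninformative 0.5 uses the Hanley–McNeil
normal approximation of the Mann–Whitney statistic, one-sided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

DEFAULT_CITATION_THRESHOLDS = (1, 5, 10, 15)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Four-way partition of one search space."""

    tp: int
    fp: int
    fn: int
    tn: int
    search_space_id: int | None = None
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tpr(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def fpr(self) -> float | None:
        neg = self.fp + self.tn
        return self.fp / neg if neg else None


def build_confusion_matrix(
    search_space: Iterable[str],
    predicted: Iterable[str],
    known_targets: Iterable[str],
    druggable: Iterable[str],
    search_space_id: int | None = None,
    phenotype: str | None = None,
) -> ConfusionMatrix:
    """Label every gene in the search space and return the cell counts.

    TN is defined as the partition remainder (everything not TP/FP/FN),
    which notably absorbs predicted-but-not-druggable genes; this is the
    definition under which the four cells always sum to the space size.
    Known targets outside the search space are unrecoverable by any
    predictor on that space and are excluded from FN with a logged note.
    """
    space = set(search_space)
    pred = set(predicted)
    known = set(known_targets)
    drug = set(druggable)
    if not pred <= space:
        extra = sorted(pred - space)[:5]
        raise ValueError(f"predicted genes outside the search space, e.g. {extra}")
    outside = known - space
    if outside:
        logger.info(
            "%s/space%s: %d known targets outside the search space excluded from FN",
            phenotype,
            search_space_id,
            len(outside),
        )
    tp = len(pred & drug & known)
    fp = len((pred & drug) - known)
    fn = len((known & space) - pred)
    tn = len(space) - tp - fp - fn
    cm = ConfusionMatrix(
        tp=tp, fp=fp, fn=fn, tn=tn, search_space_id=search_space_id, phenotype=phenotype
    )
    assert cm.total == len(space), "confusion cells must partition the search space"
    return cm


@dataclass
class RocCurve:
    """Ordered ROC operating points with trapezoidal AUC and significance."""

    points: list[tuple[float, float]]  # (FPR, TPR) incl. anchors, sorted by FPR
    auc: float | None
    p_value: float | None = None
    undefined_tpr: bool = False
    n_pos: int | None = None
    n_neg: int | None = None

    def to_dict(self) -> dict:
        return {
            "points": [[round(f, 6), round(t, 6)] for f, t in self.points],
            "auc": None if self.auc is None else round(self.auc, 6),
            "p_value": None if self.p_value is None else float(f"{self.p_value:.6g}"),
            "undefined_tpr": self.undefined_tpr,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _assemble_curve(points: Iterable[tuple[float, float]]) -> tuple[list[tuple[float, float]], float]:
    # sort by FPR then TPR ascending: vertical segments contribute no area and
    # later horizontal segments integrate from the higher TPR
    pts = set(points) | {(0.0, 0.0), (1.0, 1.0)}
    ordered = sorted(pts)
    x = np.array([p[0] for p in ordered])
    y = np.array([p[1] for p in ordered])
    auc = float(np.trapezoid(y, x))
    return ordered, auc


def roc_from_search_spaces(matrices: Sequence[ConfusionMatrix]) -> RocCurve:
    """One operating point per search-space confusion matrix.

    When no matrix has any positive (TP+FN == 0 everywhere — a phenotype
    with no known targets), TPR is undefined and no AUC is reported.
    """
    if not matrices:
        raise ValueError("need at least one confusion matrix for a curve")
    phenos = {m.phenotype for m in matrices}
    if len(phenos) > 1:
        raise ValueError(f"matrices mix phenotypes: {sorted(map(str, phenos))}")
    usable = [(m.fpr, m.tpr) for m in matrices if m.tpr is not None and m.fpr is not None]
    if not usable:
        return RocCurve(points=[], auc=None, undefined_tpr=True)
    ordered, auc = _assemble_curve(usable)
    n_pos = max(m.tp + m.fn for m in matrices)
    n_neg = max(m.fp + m.tn for m in matrices)
    return RocCurve(points=ordered, auc=auc, n_pos=n_pos, n_neg=n_neg)


def auc_significance(curve: "RocCurve | float", n_pos: int, n_neg: int) -> float:
    """One-sided p-value for AUC > 0.5 (Hanley–McNeil approximation).

    The AUC's standard error uses SE² = (A(1−A) + (n₊−1)(Q₁−A²)
    + (n₋−1)(Q₂−A²)) / (n₊ n₋) with Q₁ = A/(2−A) and Q₂ = 2A²/(1+A); the
    one-sided p is 1 − Φ((A − 0.5)/SE).  A degenerate SE of zero yields 0,
    0.5 or 1 depending on the AUC's side of 0.5.
    """
    auc = curve.auc if isinstance(curve, RocCurve) else float(curve)
    if auc is None:
        raise ValueError("cannot test significance of an undefined AUC")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must both be at least 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc) + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        return 0.0 if auc > 0.5 else (1.0 if auc < 0.5 else 0.5)
    return float(norm.sf((auc - 0.5) / se))


# ---------------------------------------------------------------------------
# citation benchmark
# ---------------------------------------------------------------------------


@dataclass
class CitationIndex:
    """(gene, phenotype) → number of co-citing articles; absent means 0."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def get(self, gene: str, phenotype: str) -> int:
        return self.counts.get((gene, phenotype), 0)

    def for_phenotype(self, phenotype: str) -> dict[str, int]:
        return {g: c for (g, p), c in self.counts.items() if p == phenotype}


@dataclass
class CitationBenchmarkResult:
    curve: RocCurve
    per_threshold: dict[int, ConfusionMatrix]


def citation_benchmark(
    predicted_targets: Iterable[str],
    search_space: Iterable[str],
    citations: Mapping[str, int],
    thresholds: Sequence[int] = DEFAULT_CITATION_THRESHOLDS,
    phenotype: str | None = None,
) -> CitationBenchmarkResult:
    """ROC over citation-count thresholds on the search-space background.

    At threshold t the literature-supported set is {g : citations(g) ≥ t};
    TP = predicted ∧ supported, FP = predicted ∧ ¬supported, FN = supported
    ∧ ¬predicted, TN = the rest of the space.  Thresholds with an empty
    supported set give no operating point; if every threshold is empty the
    curve is flagged undefined.  n_pos/n_neg for the significance test come
    from the loosest threshold's supported set.
    """
    if not thresholds:
        raise ValueError("thresholds list must be non-empty")
    space = set(search_space)
    pred = set(predicted_targets) & space
    matrices: dict[int, ConfusionMatrix] = {}
    points: list[tuple[float, float]] = []
    for t in sorted(thresholds):
        supported = {g for g in space if citations.get(g, 0) >= t}
        tp = len(pred & supported)
        fp = len(pred - supported)
        fn = len(supported - pred)
        tn = len(space) - tp - fp - fn
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, phenotype=phenotype)
        matrices[t] = cm
        if cm.tpr is not None and cm.fpr is not None:
            points.append((cm.fpr, cm.tpr))
    if not points:
        curve = RocCurve(points=[], auc=None, undefined_tpr=True)
    else:
        ordered, auc = _assemble_curve(points)
        loosest = matrices[min(thresholds)]
        n_pos = loosest.tp + loosest.fn
        n_neg = loosest.fp + loosest.tn
        p = auc_significance(auc, n_pos, n_neg) if n_pos and n_neg else None
        curve = RocCurve(points=ordered, auc=auc, p_value=p, n_pos=n_pos, n_neg=n_neg)
    return CitationBenchmarkResult(curve=curve, per_threshold=matrices)


def read_citations(path) -> CitationIndex:
    """Read the citations TSV: [gene_symbol, phenotype_code, n_citations]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_symbol", "phenotype_code", "n_citations"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{col}'")
    counts: dict[tuple[str, str], int] = {}
    for r in df.itertuples(index=False):
        n = int(r.n_citations)
        if n < 0:
            raise ValueError(f"{path}: negative citation count for {r.gene_symbol}")
        counts[(r.gene_symbol, r.phenotype_code)] = n
    return CitationIndex(counts=counts)
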