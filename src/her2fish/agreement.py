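"""Interrater agreement statistics for nucleus classifications.

Two readers of the same set of nuclei (pathologists, or either automated
read) are compared on a four-class scale — ``unidentifiable`` (merging
uncertain and artifact), ``normal``, ``low``, ``high`` — with chance
correction by weighted Cohen's kappa.  The default disagreement weights are
linear in the ordinal distance among (normal, low, high) and maximal (1)
between ``unidentifiable`` and every other class, reflecting that calling a
nucleus unscorable is qualitatively different from mis-grading it.  Because
kappa values depend on this choice, the weight scheme (linear, quadratic or
a custom matrix) is an explicit argument everywhere.

Multi-rater agreement uses Light's kappa (the mean of all pairwise kappas),
and a detector is compared against a team of raters by averaging its
pairwise kappas with each member.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import NucleusClass

__all__ = [
    "UNIDENTIFIABLE",
    "DEFAULT_CLASS_ORDER",
    "RaterLabels",
    "ConfusionMatrix",
    "linear_weights",
    "quadratic_weights",
    "identity_weights",
    "confusion",
    "accuracy",
    "per_class_accuracy",
    "weighted_kappa",
    "lights_kappa",
    "detector_vs_team_kappa",
    "stratified_agreement",
    "merge_unidentifiable",
]

#: Evaluation label that pools nuclei read as uncertain or artifact.
UNIDENTIFIABLE = "unidentifiable"

#: Default class order: unscorable first, then the ordinal grades.
DEFAULT_CLASS_ORDER: tuple[str, ...] = (UNIDENTIFIABLE, "normal", "low", "high")

#: Ordinal grades that carry a distance for weighting.
_ORDINAL = ("normal", "low", "high")


def merge_unidentifiable(label: NucleusClass | str) -> str:
    """Map a five-class nucleus label onto the four-class evaluation scale."""
    s = str(label)
    return UNIDENTIFIABLE if s in ("uncertain", "artifact") else s


@dataclass(frozen=True)
class RaterLabels:
    """One rater's labels over a shared, position-aligned item index."""

    rater_id: str
    labels: tuple[str, ...]
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER

    def __post_init__(self) -> None:
        bad = sorted({l for l in self.labels if l not in self.class_order})
        if bad:
            raise ValueError(
                f"rater {self.rater_id!r} uses labels {bad} outside class order {self.class_order}"
            )

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_classes(
        cls,
        rater_id: str,
        labels: Iterable[NucleusClass | str],
        class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER,
    ) -> "RaterLabels":
        """Build from five-class nucleus labels, pooling unscorable classes."""
        return cls(rater_id, tuple(merge_unidentifiable(l) for l in labels), class_order)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K co-classification counts: rows = rater A, columns = rater B."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _check_aligned(a: RaterLabels, b: RaterLabels) -> None:
    if a.class_order != b.class_order:
        raise ValueError(
            f"raters {a.rater_id!r} and {b.rater_id!r} use different class orders"
        )
    if len(a) != len(b):
        raise ValueError(
            f"raters {a.rater_id!r} ({len(a)} items) and {b.rater_id!r} "
            f"({len(b)} items) are not aligned"
        )


def confusion(a: RaterLabels, b: RaterLabels) -> ConfusionMatrix:
    """Co-classification counts of two aligned raters."""
    _check_aligned(a, b)
    index = {c: i for i, c in enumerate(a.class_order)}
    k = len(a.class_order)
    counts = np.zeros((k, k), dtype=np.int64)
    for la, lb in zip(a.labels, b.labels):
        counts[index[la], index[lb]] += 1
    return ConfusionMatrix(counts, a.class_order)


def accuracy(matrix: ConfusionMatrix) -> float:
    """Fraction of items on the diagonal (raw agreement)."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(matrix.counts) / matrix.total)


def per_class_accuracy(matrix: ConfusionMatrix) -> dict[str, float]:
    """Per-class agreement: diagonal / row total of rater A, NaN if unused."""
    row_tot = matrix.counts.sum(axis=1)
    out = {}
    for i, cls in enumerate(matrix.class_order):
        out[cls] = float(matrix.counts[i, i] / row_tot[i]) if row_tot[i] else float("nan")
    return out


# ---------------------------------------------------------------------------
# Disagreement weight matrices
# ---------------------------------------------------------------------------

def _ordinal_weights(class_order: Sequence[str], power: int) -> np.ndarray:
    """Ordinal weights among the graded classes, 1 against unscorable ones.

    Positions of (normal, low, high) are normalised so the largest graded
    disagreement has weight 1; any class outside the ordinal scale is at
    maximal disagreement (weight 1) with every other class.
    """
    k = len(class_order)
    pos = {c: _ORDINAL.index(c) for c in class_order if c in _ORDINAL}
    span = max(pos.values()) - min(pos.values()) if len(pos) > 1 else 1
    w = np.ones((k, k), dtype=float)
    for i, ci in enumerate(class_order):
        for j, cj in enumerate(class_order):
            if i == j:
                w[i, j] = 0.0
            elif ci in pos and cj in pos:
                w[i, j] = (abs(pos[ci] - pos[cj]) / span) ** power
    return w


def linear_weights(class_order: Sequence[str] = DEFAULT_CLASS_ORDER) -> np.ndarray:
    return _ordinal_weights(class_order, power=1)


def quadratic_weights(class_order: Sequence[str] = DEFAULT_CLASS_ORDER) -> np.ndarray:
    return _ordinal_weights(class_order, power=2)


def identity_weights(class_order: Sequence[str] = DEFAULT_CLASS_ORDER) -> np.ndarray:
    """0/1 weights: reduces weighted kappa to unweighted Cohen's kappa."""
    k = len(class_order)
    return np.ones((k, k)) - np.eye(k)


def _validate_weights(weights: np.ndarray, k: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (k, k):
        raise ValueError(f"weight matrix must be {k}x{k}, got {w.shape}")
    if not np.allclose(np.diag(w), 0):
        raise ValueError("weight matrix must have a zero diagonal")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if ((w < 0) | ~np.isfinite(w)).any():
        raise ValueError("weights must be finite and non-negative")
    return w


def weighted_kappa(matrix: ConfusionMatrix, weights: np.ndarray | None = None) -> float:
    """Weighted Cohen's kappa of a confusion matrix.

    kappa = 1 - sum(w * O) / sum(w * E), with O the observed proportions and
    E the outer product of the marginals.  Degenerate marginals (all mass in
    one class for either rater) give zero expected disagreement; kappa is
    then 1.0 when observed disagreement is also zero and a ``ValueError`` is
    raised otherwise, as chance correction is undefined.
    """
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    k = len(matrix.class_order)
    w = _validate_weights(
        linear_weights(matrix.class_order) if weights is None else weights, k
    )
    observed = matrix.counts / matrix.total
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    expected = np.outer(row, col)
    num = float((w * observed).sum())
    den = float((w * expected).sum())
    if den == 0.0:
        if num == 0.0:
            return 1.0
        raise ValueError("kappa undefined: zero expected disagreement but observed disagreement")
    return 1.0 - num / den


def _pairwise_kappa(a: RaterLabels, b: RaterLabels, weights: np.ndarray | None) -> float:
    try:
        return weighted_kappa(confusion(a, b), weights)
    except ValueError as exc:
        raise ValueError(f"kappa undefined for pair ({a.rater_id!r}, {b.rater_id!r}): {exc}") from exc


def lights_kappa(raters: Sequence[RaterLabels], weights: np.ndarray | None = None) -> float:
    """Light's kappa: mean weighted kappa over all unordered rater pairs."""
    if len(raters) < 2:
        raise ValueError("Light's kappa needs at least two raters")
    pairs = list(combinations(raters, 2))
    return float(np.mean([_pairwise_kappa(a, b, weights) for a, b in pairs]))


def detector_vs_team_kappa(
    detector: RaterLabels,
    team: Sequence[RaterLabels],
    weights: np.ndarray | None = None,
) -> float:
    """Mean weighted kappa between a detector and each team member."""
    if not team:
        raise ValueError("team must contain at least one rater")
    return float(np.mean([_pairwise_kappa(detector, m, weights) for m in team]))


# ---------------------------------------------------------------------------
# Quality-stratified evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumReport:
    """Agreement statistics for one quality stratum (or the pooled set)."""

    stratum: str
    n: int
    lights_kappa: float | None
    detector_vs_team: float | None
    pairwise: dict[tuple[str, str], float]


def _subset(rater: RaterLabels, idx: Sequence[int]) -> RaterLabels:
    return RaterLabels(rater.rater_id, tuple(rater.labels[i] for i in idx), rater.class_order)


def stratified_agreement(
    quality: Sequence[str],
    raters: Sequence[RaterLabels],
    detector: RaterLabels | None = None,
    weights: np.ndarray | None = None,
    strata: tuple[str, ...] = ("high", "low"),
) -> dict[str, StratumReport]:
    """Agreement per quality stratum and overall.

    *quality* tags every item as one of *strata* (nuclei imaged cleanly vs
    blurred/noisy/overlapping).  A stratum with too few items to define the
    statistics is reported with ``None`` values rather than raising.
    """
    n_items = len(quality)
    for r in list(raters) + ([detector] if detector is not None else []):
        if len(r) != n_items:
            raise ValueError(f"rater {r.rater_id!r} not aligned with quality tags")
    bad = sorted({q for q in quality if q not in strata})
    if bad:
        raise ValueError(f"unknown quality tags {bad}; expected {strata}")

    reports: dict[str, StratumReport] = {}
    for name in strata + ("overall",):
        idx = list(range(n_items)) if name == "overall" else [
            i for i, q in enumerate(quality) if q == name
        ]
        sub_raters = [_subset(r, idx) for r in raters]
        sub_det = _subset(detector, idx) if detector is not None else None
        lk = dvt = None
        pairwise: dict[tuple[str, str], float] = {}
        if idx:
            try:
                if len(sub_raters) >= 2:
                    lk = lights_kappa(sub_raters, weights)
                    for a, b in combinations(sub_raters, 2):
                        pairwise[(a.rater_id, b.rater_id)] = _pairwise_kappa(a, b, weights)
                if sub_det is not None and sub_raters:
                    dvt = detector_vs_team_kappa(sub_det, sub_raters, weights)
            except ValueError:
                lk = dvt = None  # degenerate stratum: kappa undefined
        reports[name] = StratumReport(
            stratum=name, n=len(idx), lights_kappa=lk,
            detector_vs_team=dvt, pairwise=pairwise,
        )
    return reports
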