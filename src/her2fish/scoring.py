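"""HER2/CEN17 ratio scoring: per-nucleus rules, image-level calls, consensus.

Every detected nucleus is graded twice: once by appearance (the nucleus
detector's class, here called the ND read) and once from its signal counts
(the SD read).  The SD read applies, in order:

1. no CEN17 signal            -> the nucleus is an *artifact* (no reference);
2. exactly one CEN17 signal   -> *uncertain* (ratio not trustworthy);
3. any HER2 cluster           -> ratio fixed at 10 (strong amplification);
4. no HER2 single signal      -> ratio fixed at 1;
5. otherwise                  -> ratio = n_HER2 / n_CEN17, capped at 10;

and then grades the ratio: <= 1.5 normal, (1.5, 6] low, > 6 high.

At image level the ND read yields ratio-1 (fraction of classified nuclei
graded low) and ratio-2 (fraction graded high); ratio-2 > 0.4 calls the
image HIGH, else ratio-1 >= 0.2 calls it LOW, else NORMAL.  The SD read
averages the defined per-nucleus ratios; a mean > 6 is HIGH, > 1 is LOW,
else NORMAL.  The final call requires both reads to agree — disagreement is
surfaced as DISCORDANT for manual review rather than arbitrated away.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotations import NucleusClass

__all__ = [
    "SignalCounts",
    "RatioSentinel",
    "ScoringThresholds",
    "ImageCall",
    "NucleusRecord",
    "ImageResult",
    "nucleus_ratio",
    "classify_nucleus_from_ratio",
    "score_counts",
    "image_ratios",
    "mean_image_ratio",
    "nd_image_call",
    "sd_image_call",
    "consensus",
    "score_image",
]


@dataclass(frozen=True)
class SignalCounts:
    """Signals assigned to one nucleus."""

    n_her2: int = 0
    n_cen17: int = 0
    n_cluster: int = 0

    def __post_init__(self) -> None:
        for name in ("n_her2", "n_cen17", "n_cluster"):
            v = getattr(self, name)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}") from None
            if iv != v or iv < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, iv)  # accept numpy integers


class RatioSentinel(enum.Enum):
    """Non-numeric outcomes of the per-nucleus ratio rule."""

    ARTIFACT = "artifact"
    UNCERTAIN = "uncertain"


ARTIFACT = RatioSentinel.ARTIFACT
UNCERTAIN = RatioSentinel.UNCERTAIN


@dataclass(frozen=True)
class ScoringThresholds:
    """All scoring cut-offs; every field is meant to be adjusted per lab.

    Defaults implement the rule set described in the module docstring.
    ``one_her2_uncertain`` optionally extends the uncertainty rule to nuclei
    with exactly one HER2 single signal; it is off by default.
    """

    t_ratio1: float = 0.2     # ND image rule: ratio-1 >= t_ratio1 -> LOW
    t_ratio2: float = 0.4     # ND image rule: ratio-2 >  t_ratio2 -> HIGH
    nucleus_low_lo: float = 1.5   # nucleus grade: ratio in (low_lo, high_lo] -> low
    nucleus_high_lo: float = 6.0  # nucleus grade: ratio > high_lo -> high
    image_low_lo: float = 1.0     # SD image rule: mean ratio > low_lo -> LOW
    image_high_lo: float = 6.0    # SD image rule: mean ratio > high_lo -> HIGH
    cluster_ratio: float = 10.0   # ratio assigned when a HER2 cluster is present
    no_her2_ratio: float = 1.0    # ratio assigned when no HER2 signal was found
    one_her2_uncertain: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.t_ratio1 <= 1 and 0 < self.t_ratio2 <= 1):
            raise ValueError("t_ratio1 and t_ratio2 must be in (0, 1]")
        if not self.nucleus_low_lo < self.nucleus_high_lo:
            raise ValueError("nucleus_low_lo must be below nucleus_high_lo")
        if not self.image_low_lo < self.image_high_lo:
            raise ValueError("image_low_lo must be below image_high_lo")


DEFAULT_THRESHOLDS = ScoringThresholds()


class ImageCall(str, enum.Enum):
    """Image-wide HER2 amplification grade."""

    NORMAL = "NORMAL"
    LOW = "LOW"
    HIGH = "HIGH"
    DISCORDANT = "DISCORDANT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CLASS_TO_CALL = {
    NucleusClass.NORMAL: ImageCall.NORMAL,
    NucleusClass.LOW: ImageCall.LOW,
    NucleusClass.HIGH: ImageCall.HIGH,
}


def nucleus_ratio(
    counts: SignalCounts, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS
) -> float | RatioSentinel:
    """Per-nucleus HER2/CEN17 ratio, or a sentinel for unscorable nuclei.

    The special cases are evaluated in a fixed order (artifact, uncertain,
    cluster, no-HER2, plain ratio); see the module docstring.
    """
    if counts.n_cen17 == 0:
        return ARTIFACT
    if counts.n_cen17 == 1:
        return UNCERTAIN
    if counts.n_cluster >= 1:
        return thresholds.cluster_ratio
    if counts.n_her2 == 0:
        return thresholds.no_her2_ratio
    if thresholds.one_her2_uncertain and counts.n_her2 == 1:
        return UNCERTAIN
    return min(counts.n_her2 / counts.n_cen17, thresholds.cluster_ratio)


def classify_nucleus_from_ratio(
    ratio: float | RatioSentinel,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
) -> NucleusClass:
    """Grade a nucleus from its ratio (the signal-count read)."""
    if ratio is ARTIFACT:
        return NucleusClass.ARTIFACT
    if ratio is UNCERTAIN:
        return NucleusClass.UNCERTAIN
    if ratio <= thresholds.nucleus_low_lo:
        return NucleusClass.NORMAL
    if ratio <= thresholds.nucleus_high_lo:
        return NucleusClass.LOW
    return NucleusClass.HIGH


def score_counts(
    counts: SignalCounts, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS
) -> tuple[float | RatioSentinel, NucleusClass]:
    """Convenience composition of ratio rule and ratio grading."""
    r = nucleus_ratio(counts, thresholds)
    return r, classify_nucleus_from_ratio(r, thresholds)


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus with both of its reads.

    ``nd_class`` is the appearance-based grade (first read); ``sd_class`` is
    derived from the signal counts (second read).  ``ratio`` is ``None`` iff
    the second read is artifact/uncertain.
    """

    nucleus_id: int
    counts: SignalCounts
    nd_class: NucleusClass
    sd_class: NucleusClass
    ratio: float | None
    box: object | None = None  # BoundingBox when produced by the pipeline
    confidence: float = 1.0

    @property
    def concordant(self) -> bool:
        return self.nd_class == self.sd_class

    @classmethod
    def from_counts(
        cls,
        nucleus_id: int,
        counts: SignalCounts,
        nd_class: NucleusClass,
        thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
        box: object | None = None,
        confidence: float = 1.0,
    ) -> "NucleusRecord":
        ratio, sd_class = score_counts(counts, thresholds)
        return cls(
            nucleus_id=nucleus_id,
            counts=counts,
            nd_class=NucleusClass(nd_class),
            sd_class=sd_class,
            ratio=None if isinstance(ratio, RatioSentinel) else float(ratio),
            box=box,
            confidence=confidence,
        )


def image_ratios(records: Sequence[NucleusRecord]) -> tuple[float, float]:
    """(ratio-1, ratio-2): fractions of *classified* nuclei graded low / high.

    The denominator counts nuclei whose appearance read is normal, low or
    high; uncertain and artifact nuclei are excluded.  An empty classified
    set yields (0, 0).
    """
    classified = [r for r in records if r.nd_class.is_classified]
    if not classified:
        return 0.0, 0.0
    n = len(classified)
    n_low = sum(1 for r in classified if r.nd_class is NucleusClass.LOW)
    n_high = sum(1 for r in classified if r.nd_class is NucleusClass.HIGH)
    return n_low / n, n_high / n


def mean_image_ratio(records: Sequence[NucleusRecord]) -> float | None:
    """Mean HER2/CEN17 ratio over nuclei with a defined ratio, else ``None``."""
    ratios = [r.ratio for r in records if r.ratio is not None]
    if not ratios:
        return None
    return sum(ratios) / len(ratios)


def nd_image_call(
    ratio1: float, ratio2: float,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
) -> ImageCall:
    """Image call from the nucleus-detector read; HIGH takes precedence."""
    if ratio2 > thresholds.t_ratio2:
        return ImageCall.HIGH
    if ratio1 >= thresholds.t_ratio1:
        return ImageCall.LOW
    return ImageCall.NORMAL


def sd_image_call(
    mean_ratio: float | None,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
) -> ImageCall:
    """Image call from the mean HER2/CEN17 ratio.

    An undefined mean (no scorable nucleus) falls back to NORMAL; callers
    should surface the accompanying warning.
    """
    if mean_ratio is None:
        return ImageCall.NORMAL
    if mean_ratio > thresholds.image_high_lo:
        return ImageCall.HIGH
    if mean_ratio > thresholds.image_low_lo:
        return ImageCall.LOW
    return ImageCall.NORMAL


def consensus(nd_call: ImageCall, sd_call: ImageCall) -> ImageCall:
    """Final call: the two reads must agree, otherwise DISCORDANT."""
    return nd_call if nd_call == sd_call else ImageCall.DISCORDANT


@dataclass(frozen=True)
class ImageResult:
    """Per-image aggregate of both reads and their reconciliation."""

    nuclei: tuple[NucleusRecord, ...]
    ratio1: float
    ratio2: float
    mean_ratio: float | None
    nd_call: ImageCall
    sd_call: ImageCall
    final_call: ImageCall
    warnings: tuple[str, ...] = ()


def score_image(
    records: Sequence[NucleusRecord],
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
) -> ImageResult:
    """Aggregate per-nucleus records into the image-wide result."""
    warnings: list[str] = []
    r1, r2 = image_ratios(records)
    if not any(r.nd_class.is_classified for r in records):
        warnings.append("no classified nuclei: ratio-1/ratio-2 undefined, set to 0")
    mean = mean_image_ratio(records)
    if mean is None:
        warnings.append("no scorable nuclei: mean HER2/CEN17 ratio undefined")
    nd = nd_image_call(r1, r2, thresholds)
    sd = sd_image_call(mean, thresholds)
    return ImageResult(
        nuclei=tuple(records),
        ratio1=r1,
        ratio2=r2,
        mean_ratio=mean,
        nd_call=nd,
        sd_call=sd,
        final_call=consensus(nd, sd),
        warnings=tuple(warnings),
    )
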