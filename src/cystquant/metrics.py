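"""Recognition-error accounting and usability scoring.

The supervision log is the ground truth for scoring automatic recognition:
every automatic cyst the user had to touch counts as a false positive and
every cyst the user had to add counts as a false negative, while untouched
automatic cysts are true positives.  Concretely::

    TP = automatic cysts surviving the supervision untouched
    FP = automatic cysts deleted/modified by any tool
    FN = cysts added manually or by a supervision tool

so NA = TP + FP is the automatic count and NS = TP + FN the supervised
count.  One user action can therefore cost several errors (a split of one
cyst = 1 FP + 2 FN; a merge of k fragments = k FP + 1 FN; a completed
outline = 1 FP + 1 FN).

From the counts: Se = 100*TP/(TP+FN), Sp = (1 - FP/NA)*100, and the deleted/
added percentages PCD = 100*FP/NA and PCA = 100*FN/NS (so Sp = 100 - PCD).
"""

from __future__ import annotations

from dataclasses import dataclass

from .edits import EditLog, replay
from .raster import CystSet

__all__ = [
    "EvalCounts",
    "EvalMetrics",
    "counts_from_log",
    "aggregate_counts",
    "sensitivity",
    "specificity",
    "pcd_pca",
    "evaluate",
    "sus_score",
    "sus_adjective",
]


@dataclass(frozen=True)
class EvalCounts:
    """True-positive / false-positive / false-negative cyst counts."""

    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def NA(self) -> int:
        """Number of cysts automatically recognised."""
        return self.TP + self.FP

    @property
    def NS(self) -> int:
        """Number of cysts after supervision."""
        return self.TP + self.FN


@dataclass(frozen=True)
class EvalMetrics:
    Se: float
    Sp: float
    PCD: float
    PCA: float


def counts_from_log(
    initial_auto: CystSet, log: EditLog, add_smaller_counts_as: str = "fn"
) -> EvalCounts:
    """Tally TP/FP/FN by replaying the supervision log.

    ``add_smaller_counts_as`` selects how cysts added by the automatic
    small-cyst tool are counted: as false negatives (``'fn'``, the general
    "added by a supervision tool" rule, the default) or as false positives
    (``'fp'``, the literal alternative reading).
    """
    if add_smaller_counts_as not in ("fn", "fp"):
        raise ValueError("add_smaller_counts_as must be 'fn' or 'fp'")
    final = replay(initial_auto, log)
    initial_ids = initial_auto.ids()
    final_ids = final.ids()
    tp = len(initial_ids & final_ids)
    fp = len(initial_ids - final_ids)
    fn = len(final_ids - initial_ids)
    if add_smaller_counts_as == "fp":
        small_ids = set()
        for record in log.active():
            if record.kind == "add_smaller":
                small_ids.update(record.created_ids)
        moved = len(small_ids & (final_ids - initial_ids))
        fp += moved
        fn -= moved
    return EvalCounts(TP=tp, FP=fp, FN=fn)


def aggregate_counts(counts: list[EvalCounts]) -> EvalCounts:
    """Micro-average: sum counts over images before computing metrics."""
    return EvalCounts(
        TP=sum(c.TP for c in counts),
        FP=sum(c.FP for c in counts),
        FN=sum(c.FN for c in counts),
    )


def sensitivity(counts: EvalCounts) -> float:
    """Se = 100 * TP / (TP + FN), in percent."""
    if counts.NS == 0:
        raise ZeroDivisionError("sensitivity undefined: no supervised cysts (TP + FN = 0)")
    return 100.0 * counts.TP / counts.NS


def specificity(counts: EvalCounts) -> float:
    """Sp = (1 - FP / NA) * 100, in percent."""
    if counts.NA == 0:
        raise ZeroDivisionError("specificity undefined: no automatic cysts (TP + FP = 0)")
    return (1.0 - counts.FP / counts.NA) * 100.0


def pcd_pca(counts: EvalCounts) -> tuple[float, float]:
    """Percentage of cysts deleted (100*FP/NA) and added (100*FN/NS)."""
    if counts.NA == 0 or counts.NS == 0:
        raise ZeroDivisionError("PCD/PCA undefined for zero NA or NS")
    return 100.0 * counts.FP / counts.NA, 100.0 * counts.FN / counts.NS


def evaluate(counts: EvalCounts) -> EvalMetrics:
    pcd, pca = pcd_pca(counts)
    return EvalMetrics(Se=sensitivity(counts), Sp=specificity(counts), PCD=pcd, PCA=pca)


#: SUS score bands -> adjective; boundaries belong to the upper band
_SUS_BANDS = (
    (25.0, "worst imaginable"),
    (39.0, "worst imaginable to poor"),
    (52.0, "poor to ok"),
    (73.0, "ok to good"),
    (85.0, "good to excellent"),
    (100.0 + 1e-9, "excellent to best imaginable"),
)


def sus_adjective(score: float) -> str:
    """Adjective band of a 0..100 SUS score (boundaries go to the upper band)."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("SUS score must lie in [0, 100]")
    for upper, adjective in _SUS_BANDS:
        if score < upper:
            return adjective
    return _SUS_BANDS[-1][1]


def sus_score(responses) -> tuple[float, str]:
    """System Usability Scale score and adjective band.

    ``responses`` are the 10 item answers on the 1..5 Likert scale, in
    questionnaire order.  Odd items (positively worded) contribute
    ``answer - 1``; even items (negatively worded) contribute
    ``5 - answer``; the sum is scaled by 2.5 to a 0..100 score.
    """
    items = list(responses)
    if len(items) != 10:
        raise ValueError("SUS requires exactly 10 item responses")
    total = 0
    for i, ans in enumerate(items, start=1):
        ans = int(ans)
        if not 1 <= ans <= 5:
            raise ValueError(f"item {i} response {ans} outside the 1..5 scale")
        total += (ans - 1) if i % 2 == 1 else (5 - ans)
    score = 2.5 * total
    return score, sus_adjective(score)
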