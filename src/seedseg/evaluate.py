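"""Segmentation-accuracy metric and the method/kernel sweep harness.

Accuracy is the number of properly segmented individual-seed outputs over
the total number of segmented outputs:

    Acc = n_proper / n_total

"Properly segmented" is operationalized as a one-to-one greedy match
between predicted boxes and ground-truth seed boxes at an
intersection-over-union threshold (default 0.5): merged clusters and
fragments fail the threshold and count as improper. Because the
denominator is segmented outputs rather than true seeds, missed seeds do
not lower Acc; recall is reported alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .enhance import RetinexParams, msrcr
from .errors import ParameterError, UndefinedAccuracyError
from .extract import run_pipeline
from .segment import ContactRule, SeedBox, SeparationConfig
from .synthgen import SceneTruth

__all__ = [
    "MatchCriterion",
    "AccuracyReport",
    "SweepRow",
    "SweepReport",
    "box_iou",
    "truth_boxes",
    "match_boxes",
    "accuracy",
    "evaluate_scene",
    "sweep",
]


@dataclass(frozen=True)
class MatchCriterion:
    """What counts as a properly segmented seed."""

    iou_threshold: float = 0.5
    one_to_one: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ParameterError("iou_threshold must be in (0, 1]")


@dataclass(frozen=True)
class AccuracyReport:
    """Acc = n_proper / n_total, with the exact rational kept alongside."""

    n_proper: int
    n_total: int
    #: matched ground-truth seeds / total ground-truth seeds (diagnostic,
    #: not part of Acc); None when no truth was supplied
    n_truth: int | None = None
    n_matched_truth: int | None = None

    @property
    def acc(self) -> float:
        return self.n_proper / self.n_total

    @property
    def acc_exact(self) -> Fraction:
        return Fraction(self.n_proper, self.n_total)

    @property
    def recall(self) -> float | None:
        if self.n_truth in (None, 0):
            return None
        return self.n_matched_truth / self.n_truth


def box_iou(a: SeedBox, b: SeedBox) -> float:
    """Intersection-over-union of two half-open axis-aligned boxes."""
    ix = max(0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.box_area + b.box_area - inter
    return inter / union if union > 0 else 0.0


def truth_boxes(truth: SceneTruth) -> list[SeedBox]:
    """Tight bounding boxes of the ground-truth seed masks."""
    return [s.bbox for s in truth.seeds]


def match_boxes(
    pred: Sequence[SeedBox],
    truth: SceneTruth | Sequence[SeedBox],
    crit: MatchCriterion | None = None,
) -> list[bool]:
    """Label each predicted box proper/improper against ground truth.

    Greedy one-to-one assignment by descending IoU: a predicted box is
    proper iff it is matched to a true seed with IoU >= the threshold. One
    box spanning two seeds, or two fragments of one seed, cannot both
    claim the same truth, so merges and oversplits fail. Labels are
    invariant under permutation of the predictions (ties are resolved on
    IoU only, then deterministically).
    """
    crit = crit or MatchCriterion()
    tboxes = truth_boxes(truth) if isinstance(truth, SceneTruth) else list(truth)
    labels = [False] * len(pred)
    if not pred or not tboxes:
        return labels
    iou = np.array([[box_iou(p, t) for t in tboxes] for p in pred])
    if not crit.one_to_one:
        return [bool(iou[i].max() >= crit.iou_threshold) for i in range(len(pred))]
    # stable greedy: order candidate pairs by IoU desc, ties by box geometry
    order = sorted(
        ((i, j) for i in range(len(pred)) for j in range(len(tboxes))
         if iou[i, j] >= crit.iou_threshold),
        key=lambda ij: (-iou[ij], (pred[ij[0]].y, pred[ij[0]].x), ij[1]),
    )
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    for i, j in order:
        if i in used_pred or j in used_truth:
            continue
        used_pred.add(i)
        used_truth.add(j)
        labels[i] = True
    return labels


def accuracy(labels: Sequence[bool], n_truth: int | None = None) -> AccuracyReport:
    """Aggregate per-box proper flags into an accuracy report."""
    n_total = len(labels)
    if n_total == 0:
        raise UndefinedAccuracyError("accuracy over zero segmented outputs is undefined")
    n_proper = int(sum(bool(x) for x in labels))
    return AccuracyReport(
        n_proper=n_proper,
        n_total=n_total,
        n_truth=n_truth,
        n_matched_truth=n_proper if n_truth is not None else None,
    )


def evaluate_scene(
    pred: Sequence[SeedBox],
    truth: SceneTruth,
    crit: MatchCriterion | None = None,
) -> AccuracyReport:
    """Accuracy of one scene's predicted boxes against its ground truth."""
    labels = match_boxes(pred, truth, crit)
    return accuracy(labels, n_truth=truth.n_seeds)


@dataclass(frozen=True)
class SweepRow:
    method: str
    kernel: int | None
    acc: float
    n_proper: int
    n_total: int
    n_scenes: int
    n_seeds: int
    recall: float | None = None


@dataclass
class SweepReport:
    """One row of Eq.-style accuracy per separation configuration."""

    rows: list[SweepRow] = field(default_factory=list)

    def to_csv(self, path: Path | str) -> None:
        lines = ["method,kernel,acc,n_proper,n_total,n_scenes,n_seeds"]
        for r in self.rows:
            kernel = "" if r.kernel is None else str(r.kernel)
            lines.append(
                f"{r.method},{kernel},{r.acc:.6f},{r.n_proper},{r.n_total},"
                f"{r.n_scenes},{r.n_seeds}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def __str__(self) -> str:
        head = f"{'method':<8}{'kernel':<8}{'acc':<10}{'proper':<8}{'total':<8}"
        out = [head, "-" * len(head)]
        for r in self.rows:
            kernel = "-" if r.kernel is None else f"{r.kernel}x{r.kernel}"
            out.append(
                f"{r.method:<8}{kernel:<8}{r.acc:<10.4f}{r.n_proper:<8}{r.n_total:<8}"
            )
        return "\n".join(out)


def sweep(
    scenes: Sequence[tuple[np.ndarray, SceneTruth]],
    configs: Sequence[SeparationConfig],
    crit: MatchCriterion | None = None,
    retinex: RetinexParams | None = None,
    rule: ContactRule | None = None,
    precomputed_enhanced: Sequence[np.ndarray] | None = None,
) -> SweepReport:
    """Run the full pipeline per configuration over all scenes and
    aggregate accuracy per configuration.

    Enhancement does not depend on the separation configuration, so each
    scene is enhanced once and reused across configs. Deterministic given
    the scene seeds.
    """
    if not scenes:
        raise ParameterError("sweep needs at least one scene")
    if not configs:
        raise ParameterError("sweep needs at least one separation config")
    crit = crit or MatchCriterion()
    retinex = retinex or RetinexParams()
    if precomputed_enhanced is None:
        enhanced = [msrcr(scene, retinex) for scene, _ in scenes]
    else:
        if len(precomputed_enhanced) != len(scenes):
            raise ParameterError("precomputed_enhanced must match scenes one-to-one")
        enhanced = list(precomputed_enhanced)

    report = SweepReport()
    for cfg in configs:
        n_proper = 0
        n_total = 0
        n_truth = 0
        n_matched = 0
        for (scene, truth), enh in zip(scenes, enhanced):
            crops = run_pipeline(
                scene, retinex, rule, cfg, enhanced=enh, scene_id="sweep"
            )
            labels = match_boxes([c.crop_box for c in crops], truth, crit)
            n_proper += sum(labels)
            n_total += len(labels)
            n_truth += truth.n_seeds
            n_matched += sum(labels)
        report.rows.append(
            SweepRow(
                method=cfg.method,
                kernel=cfg.kernel if cfg.method == "EOP" else None,
                acc=n_proper / n_total if n_total else 0.0,
                n_proper=n_proper,
                n_total=n_total,
                n_scenes=len(scenes),
                n_seeds=n_truth,
                recall=n_matched / n_truth if n_truth else None,
            )
        )
    return report
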