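"""Annotation-protocol comparison: conventional single-round training
versus the iterative pre-label-and-revise active-learning loop.

Conventional protocol: every training image is annotated manually from
scratch (full polygon-drawing cost), one model is trained on all of
them.  Active protocol: a small first batch is annotated manually and
trains the first model; each subsequent batch is pre-labeled by the
previous model and only *revised* by the (simulated) pathologist, so the
cost ledger charges drawing only for missed nuclei and cheap fixes for
wrong labels.  Both protocols hold out the same fixed test set and are
scored per round with mAP/mAR and classification PR-AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from cytoscreen.annotio import LabelSet
from cytoscreen.cellnet import DetectorConfig, ReferenceDetector, train_detector
from cytoscreen.evalkit import detection_pr_auc, map_mar
from cytoscreen.synthcyto import OracleSpec, RevisionCost, simulate_revision

logger = logging.getLogger(__name__)


@dataclass
class FieldRecord:
    """One dataset item: rendered field image plus ground-truth labels."""

    image_id: str
    image: np.ndarray
    truth: LabelSet


@dataclass
class ProtocolConfig:
    """Shared configuration of both annotation protocols."""

    strategy: str = "active"  # "conventional" | "active" | "both"
    round_sizes: tuple[int, ...] = (100, 200, 150)
    test_size: int = 50
    seed: int = 0
    oracle: OracleSpec = field(default_factory=OracleSpec)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    cumulative: bool = True  # later rounds retrain on all revised data so far

    def validate(self, n_images: int) -> None:
        if self.strategy not in ("conventional", "active", "both"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.test_size >= n_images:
            raise ValueError("test_size must leave at least one training image")
        if self.strategy != "conventional":
            if not self.round_sizes:
                raise ValueError("active protocol needs nonempty round_sizes")
            if sum(self.round_sizes) + self.test_size > n_images:
                raise ValueError(
                    f"round sizes {self.round_sizes} + test {self.test_size} "
                    f"exceed the {n_images}-image dataset"
                )


@dataclass
class RoundLog:
    """Record of one annotation/training round."""

    round_index: int
    model_name: str
    image_ids: list[str]
    cost: RevisionCost
    cost_total: float
    n_annotations: int
    label_agreement: float  # fraction of training labels equal to truth
    metrics: dict


def split_dataset(
    dataset: Sequence[FieldRecord], config: ProtocolConfig
) -> tuple[list[FieldRecord], list[FieldRecord]]:
    """Seeded uniform split into (training pool, fixed test set)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xD15C)))
    order = rng.permutation(len(dataset))
    test_idx = set(order[: config.test_size].tolist())
    test = [dataset[i] for i in sorted(test_idx)]
    pool = [dataset[i] for i in order[config.test_size:]]
    return pool, test


def _evaluate(
    model: ReferenceDetector, test: Sequence[FieldRecord], cache: dict | None = None
) -> dict:
    det_lists = [model.detect(rec.image, rec.image_id, cache=cache) for rec in test]
    truth_sets = [rec.truth for rec in test]
    seg = map_mar(truth_sets, det_lists)
    _, auc = detection_pr_auc(truth_sets, det_lists)
    return {
        "mAP": seg["mAP"],
        "mAR": seg["mAR"],
        "pr_auc": 100.0 * auc,
    }


def _manual_cost(labelsets: Sequence[LabelSet], oracle: OracleSpec) -> tuple[RevisionCost, float]:
    n = sum(len(ls.annotations) for ls in labelsets)
    cost = RevisionCost(n_drawn=n)
    return cost, cost.total(oracle)


def run_conventional(
    dataset: Sequence[FieldRecord], config: ProtocolConfig
) -> tuple[ReferenceDetector, list[RoundLog], list[FieldRecord]]:
    """Train one model on fully manual labels (the T1 protocol).

    Every annotation in the training pool is drawn by hand, so the cost
    ledger is ``cost_draw x total annotation count``.  Returns the
    model, a single-round log, and the held-out test set.
    """
    config.validate(len(dataset))
    pool, test = split_dataset(dataset, config)
    if len(pool) < 2 * config.test_size:
        warnings.warn(
            f"training pool of {len(pool)} images is small relative to the "
            f"{config.test_size}-image test set", RuntimeWarning,
        )
    labelsets = [rec.truth for rec in pool]
    cost, total = _manual_cost(labelsets, config.oracle)
    cache: dict = {}
    model = train_detector(
        [rec.image for rec in pool], labelsets, config.detector, seed=config.seed,
        cache=cache,
    )
    log = RoundLog(
        round_index=1,
        model_name="T1",
        image_ids=[rec.image_id for rec in pool],
        cost=cost,
        cost_total=total,
        n_annotations=cost.n_drawn,
        label_agreement=1.0,
        metrics=_evaluate(model, test, cache),
    )
    return model, [log], test


def _agreement(labels: Sequence[LabelSet], truths: dict[str, LabelSet]) -> float:
    """Fraction of training annotations identical to a ground-truth nucleus."""
    total, agree = 0, 0
    for ls in labels:
        truth = truths[ls.image_id]
        for ann in ls.annotations:
            total += 1
            if any(ann.same_as(t, tol=1e-9) for t in truth.annotations):
                agree += 1
    return agree / total if total else 1.0


def run_active(
    dataset: Sequence[FieldRecord], config: ProtocolConfig
) -> tuple[list[ReferenceDetector], list[RoundLog], list[FieldRecord]]:
    """Run the iterative pre-label-and-revise protocol (A1..Ak).

    Round 1 trains on fully manual labels.  Round k > 1 pre-labels its
    batch with model A(k-1), passes the pre-labels through the revision
    oracle, and trains A_k warm-started from A(k-1) -- by default on all
    revised data accumulated so far.  Batches are disjoint and disjoint
    from the fixed test set; per-round test metrics are logged.
    """
    config.validate(len(dataset))
    pool, test = split_dataset(dataset, config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xAC71)))

    batches: list[list[FieldRecord]] = []
    cursor = 0
    for size in config.round_sizes:
        batches.append(pool[cursor: cursor + size])
        cursor += size

    truths = {rec.truth.image_id: rec.truth for rec in pool}
    cache: dict = {}
    models: list[ReferenceDetector] = []
    logs: list[RoundLog] = []
    cumulative_labels: list[LabelSet] = []
    cumulative_images: list[np.ndarray] = []

    for k, batch in enumerate(batches, start=1):
        batch_images = [rec.image for rec in batch]
        if k == 1:
            batch_labels = [rec.truth for rec in batch]
            cost, total = _manual_cost(batch_labels, config.oracle)
        else:
            prev = models[-1]
            batch_labels = []
            cost = RevisionCost()
            for rec in batch:
                prelabels = prev.detect(rec.image, rec.image_id, cache=cache)
                revised, c = simulate_revision(
                    rec.truth.annotations,
                    prelabels,
                    replace(config.oracle, seed=0),
                    rng=rng,
                )
                batch_labels.append(
                    LabelSet(rec.image_id, rec.truth.width, rec.truth.height, revised)
                )
                cost.n_prelabels += c.n_prelabels
                cost.n_accepted += c.n_accepted
                cost.n_class_fixes += c.n_class_fixes
                cost.n_contour_fixes += c.n_contour_fixes
                cost.n_spurious_removed += c.n_spurious_removed
                cost.n_drawn += c.n_drawn
            total = cost.total(config.oracle)
        cumulative_labels.extend(batch_labels)
        cumulative_images.extend(batch_images)
        if config.cumulative:
            fit_images, fit_labels = cumulative_images, cumulative_labels
        else:
            fit_images, fit_labels = batch_images, batch_labels
        model = train_detector(
            fit_images,
            fit_labels,
            config.detector,
            seed=config.seed,
            warm_start_from=models[-1] if models else None,
            cache=cache,
        )
        models.append(model)
        logs.append(
            RoundLog(
                round_index=k,
                model_name=f"A{k}",
                image_ids=[rec.image_id for rec in batch],
                cost=cost,
                cost_total=total,
                n_annotations=sum(len(ls.annotations) for ls in batch_labels),
                label_agreement=_agreement(batch_labels, truths),
                metrics=_evaluate(model, test, cache),
            )
        )
    return models, logs, test


def compare_protocols(
    conventional_logs: Sequence[RoundLog],
    active_logs: Sequence[RoundLog],
) -> pd.DataFrame:
    """Side-by-side table of both protocols: cost and test metrics per model.

    One row per model (T1, A1..Ak) with the cumulative annotation cost,
    batch label agreement, and the fixed-test-set mAP/mAR/PR-AUC; the
    ``cost_ratio`` column is conventional total cost over cumulative
    active cost at each round.
    """
    conv_total = sum(l.cost_total for l in conventional_logs)
    rows = []
    for log in conventional_logs:
        rows.append(
            {
                "model": log.model_name,
                "protocol": "conventional",
                "n_images": len(log.image_ids),
                "n_annotations": log.n_annotations,
                "cost_total": log.cost_total,
                "cost_cumulative": conv_total,
                "cost_ratio": 1.0,
                "label_agreement": log.label_agreement,
                **log.metrics,
            }
        )
    running = 0.0
    for log in active_logs:
        running += log.cost_total
        rows.append(
            {
                "model": log.model_name,
                "protocol": "active",
                "n_images": len(log.image_ids),
                "n_annotations": log.n_annotations,
                "cost_total": log.cost_total,
                "cost_cumulative": running,
                "cost_ratio": conv_total / running if running > 0 else np.inf,
                "label_agreement": log.label_agreement,
                **log.metrics,
            }
        )
    return pd.DataFrame(rows)
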