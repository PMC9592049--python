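"""Repeated k-fold cross-validation of the DDAE over acquisition batches.

Batches (one frame stack + answer per imaged location) are partitioned
into 5 folds; each fold serves once as the test set per repeat, one of the
remaining folds is drawn at random as the validation set, and the rest
train the model. The plan is re-randomized for each of the 3 repeats, and
grand averages pool every fold of every repeat.

Scoring follows the evaluation pipeline: PSNR/SSIM against the batch's
answer image plus the boundary F-measure, reported for both the raw noisy
frames and their denoised counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .boundary import evaluate_boundary
from .ddae import DDAE, DenoiserConfig, TrainingReport, build_ddae, denoise, train
from .metrics import psnr, ssim
from .noise import AnswerImage, FrameStack

Batch = Tuple[FrameStack, AnswerImage]


@dataclass(frozen=True)
class FoldPlan:
    """Per-repeat assignment of batch index -> fold id."""

    n_folds: int
    n_repeats: int
    assignments: Tuple[Tuple[int, ...], ...]  # [repeat][batch] -> fold
    seed: int

    @classmethod
    def make(cls, n_batches: int, n_folds: int = 5, n_repeats: int = 3, seed: int = 0) -> "FoldPlan":
        if n_batches < n_folds:
            raise ValueError(f"need at least {n_folds} batches, got {n_batches}")
        rng = np.random.default_rng(seed)
        assignments = []
        for _ in range(n_repeats):
            order = rng.permutation(n_batches)
            folds = np.empty(n_batches, dtype=int)
            for fold, members in enumerate(np.array_split(order, n_folds)):
                folds[members] = fold
            assignments.append(tuple(int(f) for f in folds))
        plan = cls(n_folds=n_folds, n_repeats=n_repeats, assignments=tuple(assignments), seed=seed)
        plan.validate()
        return plan

    def validate(self) -> None:
        """Every repeat must partition all batches into exhaustive folds."""
        if len(self.assignments) != self.n_repeats:
            raise ValueError("one assignment per repeat required")
        for rep, assign in enumerate(self.assignments):
            present = set(assign)
            if present != set(range(self.n_folds)):
                raise ValueError(f"repeat {rep}: folds {sorted(present)} not exhaustive over {self.n_folds}")


def _training_pairs(batches: Sequence[Batch], ids: Sequence[int]) -> list:
    pairs = []
    for i in ids:
        stack, answer = batches[i]
        for frame in stack.frames:
            pairs.append((frame, answer.pixels))
    return pairs


def cross_validate(
    batches: Sequence[Batch],
    config: DenoiserConfig,
    plan: Optional[FoldPlan] = None,
    n_test_frames: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Run the repeated k-fold protocol and score held-out batches.

    Returns a per-(repeat, fold, batch, frame) row table and a summary with
    grand averages. Every frame of a training stack is paired with that
    stack's answer; ``n_test_frames`` frames per held-out batch are scored.
    """
    batches = list(batches)
    if plan is None:
        plan = FoldPlan.make(len(batches), seed=config.seed)
    plan.validate()
    if len(batches) < plan.n_folds:
        raise ValueError(f"{len(batches)} batches < {plan.n_folds} folds")
    rows = []
    reports: List[TrainingReport] = []
    for rep, assign in enumerate(plan.assignments):
        assign = np.asarray(assign)
        for fold in range(plan.n_folds):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, rep, fold)).generate_state(1))
            test_ids = np.flatnonzero(assign == fold)
            train_folds = [f for f in range(plan.n_folds) if f != fold]
            val_fold = int(rng.choice(train_folds))
            val_ids = np.flatnonzero(assign == val_fold)
            train_ids = np.flatnonzero((assign != fold) & (assign != val_fold))
            fold_config = replace(config, seed=int(rng.integers(2**31 - 1)))
            model = build_ddae(fold_config)
            report = train(
                model,
                _training_pairs(batches, train_ids),
                fold_config,
                val_pairs=_training_pairs(batches, val_ids),
            )
            reports.append(report)
            for b in test_ids:
                stack, answer = batches[b]
                n_frames = stack.frames.shape[0]
                picks = rng.choice(n_frames, size=min(n_test_frames, n_frames), replace=False)
                for fr in sorted(int(p) for p in picks):
                    noisy = stack.frames[fr]
                    den = denoise(model, noisy)
                    ans = answer.pixels
                    f_noisy = evaluate_boundary(noisy, ans)[0].f_measure
                    f_den = evaluate_boundary(den, ans)[0].f_measure
                    rows.append(
                        {
                            "repeat": rep,
                            "fold": fold,
                            "batch": int(b),
                            "frame": fr,
                            "psnr_noisy": psnr(noisy, ans),
                            "psnr_denoised": psnr(den, ans),
                            "ssim_noisy": ssim(noisy, ans),
                            "ssim_denoised": ssim(den, ans),
                            "f_noisy": f_noisy,
                            "f_denoised": f_den,
                        }
                    )
    table = pd.DataFrame(rows)
    metric_cols = [c for c in table.columns if c not in ("repeat", "fold", "batch", "frame")]
    summary = {c: float(table[c].mean()) for c in metric_cols}
    summary["n_rows"] = len(table)
    summary["psnr_gain_db"] = summary["psnr_denoised"] - summary["psnr_noisy"]
    summary["f_gain"] = summary["f_denoised"] - summary["f_noisy"]
    return table, summary
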