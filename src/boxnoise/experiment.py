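"""End-to-end label-noise sweeps: noise grids x folds x test conditions.

For every noise setting the whole dataset — training, validation and test
splits alike — is corrupted, mirroring the realistic situation where test
labels come from the same noisy annotation process as training labels.  Each
fold is an independent seeded 60/20/20 re-partition; the detector is fitted
on the corrupted training labels and scored twice on the test images:

* against the **noisy** test labels (what a practitioner with a noisily
  labeled dataset would measure), and
* against the **accurate** test labels (the true performance).

The divergence between the two curves is the study's object: noisy-test
scores can stay high while accurate-test scores collapse, disguising the
damage done by noisy training labels.

Fold mAP50 samples at each noise level are compared with the base case
(``alpha = 1`` or ``delta = 0``) using the exact two-sided Mann-Whitney U
test, separately per test condition; the base case compares with itself with
``p = 1`` by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotatedDataset, AnnotationError, split_dataset
from .detector import detect, fit
from .evaluation import evaluate_dataset, mann_whitney_u
from .noise import (
    ConsistentNoiseConfig,
    InconsistentNoiseConfig,
    apply_consistent_noise,
    apply_inconsistent_noise,
)

__all__ = ["SweepResult", "run_consistent_sweep", "run_inconsistent_sweep",
           "plot_sweep", "fold_seeds"]

TEST_CONDITIONS = ("noisy", "accurate")


@dataclass(frozen=True)
class SweepResult:
    """Per-(noise level, fold, test condition) mAP50 scores plus summaries.

    ``table`` has columns ``mode, param, fold, test_condition, map50``;
    ``summary`` aggregates mean/sd/min/max across folds and carries the
    exact Mann-Whitney p-value against the base case per test condition.
    """

    mode: str
    base_param: float
    table: pd.DataFrame
    summary: pd.DataFrame

    def fold_scores(self, param: float, test_condition: str) -> np.ndarray:
        sel = self.table[(self.table["param"] == param)
                         & (self.table["test_condition"] == test_condition)]
        return sel.sort_values("fold")["map50"].to_numpy()

    def to_csv(self, path) -> None:
        merged = self.table.merge(
            self.summary[["param", "test_condition", "p_value"]],
            on=["param", "test_condition"], how="left")
        merged.to_csv(path, index=False)


def fold_seeds(seed: int, n_folds: int) -> list[int]:
    """Independent per-fold split seeds derived from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n_folds) % (2**31)]


def _score_condition(noisy: AnnotatedDataset, accurate: AnnotatedDataset,
                     seeds: list[int]) -> list[dict]:
    """Fit on noisy train labels and score each fold on both test label sets."""
    rows = []
    for fold, s in enumerate(seeds):
        resplit = split_dataset(accurate, seed=s)  # fold assignment by id
        fold_splits = resplit.splits
        train = [im for im in noisy.images if fold_splits[im.image_id] == "train"]
        test_noisy = [im for im in noisy.images if fold_splits[im.image_id] == "test"]
        test_acc = [im for im in accurate.images if fold_splits[im.image_id] == "test"]
        model = fit(train)
        preds = {im.image_id: detect(im.image, model) for im in test_noisy}
        truths_noisy = {im.image_id: list(im.boxes) for im in test_noisy}
        truths_acc = {im.image_id: list(im.boxes) for im in test_acc}
        rows.append({"fold": fold, "test_condition": "noisy",
                     "map50": evaluate_dataset(preds, truths_noisy).map50})
        rows.append({"fold": fold, "test_condition": "accurate",
                     "map50": evaluate_dataset(preds, truths_acc).map50})
    return rows


def _assemble(mode: str, base_param: float, rows: list[dict]) -> SweepResult:
    table = pd.DataFrame(rows, columns=["mode", "param", "fold",
                                        "test_condition", "map50"])
    summaries = []
    for (param, cond), grp in table.groupby(["param", "test_condition"]):
        scores = grp["map50"].to_numpy()
        base = table[(table["param"] == base_param)
                     & (table["test_condition"] == cond)]["map50"].to_numpy()
        if param == base_param:
            p = 1.0
        else:
            _, p = mann_whitney_u(scores, base)
        summaries.append({
            "mode": mode, "param": param, "test_condition": cond,
            "mean": scores.mean(), "sd": scores.std(ddof=1) if scores.size > 1 else 0.0,
            "min": scores.min(), "max": scores.max(), "p_value": p,
        })
    summary = pd.DataFrame(summaries).sort_values(
        ["param", "test_condition"]).reset_index(drop=True)
    return SweepResult(mode=mode, base_param=base_param, table=table,
                       summary=summary)


def run_consistent_sweep(base_dataset: AnnotatedDataset, alphas,
                         n_folds: int = 5, seed: int = 0) -> SweepResult:
    """Sweep consistent area-scale noise over ``alphas`` (base alpha=1 is
    always included as the comparison referent)."""
    alphas = list(alphas)
    if not alphas:
        raise AnnotationError("alphas must be non-empty")
    alphas = sorted({float(a) for a in alphas} | {1.0})
    seeds = fold_seeds(seed, n_folds)
    rows: list[dict] = []
    for alpha in alphas:
        noisy = apply_consistent_noise(base_dataset, ConsistentNoiseConfig(alpha))
        for r in _score_condition(noisy, base_dataset, seeds):
            rows.append({"mode": "consistent", "param": alpha, **r})
    return _assemble("consistent", 1.0, rows)


def run_inconsistent_sweep(base_dataset: AnnotatedDataset, deltas,
                           n_folds: int = 5, seed: int = 0) -> SweepResult:
    """Sweep inconsistent three-annotator noise over ``deltas`` in (0, 1).

    ``delta = 0`` (the uncorrupted base case) is always included; annotator
    thirds are re-drawn per fold from the fold seed.
    """
    deltas = sorted({float(d) for d in deltas} | {0.0})
    if any(not (0.0 <= d < 1.0) for d in deltas):
        raise AnnotationError(f"deltas must lie in [0, 1), got {deltas}")
    seeds = fold_seeds(seed, n_folds)
    rows: list[dict] = []
    for delta in deltas:
        for fold, s in enumerate(seeds):
            if delta == 0.0:
                noisy = base_dataset
            else:
                noisy = apply_inconsistent_noise(
                    base_dataset, InconsistentNoiseConfig(delta, partition_seed=s))
            for r in _score_condition(noisy, base_dataset, [s]):
                rows.append({"mode": "inconsistent", "param": delta,
                             "fold": fold, "test_condition": r["test_condition"],
                             "map50": r["map50"]})
    return _assemble("inconsistent", 0.0, rows)


def plot_sweep(result: SweepResult, path, title: str | None = None) -> None:
    """Two-curve sweep figure: mean line with min-max band per test condition
    (orange = noisy test labels, green = accurate), dashed blue base-case
    reference.  Consistent sweeps use a log-scaled noise axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"noisy": "tab:orange", "accurate": "tab:green"}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond in TEST_CONDITIONS:
        s = result.summary[result.summary["test_condition"] == cond].sort_values("param")
        ax.plot(s["param"], s["mean"], "-o", ms=3, color=colors[cond],
                label=f"tested on {cond} labels")
        ax.fill_between(s["param"], s["min"], s["max"], color=colors[cond], alpha=0.2)
    base = result.summary[
        (result.summary["param"] == result.base_param)
        & (result.summary["test_condition"] == "accurate")]["mean"].iloc[0]
    ax.axhline(base, ls="--", color="tab:blue", label="base case")
    if result.mode == "consistent":
        ax.set_xscale("log")
        ax.set_xlabel(r"area scale factor $\alpha$")
    else:
        ax.set_xlabel(r"annotator deviation $\delta$")
    ax.set_ylabel("mAP50")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
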