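"""Cross-validation protocol and accuracy analyses.

The evaluation unit is a recording (one 10 m walk): five-fold splits hold
out exactly one fifth of each user's trials, so with 16 users x 10 trials a
fold tests 32 recordings against a model trained on the other 128.  Accuracy
is per-window by default -- each extracted test window counts as one
identification attempt -- and is reported as a percentage, broken out by
test window size (20, 30, 50, 100, 150, 200 samples) and by the three
partial-data sizes 42, 63, 84 labeled with their nominal data rates
(26, 39, 52 %).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AccelRecording, extract_test_windows, normalize
from .model import ModelConfig, StackedLSTMClassifier, build_model

WINDOW_SIZES = (20, 30, 50, 100, 150, 200)
DATA_RATE_SIZES = (42, 63, 84)
DATA_RATE_LABELS = (26, 39, 52)
K_TEST_WINDOWS = 10


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: frozenset[str]
    test_ids: frozenset[str]


@dataclass
class EvalReport:
    """Accuracy tables averaged over fold x repeat runs, all values in %."""

    accuracy_by_window_size: dict[int, float]
    accuracy_by_data_rate: dict[int, float]
    per_run_window_size: dict[int, list[float]]
    per_run_data_rate: dict[int, list[float]]
    window_size_for_rate: dict[int, int]
    n_repeats: int
    n_folds: int
    seeds: dict
    windows_evaluated: int

    def std_by_window_size(self) -> dict[int, float]:
        return {t: float(np.std(v)) for t, v in self.per_run_window_size.items()}


def seconds_label(t: int, sample_rate: int = 30) -> float:
    """Window duration in seconds as printed in the results tables.

    Durations are rounded *up* at two decimals (so 100 samples at 30 Hz
    reads 3.34 s, not 3.33 s).
    """
    return math.ceil(round(t / sample_rate * 100, 6)) / 100


def make_folds(
    recordings: list[AccelRecording], n_folds: int = 5, rng_seed: int = 0
) -> list[FoldSplit]:
    """Stratified k-fold over recordings: equal per-user test blocks.

    Each user's trials are randomly permuted and dealt into ``n_folds``
    equal blocks; fold i tests block i of every user.  Requires every user's
    trial count to be divisible by ``n_folds`` so folds are exactly balanced.
    """
    by_user: dict[int, list[str]] = defaultdict(list)
    for rec in recordings:
        by_user[rec.user_id].append(rec.recording_id)
    for user, ids in by_user.items():
        if len(ids) % n_folds:
            raise ValueError(
                f"user {user} has {len(ids)} trials, not divisible by {n_folds} folds"
            )
    rng = np.random.default_rng(rng_seed)
    all_ids = frozenset(r.recording_id for r in recordings)
    test_sets: list[set[str]] = [set() for _ in range(n_folds)]
    for user in sorted(by_user):
        ids = sorted(by_user[user])
        perm = rng.permutation(len(ids))
        block = len(ids) // n_folds
        for f in range(n_folds):
            test_sets[f].update(ids[i] for i in perm[f * block : (f + 1) * block])
    return [
        FoldSplit(
            fold_index=f,
            train_ids=frozenset(all_ids - test_sets[f]),
            test_ids=frozenset(test_sets[f]),
        )
        for f in range(n_folds)
    ]


def _window_accuracy(
    model: StackedLSTMClassifier,
    recordings: list[AccelRecording],
    sizes,
    k: int,
    rng: np.random.Generator,
    majority_vote: bool = False,
) -> tuple[dict[int, float], int]:
    """Per-window accuracy (%) for each requested size; (table, n windows).

    Recordings shorter than a size are excluded from that size's cell; a size
    with no eligible recording is reported as NaN rather than raised.
    ``majority_vote=True`` scores each recording once by the modal prediction
    of its k windows instead of scoring every window.
    """
    assert model.classes_ is not None, "model must be trained"
    out: dict[int, float] = {}
    total = 0
    for t in sizes:
        eligible = [r for r in recordings if r.n_samples >= t]
        if not eligible:
            out[int(t)] = float("nan")
            continue
        hits = 0
        n = 0
        for rec in eligible:
            wins = extract_test_windows(rec, t, k, rng)
            x = np.stack([w.data for w in wins], axis=1).astype(np.float32)
            probs = model.predict_proba_batch(x)
            pred = model.classes_[probs.argmax(axis=1)]
            if majority_vote:
                vals, counts = np.unique(pred, return_counts=True)
                hits += int(vals[counts.argmax()] == rec.user_id)
                n += 1
            else:
                hits += int((pred == rec.user_id).sum())
                n += len(wins)
            total += len(wins)
        out[int(t)] = 100.0 * hits / n
    return out, total


def evaluate_by_window_size(
    model: StackedLSTMClassifier,
    recordings: list[AccelRecording],
    sizes=WINDOW_SIZES,
    k: int = K_TEST_WINDOWS,
    rng_seed: int = 0,
    majority_vote: bool = False,
) -> dict[int, float]:
    """Identification rate (%) at each test window size."""
    rng = np.random.default_rng(rng_seed)
    table, _ = _window_accuracy(model, recordings, sizes, k, rng, majority_vote)
    return table


def evaluate_by_data_rate(
    model: StackedLSTMClassifier,
    recordings: list[AccelRecording],
    window_sizes=DATA_RATE_SIZES,
    rate_labels=DATA_RATE_LABELS,
    k: int = K_TEST_WINDOWS,
    rng_seed: int = 0,
    majority_vote: bool = False,
) -> dict[int, float]:
    """Identification rate (%) at the partial-data sizes, keyed by rate label."""
    rng = np.random.default_rng(rng_seed)
    table, _ = _window_accuracy(model, recordings, window_sizes, k, rng, majority_vote)
    return {int(rate): table[int(t)] for rate, t in zip(rate_labels, window_sizes)}


def cross_validated_report(
    recordings: list[AccelRecording],
    config: ModelConfig,
    n_repeats: int = 5,
    n_folds: int = 5,
    rng_seed: int = 0,
    sizes=WINDOW_SIZES,
    rate_sizes=DATA_RATE_SIZES,
    rate_labels=DATA_RATE_LABELS,
    k: int = K_TEST_WINDOWS,
    already_normalized: bool = False,
) -> EvalReport:
    """Repeated stratified five-fold cross-validation of the full pipeline.

    For each repeat the recordings are reshuffled into fresh folds; a model
    is trained per fold and scored on that fold's held-out recordings, so
    every recording is tested exactly once per repeat.  Cell means are over
    the ``n_repeats x n_folds`` runs.  Fully deterministic given ``rng_seed``.
    """
    if not already_normalized:
        recordings = [normalize(r) for r in recordings]
    by_id = {r.recording_id: r for r in recordings}
    master = np.random.SeedSequence(rng_seed)
    repeat_seeds = master.generate_state(3 * n_repeats, dtype=np.uint32).reshape(n_repeats, 3)

    per_run_ws: dict[int, list[float]] = {int(t): [] for t in sizes}
    per_run_dr: dict[int, list[float]] = {int(r): [] for r in rate_labels}
    total_windows = 0
    for rep in range(n_repeats):
        fold_seed, model_seed, eval_seed = (int(s) % (2**31) for s in repeat_seeds[rep])
        folds = make_folds(recordings, n_folds=n_folds, rng_seed=fold_seed)
        for fold in folds:
            cfg = ModelConfig(
                **{
                    **config.__dict__,
                    "rng_seed": (model_seed + fold.fold_index) % (2**31),
                }
            )
            model = build_model(cfg)
            model.fit([by_id[i] for i in sorted(fold.train_ids)])
            test = [by_id[i] for i in sorted(fold.test_ids)]
            rng = np.random.default_rng(eval_seed + fold.fold_index)
            ws, nw = _window_accuracy(model, test, sizes, k, rng)
            dr, nd = _window_accuracy(model, test, rate_sizes, k, rng)
            total_windows += nw + nd
            for t, acc in ws.items():
                per_run_ws[t].append(acc)
            for rate, t in zip(rate_labels, rate_sizes):
                per_run_dr[int(rate)].append(dr[int(t)])

    return EvalReport(
        accuracy_by_window_size={t: float(np.mean(v)) for t, v in per_run_ws.items()},
        accuracy_by_data_rate={r: float(np.mean(v)) for r, v in per_run_dr.items()},
        per_run_window_size=per_run_ws,
        per_run_data_rate=per_run_dr,
        window_size_for_rate={int(r): int(t) for r, t in zip(rate_labels, rate_sizes)},
        n_repeats=n_repeats,
        n_folds=n_folds,
        seeds={"master": rng_seed, "per_repeat": repeat_seeds.tolist()},
        windows_evaluated=total_windows,
    )


# -- table rendering ------------------------------------------------------

def window_size_table(report: EvalReport) -> pd.DataFrame:
    """Accuracy by window size, shaped like the headline results table."""
    rows = [
        {
            "window_size": t,
            "seconds": seconds_label(t),
            "accuracy_pct": report.accuracy_by_window_size[t],
            "std_pct": float(np.std(report.per_run_window_size[t])),
        }
        for t in sorted(report.accuracy_by_window_size)
    ]
    return pd.DataFrame(rows)


def data_rate_table(report: EvalReport) -> pd.DataFrame:
    """Accuracy by partial-data rate (window sizes 42/63/84)."""
    rows = [
        {
            "data_rate_pct": r,
            "window_size": report.window_size_for_rate[r],
            "accuracy_pct": report.accuracy_by_data_rate[r],
            "std_pct": float(np.std(report.per_run_data_rate[r])),
        }
        for r in sorted(report.accuracy_by_data_rate)
    ]
    return pd.DataFrame(rows)
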