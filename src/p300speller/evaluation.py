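"""Offline evaluation harness: accuracy versus number of trials,
mistype-distribution grids, directional error dispersion, windowed
feature analysis and the analytic chance level.

The central routine decodes every typed character from every k-element
combination of its available intensification sequences (exhaustively by
default, uniformly subsampled above ``max_combinations``), retraining
the classifier per k so that training averages use the same k as
testing.  Error grids histogram the typed-minus-intended (row, column)
offsets; the dispersion curve tracks their directional population
standard deviations as k grows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np

from . import preprocessing as pp
from .classifiers import BayesianLDA, BoundaryClassifier
from .pipeline import (
    SessionFeatures,
    character_feature_tensor,
    training_set_from_session,
)
from .simulate import StimulusSchedule
from .speller import DecodedCharacter, SpellerLayout

__all__ = [
    "AccuracyCurve",
    "ErrorGrid",
    "DispersionCurve",
    "KEvaluation",
    "chance_level",
    "decode_block_scores",
    "evaluate_session_at_k",
    "accuracy_vs_k",
    "error_grid",
    "error_grid_from_offsets",
    "dispersion_curve",
    "windowed_accuracy",
]

MAX_OFFSET = 5  # 6x6 grid: offsets span -5..5


def chance_level(layout: SpellerLayout) -> float:
    """Percentage accuracy of picking a character uniformly at random."""
    return 100.0 / (layout.n_rows * layout.n_columns)


@dataclass(frozen=True)
class AccuracyCurve:
    """Character accuracy as a function of the number of trials averaged."""

    ks: tuple[int, ...]
    accuracies: tuple[float, ...]          # fractions in [0, 1]
    n_evaluations: tuple[int, ...]
    method: str = ""

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.ks, self.accuracies))


@dataclass(frozen=True)
class ErrorGrid:
    """11x11 percentage histogram of typed-minus-intended offsets.

    Entry [i, j] is the percentage of typed characters whose row offset
    is i - 5 and column offset j - 5; the centre cell is the correct
    rate and all entries sum to 100.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (2 * MAX_OFFSET + 1, 2 * MAX_OFFSET + 1):
            raise ValueError("error grid must be 11x11")
        if not np.isclose(v.sum(), 100.0):
            raise ValueError("error grid must sum to 100%")
        object.__setattr__(self, "values", v)

    @property
    def correct_rate(self) -> float:
        return float(self.values[MAX_OFFSET, MAX_OFFSET])

    def directional_std(self) -> tuple[float, float]:
        """(vertical std of row offsets, horizontal std of column offsets),
        population convention."""
        w = self.values / 100.0
        off = np.arange(-MAX_OFFSET, MAX_OFFSET + 1, dtype=float)
        p_row, p_col = w.sum(axis=1), w.sum(axis=0)
        v = np.sqrt(max(p_row @ off**2 - (p_row @ off) ** 2, 0.0))
        h = np.sqrt(max(p_col @ off**2 - (p_col @ off) ** 2, 0.0))
        return float(v), float(h)


@dataclass(frozen=True)
class DispersionCurve:
    """Directional offset standard deviations per k."""

    ks: tuple[int, ...]
    vertical_std: tuple[float, ...]     # rows
    horizontal_std: tuple[float, ...]   # columns
    method: str = ""


@dataclass(frozen=True)
class KEvaluation:
    """Full per-k evaluation product of one session and one method."""

    curve: AccuracyCurve
    grids: dict[int, ErrorGrid]

    def dispersion(self) -> DispersionCurve:
        return dispersion_curve(self.grids, method=self.curve.method)


def decode_block_scores(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized row/column argmax decoding of [n, 12] score blocks."""
    scores = np.atleast_2d(scores)
    rows = np.argmax(scores[:, :6], axis=1) + 1
    cols = np.argmax(scores[:, 6:], axis=1) + 1
    return rows, cols


def _k_subsets(n_trials: int, k: int, max_combinations: int,
               rng: np.random.Generator) -> np.ndarray:
    if comb(n_trials, k) <= max_combinations:
        return np.array(list(itertools.combinations(range(n_trials), k)), dtype=int)
    # uniform subsample of k-subsets (independent draws)
    return np.argsort(rng.random((max_combinations, n_trials)), axis=1)[:, :k]


def evaluate_session_at_k(
    model: BoundaryClassifier,
    stats: pp.NormalizationStats,
    test_sf: SessionFeatures,
    test_schedule: StimulusSchedule,
    k: int,
    max_combinations: int = 5000,
    seed: int = 0,
    feature_mask: np.ndarray | None = None,
) -> tuple[float, int, np.ndarray, np.ndarray]:
    """Decode every (character, k-subset) pair with a fitted model.

    Returns (accuracy, n_evaluations, row_offsets, col_offsets).
    """
    rng = np.random.default_rng(seed)
    n_correct = n_total = 0
    row_offs, col_offs = [], []
    for ci in test_sf.characters():
        T = character_feature_tensor(test_sf, int(ci), feature_mask)
        if T.shape[0] < k:
            raise ValueError(f"character {ci}: fewer than k={k} trials")
        combos = _k_subsets(T.shape[0], k, max_combinations, rng)
        # subset averages as an indicator-matrix product over trials
        M = np.zeros((len(combos), T.shape[0]))
        M[np.arange(len(combos))[:, None], combos] = 1.0 / k
        A = (M @ T.reshape(T.shape[0], -1)).reshape(len(combos), 12, -1)
        A = (A - stats.mean) / stats.std
        scores = np.asarray(
            model.decision_function(A.reshape(-1, A.shape[-1]))
        ).reshape(len(combos), 12)
        rows, cols = decode_block_scores(scores)
        truth = test_schedule.attended_for(int(ci))
        row_offs.append(rows - truth.row)
        col_offs.append(cols - truth.column)
        n_correct += int(np.sum((rows == truth.row) & (cols == truth.column)))
        n_total += len(combos)
    return (
        n_correct / n_total,
        n_total,
        np.concatenate(row_offs),
        np.concatenate(col_offs),
    )


def accuracy_vs_k(
    train_sf: SessionFeatures,
    test_sf: SessionFeatures,
    test_schedule: StimulusSchedule,
    classifier_factory: Callable[[], BoundaryClassifier] = BayesianLDA,
    k_range: Sequence[int] = range(1, 16),
    m_per_class: int = 1000,
    max_combinations: int = 5000,
    seed: int = 0,
    method: str = "",
    refit_per_k: bool = True,
    feature_mask: np.ndarray | None = None,
) -> KEvaluation:
    """Accuracy (and offset grids) as a function of the trial count k.

    By default one classifier is retrained per k so that the averaged
    training responses use the same k as the testing averages; with
    ``refit_per_k=False`` a single model trained at max(k_range) is
    reused across the curve (sensitivity analysis).
    """
    ks, accs, nevals, grids = [], [], [], {}
    model = stats = None
    if not refit_per_k:
        ts = training_set_from_session(
            train_sf, max(k_range), m_per_class, seed, feature_mask
        )
        model = classifier_factory().fit(ts.features, ts.labels)
        stats = ts.stats
    for k in k_range:
        if refit_per_k:
            ts = training_set_from_session(
                train_sf, k, m_per_class, seed + k, feature_mask
            )
            model = classifier_factory().fit(ts.features, ts.labels)
            stats = ts.stats
        acc, n, ro, co = evaluate_session_at_k(
            model, stats, test_sf, test_schedule, k,
            max_combinations, seed + 1000 + k, feature_mask,
        )
        ks.append(k)
        accs.append(acc)
        nevals.append(n)
        grids[k] = error_grid_from_offsets(ro, co)
    curve = AccuracyCurve(
        ks=tuple(ks), accuracies=tuple(accs), n_evaluations=tuple(nevals),
        method=method,
    )
    return KEvaluation(curve=curve, grids=grids)


def error_grid_from_offsets(row_offsets: np.ndarray,
                            col_offsets: np.ndarray) -> ErrorGrid:
    row_offsets = np.asarray(row_offsets, dtype=int)
    col_offsets = np.asarray(col_offsets, dtype=int)
    if row_offsets.size == 0:
        raise ValueError("no decoded characters")
    hist = np.zeros((2 * MAX_OFFSET + 1, 2 * MAX_OFFSET + 1))
    np.add.at(hist, (row_offsets + MAX_OFFSET, col_offsets + MAX_OFFSET), 1.0)
    return ErrorGrid(values=hist / row_offsets.size * 100.0)


def error_grid(decoded: Sequence[DecodedCharacter],
               truth: Sequence[tuple[int, int]]) -> ErrorGrid:
    """Histogram of typed-minus-intended positions.

    ``truth`` holds the intended (row, column), 1-based, per decoded
    character.
    """
    if len(decoded) != len(truth):
        raise ValueError("decoded and truth length mismatch")
    ro = np.array([d.row_index - t[0] for d, t in zip(decoded, truth)])
    co = np.array([d.column_index - t[1] for d, t in zip(decoded, truth)])
    return error_grid_from_offsets(ro, co)


def dispersion_curve(grids: dict[int, ErrorGrid], method: str = "") -> DispersionCurve:
    ks = tuple(sorted(grids))
    stds = [grids[k].directional_std() for k in ks]
    return DispersionCurve(
        ks=ks,
        vertical_std=tuple(s[0] for s in stds),
        horizontal_std=tuple(s[1] for s in stds),
        method=method,
    )


def windowed_accuracy(
    train_sf: SessionFeatures,
    test_sf: SessionFeatures,
    test_schedule: StimulusSchedule,
    window_centers: Sequence[float],
    window_width: float = 50.0,
    classifier_factory: Callable[[], BoundaryClassifier] = BayesianLDA,
    k: int = 15,
    m_per_class: int = 1000,
    seed: int = 0,
) -> dict[float, float]:
    """Character accuracy using only features inside short time windows.

    For each window centre the full train/decode cycle is repeated with
    the feature set restricted to the instants within +/- width/2 of the
    centre (2-3 instants per channel for the default 50 ms width on the
    25 ms grid), at ``k`` intensification sequences per character.
    """
    instants = pp.feature_instants_ms(train_sf.window_ms)
    n_channels = train_sf.features.shape[1] // instants.size
    out: dict[float, float] = {}
    for c in window_centers:
        inst_mask = np.abs(instants - c) <= window_width / 2 + 1e-9
        if not inst_mask.any():
            raise ValueError(f"no feature instants inside window at {c} ms")
        mask = np.tile(inst_mask, n_channels)
        ts = training_set_from_session(train_sf, k, m_per_class, seed, mask)
        model = classifier_factory().fit(ts.features, ts.labels)
        acc, _, _, _ = evaluate_session_at_k(
            model, ts.stats, test_sf, test_schedule, k,
            max_combinations=1, seed=seed, feature_mask=mask,
        )
        out[float(c)] = acc
    return out
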