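"""Character decoding for the 6x6 row/column matrix speller.

Stimulus types 1..6 intensify rows, 7..12 columns.  Per trial block the
classifier yields 12 signed scores (c1..c12); the decoded character sits
at the intersection of the best-scoring row and the best-scoring column:

    i_r = argmax_{i=1..6} c_i,      i_c = argmax_{i=7..12} c_i - 6.

Ties break toward the lowest index — a measure-zero event on real
scores, but certain on degenerate inputs, so the rule is fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .preprocessing import (
    Epoch,
    NormalizationStats,
    apply_normalization,
    epoch_feature_matrix,
    FEATURE_WINDOW_MS,
)

__all__ = [
    "SpellerLayout",
    "TrialBlockScores",
    "DecodedCharacter",
    "default_layout",
    "decode",
    "average_by_stimulus",
]

N_STIM_TYPES = 12


@dataclass(frozen=True)
class SpellerLayout:
    """6x6 (or r x c) character grid; rows flash as types 1..r, columns
    as types r+1..r+c."""

    grid: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        cells = [ch for row in self.grid for ch in row]
        if len(set(cells)) != len(cells):
            raise ValueError("layout cells must be unique")
        widths = {len(row) for row in self.grid}
        if len(widths) != 1:
            raise ValueError("layout rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.grid)

    @property
    def n_columns(self) -> int:
        return len(self.grid[0])

    def char_at(self, row: int, column: int) -> str:
        """Character at 1-based (row, column)."""
        return self.grid[row - 1][column - 1]

    @classmethod
    def from_json(cls, path) -> "SpellerLayout":
        with open(path) as fh:
            rows = json.load(fh)
        return cls(grid=tuple(tuple(r) for r in rows))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([list(r) for r in self.grid], fh, ensure_ascii=False, indent=1)


def default_layout() -> SpellerLayout:
    """The shipped Latin layout: 26 letters, digits 1-8, '_' and the
    end-of-input mark."""
    ref = resources.files("p300speller") / "layouts" / "latin.json"
    with resources.as_file(ref) as path:
        return SpellerLayout.from_json(path)


@dataclass(frozen=True)
class TrialBlockScores:
    """The 12 classifier scores of one testing block (c1..c12)."""

    scores: np.ndarray
    k_used: int = 1

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (N_STIM_TYPES,):
            raise ValueError("need exactly 12 scores")
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class DecodedCharacter:
    row_index: int      # 1..6
    column_index: int   # 1..6
    character: str


def decode(scores: TrialBlockScores | np.ndarray,
           layout: SpellerLayout) -> DecodedCharacter:
    """Best row from c1..c6, best column from c7..c12; ties to lowest index."""
    c = scores.scores if isinstance(scores, TrialBlockScores) else np.asarray(
        scores, dtype=float)
    if c.shape != (N_STIM_TYPES,):
        raise ValueError("need exactly 12 scores")
    if not np.isfinite(c).all():
        raise ValueError("scores must be finite")
    nr = layout.n_rows
    row = int(np.argmax(c[:nr])) + 1
    col = int(np.argmax(c[nr:])) + 1
    return DecodedCharacter(row_index=row, column_index=col,
                            character=layout.char_at(row, col))


def average_by_stimulus(
    epochs: Sequence[Epoch],
    k: int,
    stats: NormalizationStats,
    subset: Sequence[int] | None = None,
    window_ms: tuple[float, float] = FEATURE_WINDOW_MS,
) -> np.ndarray:
    """One averaged, normalized feature vector per stimulus type.

    ``subset`` selects which of the available trial blocks enter the
    average (indices into the sorted distinct trial indices of the
    epochs); by default the first ``k`` are used.  Exactly ``k`` epochs
    per stimulus type must be selected.  Returns a [12, N] array ordered
    by stimulus type 1..12.
    """
    trials = sorted({ep.trial_index for ep in epochs})
    if subset is None:
        subset = range(k)
    chosen = {trials[i] for i in subset}
    if len(chosen) != k:
        raise ValueError(f"subset must select exactly k={k} trials")
    by_type: dict[int, list[Epoch]] = {t: [] for t in range(1, N_STIM_TYPES + 1)}
    for ep in epochs:
        if ep.trial_index in chosen:
            if ep.stim_type not in by_type:
                raise ValueError(f"unexpected stimulus type {ep.stim_type}")
            by_type[ep.stim_type].append(ep)
    out = np.empty((N_STIM_TYPES, stats.mean.shape[0]))
    for stim in range(1, N_STIM_TYPES + 1):
        grp = by_type[stim]
        if len(grp) != k:
            raise ValueError(
                f"stimulus type {stim}: expected {k} epochs, found {len(grp)}"
            )
        F = epoch_feature_matrix(grp, window_ms)
        out[stim - 1] = apply_normalization(stats, F.mean(axis=0))
    return out
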