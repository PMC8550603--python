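"""Paired-comparison data handling: pair enumeration, the deposited
7-column response format, aggregation and the conjoint-proportions matrix.

The deposited per-observer response file is a comma-separated table with
4140 rows (1035 unordered pairs x 4 repetitions) and 7 columns:

1. response (0 = stimulus 1 judged more regular, 1 = stimulus 2),
2-3. element spacing level of stimulus 1 / 2 (1-3),
4-5. element size level of stimulus 1 / 2 (1-3),
6-7. element jitter level of stimulus 1 / 2 (1-5).

Left/right screen position is already abstracted by the format; responses
are recoded internally to "the condition listed first in the canonical
pair wins", which is lossless because the decision model is antisymmetric
in the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conditions import (N_CONDITIONS, N_JITTER, N_SIZE, N_SPACING,
                         StimulusCondition, condition_from_index)

COLUMNS = ["response", "spacing1", "spacing2", "size1", "size2",
           "jitter1", "jitter2"]

_LEVEL_RANGE = {"spacing": N_SPACING, "size": N_SIZE, "jitter": N_JITTER}


def enumerate_pairs(n_conditions: int) -> list[tuple[int, int]]:
    """All unordered pairs of ``n_conditions`` items, including self-pairs.

    Returns n(n+1)/2 pairs ``(a, b)`` with ``a <= b`` in deterministic
    lexicographic order; for the 45-condition design this is the exhaustive
    set of 1035 pair judgements.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    return [(a, b) for a in range(n_conditions)
            for b in range(a, n_conditions)]


def _condition_index(spacing, size, jitter) -> np.ndarray:
    return ((np.asarray(jitter) - 1) * N_SIZE * N_SPACING
            + (np.asarray(size) - 1) * N_SPACING
            + (np.asarray(spacing) - 1))


@dataclass
class PairResponseTable:
    """Per-trial binary choices over ordered condition pairs.

    ``trials`` holds one row per trial in the deposited column layout.
    ``aggregate()`` collapses the table to canonical unordered pairs.
    """

    trials: pd.DataFrame

    def __post_init__(self):
        t = self.trials
        missing = [c for c in COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"trials table missing columns {missing}")
        self.trials = t[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def condition_indices(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.trials
        c1 = _condition_index(t["spacing1"], t["size1"], t["jitter1"])
        c2 = _condition_index(t["spacing2"], t["size2"], t["jitter2"])
        return np.asarray(c1), np.asarray(c2)

    def aggregate(self) -> pd.DataFrame:
        """Counts per canonical unordered pair.

        Returns a frame indexed by ``(first, second)`` condition indices
        (``first <= second``) with columns ``n_first`` (trials on which the
        first-listed canonical condition was judged more regular) and
        ``n_total``.
        """
        c1, c2 = self.condition_indices
        resp = self.trials["response"].to_numpy()
        lo, hi = np.minimum(c1, c2), np.maximum(c1, c2)
        # response 0 means "stimulus 1 wins"; recode to "canonical-first wins"
        first_wins = np.where(c1 <= c2, resp == 0, resp == 1)
        frame = pd.DataFrame({"first": lo, "second": hi,
                              "win": first_wins.astype(int)})
        agg = (frame.groupby(["first", "second"])["win"]
               .agg(n_first="sum", n_total="count"))
        return agg

    def write(self, path) -> None:
        """Write the trials in the deposited 7-column CSV dialect (no header)."""
        self.trials.to_csv(path, header=False, index=False)


def table_from_pair_counts(first: Sequence[int], second: Sequence[int],
                           n_first_wins: Sequence[int],
                           n_total: int | Sequence[int]) -> PairResponseTable:
    """Expand per-pair win counts into a trial table.

    Used by the observer simulator: ``n_first_wins[i]`` of the
    ``n_total`` trials of pair ``i`` get response 0, the rest response 1.
    """
    first = np.asarray(first)
    second = np.asarray(second)
    wins = np.asarray(n_first_wins)
    totals = np.broadcast_to(np.asarray(n_total), first.shape)
    rows = np.repeat(np.arange(len(first)), totals)
    # within each pair the first `wins` trials are responses 0
    offsets = np.concatenate([np.arange(t) for t in totals])
    response = (offsets >= np.repeat(wins, totals)).astype(int)
    conds = [condition_from_index(i) for i in range(N_CONDITIONS)]
    sp = np.array([c.spacing_level for c in conds])
    sz = np.array([c.size_level for c in conds])
    jt = np.array([c.jitter_level for c in conds])
    c1, c2 = first[rows], second[rows]
    trials = pd.DataFrame({
        "response": response,
        "spacing1": sp[c1], "spacing2": sp[c2],
        "size1": sz[c1], "size2": sz[c2],
        "jitter1": jt[c1], "jitter2": jt[c2],
    })
    return PairResponseTable(trials)


def read_responses(path) -> PairResponseTable:
    """Read a deposited-format response CSV.

    A header row is tolerated (sniffed: a first row that does not parse as
    numbers is treated as a header).  Rows failing validation -- wrong
    column count, out-of-range level, non-binary response -- raise a
    ``ValueError`` naming the first offending row.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=None, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame()
    if raw.empty:
        return PairResponseTable(
            pd.DataFrame({c: pd.Series(dtype=int) for c in COLUMNS}))
    first_row = raw.iloc[0]
    if not all(_is_number(v) for v in first_row):
        raw = raw.iloc[1:].reset_index(drop=True)
    if raw.shape[1] != len(COLUMNS):
        raise ValueError(
            f"{path}: expected {len(COLUMNS)} columns, found {raw.shape[1]}")
    try:
        data = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entry ({exc})") from exc
    if not np.allclose(data, np.round(data)):
        bad = int(np.argmax(~np.isclose(data, np.round(data)).all(axis=1)))
        raise ValueError(f"{path}: non-integer entry at row {bad}")
    data = data.astype(int)
    data.columns = COLUMNS
    _validate_levels(data, str(path))
    return PairResponseTable(data)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _validate_levels(data: pd.DataFrame, origin: str) -> None:
    bad = ~data["response"].isin([0, 1])
    if bad.any():
        raise ValueError(
            f"{origin}: non-binary response at row {int(bad.idxmax())}")
    for factor, top in _LEVEL_RANGE.items():
        for col in (f"{factor}1", f"{factor}2"):
            out = ~data[col].between(1, top)
            if out.any():
                raise ValueError(
                    f"{origin}: {col} out of range 1..{top} "
                    f"at row {int(out.idxmax())}")


def proportions_matrix(tables: PairResponseTable | Iterable[PairResponseTable]
                       ) -> np.ndarray:
    """Conjoint-proportions matrix (percentages).

    Entry ``(row q, column p)`` is the percentage of trials on which
    condition ``p`` was judged more regular than condition ``q``, pooling
    both presentation orders.  For a list of observer tables the per-observer
    percentage matrices are averaged.  Conditions are in canonical
    (jitter-major) order, so the matrix is block-structured by jitter level.
    """
    if isinstance(tables, PairResponseTable):
        tables = [tables]
    mats = []
    for table in tables:
        if len(table) == 0:
            raise ValueError("cannot build proportions from an empty table")
        wins = np.zeros((N_CONDITIONS, N_CONDITIONS))
        totals = np.zeros((N_CONDITIONS, N_CONDITIONS))
        c1, c2 = table.condition_indices
        resp = table.trials["response"].to_numpy()
        for a, b, r in zip(c1, c2, resp):
            if a == b:
                totals[a, a] += 1
                wins[a, a] += (r == 0)
            else:
                totals[b, a] += 1
                totals[a, b] += 1
                if r == 0:     # stimulus 1 (condition a) judged more regular
                    wins[b, a] += 1
                else:
                    wins[a, b] += 1
        with np.errstate(invalid="ignore"):
            mats.append(np.where(totals > 0, 100.0 * wins / totals, np.nan))
    return np.nanmean(mats, axis=0) if len(mats) > 1 else mats[0]


def plot_proportions(matrix: np.ndarray, ax=None, cmap: str = "viridis"):
    """Heat map of a conjoint-proportions matrix with jitter-block guides."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix, origin="lower", vmin=0, vmax=100, cmap=cmap)
    block = N_SIZE * N_SPACING
    for edge in np.arange(block, N_CONDITIONS, block) - 0.5:
        ax.axhline(edge, color="w", lw=0.6)
        ax.axvline(edge, color="w", lw=0.6)
    ax.set_xlabel("condition judged more regular (canonical index)")
    ax.set_ylabel("comparison condition")
    ax.figure.colorbar(im, ax=ax, label="% judged more regular")
    return ax
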