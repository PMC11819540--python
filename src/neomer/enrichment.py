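"""Outer-product frequency reconstruction and enrichment screening.

The full library space (``4**(wA+wB)`` sequences) is too large to count
directly, but each module space is counted exhaustively.  Under
independence of the two module marginals, the frequency of the full
sequence with module fills (a, b) is estimated as the outer product
``f(a, b) = fA[a] * fB[b]`` — never materialized as a dense
``4**16``-cell array, but streamed row by row (one module-A fill at a
time).

Across selection replicates we form the per-sequence mean and standard
deviation of these reconstructed frequencies, score each sequence by

    z = (mean_target - mean_control) / max(0.5 * (sd_target + sd_control), eps)

rank the whole space by z with an exact bounded-memory top-k, and screen
the retained candidates for specificity as fold ratios

    fold = mean_target / max(mean_counter, pseudo)

against each counter-target condition.  ``eps`` and ``pseudo`` are
count-resolution floors that keep z and fold finite where replicate
standard deviations or counter frequencies underflow the sequencing
depth.

A known artifact of the outer-product reconstruction is kept, not hidden:
enrichment of one sequence inflates the predicted frequency of every
sequence sharing either of its modules, because only marginals are
observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .library_model import index_to_fill
from .module_counting import ModuleCountTable, frequency

__all__ = [
    "FullFrequencyAccessor",
    "ReplicateStats",
    "ZScoreAccessor",
    "FoldAccessor",
    "ScreenResult",
    "outer_frequency",
    "replicate_stats",
    "zscore",
    "top_k",
    "fold_values",
    "counter_screen",
    "stats_from_tables",
    "default_eps",
    "results_frame",
]

#: Guard for convenience full-matrix materialization.
MATERIALIZE_CAP = 4**8


def _check_pow4(n: int, what: str) -> int:
    w = round(math.log(n, 4))
    if 4**w != n:
        raise ValueError(f"{what} length {n} is not a power of 4")
    return w


@dataclass(frozen=True)
class FullFrequencyAccessor:
    """Lazy outer-product frequency surface f(a, b) = fA[a] * fB[b]."""

    fA: np.ndarray
    fB: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return (self.fA.size, self.fB.size)

    @property
    def widths(self) -> tuple[int, int]:
        return (_check_pow4(self.fA.size, "fA"), _check_pow4(self.fB.size, "fB"))

    def __call__(self, a: int, b: int) -> float:
        return float(self.fA[a] * self.fB[b])

    def row(self, a: int) -> np.ndarray:
        """All frequencies sharing module-A fill ``a`` (one streaming block)."""
        return self.fA[a] * self.fB

    def total(self) -> float:
        return float(self.fA.sum() * self.fB.sum())


def outer_frequency(fA: np.ndarray, fB: np.ndarray) -> FullFrequencyAccessor:
    """Build the outer-product accessor from two module frequency vectors.

    Both vectors must be probability vectors over a power-of-4 space; the
    joint surface then sums to 1 by construction and is accessed blockwise,
    never materialized.
    """
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    _check_pow4(fA.size, "fA")
    _check_pow4(fB.size, "fB")
    for name, v in (("fA", fA), ("fB", fB)):
        if not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} sums to {v.sum():.6g}, expected 1")
        if (v < 0).any():
            raise ValueError(f"{name} has negative entries")
    return FullFrequencyAccessor(fA, fB)


@dataclass(frozen=True)
class ReplicateStats:
    """Per-sequence mean and sample standard deviation across replicates.

    Built from one :class:`FullFrequencyAccessor` per replicate; rows are
    computed on demand so the full space is never materialized.  With a
    single replicate the standard deviation is 0 by convention and
    ``single_replicate`` is flagged.
    """

    accessors: tuple[FullFrequencyAccessor, ...]
    ddof: int = 1

    def __post_init__(self) -> None:
        if not self.accessors:
            raise ValueError("at least one replicate accessor required")
        shapes = {acc.shape for acc in self.accessors}
        if len(shapes) != 1:
            raise ValueError(f"replicate shape mismatch: {sorted(shapes)}")

    @property
    def n(self) -> int:
        return len(self.accessors)

    @property
    def single_replicate(self) -> bool:
        return self.n == 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.accessors[0].shape

    def _stack_row(self, a: int) -> np.ndarray:
        return np.stack([acc.row(a) for acc in self.accessors])

    def mean_row(self, a: int) -> np.ndarray:
        return self._stack_row(a).mean(axis=0)

    def sd_row(self, a: int) -> np.ndarray:
        if self.single_replicate:
            return np.zeros(self.shape[1])
        return self._stack_row(a).std(axis=0, ddof=self.ddof)

    def mean_matrix(self) -> np.ndarray:
        self._check_materialize()
        return np.stack([acc.fA[:, None] * acc.fB[None, :]
                         for acc in self.accessors]).mean(axis=0)

    def sd_matrix(self) -> np.ndarray:
        self._check_materialize()
        if self.single_replicate:
            return np.zeros(self.shape)
        return np.stack([acc.fA[:, None] * acc.fB[None, :]
                         for acc in self.accessors]).std(axis=0, ddof=self.ddof)

    def _check_materialize(self) -> None:
        if self.shape[0] * self.shape[1] > MATERIALIZE_CAP:
            raise ValueError(
                f"refusing to materialize {self.shape[0] * self.shape[1]:,} "
                "cells; use row access"
            )


def replicate_stats(
    accessors: Sequence[FullFrequencyAccessor], ddof: int = 1
) -> ReplicateStats:
    """Replicate mean/sd statistics over reconstructed frequency surfaces."""
    return ReplicateStats(accessors=tuple(accessors), ddof=ddof)


@dataclass(frozen=True)
class ZScoreAccessor:
    """Row-streamed z = (mean_T - mean_C) / max(0.5 (sd_T + sd_C), eps)."""

    target: ReplicateStats
    control: ReplicateStats
    eps: float

    def __post_init__(self) -> None:
        if self.target.shape != self.control.shape:
            raise ValueError(
                f"shape mismatch: target {self.target.shape} vs "
                f"control {self.control.shape}"
            )
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.target.shape

    def row(self, a: int) -> np.ndarray:
        num = self.target.mean_row(a) - self.control.mean_row(a)
        den = 0.5 * (self.target.sd_row(a) + self.control.sd_row(a))
        return num / np.maximum(den, self.eps)

    def matrix(self) -> np.ndarray:
        return np.stack([self.row(a) for a in range(self.shape[0])])


def zscore(
    target: ReplicateStats, control: ReplicateStats, eps: float
) -> ZScoreAccessor:
    """Replicate z-score of target vs control reconstructed frequencies.

    The denominator is the average of the two conditions' standard
    deviations, floored at ``eps`` (use :func:`default_eps` for a
    count-resolution floor of 1/median library size).  Swapping target and
    control negates z.
    """
    return ZScoreAccessor(target=target, control=control, eps=eps)


def default_eps(tables: Iterable[ModuleCountTable]) -> float:
    """Count-resolution floor: 1 / median accepted-read total."""
    totals = [t.total_reads for t in tables]
    if not totals:
        raise ValueError("no tables")
    return 1.0 / float(np.median(totals))


@dataclass(frozen=True)
class ScreenResult:
    """One ranked candidate sequence (a module-A/module-B fill pair)."""

    fill_a: str
    fill_b: str
    z: float
    mean_target: float
    mean_control: float
    folds: dict[str, float] = field(default_factory=dict)

    @property
    def sequence_key(self) -> str:
        return self.fill_a + self.fill_b


def top_k(z_acc: ZScoreAccessor, k: int) -> list[ScreenResult]:
    """Exact top-k sequences by z over the full outer space, blockwise.

    Ties break by (z desc, target mean desc, sequence lexicographic asc).
    Memory is bounded by O(k + row length); the result equals a
    brute-force sort of the materialized space.  If ``k`` exceeds the
    space the full ranking is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nA, nB = z_acc.shape
    k = min(k, nA * nB)
    wA = _check_pow4(nA, "module A space")
    wB = _check_pow4(nB, "module B space")

    def row_top(zrow: np.ndarray, mrow: np.ndarray) -> np.ndarray:
        """Indices of the row's exact top-k by (z desc, mean desc, idx asc)."""
        if nB <= k:
            return np.arange(nB)
        thr = np.partition(zrow, nB - k)[nB - k]  # k-th largest z
        gt = np.flatnonzero(zrow > thr)
        eq = np.flatnonzero(zrow == thr)
        need = k - gt.size
        if eq.size > need:
            order = np.lexsort((eq, -mrow[eq]))
            eq = eq[order[:need]]
        return np.concatenate([gt, eq])

    # (z desc, mean_target desc, index asc) == ascending sort on this key:
    best: list[tuple[float, float, int, int]] = []
    threshold = None  # key of current k-th best
    for a in range(nA):
        zrow = z_acc.row(a)
        mrow = z_acc.target.mean_row(a)
        for b in row_top(zrow, mrow):
            key = (-float(zrow[b]), -float(mrow[b]), a, int(b))
            if threshold is None or key < threshold:
                best.append(key)
        if len(best) > 4 * k:
            best.sort()
            del best[k:]
            threshold = best[-1]
    best.sort()
    del best[k:]

    crow_cache: dict[int, np.ndarray] = {}
    out = []
    for negz, negm, a, b in best:
        if a not in crow_cache:
            crow_cache.clear()
            crow_cache[a] = z_acc.control.mean_row(a)
        out.append(
            ScreenResult(
                fill_a=index_to_fill(a, wA),
                fill_b=index_to_fill(b, wB),
                z=-negz,
                mean_target=-negm,
                mean_control=float(crow_cache[a][b]),
            )
        )
    return out


@dataclass(frozen=True)
class FoldAccessor:
    """Row-streamed fold = mean_target / max(mean_counter, pseudo)."""

    target: ReplicateStats
    counter: ReplicateStats
    pseudo: float
    minus_one: bool = False

    def __post_init__(self) -> None:
        if self.target.shape != self.counter.shape:
            raise ValueError("shape mismatch between target and counter stats")
        if self.pseudo <= 0:
            raise ValueError("pseudo must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.target.shape

    def row(self, a: int) -> np.ndarray:
        fold = self.target.mean_row(a) / np.maximum(
            self.counter.mean_row(a), self.pseudo
        )
        return fold - 1.0 if self.minus_one else fold

    def __call__(self, a: int, b: int) -> float:
        return float(self.row(a)[b])


def fold_values(
    target: ReplicateStats,
    counter: ReplicateStats,
    pseudo: float,
    minus_one: bool = False,
) -> FoldAccessor:
    """Specificity fold of target vs a counter condition.

    The counter mean is floored at ``pseudo`` (half a count at median
    depth is the conventional choice) so folds stay finite when a
    sequence is absent from the counter selection; ``minus_one`` gives
    the fold-minus-one variant used for enrichment plots.
    """
    return FoldAccessor(target=target, counter=counter, pseudo=pseudo,
                        minus_one=minus_one)


def counter_screen(
    candidates: Sequence[ScreenResult],
    folds: Mapping[str, FoldAccessor],
    thresholds: Mapping[str, float],
) -> tuple[list[ScreenResult], pd.DataFrame]:
    """Filter ranked candidates by per-counter-target fold thresholds.

    A candidate is retained iff its fold against *every* thresholded
    counter condition is >= that counter's threshold — the in-silico
    analogue of immune tolerance over the closed sequence set.  Returns
    the retained candidates (with folds attached) and a per-candidate
    report table.
    """
    unknown = set(thresholds) - set(folds)
    if unknown:
        raise KeyError(f"thresholds for unknown counter conditions: {sorted(unknown)}")

    from .library_model import fill_to_index  # noqa: PLC0415

    kept: list[ScreenResult] = []
    rows = []
    for cand in candidates:
        a = fill_to_index(cand.fill_a)
        b = fill_to_index(cand.fill_b)
        cand_folds = {name: acc(a, b) for name, acc in folds.items()}
        ok = all(cand_folds[name] >= thr for name, thr in thresholds.items())
        row = {
            "fill_a": cand.fill_a, "fill_b": cand.fill_b, "z": cand.z,
            "mean_target": cand.mean_target, "mean_control": cand.mean_control,
        }
        row.update({f"fold_{name}": v for name, v in cand_folds.items()})
        row["kept"] = ok
        rows.append(row)
        if ok:
            kept.append(
                ScreenResult(
                    fill_a=cand.fill_a, fill_b=cand.fill_b, z=cand.z,
                    mean_target=cand.mean_target,
                    mean_control=cand.mean_control, folds=cand_folds,
                )
            )
    return kept, pd.DataFrame(rows)


def stats_from_tables(
    tables_a: Sequence[ModuleCountTable],
    tables_b: Sequence[ModuleCountTable],
    ddof: int = 1,
) -> ReplicateStats:
    """Replicate statistics from paired module-A/module-B count tables.

    ``tables_a[i]`` and ``tables_b[i]`` must come from the same replicate
    sample; each pair yields one outer-product accessor.
    """
    if len(tables_a) != len(tables_b):
        raise ValueError("module A and B table lists differ in length")
    accs = [
        outer_frequency(frequency(ta), frequency(tb))
        for ta, tb in zip(tables_a, tables_b)
    ]
    return replicate_stats(accs, ddof=ddof)


def results_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Ranked results as a tidy table (one row per candidate)."""
    rows = []
    for rank, r in enumerate(results, start=1):
        row = {
            "rank": rank, "fill_a": r.fill_a, "fill_b": r.fill_b, "z": r.z,
            "mean_target": r.mean_target, "mean_control": r.mean_control,
        }
        row.update({f"fold_{name}": v for name, v in r.folds.items()})
        rows.append(row)
    return pd.DataFrame(rows)
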