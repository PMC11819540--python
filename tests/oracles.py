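"""Independent brute-force oracles used to check the real implementations.

Everything here is deliberately naive — exhaustive enumeration and dense
materialization — and shares no code with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np

PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def max_pairs_exhaustive(seq: str, min_loop: int = 3, min_helix: int = 2) -> int:
    """Maximum base pairs by enumerating every valid non-crossing pair set."""
    n = len(seq)
    best = 0

    def rec(i: int, j: int):
        if i > j:
            yield []
            return
        yield from ([p for p in rest] for rest in rec(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRS:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield [(i, k)] + inner + outer

    def valid(ps: list[tuple[int, int]]) -> bool:
        pset = set(ps)
        for (i, k) in ps:
            run = 1
            a, b = i - 1, k + 1
            while (a, b) in pset:
                run += 1
                a -= 1
                b += 1
            a, b = i + 1, k - 1
            while (a, b) in pset:
                run += 1
                a += 1
                b -= 1
            if run < min_helix:
                return False
            if not any(i < x < y < k for (x, y) in pset):
                if k - i - 1 < min_loop:
                    return False
        return True

    for ps in rec(0, n - 1):
        if valid(ps):
            best = max(best, len(ps))
    return best


def run_lengths(labels: str) -> list[tuple[str, int]]:
    """Maximal same-character runs, scanned left to right."""
    out: list[tuple[str, int]] = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], j - i))
        i = j
    return out


def dense_screen(
    fa_reps_t, fb_reps_t, fa_reps_c, fb_reps_c, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Materialized z-score: stacks full outer products, no streaming.

    Returns (z, mean_target, mean_control) matrices.
    """
    t = np.stack([np.outer(a, b) for a, b in zip(fa_reps_t, fb_reps_t)])
    c = np.stack([np.outer(a, b) for a, b in zip(fa_reps_c, fb_reps_c)])
    mt, mc = t.mean(axis=0), c.mean(axis=0)
    st = t.std(axis=0, ddof=1) if t.shape[0] > 1 else np.zeros_like(mt)
    sc = c.std(axis=0, ddof=1) if c.shape[0] > 1 else np.zeros_like(mc)
    z = (mt - mc) / np.maximum(0.5 * (st + sc), eps)
    return z, mt, mc


def dense_top_k(z: np.ndarray, mt: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Full sort of the materialized z matrix with the screening tie-break."""
    nA, nB = z.shape
    cells = [
        (-z[a, b], -mt[a, b], a, b) for a in range(nA) for b in range(nB)
    ]
    cells.sort()
    return [(a, b) for _, _, a, b in cells[: min(k, len(cells))]]
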