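"""Secondary-structure tools for library structural-diversity analysis.

An interspersed fixed/random library is designed so that secondary
structure is driven by the identity of the random bases, not by the fixed
scaffold.  To compare designs, we sample full-length sequences from a
template, predict a secondary structure for each, annotate every position
with a structural element, and summarize the ensemble as a
position-by-element abundance matrix, its per-position Shannon diversity,
and per-element motif statistics.

The default folding engine maximizes Watson-Crick (plus G-T wobble) base
pairs by dynamic programming under three hard constraints: no pseudoknots,
hairpin loops of at least ``min_loop`` unpaired bases, and helices of at
least ``min_helix`` stacked pairs (``min_helix=2`` forbids isolated
pairs).  An external thermodynamic folder (e.g. RNAfold with DNA
parameters) can be plugged in wherever a fold engine is accepted.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .library_model import (
    BASES,
    AlphabetError,
    CapacityError,
    LibraryTemplate,
    index_to_fill,
    split_modules,
)

__all__ = [
    "DotBracket",
    "StructureAnnotation",
    "ELEMENT_CODES",
    "fold_default",
    "make_fold_engine",
    "rnafold_engine",
    "annotate",
    "element_position_matrix",
    "positional_shannon",
    "motif_summary",
    "sample_random_sequences",
]

#: Structural element codes: stem, hairpin loop, bulge, internal loop,
#: multiloop, external (dangling) — the standard loop decomposition.
ELEMENT_CODES = ("S", "H", "B", "I", "M", "E")

_WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}


class StructureError(ValueError):
    """A dot-bracket string is unbalanced or inconsistent."""


@dataclass(frozen=True)
class DotBracket:
    """A sequence plus its dot-bracket structure (Vienna notation)."""

    sequence: str
    structure: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise StructureError("sequence and structure lengths differ")
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise StructureError("unbalanced ')' in structure")
            elif ch != ".":
                raise StructureError(f"invalid structure character {ch!r}")
        if depth != 0:
            raise StructureError("unbalanced '(' in structure")

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as (i, j) with i < j, 0-based."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                out.append((stack.pop(), i))
        return sorted(out)

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


@dataclass(frozen=True)
class StructureAnnotation:
    """Per-position element labels for one structure."""

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(ELEMENT_CODES)
        if bad:
            raise ValueError(f"invalid element codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


def _pair_ok(a: str, b: str, allow_gt: bool) -> bool:
    return (a, b) in _WC_PAIRS or (allow_gt and (a, b) in _WOBBLE)


def fold_default(
    seq: str,
    min_loop: int = 3,
    min_helix: int = 2,
    allow_gt: bool = True,
) -> DotBracket:
    """Maximum-base-pair fold under hairpin and helix-length constraints.

    Nussinov-style interval dynamic programming where base i either stays
    unpaired or opens a helix of ``h >= min_helix`` stacked pairs
    ``(i, k), (i+1, k-1), ...``; the hairpin constraint requires at least
    ``min_loop`` unpaired bases inside an innermost helix.  No pseudoknots.

    Co-optimal structures are resolved deterministically: pairing the
    5'-most base is preferred over leaving it unpaired, the outermost
    (farthest) partner is preferred, and the longest helix at that
    partner is preferred.
    """
    s = seq.upper()
    bad = set(s) - set(BASES)
    if bad:
        raise AlphabetError(f"invalid sequence characters: {sorted(bad)}")
    n = len(s)
    if n == 0:
        return DotBracket("", "")

    # helix_len[i][k]: maximal stack depth extending inward from pair (i, k)
    # (0 where i,k cannot pair).
    helix_len = [[0] * n for _ in range(n)]
    for i in range(n - 1, -1, -1):
        for k in range(n - 1, i, -1):
            if _pair_ok(s[i], s[k], allow_gt):
                inner = helix_len[i + 1][k - 1] if i + 1 < k - 1 else 0
                helix_len[i][k] = 1 + inner if k - i >= 3 else 1

    # C[i][j]: max pairs on s[i..j]; intervals by increasing length.
    C = [[0] * (n + 1) for _ in range(n + 1)]

    def options(i: int, j: int):
        """Scoring options for interval [i, j], in tie-break preference order."""
        # Helix openings at i: partner k descending (outermost first),
        # then longest helix; inner hairpin needs >= min_loop unpaired.
        k_min = i + min_loop + 2 * min_helix - 1
        for k in range(j, k_min - 1, -1):
            max_h = helix_len[i][k]
            if max_h < min_helix:
                continue
            for h in range(max_h, min_helix - 1, -1):
                if (k - h) - (i + h) + 1 < min_loop:
                    continue
                score = h + C[i + h][k - h] + (C[k + 1][j] if k < j else 0)
                yield score, ("helix", k, h)
        yield (C[i + 1][j] if i < j else 0), ("skip",)

    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            C[i][j] = max(score for score, _ in options(i, j))

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i <= j:
            target = C[i][j]
            for score, choice in options(i, j):
                if score == target:
                    break
            if choice[0] == "skip":
                i += 1
                continue
            _, k, h = choice
            for d in range(h):
                structure[i + d] = "("
                structure[k - d] = ")"
            traceback(i + h, k - h)
            i = k + 1

    if n >= 2:
        traceback(0, n - 1)
    return DotBracket(s, "".join(structure))


def make_fold_engine(
    min_loop: int = 3, min_helix: int = 2, allow_gt: bool = True
) -> Callable[[str], DotBracket]:
    """A fold engine (seq -> DotBracket) with fixed constraint parameters."""

    def engine(seq: str) -> DotBracket:
        return fold_default(seq, min_loop=min_loop, min_helix=min_helix,
                            allow_gt=allow_gt)

    return engine


def rnafold_engine(
    temperature: float = 22.0, no_lonely_pairs: bool = True
) -> Callable[[str], DotBracket]:
    """Plug-in engine that shells out to the ViennaRNA ``RNAfold`` binary.

    Intended for thermodynamic (MFE) folding of DNA templates when the
    ViennaRNA suite is installed; raises ``RuntimeError`` otherwise.  Note
    that without a DNA parameter file RNAfold uses RNA energies; this
    engine is a convenience adapter, not part of the default pipeline.
    """
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found on PATH")

    args = [exe, "--noPS", "-T", str(temperature)]
    if no_lonely_pairs:
        args.append("--noLP")

    def engine(seq: str) -> DotBracket:
        proc = subprocess.run(
            args, input=seq + "\n", capture_output=True, text=True, check=True
        )
        lines = proc.stdout.strip().splitlines()
        structure = lines[-1].split()[0]
        return DotBracket(seq.upper().replace("U", "T"), structure)

    return engine


def annotate(db: DotBracket) -> StructureAnnotation:
    """Label every position with its structural element.

    Paired positions are stems (S).  An unpaired position enclosed by no
    pair is external (E).  Otherwise its innermost enclosing pair closes a
    loop whose classification depends on the number of helix branches
    directly inside it: none -> hairpin (H); one, with unpaired bases on a
    single side -> bulge (B); one, both sides -> internal loop (I); two or
    more -> multiloop (M).
    """
    n = len(db.structure)
    partner = [-1] * n
    for i, j in db.pairs():
        partner[i] = j
        partner[j] = i

    labels = ["E"] * n
    for i in range(n):
        if partner[i] >= 0:
            labels[i] = "S"

    def classify_loop(i: int, j: int) -> None:
        """Label the unpaired positions directly inside pair (i, j)."""
        children: list[tuple[int, int]] = []
        loose: list[int] = []
        p = i + 1
        while p < j:
            if partner[p] > p:
                children.append((p, partner[p]))
                p = partner[p] + 1
            else:
                loose.append(p)
                p += 1
        if not loose:
            pass
        elif not children:
            code = "H"
            for p in loose:
                labels[p] = code
        elif len(children) == 1:
            a, b = children[0]
            left = [p for p in loose if p < a]
            right = [p for p in loose if p > b]
            code = "I" if (left and right) else "B"
            for p in loose:
                labels[p] = code
        else:
            for p in loose:
                labels[p] = "M"
        for a, b in children:
            classify_loop(a, b)

    # Top-level scan: positions outside all pairs stay E.
    p = 0
    while p < n:
        if partner[p] > p:
            classify_loop(p, partner[p])
            p = partner[p] + 1
        else:
            p += 1

    return StructureAnnotation("".join(labels))


def element_position_matrix(
    annotations: Sequence[StructureAnnotation],
) -> pd.DataFrame:
    """Element-by-position relative abundance over an annotation ensemble.

    Rows are the six element codes, columns are 0-based positions; each
    column sums to 1.  All annotations must share one length.
    """
    if not annotations:
        raise ValueError("no annotations")
    lengths = {len(a) for a in annotations}
    if len(lengths) != 1:
        raise ValueError(f"annotations have ragged lengths: {sorted(lengths)}")
    (length,) = lengths
    counts = np.zeros((len(ELEMENT_CODES), length), dtype=float)
    row = {code: r for r, code in enumerate(ELEMENT_CODES)}
    for ann in annotations:
        for pos, code in enumerate(ann.labels):
            counts[row[code], pos] += 1
    counts /= len(annotations)
    return pd.DataFrame(counts, index=list(ELEMENT_CODES),
                        columns=range(length))


def positional_shannon(matrix: pd.DataFrame) -> np.ndarray:
    """Per-position Shannon diversity H_j = -sum_e p_ej log2 p_ej (bits).

    Zero at positions where a single element dominates completely; at most
    log2(6) ~ 2.585 bits when all six elements are equally likely.
    """
    p = np.asarray(matrix, dtype=float)
    if not np.allclose(p.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("matrix columns must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=0)


def _runs(labels: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], i - start))
            start = i
    return out


def motif_summary(annotations: Sequence[StructureAnnotation]) -> pd.DataFrame:
    """Per-element motif statistics over an ensemble.

    ``mean_count``: mean number of maximal same-element runs per sequence
    (how often the motif occurs); ``mean_run_length``: mean length of
    those runs in nucleotides (0 where the element never occurs).
    """
    if not annotations:
        raise ValueError("no annotations")
    run_counts = {c: 0 for c in ELEMENT_CODES}
    run_lengths = {c: 0 for c in ELEMENT_CODES}
    for ann in annotations:
        for code, length in _runs(ann.labels):
            run_counts[code] += 1
            run_lengths[code] += length
    n = len(annotations)
    return pd.DataFrame(
        {
            "mean_count": [run_counts[c] / n for c in ELEMENT_CODES],
            "mean_run_length": [
                run_lengths[c] / run_counts[c] if run_counts[c] else 0.0
                for c in ELEMENT_CODES
            ],
        },
        index=list(ELEMENT_CODES),
    )


def sample_random_sequences(
    t: LibraryTemplate, n: int, seed: int | np.random.Generator = 0
) -> list[str]:
    """Draw ``n`` distinct full-length sequences uniformly from a template.

    Fills are drawn uniformly over the joint random space; uniqueness is
    enforced (by permutation for small spaces, rejection otherwise).
    Reproducible for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = t.n_random
    space = 4**w
    if n > space:
        raise CapacityError(f"requested {n} unique sequences from a space of {space}")
    if n == 0:
        return []

    if space <= 1 << 22:
        indices = rng.permutation(space)[:n]
    else:
        chosen: set[int] = set()
        while len(chosen) < n:
            draw = rng.integers(0, space, size=n - len(chosen))
            chosen.update(int(x) for x in draw)
        indices = np.fromiter(chosen, dtype=np.int64, count=n)
        indices.sort()

    mod_a, mod_b = split_modules(t)
    wa, wb = mod_a.width, mod_b.width
    out = []
    for idx in indices:
        idx = int(idx)
        fill_a = index_to_fill(idx >> (2 * wb), wa)
        fill_b = index_to_fill(idx & (4**wb - 1), wb)
        out.append(mod_a.render(fill_a) + mod_b.render(fill_b))
    return out
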