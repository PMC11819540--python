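"""Module-amplicon read counting over the 4**w module sequence space.

After selection the library is cut at the central restriction site and
each half (module) is sequenced separately.  Every accepted read is
reduced to its *fill* — the bases at the module's random positions — and
tallied into a dense count vector of length ``4**w`` indexed
lexicographically (A<C<G<T).  Frequencies are counts divided by the
accepted-read total, so each module table is a probability vector over
its 65,536-sequence space (for w=8).

Reads are matched by their fixed positions at fixed offsets (no indels),
on either strand, with a configurable mismatch budget; everything else is
rejected with a reason, never silently dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
import pandas as pd

from .library_model import BASES, ModuleSpec, index_to_fill

__all__ = [
    "Rejection",
    "ModuleCountTable",
    "EmptySampleError",
    "extract_fill",
    "count_modules",
    "frequency",
    "read_count_table",
]

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# complement of code: A<->T, C<->G; anything else stays non-matching
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)

#: Rejection reasons, in ledger order.
REASONS = ("length", "anchor", "ambiguous")


class EmptySampleError(ValueError):
    """Frequency requested for a table with zero accepted reads."""


@dataclass(frozen=True)
class Rejection:
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass
class ModuleCountTable:
    """Per-sample counts over one module's 4**w sequence space."""

    module_id: str
    sample_id: str
    width: int
    counts: np.ndarray
    rejected: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.width,):
            raise ValueError(
                f"counts length {self.counts.size} != 4**{self.width}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    @property
    def frequencies(self) -> np.ndarray:
        return frequency(self)

    def to_tsv(self, path: str | Path, all_fills: bool = False) -> None:
        """Write ``fill\\tcount\\tfrequency`` rows (nonzero fills by default)."""
        total = self.total_reads
        idx = np.arange(self.counts.size) if all_fills else np.flatnonzero(self.counts)
        df = pd.DataFrame(
            {
                "fill": [index_to_fill(int(i), self.width) for i in idx],
                "count": self.counts[idx],
                "frequency": self.counts[idx] / total if total else 0.0,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# module={self.module_id} sample={self.sample_id} "
                     f"width={self.width} total_reads={total} "
                     f"rejected={self.n_rejected}\n")
            df.to_csv(fh, sep="\t", index=False)


def read_count_table(path: str | Path) -> ModuleCountTable:
    """Read a count table written by :meth:`ModuleCountTable.to_tsv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing count-table header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    width = int(meta["width"])
    counts = np.zeros(4**width, dtype=np.int64)
    from .library_model import fill_to_index  # noqa: PLC0415

    for fill, cnt in zip(df["fill"], df["count"]):
        counts[fill_to_index(str(fill))] = int(cnt)
    table = ModuleCountTable(
        module_id=meta["module"], sample_id=meta["sample"],
        width=width, counts=counts,
        rejected={"unknown": int(meta.get("rejected", 0))} if int(meta.get("rejected", 0)) else {},
    )
    return table


def _module_arrays(m: ModuleSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = _CODE[np.frombuffer(m.sequence.encode(), dtype=np.uint8)].copy()
    fixed = np.array(m.fixed_offsets, dtype=np.int64)
    rand = np.array(m.random_offsets, dtype=np.int64)
    return codes, fixed, rand


def _chunk_extract(
    reads: list[str], m: ModuleSpec, max_mismatch: int,
    counts: np.ndarray, rejected: dict[str, int],
) -> None:
    """Vectorized fill extraction for a chunk of equal-length candidate reads."""
    L = m.length
    keep = [r for r in reads if len(r) == L]
    n_len = len(reads) - len(keep)
    if n_len:
        rejected["length"] = rejected.get("length", 0) + n_len
    if not keep:
        return
    mat = _CODE[
        np.frombuffer("".join(keep).encode(), dtype=np.uint8)
    ].reshape(len(keep), L)

    codes, fixed, rand = _module_arrays(m)
    tmpl_fixed = codes[fixed]

    # forward strand
    mism_f = (mat[:, fixed] != tmpl_fixed).sum(axis=1)
    ok_f = mism_f <= max_mismatch

    # reverse strand: revcomp(read) matches template <=> read matches
    # revcomp(template); extract by complementing mirrored positions.
    rc_fixed_pos = L - 1 - fixed
    rc_tmpl_fixed = _COMP[tmpl_fixed]
    mism_r = (mat[:, rc_fixed_pos] != rc_tmpl_fixed).sum(axis=1)
    ok_r = ~ok_f & (mism_r <= max_mismatch)

    n_anchor = int((~ok_f & ~ok_r).sum())
    if n_anchor:
        rejected["anchor"] = rejected.get("anchor", 0) + n_anchor

    w = m.width
    weights = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    for ok, fills in (
        (ok_f, mat[ok_f][:, rand]),
        (ok_r, _COMP[mat[ok_r][:, L - 1 - rand]]),
    ):
        if not ok.any():
            continue
        clean = (fills < 4).all(axis=1)
        n_amb = int((~clean).sum())
        if n_amb:
            rejected["ambiguous"] = rejected.get("ambiguous", 0) + n_amb
        if clean.any():
            idx = (fills[clean].astype(np.int64) * weights).sum(axis=1)
            np.add.at(counts, idx, 1)


def extract_fill(
    read: str, m: ModuleSpec, max_mismatch: int = 1
) -> Union[str, Rejection]:
    """Extract the module fill from one read, or return a :class:`Rejection`.

    The read (or its reverse complement) must match the module's fixed
    positions with at most ``max_mismatch`` mismatches and be exactly the
    module length; the bases at the random positions, which must be
    unambiguous, form the fill.
    """
    counts = np.zeros(m.space, dtype=np.int64)
    rejected: dict[str, int] = {}
    _chunk_extract([read.upper()], m, max_mismatch, counts, rejected)
    if rejected:
        return Rejection(next(iter(rejected)))
    (idx,) = np.flatnonzero(counts)
    return index_to_fill(int(idx), m.width)


def _iter_reads(source: Union[str, Path, Iterable[str]]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        is_fastq = stem.endswith((".fastq", ".fq"))
        with opener(path, "rt") as fh:
            if is_fastq:
                from Bio.SeqIO.QualityIO import FastqGeneralIterator  # noqa: PLC0415

                for _title, seq, _qual in FastqGeneralIterator(fh):
                    yield seq
            else:
                from Bio.SeqIO.FastaIO import SimpleFastaParser  # noqa: PLC0415

                for _title, seq in SimpleFastaParser(fh):
                    yield seq
    else:
        yield from source


def count_modules(
    reads: Union[str, Path, Iterable[str]],
    m: ModuleSpec,
    max_mismatch: int = 1,
    sample_id: str = "sample",
    chunk_size: int = 200_000,
) -> ModuleCountTable:
    """Count module fills over a read stream in one pass.

    ``reads`` may be a FASTQ/FASTA path (gzip transparent; format sniffed
    from the extension, FASTA assumed otherwise) or any iterable of read
    strings.  Every input read is either counted or recorded in the
    rejection ledger, so ``total_reads + n_rejected`` equals the number of
    input records.
    """
    counts = np.zeros(m.space, dtype=np.int64)
    rejected: dict[str, int] = {}
    chunk: list[str] = []
    for seq in _iter_reads(reads):
        chunk.append(seq.upper())
        if len(chunk) >= chunk_size:
            _chunk_extract(chunk, m, max_mismatch, counts, rejected)
            chunk = []
    if chunk:
        _chunk_extract(chunk, m, max_mismatch, counts, rejected)
    return ModuleCountTable(
        module_id=m.module_id, sample_id=sample_id, width=m.width,
        counts=counts, rejected=rejected,
    )


def frequency(table: ModuleCountTable) -> np.ndarray:
    """Per-fill frequency: counts / total accepted reads (sums to 1)."""
    total = table.total_reads
    if total == 0:
        raise EmptySampleError(
            f"sample {table.sample_id!r} module {table.module_id!r} has no "
            "accepted reads"
        )
    return table.counts / total
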