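"""Library templates with interspersed fixed and random positions.

A closed-space aptamer library is described by a template string over
``{A, C, G, T, N}`` in which every ``N`` is a uniformly random position.
With sixteen random positions the library spans exactly ``4**16`` =
4,294,967,296 sequences — small enough that a selection can start from
~1000 copies of every possible sequence and be re-run on the same closed
set.  A central restriction site lets the template be cut into two
*modules* (A and B), each carrying half of the random positions, so that
each module's ``4**8`` = 65,536-sequence space can be counted exhaustively
on a single NGS lane.

This module parses and validates templates, derives the module split,
enumerates module sequence spaces, converts between random-position
*fills* and lexicographic indices, and computes the sequence-space
combinatorics (space size, copies per sequence, sampled proportion).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

__all__ = [
    "DEFAULT_TEMPLATE",
    "KASI_SITE",
    "LibraryTemplate",
    "ModuleSpec",
    "ValidationReport",
    "AlphabetError",
    "DegenerateTemplateError",
    "SplitError",
    "CapacityError",
    "FillError",
    "parse_template",
    "split_modules",
    "enumerate_module_space",
    "instantiate_sequence",
    "extract_fills",
    "sequence_space_stats",
    "validate_fixed_regions",
    "fill_to_index",
    "index_to_fill",
    "read_template",
]

#: Canonical base order used for all lexicographic indexing (A < C < G < T).
BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: KasI recognition context used as the central module separator.
KASI_SITE = "CCATCGGCGCC"

#: The 74-character production template: sixteen random positions in a
#: symmetric 2:3:3 block arrangement around the central KasI site, eight
#: random positions per module.
DEFAULT_TEMPLATE = (
    "TGTGTATAAGTCNNGAGGNNNGAATNNNAACCATCGGCGCCAACANNNCATTCNNNCAGANNTCTACTAGTCAC"
)


class AlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


class DegenerateTemplateError(ValueError):
    """A template contains no random (N) positions."""


class SplitError(ValueError):
    """The restriction site is absent, ambiguous, or overlaps a random position."""


class CapacityError(ValueError):
    """A requested enumeration or materialization exceeds the configured cap."""


class FillError(ValueError):
    """A fill string does not match the module width or alphabet."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fill_to_index(fill: str) -> int:
    """Map a fill over {A,C,G,T} to its lexicographic index in the 4**w space."""
    idx = 0
    for ch in fill:
        try:
            idx = idx * 4 + _BASE_CODE[ch]
        except KeyError:
            raise AlphabetError(f"invalid base {ch!r} in fill {fill!r}") from None
    return idx


def index_to_fill(index: int, width: int) -> str:
    """Inverse of :func:`fill_to_index` for a module of ``width`` random positions."""
    if not 0 <= index < 4**width:
        raise ValueError(f"index {index} out of range for width {width}")
    out = []
    for _ in range(width):
        out.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class LibraryTemplate:
    """A parsed library template.

    Attributes
    ----------
    template
    Upper-case template string over {A,C,G,T,N}.
    random_blocks
        Maximal runs of N as ``(start, length)`` in 5'->3' order.
    restriction_site
        The central separator sequence expected once in the fixed portion.
    """

    template: str
    random_blocks: tuple[tuple[int, int], ...]
    restriction_site: str = KASI_SITE

    @property
    def length(self) -> int:
        return len(self.template)

    @property
    def random_offsets(self) -> tuple[int, ...]:
        return tuple(
            i for start, ln in self.random_blocks for i in range(start, start + ln)
        )

    @property
    def n_random(self) -> int:
        return sum(ln for _, ln in self.random_blocks)

    @property
    def fixed_offsets(self) -> tuple[int, ...]:
        rand = set(self.random_offsets)
        return tuple(i for i in range(self.length) if i not in rand)

    @property
    def block_lengths(self) -> tuple[int, ...]:
        return tuple(ln for _, ln in self.random_blocks)

    def site_occurrences(self) -> list[int]:
        """Start offsets of the restriction site within the template."""
        site, hits, start = self.restriction_site, [], 0
        while True:
            i = self.template.find(site, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1


@dataclass(frozen=True)
class ModuleSpec:
    """One module (half-template) of a split library.

    ``sequence`` is the module's own template string (with N at random
    positions); ``random_offsets`` are module-local.  The module indexes a
    ``4**width`` count space keyed by the fill (the concatenated random
    bases in 5'->3' order).
    """

    module_id: str
    sequence: str
    random_offsets: tuple[int, ...]
    template_offset: int = 0

    @property
    def width(self) -> int:
        return len(self.random_offsets)

    @property
    def space(self) -> int:
        return 4**self.width

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def fixed_offsets(self) -> tuple[int, ...]:
        rand = set(self.random_offsets)
        return tuple(i for i in range(self.length) if i not in rand)

    @property
    def fixed_segments(self) -> tuple[tuple[str, int], ...]:
        """Maximal fixed runs as ``(sequence, offset)`` pairs."""
        segs: list[tuple[str, int]] = []
        run_start = None
        for i, ch in enumerate(self.sequence + "N"):
            if ch != "N" and run_start is None:
                run_start = i
            elif ch == "N" and run_start is not None:
                segs.append((self.sequence[run_start:i], run_start))
                run_start = None
        return tuple(segs)

    def render(self, fill: str) -> str:
        """The module amplicon with random positions replaced by ``fill``."""
        if len(fill) != self.width:
            raise FillError(
                f"module {self.module_id} expects fill of width {self.width}, "
                f"got {len(fill)}"
            )
        seq = list(self.sequence)
        for off, base in zip(self.random_offsets, fill):
            if base not in _BASE_CODE:
                raise FillError(f"invalid base {base!r} in fill {fill!r}")
            seq[off] = base
        return "".join(seq)


def parse_template(
    template_string: str, restriction_site: str = KASI_SITE
) -> LibraryTemplate:
    """Parse a template string into a :class:`LibraryTemplate`.

    The string is case-insensitive and must be over {A,C,G,T,N} with at
    least one N.  Maximal N-runs become the random blocks.
    """
    s = "".join(template_string.split()).upper()
    if not s:
        raise AlphabetError("empty template")
    bad = sorted(set(s) - set("ACGTN"))
    if bad:
        raise AlphabetError(f"invalid template characters: {bad}")
    blocks: list[tuple[int, int]] = []
    i = 0
    while i < len(s):
        if s[i] == "N":
            j = i
            while j < len(s) and s[j] == "N":
                j += 1
            blocks.append((i, j - i))
            i = j
        else:
            i += 1
    if not blocks:
        raise DegenerateTemplateError("template has no random (N) positions")
    return LibraryTemplate(
        template=s, random_blocks=tuple(blocks), restriction_site=restriction_site.upper()
    )


def read_template(path: str | Path, restriction_site: str = KASI_SITE) -> LibraryTemplate:
    """Read a template from plain text or a single-record FASTA file."""
    text = Path(path).read_text().strip()
    if text.startswith(">"):
        lines = text.splitlines()
        seqs = [ln.strip() for ln in lines[1:] if not ln.startswith(">")]
        if any(ln.startswith(">") for ln in lines[1:]):
            raise ValueError(f"{path}: expected a single FASTA record")
        text = "".join(seqs)
    return parse_template(text, restriction_site=restriction_site)


def _split_point(t: LibraryTemplate) -> int:
    """Midpoint of the unique restriction-site occurrence.

    Any cut inside the central fixed run preserves the module partition of
    random positions; the site midpoint is the symmetric, deterministic
    choice.
    """
    hits = t.site_occurrences()
    if not hits:
        raise SplitError(
            f"restriction site {t.restriction_site!r} not found in template"
        )
    if len(hits) > 1:
        raise SplitError(
            f"restriction site {t.restriction_site!r} occurs {len(hits)} times"
        )
    start = hits[0]
    site_span = range(start, start + len(t.restriction_site))
    if any(t.template[i] == "N" for i in site_span):
        raise SplitError("restriction site overlaps a random position")
    return start + len(t.restriction_site) // 2


def split_modules(
    t: LibraryTemplate, split_point: int | None = None
) -> tuple[ModuleSpec, ModuleSpec]:
    """Split a template into module A (5') and module B (3').

    The default split point is the midpoint of the unique restriction-site
    occurrence; pass ``split_point`` to override.  Every template position,
    random or fixed, lands in exactly one module.
    """
    sp = _split_point(t) if split_point is None else split_point
    if not 0 < sp < t.length:
        raise SplitError(f"split point {sp} outside template")
    if t.template[sp - 1] == "N" or t.template[sp] == "N":
        raise SplitError(f"split point {sp} falls inside a random block")

    def module(module_id: str, start: int, stop: int) -> ModuleSpec:
        return ModuleSpec(
            module_id=module_id,
            sequence=t.template[start:stop],
            random_offsets=tuple(
                off - start for off in t.random_offsets if start <= off < stop
            ),
            template_offset=start,
        )

    return module("A", 0, sp), module("B", sp, t.length)


def enumerate_module_space(m: ModuleSpec, cap: int = 12) -> Iterator[str]:
    """Yield every fill of the module space once, lexicographically (A<C<G<T).

    ``cap`` guards against accidentally enumerating the full-template
    space: widths above it raise :class:`CapacityError`.
    """
    if m.width < 1:
        raise ValueError("module has no random positions")
    if m.width > cap:
        raise CapacityError(
            f"module width {m.width} exceeds enumeration cap {cap} "
            f"({4**m.width:,} fills)"
        )
    for tup in itertools.product(BASES, repeat=m.width):
        yield "".join(tup)


def instantiate_sequence(t: LibraryTemplate, fill_a: str, fill_b: str) -> str:
    """Render the full-length sequence for a pair of module fills.

    Random positions 5' of the module split take ``fill_a`` in order, the
    remainder take ``fill_b``.  Deterministic inverse of
    :func:`extract_fills`.
    """
    mod_a, mod_b = split_modules(t)
    if len(fill_a) != mod_a.width or len(fill_b) != mod_b.width:
        raise FillError(
            f"fill widths ({len(fill_a)}, {len(fill_b)}) do not match module "
            f"widths ({mod_a.width}, {mod_b.width})"
        )
    return mod_a.render(fill_a) + mod_b.render(fill_b)


def extract_fills(t: LibraryTemplate, sequence: str) -> tuple[str, str]:
    """Recover the (fill_a, fill_b) pair from a full-length sequence."""
    seq = sequence.upper()
    if len(seq) != t.length:
        raise FillError(
            f"sequence length {len(seq)} does not match template length {t.length}"
        )
    mod_a, mod_b = split_modules(t)
    sp = mod_a.length
    fill_a = "".join(seq[off] for off in mod_a.random_offsets)
    fill_b = "".join(seq[sp + off] for off in mod_b.random_offsets)
    for fill in (fill_a, fill_b):
        bad = set(fill) - set(BASES)
        if bad:
            raise FillError(f"non-ACGT base {sorted(bad)} at a random position")
    return fill_a, fill_b


def sequence_space_stats(
    n_random: int,
    pool_size: float | None = None,
    synthesized: float | None = None,
) -> dict[str, float | int | None]:
    """Combinatorics of a library with ``n_random`` random positions.

    Returns the exact sequence-space size ``4**n_random``, the average
    copies per possible sequence for a physical pool of ``pool_size``
    molecules, and the proportion of the space covered by ``synthesized``
    unique molecules.  With n=16 and a 4.29e12-molecule pool every
    possible sequence is represented ~1000 times; a classic 40-nt random
    region at 1e15 molecules covers only ~8.3e-10 of its space.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    space = 4**n_random
    return {
        "space": space,
        "copies_per_sequence": None if pool_size is None else pool_size / space,
        "sampled_proportion": None if synthesized is None else synthesized / space,
    }


@dataclass
class ValidationReport:
    """Report from :func:`validate_fixed_regions`.

    ``passed`` reflects the hard checks (parseable template, unique
    restriction site, fixed-region GC within bounds).  The
    self-hybridization screen is informational: ``fixed_fixed_pairs``
    lists predicted base pairs whose both partners are fixed positions
    outside the restriction site, under a maximum-base-pair fold of the
    template with every N replaced by A (a non-pairing proxy).
    """

    template_length: int
    n_random: int
    block_lengths: tuple[int, ...]
    module_widths: tuple[int, int] | None
    gc_percent: float
    gc_bounds: tuple[float, float]
    gc_pass: bool
    site_count: int
    site_pass: bool
    fixed_fixed_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.gc_pass and self.site_pass

    def to_rows(self) -> list[tuple[str, str]]:
        return [
            ("template_length", str(self.template_length)),
            ("n_random", str(self.n_random)),
            ("block_lengths", ",".join(map(str, self.block_lengths))),
            (
                "module_widths",
                "NA" if self.module_widths is None else
                ",".join(map(str, self.module_widths)),
            ),
            ("fixed_gc_percent", f"{self.gc_percent:.2f}"),
            ("gc_bounds", f"{self.gc_bounds[0]:g},{self.gc_bounds[1]:g}"),
            ("gc_pass", str(self.gc_pass)),
            ("restriction_site_count", str(self.site_count)),
            ("site_pass", str(self.site_pass)),
            (
                "fixed_fixed_pairs",
                ";".join(f"{i}-{j}" for i, j in self.fixed_fixed_pairs) or "none",
            ),
            ("passed", str(self.passed)),
        ]


def validate_fixed_regions(
    t: LibraryTemplate,
    gc_lo: float = 40.0,
    gc_hi: float = 60.0,
    fold_engine: Callable[[str], "object"] | None = None,
) -> ValidationReport:
    """Check the design rules for a template's fixed scaffold.

    GC content is computed over the concatenated fixed positions only and
    compared against ``[gc_lo, gc_hi]`` (percent).  The self-hybridization
    screen folds the template with N->A and reports base pairs internal to
    the fixed scaffold (both partners fixed, neither inside the
    restriction site); a well-designed scaffold keeps these to a minimum
    so that secondary structure is driven by the random positions.
    """
    fixed = [t.template[i] for i in t.fixed_offsets]
    gc = 100.0 * sum(b in "GC" for b in fixed) / len(fixed) if fixed else float("nan")
    gc_pass = gc_lo <= gc <= gc_hi

    hits = t.site_occurrences()
    site_pass = len(hits) == 1 and not any(
        t.template[i] == "N"
        for h in hits
        for i in range(h, h + len(t.restriction_site))
    )

    module_widths: tuple[int, int] | None
    try:
        mod_a, mod_b = split_modules(t)
        module_widths = (mod_a.width, mod_b.width)
    except SplitError:
        module_widths = None

    if fold_engine is None:
        from .structure_tools import fold_default as fold_engine  # noqa: PLC0415

    proxy = t.template.replace("N", "A")
    db = fold_engine(proxy)
    fixed_set = set(t.fixed_offsets)
    site_span: set[int] = set()
    if hits:
        site_span = set(range(hits[0], hits[0] + len(t.restriction_site)))
    ff_pairs = [
        (i, j)
        for i, j in db.pairs()
        if i in fixed_set and j in fixed_set
        and i not in site_span and j not in site_span
    ]
    return ValidationReport(
        template_length=t.length,
        n_random=t.n_random,
        block_lengths=t.block_lengths,
        module_widths=module_widths,
        gc_percent=gc,
        gc_bounds=(gc_lo, gc_hi),
        gc_pass=gc_pass,
        site_count=len(hits),
        site_pass=site_pass,
        fixed_fixed_pairs=ff_pairs,
    )
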