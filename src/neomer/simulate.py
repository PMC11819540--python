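"""Synthetic single-round selections with planted binders.

No public sequencing data exist for closed-space aptamer selections, so
every downstream stage is validated against simulations with a known
ground truth.  The generative model mirrors the experimental design:

1. Each *naive* replicate draws a full-sequence abundance vector from a
   symmetric Dirichlet over the reduced full space.  The concentration
   parameter is the expected copy number per sequence in the physical
   pool (default 1000, the redundancy the closed design is built
   around), so replicate-to-replicate variation matches Poisson-scale
   pool sampling.
2. A selection multiplies each planted binder's abundance by its
   enrichment factor and renormalizes; everything else rides along
   unchanged.  Target binders are enriched in target conditions,
   counter binders in their counter conditions.
3. Sequencing draws one multinomial read sample per replicate at the
   configured depth, marginalizes molecules to module A and module B
   amplicons (restriction digest), renders each amplicon with optional
   per-base substitution errors, and emits FASTQ (or in-memory read
   arrays).

The full production space (4**16) cannot be materialized as an abundance
vector; simulations run on a width-reduced template (default 4 random
positions per module, 65,536 full sequences) and the screening code path
is identical at any width.  A :class:`TruthManifest` records the planted
binders and the analytic expectations (including the outer-product
dilution of enrichment across shared modules) needed to score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .library_model import (
    DEFAULT_TEMPLATE,
    CapacityError,
    LibraryTemplate,
    ModuleSpec,
    fill_to_index,
    parse_template,
    split_modules,
)
from .module_counting import ModuleCountTable

__all__ = [
    "PlantedBinder",
    "SimulationConfig",
    "TruthManifest",
    "SampleReads",
    "reduce_template",
    "simulate_naive",
    "apply_selection",
    "render_reads",
    "write_fastq",
    "run_simulation",
    "recovery_report",
]

#: Dense abundance vectors above this size are refused.
SPACE_CAP = 4**8


@dataclass(frozen=True)
class PlantedBinder:
    """A sequence with a known selection effect.

    ``binds`` names the condition family the effect applies to: the
    positive target ("target") or a named counter-target condition.
    """

    fill_a: str
    fill_b: str
    factor: float
    binds: str = "target"

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("enrichment factor must be >= 1")


def reduce_template(t: LibraryTemplate, w_a: int, w_b: int) -> LibraryTemplate:
    """Shrink module widths by freezing surplus random positions to A.

    Keeps the first ``w_a`` (module A) and ``w_b`` (module B) random
    positions random; later ones become fixed A. Anchors, site, and split
    are unchanged, so counting code behaves identically at reduced width.
    """
    mod_a, mod_b = split_modules(t)
    if w_a > mod_a.width or w_b > mod_b.width:
        raise ValueError(
            f"cannot widen modules: requested ({w_a}, {w_b}), "
            f"template has ({mod_a.width}, {mod_b.width})"
        )
    keep = set(t.random_offsets[:w_a]) | {
        off + mod_a.length for off in mod_b.random_offsets[:w_b]
    }
    chars = [
        ("N" if i in keep else "A") if ch == "N" else ch
        for i, ch in enumerate(t.template)
    ]
    return parse_template("".join(chars), restriction_site=t.restriction_site)


@dataclass
class SimulationConfig:
    """Study design for one simulated selection experiment.

    Defaults follow the triplicate single-round design: 3 replicates per
    condition, 5e6 reads per module sample (the depth considered
    sufficient for 65,536-sequence module coverage, ~76 reads per module
    sequence), Dirichlet concentration 1000 (copies per sequence in the
    pool), and a 1e-3 per-base substitution error rate typical of
    short-read sequencing.  ``w_a``/``w_b`` default to 4+4 so the full
    space is materializable.
    """

    template: str = DEFAULT_TEMPLATE
    w_a: int = 4
    w_b: int = 4
    replicates: int = 3
    reads_per_sample: int = 5_000_000
    binders: tuple[PlantedBinder, ...] = ()
    concentration: float = 1000.0
    error_rate: float = 1e-3
    counter_conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.reads_per_sample < 0:
            raise ValueError("replicates must be >= 1 and reads >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        self.binders = tuple(self.binders)
        self.counter_conditions = tuple(self.counter_conditions)

    @property
    def library(self) -> LibraryTemplate:
        full = parse_template(self.template)
        mod_a, mod_b = split_modules(full)
        if (self.w_a, self.w_b) == (mod_a.width, mod_b.width):
            return full
        return reduce_template(full, self.w_a, self.w_b)

    @property
    def modules(self) -> tuple[ModuleSpec, ModuleSpec]:
        return split_modules(self.library)

    @property
    def space(self) -> int:
        return 4 ** (self.w_a + self.w_b)

    @property
    def conditions(self) -> tuple[str, ...]:
        return ("target", "naive") + self.counter_conditions

    def binder_index(self, b: PlantedBinder) -> int:
        if len(b.fill_a) != self.w_a or len(b.fill_b) != self.w_b:
            raise ValueError(
                f"binder ({b.fill_a}, {b.fill_b}) outside the "
                f"({self.w_a}, {self.w_b}) module space"
            )
        return fill_to_index(b.fill_a) * 4**self.w_b + fill_to_index(b.fill_b)


def simulate_naive(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-replicate naive abundance draws, shape (replicates, space).

    Rows are independent symmetric Dirichlet(concentration) draws; as the
    concentration grows the pool approaches uniform 1/space.
    """
    if config.space > SPACE_CAP:
        raise CapacityError(
            f"full space {config.space:,} exceeds the dense cap {SPACE_CAP:,}; "
            "reduce module widths for simulation"
        )
    alpha = np.full(config.space, config.concentration)
    return rng.dirichlet(alpha, size=config.replicates)


def apply_selection(
    abundances: np.ndarray,
    binders: Sequence[PlantedBinder],
    config: SimulationConfig,
    condition: str = "target",
) -> np.ndarray:
    """Enrich planted binders of ``condition`` and renormalize.

    Binders bound to other conditions are untouched; with no applicable
    binder this is the identity.
    """
    out = np.array(abundances, dtype=float, copy=True)
    single = out.ndim == 1
    if single:
        out = out[None, :]
    touched = False
    for b in binders:
        if b.binds != condition:
            continue
        out[:, config.binder_index(b)] *= b.factor
        touched = True
    if touched:
        out /= out.sum(axis=1, keepdims=True)
    return out[0] if single else out


@dataclass
class SampleReads:
    """Rendered module reads for one sample (one replicate, one condition)."""

    sample_id: str
    condition: str
    replicate: int
    reads_a: list[str]
    reads_b: list[str]
    joint_counts: np.ndarray


def _render_module_reads(
    marginal_counts: np.ndarray,
    module: ModuleSpec,
    error_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    """Render one read per counted molecule, with substitution errors."""
    total = int(marginal_counts.sum())
    if total == 0:
        return []
    L = module.length
    fills = np.repeat(np.arange(marginal_counts.size), marginal_counts)
    rng.shuffle(fills)

    base_codes = np.frombuffer(module.sequence.encode(), dtype=np.uint8)
    mat = np.tile(base_codes, (total, 1))
    code_of = {b: ord(b) for b in "ACGT"}
    # write fills: digit d of the fill index -> random offset d
    rem = fills.copy()
    for pos in range(module.width - 1, -1, -1):
        digit = rem % 4
        rem //= 4
        mat[:, module.random_offsets[pos]] = np.array(
            [code_of["A"], code_of["C"], code_of["G"], code_of["T"]],
            dtype=np.uint8,
        )[digit]
    if error_rate > 0:
        acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
        step = max(1, 200_000)
        for lo in range(0, total, step):
            block = mat[lo:lo + step]
            hit = rng.random(block.shape) < error_rate
            n_hit = int(hit.sum())
            if n_hit:
                # substitute with a uniformly random *different* base
                cur = block[hit]
                shift = rng.integers(1, 4, size=n_hit)
                cur_idx = np.searchsorted(acgt, cur)
                block[hit] = acgt[(cur_idx + shift) % 4]
    return [bytes(row).decode() for row in mat]


def render_reads(
    abundances: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    condition: str = "na",
    replicate: int = 1,
) -> SampleReads:
    """Sequence one sample: multinomial draw, digest to modules, render.

    Draws ``reads_per_sample`` molecules from the full-sequence abundance
    vector, splits each molecule into its module A and module B amplicons
    (so the two module read sets share one underlying draw), and renders
    reads with per-base substitution errors at ``error_rate``.
    """
    p = np.asarray(abundances, dtype=float)
    if p.ndim != 1 or p.size != config.space:
        raise ValueError("abundances must be a vector over the full space")
    joint = rng.multinomial(config.reads_per_sample, p)
    nB = 4**config.w_b
    marg_a = joint.reshape(4**config.w_a, nB).sum(axis=1)
    marg_b = joint.reshape(4**config.w_a, nB).sum(axis=0)
    mod_a, mod_b = config.modules
    return SampleReads(
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
        reads_a=_render_module_reads(marg_a, mod_a, config.error_rate, rng),
        reads_b=_render_module_reads(marg_b, mod_b, config.error_rate, rng),
        joint_counts=joint,
    )


def write_fastq(reads: Iterable[str], path: str | Path, quality: str = "I") -> None:
    """Write reads as FASTQ with constant base quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")


@dataclass
class TruthManifest:
    """Ground truth for one simulated experiment.

    Carries everything needed to score a screen analytically: the planted
    binders, the expected *outer-product* frequency of every binder under
    each condition (module marginals of the enriched pool, multiplied),
    and the realized per-replicate pre/post frequencies of each binder.
    The expected outer-product fold is deliberately smaller than the raw
    enrichment factor: marginal counting spreads a binder's enrichment
    over every sequence sharing one of its modules.
    """

    seed: int
    config: SimulationConfig
    realized_pre: dict[str, list[float]] = field(default_factory=dict)
    realized_post: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def _expected_joint(self, condition: str) -> np.ndarray:
        space = self.config.space
        q = np.full(space, 1.0 / space)
        for b in self.config.binders:
            if b.binds == condition:
                q[self.config.binder_index(b)] *= b.factor
        return q / q.sum()

    def expected_outer_frequency(self, condition: str) -> "np.ndarray":
        """Expected reconstructed (outer-product) frequency surface."""
        q = self._expected_joint(condition)
        nB = 4**self.config.w_b
        m = q.reshape(4**self.config.w_a, nB)
        return np.outer(m.sum(axis=1), m.sum(axis=0))

    def expected_fold(self, binder: PlantedBinder, condition: str = "target",
                      control: str = "naive") -> float:
        """Analytic outer-product fold of a binder between two conditions."""
        idx_a = fill_to_index(binder.fill_a)
        idx_b = fill_to_index(binder.fill_b)
        num = self.expected_outer_frequency(condition)[idx_a, idx_b]
        den = self.expected_outer_frequency(control)[idx_a, idx_b]
        return float(num / den)

    def target_binders(self) -> list[PlantedBinder]:
        return [b for b in self.config.binders if b.binds == "target"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": {
                **{k: v for k, v in asdict(self.config).items() if k != "binders"},
                "binders": [asdict(b) for b in self.config.binders],
            },
            "realized_pre": self.realized_pre,
            "realized_post": self.realized_post,
            "expected_target_folds": {
                b.fill_a + b.fill_b: self.expected_fold(b)
                for b in self.target_binders()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        binders = tuple(PlantedBinder(**b) for b in cfg.pop("binders"))
        cfg["counter_conditions"] = tuple(cfg.get("counter_conditions", ()))
        config = SimulationConfig(binders=binders, **cfg)
        return cls(
            seed=payload["seed"], config=config,
            realized_pre=payload.get("realized_pre", {}),
            realized_post=payload.get("realized_post", {}),
        )


def run_simulation(
    config: SimulationConfig, seed: int
) -> tuple[dict[str, list[SampleReads]], TruthManifest]:
    """Simulate every condition of the configured design.

    Returns reads grouped by condition (``target``, ``naive``, then any
    counter conditions) and the ground-truth manifest.  All randomness
    derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    truth = TruthManifest(seed=seed, config=config)
    binder_keys = [b.fill_a + b.fill_b for b in config.binders]
    binder_idx = [config.binder_index(b) for b in config.binders]
    for key in binder_keys:
        truth.realized_pre.setdefault(key, [])

    out: dict[str, list[SampleReads]] = {}
    for condition in config.conditions:
        pre = simulate_naive(config, rng)
        post = (
            pre if condition == "naive"
            else apply_selection(pre, config.binders, config, condition)
        )
        truth.realized_post[condition] = {key: [] for key in binder_keys}
        for key, idx in zip(binder_keys, binder_idx):
            if condition == "target":
                truth.realized_pre[key].extend(float(x) for x in pre[:, idx])
            truth.realized_post[condition][key].extend(
                float(x) for x in post[:, idx]
            )
        out[condition] = [
            render_reads(
                post[r], config, rng,
                sample_id=f"{condition}_{r + 1}",
                condition=condition, replicate=r + 1,
            )
            for r in range(config.replicates)
        ]
    return out, truth


def count_sample(
    sample: SampleReads, config: SimulationConfig, max_mismatch: int = 1
) -> tuple[ModuleCountTable, ModuleCountTable]:
    """Count one simulated sample's module reads (convenience wrapper)."""
    from .module_counting import count_modules  # noqa: PLC0415

    mod_a, mod_b = config.modules
    return (
        count_modules(sample.reads_a, mod_a, max_mismatch=max_mismatch,
                      sample_id=sample.sample_id),
        count_modules(sample.reads_b, mod_b, max_mismatch=max_mismatch,
                      sample_id=sample.sample_id),
    )


def recovery_report(
    screen: Sequence["object"],
    truth: TruthManifest,
    top: int = 100,
) -> dict[str, object]:
    """Score a ranked screen against the planted truth.

    Reports each target binder's rank by z (1-based; None if absent from
    the ranked list), the fraction inside the ``top`` first ranks, and
    the relative error of each estimated target/naive fold against the
    analytic outer-product expectation (requires fold values attached to
    the screen results under the ``"naive"`` key).
    """
    binders = truth.target_binders()
    if not binders:
        return {"n_binders": 0, "ranks": {}, "fraction_in_top": None,
                "fold_relative_errors": {}, "note": "no planted target binders"}
    rank_of = {
        r.fill_a + r.fill_b: i + 1 for i, r in enumerate(screen)
    }
    ranks = {b.fill_a + b.fill_b: rank_of.get(b.fill_a + b.fill_b)
             for b in binders}
    in_top = sum(1 for r in ranks.values() if r is not None and r <= top)
    fold_err: dict[str, float] = {}
    by_key = {r.fill_a + r.fill_b: r for r in screen}
    for b in binders:
        key = b.fill_a + b.fill_b
        res = by_key.get(key)
        if res is None or "naive" not in getattr(res, "folds", {}):
            continue
        expected = truth.expected_fold(b)
        fold_err[key] = abs(res.folds["naive"] - expected) / expected
    return {
        "n_binders": len(binders),
        "ranks": ranks,
        "fraction_in_top": in_top / len(binders),
        "fold_relative_errors": fold_err,
    }
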