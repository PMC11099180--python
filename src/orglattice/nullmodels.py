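"""Randomized null models and the virtual subsampling experiment.

The hierarchy statistics (closure size, introducing sets, additional
organizations) are only meaningful against a chance baseline.  Three
standard binary-matrix randomizations are provided:

``bernoulli_frequency``
    each artificial sample includes each taxon independently with the
    taxon's empirical occurrence frequency (margins preserved in
    expectation only);
``column_shuffle``
    each taxon's presence column is permuted across samples — per-taxon
    prevalence preserved exactly, all co-occurrence destroyed (the
    default: the most conservative structure destruction);
``curveball_swap``
    margin-preserving checkerboard randomization (curveball trades), so
    both sample richness and taxon prevalence are kept exactly.

The subsampling experiment asks how many additional organizations are
*derivable* when only part of the organization family has been
observed: organizations are inserted one by one in random order and
after each insertion the sets that are simultaneously an intersection
of >=2 and a union of >=2 inserted sets (and not themselves inserted)
are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .concepts import _additional_masks, _closure_and_additional
from .errors import ValidationError
from .io import MeasurementTable, SampleRecord
from .taxa import TaxaSet

__all__ = [
    "NullModelConfig",
    "NullSummary",
    "SubsampleCurve",
    "generate_artificial_tables",
    "null_summary",
    "subsample_curve",
]

SCHEMES = ("bernoulli_frequency", "column_shuffle", "curveball_swap")


@dataclass(frozen=True)
class NullModelConfig:
    scheme: str = "column_shuffle"
    n_tables: int = 100
    n_samples_per_table: int | None = None  # None -> template's count
    seed: int = 0
    curveball_sweeps: int = 5  # trade sweeps per sample for curveball

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValidationError(
                f"unknown scheme {self.scheme!r}; choose from {SCHEMES}"
            )
        if self.n_tables < 1:
            raise ValidationError("n_tables must be >= 1")
        if self.n_samples_per_table is not None and self.n_samples_per_table < 1:
            raise ValidationError("n_samples_per_table must be >= 1")


def _table_from_bool(template: MeasurementTable, mat: np.ndarray, tag: str):
    universe = template.universe
    samples = []
    for i, row in enumerate(mat):
        mask = 0
        for j in np.flatnonzero(row):
            mask |= 1 << int(j)
        samples.append(
            SampleRecord(f"{tag}:{i}", tag, i, TaxaSet(universe, mask))
        )
    return MeasurementTable(universe, samples)


def _curveball(mat: np.ndarray, rng: np.random.Generator, sweeps: int):
    """In-place curveball trades on a samples-by-taxa boolean matrix."""
    rows = [set(np.flatnonzero(r)) for r in mat]
    n = len(rows)
    for _ in range(sweeps * n):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = rows[i], rows[j]
        a_only = list(a - b)
        b_only = list(b - a)
        k = min(len(a_only), len(b_only))
        if k == 0:
            continue
        pool = a_only + b_only
        rng.shuffle(pool)
        new_a_only = set(pool[: len(a_only)])
        shared = a & b
        rows[i] = shared | new_a_only
        rows[j] = shared | (set(pool) - new_a_only)
    out = np.zeros_like(mat)
    for i, r in enumerate(rows):
        out[i, list(r)] = True
    return out


def generate_artificial_tables(
    template: MeasurementTable, cfg: NullModelConfig
) -> list[MeasurementTable]:
    """Draw ``cfg.n_tables`` randomized tables from *template*.

    Margin-preserving schemes (column_shuffle, curveball_swap) keep the
    template's sample count; requesting a different
    ``n_samples_per_table`` with them is a validation error.  Fully
    reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_template = template.n_samples
    m = cfg.n_samples_per_table or n_template
    mat = np.array(
        [
            [bool(rec.taxa.mask >> j & 1) for j in range(template.universe.size)]
            for rec in template.samples
        ],
        dtype=bool,
    )
    out = []
    for t in range(cfg.n_tables):
        if cfg.scheme == "bernoulli_frequency":
            p = mat.mean(axis=0)
            art = rng.random((m, mat.shape[1])) < p
        elif cfg.scheme == "column_shuffle":
            if m != n_template:
                raise ValidationError(
                    "column_shuffle preserves per-taxon prevalence and so "
                    "requires n_samples_per_table == template sample count"
                )
            art = np.stack(
                [rng.permutation(mat[:, j]) for j in range(mat.shape[1])],
                axis=1,
            )
        else:  # curveball_swap
            if m != n_template:
                raise ValidationError(
                    "curveball_swap preserves both margins and so requires "
                    "n_samples_per_table == template sample count"
                )
            art = _curveball(mat, rng, cfg.curveball_sweeps)
        out.append(_table_from_bool(template, art, f"art{t}"))
    return out


@dataclass(frozen=True)
class NullSummary:
    """Per-table hierarchy statistics with mean and sample (n-1) sd."""

    closure_sizes: tuple[int, ...]
    n_introducing: tuple[int, ...]
    n_additional: tuple[int, ...]

    def _stats(self, xs: Sequence[int]) -> tuple[float, float]:
        arr = np.asarray(xs, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return float(arr.mean()), sd

    @property
    def closure_mean_sd(self) -> tuple[float, float]:
        return self._stats(self.closure_sizes)

    @property
    def introducing_mean_sd(self) -> tuple[float, float]:
        return self._stats(self.n_introducing)

    @property
    def additional_mean_sd(self) -> tuple[float, float]:
        return self._stats(self.n_additional)

    def to_jsonable(self) -> dict:
        cm, cs = self.closure_mean_sd
        im, isd = self.introducing_mean_sd
        am, asd = self.additional_mean_sd
        return {
            "type": "null_summary",
            "columns": ["table", "closure_size", "n_introducing", "n_additional"],
            "rows": [
                [i, c, ni, na]
                for i, (c, ni, na) in enumerate(
                    zip(self.closure_sizes, self.n_introducing, self.n_additional)
                )
            ],
            "closure_mean": cm,
            "closure_sd": cs,
            "introducing_mean": im,
            "introducing_sd": isd,
            "additional_mean": am,
            "additional_sd": asd,
        }


def _table_stats(table: MeasurementTable) -> tuple[int, int, int]:
    masks = list(dict.fromkeys(s.mask for s in table.taxa_sets()))
    closure_size, additional = _closure_and_additional(masks)
    observed = 0
    for m in masks:
        observed |= m
    # distinct attribute concepts: intersection of samples containing taxon
    concepts = set()
    for i in range(table.universe.size):
        if not observed >> i & 1:
            continue
        inter = ~0
        for m in (rec.taxa.mask for rec in table.samples):
            if m >> i & 1:
                inter &= m
        concepts.add(inter)
    return closure_size, len(concepts), len(additional)


def null_summary(tables: Sequence[MeasurementTable]) -> NullSummary:
    """Closure size, introducing-set count and additional-organization
    count per table, with mean +/- sd across tables."""
    if not tables:
        raise ValidationError("at least one table is required")
    stats = [_table_stats(t) for t in tables]
    return NullSummary(
        tuple(s[0] for s in stats),
        tuple(s[1] for s in stats),
        tuple(s[2] for s in stats),
    )


@dataclass(frozen=True)
class SubsampleCurve:
    """min/mean/max derivable additional organizations per insertion step."""

    steps: tuple[int, ...]  # 1..K inserted organizations
    mins: tuple[int, ...]
    means: tuple[float, ...]
    maxs: tuple[int, ...]
    n_repeats: int = 1
    seed: int = 0

    def to_jsonable(self) -> dict:
        return {
            "type": "subsample_curve",
            "columns": ["step", "min", "mean", "max"],
            "rows": [
                [k, lo, mu, hi]
                for k, lo, mu, hi in zip(self.steps, self.mins, self.means, self.maxs)
            ],
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }


def subsample_curve(
    organizations: Sequence[TaxaSet], n_repeats: int, seed: int = 0
) -> SubsampleCurve:
    """Random-insertion experiment over a family of organizations.

    Per repeat, a uniform random insertion order without replacement;
    after each insertion the number of sets that are simultaneously an
    intersection of >=2 and a union of >=2 currently-inserted sets (and
    not themselves inserted) is recorded.  The final step is
    deterministic and equals the additional-organization count of the
    full family.
    """
    orgs = list(organizations)
    if not orgs:
        raise ValidationError("at least one organization is required")
    if len({o.mask for o in orgs}) != len(orgs):
        raise ValidationError("organizations must be distinct")
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(orgs)
    masks = [o.mask for o in orgs]
    counts = np.zeros((n_repeats, k), dtype=int)
    for r in range(n_repeats):
        order = rng.permutation(k)
        inserted: list[int] = []
        for step, idx in enumerate(order):
            inserted.append(masks[idx])
            counts[r, step] = len(_additional_masks(inserted))
    return SubsampleCurve(
        steps=tuple(range(1, k + 1)),
        mins=tuple(int(x) for x in counts.min(axis=0)),
        means=tuple(float(x) for x in counts.mean(axis=0)),
        maxs=tuple(int(x) for x in counts.max(axis=0)),
        n_repeats=n_repeats,
        seed=seed,
    )
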