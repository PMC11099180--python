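"""Synthetic community tables with planted hierarchical structure.

Real groundwater community time series show three ingredients the
lattice method feeds on: a small always-present core, well-specific
taxa blocks (each sampling site favours some taxa), and a tail of
rarer taxa that fluctuate over time with occupancy falling off with
abundance rank.  :func:`make_planted_table` generates exactly that,
with the planted truth returned alongside so recovery can be asserted.

:func:`make_additional_org_instance` builds the minimal motif whose
closure contains a known additional organization: measurements
``base+{p}``, ``base+{q}``, ``base+{p,q,x}``, ``base+{p,q,y}`` make
``base+{p,q}`` an intersection of two and a union of two measurements
without being measured itself.

The ``hainich_like`` preset mirrors the shape of a four-well, 30-month
phylum-level survey: 50 taxa, 4 wells, 30 time points, a 3-taxon global
core, 2 planted core taxa per well and rank-decaying occupancy for the
fluctuating tail (mean richness around 23 taxa per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .io import MeasurementTable, SampleRecord
from .taxa import TaxaSet, TaxaUniverse

__all__ = [
    "PlantedDesign",
    "PlantedTruth",
    "hainich_like",
    "make_planted_table",
    "make_additional_org_instance",
]


@dataclass(frozen=True)
class PlantedDesign:
    """Recipe for a planted-structure community table."""

    n_taxa: int
    wells: tuple[str, ...]
    n_times: int
    global_core: tuple[int, ...]
    per_well_core: Mapping[str, tuple[int, ...]]
    fluctuating_p: Mapping[int, float]
    seed: int = 0
    missing: tuple[tuple[str, int], ...] = ()  # (well, time) pairs to drop
    nestedness: float = 0.95  # weight of the shared per-sample occupancy level
    well_core_leak: float = 0.0  # chance a well-core taxon shows in a foreign well

    def __post_init__(self):
        core = set(self.global_core)
        for w in self.wells:
            if w not in self.per_well_core:
                raise ValidationError(f"no core block for well {w!r}")
        wcores = [set(self.per_well_core[w]) for w in self.wells]
        fluct = set(self.fluctuating_p)
        all_idx = core | fluct | set().union(*wcores) if wcores else core | fluct
        if any(i < 0 or i >= self.n_taxa for i in all_idx):
            raise ValidationError("taxon index out of range for n_taxa")
        for i, wc in enumerate(wcores):
            if wc & core:
                raise ValidationError("well cores must be disjoint from global core")
            for wc2 in wcores[i + 1 :]:
                if wc & wc2:
                    raise ValidationError("well cores must be pairwise disjoint")
        if fluct & core or any(fluct & wc for wc in wcores):
            raise ValidationError(
                "fluctuating taxa must be disjoint from the planted cores"
            )
        if any(not 0 <= p <= 1 for p in self.fluctuating_p.values()):
            raise ValidationError("fluctuation probabilities must be in [0, 1]")
        if not 0 <= self.nestedness <= 1:
            raise ValidationError("nestedness must be in [0, 1]")
        if not 0 <= self.well_core_leak <= 1:
            raise ValidationError("well_core_leak must be in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth carried alongside a planted table."""

    global_core: TaxaSet
    well_concepts: dict[str, TaxaSet] = field(default_factory=dict)


def hainich_like(seed: int = 0) -> PlantedDesign:
    """Default design: 50 taxa, wells H41/H43/H51/H52, 30 months."""
    wells = ("H41", "H43", "H51", "H52")
    global_core = (0, 1, 2)
    per_well_core = {
        "H41": (3, 4),
        "H43": (5, 6),
        "H51": (7, 8),
        "H52": (9, 10),
    }
    fluct = {
        i: float(max(0.02, 0.95 * np.exp(-0.035 * (i - 11)))) for i in range(11, 50)
    }
    return PlantedDesign(
        n_taxa=50,
        wells=wells,
        n_times=30,
        global_core=global_core,
        per_well_core=per_well_core,
        fluctuating_p=fluct,
        seed=seed,
        nestedness=0.95,
        well_core_leak=0.4,
    )


def make_planted_table(
    design: PlantedDesign,
) -> tuple[MeasurementTable, PlantedTruth]:
    """Draw a table from *design*: each sample's taxa = global core +
    its well's core + Bernoulli draws from the fluctuating pool.

    Each fluctuating taxon i keeps its marginal presence probability
    ``fluctuating_p[i]`` exactly, but the draws within one sample share
    a common occupancy level with weight ``design.nestedness`` (taxon i
    is present iff V < p_i where V is the sample's shared uniform level
    with probability *nestedness*, else a fresh uniform).  At
    nestedness 1 samples are perfectly nested along the occupancy
    ranking, at 0 the draws are independent; intermediate values mimic
    the partially nested hierarchy of real presence/absence series.
    Reproducible under ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    labels = [f"t{i}" for i in range(design.n_taxa)]
    universe = TaxaUniverse(labels)
    g_mask = sum(1 << i for i in design.global_core)
    missing = set(design.missing)
    fl_idx = sorted(design.fluctuating_p)
    fl_p = np.array([design.fluctuating_p[i] for i in fl_idx])
    foreign = {
        w: sorted(
            set().union(
                *(design.per_well_core[v] for v in design.wells if v != w)
            )
        )
        for w in design.wells
    }
    samples = []
    for well in design.wells:
        w_mask = g_mask | sum(1 << i for i in design.per_well_core[well])
        for t in range(design.n_times):
            leak = rng.random(len(foreign[well])) < design.well_core_leak
            level = rng.random()
            fresh = rng.random(len(fl_idx))
            own = rng.random(len(fl_idx)) >= design.nestedness
            v = np.where(own, fresh, level)
            if (well, t) in missing:
                continue
            mask = w_mask
            for j in np.flatnonzero(leak):
                mask |= 1 << foreign[well][int(j)]
            for j in np.flatnonzero(v < fl_p):
                mask |= 1 << fl_idx[int(j)]
            samples.append(
                SampleRecord(f"{well}:{t}", well, t, TaxaSet(universe, mask))
            )
    truth = PlantedTruth(
        global_core=TaxaSet(universe, g_mask),
        well_concepts={
            w: TaxaSet(
                universe, g_mask | sum(1 << i for i in design.per_well_core[w])
            )
            for w in design.wells
        },
    )
    return MeasurementTable(universe, samples), truth


def make_additional_org_instance(
    k: int, seed: int = 0, n_base: int = 3
) -> tuple[MeasurementTable, list[TaxaSet]]:
    """k disjoint four-measurement motifs, each planting exactly one
    additional organization (``base + {p, q}``); returns the table and
    the expected additional organizations in deterministic order."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    block = n_base + 4  # base taxa + p, q, x, y
    universe = TaxaUniverse([f"t{i}" for i in range(k * block)])
    samples = []
    expected = []
    for c in range(k):
        off = c * block
        base = sum(1 << (off + i) for i in range(n_base))
        p, q, x, y = (1 << (off + n_base + j) for j in range(4))
        motif = [base | p, base | q, base | p | q | x, base | p | q | y]
        for t, m in enumerate(motif):
            samples.append(
                SampleRecord(
                    f"motif{c}:{t}", f"motif{c}", t, TaxaSet(universe, m)
                )
            )
        expected.append(TaxaSet(universe, base | p | q))
    # seed reserved for future noise injection; the motif itself is exact
    return MeasurementTable(universe, samples), expected
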