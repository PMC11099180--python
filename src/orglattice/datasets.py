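"""Packaged example networks and the deposited groundwater matrix hook."""

from __future__ import annotations

import os
from importlib import resources

from .cot import ReactionNetwork
from .errors import InputOutputError
from .io import MeasurementTable, parse_reaction_network, read_measurement_matrix

__all__ = [
    "example_network",
    "theorem1_network",
    "theorem2_network",
    "fig1_network",
    "load_deposited_matrix",
]

_NETWORKS = (
    "theorem1",
    "theorem2",
    "fig1_as_listed",
    "fig1_as_described",
)


def example_network(name: str) -> ReactionNetwork:
    """Load a packaged ``.rxn`` example network by name."""
    if name not in _NETWORKS:
        raise InputOutputError(
            f"unknown example network {name!r}; choose from {_NETWORKS}"
        )
    text = resources.files("orglattice.data").joinpath(f"{name}.rxn").read_text()
    return parse_reaction_network(text)


def theorem1_network() -> ReactionNetwork:
    """Three-species replicator system with 7 organizations; its
    organization {A,C} ∩ {B,C} = {C} is closed but not self-maintaining."""
    return example_network("theorem1")


def theorem2_network() -> ReactionNetwork:
    """Three-species replicator system with 4 organizations; its
    organization union {A} ∪ {B} is self-maintaining but not closed."""
    return example_network("theorem2")


def fig1_network(variant: str = "as_listed") -> ReactionNetwork:
    """The five-taxon illustrative network, in either published variant
    (``as_listed`` or ``as_described``; they differ in the helper of d)."""
    return example_network(f"fig1_{variant}")


def load_deposited_matrix(path: str | os.PathLike) -> MeasurementTable:
    """Load the deposited Hainich groundwater phylum matrix (114 samples
    over 50 phyla; wells H41/H43/H51/H52, monthly time points).

    The matrix is not redistributed with this package; obtain it from
    the study's data repository and pass its local path (TSV/CSV, taxa
    in rows, sample columns labelled ``WELL:TIME``).
    """
    if not os.path.exists(path):
        raise InputOutputError(
            f"deposited matrix not found at {path}; download it from the "
            "study's data repository (it is not packaged here)"
        )
    return read_measurement_matrix(path)
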