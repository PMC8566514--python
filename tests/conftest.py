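"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import pytest

from halomet import annotate, chem, io


@pytest.fixture(scope="session")
def catalog():
    return io.load_catalog()


@pytest.fixture(scope="session")
def catalog_by_name(catalog):
    return {r.name: r for r in catalog}


@pytest.fixture(scope="session")
def pathway_edges():
    return annotate.load_pathway_edges()


@pytest.fixture(scope="session")
def suspects():
    return io.suspects_from_catalog()


def oracle_isotope_pattern(formula: str, bin_width: float = 0.01):
    """Brute-force isotopologue oracle: enumerate every per-atom isotope
    assignment of the [M+H]+ ion, accumulate probabilities, merge species
    closer than ``bin_width`` and normalize the base to 100.

    Exponential in atom count — usable only for small formulas — and
    deliberately independent of the convolution implementation.
    """
    counts = chem.parse_formula(formula).as_dict()
    counts["H"] = counts.get("H", 0) + 1  # protonation
    atoms = [el for el, n in sorted(counts.items()) for _ in range(n)]
    species: dict[float, float] = {}
    for choice in itertools.product(*(chem.ISOTOPES[el] for el in atoms)):
        mass = sum(m for m, _ in choice)
        prob = math.prod(a for _, a in choice)
        species[mass] = species.get(mass, 0.0) + prob
    merged: list[tuple[float, float]] = []
    group_mass = group_prob = 0.0
    last = None
    for mass in sorted(species):
        prob = species[mass]
        if last is not None and mass - last > bin_width:
            merged.append((group_mass / group_prob, group_prob))
            group_mass = group_prob = 0.0
        group_mass += mass * prob
        group_prob += prob
        last = mass
    merged.append((group_mass / group_prob, group_prob))
    base = max(p for _, p in merged)
    return [(m - chem.ELECTRON_MASS, p / base * 100.0) for m, p in merged]
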