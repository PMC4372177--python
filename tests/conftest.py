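"""Shared fixtures: hand-built pedigrees covering the classic relationship
classes, and a small deterministic synthetic cohort."""

from __future__ import annotations

import pytest

from kinewas.pedigree import Individual, Pedigree
from kinewas.simulate import SimulationConfig, simulate_cohort


def _ind(iid, father=None, mother=None, sex="unknown", fam="F1"):
    return Individual(id=iid, father_id=father, mother_id=mother, sex=sex,
                      family_id=fam)


@pytest.fixture(scope="session")
def trio() -> Pedigree:
    return Pedigree([
        _ind("F", sex="male"),
        _ind("M", sex="female"),
        _ind("C", father="F", mother="M"),
    ])


@pytest.fixture(scope="session")
def extended_pedigree() -> Pedigree:
    """Four generations with every unambiguous outbred relationship class.

    Generation 0: founder couple A x B.
    Generation 1: their children C, D (siblings), married to founders S1, S2.
    Generation 2: C's children FF, G; D's child H  (FF-H first cousins).
    Generation 3: FF's child II (A-II great-grandparent, D-II grand-avuncular,
    H-II first cousins once removed); G's child J (II-J also first cousins);
    H's child K (II-K second cousins).
    """
    members = [
        _ind("A", sex="male"), _ind("B", sex="female"),
        _ind("S1", sex="female"), _ind("S2", sex="male"),
        _ind("C", "A", "B", "male"), _ind("D", "A", "B", "female"),
        _ind("S3", sex="female"), _ind("S4", sex="female"), _ind("S5", sex="male"),
        _ind("FF", "C", "S1", "male"), _ind("G", "C", "S1", "male"),
        _ind("H", "S2", "D", "female"),
        _ind("II", "FF", "S3", "male"),
        _ind("J", "G", "S4", "female"),
        _ind("K", "S5", "H", "male"),
    ]
    return Pedigree(members)


@pytest.fixture(scope="session")
def half_pedigree() -> Pedigree:
    """Half relationships: one shared parent only.

    X has children P (with M1) and Q (with M2): half siblings. P's child R is
    Q's half nephew: half avuncular.
    """
    return Pedigree([
        _ind("X", sex="male"), _ind("M1", sex="female"), _ind("M2", sex="female"),
        _ind("P", "X", "M1", "male"), _ind("Q", "X", "M2", "female"),
        _ind("SP", sex="female"),
        _ind("R", "P", "SP", "male"),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic compact cohort: 2 families, 120 probes, 1 planted cluster."""
    cfg = SimulationConfig(
        n_families=2, generations=3, n_probes=120, n_age_probes=20,
        n_clustered_regions=1, n_mets_probes=2, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default synthetic scenario (7 families, 2,000 probes)."""
    return simulate_cohort(SimulationConfig(seed=11))
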