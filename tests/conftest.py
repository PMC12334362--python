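"""Shared fixture webs, built programmatically."""

import pytest

from webstab import DietSpec, FoodWeb, FunctionalGroup


def make_web(groups, diet_entries, mode="preference", **kw):
    return FoodWeb(
        groups=tuple(groups),
        diet=DietSpec(mode=mode, entries=dict(diet_entries)),
        **kw,
    )


@pytest.fixture
def toy3():
    """Producer P, consumer A eating P and detritus D with equal preference.

    F*_A = 1·2/0.25 = 8; biomass-weighted shares: P 10/(10+50) = 1/6,
    D 5/6 → flows (P→A, D→A) = (4/3, 20/3); m_P = 5 − 0.1333 = 4.8667,
    m_A = 1.
    """
    return make_web(
        [
            FunctionalGroup("D", "detritus", 50.0),
            FunctionalGroup("P", "producer", 10.0, pb=5.0),
            FunctionalGroup("A", "consumer", 2.0, pb=1.0, efficiency=0.25),
        ],
        {("P", "A"): 1.0, ("D", "A"): 1.0},
    )


@pytest.fixture
def pred_prey():
    """Two living groups (A eats P), detritus present but unconsumed."""
    return make_web(
        [
            FunctionalGroup("D", "detritus", 50.0),
            FunctionalGroup("P", "producer", 10.0, pb=2.0),
            FunctionalGroup("A", "consumer", 2.0, pb=1.0, efficiency=0.25),
        ],
        {("P", "A"): 1.0},
    )


@pytest.fixture
def omnivory():
    """Three-link omnivorous feedback: O eats both H and H's prey P, and H
    also feeds on detritus (coupling the pool into the web)."""
    return make_web(
        [
            FunctionalGroup("D", "detritus", 80.0),
            FunctionalGroup("P", "producer", 40.0, pb=10.0),
            FunctionalGroup("H", "consumer", 8.0, pb=4.0, efficiency=0.2),
            FunctionalGroup("O", "consumer", 1.5, pb=1.0, efficiency=0.25),
        ],
        {
            ("P", "H"): 1.0,
            ("D", "H"): 0.5,
            ("P", "O"): 0.6,
            ("H", "O"): 1.0,
        },
    )
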