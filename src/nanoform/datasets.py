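"""Packaged reference dataset: the 5-FU PLGA–lecithin nanoparticle study.

A 3-factor Box–Behnken screen of polymer–lipid hybrid nanoparticles (PLNs)
loaded with 5-fluorouracil: PLGA and lecithin amounts plus poloxamer 188
surfactant level, with mean particle size (nm) and entrapment efficiency
(%) measured over 15 runs (12 edge runs, 3 centre replicates).  Also ships
the desirability goals used to pick the optimized formulation and the three
ranked software solutions, so the full fit → optimize pipeline can be
exercised and cross-checked without any external files.
"""

from __future__ import annotations

import numpy as np

from .desirability import Goal
from .doe import DesignTable, FactorSpec

__all__ = [
    "pln_factors",
    "pln_design",
    "pln_goals",
    "pln_reference_solutions",
]

_FACTORS = (
    FactorSpec("PLGA", "mg in 100 mL", 33.34, 66.67, 100.0),
    FactorSpec("lecithin", "mg in 100 mL", 66.67, 133.34, 200.0),
    FactorSpec("poloxamer", "% w/v", 0.50, 1.00, 1.50),
)

# run label, coded (X1, X2, X3), particle size ± sd (nm), EE ± sd (%)
_RUNS = (
    ("PLNs-01", (-1, -1, 0), 153.0, 0.50, 59.1, 0.15),
    ("PLNs-02", (1, -1, 0), 155.0, 1.00, 71.0, 0.58),
    ("PLNs-03", (-1, 1, 0), 172.0, 0.76, 61.0, 0.20),
    ("PLNs-04", (1, 1, 0), 210.0, 1.53, 65.5, 0.75),
    ("PLNs-05", (-1, 0, -1), 154.0, 1.00, 58.7, 0.61),
    ("PLNs-06", (1, 0, -1), 152.0, 0.58, 67.5, 1.00),
    ("PLNs-07", (-1, 0, 1), 140.0, 1.00, 60.0, 0.55),
    ("PLNs-08", (1, 0, 1), 159.0, 1.00, 69.3, 1.15),
    ("PLNs-09", (0, -1, -1), 140.0, 0.58, 74.2, 0.20),
    ("PLNs-10", (0, 1, -1), 191.0, 1.00, 72.1, 0.51),
    ("PLNs-11", (0, -1, 1), 139.0, 0.58, 75.6, 0.25),
    ("PLNs-12", (0, 1, 1), 163.0, 1.53, 72.0, 0.61),
    ("PLNs-13", (0, 0, 0), 150.0, 0.58, 73.0, 0.25),
    ("PLNs-14", (0, 0, 0), 151.0, 1.00, 72.7, 0.20),
    ("PLNs-15", (0, 0, 0), 149.0, 0.58, 73.4, 0.25),
)

# (PLGA mg, lecithin mg, poloxamer % w/v), predicted size nm, predicted EE %
_SOLUTIONS = (
    {"settings": (72.1, 86.8, 1.5), "particle_size": 139.089, "ee": 75.6},
    {"settings": (67.5, 69.9, 1.5), "particle_size": 141.145, "ee": 75.6002,
     "selected": True},
    {"settings": (70.9, 78.6, 1.4), "particle_size": 141.817, "ee": 75.6},
)


def pln_factors() -> list[FactorSpec]:
    """The three formulation factors with their low/centre/high levels."""
    return list(_FACTORS)


def pln_design() -> DesignTable:
    """The 15-run design with measured size and EE responses."""
    coded = np.array([r[1] for r in _RUNS], dtype=float)
    return DesignTable.from_records(
        pln_factors(),
        coded,
        responses={
            "particle_size": [r[2] for r in _RUNS],
            "ee": [r[4] for r in _RUNS],
        },
        response_sds={
            "particle_size": [r[3] for r in _RUNS],
            "ee": [r[5] for r in _RUNS],
        },
        run_ids=[r[0] for r in _RUNS],
    )


def pln_goals() -> list[Goal]:
    """The desirability goals of the optimization study.

    Factors are held within their studied ranges (importance 3); particle
    size is minimized over its observed 139–210 nm span (importance 1) and
    EE maximized over 58.7–75.6 % (importance 5).
    """
    return [
        Goal("PLGA", "in_range", 33.3, 100.0, importance=3),
        Goal("lecithin", "in_range", 66.7, 200.0, importance=3),
        Goal("poloxamer", "in_range", 0.5, 1.5, importance=3),
        Goal("particle_size", "minimize", 139.0, 210.0, weight=1.0, importance=1),
        Goal("ee", "maximize", 58.7, 75.6, weight=1.0, importance=5),
    ]


def pln_reference_solutions() -> list[dict]:
    """The three ranked optimizer solutions reported for this study."""
    return [dict(s) for s in _SOLUTIONS]
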