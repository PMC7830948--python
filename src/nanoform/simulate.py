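"""Synthetic data generators mirroring the structure of the real inputs.

Three generators cover the three data streams of the pipeline:

* quadratic response surfaces over a 3-factor Box–Behnken design with
  additive Gaussian response noise (the structure behind a measured run
  table);
* first-order dissolution release sampled with explicit
  withdraw-and-replace bookkeeping and multiplicative measurement noise;
* grouped qPCR Ct values with a housekeeping reference gene and per-group
  log2 expression shifts.

Every generator is deterministic for a fixed seed and emits the exact
containers the analysis functions ingest, so parameter-recovery tests can
run the full pipeline end to end.  The noise models are deliberately
simple — i.i.d. Gaussian on responses and Ct values, constant-CV on
concentrations — matching mean ± SD style reporting; real instruments add
structure (drift, heteroscedasticity) these generators do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doe import DesignTable, FactorSpec, generate_bbd
from .metrics import ReleaseExperiment
from .qpcr import CtTable

__all__ = [
    "SurfaceSpec",
    "ReleaseSpec",
    "simulate_design_responses",
    "simulate_release",
    "simulate_ct",
]


@dataclass
class SurfaceSpec:
    """True quadratic surfaces and noise levels for design simulation.

    ``true_coefficients`` maps each response name to its 10 coefficients
    (intercept, 3 linear, 3 interaction, 3 pure quadratic — coded scale);
    ``noise_sd`` maps response names to additive Gaussian SDs in response
    units (0 gives noiseless data).
    """

    factors: list[FactorSpec]
    true_coefficients: Mapping[str, Sequence[float]]
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, coefs in self.true_coefficients.items():
            if len(coefs) != 10:
                raise ValueError(f"response {name!r}: need 10 coefficients, got {len(coefs)}")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"response {name!r}: noise_sd must be >= 0")


def simulate_design_responses(spec: SurfaceSpec, center_replicates: int = 3) -> DesignTable:
    """Generate a BBD and measure each true surface with Gaussian noise."""
    from .rsm import quadratic_terms  # local import avoids a module cycle

    design = generate_bbd(spec.factors, center_replicates)
    rng = np.random.default_rng(spec.seed)
    X = quadratic_terms(design.coded_matrix())
    data = design.data.copy()
    for name, coefs in spec.true_coefficients.items():
        y = X @ np.asarray(coefs, dtype=float)
        sd = float(spec.noise_sd.get(name, 0.0))
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=len(y))
        data[name] = y
    return DesignTable(factors=list(design.factors), data=data)


@dataclass
class ReleaseSpec:
    """First-order release signal with withdraw-and-replace sampling.

    The true released mass follows
    ``dose * plateau_fraction * (1 - exp(-rate_constant * t))``; at each
    sampling time ``sample_volume`` mL is withdrawn (concentration
    measured, with relative noise ``noise_cv``) and replaced with fresh
    medium, depleting the vessel exactly as in a real dissolution run.
    """

    dose: float = 33.3  # mg in the dialysis tube
    vessel_volume: float = 50.0  # mL of medium
    sample_volume: float = 1.0  # mL withdrawn per time point
    rate_constant: float = 0.35  # 1/h
    plateau_fraction: float = 0.95
    times: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 1, 2, 3, 4, 6, 8, 10, 12, 24.0])
    )
    noise_cv: float = 0.0
    medium_ph: float = 6.8
    saturation_solubility: float | None = 12.2  # mg/mL, highly water-soluble drug
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.rate_constant <= 0:
            raise ValueError("rate_constant must be positive")
        if not 0 < self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must be in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if len(self.times) == 0:
            raise ValueError("sampling grid must be nonempty")


def simulate_release(spec: ReleaseSpec) -> tuple[ReleaseExperiment, pd.DataFrame]:
    """Simulate sampled concentrations plus the hidden true trajectory.

    Returns the experiment (measured concentrations) and a truth table with
    per-time true released mass, vessel mass after withdrawal, and the
    running total of withdrawn mass — the oracle for mass-balance tests.
    """
    rng = np.random.default_rng(spec.seed)
    released_true = spec.dose * spec.plateau_fraction * (
        1.0 - np.exp(-spec.rate_constant * spec.times)
    )
    withdrawn_total = 0.0
    true_conc = np.empty_like(spec.times)
    vessel_mass = np.empty_like(spec.times)
    withdrawn_cum = np.empty_like(spec.times)
    for i, R in enumerate(released_true):
        mass_in_vessel = R - withdrawn_total  # what withdrawals already removed
        conc = mass_in_vessel / spec.vessel_volume
        true_conc[i] = conc
        withdrawn_total += conc * spec.sample_volume
        vessel_mass[i] = mass_in_vessel - conc * spec.sample_volume
        withdrawn_cum[i] = withdrawn_total
    measured = true_conc
    if spec.noise_cv > 0:
        measured = true_conc * (1.0 + rng.normal(0.0, spec.noise_cv, size=len(true_conc)))
        measured = np.clip(measured, 0.0, None)
    exp = ReleaseExperiment(
        dose=spec.dose,
        vessel_volume=spec.vessel_volume,
        sample_volume=spec.sample_volume,
        times=spec.times,
        concentrations=measured,
        medium_ph=spec.medium_ph,
        saturation_solubility=spec.saturation_solubility,
    )
    truth = pd.DataFrame(
        {
            "time_h": spec.times,
            "released_mg_true": released_true,
            "true_concentration": true_conc,
            "vessel_mass_after_sampling": vessel_mass,
            "withdrawn_mass_cum": withdrawn_cum,
        }
    )
    return exp, truth


def simulate_ct(
    groups: Sequence[tuple[str, int, float]],
    control_group: str,
    reference_sd: float = 0.2,
    base_target_ct: float = 26.0,
    base_reference_ct: float = 18.0,
    target_gene: str = "target",
    reference_gene: str = "GAPDH",
    seed: int = 0,
) -> CtTable:
    """Simulate grouped Ct values with a housekeeping reference.

    ``groups`` is a list of (label, n samples, true log2 expression shift);
    a shift of +1 halves the target Ct distance (one cycle earlier) and so
    doubles the recovered fold change relative to the control group.
    Gaussian noise of SD ``reference_sd`` cycles is added independently to
    target and reference Ct values.
    """
    labels = [g[0] for g in groups]
    if control_group not in labels:
        raise ValueError(f"control group {control_group!r} not among {labels}")
    if any(n < 1 for _, n, _ in groups):
        raise ValueError("every group needs at least one sample")
    rng = np.random.default_rng(seed)
    rows = []
    for label, n, shift in groups:
        for k in range(n):
            sample = f"{label}-{k + 1:03d}"
            t_ct = base_target_ct - shift + rng.normal(0.0, reference_sd)
            r_ct = base_reference_ct + rng.normal(0.0, reference_sd)
            rows.append((sample, label, target_gene, t_ct))
            rows.append((sample, label, reference_gene, r_ct))
    data = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
    return CtTable(data=data, control_group=control_group, reference_gene=reference_gene)
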