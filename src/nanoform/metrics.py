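"""Formulation characterization arithmetic.

Covers the three desk-scale calculations of a dissolution/encapsulation
workflow: encapsulation efficiency from total and free drug mass,
cumulative in-vitro release with the additive correction for
withdraw-and-replace sampling, and the 10x sink-condition rule for the
dissolution medium volume.

The release correction: when a volume ``v`` is withdrawn at each time point
and replaced with fresh medium, the drug mass removed from the vessel at
earlier samplings must be added back when tallying what has been released
through the membrane by time :math:`t_n`,

.. math:: m_n = C_n V + v \\sum_{i<n} C_i,

where :math:`C_i` are the sampled concentrations and :math:`V` the vessel
volume.  Without this term the cumulative percentage is biased low by every
withdrawal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEInput",
    "ReleaseExperiment",
    "MassBalanceError",
    "SinkConditionError",
    "ee_percent",
    "cumulative_release",
    "sink_condition",
]

#: cumulative release beyond this % of dose indicates a unit/assay mistake
MASS_BALANCE_LIMIT = 110.0


class MassBalanceError(ValueError):
    """Computed release exceeds the administered dose beyond tolerance."""


class SinkConditionError(ValueError):
    """Sink condition cannot be evaluated (missing solubility)."""


@dataclass(frozen=True)
class EEInput:
    """Total and free (unencapsulated) drug mass for an EE% calculation."""

    w_total: float  # mg of drug used in the formulation
    w_free: float  # mg of free drug measured in the aqueous phase

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_total) and self.w_total > 0):
            raise ValueError("w_total must be positive and finite")
        if not np.isfinite(self.w_free) or self.w_free < 0:
            raise ValueError("w_free must be nonnegative and finite")
        if self.w_free > self.w_total:
            raise ValueError(
                f"w_free ({self.w_free}) exceeds w_total ({self.w_total}); "
                "check the assay blank or units"
            )


def ee_percent(input: EEInput) -> float:
    """Encapsulation efficiency, 100 * (w_total - w_free) / w_total.

    Clamped to [0, 100] to absorb last-ulp rounding at the boundaries.
    """
    return float(np.clip(100.0 * (input.w_total - input.w_free) / input.w_total, 0.0, 100.0))


@dataclass
class ReleaseExperiment:
    """A withdraw-and-replace dissolution sampling record.

    Parameters
    ----------
    dose
        Total drug mass loaded in the dialysis tube (mg).
    vessel_volume
        Dissolution medium volume V (mL).
    sample_volume
        Volume v withdrawn and replaced at each time point (mL).
    times, concentrations
        Sampling times (h, strictly increasing) and the measured
        concentrations in the withdrawn aliquots (mg/mL).
    medium_ph
        pH of the dissolution medium (informational).
    saturation_solubility
        Drug saturation solubility in the medium (mg/mL); required only
        for the sink-condition check.
    """

    dose: float
    vessel_volume: float
    sample_volume: float
    times: np.ndarray = field(repr=False)
    concentrations: np.ndarray = field(repr=False)
    medium_ph: float = 6.8
    saturation_solubility: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 < self.sample_volume <= self.vessel_volume:
            raise ValueError("require 0 < sample_volume <= vessel_volume")
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "ReleaseExperiment":
        """Build from a table with time_h and concentration_mg_per_ml columns."""
        return cls(
            times=df["time_h"].to_numpy(float),
            concentrations=df["concentration_mg_per_ml"].to_numpy(float),
            **kwargs,
        )


def cumulative_release(exp: ReleaseExperiment) -> pd.DataFrame:
    """Cumulative percent of dose released at each sampling time.

    Applies the additive withdraw-and-replace correction (module
    docstring).  A non-monotone cumulative sequence is reported as computed
    and flagged with a warning — it signals measurement noise, not an
    arithmetic problem — but a value beyond ``MASS_BALANCE_LIMIT`` % of the
    dose raises :class:`MassBalanceError`.
    """
    C = exp.concentrations
    withdrawn_before = exp.sample_volume * np.concatenate([[0.0], np.cumsum(C)[:-1]])
    released = C * exp.vessel_volume + withdrawn_before
    percent = 100.0 * released / exp.dose
    if np.any(percent > MASS_BALANCE_LIMIT):
        raise MassBalanceError(
            f"cumulative release reaches {percent.max():.1f}% of dose "
            f"(> {MASS_BALANCE_LIMIT}%); check concentration and volume units"
        )
    if len(percent) > 1 and np.any(np.diff(percent) < 0):
        warnings.warn(
            "cumulative release is not monotone non-decreasing; "
            "values are reported as computed",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "time_h": exp.times,
            "released_mg": released,
            "cumulative_percent": percent,
        }
    )


def sink_condition(exp: ReleaseExperiment) -> tuple[bool, float]:
    """Check the 10x sink rule for the dissolution medium volume.

    The medium volume must be at least 10 times the volume needed to
    dissolve the full dose at saturation.  Returns ``(ok, margin)`` where
    ``margin = vessel_volume / (dose / saturation_solubility)``; sink holds
    iff margin >= 10.
    """
    if exp.saturation_solubility is None or exp.saturation_solubility <= 0:
        raise SinkConditionError(
            "saturation_solubility must be provided (> 0) to evaluate sink condition"
        )
    saturation_volume = exp.dose / exp.saturation_solubility
    margin = exp.vessel_volume / saturation_volume
    return bool(margin >= 10.0), float(margin)
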