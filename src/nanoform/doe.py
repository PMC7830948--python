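"""Box–Behnken experimental designs and factor coding.

A three-level Box–Behnken design (BBD) for :math:`k` factors places runs at
the midpoints of the edges of the factor cuboid plus replicated centre
points.  For three factors this gives the classical 12 + :math:`n_c` run
layout used throughout pharmaceutical formulation work: every pair of
factors visits the four :math:`(\\pm 1, \\pm 1)` corners while the third
factor is held at its centre level.

Factor settings live on two scales: *actual* units (mg, % w/v, ...) and
*coded* units where the low/centre/high levels map onto −1/0/+1.  Coding is
linear about the centre,

.. math:: x = (A - A_0) / \\tfrac{1}{2}(A_{high} - A_{low}),

so the centre always codes exactly to 0 even when the printed actual levels
are not perfectly symmetric (e.g. a PLGA ladder of 33.34/66.67/100 mg codes
its low level to −1.0002 rather than −1).  Settings with ``|coded|`` up to
``1 + CODED_EDGE_TOL`` are still considered inside the design region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CODED_EDGE_TOL",
    "DesignError",
    "FactorSpec",
    "DesignTable",
    "generate_bbd",
    "code_setting",
    "decode_setting",
]

#: slack allowed on |coded| before a point counts as outside the design
#: region; absorbs asymmetric printed factor ladders such as 33.34/66.67/100.
CODED_EDGE_TOL = 1e-3


class DesignError(ValueError):
    """Invalid factor definition or unsupported design request."""


@dataclass(frozen=True)
class FactorSpec:
    """One independent design variable with its three actual levels.

    Parameters
    ----------
    name
        Factor label, e.g. ``"PLGA"``.  Must be nonempty.
    units
        Unit string for the actual scale, e.g. ``"mg in 100 mL"``.
    low, center, high
        Actual values mapped to coded −1, 0, +1.  Must be finite and
        strictly increasing.
    """

    name: str
    units: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not self.name:
            raise DesignError("factor name must be nonempty")
        levels = (self.low, self.center, self.high)
        if not all(np.isfinite(levels)):
            raise DesignError(f"factor {self.name!r}: levels must be finite")
        if not (self.low < self.center < self.high):
            raise DesignError(
                f"factor {self.name!r}: require low < center < high, "
                f"got {levels}"
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    def code(self, actual: float) -> float:
        """Map an actual setting onto the coded scale (centre -> 0)."""
        return code_setting(self, actual)

    def decode(self, coded: float) -> float:
        """Map a coded setting back onto actual units."""
        return decode_setting(self, coded)


def code_setting(factor: FactorSpec, actual: float) -> float:
    """Code an actual factor setting as (actual − center) / half-range.

    Values outside ``[low, high]`` are allowed (extrapolation is the
    caller's concern); a degenerate factor with ``high == low`` is rejected
    by :class:`FactorSpec` construction.
    """
    if not np.isfinite(actual):
        raise DesignError(f"factor {factor.name!r}: actual setting not finite")
    return (actual - factor.center) / factor.half_range


def decode_setting(factor: FactorSpec, coded: float) -> float:
    """Inverse of :func:`code_setting`; coded 0 returns the centre exactly."""
    if not np.isfinite(coded):
        raise DesignError(f"factor {factor.name!r}: coded setting not finite")
    return factor.center + coded * factor.half_range


def _coded_cols(factors: Sequence[FactorSpec]) -> list[str]:
    return [f"{f.name}_coded" for f in factors]


def _actual_cols(factors: Sequence[FactorSpec]) -> list[str]:
    return [f"{f.name}_actual" for f in factors]


@dataclass
class DesignTable:
    """A run matrix on both scales plus per-run response values.

    ``data`` holds one row per run with columns ``run_id``,
    ``<factor>_coded`` and ``<factor>_actual`` per factor, one column per
    response, and optional ``<response>_sd`` columns carrying replicate
    standard deviations as metadata.
    """

    factors: list[FactorSpec]
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate factor names: {names}")
        for col in ["run_id", *_coded_cols(self.factors), *_actual_cols(self.factors)]:
            if col not in self.data.columns:
                raise DesignError(f"design table missing column {col!r}")
        coded = self.coded_matrix()
        if np.any(np.abs(coded) > 1.0 + CODED_EDGE_TOL):
            raise DesignError("coded levels outside [-1, +1] design region")
        # actual and coded scales must describe the same settings
        actual = self.data[_actual_cols(self.factors)].to_numpy(float)
        recoded = np.column_stack(
            [[f.code(a) for a in actual[:, j]] for j, f in enumerate(self.factors)]
        )
        if not np.allclose(recoded, coded, atol=1e-6):
            raise DesignError("coded and actual levels disagree under the coding transform")

    # -- accessors ---------------------------------------------------------

    @property
    def n_runs(self) -> int:
        return len(self.data)

    @property
    def response_names(self) -> list[str]:
        reserved = {"run_id", *_coded_cols(self.factors), *_actual_cols(self.factors)}
        return [
            c
            for c in self.data.columns
            if c not in reserved and not c.endswith("_sd")
        ]

    def coded_matrix(self) -> np.ndarray:
        """Runs × factors array of coded levels."""
        return self.data[_coded_cols(self.factors)].to_numpy(float)

    def response(self, name: str) -> np.ndarray:
        if name not in self.response_names:
            raise KeyError(f"unknown response {name!r}; have {self.response_names}")
        return self.data[name].to_numpy(float)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        self.data.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, factors: Sequence[FactorSpec]) -> "DesignTable":
        df = pd.read_csv(path_or_buf)
        return cls(factors=list(factors), data=df)

    @classmethod
    def from_records(
        cls,
        factors: Sequence[FactorSpec],
        coded_rows: Iterable[Sequence[float]],
        responses: dict[str, Sequence[float]] | None = None,
        response_sds: dict[str, Sequence[float]] | None = None,
        run_ids: Sequence[str] | None = None,
    ) -> "DesignTable":
        """Build a table from coded rows; actual levels are filled by decoding."""
        factors = list(factors)
        coded = np.asarray(list(coded_rows), dtype=float)
        if coded.ndim != 2 or coded.shape[1] != len(factors):
            raise DesignError("coded rows must be n_runs × n_factors")
        n = coded.shape[0]
        if run_ids is None:
            run_ids = [f"run-{i + 1:02d}" for i in range(n)]
        cols: dict[str, object] = {"run_id": list(run_ids)}
        for j, f in enumerate(factors):
            cols[f"{f.name}_coded"] = coded[:, j]
        for j, f in enumerate(factors):
            cols[f"{f.name}_actual"] = [f.decode(c) for c in coded[:, j]]
        for name, vals in (responses or {}).items():
            cols[name] = np.asarray(vals, dtype=float)
        for name, vals in (response_sds or {}).items():
            cols[f"{name}_sd"] = np.asarray(vals, dtype=float)
        return cls(factors=factors, data=pd.DataFrame(cols))

    def to_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def bbd_coded_rows(n_factors: int = 3, center_replicates: int = 3) -> np.ndarray:
    """Coded run matrix of the 3-factor BBD: 12 edge runs then centres.

    Edge runs are emitted in factor-pair order (1–2, 1–3, 2–3); within a
    pair the four corners follow (−−, +−, −+, ++).  Run order carries no
    statistical meaning for a BBD, so a fixed deterministic order is used.
    """
    if n_factors != 3:
        raise DesignError(
            f"only the 3-factor Box–Behnken design is supported, got {n_factors} factors"
        )
    if center_replicates < 1:
        raise DesignError("center_replicates must be >= 1")
    corners = [(-1, -1), (1, -1), (-1, 1), (1, 1)]
    rows = []
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        for a, b in corners:
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = float(a), float(b)
            rows.append(row)
    rows.extend([[0.0, 0.0, 0.0]] * center_replicates)
    return np.asarray(rows)


def generate_bbd(
    factors: Sequence[FactorSpec], center_replicates: int = 3
) -> DesignTable:
    """Construct the 3-factor Box–Behnken design over the given factors.

    Returns a :class:`DesignTable` with 12 edge runs plus
    ``center_replicates`` all-centre runs, actual levels filled from the
    coding transform and no response columns.

    Raises
    ------
    DesignError
        If the factor count is not 3, factor names repeat, or
        ``center_replicates < 1``.
    """
    factors = list(factors)
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate factor names: {names}")
    coded = bbd_coded_rows(len(factors), center_replicates)
    return DesignTable.from_records(factors, coded)
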