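"""Reed-extract chemistry: packaged measurement tables and the
conductometric cell-constant calibration.

The study area's reed stems were characterised chemically alongside the
imaging work.  This module ships those measurements as typed fixtures:

* EDX elemental composition (wt%) of four stem samples — control reed
  (dry) and reed kept in water, each measured on the epidermis and on a
  cross-section;
* pH, electrical conductivity (mS/cm) and soluble-salt content (g/L) of
  three aqueous reed extracts;
* the concentration ranges of the remaining analytes (total nitrogen,
  nitrate, nitrite, sulphate, sulphide, phosphate), stored as (lo, hi)
  range metadata only — per-sample values were never published, so none
  are invented here.

It also implements the conductometric cell-constant calibration: the cell
constant k is the mean of the ratios gamma_i / c_i obtained from two KCl
standard solutions (0.1 n and 0.01 n), where gamma_i is the standard's
specific conductivity (cm^-1) and c_i the measured conductivity.

No conversion from conductivity to soluble-salt mass is implemented: the
published extract values are not consistent with any single linear
factor, so such a conversion is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "ExtractChemistry",
    "EdxComposition",
    "CellConstantInput",
    "PrintedRange",
    "cell_constant",
    "load_table",
    "range_summary",
]

EDX_COLUMNS = (
    "control_epiderm",
    "control_cross_section",
    "water_epiderm",
    "water_cross_section",
)

#: Tolerance on each EDX column's total (wt%); the printed columns sum to
#: 99.98-100.02.
EDX_SUM_TOL = 0.5


@dataclass(frozen=True)
class ExtractChemistry:
    """One aqueous reed-extract sample."""

    sample_id: int
    pH: float
    conductivity: float  # mS/cm
    soluble_salts: float  # g/L

    def __post_init__(self) -> None:
        if not 0 < self.pH < 14:
            raise ValueError(f"pH {self.pH} outside (0, 14)")
        if self.conductivity <= 0 or self.soluble_salts <= 0:
            raise ValueError("conductivity and soluble salts must be positive")


@dataclass(frozen=True)
class EdxComposition:
    """Weight-percent of one element across the four EDX sample columns."""

    element: str
    control_epiderm: float
    control_cross_section: float
    water_epiderm: float
    water_cross_section: float

    def __post_init__(self) -> None:
        if min(self.control_epiderm, self.control_cross_section,
               self.water_epiderm, self.water_cross_section) < 0:
            raise ValueError(f"negative wt% for element {self.element}")


@dataclass(frozen=True)
class PrintedRange:
    """A published (lo, hi) concentration range with units."""

    analyte: str
    lo: float
    hi: float
    units: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"{self.analyte}: lo {self.lo} exceeds hi {self.hi}")


@dataclass(frozen=True)
class CellConstantInput:
    """Calibration readings from the two KCl standard solutions.

    gamma1, gamma2: specific conductivities of the 0.1 n and 0.01 n KCl
    standards (cm^-1); c1, c2: the conductivities the instrument measured
    for them (instrument readout units).
    """

    gamma1: float
    gamma2: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if min(self.gamma1, self.gamma2, self.c1, self.c2) <= 0:
            raise ValueError("all calibration readings must be strictly positive")


def cell_constant(inp: CellConstantInput) -> float:
    """Cell constant k = (gamma1/c1 + gamma2/c2) / 2.

    The per-standard constants are k_i = gamma_i / c_i and k is their
    mean over the two KCl solutions.
    """
    return (inp.gamma1 / inp.c1 + inp.gamma2 / inp.c2) / 2.0


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("reedcover.data").joinpath(name)
    try:
        with ref.open("r") as fh:
            return pd.read_csv(fh, keep_default_na=False)
    except FileNotFoundError as exc:  # pragma: no cover
        raise FileNotFoundError(f"packaged fixture {name} is missing") from exc


def load_table(name: str):
    """Load a packaged fixture table as typed records.

    ``name="extract"`` -> list of :class:`ExtractChemistry` (3 samples);
    ``name="edx"`` -> list of :class:`EdxComposition` (one per element),
    with the per-column sum checked against 100 +/- 0.5 wt% on load;
    ``name="ranges"`` -> list of :class:`PrintedRange`.
    """
    if name == "extract":
        df = _read_fixture("extract_chemistry.csv")
        return [
            ExtractChemistry(
                sample_id=int(r.sample_id),
                pH=float(r.pH),
                conductivity=float(r.conductivity_mS_cm),
                soluble_salts=float(r.soluble_salts_g_L),
            )
            for r in df.itertuples()
        ]
    if name == "edx":
        df = _read_fixture("edx_composition.csv")
        for col in EDX_COLUMNS:
            total = float(df[col].sum())
            if abs(total - 100.0) > EDX_SUM_TOL:
                raise ValueError(
                    f"EDX column {col} sums to {total:.2f} wt%, "
                    f"outside 100 +/- {EDX_SUM_TOL}"
                )
        return [
            EdxComposition(
                element=str(r.element),
                control_epiderm=float(r.control_epiderm),
                control_cross_section=float(r.control_cross_section),
                water_epiderm=float(r.water_epiderm),
                water_cross_section=float(r.water_cross_section),
            )
            for r in df.itertuples()
        ]
    if name == "ranges":
        df = _read_fixture("printed_ranges.csv")
        return [
            PrintedRange(
                analyte=str(r.analyte), lo=float(r.lo), hi=float(r.hi),
                units=str(r.units), note=str(r.note),
            )
            for r in df.itertuples()
        ]
    raise ValueError(f"unknown table {name!r}; expected 'extract', 'edx' or 'ranges'")


def range_summary(records, field: str) -> tuple[float, float]:
    """Exact (min, max) of one numeric field across the records."""
    records = list(records)
    if not records:
        raise ValueError("cannot summarise an empty record list")
    values = [getattr(r, field) for r in records]
    return min(values), max(values)
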