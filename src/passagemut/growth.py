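"""Growth kinetics: population doubling time, CFU-F, and qPCR telomere T/S.

Population doubling time (PDT) follows the standard log2 growth formula

    PDT = hours * ln 2 / ln(harvested / seeded)

and is undefined (returned as NaN) when a passage shows no net growth,
which is how replicative senescence manifests in the growth records.

Relative telomere length is estimated by the standard-curve qPCR method:
each plate carries a dilution series for the telomere (T) and single-copy
gene (S) amplicons; amounts are interpolated from the fitted curves and
the per-sample T/S ratio is normalised to a reference sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthRecord:
    """Seeded/harvested counts and elapsed time for one passage."""

    passage: int
    seeded: float
    harvested: float
    hours: float

    def __post_init__(self):
        if self.seeded <= 0:
            raise ValueError("seeded count must be positive")
        if self.harvested < 0:
            raise ValueError("harvested count must be non-negative")
        if self.hours <= 0:
            raise ValueError("elapsed hours must be positive")


def pdt(record: GrowthRecord) -> float:
    """Population doubling time in hours; NaN if the culture did not grow.

    A NaN flags a senescent passage (harvested <= seeded), it is not an
    error: downstream tables carry the missing value through.
    """
    if record.harvested <= record.seeded:
        return float("nan")
    return record.hours * LN2 / math.log(record.harvested / record.seeded)


def pdt_table(records: list[GrowthRecord]) -> pd.DataFrame:
    """Per-passage PDT table with a ``senescent`` flag column."""
    rows = []
    for r in records:
        value = pdt(r)
        rows.append(
            {
                "passage": r.passage,
                "seeded": r.seeded,
                "harvested": r.harvested,
                "hours": r.hours,
                "pdt_hours": value,
                "senescent": math.isnan(value),
            }
        )
    return pd.DataFrame(rows)


def cfu_f_percentage(colony_diameters_mm) -> float:
    """Percentage of colonies with diameter >= 3 mm among all visible colonies."""
    diameters = np.asarray(list(colony_diameters_mm), dtype=float)
    if diameters.size == 0:
        raise ValueError("no colonies supplied")
    return 100.0 * float(np.count_nonzero(diameters >= 3.0)) / diameters.size


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares Cq vs log10(amount) calibration for one amplicon.

    ``efficiency`` is the conventional fractional amplification efficiency
    10**(-1/slope) - 1, i.e. 1.0 for a perfect doubling per cycle.
    """

    amplicon: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def amount(self, cq) -> np.ndarray:
        """Interpolate relative amount(s) from Cq value(s)."""
        return np.power(10.0, (np.asarray(cq, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(wells: pd.DataFrame, amplicon: str) -> StandardCurve:
    """Fit the dilution-series standard curve for one amplicon.

    ``wells`` must contain columns ``amplicon``, ``dilution`` and ``cq``;
    rows with a missing dilution (unknowns) are ignored.  Relative amount
    of a standard is 1/dilution.
    """
    std = wells[(wells["amplicon"] == amplicon) & wells["dilution"].notna()]
    if std["dilution"].nunique() < 3:
        raise ValueError(f"need >= 3 distinct dilutions for amplicon {amplicon!r}")
    x = -np.log10(std["dilution"].to_numpy(dtype=float))
    y = std["cq"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"standard curve for {amplicon!r} has non-negative slope (assay failure)")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        amplicon=amplicon,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def ts_ratio(
    wells: pd.DataFrame,
    curve_t: StandardCurve,
    curve_s: StandardCurve,
    reference_sample: str,
    use_ddcq: bool = False,
) -> pd.Series:
    """Relative telomere/single-copy (T/S) ratio per sample.

    Amounts are interpolated from the standard curves and replicate wells
    are averaged on the amount scale; ratios are reported relative to
    ``reference_sample`` (whose value is 1.0 by construction).  With
    ``use_ddcq`` the perfect-efficiency 2**-(ddCq_T - ddCq_S) shortcut is
    used instead of the curves.
    """
    unknowns = wells[wells["dilution"].isna()]
    samples = unknowns["sample"].unique()
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} missing from plate")

    raw: dict[str, float] = {}
    for sample in samples:
        sub = unknowns[unknowns["sample"] == sample]
        amounts = {}
        for amplicon, curve in (("T", curve_t), ("S", curve_s)):
            cqs = sub.loc[sub["amplicon"] == amplicon, "cq"].to_numpy(dtype=float)
            if cqs.size == 0:
                raise ValueError(f"sample {sample!r} has no {amplicon} wells")
            if use_ddcq:
                amounts[amplicon] = float(np.mean(np.power(2.0, -cqs)))
            else:
                amounts[amplicon] = float(np.mean(curve.amount(cqs)))
        raw[sample] = amounts["T"] / amounts["S"]

    ref = raw[reference_sample]
    return pd.Series({s: v / ref for s, v in raw.items()}, name="ts_ratio")
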