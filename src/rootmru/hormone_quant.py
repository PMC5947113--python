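"""Phytohormone concentration tables and variation analysis.

Covers the arithmetic layer of targeted hormone quantification by
isotope-dilution LC-MS/MS: linear calibration with internal-standard
recovery correction, limit-of-detection (LOD) censoring, the per-accession
variance-percentage transform

    Y = ((X - A) / A) * 100

where X is the concentration in one accession and A the mean over all
accessions, plus variation-envelope summaries (fold range between extremes,
maximum |Y|) and time-course percent changes.

Concentrations are pg per mg root dry weight throughout.  Censored values
are excluded from summaries — never zero-imputed — and every summary
reports its effective n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANALYTES",
    "ANALYTE_CLASSES",
    "HormoneRecord",
    "HormoneTable",
    "CalibrationModel",
    "Quantification",
    "VariationSummary",
    "HormoneError",
    "fit_calibration",
    "quantify",
    "variance_percent",
    "variation_summary",
    "timecourse_change",
    "censor_lod",
]

log = logging.getLogger(__name__)


class HormoneError(ValueError):
    pass


#: analyte -> metabolite class.  tZ(O,9)G is a single analyte: the O- and
#: 9-glucosides co-elute and are quantified together, never split.
ANALYTE_CLASSES: dict[str, str] = {
    "IAA": "auxin",
    "ABA": "ABA",
    "iP": "free base",
    "tZ": "free base",
    "cZ": "free base",
    "DZ": "free base",
    "iPR": "riboside",
    "tZR": "riboside",
    "DZR": "riboside",
    "tZ7G": "glucoside",
    "tZ(O,9)G": "glucoside",
    "GA9": "gibberellin",
    "GA1": "gibberellin",
    "GA3": "gibberellin",
    "GA7": "gibberellin",
    "GA20": "gibberellin",
}
ANALYTES = list(ANALYTE_CLASSES)


@dataclass
class HormoneRecord:
    """One measurement: accession x replicate x analyte."""

    accession: str
    replicate: int
    analyte: str
    concentration: Optional[float] = None
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTE_CLASSES:
            raise HormoneError(f"unknown analyte {self.analyte!r}")
        if self.below_lod:
            self.concentration = None
        elif self.concentration is None or self.concentration < 0:
            raise HormoneError(
                f"{self.accession}/{self.analyte}: concentration must be >= 0 "
                "unless censored"
            )


@dataclass
class HormoneTable:
    """Long-format hormone table with (accession, replicate, analyte) keys."""

    records: list[HormoneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.accession, r.replicate, r.analyte) for r in self.records]
        if len(keys) != len(set(keys)):
            raise HormoneError("(accession, replicate, analyte) must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": r.accession,
                    "replicate": r.replicate,
                    "analyte": r.analyte,
                    "concentration": r.concentration,
                    "below_lod": r.below_lod,
                }
                for r in self.records
            ],
            columns=["accession", "replicate", "analyte", "concentration", "below_lod"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HormoneTable":
        records = [
            HormoneRecord(
                accession=row.accession,
                replicate=int(row.replicate),
                analyte=row.analyte,
                concentration=None if row.below_lod else float(row.concentration),
                below_lod=bool(row.below_lod),
            )
            for row in df.itertuples()
        ]
        return cls(records)

    def accession_means(self) -> pd.DataFrame:
        """Accession x analyte mean over uncensored replicates (NaN if none)."""
        df = self.to_frame()
        ok = df[~df.below_lod]
        means = ok.pivot_table(
            index="accession", columns="analyte", values="concentration", aggfunc="mean"
        )
        # analytes/accessions whose values are all censored stay as NaN
        # columns rather than silently vanishing
        return means.reindex(
            index=sorted(df.accession.unique()), columns=sorted(df.analyte.unique())
        )


@dataclass
class CalibrationModel:
    """Linear calibration (response = slope * concentration + intercept)
    with the fractional recovery of the labelled internal standard."""

    analyte: str
    slope: float
    intercept: float
    recovery: float = 1.0
    residuals: Optional[np.ndarray] = None
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise HormoneError("calibration slope must be > 0")
        if not (0.0 < self.recovery <= 1.5):
            raise HormoneError("recovery must be in (0, 1.5]")


@dataclass
class Quantification:
    value: Optional[float]
    below_lod: bool


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte: str = "IAA",
    recovery: float = 1.0,
) -> CalibrationModel:
    """Ordinary least-squares calibration line from (concentration, response)
    standards, with residual diagnostics attached to the model."""
    if len(points) < 2:
        raise HormoneError("need >= 2 calibration points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    resp = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(conc) == 0:
        raise HormoneError("all calibration concentrations identical")
    fit = stats.linregress(conc, resp)
    fitted = fit.intercept + fit.slope * conc
    return CalibrationModel(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        recovery=recovery,
        residuals=resp - fitted,
        r_squared=float(fit.rvalue**2),
    )


def quantify(response: float, model: CalibrationModel) -> Quantification:
    """Invert the calibration line and correct by internal-standard recovery.

    concentration = ((response - intercept) / slope) / recovery; responses
    at or below the intercept yield a below-LOD result rather than a
    negative concentration.
    """
    raw = (response - model.intercept) / model.slope / model.recovery
    if raw < 0:
        return Quantification(value=None, below_lod=True)
    return Quantification(value=raw, below_lod=False)


def variance_percent(x: float, a: float) -> float:
    """Deviation of X from the all-accession mean A, in percent."""
    if not a > 0:
        raise HormoneError("cross-accession mean must be > 0")
    return (x - a) / a * 100.0


@dataclass
class VariationSummary:
    analyte: str
    fold_range: float  # max / min of accession means
    envelope: float  # max |variance percent|
    n: int  # accessions contributing
    flagged: bool = False  # True if censored/non-positive values were dropped


def variation_summary(
    values: Iterable[Optional[float]], analyte: str = ""
) -> VariationSummary:
    """Fold range and variance-percent envelope of per-accession means.

    Censored (None/NaN) or non-positive entries flag the analyte and the
    summary is computed on the remaining subset, with n reporting how many
    accessions actually contributed.
    """
    raw = list(values)
    clean = [
        float(v) for v in raw if v is not None and not math.isnan(v) and v > 0
    ]
    flagged = len(clean) != len(raw)
    if len(clean) < 2:
        raise HormoneError("need >= 2 positive accession means")
    if flagged:
        log.warning(
            "%s: %d of %d accession values censored or non-positive; "
            "summary on the remaining subset",
            analyte or "analyte",
            len(raw) - len(clean),
            len(raw),
        )
    a = sum(clean) / len(clean)
    envelope = max(abs(variance_percent(v, a)) for v in clean)
    return VariationSummary(
        analyte=analyte,
        fold_range=max(clean) / min(clean),
        envelope=envelope,
        n=len(clean),
        flagged=flagged,
    )


def timecourse_change(
    series: Sequence[tuple[float, Optional[float]]], t0: float, t1: float
) -> Optional[float]:
    """Percent change between two sampling days (negative = decrease).

    Returns ``None`` (censored) if either day's value is below LOD.
    """
    by_day = {day: value for day, value in series}
    if t0 not in by_day or t1 not in by_day:
        raise HormoneError(f"days {t0} and {t1} must both be present")
    v0, v1 = by_day[t0], by_day[t1]
    if v0 is None or v1 is None or (isinstance(v0, float) and math.isnan(v0)):
        return None
    if isinstance(v1, float) and math.isnan(v1):
        return None
    if not v0 > 0:
        raise HormoneError("value at t0 must be > 0")
    return (v1 - v0) / v0 * 100.0


def censor_lod(
    table: Union[HormoneTable, Iterable[HormoneRecord]],
    lod: Union[float, Mapping[str, float]] = 0.0,
) -> HormoneTable:
    """Flag values below the limit of detection.

    ``lod`` is a single threshold or a per-analyte map (pg/mg DW, >= 0;
    analytes absent from the map default to 0, i.e. no censoring).
    Exclusion counts are logged per analyte; an analyte whose values are
    all censored is reported with a warning.
    """
    records = table.records if isinstance(table, HormoneTable) else list(table)

    def threshold(analyte: str) -> float:
        t = lod if isinstance(lod, (int, float)) else lod.get(analyte, 0.0)
        if t < 0:
            raise HormoneError("LOD must be >= 0")
        return float(t)

    out: list[HormoneRecord] = []
    censored: dict[str, int] = {}
    total: dict[str, int] = {}
    for r in records:
        total[r.analyte] = total.get(r.analyte, 0) + 1
        below = r.below_lod or (r.concentration is not None and r.concentration < threshold(r.analyte))
        if below and not r.below_lod:
            censored[r.analyte] = censored.get(r.analyte, 0) + 1
        out.append(
            HormoneRecord(
                accession=r.accession,
                replicate=r.replicate,
                analyte=r.analyte,
                concentration=None if below else r.concentration,
                below_lod=below,
            )
        )
    for analyte, k in censored.items():
        log.info("%s: %d of %d values censored below LOD", analyte, k, total[analyte])
    result = HormoneTable(out)
    frame = result.to_frame()
    for analyte, grp in frame.groupby("analyte"):
        if grp.below_lod.all():
            log.warning("%s: all values below LOD; dropped from summaries", analyte)
    return result
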