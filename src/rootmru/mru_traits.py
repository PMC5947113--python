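"""Mature-root-unit decomposition and trait extraction.

When lateral roots become indistinguishable from the primary root in
length and diameter, a mature root system has no usable "primary root"
trait.  The mature root unit (MRU) — one basal main axis together with its
laterals and secondary laterals — is the phenotyping unit used instead.
Each main axis is divided into four equal-length sections from base (1Q)
to tip (4Q), and lateral lengths/counts are tallied per section, capturing
the basipetal age gradient of laterals.

Trait vector (per plant):

===========  =================================================
MRUN         number of mature root units
TRL          total root length, cm (all axes)
TRTN         total root-tip number (axes longer than 0.5 mm)
TRD          total root density, TRTN / TRL
PRL          primary root length, sum of main-axis lengths
LRL, LRN     lateral root length (cm) / number, with 1Q-4Q splits
LRD          lateral root density, LRN / PRL
2'-LRL/N/D   secondary-lateral length / number / density (per TRL)
RFW          root fresh weight, mg (measured or simulated)
===========  =================================================

Densities with an empty denominator are *missing* (None), never 0 or inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .root_model import RootAxis, RootSystem

__all__ = [
    "MatureRootUnit",
    "TraitRecord",
    "PhenotypingConfig",
    "TraitError",
    "decompose_mrus",
    "assign_quarter",
    "extract_traits",
    "aggregate_panel",
    "TRAIT_COLUMNS",
]


class TraitError(ValueError):
    pass


@dataclass
class PhenotypingConfig:
    """Tunable conventions of the phenotyping protocol.

    tip_length_threshold
        Minimum axis length (cm) for an axis to count as an emerged root
        tip; default 0.05 cm (0.5 mm).
    threshold_applies_to
        ``"tips_only"`` (default): the threshold filters TRTN only, so LRN
        and 2'-LRN still count sub-threshold laterals.  ``"all_counts"``
        applies it to every count trait.
    prl_mode
        ``"sum_main"`` (default): PRL is the summed length of the main
        axes of all MRUs, so LRD = LRN/PRL reads "laterals per cm of main
        axis".  ``"max_extent"``: PRL is the single longest main axis.
    """

    tip_length_threshold: float = 0.05
    threshold_applies_to: str = "tips_only"
    prl_mode: str = "sum_main"

    def __post_init__(self) -> None:
        if self.tip_length_threshold < 0:
            raise TraitError("tip_length_threshold must be >= 0")
        if self.threshold_applies_to not in ("tips_only", "all_counts"):
            raise TraitError(f"unknown threshold scope {self.threshold_applies_to!r}")
        if self.prl_mode not in ("sum_main", "max_extent"):
            raise TraitError(f"unknown prl_mode {self.prl_mode!r}")


@dataclass
class MatureRootUnit:
    """One MRU: a main axis plus its attached laterals and 2'-laterals."""

    main_axis: RootAxis
    laterals: list[RootAxis] = field(default_factory=list)
    secondary_laterals: list[RootAxis] = field(default_factory=list)


@dataclass
class TraitRecord:
    """Full per-plant trait vector; see module docstring for symbols."""

    plant_id: str
    accession: str
    mrun: int = 0
    trl: float = 0.0
    trtn: int = 0
    trd: Optional[float] = None
    prl: float = 0.0
    lrl: float = 0.0
    lrn: int = 0
    lrd: Optional[float] = None
    lrl_q: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    lrn_q: tuple[int, int, int, int] = (0, 0, 0, 0)
    sec_lrl: float = 0.0
    sec_lrn: int = 0
    sec_lrd: Optional[float] = None
    rfw: Optional[float] = None

    def to_row(self) -> dict:
        """Flatten to one table row with the documented column order."""
        row = {
            "plant_id": self.plant_id,
            "accession": self.accession,
            "RFW": self.rfw,
            "MRUN": self.mrun,
            "TRL": self.trl,
            "TRTN": self.trtn,
            "TRD": self.trd,
            "PRL": self.prl,
            "LRL": self.lrl,
            "LRN": self.lrn,
            "LRD": self.lrd,
            "2-LRL": self.sec_lrl,
            "2-LRN": self.sec_lrn,
            "2-LRD": self.sec_lrd,
        }
        for q in range(4):
            row[f"LRL-{q + 1}Q"] = self.lrl_q[q]
        for q in range(4):
            row[f"LRN-{q + 1}Q"] = self.lrn_q[q]
        return row


#: fixed column order of per-plant trait tables
TRAIT_COLUMNS = list(TraitRecord("", "").to_row().keys())


def decompose_mrus(system: RootSystem) -> list[MatureRootUnit]:
    """Split a root system into its mature root units.

    One MRU per order-1 axis; every order-2/3 axis is assigned to exactly
    one MRU via its parent chain.  Axis orders above 3 are rejected — the
    scheme stops at secondary laterals.
    """
    for ax in system.axes:
        if ax.order > 3:
            raise TraitError(
                f"axis {ax.id!r} has order {ax.order}; the MRU scheme stops at "
                "secondary laterals (order 3)"
            )
    mrus: dict[str, MatureRootUnit] = {}
    lateral_home: dict[str, str] = {}  # lateral axis id -> main axis id
    for ax in system.axes:
        if ax.order == 1:
            mrus[ax.id] = MatureRootUnit(main_axis=ax)
    for ax in system.axes:
        if ax.order == 2:
            mrus[ax.parent_id].laterals.append(ax)
            lateral_home[ax.id] = ax.parent_id
    for ax in system.axes:
        if ax.order == 3:
            mrus[lateral_home[ax.parent_id]].secondary_laterals.append(ax)
    return list(mrus.values())


def assign_quarter(insertion_pos: float, main_length: float) -> int:
    """Quarter index 1-4 of a branch point along its main axis.

    Quarters are the half-open intervals [(q-1)L/4, qL/4), counted from
    the base, with the last interval closed at L so the partition is
    total; a position exactly on a boundary belongs to the more tip-ward
    quarter.
    """
    if not main_length > 0:
        raise TraitError("main_length must be > 0")
    if not (0.0 <= insertion_pos <= main_length):
        raise TraitError(
            f"insertion_pos {insertion_pos} outside [0, {main_length}]"
        )
    return min(4, int(4.0 * insertion_pos / main_length) + 1)


def extract_traits(
    system: RootSystem,
    config: Optional[PhenotypingConfig] = None,
    rfw: Optional[float] = None,
) -> TraitRecord:
    """Compute the full trait vector of one root system.

    Accumulation runs in axis insertion order, which keeps the floating-
    point sums reproducible and lets generated ground truth match exactly.
    """
    cfg = config or PhenotypingConfig()
    strict = cfg.threshold_applies_to == "all_counts"
    thr = cfg.tip_length_threshold

    mrus = decompose_mrus(system)  # validates order <= 3
    main_length = {m.main_axis.id: m.main_axis.length for m in mrus}
    lateral_parent_main = {
        lat.id: m.main_axis.id for m in mrus for lat in m.laterals
    }

    trl = 0.0
    trtn = 0
    prl_parts: list[float] = []
    lrl = 0.0
    lrn = 0
    lrl_q = [0.0, 0.0, 0.0, 0.0]
    lrn_q = [0, 0, 0, 0]
    sec_lrl = 0.0
    sec_lrn = 0

    for ax in system.axes:
        trl += ax.length
        if ax.length > thr:
            trtn += 1
        counted = ax.length > thr if strict else True
        if ax.order == 1:
            prl_parts.append(ax.length)
        elif ax.order == 2:
            q = assign_quarter(ax.insertion_pos, main_length[ax.parent_id])
            if counted:
                lrl += ax.length
                lrn += 1
                lrl_q[q - 1] += ax.length
                lrn_q[q - 1] += 1
        else:
            if counted:
                sec_lrl += ax.length
                sec_lrn += 1

    prl = (
        sum(prl_parts)
        if cfg.prl_mode == "sum_main"
        else (max(prl_parts) if prl_parts else 0.0)
    )
    return TraitRecord(
        plant_id=system.plant_id,
        accession=system.accession,
        mrun=len(mrus),
        trl=trl,
        trtn=trtn,
        trd=(trtn / trl) if trl > 0 else None,
        prl=prl,
        lrl=lrl,
        lrn=lrn,
        lrd=(lrn / prl) if prl > 0 else None,
        lrl_q=tuple(lrl_q),
        lrn_q=tuple(lrn_q),
        sec_lrl=sec_lrl,
        sec_lrn=sec_lrn,
        sec_lrd=(sec_lrn / trl) if trl > 0 else None,
        rfw=rfw,
    )


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    """Per-plant trait table with the documented fixed column order."""
    df = pd.DataFrame([r.to_row() for r in records])
    return df.reindex(columns=TRAIT_COLUMNS)


def aggregate_panel(records: Iterable[TraitRecord]) -> pd.DataFrame:
    """Accession-level summary: mean, standard error and n per trait.

    SE = sd / sqrt(n) with the n-1 divisor; missing values (undefined
    densities, unmeasured RFW) are excluded per trait, and n = 1 yields a
    missing SE rather than zero.
    """
    df = records_to_frame(records)
    traits = [c for c in TRAIT_COLUMNS if c not in ("plant_id", "accession")]
    rows = []
    for accession, grp in df.groupby("accession", sort=True):
        for trait in traits:
            vals = grp[trait].dropna().astype(float)
            n = len(vals)
            if n == 0:
                mean, se = math.nan, math.nan
            else:
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            rows.append(
                {"accession": accession, "trait": trait, "mean": mean, "se": se, "n": n}
            )
    return pd.DataFrame(rows, columns=["accession", "trait", "mean", "se", "n"])
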