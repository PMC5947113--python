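"""Seeded generators for root architectures and hormone panels.

Two things are emulated so the whole pipeline is testable at desk scale
without any measured data:

1. **Root architectures** — multi-MRU systems with a basipetal gradient of
   lateral roots: laterals near the base (1Q) are older and longer, those
   near the tip (4Q) younger, shorter and sparser.  Lateral counts per
   quarter are Poisson, lengths log-normal (positive and right-skewed,
   like measured root-length data).  Ground-truth trait records are
   book-kept during generation, independently of the trait extractor,
   which makes the extractor fully oracle-testable.

2. **Accession panels** — 13 accessions with per-class hormone variation
   envelopes (free bases +/-10%, ribosides +/-50%, tZ glucosides +/-30%,
   auxin and ABA +/-25%, cZ +/-50%, GA9 three-fold between extremes),
   enforced *exactly* by affine rescaling of the drawn accession means.
   A shared per-accession latent factor scales architecture vigor and
   shifts hormone levels by signed loadings (auxin positive, tZ/ABA
   negative on root-size traits), which imposes the configured
   hormone-trait correlation signs.

All randomness flows from one explicit seed through
``numpy.random.SeedSequence``; identical seeds give identical output, and
the run manifest (parameters + seed) fully reproduces any dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .root_model import RootAxis, RootSystem
from .hormone_quant import ANALYTE_CLASSES, HormoneRecord, HormoneTable
from .mru_traits import PhenotypingConfig, TraitRecord

__all__ = [
    "ArchitectureParams",
    "PanelParams",
    "PanelResult",
    "DEFAULT_ACCESSIONS",
    "generate_root_system",
    "generate_panel",
    "generate_hormone_table",
    "example_system",
]

#: 13 accession labels, ordered from a small (Cvi-like) to a large
#: (Tsu-like) architecture preset via the base-vigor gradient below.
DEFAULT_ACCESSIONS = [
    "Cvi-0",
    "Ts-1",
    "An-1",
    "Bor-4",
    "Bay-0",
    "Est-1",
    "RRS-7",
    "Bur-0",
    "Col-0",
    "Fei-0",
    "Ler-0",
    "Sha",
    "Tsu-0",
]


@dataclass
class ArchitectureParams:
    """Stochastic root-architecture model of one plant.

    mru_rate
        n_MRU = 1 + Poisson(mru_rate); default 2.0 gives 1-6+ units,
        mostly 2-4.
    main_length_median / main_length_sigma
        Log-normal main-axis length, cm.
    laterals_per_quarter
        Poisson rates of lateral counts per quarter 1Q-4Q; the default
        peaks mid-axis and thins toward the tip.
    lateral_length_median
        Per-quarter log-normal medians (cm), decreasing toward 4Q where
        laterals are youngest.
    p_secondary
        Probability that a lateral bears one secondary lateral.
    short_root_fraction
        Fraction of laterals drawn as just-emerged roots below the 0.05 cm
        tip-count threshold (they appear in LRN but not TRTN under the
        default phenotyping convention).
    rfw_density / rfw_noise_cv
        Fresh weight simulated as TRL * density * log-normal noise, mg.
    """

    mru_rate: float = 2.0
    main_length_median: float = 8.0
    main_length_sigma: float = 0.25
    laterals_per_quarter: tuple[float, float, float, float] = (3.0, 4.0, 3.0, 1.5)
    lateral_length_median: tuple[float, float, float, float] = (1.5, 1.0, 0.5, 0.15)
    lateral_length_sigma: float = 0.5
    p_secondary: float = 0.3
    secondary_length_median: float = 0.3
    secondary_length_sigma: float = 0.5
    short_root_fraction: float = 0.1
    rfw_density: float = 0.15
    rfw_noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.mru_rate < 0 or any(r < 0 for r in self.laterals_per_quarter):
            raise ValueError("rates must be >= 0")
        if not (0.0 <= self.p_secondary <= 1.0):
            raise ValueError("p_secondary must be in [0, 1]")
        if not (0.0 <= self.short_root_fraction <= 1.0):
            raise ValueError("short_root_fraction must be in [0, 1]")

    def scaled(self, vigor: float) -> "ArchitectureParams":
        """A vigor-scaled copy: larger vigor, larger and busier plants."""
        return replace(
            self,
            mru_rate=self.mru_rate * vigor,
            main_length_median=self.main_length_median * vigor,
            laterals_per_quarter=tuple(r * vigor for r in self.laterals_per_quarter),
            lateral_length_median=tuple(
                m * vigor for m in self.lateral_length_median
            ),
        )


#: analytes the synthetic panel quantifies: auxin, ABA, GA9 and eight CKs
PANEL_ANALYTES = [
    "IAA",
    "ABA",
    "iP",
    "iPR",
    "tZ",
    "tZR",
    "DZR",
    "tZ7G",
    "tZ(O,9)G",
    "cZ",
    "GA9",
]

#: synthetic baseline concentrations, pg/mg dry weight (plausible scale
#: for 23-d-old root extracts; invented values, not measurements)
DEFAULT_BASELINES = {
    "IAA": 50.0,
    "ABA": 30.0,
    "iP": 2.0,
    "iPR": 5.0,
    "tZ": 1.5,
    "tZR": 4.0,
    "DZR": 1.0,
    "tZ7G": 20.0,
    "tZ(O,9)G": 15.0,
    "cZ": 1.0,
    "GA9": 5.0,
}

#: per-analyte max |variance percent| of accession means.  Free bases sit
#: in a tight +/-10% band, ribosides +/-50%, glucosides +/-30%, auxin and
#: ABA +/-25%; cZ behaves like the ribosides (+/-50%) despite being a free
#: base.  GA9 is controlled by fold range instead (see ga9_fold_range).
DEFAULT_ENVELOPES = {
    "IAA": 25.0,
    "ABA": 25.0,
    "iP": 10.0,
    "tZ": 10.0,
    "iPR": 50.0,
    "tZR": 50.0,
    "DZR": 50.0,
    "tZ7G": 30.0,
    "tZ(O,9)G": 30.0,
    "cZ": 50.0,
}

#: signed latent-factor loadings: IAA rises with root-system vigor, the
#: active CKs tZ (and ABA, GA9) fall with it; ribosides/glucosides/cZ
#: track vigor weakly positively, iP is neutral.
DEFAULT_COUPLING = {
    "IAA": 1.0,
    "ABA": -1.0,
    "tZ": -1.0,
    "GA9": -0.8,
    "iP": 0.0,
    "iPR": 0.5,
    "tZR": 0.5,
    "DZR": 0.5,
    "tZ7G": 0.5,
    "tZ(O,9)G": 0.5,
    "cZ": 0.5,
}


@dataclass
class PanelParams:
    """Design of a synthetic accession panel.

    Defaults mirror the study design: 13 accessions, 6 phenotyped plants
    and 4 hormone replicates per accession.  ``coupling`` maps analyte to
    a signed latent-factor loading in [-1, 1]; ``coupling=0`` for all
    analytes gives a null panel with no hormone-trait association.
    ``vigor_sigma`` sets how strongly the latent factor scales plant
    vigor, and ``vigor_gradient`` adds a fixed small->large accession
    ordering independent of the factor.
    """

    n_accessions: int = 13
    reps_per_accession: int = 6
    hormone_reps: int = 4
    accession_names: Optional[list[str]] = None
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    envelopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ENVELOPES))
    ga9_fold_range: float = 3.0
    coupling: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    replicate_cv: float = 0.08
    vigor_sigma: float = 0.3
    vigor_gradient: float = 0.1

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("need >= 2 accessions")
        if any(e < 0 for e in self.envelopes.values()):
            raise ValueError("envelopes must be >= 0")
        if self.ga9_fold_range < 1:
            raise ValueError("fold range must be >= 1")

    def labels(self) -> list[str]:
        if self.accession_names is not None:
            if len(self.accession_names) != self.n_accessions:
                raise ValueError("accession_names length mismatch")
            return list(self.accession_names)
        if self.n_accessions == len(DEFAULT_ACCESSIONS):
            return list(DEFAULT_ACCESSIONS)
        return [f"Acc{i + 1:02d}" for i in range(self.n_accessions)]


# ---------------------------------------------------------------------------
# architecture generation
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def generate_root_system(
    params: ArchitectureParams,
    seed: Union[int, np.random.Generator],
    plant_id: str = "plant",
    accession: str = "synthetic",
    config: Optional[PhenotypingConfig] = None,
) -> tuple[RootSystem, TraitRecord]:
    """Draw one root system plus its ground-truth trait record.

    The trait record is accumulated incrementally while axes are created
    (never by running the extractor), in the same axis order the extractor
    iterates, so extractor/ground-truth agreement is exact, not
    approximate.  Degenerate parameters (all-zero lateral rates) yield
    unbranched systems, not errors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config or PhenotypingConfig()
    thr = cfg.tip_length_threshold
    strict = cfg.threshold_applies_to == "all_counts"

    axes: list[RootAxis] = []
    trl = 0.0
    trtn = 0
    mains: list[float] = []
    lrl = 0.0
    lrn = 0
    lrl_q = [0.0, 0.0, 0.0, 0.0]
    lrn_q = [0, 0, 0, 0]
    sec_lrl = 0.0
    sec_lrn = 0
    counter = [0]

    def add(ax: RootAxis) -> None:
        nonlocal trl, trtn
        axes.append(ax)
        trl += ax.length
        if ax.length > thr:
            trtn += 1

    def next_id() -> str:
        counter[0] += 1
        return f"{plant_id}-ax{counter[0]}"

    n_mru = 1 + int(rng.poisson(params.mru_rate))
    for _ in range(n_mru):
        main_len = _lognormal(rng, params.main_length_median, params.main_length_sigma)
        main = RootAxis(id=next_id(), order=1, length=main_len)
        add(main)
        mains.append(main_len)
        for q in range(4):
            n_lat = int(rng.poisson(params.laterals_per_quarter[q]))
            # positions drawn strictly inside the quarter so the quarter
            # label is unambiguous under floating-point arithmetic
            offsets = np.sort(rng.uniform(0.02, 0.98, size=n_lat))
            for u in offsets:
                pos = (q + float(u)) * main_len / 4.0
                if rng.uniform() < params.short_root_fraction:
                    lat_len = float(rng.uniform(0.005, thr)) if thr > 0 else 0.005
                else:
                    lat_len = _lognormal(
                        rng,
                        params.lateral_length_median[q],
                        params.lateral_length_sigma,
                    )
                lat = RootAxis(
                    id=next_id(),
                    order=2,
                    length=lat_len,
                    parent_id=main.id,
                    insertion_pos=pos,
                )
                add(lat)
                if (not strict) or lat_len > thr:
                    lrl += lat_len
                    lrn += 1
                    lrl_q[q] += lat_len
                    lrn_q[q] += 1
                if rng.uniform() < params.p_secondary:
                    sec_len = _lognormal(
                        rng,
                        params.secondary_length_median,
                        params.secondary_length_sigma,
                    )
                    sec = RootAxis(
                        id=next_id(),
                        order=3,
                        length=sec_len,
                        parent_id=lat.id,
                        insertion_pos=float(rng.uniform(0.0, lat_len)),
                    )
                    add(sec)
                    if (not strict) or sec_len > thr:
                        sec_lrl += sec_len
                        sec_lrn += 1

    system = RootSystem(plant_id=plant_id, accession=accession, axes=axes)
    prl = sum(mains) if cfg.prl_mode == "sum_main" else (max(mains) if mains else 0.0)
    rfw = trl * params.rfw_density * math.exp(
        params.rfw_noise_cv * rng.standard_normal()
    )
    truth = TraitRecord(
        plant_id=plant_id,
        accession=accession,
        mrun=n_mru,
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
    return system, truth


# ---------------------------------------------------------------------------
# hormone panel generation
# ---------------------------------------------------------------------------


def _rescale_to_envelope(v: np.ndarray, target_mean: float, envelope: float) -> np.ndarray:
    """Affine map of accession means so max |variance percent| == envelope."""
    centered = v - v.mean()
    spread = np.max(np.abs(centered))
    if spread == 0 or envelope == 0:
        return np.full_like(v, target_mean)
    s = (envelope / 100.0) * target_mean / spread
    return target_mean + s * centered


def _rescale_to_fold(v: np.ndarray, target_mean: float, fold: float) -> np.ndarray:
    """Affine map so max/min of accession means == fold (positive slope)."""
    ptp = np.ptp(v)
    if ptp == 0 or fold == 1.0:
        return np.full_like(v, target_mean)
    lo = 2.0 * target_mean / (1.0 + fold)
    s = lo * (fold - 1.0) / ptp
    return lo + s * (v - v.min())


def _accession_means(
    panel: PanelParams, rng: np.random.Generator, z: np.ndarray
) -> pd.DataFrame:
    """True per-accession analyte means with coupling, envelopes enforced."""
    labels = panel.labels()
    means: dict[str, np.ndarray] = {}
    for analyte in PANEL_ANALYTES:
        g = float(np.clip(panel.coupling.get(analyte, 0.0), -1.0, 1.0))
        eps = rng.standard_normal(len(labels))
        d = g * z + math.sqrt(max(0.0, 1.0 - g * g)) * eps
        base = panel.baselines[analyte]
        raw = base * (1.0 + 0.2 * d)
        if analyte == "GA9":
            means[analyte] = _rescale_to_fold(raw, base, panel.ga9_fold_range)
        else:
            means[analyte] = _rescale_to_envelope(
                raw, base, panel.envelopes.get(analyte, 25.0)
            )
    return pd.DataFrame(means, index=pd.Index(labels, name="accession"))


def _replicate_records(
    means: pd.DataFrame, panel: PanelParams, rng: np.random.Generator
) -> HormoneTable:
    """Expand true means into replicate records.

    Replicate noise is mean-centred within each accession x analyte cell,
    so the accession means realized from the table equal the enforced
    means (and hence the configured envelopes) exactly, while replicates
    still scatter with the configured CV.
    """
    records = []
    for accession, row in means.iterrows():
        for analyte in means.columns:
            m = float(row[analyte])
            noise = rng.standard_normal(panel.hormone_reps)
            noise = noise - noise.mean()
            for rep in range(panel.hormone_reps):
                value = m * (1.0 + panel.replicate_cv * float(noise[rep]))
                records.append(
                    HormoneRecord(
                        accession=accession,
                        replicate=rep + 1,
                        analyte=analyte,
                        concentration=max(value, 0.0),
                    )
                )
    return HormoneTable(records)


def generate_hormone_table(
    panel: PanelParams,
    seed: Union[int, np.random.Generator],
    z: Optional[np.ndarray] = None,
) -> HormoneTable:
    """Synthetic accession x analyte x replicate hormone table (pg/mg DW).

    ``z`` optionally injects the shared latent factor (one value per
    accession) so the table can be coupled to an architecture panel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if z is None:
        z = rng.standard_normal(panel.n_accessions)
    means = _accession_means(panel, rng, np.asarray(z, dtype=float))
    return _replicate_records(means, panel, rng)


@dataclass
class PanelResult:
    """Everything one synthetic study produces."""

    systems: list[RootSystem]
    trait_records: list[TraitRecord]
    trait_table: pd.DataFrame
    hormone_table: HormoneTable
    latent: pd.Series  # per-accession latent factor
    manifest: dict


def generate_panel(
    arch: Union[ArchitectureParams, dict[str, ArchitectureParams]],
    panel: PanelParams,
    seed: int,
    config: Optional[PhenotypingConfig] = None,
    keep_systems: bool = True,
) -> PanelResult:
    """Simulate a full accession panel: architectures plus hormone table.

    A per-accession latent factor ``z`` drives both sides: architecture
    parameters are scaled by ``exp(vigor_sigma * z + gradient)`` and the
    hormone accession means are shifted by ``coupling * z`` before
    envelope enforcement, inducing the configured correlation signs
    between hormone levels and root-size traits.
    """
    from .mru_traits import records_to_frame

    labels = panel.labels()
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    z = master.standard_normal(panel.n_accessions)
    gradient = (
        np.linspace(-panel.vigor_gradient, panel.vigor_gradient, panel.n_accessions)
        if panel.n_accessions > 1
        else np.zeros(1)
    )

    systems: list[RootSystem] = []
    records: list[TraitRecord] = []
    for i, accession in enumerate(labels):
        base = arch[accession] if isinstance(arch, dict) else arch
        vigor = math.exp(panel.vigor_sigma * float(z[i]) + float(gradient[i]))
        acc_params = base.scaled(vigor)
        for rep in range(panel.reps_per_accession):
            system, truth = generate_root_system(
                acc_params,
                master,
                plant_id=f"{accession}-p{rep + 1}",
                accession=accession,
                config=config,
            )
            if keep_systems:
                systems.append(system)
            records.append(truth)

    hormones = generate_hormone_table(panel, master, z=z)
    manifest = {
        "seed": seed,
        "panel": asdict(panel),
        "architecture": {k: asdict(v) for k, v in arch.items()}
        if isinstance(arch, dict)
        else asdict(arch),
    }
    return PanelResult(
        systems=systems,
        trait_records=records,
        trait_table=records_to_frame(records),
        hormone_table=hormones,
        latent=pd.Series(z, index=pd.Index(labels, name="accession"), name="latent"),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# worked example
# ---------------------------------------------------------------------------


def example_system(plant_id: str = "demo", accession: str = "demo") -> RootSystem:
    """Hand-built three-MRU system used in docs and worked-example tests.

    Three basal main axes of 6, 5 and 4 cm with basipetally graded
    laterals (long near the base, short near the tip) and two secondary
    laterals — the canonical schematic of a complex mature root system
    where no single primary root can be singled out.
    """
    axes = [
        # MRU 1: main 6 cm
        RootAxis(id="m1", order=1, length=6.0),
        RootAxis(id="m1l1", order=2, length=1.2, parent_id="m1", insertion_pos=0.9),
        RootAxis(id="m1l2", order=2, length=0.8, parent_id="m1", insertion_pos=2.1),
        RootAxis(id="m1l3", order=2, length=0.5, parent_id="m1", insertion_pos=3.8),
        RootAxis(id="m1l3s1", order=3, length=0.2, parent_id="m1l3", insertion_pos=0.2),
        RootAxis(id="m1l4", order=2, length=0.2, parent_id="m1", insertion_pos=5.7),
        # MRU 2: main 5 cm
        RootAxis(id="m2", order=1, length=5.0),
        RootAxis(id="m2l1", order=2, length=0.9, parent_id="m2", insertion_pos=0.7),
        RootAxis(id="m2l2", order=2, length=0.6, parent_id="m2", insertion_pos=1.8),
        RootAxis(id="m2l2s1", order=3, length=0.15, parent_id="m2l2", insertion_pos=0.3),
        RootAxis(id="m2l3", order=2, length=0.15, parent_id="m2", insertion_pos=4.8),
        # MRU 3: main 4 cm
        RootAxis(id="m3", order=1, length=4.0),
        RootAxis(id="m3l1", order=2, length=0.7, parent_id="m3", insertion_pos=0.5),
        RootAxis(id="m3l2", order=2, length=0.4, parent_id="m3", insertion_pos=1.5),
    ]
    return RootSystem(plant_id=plant_id, accession=accession, axes=axes)
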