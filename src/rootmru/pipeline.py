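"""End-to-end pipeline: simulate/load -> extract -> summarize -> associate.

Each stage reads and writes only plain-text interfaces (RSML, CSV, JSON,
Newick) so stages are independently runnable and testable.  A run manifest
(config + seed + package version) is written first; every other output
file starts with a header line naming the code version and the manifest
hash, and the whole bundle is byte-identical across reruns with the same
config and seed.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .root_model import read_rsml, write_rsml
from .mru_traits import (
    PhenotypingConfig,
    TraitRecord,
    aggregate_panel,
    extract_traits,
    records_to_frame,
    TRAIT_COLUMNS,
)
from .hormone_quant import ANALYTE_CLASSES, HormoneTable, variation_summary
from .assoc_stats import (
    AssocError,
    hcluster,
    pca_correlation,
    pearson_matrix,
    significance_flags,
)
from .synthetic_data import ArchitectureParams, PanelParams, generate_panel

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Exactly one input mode: ``"synthetic"`` (requires ``seed``) or
    ``"rsml"`` (requires ``rsml_dir``; ``hormone_csv`` optionally supplies
    a measured hormone table in long format).
    """

    mode: str = "synthetic"
    out_dir: str = "out"
    seed: Optional[int] = None
    rsml_dir: Optional[str] = None
    hormone_csv: Optional[str] = None
    phenotyping: PhenotypingConfig = field(default_factory=PhenotypingConfig)
    architecture: ArchitectureParams = field(default_factory=ArchitectureParams)
    panel: PanelParams = field(default_factory=PanelParams)
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    linkage: str = "average"
    distance: str = "one-minus-r"
    multiple_testing: Optional[str] = None  # None or "bh"
    write_rsml_out: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "rsml"):
            raise PipelineError(f"[config] unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise PipelineError("[config] synthetic mode requires a seed")
        if self.mode == "rsml" and not self.rsml_dir:
            raise PipelineError("[config] rsml mode requires rsml_dir")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phenotyping" in d and isinstance(d["phenotyping"], dict):
            d["phenotyping"] = PhenotypingConfig(**d["phenotyping"])
        if "architecture" in d and isinstance(d["architecture"], dict):
            d["architecture"] = ArchitectureParams(**d["architecture"])
        if "panel" in d and isinstance(d["panel"], dict):
            d["panel"] = PanelParams(**d["panel"])
        if "alpha_levels" in d:
            d["alpha_levels"] = tuple(d["alpha_levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_manifest(self) -> dict:
        d = asdict(self)
        # where the bundle lives is not part of what the bundle is
        d.pop("out_dir", None)
        d["version"] = __version__
        return d


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)


class _Bundle:
    """Output directory with versioned, hash-stamped text files."""

    def __init__(self, out_dir: Path, manifest: dict):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        payload = _canonical_json(manifest)
        self.manifest_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]
        (self.dir / "manifest.json").write_text(payload + "\n")
        self.files = ["manifest.json"]

    @property
    def header(self) -> str:
        return f"# rootmru {__version__} manifest={self.manifest_hash}\n"

    def write_text(self, name: str, body: str) -> Path:
        path = self.dir / name
        path.write_text(self.header + body)
        self.files.append(name)
        return path

    def write_frame(self, name: str, df: pd.DataFrame, index: bool = False) -> Path:
        buf = io.StringIO()
        df.to_csv(buf, index=index, float_format="%.10g", lineterminator="\n")
        return self.write_text(name, buf.getvalue())


def _triangle_table(r: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Lower-triangle correlation table with asterisk flags, as published
    correlation tables are laid out (rows from the second variable on)."""
    cols = list(r.columns)
    out = pd.DataFrame("", index=cols[1:], columns=cols[:-1])
    for i, row in enumerate(cols[1:], start=1):
        for j in range(i):
            col = cols[j]
            val = r.loc[row, col]
            cell = "" if pd.isna(val) else f"{val:.2f}{flags.loc[row, col]}"
            out.loc[row, col] = cell
    out.index.name = "variable"
    return out


def _hormone_summary(table: HormoneTable) -> pd.DataFrame:
    means = table.accession_means()
    rows = []
    for analyte in means.columns:
        if means[analyte].notna().sum() < 2:
            log.warning("%s: fewer than 2 uncensored accessions; dropped", analyte)
            continue
        summ = variation_summary(means[analyte].tolist(), analyte=analyte)
        rows.append(
            {
                "analyte": analyte,
                "class": ANALYTE_CLASSES[analyte],
                "mean_pg_mg": float(means[analyte].mean()),
                "fold_range": summ.fold_range,
                "envelope_pct": summ.envelope,
                "n": summ.n,
                "censored": summ.flagged,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns a dict with the output directory, manifest hash and the list
    of files written.  Any stage failure raises :class:`PipelineError`
    naming the stage, after marking the bundle incomplete.
    """
    out = Path(config.out_dir)
    bundle = _Bundle(out, config.to_manifest())
    stage = "setup"
    t_start = time.perf_counter()
    try:
        # -- stage: acquire root systems + traits -------------------------
        stage = "extract"
        t0 = time.perf_counter()
        hormones: Optional[HormoneTable] = None
        if config.mode == "synthetic":
            result = generate_panel(
                config.architecture,
                config.panel,
                seed=config.seed,
                config=config.phenotyping,
                keep_systems=config.write_rsml_out,
            )
            records = result.trait_records
            hormones = result.hormone_table
            if config.write_rsml_out:
                write_rsml(result.systems, out / "architectures.rsml")
                bundle.files.append("architectures.rsml")
        else:
            paths = sorted(Path(config.rsml_dir).glob("*.rsml"))
            if not paths:
                raise PipelineError(f"[extract] no .rsml files in {config.rsml_dir}")
            records = []
            for p in paths:
                for system in read_rsml(p):
                    records.append(extract_traits(system, config.phenotyping))
            if config.hormone_csv:
                hormones = HormoneTable.from_frame(pd.read_csv(config.hormone_csv))
        trait_df = records_to_frame(records)
        bundle.write_frame("traits.csv", trait_df)
        bundle.write_frame("traits_by_accession.csv", aggregate_panel(records))
        log.info("extract: %d plants (%.2fs)", len(records), time.perf_counter() - t0)

        # -- stage: hormones ----------------------------------------------
        if hormones is not None:
            stage = "hormones"
            t0 = time.perf_counter()
            bundle.write_frame("hormones.csv", hormones.to_frame())
            bundle.write_frame("hormone_summary.csv", _hormone_summary(hormones))
            log.info("hormones: summarized (%.2fs)", time.perf_counter() - t0)

        # -- stage: associate ---------------------------------------------
        stage = "associate"
        t0 = time.perf_counter()
        accessions = trait_df["accession"].nunique()
        if accessions == 1:
            log.warning("associate: single accession; association stage skipped")
        else:
            if accessions < 3:
                raise AssocError(
                    ">= 3 complete pairs required for correlations "
                    f"(got {accessions} accessions)"
                )
            trait_means = (
                trait_df.drop(columns=["plant_id"])
                .groupby("accession", sort=True)
                .mean()
                .dropna(axis=1, how="all")  # e.g. RFW when not measured
            )
            assoc = pearson_matrix(trait_means)
            flags = significance_flags(
                assoc, levels=config.alpha_levels, adjust=config.multiple_testing
            )
            bundle.write_frame("trait_corr_r.csv", assoc.r, index=True)
            bundle.write_frame("trait_corr_p.csv", assoc.p, index=True)
            bundle.write_frame(
                "trait_corr_table.csv", _triangle_table(assoc.r, flags), index=True
            )

            combined = trait_means
            if hormones is not None:
                hmeans = hormones.accession_means()
                combined = trait_means.join(hmeans, how="inner")
                both = pearson_matrix(combined)
                bflags = significance_flags(
                    both, levels=config.alpha_levels, adjust=config.multiple_testing
                )
                hcols = list(hmeans.columns)
                tcols = [c for c in trait_means.columns]
                bundle.write_frame(
                    "hormone_trait_corr_r.csv", both.r.loc[hcols, tcols], index=True
                )
                bundle.write_frame(
                    "hormone_trait_corr_p.csv", both.p.loc[hcols, tcols], index=True
                )
                stars = both.r.loc[hcols, tcols].round(2).astype(str) + bflags.loc[
                    hcols, tcols
                ]
                stars.index.name = "analyte"
                bundle.write_frame("hormone_trait_corr_table.csv", stars, index=True)

            complete = combined.dropna(axis=1, how="any")
            pca = pca_correlation(complete)
            bundle.write_frame("pca_loadings.csv", pca.loadings, index=True)
            bundle.write_frame("pca_scores.csv", pca.scores, index=True)
            bundle.write_frame(
                "pca_variance.csv", pca.variance_fraction.to_frame(), index=True
            )
            clust = hcluster(
                complete, distance=config.distance, method=config.linkage
            )
            bundle.write_text(
                "dendrogram.nwk",
                f"# distance={clust.distance} linkage={clust.method}\n"
                + clust.newick
                + "\n",
            )
            log.info("associate: done (%.2fs)", time.perf_counter() - t0)
    except PipelineError:
        (out / "INCOMPLETE").write_text(f"failed at stage: {stage}\n")
        raise
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage: {stage}\n")
        raise PipelineError(f"[{stage}] {exc}") from exc

    incomplete = out / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    log.info("pipeline complete in %.2fs", time.perf_counter() - t_start)
    return {
        "out_dir": str(out),
        "manifest_hash": bundle.manifest_hash,
        "files": bundle.files,
    }
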