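"""End-to-end orchestration: stats → gst → tree → pca from one config.

A run takes individual genotypes and/or a published frequency matrix,
executes the enabled stages in dependency order, and writes one output file
per stage plus a ``manifest.json`` recording every resolved option, input,
output and warning.  Outputs are deterministic: replaying the same config
reproduces the run byte for byte.

Frequencies-only mode is first-class — comparative re-analyses typically
start from published allele-frequency tables without genotypes, in which
case the genotype-level stats stage is skipped with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .diversity import PopulationDiversity
from .gst import GstDecomposition
from .io import (
    FrequencyMatrix,
    read_frequency_matrix,
    read_genotype_table,
    write_frequency_matrix,
)
from .pca import FrequencyPCA
from .tree import NeighborJoining, write_newick

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("stats", "gst", "tree", "pca")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (also loadable from YAML)."""

    genotypes: str | None = None  #: genotype TSV path
    frequencies: str | None = None  #: frequency-matrix TSV path
    outdir: str = "alupopdiv_run"
    stages: tuple = ALL_STAGES
    het: str = "observed"
    hwe_family: str = "run"
    convention: str = "mean-of-ratios"
    distance: str = "nei1972"
    pca_components: int | None = None
    pca_scale: bool = False
    precision: int = 4  #: decimals in TSV outputs
    seed: int = 0  #: recorded for provenance; the analysis stages are deterministic

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        if self.genotypes is None and self.frequencies is None:
            raise ValueError("config must provide genotypes and/or frequencies")
        for path in (self.genotypes, self.frequencies):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input not found: {path}")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}; valid: {ALL_STAGES}")


def _fmt(df, path: Path, precision: int) -> None:
    df.to_csv(path, sep="\t", float_format=f"%.{precision}f")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {**asdict(cfg), "stages": list(cfg.stages)},
        "stages": {},
        "warnings": [],
    }

    freq: FrequencyMatrix | None = None
    table = None
    if cfg.genotypes is not None:
        table = read_genotype_table(cfg.genotypes)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if "stats" in cfg.stages:
            if table is None:
                manifest["warnings"].append(
                    "stats stage skipped: no genotype input (frequencies-only run)"
                )
            else:
                pd_est = PopulationDiversity(het=cfg.het, hwe_family=cfg.hwe_family).fit(table)
                _fmt(pd_est.summary(), outdir / "stats.tsv", cfg.precision)
                pd_est.hwe_.to_csv(outdir / "hwe.tsv", sep="\t", index=False)
                freq = pd_est.frequencies_
                write_frequency_matrix(freq, outdir / "frequencies.tsv", precision=cfg.precision)
                manifest["stages"]["stats"] = {
                    "outputs": ["stats.tsv", "hwe.tsv", "frequencies.tsv"],
                    "het": cfg.het,
                    "hwe_family": cfg.hwe_family,
                    "monomorphic_cells": [list(c) for c in pd_est.monomorphic_],
                }

        if freq is None and cfg.frequencies is not None:
            freq = read_frequency_matrix(cfg.frequencies)

        if "gst" in cfg.stages:
            gst = GstDecomposition(convention=cfg.convention).fit(freq)
            _fmt(gst.summary_frame(), outdir / "gst.tsv", max(cfg.precision, 5))
            manifest["stages"]["gst"] = {
                "outputs": ["gst.tsv"],
                "convention": cfg.convention,
                "excluded_loci": gst.excluded_loci_,
                "Gst_all": gst.Gst_all_,
            }

        if "tree" in cfg.stages:
            nj = NeighborJoining(metric=cfg.distance).fit(freq)
            write_newick(nj.tree_, outdir / "tree.nwk")
            _fmt(nj.distance_matrix_.to_data_frame(), outdir / "dist.tsv", max(cfg.precision, 6))
            manifest["stages"]["tree"] = {
                "outputs": ["tree.nwk", "dist.tsv"],
                "distance": cfg.distance,
            }

        if "pca" in cfg.stages:
            pca = FrequencyPCA(n_components=cfg.pca_components, scale=cfg.pca_scale).fit(freq)
            res = pca.result()
            _fmt(res.scores, outdir / "scores.tsv", max(cfg.precision, 6))
            _fmt(res.loadings, outdir / "loadings.tsv", max(cfg.precision, 6))
            with open(outdir / "variance.tsv", "w") as fh:
                fh.write("component\tvariance_fraction\n")
                for i, v in enumerate(res.variance_fraction):
                    fh.write(f"PC{i + 1}\t{v:.6f}\n")
            manifest["stages"]["pca"] = {
                "outputs": ["scores.tsv", "loadings.tsv", "variance.tsv"],
                "scale": cfg.pca_scale,
                "variance_fraction": [round(float(v), 6) for v in res.variance_fraction],
            }

        manifest["warnings"].extend(str(w.message) for w in caught)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
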