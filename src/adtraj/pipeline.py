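"""End-to-end pipeline driver: classify -> screen -> growth -> associate -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import run_three_step
from .growth import fit_gene_panel
from .io import read_counts, read_madrs, read_phenotypes
from .screening import screen_cohort
from .trajectories import classify_cohort

log = logging.getLogger("adtraj")


@dataclass
class PipelineConfig:
    counts: str | Path = "counts.tsv"
    phenotypes: str | Path = "phenotypes.csv"
    madrs: str | Path = "madrs.csv"
    output_dir: str | Path = "adtraj_out"
    de_fdr: float = 0.20
    corr_p: float = 0.05
    baseline_p: float = 0.20
    step1_p: float = 0.05
    final_fdr: float = 0.05
    criterion2_variable: str = "t8"
    chi_square_scale: str = "n-1"
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr", "corr_p", "baseline_p", "step1_p", "final_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"threshold {name} must lie in (0, 1), got {v}")

    def checksum(self) -> str:
        d = {k: str(v) for k, v in dataclasses.asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    config_checksum: str
    version: str
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    durations: dict = field(default_factory=dict)
    error: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full analysis and write all stage outputs plus a manifest.

    Stage failures are recorded in the manifest; outputs produced before
    the failure are kept.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: str(v) for k, v in dataclasses.asdict(config).items()},
        config_checksum=config.checksum(),
        version=__version__,
    )

    def emit(name: str, df: pd.DataFrame, sep: str = "\t") -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# adtraj {__version__} config={manifest.config_checksum}\n")
            df.to_csv(fh, sep=sep)
        manifest.outputs[name] = _file_checksum(path)

    try:
        t0 = time.perf_counter()
        counts = read_counts(config.counts)
        phenotypes = read_phenotypes(config.phenotypes)
        madrs = read_madrs(config.madrs)

        labels = classify_cohort(madrs)
        emit("labels.csv", labels, sep=",")
        manifest.stage_counts["patients"] = len(labels)
        manifest.durations["classify"] = time.perf_counter() - t0
        log.info("classified %d patients", len(labels))

        t1 = time.perf_counter()
        screen = screen_cohort(
            counts,
            phenotypes,
            labels,
            de_fdr=config.de_fdr,
            corr_p=config.corr_p,
            baseline_p=config.baseline_p,
            pseudocount=config.pseudocount,
            criterion2_variable=config.criterion2_variable,
        )
        emit("de_results.tsv", screen.de)
        emit("funnel.tsv", screen.funnel)
        (out / "selected.txt").write_text("\n".join(screen.selected) + "\n")
        manifest.outputs["selected.txt"] = _file_checksum(out / "selected.txt")
        manifest.stage_counts.update(screen.stage_counts)
        manifest.durations["screen"] = time.perf_counter() - t1
        log.info("funnel counts: %s", screen.stage_counts)

        if not screen.selected:
            empty = pd.DataFrame(
                columns=["gene", "contrast", "log_rr", "se", "p", "fdr", "rr", "ci_low", "ci_high"]
            )
            emit("association.tsv", empty)
            manifest.stage_counts["advancing_rnas"] = 0
            manifest.write(out / "manifest.json")
            return manifest

        t2 = time.perf_counter()
        _, growth_table, intercepts, slopes = fit_gene_panel(
            screen.adjusted_expression, screen.selected, chi_square_scale=config.chi_square_scale
        )
        emit("growth_fits.tsv", growth_table)
        scores = pd.concat(
            {"intercept": intercepts, "slope": slopes}, axis=1
        )
        scores.columns = [f"{g}_{kind}" for kind, g in scores.columns]
        emit("factor_scores.tsv", scores)
        manifest.durations["growth"] = time.perf_counter() - t2

        t3 = time.perf_counter()
        pheno_idx = phenotypes.set_index("subject_id")
        assoc = run_three_step(intercepts, slopes, labels, pheno_idx, step1_p=config.step1_p)
        emit("association.tsv", assoc.table.set_index("gene"))
        manifest.stage_counts["advancing_rnas"] = len(assoc.advancing)
        manifest.stage_counts["fdr_family_size"] = assoc.fdr_family_size
        manifest.stage_counts["final_fdr_hits"] = (
            int((assoc.table["fdr"] < config.final_fdr).sum()) if len(assoc.table) else 0
        )
        manifest.durations["associate"] = time.perf_counter() - t3
    except Exception as exc:  # stage failure: record and keep partial outputs
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest
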