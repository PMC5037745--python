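"""End-to-end orchestration: simulate -> features -> screen -> methylation -> survival.

The pipeline is a pure function of (config, inputs): identical
configuration and input hashes reproduce identical output hashes. Each
stage either consumes a user-supplied file or the synthetic generator's
output, writes its result in a documented text format re-loadable by its
own module, and logs its record count to the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import km_estimate, logrank_test, validate_cohort, write_clinical_tsv
from .expression import ExpressionMatrix
from .methylation import (
    dichotomize,
    methylated_fraction,
    quantify,
    read_pyrograms_tsv,
    write_profiles_tsv,
    write_pyrograms_tsv,
)
from .screen import ScreenParams, screen, write_candidates_tsv
from .sequence_features import (
    GenomeAnnotation,
    find_cpg_islands,
    read_fasta,
    read_genes_bed,
    scan_stat3_sites,
    write_fasta,
    write_genes_bed,
    write_hits_bed,
    write_islands_bed,
)
from .synthetic import (
    CohortSimSpec,
    GenomeSimSpec,
    PlantedTruth,
    generate_clinical,
    generate_expression,
    generate_genome,
    generate_methylation_levels,
    generate_pyrograms,
)

logger = logging.getLogger("episcreen")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class ConfigError(ValueError):
    pass


@dataclass
class IslandParams:
    min_length: int = 200
    gc_min: float = 0.5
    oe_min: float = 0.6
    window: int = 200
    step: int = 1


@dataclass
class MotifParams:
    spacer_min: int = 3
    spacer_max: int = 3


@dataclass
class MethylationParams:
    n_cpgs: int = 11
    noise_sd: float = 0.02
    # "median" follows the study rule (the percent cutoff is the cohort
    # median); a number fixes the survival split at that percent instead.
    survival_cutoff: float | str = "median"
    call_threshold: float = 35.0    # percent; defines a patient as "methylated"
    n_high: int | None = None       # planted high-methylation patients (default 65%)


@dataclass
class InputPaths:
    """Optional real inputs; any left unset is simulated instead."""

    genome_fasta: str | None = None
    genes_bed: str | None = None
    expression_tsv: str | None = None
    pyrograms_tsv: str | None = None
    clinical_tsv: str | None = None


@dataclass
class RunConfig:
    seed: int = 0
    regulator: str | None = None  # default: the simulated regulator gene
    genome: GenomeSimSpec = field(default_factory=GenomeSimSpec)
    cohort: CohortSimSpec = field(default_factory=CohortSimSpec)
    islands: IslandParams = field(default_factory=IslandParams)
    motif: MotifParams = field(default_factory=MotifParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    methylation: MethylationParams = field(default_factory=MethylationParams)
    inputs: InputPaths = field(default_factory=InputPaths)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        """Build from a nested dict, rejecting unknown keys at every level."""
        cfg = cls()
        known = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise ConfigError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current):
                if not isinstance(value, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                names = {f.name for f in dataclasses.fields(current)}
                bad = set(value) - names
                if bad:
                    raise ConfigError(f"unknown keys in section {key!r}: {sorted(bad)}")
                setattr(cfg, key, type(current)(**{**asdict(current), **value}))
            else:
                setattr(cfg, key, value)
        # one seed drives every stage
        cfg.genome = dataclasses.replace(cfg.genome, seed=cfg.seed)
        cfg.cohort = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _preflight(config: RunConfig) -> None:
    for name, path in asdict(config.inputs).items():
        if path is not None and not Path(path).exists():
            raise ConfigError(f"input {name}: file not found: {path}")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the run manifest."""
    _preflight(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name}: {exc}") from exc
                manifest["stages"].setdefault(name, {})["seconds"] = round(
                    time.perf_counter() - self.t0, 3
                )
                return False

            def count(self, label, n):
                manifest["stages"].setdefault(name, {})[label] = int(n)
                logger.info("stage %s: %s = %d", name, label, n)

        return _Stage()

    # -- genome -----------------------------------------------------------
    with stage("genome") as st:
        truth = PlantedTruth()
        if config.inputs.genome_fasta:
            sequences = read_fasta(config.inputs.genome_fasta)
            genes = read_genes_bed(config.inputs.genes_bed) if config.inputs.genes_bed else []
        else:
            sequences, genes, truth = generate_genome(config.genome)
        write_fasta(sequences, out / "genome.fasta")
        write_genes_bed(genes, out / "genes.bed")
        truth.to_json(out / "truth.json")
        annotation = GenomeAnnotation(sequences=sequences, genes=genes)
        st.count("genes", len(genes))

    # -- islands ----------------------------------------------------------
    with stage("islands") as st:
        ip = config.islands
        islands = []
        for chrom in sorted(sequences):
            islands.extend(
                find_cpg_islands(
                    sequences[chrom],
                    chrom=chrom,
                    min_length=ip.min_length,
                    gc_min=ip.gc_min,
                    oe_min=ip.oe_min,
                    window=ip.window,
                    step=ip.step,
                )
            )
        write_islands_bed(islands, out / "islands.bed")
        st.count("islands", len(islands))

    # -- motif scan -------------------------------------------------------
    with stage("scan") as st:
        mp = config.motif
        hits = []
        for chrom in sorted(sequences):
            hits.extend(
                scan_stat3_sites(
                    sequences[chrom],
                    chrom=chrom,
                    spacer_min=mp.spacer_min,
                    spacer_max=mp.spacer_max,
                )
            )
        write_hits_bed(hits, out / "motif_hits.bed")
        st.count("motif_hits", len(hits))

    # -- expression -------------------------------------------------------
    with stage("expression") as st:
        if config.inputs.expression_tsv:
            matrix = ExpressionMatrix.from_tsv(config.inputs.expression_tsv)
        else:
            matrix = generate_expression(config.cohort, truth, genes)
        matrix.to_tsv(out / "expression.tsv")
        st.count("genes_expressed", len(matrix.gene_ids))
        st.count("samples", len(matrix.sample_ids))

    # -- screen -----------------------------------------------------------
    with stage("screen") as st:
        regulator = config.regulator or truth.regulator_gene_id
        if regulator is None:
            raise ConfigError("no regulator gene configured and none simulated")
        candidates = screen(annotation, islands, hits, matrix, regulator, config.screen)
        write_candidates_tsv(candidates, out / "candidates.tsv")
        st.count("candidates_tested", len(candidates))
        st.count("candidates_passing", sum(c.passes for c in candidates))

    # -- methylation ------------------------------------------------------
    with stage("methylation") as st:
        meth = config.methylation
        if config.inputs.pyrograms_tsv:
            pyros = read_pyrograms_tsv(config.inputs.pyrograms_tsv)
        else:
            levels = generate_methylation_levels(
                config.cohort.n_patients,
                n_high=meth.n_high,
                threshold=meth.call_threshold,
                seed=[config.seed, 2],
            )
            pyros = generate_pyrograms(
                levels / 100.0,
                n_cpgs=meth.n_cpgs,
                noise_sd=meth.noise_sd,
                seed=[config.seed, 4],
            )
        write_pyrograms_tsv(pyros, out / "pyrograms.tsv")
        profiles = [quantify(p) for p in pyros]
        write_profiles_tsv(profiles, out / "methylation_profiles.tsv")
        st.count("pyrograms", len(pyros))

    # -- clinical + survival ----------------------------------------------
    with stage("clinical") as st:
        assay_means = np.array([p.assay_mean_percent for p in profiles])
        if config.inputs.clinical_tsv:
            cohort = validate_cohort(pd.read_csv(config.inputs.clinical_tsv, sep="\t"))
        else:
            cohort = generate_clinical(config.cohort, assay_means, truth=truth)
            truth.to_json(out / "truth.json")  # now includes methylation truth
        labels, cutoff = dichotomize(
            cohort["meth_percent"].to_numpy(), config.methylation.survival_cutoff
        )
        cohort = cohort.copy()
        cohort["meth_group"] = labels
        write_clinical_tsv(cohort, out / "clinical.tsv")

        frac = methylated_fraction(
            cohort["meth_percent"].to_numpy(), config.methylation.call_threshold
        )
        groups = {g: sub for g, sub in cohort.groupby("meth_group")}
        report: dict[str, Any] = {
            "methylation_cutoff_percent": cutoff,
            "call_threshold_percent": config.methylation.call_threshold,
            "methylated_fraction": round(frac.fraction, 4),
            "methylated_n": frac.n_called,
            "n_patients": frac.n_total,
        }
        if len(groups) == 2:
            lo, hi = groups["low"], groups["high"]
            lr = logrank_test(lo["os_months"], lo["event"], hi["os_months"], hi["event"])
            report["logrank_chi_square"] = round(lr.chi_square, 4)
            report["logrank_p"] = float(f"{lr.pvalue:.6g}")
            for label, sub in (("low", lo), ("high", hi)):
                km = km_estimate(sub["os_months"], sub["event"])
                km.to_frame().to_csv(
                    out / f"survival_{label}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                report[f"median_os_{label}"] = km.median
                report[f"n_{label}"] = len(sub)
        with open(out / "survival_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        st.count("patients", len(cohort))

    # -- manifest ---------------------------------------------------------
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = sha256_file(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
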