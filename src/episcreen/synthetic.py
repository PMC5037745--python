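"""Synthetic study generator with planted ground truth.

Emulates the inputs of the screen so every downstream stage is testable
without patient data: a genome with CpG islands and GAS motifs planted at
target-gene promoters (and scrubbed near non-target promoters), a paired
tumor/normal RNA-Seq count matrix in which planted targets are inversely
correlated with the regulator and downregulated in tumors, pyrograms with
known per-CpG methylation, and a survival cohort whose hazard depends on
dichotomized methylation.

Counts follow a negative-binomial (gamma-Poisson) law on a log-linear
mean; the regulator-target correlation is induced by sharing the
regulator's latent log-expression residual, with coefficients solved so
that the model correlation across all samples equals the requested value
while the tumor/normal mean difference equals the requested log2FC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, infer_pairing
from .methylation import DEFAULT_N_CPGS, Dispensation, Pyrogram
from .sequence_features import (
    GeneModel,
    find_cpg_islands,
    gc_fraction,
    obs_exp_cpg,
    scan_stat3_sites,
)

# Background CpG depletion (observed/expected), typical of bulk genomic DNA
# outside islands; keeps chance islands out of non-target promoters.
BACKGROUND_CPG_OE = 0.25

# Marginal SDs of log2 expression (biological variation).
REGULATOR_LOG2_SD = 1.0
REGULATOR_TUMOR_LOG2FC = 1.0  # regulator is higher in tumors
TARGET_LOG2_SD = 1.3
BASE_LOG2_MEAN = 9.5

# TSS-relative pyrosequencing assay interval (measured CpGs).
DEFAULT_ASSAY_REGION = (-3524, -3439)

# Default cohort covariate distributions (60-patient gastric cohort shape).
DEFAULT_COVARIATES = {
    "age_mean": 68.5,
    "age_sd": 9.0,
    "age_range": (47, 87),
    "p_male": 43 / 60,
    "stage_probs": (17 / 60, 11 / 60, 25 / 60, 7 / 60),
    "grade_probs": (17 / 60, 11 / 60, 25 / 60, 7 / 60),
    "p_hpylori": 44 / 60,
    "age_shift_high": 0.0,  # optional age difference for the high-meth group
}

BASELINE_MEDIAN_OS_MONTHS = 27.1


class SimulationError(ValueError):
    pass


@dataclass
class GenomeSimSpec:
    """Parameters of the planted genome."""

    n_genes: int = 200
    chrom_length: int = 3_000_000
    background_gc: float = 0.40
    island_gc: float = 0.60
    island_obs_exp: float = 0.80
    island_length: int = 300
    n_target_genes: int = 10
    motif_flank: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_genes > self.n_genes:
            raise SimulationError("n_target_genes must be <= n_genes")
        for frac in (self.background_gc, self.island_gc):
            if not 0 < frac < 1:
                raise SimulationError("GC fractions must lie in (0, 1)")
        if self.island_gc <= self.background_gc:
            raise SimulationError("island_gc must exceed background_gc")
        if self.island_length < 200:
            raise SimulationError("island_length must be >= 200 bp")


@dataclass
class CohortSimSpec:
    """Parameters of the simulated patient cohort."""

    n_pairs: int = 23
    n_patients: int = 60
    regulator_target_corr: float = -0.6
    tumor_downregulation_log2fc: float = -2.0
    dispersion: float = 0.05
    hazard_ratio_high_meth: float = 3.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise SimulationError("n_pairs must be >= 3")
        if abs(self.regulator_target_corr) >= 1:
            raise SimulationError("|regulator_target_corr| must be < 1")
        if self.regulator_target_corr > 0:
            raise SimulationError("regulator_target_corr must be <= 0 (inverse)")
        if self.hazard_ratio_high_meth <= 0:
            raise SimulationError("hazard_ratio_high_meth must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise SimulationError("censor_rate must be in [0, 1)")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating the synthetic study."""

    target_gene_ids: list[str] = field(default_factory=list)
    regulator_gene_id: str | None = None
    island_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    motif_positions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    per_gene_true_corr: dict[str, float] = field(default_factory=dict)
    per_patient_true_meth: dict[str, float] = field(default_factory=dict)
    true_group_hazards: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        truth = cls(**raw)
        truth.island_intervals = {k: tuple(v) for k, v in truth.island_intervals.items()}
        truth.motif_positions = {
            k: [tuple(p) for p in v] for k, v in truth.motif_positions.items()
        }
        return truth


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(
    rng: np.random.Generator, length: int, gc: float, cpg_oe: float
) -> np.ndarray:
    """IID sequence at the given GC, then CpG-thinned toward the target O/E."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    if cpg_oe < 1.0 and length > 1:
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        pos = np.nonzero(is_cg)[0]
        drop = pos[rng.random(pos.size) >= cpg_oe]
        arr[drop] = rng.choice(
            np.frombuffer(b"AT", dtype=np.uint8), size=drop.size
        )
    return arr


def _island_segment(rng: np.random.Generator, spec: GenomeSimSpec) -> np.ndarray:
    """A CpG-island segment verified to satisfy detector-grade criteria."""
    for _ in range(100):
        seg = _random_sequence(rng, spec.island_length, spec.island_gc, spec.island_obs_exp)
        s = seg.tobytes().decode("ascii")
        if gc_fraction(s) >= max(0.5, spec.island_gc - 0.05) and obs_exp_cpg(s) >= max(
            0.6, spec.island_obs_exp - 0.15
        ):
            return seg
    raise SimulationError("could not generate a qualifying island segment")


def _scrub_motifs(
    arr: np.ndarray, start: int, end: int, protect: set[int] = frozenset()
) -> None:
    """Destroy GAS motifs (spacers 2-4) in arr[start:end], in place.

    Mutating the C of the TTC half-site to A breaks the match on both
    strands. Positions in ``protect`` (motif starts) are left alone.
    """
    start, end = max(start, 0), min(end, len(arr))
    for _ in range(10):
        sub = arr[start:end].tobytes().decode("ascii")
        hits = [
            h
            for h in scan_stat3_sites(sub, spacer_min=2, spacer_max=4)
            if start + h.start not in protect
        ]
        if not hits:
            return
        for h in hits:
            arr[start + h.start + 2] = ord("A")
    raise SimulationError("motif scrubbing did not converge")


def generate_genome(
    spec: GenomeSimSpec,
) -> tuple[dict[str, str], list[GeneModel], PlantedTruth]:
    """Build one chromosome with islands + GAS motifs planted at target promoters.

    Genes are evenly spaced on alternating strands; gene ``G001`` is the
    regulator (never a target). Each target's island covers its TSS and a
    ``TTCNNNGAA`` motif is inserted downstream of the island within
    ``motif_flank``; chance motifs near non-target promoters are scrubbed
    so the screen's specificity is measurable against a clean truth.
    """
    rng = np.random.default_rng([spec.seed, 0])
    truth = PlantedTruth()

    arr = _random_sequence(rng, spec.chrom_length, spec.background_gc, BACKGROUND_CPG_OE)

    if spec.n_genes == 0:
        return {"chr1": arr.tobytes().decode("ascii")}, [], truth

    spacing = spec.chrom_length // (spec.n_genes + 1)
    min_spacing = 2 * spec.motif_flank + spec.island_length + 3000
    if spacing < min_spacing:
        raise SimulationError(
            f"chrom_length {spec.chrom_length} too small for {spec.n_genes} genes: "
            f"need >= {min_spacing} bp between promoters, have {spacing}"
        )

    genes = [
        GeneModel(
            gene_id=f"G{i + 1:03d}",
            chrom="chr1",
            tss=(i + 1) * spacing,
            strand="+" if i % 2 == 0 else "-",
        )
        for i in range(spec.n_genes)
    ]
    truth.regulator_gene_id = genes[0].gene_id

    # Targets drawn from genes other than the regulator (unless saturated).
    candidates = np.arange(1, spec.n_genes) if spec.n_target_genes < spec.n_genes else np.arange(spec.n_genes)
    target_idx = np.sort(rng.choice(candidates, size=spec.n_target_genes, replace=False))
    target_ids = {genes[i].gene_id for i in target_idx}
    truth.target_gene_ids = sorted(target_ids)

    motif_tail = np.frombuffer(b"GAA", dtype=np.uint8)
    motif_head = np.frombuffer(b"TTC", dtype=np.uint8)
    protect: set[int] = set()
    for i in target_idx:
        g = genes[i]
        isl_start = g.tss - spec.island_length // 2
        isl_end = isl_start + spec.island_length
        arr[isl_start:isl_end] = _island_segment(rng, spec)
        truth.island_intervals[g.gene_id] = (isl_start, isl_end)

        gap_hi = spec.motif_flank - spec.island_length - 200
        gap = int(rng.integers(50, max(51, gap_hi)))
        m_start = isl_end + gap
        arr[m_start : m_start + 3] = motif_head
        arr[m_start + 3 : m_start + 6] = rng.choice(_BASES, size=3)
        arr[m_start + 6 : m_start + 9] = motif_tail
        truth.motif_positions[g.gene_id] = [(m_start, m_start + 9)]
        protect.add(m_start)

    # Scrub chance motifs near non-target promoters (island flank zone).
    zone = spec.motif_flank + spec.island_length // 2 + 1500
    for i, g in enumerate(genes):
        if g.gene_id in target_ids:
            continue
        _scrub_motifs(arr, g.tss - zone, g.tss + zone, protect)

    seq = arr.tobytes().decode("ascii")

    # Self-consistency: every recorded motif must be recoverable by scanning.
    for gid, positions in truth.motif_positions.items():
        for s, e in positions:
            window = seq[s:e]
            if not (window.startswith("TTC") and window.endswith("GAA")):
                raise SimulationError(f"planted motif for {gid} was destroyed")

    return {"chr1": seq}, genes, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _solve_target_loadings(
    rho: float, lfc: float, delta_r: float, sigma_r: float, sigma_t: float
) -> tuple[float, float]:
    """Coefficients (a on the regulator residual, b on private noise) so that
    corr(target, regulator) = rho marginally while the tumor/normal log2
    difference equals lfc. Tumor status is Bernoulli(1/2) by design."""
    sigma_R = math.sqrt(delta_r**2 / 4 + sigma_r**2)
    a = (rho * sigma_t * sigma_R - lfc * delta_r / 4) / sigma_r
    b_sq = sigma_t**2 - lfc**2 / 4 - a**2
    if b_sq < 0:
        raise SimulationError(
            "requested correlation/log2FC combination exceeds the target's "
            "log2 variance budget; increase TARGET_LOG2_SD or soften the effects"
        )
    return a, math.sqrt(b_sq)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + dispersion * mu^2."""
    mean = np.maximum(mean, 1e-8)
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    else:
        lam = mean
    return rng.poisson(lam)


def generate_expression(
    spec: CohortSimSpec,
    truth: PlantedTruth,
    genes: Sequence[GeneModel] | Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Paired tumor/normal count matrix with planted regulator-target structure.

    The regulator runs high in tumors; each planted target shares the
    regulator's latent log2 residual so its marginal correlation with the
    regulator equals ``regulator_target_corr``, and its tumor mean sits
    ``tumor_downregulation_log2fc`` log2 units below the matched normal
    mean. All other genes are independent noise.
    """
    if truth.regulator_gene_id is None:
        raise SimulationError("truth lacks a regulator gene")
    if genes is None:
        gene_ids = sorted({truth.regulator_gene_id, *truth.target_gene_ids})
    else:
        gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    if truth.regulator_gene_id not in gene_ids:
        raise SimulationError("regulator gene missing from gene list")

    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_pairs
    patients = [f"P{i + 1:03d}" for i in range(n)]
    columns = [f"{p}_{s}" for p in patients for s in ("T", "N")]
    is_tumor = np.array([c.endswith("_T") for c in columns], dtype=float)

    rho = spec.regulator_target_corr
    lfc = spec.tumor_downregulation_log2fc
    a, b = _solve_target_loadings(rho, lfc, REGULATOR_TUMOR_LOG2FC, REGULATOR_LOG2_SD, TARGET_LOG2_SD)

    eps_reg = rng.normal(size=2 * n)
    log2_reg = BASE_LOG2_MEAN + REGULATOR_TUMOR_LOG2FC * is_tumor + REGULATOR_LOG2_SD * eps_reg

    target_set = set(truth.target_gene_ids)
    log2_means = np.empty((len(gene_ids), 2 * n))
    for gi, gid in enumerate(gene_ids):
        if gid == truth.regulator_gene_id:
            log2_means[gi] = log2_reg
            truth.per_gene_true_corr[gid] = 1.0
        elif gid in target_set:
            eta = rng.normal(size=2 * n)
            log2_means[gi] = BASE_LOG2_MEAN + lfc * is_tumor + a * eps_reg + b * eta
            truth.per_gene_true_corr[gid] = rho
        else:
            base = rng.uniform(5.0, 10.0)
            log2_means[gi] = base + rng.normal(size=2 * n)
            truth.per_gene_true_corr[gid] = 0.0

    counts = _nb_counts(rng, 2.0**log2_means, spec.dispersion)
    gene_lengths = pd.Series(
        rng.integers(500, 5001, size=len(gene_ids)), index=gene_ids, dtype=float
    )
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=columns)
    return ExpressionMatrix(
        counts=frame, gene_lengths=gene_lengths, pairing=infer_pairing(columns)
    )


# ---------------------------------------------------------------------------
# Pyrograms
# ---------------------------------------------------------------------------

def generate_pyrograms(
    true_meth: Sequence[float] | Sequence[Sequence[float]],
    n_cpgs: int = DEFAULT_N_CPGS,
    noise_sd: float = 0.02,
    seed: int | None = None,
    assay_region: tuple[int, int] = DEFAULT_ASSAY_REGION,
) -> list[Pyrogram]:
    """One pyrogram per entry of ``true_meth`` (scalar or per-CpG fractions).

    Each CpG contributes a C and a T dispensation whose expectations are
    proportional to (fraction, 1 - fraction); Gaussian noise of SD
    ``noise_sd`` is added and truncated at 0. Reference dispensations
    (non-CpG) of unit intensity are interleaved for realism.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    pyros = []
    for si, frac in enumerate(true_meth):
        per_cpg = np.broadcast_to(np.asarray(frac, dtype=float), (n_cpgs,))
        if np.any((per_cpg < 0) | (per_cpg > 1)):
            raise SimulationError("methylated fractions must lie in [0, 1]")
        disp: list[Dispensation] = []
        for ci, f in enumerate(per_cpg):
            disp.append(
                Dispensation("A", max(0.0, 1.0 + rng.normal(0, noise_sd)), None)
            )
            c = max(0.0, f + rng.normal(0, noise_sd))
            t = max(0.0, (1.0 - f) + rng.normal(0, noise_sd))
            disp.append(Dispensation("C", c, ci))
            disp.append(Dispensation("T", t, ci))
        pyros.append(
            Pyrogram(sample_id=f"S{si + 1:03d}", dispensations=disp, assay_region=assay_region)
        )
    return pyros


def generate_methylation_levels(
    n_patients: int,
    n_high: int | None = None,
    threshold: float = 35.0,
    seed: int | None = None,
    high_range: tuple[float, float] = (40.0, 80.0),
    low_range: tuple[float, float] = (5.0, 30.0),
) -> np.ndarray:
    """Planted two-component mixture of assay-mean methylation percents.

    Exactly ``n_high`` patients (default: 65% of the cohort, rounded) draw
    from ``high_range`` above the calling threshold, the rest from
    ``low_range`` below it, then the order is shuffled.
    """
    if n_high is None:
        n_high = round(0.65 * n_patients)
    if not 0 <= n_high <= n_patients:
        raise SimulationError("n_high out of range")
    if not (low_range[1] <= threshold < high_range[0]):
        raise SimulationError("mixture ranges must straddle the threshold")
    rng = np.random.default_rng(seed)
    levels = np.concatenate(
        [
            rng.uniform(*high_range, size=n_high),
            rng.uniform(*low_range, size=n_patients - n_high),
        ]
    )
    rng.shuffle(levels)
    return levels


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------

def generate_clinical(
    spec: CohortSimSpec,
    meth_levels: Sequence[float],
    truth: PlantedTruth | None = None,
    covariates: dict | None = None,
    baseline_median_os: float = BASELINE_MEDIAN_OS_MONTHS,
) -> pd.DataFrame:
    """Survival cohort whose hazard depends on dichotomized methylation.

    Patients above the cohort median methylation (ties low) carry
    ``hazard_ratio_high_meth`` times the baseline exponential hazard; the
    baseline is calibrated so the low group's median OS equals
    ``baseline_median_os`` months. Censoring is independent exponential
    at approximately ``censor_rate``.
    """
    meth = np.asarray(meth_levels, dtype=float)
    if meth.size != spec.n_patients:
        raise SimulationError(
            f"need {spec.n_patients} methylation levels, got {meth.size}"
        )
    cov = {**DEFAULT_COVARIATES, **(covariates or {})}
    rng = np.random.default_rng([spec.seed, 3])

    median = float(np.median(meth))
    high = meth > median
    lam_low = math.log(2) / baseline_median_os
    lam = np.where(high, lam_low * spec.hazard_ratio_high_meth, lam_low)

    t_event = rng.exponential(1.0 / lam)
    if spec.censor_rate > 0:
        lam_c = lam_low * spec.censor_rate / (1 - spec.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=spec.n_patients)
    else:
        t_cens = np.full(spec.n_patients, np.inf)
    os_months = np.round(np.minimum(t_event, t_cens), 2)
    event = (t_event <= t_cens).astype(int)

    lo, hi = cov["age_range"]
    age = np.clip(
        np.round(
            rng.normal(cov["age_mean"], cov["age_sd"], size=spec.n_patients)
            + cov["age_shift_high"] * high
        ),
        lo,
        hi,
    )
    sex = rng.choice(["M", "F"], size=spec.n_patients, p=[cov["p_male"], 1 - cov["p_male"]])
    stage = rng.choice(["I", "II", "III", "IV"], size=spec.n_patients, p=cov["stage_probs"])
    grade = rng.choice(["G1", "G2", "G3", "G4"], size=spec.n_patients, p=cov["grade_probs"])
    hpylori = rng.random(spec.n_patients) < cov["p_hpylori"]

    ids = [f"P{i + 1:03d}" for i in range(spec.n_patients)]
    df = pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "sex": sex,
            "stage": stage,
            "grade": grade,
            "h_pylori": hpylori,
            "meth_percent": meth,
            "os_months": os_months,
            "event": event,
            "meth_group": np.where(high, "high", "low"),
        }
    )
    if truth is not None:
        truth.per_patient_true_meth = {pid: float(m) for pid, m in zip(ids, meth)}
        truth.true_group_hazards = {
            "low": lam_low,
            "high": lam_low * spec.hazard_ratio_high_meth,
        }
    return df
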