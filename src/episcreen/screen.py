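"""Integrative candidate screen for repressed, methylation-prone TF targets.

A gene passes the screen when (i) a CpG island is assigned to its
promoter, (ii) at least one GAS motif lies within ``flank`` bp of that
island, (iii) its expression is inversely correlated with the regulator
below ``corr_threshold`` at FDR ``fdr_q``, and (iv, optionally) it is
expressed lower in tumors than in matched normals. Passing genes are
ranked by ascending correlation, then nearest-site distance, then gene id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, correlate, tumor_normal_test
from .sequence_features import (
    CpGIsland,
    GenomeAnnotation,
    MotifHit,
    assign_promoter_island,
    has_site_near_island,
    interval_gap,
)


class ScreenError(ValueError):
    pass


@dataclass
class ScreenParams:
    """Tunable thresholds of the screen; structure, not values, drives it."""

    flank: int = 5000
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    corr_threshold: float = -0.3
    corr_method: str = "pearson"
    require_tumor_down: bool = True
    fdr_q: float = 0.1

    def __post_init__(self) -> None:
        if not self.corr_threshold < 0:
            raise ScreenError("corr_threshold must be negative")
        if not 0 < self.fdr_q < 1:
            raise ScreenError("fdr_q must be in (0, 1)")
        if self.flank < 0:
            raise ScreenError("flank must be non-negative")


@dataclass
class CandidateRecord:
    gene_id: str
    has_promoter_island: bool
    n_sites_within_flank: int
    nearest_site_distance: int | None
    corr_with_regulator: float
    corr_p: float
    corr_q: float
    tumor_down: bool
    passes: bool
    rank: int | None = None


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ScreenError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sites_near_island(
    island: CpGIsland, hits: Sequence[MotifHit], flank: int
) -> tuple[int, int | None]:
    """Count hits contained within flank of the island + nearest gap distance."""
    lo, hi = island.start - flank, island.end + flank
    n = 0
    nearest: int | None = None
    for h in hits:
        if h.chrom != island.chrom:
            continue
        d = interval_gap(island.start, island.end, h.start, h.end)
        if nearest is None or d < nearest:
            nearest = d
        if h.start >= lo and h.end <= hi:
            n += 1
    return n, nearest


def screen(
    annotation: GenomeAnnotation,
    islands: Sequence[CpGIsland],
    hits: Sequence[MotifHit],
    matrix: ExpressionMatrix,
    regulator_gene_id: str,
    params: ScreenParams | None = None,
) -> list[CandidateRecord]:
    """Rank genes by the island + motif + inverse-correlation filter.

    The regulator itself is excluded from the candidate list. Correlation
    p-values are BH-adjusted across all genes with computable correlation.
    Output is deterministic: passing genes first (rank 1..k by ascending
    correlation, nearest-site distance, gene id), the rest by gene id.
    """
    params = params or ScreenParams()
    if regulator_gene_id not in matrix.counts.index:
        raise ScreenError(f"regulator {regulator_gene_id!r} not in expression matrix")
    reg = matrix.log_rpkm(regulator_gene_id).to_numpy(dtype=float)

    records: list[CandidateRecord] = []
    pvals: list[float] = []
    for gene in sorted(annotation.genes, key=lambda g: g.gene_id):
        if gene.gene_id == regulator_gene_id:
            continue
        island = assign_promoter_island(
            gene,
            islands,
            upstream=params.promoter_upstream,
            downstream=params.promoter_downstream,
        )
        if island is not None:
            n_sites, nearest = _sites_near_island(island, hits, params.flank)
        else:
            n_sites, nearest = 0, None

        if gene.gene_id in matrix.counts.index:
            expr = matrix.log_rpkm(gene.gene_id).to_numpy(dtype=float)
            try:
                corr = correlate(reg, expr, method=params.corr_method)
                r, p = corr.r, corr.pvalue
            except ValueError:
                r, p = np.nan, np.nan
            tn = tumor_normal_test(matrix, gene.gene_id)
            tumor_down = tn.tumor_down
        else:
            r, p, tumor_down = np.nan, np.nan, False

        records.append(
            CandidateRecord(
                gene_id=gene.gene_id,
                has_promoter_island=island is not None,
                n_sites_within_flank=n_sites,
                nearest_site_distance=nearest,
                corr_with_regulator=r,
                corr_p=p,
                corr_q=np.nan,
                tumor_down=tumor_down,
                passes=False,
            )
        )
        pvals.append(p)

    # BH across the genes actually tested (finite p)
    pv = np.asarray(pvals, dtype=float)
    tested = np.isfinite(pv)
    if tested.any():
        qv = np.full_like(pv, np.nan)
        qv[tested] = bh_adjust(pv[tested])
        for rec, q in zip(records, qv):
            rec.corr_q = float(q) if np.isfinite(q) else np.nan

    for rec in records:
        rec.passes = bool(
            rec.has_promoter_island
            and rec.n_sites_within_flank >= 1
            and np.isfinite(rec.corr_with_regulator)
            and rec.corr_with_regulator <= params.corr_threshold
            and np.isfinite(rec.corr_q)
            and rec.corr_q <= params.fdr_q
            and (rec.tumor_down or not params.require_tumor_down)
        )

    def sort_key(rec: CandidateRecord):
        if rec.passes:
            dist = rec.nearest_site_distance
            return (0, rec.corr_with_regulator, dist if dist is not None else np.inf, rec.gene_id)
        return (1, 0.0, 0.0, rec.gene_id)

    records.sort(key=sort_key)
    rank = 0
    for rec in records:
        if rec.passes:
            rank += 1
            rec.rank = rank
    return records


def candidates_to_frame(records: Iterable[CandidateRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    return df


def write_candidates_tsv(records: Iterable[CandidateRecord], path: str | Path) -> None:
    candidates_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_run_manifest(path: str | Path, params: ScreenParams, seed: int | None,
                       input_hashes: dict[str, str]) -> None:
    payload = {
        "params": asdict(params),
        "seed": seed,
        "input_hashes": input_hashes,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
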