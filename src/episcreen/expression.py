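"""Expression-level analytics: RPKM, tumor/normal tests, correlation, qPCR.

Covers the quantitative readouts around the screen: RPKM normalization of
a paired tumor/normal count matrix, two-sample comparison of a gene
between tumors and matched normals, regulator-target correlation,
comparative-Ct (delta-delta-Ct) relative qPCR quantification, and
ChIP-PCR fold enrichment over a control locus.

Tests and correlations run on log2(RPKM + 1) by default; the raw scale is
available via ``log_transform=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionInputError(ValueError):
    """Raised for malformed expression/qPCR input."""


def rpkm(
    counts: np.ndarray | float,
    gene_length: np.ndarray | float,
    library_size: np.ndarray | float,
):
    """Reads per kilobase per million: counts * 1e9 / (length * library size)."""
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(gene_length <= 0):
        raise ExpressionInputError("gene lengths must be positive")
    if np.any(library_size <= 0):
        raise ExpressionInputError("library sizes must be positive")
    return np.asarray(counts, dtype=float) * 1e9 / (gene_length * library_size)


@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with tumor/normal pairing metadata.

    ``counts`` is indexed by gene_id; sample columns follow the
    ``{patient}_{T|N}`` convention captured in ``pairing`` (patient ->
    (tumor column, normal column)). Library sizes are the column sums, so
    RPKM is fully derived from counts and lengths.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    pairing: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ExpressionInputError("duplicate gene_ids")
        if (self.counts.values < 0).any():
            raise ExpressionInputError("negative counts")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ExpressionInputError("every gene needs a positive length")
        cols = set(self.counts.columns)
        for patient, (t_col, n_col) in self.pairing.items():
            if t_col not in cols or n_col not in cols:
                raise ExpressionInputError(
                    f"patient {patient}: pairing refers to missing column"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def rpkm(self) -> pd.DataFrame:
        values = rpkm(
            self.counts.values,
            self.gene_lengths.values[:, None],
            self.library_sizes.values[None, :],
        )
        return pd.DataFrame(values, index=self.counts.index, columns=self.counts.columns)

    def tumor_columns(self) -> list[str]:
        return [t for t, _ in self.pairing.values()]

    def normal_columns(self) -> list[str]:
        return [n for _, n in self.pairing.values()]

    def log_rpkm(self, gene_id: str, pseudocount: float = 1.0) -> pd.Series:
        if gene_id not in self.counts.index:
            raise ExpressionInputError(f"gene {gene_id} not in matrix")
        return np.log2(self.rpkm.loc[gene_id] + pseudocount)

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.gene_lengths)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if "length_bp" not in df.columns:
            raise ExpressionInputError(f"{path}: missing length_bp column")
        lengths = df.pop("length_bp")
        pairing = infer_pairing(df.columns)
        return cls(counts=df, gene_lengths=lengths, pairing=pairing)


def infer_pairing(sample_ids: Iterable[str]) -> dict[str, tuple[str, str]]:
    """Recover patient -> (tumor, normal) columns from ``{patient}_{T|N}`` names."""
    tumors: dict[str, str] = {}
    normals: dict[str, str] = {}
    for sid in sample_ids:
        if sid.endswith("_T"):
            tumors[sid[:-2]] = sid
        elif sid.endswith("_N"):
            normals[sid[:-2]] = sid
        else:
            raise ExpressionInputError(f"sample {sid!r} lacks a _T/_N suffix")
    if set(tumors) != set(normals):
        odd = set(tumors) ^ set(normals)
        raise ExpressionInputError(f"unpaired patients: {sorted(odd)}")
    return {p: (tumors[p], normals[p]) for p in sorted(tumors)}


class TumorNormalResult(NamedTuple):
    statistic: float
    pvalue: float
    tumor_down: bool
    mean_tumor: float
    mean_normal: float


def tumor_normal_test(
    matrix: ExpressionMatrix,
    gene_id: str,
    paired: bool = False,
    log_transform: bool = True,
) -> TumorNormalResult:
    """Two-sample t-test of one gene between tumor and normal columns.

    Unpaired (pooled-variance) by default; ``paired=True`` uses the
    matched-pairs t-test. Values are log2(RPKM + 1) unless
    ``log_transform`` is off. When both groups are constant with equal
    means the test is degenerate and p = 1 by convention.
    """
    values = (
        matrix.log_rpkm(gene_id) if log_transform else matrix.rpkm.loc[gene_id]
    )
    tumor = values[matrix.tumor_columns()].to_numpy(dtype=float)
    normal = values[matrix.normal_columns()].to_numpy(dtype=float)
    if len(tumor) < 2 or len(normal) < 2:
        raise ExpressionInputError("need >= 2 samples per group")
    if paired:
        res = stats.ttest_rel(tumor, normal)
    else:
        res = stats.ttest_ind(tumor, normal, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups
        t = 0.0
        p = 1.0 if np.isclose(tumor.mean(), normal.mean()) else 0.0
    return TumorNormalResult(
        statistic=t,
        pvalue=p,
        tumor_down=bool(tumor.mean() < normal.mean()),
        mean_tumor=float(tumor.mean()),
        mean_normal=float(normal.mean()),
    )


class CorrelationResult(NamedTuple):
    r: float
    pvalue: float
    n: int
    method: str


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationResult:
    """Pearson (default) or Spearman correlation with its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ExpressionInputError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise ExpressionInputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ExpressionInputError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ExpressionInputError(f"unknown method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x), method)


# ---------------------------------------------------------------------------
# qPCR: comparative Ct and ChIP enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrRecord:
    """One sample's target and reference-gene Ct values.

    ``condition`` labels the experimental group; records whose condition
    equals the calibrator label anchor relative expression at 1.
    """

    sample_id: str
    target_ct: float
    reference_ct: float | None
    condition: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_ct) or self.target_ct <= 0:
            raise ExpressionInputError(
                f"sample {self.sample_id}: target Ct must be finite and > 0"
            )
        if self.reference_ct is not None and not (
            np.isfinite(self.reference_ct) and self.reference_ct > 0
        ):
            raise ExpressionInputError(
                f"sample {self.sample_id}: reference Ct must be finite and > 0"
            )


def comparative_ct(
    records: Sequence[QpcrRecord], calibrator: str
) -> dict[str, float]:
    """Relative expression 2^(-ddCt) versus the mean dCt of the calibrator group.

    dCt = target Ct - reference Ct (perfect doubling assumed), so the
    calibrator group maps to 1 on average.
    """
    for rec in records:
        if rec.reference_ct is None:
            raise ExpressionInputError(
                f"sample {rec.sample_id}: missing reference-gene measurement"
            )
    calib = [r for r in records if r.condition == calibrator]
    if not calib:
        raise ExpressionInputError(f"no records with calibrator condition {calibrator!r}")
    dct = {r.sample_id: r.target_ct - r.reference_ct for r in records}
    calib_mean = float(np.mean([dct[r.sample_id] for r in calib]))
    return {sid: float(2.0 ** (-(d - calib_mean))) for sid, d in dct.items()}


def chip_enrichment(
    ip_ct: float, input_ct: float, control_ip_ct: float, control_input_ct: float
) -> float:
    """ChIP-PCR fold enrichment at a test locus over a control locus.

    2^(-[(IP - input) - (control IP - control input)]); the control locus
    maps to 1 by construction.
    """
    for v in (ip_ct, input_ct, control_ip_ct, control_input_ct):
        if not np.isfinite(v):
            raise ExpressionInputError("all Ct values must be finite")
    ddct = (ip_ct - input_ct) - (control_ip_ct - control_input_ct)
    return float(2.0 ** (-ddct))
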