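"""Bisulfite-pyrosequencing methylation quantification.

After bisulfite conversion, an unmethylated CpG cytosine reads as T while
a methylated one stays C, so the C:T incorporation ratio at each CpG
dispensation measures the methylated fraction. The assay modelled here
interrogates 11 CpG sites upstream of the TSS; per-patient methylation is
the arithmetic mean over the assay's CpGs, and patients are dichotomized
at a configurable percent cutoff (strictly-greater goes high).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

DEFAULT_N_CPGS = 11


class PyrogramError(ValueError):
    """Raised for malformed pyrograms (missing or failed dispensations)."""


@dataclass(frozen=True)
class Dispensation:
    nucleotide: str
    intensity: float
    cpg_index: int | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise PyrogramError("negative dispensation intensity")


@dataclass
class Pyrogram:
    """Ordered dispensation intensities for one sample.

    Each interrogated CpG must appear in exactly one C- and one
    T-dispensation tagged with its ``cpg_index``; the TSS-relative assay
    region is carried as metadata only.
    """

    sample_id: str
    dispensations: list[Dispensation]
    assay_region: tuple[int, int] | None = None

    def cpg_intensities(self) -> dict[int, dict[str, float]]:
        table: dict[int, dict[str, float]] = {}
        for d in self.dispensations:
            if d.cpg_index is None:
                continue
            if d.nucleotide not in ("C", "T"):
                raise PyrogramError(
                    f"{self.sample_id}: CpG {d.cpg_index} tagged on a "
                    f"{d.nucleotide} dispensation"
                )
            slot = table.setdefault(d.cpg_index, {})
            if d.nucleotide in slot:
                raise PyrogramError(
                    f"{self.sample_id}: duplicate {d.nucleotide} dispensation "
                    f"for CpG {d.cpg_index}"
                )
            slot[d.nucleotide] = d.intensity
        return table


@dataclass
class MethylationProfile:
    sample_id: str
    per_cpg_percent: list[float]
    assay_mean_percent: float
    n_cpgs: int

    def __post_init__(self) -> None:
        if any(not (0 <= p <= 100) for p in self.per_cpg_percent):
            raise PyrogramError("per-CpG percent outside [0, 100]")


def quantify(pyro: Pyrogram) -> MethylationProfile:
    """Per-CpG methylation percent = 100 * C / (C + T), plus the assay mean."""
    table = pyro.cpg_intensities()
    if not table:
        raise PyrogramError(f"{pyro.sample_id}: no CpG-tagged dispensations")
    percents = []
    for idx in sorted(table):
        slot = table[idx]
        if "C" not in slot or "T" not in slot:
            raise PyrogramError(
                f"{pyro.sample_id}: CpG {idx} missing its "
                f"{'C' if 'C' not in slot else 'T'} dispensation"
            )
        total = slot["C"] + slot["T"]
        if total == 0:
            raise PyrogramError(
                f"{pyro.sample_id}: failed dispensation at CpG {idx} (C + T = 0)"
            )
        percents.append(100.0 * slot["C"] / total)
    return MethylationProfile(
        sample_id=pyro.sample_id,
        per_cpg_percent=percents,
        assay_mean_percent=float(np.mean(percents)),
        n_cpgs=len(percents),
    )


def bisulfite_convert(seq: str, methylated_positions: Iterable[int] = ()) -> str:
    """Bisulfite-convert a sequence: unmethylated C -> T, methylated CpG C kept.

    Positions must index the C of a CpG dinucleotide.
    """
    seq = seq.upper()
    meth = set(methylated_positions)
    for pos in meth:
        if pos < 0 or pos >= len(seq) or seq[pos] != "C":
            raise PyrogramError(f"methylated position {pos} is not a C")
        if pos + 1 >= len(seq) or seq[pos + 1] != "G":
            raise PyrogramError(f"methylated position {pos} is not a CpG cytosine")
    return "".join(
        "T" if c == "C" and i not in meth else c for i, c in enumerate(seq)
    )


def dichotomize(
    levels: Sequence[float], cutoff: float | str = "median"
) -> tuple[list[str], float]:
    """Split patients into low/high methylation at a percent cutoff.

    ``cutoff`` may be a number or ``"median"`` (the sample median). High
    means strictly greater than the cutoff; ties go low.
    """
    arr = np.asarray(levels, dtype=float)
    if arr.size == 0:
        raise ValueError("no methylation levels supplied")
    cut = float(np.median(arr)) if cutoff == "median" else float(cutoff)
    labels = ["high" if lv > cut else "low" for lv in arr]
    return labels, cut


class MethylatedFraction(NamedTuple):
    fraction: float
    n_called: int
    n_total: int


def methylated_fraction(
    levels_or_labels: Sequence, threshold: float | None = None
) -> MethylatedFraction:
    """Proportion of patients called methylated, with the count reported.

    Accepts either low/high labels from :func:`dichotomize` or numeric
    levels plus an explicit ``threshold`` (strictly greater is called
    methylated). The threshold is a required study parameter: no default.
    """
    items = list(levels_or_labels)
    if not items:
        raise ValueError("empty input")
    if all(isinstance(x, str) for x in items):
        called = sum(x == "high" for x in items)
    else:
        if threshold is None:
            raise ValueError("numeric levels require an explicit threshold")
        called = int(np.sum(np.asarray(items, dtype=float) > threshold))
    return MethylatedFraction(called / len(items), called, len(items))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def pyrograms_to_frame(pyros: Iterable[Pyrogram]) -> pd.DataFrame:
    rows = []
    for p in pyros:
        for i, d in enumerate(p.dispensations):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "dispensation_index": i,
                    "nucleotide": d.nucleotide,
                    "intensity": d.intensity,
                    "cpg_index": -1 if d.cpg_index is None else d.cpg_index,
                }
            )
    return pd.DataFrame(rows)


def write_pyrograms_tsv(pyros: Iterable[Pyrogram], path: str | Path) -> None:
    pyrograms_to_frame(pyros).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pyrograms_tsv(path: str | Path) -> list[Pyrogram]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "dispensation_index", "nucleotide", "intensity", "cpg_index"}
    missing = required - set(df.columns)
    if missing:
        raise PyrogramError(f"{path}: missing columns {sorted(missing)}")
    pyros = []
    for sid, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("dispensation_index")
        disp = [
            Dispensation(
                nucleotide=row.nucleotide,
                intensity=float(row.intensity),
                cpg_index=None if row.cpg_index < 0 else int(row.cpg_index),
            )
            for row in grp.itertuples()
        ]
        pyros.append(Pyrogram(sample_id=str(sid), dispensations=disp))
    return pyros


def profiles_to_frame(profiles: Iterable[MethylationProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id}
        row.update({f"cpg_{i + 1}": v for i, v in enumerate(p.per_cpg_percent)})
        row["assay_mean"] = p.assay_mean_percent
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_tsv(profiles: Iterable[MethylationProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.6g")
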