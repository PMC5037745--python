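"""CpG-island detection, promoter assignment, and GAS-motif scanning.

This module implements the sequence side of the candidate screen: find
CpG islands with sliding-window Gardiner-Garden--Frommer criteria, assign
an island to each gene promoter, and scan for STAT-family GAS elements
(consensus ``TTC N{s} GAA``) near those islands.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

# Classic Gardiner-Garden--Frommer island criteria.
DEFAULT_MIN_LENGTH = 200
DEFAULT_GC_MIN = 0.5
DEFAULT_OE_MIN = 0.6
DEFAULT_WINDOW = 200
DEFAULT_STEP = 1

DEFAULT_SPACER_MIN = 3
DEFAULT_SPACER_MAX = 3
DEFAULT_FLANK = 5000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceInputError(ValueError):
    """Raised for malformed sequence input (bad alphabet, bad parameters)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its transcription start site and orientation."""

    gene_id: str
    chrom: str
    tss: int  # 0-based position of the TSS
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise SequenceInputError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise SequenceInputError(f"gene {self.gene_id}: negative TSS")


@dataclass
class GenomeAnnotation:
    """Sequences plus gene models in one coordinate convention."""

    sequences: dict[str, str]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise SequenceInputError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom in self.sequences and g.tss >= len(self.sequences[g.chrom]):
                raise SequenceInputError(
                    f"gene {g.gene_id}: TSS {g.tss} beyond end of {g.chrom}"
                )


@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or 'both'
    matched_sequence: str
    spacer_length: int


def gc_fraction(window: str) -> float:
    """G+C fraction of a sequence window."""
    if not window:
        return 0.0
    return (window.count("C") + window.count("G")) / len(window)


def obs_exp_cpg(window: str) -> float:
    """Observed/expected CpG ratio: (#CpG x L) / (#C x #G); 0 if no C or no G."""
    n_c = window.count("C")
    n_g = window.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cpg = window.count("CG")
    return n_cpg * len(window) / (n_c * n_g)


def _validate_sequence(seq: str) -> None:
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise SequenceInputError(f"sequence contains non-ACGTN characters: {sorted(bad)}")


def _window_stats_arrays(seq: str):
    """Cumulative C/G/N/CpG counts enabling O(1) interval statistics."""
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = b == ord("C")
    is_g = b == ord("G")
    is_n = b == ord("N")
    cum_c = np.concatenate(([0], np.cumsum(is_c)))
    cum_g = np.concatenate(([0], np.cumsum(is_g)))
    cum_n = np.concatenate(([0], np.cumsum(is_n)))
    if len(b) > 1:
        cpg = is_c[:-1] & is_g[1:]
    else:
        cpg = np.zeros(0, dtype=bool)
    cum_cpg = np.concatenate(([0], np.cumsum(cpg)))
    return cum_c, cum_g, cum_n, cum_cpg


def _make_interval_qualifier(
    seq: str, gc_min: float, oe_min: float
) -> Callable[[int, int], tuple[bool, float, float]]:
    """Return qualifies(start, end) -> (ok, gc, oe) backed by cumulative sums.

    Intervals containing N never qualify. CpG dinucleotides are counted
    fully inside the interval.
    """
    cum_c, cum_g, cum_n, cum_cpg = _window_stats_arrays(seq)

    def qualifies(s: int, e: int) -> tuple[bool, float, float]:
        length = e - s
        if length <= 0:
            return False, 0.0, 0.0
        if cum_n[e] - cum_n[s] > 0:
            return False, 0.0, 0.0
        n_c = int(cum_c[e] - cum_c[s])
        n_g = int(cum_g[e] - cum_g[s])
        gc = (n_c + n_g) / length
        if n_c == 0 or n_g == 0:
            return False, gc, 0.0
        n_cpg = int(cum_cpg[e - 1] - cum_cpg[s])
        oe = n_cpg * length / (n_c * n_g)
        return gc >= gc_min and oe >= oe_min, gc, oe

    return qualifies


def merge_window_starts(starts: Sequence[int], window: int) -> list[tuple[int, int]]:
    """Merge qualifying windows [i, i+window) that overlap or are adjacent."""
    merged: list[tuple[int, int]] = []
    for s in sorted(starts):
        e = s + window
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def maximal_qualifying_subinterval(
    region: tuple[int, int],
    qualifies: Callable[[int, int], tuple[bool, float, float]],
    min_length: int,
) -> tuple[int, int, float, float] | None:
    """Largest sub-interval of ``region`` meeting all criteria; leftmost on ties.

    Scans candidate lengths in descending order, so the common case (the
    whole merged region qualifies) exits immediately.
    """
    s0, e0 = region
    for length in range(e0 - s0, min_length - 1, -1):
        for s in range(s0, e0 - length + 1):
            ok, gc, oe = qualifies(s, s + length)
            if ok:
                return s, s + length, gc, oe
    return None


def find_cpg_islands(
    seq: str,
    chrom: str = "chr1",
    min_length: int = DEFAULT_MIN_LENGTH,
    gc_min: float = DEFAULT_GC_MIN,
    oe_min: float = DEFAULT_OE_MIN,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[CpGIsland]:
    """Sliding-window CpG-island detector.

    A window qualifies when it is N-free, has GC fraction >= ``gc_min`` and
    observed/expected CpG >= ``oe_min``. Overlapping or adjacent qualifying
    windows are merged, and each merged region is reduced to its maximal
    sub-interval that itself satisfies all criteria at length >=
    ``min_length``. Reported islands are disjoint and sorted.
    """
    if min(min_length, window, step) <= 0:
        raise SequenceInputError("min_length, window and step must be positive")
    seq = seq.upper()
    _validate_sequence(seq)
    if len(seq) < window:
        return []

    cum_c, cum_g, cum_n, cum_cpg = _window_stats_arrays(seq)
    starts = np.arange(0, len(seq) - window + 1, step)
    ends = starts + window
    n_c = cum_c[ends] - cum_c[starts]
    n_g = cum_g[ends] - cum_g[starts]
    n_n = cum_n[ends] - cum_n[starts]
    n_cpg = cum_cpg[ends - 1] - cum_cpg[starts]
    gc = (n_c + n_g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cpg * window / (n_c * n_g), 0.0)
    good = (n_n == 0) & (gc >= gc_min) & (oe >= oe_min)

    qualifies = _make_interval_qualifier(seq, gc_min, oe_min)
    islands: list[CpGIsland] = []
    for region in merge_window_starts(starts[good].tolist(), window):
        best = maximal_qualifying_subinterval(region, qualifies, min_length)
        if best is not None:
            s, e, g, o = best
            islands.append(CpGIsland(chrom, s, e, g, o))
    return islands


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_stat3_sites(
    seq: str,
    chrom: str = "chr1",
    region: tuple[int, int] | None = None,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
) -> list[MotifHit]:
    """Scan for GAS elements ``TTC N{s} GAA`` with spacer_min <= s <= spacer_max.

    Both strands are scanned; since the reverse complement of
    ``TTC N{s} GAA`` is again ``TTC N{s} GAA`` (the half-sites are mutual
    reverse complements), every consensus hit matches on both strands and
    identical intervals are collapsed with strand ``both``. Ns never match.
    """
    if spacer_min > spacer_max:
        raise SequenceInputError("spacer_min must be <= spacer_max")
    if spacer_min < 0:
        raise SequenceInputError("spacer lengths must be non-negative")
    seq = seq.upper()
    _validate_sequence(seq)
    if region is None:
        region = (0, len(seq))
    r0, r1 = region
    if r0 < 0 or r1 > len(seq):
        raise SequenceInputError("region outside sequence bounds")
    sub = seq[r0:r1]

    found: dict[tuple[int, int], dict] = {}
    for spacer in range(spacer_min, spacer_max + 1):
        motif_len = 6 + spacer
        pat = re.compile(r"(?=(TTC[ACGT]{%d}GAA))" % spacer)
        for m in pat.finditer(sub):
            s = r0 + m.start()
            key = (s, s + motif_len)
            rec = found.setdefault(
                key,
                {"strands": set(), "seq": m.group(1), "spacer": spacer},
            )
            rec["strands"].add("+")
        for m in pat.finditer(reverse_complement(sub)):
            e = r1 - m.start()
            key = (e - motif_len, e)
            rec = found.setdefault(
                key,
                {"strands": set(), "seq": seq[e - motif_len : e], "spacer": spacer},
            )
            rec["strands"].add("-")

    hits = []
    for (s, e), rec in sorted(found.items()):
        strand = "both" if len(rec["strands"]) == 2 else next(iter(rec["strands"]))
        hits.append(MotifHit(chrom, s, e, strand, rec["seq"], rec["spacer"]))
    return hits


def scan_pwm_sites(
    seq: str,
    pwm: np.ndarray,
    threshold: float,
    chrom: str = "chr1",
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[MotifHit]:
    """Optional position-weight-matrix scan (log2-odds vs background).

    ``pwm`` is a 4 x L probability matrix over A, C, G, T. Windows scoring
    >= ``threshold`` on either strand are reported; Ns never match. This
    mode is off by default in the screen, which uses the GAS consensus.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise SequenceInputError("pwm must be 4 x L (rows A, C, G, T)")
    seq = seq.upper()
    _validate_sequence(seq)
    L = pwm.shape[1]
    bg = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        logodds = np.log2(np.maximum(pwm, 1e-12) / bg[:, None])
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand, s_scan in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(len(s_scan) - L + 1):
            win = s_scan[i : i + L]
            if "N" in win:
                continue
            score = sum(logodds[idx[c], j] for j, c in enumerate(win))
            if score >= threshold:
                if strand == "+":
                    s, e = i, i + L
                else:
                    s, e = len(seq) - i - L, len(seq) - i
                hits.append(MotifHit(chrom, s, e, strand, seq[s:e], L - 6))
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


def promoter_window(gene: GeneModel, upstream: int, downstream: int) -> tuple[int, int]:
    """Strand-aware promoter interval [tss-up, tss+down) along the gene."""
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream + 1, gene.tss + upstream + 1


def _island_tss_distance(island: CpGIsland, tss: int) -> int:
    if island.start <= tss < island.end:
        return 0
    if tss < island.start:
        return island.start - tss
    return tss - (island.end - 1)


def assign_promoter_island(
    gene: GeneModel,
    islands: Iterable[CpGIsland],
    upstream: int = 1000,
    downstream: int = 500,
) -> CpGIsland | None:
    """Island overlapping the gene's promoter window, nearest to the TSS on ties."""
    w0, w1 = promoter_window(gene, upstream, downstream)
    overlapping = [
        isl
        for isl in islands
        if isl.chrom == gene.chrom and isl.start < w1 and isl.end > w0
    ]
    if not overlapping:
        return None
    return min(overlapping, key=lambda isl: (_island_tss_distance(isl, gene.tss), isl.start))


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 if they overlap or touch."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end, 0)


def has_site_near_island(
    island: CpGIsland,
    hits: Iterable[MotifHit],
    flank: int = DEFAULT_FLANK,
) -> tuple[bool, int | None]:
    """Whether any hit lies within ``flank`` bp of the island boundaries.

    A hit counts when its interval is contained in
    ``[island.start - flank, island.end + flank)``. Returns the gap-wise
    distance of the nearest same-chromosome hit (0 if it overlaps the
    island), or None when there are no hits on the chromosome.
    """
    nearest: int | None = None
    ok = False
    lo, hi = island.start - flank, island.end + flank
    for h in hits:
        if h.chrom != island.chrom:
            continue
        d = interval_gap(island.start, island.end, h.start, h.end)
        if nearest is None or d < nearest:
            nearest = d
        if h.start >= lo and h.end <= hi:
            ok = True
    return ok, nearest


# ---------------------------------------------------------------------------
# I/O: FASTA and BED6
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Genes as 1-bp BED6 features at the TSS."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise SequenceInputError(f"{path}:{line_no}: expected BED6, got {len(parts)} columns")
            chrom, start, end, name, _score, strand = parts[:6]
            start_i = int(start)
            tss = start_i if strand == "+" else int(end) - 1
            genes.append(GeneModel(name, chrom, tss, strand))
    return genes


def write_islands_bed(islands: Iterable[CpGIsland], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, isl in enumerate(islands):
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tCpG_{i + 1}\t"
                f"{isl.obs_exp_cpg:.4f}\t+\n"
            )


def read_islands_bed(path: str | Path) -> list[CpGIsland]:
    islands = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, _name, score, _strand = line.split("\t")[:6]
            islands.append(CpGIsland(chrom, int(start), int(end), float("nan"), float(score)))
    return islands


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            strand = "+" if h.strand == "both" else h.strand
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.matched_sequence}\t"
                f"{h.spacer_length}\t{strand}\n"
            )


def read_hits_bed(path: str | Path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            hits.append(MotifHit(chrom, int(start), int(end), strand, name, int(score)))
    return hits
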