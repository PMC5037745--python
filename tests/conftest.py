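"""Shared fixtures and independent oracles used across the suite.

The oracles here recompute results by brute force (naive counting,
exhaustive enumeration, hand risk tables) and stay independent of the
vectorized implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from episcreen.sequence_features import (
    maximal_qualifying_subinterval,
    merge_window_starts,
)

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=p))


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Island oracle: naive per-window counting + the shared merge/trim rule
# ---------------------------------------------------------------------------

def brute_force_islands(
    seq: str,
    min_length: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    window: int = 200,
    step: int = 1,
):
    def window_stats(w: str):
        if "N" in w or not w:
            return False, 0.0, 0.0
        nc, ng = w.count("C"), w.count("G")
        gc = (nc + ng) / len(w)
        oe = w.count("CG") * len(w) / (nc * ng) if nc and ng else 0.0
        return gc >= gc_min and oe >= oe_min, gc, oe

    starts = [
        i
        for i in range(0, len(seq) - window + 1, step)
        if window_stats(seq[i : i + window])[0]
    ]

    def naive_qualifies(s: int, e: int):
        return window_stats(seq[s:e])

    out = []
    for region in merge_window_starts(starts, window):
        best = maximal_qualifying_subinterval(region, naive_qualifies, min_length)
        if best is not None:
            out.append(best)
    return out


# ---------------------------------------------------------------------------
# Motif oracle: exhaustive pattern enumeration on both strands
# ---------------------------------------------------------------------------

def brute_force_gas(seq: str, spacer_min: int = 3, spacer_max: int = 3):
    intervals = set()
    for s in range(spacer_min, spacer_max + 1):
        L = 6 + s
        for i in range(len(seq) - L + 1):
            for w in (seq[i : i + L], revcomp(seq[i : i + L])):
                if (
                    w.startswith("TTC")
                    and w.endswith("GAA")
                    and all(c in "ACGT" for c in w[3 : 3 + s])
                ):
                    intervals.add((i, i + L))
    return sorted(intervals)


# ---------------------------------------------------------------------------
# Survival oracles: hand risk-table Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_oracle(times, events):
    """Product-limit estimate by explicit risk-table bookkeeping."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    rows = []
    for t in sorted(set(times[events == 1])):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        rows.append((t, n_at_risk, d, s))
    return rows


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Log-rank chi-square from hand-computed observed/expected tables."""
    t = np.concatenate([np.asarray(times_a, float), np.asarray(times_b, float)])
    e = np.concatenate([np.asarray(events_a, int), np.asarray(events_b, int)])
    g = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    obs = exp = var = 0.0
    for tt in sorted(set(t[e == 1])):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (g == 1)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs - exp) ** 2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


@pytest.fixture(scope="session")
def small_genome():
    """A compact planted genome shared by feature-recovery tests."""
    from episcreen.synthetic import GenomeSimSpec, generate_genome

    spec = GenomeSimSpec(
        n_genes=20, n_target_genes=5, chrom_length=400_000, seed=7
    )
    sequences, genes, truth = generate_genome(spec)
    return spec, sequences, genes, truth
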