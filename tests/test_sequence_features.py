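"""Island detector, promoter assignment, and GAS-motif scanner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from episcreen.sequence_features import (
    CpGIsland,
    GeneModel,
    MotifHit,
    SequenceInputError,
    assign_promoter_island,
    find_cpg_islands,
    gc_fraction,
    has_site_near_island,
    obs_exp_cpg,
    read_genes_bed,
    read_hits_bed,
    read_islands_bed,
    scan_stat3_sites,
    write_genes_bed,
    write_hits_bed,
    write_islands_bed,
)

from conftest import brute_force_gas, brute_force_islands, random_dna, revcomp


@pytest.mark.parametrize(
    "window, expected",
    [("CGCG", 2.0), ("CCGG", 1.0), ("CATG", 0.0), ("AAAA", 0.0)],
)
def test_obs_exp_cpg_closed_forms(window, expected):
    assert obs_exp_cpg(window) == pytest.approx(expected)


def test_no_islands_in_polyA():
    assert find_cpg_islands("A" * 1000) == []


def test_pure_cpg_repeat_is_one_full_length_island():
    seq = "CG" * 200
    islands = find_cpg_islands(seq)
    assert len(islands) == 1
    isl = islands[0]
    assert (isl.start, isl.end) == (0, 400)
    assert isl.gc_fraction == pytest.approx(1.0)


def test_sequence_shorter_than_window_gives_empty():
    assert find_cpg_islands("CG" * 50) == []


def test_non_acgtn_characters_rejected():
    with pytest.raises(SequenceInputError):
        find_cpg_islands("ACGTX" * 100)


def test_windows_containing_n_are_skipped():
    # an island-grade segment poisoned with an N in the middle still yields
    # islands only on N-free intervals
    core = "CG" * 150
    seq = core + "N" + core
    for isl in find_cpg_islands(seq):
        assert "N" not in seq[isl.start : isl.end]


@pytest.mark.parametrize("seed", range(10))
def test_island_detector_matches_brute_force_on_planted_sequences(seed):
    """Detector == exhaustive window enumeration + same merge rule."""
    rng = np.random.default_rng(seed)
    background = random_dna(rng, 5000, gc=0.40)
    island = random_dna(rng, 300, gc=0.62)
    pos = int(rng.integers(500, 4000))
    seq = background[:pos] + island + background[pos:]
    ours = [(i.start, i.end, i.gc_fraction, i.obs_exp_cpg) for i in find_cpg_islands(seq)]
    oracle = brute_force_islands(seq)
    assert len(ours) == len(oracle)
    for (s1, e1, g1, o1), (s2, e2, g2, o2) in zip(ours, oracle):
        assert (s1, e1) == (s2, e2)
        assert g1 == pytest.approx(g2)
        assert o1 == pytest.approx(o2)


@pytest.mark.parametrize("seed", range(5))
def test_reported_islands_satisfy_criteria_and_are_disjoint_sorted(seed):
    rng = np.random.default_rng(seed + 100)
    seq = random_dna(rng, 3000, gc=0.55)
    islands = find_cpg_islands(seq)
    prev_end = -1
    for isl in islands:
        window = seq[isl.start : isl.end]
        assert isl.end - isl.start >= 200
        assert gc_fraction(window) >= 0.5
        assert obs_exp_cpg(window) >= 0.6
        assert 0 <= isl.start < isl.end <= len(seq)
        assert isl.start > prev_end - 1  # non-overlapping, sorted
        prev_end = isl.end


# -- motif scanning ---------------------------------------------------------

def test_direct_gas_match():
    hits = scan_stat3_sites("TTCTTAGAA", spacer_min=2, spacer_max=4)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.spacer_length) == (0, 9, 3)


def test_gas_consensus_is_strand_symmetric():
    """Scanning a sequence and its reverse complement yields mirror hits."""
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 2000, gc=0.5)
    fwd = {(h.start, h.end) for h in scan_stat3_sites(seq)}
    rc = {
        (len(seq) - e, len(seq) - s)
        for (s, e) in (
            (h.start, h.end) for h in scan_stat3_sites(revcomp(seq))
        )
    }
    assert fwd == rc


@pytest.mark.parametrize("spacer_range", [(3, 3), (2, 4)])
def test_scanner_matches_exhaustive_enumeration(spacer_range):
    rng = np.random.default_rng(17)
    seq = random_dna(rng, 10_000, gc=0.45)
    smin, smax = spacer_range
    ours = [(h.start, h.end) for h in scan_stat3_sites(seq, spacer_min=smin, spacer_max=smax)]
    assert ours == brute_force_gas(seq, smin, smax)


def test_scanner_rejects_bad_spacer_range():
    with pytest.raises(SequenceInputError):
        scan_stat3_sites("TTCAAAGAA", spacer_min=4, spacer_max=2)


def test_motifs_never_match_n():
    assert scan_stat3_sites("TTCNNNGAA") == []


def test_scan_respects_region_bounds():
    seq = "AAAA" + "TTCTTTGAA" + "AAAA"
    assert scan_stat3_sites(seq, region=(0, 4)) == []
    hits = scan_stat3_sites(seq, region=(4, 13))
    assert [(h.start, h.end) for h in hits] == [(4, 13)]


# -- promoter assignment ----------------------------------------------------

def make_island(start, end):
    return CpGIsland("chr1", start, end, 0.6, 0.8)


def test_no_islands_on_chrom_gives_none():
    gene = GeneModel("g", "chr1", 5000, "+")
    other_chrom = CpGIsland("chr2", 0, 300, 0.6, 0.8)
    assert assign_promoter_island(gene, [other_chrom]) is None


def test_island_covering_tss_is_assigned():
    gene = GeneModel("g", "chr1", 5000, "+")
    isl = make_island(4900, 5200)
    assert assign_promoter_island(gene, [isl]) is isl


def test_nearest_island_wins_on_multiple_overlaps():
    """Constructed 3-island case: distances to the TSS decide."""
    gene = GeneModel("g", "chr1", 5000, "+")
    far = make_island(4000, 4210)      # gap to TSS: 5000-4209 = 791
    near = make_island(4600, 4900)     # gap: 5000-4899 = 101
    covering = make_island(4950, 5300) # contains TSS: distance 0
    assert assign_promoter_island(gene, [far, near]) is near
    assert assign_promoter_island(gene, [far, near, covering]) is covering


def test_promoter_window_is_strand_aware():
    # island upstream of a minus-strand gene lies at higher coordinates
    gene = GeneModel("g", "chr1", 5000, "-")
    upstream_isl = make_island(5200, 5500)
    assert assign_promoter_island(gene, [upstream_isl], upstream=1000, downstream=100) is upstream_isl
    plus = GeneModel("g2", "chr1", 5000, "+")
    assert assign_promoter_island(plus, [upstream_isl], upstream=1000, downstream=100) is None


# -- flank rule -------------------------------------------------------------

def test_hit_inside_island_counts_with_distance_zero():
    isl = make_island(1000, 1300)
    hit = MotifHit("chr1", 1100, 1109, "both", "TTCAAAGAA", 3)
    ok, dist = has_site_near_island(isl, [hit], flank=5000)
    assert ok and dist == 0


def test_flank_boundary_is_half_open():
    isl = make_island(1000, 1300)
    at_boundary = MotifHit("chr1", 1300 + 5000, 1300 + 5009, "both", "TTCAAAGAA", 3)
    ok, dist = has_site_near_island(isl, [at_boundary], flank=5000)
    assert not ok
    assert dist == 5000
    just_inside = MotifHit("chr1", 1300 + 4991, 1300 + 5000, "both", "TTCAAAGAA", 3)
    ok, _ = has_site_near_island(isl, [just_inside], flank=5000)
    assert ok


def test_flank_rule_flags_exactly_planted_targets(small_genome):
    """On a planted genome the island+motif filter recovers the truth."""
    _, sequences, genes, truth = small_genome
    seq = sequences["chr1"]
    islands = find_cpg_islands(seq)
    hits = scan_stat3_sites(seq)
    flagged = set()
    for gene in genes:
        isl = assign_promoter_island(gene, islands)
        if isl is None:
            continue
        ok, _ = has_site_near_island(isl, hits, flank=5000)
        if ok:
            flagged.add(gene.gene_id)
    assert flagged == set(truth.target_gene_ids)


# -- BED round trips --------------------------------------------------------

def test_bed_round_trips(tmp_path):
    genes = [GeneModel("a", "chr1", 100, "+"), GeneModel("b", "chr1", 900, "-")]
    write_genes_bed(genes, tmp_path / "genes.bed")
    assert read_genes_bed(tmp_path / "genes.bed") == genes

    islands = [CpGIsland("chr1", 10, 310, 0.61, 0.82)]
    write_islands_bed(islands, tmp_path / "islands.bed")
    back = read_islands_bed(tmp_path / "islands.bed")
    assert [(i.chrom, i.start, i.end) for i in back] == [("chr1", 10, 310)]
    assert back[0].obs_exp_cpg == pytest.approx(0.82)

    hits = [MotifHit("chr1", 5, 14, "+", "TTCAAAGAA", 3)]
    write_hits_bed(hits, tmp_path / "hits.bed")
    assert read_hits_bed(tmp_path / "hits.bed") == hits


@settings(derandomize=True, max_examples=30)
@given(st.text(alphabet="ACGT", min_size=4, max_size=60))
def test_obs_exp_cpg_matches_definition(seq):
    n_c, n_g = seq.count("C"), seq.count("G")
    expected = seq.count("CG") * len(seq) / (n_c * n_g) if n_c and n_g else 0.0
    assert obs_exp_cpg(seq) == pytest.approx(expected)
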