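"""Haplotype collapsing, diversity estimators, AMOVA and the network."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refugia.popgen import (
    Alignment,
    amova_phi,
    build_network,
    collapse_haplotypes,
    crop_and_filter,
    diversity_stats,
    diversity_table,
    hamming_matrix,
)


def aln(seqs, regions=None, ids=None):
    n = len(seqs)
    regions = regions or ["r1"] * n
    ids = ids or [f"s{i}" for i in range(n)]
    return Alignment(tuple(ids), tuple(regions), tuple(seqs))


# ---------------------------------------------------------------- filtering


def test_filter_keeps_clean_alignment_unchanged():
    a = crop_and_filter(aln(["ACGT", "ACGT", "ACGT"]))
    assert a.length == 4 and a.sequences == ("ACGT", "ACGT", "ACGT")


def test_filter_drops_columns_with_ambiguity_alignment_wide():
    a = crop_and_filter(aln(["ACNT", "ACGT"]))
    assert a.length == 3
    assert a.sequences == ("ACT", "ACT")


def test_filter_gap_column_removed_and_keep_all_policy():
    a = aln(["A-GT", "ACGT"])
    assert crop_and_filter(a).length == 3
    assert crop_and_filter(a, "keep-all").length == 4


def test_filter_errors():
    with pytest.raises(ValueError, match="zero length"):
        crop_and_filter(aln(["NN", "AC"]))
    with pytest.raises(ValueError, match="unequal"):
        aln(["ACG", "AC"])


# ----------------------------------------------------------------- collapse


def test_collapse_identical_sequences_one_haplotype():
    t = collapse_haplotypes(aln(["ACGT"] * 3))
    assert t.n_haplotypes == 1 and t.frequency(1) == 3


def test_collapse_counts_and_first_appearance_order():
    t = collapse_haplotypes(aln(["AAAA", "AAAT", "AAAA"]))
    assert t.n_haplotypes == 2
    assert t.sequences == ("AAAA", "AAAT")
    assert [t.frequency(h) for h in t.hap_ids] == [2, 1]


def test_collapse_rejects_ambiguity():
    with pytest.raises(ValueError, match="filter"):
        collapse_haplotypes(aln(["ACNT", "ACGT"]))


# ---------------------------------------------------------------- diversity


def brute_hd(counts):
    """Discordant unordered pairs / C(n,2), scaled by n/(n-1) sample correction.

    Equality of the corrected estimator with discordant-pairs/C(n,2) is an
    identity: n(1-sum p^2)/(n-1) = sum_{i!=j} c_i c_j / (n(n-1)).
    """
    items = [h for h, c in enumerate(counts) for _ in range(c)]
    pairs = list(itertools.combinations(items, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_pi(seqs):
    pairs = list(itertools.combinations(seqs, 2))
    diffs = sum(sum(x != y for x, y in zip(a, b)) for a, b in pairs)
    return diffs / (len(pairs) * len(seqs[0]))


def test_monomorphic_region_zero_diversity():
    a = aln(["ACGT"] * 5)
    st_ = diversity_stats(collapse_haplotypes(a), a, "r1")
    assert st_.hd == 0.0 and st_.pi == 0.0 and st_.hn == 1


def test_two_sequences_one_difference():
    s1 = "A" * 100
    s2 = "A" * 99 + "T"
    a = aln([s1, s2])
    st_ = diversity_stats(collapse_haplotypes(a), a, "r1")
    assert st_.hd == pytest.approx(1.0)
    assert st_.pi == pytest.approx(0.01)


def test_hd_two_by_two_counts():
    a = aln(["AAAA", "AAAA", "TTTT", "TTTT"])
    st_ = diversity_stats(collapse_haplotypes(a), a, "r1")
    assert st_.hd == pytest.approx(4 / 6)


def test_singleton_scope_flagged_and_zeroed():
    a = aln(["ACGT", "AGGT"], regions=["r1", "r2"])
    t = collapse_haplotypes(a)
    with pytest.warns(UserWarning, match="n=1"):
        st_ = diversity_stats(t, a, "r1")
    assert st_.hd == 0.0 and st_.pi == 0.0 and st_.n == 1


def test_unknown_scope_errors():
    a = aln(["ACGT"] * 2)
    with pytest.raises(ValueError, match="unknown scope"):
        diversity_stats(collapse_haplotypes(a), a, "nowhere")


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(1, 5), min_size=2, max_size=5))
def test_hd_matches_discordant_pair_enumeration(counts):
    """The corrected Hd estimator equals brute-force pair counting."""
    if sum(counts) > 12:
        counts = counts[:2]
    seqs = []
    for h, c in enumerate(counts):
        hap = "".join("ACGT"[(h >> (2 * k)) & 3] for k in range(5))
        seqs.extend([hap] * c)
    a = aln(seqs)
    t = collapse_haplotypes(a)
    st_ = diversity_stats(t, a, "r1")
    assert st_.hd == pytest.approx(brute_hd(counts), abs=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(
        st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=2, max_size=8
    )
)
def test_pi_matches_brute_force_mean_pairwise_difference(seqs):
    a = aln(list(seqs))
    t = collapse_haplotypes(a)
    st_ = diversity_stats(t, a, "All")
    assert st_.pi == pytest.approx(brute_pi(seqs), abs=1e-12)


def test_regional_n_sums_and_hu_bound(world):
    """Region-level n adds to the pooled n; unique haplotypes never exceed Hn."""
    a = crop_and_filter(world.alignment)
    t = collapse_haplotypes(a)
    div = diversity_table(t, a)
    allrow = div[div.region == "All"].iloc[0]
    regional = div[div.region != "All"]
    assert regional["n"].sum() == allrow["n"]
    assert regional["Hu"].sum() <= allrow["Hn"]
    assert (regional["Hu"] <= regional["Hn"]).all()
    assert (regional["Hn"] <= regional["n"]).all()


# -------------------------------------------------------------------- AMOVA


def brute_amova_phi(d, labels):
    """Independent variance-component computation from first principles."""
    labels = np.asarray(labels)
    N = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(
        d[i, j] ** 2 for i in range(N) for j in range(i + 1, N)
    ) / N
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(N) if labels[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_among = ss_total - ss_within
    G = len(groups)
    ms_among = ss_among / (G - 1)
    ms_within = ss_within / (N - G)
    sizes = [sum(labels == g) for g in groups]
    n0 = (N - sum(s**2 for s in sizes) / N) / (G - 1)
    va = (ms_among - ms_within) / n0
    return va / (va + ms_within)


def test_amova_perfect_between_group_structure():
    a = aln(
        ["AAAA"] * 3 + ["TTTT"] * 3,
        regions=["g1"] * 3 + ["g2"] * 3,
    )
    res = amova_phi(a, n_permutations=99, seed=0)
    assert res.phi == pytest.approx(1.0)
    assert res.variance_within == 0.0


def test_amova_no_structure_small_phi():
    haps = ["AAAA", "AATT", "TTAA", "TTTT"]
    a = aln(haps * 2, regions=["g1"] * 4 + ["g2"] * 4)
    res = amova_phi(a, n_permutations=99, seed=0)
    assert res.phi <= 0.05


def test_amova_matches_brute_force_components():
    seqs = ["AAAAAA", "AAAATT", "AATTTT", "TTTTTT", "TTTTAA", "TTAAAA"]
    labels = ["g1"] * 3 + ["g2"] * 3
    a = aln(seqs, regions=labels)
    res = amova_phi(a, n_permutations=9, seed=0)
    d = hamming_matrix(seqs)
    assert res.phi == pytest.approx(brute_amova_phi(d, labels), abs=1e-12)


def test_amova_single_group_errors_and_p_correction():
    a = aln(["AAAA", "TTTT"], regions=["g1", "g1"])
    with pytest.raises(ValueError, match="2 groups"):
        amova_phi(a, n_permutations=9)
    b = aln(["AAAA"] * 3 + ["TTTT"] * 3, regions=["g1"] * 3 + ["g2"] * 3)
    res = amova_phi(b, n_permutations=19, seed=1)
    assert res.p_value >= 1 / 20  # +1 correction keeps p off zero


def test_amova_seed_reproducibility():
    a = aln(
        ["AAAA", "AATT", "TTAA", "TTTT"] * 2, regions=["g1"] * 4 + ["g2"] * 4
    )
    r1 = amova_phi(a, n_permutations=99, seed=7)
    r2 = amova_phi(a, n_permutations=99, seed=7)
    assert r1.p_value == r2.p_value


# ------------------------------------------------------------------ network


def test_network_single_haplotype_no_edges():
    t = collapse_haplotypes(aln(["ACGT"] * 3))
    assert build_network(t).edges == []


def test_network_two_haplotypes_single_step():
    t = collapse_haplotypes(aln(["AAAA", "AAAT"]))
    assert build_network(t).edges == [(1, 2, 1)]


def test_network_chain_excludes_longer_redundant_edge():
    # A-B 1, B-C 1, A-C 2: the A-C edge is not tied with any MST bottleneck
    t = collapse_haplotypes(aln(["AAAA", "AAAT", "AATT"]))
    assert build_network(t).edges == [(1, 2, 1), (2, 3, 1)]


def test_network_retains_tied_alternative_connections():
    # equilateral triple at distance 2: all three edges equally parsimonious
    t = collapse_haplotypes(aln(["AACC", "CCCC", "TTCC"]))
    assert build_network(t).edges == [(1, 2, 2), (1, 3, 2), (2, 3, 2)]


def test_network_connection_limit_and_validation():
    t = collapse_haplotypes(aln(["AAAA", "AAAT", "TTTT"]))
    with pytest.raises(ValueError):
        build_network(t, 0)
    limited = build_network(t, 1)
    assert all(w <= 1 for _, _, w in limited.edges)


def test_network_path_weight_bounds_hamming_distance(world):
    """Any network path between two haplotypes is at least their distance."""
    import networkx as nx

    a = crop_and_filter(world.alignment)
    t = collapse_haplotypes(a)
    net = build_network(t)
    d = hamming_matrix(t.sequences)
    assert nx.is_connected(net.graph)
    lengths = dict(
        nx.all_pairs_dijkstra_path_length(net.graph, weight="substitutions")
    )
    for i in t.hap_ids:
        for j in t.hap_ids:
            if i < j:
                assert lengths[i][j] >= d[i - 1, j - 1]
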