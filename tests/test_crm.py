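"""Site projection, CRMC partitioning, island merging and the CRM score."""

import numpy as np
import pytest

from conftest import sharp_pwm
from crmkit import intervals
from crmkit.clustering import GenomicMotifSite, UniqueMotif
from crmkit.crm import (
    CRMC,
    GenomicSite,
    crm_score,
    functional_state,
    merge_islands,
    partition_crmcs,
    project_sites,
)
from crmkit.network import InteractionNetwork


def site(start, end, um="UM0", score=5.0, chrom="chr1"):
    return GenomicSite(chrom, start, end, "+", um, score)


def net_with(weights, ids=("UM0", "UM1", "UM2")):
    return InteractionNetwork(list(ids), np.asarray(weights, float))


# ------------------------------------------------------------- projection


def test_project_sites_coordinates_dedup_and_score_filter():
    consensus = "ACGTTGCATC"
    genome = {"chr1": "T" * 10_037 + consensus + "T" * 100}
    model = sharp_pwm(consensus, 0.9)
    um = UniqueMotif(
        um_id="UM0", member_motifs=[], model=model,
        sites=[
            GenomicMotifSite("d1", "p1", "chr1", 10_037, 10_047, "+"),
            GenomicMotifSite("d2", "p9", "chr1", 10_037, 10_047, "+"),  # dup coords
            GenomicMotifSite("d1", "p2", "chr1", 5_000, 5_010, "+"),  # background
        ],
    )
    out = project_sites([um], genome)
    assert len(out) == 1  # duplicate collapsed, poly-T site scores <= 0
    s = out[0]
    assert (s.start, s.end) == (10_037, 10_047)
    assert s.score == pytest.approx(model.max_score)


def test_project_sites_out_of_bounds_errors():
    um = UniqueMotif("UM0", [], sharp_pwm("ACGTTGCATC"),
                     sites=[GenomicMotifSite("d", "p", "chr1", 95, 105, "+")])
    with pytest.raises(ValueError):
        project_sites([um], {"chr1": "A" * 100})


# ------------------------------------------------------------ partitioning


def test_gap_at_threshold_links_and_above_splits():
    covered = {"chr1": np.array([[0, 1000]])}
    linked = partition_crmcs([site(100, 110), site(400, 410)], covered)
    assert len(linked.crmcs) == 1
    assert (linked.crmcs[0].start, linked.crmcs[0].end) == (100, 410)

    split = partition_crmcs([site(100, 110), site(411, 421)], covered)
    assert len(split.crmcs) == 2  # gap 301 > 300


def test_non_crmc_is_covered_complement():
    covered = {"chr1": np.array([[0, 1000]])}
    part = partition_crmcs([site(100, 110), site(400, 410)], covered)
    assert part.non_crmcs["chr1"].tolist() == [[0, 100], [410, 1000]]


def test_lone_site_forms_single_site_crmc():
    part = partition_crmcs([site(50, 60)], {"chr1": np.array([[0, 500]])})
    (c,) = part.crmcs
    assert c.n_sites == 1 and (c.start, c.end) == (50, 60)


@pytest.mark.parametrize("trial", range(20))
def test_partition_exactness_randomized_vs_bitmask(trial):
    """CRMCs and non-CRMCs exactly partition the covered regions."""
    rng = np.random.default_rng(trial)
    span = 3000
    cov_pairs = sorted(
        (int(s), int(s) + int(l))
        for s, l in zip(rng.integers(0, span - 200, 4), rng.integers(50, 400, 4))
    )
    covered = {"chr1": intervals.merge(cov_pairs)}
    sites = [site(int(s), int(s) + 10) for s in np.sort(rng.integers(0, span - 10, 15))]
    part = partition_crmcs(sites, covered, max_gap=100)

    cov_mask = np.zeros(span + 500, bool)
    for s, e in covered["chr1"]:
        cov_mask[s:e] = True
    crmc_mask = np.zeros_like(cov_mask)
    for c in part.crmcs:
        crmc_mask[c.start:c.end] = True
    non_mask = np.zeros_like(cov_mask)
    for s, e in part.non_crmcs["chr1"]:
        non_mask[s:e] = True
    assert not np.any(crmc_mask & non_mask)
    assert np.array_equal((crmc_mask | non_mask) & cov_mask, cov_mask)
    assert np.array_equal(non_mask, cov_mask & ~crmc_mask)


# ---------------------------------------------------------------- islands


def test_islands_merge_and_half_open_abutting():
    islands = merge_islands([
        site(100, 110, "UM0"), site(105, 117, "UM1"),  # overlap -> merge
        site(200, 210, "UM0"), site(210, 220, "UM1"),  # abutting -> separate
    ])
    assert [(s, e) for _, s, e, _ in islands] == [(100, 117), (200, 210), (210, 220)]
    assert islands[0][3] == ["UM0", "UM1"]


def test_non_overlapping_sites_are_their_own_islands():
    sites = [site(i * 100, i * 100 + 10) for i in range(4)]
    islands = merge_islands(sites)
    assert len(islands) == 4


# ------------------------------------------------------------------ score


def test_crm_score_two_sites_hand_value():
    # n=2, weight 1.5, scores 3 and 5 -> (2/1) * 1.5 * 8 = 24
    c = CRMC("chr1", 0, 500, [site(0, 10, "UM0", 3.0), site(200, 210, "UM1", 5.0)])
    net = net_with([[0, 1.5, 0], [1.5, 0, 0], [0, 0, 0]])
    assert crm_score(c, net) == pytest.approx(24.0)


def test_crm_score_three_sites_hand_value():
    # n=3, all weights 1, all scores 1 -> (2/2) * (2+2+2) = 6
    c = CRMC("chr1", 0, 500, [
        site(0, 10, "UM0", 1.0), site(50, 60, "UM1", 1.0), site(100, 110, "UM2", 1.0)
    ])
    net = net_with(np.ones((3, 3)) - np.eye(3))
    assert crm_score(c, net) == pytest.approx(6.0)


def test_single_site_scores_zero_and_empty_errors():
    net = net_with(np.zeros((3, 3)))
    assert crm_score(CRMC("chr1", 0, 10, [site(0, 10)]), net) == 0.0
    with pytest.raises(ValueError):
        crm_score(CRMC("chr1", 0, 10, []), net)


def test_score_invariant_under_site_reordering():
    rng = np.random.default_rng(8)
    sites = [site(i * 50, i * 50 + 10, f"UM{i % 3}", float(rng.uniform(1, 9)))
             for i in range(6)]
    raw = np.triu(np.round(rng.uniform(0, 3, (3, 3)), 3), 1)
    net = net_with(raw + raw.T)
    c1 = CRMC("chr1", 0, 500, sites)
    c2 = CRMC("chr1", 0, 500, list(reversed(sites)))
    assert crm_score(c1, net) == pytest.approx(crm_score(c2, net))


@pytest.mark.parametrize("trial", range(10))
def test_score_matches_bruteforce_pair_sum_and_monotone(trial):
    rng = np.random.default_rng(100 + trial)
    n_um = 4
    w = np.triu(rng.uniform(0, 2, (n_um, n_um)), 1)
    net = InteractionNetwork([f"UM{i}" for i in range(n_um)], w + w.T)
    n = int(rng.integers(2, 8))
    sites = [site(i * 40, i * 40 + 10, f"UM{int(rng.integers(n_um))}",
                  float(rng.uniform(0.5, 8))) for i in range(n)]
    c = CRMC("chr1", 0, 2000, sites)

    brute = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            brute += net.weight(sites[i].um_id, sites[j].um_id) * (
                sites[i].score + sites[j].score
            )
    brute *= 2.0 / (n - 1)
    assert crm_score(c, net) == pytest.approx(brute)
    assert crm_score(c, net) >= 0.0

    # adding a positive-score site never decreases the pairwise sum part
    extra = site(n * 40, n * 40 + 10, "UM0", 2.0)
    bigger = CRMC("chr1", 0, 2000, sites + [extra])
    sum_before = crm_score(c, net) * (n - 1) / 2.0
    sum_after = crm_score(bigger, net) * n / 2.0
    assert sum_after >= sum_before - 1e-12


# ------------------------------------------------------- functional state


def test_functional_state_one_bp_overlap_suffices():
    c = CRMC("chr1", 90, 120, [site(100, 110)])
    assert functional_state(c, {"chr1": np.array([[105, 400]])}) == "bound"
    assert functional_state(c, {"chr1": np.array([[109, 400]])}) == "bound"
    assert functional_state(c, {"chr1": np.array([[110, 400]])}) == "unbound"
    assert functional_state(c, {"chr2": np.array([[0, 10]])}) == "unbound"


def test_positive_score_invariant():
    with pytest.raises(ValueError):
        GenomicSite("chr1", 0, 10, "+", "UM0", -0.3)
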