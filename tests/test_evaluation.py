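"""Recall under the 50%-of-shorter rule, matched controls, neutrality
proportions and position decomposition."""

import numpy as np
import pytest

from crmkit.evaluation import (
    ElementSet,
    NeutralityProfile,
    chance_recall_expectation,
    decompose_positions,
    length_ratio_stats,
    matched_controls,
    proportion_of_neutrality,
    recall,
)


def eset(label, *triples):
    return ElementSet.from_tuples(label, triples)


# ----------------------------------------------------------------- recall


def test_identical_intervals_recalled():
    r = recall(eset("p", ("chr1", 0, 100)), eset("r", ("chr1", 0, 100)))
    assert r.sensitivity == 1.0


def test_recall_boundary_is_inclusive():
    # overlap 50 = exactly 50% of the shorter (100) -> recalled
    r = recall(eset("p", ("chr1", 0, 100)), eset("r", ("chr1", 50, 200)))
    assert r.sensitivity == 1.0
    # overlap 49 of shorter 100 -> not recalled
    r2 = recall(eset("p", ("chr1", 0, 100)), eset("r", ("chr1", 51, 200)))
    assert r2.sensitivity == 0.0


def test_recall_monotone_in_predictions():
    ref = eset("r", ("chr1", 0, 100), ("chr1", 1000, 1100), ("chr1", 5000, 5100))
    small = eset("p", ("chr1", 0, 100))
    big = eset("p", ("chr1", 0, 100), ("chr1", 1000, 1100))
    assert recall(big, ref).sensitivity >= recall(small, ref).sensitivity


def test_recall_mapping_prefers_longest_overlap():
    ref = eset("r", ("chr1", 100, 300))
    pred = eset("p", ("chr1", 90, 310), ("chr1", 150, 260))
    r = recall(pred, ref)
    assert r.mapping[("chr1", 100, 300)] == ("chr1", 90, 310)


# ------------------------------------------------------- matched controls


def test_matched_controls_preserve_length_multiset():
    pred = eset("p", ("chr1", 0, 100), ("chr1", 500, 850), ("chr2", 0, 40))
    universe = {"chr1": np.array([[0, 10_000]]), "chr2": np.array([[0, 5_000]])}
    ctl = matched_controls(pred, universe, seed=5)
    lengths = sorted(e - s for v in ctl.intervals.values() for s, e in v)
    assert lengths == [40, 100, 350]
    # determinism and self-consistency
    ctl2 = matched_controls(pred, universe, seed=5)
    assert {c: v.tolist() for c, v in ctl.intervals.items()} == \
           {c: v.tolist() for c, v in ctl2.intervals.items()}


def test_matched_controls_do_not_self_overlap():
    pred = eset("p", *[("chr1", i * 100, i * 100 + 90) for i in range(20)])
    universe = {"chr1": np.array([[0, 4_000]])}
    ctl = matched_controls(pred, universe, seed=1)
    ivs = sorted(map(tuple, ctl.intervals["chr1"].tolist()))
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 <= s2


def test_matched_controls_infeasible_raises():
    pred = eset("p", ("chr1", 0, 500))
    with pytest.raises(ValueError):
        matched_controls(pred, {"chr1": np.array([[0, 100]])}, seed=0)


def test_control_recall_near_chance_on_sparse_reference():
    rng = np.random.default_rng(0)
    universe = {"chr1": np.array([[0, 1_000_000]])}
    ref = eset("r", *[("chr1", int(s), int(s) + 500)
                      for s in rng.choice(900_000, 40, replace=False)])
    pred = eset("p", *[("chr1", i * 1000, i * 1000 + 400) for i in range(50)])
    chance = chance_recall_expectation(pred, ref, 1_000_000)
    recalls = []
    for seed in range(8):
        ctl = matched_controls(pred, universe, seed=seed)
        recalls.append(recall(ctl, ref).sensitivity)
    assert np.mean(recalls) <= 3 * chance
    assert chance > 0


# ------------------------------------------------------------- neutrality


def runs_profile(values, delta=1.0):
    """1-bp-resolution profile over chr1 from a list of scores."""
    v = np.asarray(values, float)
    starts = np.arange(len(v))
    return NeutralityProfile({"chr1": (starts, starts + 1, v)}, delta=delta)


def test_neutrality_all_zero_scores():
    p = runs_profile([0.0] * 10)
    assert proportion_of_neutrality({"chr1": np.array([[0, 10]])}, p) == 1.0


def test_neutrality_direct_count():
    p = runs_profile([-2.0, 0.0, 2.0, 0.5])
    assert proportion_of_neutrality({"chr1": np.array([[0, 4]])}, p) == 0.5


def test_neutrality_band_edges_inclusive():
    p = runs_profile([-1.0, 1.0, 1.0000001, -1.0000001])
    assert proportion_of_neutrality({"chr1": np.array([[0, 4]])}, p) == 0.5


def test_neutrality_dual_implementation_agreement():
    rng = np.random.default_rng(3)
    scores = np.round(rng.normal(0, 1.2, 10_000), 4)
    p = runs_profile(scores)
    iv = {"chr1": np.array([[0, 10_000]])}
    a = proportion_of_neutrality(iv, p, method="count")
    b = proportion_of_neutrality(iv, p, method="integrate")
    assert abs(a - b) < 1e-12


def test_neutrality_missing_positions_rejected():
    p = runs_profile([0.0] * 10)
    with pytest.raises(ValueError):
        proportion_of_neutrality({"chr1": np.array([[0, 100]])}, p)
    with pytest.raises(ValueError):
        proportion_of_neutrality({"chr2": np.array([[0, 10]])}, p)


def test_bedgraph_reader_and_run_expansion(tmp_path):
    bg = tmp_path / "c.bedGraph"
    bg.write_text("chr1\t0\t5\t0.0\nchr1\t5\t8\t2.5\n")
    p = NeutralityProfile.from_bedgraph(bg)
    scores, missing = p.scores_over({"chr1": np.array([[2, 8]])})
    assert missing == 0
    assert scores.tolist() == [0.0, 0.0, 0.0, 2.5, 2.5, 2.5]


# ---------------------------------------------------------- decomposition


def test_decompose_hand_example():
    a = eset("a", ("chr1", 0, 100))
    b = eset("b", ("chr1", 50, 150))
    assert decompose_positions(a, b) == (50, 50, 50)


def test_decompose_disjoint_and_symmetry():
    a = eset("a", ("chr1", 0, 100), ("chr2", 0, 30))
    b = eset("b", ("chr1", 500, 600))
    assert decompose_positions(a, b)[0] == 0
    s1, a1, b1 = decompose_positions(a, b)
    s2, b2, a2 = decompose_positions(b, a)
    assert (s1, a1, b1) == (s2, a2, b2)


@pytest.mark.parametrize("trial", range(10))
def test_decompose_matches_per_bp_sets(trial):
    rng = np.random.default_rng(trial)
    mk = lambda: [("chr1", int(s), int(s) + int(l))
                  for s, l in zip(rng.integers(0, 900, 6), rng.integers(1, 120, 6))]
    a, b = eset("a", *mk()), eset("b", *mk())
    pa = {x for c, s, e in a.elements() for x in range(s, e)}
    pb = {x for c, s, e in b.elements() for x in range(s, e)}
    assert decompose_positions(a, b) == (
        len(pa & pb), len(pa - pb), len(pb - pa)
    )


# ---------------------------------------------------------- length ratios


def test_length_ratio_identical_and_doubled():
    m1 = {("chr1", 0, 100): ("chr1", 0, 100), ("chr1", 500, 600): ("chr1", 500, 600)}
    assert length_ratio_stats(m1)["median"] == 1.0
    m2 = {("chr1", 0, 100): ("chr1", 0, 200), ("chr1", 500, 600): ("chr1", 450, 650)}
    assert length_ratio_stats(m2)["median"] == 2.0


def test_length_ratio_matches_construction():
    rng = np.random.default_rng(9)
    mapping = {}
    ratios = []
    for i in range(30):
        ref_len = int(rng.integers(50, 400))
        ratio = float(rng.uniform(0.8, 4.0))
        pred_len = int(round(ref_len * ratio))
        mapping[("chr1", 10_000 * i, 10_000 * i + ref_len)] = (
            "chr1", 10_000 * i, 10_000 * i + pred_len
        )
        ratios.append(pred_len / ref_len)
    stats = length_ratio_stats(mapping)
    assert stats["median"] == pytest.approx(np.median(ratios))
    assert stats["n"] == 30
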