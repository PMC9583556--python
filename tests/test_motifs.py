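"""PWM scoring, the score-distribution DP, and the baseline motif finder."""

from itertools import product

import numpy as np
import pytest

from conftest import sharp_pwm
from crmkit.motifs import (
    DiscoveryParams,
    PWMModel,
    discover_motifs,
    encode,
    hit_probability,
    read_meme_minimal,
    read_sites_tsv,
    revcomp,
    score_site,
    threshold_for_fpr,
    write_meme_minimal,
    write_sites_tsv,
)


def test_background_model_scores_zero():
    m = PWMModel(np.full((4, 6), 0.25), background=np.full(4, 0.25))
    for kmer in ("ACGTAC", "TTTTTT", "GCGCGC"):
        assert score_site(m, kmer) == pytest.approx(0.0)


def test_single_column_analytic_score():
    m = PWMModel(np.array([[0.5], [1 / 6], [1 / 6], [1 / 6]]),
                 background=np.full(4, 0.25))
    assert score_site(m, "A") == pytest.approx(1.0)  # log2(0.5/0.25)


@pytest.mark.parametrize("consensus", ["ACGTAC", "TTGACA"])
def test_consensus_maximizes_score_by_enumeration(consensus):
    """Exhaustive check over all 4^w k-mers at small width."""
    m = sharp_pwm(consensus, p=0.7)
    best = max(
        ("".join(k) for k in product("ACGT", repeat=len(consensus))),
        key=lambda k: score_site(m, k),
    )
    assert best == consensus
    assert score_site(m, consensus) == pytest.approx(m.max_score)


def test_reverse_complement_scoring_identity():
    rng = np.random.default_rng(3)
    for _ in range(10):
        p = rng.dirichlet(np.ones(4), size=8).T
        m = PWMModel(p, background=np.full(4, 0.25))
        kmer = "".join(rng.choice(list("ACGT"), 8))
        assert score_site(m, kmer) == pytest.approx(
            score_site(m.reverse_complement(), revcomp(kmer))
        )


def test_ambiguous_base_scores_minus_inf():
    m = sharp_pwm("ACGTAC")
    assert score_site(m, "ACGNAC") == -np.inf


def test_pwm_column_sum_validation():
    with pytest.raises(ValueError):
        PWMModel(np.full((4, 5), 0.3), background=np.full(4, 0.25))


def test_hit_probability_matches_enumeration():
    """The DP tail probability equals brute-force enumeration at width 5."""
    m = sharp_pwm("ACGTA", p=0.7)
    for thr in (0.0, 3.0, 6.0):
        exact = sum(
            0.25 ** 5
            for k in product("ACGT", repeat=5)
            if score_site(m, "".join(k)) > thr
        )
        assert hit_probability(m, thr) == pytest.approx(exact, abs=1e-6)


def test_threshold_for_fpr_is_tight():
    m = sharp_pwm("ACGTACGTAC", p=0.9)
    for fpr in (1e-3, 1e-4, 1e-5):
        t = threshold_for_fpr(m, fpr)
        assert hit_probability(m, t) <= fpr
        if t > 0:
            # one bin lower would violate the bound
            assert hit_probability(m, t - 0.1) > fpr


def _windows_with_planted(rng, n, length, consensus, p=0.9):
    """Random windows, each with one planted PWM draw at a random offset."""
    mat = sharp_pwm(consensus, p).probabilities
    seqs = []
    for _ in range(n):
        codes = rng.integers(0, 4, size=length)
        off = int(rng.integers(0, length - len(consensus)))
        site = [int(rng.choice(4, p=mat[:, j])) for j in range(len(consensus))]
        codes[off:off + len(consensus)] = site
        seqs.append("".join("ACGT"[c] for c in codes))
    return seqs


def test_discovery_recovers_planted_consensus():
    rng = np.random.default_rng(5)
    consensus = "CATTGCGTCA"
    seqs = _windows_with_planted(rng, 60, 300, consensus)
    found = discover_motifs(seqs, params=DiscoveryParams(), seed=0, dataset_id="d")
    assert found, "planted motif not discovered"
    top = found[0].model().consensus
    ham = min(
        sum(a != b for a, b in zip(top, consensus)),
        sum(a != b for a, b in zip(top, revcomp(consensus))),
    )
    assert ham <= 1


def test_discovery_negative_control_on_uniform_sequence():
    rng = np.random.default_rng(7)
    seqs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(60)]
    found = discover_motifs(seqs, params=DiscoveryParams(), seed=0, dataset_id="d")
    assert found == []


def test_discovery_requires_min_peaks():
    seqs = ["ACGT" * 50] * 5
    assert discover_motifs(seqs, params=DiscoveryParams(min_peaks=20)) == []


def test_discovery_reverse_complement_symmetry():
    """Discovering on reverse-complemented windows yields the same motif
    family (consensus matches up to reverse complement)."""
    rng = np.random.default_rng(5)
    consensus = "CATTGCGTCA"
    seqs = _windows_with_planted(rng, 60, 300, consensus)
    fwd = discover_motifs(seqs, params=DiscoveryParams(), seed=0)
    rev = discover_motifs([revcomp(s) for s in seqs],
                          params=DiscoveryParams(), seed=0)
    assert fwd and rev
    a, b = fwd[0].model().consensus, rev[0].model().consensus
    ham = min(sum(x != y for x, y in zip(a, b)),
              sum(x != y for x, y in zip(a, revcomp(b))))
    assert ham <= 1


def test_meme_minimal_roundtrip(tmp_path):
    models = {"m1": sharp_pwm("ACGTACGTAC", 0.8), "m2": sharp_pwm("TTGACATTGA", 0.9)}
    path = tmp_path / "motifs.meme"
    write_meme_minimal(models, path)
    back = read_meme_minimal(path)
    for name in models:
        np.testing.assert_allclose(
            back[name].probabilities, models[name].probabilities, atol=1e-5
        )


def test_sites_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    seqs = _windows_with_planted(rng, 60, 300, "CATTGCGTCA")
    found = discover_motifs(seqs, params=DiscoveryParams(), seed=0, dataset_id="ds1")
    path = tmp_path / "sites.tsv"
    write_sites_tsv(found, path)
    back = read_sites_tsv(path)
    assert [m.motif_id for m in back] == [m.motif_id for m in found]
    assert back[0].n_sites == found[0].n_sites
    assert {s.sequence for s in back[0].sites} == {s.sequence for s in found[0].sites}
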