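import itertools

import numpy as np
import pandas as pd
import pytest

from motiffoot import association_stats as stats_mod
from motiffoot import synthetic_data as sd
from motiffoot._seq import revcomp
from motiffoot.association_stats import (
    associate,
    collect_groups,
    fisher_exact_2x2,
    mc_test,
    per_sample_associate,
    profile_correlation,
    upgma_cluster,
    welch_t,
)
from motiffoot.io_formats import MutationRecord, RunConfig
from motiffoot.motif_matrix import WeightMatrix


def exact_subset_p(w1, w2, alternative="greater"):
    """Enumerate every size-|w1| subset of w2 (the oracle for the MC test)."""
    w1, w2 = list(w1), list(w2)
    target = np.mean(w1)
    count = total = 0
    for combo in itertools.combinations(w2, len(w1)):
        total += 1
        m = np.mean(combo)
        if alternative == "greater":
            count += m >= target - 1e-12
        else:
            count += m <= target + 1e-12
    return count / total


def test_mc_test_hand_enumeration():
    # 4 of the C(5,2)=10 subsets of {0,0,0,0,20} have mean >= 10
    p = mc_test([10, 10], [0, 0, 0, 0, 20], n_samples=20_000, seed=0)
    se = np.sqrt(0.4 * 0.6 / 20_000)
    assert abs(p - 0.4) < 3 * se


def test_mc_test_saturates_at_one():
    assert mc_test([0, 0], [100] * 10, n_samples=1_000, seed=0) == 1.0


def test_mc_test_zero_count_reports_resolution_floor():
    p = mc_test([100, 100], [0.0] * 50, n_samples=1_000, seed=0)
    assert p == 1 / 1_000


def test_mc_test_requires_larger_pool():
    with pytest.raises(ValueError, match="exceed"):
        mc_test([1, 2, 3], [4, 5, 6])
    with pytest.raises(ValueError):
        mc_test([1], [1, 2, 3])


@pytest.mark.parametrize("case", range(12))
def test_mc_matches_enumeration_on_random_small_groups(case):
    rng = np.random.default_rng(100 + case)
    s2 = int(rng.integers(4, 13))
    s1 = int(rng.integers(2, s2))
    w1 = rng.integers(0, 100, size=s1).astype(float)
    w2 = rng.integers(0, 100, size=s2).astype(float)
    exact = exact_subset_p(w1, w2)
    n = 10_000
    p = mc_test(w1, w2, n_samples=n, seed=case)
    se = np.sqrt(max(exact * (1 - exact), 1e-4) / n)
    assert abs(p - max(exact, 1 / n)) <= 3 * se + 1 / n


def test_mc_dense_draws_use_complement_correctly():
    # s1 close to s2 exercises the complement sampling path
    rng = np.random.default_rng(5)
    w2 = rng.normal(size=9)
    w1 = rng.normal(size=7) + 0.1
    exact = exact_subset_p(w1, w2)
    p = mc_test(w1, w2, n_samples=20_000, seed=1)
    assert abs(p - exact) < 3 * np.sqrt(exact * (1 - exact) / 20_000) + 5e-5


def test_welch_t_agrees_with_permutation_on_null_groups():
    for seed in range(3):
        rng = np.random.default_rng(seed)
        g1, g2 = rng.normal(size=60), rng.normal(size=90)
        t, p = welch_t(g1, g2)
        pooled = np.concatenate([g1, g2])
        perm = np.empty(4_000)
        for i in range(4_000):
            rng.shuffle(pooled)
            a, b = pooled[:60], pooled[60:]
            perm[i] = a.mean() - b.mean()
        obs = g1.mean() - g2.mean()
        p_perm = np.mean(np.abs(perm) >= abs(obs))
        assert abs(p - p_perm) <= 0.02


def test_fisher_examples():
    assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)
    # 2 of the C(10,5) splits are as extreme as (5,0 / 0,5)
    assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-3)
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 3, 4)


def _flat_gc_matrix():
    return WeightMatrix(W=np.zeros((4, 11)), score_cols=np.arange(2, 9),
                        smin=0.0, smax=0.0, site_class="GC", label="flat",
                        flank=5)


def _null_study(seed, n_mutations=120, length=30_000, bias=0.0, wm=None):
    spec = sd.SimulationSpec(genome_length=length, planted_matrix=wm,
                             motif_bias=bias, n_mutations=n_mutations, seed=seed)
    genome = sd.simulate_genome(spec)
    muts = sd.simulate_mutations(genome, spec)
    return genome, muts


def test_associate_constant_matrix_is_degenerate_null(aid_wm):
    genome, muts = _null_study(1, wm=aid_wm)
    res = associate(muts, genome, _flat_gc_matrix(), seed=2)
    assert res.mean1 == pytest.approx(50.0)
    assert res.ratio == pytest.approx(1.0)
    assert not res.significant
    assert res.t_stat == 0.0 and res.t_p == 1.0


def test_associate_joint_significance_rule(aid_wm):
    genome, muts = _null_study(3, wm=aid_wm, bias=2.0, n_mutations=300,
                               length=60_000)
    cfg = RunConfig(mc_samples=2_000)
    res = associate(muts, genome, aid_wm, cfg, seed=4)
    assert res.significant == (res.t_p < cfg.alpha and res.mc_p < cfg.alpha)
    assert res.ratio > 1.0
    assert 1 / cfg.mc_samples <= res.mc_p <= 1.0
    assert res.s2 > res.s1 == res.exclusions["retained"]


def _mirror(genome, muts):
    rc = {c: revcomp(s) for c, s in genome.items()}
    comp = str.maketrans("ACGT", "TGCA")
    mirrored = [
        MutationRecord(m.chrom, len(genome[m.chrom]) - m.pos + 1,
                       m.ref.translate(comp), m.alt.translate(comp), m.sample_id)
        for m in muts
    ]
    return rc, mirrored


def test_associate_invariant_under_genome_revcomp(aid_wm):
    genome, muts = _null_study(7, n_mutations=60, wm=aid_wm)
    g1, g2, _ = collect_groups(muts, genome, aid_wm)
    rc_genome, rc_muts = _mirror(genome, muts)
    h1, h2, _ = collect_groups(rc_muts, rc_genome, aid_wm)
    assert np.allclose(np.sort(g1), np.sort(h1))
    assert np.allclose(np.sort(g2), np.sort(h2))


def test_per_sample_pools_to_merged_sizes(aid_wm, caplog):
    genome, muts = _null_study(9, n_mutations=150, wm=aid_wm, bias=2.0)
    # add a one-mutation sample that must be skipped
    lone = MutationRecord("chr1", muts[0].pos, muts[0].ref, muts[0].alt, "LONE")
    cfg = RunConfig(mc_samples=500)
    results = per_sample_associate(muts + [lone], genome, aid_wm, cfg, seed=11)
    assert all(r.sample_id != "LONE" for r in results)
    merged = associate(muts, genome, aid_wm, cfg, seed=12)
    # the skipped sample's mutation is excluded, the rest pool exactly
    assert sum(r.s1 for r in results) == merged.s1


def test_planted_bias_increases_rejection(aid_wm):
    cfg = RunConfig(mc_samples=1_000)
    hits = {0.0: 0, 2.0: 0}
    for lam in hits:
        for rep in range(6):
            genome, muts = _null_study(50 + rep, n_mutations=400,
                                       length=80_000, bias=lam, wm=aid_wm)
            res = associate(muts, genome, aid_wm, cfg, seed=70 + rep)
            hits[lam] += res.significant
    assert hits[2.0] >= hits[0.0]
    assert hits[2.0] >= 5


def test_profile_correlation_limits():
    base = pd.DataFrame({"a": [10.0, 50.0, 90.0, 30.0]})
    df = base.assign(b=base["a"], c=100 - base["a"], d=5.0)
    cc = profile_correlation(df)
    assert cc.loc["a", "b"] == pytest.approx(1.0)
    assert cc.loc["a", "c"] == pytest.approx(-1.0)
    assert np.isnan(cc.loc["a", "d"])  # zero-variance profile
    with pytest.raises(ValueError):
        profile_correlation(df.iloc[:2])


def test_upgma_orders():
    df = pd.DataFrame(
        [[0.0, 0.0], [1.0, 1.0], [10.0, 10.0]], index=["x", "y", "z"],
        columns=["t1", "t2"],
    )
    rows, cols = upgma_cluster(df)
    assert abs(rows.index("x") - rows.index("y")) == 1  # closest pair adjacent
    blocks = pd.DataFrame(
        [[1, 1, 9, 9], [1, 1, 9, 9], [9, 9, 1, 1], [9, 9, 1, 1]],
        index=list("abcd"), columns=list("wxyz"), dtype=float,
    )
    rows, cols = upgma_cluster(blocks)
    assert {rows[0], rows[1]} in ({"a", "b"}, {"c", "d"})
    assert {cols[0], cols[1]} in ({"w", "x"}, {"y", "z"})


def test_upgma_identical_rows_merge_at_zero():
    df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [8.0, 9.0]], index=list("pqr"),
                      columns=["u", "v"])
    rows, _ = upgma_cluster(df)
    assert abs(rows.index("p") - rows.index("q")) == 1


def test_shuffle_control_trivial_rep_and_determinism(aid_wm, rng):
    genome, muts = _null_study(13, n_mutations=80, wm=aid_wm)
    wins = []
    for _ in range(100):
        w = rng.choice(list("ACGT"), size=11)
        w[5] = "C"
        wins.append("".join(w))
    cfg = RunConfig(mc_samples=300)
    one = stats_mod.shuffle_control(wins, muts, genome, "GC", reps=1, seed=5,
                                    config=cfg)
    assert one.false_positive_rate in (0.0, 1.0)
    again = stats_mod.shuffle_control(wins, muts, genome, "GC", reps=1, seed=5,
                                      config=cfg)
    assert one == again
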