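"""Inferential machinery: ratio / t / Monte-Carlo association tests,
shuffle controls, Fisher exact tests, per-sample analysis, methylation
profile correlation, and UPGMA clustering of association values.

The core comparison: group 1 holds the percent motif weights at mutated
sites, group 2 the weights at non-mutated candidate sites of the same
class pooled over all neighborhoods.  An association is called when both
a two-tailed Welch t-test and a one-tailed Monte-Carlo resampling test
are significant at alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .context_windows import (
    WindowExclusion,
    extract_neighborhood,
    score_candidates,
    site_class_of,
)
from .io_formats import MutationRecord, RunConfig
from .motif_matrix import (
    WeightMatrix,
    build_frequency_matrix,
    shuffle_windows,
    weight_matrix,
)

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    label: str
    site_class: str
    s1: int
    s2: int
    mean1: float
    mean2: float
    ratio: float
    t_stat: float
    t_p: float
    mc_p: float
    significant: bool
    sample_id: str | None = None
    exclusions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "site_class": self.site_class,
            "s1": self.s1,
            "s2": self.s2,
            "mean1": self.mean1,
            "mean2": self.mean2,
            "ratio": self.ratio,
            "t_stat": self.t_stat,
            "t_p": self.t_p,
            "mc_p": self.mc_p,
            "significant": self.significant,
            "sample_id": self.sample_id,
            "exclusions": self.exclusions,
        }


@dataclass
class ShuffleControlResult:
    reps: int
    n_significant: int
    false_positive_rate: float


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Monte-Carlo test


def _subset_sums(pool: np.ndarray, k: int, n_rows: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Sums of ``n_rows`` uniform size-k subsets of pool (sampling
    without replacement within each subset).

    The set of the first k distinct values of an i.i.d. uniform index
    stream is a uniform k-subset, so each row draws a slightly over-
    long stream, keeps its first k distinct indices, and redraws the
    rare rows that came up short.
    """
    m = pool.size
    # expected stream length to hit k distinct values (coupon collector)
    expected = m * np.log(m / (m - k)) if k < m else float("inf")
    stream = max(k, int(1.2 * expected) + 8)
    out = np.empty(n_rows)
    pending = np.arange(n_rows)
    while pending.size:
        chunk = max(1, int(4e6) // stream)
        todo, pending = pending[:chunk], pending[chunk:]
        rows = todo.size
        v = rng.integers(0, m, size=(rows, stream))
        order = np.argsort(v, axis=1, kind="stable")
        sv = np.take_along_axis(v, order, axis=1)
        first_sorted = np.empty((rows, stream), dtype=bool)
        first_sorted[:, 0] = True
        first_sorted[:, 1:] = sv[:, 1:] != sv[:, :-1]
        first = np.empty_like(first_sorted)
        np.put_along_axis(first, order, first_sorted, axis=1)
        n_distinct = np.cumsum(first, axis=1)
        complete = n_distinct[:, -1] >= k
        sel = first & (n_distinct <= k)
        out[todo[complete]] = (pool[v] * sel)[complete].sum(axis=1)
        if not complete.all():
            pending = np.concatenate([pending, todo[~complete]])
            stream = int(1.5 * stream) + 8
    return out


def _resample_means(pool: np.ndarray, k: int, n_samples: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Means of ``n_samples`` size-k subsets of pool, drawn without
    replacement within each subset.  Dense draws (k > m/2) sample the
    complement instead."""
    m = pool.size
    if k > m // 2:
        total = pool.sum()
        return (total - _subset_sums(pool, m - k, n_samples, rng)) / k
    return _subset_sums(pool, k, n_samples, rng) / k


def mc_test(
    weights1,
    weights2,
    n_samples: int = 10_000,
    seed=None,
    alternative: str = "greater",
) -> float:
    """One-tailed Monte-Carlo resampling test.

    Draws ``n_samples`` groups of size len(weights1) from weights2
    (without replacement within each group) and reports the fraction of
    resampled means >= mean(weights1) ("greater"; <= for "less").  A
    zero count is reported at the resolution floor 1/n_samples.
    """
    w1 = np.asarray(weights1, dtype=float)
    w2 = np.asarray(weights2, dtype=float)
    if w1.size < 2:
        raise ValueError("group 1 must contain at least 2 values")
    if w2.size <= w1.size:
        raise ValueError("group 2 must exceed group 1")
    rng = _rng(seed)
    means = _resample_means(w2, w1.size, n_samples, rng)
    target = w1.mean()
    tol = 1e-9 * max(1.0, abs(target))
    if alternative == "greater":
        count = int((means >= target - tol).sum())
    elif alternative == "less":
        count = int((means <= target + tol).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return max(count, 1) / n_samples


def welch_t(group1, group2, pooled: bool = False):
    """Two-sample two-tailed t; Welch by default.  Degenerate inputs
    (zero pooled variance) yield t = 0, p = 1."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    res = stats.ttest_ind(g1, g2, equal_var=pooled)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) or np.isnan(p):
        return 0.0, 1.0
    return t, p


# ---------------------------------------------------------------------------
# neighborhood association


def collect_groups(mutations, genome, wm: WeightMatrix, config: RunConfig | None = None):
    """Percent-weight groups for the association test.

    Returns (group1, group2, exclusions): weights at mutated sites,
    weights at pooled non-mutated candidates, and a census of dropped
    records (wrong class, contig edge, ref mismatch, ambiguous bases).
    """
    cfg = config or RunConfig()
    group1, group2 = [], []
    excl = {"wrong_class": 0, "edge": 0, "ref_mismatch": 0, "missing_contig": 0,
            "ambiguous_center": 0, "ambiguous_sites": 0, "retained": 0}
    for m in mutations:
        if site_class_of(m.ref) != wm.site_class:
            excl["wrong_class"] += 1
            continue
        try:
            w = extract_neighborhood(genome, m, cfg.neighborhood_halfwidth)
        except WindowExclusion as exc:
            excl[exc.reason] += 1
            continue
        mutated, others, n_amb = score_candidates(w, wm, cfg.flank_collect)
        excl["ambiguous_sites"] += n_amb
        if mutated.size == 0:
            excl["ambiguous_center"] += 1
            continue
        excl["retained"] += 1
        group1.append(mutated)
        group2.append(others)
    g1 = np.concatenate(group1) if group1 else np.empty(0)
    g2 = np.concatenate(group2) if group2 else np.empty(0)
    return g1, g2, excl


def _association_from_groups(
    g1, g2, wm, cfg, seed, sample_id=None, exclusions=None
) -> AssociationResult:
    if g1.size < 2:
        raise ValueError("need at least 2 scoreable mutated sites")
    if g2.size <= g1.size:
        raise ValueError("group 2 must exceed group 1")
    mean1, mean2 = float(g1.mean()), float(g2.mean())
    t, t_p = welch_t(g1, g2)
    mc_p = mc_test(g1, g2, n_samples=cfg.mc_samples, seed=seed)
    return AssociationResult(
        label=wm.label,
        site_class=wm.site_class,
        s1=int(g1.size),
        s2=int(g2.size),
        mean1=mean1,
        mean2=mean2,
        ratio=mean1 / mean2,
        t_stat=t,
        t_p=t_p,
        mc_p=mc_p,
        significant=bool(t_p < cfg.alpha and mc_p < cfg.alpha),
        sample_id=sample_id,
        exclusions=exclusions or {},
    )


def associate(
    mutations,
    genome,
    wm: WeightMatrix,
    config: RunConfig | None = None,
    seed=None,
) -> AssociationResult:
    """Test whether mutated sites carry higher motif weights than the
    non-mutated sites of the same class in their neighborhoods."""
    cfg = config or RunConfig()
    g1, g2, excl = collect_groups(mutations, genome, wm, cfg)
    return _association_from_groups(
        g1, g2, wm, cfg, seed if seed is not None else cfg.seed, exclusions=excl
    )


def per_sample_associate(
    mutations,
    genome,
    wm: WeightMatrix,
    config: RunConfig | None = None,
    seed=None,
) -> list[AssociationResult]:
    """One association result per sample_id; samples with fewer than two
    scoreable mutations are skipped and logged."""
    cfg = config or RunConfig()
    rng = _rng(seed if seed is not None else cfg.seed)
    by_sample: dict[str, list[MutationRecord]] = {}
    for m in mutations:
        by_sample.setdefault(m.sample_id, []).append(m)
    results = []
    for sample in sorted(by_sample):
        g1, g2, excl = collect_groups(by_sample[sample], genome, wm, cfg)
        if g1.size < 2 or g2.size <= g1.size:
            log.warning("sample %s skipped: %d scoreable mutations", sample, g1.size)
            continue
        results.append(
            _association_from_groups(g1, g2, wm, cfg, rng, sample_id=sample,
                                     exclusions=excl)
        )
    return results


# ---------------------------------------------------------------------------
# shuffle control


def shuffle_control(
    windows,
    mutations,
    genome,
    site_class: str,
    reps: int = 1_000,
    seed=None,
    config: RunConfig | None = None,
) -> ShuffleControlResult:
    """False-positive rate of the association call under shuffled motifs.

    Each replicate independently permutes the flanks of the source
    windows (centers fixed), rebuilds the frequency and weight matrices,
    and reruns the association test against the same mutation catalog.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = config or RunConfig()
    rng = _rng(seed if seed is not None else cfg.seed)
    n_sig = 0
    for i in range(reps):
        shuffled = shuffle_windows(windows, rng)
        fm = build_frequency_matrix(shuffled, flank=cfg.flank_collect)
        wm = weight_matrix(fm, site_class, label=f"shuffled_{i}",
                           score_flank=cfg.flank_score)
        res = associate(mutations, genome, wm, cfg, seed=rng)
        n_sig += int(res.significant)
    return ShuffleControlResult(reps=reps, n_significant=n_sig,
                                false_positive_rate=n_sig / reps)


# ---------------------------------------------------------------------------
# exact tests and descriptive analyses


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def profile_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of per-sample methylation profiles.

    ``profiles``: positions x samples frame of methylation ratios;
    pairwise-complete positions are used; a zero-variance profile gives
    NaN against every partner."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 shared positions")
    cc = profiles.corr(method="pearson", min_periods=3)
    if cc.isna().any().any():
        log.warning("correlation undefined for some pairs (zero variance)")
    return cc


def upgma_cluster(values: pd.DataFrame):
    """UPGMA (average-linkage) leaf orders for rows and columns of an
    association-value matrix, using Euclidean distances.  NaN entries
    are imputed with the row mean and flagged."""
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    mat = values.to_numpy(dtype=float).copy()
    if np.isnan(mat).any():
        log.warning("imputing %d NaN entries with row means", int(np.isnan(mat).sum()))
        row_means = np.nanmean(mat, axis=1)
        idx = np.where(np.isnan(mat))
        mat[idx] = np.take(row_means, idx[0])
    row_order = leaves_list(linkage(mat, method="average", metric="euclidean"))
    if values.shape[1] >= 2:
        col_order = leaves_list(linkage(mat.T, method="average", metric="euclidean"))
    else:
        col_order = np.array([0])
    return list(values.index[row_order]), list(values.columns[col_order])
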