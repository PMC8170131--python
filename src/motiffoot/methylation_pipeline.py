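"""CpG methylation analyses: ratios, depth filtering, threshold
partitions, motif weights at CpG cytosines, and mutated-CpG overlap.

Because bisulfite data lack a natural control set, methylation levels
are compared across threshold partitions: at the 25% threshold group 1
is the hypo-methylated side (ratio < 25), at the 75% threshold group 1
is the hyper-methylated side (ratio > 75); group 2 is the complement.
Sites exactly at a threshold fall in group 2 (both inequalities are
strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ._seq import N_CODE, encode, revcomp_codes
from .association_stats import AssociationResult, mc_test, welch_t
from .io_formats import MethylationRecord, RunConfig
from .motif_matrix import WeightMatrix, percent_scores

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MethylationSite:
    chrom: str
    pos: int
    strand: str
    meth_reads: int
    total_reads: int
    ratio: float
    weight: float | None = None


@dataclass
class ThresholdPartition:
    threshold: float
    group1: list
    group2: list
    orientation: str  # "below" or "above": which side is group 1


@dataclass
class MutatedCpGResult:
    threshold: float
    n_above: int
    n_below: int
    fraction_below: float
    association: AssociationResult | None


def pool_records(records) -> list[MethylationRecord]:
    """Sum read counts across samples per (chrom, pos, strand).

    Cohort-level analyses pool all patients' reads at each position
    before computing the methylation ratio."""
    acc: dict[tuple, list[int]] = {}
    for r in records:
        key = (r.chrom, r.pos, r.strand)
        entry = acc.setdefault(key, [0, 0])
        entry[0] += r.meth_reads
        entry[1] += r.total_reads
    return [
        MethylationRecord(chrom=c, pos=p, strand=s, meth_reads=m, total_reads=t)
        for (c, p, s), (m, t) in sorted(acc.items())
    ]


def filter_and_ratio(records, min_reads: int = 10) -> list[MethylationSite]:
    """Keep positions with at least ``min_reads`` reads and attach the
    methylation ratio (percent)."""
    out = []
    for r in records:
        if r.total_reads < min_reads:
            continue
        out.append(
            MethylationSite(
                chrom=r.chrom,
                pos=r.pos,
                strand=r.strand,
                meth_reads=r.meth_reads,
                total_reads=r.total_reads,
                ratio=100.0 * r.meth_reads / r.total_reads,
            )
        )
    dropped = len(list(records)) - len(out)
    if dropped:
        log.info("depth filter dropped %d of %d positions", dropped,
                 dropped + len(out))
    return out


def score_methylation_sites(
    sites, genome, wm: WeightMatrix, flank: int = 5
) -> list[MethylationSite]:
    """Attach percent motif weights to cytosine sites, strand-aware.

    Minus-strand cytosines (reference G on the plus strand) are scored
    on the reverse complement of their 11-mer.  Sites whose reference
    base is not a cytosine on their strand, or whose context is
    incomplete or ambiguous, are dropped and counted in the log.
    """
    scored = []
    reasons = {"not_cytosine": 0, "edge": 0, "ambiguous": 0, "missing_contig": 0}
    rows, keep = [], []
    for site in sites:
        contig = genome.get(site.chrom)
        if contig is None:
            reasons["missing_contig"] += 1
            continue
        i = site.pos - 1
        expected = "C" if site.strand == "+" else "G"
        if i < 0 or i >= len(contig) or contig[i] != expected:
            reasons["not_cytosine"] += 1
            continue
        if i - flank < 0 or i + flank >= len(contig):
            reasons["edge"] += 1
            continue
        codes = encode(contig[i - flank : i + flank + 1])
        if (codes >= N_CODE).any():
            reasons["ambiguous"] += 1
            continue
        if site.strand == "-":
            codes = revcomp_codes(codes)
        rows.append(codes)
        keep.append(site)
    if rows:
        pct = percent_scores(np.vstack(rows), wm)
        for site, w in zip(keep, pct):
            scored.append(replace(site, weight=float(w)))
    dropped = {k: v for k, v in reasons.items() if v}
    if dropped:
        log.info("unscoreable methylation sites: %s", dropped)
    return scored


def partition_by_threshold(sites, threshold: float) -> ThresholdPartition:
    """Split scored sites into the threshold's contrast groups.

    Group 1 is the extreme side named by the design: the hypo-methylated
    side for thresholds below 50, the hyper-methylated side otherwise.
    """
    orientation = "below" if threshold < 50 else "above"
    if orientation == "below":
        g1 = [s for s in sites if s.ratio < threshold]
        g2 = [s for s in sites if s.ratio >= threshold]
    else:
        g1 = [s for s in sites if s.ratio > threshold]
        g2 = [s for s in sites if s.ratio <= threshold]
    return ThresholdPartition(threshold=threshold, group1=g1, group2=g2,
                              orientation=orientation)


def _weights_of(sites) -> np.ndarray:
    w = np.array([s.weight for s in sites], dtype=float)
    return w[~np.isnan(w)]


def weights_association(
    w1: np.ndarray,
    w2: np.ndarray,
    label: str,
    site_class: str,
    config: RunConfig | None = None,
    seed=None,
) -> AssociationResult:
    """Ratio / t / MC comparison of two weight groups, group 1 first.

    The MC test resamples from the larger group; when group 1 is the
    larger one the resamples are size-S2 subsets of group 1 and the
    one-tailed direction still follows group 1's mean (fraction of
    subset means <= mean of group 2).
    """
    cfg = config or RunConfig()
    if w1.size < 2 or w2.size < 2:
        raise ValueError(f"both groups need >= 2 sites (got {w1.size}, {w2.size})")
    mean1, mean2 = float(w1.mean()), float(w2.mean())
    t, t_p = welch_t(w1, w2)
    if w2.size > w1.size:
        mc_p = mc_test(w1, w2, n_samples=cfg.mc_samples, seed=seed,
                       alternative="greater")
    else:
        mc_p = mc_test(w2, w1, n_samples=cfg.mc_samples, seed=seed,
                       alternative="less")
    return AssociationResult(
        label=label,
        site_class=site_class,
        s1=int(w1.size),
        s2=int(w2.size),
        mean1=mean1,
        mean2=mean2,
        ratio=mean1 / mean2,
        t_stat=t,
        t_p=t_p,
        mc_p=mc_p,
        significant=bool(t_p < cfg.alpha and mc_p < cfg.alpha),
    )


def threshold_association(
    sites,
    threshold: float,
    config: RunConfig | None = None,
    seed=None,
    label: str = "",
) -> AssociationResult:
    """Compare mean motif weights across a methylation-threshold split."""
    cfg = config or RunConfig()
    part = partition_by_threshold(sites, threshold)
    w1, w2 = _weights_of(part.group1), _weights_of(part.group2)
    if w1.size < 2 or w2.size < 2:
        raise ValueError(
            f"threshold {threshold}: partition sizes {w1.size}/{w2.size} too small"
        )
    return weights_association(w1, w2, label or f"threshold_{threshold:g}",
                               "GC", cfg, seed if seed is not None else cfg.seed)


def _dyad_positions(site: MethylationSite) -> tuple[int, int]:
    """1-based positions of both bases of the site's CpG dyad."""
    if site.strand == "+":
        return site.pos, site.pos + 1
    return site.pos - 1, site.pos


def mutated_cpg_analysis(
    mutations,
    sites,
    threshold: float = 75.0,
    config: RunConfig | None = None,
    seed=None,
    label: str = "mutated_cpg",
) -> MutatedCpGResult:
    """Methylation of CpG sites that coincide with somatic mutations.

    A mutation matches a CpG when its position equals either base of
    the CpG dyad.  Counts the mutated sites above/below the threshold
    (ties count as below, mirroring the strict "larger than" rule) and
    compares motif weights between below- and above-threshold mutated
    sites (group 1 = below).
    """
    cfg = config or RunConfig()
    mut_pos: dict[str, set[int]] = {}
    for m in mutations:
        mut_pos.setdefault(m.chrom, set()).add(m.pos)
    hit = []
    for s in sites:
        positions = mut_pos.get(s.chrom)
        if not positions:
            continue
        p1, p2 = _dyad_positions(s)
        if p1 in positions or p2 in positions:
            hit.append(s)
    above = [s for s in hit if s.ratio > threshold]
    below = [s for s in hit if s.ratio <= threshold]
    n_above, n_below = len(above), len(below)
    total = n_above + n_below
    fraction_below = n_below / total if total else float("nan")
    association = None
    w_below, w_above = _weights_of(below), _weights_of(above)
    if w_below.size >= 2 and w_above.size >= 2:
        association = weights_association(
            w_below, w_above, label, "GC", cfg, seed if seed is not None else cfg.seed
        )
    else:
        log.info("mutated-CpG weight tests skipped: groups %d/%d",
                 w_below.size, w_above.size)
    return MutatedCpGResult(
        threshold=threshold,
        n_above=n_above,
        n_below=n_below,
        fraction_below=fraction_below,
        association=association,
    )
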