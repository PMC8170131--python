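"""Per-position frequency matrices, log2-odds weight matrices, and site scoring.

The model: around a collection of aligned mutation sites (the mutated
base at the central position), tally the nucleotide frequency f(b, j)
at each flanking position j.  The background e(b) is the mean of f(b, j)
over the outermost positions (-5, -4, +4, +5), i.e. flanks far enough
from the mutated base to be context-neutral.  The weight matrix is

    W(b, j) = log2( f(b, j) / e(b) )

and a site's matching score is the sum of W over the scoring span
(-3..+3 including the center), normalized to a 0-100 "% matching score"
via the column-wise minimal and maximal attainable sums (Smin, Smax).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seq import BASES, N_CODE, encode, encode_many, revcomp_codes

log = logging.getLogger(__name__)

SITE_CLASSES = {"GC", "AT"}


class AmbiguousBaseError(ValueError):
    """A non-ACGT base fell inside a scoring span."""


@dataclass
class FrequencyMatrix:
    """Raw counts and smoothed frequencies of bases around aligned sites.

    counts[b, j] are exact tallies (rows A, C, G, T; columns -flank..+flank).
    f[b, j] is the smoothed frequency; e[b] the background frequency.
    """

    counts: np.ndarray
    f: np.ndarray
    e: np.ndarray
    n_windows: int
    flank: int
    smoothing: float = 0.25

    @property
    def length(self) -> int:
        return 2 * self.flank + 1

    def validate(self) -> None:
        assert np.allclose(self.f.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(self.e.sum(), 1.0, atol=1e-9)
        assert (self.counts.sum(axis=0) == self.n_windows).all()


@dataclass
class WeightMatrix:
    """Log2-odds weights with a scoring span and its score bounds."""

    W: np.ndarray
    score_cols: np.ndarray
    smin: float
    smax: float
    site_class: str
    label: str
    flank: int
    n_windows: int = 0
    e: np.ndarray | None = None
    counts: np.ndarray | None = None

    @property
    def degenerate(self) -> bool:
        return not self.smax > self.smin


@dataclass
class SiteScore:
    S: float
    percent: float
    degenerate: bool = False


def _as_codes(windows, flank: int | None = None) -> np.ndarray:
    codes = encode_many(windows)
    if codes.ndim != 2 or codes.shape[0] == 0:
        raise ValueError("need at least one window")
    if codes.shape[1] % 2 == 0:
        raise ValueError("windows must have odd length (a defined center)")
    if flank is not None and codes.shape[1] != 2 * flank + 1:
        raise ValueError(
            f"window length {codes.shape[1]} != 2*flank+1 = {2 * flank + 1}"
        )
    return codes


def build_frequency_matrix(
    windows, flank: int = 5, smoothing: float = 0.25
) -> FrequencyMatrix:
    """Tally aligned windows into a FrequencyMatrix.

    ``windows`` is a list of equal-length ACGT strings (or an (n, L)
    code array) with the mutated/candidate site at the center.  An
    add-``smoothing`` pseudocount per cell keeps every frequency
    positive so the log-odds are finite; raw counts are preserved for
    the chi-square comparison.
    """
    codes = _as_codes(windows, flank)
    if (codes >= N_CODE).any():
        raise ValueError("aligned windows must not contain non-ACGT bases")
    n, length = codes.shape
    counts = np.zeros((4, length), dtype=np.int64)
    for j in range(length):
        counts[:, j] = np.bincount(codes[:, j], minlength=4)
    f = (counts + smoothing) / (n + 4 * smoothing)
    fm = FrequencyMatrix(counts=counts, f=f, e=_background(f), n_windows=n,
                         flank=flank, smoothing=smoothing)
    fm.validate()
    return fm


def frequency_matrix_from_counts(
    counts: np.ndarray, flank: int = 5, smoothing: float = 0.25
) -> FrequencyMatrix:
    """Build a FrequencyMatrix from a pre-tallied (4, 2*flank+1) count table."""
    counts = np.asarray(counts, dtype=np.int64)
    totals = counts.sum(axis=0)
    if not (totals == totals[0]).all():
        raise ValueError("count columns must share one total")
    n = int(totals[0])
    f = (counts + smoothing) / (n + 4 * smoothing)
    fm = FrequencyMatrix(counts=counts, f=f, e=_background(f), n_windows=n,
                         flank=flank, smoothing=smoothing)
    fm.validate()
    return fm


def _background(f: np.ndarray) -> np.ndarray:
    # mean frequency over the two outermost positions on each side
    length = f.shape[1]
    edge_cols = [0, 1, length - 2, length - 1]
    return f[:, edge_cols].mean(axis=1)


def weight_matrix(
    fm: FrequencyMatrix,
    site_class: str,
    label: str,
    score_flank: int = 3,
    include_center: bool = True,
) -> WeightMatrix:
    """Turn frequencies into log2-odds weights with score bounds.

    The scoring span is the center +/- ``score_flank`` columns; the
    center column itself participates unless ``include_center`` is off.
    """
    if site_class not in SITE_CLASSES:
        raise ValueError(f"site_class must be one of {sorted(SITE_CLASSES)}")
    if (fm.e <= 0).any():
        raise ValueError("background frequency e(b) must be positive")
    if score_flank > fm.flank:
        raise ValueError("score_flank exceeds matrix flank")
    W = np.log2(fm.f / fm.e[:, None])
    center = fm.flank
    cols = np.arange(center - score_flank, center + score_flank + 1)
    if not include_center:
        cols = cols[cols != center]
    smin = float(W[:, cols].min(axis=0).sum())
    smax = float(W[:, cols].max(axis=0).sum())
    return WeightMatrix(W=W, score_cols=cols, smin=smin, smax=smax,
                        site_class=site_class, label=label, flank=fm.flank,
                        n_windows=fm.n_windows, e=fm.e.copy(),
                        counts=fm.counts.copy())


# ---------------------------------------------------------------------------
# scoring


def raw_scores(codes: np.ndarray, wm: WeightMatrix) -> np.ndarray:
    """Sum of W over the scoring span for each row of an (n, L) code
    matrix centered like the matrix; NaN where the span holds a
    non-ACGT base."""
    codes = np.atleast_2d(codes)
    center = codes.shape[1] // 2
    if center < (wm.score_cols.max() - wm.flank):
        raise ValueError("window too short for the scoring span")
    Wx = np.vstack([wm.W, np.full(wm.W.shape[1], np.nan)])  # row 4 = ambiguous
    S = np.zeros(codes.shape[0])
    for c in wm.score_cols:
        S = S + Wx[codes[:, center + (c - wm.flank)], c]
    return S


def percent_scores(codes: np.ndarray, wm: WeightMatrix) -> np.ndarray:
    """0-100 normalized matching scores; NaN marks unscoreable rows.

    When the matrix is degenerate (Smax == Smin, a constant matrix) the
    percent is defined as 50 for every scoreable site.
    """
    S = raw_scores(codes, wm)
    if wm.degenerate:
        out = np.full_like(S, 50.0)
        out[np.isnan(S)] = np.nan
        return out
    return 100.0 * (S - wm.smin) / (wm.smax - wm.smin)


def score_site(window: str, wm: WeightMatrix) -> SiteScore:
    """Score one window centered on a candidate site."""
    codes = encode(window)[None, :]
    if codes.shape[1] % 2 == 0:
        raise ValueError("window must have odd length")
    S = float(raw_scores(codes, wm)[0])
    if np.isnan(S):
        raise AmbiguousBaseError("non-ACGT base inside the scoring span")
    if wm.degenerate:
        return SiteScore(S=S, percent=50.0, degenerate=True)
    return SiteScore(S=S, percent=100.0 * (S - wm.smin) / (wm.smax - wm.smin))


def percent_tracks(codes: np.ndarray, wm: WeightMatrix):
    """Percent scores for every position of a contig, both orientations.

    Returns (plus, minus): arrays of len(codes) where plus[i] scores the
    window read on the given strand centered at i, and minus[i] scores
    the reverse complement of that window.  NaN at positions whose span
    leaves the contig or touches a non-ACGT base.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    n = codes.size
    pad = wm.flank
    padded = np.full(n + 2 * pad, N_CODE, dtype=np.uint8)
    padded[pad : pad + n] = codes
    Wx = np.vstack([wm.W, np.full(wm.W.shape[1], np.nan)])
    comp = np.array([3, 2, 1, 0, 4])
    S_plus = np.zeros(n)
    S_minus = np.zeros(n)
    for c in wm.score_cols:
        j = c - wm.flank
        S_plus = S_plus + Wx[padded[pad + j : pad + j + n], c]
        S_minus = S_minus + Wx[comp[padded[pad - j : pad - j + n]], c]
    if wm.degenerate:
        out_p = np.where(np.isnan(S_plus), np.nan, 50.0)
        out_m = np.where(np.isnan(S_minus), np.nan, 50.0)
        return out_p, out_m
    span = wm.smax - wm.smin
    return 100.0 * (S_plus - wm.smin) / span, 100.0 * (S_minus - wm.smin) / span


# ---------------------------------------------------------------------------
# shuffle control


def shuffle_windows(windows, seed=None) -> list[str]:
    """Independently permute the flanking bases of each window, keeping
    the central (mutated) base fixed.  Conserves each window's base
    multiset and hence both per-window and overall composition."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _as_codes(windows)
    center = codes.shape[1] // 2
    flank_cols = np.r_[0:center, center + 1 : codes.shape[1]]
    flanks = rng.permuted(codes[:, flank_cols], axis=1)
    out = codes.copy()
    out[:, flank_cols] = flanks
    from ._seq import decode

    return [decode(row) for row in out]


# ---------------------------------------------------------------------------
# matrix comparison


def compare_matrices_chi2(
    fmA: FrequencyMatrix, fmB: FrequencyMatrix, df_convention: str = "per_position"
):
    """Compare the flank composition of two mutation collections.

    For each of the flanking positions j != 0 a Pearson chi-square is
    computed on the 2x4 table [countsA(., j); countsB(., j)] and the
    statistics are summed.  Bases absent from both collections at a
    position are pooled (dropped; their counts are zero) and logged.

    df_convention: "per_position" uses sum_j (categories_j - 1), i.e.
    30 for full 4-base columns over 10 positions; "positions_x4" is the
    legacy convention 10 * 4 = 40.  The statistic itself does not
    depend on the convention.
    """
    if fmA.counts.shape != fmB.counts.shape:
        raise ValueError("matrices must have the same shape")
    length = fmA.counts.shape[1]
    center = length // 2
    chi2 = 0.0
    df = 0
    n_flank = 0
    for j in range(length):
        if j == center:
            continue
        n_flank += 1
        a = fmA.counts[:, j].astype(float)
        b = fmB.counts[:, j].astype(float)
        margin = a + b
        keep = margin > 0
        if not keep.all():
            dropped = [BASES[k] for k in np.flatnonzero(~keep)]
            log.info("position %d: pooling absent bases %s", j - center, dropped)
        a, b = a[keep], b[keep]
        table = np.vstack([a, b])
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        chi2 += float(((table - expected) ** 2 / expected).sum())
        df += keep.sum() - 1
    if df_convention == "positions_x4":
        df = n_flank * 4
    elif df_convention != "per_position":
        raise ValueError(f"unknown df convention {df_convention!r}")
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, int(df), p


# ---------------------------------------------------------------------------
# serialization: TSV body + JSON sidecar


def save_weight_matrix(wm: WeightMatrix, path) -> None:
    path = str(path)
    cols = [str(j - wm.flank) for j in range(2 * wm.flank + 1)]
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(cols) + "\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(repr(float(x)) for x in wm.W[i]) + "\n")
    sidecar = {
        "label": wm.label,
        "site_class": wm.site_class,
        "flank": wm.flank,
        "n_windows": wm.n_windows,
        "score_cols": [int(c) for c in wm.score_cols],
        "smin": wm.smin,
        "smax": wm.smax,
        "e": None if wm.e is None else list(map(float, wm.e)),
        "counts": None if wm.counts is None else wm.counts.tolist(),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_weight_matrix(path) -> WeightMatrix:
    path = str(path)
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("base"):
            raise ValueError(f"{path}: not a weight-matrix TSV")
        for line in fh:
            rows.append([float(x) for x in line.split("\t")[1:]])
    with open(path + ".json") as fh:
        meta = json.load(fh)
    return WeightMatrix(
        W=np.array(rows),
        score_cols=np.array(meta["score_cols"]),
        smin=meta["smin"],
        smax=meta["smax"],
        site_class=meta["site_class"],
        label=meta["label"],
        flank=meta["flank"],
        n_windows=meta["n_windows"],
        e=None if meta["e"] is None else np.array(meta["e"]),
        counts=None if meta["counts"] is None else np.array(meta["counts"]),
    )
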