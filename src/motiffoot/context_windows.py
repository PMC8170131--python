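"""Mutation neighborhoods and strand-aware candidate-site enumeration.

Each base substitution is examined inside the 121-bp reference slice
centered on it (the DNA neighborhood).  Candidate sites of a class
(G:C or A:T) are every position in the neighborhood whose reference
base belongs to the class; the central position is the mutated site.
Matrices are defined with the pyrimidine (C) at center for the GC
class and with A at center for the AT class, so G- and T-centered
sites are scored on the reverse complement of their 11-mer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import N_CODE, encode, revcomp_codes
from .io_formats import MutationRecord
from .motif_matrix import WeightMatrix, percent_scores

PLUS_CENTER = {"GC": "C", "AT": "A"}
MINUS_CENTER = {"GC": "G", "AT": "T"}


class WindowExclusion(ValueError):
    """A mutation could not be turned into a usable neighborhood."""

    def __init__(self, reason: str, message: str = ""):
        super().__init__(message or reason)
        self.reason = reason


@dataclass
class NeighborhoodWindow:
    chrom: str
    center_pos: int  # 1-based
    seq: str
    center_is_mutation: bool
    site_class: str


@dataclass(frozen=True)
class CandidateSite:
    offset: int  # relative to window center
    base: str
    strand_used: str
    mutated: bool


def site_class_of(base: str) -> str:
    return "GC" if base in "CG" else "AT"


def extract_neighborhood(
    genome: dict[str, str], m: MutationRecord, halfwidth: int = 60
) -> NeighborhoodWindow:
    """Slice the reference around a mutation.

    Raises WindowExclusion("edge") when the window would overrun the
    contig and WindowExclusion("ref_mismatch") when the reference base
    disagrees with the record's ref allele.
    """
    if m.chrom not in genome:
        raise WindowExclusion("missing_contig", f"contig {m.chrom!r} not in reference")
    contig = genome[m.chrom]
    i = m.pos - 1
    if i - halfwidth < 0 or i + halfwidth >= len(contig):
        raise WindowExclusion("edge", f"{m.chrom}:{m.pos} too close to contig end")
    if contig[i] != m.ref:
        raise WindowExclusion(
            "ref_mismatch",
            f"{m.chrom}:{m.pos} reference is {contig[i]}, record says {m.ref}",
        )
    return NeighborhoodWindow(
        chrom=m.chrom,
        center_pos=m.pos,
        seq=contig[i - halfwidth : i + halfwidth + 1],
        center_is_mutation=True,
        site_class=site_class_of(m.ref),
    )


def enumerate_candidates(
    w: NeighborhoodWindow, site_class: str, flank: int = 5
) -> list[CandidateSite]:
    """All positions of the class in the neighborhood, edge-trimmed.

    Offsets within ``flank`` of the window edge are excluded so that
    every candidate has a full scoring context.
    """
    half = len(w.seq) // 2
    wanted = PLUS_CENTER[site_class] + MINUS_CENTER[site_class]
    out = []
    for offset in range(-(half - flank), half - flank + 1):
        base = w.seq[offset + half]
        if base not in wanted:
            continue
        strand = "+" if base == PLUS_CENTER[site_class] else "-"
        mutated = offset == 0 and w.center_is_mutation
        out.append(CandidateSite(offset=offset, base=base, strand_used=strand,
                                 mutated=mutated))
    return out


def window_at(w: NeighborhoodWindow, c: CandidateSite, flank: int = 5) -> str:
    """11-mer centered on a candidate, reverse-complemented for minus-
    strand sites so the center base is the matrix's reference base."""
    from ._seq import decode
    from .motif_matrix import AmbiguousBaseError

    half = len(w.seq) // 2
    i = c.offset + half
    if i - flank < 0 or i + flank >= len(w.seq):
        raise WindowExclusion("edge", "candidate context overruns the window")
    codes = encode(w.seq[i - flank : i + flank + 1])
    if (codes >= N_CODE).any():
        raise AmbiguousBaseError("non-ACGT base in candidate context")
    if c.strand_used == "-":
        codes = revcomp_codes(codes)
    return decode(codes)


def score_candidates(w: NeighborhoodWindow, wm: WeightMatrix, flank: int = 5):
    """Vectorized scoring of every candidate in one neighborhood.

    Returns (mutated_percents, other_percents, n_ambiguous): percent
    scores of the mutated center (empty when the center is unscoreable
    or not of the matrix's class) and of all non-mutated candidates.
    """
    codes = encode(w.seq)
    half = len(codes) // 2
    sw = sliding_window_view(codes, 2 * flank + 1)  # one row per valid offset
    offsets = np.arange(len(sw)) - (half - flank)
    centers = sw[:, flank]
    plus_code = encode(PLUS_CENTER[wm.site_class])[0]
    minus_code = encode(MINUS_CENTER[wm.site_class])[0]
    is_plus = centers == plus_code
    is_minus = centers == minus_code
    mask = is_plus | is_minus
    if not mask.any():
        return np.empty(0), np.empty(0), 0
    rows = sw[mask].copy()
    rows[is_minus[mask]] = revcomp_codes(rows[is_minus[mask]])
    pct = percent_scores(rows, wm)
    valid = ~np.isnan(pct)
    n_ambiguous = int((~valid).sum())
    is_center = (offsets[mask] == 0) & w.center_is_mutation
    mutated = pct[is_center & valid]
    others = pct[~is_center & valid]
    return mutated, others, n_ambiguous
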