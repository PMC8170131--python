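"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a lymphoma-like study: a small genome with CpG
dyads, a mutation catalog whose sequence context is biased toward a
planted weight matrix, a bimodal bisulfite methylation cohort whose
mode choice can be coupled to motif weight, driver-prediction tables
with a planted driver-gene subset, and an FPKM expression matrix with
inflated variance for driver genes.  Every generator is deterministic
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import BASES, decode, encode
from .io_formats import (
    MethylationRecord,
    MutationRecord,
    PredictionRecord,
    write_expression,
    write_fasta,
    write_methylation,
    write_mutations,
    write_predictions,
)
from .motif_matrix import (
    WeightMatrix,
    build_frequency_matrix,
    percent_tracks,
    weight_matrix,
)

_PLUS_CENTER = {"GC": "C", "AT": "A"}
_MINUS_CENTER = {"GC": "G", "AT": "T"}


@dataclass
class SimulationSpec:
    """Planted parameters of a synthetic study.

    Defaults mirror the study shape: a 100-kb genome, 26 patient
    samples, and a bimodal methylation mixture tuned to a ~78% cohort
    mean (the mixture weight 0.84 of a Beta(20, 2) high mode against a
    Beta(2, 18) low mode).
    """

    genome_length: int = 100_000
    gc_content: float = 0.42
    cpg_enrichment: float = 1.0
    planted_matrix: WeightMatrix | None = None
    motif_bias: float = 0.0  # lambda: mutation rate multiplier exp(bias * pct/100)
    n_mutations: int = 500
    n_samples: int = 26
    meth_mix: tuple = ((2.0, 18.0), (20.0, 2.0), 0.84)
    depth_mean: float = 30.0
    coupling: float = 0.0  # links motif weight to the low-methylation mode
    seed: int = 0
    n_driver_genes: int = 20
    n_genes: int = 100
    expr_var_inflation: float = 4.0

    def __post_init__(self):
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.motif_bias < 0:
            raise ValueError("motif_bias must be >= 0")
        if not 0.0 <= self.meth_mix[2] <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [-1, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# planted matrices


def matrix_from_profile(
    profile: dict[int, dict[str, float]],
    site_class: str,
    label: str,
    flank: int = 5,
    n_windows: int = 2_000,
    seed: int = 7,
) -> WeightMatrix:
    """Build a weight matrix from windows sampled under a per-position
    composition profile (uniform where unspecified, center fixed to the
    class's reference base)."""
    rng = np.random.default_rng(seed)
    length = 2 * flank + 1
    probs = np.full((length, 4), 0.25)
    for j, dist in profile.items():
        col = np.array([dist.get(b, 0.0) for b in BASES])
        if not np.isclose(col.sum(), 1.0):
            raise ValueError(f"profile at position {j} does not sum to 1")
        probs[j + flank] = col
    center_code = encode(_PLUS_CENTER[site_class])[0]
    codes = np.empty((n_windows, length), dtype=np.uint8)
    for j in range(length):
        codes[:, j] = rng.choice(4, size=n_windows, p=probs[j])
    codes[:, flank] = center_code
    fm = build_frequency_matrix(codes, flank=flank)
    return weight_matrix(fm, site_class, label)


def aid_like_matrix(seed: int = 7) -> WeightMatrix:
    """WRC-style deaminase motif: W at -2, R at -1, C at the center."""
    w = {"A": 0.45, "T": 0.45, "G": 0.05, "C": 0.05}
    r = {"A": 0.45, "G": 0.45, "C": 0.05, "T": 0.05}
    return matrix_from_profile({-2: w, -1: r}, "GC", "aid_like", seed=seed)


def syc_control_matrix(seed: int = 7) -> WeightMatrix:
    """SYC-style control, anti-correlated with the WRC motif."""
    s = {"G": 0.45, "C": 0.45, "A": 0.05, "T": 0.05}
    y = {"C": 0.45, "T": 0.45, "A": 0.05, "G": 0.05}
    return matrix_from_profile({-2: s, -1: y}, "GC", "syc_control", seed=seed)


def pol_eta_like_matrix(seed: int = 7) -> WeightMatrix:
    """WA-style translesion-polymerase motif: W at -1, A at the center."""
    w = {"A": 0.45, "T": 0.45, "G": 0.05, "C": 0.05}
    return matrix_from_profile({-1: w}, "AT", "pol_eta_like", seed=seed)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(spec: SimulationSpec, seed=None) -> dict[str, str]:
    """I.i.d. draw at the requested GC content; when cpg_enrichment
    differs from 1 a first-order chain up/down-weights G after C."""
    rng = _rng(spec.seed if seed is None else seed)
    n = spec.genome_length
    p = np.array([
        (1 - spec.gc_content) / 2,
        spec.gc_content / 2,
        spec.gc_content / 2,
        (1 - spec.gc_content) / 2,
    ])
    if spec.cpg_enrichment == 1.0:
        codes = rng.choice(4, size=n, p=p)
    else:
        after_c = p.copy()
        after_c[2] *= spec.cpg_enrichment
        after_c = after_c / after_c.sum()
        cum = np.cumsum(p)
        cum_c = np.cumsum(after_c)
        u = rng.random(n)
        codes = np.empty(n, dtype=np.uint8)
        codes[0] = np.searchsorted(cum, u[0])
        for i in range(1, n):
            thresholds = cum_c if codes[i - 1] == 1 else cum
            codes[i] = np.searchsorted(thresholds, u[i])
    return {"chr1": decode(codes.astype(np.uint8))}


# ---------------------------------------------------------------------------
# mutations


def _site_percents(contig_codes, wm: WeightMatrix):
    """Per-position percent weight on the scoring strand for each base
    of the matrix's class (plus track for the pyrimidine/A sites,
    minus track for their complements)."""
    plus, minus = percent_tracks(contig_codes, wm)
    plus_code = encode(_PLUS_CENTER[wm.site_class])[0]
    minus_code = encode(_MINUS_CENTER[wm.site_class])[0]
    pct = np.full(contig_codes.size, np.nan)
    sel_p = contig_codes == plus_code
    sel_m = contig_codes == minus_code
    pct[sel_p] = plus[sel_p]
    pct[sel_m] = minus[sel_m]
    return pct


def simulate_mutations(
    genome: dict[str, str], spec: SimulationSpec, seed=None, margin: int = 60
) -> list[MutationRecord]:
    """Draw distinct mutated sites with probability proportional to
    exp(motif_bias * percent/100) under the planted matrix.

    Sites are restricted to the matrix's class (any base when no matrix
    is planted) and kept ``margin`` bases from contig ends so every
    simulated mutation has a full neighborhood.  Sampling without
    replacement uses random keys (Gumbel top-k), so motif_bias = 0 is a
    uniform draw.
    """
    rng = _rng(spec.seed if seed is None else seed)
    records = []
    contigs = sorted(genome)
    all_sites, all_weights, all_chrom = [], [], []
    for chrom in contigs:
        codes = encode(genome[chrom])
        if spec.planted_matrix is not None:
            pct = _site_percents(codes, spec.planted_matrix)
        else:
            pct = np.where(codes < 4, 50.0, np.nan)
        pct[:margin] = np.nan
        pct[len(pct) - margin :] = np.nan
        idx = np.flatnonzero(~np.isnan(pct))
        all_sites.append(idx)
        all_weights.append(np.exp(spec.motif_bias * pct[idx] / 100.0))
        all_chrom.extend([chrom] * idx.size)
    sites = np.concatenate(all_sites)
    weights = np.concatenate(all_weights)
    if spec.n_mutations > sites.size:
        raise ValueError(
            f"n_mutations {spec.n_mutations} exceeds {sites.size} eligible sites"
        )
    if spec.n_mutations == 0:
        return []
    keys = np.log(weights) + rng.gumbel(size=weights.size)
    chosen = np.argpartition(-keys, spec.n_mutations - 1)[: spec.n_mutations]
    chosen = chosen[np.argsort(sites[chosen])]
    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    for c in chosen:
        chrom = all_chrom[c]
        i = int(sites[c])
        ref = genome[chrom][i]
        alt = rng.choice([b for b in BASES if b != ref])
        records.append(
            MutationRecord(chrom=chrom, pos=i + 1, ref=ref, alt=str(alt),
                           sample_id=str(rng.choice(sample_ids)))
        )
    return records


# ---------------------------------------------------------------------------
# methylation


def cpg_cytosines(genome: dict[str, str]):
    """Yield (chrom, 1-based pos, strand) for both cytosines of every
    CpG dyad."""
    out = []
    for chrom in sorted(genome):
        codes = encode(genome[chrom])
        starts = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
        for i in starts:
            out.append((chrom, int(i) + 1, "+"))
            out.append((chrom, int(i) + 2, "-"))
    return out


def simulate_methylation(
    genome: dict[str, str], spec: SimulationSpec, seed=None
) -> list[MethylationRecord]:
    """Bimodal beta-binomial methylation at every CpG cytosine.

    Each cytosine picks the high-methylation mode with probability
    ``meth_mix[2]``, shifted by -coupling * (percent - 50)/100 when a
    matrix is planted (positive coupling sends high-weight sites toward
    the low-methylation mode).  The latent ratio is beta-distributed
    within the mode; reads are Poisson(depth_mean) with a floor of one;
    methylated reads are binomial.
    """
    rng = _rng(spec.seed if seed is None else seed)
    (a_lo, b_lo), (a_hi, b_hi), w_hi = spec.meth_mix
    sites = cpg_cytosines(genome)
    if not sites:
        return []
    n = len(sites)
    p_hi = np.full(n, w_hi)
    if spec.planted_matrix is not None and spec.coupling != 0.0:
        tracks = {}
        for chrom in sorted(genome):
            codes = encode(genome[chrom])
            tracks[chrom] = percent_tracks(codes, spec.planted_matrix)
        w = np.array(
            [
                tracks[chrom][0 if strand == "+" else 1][pos - 1]
                for chrom, pos, strand in sites
            ]
        )
        ok = ~np.isnan(w)
        p_hi[ok] = np.clip(w_hi - spec.coupling * (w[ok] - 50.0) / 100.0, 0.0, 1.0)
    high = rng.random(n) < p_hi
    latent = np.where(high, rng.beta(a_hi, b_hi, size=n), rng.beta(a_lo, b_lo, size=n))
    total = np.maximum(1, rng.poisson(spec.depth_mean, size=n))
    meth = rng.binomial(total, latent)
    return [
        MethylationRecord(chrom=chrom, pos=pos, strand=strand,
                          meth_reads=int(m), total_reads=int(t))
        for (chrom, pos, strand), m, t in zip(sites, meth, total)
    ]


def simulate_sample_profiles(
    genome: dict[str, str], spec: SimulationSpec, seed=None
):
    """Per-sample methylation profiles over shared CpG positions.

    Every sample observes the same latent per-site methylation level
    (drawn once from the bimodal mixture) through independent
    Poisson/binomial read noise, emulating replicate patients of one
    cohort: profiles correlate strongly by construction.  Returns a
    positions x samples DataFrame of observed ratios (percent).
    """
    import pandas as pd

    rng = _rng(spec.seed if seed is None else seed)
    (a_lo, b_lo), (a_hi, b_hi), w_hi = spec.meth_mix
    sites = cpg_cytosines(genome)
    n = len(sites)
    high = rng.random(n) < w_hi
    latent = np.where(high, rng.beta(a_hi, b_hi, size=n),
                      rng.beta(a_lo, b_lo, size=n))
    data = {}
    for s in range(spec.n_samples):
        total = np.maximum(1, rng.poisson(spec.depth_mean, size=n))
        meth = rng.binomial(total, latent)
        data[f"S{s + 1:02d}"] = 100.0 * meth / total
    index = [f"{c}:{p}:{st}" for c, p, st in sites]
    return pd.DataFrame(data, index=index)


# ---------------------------------------------------------------------------
# predictions and expression


def simulate_predictions(
    genes: list[str], spec: SimulationSpec, seed=None
) -> tuple[list[PredictionRecord], set]:
    """Prediction table with a planted driver-gene subset.

    Driver genes receive one recurrent driver-consistent mutation
    (MutaGene driver calls, CHASMplus score > 0.5) plus passenger
    mutations; all other genes receive only recurrent passenger
    mutations.  Returns (records, planted driver gene set).
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    rng = _rng(spec.seed if seed is None else seed)
    n_driver = min(spec.n_driver_genes, len(genes))
    drivers = set(rng.choice(genes, size=n_driver, replace=False).tolist())
    records = []

    def passenger(gene, k):
        return PredictionRecord(
            gene=gene,
            mutation_key=f"{gene}:p{k}",
            mutagene_pancancer=str(rng.choice(["passenger", "neutral"])),
            mutagene_cohort=str(rng.choice(["passenger", "neutral"])),
            chasm_score=float(rng.uniform(0.01, 0.4)),
            recurrence=int(rng.integers(2, 5)),
        )

    for gene in genes:
        if gene in drivers:
            records.append(
                PredictionRecord(
                    gene=gene,
                    mutation_key=f"{gene}:d1",
                    mutagene_pancancer="driver",
                    mutagene_cohort=str(rng.choice(["driver", "potential driver"])),
                    chasm_score=float(rng.uniform(0.6, 0.99)),
                    recurrence=int(rng.integers(2, 6)),
                )
            )
            for k in range(int(rng.integers(0, 3))):
                records.append(passenger(gene, k))
        else:
            for k in range(int(rng.integers(1, 4))):
                records.append(passenger(gene, k))
    return records, drivers


def simulate_expression(
    genes: list[str], driver_genes, spec: SimulationSpec, seed=None
):
    """Genes x samples FPKM matrix, log-normal per gene, with the
    driver genes' across-sample variance inflated by
    ``expr_var_inflation`` (sigma scaled by its square root)."""
    import pandas as pd

    rng = _rng(spec.seed if seed is None else seed)
    driver_genes = set(driver_genes)
    base_sigma = 0.5
    rows = []
    for gene in genes:
        mu = rng.normal(3.0, 1.0)
        sigma = base_sigma * (
            np.sqrt(spec.expr_var_inflation) if gene in driver_genes else 1.0
        )
        rows.append(2.0 ** (mu + sigma * rng.standard_normal(spec.n_samples)))
    cols = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    return pd.DataFrame(rows, index=genes, columns=cols)


# ---------------------------------------------------------------------------
# one-call study


def simulate_all(spec: SimulationSpec, outdir: str | Path | None = None) -> dict:
    """Generate a full synthetic study; optionally write the standard
    files (ref.fa, muts.tsv, meth.tsv, preds.tsv, expr.tsv, truth.json).
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = [np.random.default_rng(c) for c in ss.spawn(5)]
    genome = simulate_genome(spec, seeds[0])
    mutations = simulate_mutations(genome, spec, seeds[1])
    methylation = simulate_methylation(genome, spec, seeds[2])
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    predictions, drivers = simulate_predictions(genes, spec, seeds[3])
    expression = simulate_expression(genes, drivers, spec, seeds[4])
    truth = {
        "seed": spec.seed,
        "motif_bias": spec.motif_bias,
        "coupling": spec.coupling,
        "planted_matrix": None
        if spec.planted_matrix is None
        else spec.planted_matrix.label,
        "driver_genes": sorted(drivers),
        "expr_var_inflation": spec.expr_var_inflation,
    }
    out = {
        "genome": genome,
        "mutations": mutations,
        "methylation": methylation,
        "predictions": predictions,
        "expression": expression,
        "driver_genes": drivers,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "ref.fa")
        write_mutations(mutations, outdir / "muts.tsv")
        write_methylation(methylation, outdir / "meth.tsv")
        write_predictions(predictions, outdir / "preds.tsv")
        write_expression(expression, outdir / "expr.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return out
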