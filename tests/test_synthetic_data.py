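import numpy as np
import pytest
from scipy import stats

from motiffoot import io_formats as io
from motiffoot import synthetic_data as sd
from motiffoot._seq import encode


def test_genome_gc_calibration():
    spec = sd.SimulationSpec(genome_length=100_000, gc_content=0.5, seed=1)
    seq = sd.simulate_genome(spec)["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.5) < 0.01


def test_cpg_enrichment_zero_removes_dyads():
    spec = sd.SimulationSpec(genome_length=20_000, cpg_enrichment=0.0, seed=2)
    seq = sd.simulate_genome(spec)["chr1"]
    assert "CG" not in seq


def test_cpg_enrichment_raises_dyad_frequency():
    base = sd.SimulationSpec(genome_length=50_000, seed=3)
    rich = sd.SimulationSpec(genome_length=50_000, cpg_enrichment=3.0, seed=3)
    n_base = sd.simulate_genome(base)["chr1"].count("CG")
    n_rich = sd.simulate_genome(rich)["chr1"].count("CG")
    assert n_rich > 1.5 * n_base


def test_generators_deterministic_under_seed(aid_wm):
    spec = sd.SimulationSpec(genome_length=20_000, planted_matrix=aid_wm,
                             motif_bias=1.0, n_mutations=50, seed=4)
    a, b = sd.simulate_all(spec), sd.simulate_all(spec)
    assert a["genome"] == b["genome"]
    assert a["mutations"] == b["mutations"]
    assert a["methylation"] == b["methylation"]
    assert a["predictions"] == b["predictions"]
    assert a["expression"].equals(b["expression"])


def test_unbiased_mutations_are_uniform_over_eligible_sites(aid_wm):
    spec = sd.SimulationSpec(genome_length=60_000, planted_matrix=aid_wm,
                             motif_bias=0.0, n_mutations=10_000, seed=5)
    genome = sd.simulate_genome(spec)
    muts = sd.simulate_mutations(genome, spec)
    codes = encode(genome["chr1"])
    eligible = np.flatnonzero((codes == 1) | (codes == 2))
    eligible = eligible[(eligible >= 60) & (eligible < codes.size - 60)]
    # bin positions; expected counts proportional to eligible sites per bin
    bins = np.linspace(60, codes.size - 60, 21)
    got = np.histogram([m.pos - 1 for m in muts], bins=bins)[0]
    exp = np.histogram(eligible, bins=bins)[0]
    exp = exp / exp.sum() * len(muts)
    p = stats.chisquare(got, exp).pvalue
    assert p > 0.01
    assert all(m.ref in "CG" for m in muts)


def test_biased_mutations_prefer_high_weight_sites(aid_wm):
    spec = sd.SimulationSpec(genome_length=60_000, planted_matrix=aid_wm,
                             motif_bias=2.0, n_mutations=500, seed=6)
    genome = sd.simulate_genome(spec)
    muts = sd.simulate_mutations(genome, spec)
    codes = encode(genome["chr1"])
    pct = sd._site_percents(codes, aid_wm)
    mutated_idx = np.array([m.pos - 1 for m in muts])
    mutated_mean = np.nanmean(pct[mutated_idx])
    others = np.ones(codes.size, dtype=bool)
    others[mutated_idx] = False
    other_mean = np.nanmean(pct[60:-60][others[60:-60]])
    assert mutated_mean > other_mean


def test_mutation_edge_cases(aid_wm):
    spec = sd.SimulationSpec(genome_length=5_000, planted_matrix=aid_wm,
                             n_mutations=0, seed=7)
    genome = sd.simulate_genome(spec)
    assert sd.simulate_mutations(genome, spec) == []
    too_many = sd.SimulationSpec(genome_length=1_000, planted_matrix=aid_wm,
                                 n_mutations=10_000, seed=7)
    with pytest.raises(ValueError, match="eligible"):
        sd.simulate_mutations(genome, too_many)


def test_methylation_high_mode_mean():
    # all-high mixture: Beta(20, 2) has mean 20/22 = 90.9%
    spec = sd.SimulationSpec(genome_length=250_000,
                             meth_mix=((2.0, 18.0), (20.0, 2.0), 1.0), seed=8)
    genome = sd.simulate_genome(spec)
    meth = sd.simulate_methylation(genome, spec)
    assert len(meth) > 10_000
    ratios = [100 * r.meth_reads / r.total_reads for r in meth]
    assert abs(np.mean(ratios) - 100 * 20 / 22) < 1.0


def test_methylation_records_sit_on_cpg_cytosines():
    spec = sd.SimulationSpec(genome_length=5_000, seed=9)
    genome = sd.simulate_genome(spec)
    seq = genome["chr1"]
    for r in sd.simulate_methylation(genome, spec)[:200]:
        if r.strand == "+":
            assert seq[r.pos - 1 : r.pos + 1] == "CG"
        else:
            assert seq[r.pos - 2 : r.pos] == "CG"


def test_prediction_tables_recover_planted_drivers():
    from motiffoot.gene_sets import build_gene_sets, label_mutations

    spec = sd.SimulationSpec(seed=10, n_driver_genes=20)
    genes = [f"G{i:03d}" for i in range(100)]
    preds, drivers = sd.simulate_predictions(genes, spec)
    sets = build_gene_sets(label_mutations(preds))
    assert sets.driver_genes == drivers
    assert sets.non_driver_genes == set(genes) - drivers


def test_expression_variance_inflation_detected():
    from motiffoot.gene_sets import expression_compare

    spec = sd.SimulationSpec(seed=11, expr_var_inflation=4.0)
    genes = [f"G{i:03d}" for i in range(200)]
    drivers = set(genes[:100])
    fpkm = sd.simulate_expression(genes, drivers, spec)
    res = expression_compare(fpkm, sorted(drivers), sorted(set(genes) - drivers))
    assert res.f_p < 0.05
    assert res.mean_variance["set1"] > res.mean_variance["set2"]


def test_written_files_validate_against_readers(tmp_path, aid_wm):
    spec = sd.SimulationSpec(genome_length=20_000, planted_matrix=aid_wm,
                             motif_bias=1.0, n_mutations=80, seed=12)
    out = sd.simulate_all(spec, tmp_path)
    genome = io.read_fasta(tmp_path / "ref.fa")
    assert genome == out["genome"]
    assert io.read_mutations(tmp_path / "muts.tsv") == out["mutations"]
    assert io.read_methylation(tmp_path / "meth.tsv") == out["methylation"]
    assert io.read_predictions(tmp_path / "preds.tsv") == out["predictions"]
    expr = io.read_expression(tmp_path / "expr.tsv")
    assert np.allclose(expr.to_numpy(), out["expression"].to_numpy())


def test_sample_profiles_share_latent_structure():
    spec = sd.SimulationSpec(genome_length=40_000, seed=13, n_samples=4)
    genome = sd.simulate_genome(spec)
    profiles = sd.simulate_sample_profiles(genome, spec)
    assert profiles.shape[1] == 4
    cc = profiles.corr()
    off_diag = cc.to_numpy()[~np.eye(4, dtype=bool)]
    assert (off_diag > 0.9).all()
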