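"""Generator contracts: design sizes, determinism, NB moments, planted effects."""

import json

import numpy as np
import pandas as pd
import pytest

from mitonuc.simulate import (
    SimulationConfig,
    extend_cohort,
    read_counts,
    read_metadata,
    read_truth,
    simulate_counts,
    simulate_genotypes,
    simulate_metadata,
    write_fixture_set,
)
from mitonuc.structure import genotype_pca
from mitonuc.variants import MISSING


def test_metadata_matches_design(default_config, default_metadata):
    meta = default_metadata
    assert len(meta) == 15
    assert meta["station"].value_counts().to_dict() == {"Base": 5, "Glacier": 5, "Faro": 5}
    assert meta["mitotype"].value_counts().to_dict() == {"h1h1": 2, "h2h2": 7, "h1h3": 3, "h2h3": 3}
    assert meta["nuclear_type"].value_counts().to_dict() == {"NucA": 10, "NucB": 5}


def test_metadata_single_group_and_determinism():
    cfg = SimulationConfig(group_design={"g": [("only", 1)]}, n_loci_mito=1, seed=3)
    meta = simulate_metadata(cfg)
    assert len(meta) == 1 and meta["g"].iloc[0] == "only"
    a = simulate_metadata(SimulationConfig(seed=9)).to_csv()
    b = simulate_metadata(SimulationConfig(seed=9)).to_csv()
    assert a == b


def test_inconsistent_design_totals_rejected():
    with pytest.raises(ValueError, match="sample total"):
        SimulationConfig(group_design={"a": [("x", 3)], "b": [("y", 4)]})


@pytest.mark.parametrize(
    "de_fraction,n_genes,expected", [(0.0, 500, 0), (0.05, 2000, 100)]
)
def test_planted_gene_counts(de_fraction, n_genes, expected):
    cfg = SimulationConfig(n_genes=n_genes, de_fraction=de_fraction, seed=5)
    meta = simulate_metadata(cfg)
    _, truth = simulate_counts(cfg, meta)
    for contrast, genes in truth.de_genes.items():
        assert len(genes) == expected, contrast


def test_planted_sets_disjoint_and_present(default_counts):
    counts, truth = default_counts
    all_sets = [set(v) for v in truth.de_genes.values()]
    union = set().union(*all_sets)
    assert sum(map(len, all_sets)) == len(union)  # disjoint
    assert union <= set(counts.index)


def test_nb_moment_oracle():
    """Null-gene counts satisfy var ~ mean + alpha mean^2 (moment oracle, 10k draws)."""
    alpha, mean = 0.2, 100.0
    rng = np.random.default_rng(0)
    r = 1 / alpha
    draws = rng.negative_binomial(r, r / (r + mean), size=10_000)
    v, m = draws.var(ddof=1), draws.mean()
    assert abs(m - mean) / mean < 0.05
    assert abs(v - (m + alpha * m**2)) / (m + alpha * m**2) < 0.10


def test_dispersion_slope_converges():
    """var-vs-(mean, mean^2) regression recovers alpha within 10% at n = 5000."""
    cfg = SimulationConfig(
        n_genes=300,
        de_fraction=0.0,
        dispersion=0.2,
        libsize_range=(1.0, 1.0),
        group_design={"g": [("a", 5000)]},
        seed=17,
    )
    meta = simulate_metadata(cfg)
    counts, _ = simulate_counts(cfg, meta)
    k = counts.to_numpy(float)
    m = k.mean(axis=1)
    v = k.var(axis=1, ddof=1)
    slope = np.linalg.lstsq(
        np.column_stack([m, m**2]), v, rcond=None
    )[0][1]
    assert abs(slope - 0.2) / 0.2 < 0.10


def test_planted_effect_recoverable():
    """Normalized count ratio between groups within 15% of 2^lfc at n = 50/group."""
    cfg = SimulationConfig(
        n_genes=400,
        de_fraction=0.1,
        effect_log2fc=1.5,
        libsize_range=(1.0, 1.0),
        group_design={"g": [("a", 50), ("b", 50)]},
        seed=23,
    )
    meta = simulate_metadata(cfg)
    counts, truth = simulate_counts(cfg, meta)
    affected = truth.contrast_groups["g"]
    other = [s for s in counts.columns if s not in affected]
    ratios = []
    for gene, lfc in truth.de_genes["g"].items():
        row = counts.loc[gene]
        ra = row[affected].mean() / max(row[other].mean(), 1e-9)
        ratios.append(ra if lfc > 0 else 1.0 / ra)
    assert abs(np.mean(ratios) - 2**1.5) / 2**1.5 < 0.15


def _weir_cockerham_theta(geno: np.ndarray, pops: np.ndarray) -> float:
    """Multi-population Weir-Cockerham theta, ratio-of-sums over loci (oracle)."""
    labels = np.unique(pops)
    r = len(labels)
    n_i = np.array([(pops == p).sum() for p in labels], dtype=float)
    n_bar = n_i.mean()
    nc = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    num_sum = 0.0
    den_sum = 0.0
    for locus in geno:
        p_i = np.array([locus[pops == p].mean() / 2 for p in labels])
        h_i = np.array([(locus[pops == p] == 1).mean() for p in labels])
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        num_sum += a
        den_sum += a + b + c
    return num_sum / den_sum


def test_balding_nichols_fst_recovered():
    """WC-style differentiation on 10,000 loci within +-0.01 of fst_nuclear=0.03."""
    cfg = SimulationConfig(
        n_loci_nuclear=10_000, n_loci_mito=1, fst_nuclear=0.03, missing_rate=0.0, seed=31
    )
    meta = simulate_metadata(cfg)
    cohort = extend_cohort(cfg, meta)
    v = simulate_genotypes(cfg, cohort)
    nuc = v.genotypes[v.compartment == "nuclear"]
    pops = cohort["station"].to_numpy()
    theta = _weir_cockerham_theta(nuc, pops)
    assert abs(theta - 0.03) <= 0.01


def test_fst_zero_shares_frequencies():
    """fst_nuclear = 0: one shared frequency vector, so WC differentiation ~ 0."""
    cfg = SimulationConfig(n_loci_nuclear=3000, n_loci_mito=1, fst_nuclear=0.0,
                           missing_rate=0.0, seed=37)
    meta = simulate_metadata(cfg)
    cohort = extend_cohort(cfg, meta)
    v = simulate_genotypes(cfg, cohort)
    nuc = v.genotypes[v.compartment == "nuclear"]
    theta = _weir_cockerham_theta(nuc, cohort["station"].to_numpy())
    assert abs(theta) < 0.01


def test_mito_split_dominates_pc1(default_config):
    """Genotype PCA on mitochondrial loci separates h1- from h2-carriers on PC1."""
    cfg = default_config
    meta = simulate_metadata(cfg)
    cohort = extend_cohort(cfg, meta)
    v = simulate_genotypes(cfg, cohort)
    mito = v.take_loci(v.compartment == "mitochondrial")
    pca = genotype_pca(mito)
    assert pca.explained_pct[0] >= 5 * pca.explained_pct[1]
    is_h1 = cohort["mitotype"].str.startswith("h1").to_numpy()
    pc1 = pca.scores[:, 0]
    assert (pc1[is_h1].max() < pc1[~is_h1].min()) or (pc1[~is_h1].max() < pc1[is_h1].min())


def test_missing_rate_zero_has_no_missing():
    cfg = SimulationConfig(n_loci_nuclear=200, n_loci_mito=20, missing_rate=0.0, seed=41)
    meta = simulate_metadata(cfg)
    v = simulate_genotypes(cfg, meta)
    assert not (v.genotypes == MISSING).any()


def test_fixture_roundtrip(tmp_path):
    cfg = SimulationConfig(n_genes=50, n_loci_nuclear=40, n_loci_mito=10, seed=7)
    manifest = write_fixture_set(cfg, tmp_path)
    assert manifest["seed"] == 7
    assert len(manifest["files"]) == 6
    counts = read_counts(tmp_path / "counts.tsv")
    meta = read_metadata(tmp_path / "metadata.tsv")
    truth = read_truth(tmp_path / "truth.json")
    ref_counts, _ = simulate_counts(cfg, simulate_metadata(cfg))
    pd.testing.assert_frame_equal(counts, ref_counts, check_dtype=False)
    assert len(meta) == 15 + cfg.n_extra_individuals
    assert set(truth.de_genes) == {"station", "mitotype", "nuclear_type"}


def test_fixture_seed_determinism(tmp_path):
    cfg = SimulationConfig(n_genes=30, n_loci_nuclear=30, n_loci_mito=8, seed=99)
    write_fixture_set(cfg, tmp_path / "a")
    write_fixture_set(cfg, tmp_path / "b")
    for name in ("counts.tsv", "metadata.tsv", "genotypes.vcf", "compartments.tsv", "truth.json", "manifest.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name
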