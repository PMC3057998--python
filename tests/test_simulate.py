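"""Synthetic-data generator: determinism, planted truth, planted effects."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from l1host import (
    SimulationConfig, classify_l1_locations, call_genes, down_probabilities,
    filter_sites, l1_proximity_histogram, simulate_ago2_sites,
    simulate_expression, simulate_genome, write_bundle,
)
from l1host.intervals import INTRAGENIC


BUNDLE_FILES = ["genes.bed", "l1.bed", "l1_features.tsv", "expr.tsv",
                "groups.csv", "probe_map.tsv", "sites.bed", "truth.json"]


def test_same_seed_gives_byte_identical_bundle(tmp_path):
    cfg = SimulationConfig(seed=42, n_genes=80, n_intergenic_l1=40, chrom_count=2)
    write_bundle(cfg, tmp_path / "a")
    write_bundle(cfg, tmp_path / "b")
    for name in BUNDLE_FILES:
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name


def test_different_seed_changes_output(tmp_path):
    write_bundle(SimulationConfig(seed=1, n_genes=50, n_intergenic_l1=20), tmp_path / "a")
    write_bundle(SimulationConfig(seed=2, n_genes=50, n_intergenic_l1=20), tmp_path / "b")
    assert not filecmp.cmp(tmp_path / "a" / "expr.tsv", tmp_path / "b" / "expr.tsv",
                           shallow=False)


def test_zero_l1_fraction_yields_no_intragenic():
    genome = simulate_genome(SimulationConfig(seed=5, n_genes=60, frac_l1_genes=0.0,
                                              n_intergenic_l1=30))
    l1s = classify_l1_locations(genome.l1s, genome.genes)
    assert all(x.location_class != INTRAGENIC for x in l1s)
    assert genome.l1_gene_set == set()


def test_classification_recovers_planted_locations(small_genome):
    cfg, genome, l1s = small_genome
    for l1 in l1s:
        assert l1.location_class == genome.truth.loc[l1.l1_id, "location_class"]
        if l1.location_class == INTRAGENIC:
            assert genome.truth.loc[l1.l1_id, "host_gene"] in l1.host_genes


def test_planted_l1_gene_count_matches_fraction():
    cfg = SimulationConfig(seed=9, n_genes=200, frac_l1_genes=0.25)
    genome = simulate_genome(cfg)
    assert len(genome.l1_gene_set) == 50


def test_feature_prevalences_differ_by_class(small_genome):
    cfg, genome, l1s = small_genome
    intra = [x for x in l1s if x.location_class == INTRAGENIC]
    inter = [x for x in l1s if x.location_class != INTRAGENIC]
    prev = lambda group: np.mean(
        [x.categorical_features["conserved_orf2"] == "present" for x in group])
    assert prev(intra) > prev(inter)


# --- planted odds ratio -----------------------------------------------------

def test_down_probabilities_satisfy_margin_and_or():
    for omega in (1.0, 2.0, 4.0):
        p1, p0 = down_probabilities(0.15, 0.2, omega)
        assert 0.2 * p1 + 0.8 * p0 == pytest.approx(0.15)
        odds = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds == pytest.approx(omega)


def test_infeasible_down_fraction_errors():
    with pytest.raises(ValueError, match="feasible"):
        down_probabilities(0.0, 0.2, 3.0)
    with pytest.raises(ValueError):
        down_probabilities(1.0, 0.2, 3.0)
    with pytest.raises(ValueError):
        down_probabilities(0.2, 0.2, -1.0)


def test_planted_truth_odds_ratio_unbiased():
    """The planted (L1 x down) truth table's OR averages to the target."""
    gene_ids = [f"g{i}" for i in range(2000)]
    l1_set = set(gene_ids[:400])
    log_ors = []
    for seed in range(40):
        cfg = SimulationConfig(seed=seed, planted_or_down=3.0)
        _, truth = simulate_expression(cfg, gene_ids, l1_set)
        a = int((truth["down"] & truth["l1_gene"]).sum())
        b = int((~truth["down"] & truth["l1_gene"]).sum())
        c = int((truth["down"] & ~truth["l1_gene"]).sum())
        d = int((~truth["down"] & ~truth["l1_gene"]).sum())
        log_ors.append(np.log(a * d / (b * c)))
    assert np.exp(np.mean(log_ors)) == pytest.approx(3.0, rel=0.1)


def test_null_effect_size_call_rate_matches_probe_rule(rng):
    """With no planted shift, the fraction of genes called follows the
    family-wise rate implied by the probe rule and alpha."""
    cfg = SimulationConfig(seed=77, n_genes=3000, de_effect_size=0.0,
                           frac_down=0.15, frac_up=0.0)
    gene_ids = [f"g{i}" for i in range(3000)]
    exp, _ = simulate_expression(cfg, gene_ids, set(gene_ids[:600]))
    alpha = 0.01
    calls = call_genes(exp, alpha=alpha)
    # expected per-gene null rate from the probe layout
    from collections import Counter
    route_counts = {}
    for probe, genes in exp.probe_map.items():
        for g in genes:
            uniq, hom = route_counts.get(g, (0, 0))
            if len(genes) == 1:
                uniq += 1
            else:
                hom += 1
            route_counts[g] = (uniq, hom)
    expected = 0.0
    for g, (uniq, hom) in route_counts.items():
        if uniq:
            expected += 1 - (1 - alpha) ** uniq
        else:
            # P(>=2 of hom significant)
            p = 0.0
            for k in range(2, hom + 1):
                from math import comb
                p += comb(hom, k) * alpha ** k * (1 - alpha) ** (hom - k)
            expected += p
    n_called = int(calls.frame["down"].sum())
    se = np.sqrt(expected)  # Poisson-scale tolerance
    assert abs(n_called - expected) < 4 * se + 2


# --- AGO2 sites -------------------------------------------------------------

def test_all_short_sites_filtered_out():
    cfg = SimulationConfig(seed=3, n_genes=60, n_intergenic_l1=20,
                           ago2_short_site_fraction=1.0,
                           short_site_length_range_bp=(18, 18))
    genome = simulate_genome(cfg)
    sites = simulate_ago2_sites(cfg, genome)
    assert len(sites) > 0
    assert filter_sites(sites) == []


def test_fold_excess_creates_central_peak():
    # sparse anchors (long intergenic gaps) so each +/-600 kb window holds
    # one L1's excess signal rather than its neighbours'
    wins = 0
    n_seeds = 25
    for seed in range(n_seeds):
        cfg = SimulationConfig(seed=seed, n_genes=60, n_intergenic_l1=10,
                               frac_l1_genes=0.1, chrom_count=1,
                               intergenic_gap_range_bp=(100_000, 300_000),
                               ago2_site_density_per_mb=20.0,
                               ago2_near_l1_fold=10.0)
        genome = simulate_genome(cfg)
        l1s = classify_l1_locations(genome.l1s, genome.genes)
        sites = filter_sites(simulate_ago2_sites(cfg, genome))
        central = peripheral = 0
        for orientation in ("sense", "antisense"):
            hist = l1_proximity_histogram(sites, l1s, genome.genes, orientation,
                                          anchor="midpoint")
            central += hist.counts[22:26].sum()      # +/-100 kb core
            peripheral += hist.counts[:4].sum() + hist.counts[-4:].sum()
        if central > peripheral:
            wins += 1
    assert wins >= 0.95 * n_seeds


def test_unit_fold_is_statistically_flat():
    cfg = SimulationConfig(seed=8, n_genes=150, n_intergenic_l1=30,
                           ago2_near_l1_fold=1.0, chrom_count=2,
                           ago2_site_density_per_mb=20.0)
    genome = simulate_genome(cfg)
    l1s = classify_l1_locations(genome.l1s, genome.genes)
    sites = filter_sites(simulate_ago2_sites(cfg, genome))
    hist = l1_proximity_histogram(sites, l1s, genome.genes, "sense", anchor="midpoint")
    counts = hist.counts
    # central 8 bins not enriched relative to the outer 8 beyond noise
    central = counts[20:28].sum()
    outer = counts[:4].sum() + counts[-4:].sum()
    total = central + outer
    if total > 0:
        from scipy import stats
        p = stats.binomtest(int(central), int(total), 0.5).pvalue
        assert p > 0.001
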