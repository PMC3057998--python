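"""Synthetic-data generation for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:

* a genome of non-overlapping gene spans on a few chromosomes, with a
  configurable fraction of genes carrying an intragenic L1 and a set of
  intergenic L1s placed between genes, each L1 carrying categorical and
  numeric features drawn at class-specific prevalences;
* a two-group expression experiment with Gaussian probe noise, planted
  mean-shift effects, and a down-regulated gene set sampled so that the
  (L1 membership x down-regulation) 2x2 table has a target odds ratio in
  expectation (closed-form cell probabilities given the margins and OR);
* AGO2 binding sites with a uniform background density plus a configurable
  fold-excess within a flank window around intragenic L1s, with a
  configurable fraction of sites short enough to fail the >18 bp filter.

All generators are deterministic under a fixed seed, and planted truth is
returned alongside every dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ago2 import BindingSite
from .expression import ExpressionExperiment
from .intervals import GeneModel, GenomicInterval, L1Element, write_bed6


def default_feature_spec():
    """Class-specific feature prevalences/means: intragenic L1s are more
    conserved (higher conserved-ORF and CpG-island prevalence, higher G-C
    and intactness), intergenic L1s carry more disruptions."""
    return {
        "conserved_orf2": {"kind": "categorical", "intragenic": 0.60, "intergenic": 0.35},
        "cpg_island": {"kind": "categorical", "intragenic": 0.45, "intergenic": 0.25},
        "gc_content": {"kind": "numeric", "intragenic_mean": 0.43, "intergenic_mean": 0.40, "sd": 0.03},
        "intactness_score": {"kind": "numeric", "intragenic_mean": 0.65, "intergenic_mean": 0.55, "sd": 0.12},
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_genes: int = 2000
    gene_length_range_bp: tuple = (5_000, 50_000)
    intergenic_gap_range_bp: tuple = (2_000, 20_000)
    chrom_count: int = 4
    frac_l1_genes: float = 0.2
    n_intergenic_l1: int = 500
    l1_length_range_bp: tuple = (500, 6_000)
    l1_feature_spec: dict = field(default_factory=default_feature_spec)
    # expression
    n_samples_per_group: int = 5
    probe_counts: tuple = (1, 2, 3)
    probe_count_probs: tuple = (0.6, 0.3, 0.1)
    frac_homolog_only_genes: float = 0.05   # genes represented only by homologous probes
    frac_extra_homolog: float = 0.10        # genes that also get one homologous probe
    baseline_expression_mean: float = 8.0
    baseline_expression_sd: float = 1.0
    noise_sd: float = 0.5
    de_effect_size: float = 2.0             # shift in units of noise_sd
    frac_down: float = 0.15
    frac_up: float = 0.05
    planted_or_down: float = 3.0
    # AGO2 sites
    ago2_site_density_per_mb: float = 5.0
    ago2_near_l1_fold: float = 10.0
    ago2_flank_window_bp: int = 50_000
    ago2_short_site_fraction: float = 0.2
    site_length_range_bp: tuple = (19, 40)
    short_site_length_range_bp: tuple = (10, 18)

    def __post_init__(self):
        for name in ("frac_l1_genes", "frac_down", "frac_up",
                     "frac_homolog_only_genes", "frac_extra_homolog",
                     "ago2_short_site_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.planted_or_down <= 0:
            raise ValueError("planted_or_down must be > 0")

    def rng(self):
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedGenome:
    genes: list
    l1s: list                  # location_class left unassigned (planted truth separate)
    truth: pd.DataFrame        # l1_id -> planted class + host genes
    l1_gene_set: set
    chrom_lengths: dict


def simulate_genome(config: SimulationConfig, rng=None) -> SimulatedGenome:
    """Place non-overlapping genes, intragenic L1s in a chosen gene subset,
    and intergenic L1s in the gaps."""
    rng = rng or config.rng()
    gmin, gmax = config.gene_length_range_bp
    gap_min, gap_max = config.intergenic_gap_range_bp
    l1_min, l1_max = config.l1_length_range_bp
    if gmin <= l1_min:
        raise ValueError("min gene length must exceed min L1 length")

    genes, gaps = [], []   # gaps: (chrom, start, end)
    per_chrom = [config.n_genes // config.chrom_count] * config.chrom_count
    for i in range(config.n_genes % config.chrom_count):
        per_chrom[i] += 1
    gi = 0
    chrom_lengths = {}
    for ci, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 0
        for _ in range(n_on_chrom):
            gap = int(rng.integers(gap_min, gap_max + 1))
            gaps.append((chrom, pos, pos + gap))
            start = pos + gap
            length = int(rng.integers(gmin, gmax + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(
                gene_id=f"G{gi:05d}", symbol=f"G{gi:05d}",
                span=GenomicInterval(chrom, start, start + length, strand),
                strand=strand,
            ))
            gi += 1
            pos = start + length
        tail = int(rng.integers(gap_min, gap_max + 1))
        gaps.append((chrom, pos, pos + tail))
        chrom_lengths[chrom] = pos + tail

    # intragenic L1s
    n_l1_genes = round(config.frac_l1_genes * config.n_genes)
    host_idx = rng.choice(len(genes), size=n_l1_genes, replace=False) if n_l1_genes else np.array([], int)
    l1s, truth_rows = [], []
    li = 0
    for idx in sorted(host_idx):
        g = genes[idx]
        max_len = min(l1_max, g.span.length - 2)
        length = int(rng.integers(l1_min, max_len + 1)) if max_len > l1_min else max_len
        start = g.span.start + int(rng.integers(1, g.span.length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        l1s.append(L1Element(
            l1_id=f"L1_{li:05d}",
            span=GenomicInterval(g.span.chrom, start, start + length, strand),
            strand=strand,
        ))
        truth_rows.append((f"L1_{li:05d}", "intragenic", g.gene_id))
        li += 1

    # intergenic L1s in gaps large enough to hold them
    usable = [(c, s, e) for c, s, e in gaps if e - s > l1_min + 2]
    if not usable and config.n_intergenic_l1 > 0:
        raise ValueError(
            f"genome too small: no intergenic gap exceeds {l1_min + 2} bp; "
            f"increase intergenic_gap_range_bp"
        )
    weights = np.array([e - s for _, s, e in usable], dtype=float)
    weights /= weights.sum()
    for _ in range(config.n_intergenic_l1):
        c, s, e = usable[int(rng.choice(len(usable), p=weights))]
        max_len = min(l1_max, e - s - 2)
        length = int(rng.integers(l1_min, max_len + 1)) if max_len > l1_min else max_len
        start = s + 1 + int(rng.integers(0, e - s - length - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        l1s.append(L1Element(
            l1_id=f"L1_{li:05d}",
            span=GenomicInterval(c, start, start + length, strand),
            strand=strand,
        ))
        truth_rows.append((f"L1_{li:05d}", "intergenic", ""))
        li += 1

    # per-class features
    truth = pd.DataFrame(truth_rows, columns=["l1_id", "location_class", "host_gene"]).set_index("l1_id")
    decorated = []
    for l1 in l1s:
        cls = truth.loc[l1.l1_id, "location_class"]
        cat, num = {}, {}
        for name, spec in config.l1_feature_spec.items():
            if spec["kind"] == "categorical":
                prev = spec[cls] if cls in spec else spec["intragenic" if cls == "intragenic" else "intergenic"]
                cat[name] = "present" if rng.random() < prev else "absent"
            else:
                mean = spec[f"{cls}_mean"]
                num[name] = float(rng.normal(mean, spec["sd"]))
        decorated.append(dataclasses.replace(l1, categorical_features=cat, numeric_features=num))

    l1_gene_set = {g for g in truth["host_gene"] if g}
    return SimulatedGenome(genes=genes, l1s=decorated, truth=truth,
                           l1_gene_set=l1_gene_set, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def down_probabilities(frac_down: float, frac_l1: float, odds_ratio: float):
    """Per-class down-regulation probabilities (p_l1, p_other) such that the
    L1 x down 2x2 has the target odds ratio with overall down fraction
    ``frac_down``.

    Solves f*p1 + (1-f)*p0 = frac_down with p1 = w*p0 / (1 - p0 + w*p0).
    """
    if not 0 < frac_down < 1:
        raise ValueError(
            f"planted odds ratio requires 0 < frac_down < 1 (got {frac_down}); "
            "feasible overall down fractions are the open unit interval"
        )
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if odds_ratio == 1 or frac_l1 in (0.0, 1.0):
        return frac_down, frac_down
    w = odds_ratio

    def gap(p0):
        p1 = w * p0 / (1 - p0 + w * p0)
        return frac_l1 * p1 + (1 - frac_l1) * p0 - frac_down

    p0 = brentq(gap, 1e-12, 1 - 1e-12)
    p1 = w * p0 / (1 - p0 + w * p0)
    return p1, p0


def simulate_expression(config: SimulationConfig, genes, l1_gene_set, rng=None):
    """Two-group expression experiment with planted shifts.

    ``genes`` may be GeneModel objects or bare gene ids.  Down-regulated
    genes are sampled per-gene with class probabilities from
    :func:`down_probabilities`; up-regulated genes are sampled independently
    of L1 membership among the remaining genes.  Returns
    ``(ExpressionExperiment, truth)`` where truth is a per-gene DataFrame of
    planted ``down``/``up`` flags.
    """
    rng = rng or config.rng()
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    n = len(gene_ids)
    is_l1 = np.array([g in l1_gene_set for g in gene_ids])
    frac_l1 = is_l1.mean()

    p1, p0 = down_probabilities(config.frac_down, frac_l1, config.planted_or_down)
    down = rng.random(n) < np.where(is_l1, p1, p0)
    up = (~down) & (rng.random(n) < config.frac_up / max(1e-12, 1 - config.frac_down))

    # probe layout
    probe_map = {}
    probe_gene_idx = []     # index of the gene whose signal the probe carries
    pi = 0
    for i, gid in enumerate(gene_ids):
        if n > 1 and rng.random() < config.frac_homolog_only_genes:
            for _ in range(2):   # homologous-only gene: two shared probes
                partner = int(rng.integers(0, n - 1))
                partner += partner >= i
                probe_map[f"P{pi:06d}"] = (gid, gene_ids[partner])
                probe_gene_idx.append(i)
                pi += 1
        else:
            k = int(rng.choice(config.probe_counts, p=config.probe_count_probs))
            for _ in range(k):
                probe_map[f"P{pi:06d}"] = (gid,)
                probe_gene_idx.append(i)
                pi += 1
            if n > 1 and rng.random() < config.frac_extra_homolog:
                partner = int(rng.integers(0, n - 1))
                partner += partner >= i
                probe_map[f"P{pi:06d}"] = (gid, gene_ids[partner])
                probe_gene_idx.append(i)
                pi += 1

    probe_gene_idx = np.asarray(probe_gene_idx)
    n_probes = len(probe_gene_idx)
    m = config.n_samples_per_group

    baseline = rng.normal(config.baseline_expression_mean, config.baseline_expression_sd, size=n)
    shift = np.zeros(n)
    shift[down] = -config.de_effect_size * config.noise_sd
    shift[up] = config.de_effect_size * config.noise_sd

    base = baseline[probe_gene_idx][:, None]
    noise = rng.normal(0.0, config.noise_sd, size=(n_probes, 2 * m))
    matrix = base + noise
    matrix[:, :m] += shift[probe_gene_idx][:, None]   # test group first

    samples = [f"T{j + 1}" for j in range(m)] + [f"C{j + 1}" for j in range(m)]
    frame = pd.DataFrame(matrix, index=list(probe_map), columns=samples)
    groups = pd.Series(["test"] * m + ["control"] * m, index=samples)

    experiment = ExpressionExperiment(
        experiment_id=f"sim_seed{config.seed}",
        matrix=frame, groups=groups, probe_map=probe_map,
        design="unpaired", ip_derived=False,
    )
    truth = pd.DataFrame({"down": down, "up": up, "l1_gene": is_l1},
                         index=pd.Index(gene_ids, name="gene_id"))
    return experiment, truth


# ---------------------------------------------------------------------------
# AGO2 sites
# ---------------------------------------------------------------------------

def simulate_ago2_sites(config: SimulationConfig, genome: SimulatedGenome, rng=None):
    """Background sites uniform over the genome plus excess sites in a flank
    window around each planted intragenic L1."""
    rng = rng or config.rng()
    sites = []
    si = 0

    def draw_length():
        if rng.random() < config.ago2_short_site_fraction:
            lo, hi = config.short_site_length_range_bp
        else:
            lo, hi = config.site_length_range_bp
        return int(rng.integers(lo, hi + 1))

    density_bp = config.ago2_site_density_per_mb / 1e6
    for chrom, clen in genome.chrom_lengths.items():
        n_bg = rng.poisson(density_bp * clen)
        for start in rng.integers(0, max(1, clen), size=n_bg):
            length = draw_length()
            sites.append(BindingSite(
                f"S{si:06d}", GenomicInterval(chrom, int(start), int(start) + length, ".")))
            si += 1

    excess_rate = density_bp * 2 * config.ago2_flank_window_bp * max(0.0, config.ago2_near_l1_fold - 1)
    intragenic = genome.truth.index[genome.truth["location_class"] == "intragenic"]
    by_id = {l1.l1_id: l1 for l1 in genome.l1s}
    for l1_id in intragenic:
        l1 = by_id[l1_id]
        mid = (l1.span.start + l1.span.end) // 2
        n_extra = rng.poisson(excess_rate)
        for off in rng.integers(-config.ago2_flank_window_bp, config.ago2_flank_window_bp,
                                size=n_extra):
            start = max(0, mid + int(off))
            length = draw_length()
            sites.append(BindingSite(
                f"S{si:06d}", GenomicInterval(l1.span.chrom, start, start + length, ".")))
            si += 1
    return sites


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------

def write_bundle(config: SimulationConfig, outdir):
    """Generate a full dataset and write it as the pipeline's input files:
    genes.bed, l1.bed, l1_features.tsv, expr.tsv, groups.csv, probe_map.tsv,
    sites.bed, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    genome = simulate_genome(config, rng)
    experiment, expr_truth = simulate_expression(config, genome.genes, genome.l1_gene_set, rng)
    sites = simulate_ago2_sites(config, genome, rng)

    write_bed6(genome.genes, outdir / "genes.bed")
    write_bed6(genome.l1s, outdir / "l1.bed")
    feats = pd.DataFrame(
        [{"l1_id": l1.l1_id, **l1.categorical_features, **l1.numeric_features}
         for l1 in genome.l1s]
    )
    feats.to_csv(outdir / "l1_features.tsv", sep="\t", index=False)

    mat = experiment.matrix.copy()
    mat.insert(0, "probe", mat.index)
    mat.to_csv(outdir / "expr.tsv", sep="\t", index=False, float_format="%.6f")
    pd.DataFrame({"sample": experiment.groups.index, "group": experiment.groups.values}).to_csv(
        outdir / "groups.csv", index=False)
    with open(outdir / "probe_map.tsv", "w") as fh:
        fh.write("probe\tgenes\n")
        for probe, gg in experiment.probe_map.items():
            fh.write(probe + "\t" + "\t".join(gg) + "\n")
    write_bed6(sites, outdir / "sites.bed")

    truth = {
        "l1_gene_set": sorted(genome.l1_gene_set),
        "l1_locations": {i: r.location_class for i, r in genome.truth.iterrows()},
        "down_genes": sorted(expr_truth.index[expr_truth["down"]]),
        "up_genes": sorted(expr_truth.index[expr_truth["up"]]),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return genome, experiment, expr_truth, sites
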