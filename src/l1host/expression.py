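"""Gene-level regulation calls from two-group expression arrays.

Every probe is tested with two one-sided Student's t-tests (pooled variance;
paired variant when the design is paired): test > control for up-regulation
and test < control for down-regulation.  Probe-level p-values are then
aggregated to genes:

* a gene with at least one *unique* probe (a probe mapping to exactly one
  gene) is called regulated when any unique probe is significant;
* a gene represented only by *homologous* probes (probes mapping to more
  than one gene) needs at least two significant homologous probes, in the
  same direction;
* the significance threshold is 0.01, relaxed to 0.05 when either group has
  only two samples or the mRNA was prepared by immunoprecipitation.

A gene is never simultaneously up and down: if both directions qualify the
direction with the smaller best p-value wins and the gene is flagged as a
conflict.  Genes with no mapped (testable) probes are excluded from the call
set rather than treated as not-regulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("l1host")


@dataclass
class ExpressionExperiment:
    """A probe x sample expression matrix with group labels and a probe map.

    ``probe_map`` maps each probe id to the tuple of gene ids it represents;
    a probe is *unique* when it maps to exactly one gene.
    """

    experiment_id: str
    matrix: pd.DataFrame          # probes x samples
    groups: pd.Series             # sample id -> {"test", "control"}
    probe_map: dict
    design: str = "unpaired"      # unpaired | paired
    ip_derived: bool = False

    def __post_init__(self):
        if self.design not in {"unpaired", "paired"}:
            raise ValueError(f"design must be unpaired or paired, got {self.design!r}")
        missing = set(self.matrix.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        bad = set(self.groups.unique()) - {"test", "control"}
        if bad:
            raise ValueError(f"group labels must be test/control, got {sorted(bad)}")
        if self.n_test < 2 or self.n_control < 2:
            raise ValueError("need >= 2 samples per group")
        if self.design == "paired" and self.n_test != self.n_control:
            raise ValueError("paired design requires equal group sizes")

    @property
    def test_samples(self):
        return [s for s in self.matrix.columns if self.groups[s] == "test"]

    @property
    def control_samples(self):
        return [s for s in self.matrix.columns if self.groups[s] == "control"]

    @property
    def n_test(self):
        return len(self.test_samples)

    @property
    def n_control(self):
        return len(self.control_samples)


def select_alpha(n_test: int, n_control: int, ip_derived: bool = False) -> float:
    """Significance threshold for probe tests: 0.05 when either group has
    exactly two samples or the mRNA is immunoprecipitation-derived, else 0.01."""
    if n_test < 2 or n_control < 2:
        raise ValueError("t-test undefined with fewer than 2 samples per group")
    if min(n_test, n_control) == 2 or ip_derived:
        return 0.05
    return 0.01


def probe_tests(experiment: ExpressionExperiment, mode: str = "one_sided") -> pd.DataFrame:
    """Per-probe p-values for up- (test > control) and down-regulation.

    Returns a DataFrame indexed like the matrix with columns ``p_up`` and
    ``p_down``; probes with fewer than two usable samples in a group get NaN.

    ``mode="one_sided"`` (default) runs two one-sided tests; ``"two_sided"``
    assigns the two-sided p to the direction of the observed difference and
    1.0 to the other.
    """
    if mode not in {"one_sided", "two_sided"}:
        raise ValueError(f"bad mode {mode!r}")
    T = experiment.matrix[experiment.test_samples].to_numpy(dtype=float)
    C = experiment.matrix[experiment.control_samples].to_numpy(dtype=float)

    if experiment.design == "paired":
        t, diff, df, valid = _paired_t(T, C)
    else:
        t, diff, df, valid = _pooled_t(T, C)

    p_up = np.full(len(t), np.nan)
    p_down = np.full(len(t), np.nan)

    finite = valid & np.isfinite(t)
    p_up[finite] = stats.t.sf(t[finite], df[finite])
    p_down[finite] = stats.t.cdf(t[finite], df[finite])

    # zero-variance probes: equal means -> uninformative; unequal -> one-sided certainty
    degen = valid & ~np.isfinite(t)
    eq = degen & (diff == 0)
    p_up[eq] = p_down[eq] = 1.0
    up_sure = degen & (diff > 0)
    p_up[up_sure], p_down[up_sure] = 0.0, 1.0
    down_sure = degen & (diff < 0)
    p_up[down_sure], p_down[down_sure] = 1.0, 0.0

    if mode == "two_sided":
        p2 = np.minimum(1.0, 2 * np.minimum(p_up, p_down))
        new_up = np.where(diff > 0, p2, 1.0)
        new_down = np.where(diff < 0, p2, 1.0)
        both_one = np.isclose(diff, 0)
        new_up[both_one] = 1.0
        new_down[both_one] = 1.0
        keep = ~np.isnan(p_up)
        p_up = np.where(keep, new_up, np.nan)
        p_down = np.where(keep, new_down, np.nan)

    return pd.DataFrame({"p_up": p_up, "p_down": p_down}, index=experiment.matrix.index)


def _pooled_t(T, C):
    """Vectorized two-sample pooled-variance t over matrix rows (NaN-aware)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        nt = np.sum(~np.isnan(T), axis=1).astype(float)
        nc = np.sum(~np.isnan(C), axis=1).astype(float)
        valid = (nt >= 2) & (nc >= 2)
        mt = np.where(nt > 0, np.nansum(T, axis=1) / np.maximum(nt, 1), np.nan)
        mc = np.where(nc > 0, np.nansum(C, axis=1) / np.maximum(nc, 1), np.nan)
        sst = np.nansum((T - mt[:, None]) ** 2, axis=1)
        ssc = np.nansum((C - mc[:, None]) ** 2, axis=1)
        df = nt + nc - 2
        sp2 = np.where(df > 0, (sst + ssc) / np.maximum(df, 1), np.nan)
        diff = mt - mc
        se = np.sqrt(sp2 * (1 / np.maximum(nt, 1) + 1 / np.maximum(nc, 1)))
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.sign(diff) * np.inf)
        t = np.where(np.isclose(diff, 0) & (se == 0), np.inf * 0, t)  # NaN -> handled as equal-mean
    return t, diff, df, valid


def _paired_t(T, C):
    """Vectorized paired t over matrix rows; samples paired by column order."""
    with np.errstate(invalid="ignore", divide="ignore"):
        D = T - C
        n = np.sum(~np.isnan(D), axis=1).astype(float)
        valid = n >= 2
        m = np.nansum(D, axis=1) / np.maximum(n, 1)
        ss = np.nansum((D - m[:, None]) ** 2, axis=1)
        df = n - 1
        sd = np.sqrt(np.where(df > 0, ss / np.maximum(df, 1), np.nan))
        se = sd / np.sqrt(np.maximum(n, 1))
        t = np.where(se > 0, m / np.where(se > 0, se, 1.0), np.sign(m) * np.inf)
        t = np.where(np.isclose(m, 0) & (se == 0), np.inf * 0, t)
    return t, m, df, valid


@dataclass
class GeneCallSet:
    """Per-gene up/down regulation calls for one experiment.

    ``frame`` is indexed by gene id with boolean ``up``/``down`` columns,
    best probe p-values, significant-probe counts, and a conflict flag.
    """

    experiment_id: str
    frame: pd.DataFrame
    alpha: float

    def genes(self):
        return set(self.frame.index)

    def regulated(self, direction: str) -> set:
        """Gene set for a direction in {up, down, not_up, not_down}."""
        if direction == "up":
            return set(self.frame.index[self.frame["up"]])
        if direction == "down":
            return set(self.frame.index[self.frame["down"]])
        if direction == "not_up":
            return set(self.frame.index[~self.frame["up"]])
        if direction == "not_down":
            return set(self.frame.index[~self.frame["down"]])
        raise ValueError(f"bad direction {direction!r}")

    def to_tsv(self, path):
        out = self.frame.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, experiment_id=None, alpha=float("nan")):
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
        df["up"] = df["up"].astype(bool)
        df["down"] = df["down"].astype(bool)
        return cls(experiment_id or str(path), df, alpha)


def call_genes(experiment: ExpressionExperiment, alpha: float = None,
               probe_p: pd.DataFrame = None, mode: str = "one_sided") -> GeneCallSet:
    """Aggregate probe tests into per-gene up/down calls.

    ``alpha`` defaults to :func:`select_alpha` for the experiment's design;
    ``probe_p`` (from :func:`probe_tests`) is computed if not supplied.
    """
    if alpha is None:
        alpha = select_alpha(experiment.n_test, experiment.n_control, experiment.ip_derived)
    if probe_p is None:
        probe_p = probe_tests(experiment, mode=mode)

    rows = []
    for probe, genes in experiment.probe_map.items():
        if probe not in probe_p.index:
            continue
        for g in genes:
            rows.append((probe, g, len(genes) == 1))
    if not rows:
        raise ValueError("probe map shares no probes with the matrix")
    long = pd.DataFrame(rows, columns=["probe", "gene", "is_unique"])
    long = long.join(probe_p, on="probe")
    long = long.dropna(subset=["p_up", "p_down"])  # untestable probes contribute nothing

    long["sig_up"] = long["p_up"] < alpha
    long["sig_down"] = long["p_down"] < alpha

    def agg(sub):
        return sub.groupby("gene").agg(
            n_up=("sig_up", "sum"), n_down=("sig_down", "sum"),
            bp_up=("p_up", "min"), bp_down=("p_down", "min"),
        )

    uq = agg(long[long["is_unique"]])
    hm = agg(long[~long["is_unique"]])

    genes = sorted(set(uq.index) | set(hm.index))
    idx = pd.Index(genes, name="gene_id")
    has_unique = idx.isin(uq.index)

    n_up = np.where(has_unique, uq.reindex(idx)["n_up"], hm.reindex(idx)["n_up"]).astype(int)
    n_down = np.where(has_unique, uq.reindex(idx)["n_down"], hm.reindex(idx)["n_down"]).astype(int)
    bp_up = np.where(has_unique, uq.reindex(idx)["bp_up"], hm.reindex(idx)["bp_up"])
    bp_down = np.where(has_unique, uq.reindex(idx)["bp_down"], hm.reindex(idx)["bp_down"])

    need = np.where(has_unique, 1, 2)
    qual_up = n_up >= need
    qual_down = n_down >= need

    conflict = qual_up & qual_down
    # resolve conflicts to the direction with the smaller best p (down on a tie)
    up = qual_up & (~conflict | (bp_up < bp_down))
    down = qual_down & (~conflict | (bp_down <= bp_up))
    up = up & ~(up & down)

    n_conf = int(conflict.sum())
    if n_conf:
        logger.warning("%s: %d gene(s) qualified in both directions; resolved by best p",
                       experiment.experiment_id, n_conf)

    frame = pd.DataFrame(
        {
            "up": up, "down": down,
            "best_p_up": bp_up, "best_p_down": bp_down,
            "n_sig_up": n_up, "n_sig_down": n_down,
            "conflict": conflict,
        },
        index=idx,
    )
    return GeneCallSet(experiment.experiment_id, frame, alpha)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_experiment(matrix_path, groups_path, probe_map_path, experiment_id=None,
                    design="unpaired", ip_derived=False) -> ExpressionExperiment:
    """Read an experiment from an expression TSV (first column = probe id),
    a groups CSV (sample, group), and a probe-map TSV (probe, gene ids)."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    groups_df = pd.read_csv(groups_path, dtype=str)
    groups = pd.Series(groups_df["group"].values, index=groups_df["sample"].values)
    probe_map = {}
    with open(probe_map_path) as fh:
        header = fh.readline()
        for line in fh:
            parts = [p for p in line.rstrip("\n").split("\t") if p]
            if parts:
                probe_map[parts[0]] = tuple(parts[1:])
    return ExpressionExperiment(
        experiment_id=experiment_id or str(matrix_path),
        matrix=matrix, groups=groups, probe_map=probe_map,
        design=design, ip_derived=ip_derived,
    )
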