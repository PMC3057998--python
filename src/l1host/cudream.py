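"""Cross-experiment regulation concordance (CU-DREAM) and the multi-experiment
commonality score.

CU-DREAM (Connection Up- or Down-Regulation Expression Analysis of
Microarrays) asks whether two expression experiments perturb a shared
regulatory program: every gene present in both experiments is placed in a
2x2 table (regulated in both / in one only / in neither) and the table is
tested by chi-square with an odds ratio.  Directions can be mixed: an
experiment's "regulated" class may be ``up``, ``down``, ``not_up`` or
``not_down``, which supports comparisons such as genes up-regulated under
AGO2 knockdown versus genes down- or not-up-regulated in a carcinoma.

The commonality score counts, per gene, the number of independent
experiments in which it is down-regulated, and compares the mean count
between a gene set (genes containing L1s) and its complement by a
homoscedastic t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import AssociationResult, ContingencyTable2x2, chisq_or
from .features import numeric_feature_test

DIRECTIONS = {"up", "down", "not_up", "not_down"}


class EmptyUniverseError(ValueError):
    """Raised when two call sets (or a stratum) share no genes."""


@dataclass(frozen=True)
class CrossExperimentResult:
    experiment_a: str
    experiment_b: str
    direction_a: str
    direction_b: str
    table: ContingencyTable2x2
    association: AssociationResult
    n_shared_genes: int
    low_n: bool = False

    def to_dict(self):
        d = self.association.to_dict()
        d.update(
            experiment_a=self.experiment_a, experiment_b=self.experiment_b,
            direction_a=self.direction_a, direction_b=self.direction_b,
            n_shared_genes=self.n_shared_genes, low_n=self.low_n,
        )
        return d


@dataclass(frozen=True)
class CommonalityScore:
    counts: pd.Series          # gene -> number of experiments down-regulated
    mean_in_set: float
    mean_out_set: float
    t_statistic: float
    p_value: float
    n_in_set: int
    n_out_set: int


def intersect_experiments(calls_a, calls_b, direction_a="down", direction_b="down",
                          universe=None) -> CrossExperimentResult:
    """Cross-tabulate regulation calls of two experiments over their shared
    gene universe.

    Table layout matches the four-group classification: rows are experiment
    B's status, columns experiment A's, so cell a = regulated in both,
    b = regulated in B only, c = regulated in A only, d = neither.
    """
    for dname, dval in (("direction_a", direction_a), ("direction_b", direction_b)):
        if dval not in DIRECTIONS:
            raise ValueError(f"{dname} must be one of {sorted(DIRECTIONS)}, got {dval!r}")
    shared = calls_a.genes() & calls_b.genes()
    if universe is not None:
        shared &= set(universe)
    if not shared:
        raise EmptyUniverseError(
            f"no shared genes between {calls_a.experiment_id} and {calls_b.experiment_id}"
        )
    reg_a = calls_a.regulated(direction_a) & shared
    reg_b = calls_b.regulated(direction_b) & shared
    a = len(reg_a & reg_b)
    b = len(reg_b - reg_a)
    c = len(reg_a - reg_b)
    d = len(shared) - a - b - c
    table = ContingencyTable2x2(
        a, b, c, d,
        row_labels=(f"B_{direction_b}", f"B_not"),
        col_labels=(f"A_{direction_a}", f"A_not"),
    )
    return CrossExperimentResult(
        experiment_a=calls_a.experiment_id, experiment_b=calls_b.experiment_id,
        direction_a=direction_a, direction_b=direction_b,
        table=table, association=chisq_or(table), n_shared_genes=len(shared),
        low_n=len(shared) < 10,
    )


def stratified_intersect(calls_a, calls_b, gene_set, direction_a="down",
                         direction_b="down"):
    """Run the cross-experiment analysis separately inside and outside a gene
    set.  Returns ``(within, outside)``; an empty stratum raises
    :class:`EmptyUniverseError`."""
    gene_set = set(gene_set)
    shared = calls_a.genes() & calls_b.genes()
    within = intersect_experiments(
        calls_a, calls_b, direction_a, direction_b, universe=shared & gene_set
    )
    outside = intersect_experiments(
        calls_a, calls_b, direction_a, direction_b, universe=shared - gene_set
    )
    return within, outside


def commonality_score(call_sets, gene_set, direction="down",
                      universe_mode="all") -> CommonalityScore:
    """Per-gene count of experiments where the gene is regulated in
    ``direction``, compared between a gene set and its complement.

    ``universe_mode="all"`` restricts to genes present in every call set
    (default); ``"any"`` uses the union, counting only experiments in which
    the gene is present.
    """
    if len(call_sets) < 2:
        raise ValueError("need >= 2 call sets")
    if universe_mode not in {"all", "any"}:
        raise ValueError(f"bad universe_mode {universe_mode!r}")
    gene_lists = [cs.genes() for cs in call_sets]
    universe = set.intersection(*gene_lists) if universe_mode == "all" else set.union(*gene_lists)
    if not universe:
        raise EmptyUniverseError("no genes in the commonality universe")

    counts = pd.Series(0, index=sorted(universe), dtype=int)
    for cs in call_sets:
        reg = cs.regulated(direction) & universe
        counts.loc[sorted(reg)] += 1

    in_set = counts.index.isin(set(gene_set))
    x = counts[in_set].to_numpy(float)
    y = counts[~in_set].to_numpy(float)
    if len(x) >= 2 and len(y) >= 2:
        res = numeric_feature_test("commonality", x, y)
        t_stat, p = res.statistic, res.p_value
    else:  # a stratum too small for a t-test: report the means only
        t_stat = p = float("nan")
    return CommonalityScore(
        counts=counts,
        mean_in_set=float(np.mean(x)) if len(x) else float("nan"),
        mean_out_set=float(np.mean(y)) if len(y) else float("nan"),
        t_statistic=t_stat, p_value=p,
        n_in_set=len(x), n_out_set=len(y),
    )
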