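"""2x2 contingency statistics: Pearson chi-square, odds ratio, Woolf 95% CI.

This is the statistics layer behind every association reported by the
pipeline: regulated-gene x L1-membership tables, cross-experiment
concordance tables, and AGO2 binding-site association tables.

Conventions
-----------
* Pearson chi-square with df=1 and no continuity correction by default
  (Yates correction available as a flag); computed on the raw counts.
* Odds ratio (a*d)/(b*c).  When any cell is zero, the Haldane-Anscombe
  correction (add 0.5 to every cell) is applied to the OR and its CI only
  and the result is flagged; the chi-square stays on raw counts.
* 95% CI by the Woolf (log) method:
  exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
* A zero row or column margin makes the table degenerate: p=1, OR undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Labeled 2x2 table of non-negative integer counts.

    Layout::

                      col1          col2
        row1           a             b
        row2           c             d
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("row1", "row2")
    col_labels: tuple = ("col1", "col2")

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self):
        return (self.a, self.b, self.c, self.d)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a, self.c, self.b, self.d,
            row_labels=self.col_labels, col_labels=self.row_labels,
        )

    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0 or self.c + self.d == 0
            or self.a + self.c == 0 or self.b + self.d == 0
        )


@dataclass(frozen=True)
class AssociationResult:
    chi_square: float
    p_value: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    zero_cell_corrected: bool = False
    degenerate: bool = False
    table: ContingencyTable2x2 = None

    def to_dict(self):
        d = {
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "zero_cell_corrected": self.zero_cell_corrected,
            "degenerate": self.degenerate,
        }
        if self.table is not None:
            d["table"] = {
                "a": self.table.a, "b": self.table.b,
                "c": self.table.c, "d": self.table.d,
                "rows": list(self.table.row_labels),
                "cols": list(self.table.col_labels),
            }
        return d


def pearson_chi2(a, b, c, d):
    """Pearson chi-square statistic (df=1, no correction) on raw counts."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 0.0
    # algebraically equal to sum (O-E)^2/E for the 2x2 case
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def chisq_or(table: ContingencyTable2x2, yates: bool = False) -> AssociationResult:
    """Chi-square test of independence plus odds ratio with Woolf 95% CI."""
    a, b, c, d = table.cells

    if table.has_zero_margin():
        return AssociationResult(
            chi_square=0.0, p_value=1.0,
            odds_ratio=math.nan, ci95_low=math.nan, ci95_high=math.nan,
            zero_cell_corrected=False, degenerate=True, table=table,
        )

    if yates:
        chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=True)[:4]
    else:
        chi2 = pearson_chi2(a, b, c, d)
        p = float(stats.chi2.sf(chi2, df=1))

    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    oratio = (aa * dd) / (bb * cc)
    se_log = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = math.exp(math.log(oratio) - Z_95 * se_log)
    hi = math.exp(math.log(oratio) + Z_95 * se_log)

    return AssociationResult(
        chi_square=float(chi2), p_value=float(p),
        odds_ratio=float(oratio), ci95_low=float(lo), ci95_high=float(hi),
        zero_cell_corrected=corrected, degenerate=False, table=table,
    )


def build_membership_table(calls, gene_set, direction) -> ContingencyTable2x2:
    """Cross-tabulate regulation calls against membership in a gene set.

    Rows: in set / not in set.  Columns: regulated (in ``direction``) /
    not regulated.  The universe is the genes carrying calls; gene-set
    members absent from the call set are ignored.

    ``calls`` is a :class:`l1host.expression.GeneCallSet`; ``direction`` is
    ``"up"`` or ``"down"``.
    """
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    universe = set(calls.genes())
    if not universe:
        raise ValueError("empty call set")
    members = set(gene_set) & universe
    if not members:
        raise ValueError("gene set does not intersect the call-set universe")
    regulated = calls.regulated(direction) & universe
    a = len(members & regulated)
    b = len(members - regulated)
    c = len(regulated - members)
    d = len(universe - members - regulated)
    return ContingencyTable2x2(
        a, b, c, d,
        row_labels=("in_set", "not_in_set"),
        col_labels=(direction, f"not_{direction}"),
    )
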