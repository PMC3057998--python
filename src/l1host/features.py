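"""Structural-feature screen: intragenic vs intergenic L1 comparisons.

Categorical features (conserved-sequence presence, CpG islands, subfamily)
are compared with a Pearson chi-square on a 2x2 of present/absent counts;
numeric features (G-C fraction, A/T counts, frameshifts, gaps, stop codons,
intactness score) with a two-sided homoscedastic (pooled-variance) t-test.

Categorical counting runs in two modes, mirroring how intragenic L1 features
can be tallied either per L1 copy or per host gene: in ``per_gene`` mode the
intragenic side counts each host gene once (present if any of its L1s carries
the feature) while the intergenic side, having no host genes, stays per-L1.
Multi-category features are decomposed into one-vs-rest 2x2 tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import pearson_chi2
from .intervals import INTRAGENIC, INTERGENIC

logger = logging.getLogger("l1host")

PRESENT_VALUES = {"present", "yes", "true", "1"}
ABSENT_VALUES = {"absent", "no", "false", "0"}


@dataclass(frozen=True)
class FeatureRegistry:
    """Declares which L1 feature names are categorical vs numeric."""

    categorical: tuple
    numeric: tuple

    def __post_init__(self):
        if set(self.categorical) & set(self.numeric):
            raise ValueError("a feature cannot be both categorical and numeric")


@dataclass(frozen=True)
class FeatureTestResult:
    feature_name: str
    test_kind: str  # chi_square | t_test_homoscedastic
    counting_mode: str  # per_l1 | per_gene | not_applicable
    statistic: float
    p_value: float
    direction: str  # intragenic_higher | intergenic_higher | none
    degenerate: bool = False


def categorical_feature_test(feature, intragenic_counts, intergenic_counts,
                             counting_mode="per_l1") -> FeatureTestResult:
    """Pearson chi-square (df=1, uncorrected) on present/absent counts."""
    (a_p, a_a), (b_p, b_a) = intragenic_counts, intergenic_counts
    for v in (a_p, a_a, b_p, b_a):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a_p + a_a == 0 or b_p + b_a == 0:
        raise ValueError("each group total must be > 0")

    degenerate = (a_p + b_p == 0) or (a_a + b_a == 0)
    if degenerate:
        return FeatureTestResult(feature, "chi_square", counting_mode,
                                 0.0, 1.0, "none", degenerate=True)
    chi2 = pearson_chi2(a_p, a_a, b_p, b_a)
    p = float(stats.chi2.sf(chi2, df=1))
    frac_intra = a_p / (a_p + a_a)
    frac_inter = b_p / (b_p + b_a)
    if chi2 == 0.0 or frac_intra == frac_inter:
        direction = "none"
    else:
        direction = "intragenic_higher" if frac_intra > frac_inter else "intergenic_higher"
    return FeatureTestResult(feature, "chi_square", counting_mode, float(chi2), p, direction)


def numeric_feature_test(feature, intragenic_values, intergenic_values) -> FeatureTestResult:
    """Two-sided pooled-variance two-sample t-test on feature values."""
    x = np.asarray(intragenic_values, dtype=float)
    y = np.asarray(intergenic_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    mx, my = x.mean(), y.mean()
    nx, ny = len(x), len(y)
    sp2 = (((x - mx) ** 2).sum() + ((y - my) ** 2).sum()) / (nx + ny - 2)
    if sp2 == 0.0:
        if mx == my:
            return FeatureTestResult(feature, "t_test_homoscedastic", "not_applicable",
                                     0.0, 1.0, "none")
        return FeatureTestResult(feature, "t_test_homoscedastic", "not_applicable",
                                 math.inf if mx > my else -math.inf, 0.0,
                                 "intragenic_higher" if mx > my else "intergenic_higher",
                                 degenerate=True)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * float(stats.t.sf(abs(t), df=nx + ny - 2))
    if mx == my:
        direction = "none"
    else:
        direction = "intragenic_higher" if mx > my else "intergenic_higher"
    return FeatureTestResult(feature, "t_test_homoscedastic", "not_applicable",
                             float(t), p, direction)


def _present(value: str, category=None) -> bool:
    if category is not None:
        return value == category
    return str(value).strip().lower() in PRESENT_VALUES


def _binary_feature(values) -> bool:
    """True when a categorical feature uses a recognizable present/absent coding."""
    lowered = {str(v).strip().lower() for v in values}
    return lowered <= (PRESENT_VALUES | ABSENT_VALUES)


def run_feature_screen(l1s, registry: FeatureRegistry, min_coverage: float = 0.5,
                       bonferroni: bool = False):
    """Run the full intragenic-vs-intergenic feature screen.

    One chi-square result per (categorical feature [x category] x counting
    mode) plus one t-test per numeric feature.  Features observed on fewer
    than ``min_coverage`` of L1s are excluded with a warning.
    """
    intra = [l1 for l1 in l1s if l1.location_class == INTRAGENIC]
    inter = [l1 for l1 in l1s if l1.location_class == INTERGENIC]
    if not intra or not inter:
        raise ValueError("feature screen needs both intragenic and intergenic L1s")
    n_total = len(intra) + len(inter)

    results = []
    for feat in registry.categorical:
        observed = [l1 for l1 in intra + inter if feat in l1.categorical_features]
        if len(observed) < min_coverage * n_total:
            logger.warning("feature %s observed on %d/%d L1s; excluded",
                           feat, len(observed), n_total)
            continue
        values = {l1.categorical_features[feat] for l1 in observed}
        categories = [None] if _binary_feature(values) else sorted(values)
        for cat in categories:
            name = feat if cat is None else f"{feat}={cat}"
            for mode in ("per_l1", "per_gene"):
                intra_counts = _categorical_counts(intra, feat, cat, mode)
                inter_counts = _categorical_counts(inter, feat, cat, "per_l1")
                results.append(categorical_feature_test(name, intra_counts, inter_counts, mode))

    for feat in registry.numeric:
        xs = [l1.numeric_features[feat] for l1 in intra if feat in l1.numeric_features]
        ys = [l1.numeric_features[feat] for l1 in inter if feat in l1.numeric_features]
        if len(xs) + len(ys) < min_coverage * n_total:
            logger.warning("feature %s observed on %d/%d L1s; excluded",
                           feat, len(xs) + len(ys), n_total)
            continue
        results.append(numeric_feature_test(feat, xs, ys))
    if bonferroni:
        m = len(results)
        results = [
            (r, min(1.0, r.p_value * m)) for r in results
        ]
    return results


def _categorical_counts(group, feat, category, mode):
    """(present, absent) counts for one L1 group under a counting mode."""
    if mode == "per_l1":
        present = sum(
            1 for l1 in group
            if feat in l1.categorical_features and _present(l1.categorical_features[feat], category)
        )
        total = sum(1 for l1 in group if feat in l1.categorical_features)
        return (present, total - present)
    if mode == "per_gene":
        gene_has: dict[str, bool] = {}
        for l1 in group:
            if feat not in l1.categorical_features:
                continue
            flag = _present(l1.categorical_features[feat], category)
            for g in l1.host_genes:
                gene_has[g] = gene_has.get(g, False) or flag
        present = sum(gene_has.values())
        return (present, len(gene_has) - present)
    raise ValueError(f"bad counting mode {mode!r}")


def screen_to_frame(results) -> pd.DataFrame:
    """Tabulate screen results (optionally (result, p_bonferroni) pairs)."""
    rows = []
    for item in results:
        if isinstance(item, tuple):
            r, p_bonf = item
        else:
            r, p_bonf = item, None
        row = {
            "feature": r.feature_name, "test": r.test_kind, "mode": r.counting_mode,
            "statistic": r.statistic, "p": r.p_value, "direction": r.direction,
            "degenerate": r.degenerate,
        }
        if p_bonf is not None:
            row["p_bonferroni"] = p_bonf
        rows.append(row)
    return pd.DataFrame(rows)
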