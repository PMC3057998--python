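"""COBRA methylation quantification and methylation-expression correlation.

COBRA (combined bisulfite restriction analysis) digests bisulfite-PCR
amplicons with TaqI (cuts only methylation-retained sites, 80-bp product)
and TasI (cuts unmethylated product, 97-bp band).  The methylation level is
the TaqI band intensity as a percentage of the TaqI + TasI total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CobraMeasurement:
    sample_id: str
    locus_id: str
    taqI_intensity: float
    tasI_intensity: float

    @property
    def percent_methylation(self) -> float:
        return cobra_percent(self.taqI_intensity, self.tasI_intensity)


def cobra_percent(taqI: float, tasI: float) -> float:
    """Percent methylation: 100 * TaqI / (TaqI + TasI)."""
    if taqI < 0 or tasI < 0:
        raise ValueError("band intensities must be non-negative")
    total = taqI + tasI
    if total == 0:
        raise ValueError("both band intensities are zero: percent methylation undefined")
    return 100.0 * taqI / total


def methylation_expression_correlation(x, y):
    """Pearson correlation between per-sample methylation percentages and
    expression (or RNA) levels.  Returns ``(r, two_sided_p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def read_cobra_tsv(path):
    """Read band intensities (sample, locus, taqI, tasI) into measurements."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "locus": str})
    return [
        CobraMeasurement(r.sample, r.locus, float(r.taqI), float(r.tasI))
        for r in df.itertuples(index=False)
    ]


def cobra_table(measurements) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [m.sample_id for m in measurements],
            "locus": [m.locus_id for m in measurements],
            "taqI": [m.taqI_intensity for m in measurements],
            "tasI": [m.tasI_intensity for m in measurements],
            "percent_methylation": [m.percent_methylation for m in measurements],
        }
    )
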