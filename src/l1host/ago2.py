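"""AGO2 (Argonaute-2) CLIP binding-site analysis around intragenic L1s.

Binding sites shorter than or equal to 18 bp are discarded.  Two analyses
follow: a 2x2 association between L1 membership and binding-site presence
among up-regulated genes, and a signed-distance histogram of sites within
+/-600 kb of intragenic L1s in 25-kb bins, split by whether the L1 lies in
sense or antisense orientation relative to its host gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .enrichment import ContingencyTable2x2, chisq_or
from .intervals import GenomicInterval, INTRAGENIC, read_bed6

logger = logging.getLogger("l1host")

MIN_SITE_LENGTH_EXCLUSIVE = 18      # sites must be strictly longer than this
DEFAULT_BIN_WIDTH = 25_000
DEFAULT_RANGE = 600_000


@dataclass(frozen=True)
class BindingSite:
    site_id: str
    span: GenomicInterval

    @property
    def length_bp(self) -> int:
        return self.span.length

    @property
    def midpoint(self) -> float:
        return (self.span.start + self.span.end) / 2


@dataclass
class ProximityHistogram:
    """Signed-distance bin counts of binding sites around L1 anchors.

    Bins are half-open 25-kb intervals covering [-600000, +600000); positive
    distances lie downstream of the L1 in the host gene's transcription
    direction.  Counting is pair-based: a site within range of several
    anchors contributes once per anchor.
    """

    orientation: str                     # sense | antisense
    bin_width_bp: int
    range_bp: int
    counts: np.ndarray
    n_anchors: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_sites_in_range(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(-self.range_bp, self.range_bp + 1, self.bin_width_bp)

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame(
            {"bin_start": edges[:-1], "bin_end": edges[1:], "count": self.counts}
        )


def filter_sites(sites):
    """Keep binding sites strictly longer than 18 bp. Idempotent."""
    return [s for s in sites if s.length_bp > MIN_SITE_LENGTH_EXCLUSIVE]


def read_sites_bed(path):
    df = read_bed6(path)
    return [
        BindingSite(str(r.name), GenomicInterval(r.chrom, int(r.start), int(r.end), "."))
        for r in df.itertuples(index=False)
    ]


def ago2_l1_association(sites, genes, l1_genes, upregulated):
    """2x2 association between L1 membership and binding-site presence among
    up-regulated genes.

    Rows: gene contains an L1 / does not.  Columns: gene overlapped by >= 1
    (filtered) binding site / by none.  Returns ``(table, association)``.
    """
    upregulated = set(upregulated)
    if not upregulated:
        raise ValueError("empty up-regulated gene set")
    l1_genes = set(l1_genes)

    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.span.chrom, IntervalTree()).addi(s.span.start, s.span.end, s.site_id)

    gene_by_id = {g.gene_id: g for g in genes}
    with_site = set()
    for gid in upregulated:
        g = gene_by_id.get(gid)
        if g is None:
            continue
        tree = trees.get(g.span.chrom)
        if tree is not None and tree.overlap(g.span.start, g.span.end):
            with_site.add(gid)

    universe = upregulated & set(gene_by_id)
    in_l1 = universe & l1_genes
    a = len(in_l1 & with_site)
    b = len(in_l1 - with_site)
    c = len((universe - l1_genes) & with_site)
    d = len(universe - l1_genes - with_site)
    table = ContingencyTable2x2(
        a, b, c, d,
        row_labels=("L1_gene", "no_L1"),
        col_labels=("has_site", "no_site"),
    )
    return table, chisq_or(table)


def _anchor_coord(l1, gene_strand, anchor):
    """Anchor coordinate of an L1 in host-gene orientation."""
    if anchor == "midpoint":
        return (l1.span.start + l1.span.end) / 2
    if anchor == "five_prime":
        return l1.span.start if gene_strand == "+" else l1.span.end
    if anchor == "three_prime":
        return l1.span.end if gene_strand == "+" else l1.span.start
    raise ValueError(f"bad anchor {anchor!r}")


def l1_proximity_histogram(sites, l1s, genes, orientation,
                           anchor="five_prime",
                           bin_width_bp=DEFAULT_BIN_WIDTH,
                           range_bp=DEFAULT_RANGE) -> ProximityHistogram:
    """Histogram of signed distances from intragenic L1s to binding-site
    midpoints.

    One anchor per (L1, host gene) pair whose sense/antisense orientation
    matches ``orientation``.  For each site on the anchor's chromosome the
    signed distance d (positive downstream in the host gene's transcription
    direction) is binned into floor(d / bin_width) over [-range, +range).
    L1s whose host gene strand cannot be resolved are skipped with a warning.
    """
    if orientation not in {"sense", "antisense"}:
        raise ValueError(f"orientation must be sense or antisense, got {orientation!r}")
    if range_bp % bin_width_bp != 0:
        raise ValueError("range_bp must be a multiple of bin_width_bp")
    n_bins = 2 * range_bp // bin_width_bp
    counts = np.zeros(n_bins, dtype=int)
    gene_by_id = {g.gene_id: g for g in genes}

    # site midpoints grouped by chromosome, sorted for windowed lookup
    mids: dict[str, np.ndarray] = {}
    for s in sites:
        mids.setdefault(s.span.chrom, []).append(s.midpoint)
    mids = {k: np.sort(np.asarray(v, dtype=float)) for k, v in mids.items()}

    n_anchors = 0
    for l1 in l1s:
        if l1.location_class != INTRAGENIC:
            continue
        for gid in l1.host_genes:
            g = gene_by_id.get(gid)
            if g is None or g.strand not in {"+", "-"}:
                logger.warning("skipping anchor (%s, %s): host gene strand unknown", l1.l1_id, gid)
                continue
            if l1.strand == ".":
                logger.warning("skipping anchor (%s, %s): L1 strand unknown", l1.l1_id, gid)
                continue
            rel = "sense" if l1.strand == g.strand else "antisense"
            if rel != orientation:
                continue
            n_anchors += 1
            pos = _anchor_coord(l1, g.strand, anchor)
            chrom_mids = mids.get(l1.span.chrom)
            if chrom_mids is None:
                continue
            lo = np.searchsorted(chrom_mids, pos - range_bp - 1)
            hi = np.searchsorted(chrom_mids, pos + range_bp + 1)
            for m in chrom_mids[lo:hi]:
                d = (m - pos) if g.strand == "+" else (pos - m)
                if -range_bp <= d < range_bp:
                    counts[int(math.floor(d / bin_width_bp)) + range_bp // bin_width_bp] += 1

    return ProximityHistogram(
        orientation=orientation, bin_width_bp=bin_width_bp, range_bp=range_bp,
        counts=counts, n_anchors=n_anchors,
    )
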