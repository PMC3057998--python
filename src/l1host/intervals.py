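"""Genomic interval types, L1 location classification, and flanking-L1 search.

Coordinates are 0-based half-open (BED convention) throughout. GFF3 input is
converted on read. An L1 element is *intragenic* when it overlaps at least one
annotated gene span by >= 1 bp ("overlap" mode, the default) or when it lies
entirely within a gene span ("containment" mode); otherwise it is *intergenic*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("l1host")

VALID_STRANDS = {"+", "-", "."}

INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"
UNASSIGNED = "unassigned"


class ChromosomeNamespaceError(ValueError):
    """Raised when two annotation sets share no chromosome names."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded transcript span."""

    gene_id: str
    symbol: str
    span: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Coordinate of the transcription start (5' terminus)."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def three_prime(self) -> int:
        return self.span.end if self.strand == "+" else self.span.start


@dataclass(frozen=True)
class L1Element:
    """A LINE-1 insertion with its location class and per-element features.

    ``categorical_features`` holds category labels (e.g. CpG island present /
    absent, subfamily name); ``numeric_features`` holds real-valued attributes
    (G-C fraction, nucleotide counts, intactness score).
    """

    l1_id: str
    span: GenomicInterval
    strand: str
    location_class: str = UNASSIGNED
    host_genes: tuple = ()
    categorical_features: dict = field(default_factory=dict)
    numeric_features: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"L1 strand must be +, - or ., got {self.strand!r}")
        if self.location_class not in {INTRAGENIC, INTERGENIC, UNASSIGNED}:
            raise ValueError(f"bad location_class {self.location_class!r}")
        if (self.location_class == INTRAGENIC) != bool(self.host_genes):
            raise ValueError(
                f"{self.l1_id}: host_genes must be non-empty iff intragenic "
                f"(class={self.location_class}, hosts={self.host_genes})"
            )


@dataclass(frozen=True)
class FlankAssignment:
    """An intergenic L1 near a gene terminus."""

    l1_id: str
    gene_id: str
    gene_end: str  # five_prime | three_prime
    window_bp: int
    orientation: str  # sense | antisense
    distance_bp: int

    def __post_init__(self):
        if self.gene_end not in {"five_prime", "three_prime"}:
            raise ValueError(f"bad gene_end {self.gene_end!r}")
        if self.orientation not in {"sense", "antisense"}:
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0 <= self.distance_bp <= self.window_bp:
            raise ValueError(
                f"distance {self.distance_bp} outside [0, window={self.window_bp}]"
            )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _check_namespaces(l1s, genes):
    l1_chroms = {l1.span.chrom for l1 in l1s}
    gene_chroms = {g.span.chrom for g in genes}
    if l1s and genes and not (l1_chroms & gene_chroms):
        raise ChromosomeNamespaceError(
            f"no shared chromosome names between L1 set {sorted(l1_chroms)[:5]} "
            f"and gene set {sorted(gene_chroms)[:5]}"
        )


def classify_l1_locations(l1s, genes, mode: str = "overlap"):
    """Assign each L1 a location class and its host genes.

    Parameters
    ----------
    l1s, genes
        L1 elements and gene models on the same assembly.
    mode
        ``"overlap"`` (any >=1 bp overlap with a gene span makes the L1
        intragenic) or ``"containment"`` (the L1 must lie entirely within the
        span).

    Returns a new list of :class:`L1Element` in input order with
    ``location_class`` and ``host_genes`` populated.
    """
    if mode not in {"overlap", "containment"}:
        raise ValueError(f"mode must be 'overlap' or 'containment', got {mode!r}")
    _check_namespaces(l1s, genes)

    trees: dict[str, IntervalTree] = {}
    by_id = {}
    for g in genes:
        trees.setdefault(g.span.chrom, IntervalTree()).addi(g.span.start, g.span.end, g.gene_id)
        by_id[g.gene_id] = g

    out = []
    for l1 in l1s:
        tree = trees.get(l1.span.chrom)
        hits = []
        if tree is not None:
            for iv in tree.overlap(l1.span.start, l1.span.end):
                if mode == "containment" and not (iv.begin <= l1.span.start and l1.span.end <= iv.end):
                    continue
                hits.append(iv.data)
        hits = tuple(sorted(set(hits)))
        if hits:
            out.append(replace(l1, location_class=INTRAGENIC, host_genes=hits))
        else:
            out.append(replace(l1, location_class=INTERGENIC, host_genes=()))
    return out


def find_flanking_l1s(l1s, genes, window_bp: int):
    """Find intergenic L1s whose nearest edge lies within ``window_bp`` of a
    gene's 5' or 3' terminus.

    One assignment is emitted per (L1, gene, end). Orientation is sense when
    the L1 strand equals the gene strand. Pairs where either strand is unknown
    are skipped with a warning.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    assignments = []
    genes_by_chrom: dict[str, list] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.span.chrom, []).append(g)

    for l1 in l1s:
        if l1.location_class != INTERGENIC:
            continue
        for g in genes_by_chrom.get(l1.span.chrom, ()):
            if l1.strand == ".":
                logger.warning("skipping flank pair (%s, %s): L1 strand unknown", l1.l1_id, g.gene_id)
                continue
            # gap between nearest L1 edge and the gene body
            if l1.span.end <= g.span.start:
                gap = g.span.start - l1.span.end
                terminus = "five_prime" if g.strand == "+" else "three_prime"
            elif l1.span.start >= g.span.end:
                gap = l1.span.start - g.span.end
                terminus = "three_prime" if g.strand == "+" else "five_prime"
            else:
                continue  # overlap: cannot occur for a correctly classified intergenic L1
            if gap <= window_bp:
                assignments.append(
                    FlankAssignment(
                        l1_id=l1.l1_id,
                        gene_id=g.gene_id,
                        gene_end=terminus,
                        window_bp=window_bp,
                        orientation="sense" if l1.strand == g.strand else "antisense",
                        distance_bp=gap,
                    )
                )
    return assignments


# ---------------------------------------------------------------------------
# I/O: BED6, GFF3 (gene lines), feature sidecar TSV
# ---------------------------------------------------------------------------

def read_bed6(path):
    """Read a BED6 (or BED4+) file into a DataFrame with BED-native coordinates."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"chrom": str, "name": str},
    )
    return df


def read_genes_bed(path):
    df = read_bed6(path)
    return [
        GeneModel(
            gene_id=str(r.name),
            symbol=str(r.name),
            span=GenomicInterval(r.chrom, int(r.start), int(r.end), str(r.strand)),
            strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]


def read_genes_gff3(path):
    """Read gene records from a GFF3 file (type == 'gene'); 1-based closed
    coordinates are converted to 0-based half-open."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"gene line without ID attribute: {line[:80]}")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    symbol=attrs.get("Name", gid),
                    span=GenomicInterval(parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]),
                    strand=parts[6],
                )
            )
    return genes


def read_l1_bed(path, features_path=None):
    """Read L1 elements from BED6, optionally attaching a sidecar feature TSV
    keyed by l1_id.  Columns of the sidecar whose values parse as numbers
    become numeric features; the rest become categorical features."""
    df = read_bed6(path)
    cat: dict[str, dict] = {}
    num: dict[str, dict] = {}
    if features_path is not None:
        feats = pd.read_csv(features_path, sep="\t", dtype={"l1_id": str}).set_index("l1_id")
        for col in feats.columns:
            series = feats[col]
            if pd.api.types.is_numeric_dtype(series):
                for l1_id, v in series.items():
                    num.setdefault(l1_id, {})[col] = float(v)
            else:
                for l1_id, v in series.items():
                    cat.setdefault(l1_id, {})[col] = str(v)
    return [
        L1Element(
            l1_id=str(r.name),
            span=GenomicInterval(r.chrom, int(r.start), int(r.end), str(r.strand)),
            strand=str(r.strand),
            categorical_features=cat.get(str(r.name), {}),
            numeric_features=num.get(str(r.name), {}),
        )
        for r in df.itertuples(index=False)
    ]


def write_annotated_l1_tsv(l1s, path):
    rows = []
    for l1 in l1s:
        row = {
            "l1_id": l1.l1_id,
            "chrom": l1.span.chrom,
            "start": l1.span.start,
            "end": l1.span.end,
            "strand": l1.strand,
            "location_class": l1.location_class,
            "host_genes": ",".join(l1.host_genes),
        }
        row.update(l1.categorical_features)
        row.update(l1.numeric_features)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotated_l1_tsv(path, registry=None):
    """Read back the TSV written by :func:`write_annotated_l1_tsv`.

    ``registry`` (optional) declares which extra columns are categorical vs
    numeric; without it, dtype decides.
    """
    df = pd.read_csv(path, sep="\t", dtype={"l1_id": str, "host_genes": str})
    core = {"l1_id", "chrom", "start", "end", "strand", "location_class", "host_genes"}
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        hosts = tuple(str(d["host_genes"]).split(",")) if isinstance(d["host_genes"], str) and d["host_genes"] else ()
        cat, num = {}, {}
        for col in df.columns:
            if col in core:
                continue
            v = d[col]
            if registry is not None and col in registry.categorical:
                cat[col] = str(v)
            elif registry is not None and col in registry.numeric:
                num[col] = float(v)
            elif isinstance(v, (int, float)):
                num[col] = float(v)
            else:
                cat[col] = str(v)
        out.append(
            L1Element(
                l1_id=str(d["l1_id"]),
                span=GenomicInterval(str(d["chrom"]), int(d["start"]), int(d["end"]), str(d["strand"])),
                strand=str(d["strand"]),
                location_class=str(d["location_class"]),
                host_genes=hosts,
                categorical_features=cat,
                numeric_features=num,
            )
        )
    return out


def write_bed6(intervals, path):
    """Write (name, GenomicInterval) pairs or objects with .span/.l1_id/.gene_id to BED6."""
    with open(path, "w") as fh:
        for item in intervals:
            if isinstance(item, GeneModel):
                name, span, strand = item.gene_id, item.span, item.strand
            elif isinstance(item, L1Element):
                name, span, strand = item.l1_id, item.span, item.strand
            elif hasattr(item, "site_id"):
                name, span, strand = item.site_id, item.span, item.span.strand
            else:
                name, span = item
                strand = span.strand
            fh.write(f"{span.chrom}\t{span.start}\t{span.end}\t{name}\t0\t{strand}\n")
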