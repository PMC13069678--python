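"""Biological characterization of co-accessibility communities.

Covers: (i) target-gene assignment through basal-plus-extension regulatory
domains (a basal window around each TSS — 5 kb upstream / 1 kb downstream by
default — extended toward the neighboring genes' basal domains up to 1 Mb);
(ii) gene-set over-representation by one-sided hypergeometric test with the
full node set as background and Benjamini–Hochberg correction; (iii)
genomic-class annotation (e.g. SCREEN cCRE classes PLS/pELS/dELS) by maximal
overlap; (iv) local transcription-factor enrichment scored per ChIP-seq
experiment as -log10(p) * log2(odds ratio) of a Fisher exact 2x2 test
(community vs rest of the node universe, overlap vs no overlap), averaged
per factor; and (v) per-community temporal trend summaries of z-scored
signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import Region, SignalMatrix, zscore_rows

__all__ = [
    "GeneModel",
    "RegulatoryDomain",
    "EnrichmentRow",
    "GiggleTable",
    "CommunityTrend",
    "read_gene_models",
    "read_gmt",
    "read_class_bed",
    "regulatory_domains",
    "assign_targets",
    "enrich",
    "annotate_classes",
    "giggle_score",
    "score_tf_experiments",
    "aggregate_tf",
    "community_trends",
    "lift",
]

P_FLOOR = 1e-300
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k: int  # query genes in the set
    K: int  # background genes in the set
    n: int  # query size
    N: int  # background size
    fold: float
    p: float
    q: float


@dataclass
class GiggleTable:
    """Per-experiment TF enrichment rows plus the per-TF aggregated view."""

    rows: pd.DataFrame  # columns: tf, experiment_id, score, p, odds_ratio

    def aggregated(self) -> pd.DataFrame:
        agg = (
            self.rows.groupby("tf")["score"]
            .agg(mean_score="mean", n_experiments="size")
            .reset_index()
            .sort_values(["mean_score", "tf"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True)
        )
        agg["rank"] = np.arange(1, len(agg) + 1)
        return agg


@dataclass
class CommunityTrend:
    community: int
    time_points: list[float]
    median: list[float]
    q1: list[float]
    q3: list[float]


# ---------------------------------------------------------------------------
# readers

def read_gene_models(path) -> list[GeneModel]:
    """TSV with columns symbol, chrom, strand, tss."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "strand": str})
    return [
        GeneModel(r.symbol, r.chrom, r.strand, int(r.tss)) for r in df.itertuples(index=False)
    ]


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_class_bed(path) -> list[tuple[str, int, int, str]]:
    """BED4 with the class label (or tf:experiment tag) in column 4."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4 or not parts[3]:
                raise ValueError(f"malformed BED4 at line {lineno}: need 4 non-empty columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED4 at line {lineno}: bad coordinates") from exc
            if end <= start:
                raise ValueError(f"malformed BED4 at line {lineno}: end <= start")
            out.append((parts[0], start, end, parts[3]))
    return out


# ---------------------------------------------------------------------------
# regulatory domains & target genes

def regulatory_domains(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    Each gene gets a basal window of ``basal_up`` bp upstream and
    ``basal_down`` bp downstream of its TSS (strand-aware), then both ends
    are extended to at most ``max_ext`` bp from the TSS, stopping at the
    nearest neighboring gene's basal domain and at chromosome bounds. Basal
    windows may overlap each other; only the extensions are trimmed.
    """
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {g.chrom}")
        if g.tss >= chrom_sizes[g.chrom]:
            raise ValueError(f"gene {g.symbol} TSS {g.tss} beyond {g.chrom} bounds")

    def basal(g: GeneModel) -> tuple[int, int]:
        if g.strand == "+":
            s, e = g.tss - basal_up, g.tss + basal_down
        else:
            s, e = g.tss - basal_down, g.tss + basal_up
        return max(0, s), min(chrom_sizes[g.chrom], e)

    domains = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, glist in by_chrom.items():
        glist = sorted(glist, key=lambda g: (g.tss, g.symbol))
        basals = [basal(g) for g in glist]
        L = chrom_sizes[chrom]
        # running constraints from the neighbors' basal domains
        left_limit = [0] * len(glist)
        run = 0
        for i in range(1, len(glist)):
            run = max(run, basals[i - 1][1])
            left_limit[i] = run
        right_limit = [L] * len(glist)
        run = L
        for i in range(len(glist) - 2, -1, -1):
            run = min(run, basals[i + 1][0])
            right_limit[i] = run
        for g, (bs, be), ll, rl in zip(glist, basals, left_limit, right_limit):
            ext_s = min(bs, max(g.tss - max_ext, ll, 0))
            ext_e = max(be, min(g.tss + max_ext, rl, L))
            domains.append(RegulatoryDomain(g.symbol, chrom, ext_s, ext_e))
    return domains


def assign_targets(
    regions: list[Region],
    domains: list[RegulatoryDomain],
    midpoint: bool = False,
) -> dict[str, set[str]]:
    """Map each region to the genes whose regulatory domain it overlaps.

    Default rule is >= 1 bp overlap; with ``midpoint`` the region's midpoint
    must fall inside the domain. Regions overlapping nothing map to an
    empty set.
    """
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.chrom, IntervalTree()).addi(d.start, d.end, d.gene)
    out: dict[str, set[str]] = {}
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            out[r.id] = set()
            continue
        if midpoint:
            mid = (r.start + r.end) // 2
            hits = tree.at(mid)
        else:
            hits = tree.overlap(r.start, r.end)
        out[r.id] = {iv.data for iv in hits}
    return out


# ---------------------------------------------------------------------------
# gene-set enrichment

def enrich(
    query_genes: set[str],
    background_genes: set[str],
    gene_sets: dict[str, set[str]],
    q_max: float = 0.05,
    p_max: float | None = None,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation against the node background.

    Gene sets are intersected with the background before testing; BH
    correction is applied across all tested terms. Rows passing the filter
    (q < q_max, or p < p_max when given) are returned sorted by q then
    decreasing fold.
    """
    if not query_genes <= background_genes:
        raise ValueError("query genes must be a subset of the background")
    query = set(query_genes)
    bg = set(background_genes)
    if not query:
        warnings.warn("empty query gene set: no enrichment computed", stacklevel=2)
        return []
    N, n = len(bg), len(query)
    rows = []
    for term in sorted(gene_sets):
        members = gene_sets[term] & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term, k, K, p, fold))
    if not rows:
        return []
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    out = [
        EnrichmentRow(term=t, k=k, K=K, n=n, N=N, fold=f, p=p, q=float(q))
        for (t, k, K, p, f), q in zip(rows, qvals)
    ]
    if p_max is not None:
        out = [r for r in out if r.p < p_max]
    else:
        out = [r for r in out if r.q < q_max]
    return sorted(out, key=lambda r: (r.q, -r.fold, r.term))


# ---------------------------------------------------------------------------
# genomic-class annotation

def annotate_classes(
    regions: list[Region],
    annotation_bed: list[tuple[str, int, int, str]],
    labels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-community fractions of regions in each genomic class.

    Each region takes the class of its maximal-overlap annotation interval
    (ties broken by BED order; no overlap -> "unclassified"). Returns a
    DataFrame indexed by community with one column per class; each row sums
    to 1. With ``labels=None`` all regions form a single community 0.
    """
    trees: dict[str, IntervalTree] = {}
    for order, (chrom, start, end, cls) in enumerate(annotation_bed):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, (order, cls))
    assigned: dict[str, str] = {}
    for r in regions:
        tree = trees.get(r.chrom)
        best = None
        if tree is not None:
            for iv in tree.overlap(r.start, r.end):
                ov = min(r.end, iv.end) - max(r.start, iv.begin)
                order, cls = iv.data
                key = (-ov, order)
                if best is None or key < best[0]:
                    best = (key, cls)
        assigned[r.id] = best[1] if best else UNCLASSIFIED
    labels = labels or {r.id: 0 for r in regions}
    df = pd.DataFrame(
        {
            "community": [labels[r.id] for r in regions if r.id in labels],
            "cls": [assigned[r.id] for r in regions if r.id in labels],
        }
    )
    frac = df.groupby("community")["cls"].value_counts(normalize=True).unstack(fill_value=0.0)
    frac.columns.name = None
    return frac


# ---------------------------------------------------------------------------
# TF enrichment (local GIGGLE-style scoring)

def giggle_score(p: float, odds_ratio: float) -> float:
    """-log10(p) * log2(odds ratio): significance times effect size."""
    if p <= 0:
        raise ValueError("p must be > 0 (floor it at 1e-300 first)")
    if p > 1:
        raise ValueError("p must be <= 1")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be > 0")
    return float(-math.log10(p) * math.log2(odds_ratio))


def _overlap_mask(regions: list[Region], bed: list[tuple[str, int, int, str]]) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _ in bed:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    mask = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlaps(r.start, r.end):
            mask[i] = True
    return mask


def score_tf_experiments(
    community_regions: list[Region],
    tf_beds: dict[str, list[tuple[str, int, int, str]]],
    universe: list[Region],
) -> GiggleTable:
    """Score each TF ChIP-seq experiment against one community.

    Per experiment, a 2x2 table (community vs rest-of-universe x overlaps vs
    not) gives a Fisher exact p-value and odds ratio (Haldane–Anscombe +0.5
    when any cell is zero), combined into -log10(p) * log2(OR). Keys of
    ``tf_beds`` are "tf" or "tf:experiment_id".
    """
    if not universe:
        raise ValueError("empty region universe")
    comm_ids = {r.id for r in community_regions}
    if not comm_ids <= {r.id for r in universe}:
        raise ValueError("community regions must be contained in the universe")
    in_comm = np.array([r.id in comm_ids for r in universe])
    rows = []
    for key in sorted(tf_beds):
        tf, _, experiment = key.partition(":")
        experiment = experiment or key
        hit = _overlap_mask(universe, tf_beds[key])
        a = int(np.sum(hit & in_comm))
        b = int(np.sum(~hit & in_comm))
        c = int(np.sum(hit & ~in_comm))
        d = int(np.sum(~hit & ~in_comm))
        _, p = stats.fisher_exact([[a, b], [c, d]])
        p = max(float(p), P_FLOOR)
        if min(a, b, c, d) == 0:
            oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            oddsr = (a * d) / (b * c)
        rows.append(
            {
                "tf": tf,
                "experiment_id": experiment,
                "score": giggle_score(p, oddsr),
                "p": p,
                "odds_ratio": oddsr,
            }
        )
    return GiggleTable(rows=pd.DataFrame(rows, columns=["tf", "experiment_id", "score", "p", "odds_ratio"]))


def aggregate_tf(table: GiggleTable, top_k: int = 10) -> list[tuple[str, float]]:
    """Mean score per TF, ranked descending (ties by name), top_k retained."""
    if table.rows.empty:
        raise ValueError("empty GIGGLE table")
    agg = table.aggregated()
    return [(r.tf, float(r.mean_score)) for r in agg.head(top_k).itertuples(index=False)]


# ---------------------------------------------------------------------------
# temporal trends

def community_trends(sm: SignalMatrix, labels: dict[str, int]) -> list[CommunityTrend]:
    """Median/quartile z-score profiles per community and time point."""
    z = zscore_rows(sm)
    tps = [s.time_point for s in z.samples]
    idx_of = {rid: i for i, rid in enumerate(z.region_ids)}
    trends = []
    for comm in sorted(set(labels.values())):
        rows = [idx_of[rid] for rid, c in labels.items() if c == comm and rid in idx_of]
        if not rows:
            warnings.warn(f"community {comm} absent from the matrix; skipped", stacklevel=2)
            continue
        block = z.values[rows, :]
        trends.append(
            CommunityTrend(
                community=comm,
                time_points=list(tps),
                median=list(np.median(block, axis=0)),
                q1=list(np.percentile(block, 25, axis=0)),
                q3=list(np.percentile(block, 75, axis=0)),
            )
        )
    return trends


def lift(regions: list[Region], chain=None) -> list[Region]:
    """Coordinate lift-over hook: pre-lifted input is required.

    Converting between genome assemblies needs an external chain-file engine;
    supplying a chain here is an error, and the regions are returned as-is.
    """
    if chain is not None:
        raise NotImplementedError(
            "chain-file lift-over is not performed here; supply pre-lifted coordinates"
        )
    return list(regions)
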