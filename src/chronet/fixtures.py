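"""Synthetic longitudinal epigenomic data with planted community structure.

Generates a raw count matrix emulating a peak-by-sample time course: K
communities of regions, each following one temporal archetype (shapes
mirroring the trends seen in stimulated-cell and developmental time courses:
early up, gradual up, early down, transient dip, bimodal), with Gaussian
noise on the log2 mean, optional per-batch shifts, and Poisson (optionally
negative-binomial) count sampling. Regions are laid out on a toy genome of
two autosomes, plus chrX decoy regions exercising the sex-chromosome filter.

``simulate_annotations`` adds matched gene models, gene sets, genomic-class
annotations and TF interval files in which each community has one planted
gene set (its regions sit inside those genes' regulatory domains) and one
planted TF (covering its regions and a small background fraction), so
the full characterization stage has a known ground truth.

Archetypes are functions of the time *rank*, matching the rank invariance
of the Spearman correlation used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_preprocess import Region, SampleMeta, SignalMatrix

__all__ = ["ARCHETYPES", "PlantedDesign", "simulate", "simulate_annotations", "write_annotations"]


def _monotone_up(t):
    return t


def _monotone_down(t):
    return 1.0 - t


def _early_peak(t):
    return np.exp(-(((t - 0.2) / 0.22) ** 2))


def _transient_dip(t):
    return 1.0 - np.exp(-(((t - 0.5) / 0.2) ** 2))


def _bimodal(t):
    return 0.5 + 0.5 * np.cos(4.0 * math.pi * t)


#: archetype name -> unit-range trend over the normalized time rank in [0, 1]
ARCHETYPES = {
    "monotone_up": _monotone_up,
    "monotone_down": _monotone_down,
    "early_peak": _early_peak,
    "transient_dip": _transient_dip,
    "bimodal": _bimodal,
}


@dataclass(frozen=True)
class PlantedDesign:
    n_communities: int = 5
    regions_per_community: int = 200
    n_timepoints: int = 8
    replicates: int = 2
    archetypes: tuple[str, ...] = tuple(ARCHETYPES)
    noise_sd: float = 0.2
    baseline_log2: float = 8.0  # mean log2 count level (~256 counts)
    amplitude_log2: float = 2.0  # dynamic range of the planted trend (4-fold)
    batch_shift: float | None = None  # log2 offset of batch "B" (replicate 2)
    n_decoys: int = 20  # chrX regions exercising the chromosome filter
    dispersion: float | None = None  # NB dispersion; None -> Poisson
    region_width: int = 500
    region_spacing: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.n_communities < 1:
            raise ValueError("need at least one community")
        if len(self.archetypes) < self.n_communities:
            raise ValueError("need at least one archetype per community")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


def _layout_regions(design: PlantedDesign) -> tuple[list[Region], np.ndarray]:
    """Communities laid out as contiguous blocks alternating over 2 autosomes,
    plus chrX decoys; returns regions and planted labels (0 for decoys)."""
    regions, labels = [], []
    cursor = {"chr1": 10_000, "chr2": 10_000}
    for c in range(design.n_communities):
        chrom = "chr1" if c % 2 == 0 else "chr2"
        for _ in range(design.regions_per_community):
            start = cursor[chrom]
            regions.append(Region(chrom, start, start + design.region_width))
            labels.append(c + 1)
            cursor[chrom] += design.region_spacing
        cursor[chrom] += 20 * design.region_spacing  # gap between community blocks
    x = 10_000
    for _ in range(design.n_decoys):
        regions.append(Region("chrX", x, x + design.region_width))
        labels.append(0)
        x += design.region_spacing
    return regions, np.asarray(labels)


def simulate(design: PlantedDesign) -> tuple[SignalMatrix, dict[str, int], list[SampleMeta]]:
    """Raw counts with planted temporal communities.

    Region i of community c has log2 mean = baseline + amplitude *
    archetype_c(rank(t)) (archetypes rescaled to unit range over the time
    grid) + N(0, noise_sd) + batch shift, and counts drawn from a Poisson
    (or negative binomial) with that mean. Returns the raw SignalMatrix,
    the truth labels {region_id: community, 0 for decoys} and the sample
    metadata.
    """
    rng = np.random.default_rng(design.seed)
    regions, labels = _layout_regions(design)
    n = len(regions)

    t = (
        np.arange(design.n_timepoints) / (design.n_timepoints - 1)
        if design.n_timepoints > 1
        else np.zeros(1)
    )
    shapes = []
    for name in design.archetypes[: design.n_communities]:
        y = np.asarray(ARCHETYPES[name](t), dtype=float)
        span = y.max() - y.min()
        shapes.append((y - y.min()) / span if span > 0 else np.zeros_like(y))

    samples = []
    for j in range(design.n_timepoints):
        for rep in range(design.replicates):
            samples.append(
                SampleMeta(
                    sample_id=f"t{j}_r{rep + 1}",
                    time_point=float(j),
                    replicate=str(rep + 1),
                    batch=chr(ord("A") + rep),
                )
            )
    m = len(samples)

    log2_mean = np.empty((n, m))
    for i in range(n):
        if labels[i] == 0:  # decoy: flat profile, noise only
            base = np.full(design.n_timepoints, 0.5)
        else:
            base = shapes[labels[i] - 1]
        for j, s in enumerate(samples):
            mu = design.baseline_log2 + design.amplitude_log2 * base[int(s.time_point)]
            if design.batch_shift is not None and s.batch == "B":
                mu += design.batch_shift
            log2_mean[i, j] = mu
    log2_mean += rng.normal(0.0, design.noise_sd, size=log2_mean.shape)

    lam = np.exp2(log2_mean)
    if design.dispersion is None:
        counts = rng.poisson(lam).astype(float)
    else:
        # NB with mean lam and variance lam + dispersion * lam^2
        r = 1.0 / design.dispersion
        counts = rng.negative_binomial(r, r / (r + lam)).astype(float)

    sm = SignalMatrix(regions=regions, samples=samples, values=counts)
    truth = {r.id: int(c) for r, c in zip(regions, labels)}
    return sm, truth, samples


# ---------------------------------------------------------------------------
# matched annotation fixtures

@dataclass
class AnnotationFixture:
    genes: list  # GeneModel records
    gene_sets: dict[str, set[str]]
    class_bed: list[tuple[str, int, int, str]]
    tf_beds: dict[str, list[tuple[str, int, int, str]]]
    chrom_sizes: dict[str, int]
    planted_sets: dict[int, str] = field(default_factory=dict)  # community -> set name
    planted_tfs: dict[int, str] = field(default_factory=dict)  # community -> tf name


def simulate_annotations(
    regions: list[Region],
    truth: dict[str, int],
    design: PlantedDesign,
    genes_per_community: int = 4,
    n_decoy_sets: int = 5,
    tf_background_frac: float = 0.05,
    classes: tuple[str, ...] = ("PLS", "pELS", "dELS"),
) -> AnnotationFixture:
    """Gene models, gene sets, class annotations and TF intervals matched to
    the planted communities.

    Each community gets a dedicated gene set whose genes' TSSs sit inside the
    community's region block (so basal-plus-extension assignment recovers
    them), and a dedicated TF whose intervals cover all the community's
    regions plus ``tf_background_frac`` of the other regions.
    """
    from .annotate import GeneModel

    rng = np.random.default_rng(design.seed + 1)
    by_comm: dict[int, list[Region]] = {}
    for r in regions:
        by_comm.setdefault(truth[r.id], []).append(r)
    communities = sorted(c for c in by_comm if c != 0)

    chrom_sizes: dict[str, int] = {}
    for r in regions:
        chrom_sizes[r.chrom] = max(chrom_sizes.get(r.chrom, 0), r.end + 1_000_000)

    genes: list[GeneModel] = []
    gene_sets: dict[str, set[str]] = {}
    planted_sets: dict[int, str] = {}
    for c in communities:
        block = by_comm[c]
        picks = np.linspace(0, len(block) - 1, genes_per_community).astype(int)
        members = set()
        for gi, pi in enumerate(picks):
            r = block[pi]
            sym = f"GENE_C{c}_{gi}"
            strand = "+" if (c + gi) % 2 == 0 else "-"
            genes.append(GeneModel(sym, r.chrom, strand, (r.start + r.end) // 2))
            members.add(sym)
        name = f"SET_COMMUNITY_{c}"
        gene_sets[name] = members
        planted_sets[c] = name
    all_symbols = sorted({g.symbol for g in genes})
    for d in range(n_decoy_sets):
        size = min(len(all_symbols), max(2, genes_per_community))
        gene_sets[f"SET_DECOY_{d}"] = set(rng.choice(all_symbols, size=size, replace=False))

    class_bed = []
    for r in regions:
        cls = classes[rng.integers(len(classes))]
        class_bed.append((r.chrom, r.start, r.end, cls))

    tf_beds: dict[str, list[tuple[str, int, int, str]]] = {}
    planted_tfs: dict[int, str] = {}
    others = {c: [r for r in regions if truth[r.id] != c] for c in communities}
    for c in communities:
        tf = f"TF_C{c}"
        intervals = [(r.chrom, r.start, r.end, tf) for r in by_comm[c]]
        bg = others[c]
        n_bg = int(round(tf_background_frac * len(bg)))
        if n_bg:
            for bi in rng.choice(len(bg), size=n_bg, replace=False):
                r = bg[bi]
                intervals.append((r.chrom, r.start, r.end, tf))
        tf_beds[f"{tf}:exp1"] = sorted(intervals)
        planted_tfs[c] = tf
    # one decoy TF hitting a uniform random subset of all regions
    n_rand = max(1, int(0.1 * len(regions)))
    rand_idx = rng.choice(len(regions), size=n_rand, replace=False)
    tf_beds["TF_DECOY:exp1"] = sorted(
        (regions[i].chrom, regions[i].start, regions[i].end, "TF_DECOY") for i in rand_idx
    )

    return AnnotationFixture(
        genes=genes,
        gene_sets=gene_sets,
        class_bed=class_bed,
        tf_beds=tf_beds,
        chrom_sizes=chrom_sizes,
        planted_sets=planted_sets,
        planted_tfs=planted_tfs,
    )


def write_annotations(fix: AnnotationFixture, outdir: str | Path) -> None:
    """Write the annotation fixture as genes.tsv, sets.gmt, classes.bed, tf_beds/."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genes.tsv", "w") as fh:
        fh.write("symbol\tchrom\tstrand\ttss\n")
        for g in fix.genes:
            fh.write(f"{g.symbol}\t{g.chrom}\t{g.strand}\t{g.tss}\n")
    with open(out / "sets.gmt", "w") as fh:
        for name in sorted(fix.gene_sets):
            genes = "\t".join(sorted(fix.gene_sets[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")
    with open(out / "classes.bed", "w") as fh:
        for chrom, s, e, cls in fix.class_bed:
            fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
    tf_dir = out / "tf_beds"
    tf_dir.mkdir(exist_ok=True)
    for key in sorted(fix.tf_beds):
        fname = key.replace(":", "__") + ".bed"
        with open(tf_dir / fname, "w") as fh:
            for chrom, s, e, name in fix.tf_beds[key]:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom in sorted(fix.chrom_sizes):
            fh.write(f"{chrom}\t{fix.chrom_sizes[chrom]}\n")
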