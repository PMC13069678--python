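"""Input parsing and preprocessing of longitudinal epigenomic count matrices.

The network substrate is a :class:`SignalMatrix`: *n* genomic regions
(ATAC-seq peaks or histone-mark domains) by *m* samples of log2-normalized
signal, with BED-convention coordinates (0-based, half-open) and per-sample
metadata carrying the longitudinal design (time point, replicate, batch).

The preprocessing recipe mirrors standard practice for count matrices over
peaks: log-CPM normalization, optional batch-mean removal, exclusion of sex
chromosomes and low-variance regions, replicate averaging per time point,
and per-region z-scoring for temporal trend display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "SampleMeta",
    "SignalMatrix",
    "read_counts",
    "log_cpm",
    "remove_batch_effect",
    "filter_regions",
    "average_replicates",
    "zscore_rows",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval (BED convention: 0-based start, exclusive end).

    Regions are unstranded: cis-regulatory elements have no orientation.
    """

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start, got {self.chrom}:{self.start}-{self.end}"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @classmethod
    def from_id(cls, region_id: str) -> "Region":
        """Parse a canonical ``chrom:start-end`` identifier."""
        try:
            chrom, rest = region_id.rsplit(":", 1)
            start_s, end_s = rest.split("-", 1)
            return cls(chrom, int(start_s), int(end_s), region_id)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cannot parse region id {region_id!r} as chrom:start-end") from exc

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample design metadata; ``time_point`` must have a numeric rank."""

    sample_id: str
    time_point: float
    replicate: str = "1"
    batch: str | None = None


@dataclass
class SignalMatrix:
    """n regions x m samples of signal with coordinates and design metadata."""

    regions: list[Region]
    samples: list[SampleMeta]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.regions) != n:
            raise ValueError(
                f"row axis mismatch: {len(self.regions)} regions vs {n} matrix rows"
            )
        if len(self.samples) != m:
            raise ValueError(
                f"column axis mismatch: {len(self.samples)} samples vs {m} matrix columns"
            )
        if n < 1:
            raise ValueError("SignalMatrix needs at least one region")
        if np.isnan(self.values).any():
            raise ValueError("SignalMatrix must not contain missing values")
        ids = [r.id for r in self.regions]
        if len(set(ids)) != n:
            raise ValueError("region ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def region_ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.region_ids, columns=[s.sample_id for s in self.samples]
        )

    def write_tsv(self, matrix_path, meta_path=None, bed_path=None) -> None:
        df = self.to_frame()
        df.index.name = "region_id"
        df.to_csv(matrix_path, sep="\t")
        if meta_path is not None:
            pd.DataFrame(
                {
                    "sample_id": [s.sample_id for s in self.samples],
                    "time_point": [s.time_point for s in self.samples],
                    "replicate": [s.replicate for s in self.samples],
                    "batch": [s.batch if s.batch is not None else "" for s in self.samples],
                }
            ).to_csv(meta_path, sep="\t", index=False)
        if bed_path is not None:
            with open(bed_path, "w") as fh:
                for r in self.regions:
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def _read_bed_regions(bed_path) -> list[Region]:
    regions = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: need >= 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise ValueError(
                    f"invalid interval on BED line {lineno}: {chrom}:{start}-{end}"
                )
            name = parts[3] if len(parts) >= 4 and parts[3] not in ("", ".") else ""
            regions.append(Region(chrom, start, end, name))
    return regions


def read_counts(matrix_path, meta_path, bed_path=None) -> SignalMatrix:
    """Read a raw count matrix (TSV, first column region id, header sample ids).

    Region coordinates come either from ids of the form ``chrom:start-end``
    or from a BED file whose rows match the matrix row order. Sample metadata
    is a TSV with columns sample_id, time_point, replicate and optional batch.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError("count matrix has no sample columns")

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "replicate": str})
    required = {"sample_id", "time_point", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    matrix_samples = [str(c) for c in df.columns]
    absent = [s for s in matrix_samples if s not in meta.index]
    if absent:
        raise ValueError(f"sample axis mismatch: no metadata for samples {absent}")

    samples = []
    for sid in matrix_samples:
        row = meta.loc[sid]
        batch = row.get("batch")
        if batch is not None and (pd.isna(batch) or str(batch) == ""):
            batch = None
        samples.append(
            SampleMeta(
                sample_id=sid,
                time_point=float(row["time_point"]),
                replicate=str(row["replicate"]),
                batch=None if batch is None else str(batch),
            )
        )

    if bed_path is not None:
        regions = _read_bed_regions(bed_path)
        if len(regions) != df.shape[0]:
            raise ValueError(
                f"region count mismatch: matrix has {df.shape[0]} rows, "
                f"BED has {len(regions)}"
            )
    else:
        regions = [Region.from_id(str(rid)) for rid in df.index]

    return SignalMatrix(regions=regions, samples=samples, values=df.to_numpy(dtype=float))


def log_cpm(raw: SignalMatrix, prior: float = 0.5) -> SignalMatrix:
    """log2 counts-per-million with a prior count.

    ``log2((x + prior) / (libsize + 2*prior) * 1e6)`` per entry, where
    libsize is the column sum of raw counts. A self-contained analog of the
    log-CPM transforms used for count matrices over peaks.
    """
    x = raw.values
    if (x < 0).any():
        raise ValueError("raw counts must be non-negative")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = [raw.samples[j].sample_id for j in np.flatnonzero(lib <= 0)]
        raise ValueError(f"zero library size for samples {bad}")
    vals = np.log2((x + prior) / (lib + 2.0 * prior) * 1e6)
    return replace(raw, values=vals)


def remove_batch_effect(sm: SignalMatrix) -> SignalMatrix:
    """Equalize per-feature batch means (least-squares batch indicator model).

    For each feature, the batch-mean deviations from the grand mean are
    subtracted, so every batch ends up with the same per-feature mean while
    the grand mean is preserved. With a single batch this is the identity
    (a warning is emitted).
    """
    batches = [s.batch for s in sm.samples]
    if any(b is None for b in batches):
        raise ValueError("remove_batch_effect requires a batch label for every sample")
    uniq = sorted(set(batches))
    if len(uniq) < 2:
        warnings.warn("single batch: batch correction is the identity", stacklevel=2)
        return replace(sm, values=sm.values.copy())
    vals = sm.values.copy()
    grand = vals.mean(axis=1, keepdims=True)
    for b in uniq:
        cols = [j for j, bb in enumerate(batches) if bb == b]
        bmean = vals[:, cols].mean(axis=1, keepdims=True)
        vals[:, cols] -= bmean - grand
    return replace(sm, values=vals)


def filter_regions(
    sm: SignalMatrix,
    drop_chroms: set[str] = frozenset(),
    min_variance: float = 0.0,
    drop_ids: set[str] | None = None,
) -> SignalMatrix:
    """Drop regions on excluded chromosomes (exact string match, e.g. chrX/chrY),
    regions with sample variance (ddof=1) below ``min_variance``, and regions
    whose id is in ``drop_ids``. Row order is preserved."""
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    drop_ids = drop_ids or set()
    if sm.m >= 2:
        var = sm.values.var(axis=1, ddof=1)
    else:
        var = np.zeros(sm.n)
    keep = [
        i
        for i, r in enumerate(sm.regions)
        if r.chrom not in drop_chroms and var[i] >= min_variance and r.id not in drop_ids
    ]
    if not keep:
        raise ValueError("all regions filtered out; refusing to build an empty network")
    return SignalMatrix(
        regions=[sm.regions[i] for i in keep],
        samples=list(sm.samples),
        values=sm.values[keep, :],
    )


def average_replicates(sm: SignalMatrix) -> SignalMatrix:
    """Average biological replicates of the same time point.

    Output has one column per distinct time point, in increasing time order;
    the resulting samples carry replicate="mean" and no batch.
    """
    tps = sorted({s.time_point for s in sm.samples})
    cols = []
    out_samples = []
    for t in tps:
        idx = [j for j, s in enumerate(sm.samples) if s.time_point == t]
        cols.append(sm.values[:, idx].mean(axis=1))
        out_samples.append(SampleMeta(sample_id=f"t{t:g}", time_point=t, replicate="mean"))
    return SignalMatrix(
        regions=list(sm.regions), samples=out_samples, values=np.column_stack(cols)
    )


def zscore_rows(sm: SignalMatrix) -> SignalMatrix:
    """Standardize each region's signal to mean 0, sample sd 1 (ddof=1)."""
    mu = sm.values.mean(axis=1, keepdims=True)
    sd = sm.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        ids = [sm.regions[i].id for i in zero[:10]]
        raise ValueError(f"zero-variance rows cannot be z-scored: {ids}")
    return replace(sm, values=(sm.values - mu) / sd)
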