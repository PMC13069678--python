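"""Co-accessibility network construction.

All-pairs Spearman correlations between region signal profiles, computed as
dot products of standardized rank vectors in memory-bounded blocks, filtered
by a significance-derived minimum correlation, and persisted to an on-disk
edge store partitioned into correlation bins of width 0.1.

The Spearman coefficient of two rows equals the Pearson correlation of their
tie-averaged ranks; after ranking each row and scaling it to zero mean and
unit *population* standard deviation, the correlation of rows a and b is the
dot product Z_a . Z_b / m. A lower bound on the coefficient is either given
directly or derived from a two-sided p-value through the exact monotone map
between r and the t statistic t = r * sqrt(df / (1 - r^2)), df = m - 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

__all__ = [
    "ThresholdConfig",
    "BatchPlan",
    "Edge",
    "EdgeStore",
    "pvalue_to_min_correlation",
    "rank_standardize",
    "spearman_block",
    "build_network",
    "load_edges",
]

#: decimals rho is rounded to before binning/storage, so bin membership is
#: reproducible across blockings and platforms.
RHO_DECIMALS = 12
BIN_WIDTH = 0.1


def pvalue_to_min_correlation(p: float, m: int) -> float:
    """Minimum |Spearman rho| whose two-sided p-value is <= ``p`` at m samples.

    Computes the critical t value at level ``p`` (two-sided, df = m - 2) and
    inverts t = r * sqrt(df / (1 - r^2)) to r = t / sqrt(t^2 + df).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if m < 3:
        raise ValueError(f"need m >= 3 samples (df = m - 2 >= 1), got m = {m}")
    df = m - 2
    t_crit = stats.t.ppf(1.0 - p / 2.0, df)
    if t_crit <= 0:  # p == 1
        return 0.0
    return float(t_crit / math.sqrt(t_crit * t_crit + df))


@dataclass(frozen=True)
class ThresholdConfig:
    """Edge-retention threshold: a direct minimum correlation or a p-value."""

    mode: str  # "pval" | "corr"
    value: float
    m: int  # sample count (df = m - 2)
    sign: str = "positive"  # "positive" | "absolute"

    def __post_init__(self):
        if self.mode not in ("pval", "corr"):
            raise ValueError(f"mode must be 'pval' or 'corr', got {self.mode!r}")
        if self.sign not in ("positive", "absolute"):
            raise ValueError(f"sign must be 'positive' or 'absolute', got {self.sign!r}")
        if self.mode == "corr" and not (0.0 <= self.value <= 1.0):
            raise ValueError(f"corr-mode threshold must be in [0, 1], got {self.value}")

    @property
    def df(self) -> int:
        return self.m - 2

    @property
    def r_min(self) -> float:
        if self.mode == "corr":
            return float(self.value)
        return pvalue_to_min_correlation(self.value, self.m)


@dataclass(frozen=True)
class BatchPlan:
    """Memory plan: nodes per chunk, pair evaluations per batch, worker count."""

    chunk_size: int = 2000
    step_size: int = 100_000
    workers: int = 1

    def __post_init__(self):
        if self.chunk_size < 1 or self.step_size < 1 or self.workers < 1:
            raise ValueError("chunk_size, step_size and workers must all be >= 1")


@dataclass(frozen=True)
class Edge:
    source_id: str
    target_id: str
    rho: float


def rank_standardize(values: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Tie-averaged ranks per row, centered and scaled to unit population sd.

    With this scaling rho(a, b) = Z_a . Z_b / m is exactly the Pearson
    correlation of the rank vectors, i.e. the Spearman coefficient.
    Constant rows have no defined rank correlation and raise.
    """
    X = np.asarray(values, dtype=float)
    n, m = X.shape
    R = stats.rankdata(X, axis=1, method="average")
    mu = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, ddof=0, keepdims=True)
    const = np.flatnonzero(sd.ravel() == 0)
    if const.size:
        names = [ids[i] for i in const[:10]] if ids else const[:10].tolist()
        raise ValueError(f"constant rows have undefined rank correlation: {names}")
    return (R - mu) / sd


def spearman_block(Z: np.ndarray, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Spearman correlations for all pairs (a, b) between two row index sets."""
    m = Z.shape[1]
    return Z[rows_a] @ Z[rows_b].T / m


def _bin_bounds(r_min: float, sign: str) -> list[tuple[float, float]]:
    """Half-open 0.1-width bins covering [floor(r_min, 0.1), 1]; top bin closed."""
    lo0 = math.floor(round(r_min, RHO_DECIMALS) * 10) / 10
    lo0 = min(max(lo0, 0.0), 0.9)
    bounds = []
    lo = lo0
    while lo < 1.0 - 1e-9:
        bounds.append((round(lo, 1), round(lo + BIN_WIDTH, 1)))
        lo += BIN_WIDTH
    return bounds


def _bin_index(rho_abs: np.ndarray, lo0: float) -> np.ndarray:
    """Bin index for |rho| values (rounded); rho == 1.0 joins the top bin."""
    r = np.round(rho_abs, RHO_DECIMALS)
    idx = np.floor(r * 10 + 1e-9).astype(int) - int(round(lo0 * 10))
    top = int(round((0.9 - lo0) * 10))
    return np.minimum(idx, top)


class EdgeStore:
    """On-disk columnar edge list, one Parquet (or CSV) file per 0.1 rho bin.

    Layout: ``<root>/edges_<lo>_<hi>.parquet`` with columns
    (source_id, target_id, rho), plus ``manifest.json`` recording n, m, the
    threshold configuration, sign policy, node ids and per-bin edge counts.
    """

    MANIFEST = "manifest.json"

    def __init__(self, root: str | Path):
        self.root = Path(root)
        mf = self.root / self.MANIFEST
        if not mf.exists():
            raise FileNotFoundError(f"no edge-store manifest at {mf}")
        self.manifest = json.loads(mf.read_text())

    # -- manifest accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.manifest["n"]

    @property
    def m(self) -> int:
        return self.manifest["m"]

    @property
    def r_min(self) -> float:
        return self.manifest["r_min"]

    @property
    def node_ids(self) -> list[str]:
        return self.manifest["node_ids"]

    @property
    def bins(self) -> list[tuple[float, float]]:
        return [tuple(b) for b in self.manifest["bins"]]

    @property
    def fmt(self) -> str:
        return self.manifest.get("format", "parquet")

    def bin_path(self, lo: float, hi: float) -> Path:
        ext = "parquet" if self.fmt == "parquet" else "csv"
        return self.root / f"edges_{lo:g}_{hi:g}.{ext}"

    def read_bin(self, lo: float, hi: float) -> pd.DataFrame:
        path = self.bin_path(lo, hi)
        if not path.exists():
            raise FileNotFoundError(f"missing bin file for [{lo}, {hi}): {path}")
        if self.fmt == "parquet":
            return pd.read_parquet(path)
        return pd.read_csv(path, dtype={"source_id": str, "target_id": str})

    def edges_frame(self, tau: float | None = None) -> pd.DataFrame:
        """All stored edges with rho >= tau, reading only the bins intersecting
        [tau, 1] (|rho| >= tau under the absolute sign policy)."""
        tau = self.r_min if tau is None else float(tau)
        strength = abs if self.manifest.get("sign") == "absolute" else (lambda s: s)
        frames = []
        for lo, hi in self.bins:
            # half-open [lo, hi) bins; the top bin is closed at 1.0
            if hi <= tau and hi != 1.0:
                continue
            df = self.read_bin(lo, hi)
            frames.append(df[strength(df["rho"]) >= tau])
        if not frames:
            return pd.DataFrame(columns=["source_id", "target_id", "rho"])
        return pd.concat(frames, ignore_index=True)

    def total_edges(self) -> int:
        return sum(self.manifest["bin_counts"].values())

    @classmethod
    def from_edges(
        cls,
        root: str | Path,
        node_ids: list[str],
        m: int,
        edges: list[tuple[str, str, float]],
        r_min: float = 0.0,
        sign: str = "positive",
        mode: str = "corr",
        value: float | None = None,
    ) -> "EdgeStore":
        """Build a store from an explicit edge list (e.g. an imported network).

        Pairs are oriented source_id < target_id and must be unique; rho
        values below r_min (in magnitude under the absolute policy) raise.
        """
        known = set(node_ids)
        src, tgt, rho = [], [], []
        seen = set()
        for a, b, r in edges:
            if a == b:
                raise ValueError(f"self-edge on {a}")
            if a not in known or b not in known:
                raise ValueError(f"edge endpoint not in node set: {a}--{b}")
            s, t = (a, b) if a < b else (b, a)
            if (s, t) in seen:
                raise ValueError(f"duplicate edge {s}--{t}")
            seen.add((s, t))
            r = round(float(r), RHO_DECIMALS)
            strength = abs(r) if sign == "absolute" else r
            if strength < r_min:
                raise ValueError(f"edge {s}--{t} rho {r} below r_min {r_min}")
            src.append(s)
            tgt.append(t)
            rho.append(r)
        return _write_store(
            Path(root),
            np.asarray(src, dtype=object),
            np.asarray(tgt, dtype=object),
            np.asarray(rho, dtype=float),
            node_ids=list(node_ids),
            m=m,
            mode=mode,
            value=r_min if value is None else value,
            r_min=float(r_min),
            sign=sign,
        )


def load_edges(store: EdgeStore, tau: float) -> Iterator[Edge]:
    """Iterate edges with rho >= tau (reads only bins intersecting [tau, 1])."""
    df = store.edges_frame(tau)
    for s, t, r in zip(df["source_id"], df["target_id"], df["rho"]):
        yield Edge(s, t, float(r))


def _pair_blocks(chunks: list[np.ndarray], step_size: int):
    """Deterministic schedule of (rows_a, rows_b, same) sub-blocks bounded by
    step_size pair evaluations each."""
    tasks = []
    for ci in range(len(chunks)):
        for cj in range(ci, len(chunks)):
            a, b = chunks[ci], chunks[cj]
            # split the a x b block into row slabs of <= step_size pairs
            rows_per = max(1, step_size // max(1, len(b)))
            for start in range(0, len(a), rows_per):
                tasks.append((a[start : start + rows_per], b, ci == cj))
    return tasks


def _score_block(Z, rows_a, rows_b, same, r_min, sign):
    rho = spearman_block(Z, rows_a, rows_b)
    ia = np.repeat(rows_a, len(rows_b)).reshape(rho.shape)
    ib = np.tile(rows_b, (len(rows_a), 1))
    if same:
        # keep strictly upper-triangular pairs only (global indices)
        mask_ut = ib > ia
    else:
        mask_ut = np.ones_like(rho, dtype=bool)
    vals = np.round(rho, RHO_DECIMALS)
    keep = (np.abs(vals) >= r_min) if sign == "absolute" else (vals >= r_min)
    keep &= mask_ut
    return ia[keep], ib[keep], vals[keep]


def build_network(
    sm,
    tc: ThresholdConfig,
    plan: BatchPlan = BatchPlan(),
    out: str | Path = "edge_store",
) -> EdgeStore:
    """Compute all-pairs Spearman correlations and persist retained edges.

    The result is independent of the batch plan: blocks only partition the
    pair set, every retained pair is emitted exactly once (source_id <
    target_id lexicographically), and bins are sorted before writing.
    """
    if sm.n < 2:
        raise ValueError("need at least 2 regions to build a network")
    if sm.m < 3:
        raise ValueError("need at least 3 samples (df = m - 2 >= 1)")
    if tc.m != sm.m:
        raise ValueError(f"threshold config m = {tc.m} does not match matrix m = {sm.m}")

    ids = np.asarray(sm.region_ids, dtype=object)
    Z = rank_standardize(sm.values, sm.region_ids)
    r_min = tc.r_min

    chunks = [
        np.arange(s, min(s + plan.chunk_size, sm.n))
        for s in range(0, sm.n, plan.chunk_size)
    ]
    tasks = _pair_blocks(chunks, plan.step_size)

    results = Parallel(n_jobs=plan.workers, prefer="threads")(
        delayed(_score_block)(Z, a, b, same, r_min, tc.sign) for a, b, same in tasks
    )

    ia = np.concatenate([r[0] for r in results]) if results else np.array([], dtype=int)
    ib = np.concatenate([r[1] for r in results]) if results else np.array([], dtype=int)
    rho = np.concatenate([r[2] for r in results]) if results else np.array([])

    # orient each pair lexicographically on canonical ids
    id_a, id_b = ids[ia], ids[ib]
    flip = id_a > id_b
    src = np.where(flip, id_b, id_a)
    tgt = np.where(flip, id_a, id_b)

    return _write_store(
        Path(out), src, tgt, rho,
        node_ids=[str(i) for i in ids], m=sm.m,
        mode=tc.mode, value=tc.value, r_min=float(r_min), sign=tc.sign,
    )


def _write_store(root, src, tgt, rho, *, node_ids, m, mode, value, r_min, sign) -> EdgeStore:
    bounds = _bin_bounds(r_min, sign)
    lo0 = bounds[0][0] if bounds else 0.9
    bidx = _bin_index(np.abs(rho), lo0) if len(rho) else np.array([], dtype=int)

    root.mkdir(parents=True, exist_ok=True)
    use_parquet = _parquet_available()
    bin_counts = {}
    for k, (lo, hi) in enumerate(bounds):
        sel = np.flatnonzero(bidx == k)
        df = pd.DataFrame(
            {
                "source_id": src[sel].astype(str) if sel.size else np.array([], dtype=str),
                "target_id": tgt[sel].astype(str) if sel.size else np.array([], dtype=str),
                "rho": rho[sel] if sel.size else np.array([], dtype=float),
            }
        )
        df = df.sort_values(["source_id", "target_id"], kind="mergesort").reset_index(drop=True)
        name = f"edges_{lo:g}_{hi:g}"
        if use_parquet:
            df.to_parquet(root / f"{name}.parquet", index=False)
        else:
            df.to_csv(root / f"{name}.csv", index=False)
        bin_counts[f"{lo:g}_{hi:g}"] = int(len(df))

    manifest = {
        "n": len(node_ids),
        "m": int(m),
        "mode": mode,
        "value": value,
        "r_min": r_min,
        "sign": sign,
        "bins": [[lo, hi] for lo, hi in bounds],
        "bin_counts": bin_counts,
        "node_ids": list(node_ids),
        "format": "parquet" if use_parquet else "csv",
    }
    (root / EdgeStore.MANIFEST).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return EdgeStore(root)


def _parquet_available() -> bool:
    try:
        import pyarrow  # noqa: F401

        return True
    except ImportError:
        return False
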