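"""Bump-hunting detection of differentially methylated regions.

Probes are grouped into position-based clusters (gap threshold within a
chromosome), per-probe exposure coefficients are smoothed within each
cluster, and a region is a maximal run of consecutive probes whose smoothed
coefficients all exceed a genome-wide cutoff in the same direction.  Region
significance comes from a pooled permutation null: the exposure vector is
permuted B times, coefficients are recomputed and smoothed, and every
above-cutoff run area across all permutations forms the null area pool.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_key(c: str) -> int:
    return _CHROM_ORDER.get(str(c).removeprefix("chr"), 100)


def cluster_probes(annot: pd.DataFrame, max_gap_bp: int = 1000) -> pd.DataFrame:
    """Assign probes to maximal position clusters.

    Returns a copy of the annotation sorted by (chromosome, position) with an
    integer ``cluster`` column; a new cluster starts whenever the chromosome
    changes or the gap to the previous probe exceeds ``max_gap_bp``.
    """
    ann = annot.copy()
    ann["_ck"] = ann["chromosome"].map(_chrom_key)
    ann = ann.sort_values(["_ck", "position"], kind="mergesort").drop(columns="_ck")
    dup = ann.duplicated(subset=["chromosome", "position"])
    if dup.any():
        raise ValueError(
            f"duplicate (chromosome, position): {list(ann.index[dup][:5])}"
        )
    chrom = ann["chromosome"].to_numpy()
    pos = ann["position"].to_numpy(int)
    new = np.ones(len(ann), dtype=bool)
    if len(ann) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= max_gap_bp
        new[1:] = ~(same_chrom & close)
    ann["cluster"] = np.cumsum(new) - 1
    return ann


def smooth_coefficients(
    values: np.ndarray,
    method: str = "runmed",
    window: int = 3,
    positions: np.ndarray | None = None,
    span: float = 0.75,
) -> np.ndarray:
    """Smooth one cluster's coefficient vector.

    "runmed" is a running mean over a centered window of ``window`` probes
    with truncated edges; "loess" is a local linear fit on position with
    tricube weights over a ``span`` fraction of the cluster.  Clusters
    smaller than the window pass through unchanged.
    """
    v = np.asarray(values, float)
    m = len(v)
    if method == "runmed":
        if m < window:
            return v.copy()
        h = window // 2
        out = np.empty(m)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        for i in range(m):
            lo, hi = max(0, i - h), min(m, i + h + 1)
            out[i] = (csum[hi] - csum[lo]) / (hi - lo)
        return out
    if method == "loess":
        if m < 3:
            return v.copy()
        if positions is None:
            positions = np.arange(m, dtype=float)
        pos = np.asarray(positions, float)
        k = max(3, math.ceil(span * m))
        out = np.empty(m)
        for i in range(m):
            d = np.abs(pos - pos[i])
            idx = np.argsort(d, kind="mergesort")[:k]
            dmax = d[idx].max()
            w = (1 - (d[idx] / max(dmax, 1e-12)) ** 3) ** 3
            w = np.maximum(w, 1e-9)
            xw = pos[idx]
            X = np.column_stack([np.ones(k), xw - pos[i]])
            W = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(X * W[:, None], v[idx] * W, rcond=None)
            out[i] = coef[0]
        return out
    raise ValueError("method must be 'runmed' or 'loess'")


def smooth_by_cluster(
    values: np.ndarray,
    cluster_ids: np.ndarray,
    method: str = "runmed",
    window: int = 3,
    positions: np.ndarray | None = None,
    span: float = 0.75,
) -> np.ndarray:
    """Apply within-cluster smoothing to a genome-length coefficient vector."""
    v = np.asarray(values, float)
    cl = np.asarray(cluster_ids)
    if method == "runmed":
        # vectorized truncated running mean restricted to same-cluster neighbors
        h = window // 2
        n = len(v)
        num = v.copy()
        den = np.ones(n)
        for off in range(1, h + 1):
            same = cl[off:] == cl[:-off]
            num[off:][same] += v[:-off][same]
            den[off:][same] += 1
            num[:-off][same] += v[off:][same]
            den[:-off][same] += 1
        out = num / den
        # clusters smaller than the window pass through unchanged
        sizes = pd.Series(cl).groupby(cl).transform("size").to_numpy()
        small = sizes < window
        out[small] = v[small]
        return out
    out = np.empty(len(v))
    for c in np.unique(cl):
        sel = cl == c
        pos = None if positions is None else np.asarray(positions)[sel]
        out[sel] = smooth_coefficients(v[sel], method=method, window=window,
                                       positions=pos, span=span)
    return out


def _runs(smoothed: np.ndarray, cluster_ids: np.ndarray, cutoff: float):
    """Maximal same-direction above-cutoff runs: (start_idx, end_idx, sign, area)."""
    cat = np.zeros(len(smoothed), dtype=int)
    cat[smoothed > cutoff] = 1
    cat[smoothed < -cutoff] = -1
    boundary = np.ones(len(smoothed), dtype=bool)
    if len(smoothed) > 1:
        boundary[1:] = (cat[1:] != cat[:-1]) | (cluster_ids[1:] != cluster_ids[:-1])
    run_id = np.cumsum(boundary) - 1
    out = []
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], len(smoothed))
    for s, e in zip(starts, ends):
        if cat[s] == 0:
            continue
        area = float(np.sum(np.abs(smoothed[s:e]) - cutoff))
        out.append((int(s), int(e) - 1, int(cat[s]), area))
    return out


def find_bumps(
    smoothed: np.ndarray,
    annot_clustered: pd.DataFrame,
    cutoff: float | None = None,
    cutoff_quantile: float = 0.99,
    min_probes: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Call candidate regions from smoothed coefficients.

    The cutoff is the ``cutoff_quantile`` of the genome-wide pooled
    |smoothed| values unless given explicitly.  A candidate is a maximal run
    of consecutive same-cluster probes all above +cutoff or all below
    -cutoff, retained if it spans at least ``min_probes`` probes; its area is
    the summed exceedance beyond the cutoff.
    """
    smoothed = np.asarray(smoothed, float)
    if cutoff is None:
        cutoff = float(np.quantile(np.abs(smoothed), cutoff_quantile))
    cl = annot_clustered["cluster"].to_numpy()
    pos = annot_clustered["position"].to_numpy(int)
    chrom = annot_clustered["chromosome"].to_numpy()
    rows = []
    for s, e, sign, area in _runs(smoothed, cl, cutoff):
        n = e - s + 1
        if n < min_probes:
            continue
        rows.append(
            {
                "chromosome": chrom[s],
                "start": int(pos[s]),
                "end": int(pos[e]),
                "n_probes": n,
                "area": area,
                "direction": sign,
                "probe_ids": list(annot_clustered.index[s : e + 1]),
            }
        )
    return pd.DataFrame(rows), cutoff


def _slopes(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    return (Y @ xc) / float((xc**2).sum())


def find_dmrs(
    residuals: pd.DataFrame,
    exposure: np.ndarray,
    annot: pd.DataFrame,
    max_gap_bp: int = 1000,
    method: str = "runmed",
    window: int = 3,
    cutoff_quantile: float = 0.99,
    min_probes: int = 5,
    B: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Full bump-hunting pass: cluster, regress, smooth, call, permute.

    Per-probe coefficients are the (unmoderated) slopes of adjusted
    methylation on the exposure vector.  Each candidate region's
    ``p_perm`` is ``(1 + #null areas >= observed area) / (1 + #null areas)``
    where the null pool collects every above-cutoff run area (any length)
    from ``B`` seeded permutations of the exposure, using the observed cutoff.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ann = cluster_probes(annot.loc[annot.index.intersection(residuals.index)],
                         max_gap_bp=max_gap_bp)
    Y = residuals.loc[ann.index].to_numpy(float)
    x = np.asarray(exposure, float)
    cl = ann["cluster"].to_numpy()
    pos = ann["position"].to_numpy(float)

    obs = smooth_by_cluster(_slopes(Y, x), cl, method=method, window=window,
                            positions=pos)
    regions, cutoff = find_bumps(obs, ann, cutoff_quantile=cutoff_quantile,
                                 min_probes=min_probes)

    rng = np.random.default_rng(seed)
    null_areas = []
    for _ in range(B):
        xp = rng.permutation(x)
        sm = smooth_by_cluster(_slopes(Y, xp), cl, method=method, window=window,
                               positions=pos)
        null_areas.extend(a for *_xx, a in _runs(sm, cl, cutoff))
    null_areas = np.sort(np.asarray(null_areas))
    n_null = len(null_areas)

    if len(regions):
        ge = n_null - np.searchsorted(null_areas, regions["area"].to_numpy(), side="left")
        regions["p_perm"] = (1.0 + ge) / (1.0 + n_null)
        regions = regions.sort_values(
            ["p_perm", "area"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
        regions.index.name = "region_id"
    else:
        regions = pd.DataFrame(
            columns=["chromosome", "start", "end", "n_probes", "area",
                     "direction", "probe_ids", "p_perm"]
        )
    regions.attrs["cutoff"] = cutoff
    regions.attrs["n_null_areas"] = n_null
    return regions


def dmrs_to_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as BED (0-based half-open; score = -log10 p capped at 1000)."""
    with open(path, "w") as fh:
        for rid, row in regions.iterrows():
            score = min(1000.0, -math.log10(max(row["p_perm"], 1e-1000)))
            fh.write(
                f"{row['chromosome']}\t{row['start'] - 1}\t{row['end']}\t"
                f"DMR{rid}\t{score:.4g}\n"
            )
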