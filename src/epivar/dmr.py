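"""Differentially methylated region (DMR) detection.

Two complementary detectors:

* ``strict_dmrs`` clusters retained per-sample DMCpG calls: maximal runs
  of >=2 calls on one chromosome with consecutive inter-probe gaps below
  ``max_gap_bp``.
* ``comb_p_scan`` finds subtler regional signal on a per-probe p-value
  track, in the style of comb-p: estimate the autocorrelation of
  normal-quantile z-scores in 50-bp distance bins, smooth each probe's p
  by a correlation-adjusted Stouffer-Liptak combination of its
  neighbourhood, seed and extend regions where the smoothed p clears a
  nominal threshold, combine raw p-values per region, and Sidak-correct
  for the number of independent windows of that size in the scanned span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DMR",
    "AcfEstimate",
    "strict_dmrs",
    "stouffer_liptak",
    "estimate_acf",
    "comb_p_scan",
    "dmrs_to_bed",
]

_P_EPS = 1e-15  # truncation for normal quantiles


@dataclass
class DMR:
    """A region of >=2 clustered probes.  Coordinates are 0-based
    half-open internally; TSV/BED writers document their own convention."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    sample_id: str | None = None
    mean_delta_beta: float | None = None
    combined_p: float | None = None
    sidak_p: float | None = None
    method: str = "strict"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("DMR end must exceed start")
        if len(self.probe_ids) < 2:
            raise ValueError("a DMR needs >=2 probes")


@dataclass
class AcfEstimate:
    """Correlation of p-value z-scores by inter-probe distance bin.

    ``bins`` holds the upper edge (bp) of each bin; lag 0 has correlation
    1 by definition and distances beyond the last bin correlate 0.
    """

    bin_edges_bp: list[int] = field(default_factory=list)
    correlations: list[float] = field(default_factory=list)

    def corr_at(self, distance_bp: np.ndarray) -> np.ndarray:
        d = np.asarray(distance_bp)
        out = np.zeros(d.shape, dtype=float)
        out[d == 0] = 1.0
        lo = 0
        for edge, corr in zip(self.bin_edges_bp, self.correlations):
            mask = (d > lo) & (d <= edge)
            out[mask] = corr
            lo = edge
        return out


def strict_dmrs(
    calls: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    max_gap_bp: int = 1000,
) -> list[DMR]:
    """Cluster one sample's retained calls into regions.

    ``calls`` needs columns probe_id, delta_beta and either chrom/pos
    columns or an ``annotation`` (probe_id-indexed, chrom/pos) to supply
    them.  Calls must all belong to one sample; a maximal run of >=2
    calls with successive gaps <= ``max_gap_bp`` on the same chromosome
    becomes one DMR.
    """
    if calls.empty:
        return []
    samples = calls["sample_id"].unique() if "sample_id" in calls else ["?"]
    if len(samples) > 1:
        raise ValueError("strict_dmrs expects calls from a single sample")
    df = calls.copy()
    if "chrom" not in df or "pos" not in df:
        if annotation is None:
            raise ValueError("need chrom/pos columns or a probe annotation")
        ann = annotation.reindex(df["probe_id"])
        df["chrom"] = ann["chrom"].to_numpy()
        df["pos"] = ann["pos"].to_numpy()
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    regions: list[DMR] = []
    run: list[int] = []
    for i in range(len(df)):
        if run and (
            df.at[i, "chrom"] != df.at[run[-1], "chrom"]
            or df.at[i, "pos"] - df.at[run[-1], "pos"] > max_gap_bp
        ):
            _flush_run(df, run, regions, samples[0])
            run = []
        run.append(i)
    _flush_run(df, run, regions, samples[0])
    return regions


def _flush_run(df, run, regions, sample_id):
    if len(run) < 2:
        return
    sub = df.iloc[run]
    pos = sub["pos"].to_numpy(dtype=int)
    regions.append(
        DMR(
            chrom=str(sub["chrom"].iloc[0]),
            start=int(pos.min()) - 1,  # 1-based CpG -> 0-based start
            end=int(pos.max()) + 1,  # covers the G of the last CpG
            probe_ids=list(sub["probe_id"]),
            sample_id=str(sample_id),
            mean_delta_beta=float(sub["delta_beta"].mean())
            if "delta_beta" in sub
            else None,
            method="strict",
        )
    )


def stouffer_liptak(
    p: np.ndarray,
    corr: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Correlation-adjusted Stouffer-Liptak combination of p-values.

    z_i = Phi^-1(1 - p_i); combined z = sum(w_i z_i) / sqrt(w' Sigma w)
    with Sigma the correlation matrix scaled by the weights; combined
    p = 1 - Phi(z).  Identity correlation with unit weights is the classic
    Stouffer combination; perfect correlation returns the common p.  A
    non-positive scaled variance falls back to a jittered diagonal.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        p = np.clip(p, _P_EPS, 1.0)
    if p.size == 1:
        return float(p[0])
    k = p.size
    if corr is None:
        corr = np.eye(k)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError("correlation matrix shape mismatch")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if weights is None:
        weights = np.ones(k)
    w = np.asarray(weights, dtype=float)

    z = stats.norm.isf(np.clip(p, _P_EPS, 1 - _P_EPS))
    var = float(w @ corr @ w)
    if var <= 0:  # not positive definite; jitter toward independence
        var = float(w @ (corr + 0.05 * np.eye(k)) @ w)
        if var <= 0:
            var = float(w @ w)
    zc = float(w @ z) / np.sqrt(var)
    return float(stats.norm.sf(zc))


def estimate_acf(
    p: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    max_lag_bp: int = 1000,
    bin_bp: int = 50,
    min_pairs: int = 10,
) -> AcfEstimate:
    """Estimate the distance-binned autocorrelation of z = Phi^-1(1-p).

    Pairs of probes are pooled across chromosomes into distance bins
    (0, bin], (bin, 2*bin], ...; each bin's Pearson correlation is clipped
    to [-1, 1] and bins with fewer than ``min_pairs`` pairs fall back to 0.
    """
    p = np.asarray(p, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if chroms is None:
        chroms = np.zeros(p.shape, dtype=int)
    chroms = np.asarray(chroms)
    z = stats.norm.isf(np.clip(p, _P_EPS, 1 - _P_EPS))

    edges = list(range(bin_bp, max_lag_bp + 1, bin_bp))
    pairs_x: list[list[float]] = [[] for _ in edges]
    pairs_y: list[list[float]] = [[] for _ in edges]
    order = np.lexsort((positions, chroms.astype(str)))
    zs, ps_, cs = z[order], positions[order], chroms[order]
    n = len(zs)
    for i in range(n):
        j = i + 1
        while j < n and cs[j] == cs[i] and ps_[j] - ps_[i] <= max_lag_bp:
            d = int(ps_[j] - ps_[i])
            if d > 0:
                b = (d - 1) // bin_bp
                if b < len(edges):
                    pairs_x[b].append(zs[i])
                    pairs_y[b].append(zs[j])
            j += 1

    corrs = []
    for bx, by in zip(pairs_x, pairs_y):
        if len(bx) < min_pairs:
            corrs.append(0.0)
            continue
        cx = np.asarray(bx) - np.mean(bx)
        cy = np.asarray(by) - np.mean(by)
        denom = np.sqrt((cx @ cx) * (cy @ cy))
        corrs.append(float(np.clip(cx @ cy / denom, -1.0, 1.0)) if denom > 0 else 0.0)
    return AcfEstimate(bin_edges_bp=edges, correlations=corrs)


def comb_p_scan(
    probe_p: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    seed_p: float = 0.01,
    window_bp: int = 1000,
    acf_bin_bp: int = 50,
    sample_id: str | None = None,
    acf: AcfEstimate | None = None,
    probe_ids: np.ndarray | None = None,
) -> list[DMR]:
    """Sliding-window correlation-adjusted scan of a p-value track.

    Steps: (1) estimate the z-score ACF in ``acf_bin_bp`` distance bins up
    to ``window_bp``; (2) smooth each probe's p by Stouffer-Liptak over
    its neighbours within ``window_bp``; (3) seed regions where the
    smoothed p < ``seed_p`` and extend over consecutive sub-threshold
    probes within ``window_bp`` of each other, keeping regions of >=2
    probes; (4) combine each region's raw p-values by Stouffer-Liptak;
    (5) Sidak-correct for the number of independent windows
    (scanned span / region span).
    """
    p = np.asarray(probe_p, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if chroms is None:
        chroms = np.array(["chr?"] * len(p))
    chroms = np.asarray(chroms).astype(str)
    if not (len(p) == len(positions) == len(chroms)):
        raise ValueError("probe_p, positions and chroms must align")
    if len(p) == 0:
        return []

    if acf is None:
        acf = estimate_acf(p, positions, chroms, max_lag_bp=window_bp, bin_bp=acf_bin_bp)

    # correlations below zero destabilise the combination; use them only
    # as independence (comb-p clips the same way)
    acf_clipped = AcfEstimate(
        acf.bin_edges_bp, [max(0.0, c) for c in acf.correlations]
    )

    order = np.lexsort((positions, chroms))
    total_span = 0
    regions: list[DMR] = []
    if probe_ids is None:
        probe_index = np.array([f"idx{k}" for k in range(len(p))])
    else:
        probe_index = np.asarray(probe_ids).astype(str)
    for chrom in pd.unique(chroms[order]):
        sel = order[chroms[order] == chrom]
        pos_c = positions[sel]
        p_c = p[sel]
        idx_c = probe_index[sel]
        total_span += int(pos_c.max() - pos_c.min()) + 1

        smoothed = np.empty_like(p_c)
        for i in range(len(p_c)):
            lo = np.searchsorted(pos_c, pos_c[i] - window_bp, side="left")
            hi = np.searchsorted(pos_c, pos_c[i] + window_bp, side="right")
            pw = p_c[lo:hi]
            dw = np.abs(pos_c[lo:hi][:, None] - pos_c[lo:hi][None, :])
            corr = acf_clipped.corr_at(dw)
            np.fill_diagonal(corr, 1.0)
            smoothed[i] = stouffer_liptak(pw, corr)

        below = smoothed < seed_p
        i = 0
        while i < len(p_c):
            if not below[i]:
                i += 1
                continue
            j = i
            while (
                j + 1 < len(p_c)
                and below[j + 1]
                and pos_c[j + 1] - pos_c[j] <= window_bp
            ):
                j += 1
            if j > i:  # >=2 probes
                member = slice(i, j + 1)
                pw = p_c[member]
                dw = np.abs(
                    pos_c[member][:, None] - pos_c[member][None, :]
                )
                corr = acf_clipped.corr_at(dw)
                np.fill_diagonal(corr, 1.0)
                combined = stouffer_liptak(pw, corr)
                regions.append(
                    DMR(
                        chrom=str(chrom),
                        start=int(pos_c[member][0]) - 1,
                        end=int(pos_c[member][-1]) + 1,
                        probe_ids=list(idx_c[member]),
                        sample_id=sample_id,
                        combined_p=combined,
                        method="combined",
                    )
                )
            i = j + 1

    for r in regions:
        span = max(r.end - r.start, 1)
        n_windows = max(total_span / span, 1.0)
        r.sidak_p = float(1.0 - (1.0 - min(r.combined_p, 1.0)) ** n_windows)
    return regions


def dmrs_to_bed(regions: list[DMR]) -> pd.DataFrame:
    """BED frame (0-based half-open): chrom, start, end, name, score.

    Name is ``sample:method``; score is -10*log10 of the combined p
    (0 for strict regions without one).
    """
    rows = []
    for r in regions:
        if r.combined_p is not None and r.combined_p > 0:
            score = -10.0 * np.log10(r.combined_p)
        else:
            score = 0.0
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "name": f"{r.sample_id or '.'}:{r.method}",
                "score": round(float(score), 3),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
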