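"""Genetic/epigenetic classification of calls and cis-expression linkage.

A retained DMCpG call can be explained by a known rare variant sitting on
the CG dinucleotide (meSNP), by a candidate sequence variant yet to be
confirmed by sequencing (meSNV candidate), or — when it sits inside a
clustered region with no underlying variant — by a pure epimutation.

Expression integration scores each call's cis genes (annotated span
intersecting +/-50 kb around the CpG) by cohort Z-score of the calling
sample and flags a locus as altered when one gene exceeds |z| > 2 or at
least two genes in the window each exceed |z| > 1.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "MeClassification",
    "classify_call",
    "classify_calls",
    "recurrent_calls",
    "cis_genes",
    "expression_zscore",
    "link_dm_expression",
    "ExpressionOutlierLinker",
    "expression_effect_fractions",
]

RARE_MAF = 0.005


@dataclass
class MeClassification:
    """Assigned mechanism for one (probe, sample) call."""

    probe_id: str
    sample_id: str
    klass: str  # meSNP_known | meSNV_candidate | epimutation
    snp_id: str | None = None
    snp_maf: float | None = None


def _snp_at_cg(probe_chrom, probe_pos, snp_table: pd.DataFrame) -> pd.DataFrame:
    """Catalogued variants on the CG dinucleotide (pos or pos+1)."""
    if snp_table is None or snp_table.empty:
        return pd.DataFrame(columns=["snp_id", "chrom", "pos", "maf"])
    hit = snp_table[
        (snp_table["chrom"] == probe_chrom)
        & snp_table["pos"].isin([probe_pos, probe_pos + 1])
    ]
    return hit


def classify_call(
    call: pd.Series,
    snp_table: pd.DataFrame | None,
    dmr_set: list | None = None,
) -> MeClassification:
    """Classify one call as meSNP_known / epimutation / meSNV_candidate.

    A known variant at the CG with MAF < 0.005 makes the call genetic
    (meSNP_known).  A call inside a region of ``dmr_set`` with no
    underlying variant defaults to epimutation.  Everything else is a
    meSNV candidate awaiting sequencing.  A CG variant with MAF >= 0.005
    contradicts upstream QC and raises a consistency warning.
    """
    probe = str(call["probe_id"])
    sample = str(call["sample_id"])
    chrom = call.get("chrom")
    pos = call.get("pos")
    hits = (
        _snp_at_cg(chrom, int(pos), snp_table)
        if chrom is not None and pos is not None and not pd.isna(pos)
        else pd.DataFrame(columns=["snp_id", "maf"])
    )
    if len(hits):
        best = hits.sort_values("maf").iloc[0]
        if float(best["maf"]) < RARE_MAF:
            return MeClassification(
                probe, sample, "meSNP_known", str(best["snp_id"]), float(best["maf"])
            )
        warnings.warn(
            f"probe {probe}: SNP {best['snp_id']} at the CG has MAF "
            f"{best['maf']:.3g} >= {RARE_MAF}; probe should have been "
            "removed by QC",
            stacklevel=2,
        )
    in_dmr = False
    for r in dmr_set or []:
        if probe in r.probe_ids and (r.sample_id is None or r.sample_id == sample):
            in_dmr = True
            break
    if in_dmr:
        return MeClassification(probe, sample, "epimutation")
    return MeClassification(probe, sample, "meSNV_candidate")


def classify_calls(
    calls: pd.DataFrame,
    snp_table: pd.DataFrame | None,
    dmr_set: list | None = None,
) -> pd.DataFrame:
    """Vector version of :func:`classify_call`; one row per call."""
    rows = []
    for _, call in calls.iterrows():
        c = classify_call(call, snp_table, dmr_set)
        rows.append(
            {
                "probe_id": c.probe_id,
                "sample_id": c.sample_id,
                "class": c.klass,
                "snp_id": c.snp_id or "",
                "snp_maf": c.snp_maf if c.snp_maf is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["probe_id", "sample_id", "class", "snp_id", "snp_maf"]
    )


def recurrent_calls(calls: pd.DataFrame) -> dict[str, list[str]]:
    """Probes called in >=2 distinct case samples -> their sample lists."""
    if calls.empty:
        return {}
    grouped = calls.groupby("probe_id")["sample_id"].agg(lambda s: sorted(set(s)))
    return {probe: samples for probe, samples in grouped.items() if len(samples) >= 2}


def cis_genes(
    chrom: str,
    pos: int,
    gene_annotation: pd.DataFrame,
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Genes whose span intersects [pos - window, pos + window].

    ``gene_annotation`` columns: chrom, start, end (0-based half-open),
    gene_id.  Strand-agnostic; result is sorted by distance from the CpG
    (0 when the gene body covers it).
    """
    g = gene_annotation
    sel = g[
        (g["chrom"] == chrom)
        & (g["start"] < pos + window_bp)  # half-open span vs closed window
        & (g["end"] > pos - window_bp)
    ].copy()
    if sel.empty:
        sel["distance"] = pd.Series(dtype=int)
        return sel
    dist = np.where(
        (sel["start"] <= pos) & (pos < sel["end"]),
        0,
        np.minimum(np.abs(sel["start"] - pos), np.abs(sel["end"] - 1 - pos)),
    )
    sel["distance"] = dist.astype(int)
    return sel.sort_values(["distance", "gene_id"], kind="stable").reset_index(drop=True)


def expression_zscore(
    gene: str,
    sample: str,
    expr_matrix: pd.DataFrame,
    leave_one_out: bool = False,
) -> float:
    """Cohort Z-score of one sample's expression for one gene.

    z = (x - cohort mean) / cohort sd (ddof=1).  The cohort includes the
    sample itself unless ``leave_one_out``.  A zero sd raises ValueError.
    """
    row = expr_matrix.loc[gene]
    x = float(row[sample])
    if leave_one_out:
        cohort = row.drop(sample).to_numpy(dtype=float)
    else:
        cohort = row.to_numpy(dtype=float)
    sd = float(np.std(cohort, ddof=1))
    if sd == 0:
        raise ValueError(f"gene {gene!r}: zero expression variance, z undefined")
    return (x - float(np.mean(cohort))) / sd


class ExpressionOutlierLinker(BaseEstimator):
    """Cohort Z-score scorer for cis-expression effects of DMCpG calls.

    Fit on a genes x samples expression matrix (learns per-gene cohort
    mean/sd and an expressed-in-cohort mask); transform a call table into
    per-(call, gene) expression links.

    Parameters
    ----------
    z_main : float
        |z| threshold for a single altered gene (default 2.0).
    z_two_gene : float
        relaxed |z| threshold when >=2 genes in the same cis window are
        altered together (default 1.5).
    cis_window_bp : int
        half-width of the cis window around the CpG (default 50 kb).
    min_expressed_fraction : float
        a gene counts as expressed when nonzero in at least this fraction
        of cohort samples (default 0.5).
    leave_one_out : bool
        exclude the scored sample from its own cohort moments.
    """

    def __init__(
        self,
        z_main: float = 2.0,
        z_two_gene: float = 1.5,
        cis_window_bp: int = 50_000,
        min_expressed_fraction: float = 0.5,
        leave_one_out: bool = False,
    ):
        self.z_main = z_main
        self.z_two_gene = z_two_gene
        self.cis_window_bp = cis_window_bp
        self.min_expressed_fraction = min_expressed_fraction
        self.leave_one_out = leave_one_out

    def fit(self, X: pd.DataFrame, y=None):
        """X: genes x samples expression matrix (nonnegative)."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expression matrix must be a DataFrame")
        self.expr_ = X.astype(float)
        frac_nonzero = (self.expr_ > 0).mean(axis=1)
        self.expressed_ = frac_nonzero >= self.min_expressed_fraction
        self.mean_ = self.expr_.mean(axis=1)
        self.sd_ = self.expr_.std(axis=1, ddof=1)
        return self

    def transform(self, calls: pd.DataFrame, gene_annotation: pd.DataFrame) -> pd.DataFrame:
        """Score every cis gene of every call; returns the link table.

        Output columns: probe_id, sample_id, gene_id, distance, z_score,
        altered, direction.  Genes absent from the expression matrix or
        below the expressed floor are skipped; genes with zero variance
        are skipped with a log entry.
        """
        if not hasattr(self, "expr_"):
            raise RuntimeError("linker is not fitted")
        rows = []
        for _, call in calls.iterrows():
            sample = str(call["sample_id"])
            if sample not in self.expr_.columns:
                continue
            genes = cis_genes(
                call["chrom"], int(call["pos"]), gene_annotation, self.cis_window_bp
            )
            scored = []
            for _, g in genes.iterrows():
                gid = str(g["gene_id"])
                if gid not in self.expr_.index or not bool(self.expressed_.get(gid)):
                    continue
                try:
                    z = expression_zscore(
                        gid, sample, self.expr_, leave_one_out=self.leave_one_out
                    )
                except ValueError as exc:
                    logger.info("skipping gene: %s", exc)
                    continue
                scored.append((gid, int(g["distance"]), z))
            n_relaxed = sum(1 for _, _, z in scored if abs(z) > self.z_two_gene)
            for gid, dist, z in scored:
                altered = abs(z) > self.z_main or (
                    n_relaxed >= 2 and abs(z) > self.z_two_gene
                )
                rows.append(
                    {
                        "probe_id": str(call["probe_id"]),
                        "sample_id": sample,
                        "gene_id": gid,
                        "distance": dist,
                        "z_score": float(z),
                        "altered": bool(altered),
                        "direction": "over" if z > 0 else "under",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "probe_id",
                "sample_id",
                "gene_id",
                "distance",
                "z_score",
                "altered",
                "direction",
            ],
        )


def link_dm_expression(
    calls: pd.DataFrame,
    expr_matrix: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    z_main: float = 2.0,
    z_two_gene: float = 1.5,
    cis_window_bp: int = 50_000,
    min_expressed_fraction: float = 0.5,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Functional wrapper over :class:`ExpressionOutlierLinker`."""
    linker = ExpressionOutlierLinker(
        z_main=z_main,
        z_two_gene=z_two_gene,
        cis_window_bp=cis_window_bp,
        min_expressed_fraction=min_expressed_fraction,
        leave_one_out=leave_one_out,
    )
    return linker.fit(expr_matrix).transform(calls, gene_annotation)


def expression_effect_fractions(links: pd.DataFrame, n_calls_tested: int) -> dict:
    """Altered-locus fractions under both candidate denominators.

    The natural denominator is the number of loci with at least one
    expressed cis gene; the fraction over all tested calls is reported
    alongside because either reading of "fraction of loci" is defensible.
    """
    if links.empty:
        return {
            "n_loci_with_expressed_gene": 0,
            "n_loci_altered": 0,
            "fraction_of_expressed_loci": float("nan"),
            "fraction_of_tested_calls": float("nan") if n_calls_tested == 0 else 0.0,
        }
    loci = links.groupby(["probe_id", "sample_id"])["altered"].any()
    n_loci = int(len(loci))
    n_alt = int(loci.sum())
    return {
        "n_loci_with_expressed_gene": n_loci,
        "n_loci_altered": n_alt,
        "fraction_of_expressed_loci": n_alt / n_loci if n_loci else float("nan"),
        "fraction_of_tested_calls": n_alt / n_calls_tested if n_calls_tested else float("nan"),
    }
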