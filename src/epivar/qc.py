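"""Probe-level quality control before differential-methylation analysis.

Three exclusion rules, applied in a fixed order so each removed probe is
counted once under the first rule that triggers:

1. detection: probe fails detection (p > 0.01) in more than 5% of samples;
2. cross-reactive: probe flagged as cross-hybridising in the annotation;
3. SNP: a known polymorphism with MAF > 0.005 within +/-5 nt of the CpG.

All thresholds are strict inequalities.  Offsets are measured in nt from
the C of the 1-based CpG position (the G is offset +1, so offsets 0 and 1
both sit on the dinucleotide); a SNP is inside the window iff
|offset| <= 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "filter_detection",
    "filter_cross_reactive",
    "filter_snp_probes",
    "parse_snp_overlap",
    "snp_overlaps_from_table",
    "run_qc",
]


@dataclass
class QCReport:
    """Funnel counts for one QC run."""

    n_input_probes: int
    n_removed_detection: int = 0
    n_removed_crossreactive: int = 0
    n_removed_snp: int = 0
    removed_probe_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_surviving(self) -> int:
        return (
            self.n_input_probes
            - self.n_removed_detection
            - self.n_removed_crossreactive
            - self.n_removed_snp
        )

    def to_dict(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_removed_detection": self.n_removed_detection,
            "n_removed_crossreactive": self.n_removed_crossreactive,
            "n_removed_snp": self.n_removed_snp,
            "n_surviving": self.n_surviving,
        }


def filter_detection(
    detection_p: pd.DataFrame,
    p_threshold: float = 0.01,
    max_fail_fraction: float = 0.05,
) -> pd.Index:
    """Probes failing detection (p > threshold) in a strict majority of
    more than ``max_fail_fraction`` of samples are removed; the surviving
    probe index is returned."""
    if detection_p.ndim != 2:
        raise ValueError("detection_p must be a probes x samples matrix")
    fail_frac = (detection_p.to_numpy() > p_threshold).mean(axis=1)
    keep = fail_frac <= max_fail_fraction  # removed iff strictly greater
    return detection_p.index[keep]


def filter_cross_reactive(annotation: pd.DataFrame) -> pd.Index:
    """Drop probes flagged ``cross_reactive`` (truthy) in the annotation."""
    flag = annotation.get("cross_reactive")
    if flag is None:
        return annotation.index
    return annotation.index[~flag.astype(bool).to_numpy()]


def parse_snp_overlap(cell: str | float) -> list[tuple[int, float]]:
    """Parse ``"offset:maf;offset:maf"`` annotation cells."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    out = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        off, maf = part.split(":")
        out.append((int(off), float(maf)))
    return out


def filter_snp_probes(
    annotation: pd.DataFrame,
    maf_threshold: float = 0.005,
    window_nt: int = 5,
) -> pd.Index:
    """Remove probes with a SNP of MAF strictly above ``maf_threshold``
    within ``|offset| <= window_nt`` of the CpG (offsets 0/1 are the
    dinucleotide itself; negative offsets are upstream of the C)."""
    keep = []
    overlaps = annotation.get("snp_overlap")
    for probe in annotation.index:
        removed = False
        if overlaps is not None:
            for off, maf in parse_snp_overlap(overlaps.loc[probe]):
                if abs(off) <= window_nt and maf > maf_threshold:
                    removed = True
                    break
        if not removed:
            keep.append(probe)
    return pd.Index(keep, name=annotation.index.name)


def snp_overlaps_from_table(
    annotation: pd.DataFrame,
    snp_table: pd.DataFrame,
    window_nt: int = 5,
) -> pd.DataFrame:
    """Fill the ``snp_overlap`` column by position intersection with a
    VCF-like table (columns chrom, pos, maf); offsets are snp_pos - cpg_pos."""
    ann = annotation.copy()
    cells = {p: [] for p in ann.index}
    for _, snp in snp_table.iterrows():
        near = ann[
            (ann["chrom"] == snp["chrom"])
            & (ann["pos"] - window_nt <= snp["pos"])
            & (snp["pos"] <= ann["pos"] + window_nt)
        ]
        for probe in near.index:
            off = int(snp["pos"] - ann.at[probe, "pos"])
            cells[probe].append(f"{off}:{float(snp['maf'])}")
    existing = ann.get("snp_overlap")
    merged = []
    for p in ann.index:
        prior = "" if existing is None else str(existing.loc[p] or "")
        parts = [s for s in ([prior] if prior and prior != "nan" else []) + cells[p] if s]
        merged.append(";".join(parts))
    ann["snp_overlap"] = merged
    return ann


def run_qc(
    detection_p: pd.DataFrame,
    annotation: pd.DataFrame,
    beta_index: pd.Index | None = None,
    p_threshold: float = 0.01,
    max_fail_fraction: float = 0.05,
    maf_threshold: float = 0.005,
    window_nt: int = 5,
) -> tuple[pd.Index, QCReport]:
    """Apply all QC rules in fixed order: detection, cross-reactive, SNP.

    Returns the surviving probe index (in input order) and a report whose
    per-rule counts attribute each removed probe to the first rule that
    removed it.  Idempotent: re-running on survivors removes nothing.
    """
    if beta_index is not None and not detection_p.index.equals(beta_index):
        raise ValueError("detection matrix and beta matrix probe sets differ")
    probes = detection_p.index
    ann = annotation.reindex(probes)

    after_det = filter_detection(detection_p, p_threshold, max_fail_fraction)
    removed_det = probes.difference(after_det, sort=False)

    after_xr = filter_cross_reactive(ann.loc[after_det])
    removed_xr = after_det.difference(after_xr, sort=False)

    after_snp = filter_snp_probes(ann.loc[after_xr], maf_threshold, window_nt)
    removed_snp = after_xr.difference(after_snp, sort=False)

    report = QCReport(
        n_input_probes=len(probes),
        n_removed_detection=len(removed_det),
        n_removed_crossreactive=len(removed_xr),
        n_removed_snp=len(removed_snp),
        removed_probe_ids={
            "detection": list(removed_det),
            "cross_reactive": list(removed_xr),
            "snp": list(removed_snp),
        },
    )
    surviving = probes[probes.isin(after_snp)]
    return surviving, report
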