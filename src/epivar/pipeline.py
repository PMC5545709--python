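"""End-to-end orchestration: QC -> per-sample outlier calling -> DMRs ->
classification -> cis-expression linkage -> association, with a flat
config, per-stage logging and a machine-readable run report.

Every stage is a pure function of its inputs plus the config, so a rerun
with the same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import associate
from .dmr import comb_p_scan, dmrs_to_bed, strict_dmrs
from .integrate import (
    classify_calls,
    expression_effect_fractions,
    link_dm_expression,
    recurrent_calls,
)
from .outlier import DMCpGCaller
from .qc import run_qc, snp_overlaps_from_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize_direction"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Every threshold defaults to the analysis' published operating point;
    the config round-trips through YAML unchanged.
    """

    beta: str = "beta.tsv"
    detection: str = "detection.tsv"
    annotation: str = "probes.tsv"
    controls: str = "controls.txt"
    panel: str | None = "panel.tsv"
    expression: str | None = "expression.tsv"
    genes: str | None = "genes.bed"
    snps: str | None = "snps.tsv"
    variants: str | None = "variants.tsv"
    extended_controls: str | None = None
    out_dir: str = "epivar_out"

    q_max: float = 0.01
    delta_min: float = 0.18
    delta_min_pass2: float = 0.15
    panel_freq_max: float = 0.005
    detection_p_threshold: float = 0.01
    detection_max_fail_fraction: float = 0.05
    snp_maf_threshold: float = 0.005
    snp_window_nt: int = 5
    max_gap_bp: int = 1000
    window_bp: int = 1000
    seed_p: float = 0.01
    acf_bin_bp: int = 50
    z_main: float = 2.0
    z_two_gene: float = 1.5
    cis_window_bp: int = 50_000
    fdr_method: str = "bh"
    run_comb_p: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Per-stage counts, timings and a config echo."""

    config: dict
    versions: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    calls_per_sample: dict = field(default_factory=dict)
    candidates_per_sample: dict = field(default_factory=dict)
    n_calls: int = 0
    n_candidates: int = 0
    n_strict_dmrs: int = 0
    n_comb_p_dmrs: int = 0
    n_recurrent_probes: int = 0
    n_links: int = 0
    n_links_altered: int = 0
    expression_fractions: dict = field(default_factory=dict)
    n_assoc_variants: int = 0
    n_assoc_significant: int = 0
    fraction_hypomethylated_pct: float | None = None
    stage_seconds: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_calls > self.n_candidates:
            raise AssertionError("retained calls exceed candidates")
        if sum(self.calls_per_sample.values()) != self.n_calls:
            raise AssertionError("per-sample call counts do not reconcile")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def summarize_direction(calls: pd.DataFrame) -> float | None:
    """Fraction of retained calls with negative delta-beta, as a percent
    rounded to 1 dp; None (reported NA) for an empty call set."""
    if calls is None or len(calls) == 0:
        return None
    frac = float((calls["delta_beta"] < 0).mean())
    return round(100.0 * frac, 1)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # surface file context on parse failures
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: no columns parsed")
    return df


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage on the files named in ``config``.

    Writes calls.tsv, dmrs.bed / dmrs.tsv, classification.tsv, links.tsv,
    assoc.tsv, qc_report.json and report.json under ``config.out_dir`` and
    returns the report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), versions=_versions())
    t0 = time.time()

    beta = _read_matrix(config.beta)
    detection = _read_matrix(config.detection)
    annotation = pd.read_csv(config.annotation, sep="\t", index_col=0)
    control_ids = [
        s.strip() for s in Path(config.controls).read_text().splitlines() if s.strip()
    ]
    missing = [c for c in control_ids if c not in beta.columns]
    if missing:
        raise ValueError(f"control samples missing from beta matrix: {missing}")
    if not beta.index.equals(detection.index) or not beta.columns.equals(
        detection.columns
    ):
        raise ValueError("beta and detection matrices are not aligned")
    case_ids = [c for c in beta.columns if c not in control_ids]
    panel = _read_matrix(config.panel) if config.panel else None
    extended = (
        _read_matrix(config.extended_controls) if config.extended_controls else None
    )
    report.stage_seconds["read"] = round(time.time() - t0, 3)

    # ---- QC ----------------------------------------------------------
    t0 = time.time()
    if config.snps:
        snp_table = pd.read_csv(config.snps, sep="\t")
        annotation = snp_overlaps_from_table(
            annotation, snp_table, window_nt=config.snp_window_nt
        )
    else:
        snp_table = None
    surviving, qc_report = run_qc(
        detection,
        annotation,
        beta_index=beta.index,
        p_threshold=config.detection_p_threshold,
        max_fail_fraction=config.detection_max_fail_fraction,
        maf_threshold=config.snp_maf_threshold,
        window_nt=config.snp_window_nt,
    )
    report.qc = qc_report.to_dict()
    logger.info(
        "QC: %d probes in, removed %d detection / %d cross-reactive / %d SNP, %d kept",
        qc_report.n_input_probes,
        qc_report.n_removed_detection,
        qc_report.n_removed_crossreactive,
        qc_report.n_removed_snp,
        qc_report.n_surviving,
    )
    (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2))
    beta_qc = beta.loc[surviving]
    panel_qc = panel.loc[surviving] if panel is not None else None
    report.stage_seconds["qc"] = round(time.time() - t0, 3)

    # ---- per-sample outlier calling ---------------------------------
    t0 = time.time()
    caller = DMCpGCaller(
        q_max=config.q_max,
        delta_min=config.delta_min,
        delta_min_pass2=config.delta_min_pass2,
        panel_freq_max=config.panel_freq_max,
    )
    caller.fit(
        beta_qc[control_ids].T,
        panel=panel_qc,
        extended_controls=None if extended is None else extended.loc[surviving].T,
        annotation=annotation,
    )
    candidates = caller.predict(beta_qc[case_ids].T, keep_candidates=True)
    calls = candidates[candidates["retained"]].reset_index(drop=True)
    report.n_candidates = int(len(candidates))
    report.n_calls = int(len(calls))
    report.candidates_per_sample = {
        s: int((candidates["sample_id"] == s).sum()) for s in case_ids
    }
    report.calls_per_sample = {s: int((calls["sample_id"] == s).sum()) for s in case_ids}
    report.fraction_hypomethylated_pct = summarize_direction(calls)
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    logger.info(
        "calling: %d candidates, %d retained calls across %d case samples",
        report.n_candidates,
        report.n_calls,
        len(case_ids),
    )
    report.stage_seconds["calling"] = round(time.time() - t0, 3)

    # ---- DMRs --------------------------------------------------------
    t0 = time.time()
    all_dmrs = []
    for s in case_ids:
        sample_calls = calls[calls["sample_id"] == s]
        if len(sample_calls):
            all_dmrs.extend(
                strict_dmrs(sample_calls, annotation, max_gap_bp=config.max_gap_bp)
            )
    if config.run_comb_p:
        ann_qc = annotation.loc[surviving]
        case_p = _per_sample_p(caller, beta_qc, case_ids)
        for s in case_ids:
            regions = comb_p_scan(
                case_p[s],
                ann_qc["pos"].to_numpy(),
                ann_qc["chrom"].to_numpy(),
                seed_p=config.seed_p,
                window_bp=config.window_bp,
                acf_bin_bp=config.acf_bin_bp,
                sample_id=s,
                probe_ids=ann_qc.index.to_numpy(),
            )
            all_dmrs.extend(r for r in regions if r.sidak_p is not None and r.sidak_p < 0.05)
    strict = [r for r in all_dmrs if r.method == "strict"]
    combined = [r for r in all_dmrs if r.method == "combined"]
    report.n_strict_dmrs = len(strict)
    report.n_comb_p_dmrs = len(combined)
    dmrs_to_bed(all_dmrs).to_csv(out / "dmrs.bed", sep="\t", index=False, header=False)
    _dmr_table(all_dmrs).to_csv(out / "dmrs.tsv", sep="\t", index=False)
    report.stage_seconds["dmr"] = round(time.time() - t0, 3)

    # ---- classification + recurrence --------------------------------
    t0 = time.time()
    classification = classify_calls(calls, snp_table, all_dmrs)
    classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    recurrent = recurrent_calls(calls)
    report.n_recurrent_probes = len(recurrent)
    pd.DataFrame(
        [(probe, ";".join(samples)) for probe, samples in sorted(recurrent.items())],
        columns=["probe_id", "sample_ids"],
    ).to_csv(out / "recurrent.tsv", sep="\t", index=False)
    report.stage_seconds["classify"] = round(time.time() - t0, 3)

    # ---- cis-expression linkage -------------------------------------
    t0 = time.time()
    if config.expression and config.genes:
        expr = _read_matrix(config.expression)
        genes = pd.read_csv(
            config.genes,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "gene_id"],
        )
        links = link_dm_expression(
            calls,
            expr,
            genes,
            z_main=config.z_main,
            z_two_gene=config.z_two_gene,
            cis_window_bp=config.cis_window_bp,
        )
        links.to_csv(out / "links.tsv", sep="\t", index=False)
        report.n_links = int(len(links))
        report.n_links_altered = int(links["altered"].sum()) if len(links) else 0
        n_tested = int(len(calls[calls["sample_id"].isin(expr.columns)]))
        report.expression_fractions = expression_effect_fractions(links, n_tested)
    report.stage_seconds["expression"] = round(time.time() - t0, 3)

    # ---- association -------------------------------------------------
    t0 = time.time()
    if config.variants:
        variants = pd.read_csv(config.variants, sep="\t")
        assoc_results = associate(variants, fdr_method=config.fdr_method)
        assoc_results.to_csv(out / "assoc.tsv", sep="\t", index=False)
        report.n_assoc_variants = int(len(assoc_results))
        report.n_assoc_significant = int((assoc_results["q_value"] < 0.05).sum())
    report.stage_seconds["assoc"] = round(time.time() - t0, 3)

    report.to_json(out / "report.json")
    return report


def _per_sample_p(caller: DMCpGCaller, beta_qc: pd.DataFrame, case_ids) -> dict:
    """Raw per-probe moderated p-value track for each case sample."""
    out = {}
    for s in case_ids:
        _, p, _ = caller._stats_for_case(beta_qc[s].to_numpy(dtype=float))
        out[s] = p
    return out


def _dmr_table(regions) -> pd.DataFrame:
    """1-based inclusive coordinates, documented in the header names."""
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start_1based": r.start + 1,
                "end_1based": r.end,
                "sample_id": r.sample_id or "",
                "n_probes": len(r.probe_ids),
                "probe_ids": ";".join(map(str, r.probe_ids)),
                "mean_delta_beta": r.mean_delta_beta,
                "combined_p": r.combined_p,
                "sidak_p": r.sidak_p,
                "method": r.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_1based",
            "end_1based",
            "sample_id",
            "n_probes",
            "probe_ids",
            "mean_delta_beta",
            "combined_p",
            "sidak_p",
            "method",
        ],
    )


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "epivar": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
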