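"""Seeded synthetic methylation-study generator.

Emulates the statistical structure a per-individual epimutation screen
assumes on real 450K-style data: per-probe Beta-distributed control
beta-values in three archetypes (hypomethylated ~0.1, intermediate ~0.5,
hypermethylated ~0.85), rare heterozygous CG-destroying variants (meSNVs)
that pull hypermethylated probes into the intermediate 0.3-0.6 range,
clustered hypermethylation epimutations spanning consecutive probes,
log-scale expression with multiplicative cis effects in carriers, and
binomial allele counts at given case/control minor-allele frequencies.

Every generated signal is recorded in a :class:`TruthRecord` so downstream
recovery can be scored without external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbeArchetype",
    "TruthRecord",
    "BetaMatrix",
    "StudyConfig",
    "SyntheticStudy",
    "DEFAULT_ARCHETYPES",
    "simulate_control_betas",
    "betas_for_assignment",
    "spike_mesnv",
    "spike_dmr",
    "revert_spike",
    "simulate_expression",
    "simulate_allele_counts",
    "simulate_probe_annotation",
    "simulate_study",
]

#: Background beta of a fully unmethylated allele (array noise floor).
BACKGROUND_BETA = 0.05


@dataclass(frozen=True)
class ProbeArchetype:
    """One of the three canonical probe behaviours on a methylation array.

    Parameters
    ----------
    name : str
        ``"hypo"``, ``"intermediate"`` or ``"hyper"``.
    mean_beta : float
        Cross-sample mean methylation fraction, strictly inside (0, 1).
        Archetype means respect the status bins (hypo < 0.3, hyper > 0.7).
    concentration : float
        Beta-distribution concentration ``a + b``; larger means tighter
        probes.  Extreme (hypo/hyper) probes on real arrays are tight
        (cross-sample sd around 0.02), intermediate probes are noisier.
    """

    name: str
    mean_beta: float
    concentration: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_beta < 1.0:
            raise ValueError(f"mean_beta must be in (0,1), got {self.mean_beta}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.name not in ("hypo", "intermediate", "hyper"):
            raise ValueError(f"unknown archetype name {self.name!r}")
        if self.name == "hypo" and self.mean_beta >= 0.3:
            raise ValueError("hypo archetype mean must be < 0.3")
        if self.name == "hyper" and self.mean_beta <= 0.7:
            raise ValueError("hyper archetype mean must be > 0.7")

    @property
    def a(self) -> float:
        return self.mean_beta * self.concentration

    @property
    def b(self) -> float:
        return (1.0 - self.mean_beta) * self.concentration


DEFAULT_ARCHETYPES: dict[str, ProbeArchetype] = {
    "hypo": ProbeArchetype("hypo", 0.10, 300.0),
    "intermediate": ProbeArchetype("intermediate", 0.50, 40.0),
    "hyper": ProbeArchetype("hyper", 0.85, 300.0),
}


@dataclass
class TruthRecord:
    """Ground truth for one spiked signal, used by recovery tests.

    ``kind`` is one of ``meSNV``, ``epimutation``, ``expression_effect``,
    ``assoc_variant``.  ``original_values`` stores pre-spike cell values so
    a spike can be reverted exactly.
    """

    kind: str
    sample_id: str
    probe_ids: list[str]
    expected_direction: str
    effect_size: float
    carrier_flags: dict[str, bool] = field(default_factory=dict)
    gene_id: str | None = None
    original_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("probe_ids must be nonempty")
        if self.kind == "epimutation" and len(self.probe_ids) < 2:
            raise ValueError("an epimutation record must span >=2 probes")
        if self.effect_size == 0:
            raise ValueError("effect_size must be nonzero")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions plus per-probe archetypes."""

    values: pd.DataFrame  # probes x samples, floats in [0,1]
    archetypes: pd.Series  # probe_id -> archetype name

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy(), self.archetypes.copy())


def _check_mix(archetype_mix: dict[str, float]) -> dict[str, float]:
    if not archetype_mix:
        raise ValueError("archetype_mix must be nonempty")
    if any(f < 0 for f in archetype_mix.values()):
        raise ValueError("mix fractions must be nonnegative")
    total = float(sum(archetype_mix.values()))
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"archetype mix fractions must sum to 1, got {total}")
    return archetype_mix


def simulate_control_betas(
    n_probes: int,
    n_samples: int,
    archetype_mix: dict[str, float] | None = None,
    seed: int = 0,
    archetypes: dict[str, ProbeArchetype] | None = None,
    sample_prefix: str = "CTL",
) -> BetaMatrix:
    """Draw a control beta matrix with per-probe archetype assignment.

    Each probe is assigned an archetype by sampling ``archetype_mix`` and
    its values across samples are i.i.d. Beta(mean * conc, (1-mean) * conc).
    Identical seed gives an identical matrix.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if archetype_mix is None:
        archetype_mix = {"hyper": 0.4, "intermediate": 0.3, "hypo": 0.3}
    archetype_mix = _check_mix(archetype_mix)
    archetypes = archetypes or DEFAULT_ARCHETYPES
    for name in archetype_mix:
        if name not in archetypes:
            raise ValueError(f"mix names unknown archetype {name!r}")

    rng = np.random.default_rng(seed)
    names = sorted(archetype_mix)  # stable order, independent of dict order
    probs = np.array([archetype_mix[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    assigned = rng.choice(names, size=n_probes, p=probs)

    mat = np.empty((n_probes, n_samples), dtype=float)
    for name in names:
        mask = assigned == name
        arch = archetypes[name]
        mat[mask] = rng.beta(arch.a, arch.b, size=(int(mask.sum()), n_samples))

    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id")
    sample_ids = pd.Index(
        [f"{sample_prefix}_{j + 1}" for j in range(n_samples)], name="sample_id"
    )
    values = pd.DataFrame(mat, index=probe_ids, columns=sample_ids)
    return BetaMatrix(values, pd.Series(assigned, index=probe_ids, name="archetype"))


def betas_for_assignment(
    assigned: pd.Series,
    n_samples: int,
    seed: int,
    archetypes: dict[str, ProbeArchetype] | None = None,
    sample_prefix: str = "CTL",
) -> BetaMatrix:
    """Draw a beta matrix for an existing per-probe archetype assignment.

    Used to generate additional cohorts (e.g. a large reference panel)
    that share probe behaviour with a primary matrix.
    """
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)
    arr = assigned.to_numpy()
    mat = np.empty((len(arr), n_samples), dtype=float)
    for name in sorted(set(arr)):
        mask = arr == name
        arch = archetypes[name]
        mat[mask] = rng.beta(arch.a, arch.b, size=(int(mask.sum()), n_samples))
    sample_ids = pd.Index(
        [f"{sample_prefix}_{j + 1}" for j in range(n_samples)], name="sample_id"
    )
    values = pd.DataFrame(mat, index=assigned.index, columns=sample_ids)
    return BetaMatrix(values, assigned.copy())


def _beta_around(rng: np.random.Generator, mean: float, concentration: float) -> float:
    """One Beta draw with the given mean; degenerate means return exactly 0/1."""
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))


def spike_mesnv(
    matrix: BetaMatrix,
    probe: str,
    sample: str,
    zygosity: str = "het",
    seed: int = 0,
    archetypes: dict[str, ProbeArchetype] | None = None,
) -> tuple[BetaMatrix, TruthRecord]:
    """Spike a CG-destroying single-nucleotide variant into one cell.

    The measured beta is modelled as the mean of the two allele betas; a
    mutant allele cannot be methylated and reads at the array background
    (~0.05).  A heterozygote on a hypermethylated probe therefore lands in
    the intermediate 0.3-0.6 range; a homozygote reads near zero.  Noise is
    Beta-distributed around the shifted mean with the probe's concentration.
    Returns a new matrix (input untouched) plus the truth record.
    """
    if zygosity not in ("het", "hom"):
        raise ValueError(f"zygosity must be 'het' or 'hom', got {zygosity!r}")
    if probe not in matrix.values.index:
        raise KeyError(f"unknown probe {probe!r}")
    if sample not in matrix.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)

    old = float(matrix.values.at[probe, sample])
    conc = archetypes[matrix.archetypes[probe]].concentration
    if zygosity == "het":
        new_mean = (old + BACKGROUND_BETA) / 2.0
    else:
        new_mean = BACKGROUND_BETA
    new = _beta_around(rng, new_mean, conc)

    out = matrix.copy()
    out.values.at[probe, sample] = new
    direction = "hypo" if new < old else "hyper"
    rec = TruthRecord(
        kind="meSNV",
        sample_id=sample,
        probe_ids=[probe],
        expected_direction=direction,
        effect_size=new - old,
        carrier_flags={sample: True},
        original_values=[old],
    )
    return out, rec


def spike_dmr(
    matrix: BetaMatrix,
    probes: list[str],
    sample: str,
    delta: float,
    seed: int = 0,
    archetypes: dict[str, ProbeArchetype] | None = None,
) -> tuple[BetaMatrix, TruthRecord]:
    """Shift a run of >=2 adjacent probes in one sample by ``delta``.

    Each probe's value is shifted by ``delta``, clipped to [0,1], and Beta
    noise with the probe's concentration is applied around the shifted mean
    (a mean clipped to 0 or 1 stays exactly at the boundary).
    """
    if len(probes) < 2:
        raise ValueError("a region spike needs >=2 probes")
    if delta == 0:
        raise ValueError("delta must be nonzero")
    if sample not in matrix.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    missing = [p for p in probes if p not in matrix.values.index]
    if missing:
        raise KeyError(f"unknown probes {missing}")
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(seed)

    out = matrix.copy()
    originals: list[float] = []
    for p in probes:
        old = float(out.values.at[p, sample])
        originals.append(old)
        conc = archetypes[out.archetypes[p]].concentration
        mean = float(np.clip(old + delta, 0.0, 1.0))
        out.values.at[p, sample] = _beta_around(rng, mean, conc)
    rec = TruthRecord(
        kind="epimutation",
        sample_id=sample,
        probe_ids=list(probes),
        expected_direction="hyper" if delta > 0 else "hypo",
        effect_size=delta,
        carrier_flags={sample: True},
        original_values=originals,
    )
    return out, rec


def revert_spike(matrix: BetaMatrix, record: TruthRecord) -> BetaMatrix:
    """Undo a spike using its truth record (exact round-trip)."""
    out = matrix.copy()
    for p, v in zip(record.probe_ids, record.original_values):
        out.values.at[p, record.sample_id] = v
    return out


def simulate_expression(
    n_genes: int,
    samples: list[str],
    links: dict[str, dict] | None = None,
    seed: int = 0,
    cv: float = 0.2,
    baseline_log2_mean: float = 6.0,
    baseline_log2_sd: float = 1.5,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Log-normal expression (genes x samples) with cis effects in carriers.

    Each gene has a log-normal baseline; per-sample values are the baseline
    times a log-normal noise factor whose coefficient of variation is
    ``cv``.  ``links`` maps gene_id -> {"lfc": log2 fold-change,
    "carriers": [sample ids], "probe_id": optional} and multiplies carrier
    values by ``2**lfc``.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene_id")
    cols = pd.Index(list(samples), name="sample_id")
    if n_genes == 0 or len(cols) == 0:
        return pd.DataFrame(index=gene_ids, columns=cols, dtype=float), []

    base = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    sigma = float(np.sqrt(np.log1p(cv * cv)))  # lognormal sigma for the given CV
    noise = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=(n_genes, len(cols)))
    mat = base[:, None] * noise
    expr = pd.DataFrame(mat, index=gene_ids, columns=cols)

    truths: list[TruthRecord] = []
    for gene, spec_ in (links or {}).items():
        if gene not in expr.index:
            raise KeyError(f"link for unknown gene {gene!r}")
        lfc = float(spec_["lfc"])
        carriers = list(spec_.get("carriers", []))
        if lfc == 0 or not carriers:
            continue
        expr.loc[gene, carriers] *= 2.0**lfc
        truths.append(
            TruthRecord(
                kind="expression_effect",
                sample_id=carriers[0],
                probe_ids=[spec_.get("probe_id", gene)],
                expected_direction="hyper" if lfc > 0 else "hypo",
                effect_size=lfc,
                carrier_flags={s: s in carriers for s in cols},
                gene_id=gene,
            )
        )
    return expr, truths


def simulate_allele_counts(
    n_cases: int,
    n_controls: int,
    maf_cases: float,
    maf_controls: float,
    seed: int = 0,
) -> dict[str, int]:
    """Binomial minor-allele counts for a biallelic variant.

    Returns a dict with keys a (case minor), b (case major), c (control
    minor), d (control major); margins are exactly 2n per group.
    """
    for maf in (maf_cases, maf_controls):
        if not 0.0 <= maf <= 0.5:
            raise ValueError("MAF must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(2 * n_cases, maf_cases))
    c = int(rng.binomial(2 * n_controls, maf_controls))
    return {
        "a": a,
        "b": 2 * n_cases - a,
        "c": c,
        "d": 2 * n_controls - c,
        "n_cases": n_cases,
        "n_controls": n_controls,
    }


def simulate_probe_annotation(
    probe_ids: pd.Index,
    seed: int = 0,
    n_chroms: int = 4,
    min_gap: int = 200,
    max_gap: int = 2000,
    cluster: tuple[int, int] | None = None,
    cluster_gap: int = 100,
) -> pd.DataFrame:
    """Place probes on chromosomes with realistic inter-probe spacing.

    Probes are split evenly over ``n_chroms`` chromosomes in index order,
    with successive gaps uniform in [min_gap, max_gap].  ``cluster``
    = (start_index, length) forces that run of probes onto tight
    ``cluster_gap`` spacing, emulating a promoter CpG cluster.
    """
    rng = np.random.default_rng(seed)
    n = len(probe_ids)
    per_chrom = int(np.ceil(n / n_chroms))
    chroms = []
    positions = []
    pos = 0
    for i in range(n):
        if i % per_chrom == 0:
            pos = int(rng.integers(10_000, 100_000))
        else:
            gap = int(rng.integers(min_gap, max_gap + 1))
            if cluster is not None and cluster[0] < i < cluster[0] + cluster[1]:
                gap = cluster_gap
            pos += gap
        chroms.append(f"chr{i // per_chrom + 1}")
        positions.append(pos)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": positions,
            "cross_reactive": 0,
            "snp_overlap": "",
            "gene_ids": "",
            "tss_distance": 0,
        }
    ).set_index("probe_id")


@dataclass
class StudyConfig:
    """Conditions of a full synthetic study.

    Defaults mirror the screen design the generator emulates: 10 matched
    control children, a large (757-sample) reference panel, a 450K-like
    probe set scaled to 10,000 probes, ~20 rare heterozygous meSNVs spiked
    on hypermethylated probes of a subset of cases, one clustered
    13-probe hypermethylation epimutation, multiplicative cis-expression
    effects (log2 fold-change 2) in carriers, and rare allele frequencies
    of the order seen in the genotyped loci.
    """

    n_probes: int = 10_000
    n_cases: int = 29
    n_controls: int = 10
    n_panel: int = 757
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {"hyper": 0.4, "intermediate": 0.3, "hypo": 0.3}
    )
    archetypes: dict[str, ProbeArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    n_mesnv: int = 20
    n_mesnv_carrier_samples: int = 8
    known_mesnp_fraction: float = 0.45  # fraction of meSNVs with a catalogued SNP
    dmr_n_probes: int = 13
    dmr_delta: float = 0.30
    expression_lfc: float = 2.0
    expression_cv: float = 0.2
    n_background_genes: int = 50
    assoc_variants: dict[str, tuple[int, int, float, float]] = field(
        default_factory=lambda: {
            "var1": (447, 1349, 0.0067, 0.0019),
            "var2": (446, 1349, 0.0045, 0.0007),
            "var3": (444, 1348, 0.0079, 0.0022),
        }
    )
    detection_fail_rate: float = 0.001
    n_detection_fail_probes: int = 20
    n_cross_reactive: int = 20
    n_snp_probes: int = 20


@dataclass
class SyntheticStudy:
    """All inputs for one end-to-end pipeline run plus ground truth."""

    betas: BetaMatrix  # cases + matched controls
    detection_p: pd.DataFrame
    panel: BetaMatrix
    annotation: pd.DataFrame
    case_ids: list[str]
    control_ids: list[str]
    expression: pd.DataFrame
    gene_annotation: pd.DataFrame
    snp_table: pd.DataFrame
    allele_tables: pd.DataFrame
    truth: list[TruthRecord]
    config: StudyConfig
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                {
                    "kind": t.kind,
                    "sample_id": t.sample_id,
                    "probe_ids": ";".join(t.probe_ids),
                    "expected_direction": t.expected_direction,
                    "effect_size": t.effect_size,
                    "gene_id": t.gene_id or "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "kind",
                "sample_id",
                "probe_ids",
                "expected_direction",
                "effect_size",
                "gene_id",
            ],
        )

    def write(self, outdir: str | Path) -> None:
        """Write every input in the TSV formats the pipeline reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.betas.values.to_csv(out / "beta.tsv", sep="\t")
        self.detection_p.to_csv(out / "detection.tsv", sep="\t")
        self.panel.values.to_csv(out / "panel.tsv", sep="\t")
        self.annotation.to_csv(out / "probes.tsv", sep="\t")
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.gene_annotation.to_csv(
            out / "genes.bed", sep="\t", header=False, index=False
        )
        self.snp_table.to_csv(out / "snps.tsv", sep="\t", index=False)
        self.allele_tables.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "controls.txt").write_text("\n".join(self.control_ids) + "\n")
        cfg = dataclasses.asdict(self.config)
        cfg["archetypes"] = {
            k: dataclasses.asdict(v) for k, v in self.config.archetypes.items()
        }
        (out / "manifest.json").write_text(
            json.dumps({"seed": self.seed, "config": cfg}, indent=2, default=str)
        )


def _pick_spaced(rng, candidates: np.ndarray, k: int, min_sep: int) -> np.ndarray:
    """Pick k indices from candidates pairwise separated by >= min_sep."""
    chosen: list[int] = []
    pool = rng.permutation(candidates)
    for idx in pool:
        if all(abs(int(idx) - c) >= min_sep for c in chosen):
            chosen.append(int(idx))
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise ValueError("not enough spaced candidate probes for the requested spikes")
    return np.array(sorted(chosen))


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate one complete synthetic study with ground truth.

    The spiked meSNVs sit on hypermethylated probes (pairwise well
    separated so they never cluster into a region), the clustered
    epimutation sits on a tightly spaced run of hypomethylated probes, and
    each meSNV carrier gets a cis gene with a multiplicative expression
    effect.  All randomness derives from ``seed``.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=16)  # independent stage seeds

    n_total = config.n_cases + config.n_controls
    mat = simulate_control_betas(
        config.n_probes,
        n_total,
        config.archetype_mix,
        seed=int(sub[0]),
        archetypes=config.archetypes,
        sample_prefix="S",
    )
    case_ids = [f"ASD_{i + 1}" for i in range(config.n_cases)]
    control_ids = [f"CTL_{i + 1}" for i in range(config.n_controls)]
    mat.values.columns = pd.Index(case_ids + control_ids, name="sample_id")

    # panel shares the per-probe archetype assignment with the cohort
    panel = betas_for_assignment(
        mat.archetypes,
        config.n_panel,
        seed=int(sub[1]),
        archetypes=config.archetypes,
        sample_prefix="PANEL",
    )

    # --- annotation with a tight cluster reserved for the epimutation ---
    n_chroms = 4
    per_chrom = int(np.ceil(config.n_probes / n_chroms))
    hypo_idx = np.flatnonzero(mat.archetypes.to_numpy() == "hypo")
    # cluster start must leave room before the chromosome boundary
    ok_start = hypo_idx[
        (hypo_idx % per_chrom) < per_chrom - config.dmr_n_probes
    ]
    if config.dmr_n_probes >= 2 and len(ok_start) > 0:
        # force a consecutive index run onto the hypo archetype
        start = int(rng.choice(ok_start))
        run = np.arange(start, start + config.dmr_n_probes)
        arch_vals = mat.archetypes.to_numpy().copy()
        arch_vals[run] = "hypo"
        hypo_arch = config.archetypes["hypo"]
        redraw = [i for i in run if mat.archetypes.iloc[i] != "hypo"]
        if redraw:
            mat.values.iloc[redraw, :] = np.random.default_rng(int(sub[2])).beta(
                hypo_arch.a, hypo_arch.b, size=(len(redraw), n_total)
            )
            panel.values.iloc[redraw, :] = np.random.default_rng(int(sub[3])).beta(
                hypo_arch.a, hypo_arch.b, size=(len(redraw), config.n_panel)
            )
        mat.archetypes = pd.Series(arch_vals, index=mat.probe_ids, name="archetype")
        panel.archetypes = mat.archetypes.copy()
        cluster = (int(run[0]), config.dmr_n_probes)
        dmr_probes = [str(mat.probe_ids[i]) for i in run]
    else:
        cluster = None
        dmr_probes = []

    annotation = simulate_probe_annotation(
        mat.probe_ids, seed=int(sub[4]), n_chroms=n_chroms, cluster=cluster
    )

    truth: list[TruthRecord] = []

    # --- meSNV spikes on hyper probes, well separated in index space ---
    hyper_idx = np.flatnonzero(mat.archetypes.to_numpy() == "hyper")
    spike_rng = np.random.default_rng(int(sub[5]))
    mesnv_idx = _pick_spaced(spike_rng, hyper_idx, config.n_mesnv, min_sep=10)
    carriers = [
        case_ids[i % max(1, config.n_mesnv_carrier_samples)]
        for i in range(config.n_mesnv)
    ]
    for j, (pi, sample) in enumerate(zip(mesnv_idx, carriers)):
        probe = str(mat.probe_ids[pi])
        mat, rec = spike_mesnv(
            mat, probe, sample, "het", seed=int(sub[6]) + j, archetypes=config.archetypes
        )
        truth.append(rec)

    # --- clustered hypermethylation epimutation in one case ---
    if dmr_probes:
        dmr_sample = case_ids[config.n_mesnv_carrier_samples % config.n_cases]
        mat, rec = spike_dmr(
            mat,
            dmr_probes,
            dmr_sample,
            config.dmr_delta,
            seed=int(sub[7]),
            archetypes=config.archetypes,
        )
        truth.append(rec)

    # spiked probes must survive QC; keep broken/flagged probes off them
    spiked = set(int(i) for i in mesnv_idx) | set(
        int(np.flatnonzero(mat.probe_ids == p)[0]) for p in dmr_probes
    )

    # --- detection p-values: mostly tiny, a few probes failing broadly ---
    det_rng = np.random.default_rng(int(sub[8]))
    det = det_rng.uniform(0.0, 0.005, size=mat.values.shape)
    fail = det_rng.random(mat.values.shape) < config.detection_fail_rate
    det[fail] = det_rng.uniform(0.02, 0.5, size=int(fail.sum()))
    unspiked = np.array([i for i in range(config.n_probes) if i not in spiked])
    det[list(spiked), :] = np.minimum(det[list(spiked), :], 0.005)
    n_fail = min(config.n_detection_fail_probes, len(unspiked))
    fail_probes = det_rng.choice(unspiked, size=n_fail, replace=False)
    det[fail_probes, :] = det_rng.uniform(0.02, 0.5, size=(n_fail, mat.values.shape[1]))
    detection_p = pd.DataFrame(det, index=mat.probe_ids, columns=mat.values.columns)

    # --- annotation flags: cross-reactive and SNP-harbouring probes ---
    spiked = spiked | set(int(i) for i in fail_probes)
    clean = np.array([i for i in range(config.n_probes) if i not in spiked])
    flag_rng = np.random.default_rng(int(sub[9]))
    xr = flag_rng.choice(clean, size=min(config.n_cross_reactive, len(clean)), replace=False)
    annotation.iloc[xr, annotation.columns.get_loc("cross_reactive")] = 1
    remaining = np.array([i for i in clean if i not in set(int(v) for v in xr)])
    snp_probes = flag_rng.choice(
        remaining, size=min(config.n_snp_probes, len(remaining)), replace=False
    )
    for i in snp_probes:
        off = int(flag_rng.integers(-5, 6))
        maf = float(flag_rng.uniform(0.01, 0.4))
        annotation.iloc[i, annotation.columns.get_loc("snp_overlap")] = f"{off}:{maf:.4f}"

    # --- genes: one cis gene per spiked locus plus background genes ---
    mesnv_records = [t for t in truth if t.kind == "meSNV"]
    n_genes = len(mesnv_records) + (1 if dmr_probes else 0) + config.n_background_genes
    gene_rows = []
    links: dict[str, dict] = {}
    gi = 0
    for rec in mesnv_records:
        probe = rec.probe_ids[0]
        chrom = annotation.at[probe, "chrom"]
        pos = int(annotation.at[probe, "pos"])
        gid = f"gene{gi:05d}"
        start = max(0, pos + int(flag_rng.integers(-30_000, 10_000)))
        gene_rows.append((chrom, start, start + 5000, gid))
        links[gid] = {"lfc": config.expression_lfc, "carriers": [rec.sample_id],
                      "probe_id": probe}
        rec.gene_id = gid
        gi += 1
    if dmr_probes:
        probe = dmr_probes[0]
        chrom = annotation.at[probe, "chrom"]
        pos = int(annotation.at[probe, "pos"])
        gid = f"gene{gi:05d}"
        gene_rows.append((chrom, max(0, pos - 2000), pos + 3000, gid))
        links[gid] = {
            "lfc": -config.expression_lfc,
            "carriers": [truth[-1].sample_id],
            "probe_id": probe,
        }
        truth[-1].gene_id = gid
        gi += 1
    far_pos = int(annotation["pos"].max()) + 1_000_000
    for k in range(config.n_background_genes):
        gene_rows.append(("chr1", far_pos + 100_000 * k, far_pos + 100_000 * k + 5000,
                          f"gene{gi:05d}"))
        gi += 1
    gene_annotation = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])

    expression, expr_truth = simulate_expression(
        n_genes,
        case_ids,
        links=links,
        seed=int(sub[10]),
        cv=config.expression_cv,
    )
    truth.extend(expr_truth)

    # --- SNP catalogue: a known rare SNP under ~45% of the meSNV CpGs ---
    snp_rows = []
    n_known = int(round(config.known_mesnp_fraction * len(mesnv_records)))
    for j, rec in enumerate(mesnv_records[:n_known]):
        probe = rec.probe_ids[0]
        snp_rows.append(
            {
                "snp_id": f"rs{900000 + j}",
                "chrom": annotation.at[probe, "chrom"],
                "pos": int(annotation.at[probe, "pos"]),
                "maf": 0.001,
            }
        )
    snp_table = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "maf"])

    # --- case/control allele-count tables for the association stage ---
    at_rows = []
    for j, (vid, (nc, nk, mc, mk)) in enumerate(sorted(config.assoc_variants.items())):
        tab = simulate_allele_counts(nc, nk, mc, mk, seed=int(sub[11]) + j)
        at_rows.append({"variant_id": vid, **tab})
        truth.append(
            TruthRecord(
                kind="assoc_variant",
                sample_id="cohort",
                probe_ids=[vid],
                expected_direction="hyper" if mc > mk else "hypo",
                effect_size=mc - mk if mc != mk else 1e-9,
            )
        )
    allele_tables = pd.DataFrame(
        at_rows,
        columns=["variant_id", "a", "b", "c", "d", "n_cases", "n_controls"],
    )

    return SyntheticStudy(
        betas=mat,
        detection_p=detection_p,
        panel=panel,
        annotation=annotation,
        case_ids=case_ids,
        control_ids=control_ids,
        expression=expression,
        gene_annotation=gene_annotation,
        snp_table=snp_table,
        allele_tables=allele_tables,
        truth=truth,
        config=config,
        seed=seed,
    )
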