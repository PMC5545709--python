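"""Per-individual differential-methylation outlier calling.

One case sample is tested against a matched control group probe by probe
with an empirical-Bayes moderated t statistic: per-probe control variances
are shrunk toward a prior (d0, s0^2) estimated across all probes by
moment-matching of log-variances to a scaled-F distribution, which adds d0
degrees of freedom to each test.  Per-sample p-values get a
Benjamini-Hochberg step-up adjustment; retained differentially methylated
CpG (DMCpG) calls must additionally

* move by at least ``delta_min`` (default 0.18, i.e. 18 percentage points
  of methylation) from the control mean,
* change methylation status (hypo < 0.3, hyper > 0.7, intermediate in
  [0.3, 0.7]),
* not be mirrored by any matched-control sample ("altered in controls",
  evaluated leave-one-out with the same delta and status criteria),
* be rare in a large reference panel (panel frequency <= 0.005), and
* when an extended control set is supplied, survive a second-pass test
  against it at a less strict delta (default 0.15).

The caller is a scikit-learn style estimator: ``fit`` on the control
samples, ``predict`` on case samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "classify_status",
    "fit_ebayes_prior",
    "moderated_one_vs_group",
    "bh_adjust",
    "panel_frequency",
    "call_dmcpgs",
    "DMCpGCaller",
]

HYPO_MAX = 0.3  # beta < 0.3 -> hypomethylated
HYPER_MIN = 0.7  # beta > 0.7 -> hypermethylated


def classify_status(beta):
    """Methylation status bin of a beta value.

    beta < 0.3 is ``hypo``, beta > 0.7 is ``hyper``, the closed interval
    [0.3, 0.7] is ``intermediate``.  Accepts scalars or arrays.
    """
    arr = np.asarray(beta, dtype=float)
    out = np.full(arr.shape, "intermediate", dtype=object)
    out[arr < HYPO_MAX] = "hypo"
    out[arr > HYPER_MIN] = "hyper"
    if np.isscalar(beta) or arr.ndim == 0:
        return str(out.flat[0])
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_ebayes_prior(s2: np.ndarray, df: float | np.ndarray) -> tuple[float, float]:
    """Moment-match per-probe variances to a scaled-F prior.

    Under the hierarchical model s2_g ~ s0^2 * F(d_g, d0), the log
    variances have mean log(s0^2) + E[log chi2 terms] and excess variance
    trigamma(d0/2) beyond the trigamma(d_g/2) sampling term; matching the
    first two moments of log(s2) yields (d0, s0^2).  Zero excess spread
    gives d0 = +inf (complete shrinkage to s0^2).

    Parameters
    ----------
    s2 : array of per-probe residual variances (positive; zeros dropped).
    df : residual degrees of freedom, scalar or per-probe, >= 1.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if ok.sum() == 0:
        raise ValueError("all variances are zero; prior is undefined")
    if np.any(df_arr < 1):
        raise ValueError("residual df must be >= 1")
    s2 = s2[ok]
    dfs = df_arr[ok]
    if s2.size < 2 or np.allclose(s2, s2[0], rtol=1e-12, atol=0):
        # no spread at all: complete shrinkage to the common value
        return np.inf, float(s2[0])

    z = np.log(s2)
    e = z - special.digamma(dfs / 2.0) + np.log(dfs / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    excess = evar - float(np.mean(special.polygamma(1, dfs / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def _moderate_var(s2, df, d0, s02):
    """Posterior (shrunk) variance (d0*s02 + df*s2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    if d0 == 0:
        return s2
    return (d0 * s02 + df * s2) / (d0 + df)


def moderated_one_vs_group(
    case_beta: float,
    control_betas: np.ndarray,
    d0: float = 0.0,
    s02: float = 0.0,
) -> tuple[float, float]:
    """Moderated one-versus-group t test for a single probe.

    t = (case - mean(controls)) / (s_tilde * sqrt(1 + 1/n)), with
    s_tilde^2 the moderated control variance and a two-sided p on
    d0 + (n - 1) degrees of freedom (normal when d0 is infinite).
    """
    x = np.asarray(control_betas, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 control samples")
    dg = n - 1
    s2 = float(np.var(x, ddof=1))
    st2 = float(_moderate_var(np.array([s2]), dg, d0, s02)[0])
    se = np.sqrt(st2 * (1.0 + 1.0 / n))
    if se == 0:
        t = 0.0 if case_beta == x.mean() else np.inf * np.sign(case_beta - x.mean())
    else:
        t = (float(case_beta) - float(x.mean())) / se
    df_total = d0 + dg
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df_total)
    return float(t), float(min(p, 1.0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (linear FDR adjustment)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def panel_frequency(
    probe_id: str,
    panel: pd.DataFrame,
    ctrl_mean: float,
    call_direction: str,
    delta_min: float = 0.18,
) -> float:
    """Fraction of panel samples altered like the case call at this probe.

    A panel sample counts as altered when, relative to the matched-control
    mean, it moves by at least ``delta_min`` in the call's direction and
    changes methylation status.
    """
    vals = panel.loc[probe_id].to_numpy(dtype=float)
    return _panel_frequency_values(vals, ctrl_mean, call_direction, delta_min)


def _panel_frequency_values(vals, ctrl_mean, call_direction, delta_min):
    delta = vals - float(ctrl_mean)
    if call_direction == "hypo":
        big = delta <= -delta_min
    else:
        big = delta >= delta_min
    status_change = classify_status(vals) != classify_status(float(ctrl_mean))
    return float(np.mean(big & status_change))


class DMCpGCaller(BaseEstimator):
    """Per-individual methylation-outlier caller (novelty-detection shaped).

    Fit on the matched control group (optionally with a large reference
    panel and an extended control set); predict on case samples to obtain
    retained DMCpG calls plus the per-filter flags of every candidate.

    Parameters
    ----------
    q_max : float
        BH q-value cutoff per sample (default 0.01).
    delta_min : float
        Minimum |delta beta| versus the matched-control mean (default
        0.18).
    delta_min_pass2 : float
        Less strict |delta beta| cutoff for the second-pass comparison
        against the extended control set (default 0.15), applied only when
        an extended set is given to ``fit``.
    panel_freq_max : float
        Maximum panel frequency for a retained call (default 0.005,
        strictly greater discards).

    Attributes (after ``fit``)
    --------------------------
    probe_ids_ : probe index; mean_, var_ : per-probe control mean and
    variance; d0_, s02_ : empirical-Bayes prior; control_altered_ :
    boolean per probe, any matched control itself altered (leave-one-out);
    panel_freq_hypo_ / panel_freq_hyper_ : per-probe panel frequencies for
    downward/upward calls.
    """

    def __init__(
        self,
        q_max: float = 0.01,
        delta_min: float = 0.18,
        delta_min_pass2: float = 0.15,
        panel_freq_max: float = 0.005,
    ):
        self.q_max = q_max
        self.delta_min = delta_min
        self.delta_min_pass2 = delta_min_pass2
        self.panel_freq_max = panel_freq_max

    # ------------------------------------------------------------------
    def fit(
        self,
        X: pd.DataFrame,
        y=None,
        panel: pd.DataFrame | None = None,
        extended_controls: pd.DataFrame | None = None,
        annotation: pd.DataFrame | None = None,
    ):
        """Learn control means/variances and the variance prior.

        Parameters
        ----------
        X : DataFrame, control samples x probes (sklearn orientation).
        panel : optional DataFrame, probes x panel-samples, the large
            reference control panel used for the frequency filter.
        extended_controls : optional DataFrame, extra control samples x
            probes, enabling the second-pass test.
        annotation : optional probe annotation (chrom, pos) merged into
            call output.
        """
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        ctrl = X.to_numpy(dtype=float).T  # probes x samples
        n = ctrl.shape[1]
        if n < 3:
            raise ValueError("need at least 3 control samples")
        self.probe_ids_ = X.columns
        self.n_controls_ = n
        self.mean_ = ctrl.mean(axis=1)
        self.var_ = ctrl.var(axis=1, ddof=1)
        self.df_ = n - 1
        self.d0_, self.s02_ = fit_ebayes_prior(self.var_, self.df_)
        self.mod_var_ = _moderate_var(self.var_, self.df_, self.d0_, self.s02_)

        # leave-one-out "altered in any control" screen
        loo_mean = (self.mean_[:, None] * n - ctrl) / (n - 1)
        d = ctrl - loo_mean
        status_x = _status_codes(ctrl)
        status_m = _status_codes(loo_mean)
        altered = (np.abs(d) >= self.delta_min) & (status_x != status_m)
        self.control_altered_ = altered.any(axis=1)

        if panel is not None:
            panel = panel.loc[self.probe_ids_]
            pv = panel.to_numpy(dtype=float)
            dm = pv - self.mean_[:, None]
            sc = _status_codes(pv) != _status_codes(self.mean_)[:, None]
            self.panel_freq_hypo_ = ((dm <= -self.delta_min) & sc).mean(axis=1)
            self.panel_freq_hyper_ = ((dm >= self.delta_min) & sc).mean(axis=1)
            self.n_panel_ = pv.shape[1]
        else:
            self.panel_freq_hypo_ = None
            self.panel_freq_hyper_ = None
            self.n_panel_ = 0

        if extended_controls is not None:
            ext = pd.concat([X, extended_controls[self.probe_ids_]], axis=0)
            sub = DMCpGCaller(
                q_max=self.q_max,
                delta_min=self.delta_min_pass2,
                panel_freq_max=self.panel_freq_max,
            )
            sub.fit(ext)
            self.pass2_ = sub
        else:
            self.pass2_ = None

        self.annotation_ = annotation
        return self

    # ------------------------------------------------------------------
    def _stats_for_case(self, case: np.ndarray):
        se = np.sqrt(self.mod_var_ * (1.0 + 1.0 / self.n_controls_))
        delta = case - self.mean_
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf))
        df_total = self.d0_ + self.df_
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        return t, np.minimum(p, 1.0), delta

    def predict(self, X: pd.DataFrame, keep_candidates: bool = False) -> pd.DataFrame:
        """Call DMCpGs for each case sample (rows of ``X``).

        Returns a call table; with ``keep_candidates`` every q-significant
        candidate is returned with its per-filter flags, otherwise only
        fully retained calls.
        """
        if not hasattr(self, "mean_"):
            raise RuntimeError("caller is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.probe_ids_)
        if not X.columns.equals(self.probe_ids_):
            X = X[self.probe_ids_]
        frames = []
        for sample_id, row in X.iterrows():
            frames.append(self._call_one(str(sample_id), row.to_numpy(dtype=float)))
        cols = _CALL_COLUMNS
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=cols)
        calls = pd.concat(frames, ignore_index=True)
        if not keep_candidates:
            calls = calls[calls["retained"]].reset_index(drop=True)
        return calls

    def _call_one(self, sample_id: str, case: np.ndarray) -> pd.DataFrame:
        t, p, delta = self._stats_for_case(case)
        q = bh_adjust(p)
        cand = q < self.q_max
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            return pd.DataFrame(columns=_CALL_COLUMNS)

        rows = []
        for i in idx:
            case_beta = float(case[i])
            ctrl_mean = float(self.mean_[i])
            d = float(delta[i])
            s_from = classify_status(ctrl_mean)
            s_to = classify_status(case_beta)
            direction = "hypo" if d < 0 else "hyper"
            pass_delta = abs(d) >= self.delta_min
            pass_status = s_from != s_to
            pass_ctrl = not bool(self.control_altered_[i])
            if self.panel_freq_hypo_ is None:
                pf = 0.0
            else:
                pf = float(
                    self.panel_freq_hypo_[i]
                    if direction == "hypo"
                    else self.panel_freq_hyper_[i]
                )
            pass_panel = pf <= self.panel_freq_max
            retained = pass_delta and pass_status and pass_ctrl and pass_panel
            rows.append(
                {
                    "sample_id": sample_id,
                    "probe_id": str(self.probe_ids_[i]),
                    "case_beta": case_beta,
                    "control_mean_beta": ctrl_mean,
                    "delta_beta": d,
                    "t": float(t[i]),
                    "p": float(p[i]),
                    "q_value": float(q[i]),
                    "status_from": s_from,
                    "status_to": s_to,
                    "panel_frequency": pf,
                    "pass_q": True,
                    "pass_delta": pass_delta,
                    "pass_status": pass_status,
                    "pass_control_altered": pass_ctrl,
                    "pass_panel": pass_panel,
                    "pass_second": True,
                    "retained": retained,
                }
            )
        calls = pd.DataFrame(rows, columns=_CALL_COLUMNS)

        if self.pass2_ is not None and len(calls):
            second = self.pass2_.predict(
                pd.DataFrame([case], index=[sample_id], columns=self.probe_ids_),
                keep_candidates=False,
            )
            ok = set(second["probe_id"])
            calls["pass_second"] = calls["probe_id"].isin(ok)
            calls["retained"] = calls["retained"] & calls["pass_second"]

        if self.annotation_ is not None and len(calls):
            ann = self.annotation_.reindex(calls["probe_id"])
            calls.insert(2, "chrom", ann["chrom"].to_numpy())
            calls.insert(3, "pos", ann["pos"].to_numpy())
        return calls


_CALL_COLUMNS = [
    "sample_id",
    "probe_id",
    "case_beta",
    "control_mean_beta",
    "delta_beta",
    "t",
    "p",
    "q_value",
    "status_from",
    "status_to",
    "panel_frequency",
    "pass_q",
    "pass_delta",
    "pass_status",
    "pass_control_altered",
    "pass_panel",
    "pass_second",
    "retained",
]


def _status_codes(beta: np.ndarray) -> np.ndarray:
    """Integer status codes (0 hypo, 1 intermediate, 2 hyper) for speed."""
    arr = np.asarray(beta, dtype=float)
    out = np.ones(arr.shape, dtype=np.int8)
    out[arr < HYPO_MAX] = 0
    out[arr > HYPER_MIN] = 2
    return out


def call_dmcpgs(
    case_id: str,
    beta_matrix: pd.DataFrame,
    control_ids: list[str],
    panel: pd.DataFrame | None = None,
    params: dict | None = None,
    annotation: pd.DataFrame | None = None,
    extended_controls: pd.DataFrame | None = None,
    keep_candidates: bool = False,
) -> pd.DataFrame:
    """Call DMCpGs for one case against a control group.

    Thin functional wrapper over :class:`DMCpGCaller`.  ``beta_matrix`` is
    probes x samples; ``control_ids`` name its control columns.
    """
    if case_id in control_ids:
        raise ValueError(f"case {case_id!r} is listed among the controls")
    missing = [c for c in [case_id, *control_ids] if c not in beta_matrix.columns]
    if missing:
        raise KeyError(f"samples missing from beta matrix: {missing}")
    params = params or {}
    caller = DMCpGCaller(
        q_max=params.get("q_max", 0.01),
        delta_min=params.get("delta_min", 0.18),
        delta_min_pass2=params.get("delta_min_pass2", 0.15),
        panel_freq_max=params.get("panel_freq_max", 0.005),
    )
    caller.fit(
        beta_matrix[control_ids].T,
        panel=panel,
        extended_controls=None if extended_controls is None else extended_controls.T,
        annotation=annotation,
    )
    return caller.predict(beta_matrix[[case_id]].T, keep_candidates=keep_candidates)
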