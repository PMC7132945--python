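"""Structure-cognition statistics.

This module implements the complete analysis layer for relating tract
microstructure (and regional volumes) to cognitive scores in a cohort:

* intracranial-volume adjustment of regional volumes,
  ``adj_i = raw_i - beta * (ICV_i - mean(ICV))`` with ``beta`` the OLS slope
  of the measure on ICV;
* two-tailed Pearson correlations with percentile bootstrap confidence
  intervals (1000 resamples by default);
* Bonferroni-Holm step-down adjustment within correlation families
  (6 structure-cognition tests per tract; 15 volume-cognition tests);
* Steiger's Z for comparing two dependent correlations that share one
  variable (the pooled-r variant of the Z1* statistic), reported with
  Cohen's q = atanh(r1) - atanh(r2);
* a Spearman / outlier-removal sensitivity block;
* a default two-sided Bayes factor for a Pearson correlation under a
  stretched-beta prior on (-1, 1), evaluated by numerical quadrature of the
  sampling density of r, with a central 95% posterior credible interval.

The cohort-level pipeline is exposed statsmodels-style:
``StructureCognitionModel(cohort).fit()`` returns a
:class:`StructureCognitionResults` carrying tidy result tables and a
``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

from .io import ValidationError

logger = logging.getLogger("commissura")

__all__ = [
    "CorrResult",
    "DependentCorrComparison",
    "BayesCorrResult",
    "icv_adjust",
    "pearson_bootstrap",
    "spearman",
    "holm_adjust",
    "steiger_dependent_z",
    "cohens_q",
    "correlation_bf10",
    "StructureCognitionModel",
    "StructureCognitionResults",
    "run_structure_cognition_analysis",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class CorrResult:
    """A Pearson correlation with its bootstrap CI and family bookkeeping."""

    r: float
    n: int
    p: float
    ci_low: float
    ci_high: float
    p_holm: float | None = None
    family: str = ""
    family_size: int | None = None


@dataclass
class DependentCorrComparison:
    """Steiger test of two overlapping correlations sharing one variable."""

    r1: float
    r2: float
    r12: float
    n: int
    z: float
    p: float
    q: float
    tail: str = "one"


@dataclass
class BayesCorrResult:
    """Default Bayes factor for a correlation plus 95% credible interval."""

    bf10: float
    ci_low: float
    ci_high: float
    kappa: float = 1.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def icv_adjust(measure, icv) -> np.ndarray:
    """Remove the linear ICV component from a regional measure.

    ``adjusted_i = raw_i - beta * (ICV_i - mean(ICV))``; the adjusted values
    keep the raw mean and are exactly uncorrelated with ICV (OLS
    orthogonality).
    """
    measure = np.asarray(measure, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if measure.shape != icv.shape or measure.ndim != 1:
        raise ValidationError("measure and icv must be equal-length 1-D arrays")
    if len(measure) < 3:
        raise ValidationError("need n >= 3 for the adjustment slope")
    if np.ptp(icv) == 0:
        raise ValidationError("ICV is constant; adjustment slope undefined")
    beta = np.polyfit(icv, measure, 1)[0]
    return measure - beta * (icv - icv.mean())


def _check_pair(x, y, min_n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    if len(x) < min_n:
        raise ValidationError(f"need n >= {min_n}, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    return x, y


def _bootstrap_r(x: np.ndarray, y: np.ndarray, n_boot: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Pearson r over paired resamples, fully vectorised."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r[np.isfinite(r)]


def pearson_bootstrap(x, y, n_boot: int = 1000, seed=None,
                      ci_method: str = "percentile") -> CorrResult:
    """Two-tailed Pearson r with a paired-bootstrap 95% CI.

    The p-value uses the exact t transform with n-2 degrees of freedom; the
    CI is the 2.5/97.5 percentile interval of r over ``n_boot`` paired
    resamples (``ci_method="bca"`` switches to bias-corrected accelerated
    intervals), deterministic under ``seed``.
    """
    if ci_method not in ("percentile", "bca"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    x, y = _check_pair(x, y)
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    lo = hi = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        if ci_method == "percentile":
            rs = _bootstrap_r(x, y, n_boot, rng)
            lo, hi = np.percentile(rs, [2.5, 97.5])
        else:
            def stat(xs, ys):
                return sps.pearsonr(xs, ys).statistic

            bres = sps.bootstrap((x, y), stat, paired=True, vectorized=False,
                                 n_resamples=n_boot, method="BCa",
                                 confidence_level=0.95, rng=rng)
            lo, hi = bres.confidence_interval
    return CorrResult(r=r, n=len(x), p=p, ci_low=float(lo), ci_high=float(hi))


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho (average ranks on ties) and its two-sided p."""
    x, y = _check_pair(x, y)
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in the input order.

    ``m`` is the family size and may exceed ``len(pvals)`` (e.g. when only
    the significant members of a family are re-examined); it defaults to
    ``len(pvals)``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("pvals must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValidationError(f"family size m={m} smaller than {len(p)} tests")
    order = np.argsort(p, kind="stable")
    adj = np.empty_like(p)
    running = 0.0
    for k, i in enumerate(order):
        running = max(running, (m - k) * p[i])
        adj[i] = min(1.0, running)
    return adj


def cohens_q(r1: float, r2: float) -> float:
    """Effect size for a difference of correlations: atanh(r1) - atanh(r2)."""
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValidationError("correlations must lie in (-1, 1)")
    return float(np.arctanh(r1) - np.arctanh(r2))


def steiger_dependent_z(r1: float, r2: float, r12: float, n: int,
                        tail: str = "one") -> DependentCorrComparison:
    """Steiger's Z for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` both involve the shared variable; ``r12`` is the
    correlation between the two non-shared variables.  Uses the pooled-r
    covariance approximation (the Z1* statistic): with rb = (r1+r2)/2,

        psi = r12 (1 - 2 rb^2) - rb^2 (1 - 2 rb^2 - r12^2) / 2
        c   = psi / (1 - rb^2)^2
        Z   = (atanh(r1) - atanh(r2)) * sqrt((n-3) / (2 - 2c))

    One-tailed p is in the direction of the observed difference.
    """
    for r in (r1, r2, r12):
        if not abs(r) < 1:
            raise ValidationError("correlations must lie in (-1, 1)")
    if n < 10:
        raise ValidationError("need n >= 10 for the Steiger approximation")
    if tail not in ("one", "two"):
        raise ValidationError("tail must be 'one' or 'two'")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rb = (r1 + r2) / 2.0
    psi = r12 * (1 - 2 * rb**2) - 0.5 * rb**2 * (1 - 2 * rb**2 - r12**2)
    c = psi / (1 - rb**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = sps.norm.sf(abs(z))
    if tail == "two":
        p *= 2.0
    return DependentCorrComparison(r1=r1, r2=r2, r12=r12, n=n, z=float(z),
                                   p=float(p), q=cohens_q(r1, r2), tail=tail)


# ---------------------------------------------------------------------------
# Bayesian correlation test
# ---------------------------------------------------------------------------

def _log_likelihood_ratio(rho, r: float, n: int):
    """log f(r | rho, n) - log f(r | 0, n) for the sampling density of
    Pearson r under a bivariate normal population."""
    rho = np.asarray(rho, dtype=float)
    out = ((n - 1) / 2.0) * np.log1p(-rho**2) - (n - 1.5) * np.log1p(-rho * r)
    h = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    h0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return out + np.log(h) - np.log(h0)


def _stretched_beta(rho, kappa: float):
    """Symmetric beta(1/kappa, 1/kappa) density stretched to (-1, 1)."""
    a = 1.0 / kappa
    return (1.0 - np.asarray(rho) ** 2) ** (a - 1.0) * 2.0 ** (1.0 - 2.0 * a) \
        / special.beta(a, a)


def correlation_bf10(r: float, n: int, kappa: float = 1.0,
                     grid_size: int = 8001) -> BayesCorrResult:
    """Two-sided default Bayes factor for a Pearson correlation.

    H1 places a stretched-beta prior of width ``kappa`` on rho over (-1, 1)
    (``kappa = 1`` is the flat default); H0 fixes rho = 0.  BF10 is the
    marginal likelihood ratio, computed by adaptive quadrature of the
    sampling density of the observed r; the 95% central posterior interval
    for rho is read off a dense grid of the (normalised) posterior.
    """
    if not abs(r) < 1:
        raise ValidationError("r must lie in (-1, 1)")
    if n < 5:
        raise ValidationError("need n >= 5 for the Bayesian correlation test")
    if not kappa > 0:
        raise ValidationError("prior width kappa must be > 0")

    def integrand(rho):
        return np.exp(_log_likelihood_ratio(rho, r, n)) * _stretched_beta(rho, kappa)

    bf10, err = integrate.quad(integrand, -1.0, 1.0, limit=200)
    if not np.isfinite(bf10) or bf10 <= 0 or err > 1e-6 * max(bf10, 1.0):
        raise ArithmeticError(
            f"Bayes factor quadrature did not converge (value={bf10}, err={err})"
        )
    eps = 1.0 / (10.0 * grid_size)
    grid = np.linspace(-1.0 + eps, 1.0 - eps, grid_size)
    post = integrand(grid)
    cdf = integrate.cumulative_trapezoid(post, grid, initial=0.0)
    cdf /= cdf[-1]
    lo = float(np.interp(0.025, cdf, grid))
    hi = float(np.interp(0.975, cdf, grid))
    return BayesCorrResult(bf10=float(bf10), ci_low=lo, ci_high=hi, kappa=kappa)


# ---------------------------------------------------------------------------
# cohort-level model
# ---------------------------------------------------------------------------

DEFAULT_TRACTS = ("dhc", "ac")
DEFAULT_TASKS = ("cpwm", "psmt", "lswmt")
DEFAULT_VOLUMES = ("hippocampus", "amygdala", "entorhinal",
                   "parahippocampal", "temporal_pole")


class StructureCognitionModel:
    """Cohort-level structure-cognition analysis.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject.  Tract metrics are ``{tract}_{metric}`` columns
        (``dhc_fa``, ``dhc_md``, ...), cognition scores and volumes are named
        columns, and ``icv`` holds total intracranial volume.  Subjects with
        missing tract metrics are excluded listwise so that all between-tract
        comparisons are made on the same (dependent) sample.
    """

    def __init__(self, cohort: pd.DataFrame,
                 tracts=DEFAULT_TRACTS, tasks=DEFAULT_TASKS,
                 metrics=("fa", "md"),
                 volumes=DEFAULT_VOLUMES, icv_col: str = "icv"):
        self.tracts = tuple(tracts)
        self.tasks = tuple(tasks)
        self.metrics = tuple(metrics)
        self.volumes = tuple(volumes) if volumes else ()
        self.icv_col = icv_col
        tract_cols = [f"{t}_{m}" for t in self.tracts for m in self.metrics]
        needed = tract_cols + list(self.tasks)
        if self.volumes:
            needed += list(self.volumes) + [icv_col]
        missing = [c for c in needed if c not in cohort.columns]
        if missing:
            raise ValidationError(f"cohort table lacks column(s): {missing}")
        complete = cohort.dropna(subset=tract_cols + list(self.tasks))
        if "subject" in complete.columns and complete["subject"].duplicated().any():
            raise ValidationError("duplicated subject ids in cohort")
        self.cohort = complete.reset_index(drop=True)
        self.n_complete = len(self.cohort)
        if self.n_complete < 4:
            raise ValidationError("fewer than 4 complete-case subjects")

    # -- correlation families ------------------------------------------------

    def _tract_family(self, tract: str, n_boot: int, seeds) -> pd.DataFrame:
        rows = []
        for i, (metric, task) in enumerate(
                (m, t) for m in self.metrics for t in self.tasks):
            x = self.cohort[f"{tract}_{metric}"].to_numpy()
            y = self.cohort[task].to_numpy()
            res = pearson_bootstrap(x, y, n_boot=n_boot, seed=seeds[i])
            rows.append({"tract": tract, "metric": metric, "task": task,
                         "r": res.r, "n": res.n, "p": res.p,
                         "ci_low": res.ci_low, "ci_high": res.ci_high})
        fam = pd.DataFrame(rows)
        fam["p_holm"] = holm_adjust(fam["p"].to_numpy(), m=len(fam))
        fam["family"] = f"{tract}:structure-cognition"
        fam["m"] = len(fam)
        return fam

    def fit(self, n_boot: int = 1000, alpha: float = 0.05, seed=None,
            sensitivity: bool = True) -> "StructureCognitionResults":
        """Run the full analysis; deterministic under ``seed``."""
        ss = np.random.SeedSequence(seed)
        n_tract_tests = len(self.metrics) * len(self.tasks)
        tract_seeds = ss.spawn(len(self.tracts))
        fams = []
        for tract, t_ss in zip(self.tracts, tract_seeds):
            fams.append(self._tract_family(tract, n_boot, t_ss.spawn(n_tract_tests)))
        tract_corr = pd.concat(fams, ignore_index=True)
        tract_corr["significant"] = tract_corr["p_holm"] <= alpha

        comparisons = self._compare_tracts(tract_corr[tract_corr["significant"]])
        volume_corr = self._volume_family(n_boot, ss.spawn(1)[0]) \
            if self.volumes else None
        sens = self._sensitivity(tract_corr[tract_corr["significant"]]) \
            if sensitivity else None
        return StructureCognitionResults(
            model=self, tract_correlations=tract_corr, comparisons=comparisons,
            volume_correlations=volume_corr, sensitivity=sens,
            alpha=alpha, n_boot=n_boot,
        )

    def _compare_tracts(self, significant: pd.DataFrame) -> pd.DataFrame:
        """Steiger comparison of each significant association against the
        corresponding correlation in every other tract (shared variable =
        the cognitive score)."""
        rows = []
        n = self.n_complete
        for _, row in significant.iterrows():
            for other in self.tracts:
                if other == row["tract"]:
                    continue
                a = self.cohort[f"{row['tract']}_{row['metric']}"].to_numpy()
                b = self.cohort[f"{other}_{row['metric']}"].to_numpy()
                y = self.cohort[row["task"]].to_numpy()
                r1 = float(sps.pearsonr(a, y).statistic)
                r2 = float(sps.pearsonr(b, y).statistic)
                r12 = float(sps.pearsonr(a, b).statistic)
                cmp_res = steiger_dependent_z(r1, r2, r12, n, tail="one")
                rows.append({"tract": row["tract"], "vs": other,
                             "metric": row["metric"], "task": row["task"],
                             "r1": r1, "r2": r2, "r12": r12, "n": n,
                             "z": cmp_res.z, "p": cmp_res.p,
                             "q_abs": abs(cmp_res.q)})
        return pd.DataFrame(rows, columns=["tract", "vs", "metric", "task",
                                           "r1", "r2", "r12", "n", "z", "p",
                                           "q_abs"])

    def _volume_family(self, n_boot: int, ss) -> pd.DataFrame:
        icv = self.cohort[self.icv_col].to_numpy()
        seeds = ss.spawn(len(self.volumes) * len(self.tasks))
        rows = []
        i = 0
        for vol in self.volumes:
            adj = icv_adjust(self.cohort[vol].to_numpy(), icv)
            for task in self.tasks:
                res = pearson_bootstrap(adj, self.cohort[task].to_numpy(),
                                        n_boot=n_boot, seed=seeds[i])
                i += 1
                rows.append({"volume": vol, "task": task, "r": res.r,
                             "n": res.n, "p": res.p,
                             "ci_low": res.ci_low, "ci_high": res.ci_high})
        fam = pd.DataFrame(rows)
        fam["p_holm"] = holm_adjust(fam["p"].to_numpy(), m=len(fam))
        fam["m"] = len(fam)
        return fam

    def _sensitivity(self, significant: pd.DataFrame) -> dict:
        """Spearman, boxplot-rule (1.5 IQR) outlier re-run, and Bayes factor
        for each Holm-significant structure-cognition association."""
        blocks = []
        for _, row in significant.iterrows():
            x = self.cohort[f"{row['tract']}_{row['metric']}"].to_numpy()
            y = self.cohort[row["task"]].to_numpy()
            rho, p_s = spearman(x, y)
            q1, q3 = np.percentile(x, [25, 75])
            iqr = q3 - q1
            keep = (x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)
            if keep.sum() >= 4 and keep.sum() < len(x):
                trimmed = sps.pearsonr(x[keep], y[keep])
                r_trim, p_trim = float(trimmed.statistic), float(trimmed.pvalue)
            else:
                r_trim, p_trim = np.nan, np.nan
            r_full = float(sps.pearsonr(x, y).statistic)
            bayes = correlation_bf10(r_full, len(x))
            blocks.append({
                "tract": row["tract"], "metric": row["metric"],
                "task": row["task"],
                "spearman_rho": rho, "spearman_p": p_s,
                "n_outliers": int(len(x) - keep.sum()),
                "r_no_outliers": r_trim, "p_no_outliers": p_trim,
                "bf10": bayes.bf10, "bci_low": bayes.ci_low,
                "bci_high": bayes.ci_high,
            })
        return {"per_association": pd.DataFrame(blocks)}


@dataclass
class StructureCognitionResults:
    """Fitted structure-cognition tables with a printable summary."""

    model: StructureCognitionModel
    tract_correlations: pd.DataFrame
    comparisons: pd.DataFrame
    volume_correlations: pd.DataFrame | None
    sensitivity: dict | None
    alpha: float
    n_boot: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.tract_correlations[self.tract_correlations["significant"]]

    def summary(self) -> str:
        lines = [
            "Structure-cognition analysis",
            "=" * 60,
            f"complete-case subjects: {self.model.n_complete}",
            f"bootstrap resamples: {self.n_boot}; alpha = {self.alpha}",
            "",
            "Tract correlations (Holm-adjusted within tract):",
            self.tract_correlations.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if len(self.comparisons):
            lines += ["", "Dependent-correlation comparisons (Steiger Z, one-tailed):",
                      self.comparisons.to_string(
                          index=False, float_format=lambda v: f"{v:.4g}")]
        if self.volume_correlations is not None:
            lines += ["", "ICV-adjusted volume correlations (Holm over family):",
                      self.volume_correlations.to_string(
                          index=False, float_format=lambda v: f"{v:.4g}")]
        if self.sensitivity is not None and len(self.sensitivity["per_association"]):
            lines += ["", "Sensitivity (Spearman / outlier re-run / Bayes factor):",
                      self.sensitivity["per_association"].to_string(
                          index=False, float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    def plot_association(self, tract: str, metric: str, task: str, ax=None):
        """Scatter of a structure-cognition pair with its OLS line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        x = self.model.cohort[f"{tract}_{metric}"].to_numpy()
        y = self.model.cohort[task].to_numpy()
        ax.scatter(x, y, s=12, alpha=0.7)
        coef = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, np.polyval(coef, xs), color="C3")
        ax.set_xlabel(f"{tract} {metric}")
        ax.set_ylabel(task)
        return ax


def run_structure_cognition_analysis(cohort: pd.DataFrame, config=None,
                                     **fit_kwargs) -> StructureCognitionResults:
    """Functional wrapper: build the model from a cohort table and fit it."""
    kwargs = {}
    if config is not None:
        kwargs = {"n_boot": config.stats.n_boot, "alpha": config.stats.alpha}
    kwargs.update(fit_kwargs)
    return StructureCognitionModel(cohort).fit(**kwargs)
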