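"""Two-sample MR estimator panel with heterogeneity diagnostics.

Each per-SNP causal estimate is a Wald ratio (SNP-outcome beta over
SNP-exposure beta, SE by the first-order NOME approximation). The panel
pools them five ways with different robustness to horizontal pleiotropy:

* ``IVWEstimator`` — inverse-variance-weighted meta-analysis, equivalently a
  zero-intercept weighted regression of outcome betas on exposure betas;
  multiplicative random effects inflate the SE by the residual scale
  (floored at 1) when Cochran's Q exceeds its degrees of freedom.
* ``EggerEstimator`` — the same weighted regression with a free intercept;
  the slope is consistent under the InSIDE assumption and a non-zero
  intercept indicates directional pleiotropy.
* ``WeightedMedianEstimator`` — inverse-variance-weighted median of the Wald
  ratios; consistent when under half the weight is on invalid instruments.
* ``ModeEstimator`` — argmax of a kernel-smoothed density of the ratios
  (simple or inverse-variance-weighted); consistent when the largest
  cluster of instruments is valid.

Estimators follow the scikit-learn protocol: construct with hyperparameters,
``fit`` on a :class:`~mrmediate.sumstats.HarmonizedInstrumentSet` (or a
DataFrame/array with columns beta_exposure, se_exposure, beta_outcome,
se_outcome), read fitted attributes with trailing underscores. Module-level
functions mirroring the estimator names are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .sumstats import HarmonizedInstrumentSet

Z95 = 1.96  # normal quantile used for all 95% confidence intervals
_TINY_P = 1e-300

DEFAULT_BOOT = 1000
DEFAULT_SEED = 20240401

INSTRUMENT_COLUMNS = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


@dataclass
class MRMethodResult:
    """One estimator's causal estimate with uncertainty."""

    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    scale: str = "sd"


@dataclass
class HeterogeneityResult:
    """Cochran's Q (and, for Egger fits, the intercept pleiotropy test)."""

    q: float
    df: int
    q_pvalue: float
    egger_intercept: float | None = None
    egger_intercept_pvalue: float | None = None


def _clamp_p(p: float) -> float:
    return float(min(max(p, _TINY_P), 1.0))


def _two_sided_normal_p(z: float) -> float:
    return _clamp_p(2.0 * stats.norm.sf(abs(z)))


def _extract(X):
    """Coerce instrument data to (bx, sx, by, sy) float arrays with checks."""
    if isinstance(X, HarmonizedInstrumentSet):
        arrs = (X.beta_exposure, X.se_exposure, X.beta_outcome, X.se_outcome)
    elif isinstance(X, pd.DataFrame):
        missing = [c for c in INSTRUMENT_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"instrument frame missing columns {missing}")
        arrs = tuple(X[c].to_numpy(float) for c in INSTRUMENT_COLUMNS)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError(
                "expected an (n_snps, 4) array with columns "
                "(beta_exposure, se_exposure, beta_outcome, se_outcome)"
            )
        arrs = tuple(arr[:, i] for i in range(4))
    bx, sx, by, sy = (np.asarray(a, float).ravel() for a in arrs)
    if not (len(bx) == len(sx) == len(by) == len(sy)):
        raise ValueError("instrument columns have unequal lengths")
    for a in (bx, sx, by, sy):
        if not np.all(np.isfinite(a)):
            raise ValueError("instrument data must be finite")
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("standard errors must be positive")
    if np.any(bx == 0):
        raise ValueError("beta_exposure of 0 gives an undefined Wald ratio; drop the variant")
    return bx, sx, by, sy


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float):
    """Single-SNP causal estimate: beta_out/beta_exp, SE = se_out/|beta_exp|.

    The SE is the first-order (NOME) approximation that ignores exposure
    uncertainty, appropriate for strong instruments.
    """
    if beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    if se_out <= 0:
        raise ValueError("se_out must be positive")
    return beta_out / beta_exp, se_out / abs(beta_exp)


class _FittedMixin:
    def _check_fitted(self):
        if not hasattr(self, "estimate_"):
            raise AttributeError(f"{type(self).__name__} is not fitted yet; call fit first")

    def _finalize(self, scale: str = "sd"):
        self.ci_low_ = self.estimate_ - Z95 * self.se_
        self.ci_high_ = self.estimate_ + Z95 * self.se_
        self.scale_ = scale

    def result(self) -> MRMethodResult:
        self._check_fitted()
        return MRMethodResult(
            method=self.method,
            n_snps=self.n_snps_,
            beta=float(self.estimate_),
            se=float(self.se_),
            ci_low=float(self.ci_low_),
            ci_high=float(self.ci_high_),
            pvalue=float(self.pvalue_),
            scale=self.scale_,
        )


class IVWEstimator(BaseEstimator, _FittedMixin):
    """Inverse-variance-weighted MR with multiplicative random effects.

    Weights are 1/se_outcome^2, so the pooled estimate is the slope of the
    zero-intercept weighted regression of outcome betas on exposure betas.
    With ``random_effects=True`` the fixed-effects SE is inflated by
    sqrt(Q/(n-1)) when Cochran's Q exceeds its expectation (floor at 1), the
    common implementation of the multiplicative random-effects IVW.
    """

    method = "ivw_mre"

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y=None):
        bx, sx, by, sy = _extract(X)
        n = len(bx)
        if n < 1:
            raise ValueError("IVW requires at least one instrument")
        w = 1.0 / sy**2
        denom = np.sum(w * bx**2)
        beta = float(np.sum(w * bx * by) / denom)
        fixed_se = float(denom**-0.5)
        q = float(np.sum(w * (by - beta * bx) ** 2))
        df = n - 1
        if self.random_effects and df > 0:
            scale_factor = max(1.0, np.sqrt(q / df))
        else:
            scale_factor = 1.0
        self.n_snps_ = n
        self.estimate_ = beta
        self.fixed_se_ = fixed_se
        self.scale_factor_ = float(scale_factor)
        self.se_ = fixed_se * scale_factor
        self.pvalue_ = _two_sided_normal_p(beta / self.se_)
        self.q_ = q
        self.q_df_ = df
        self.q_pvalue_ = _clamp_p(stats.chi2.sf(q, df)) if df > 0 else 1.0
        self._finalize(getattr(X, "scale", "sd"))
        return self

    def heterogeneity(self) -> HeterogeneityResult:
        self._check_fitted()
        return HeterogeneityResult(q=self.q_, df=self.q_df_, q_pvalue=self.q_pvalue_)


class EggerEstimator(BaseEstimator, _FittedMixin):
    """MR-Egger regression: weighted fit of outcome on exposure betas with a
    free intercept.

    Instruments are first recoded so every beta_exposure is positive (Egger
    is not invariant to allele coding; a canonical orientation makes the fit
    reproducible). The residual variance is floored at 1 (multiplicative
    random effects) and inference uses a t distribution with n - 2 df. The
    intercept estimates the average directional pleiotropic effect.
    """

    method = "egger"

    def fit(self, X, y=None):
        bx, sx, by, sy = _extract(X)
        n = len(bx)
        if n < 3:
            raise ValueError("MR-Egger requires at least 3 instruments")
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        w = 1.0 / sy**2
        design = np.column_stack([np.ones(n), bx])
        xtwx = design.T @ (w[:, None] * design)
        xtwy = design.T @ (w * by)
        coef = np.linalg.solve(xtwx, xtwy)
        resid = by - design @ coef
        rss_w = float(np.sum(w * resid**2))
        df = n - 2
        sigma2 = max(1.0, rss_w / df)
        cov = np.linalg.inv(xtwx) * sigma2
        intercept, slope = coef
        se_int, se_slope = np.sqrt(np.diag(cov))

        self.n_snps_ = n
        self.estimate_ = float(slope)
        self.se_ = float(se_slope)
        self.pvalue_ = _clamp_p(2.0 * stats.t.sf(abs(slope / se_slope), df))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_pvalue_ = _clamp_p(2.0 * stats.t.sf(abs(intercept / se_int), df))
        self.residual_scale_ = float(sigma2)
        self.q_ = rss_w
        self.q_df_ = df
        self.q_pvalue_ = _clamp_p(stats.chi2.sf(rss_w, df))
        self._finalize(getattr(X, "scale", "sd"))
        return self

    def heterogeneity(self) -> HeterogeneityResult:
        self._check_fitted()
        return HeterogeneityResult(
            q=self.q_,
            df=self.q_df_,
            q_pvalue=self.q_pvalue_,
            egger_intercept=self.intercept_,
            egger_intercept_pvalue=self.intercept_pvalue_,
        )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median with mid-cumulative standardised weights."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, v))


class WeightedMedianEstimator(BaseEstimator, _FittedMixin):
    """Weighted median of Wald ratios; SE by parametric bootstrap.

    Ratios are weighted by the inverse variance of each Wald ratio. The
    bootstrap perturbs the per-SNP exposure and outcome betas by their SEs
    and takes the standard deviation of the re-estimated median.
    """

    method = "weighted_median"

    def __init__(self, n_boot: int = DEFAULT_BOOT, random_state: int = DEFAULT_SEED):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        bx, sx, by, sy = _extract(X)
        n = len(bx)
        if n < 3:
            raise ValueError("weighted median requires at least 3 instruments")
        ratios = by / bx
        w = (bx / sy) ** 2  # 1 / Var(wald ratio) under NOME
        self.estimate_ = _weighted_median(ratios, w)

        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb = bx + rng.standard_normal(n) * sx
            byb = by + rng.standard_normal(n) * sy
            bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
            boots[b] = _weighted_median(byb / bxb, (bxb / sy) ** 2)
        self.se_ = float(np.std(boots, ddof=1))
        self.n_snps_ = n
        self.pvalue_ = _two_sided_normal_p(self.estimate_ / self.se_) if self.se_ > 0 else _TINY_P
        self._finalize(getattr(X, "scale", "sd"))
        return self


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9 * min(sd, MAD) * n^(-1/5), scaled by
    ``factor``; falls back to whichever of sd/MAD is positive."""
    sd = float(np.std(ratios, ddof=1))
    mad = float(1.4826 * np.median(np.abs(ratios - np.median(ratios))))
    spreads = [s for s in (sd, mad) if s > 0]
    if not spreads:
        return 0.0
    return factor * 0.9 * min(spreads) * len(ratios) ** (-0.2)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float, n_grid: int = 2048) -> float:
    h = _mode_bandwidth(ratios, bandwidth_factor)
    if h == 0.0:  # all ratios identical
        return float(ratios[0])
    grid = np.linspace(ratios.min() - h, ratios.max() + h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


class ModeEstimator(BaseEstimator, _FittedMixin):
    """Mode-based MR: argmax of the kernel-smoothed Wald-ratio density.

    ``weighted=False`` gives the simple mode (equal weights),
    ``weighted=True`` the weighted mode (inverse-variance weights in the
    density). Bandwidth is a modified Silverman rule on the ratios scaled by
    ``bandwidth_factor``; SE by the same parametric bootstrap as the
    weighted median.
    """

    def __init__(
        self,
        weighted: bool = False,
        bandwidth_factor: float = 1.0,
        n_boot: int = DEFAULT_BOOT,
        random_state: int = DEFAULT_SEED,
    ):
        self.weighted = weighted
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.random_state = random_state

    @property
    def method(self) -> str:
        return "weighted_mode" if self.weighted else "simple_mode"

    def _weights(self, bx, sy):
        return (bx / sy) ** 2 if self.weighted else np.ones_like(bx)

    def fit(self, X, y=None):
        bx, sx, by, sy = _extract(X)
        n = len(bx)
        if n < 3:
            raise ValueError("mode estimation requires at least 3 instruments")
        ratios = by / bx
        self.bandwidth_ = _mode_bandwidth(ratios, self.bandwidth_factor)
        self.estimate_ = _mode_point(ratios, self._weights(bx, sy), self.bandwidth_factor)

        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb = bx + rng.standard_normal(n) * sx
            byb = by + rng.standard_normal(n) * sy
            bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
            boots[b] = _mode_point(byb / bxb, self._weights(bxb, sy), self.bandwidth_factor)
        self.se_ = float(np.std(boots, ddof=1))
        self.n_snps_ = n
        self.pvalue_ = _two_sided_normal_p(self.estimate_ / self.se_) if self.se_ > 0 else _TINY_P
        self._finalize(getattr(X, "scale", "sd"))
        return self


# ---------------------------------------------------------------------------
# functional wrappers and diagnostics


def ivw_mre(h) -> tuple[MRMethodResult, HeterogeneityResult]:
    est = IVWEstimator().fit(h)
    return est.result(), est.heterogeneity()


def mr_egger(h) -> tuple[MRMethodResult, HeterogeneityResult]:
    est = EggerEstimator().fit(h)
    return est.result(), est.heterogeneity()


def weighted_median(h, n_boot: int = DEFAULT_BOOT, seed: int = DEFAULT_SEED) -> MRMethodResult:
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(h).result()


def mode_estimate(
    h, weighted: bool = False, bandwidth_factor: float = 1.0,
    n_boot: int = DEFAULT_BOOT, seed: int = DEFAULT_SEED,
) -> MRMethodResult:
    return ModeEstimator(
        weighted=weighted, bandwidth_factor=bandwidth_factor, n_boot=n_boot, random_state=seed
    ).fit(h).result()


def cochran_q(h, beta_hat: float) -> HeterogeneityResult:
    """Cochran's Q about a supplied pooled estimate, chi-square on n-1 df."""
    bx, sx, by, sy = _extract(h)
    n = len(bx)
    if n < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - beta_hat * bx) ** 2))
    df = n - 1
    return HeterogeneityResult(q=q, df=df, q_pvalue=_clamp_p(stats.chi2.sf(q, df)))


def beta_to_or(beta: float, se: float, scale: str = "log_odds"):
    """Exponentiate a log-odds estimate to an odds ratio with 95% CI."""
    if scale != "log_odds":
        raise ValueError(f"odds-ratio conversion requires a log_odds outcome, got scale={scale!r}")
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


@dataclass
class PanelReport:
    """Full estimator-panel output for one exposure-outcome pair."""

    exposure_label: str
    outcome_label: str
    n_snps: int
    mean_f: float
    scale: str
    results: dict = field(default_factory=dict)  # method -> MRMethodResult
    heterogeneity: dict = field(default_factory=dict)  # method -> HeterogeneityResult
    absent: dict = field(default_factory=dict)  # method -> reason

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, res in self.results.items():
            het = self.heterogeneity.get(method)
            rows.append(
                {
                    "exposure": self.exposure_label,
                    "outcome": self.outcome_label,
                    "method": method,
                    "n_snps": res.n_snps,
                    "beta": res.beta,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "pvalue": res.pvalue,
                    "scale": res.scale,
                    "mean_f": self.mean_f,
                    "q": het.q if het else np.nan,
                    "q_df": het.df if het else np.nan,
                    "q_pvalue": het.q_pvalue if het else np.nan,
                    "egger_intercept": het.egger_intercept if het and het.egger_intercept is not None else np.nan,
                    "egger_intercept_pvalue": (
                        het.egger_intercept_pvalue if het and het.egger_intercept_pvalue is not None else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)


def run_method_panel(
    h: HarmonizedInstrumentSet,
    n_boot: int = DEFAULT_BOOT,
    seed: int = DEFAULT_SEED,
    bandwidth_factor: float = 1.0,
) -> PanelReport:
    """Run the full estimator panel, degrading gracefully for small sets.

    One instrument gives the Wald ratio only; two give IVW; three or more
    give IVW, MR-Egger, weighted median and the two modes. Per-method
    failures are recorded as absent entries with reasons, never raised.
    """
    from .sumstats import mean_f_statistic

    n = len(h)
    report = PanelReport(
        exposure_label=h.exposure_label,
        outcome_label=h.outcome_label,
        n_snps=n,
        mean_f=mean_f_statistic(h),
        scale=h.scale,
    )

    if n == 1:
        beta, se = wald_ratio(
            h.beta_exposure[0], h.se_exposure[0], h.beta_outcome[0], h.se_outcome[0]
        )
        report.results["wald_ratio"] = MRMethodResult(
            method="wald_ratio", n_snps=1, beta=float(beta), se=float(se),
            ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
            pvalue=_two_sided_normal_p(beta / se), scale=h.scale,
        )
        for m in ("ivw_mre", "egger", "weighted_median", "simple_mode", "weighted_mode"):
            report.absent[m] = "requires more instruments"
        return report

    candidates: list[tuple[str, object]] = [("ivw_mre", IVWEstimator())]
    if n >= 3:
        candidates += [
            ("egger", EggerEstimator()),
            ("weighted_median", WeightedMedianEstimator(n_boot=n_boot, random_state=seed)),
            ("simple_mode", ModeEstimator(weighted=False, bandwidth_factor=bandwidth_factor,
                                          n_boot=n_boot, random_state=seed)),
            ("weighted_mode", ModeEstimator(weighted=True, bandwidth_factor=bandwidth_factor,
                                            n_boot=n_boot, random_state=seed)),
        ]
    else:
        for m in ("egger", "weighted_median", "simple_mode", "weighted_mode"):
            report.absent[m] = "requires at least 3 instruments"

    for name, est in candidates:
        try:
            est.fit(h)
        except (ValueError, np.linalg.LinAlgError) as exc:
            report.absent[name] = str(exc)
            continue
        report.results[name] = est.result()
        if hasattr(est, "heterogeneity"):
            report.heterogeneity[name] = est.heterogeneity()
    return report
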