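"""Causal-effect estimators: three TSLS variants and summary-data MR methods.

The three instrumental-variable estimators mirror the trio design:

* ``mr_tsls1`` — plain TSLS of the outcome on the exposure with the offspring
  weighted allele score as the single instrument.
* ``mr_tsls2`` — TSLS adjusting for the mother's and father's allele scores in
  both stages; the joint Wald test of the parental-score coefficients in the
  structural equation is a test for the presence (and, via their signs, the
  direction) of assortative-mating bias.
* ``mr_tsls3`` — three endogenous regressors (offspring, mother and father
  exposure phenotypes) instrumented by the offspring score and the two
  parental nontransmitted scores; the parental coefficients estimate direct
  (dynastic) parental effects and their joint Wald test again flags
  assortment/dynastic bias.

Summary-data methods (IVW, MR-Egger, weighted median, mode-based estimate)
operate on per-SNP exposure and outcome association statistics and follow the
standard formulations from their source publications.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scores import ScoreSet
from .sim_population import TrioDataset

__all__ = [
    "IdentificationError",
    "EstimateResult",
    "SummaryStats",
    "fit_2sls",
    "mr_tsls1",
    "mr_tsls2",
    "mr_tsls3",
    "snp_summary_stats",
    "summary_mr",
    "heterogeneity_tests",
    "score_correlation_test",
]

Z95 = 1.959963984540054  # normal 97.5% quantile, for 95% CIs


class IdentificationError(ValueError):
    """Raised when the IV system is under-identified or rank-deficient."""


@dataclass
class EstimateResult:
    """A causal-effect estimate with normal-theory 95% CI and auxiliaries."""

    method: str
    estimate: float
    se: float
    n: int
    aux: dict = field(default_factory=dict)  # named auxiliary coefficients/SEs
    assort_stat: Optional[float] = None  # joint Wald statistic (chi-square)
    assort_df: Optional[int] = None
    assort_p: Optional[float] = None

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)

    @property
    def p_value(self) -> float:
        if self.se == 0:
            return 0.0 if self.estimate != 0 else 1.0
        z = self.estimate / self.se
        return 2 * stats.norm.sf(abs(z))

    def ci_excludes(self, value: float) -> bool:
        lo, hi = self.ci
        return value < lo or value > hi


@dataclass
class SummaryStats:
    """Per-SNP association statistics for summary-data MR."""

    snp_id: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    n_x: np.ndarray
    n_y: np.ndarray

    def __post_init__(self):
        arrs = [np.asarray(getattr(self, f), dtype=float if f != "snp_id" else None)
                for f in ("snp_id", "beta_x", "se_x", "beta_y", "se_y", "n_x", "n_y")]
        n = arrs[0].shape
        for f, a in zip(("snp_id", "beta_x", "se_x", "beta_y", "se_y", "n_x", "n_y"), arrs):
            if a.shape != n:
                raise ValueError("summary-stat vectors must have equal length")
            setattr(self, f, a)
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.beta_x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "beta_x": self.beta_x, "se_x": self.se_x,
            "beta_y": self.beta_y, "se_y": self.se_y,
            "n_x": self.n_x.astype(int), "n_y": self.n_y.astype(int)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SummaryStats":
        return cls(**{c: df[c].to_numpy() for c in
                      ("snp_id", "beta_x", "se_x", "beta_y", "se_y", "n_x", "n_y")})


# ---------------------------------------------------------------------------
# Two-stage least squares
# ---------------------------------------------------------------------------


@dataclass
class IVFit:
    """Raw 2SLS fit: coefficients and covariance for [endog..., exog..., const]."""

    params: np.ndarray
    cov: np.ndarray
    names: list[str]
    n: int
    resid: np.ndarray

    def wald(self, which: Sequence[int]) -> tuple[float, int, float]:
        """Joint Wald chi-square test that the selected coefficients are 0."""
        idx = np.asarray(which, dtype=int)
        b = self.params[idx]
        v = self.cov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError as e:
            raise IdentificationError("singular covariance in Wald test") from e
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))


def fit_2sls(y: np.ndarray, endog: np.ndarray, instruments: np.ndarray,
             exog: Optional[np.ndarray] = None, robust: bool = False,
             names: Optional[list[str]] = None) -> IVFit:
    """Two-stage least squares with IV-consistent standard errors.

    ``endog`` (n, k_end) are the endogenous regressors, ``instruments``
    (n, k_iv) the excluded instruments, ``exog`` (n, k_ex) optional included
    exogenous covariates.  A constant is always appended.  The coefficient
    covariance is the IV sandwich s^2 (X'P_Z X)^{-1} (homoskedastic, with
    s^2 = e'e/(n-k) from the *structural* residuals, so first-stage estimation
    error is accounted for), or the HC0 heteroskedasticity-robust form when
    ``robust`` is set.
    """
    y = np.asarray(y, dtype=float).ravel()
    endog = np.atleast_2d(np.asarray(endog, dtype=float))
    if endog.shape[0] != len(y):
        endog = endog.T
    n = len(y)
    instruments = np.atleast_2d(np.asarray(instruments, dtype=float))
    if instruments.shape[0] != n:
        instruments = instruments.T
    blocks_x = [endog]
    blocks_z = [instruments]
    if exog is not None and np.size(exog):
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != n:
            exog = exog.T
        blocks_x.append(exog)
        blocks_z.append(exog)
    const = np.ones((n, 1))
    X = np.hstack(blocks_x + [const])
    Z = np.hstack(blocks_z + [const])
    k_end = endog.shape[1]
    if Z.shape[1] < X.shape[1]:
        raise IdentificationError(
            f"under-identified: {Z.shape[1]} instruments for {X.shape[1]} regressors")

    # first stage projection X_hat = P_Z X via least squares (rank-checked)
    ztz = Z.T @ Z
    rank = np.linalg.matrix_rank(ztz)
    if rank < Z.shape[1]:
        raise IdentificationError("instrument matrix is rank deficient")
    coef_first = np.linalg.solve(ztz, Z.T @ X)
    Xhat = Z @ coef_first
    xtx = Xhat.T @ X  # equals X'P_Z X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise IdentificationError("X'P_Z X is rank deficient (weak/collinear system)")
    params = np.linalg.solve(xtx, Xhat.T @ y)
    resid = y - X @ params
    bread = np.linalg.inv(xtx)
    if robust:
        meat = (Xhat * resid[:, None] ** 2).T @ Xhat
        cov = bread @ meat @ bread.T
    else:
        dof = max(n - X.shape[1], 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * bread
    if names is None:
        names = [f"endog{i}" for i in range(k_end)]
        if exog is not None and np.size(exog):
            names += [f"exog{i}" for i in range(exog.shape[1])]
    names = list(names) + ["const"]
    return IVFit(params=params, cov=cov, names=names, n=n, resid=resid)


def _result_from_fit(fit: IVFit, method: str, causal_idx: int = 0,
                     aux_idx: Optional[Sequence[int]] = None) -> EstimateResult:
    aux = {}
    assort = (None, None, None)
    if aux_idx:
        for i in aux_idx:
            aux[fit.names[i]] = float(fit.params[i])
            aux[f"se_{fit.names[i]}"] = float(math.sqrt(fit.cov[i, i]))
        assort = fit.wald(aux_idx)
    return EstimateResult(
        method=method, estimate=float(fit.params[causal_idx]),
        se=float(math.sqrt(fit.cov[causal_idx, causal_idx])), n=fit.n, aux=aux,
        assort_stat=assort[0], assort_df=assort[1], assort_p=assort[2])


def mr_tsls1(scores: ScoreSet, trios: TrioDataset, robust: bool = False) -> EstimateResult:
    """Plain TSLS: outcome on exposure, offspring allele score as instrument."""
    r = scores.rows
    fit = fit_2sls(trios.y[r], trios.x[r], scores.s, robust=robust,
                   names=["causal"])
    return _result_from_fit(fit, "tsls1")


def mr_tsls2(scores: ScoreSet, trios: TrioDataset, robust: bool = False) -> EstimateResult:
    """TSLS adjusting for parental allele scores in both stages.

    The parental-score coefficients in the structural equation carry the
    assortment signal; their joint 2-df Wald test is reported as the
    assortment test, and the signed coefficients are kept as auxiliaries.
    """
    r = scores.rows
    exog = np.column_stack([scores.s_m, scores.s_f])
    fit = fit_2sls(trios.y[r], trios.x[r], scores.s, exog=exog, robust=robust,
                   names=["causal", "score_m", "score_f"])
    return _result_from_fit(fit, "tsls2", aux_idx=[1, 2])


def mr_tsls3(scores: ScoreSet, trios: TrioDataset, robust: bool = False) -> EstimateResult:
    """TSLS with nontransmitted parental scores instrumenting parental exposure.

    Endogenous regressors: offspring, mother and father exposure phenotypes;
    instruments: offspring score S and the nontransmitted scores W^m, W^f.
    The parental-phenotype coefficients estimate direct dynastic effects; the
    joint Wald test of the two is the assortment/dynastic test.
    """
    r = scores.rows
    x_m = trios.x_m[r]
    x_f = trios.x_f[r]
    if np.any(~np.isfinite(x_m)) or np.any(~np.isfinite(x_f)):
        raise ValueError("mr_tsls3 requires parental exposure phenotypes (x_m, x_f)")
    endog = np.column_stack([trios.x[r], x_m, x_f])
    instruments = np.column_stack([scores.s, scores.w_m, scores.w_f])
    fit = fit_2sls(trios.y[r], endog, instruments, robust=robust,
                   names=["causal", "dynastic_m", "dynastic_f"])
    return _result_from_fit(fit, "tsls3", aux_idx=[1, 2])


# ---------------------------------------------------------------------------
# Per-SNP summary statistics and summary-data MR
# ---------------------------------------------------------------------------


def _simple_regressions(g: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column simple regression of v on g: slopes and SEs."""
    n = len(v)
    gc = g - g.mean(axis=0)
    vc = v - v.mean()
    ss_g = np.einsum("ij,ij->j", gc, gc)
    slope = (gc.T @ vc) / ss_g
    resid_ss = float(vc @ vc) - slope**2 * ss_g
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / ss_g)
    return slope, se


def snp_summary_stats(trios: TrioDataset, instrument_snps: Optional[Sequence[int]] = None,
                      half: str = "B", two_sample: bool = False) -> SummaryStats:
    """Per-SNP exposure and outcome regressions on offspring genotype.

    One-sample by default (both regressions in the analysis half).  With
    ``two_sample`` the genotype-outcome regressions come from the opposite
    half, emulating non-overlapping exposure and outcome samples.
    """
    if instrument_snps is None:
        if trios.instrument_snps is None:
            raise ValueError("instrument_snps not given and not recorded")
        instrument_snps = trios.instrument_snps
    idx = np.asarray(instrument_snps, dtype=int)
    rows_x = trios.half(half)
    rows_y = trios.half("A" if half == "B" else "B") if two_sample else rows_x
    g_x = trios.g_o[np.ix_(rows_x, idx)].astype(float)
    g_y = trios.g_o[np.ix_(rows_y, idx)].astype(float)
    poly = (np.ptp(g_x, axis=0) > 0) & (np.ptp(g_y, axis=0) > 0)
    if not poly.all():
        warnings.warn(f"{int((~poly).sum())} monomorphic SNP(s) excluded from "
                      "summary statistics", RuntimeWarning)
    idx = idx[poly]
    g_x, g_y = g_x[:, poly], g_y[:, poly]
    bx, sx = _simple_regressions(g_x, trios.x[rows_x])
    by, sy = _simple_regressions(g_y, trios.y[rows_y])
    return SummaryStats(snp_id=idx, beta_x=bx, se_x=sx, beta_y=by, se_y=sy,
                        n_x=np.full(len(idx), len(rows_x)),
                        n_y=np.full(len(idx), len(rows_y)))


def _wald_ratios(stats_: SummaryStats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios, first-order SEs and IVW weights; drops beta_x == 0."""
    keep = stats_.beta_x != 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} SNP(s) with zero exposure association "
                      "excluded (undefined Wald ratio)", RuntimeWarning)
    bx, by = stats_.beta_x[keep], stats_.beta_y[keep]
    se_y = stats_.se_y[keep]
    ratio = by / bx
    se_ratio = np.abs(se_y / bx)  # first-order (NOME) approximation
    w = bx**2 / se_y**2  # = 1 / se_ratio^2
    return ratio, se_ratio, w


def _ivw(stats_: SummaryStats) -> tuple[float, float, np.ndarray, np.ndarray]:
    ratio, _, w = _wald_ratios(stats_)
    est = float(np.sum(w * ratio) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return est, se, ratio, w


def _weighted_median(ratio: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by cumulative-weight interpolation at 50%."""
    order = np.argsort(ratio)
    r = ratio[order]
    ws = w[order] / w.sum()
    cum = np.cumsum(ws) - ws / 2
    return float(np.interp(0.5, cum, r))


def _mbe_point(ratio: np.ndarray, w: Optional[np.ndarray], phi: float) -> float:
    """Mode of the kernel-smoothed Wald-ratio density.

    Bandwidth is phi times the modified Silverman rule
    0.9 min(sd, mad/0.6745) n^{-1/5}; a Gaussian kernel and a fine grid over
    the ratio range locate the mode.
    """
    n = len(ratio)
    sd = float(np.std(ratio, ddof=1)) if n > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratio, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    if s == 0.0:
        return float(ratio[0])  # all ratios identical
    h = max(phi * 0.9 * s * n ** (-0.2), 1e-12)
    lo, hi = ratio.min() - 3 * h, ratio.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    if w is None:
        w = np.ones(n)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def summary_mr(stats_: SummaryStats, method: str, phi: float = 1.0,
               weighted_mode: bool = True, n_boot: int = 1000,
               seed=0) -> EstimateResult:
    """Summary-data MR estimate by one of {ivw, egger, weighted_median, mbe}.

    * ``ivw``: fixed-effect inverse-variance-weighted mean of Wald ratios.
    * ``egger``: weighted regression of beta_Y on beta_X with intercept
      (weights 1/se_Y^2); slope is the causal estimate, the intercept is kept
      as the pleiotropy auxiliary.
    * ``weighted_median``: cumulative-weight interpolation at 50% with a
      parametric-bootstrap SE.
    * ``mbe``: mode of the kernel-smoothed ratio density (modified Silverman
      bandwidth scaled by ``phi``), parametric-bootstrap SE.
    """
    j = stats_.n_snps
    if method == "egger" and j < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    if method != "ivw" and j < 2:
        raise ValueError("summary-data MR needs at least 2 SNPs")
    if j < 1:
        raise ValueError("no SNPs in summary statistics")
    rng = np.random.default_rng(seed)

    if method == "ivw":
        est, se, _, _ = _ivw(stats_)
        return EstimateResult(method="ivw", estimate=est, se=se, n=j)

    if method == "egger":
        # orient so all exposure associations are positive (standard practice)
        sign = np.sign(stats_.beta_x)
        bx = stats_.beta_x * sign
        by = stats_.beta_y * sign
        w = 1.0 / stats_.se_y**2
        W = np.diag(w)
        X = np.column_stack([np.ones(j), bx])
        xtwx = X.T @ W @ X
        coef = np.linalg.solve(xtwx, X.T @ (w * by))
        resid = by - X @ coef
        # multiplicative overdispersion, floored at 1 (random-effect Egger)
        s2 = max(float(resid @ (w * resid)) / (j - 2), 1.0)
        cov = s2 * np.linalg.inv(xtwx)
        return EstimateResult(
            method="egger", estimate=float(coef[1]), se=float(math.sqrt(cov[1, 1])),
            n=j, aux={"intercept": float(coef[0]),
                      "se_intercept": float(math.sqrt(cov[0, 0]))})

    ratio, se_ratio, w = _wald_ratios(stats_)
    if method == "weighted_median":
        est = _weighted_median(ratio, w)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            rb = rng.normal(ratio, se_ratio)
            boots[b] = _weighted_median(rb, w)
        return EstimateResult(method="weighted_median", estimate=est,
                              se=float(np.std(boots, ddof=1)), n=j)

    if method == "mbe":
        wk = w if weighted_mode else None
        est = _mbe_point(ratio, wk, phi)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            rb = rng.normal(ratio, se_ratio)
            boots[b] = _mbe_point(rb, wk, phi)
        return EstimateResult(method="mbe", estimate=est,
                              se=float(np.std(boots, ddof=1)), n=j,
                              aux={"phi": phi})

    raise ValueError(f"unknown summary-data MR method: {method!r}")


def heterogeneity_tests(stats_: SummaryStats) -> dict:
    """Cochran's Q and the MR-Egger intercept test for pleiotropy/heterogeneity.

    Q = sum_k w_k (ratio_k - ivw)^2 ~ chi-square(J-1) under homogeneity with
    IVW weights w_k = beta_Xk^2 / se_Yk^2.
    """
    est, _, ratio, w = _ivw(stats_)
    q = float(np.sum(w * (ratio - est) ** 2))
    df = len(ratio) - 1
    out = {"q": q, "q_df": df, "q_p": float(stats.chi2.sf(q, df))}
    if stats_.n_snps >= 3:
        egger = summary_mr(stats_, "egger")
        z = egger.aux["intercept"] / egger.aux["se_intercept"]
        out.update(egger_intercept=egger.aux["intercept"],
                   egger_intercept_se=egger.aux["se_intercept"],
                   egger_intercept_p=float(2 * stats.norm.sf(abs(z))))
    return out


def score_correlation_test(score_x: np.ndarray, score_y: np.ndarray) -> dict:
    """Correlation between exposure and outcome allele scores.

    With unlinked instrument sets, a nonzero correlation indicates cross-trait
    assortative mating (or population substructure).
    """
    r, p = stats.pearsonr(score_x, score_y)
    return {"r": float(r), "p": float(p), "n": len(score_x)}
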