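"""Single-SNP logistic association models.

The IRLS logistic fitter here is the workhorse for every model in the
package (single-SNP codominant/trend models, haplotype-dosage GLMs,
interaction LRTs, and the permutation engine, which needs hundreds of
thousands of small refits).  Wald intervals are exp(beta +/- 1.96 SE);
the trend p-value is the two-sided Wald test on the 0/1/2 dosage term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cohort import MISSING, GenotypeMatrix

Z975 = 1.959963984540054

_W_FLOOR = 1e-10
_BETA_SEPARATION = 15.0


class AliasingWarning(UserWarning):
    pass


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

DEFAULT_COVARIATES = ("age", "sex", "center")

_CONTINUOUS = {"age", "vegetable_freq", "alcohol_freq"}


def build_design(subjects: pd.DataFrame,
                 covariates: Sequence[str] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Intercept + covariate columns; categoricals become dummy indicators
    (first level is the reference).  Rows with any missing covariate get NaN
    and are dropped listwise by the callers."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(subjects))}
    for cov in covariates:
        if cov not in subjects.columns:
            raise ModelError(f"covariate {cov!r} not in subject table")
        s = subjects[cov]
        if cov in _CONTINUOUS or (pd.api.types.is_numeric_dtype(s)
                                  and s.dropna().nunique() > 2):
            cols[cov] = pd.to_numeric(s).to_numpy(dtype=float)
        elif pd.api.types.is_numeric_dtype(s) and s.dropna().nunique() <= 2:
            cols[cov] = pd.to_numeric(s).to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True,
                                     dtype=float)
            na = s.isna().to_numpy()
            for c in dummies.columns:
                col = dummies[c].to_numpy()
                col[na] = np.nan
                cols[c] = col
    return pd.DataFrame(cols, index=subjects.index)


# ---------------------------------------------------------------------------
# IRLS logistic fit
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    converged: bool
    n: int
    dropped: list[str] = field(default_factory=list)
    separated: list[str] = field(default_factory=list)

    def wald_p(self, term: str) -> float:
        b, se = self.params[term], self.bse[term]
        if not np.isfinite(b) or not np.isfinite(se) or se == 0:
            return np.nan
        return float(2.0 * stats.norm.sf(abs(b / se)))

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        """(OR, 95% lower, 95% upper) for one coefficient."""
        b, se = self.params[term], self.bse[term]
        return (float(np.exp(b)), float(np.exp(b - Z975 * se)),
                float(np.exp(b + Z975 * se)))


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in sorted(piv[rank:])]
    if dropped:
        warnings.warn(f"dropping aliased column(s): {dropped}", AliasingWarning,
                      stacklevel=3)
    return X[:, keep], [names[i] for i in keep], dropped


def irls_logit(y: np.ndarray, X: np.ndarray, tol: float = 1e-8,
               max_iter: int = 100, start: np.ndarray | None = None,
               ) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Bare-array IRLS maximum-likelihood logistic fit.

    Returns (beta, covariance, log-likelihood, converged).  Convergence is
    |delta log-likelihood| < tol; step-halving guards overshoot.
    """
    n, p = X.shape
    beta = np.zeros(p) if start is None else start.copy()
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                      (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    converged = False
    XtWX = np.eye(p)
    for _ in range(max_iter):
        w = np.clip(mu * (1.0 - mu), _W_FLOOR, None)
        XtWX = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = linalg.solve(XtWX, score, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(XtWX, score)[0]
        new_beta = beta + step
        for _half in range(30):
            eta = X @ new_beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            new_ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                                  (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
            if new_ll >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        delta = new_ll - ll
        beta, ll = new_beta, new_ll
        if abs(delta) < tol:
            converged = True
            break
    w = np.clip(mu * (1.0 - mu), _W_FLOOR, None)
    XtWX = (X * w[:, None]).T @ X
    try:
        cov = linalg.inv(XtWX)
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, ll, converged


def fit_logistic(y: np.ndarray | pd.Series, design: pd.DataFrame,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression on a named design matrix.

    Rows with NaN anywhere are dropped listwise; aliased (rank-deficient)
    columns are dropped with a warning; complete separation is flagged via
    ``converged``/``separated`` and the runaway terms report NaN estimates.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y) & np.isfinite(design.to_numpy(dtype=float)).all(axis=1)
    yv = y[mask]
    Xdf = design.loc[mask]
    if len(yv) == 0:
        raise ModelError("no complete observations")
    if yv.min() == yv.max():
        raise ModelError("outcome has a single class")
    names = list(Xdf.columns)
    X, kept, dropped = _drop_aliased(Xdf.to_numpy(dtype=float), names)
    beta, cov, ll, converged = irls_logit(yv, X, tol=tol, max_iter=max_iter)

    separated = [kept[i] for i in range(len(kept))
                 if abs(beta[i]) > _BETA_SEPARATION]
    if separated:
        converged = False
        for i, nm in enumerate(kept):
            if nm in separated:
                beta[i] = np.nan
                cov[i, :] = cov[:, i] = np.nan

    params = pd.Series(beta, index=kept)
    bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=kept)
    return LogisticFit(params=params, bse=bse,
                       cov_params=pd.DataFrame(cov, index=kept, columns=kept),
                       llf=ll, converged=converged, n=len(yv), dropped=dropped,
                       separated=separated)


# ---------------------------------------------------------------------------
# per-SNP models
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    rsid: str
    model: str                        # "codominant" | "trend" | "joint"
    terms: pd.DataFrame               # term, OR, lcl, ucl, p
    trend_p: float
    n: int
    covariates: tuple[str, ...]
    fit: LogisticFit | None = None


def _snp_series(gm: GenotypeMatrix, rsid: str) -> np.ndarray:
    g = gm.column(rsid).astype(float)
    g[g == MISSING] = np.nan
    return g


def snp_models(gm: GenotypeMatrix, subjects: pd.DataFrame, rsid: str,
               covariates: Sequence[str] = DEFAULT_COVARIATES,
               ) -> tuple[AssociationResult, AssociationResult]:
    """Codominant and trend logistic models for one SNP.

    Codominant: heterozygote and rare-homozygote indicators vs the common
    homozygote; trend: a single 0/1/2 minor-allele-count term.  Subjects
    with missing genotype or covariates are excluded listwise.
    """
    g = _snp_series(gm, rsid)
    obs = g[~np.isnan(g)]
    if obs.size == 0 or obs.min() == obs.max():
        raise ModelError(f"SNP {rsid} is monomorphic among non-missing subjects")
    y = subjects["status"].to_numpy(dtype=float)
    X0 = build_design(subjects, covariates)

    # trend
    Xt = X0.copy()
    Xt[rsid] = g
    fit_t = fit_logistic(y, Xt)
    or_, lo, hi = fit_t.odds_ratio(rsid)
    trend_p = fit_t.wald_p(rsid)
    trend = AssociationResult(
        rsid, "trend",
        pd.DataFrame([{"term": rsid, "OR": or_, "lcl": lo, "ucl": hi,
                       "p": trend_p}]),
        trend_p, fit_t.n, tuple(covariates), fit_t)

    # codominant
    Xc = X0.copy()
    Xc[f"{rsid}_het"] = (g == 1).astype(float)
    terms = [f"{rsid}_het"]
    if (obs == 2).any():
        Xc[f"{rsid}_hom"] = (g == 2).astype(float)
        terms.append(f"{rsid}_hom")
    Xc[Xc.columns] = Xc.to_numpy() * np.where(np.isnan(g), np.nan, 1.0)[:, None]
    fit_c = fit_logistic(y, Xc)
    rows = []
    for t in terms:
        orr, lo, hi = fit_c.odds_ratio(t)
        rows.append({"term": t, "OR": orr, "lcl": lo, "ucl": hi,
                     "p": fit_c.wald_p(t)})
    codom = AssociationResult(rsid, "codominant", pd.DataFrame(rows),
                              trend_p, fit_c.n, tuple(covariates), fit_c)
    return codom, trend


def joint_snp_model(gm: GenotypeMatrix, subjects: pd.DataFrame,
                    rsids: Sequence[str],
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    ) -> list[AssociationResult]:
    """One model containing all listed SNPs as trend terms plus covariates."""
    if len(rsids) < 2:
        raise ModelError("joint model needs at least 2 SNPs")
    y = subjects["status"].to_numpy(dtype=float)
    X = build_design(subjects, covariates)
    for r in rsids:
        X[r] = _snp_series(gm, r)
    fit = fit_logistic(y, X)
    out = []
    for r in rsids:
        if r in fit.dropped:
            res = AssociationResult(r, "joint", pd.DataFrame(
                [{"term": r, "OR": np.nan, "lcl": np.nan, "ucl": np.nan,
                  "p": np.nan}]), np.nan, fit.n, tuple(covariates), fit)
        else:
            orr, lo, hi = fit.odds_ratio(r)
            p = fit.wald_p(r)
            res = AssociationResult(r, "joint", pd.DataFrame(
                [{"term": r, "OR": orr, "lcl": lo, "ucl": hi, "p": p}]),
                p, fit.n, tuple(covariates), fit)
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj(k) = min_{j>=k} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# sensitivity and interaction
# ---------------------------------------------------------------------------

def confounder_sensitivity(gm: GenotypeMatrix, subjects: pd.DataFrame,
                           rsid: str, extra: str,
                           covariates: Sequence[str] = DEFAULT_COVARIATES,
                           threshold: float = 5.0) -> dict:
    """Percent change in the trend log-OR when ``extra`` joins the model.

    Returns {rsid, beta_base, beta_adjusted, pct_change, flagged,
    relative_defined}.  A base coefficient of exactly 0 falls back to the
    absolute difference with ``relative_defined=False``.
    """
    _, base = snp_models(gm, subjects, rsid, covariates)
    _, adj = snp_models(gm, subjects, rsid, tuple(covariates) + (extra,))
    b0 = float(np.log(base.terms["OR"].iloc[0]))
    b1 = float(np.log(adj.terms["OR"].iloc[0]))
    if b0 == 0.0:
        return {"rsid": rsid, "beta_base": b0, "beta_adjusted": b1,
                "pct_change": abs(b1 - b0), "flagged": True,
                "relative_defined": False}
    pct = 100.0 * abs(b1 - b0) / abs(b0)
    return {"rsid": rsid, "beta_base": b0, "beta_adjusted": b1,
            "pct_change": pct, "flagged": pct >= threshold,
            "relative_defined": True}


def likelihood_ratio_test(fit_full: LogisticFit, fit_reduced: LogisticFit,
                          df: int) -> tuple[float, int, float]:
    lrt = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    return lrt, df, float(stats.chi2.sf(lrt, df)) if df > 0 else np.nan


def snp_factor_interaction_lrt(gm: GenotypeMatrix, subjects: pd.DataFrame,
                               rsid: str, factor: str,
                               covariates: Sequence[str] = DEFAULT_COVARIATES,
                               ) -> tuple[float, int, float]:
    """LRT of SNP-trend x factor interaction; df = (#factor levels) - 1."""
    s = subjects[factor]
    levels = (list(s.cat.categories) if isinstance(s.dtype, pd.CategoricalDtype)
              else sorted(s.dropna().unique()))
    levels = [lv for lv in levels if (s == lv).any()]
    if len(levels) < 2:
        raise ModelError(f"factor {factor!r} has fewer than 2 observed levels")
    y = subjects["status"].to_numpy(dtype=float)
    g = _snp_series(gm, rsid)
    covs = tuple(c for c in covariates if c != factor)
    X0 = build_design(subjects, covs + (factor,))
    X0[rsid] = g
    fit0 = fit_logistic(y, X0)
    X1 = X0.copy()
    na = s.isna().to_numpy()
    for lv in levels[1:]:
        col = g * (s == lv).to_numpy(dtype=float)
        col[na] = np.nan
        X1[f"{rsid}:{factor}={lv}"] = col
    fit1 = fit_logistic(y, X1)
    df = len(levels) - 1 - sum(1 for d in fit1.dropped if d.startswith(f"{rsid}:"))
    return likelihood_ratio_test(fit1, fit0, df)


# ---------------------------------------------------------------------------
# per-SNP report
# ---------------------------------------------------------------------------

def snp_report(gm: GenotypeMatrix, subjects: pd.DataFrame,
               covariates: Sequence[str] = DEFAULT_COVARIATES,
               fdr_within_gene: bool = True) -> pd.DataFrame:
    """Per-SNP table: genotype counts, codominant ORs, trend OR/p, and
    BH-adjusted trend p (within gene by default, study-wide otherwise)."""
    rows = []
    for snp in gm.snps:
        g = gm.column(snp.rsid)
        counts = [(g == k).sum() for k in (0, 1, 2)]
        try:
            codom, trend = snp_models(gm, subjects, snp.rsid, covariates)
        except ModelError:
            rows.append({"rsid": snp.rsid, "gene": snp.gene,
                         "n0": counts[0], "n1": counts[1], "n2": counts[2],
                         "OR_het": np.nan, "OR_hom": np.nan,
                         "OR_trend": np.nan, "lcl_trend": np.nan,
                         "ucl_trend": np.nan, "trend_p": np.nan})
            continue
        het = codom.terms[codom.terms["term"].str.endswith("_het")]
        hom = codom.terms[codom.terms["term"].str.endswith("_hom")]
        tr = trend.terms.iloc[0]
        rows.append({"rsid": snp.rsid, "gene": snp.gene,
                     "n0": counts[0], "n1": counts[1], "n2": counts[2],
                     "OR_het": het["OR"].iloc[0] if len(het) else np.nan,
                     "OR_hom": hom["OR"].iloc[0] if len(hom) else np.nan,
                     "OR_trend": tr["OR"], "lcl_trend": tr["lcl"],
                     "ucl_trend": tr["ucl"], "trend_p": trend.trend_p})
    table = pd.DataFrame(rows)
    table["fdr_trend_p"] = np.nan
    valid = table["trend_p"].notna()
    if fdr_within_gene:
        for gene, grp in table[valid].groupby("gene"):
            table.loc[grp.index, "fdr_trend_p"] = bh_fdr(grp["trend_p"].to_numpy())
    elif valid.any():
        table.loc[valid, "fdr_trend_p"] = bh_fdr(table.loc[valid, "trend_p"].to_numpy())
    return table
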