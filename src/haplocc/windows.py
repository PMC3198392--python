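"""Sliding-window haplotype screen, block analysis, stratified effects,
and interaction / country-heterogeneity likelihood-ratio tests.

The haplowalk scans consecutive fixed-width (default 3) SNP windows along
each gene region with the haplotype-dosage GLM, FDR-adjusts the global
Wald p-values within gene, and flags windows below the threshold (default
0.1) as regions of interest.  Block selection itself is analyst-driven
(from flagged windows plus the LD structure); the block and stratified
analyses then reuse the same GLM with a haplotype dictionary frozen from
the full-sample EM so strata share comparable rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (DEFAULT_COVARIATES, ModelError, bh_fdr,
                          build_design, fit_logistic, likelihood_ratio_test)
from .cohort import GeneRegionMap, GenotypeMatrix, MISSING
from .descriptives import TERTILE_LEVELS
from .haplotypes import (HAPLO_COVARIATES, EmptyWindowError, HaplotypeGLMResult,
                         PoolingError, _hap_term, em_haplotypes, haplotype_glm)

MIN_STRATUM_ARM = 25


@dataclass
class WindowScanResult:
    gene: str
    start: int
    rsids: list[str]
    global_p: float
    fdr_p: float = np.nan
    flagged: bool = False


def haplowalk(gm: GenotypeMatrix, subjects: pd.DataFrame,
              genes: GeneRegionMap, width: int = 3,
              covariates: Sequence[str] = HAPLO_COVARIATES,
              pool_threshold: float = 0.05, fdr_threshold: float = 0.1,
              fdr_within_gene: bool = True) -> list[WindowScanResult]:
    """Scan consecutive ``width``-SNP windows; flag FDR-adjusted p < threshold.

    Genes with fewer than ``width`` SNPs are skipped with a notice; window
    failures (EM or pooling) propagate as per-window NaN and are excluded
    from the FDR m-count.
    """
    results: list[WindowScanResult] = []
    for gene, rsids in genes:
        if len(rsids) < width:
            warnings.warn(f"gene {gene} has {len(rsids)} SNPs < width {width}; "
                          "skipped", stacklevel=2)
            continue
        for start in range(len(rsids) - width + 1):
            win = rsids[start:start + width]
            try:
                res = haplotype_glm(gm, subjects, win, covariates,
                                    pool_threshold)
                p = res.global_p
            except (EmptyWindowError, PoolingError, ModelError):
                p = np.nan
            results.append(WindowScanResult(gene, start, list(win), p))

    def adjust(group: list[WindowScanResult]) -> None:
        ok = [w for w in group if np.isfinite(w.global_p)]
        if not ok:
            return
        adj = bh_fdr([w.global_p for w in ok])
        for w, a in zip(ok, adj):
            w.fdr_p = float(a)
            w.flagged = a < fdr_threshold

    if fdr_within_gene:
        for gene in {w.gene for w in results}:
            adjust([w for w in results if w.gene == gene])
    else:
        adjust(results)
    return results


def windows_table(results: Sequence[WindowScanResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": w.gene, "start": w.start, "rsids": ",".join(w.rsids),
        "global_p": w.global_p, "fdr_p": w.fdr_p, "flagged": w.flagged,
    } for w in results])


def block_analysis(gm: GenotypeMatrix, subjects: pd.DataFrame,
                   block: Sequence[str],
                   covariates: Sequence[str] = HAPLO_COVARIATES,
                   pool_threshold: float = 0.05) -> HaplotypeGLMResult:
    """Haplotype GLM on an analyst-chosen ordered SNP block (reference =
    most frequent haplotype; haplotypes < 5% pooled as "rare")."""
    return haplotype_glm(gm, subjects, block, covariates, pool_threshold)


# ---------------------------------------------------------------------------
# stratified analysis
# ---------------------------------------------------------------------------

@dataclass
class StratifiedResult:
    block: list[str]
    stratify_by: str
    strata: dict[str, HaplotypeGLMResult | None]
    interaction_p: pd.DataFrame        # haplotype, lrt, df, p
    full: HaplotypeGLMResult
    snp_rows: pd.DataFrame | None = None


def stratified_blocks(gm: GenotypeMatrix, subjects: pd.DataFrame,
                      block: Sequence[str], stratify_by: str,
                      covariates: Sequence[str] = HAPLO_COVARIATES,
                      pool_threshold: float = 0.05,
                      min_arm: int = MIN_STRATUM_ARM) -> StratifiedResult:
    """Per-stratum haplotype GLMs plus per-haplotype interaction LRTs.

    The haplotype set, reference, and phase posteriors are frozen from the
    full-sample EM so strata share one haplotype dictionary.  The
    interaction LRT compares full-sample models with and without
    haplotype-dosage x stratum-indicator products, one haplotype at a time
    (stratum categorical; df = #strata - 1).  Strata with fewer than
    ``min_arm`` cases or controls are reported as None.
    """
    if stratify_by not in subjects.columns:
        raise ModelError(f"stratifier {stratify_by!r} not in subjects "
                         "(run assign_tertiles first)")
    full = haplotype_glm(gm, subjects, block, covariates, pool_threshold)
    em = full.em

    sub = subjects.set_index(subjects["id"].astype(str)).loc[em.subject_ids]
    strata_labels = sub[stratify_by]
    levels = [lv for lv in
              (strata_labels.cat.categories
               if isinstance(strata_labels.dtype, pd.CategoricalDtype)
               else pd.unique(strata_labels.dropna()))
              if (strata_labels == lv).any()]

    strata: dict[str, HaplotypeGLMResult | None] = {}
    for lv in levels:
        ids = list(sub.index[strata_labels == lv])
        st_sub = subjects[subjects["id"].astype(str).isin(ids)]
        n_case = int((st_sub["status"] == 1).sum())
        n_ctrl = int((st_sub["status"] == 0).sum())
        if n_case < min_arm or n_ctrl < min_arm:
            strata[str(lv)] = None
            continue
        # freeze haplotype dictionary/posteriors: restrict the EM table
        em_st = _restrict_em(em, ids)
        try:
            strata[str(lv)] = haplotype_glm(gm, st_sub, list(block),
                                            covariates, pool_threshold,
                                            em=em_st)
        except (ModelError, PoolingError):
            strata[str(lv)] = None

    interaction = _interaction_lrts(full, sub, strata_labels, levels,
                                    covariates)
    return StratifiedResult(list(block), stratify_by, strata, interaction, full)


def _restrict_em(em, ids: list[str]):
    """Subset an EM table to a list of subject ids (frequencies, haplotype
    dictionary and per-pattern posteriors unchanged)."""
    from dataclasses import replace
    pos = {sid: i for i, sid in enumerate(em.subject_ids)}
    idx = [pos[s] for s in ids]
    return replace(em, subject_ids=list(ids), pattern_of=em.pattern_of[idx])


def _interaction_lrts(full: HaplotypeGLMResult, sub: pd.DataFrame,
                      strata_labels: pd.Series, levels: list,
                      covariates: Sequence[str]) -> pd.DataFrame:
    em = full.em
    y = sub["status"].to_numpy(dtype=float)
    X = build_design(sub, covariates).reset_index(drop=True)
    D = em.dosage_matrix()
    freqs = em.frequencies
    ref = int(np.argmax(freqs))
    rare = [h for h in range(em.n_haplotypes)
            if h != ref and full.pooled_rare and
            em.haplotypes[h] in full.pooled_rare]
    common = [h for h in range(em.n_haplotypes) if h != ref and h not in rare]

    cols: dict[str, np.ndarray] = {}
    for h in common:
        cols[_hap_term(em.haplotypes[h])] = D[:, h]
    if rare:
        cols["hap_rare"] = D[:, rare].sum(axis=1)

    lab = strata_labels.astype(str).to_numpy()
    na = strata_labels.isna().to_numpy()
    stratum_dummies = {}
    for lv in levels[1:]:
        d = (lab == str(lv)).astype(float)
        d[na] = np.nan
        stratum_dummies[f"stratum={lv}"] = d

    X_base = X.copy()
    for nm, v in cols.items():
        X_base[nm] = v
    for nm, v in stratum_dummies.items():
        X_base[nm] = v
    fit0 = fit_logistic(y, X_base)

    rows = []
    for nm, dos in cols.items():
        X_int = X_base.copy()
        added = 0
        for lv in levels[1:]:
            X_int[f"{nm}:{lv}"] = dos * stratum_dummies[f"stratum={lv}"]
            added += 1
        fit1 = fit_logistic(y, X_int)
        df = added - sum(1 for d in fit1.dropped if d.startswith(f"{nm}:"))
        lrt, df, p = likelihood_ratio_test(fit1, fit0, df)
        label = nm.replace("hap_", "", 1)
        rows.append({"haplotype": label, "lrt": lrt, "df": df, "p": p})
    return pd.DataFrame(rows)


def stratified_snp_rows(gm: GenotypeMatrix, subjects: pd.DataFrame,
                        rsids: Sequence[str], stratify_by: str,
                        covariates: Sequence[str] = DEFAULT_COVARIATES,
                        coding: str = "trend",
                        min_arm: int = MIN_STRATUM_ARM) -> pd.DataFrame:
    """Per-stratum single-SNP ORs (trend coding by default, dominant
    optional) for the stratified report's single-SNP rows."""
    from .association import snp_models, _snp_series

    s = subjects[stratify_by]
    levels = [lv for lv in
              (s.cat.categories if isinstance(s.dtype, pd.CategoricalDtype)
               else pd.unique(s.dropna())) if (s == lv).any()]
    rows = []
    for rsid in rsids:
        for lv in levels:
            st = subjects[s == lv]
            gm_st = gm.subset_subjects(list(st["id"].astype(str)))
            if (st["status"] == 1).sum() < min_arm or \
                    (st["status"] == 0).sum() < min_arm:
                rows.append({"rsid": rsid, "stratum": str(lv), "OR": np.nan,
                             "lcl": np.nan, "ucl": np.nan, "p": np.nan})
                continue
            try:
                if coding == "trend":
                    _, res = snp_models(gm_st, st, rsid, covariates)
                    t = res.terms.iloc[0]
                else:   # dominant
                    g = _snp_series(gm_st, rsid)
                    X = build_design(st, covariates)
                    X[rsid] = (g >= 1).astype(float) * np.where(
                        np.isnan(g), np.nan, 1.0)
                    fit = fit_logistic(st["status"].to_numpy(float), X)
                    orr, lo, hi = fit.odds_ratio(rsid)
                    t = pd.Series({"OR": orr, "lcl": lo, "ucl": hi,
                                   "p": fit.wald_p(rsid)})
                rows.append({"rsid": rsid, "stratum": str(lv), "OR": t["OR"],
                             "lcl": t["lcl"], "ucl": t["ucl"], "p": t["p"]})
            except ModelError:
                rows.append({"rsid": rsid, "stratum": str(lv), "OR": np.nan,
                             "lcl": np.nan, "ucl": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# country heterogeneity
# ---------------------------------------------------------------------------

def country_heterogeneity_lrt(gm: GenotypeMatrix, subjects: pd.DataFrame,
                              rsid_or_block: str | Sequence[str],
                              covariates: Sequence[str] = DEFAULT_COVARIATES,
                              country_var: str = "country",
                              ) -> tuple[float, int, float]:
    """LRT of genotype/haplotype x country heterogeneity.

    For a single rsid the genetic term is the 0/1/2 trend dosage; for a
    block it is the set of non-reference haplotype dosages.  df =
    (#genetic terms) x (#countries - 1), reduced for any dropped products.
    """
    countries = [c for c in pd.unique(subjects[country_var].dropna())]
    if len(countries) < 2:
        raise ModelError("need at least 2 countries")
    covs = tuple(c for c in covariates if c != country_var)
    y = subjects["status"].to_numpy(dtype=float)

    if isinstance(rsid_or_block, str):
        from .association import _snp_series
        terms = {rsid_or_block: _snp_series(gm, rsid_or_block)}
        X = build_design(subjects, covs + (country_var,))
        sub = subjects
    else:
        res = haplotype_glm(gm, subjects, list(rsid_or_block))
        em = res.em
        sub = subjects.set_index(subjects["id"].astype(str)).loc[em.subject_ids]
        y = sub["status"].to_numpy(dtype=float)
        X = build_design(sub, covs + (country_var,)).reset_index(drop=True)
        D = em.dosage_matrix()
        freqs = em.frequencies
        ref = int(np.argmax(freqs))
        terms = {}
        rare_cols = []
        for h in range(em.n_haplotypes):
            if h == ref:
                continue
            if em.haplotypes[h] in res.pooled_rare:
                rare_cols.append(h)
            else:
                terms[_hap_term(em.haplotypes[h])] = D[:, h]
        if rare_cols:
            terms["hap_rare"] = D[:, rare_cols].sum(axis=1)

    for nm, v in terms.items():
        X[nm] = v
    fit0 = fit_logistic(y, X)

    lab = sub[country_var].astype(str).to_numpy()
    na = sub[country_var].isna().to_numpy()
    X1 = X.copy()
    added = 0
    for nm, v in terms.items():
        for c in countries[1:]:
            col = v * (lab == str(c)).astype(float)
            col[na] = np.nan
            X1[f"{nm}:{c}"] = col
            added += 1
    fit1 = fit_logistic(y, X1)
    df = added - sum(1 for d in fit1.dropped if ":" in d)
    return likelihood_ratio_test(fit1, fit0, df)


# ---------------------------------------------------------------------------
# stratified report
# ---------------------------------------------------------------------------

def stratified_table(res: StratifiedResult) -> pd.DataFrame:
    """Haplotype x stratum OR/CI layout with per-haplotype interaction p
    and per-stratum global p."""
    rows = []
    hap_order = list(res.full.table["haplotype"])
    pint = dict(zip(res.interaction_p["haplotype"], res.interaction_p["p"]))
    for hap in hap_order:
        row: dict = {"haplotype": hap}
        for lv, st in res.strata.items():
            if st is None:
                row[f"OR_{lv}"] = row[f"lcl_{lv}"] = row[f"ucl_{lv}"] = np.nan
                continue
            match = st.table[st.table["haplotype"] == hap]
            if len(match):
                row[f"OR_{lv}"] = match["OR"].iloc[0]
                row[f"lcl_{lv}"] = match["lcl"].iloc[0]
                row[f"ucl_{lv}"] = match["ucl"].iloc[0]
            else:
                row[f"OR_{lv}"] = row[f"lcl_{lv}"] = row[f"ucl_{lv}"] = np.nan
        row["p_interaction"] = pint.get(hap, np.nan)
        rows.append(row)
    glob: dict = {"haplotype": "P-global", "p_interaction": np.nan}
    for lv, st in res.strata.items():
        glob[f"OR_{lv}"] = st.global_p if st is not None else np.nan
        glob[f"lcl_{lv}"] = glob[f"ucl_{lv}"] = np.nan
    rows.append(glob)
    return pd.DataFrame(rows)
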