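"""EM haplotype-frequency estimation, phase posteriors, pairwise LD r²,
and haplotype-dosage logistic models with rare-haplotype pooling.

Phase is reconstructed from unphased multi-locus genotypes by the classic
EM for haplotype frequencies under random mating: the E-step distributes
each subject's genotype over its compatible ordered-pair resolutions with
posterior proportional to f(h1)·f(h2)·(2 if h1 != h2), the M-step sets each
frequency to its expected haplotype count over 2n.  Association uses
posterior-expected per-subject copy numbers (dosages in [0, 2]) of each
non-reference haplotype in a logistic model — the two-stage expectation
substitution approach; haplotype frequencies are estimated phenotype-blind
on the pooled case+control sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .association import (DEFAULT_COVARIATES, LogisticFit, ModelError,
                          build_design, fit_logistic)
from .cohort import MISSING, GenotypeMatrix

HAPLO_COVARIATES = ("age_class", "sex", "center")

FREQ_FLOOR = 1e-6


class EmptyWindowError(ValueError):
    pass


class PoolingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def _compatible_pairs(pattern: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Unordered haplotype pairs (as 0/1 tuples) compatible with a 0/1/2
    genotype pattern.  2^(h-1) pairs for h heterozygous sites (1 if h=0)."""
    het = np.flatnonzero(pattern == 1)
    base = (pattern // 2).astype(int)        # 0 for 0/1, 1 for 2
    if het.size == 0:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        a, b = base.copy(), base.copy()
        a[het[0]], b[het[0]] = 0, 1
        for k, bit in enumerate(bits):
            a[het[k + 1]], b[het[k + 1]] = bit, 1 - bit
        pairs.append((tuple(a), tuple(b)))
    return pairs


@dataclass
class HaplotypeTable:
    """EM solution over one SNP window."""

    rsids: list[str]
    haplotypes: list[str]          # rendered allele strings, 5'->3'
    hap_codes: np.ndarray          # H x m, 0=major 1=minor
    frequencies: np.ndarray
    loglik: float
    n_iter: int
    subject_ids: list[str]         # subjects complete in the window
    pattern_of: np.ndarray         # subject -> pattern index
    pair_a: np.ndarray             # flattened pair hap indices
    pair_b: np.ndarray
    pair_pattern: np.ndarray       # pattern index per pair
    pair_posterior: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def dosage_matrix(self) -> np.ndarray:
        """Posterior-expected copies of each haplotype per subject (n x H).

        Rows sum to 2 (copy conservation)."""
        H = self.n_haplotypes
        n_pat = int(max(self.pattern_of.max(initial=-1),
                        self.pair_pattern.max(initial=-1))) + 1
        pat_dos = np.zeros((n_pat, H))
        np.add.at(pat_dos, (self.pair_pattern, self.pair_a), self.pair_posterior)
        np.add.at(pat_dos, (self.pair_pattern, self.pair_b), self.pair_posterior)
        return pat_dos[self.pattern_of]

    def subject_phases(self, i: int) -> list[tuple[tuple[str, str], float]]:
        """Compatible (hap1, hap2) resolutions of subject i with posteriors."""
        sel = self.pair_pattern == self.pattern_of[i]
        return [((self.haplotypes[a], self.haplotypes[b]), float(p))
                for a, b, p in zip(self.pair_a[sel], self.pair_b[sel],
                                   self.pair_posterior[sel])]


def _render(codes: np.ndarray, gm: GenotypeMatrix, rsids: Sequence[str]) -> list[str]:
    snps = [gm.snps[gm.snp_index(r)] for r in rsids]
    return ["-".join(s.alleles[c] for s, c in zip(snps, row)) for row in codes]


def em_haplotypes(gm: GenotypeMatrix, rsids: Sequence[str] | None = None,
                  subject_ids: Sequence[str] | None = None,
                  tol: float = 1e-8, max_iter: int = 500,
                  n_restarts: int = 0, seed: int = 0) -> HaplotypeTable:
    """EM haplotype-frequency estimation over a 1-8 SNP window.

    Subjects with any missing genotype in the window are excluded.
    Initialization is the linkage-equilibrium product of single-SNP allele
    frequencies (deterministic); ``n_restarts`` adds random Dirichlet
    restarts (fixed sub-seeds) keeping the best likelihood.  Haplotypes
    ending below ``FREQ_FLOOR`` are dropped from the reported table.
    """
    rsids = list(rsids) if rsids is not None else gm.rsids
    if not 1 <= len(rsids) <= 8:
        raise ValueError("window must span 1-8 SNPs")
    sub = gm.subset_snps(rsids)
    if subject_ids is not None:
        sub = sub.subset_subjects(list(subject_ids))
    complete = (sub.values != MISSING).all(axis=1)
    if not complete.any():
        raise EmptyWindowError(f"no subjects complete in window {rsids}")
    geno = sub.values[complete].astype(int)
    kept_ids = [sid for sid, ok in zip(sub.subject_ids, complete) if ok]

    patterns, pattern_of, pat_counts = np.unique(
        geno, axis=0, return_inverse=True, return_counts=True)

    hap_index: dict[tuple[int, ...], int] = {}
    pa, pb, pp = [], [], []
    for pi, pat in enumerate(patterns):
        for a, b in _compatible_pairs(pat):
            for h in (a, b):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            pa.append(hap_index[a])
            pb.append(hap_index[b])
            pp.append(pi)
    haps = np.array(sorted(hap_index, key=hap_index.get), dtype=int)
    pair_a = np.array(pa)
    pair_b = np.array(pb)
    pair_pattern = np.array(pp)
    mult = np.where(pair_a == pair_b, 1.0, 2.0)
    counts = pat_counts.astype(float)
    two_n = 2.0 * counts.sum()

    # linkage-equilibrium start
    af = geno.mean(axis=0) / 2.0
    f0 = np.prod(np.where(haps == 1, af, 1.0 - af), axis=1)
    f0 = np.clip(f0, 1e-12, None)
    f0 /= f0.sum()

    def run(f: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
        ll_prev = -np.inf
        post = np.zeros_like(pair_a, dtype=float)
        for it in range(1, max_iter + 1):
            w = mult * f[pair_a] * f[pair_b]
            denom = np.bincount(pair_pattern, weights=w, minlength=len(counts))
            ll = float(counts @ np.log(np.clip(denom, 1e-300, None)))
            assert ll >= ll_prev - 1e-9, "EM log-likelihood decreased"
            post = w / np.clip(denom[pair_pattern], 1e-300, None)
            contrib = counts[pair_pattern] * post
            exp_counts = (np.bincount(pair_a, weights=contrib, minlength=len(f)) +
                          np.bincount(pair_b, weights=contrib, minlength=len(f)))
            f = exp_counts / two_n
            if abs(ll - ll_prev) < tol:
                return f, post, ll, it
            ll_prev = ll
        return f, post, ll, max_iter

    best = run(f0)
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            fr = rng.dirichlet(np.ones(len(f0)))
            cand = run(np.clip(fr, 1e-12, None) / fr.sum())
            if cand[2] > best[2]:
                best = cand
    freqs, post, ll, n_iter = best

    # drop vanishing haplotypes (keep any whose removal would orphan a pattern)
    keep = freqs >= FREQ_FLOOR
    pair_alive = keep[pair_a] & keep[pair_b]
    orphan = np.setdiff1d(np.arange(len(counts)), pair_pattern[pair_alive])
    for pi in orphan:
        sel = pair_pattern == pi
        keep[pair_a[sel]] = keep[pair_b[sel]] = True
        pair_alive = keep[pair_a] & keep[pair_b]
    remap = -np.ones(len(freqs), dtype=int)
    remap[keep] = np.arange(keep.sum())
    freqs_k = freqs[keep] / freqs[keep].sum()
    post_k = post[pair_alive]
    pat_norm = np.bincount(pair_pattern[pair_alive], weights=post_k,
                           minlength=len(counts))
    post_k = post_k / pat_norm[pair_pattern[pair_alive]]

    codes = haps[keep]
    return HaplotypeTable(
        rsids=list(rsids),
        haplotypes=_render(codes, gm, rsids),
        hap_codes=codes,
        frequencies=freqs_k,
        loglik=ll,
        n_iter=n_iter,
        subject_ids=kept_ids,
        pattern_of=pattern_of,
        pair_a=remap[pair_a[pair_alive]],
        pair_b=remap[pair_b[pair_alive]],
        pair_pattern=pair_pattern[pair_alive],
        pair_posterior=post_k,
    )


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdEstimate:
    rsid_a: str
    rsid_b: str
    r2: float
    hap_freqs: tuple[float, ...]


def ld_r2(gm: GenotypeMatrix, subjects: pd.DataFrame, rsid_a: str, rsid_b: str,
          controls_only: bool = True) -> LdEstimate:
    """LD r² between two SNPs from EM two-locus haplotype frequencies.

    Computed among controls by default.  D = f(ab) − f(a)f(b) on minor
    alleles; r² = D² / (f(a)(1−f(a)) f(b)(1−f(b))).
    """
    ids = list(subjects.loc[subjects["status"] == 0, "id"].astype(str)) \
        if controls_only else list(subjects["id"].astype(str))
    table = em_haplotypes(gm, [rsid_a, rsid_b], subject_ids=ids)
    fa = float((table.hap_codes[:, 0] * table.frequencies).sum())
    fb = float((table.hap_codes[:, 1] * table.frequencies).sum())
    if not (0.0 < fa < 1.0) or not (0.0 < fb < 1.0):
        raise ModelError(
            f"LD undefined: monomorphic SNP among subset ({rsid_a}, {rsid_b})")
    fab = float((table.hap_codes.prod(axis=1) * table.frequencies).sum())
    d = fab - fa * fb
    r2 = d * d / (fa * (1 - fa) * fb * (1 - fb))
    return LdEstimate(rsid_a, rsid_b, float(np.clip(r2, 0.0, 1.0)),
                      tuple(table.frequencies))


def ld_matrix(gm: GenotypeMatrix, subjects: pd.DataFrame,
              rsids: Sequence[str], controls_only: bool = True) -> pd.DataFrame:
    """Square r² matrix over a SNP list (controls only by default)."""
    m = len(rsids)
    out = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                out[i, j] = out[j, i] = ld_r2(gm, subjects, rsids[i], rsids[j],
                                              controls_only).r2
            except (ModelError, EmptyWindowError):
                out[i, j] = out[j, i] = np.nan
    return pd.DataFrame(out, index=list(rsids), columns=list(rsids))


# ---------------------------------------------------------------------------
# haplotype GLM
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeGLMResult:
    window: list[str]
    reference: str
    table: pd.DataFrame        # haplotype, freq, case/control freq, OR, CI, p
    global_stat: float
    global_df: int
    global_p: float
    n: int
    covariates: tuple[str, ...]
    fit: LogisticFit
    em: HaplotypeTable
    pooled_rare: list[str] = field(default_factory=list)


def _hap_term(label: str) -> str:
    return f"hap_{label}"


def haplotype_glm(gm: GenotypeMatrix, subjects: pd.DataFrame,
                  window: Sequence[str],
                  covariates: Sequence[str] = HAPLO_COVARIATES,
                  pool_threshold: float = 0.05,
                  refine: bool = False,
                  em: HaplotypeTable | None = None) -> HaplotypeGLMResult:
    """Logistic model on posterior haplotype dosages over a SNP window.

    The most frequent haplotype is the reference (dosage column omitted);
    haplotypes below ``pool_threshold`` are summed into one "rare" column.
    The global test is the Wald chi-square on all haplotype coefficients
    jointly.  ``refine=True`` alternates outcome-informed posterior updates
    with refitting until the coefficients stabilise (< 1e-6 change).
    A precomputed ``em`` table may be supplied (e.g. to freeze the haplotype
    dictionary across strata); it must cover the same window.
    """
    window = list(window)
    table = em if em is not None else em_haplotypes(gm, window)
    freqs = table.frequencies
    ref = int(np.argmax(freqs))
    if freqs[ref] < pool_threshold:
        raise PoolingError(
            f"reference haplotype frequency {freqs[ref]:.3f} is below the "
            f"pooling threshold {pool_threshold}; threshold too high")
    rare = [h for h in range(table.n_haplotypes)
            if h != ref and freqs[h] < pool_threshold]
    common = [h for h in range(table.n_haplotypes)
              if h != ref and h not in rare]

    sub = subjects.set_index(subjects["id"].astype(str)).loc[table.subject_ids]
    y = sub["status"].to_numpy(dtype=float)
    X = build_design(sub, covariates).reset_index(drop=True)

    def add_dosage_columns(D: np.ndarray) -> pd.DataFrame:
        Xd = X.copy()
        for h in common:
            Xd[_hap_term(table.haplotypes[h])] = D[:, h]
        if rare:
            Xd["hap_rare"] = D[:, rare].sum(axis=1)
        return Xd

    D = table.dosage_matrix()
    fit = fit_logistic(y, add_dosage_columns(D))

    if refine:
        fit = _refine_fit(table, y, X, fit, common, rare, ref)

    hap_terms = [t for t in fit.params.index
                 if t.startswith("hap_") and t not in fit.separated]
    b = fit.params[hap_terms].to_numpy()
    C = fit.cov_params.loc[hap_terms, hap_terms].to_numpy()
    try:
        stat = float(b @ linalg.solve(C, b, assume_a="pos"))
    except linalg.LinAlgError:
        stat = np.nan
    df = len(hap_terms)
    global_p = float(stats.chi2.sf(stat, df)) if df and np.isfinite(stat) else np.nan

    # posterior-expected haplotype frequencies split by case/control
    case_mask = y == 1.0
    split = {}
    for grp, msk in (("case", case_mask), ("control", ~case_mask)):
        denom = 2.0 * msk.sum()
        split[grp] = D[msk].sum(axis=0) / denom if denom else np.full(D.shape[1], np.nan)

    rows = [{"haplotype": table.haplotypes[ref], "freq": freqs[ref],
             "case_freq": split["case"][ref], "control_freq": split["control"][ref],
             "OR": 1.0, "lcl": np.nan, "ucl": np.nan, "p": np.nan,
             "role": "reference"}]
    for h in common:
        term = _hap_term(table.haplotypes[h])
        if term in fit.params.index and term not in fit.separated:
            orr, lo, hi = fit.odds_ratio(term)
            p = fit.wald_p(term)
        else:
            orr = lo = hi = p = np.nan
        rows.append({"haplotype": table.haplotypes[h], "freq": freqs[h],
                     "case_freq": split["case"][h],
                     "control_freq": split["control"][h],
                     "OR": orr, "lcl": lo, "ucl": hi, "p": p, "role": "common"})
    if rare:
        if "hap_rare" in fit.params.index and "hap_rare" not in fit.separated:
            orr, lo, hi = fit.odds_ratio("hap_rare")
            p = fit.wald_p("hap_rare")
        else:
            orr = lo = hi = p = np.nan
        rows.append({"haplotype": "rare", "freq": freqs[rare].sum(),
                     "case_freq": split["case"][rare].sum(),
                     "control_freq": split["control"][rare].sum(),
                     "OR": orr, "lcl": lo, "ucl": hi, "p": p, "role": "rare"})

    return HaplotypeGLMResult(
        window=window, reference=table.haplotypes[ref],
        table=pd.DataFrame(rows), global_stat=stat, global_df=df,
        global_p=global_p, n=fit.n, covariates=tuple(covariates), fit=fit,
        em=table, pooled_rare=[table.haplotypes[h] for h in rare])


def _refine_fit(table: HaplotypeTable, y: np.ndarray, X: pd.DataFrame,
                fit: LogisticFit, common: list[int], rare: list[int],
                ref: int, max_rounds: int = 20, tol: float = 1e-6) -> LogisticFit:
    """Outcome-informed posterior refinement (frequencies held fixed)."""
    f = table.frequencies
    mult = np.where(table.pair_a == table.pair_b, 1.0, 2.0)
    prior_w = mult * f[table.pair_a] * f[table.pair_b]
    # per-pair dosage of each model haplotype column
    H = table.n_haplotypes
    eye = np.eye(H)
    pair_dos = eye[table.pair_a] + eye[table.pair_b]     # n_pairs x H
    cols = [_hap_term(table.haplotypes[h]) for h in common] + \
           (["hap_rare"] if rare else [])
    pair_cols = np.column_stack(
        [pair_dos[:, h] for h in common] +
        ([pair_dos[:, rare].sum(axis=1)] if rare else [])) \
        if cols else np.zeros((len(table.pair_a), 0))

    prev = fit.params.copy()
    for _ in range(max_rounds):
        # eta without haplotype terms, per subject
        base_cols = [c for c in fit.params.index if not c.startswith("hap_")]
        eta0 = X[base_cols].to_numpy(dtype=float) @ fit.params[base_cols].to_numpy()
        bh = np.array([fit.params.get(c, 0.0) for c in cols])
        # posterior must be computed per subject (subjects sharing a genotype
        # pattern differ in covariates, hence in outcome likelihood)
        D = np.zeros((len(table.subject_ids), len(cols)))
        for i in range(len(table.subject_ids)):
            sel = table.pair_pattern == table.pattern_of[i]
            pe = eta0[i] + pair_cols[sel] @ bh
            mu = 1.0 / (1.0 + np.exp(-pe))
            like = mu if y[i] == 1.0 else 1.0 - mu
            w = prior_w[sel] * np.clip(like, 1e-300, None)
            w = w / w.sum()
            D[i] = w @ pair_cols[sel]
        Xd = X.copy()
        for j, c in enumerate(cols):
            Xd[c] = D[:, j]
        fit = fit_logistic(y, Xd)
        delta = np.max(np.abs(fit.params.reindex(prev.index).fillna(0.0)
                              - prev.fillna(0.0))) if len(prev) else 0.0
        if delta < tol:
            break
        prev = fit.params.copy()
    return fit


def haplotype_report(results: Sequence[HaplotypeGLMResult]) -> pd.DataFrame:
    """Long-format table mirroring the block-haplotype report layout:
    window header 5'-rsids-3', haplotype, case %, control %, OR, CI, p,
    global p on the last row of each window."""
    frames = []
    for res in results:
        t = res.table.copy()
        t.insert(0, "window", "5'-" + ",".join(res.window) + "-3'")
        t["case_pct"] = 100.0 * t.pop("case_freq")
        t["control_pct"] = 100.0 * t.pop("control_freq")
        t["global_p"] = np.nan
        t.loc[t.index[-1], "global_p"] = res.global_p
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
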