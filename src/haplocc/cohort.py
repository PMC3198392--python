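"""Core data model, PLINK text ped/map I/O, and genotype quality control.

Genotypes are stored as minor-allele counts (0/1/2) in a dense int8 array
with ``MISSING`` (-1) marking no-calls.  SNPs carry ordered metadata
(:class:`SnpMeta`); gene membership is an ordered 5'->3' assignment of rsids
to named gene regions (:class:`GeneRegionMap`).  Subjects live in a pandas
DataFrame validated by :func:`read_subject_table` / :func:`validate_subjects`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING: int = -1

AGE_CLASSES = ["<50", "50-<60", "60-<70", "70+"]
BMI_CLASSES = ["<25", "25-30", ">30"]
SMOKING_CLASSES = ["never", "former", "current"]

#: Columns a subject table must provide (tertiles are derived later).
SUBJECT_COLUMNS = [
    "id", "status", "age", "sex", "center", "country",
    "bmi_class", "smoking", "hypertension", "family_history",
    "vegetable_freq", "alcohol_freq",
]


class FormatError(ValueError):
    """Malformed input file (ragged line, triallelic site, ...)."""


class ValidationError(ValueError):
    """Semantically invalid data (bad status code, unknown category, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic tag SNP.

    ``alleles`` is the ordered (major, minor) nucleotide pair; counts in the
    genotype matrix refer to copies of the minor allele.  ``position_index``
    is the 0-based 5'->3' rank of the SNP within its gene region — no
    base-pair arithmetic is ever done on it.
    """

    rsid: str
    gene: str = ""
    chrom_band: str = ""
    position_index: int = 0
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.alleles[0] == self.alleles[1]:
            raise ValidationError(
                f"{self.rsid}: major and minor allele are both {self.alleles[0]!r}")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele counts with explicit missingness."""

    values: np.ndarray                # int8, shape (n_subjects, n_snps)
    snps: list[SnpMeta]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be 2-D")
        n, m = self.values.shape
        if n != len(self.subject_ids):
            raise ValidationError(
                f"{n} genotype rows but {len(self.subject_ids)} subject ids")
        if m != len(self.snps):
            raise ValidationError(f"{m} genotype columns but {len(self.snps)} SNPs")
        ok = (self.values == MISSING) | ((self.values >= 0) & (self.values <= 2))
        if not ok.all():
            raise ValidationError("genotype entries must be 0/1/2 or MISSING")
        seen: set[str] = set()
        for s in self.snps:
            if s.rsid in seen:
                raise ValidationError(f"duplicate rsid {s.rsid}")
            seen.add(s.rsid)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def snp_index(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"unknown rsid {rsid!r}") from None

    def column(self, rsid: str) -> np.ndarray:
        return self.values[:, self.snp_index(rsid)]

    def subset_snps(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(r) for r in rsids]
        return GenotypeMatrix(self.values[:, idx],
                              [self.snps[i] for i in idx],
                              list(self.subject_ids))

    def subset_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {sid: i for i, sid in enumerate(self.subject_ids)}
        idx = [pos[s] for s in ids]
        return GenotypeMatrix(self.values[idx, :], list(self.snps), list(ids))

    # -- summaries ----------------------------------------------------------

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return (self.values != MISSING).mean(axis=0)

    def maf(self, subject_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP minor-allele frequency among non-missing calls."""
        v = self.values if subject_mask is None else self.values[subject_mask]
        obs = v != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(0) > 0,
                            np.where(obs, v, 0).sum(0) / (2.0 * np.maximum(obs.sum(0), 1)),
                            np.nan)


@dataclass
class GeneRegionMap:
    """Ordered (5'->3') assignment of rsids to named gene regions."""

    genes: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gene, rsids in self.genes.items():
            for r in rsids:
                if r in seen:
                    raise ValidationError(
                        f"rsid {r} assigned to both {seen[r]} and {gene}")
                seen[r] = gene

    def __iter__(self):
        return iter(self.genes.items())

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def all_rsids(self) -> list[str]:
        return [r for rs in self.genes.values() for r in rs]

    def gene_of(self, rsid: str) -> str:
        for gene, rsids in self.genes.items():
            if rsid in rsids:
                return gene
        raise KeyError(f"rsid {rsid!r} not in gene map")


def apply_gene_map(gm: GenotypeMatrix, gene_map: GeneRegionMap) -> GenotypeMatrix:
    """Reorder SNPs by gene map order and fill gene / position_index metadata."""
    sub = gm.subset_snps(gene_map.all_rsids)
    snps = []
    for gene, rsids in gene_map:
        for i, r in enumerate(rsids):
            old = sub.snps[sub.snp_index(r)]
            snps.append(replace(old, gene=gene, position_index=i))
    return GenotypeMatrix(sub.values, snps, sub.subject_ids)


# ---------------------------------------------------------------------------
# subject table
# ---------------------------------------------------------------------------

_STATUS_CODES = {"0": 0, "1": 1, "control": 0, "case": 1}


def age_class(age: float) -> str:
    """Bucket a continuous age into the <50 / 50-<60 / 60-<70 / 70+ classes."""
    if age < 50:
        return AGE_CLASSES[0]
    if age < 60:
        return AGE_CLASSES[1]
    if age < 70:
        return AGE_CLASSES[2]
    return AGE_CLASSES[3]


def validate_subjects(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/type a subject table and derive ``age_class``.

    Returns a copy with ``status`` as int {0,1}, categorical lifestyle columns
    checked against their known levels (missing values allowed and preserved
    as NA), and ``age_class`` derived from ``age``.
    """
    missing_cols = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"subject table lacks columns: {missing_cols}")
    out = df.copy()
    status = out["status"].astype(str).str.strip().str.lower()
    bad = ~status.isin(_STATUS_CODES)
    if bad.any():
        raise ValidationError(
            f"invalid status value(s): {sorted(status[bad].unique())}")
    out["status"] = status.map(_STATUS_CODES).astype(int)
    out["age"] = pd.to_numeric(out["age"])
    out["sex"] = pd.to_numeric(out["sex"]).astype(int)
    for col, levels in (("bmi_class", BMI_CLASSES), ("smoking", SMOKING_CLASSES)):
        vals = out[col]
        unknown = vals.dropna()[~vals.dropna().isin(levels)]
        if len(unknown):
            raise ValidationError(
                f"unknown {col} value(s): {sorted(unknown.unique())}")
        out[col] = pd.Categorical(vals, categories=levels)
    for col in ("hypertension", "family_history"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["age_class"] = pd.Categorical(
        [age_class(a) for a in out["age"]], categories=AGE_CLASSES)
    out["id"] = out["id"].astype(str)
    return out


def read_subject_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a delimited (comma or tab) subject table with a header row."""
    sep = {"csv": ",", "tsv": "\t", None: None}[dialect]
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return validate_subjects(df)


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUBJECT_COLUMNS + ["age_class"] if c in df.columns]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PLINK text ped/map
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path,
                 minor_allele_policy: str | Mapping[str, str] = "control_freq",
                 ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PLINK text ped/map into minor-allele counts.

    ``minor_allele_policy`` is either ``"control_freq"`` (minor allele =
    rarer allele among controls, ties broken lexicographically) or a mapping
    rsid -> declared minor allele.  "0 0" genotypes become :data:`MISSING`.
    Returns the genotype matrix plus a minimal subject frame (id, status,
    sex) from the ped leading columns; phenotype 2=case, 1=control,
    0/-9=missing status (NA).
    """
    snp_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}: line {ln}: expected 4 columns")
            snp_rows.append((parts[0], parts[1]))
    m = len(snp_rows)

    ids: list[str] = []
    status: list[float] = []
    sex: list[int] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields, got {len(parts)}")
            ids.append(parts[1])
            sex.append(int(parts[4]))
            pheno = parts[5]
            status.append({"2": 1.0, "1": 0.0}.get(pheno, np.nan))
            allele_rows.append(parts[6:])

    alleles = np.array(allele_rows, dtype="U1").reshape(len(ids), m, 2)
    values = np.full((len(ids), m), MISSING, dtype=np.int8)
    snps: list[SnpMeta] = []
    status_arr = np.asarray(status)
    ctrl = status_arr == 0.0
    for j, (chrom, rsid) in enumerate(snp_rows):
        a = alleles[:, j, :]
        called = (a[:, 0] != "0") & (a[:, 1] != "0")
        obs = sorted(set(a[called].ravel()))
        if len(obs) > 2:
            raise FormatError(f"{rsid}: more than two alleles observed: {obs}")
        if not obs:
            snps.append(SnpMeta(rsid, chrom_band=chrom, alleles=("A", "B")))
            continue
        if isinstance(minor_allele_policy, str):
            if minor_allele_policy != "control_freq":
                raise ValueError(f"unknown policy {minor_allele_policy!r}")
            base = a[called & ctrl] if (called & ctrl).any() else a[called]
            uniq, counts = np.unique(base.ravel(), return_counts=True)
            freq = dict(zip(uniq.tolist(), counts.tolist()))
            if len(obs) == 1:
                major, minor = obs[0], next(
                    x for x in ("A", "C", "G", "T", "B") if x != obs[0])
            else:
                c0, c1 = freq.get(obs[0], 0), freq.get(obs[1], 0)
                # rarer allele is minor; lexicographic tie-break
                minor, major = (obs[0], obs[1]) if (c0, obs[0]) < (c1, obs[1]) else (obs[1], obs[0])
        else:
            minor = minor_allele_policy[rsid]
            rest = [x for x in obs if x != minor]
            major = rest[0] if rest else next(
                x for x in ("A", "C", "G", "T", "B") if x != minor)
        values[called, j] = (a[called] == minor).sum(axis=1)
        snps.append(SnpMeta(rsid, chrom_band=chrom, alleles=(major, minor)))

    subjects = pd.DataFrame({"id": ids, "status": status_arr, "sex": sex})
    return GenotypeMatrix(values, snps, ids), subjects


def write_ped_map(gm: GenotypeMatrix, subjects: pd.DataFrame,
                  ped_path: str | Path, map_path: str | Path) -> None:
    """Write PLINK text ped/map (phenotype 2=case, 1=control)."""
    with open(map_path, "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chrom_band or '0'}\t{s.rsid}\t0\t{s.position_index}\n")
    status = dict(zip(subjects["id"].astype(str), subjects["status"]))
    sex = dict(zip(subjects["id"].astype(str), subjects.get("sex", pd.Series(dtype=int))))
    pair = {0: "{maj} {maj}", 1: "{maj} {min}", 2: "{min} {min}", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.subject_ids):
            st = status.get(sid, np.nan)
            pheno = "2" if st == 1 else ("1" if st == 0 else "0")
            sx = sex.get(sid, 0)
            fields = [sid, sid, "0", "0", str(int(sx)), pheno]
            for j, s in enumerate(gm.snps):
                fields.append(pair[int(gm.values[i, j])].format(
                    maj=s.alleles[0], min=s.alleles[1]))
            fh.write(" ".join(fields) + "\n")


def read_gene_map(path: str | Path) -> GeneRegionMap:
    """Read a two-column (gene, rsid) tab/whitespace file, order-preserving."""
    genes: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise FormatError(f"gene map line needs 'gene rsid': {line!r}")
            genes.setdefault(parts[0], []).append(parts[1])
    return GeneRegionMap(genes)


def write_gene_map(gene_map: GeneRegionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, rsids in gene_map:
            for r in rsids:
                fh.write(f"{gene}\t{r}\n")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def hwe_test(genotype_counts: tuple[int, int, int]) -> tuple[float, float]:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions.

    ``genotype_counts`` = (n common hom, n het, n rare hom).  Expected counts
    use the sample allele frequency.  Monomorphic input gives (0.0, 1.0).
    """
    n0, n1, n2 = genotype_counts
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no genotyped subjects")
    p = (2 * n0 + n1) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class QcThresholds:
    call_rate: float = 0.98
    hwe_p: float = 0.05
    maf: float = 0.05


@dataclass
class QcReport:
    """Per-SNP QC table plus the thresholds used to flag."""

    table: pd.DataFrame
    thresholds: QcThresholds

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def qc_summary(gm: GenotypeMatrix, subjects: pd.DataFrame,
               duplicates: Iterable[tuple[str, str]] = (),
               thresholds: QcThresholds | None = None) -> QcReport:
    """Call rate, duplicate concordance, control-only HWE and MAF, with flags.

    Concordance is the per-SNP fraction of duplicate pairs whose two calls
    are both non-missing and agree; NaN when no pair is informative (or no
    duplicates were typed).  HWE and MAF are computed among controls only.
    """
    thresholds = thresholds or QcThresholds()
    subjects = subjects.set_index(subjects["id"].astype(str))
    ctrl_ids = [sid for sid in gm.subject_ids
                if sid in subjects.index and subjects.loc[sid, "status"] == 0]
    ctrl_mask = np.isin(gm.subject_ids, ctrl_ids)

    call = gm.call_rate()
    maf = gm.maf(ctrl_mask)

    pos = {sid: i for i, sid in enumerate(gm.subject_ids)}
    pairs = [(pos[a], pos[b]) for a, b in duplicates]
    for a, b in duplicates:
        if a not in pos or b not in pos:
            raise ValidationError(f"duplicate pair ({a},{b}) not in matrix")
    if pairs:
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        va, vb = gm.values[ia], gm.values[ib]
        both = (va != MISSING) & (vb != MISSING)
        agree = both & (va == vb)
        with np.errstate(invalid="ignore"):
            conc = np.where(both.sum(0) > 0, agree.sum(0) / np.maximum(both.sum(0), 1),
                            np.nan)
    else:
        conc = np.full(gm.n_snps, np.nan)

    hwe_chi2 = np.zeros(gm.n_snps)
    hwe_p = np.ones(gm.n_snps)
    cv = gm.values[ctrl_mask]
    for j in range(gm.n_snps):
        col = cv[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            hwe_chi2[j], hwe_p[j] = np.nan, np.nan
            continue
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        hwe_chi2[j], hwe_p[j] = hwe_test(counts)

    table = pd.DataFrame({
        "rsid": gm.rsids,
        "gene": [s.gene for s in gm.snps],
        "call_rate": call,
        "concordance": conc,
        "hwe_chi2": hwe_chi2,
        "hwe_p": hwe_p,
        "maf_controls": maf,
        "flag_call_rate": call < thresholds.call_rate,
        "flag_hwe": hwe_p < thresholds.hwe_p,
        "flag_maf": maf < thresholds.maf,
    })
    return QcReport(table, thresholds)
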