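"""Genotype containers, QC filters, Hardy-Weinberg exact test, PCA and PRS.

The polygenic risk score (PRS) follows the standard weighted-sum form

    PRS_j = sum_i beta_i * X_ij

where ``X_ij`` is the effect-allele dosage of SNP ``i`` in woman ``j`` and
``beta_i`` its log-odds weight.  Three weight columns (overall, ER-negative
and ER-positive breast cancer) mirror the 313-SNP breast-cancer PRS layout.

Quality control mirrors common GWAS practice: samples are filtered on call
rate and heterozygosity outliers first, then SNPs on call rate, an exact
Hardy-Weinberg test and minor allele frequency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]

ENDPOINTS = {"overall": "beta_overall", "ERneg": "beta_erneg",
             "ERpos": "beta_erpos"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypePanel:
    """Dosage matrix (individuals x SNPs) plus per-SNP metadata.

    Dosages are effect-allele counts in [0, 2]; fractional values are allowed
    (imputed dosages) and missing calls are NaN.  ``sample_ids`` aligns rows
    to a :class:`~mammotwin.cohort.Cohort`.
    """

    def __init__(self, dosages: np.ndarray, snp_meta: pd.DataFrame,
                 sample_ids: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        if dosages.shape[1] != len(snp_meta):
            raise ValueError("snp_meta length must equal dosage column count")
        if dosages.shape[0] != len(sample_ids):
            raise ValueError("sample_ids length must equal dosage row count")
        with np.errstate(invalid="ignore"):
            bad = (dosages < 0) | (dosages > 2)
        if np.any(bad & ~np.isnan(dosages)):
            raise ValueError("dosages must lie in [0, 2] or be missing")
        missing = [c for c in SNP_META_COLUMNS if c not in snp_meta.columns]
        if missing:
            raise ValueError(f"snp_meta missing columns: {missing}")
        self.dosages = dosages
        self.snp_meta = snp_meta.reset_index(drop=True)
        self.sample_ids = np.asarray(sample_ids)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def observed_maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency from the observed dosages."""
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def hard_calls(self) -> np.ndarray:
        """Round fractional dosages to {0,1,2} at thresholds 0.5 / 1.5.

        Used only for QC statistics (call rate is unaffected, heterozygosity
        and the HWE test operate on hard calls); downstream analyses keep the
        fractional dosages.
        """
        calls = np.full(self.dosages.shape, np.nan)
        d = self.dosages
        ok = ~np.isnan(d)
        calls[ok & (d < 0.5)] = 0.0
        calls[ok & (d >= 0.5) & (d < 1.5)] = 1.0
        calls[ok & (d >= 1.5)] = 2.0
        return calls

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypePanel":
        d, meta, sid = self.dosages, self.snp_meta, self.sample_ids
        if sample_mask is not None:
            d, sid = d[sample_mask], sid[sample_mask]
        if snp_mask is not None:
            d, meta = d[:, snp_mask], meta.loc[snp_mask].reset_index(drop=True)
        return GenotypePanel(d, meta, sid)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, dosage_path, meta_path) -> None:
        pd.DataFrame(self.dosages, index=pd.Index(self.sample_ids, name="id"),
                     columns=self.snp_meta["snp_id"]).to_csv(
            dosage_path, sep="\t", na_rep="NA")
        self.snp_meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, dosage_path, meta_path) -> "GenotypePanel":
        tab = pd.read_csv(dosage_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t",
                           dtype={"snp_id": str, "chrom": str})
        return cls(tab.to_numpy(dtype=float), meta,
                   tab.index.astype(str).to_numpy())

    @classmethod
    def from_plink_raw(cls, path) -> "GenotypePanel":
        """Read a PLINK ``--recode A`` style (.raw) whitespace table.

        Columns ``FID IID PAT MAT SEX PHENOTYPE`` are followed by one column
        per SNP named ``<snp_id>_<counted_allele>`` containing 0/1/2 dosages
        (``NA`` for missing).  Chromosome/position are not carried by .raw
        files and are filled with placeholders.
        """
        tab = pd.read_csv(path, sep=r"\s+")
        fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        snp_cols = [c for c in tab.columns if c not in fixed]
        ids, alleles = [], []
        for c in snp_cols:
            snp, _, allele = c.rpartition("_")
            ids.append(snp if snp else c)
            alleles.append(allele if snp else "N")
        dos = tab[snp_cols].to_numpy(dtype=float)
        meta = pd.DataFrame({
            "snp_id": ids, "chrom": "0", "pos": 0,
            "effect_allele": alleles, "other_allele": "N",
        })
        maf = np.nanmean(dos, axis=0) / 2.0
        meta["maf"] = np.minimum(maf, 1 - maf)
        return cls(dos, meta, tab["IID"].astype(str).to_numpy())

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Read dosages from a VCF 4.2 file carrying a ``DS`` FORMAT field.

        The ALT allele is taken as the effect (counted) allele.  Falls back
        to hard genotypes (``GT``) when a record has no ``DS``.
        """
        try:
            from cyvcf2 import VCF
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError("reading VCF requires the cyvcf2 package "
                              "(install mammotwin[vcf])") from exc
        vcf = VCF(str(path))
        samples = np.asarray(vcf.samples)
        rows, meta_rows = [], []
        for var in vcf:
            ds = var.format("DS")
            if ds is not None:
                col = ds[:, 0].astype(float)
                col[col < 0] = np.nan
            else:
                gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 het coding
                col = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
            rows.append(col)
            meta_rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM,
                              var.POS, var.ALT[0] if var.ALT else "N", var.REF))
        dos = np.column_stack(rows) if rows else np.empty((len(samples), 0))
        meta = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
        maf = np.nanmean(dos, axis=0) / 2.0 if rows else np.empty(0)
        meta["maf"] = np.minimum(maf, 1 - maf)
        return cls(dos, meta, samples)


@dataclass
class WeightSet:
    """Per-SNP PRS weights for the three breast-cancer endpoints.

    ``table`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    beta_overall, beta_erneg, beta_erpos.  Weights are on the log-odds scale.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = SNP_META_COLUMNS + list(ENDPOINTS.values())
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def betas(self, endpoint: str) -> np.ndarray:
        if endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}")
        return self.table[ENDPOINTS[endpoint]].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WeightSet":
        return cls(pd.read_csv(path, sep="\t",
                               dtype={"snp_id": str, "chrom": str}))


def _is_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved without frequencies."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def compute_prs(panel: GenotypePanel, weights: WeightSet,
                endpoint: str = "overall",
                drop_ambiguous: bool = False) -> pd.Series:
    """Polygenic risk score: weighted sum of effect-allele dosages.

    The panel dosage counts the panel's ``effect_allele``; wherever that
    differs from the weight file's effect allele the dosage is flipped
    (``X -> 2 - X``).  Missing dosages are mean-imputed to ``2 * maf`` of the
    weight-file effect allele.  Strand-ambiguous SNPs (A/T, C/G) trigger a
    warning and are optionally dropped.

    Returns a Series indexed by sample id, named after the endpoint.
    """
    meta = panel.snp_meta
    pos_by_id = {s: i for i, s in enumerate(meta["snp_id"])}
    missing_ids = [s for s in weights.table["snp_id"] if s not in pos_by_id]
    if missing_ids:
        raise KeyError(f"weight SNPs absent from panel: {missing_ids[:10]}"
                       + ("..." if len(missing_ids) > 10 else ""))
    betas = weights.betas(endpoint)
    cols = np.asarray([pos_by_id[s] for s in weights.table["snp_id"]])
    X = panel.dosages[:, cols].copy()
    panel_ea = meta["effect_allele"].to_numpy()[cols]
    panel_oa = meta["other_allele"].to_numpy()[cols]

    keep = np.ones(len(cols), dtype=bool)
    for k, (pea, poa, wea, woa) in enumerate(zip(
            panel_ea, panel_oa, weights.table["effect_allele"],
            weights.table["other_allele"])):
        if _is_ambiguous(pea, poa):
            logger.warning("strand-ambiguous SNP %s (%s/%s)",
                           weights.table["snp_id"].iloc[k], pea, poa)
            if drop_ambiguous:
                keep[k] = False
                continue
        if pea == wea:
            continue
        if pea == woa and poa == wea:
            X[:, k] = 2.0 - X[:, k]
        elif _COMPLEMENT.get(pea) == wea:  # strand flip, same orientation
            continue
        elif _COMPLEMENT.get(pea) == woa:
            X[:, k] = 2.0 - X[:, k]
        else:
            raise KeyError(
                f"SNP {weights.table['snp_id'].iloc[k]}: panel alleles "
                f"{pea}/{poa} cannot be oriented to weight alleles {wea}/{woa}")

    X, betas = X[:, keep], betas[keep]
    nan = np.isnan(X)
    if nan.any():
        freq = np.nanmean(X, axis=0) / 2.0
        X = np.where(nan, 2.0 * freq[np.newaxis, :], X)
        logger.info("imputed %d missing dosages to 2*maf", int(nan.sum()))
    score = X @ betas
    return pd.Series(score, index=pd.Index(panel.sample_ids, name="id"),
                     name=f"prs_{endpoint}")


# -- Hardy-Weinberg exact test -----------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows the distribution

        P(n_het) ∝ n! / (n_hom_ref! n_het! n_hom_alt!) * 2^n_het

    over all heterozygote counts of the same parity as the minor-allele
    count.  The two-sided p-value sums the probabilities of every
    configuration no more probable than the observed one.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0  # monomorphic: a single configuration
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # log P up to a constant; normalized below
    logp = (hets * np.log(2.0) - gammaln(hom_major + 1) - gammaln(hets + 1)
            - gammaln(hom_minor + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_test_matrix(calls: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per SNP column of a hard-call matrix."""
    out = np.ones(calls.shape[1])
    for j in range(calls.shape[1]):
        col = calls[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                int((col == 2).sum()))
    return out


# -- QC ---------------------------------------------------------------

@dataclass
class QcReport:
    """Per-filter removal counts, in application order (samples then SNPs)."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_call_rate: int = 0
    samples_heterozygosity: int = 0
    snps_call_rate: int = 0
    snps_hwe: int = 0
    snps_maf: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    exempt_snps: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def qc_filter(panel: GenotypePanel, snp_call_rate_min: float = 0.95,
              sample_call_rate_min: float = 0.95, hwe_p_min: float = 1e-7,
              maf_min: float = 0.01, het_sd: float = 4.89,
              exempt_snp_ids=()) -> tuple[GenotypePanel, QcReport]:
    """Sample-then-SNP genotype quality control.

    Samples failing call rate or lying more than ``het_sd`` standard
    deviations from the mean heterozygosity are removed first; SNP filters
    (call rate, exact HWE at ``hwe_p_min``, MAF at ``maf_min``) are applied
    to the surviving samples.  ``exempt_snp_ids`` (e.g. PRS weight SNPs,
    which may legitimately have MAF below the GWAS QC floor) bypass the MAF
    filter; exemptions are recorded in the report.
    """
    report = QcReport(n_samples_in=panel.n_samples, n_snps_in=panel.n_snps)
    obs = ~np.isnan(panel.dosages)

    sample_cr = obs.mean(axis=1)
    keep_s = sample_cr >= sample_call_rate_min
    report.samples_call_rate = int((~keep_s).sum())
    if not keep_s.any():
        raise ValueError("all samples removed by QC (call rate)")

    calls = panel.hard_calls()
    with np.errstate(invalid="ignore"):
        het = np.nanmean(calls == 1.0, axis=1)
    mu, sd = float(np.mean(het[keep_s])), float(np.std(het[keep_s], ddof=1))
    if sd > 0:
        het_out = np.abs(het - mu) > het_sd * sd
    else:
        het_out = np.zeros(panel.n_samples, dtype=bool)
    report.samples_heterozygosity = int((het_out & keep_s).sum())
    keep_s &= ~het_out
    if not keep_s.any():
        raise ValueError("all samples removed by QC")

    sub = panel.subset(sample_mask=keep_s)
    obs = ~np.isnan(sub.dosages)
    snp_cr = obs.mean(axis=0)
    keep_v = snp_cr >= snp_call_rate_min
    report.snps_call_rate = int((~keep_v).sum())

    hwe_p = hwe_test_matrix(sub.hard_calls())
    fail_hwe = (hwe_p < hwe_p_min) & keep_v
    report.snps_hwe = int(fail_hwe.sum())
    keep_v &= ~fail_hwe

    maf = sub.observed_maf()
    exempt = sub.snp_meta["snp_id"].isin(set(exempt_snp_ids)).to_numpy()
    fail_maf = (maf < maf_min) & ~exempt & keep_v
    report.snps_maf = int(fail_maf.sum())
    keep_v &= ~fail_maf
    exempted = sub.snp_meta["snp_id"][(maf < maf_min) & exempt & keep_v]
    report.exempt_snps = exempted.tolist()
    if report.exempt_snps:
        logger.info("MAF filter exemption for weight SNPs: %s",
                    report.exempt_snps)

    out = sub.subset(snp_mask=keep_v)
    report.n_samples_out, report.n_snps_out = out.n_samples, out.n_snps
    return out, report


# -- principal components ----------------------------------------------

def compute_pcs(panel: GenotypePanel, k: int = 10) -> np.ndarray:
    """Principal-component scores of the column-standardized dosage matrix.

    Missing dosages are imputed to the column mean before standardization.
    Columns with zero variance are dropped from the decomposition.  Scores
    are ordered by decreasing eigenvalue; the sign convention makes the
    largest-magnitude loading of each component positive.
    """
    if k >= min(panel.n_samples, panel.n_snps) or k < 1:
        raise ValueError(f"k={k} must be in [1, min(n_samples, n_snps))")
    X = panel.dosages.copy()
    mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.take(mean, np.nonzero(nan)[1])
    X -= mean
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    # eigendecomposition on the smaller side of X'X (SNPs are usually the
    # smaller dimension); scores = X V, ordered by decreasing eigenvalue
    if X.shape[1] <= X.shape[0]:
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1][:k]
        loadings = evecs[:, order]
        scores = X @ loadings
    else:
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        scores = u[:, :k] * s[:k]
        loadings = vt[:k].T
    # sign convention from loadings
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            scores[:, j] *= -1.0
    return scores
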