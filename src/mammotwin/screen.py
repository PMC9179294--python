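"""Association pipeline: MRS x PRS correlations and regressions, mutual
adjustment between risk scores, and the per-SNP screen with
multiple-testing, excess-significance and direction-consistency summaries.

Every regression is the family/MZ-pair variance-components mixed model of
:mod:`mammotwin.lmm` with the first genotype principal components as fixed
effects; coefficients are reported per covariate-adjusted standard
deviation of the predictor (OPERA convention).  The excess-significance
test treats the per-SNP tests as independent Bernoulli(alpha) trials under
the null, a simplification when the SNP list contains correlated
fine-mapped variants (noted in the output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .genotypes import GenotypePanel
from .lmm import FamilyLMM, family_corr, opera_scale
from .mrs import MRS_COLUMNS

logger = logging.getLogger(__name__)

MRS_NAMES = tuple(MRS_COLUMNS.values())

#: Table-4-style mutual-adjustment layout: outcome -> list of adjustment sets
DEFAULT_ADJUSTMENT_SETS = {
    "cumulus_mrs": [["alto_mrs"], ["cirro_mrs"], ["alto_mrs", "cirro_mrs"]],
    "percent_mrs": [["alto_mrs"], ["cirro_mrs"], ["alto_mrs", "cirro_mrs"]],
    "alto_mrs": [["cumulus_mrs"], ["cirro_mrs"], ["cumulus_mrs", "cirro_mrs"]],
    "cirro_mrs": [["cumulus_mrs"], ["alto_mrs"], ["cumulus_mrs", "alto_mrs"]],
    "white_mrs": [["alto_mrs"], ["cirro_mrs"], ["alto_mrs", "cirro_mrs"]],
}

SCREEN_CAVEAT = ("excess-significance binomial test assumes independent "
                 "SNPs; correlated fine-mapped variants make it "
                 "anti-conservative")


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _design(n: int, predictor: np.ndarray, pcs: np.ndarray | None,
            extra: np.ndarray | None = None):
    cols = [np.ones(n), predictor]
    names = ["const", "predictor"]
    if extra is not None and extra.size:
        for j in range(extra.shape[1]):
            cols.append(extra[:, j])
            names.append(f"adj{j}")
    if pcs is not None and pcs.size:
        for j in range(pcs.shape[1]):
            cols.append(pcs[:, j])
            names.append(f"pc{j + 1}")
    return np.column_stack(cols), names


def _fit_association(y, predictor, pcs, cohort, extra=None):
    """Mixed-model fit plus OPERA scaling of the predictor coefficient."""
    X, names = _design(len(y), predictor, pcs, extra)
    fit = FamilyLMM(y, X, cohort, exog_names=names).fit()
    op = opera_scale(fit, "predictor")
    return fit, op


def run_prs_analysis(mrs_table: pd.DataFrame, prs: dict[str, pd.Series],
                     pcs: np.ndarray, cohort: Cohort, n_boot: int = 1000,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations and mixed-model associations for every MRS x PRS cell.

    ``prs`` maps endpoint labels (overall, ERneg, ERpos) to score vectors.
    Returns ``(correlations, associations)``; each has one row per MRS x
    PRS with estimate, 95% CI, p and BIC, and flags the smallest-BIC
    outcome per PRS.  Correlation BICs come from the matching one-predictor
    mixed model (no principal components), association rows adjust for the
    principal components and report OPERA-scaled coefficients.
    """
    _check_alignment(mrs_table, cohort)
    corr_rows, assoc_rows = [], []
    for ep, scores in prs.items():
        if not np.array_equal(scores.index.to_numpy(), cohort.ids):
            raise ValueError(f"PRS {ep!r} not aligned to cohort ids")
        z = _standardize(scores.to_numpy(dtype=float))
        for mrs_name in MRS_NAMES:
            y = mrs_table[mrs_name].to_numpy(dtype=float)
            fc = family_corr(y, z, cohort, n_boot=n_boot, seed=seed)
            X, names = _design(len(y), z, None)
            corr_fit = FamilyLMM(y, X, cohort, exog_names=names).fit()
            corr_rows.append({
                "outcome": mrs_name, "predictor": ep, "estimate": fc.r,
                "ci_lower": fc.ci_lower, "ci_upper": fc.ci_upper,
                "p": fc.p_clustered, "p_naive": fc.p_naive,
                "bic": corr_fit.bic,
            })
            fit, op = _fit_association(y, z, pcs, cohort)
            assoc_rows.append({
                "outcome": mrs_name, "predictor": ep, "estimate": op.estimate,
                "ci_lower": op.ci_lower, "ci_upper": op.ci_upper,
                "p": op.p_value, "bic": fit.bic,
            })
    corr = _flag_best_bic(pd.DataFrame(corr_rows))
    assoc = _flag_best_bic(pd.DataFrame(assoc_rows))
    corr.attrs["kind"] = "correlation"
    assoc.attrs["kind"] = "association"
    return corr, assoc


def _flag_best_bic(tab: pd.DataFrame) -> pd.DataFrame:
    tab = tab.copy()
    tab["best_bic"] = False
    for _, grp in tab.groupby("predictor"):
        tab.loc[grp["bic"].idxmin(), "best_bic"] = True
    return tab


def _check_alignment(mrs_table, cohort) -> None:
    if not np.array_equal(mrs_table["id"].to_numpy(), cohort.ids):
        raise ValueError("MRS table not aligned to cohort ids")


def attenuation_percent(beta_unadjusted: float, beta_adjusted: float) -> float:
    """Percent attenuation of a coefficient after further adjustment."""
    if beta_unadjusted == 0:
        raise ValueError("unadjusted coefficient is zero")
    return 100.0 * (beta_unadjusted - beta_adjusted) / beta_unadjusted


def run_mutual_adjustment(mrs_table: pd.DataFrame, prs: pd.Series,
                          pcs: np.ndarray, cohort: Cohort,
                          adjustment_sets: dict | None = None) -> pd.DataFrame:
    """Refit each MRS-PRS association with other MRSs as fixed effects.

    For every outcome MRS and adjustment set the mixed model gains the
    listed co-measured MRSs as additional fixed effects; rows report the
    OPERA-scaled coefficient and the percent attenuation relative to the
    unadjusted association.
    """
    _check_alignment(mrs_table, cohort)
    sets = DEFAULT_ADJUSTMENT_SETS if adjustment_sets is None else adjustment_sets
    z = _standardize(prs.to_numpy(dtype=float))
    rows = []
    for outcome, adj_list in sets.items():
        y = mrs_table[outcome].to_numpy(dtype=float)
        _, unadj = _fit_association(y, z, pcs, cohort)
        for adj in adj_list:
            if outcome in adj:
                raise ValueError(f"adjustment set for {outcome} contains "
                                 "the outcome itself")
            extra = mrs_table[list(adj)].to_numpy(dtype=float)
            fit, op = _fit_association(y, z, pcs, cohort, extra=extra)
            rows.append({
                "outcome": outcome, "adjusted_for": "+".join(adj),
                "estimate": op.estimate, "ci_lower": op.ci_lower,
                "ci_upper": op.ci_upper, "p": op.p_value, "bic": fit.bic,
                "estimate_unadjusted": unadj.estimate,
                "attenuation_percent": attenuation_percent(unadj.estimate,
                                                           op.estimate),
            })
    out = pd.DataFrame(rows)
    out.attrs["kind"] = "adjusted_association"
    return out


# -- SNP screen ----------------------------------------------------------

def excess_significance_p(n_nominal: int, n_tests: int,
                          alpha: float = 0.05) -> float:
    """One-sided binomial tail P(K >= observed | n_tests, alpha)."""
    if not 0 <= n_nominal <= n_tests:
        raise ValueError("nominal count out of range")
    return float(stats.binom.sf(n_nominal - 1, n_tests, alpha))


@dataclass
class ScreenResult:
    """Per-SNP association rows plus per-MRS summaries.

    ``per_snp`` has one row per SNP x MRS (estimate, p, Bonferroni-adjusted
    p, direction-consistency flag); ``summary`` one row per MRS with the
    nominal-hit count, its chance expectation ``n_tests * alpha``, the
    one-sided binomial excess p, the direction-consistent count among
    nominal hits and the Bonferroni hit count.
    """

    per_snp: pd.DataFrame
    summary: pd.DataFrame
    n_tests: int
    alpha: float
    skipped_snps: list = field(default_factory=list)
    caveat: str = SCREEN_CAVEAT


def run_snp_screen(mrs_table: pd.DataFrame, panel: GenotypePanel,
                   pcs: np.ndarray, cohort: Cohort, snp_ids=None,
                   alpha: float = 0.05,
                   expected_direction: dict[str, int] | None = None
                   ) -> ScreenResult:
    """Mixed-model association of every SNP dosage with every MRS.

    Monomorphic SNPs are skipped with a warning and excluded from the test
    count; the Bonferroni adjustment uses the number of SNPs actually
    tested.  Expected directions default to positive for all five MRSs
    (each is positively associated with breast-cancer risk); direction
    consistency is counted among the nominally significant hits.
    """
    _check_alignment(mrs_table, cohort)
    if not np.array_equal(panel.sample_ids, cohort.ids):
        raise ValueError("genotype panel not aligned to cohort")
    if expected_direction is None:
        expected_direction = {m: 1 for m in MRS_NAMES}
    meta_ids = panel.snp_meta["snp_id"].tolist()
    if snp_ids is None:
        snp_ids = meta_ids
    pos = {s: i for i, s in enumerate(meta_ids)}
    unknown = [s for s in snp_ids if s not in pos]
    if unknown:
        raise KeyError(f"SNPs absent from panel: {unknown[:10]}")

    rows = []
    skipped = []
    tested = []
    for sid in snp_ids:
        dos = panel.dosages[:, pos[sid]].astype(float)
        nan = np.isnan(dos)
        if nan.any():
            dos = np.where(nan, np.nanmean(dos), dos)
        if dos.std(ddof=1) == 0:
            logger.warning("skipping monomorphic SNP %s", sid)
            skipped.append(sid)
            continue
        tested.append(sid)
        for mrs_name in MRS_NAMES:
            y = mrs_table[mrs_name].to_numpy(dtype=float)
            _, op = _fit_association(y, dos, pcs, cohort)
            rows.append({"snp_id": sid, "mrs": mrs_name,
                         "estimate": op.estimate, "p": op.p_value})
    if not tested:
        raise ValueError("no polymorphic SNPs to test")

    per_snp = pd.DataFrame(rows)
    n_tests = len(tested)
    per_snp["bonferroni_adjusted_p"] = np.minimum(1.0, per_snp["p"] * n_tests)
    per_snp["direction_consistent"] = [
        np.sign(e) == expected_direction[m]
        for e, m in zip(per_snp["estimate"], per_snp["mrs"])]

    summary_rows = []
    for mrs_name in MRS_NAMES:
        sub = per_snp[per_snp["mrs"] == mrs_name]
        nominal = sub["p"] < alpha
        summary_rows.append({
            "mrs": mrs_name,
            "n_tests": n_tests,
            "n_nominal": int(nominal.sum()),
            "n_expected": n_tests * alpha,
            "excess_p": excess_significance_p(int(nominal.sum()), n_tests,
                                              alpha),
            "n_direction_consistent": int(
                (nominal & sub["direction_consistent"]).sum()),
            "n_bonferroni_hits": int((sub["bonferroni_adjusted_p"]
                                      < alpha).sum()),
        })
    return ScreenResult(per_snp=per_snp, summary=pd.DataFrame(summary_rows),
                        n_tests=n_tests, alpha=alpha, skipped_snps=skipped)


def label_bic_evidence(delta_bic: float) -> str:
    """Kass-Raftery-style evidence label for a BIC difference.

    Bins: < 2 negligible, 2-6 positive, 6-10 strong, > 10 very strong.
    """
    if not np.isfinite(delta_bic):
        raise ValueError("delta BIC must be finite")
    d = abs(delta_bic)
    if d < 2:
        return "negligible"
    if d < 6:
        return "positive"
    if d <= 10:
        return "strong"
    return "very strong"
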