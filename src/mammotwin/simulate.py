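"""Synthetic twin/sister cohort generator.

Emulates the study design the analysis assumes: monozygotic (MZ) twin pairs
with identical germlines, dizygotic (DZ) twin pairs and non-twin sisters
with Mendelian half-sharing, age/BMI covariates, and nested mammographic
density measures whose transformed values follow an additive polygenic
(ACE) model:

    z = prs_effect * std(PRS) + A + C + E + beta_age * age~ + beta_invbmi * (1/BMI)~

with ``var(A) = a^2`` (additive polygenic), ``var(C) = c^2`` (shared
environment) and ``var(E) = e^2`` unique, ``a^2 + c^2 + e^2 = 1``.  The
additive component is decomposed as ``A = A_family + A_segregation`` with an
equal variance split, the segregation part being shared by MZ co-twins and
independent for DZ twins and sisters; the implied within-pair correlations
are ``a^2 + c^2`` (MZ) and ``a^2/2 + c^2`` (DZ/sisters).  Covariates enter
centred at their cohort means so the location targets are unaffected.

Genotypes are produced by explicit parental-gamete transmission, so sibling
dosage sharing (expected identity-by-descent 0.5) arises mechanistically
rather than by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, COHORT_COLUMNS
from .genotypes import GenotypePanel, WeightSet, SNP_META_COLUMNS, compute_prs

logger = logging.getLogger(__name__)

BACK_TRANSFORMS = ("cube", "square", "exp", "identity")

#: measures with directly generated latent traits (percent and white are derived)
GENERATED_MEASURES = ("cumulus", "altocumulus", "cirrocumulus", "total_area")


@dataclass(frozen=True)
class TraitModel:
    """Generative model for one transformed density measure.

    ``loc`` and ``scale`` place the unit-variance latent trait on the
    transformed scale of the measure before back-transformation.
    """

    var_additive: float = 0.6
    var_shared_env: float = 0.0
    var_unique: float = 0.4
    beta_age: float = 0.0
    beta_invbmi: float = 0.0
    prs_effect: float = 0.0
    back_transform: str = "identity"
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        total = self.var_additive + self.var_shared_env + self.var_unique
        if not np.isclose(total, 1.0):
            raise ValueError(f"variance fractions must sum to 1, got {total}")
        if min(self.var_additive, self.var_shared_env, self.var_unique) < 0:
            raise ValueError("variance fractions must be non-negative")
        if self.back_transform not in BACK_TRANSFORMS:
            raise ValueError(f"unknown back_transform {self.back_transform!r}")


def default_trait_models() -> dict[str, TraitModel]:
    """Per-measure defaults calibrated to typical study magnitudes.

    Additive fractions follow twin-model estimates for these measures
    (about 0.6 for the conventional and bright-area measures, 0.4 for the
    brightest-area measure); locations and scales put the back-transformed
    medians near the magnitudes reported for screening-age women (dense
    area ~29 cm^2, bright area ~11 cm^2, brightest area ~1.6 cm^2, breast
    area ~100 cm^2).  The brightest-area PRS effect ordering (largest for
    the bright-area measure) mirrors the observed association pattern.
    """
    return {
        "cumulus": TraitModel(0.6, 0.0, 0.4, beta_age=-0.012, beta_invbmi=25.0,
                              prs_effect=0.06, back_transform="cube",
                              loc=3.08, scale=0.60),
        "altocumulus": TraitModel(0.6, 0.0, 0.4, beta_age=-0.012,
                                  beta_invbmi=25.0, prs_effect=0.08,
                                  back_transform="cube", loc=2.24, scale=0.50),
        "cirrocumulus": TraitModel(0.4, 0.0, 0.6, beta_age=-0.012,
                                   beta_invbmi=25.0, prs_effect=0.05,
                                   back_transform="exp", loc=0.47, scale=1.05),
        "total_area": TraitModel(0.6, 0.0, 0.4, beta_age=0.0,
                                 beta_invbmi=-60.0, prs_effect=0.0,
                                 back_transform="exp", loc=4.70, scale=0.30),
    }


# -- pedigrees ----------------------------------------------------------

def simulate_pedigrees(n_mz_pairs: int, n_dz_pairs: int, n_sibs: int,
                       age_mean_sd: tuple[float, float] = (54.0, 8.4),
                       bmi_mean_sd: tuple[float, float] = (26.1, 5.2),
                       seed: int = 0,
                       sib_family_sizes: tuple[int, ...] = (1, 2, 3),
                       age_range: tuple[float, float] = (30.0, 80.0)) -> Cohort:
    """Generate MZ/DZ twin pairs and sister families with covariates.

    Twins share their age; sisters' ages scatter uniformly within +/- 5
    years of a family mean.  BMI is drawn independently per woman.  Ages are
    clipped to ``age_range``, BMI floored at 15 kg/m^2.
    """
    if min(n_mz_pairs, n_dz_pairs, n_sibs) < 0:
        raise ValueError("counts must be non-negative")
    if n_mz_pairs + n_dz_pairs + n_sibs == 0:
        raise ValueError("empty cohort")
    if age_mean_sd[1] <= 0 or bmi_mean_sd[1] <= 0:
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    rows = []
    fam = 0

    def draw_bmi(n):
        return np.maximum(rng.normal(*bmi_mean_sd, size=n), 15.0)

    for zyg, n_pairs in (("MZ", n_mz_pairs), ("DZ", n_dz_pairs)):
        for _ in range(n_pairs):
            fam += 1
            fid = f"F{fam:05d}"
            age = float(np.clip(rng.normal(*age_mean_sd), lo, hi))
            bmi = draw_bmi(2)
            for k in range(2):
                rows.append((f"{fid}_{k + 1}", fid, f"{fid}_P", zyg, age,
                             float(bmi[k])))

    remaining = n_sibs
    while remaining > 0:
        fam += 1
        fid = f"F{fam:05d}"
        size = min(int(rng.choice(sib_family_sizes)), remaining)
        mean_age = rng.normal(*age_mean_sd)
        ages = np.clip(mean_age + rng.uniform(-5.0, 5.0, size=size), lo, hi)
        bmi = draw_bmi(size)
        for k in range(size):
            rows.append((f"{fid}_{k + 1}", fid, None, "SIB", float(ages[k]),
                         float(bmi[k])))
        remaining -= size

    return Cohort(pd.DataFrame(rows, columns=COHORT_COLUMNS))


# -- genotypes ----------------------------------------------------------

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def _gametes(parent_dosage: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Transmit one allele per SNP from each parent to one child.

    A parent with dosage g in {0,1,2} transmits the effect allele with
    probability g/2 (heterozygotes segregate at random).  Vectorized over
    a stack of parents (families x SNPs).
    """
    return (rng.random(parent_dosage.shape)
            < parent_dosage / 2.0).astype(float)


def simulate_genotypes(cohort: Cohort, n_snps: int,
                       maf_range: tuple[float, float] = (0.05, 0.49),
                       seed: int = 0,
                       missing_rate: float = 0.0) -> GenotypePanel:
    """Unlinked SNP dosages with correct within-family sharing.

    Two founder parents are drawn per family from Hardy-Weinberg proportions
    at the SNP's allele frequency; each non-MZ child receives one sampled
    gamete from each parent, while MZ co-twins copy a single child genome.
    ``missing_rate`` nulls a random fraction of calls to exercise QC.
    """
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    if not (0 < maf_range[0] <= maf_range[1] <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_snps)
    n = len(cohort)
    dosages = np.empty((n, n_snps))

    # batch families by (zygosity-kind, size) so founder and gamete draws
    # vectorize across families
    zyg_col = cohort.table["zygosity"].to_numpy()
    groups: dict[tuple, list[np.ndarray]] = {}
    for rows in cohort.family_index().values():
        key = (zyg_col[rows[0]] == "MZ", len(rows))
        groups.setdefault(key, []).append(rows)
    for (is_mz, k), fams in sorted(groups.items()):
        idx = np.asarray(fams, dtype=int)          # (m, k)
        m = idx.shape[0]
        mother = rng.binomial(2, maf, size=(m, n_snps)).astype(float)
        father = rng.binomial(2, maf, size=(m, n_snps)).astype(float)
        if is_mz:
            child = _gametes(mother, rng) + _gametes(father, rng)
            for j in range(k):
                dosages[idx[:, j]] = child
        else:
            for j in range(k):
                dosages[idx[:, j]] = (_gametes(mother, rng)
                                      + _gametes(father, rng))

    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan

    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS),
                                                    size=n_snps)]
    meta = pd.DataFrame({
        "snp_id": [f"snp{i + 1:05d}" for i in range(n_snps)],
        "chrom": [str(1 + i % 22) for i in range(n_snps)],
        "pos": 1000 * (1 + np.arange(n_snps)),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "maf": maf,
    })
    return GenotypePanel(dosages, meta, cohort.ids)


def simulate_weights(snp_meta: pd.DataFrame, seed: int = 0,
                     scale: float = 0.08) -> WeightSet:
    """Synthetic PRS weight table aligned to a panel's SNP metadata.

    Log-odds weights are drawn N(0, scale^2) per endpoint, with the three
    endpoint columns correlated (common core plus endpoint-specific noise)
    as real breast-cancer subtype weights are.
    """
    rng = np.random.default_rng(seed)
    m = len(snp_meta)
    core = rng.normal(0.0, scale, size=m)
    tab = snp_meta[SNP_META_COLUMNS].copy()
    for col in ("beta_overall", "beta_erneg", "beta_erpos"):
        tab[col] = 0.8 * core + rng.normal(0.0, 0.6 * scale, size=m)
    return WeightSet(tab)


# -- density traits ------------------------------------------------------

def _ace_components(cohort: Cohort, rng: np.random.Generator):
    """Standardized A (additive) and C (shared-environment) draws.

    A = A_family + A_segregation with a 1/2-1/2 variance split; the
    segregation part is one draw per MZ pair (identical germline) and one
    per individual otherwise, giving cov(A) = 1 within MZ pairs and 1/2
    within DZ/sister pairs.  C is one standard normal per family.
    """
    tab = cohort.table
    half = np.sqrt(0.5)
    fam_codes, _ = pd.factorize(tab["family_id"])
    # segregation groups: one draw per MZ pair, one per other individual
    seg_keys = np.where((tab["zygosity"] == "MZ") & tab["pair_id"].notna(),
                        "p" + tab["pair_id"].astype(str),
                        "i" + pd.Series(np.arange(len(tab))).astype(str))
    seg_codes, seg_uniq = pd.factorize(seg_keys)
    a = (half * rng.normal(size=fam_codes.max() + 1)[fam_codes]
         + half * rng.normal(size=len(seg_uniq))[seg_codes])
    c = rng.normal(size=fam_codes.max() + 1)[fam_codes]
    return a, c


def _back_transform(t: np.ndarray, kind: str, floor: float):
    """Invert the normalizing transformation; clip non-positive areas."""
    if kind == "cube":
        out = np.sign(t) * np.abs(t) ** 3
    elif kind == "square":
        out = np.sign(t) * t ** 2
    elif kind == "exp":
        out = np.exp(t)
    else:
        out = t.copy()
    n_clip = int((out < floor).sum())
    if n_clip:
        logger.info("clipped %d non-positive back-transformed areas at %g",
                    n_clip, floor)
    return np.maximum(out, floor), n_clip


def simulate_density(cohort: Cohort, panel: GenotypePanel | None = None,
                     weights: WeightSet | None = None,
                     models: dict[str, TraitModel] | None = None,
                     seed: int = 0, e_shared_frac: float = 0.5,
                     area_floor: float = 0.01,
                     mediation: dict[str, tuple[str, float]] | None = None
                     ) -> pd.DataFrame:
    """Simulate nested density measures from per-measure latent ACE traits.

    The four generated measures (dense area, bright area, brightest area,
    total breast area) share the same A and C draws (loaded by each
    measure's own a^2 and c^2) plus a fraction ``e_shared_frac`` of their
    unique variance, which induces the strong cross-measure correlation of
    real thresholded density measures without altering familial
    correlations.  Nesting (brightest <= bright <= dense <= total) is
    enforced by clipping after back-transformation; the derived percent and
    white measures are computed from the clipped areas.

    ``mediation`` maps a target measure to ``(source_measure, weight)``:
    the target's structural latent becomes ``weight * z_source +
    sqrt(1 - weight^2) * z_own`` with the target's own part built from
    fresh familial draws, so any PRS effect on the source propagates into
    the target *only through the source*.  This mirrors the physical
    nesting of the thresholded areas (the dense area contains the bright
    area, so a genetic effect on the bright area mechanically appears in
    the dense area, and vanishes once the bright-area score is adjusted
    for).

    Returns a DataFrame aligned to the cohort with the area columns, the
    derived ``cumulus_percent`` and ``cumulus_white`` columns, and the
    latent transformed traits as ``latent_<measure>`` columns.
    """
    models = dict(default_trait_models() if models is None else models)
    unknown = set(models) - set(GENERATED_MEASURES)
    if unknown:
        raise ValueError(f"unknown measures in trait models: {sorted(unknown)}")
    for m in GENERATED_MEASURES:
        if m not in models:
            raise ValueError(f"missing trait model for {m!r}")
    rng = np.random.default_rng(seed)
    n = len(cohort)

    if panel is not None and weights is not None:
        if not np.array_equal(panel.sample_ids, cohort.ids):
            raise ValueError("genotype panel not aligned to cohort")
        prs = compute_prs(panel, weights, "overall").to_numpy()
        std_prs = (prs - prs.mean()) / prs.std(ddof=0)
    else:
        std_prs = np.zeros(n)

    a, c = _ace_components(cohort, rng)
    e_shared = rng.normal(size=n)
    age = cohort.table["age"].to_numpy(dtype=float)
    invbmi = 1.0 / cohort.table["bmi"].to_numpy(dtype=float)
    age_c = age - age.mean()
    invbmi_c = invbmi - invbmi.mean()

    mediation = mediation or {}
    for target, (source, lam) in mediation.items():
        if target not in GENERATED_MEASURES or source not in GENERATED_MEASURES:
            raise ValueError("mediation must link generated measures")
        if source in mediation or source == target:
            raise ValueError("mediation chains/self-links are not supported")
        if not 0.0 <= lam <= 1.0:
            raise ValueError("mediation weight must lie in [0, 1]")

    def structural(tm: TraitModel, a_comp, c_comp, e_comp):
        return (np.sqrt(tm.var_additive) * a_comp
                + np.sqrt(tm.var_shared_env) * c_comp
                + np.sqrt(tm.var_unique) * e_comp
                + tm.prs_effect * std_prs)

    struct: dict[str, np.ndarray] = {}
    for name in GENERATED_MEASURES:
        if name in mediation:
            continue
        e = (np.sqrt(e_shared_frac) * e_shared
             + np.sqrt(1.0 - e_shared_frac) * rng.normal(size=n))
        struct[name] = structural(models[name], a, c, e)
    for target, (source, lam) in mediation.items():
        # fresh familial draws keep the target's own part independent of
        # the source, so the source fully mediates its PRS effect
        a2, c2 = _ace_components(cohort, rng)
        own = structural(models[target], a2, c2, rng.normal(size=n))
        struct[target] = lam * struct[source] + np.sqrt(1 - lam ** 2) * own

    out = pd.DataFrame({"id": cohort.ids})
    areas: dict[str, np.ndarray] = {}
    for name in GENERATED_MEASURES:
        tm = models[name]
        z = (struct[name] + tm.beta_age * age_c + tm.beta_invbmi * invbmi_c)
        t = tm.loc + tm.scale * z
        areas[name], _ = _back_transform(t, tm.back_transform, area_floor)
        out[f"latent_{name}"] = t

    # enforce nesting: brightest <= bright <= dense <= 0.99 * total
    total = np.maximum(areas["total_area"], areas["cumulus"] / 0.99)
    cumulus = areas["cumulus"]
    alto = np.minimum(areas["altocumulus"], cumulus)
    cirro = np.minimum(areas["cirrocumulus"], alto)
    n_nest = int((total > areas["total_area"]).sum()
                 + (alto < areas["altocumulus"]).sum()
                 + (cirro < areas["cirrocumulus"]).sum())
    if n_nest:
        logger.info("nesting enforced by clipping at %d positions", n_nest)

    out["cumulus"] = cumulus
    out["altocumulus"] = alto
    out["cirrocumulus"] = cirro
    out["total_area"] = total
    out["cumulus_white"] = cumulus - alto
    out["cumulus_percent"] = 100.0 * cumulus / total
    return out


def simulate_cohort(n_mz_pairs: int = 584, n_dz_pairs: int = 318,
                    n_sibs: int = 755, n_snps: int = 313, seed: int = 0,
                    models: dict[str, TraitModel] | None = None,
                    maf_range: tuple[float, float] = (0.05, 0.49),
                    missing_rate: float = 0.0):
    """End-to-end synthetic study: pedigrees, genotypes, weights, density.

    Default sizes reproduce the twin-and-sister study composition (584 MZ
    pairs, 318 DZ pairs, 755 sisters; 2559 women) with a 313-SNP weight
    panel.  Sub-seeds are derived from ``seed`` so each stage is
    independently reproducible.

    Returns ``(cohort, panel, weights, density)`` where density includes
    the latent trait columns.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    cohort = simulate_pedigrees(n_mz_pairs, n_dz_pairs, n_sibs, seed=seeds[0])
    panel = simulate_genotypes(cohort, n_snps, maf_range=maf_range,
                               seed=seeds[1], missing_rate=missing_rate)
    weights = simulate_weights(panel.snp_meta, seed=seeds[2])
    density = simulate_density(cohort, panel, weights, models=models,
                               seed=seeds[3])
    return cohort, panel, weights, density


def within_pair_correlation(values: np.ndarray, cohort: Cohort,
                            zygosity: str) -> tuple[float, int]:
    """Double-entered Pearson correlation across complete pairs.

    For ``zygosity`` in {"MZ", "DZ"} uses twin pairs; for "SIB" uses all
    within-family sister pairs.  Returns ``(r, n_pairs)``.
    """
    values = np.asarray(values, dtype=float)
    tab = cohort.table
    left, right = [], []
    if zygosity in ("MZ", "DZ"):
        mask = tab["zygosity"] == zygosity
        for _, grp in tab.loc[mask].groupby("pair_id"):
            if len(grp) == 2:
                i, j = grp.index
                left.append(values[i]); right.append(values[j])
    elif zygosity == "SIB":
        for _, grp in tab.loc[tab["zygosity"] == "SIB"].groupby("family_id"):
            idx = list(grp.index)
            for u in range(len(idx)):
                for v in range(u + 1, len(idx)):
                    left.append(values[idx[u]]); right.append(values[idx[v]])
    else:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    if not left:
        raise ValueError(f"no complete {zygosity} pairs in cohort")
    x = np.concatenate([left, right])
    y = np.concatenate([right, left])
    r = float(np.corrcoef(x, y)[0, 1])
    return r, len(left)
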