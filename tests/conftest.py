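import numpy as np
import pytest

import mammotwin as mt


@pytest.fixture
def mixed_cohort():
    """Small cohort with all three zygosity groups."""
    return mt.simulate_pedigrees(15, 15, 20, seed=42)


@pytest.fixture(scope="session")
def small_study():
    """End-to-end synthetic study, scaled down for fast pipeline tests."""
    cohort, panel, weights, density = mt.simulate_cohort(
        n_mz_pairs=40, n_dz_pairs=30, n_sibs=40, n_snps=40, seed=7)
    merged = cohort.table.merge(density, on="id")
    scores, meta = mt.build_mrs_table(merged)
    pcs = mt.compute_pcs(panel, k=10)
    prs = {ep: mt.compute_prs(panel, weights, ep)
           for ep in ("overall", "ERneg", "ERpos")}
    return {"cohort": cohort, "panel": panel, "weights": weights,
            "density": density, "mrs": scores, "mrs_meta": meta,
            "pcs": pcs, "prs": prs}


@pytest.fixture(scope="session")
def identity_models():
    """Trait models with no transform and no covariate/PRS effects."""
    def make(a2, c2):
        e2 = 1.0 - a2 - c2
        return {m: mt.TraitModel(a2, c2, e2, back_transform="identity")
                for m in ("cumulus", "altocumulus", "cirrocumulus",
                          "total_area")}
    return make


def corr_se(r: float, n_pairs: int) -> float:
    """Large-sample standard error of a Pearson correlation over pairs."""
    return (1.0 - r ** 2) / np.sqrt(n_pairs)
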