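"""Shared helpers and independent oracles for the test suite."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from stratewas import CohortConfig, CovariateSpec, generate_cohort
from stratewas.association import fit_cpg_regressions
from stratewas.preprocess import CellComposition, composition_pcs


def ols_oracle(y: np.ndarray, X: np.ndarray, coef_index: int):
    """Closed-form normal-equations OLS with a t tail for one coefficient."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * XtX_inv[coef_index, coef_index])
    t = beta[coef_index] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return beta[coef_index], se, t, dof, p


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive two-sided Fisher p by exact integer enumeration.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed one by more
    than a factor 1 + 1e-7 (the probability-mass rule), using integer
    binomial-coefficient weights so comparisons are exact.
    """
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(kmin, kmax + 1)}
    w_obs = weights[a]
    # integer form of w <= w_obs * (1 + 1e-7)
    total = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    return total / comb(n, c1)


def small_null_cohort(seed: int, n_samples: int = 80, n_probes: int = 250) -> "CohortBundle":
    return generate_cohort(
        CohortConfig(
            n_samples=n_samples,
            n_probes=n_probes,
            n_reference_probes=100,
            effect_fraction=0.0,
            seed=seed,
        )
    )


def stratum_pvalues_light(bundle, stratum: str, use_true_pcs: bool = True,
                          shuffle_rng=None) -> np.ndarray:
    """Per-CpG p-values for one stratum without the ComBat step.

    Chip indicators in the regression absorb the simulated chip shifts, so
    this cheaper chain is statistically equivalent to adjust-then-regress
    for calibration and recovery checks.
    """
    pcs = composition_pcs(
        CellComposition(bundle.truth.true_compositions),
        k=min(5, bundle.config.n_cell_types - 1),
    )
    samples = bundle.samples
    if shuffle_rng is not None:
        samples = samples.copy()
        mask = samples["fetal_sex"] == stratum
        vals = samples.loc[mask, "epds"].to_numpy().copy()
        shuffle_rng.shuffle(vals)
        samples.loc[mask, "epds"] = vals
    spec = CovariateSpec(
        n_ecc_pcs=pcs.scores.shape[1], categorical=("chip", "chip_position")
    )
    table = fit_cpg_regressions(
        bundle.beta, samples, spec, stratum=stratum, ecc_pcs=pcs.scores
    )
    return table.loc[table["status"] == "ok", "p"].to_numpy()
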