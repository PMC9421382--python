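"""Stratified per-CpG association with EPDS and p-value-distribution inference.

For each fetal-sex stratum, every probe's beta values are regressed on the
EPDS score with an intercept and the configured covariates (cell-composition
principal components, technical factors).  The per-CpG two-sided p-values of
the EPDS coefficient are then examined as a distribution: a one-sided
Kolmogorov-Smirnov statistic D+ measures excess of small p-values relative
to Uniform(0, 1), probes below a nominal threshold (default 0.005) are
selected as EPDS-associated variable CpGs, and simple count summaries
(percentage of the tested universe, fold ratio between strata) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataIntegrityError

P_FLOOR = 1e-300  # keeps log-scale reporting finite


@dataclass(frozen=True)
class CovariateSpec:
    """Covariates to include beside the EPDS term.

    ``n_ecc_pcs`` cell-composition PCs, ``categorical`` sample-sheet factors
    (expanded to treatment contrasts, reference = first observed level), and
    ``numeric`` sample-sheet columns.
    """

    n_ecc_pcs: int = 0
    categorical: tuple[str, ...] = ()
    numeric: tuple[str, ...] = ()

    def build_design(
        self, samples: pd.DataFrame, ecc_pcs: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Covariate columns (no intercept, no EPDS), indexed by sample_id."""
        idx = samples["sample_id"] if "sample_id" in samples.columns else samples.index
        parts: list[pd.DataFrame] = []
        if self.n_ecc_pcs > 0:
            if ecc_pcs is None:
                raise ConfigError("CovariateSpec requests Ecc PCs but none supplied")
            if ecc_pcs.shape[1] < self.n_ecc_pcs:
                raise ConfigError(
                    f"requested {self.n_ecc_pcs} Ecc PCs, only {ecc_pcs.shape[1]} available"
                )
            parts.append(ecc_pcs.iloc[:, : self.n_ecc_pcs].reindex(list(idx)))
        for col in self.numeric:
            if col not in samples.columns:
                raise ConfigError(f"numeric covariate {col!r} not in sample sheet")
            parts.append(pd.DataFrame({col: samples[col].to_numpy(dtype=float)}, index=idx))
        for col in self.categorical:
            if col not in samples.columns:
                raise ConfigError(f"categorical covariate {col!r} not in sample sheet")
            series = samples[col]
            levels = list(pd.unique(series.dropna()))
            dummies = pd.DataFrame(index=idx)
            for lev in levels[1:]:  # first observed level is the reference
                dummies[f"{col}[{lev}]"] = (series == lev).astype(float).to_numpy()
            dummies[series.isna().to_numpy()] = np.nan
            parts.append(dummies)
        if not parts:
            return pd.DataFrame(index=idx)
        out = pd.concat(parts, axis=1)
        out.index = pd.Index(idx, name="sample_id")
        return out


def fit_cpg_regressions(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: CovariateSpec = CovariateSpec(),
    stratum: str | None = None,
    ecc_pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mass univariate OLS of each probe on EPDS within a stratum.

    Returns a table indexed by probe_id with columns slope, se, t, df, p
    (two-sided on the EPDS coefficient), n_used and status.  Probes with
    (numerically) constant beta are flagged ``degenerate`` and carry no
    p-value.  Samples with missing EPDS or covariates are dropped listwise;
    the dropped count is stored in ``result.attrs["n_dropped"]``.
    """
    sheet = samples.copy()
    if "sample_id" not in sheet.columns:
        raise DataIntegrityError("sample sheet lacks sample_id column")
    sheet = sheet.set_index("sample_id")
    if stratum is not None:
        sheet = sheet[sheet["fetal_sex"] == stratum]
        if sheet.empty:
            raise DataIntegrityError(f"stratum {stratum!r} has no samples")
    if sheet["epds"].isna().all():
        raise DataIntegrityError("all EPDS values missing in stratum")

    design = covariates.build_design(sheet.reset_index(), ecc_pcs)
    model = pd.concat([sheet[["epds"]].astype(float), design], axis=1)
    complete = model.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    model = model[complete]
    use_ids = [s for s in model.index if s in beta.columns]
    model = model.loc[use_ids]
    n_used = len(use_ids)

    X = np.column_stack([np.ones(n_used), model.to_numpy(dtype=float)])
    k = X.shape[1]
    if n_used < k + 2:
        raise DataIntegrityError(
            f"stratum has {n_used} usable samples; need at least {k + 2}"
        )

    Y = beta[use_ids].to_numpy(dtype=float)  # G x n
    dof = n_used - k
    if np.linalg.matrix_rank(X) < k:
        res = pd.DataFrame(
            {
                "slope": np.nan, "se": np.nan, "t": np.nan, "df": dof,
                "p": np.nan, "n_used": n_used, "status": "degenerate",
            },
            index=beta.index,
        )
        res.attrs["n_dropped"] = n_dropped
        return res

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # k x n
    B = Y @ H.T  # G x k
    resid = Y - B @ X.T
    sigma2 = (resid**2).sum(axis=1) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        tval = B[:, 1] / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    pval = np.maximum(pval, P_FLOOR)

    degenerate = Y.var(axis=1) < 1e-24
    status = np.where(degenerate, "degenerate", "ok")
    res = pd.DataFrame(
        {
            "slope": np.where(degenerate, np.nan, B[:, 1]),
            "se": np.where(degenerate, np.nan, se),
            "t": np.where(degenerate, np.nan, tval),
            "df": dof,
            "p": np.where(degenerate, np.nan, pval),
            "n_used": n_used,
            "status": status,
        },
        index=beta.index.copy(),
    )
    res.attrs["n_dropped"] = n_dropped
    return res


@dataclass
class KSResult:
    d_plus: float
    p: float
    n: int
    mode: str

    def to_dict(self) -> dict:
        return {"d_plus": self.d_plus, "p": self.p, "n": self.n, "mode": self.mode}


def ks_uniformity_test(pvalues, mode: str = "asymptotic") -> KSResult:
    """One-sided KS test for excess of small p-values vs Uniform(0, 1).

    D+ = max_i (i/n - p_(i)), floored at 0.  The tail is the asymptotic
    Smirnov form exp(-2 n D+^2) by default; ``mode="exact"`` uses the exact
    one-sided distribution (intended for small n), ``mode="auto"`` switches
    to exact for n <= 100.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise DataIntegrityError("no p-values supplied")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataIntegrityError("p-values must lie in [0, 1]")
    n = p.size
    p.sort()
    d_plus = float(max(np.max(np.arange(1, n + 1) / n - p), 0.0))
    if mode == "auto":
        mode = "exact" if n <= 100 else "asymptotic"
    if mode == "exact":
        tail = float(stats.ksone.sf(d_plus, n))
    elif mode == "asymptotic":
        tail = float(min(1.0, np.exp(-2.0 * n * d_plus**2)))
    else:
        raise ConfigError(f"unknown KS mode {mode!r}")
    return KSResult(d_plus=d_plus, p=tail, n=n, mode=mode)


def select_epds_vcpgs(results: pd.DataFrame, alpha: float = 0.005) -> list[str]:
    """Probe ids with status ok and p strictly below ``alpha`` (input order)."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    ok = (results["status"] == "ok") & (results["p"] < alpha)
    return list(results.index[ok])


def intersect_probe_sets(set_a, set_b) -> list[str]:
    """Exact intersection in deterministic lexicographic order."""
    return sorted(set(set_a) & set(set_b))


@dataclass
class CountSummary:
    n_selected: int
    n_universe: int
    percent: float  # of universe, rounded to 1 decimal
    n_other: int | None
    fold_ratio: float | None  # vs other_selected, rounded to 1 decimal

    def to_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "n_universe": self.n_universe,
            "percent": self.percent,
            "n_other": self.n_other,
            "fold_ratio": self.fold_ratio,
        }


def summarize_counts(selected, universe, other_selected=None) -> CountSummary:
    """Prevalence of a probe selection and its fold ratio vs another.

    ``selected`` must be a subset of ``universe``.  Accepts either id
    collections or plain integer counts.
    """
    n_sel = selected if isinstance(selected, int) else len(set(selected))
    n_uni = universe if isinstance(universe, int) else len(set(universe))
    if n_uni == 0:
        raise DataIntegrityError("empty universe")
    if not isinstance(selected, int) and not isinstance(universe, int):
        extra = set(selected) - set(universe)
        if extra:
            raise DataIntegrityError(
                f"{len(extra)} selected probes outside the universe"
            )
    if n_sel > n_uni:
        raise DataIntegrityError("selected count exceeds universe count")
    n_other = None if other_selected is None else (
        other_selected if isinstance(other_selected, int) else len(set(other_selected))
    )
    fold = None
    if n_other:
        fold = round(n_sel / n_other, 1)
    return CountSummary(
        n_selected=n_sel,
        n_universe=n_uni,
        percent=round(100.0 * n_sel / n_uni, 1),
        n_other=n_other,
        fold_ratio=fold,
    )
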