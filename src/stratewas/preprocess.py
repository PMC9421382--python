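"""Probe QC, scale transforms, batch adjustment, variable-probe selection,
and cell-composition covariates.

The processing chain mirrors standard Infinium-array practice: failing
probes are removed (detection p, bead counts, SNP/cross-hybridizing
masks), beta values are mapped to the M-scale for empirical-Bayes batch
adjustment (ComBat), mapped back, and only "variable" probes — those whose
outlier-trimmed beta range across samples reaches a threshold (default 5
percentage points) — are carried into association testing.  Cell-type
composition is estimated per sample by constrained projection onto a
reference panel, and its principal components serve as regression
covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import ConfigError, DataIntegrityError


def beta_to_m(beta, epsilon: float = 1e-6):
    """Map methylation fractions to M-values: log2(v / (1 - v)).

    Values are clipped to [epsilon, 1 - epsilon] first, so boundary betas
    stay finite.  Accepts a DataFrame or ndarray and preserves the type.
    """
    if not 0 < epsilon < 0.5:
        raise ConfigError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    values = beta.to_numpy(dtype=float) if isinstance(beta, pd.DataFrame) else np.asarray(beta, dtype=float)
    v = np.clip(values, epsilon, 1.0 - epsilon)
    m = np.log2(v / (1.0 - v))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` on the clipped domain: 2^M / (1 + 2^M)."""
    values = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    # logistic form avoids overflow for large |M|
    beta = 1.0 / (1.0 + np.exp2(-values))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    return beta


@dataclass
class ProbeQC:
    """Per probe x sample detection p-values and minimum bead counts.

    ``bead_count`` holds, per probe and sample, the smaller of the
    methylated- and unmethylated-channel bead counts.
    """

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame


def apply_probe_qc(
    beta: pd.DataFrame,
    qc: ProbeQC,
    annotation: pd.DataFrame,
    detection_p_threshold: float = 0.01,
    min_beads: int = 3,
    policy: str = "probe",
) -> tuple[pd.DataFrame, dict]:
    """Remove failing probes; returns (surviving beta, removal log).

    A probe is dropped when any sample reaches detection p >= threshold
    (boundary inclusive), any sample has fewer than ``min_beads`` beads in
    either channel, or the probe carries a SNP or cross-hybridizing mask
    flag.  ``policy="mask"`` instead sets individual failing values to NaN
    and drops only flagged probes.  Original probe order is preserved.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    for name, frame in (("detection_p", qc.detection_p), ("bead_count", qc.bead_count)):
        missing = beta.index.difference(frame.index)
        if len(missing):
            raise DataIntegrityError(
                f"{len(missing)} probes absent from QC {name} (e.g. {missing[0]!r})"
            )
    missing = beta.index.difference(ann.index)
    if len(missing):
        raise DataIntegrityError(
            f"{len(missing)} probes absent from annotation (e.g. {missing[0]!r})"
        )

    det = qc.detection_p.loc[beta.index, beta.columns].to_numpy()
    beads = qc.bead_count.loc[beta.index, beta.columns].to_numpy()
    snp = ann.loc[beta.index, "snp_flag"].to_numpy(dtype=bool)
    xhyb = ann.loc[beta.index, "cross_hybridizing_flag"].to_numpy(dtype=bool)

    det_fail = (det >= detection_p_threshold).any(axis=1)
    bead_fail = (beads < min_beads).any(axis=1)
    if policy == "probe":
        removed = det_fail | bead_fail | snp | xhyb
        out = beta.loc[~removed]
    elif policy == "mask":
        removed = snp | xhyb
        out = beta.loc[~removed].where(
            ~((det >= detection_p_threshold) | (beads < min_beads))[~removed]
        )
    else:
        raise ConfigError(f"unknown QC policy {policy!r}")
    log = {
        "policy": policy,
        "detection_p": int(det_fail.sum()),
        "bead_count": int(bead_fail.sum()),
        "snp_flag": int(snp.sum()),
        "cross_hybridizing_flag": int(xhyb.sum()),
        "removed": int(removed.sum()),
        "retained": int((~removed).sum()),
    }
    return out, log


def _design_matrix(batch_codes: np.ndarray, n_batches: int, design) -> np.ndarray:
    onehot = np.zeros((batch_codes.size, n_batches))
    onehot[np.arange(batch_codes.size), batch_codes] = 1.0
    if design is None:
        return onehot
    cov = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    return np.hstack([onehot, cov])


def combat_adjust(
    m: pd.DataFrame,
    batch,
    design=None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment of M-values.

    Per probe, data are standardized against the batch-design OLS fit and a
    pooled variance; per-batch location (normal prior) and scale
    (inverse-gamma prior) effects are shrunk with moment-matched
    hyperparameters by iterated conditional estimation, then removed.
    Covariates passed in ``design`` (columns must not encode batch) are
    preserved in the back-transform.
    """
    batch = pd.Series(np.asarray(batch, dtype=object), index=m.columns)
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        warnings.warn("single batch: returning input unchanged", stacklevel=2)
        return m.copy()
    counts = batch.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise DataIntegrityError(
            f"batch {singletons.index[0]!r} has {int(singletons.iloc[0])} sample(s); "
            "ComBat needs >= 2 per batch"
        )
    codes = np.array([levels.index(b) for b in batch])
    nb = len(levels)
    n = m.shape[1]
    Y = m.to_numpy(dtype=float).T  # n x G

    X = _design_matrix(codes, nb, design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigError("design is confounded with batch (rank-deficient)")
    beta_hat = np.linalg.solve(X.T @ X, X.T @ Y)  # p x G
    batch_sizes = np.array([(codes == i).sum() for i in range(nb)], dtype=float)
    grand_mean = (batch_sizes / n) @ beta_hat[:nb]
    resid = Y - X @ beta_hat
    var_pooled = np.maximum((resid**2).mean(axis=0), 1e-12)

    stand_mean = np.tile(grand_mean, (n, 1))
    if X.shape[1] > nb:
        stand_mean = stand_mean + X[:, nb:] @ beta_hat[nb:]
    sd = np.sqrt(var_pooled)
    Z = (Y - stand_mean) / sd

    Z_adj = np.empty_like(Z)
    for i in range(nb):
        idx = codes == i
        Zi = Z[idx]
        ni = Zi.shape[0]
        gamma_hat = Zi.mean(axis=0)
        delta_hat = Zi.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        # moment-matched inverse-gamma hyperparameters
        dm, dv = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2 * dv + dm**2) / dv
        b_prior = (dm * dv + dm**3) / dv
        g_old, d_old = gamma_hat.copy(), delta_hat.copy()
        for _ in range(max_iter):
            g_new = (ni * t2 * gamma_hat + d_old * gamma_bar) / (ni * t2 + d_old)
            sum2 = ((Zi - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior) / (ni / 2.0 + a_prior - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        Z_adj[idx] = (Zi - g_old) / np.sqrt(d_old)

    out = Z_adj * sd + stand_mean
    return pd.DataFrame(out.T, index=m.index, columns=m.columns)


def select_variable_probes(
    beta: pd.DataFrame,
    min_range: float = 0.05,
    fence_multiplier: float = 1.5,
    inclusive: bool = True,
) -> list[str]:
    """Variable-CpG filter: outlier-trimmed beta range >= ``min_range``.

    Per probe, Tukey fences (Q1 - f*IQR, Q3 + f*IQR) trim outliers; the
    probe is kept iff max - min of the remaining values reaches the
    threshold (default 5 percentage points, boundary inclusive).  Returns
    retained probe ids in input order.
    """
    if not 0 < min_range < 1:
        raise ConfigError(f"min_range must lie in (0, 1), got {min_range}")
    if beta.shape[1] < 4:
        raise DataIntegrityError(
            "variable-probe selection needs >= 4 samples (quartile trimming)"
        )
    v = beta.to_numpy(dtype=float)
    q1 = np.percentile(v, 25, axis=1)
    q3 = np.percentile(v, 75, axis=1)
    iqr = q3 - q1
    lo = q1 - fence_multiplier * iqr
    hi = q3 + fence_multiplier * iqr
    trimmed = np.where((v >= lo[:, None]) & (v <= hi[:, None]), v, np.nan)
    rng = np.nanmax(trimmed, axis=1) - np.nanmin(trimmed, axis=1)
    keep = rng >= min_range if inclusive else rng > min_range
    return list(beta.index[keep])


@dataclass
class CellComposition:
    """Estimated per-sample cell-type proportions (rows on the simplex)."""

    proportions: pd.DataFrame  # samples x cell types


def estimate_cell_composition(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
    penalty: float = 1000.0,
) -> CellComposition:
    """Reference-based deconvolution by constrained least squares.

    Per sample, solves min ||R w - b||^2 subject to w >= 0 and sum(w) = 1,
    via non-negative least squares with a weighted sum-to-one penalty row
    followed by exact renormalization onto the simplex.
    """
    missing = reference.index.difference(beta.index)
    if len(missing):
        raise DataIntegrityError(
            f"{len(missing)} reference probes absent from beta matrix"
        )
    R = reference.to_numpy(dtype=float)
    if R.shape[0] < R.shape[1]:
        raise DataIntegrityError("fewer shared probes than cell types")
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise DataIntegrityError("reference panel is rank-deficient on shared probes")
    B = beta.loc[reference.index].to_numpy(dtype=float)
    A = np.vstack([R, penalty * np.ones((1, R.shape[1]))])
    props = np.empty((beta.shape[1], R.shape[1]))
    for j in range(beta.shape[1]):
        y = np.concatenate([B[:, j], [penalty]])
        w, _ = nnls(A, y)
        s = w.sum()
        if s <= 0:
            raise DataIntegrityError(f"deconvolution degenerate for sample {beta.columns[j]!r}")
        props[j] = w / s
    return CellComposition(
        proportions=pd.DataFrame(
            props, index=pd.Index(beta.columns, name="sample_id"),
            columns=reference.columns,
        )
    )


@dataclass
class EccPCs:
    """Principal components of estimated cellular composition."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # components x cell types
    explained_variance_ratio: np.ndarray


def composition_pcs(composition: CellComposition, k: int = 5) -> EccPCs:
    """Column-centered PCA of cell compositions; top-``k`` scores.

    The sum-to-one constraint removes one dimension, so ``k`` may not
    exceed (number of cell types - 1).  Loadings are sign-fixed so each
    component's largest-magnitude loading is positive.
    """
    P = composition.proportions.to_numpy(dtype=float)
    n_types = P.shape[1]
    if k > n_types - 1:
        raise ConfigError(f"k={k} exceeds simplex rank {n_types - 1}")
    centered = P - P.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-12):
        raise DataIntegrityError("compositions have zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-|loading| entry positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :k] * s[:k]
    evr = s**2 / (s**2).sum()
    names = [f"ecc_pc{i + 1}" for i in range(k)]
    return EccPCs(
        scores=pd.DataFrame(scores, index=composition.proportions.index, columns=names),
        loadings=pd.DataFrame(
            vt[:k], index=names, columns=composition.proportions.columns
        ),
        explained_variance_ratio=evr[:k],
    )
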