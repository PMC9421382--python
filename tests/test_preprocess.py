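"""Scale transforms, probe QC, ComBat, variable-probe filter, deconvolution."""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stratewas import ConfigError, DataIntegrityError, ProbeQC
from stratewas.preprocess import (
    CellComposition,
    apply_probe_qc,
    beta_to_m,
    combat_adjust,
    composition_pcs,
    estimate_cell_composition,
    m_to_beta,
    select_variable_probes,
)


# ---------------------------------------------------------------- transforms
@pytest.mark.parametrize(
    "beta,expected",
    [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0), (1.0, np.log2((1 - 1e-6) / 1e-6))],
)
def test_beta_to_m_known_values(beta, expected):
    assert beta_to_m(np.array([beta]), epsilon=1e-6)[0] == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("m,expected", [(0.0, 0.5), (2.0, 0.8), (-2.0, 0.2)])
def test_m_to_beta_known_values(m, expected):
    assert m_to_beta(np.array([m]))[0] == pytest.approx(expected, abs=1e-12)


def test_bad_epsilon_rejected():
    with pytest.raises(ConfigError):
        beta_to_m(np.array([0.5]), epsilon=0.7)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1 - 1e-6, allow_nan=False))
def test_m_roundtrip_on_clipped_domain(x):
    assert m_to_beta(beta_to_m(np.array([x]), epsilon=1e-6))[0] == pytest.approx(x, abs=1e-12)


def test_transforms_preserve_dataframe_labels():
    df = pd.DataFrame([[0.2, 0.8]], index=["cg1"], columns=["s1", "s2"])
    out = m_to_beta(beta_to_m(df))
    pd.testing.assert_frame_equal(out, df, atol=1e-12)


# ------------------------------------------------------------------ probe QC
def _qc_fixture():
    probes = [f"cg{i}" for i in range(10)]
    samples = ["s1", "s2", "s3"]
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, (10, 3)), index=probes, columns=samples)
    det = pd.DataFrame(0.0, index=probes, columns=samples)
    beads = pd.DataFrame(10, index=probes, columns=samples)
    ann = pd.DataFrame(
        {
            "probe_id": probes,
            "snp_flag": [True, True] + [False] * 8,
            "cross_hybridizing_flag": [False, False, True] + [False] * 7,
        }
    )
    beads.loc["cg3", "s2"] = 2  # bead failure
    return beta, ProbeQC(detection_p=det, bead_count=beads), ann


def test_probe_qc_rule_enumeration():
    """2 SNP-flagged + 1 cross-hybridizing + 1 bead failure -> 6 survive."""
    beta, qc, ann = _qc_fixture()
    out, log = apply_probe_qc(beta, qc, ann)
    assert list(out.index) == [f"cg{i}" for i in (4, 5, 6, 7, 8, 9)]
    assert log == {
        "policy": "probe", "detection_p": 0, "bead_count": 1, "snp_flag": 2,
        "cross_hybridizing_flag": 1, "removed": 4, "retained": 6,
    }


def test_detection_p_boundary_is_inclusive():
    beta, qc, ann = _qc_fixture()
    qc.detection_p.loc["cg5", "s1"] = 0.01  # exactly at the threshold
    out, _ = apply_probe_qc(beta, qc, ann)
    assert "cg5" not in out.index


def test_bead_boundary_of_three_is_retained():
    beta, qc, ann = _qc_fixture()
    qc.bead_count.loc["cg6"] = 3
    out, _ = apply_probe_qc(beta, qc, ann)
    assert "cg6" in out.index


def test_qc_missing_probe_raises():
    beta, qc, ann = _qc_fixture()
    with pytest.raises(DataIntegrityError):
        apply_probe_qc(beta, ProbeQC(qc.detection_p.iloc[1:], qc.bead_count), ann)


# ---------------------------------------------------------------- vCpG filter
def test_variable_probe_threshold_arithmetic():
    evenly = np.linspace(0.40, 0.46, 12)  # range 0.06 -> retained
    narrow = np.linspace(0.50, 0.54, 12)  # range 0.04 -> excluded
    beta = pd.DataFrame([evenly, narrow], index=["wide", "narrow"])
    assert select_variable_probes(beta) == ["wide"]


def test_variable_probe_outlier_trimming():
    """A lone extreme value is trimmed by the Tukey fences before ranging."""
    vals = np.concatenate([np.linspace(0.495, 0.505, 50), [0.95]])
    beta = pd.DataFrame([vals], index=["spiky"])
    assert select_variable_probes(beta) == []
    # without the outlier rule the raw range (0.455) would pass
    assert vals.max() - vals.min() >= 0.05


def test_variable_probe_needs_four_samples():
    with pytest.raises(DataIntegrityError):
        select_variable_probes(pd.DataFrame([[0.1, 0.5, 0.9]]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_variable_probe_filter_properties(seed):
    """Sample order does not matter; raising the threshold never adds probes."""
    rng = np.random.default_rng(seed)
    beta = pd.DataFrame(rng.uniform(0.05, 0.95, (8, 12)),
                        index=[f"cg{i}" for i in range(8)])
    perm = rng.permutation(12)
    assert select_variable_probes(beta) == select_variable_probes(beta.iloc[:, perm])
    low = select_variable_probes(beta, min_range=0.05)
    high = select_variable_probes(beta, min_range=0.2)
    assert set(high) <= set(low)


# -------------------------------------------------------------------- ComBat
def _batched_matrix(seed=0, G=300, shift=0.8):
    rng = np.random.default_rng(seed)
    n = 30
    batch = np.array(["b1"] * 15 + ["b2"] * 15)
    m = rng.normal(0, 1, (G, n)) + rng.normal(0, 2, (G, 1))
    m[:, batch == "b2"] += shift
    return (
        pd.DataFrame(m, index=[f"cg{i}" for i in range(G)],
                     columns=[f"s{j}" for j in range(n)]),
        batch,
    )


def test_combat_single_batch_returns_input():
    m, _ = _batched_matrix()
    with pytest.warns(UserWarning):
        out = combat_adjust(m, ["one"] * m.shape[1])
    pd.testing.assert_frame_equal(out, m)


def test_combat_singleton_batch_names_the_batch():
    m, _ = _batched_matrix()
    batch = ["solo"] + ["rest"] * (m.shape[1] - 1)
    with pytest.raises(DataIntegrityError, match="solo"):
        combat_adjust(m, batch)


def test_combat_removes_planted_shift():
    """A planted 0.8 M-unit batch shift leaves |batch mean difference| < 0.05.

    The independent oracle is direct per-batch mean centering, which by
    construction zeroes the difference; ComBat must land close to it.
    """
    m, batch = _batched_matrix(shift=0.8)
    adj = combat_adjust(m, batch)
    diff = adj.loc[:, batch == "b2"].mean(axis=1) - adj.loc[:, batch == "b1"].mean(axis=1)
    assert np.abs(diff.mean()) < 0.05
    assert np.abs(diff).mean() < 0.6  # residual noise only, shift gone


def test_combat_location_idempotent_and_contracting():
    """Re-adjusting changes batch-mean structure by < 1e-3 and contracts.

    Full value-level idempotence does not hold for location/scale EB
    adjustment: the scale step shrinks chance between-batch variance
    differences anew on each pass (the reference implementation behaves
    identically), so the invariant checked here is that batch means stay
    put and successive passes change ever less.
    """
    m, batch = _batched_matrix(shift=0.8)
    once = combat_adjust(m, batch)
    twice = combat_adjust(once, batch)
    thrice = combat_adjust(twice, batch)

    def batch_mean_gap(df):
        return (df.loc[:, batch == "b2"].mean(axis=1)
                - df.loc[:, batch == "b1"].mean(axis=1)).to_numpy()

    # the systematic (across-probe mean) batch shift stays removed
    assert abs(batch_mean_gap(once).mean()) < 0.05
    assert abs(batch_mean_gap(twice).mean()) < 0.05
    # successive passes contract rather than oscillate
    d1 = np.abs(twice.to_numpy() - once.to_numpy()).max()
    d2 = np.abs(thrice.to_numpy() - twice.to_numpy()).max()
    assert d2 < d1


def test_combat_preserves_covariate_signal():
    """An EPDS effect orthogonal to batch survives adjustment within 10%.

    EPDS values are paired across the two batches so the covariate is
    exactly orthogonal to batch; probe-specific chip effects are planted on
    top of the EPDS signal.
    """
    rng = np.random.default_rng(1)
    n, G = 60, 300
    batch = np.array(["b1", "b2"] * (n // 2))
    epds = np.repeat(rng.normal(7, 4.2, n // 2), 2)
    slopes = rng.uniform(0.05, 0.15, G) * rng.choice([-1.0, 1.0], G)
    gamma = rng.normal(0.8, 0.4, G)
    m = rng.normal(0, 0.25, (G, n)) + np.outer(slopes, epds - epds.mean())
    m[:, batch == "b2"] += gamma[:, None]
    mdf = pd.DataFrame(m, index=[f"cg{i}" for i in range(G)],
                       columns=[f"s{j}" for j in range(n)])
    xc = epds - epds.mean()

    def refit(mat):
        yc = mat.to_numpy() - mat.to_numpy().mean(axis=1, keepdims=True)
        return yc @ xc / (xc @ xc)

    before = refit(mdf)
    after = refit(combat_adjust(mdf, batch, design=epds[:, None]))
    assert np.abs(after / before - 1).max() < 0.10


def test_combat_matches_sva_oracle(tmp_path):
    """Location/scale EB adjustment agrees with Bioconductor sva::ComBat."""
    rng = np.random.default_rng(5)
    G, n = 50, 24
    batch = np.repeat(["b1", "b2", "b3"], 8)
    codes = np.repeat([0, 1, 2], 8)
    gamma = rng.normal(0, 0.8, (G, 3))
    delta = rng.gamma(4.0, 0.25, (G, 3))
    m = rng.normal(0, 1.5, (G, 1)) + gamma[:, codes]
    m = m + rng.normal(0, 1, (G, n)) * np.sqrt(delta[:, codes])
    mdf = pd.DataFrame(m, index=[f"p{i}" for i in range(G)],
                       columns=[f"s{j}" for j in range(n)])
    mdf.to_csv(tmp_path / "m.tsv", sep="\t")
    (tmp_path / "batch.txt").write_text("\n".join(batch) + "\n")
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(sva))\n'
        'm <- as.matrix(read.table("m.tsv", header=TRUE, row.names=1, sep="\\t",'
        ' check.names=FALSE))\n'
        'batch <- scan("batch.txt", what=character(), quiet=TRUE)\n'
        'out <- ComBat(dat=m, batch=batch)\n'
        'write.table(out, "sva.tsv", sep="\\t", quote=FALSE)\n'
    )
    proc = subprocess.run(
        ["Rscript", script.name], cwd=tmp_path, capture_output=True, text=True
    )
    assert proc.returncode == 0, proc.stderr
    oracle = pd.read_csv(tmp_path / "sva.tsv", sep="\t", index_col=0)
    mine = combat_adjust(mdf, batch)
    assert np.abs(mine.to_numpy() - oracle.to_numpy()).max() < 1e-3


# ------------------------------------------------------------- deconvolution
def _reference(seed=0, n_probes=120, k=4):
    rng = np.random.default_rng(seed)
    R = rng.beta(0.8, 0.8, (n_probes, k)).clip(0.02, 0.98)
    return pd.DataFrame(R, index=[f"cg{i}" for i in range(n_probes)],
                        columns=[f"cell_{j}" for j in range(k)])


def test_exact_member_recovers_unit_proportion():
    ref = _reference()
    beta = ref[["cell_2"]].rename(columns={"cell_2": "s1"})
    est = estimate_cell_composition(beta, ref).proportions
    expected = np.array([0.0, 0.0, 1.0, 0.0])
    assert np.abs(est.loc["s1"].to_numpy() - expected).max() < 1e-6


def test_even_mixture_matches_simplex_grid_oracle():
    ref = _reference(k=2)
    mix = 0.5 * ref["cell_0"] + 0.5 * ref["cell_1"]
    beta = mix.to_frame("s1")
    est = estimate_cell_composition(beta, ref).proportions.loc["s1"].to_numpy()
    # brute-force grid search over the 1-simplex
    R = ref.to_numpy()
    grid = np.linspace(0, 1, 2001)
    sse = [np.sum((R @ np.array([w, 1 - w]) - mix.to_numpy()) ** 2) for w in grid]
    w_star = grid[int(np.argmin(sse))]
    assert est[0] == pytest.approx(w_star, abs=1e-3)
    assert est[0] == pytest.approx(0.5, abs=1e-6)


def test_noisy_six_type_mixtures_recovered():
    rng = np.random.default_rng(3)
    ref = _reference(seed=3, n_probes=600, k=6)
    W = rng.dirichlet(np.ones(6), size=30)
    noisy = ref.to_numpy() @ W.T + rng.normal(0, 0.02, (600, 30))
    beta = pd.DataFrame(noisy.clip(1e-4, 1 - 1e-4), index=ref.index,
                        columns=[f"s{j}" for j in range(30)])
    est = estimate_cell_composition(beta, ref).proportions.to_numpy()
    rmse = np.sqrt(((est - W) ** 2).mean())
    assert rmse < 0.05
    # estimates sit on the simplex
    assert (est >= 0).all()
    assert np.abs(est.sum(axis=1) - 1).max() < 1e-12


def test_rank_deficient_reference_raises():
    ref = _reference(k=3)
    ref["cell_2"] = ref["cell_1"]
    beta = ref[["cell_0"]].rename(columns={"cell_0": "s1"})
    with pytest.raises(DataIntegrityError):
        estimate_cell_composition(beta, ref)


# ---------------------------------------------------------------- Ecc PCA
def _composition(seed=0, n=40, k=6):
    rng = np.random.default_rng(seed)
    return CellComposition(
        proportions=pd.DataFrame(
            rng.dirichlet(np.ones(k), size=n),
            index=[f"s{j}" for j in range(n)],
            columns=[f"cell_{j}" for j in range(k)],
        )
    )


def test_pca_respects_simplex_rank():
    comp = _composition()
    with pytest.raises(ConfigError):
        composition_pcs(comp, k=6)
    pcs = composition_pcs(comp, k=5)
    assert pcs.scores.shape == (40, 5)
    # scores are column-orthogonal (SVD)
    gram = pcs.scores.to_numpy().T @ pcs.scores.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_pca_degenerate_composition_raises():
    comp = _composition(n=10)
    comp.proportions.iloc[:] = comp.proportions.iloc[0].to_numpy()
    with pytest.raises(DataIntegrityError):
        composition_pcs(comp, k=1)


def test_two_type_pca_matches_closed_form():
    """With 2 cell types, PC1 scores are the centered type-1 proportion."""
    comp = _composition(k=2)
    pcs = composition_pcs(comp, k=1)
    p1 = comp.proportions.iloc[:, 0].to_numpy()
    centered = p1 - p1.mean()
    expected = centered * np.sqrt(2)  # loading (1,-1)/sqrt(2), sign-fixed
    assert np.abs(pcs.scores.iloc[:, 0].to_numpy() - expected).max() < 1e-10
    assert pcs.explained_variance_ratio[0] == pytest.approx(1.0)
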