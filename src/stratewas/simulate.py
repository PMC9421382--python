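"""Synthetic Infinium-like methylation cohorts with known ground truth.

The generator emulates the statistical structure of a blood/placenta
methylation-array study: per-probe baseline beta values for a handful of
cell types, per-sample cell compositions drawn from a Dirichlet, chip-level
batch effects and measurement noise added on the M-scale, an EPDS
(Edinburgh Postnatal Depression Scale) covariate, and a linear EPDS effect
planted on the M-scale in a configurable fraction of probes — optionally
restricted to one fetal-sex stratum and biased toward chosen genomic
contexts.  Every stochastic choice flows from a single seed through named
sub-streams, so identical configurations produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import beta_to_m, m_to_beta

ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")
GENE_CONTEXTS = (
    "promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "intergenic",
)

# Rough EPIC-array-like context frequencies used as generator defaults.
DEFAULT_ISLAND_FREQS = {"island": 0.20, "shore": 0.18, "shelf": 0.06, "open_sea": 0.56}
DEFAULT_GENE_FREQS = {
    "promoter": 0.20,
    "five_prime_utr": 0.08,
    "exon": 0.10,
    "intron": 0.32,
    "three_prime_utr": 0.04,
    "intergenic": 0.26,
}

_STAGES = (
    "annotation",
    "baselines",
    "composition",
    "batch",
    "noise",
    "samplesheet",
    "effects",
)


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults are the package's reference simulation scale: 200 mothers on
    25 chips of 8, 20,000 probes, 6 blood cell types, EPDS ~ Normal(7, 4.2)
    rounded to [0, 30], 47.7% female fetuses, and a female-stratum-only
    effect in 2% of probes whose slope explains ``effect_r2`` of the total
    stochastic M-scale variance added by the generator.
    """

    n_samples: int = 200
    n_probes: int = 20_000
    female_fraction: float = 0.477
    epds_mean: float = 7.0
    epds_sd: float = 4.2
    n_cell_types: int = 6
    chip_size: int = 8
    batch_shift_sd: float = 0.45
    noise_sd: float = 0.25
    effect_fraction: float = 0.02
    effect_slope_sd: float = 0.016
    effect_r2: float | None = 0.05
    effect_stratum: str = "female"
    context_bias: float = 1.0
    biased_island_contexts: tuple[str, ...] = ("open_sea",)
    biased_gene_contexts: tuple[str, ...] = ("intergenic",)
    island_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISLAND_FREQS)
    )
    gene_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQS)
    )
    dirichlet_concentration: float = 30.0
    n_reference_probes: int = 600
    groups: tuple[str, ...] = ("normal",)
    clip: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        for name in ("female_fraction", "effect_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for scheme, freqs, vocab in (
            ("island_freqs", self.island_freqs, ISLAND_CONTEXTS),
            ("gene_freqs", self.gene_freqs, GENE_CONTEXTS),
        ):
            _check_freqs(scheme, freqs, vocab)
        if self.n_cell_types < 2:
            raise ConfigError("n_cell_types must be >= 2")
        if self.chip_size < 2:
            raise ConfigError("chip_size must be >= 2")
        if self.chip_size > self.n_samples:
            raise ConfigError(
                f"chip_size ({self.chip_size}) exceeds n_samples ({self.n_samples})"
            )
        if self.effect_stratum not in ("female", "male", "both"):
            raise ConfigError(f"unknown effect_stratum {self.effect_stratum!r}")
        if self.context_bias <= 0:
            raise ConfigError("context_bias must be positive")
        if not 0 < self.clip < 0.5:
            raise ConfigError("clip must lie in (0, 0.5)")

    def effect_slope_magnitude(self) -> float | None:
        """Fixed |slope| (M-units per EPDS point) implied by ``effect_r2``.

        The planted effect is sized so that slope^2 * Var(EPDS) equals
        r2/(1-r2) times the total stochastic M-scale variance the generator
        adds (chip shifts plus probe noise).  Returns None when slopes are
        drawn from Normal(0, effect_slope_sd) instead.
        """
        if self.effect_r2 is None:
            return None
        if not 0 < self.effect_r2 < 1:
            raise ConfigError("effect_r2 must lie in (0, 1)")
        total_var = self.noise_sd**2 + self.batch_shift_sd**2
        return float(
            np.sqrt(self.effect_r2 / (1 - self.effect_r2) * total_var)
            / self.epds_sd
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["island_freqs"] = dict(self.island_freqs)
        d["gene_freqs"] = dict(self.gene_freqs)
        return d


def _check_freqs(scheme: str, freqs: Mapping[str, float], vocab: Sequence[str]) -> None:
    unknown = set(freqs) - set(vocab)
    if unknown:
        raise ConfigError(f"{scheme}: unknown categories {sorted(unknown)}")
    vals = np.array([freqs.get(c, 0.0) for c in vocab], dtype=float)
    if (vals < 0).any():
        raise ConfigError(f"{scheme}: negative frequency")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{scheme}: frequencies sum to {vals.sum():.12f}, not 1")


@dataclass
class GroundTruth:
    """Planted-effect registry and latent variables of one cohort."""

    effect_probes: pd.DataFrame  # probe_id, stratum, slope (M per EPDS point)
    true_compositions: pd.DataFrame  # samples x cell types, rows sum to 1
    batch_assignments: pd.DataFrame  # sample_id, chip, chip_position
    category_of_probe: pd.DataFrame  # probe_id, island_context, gene_context


@dataclass
class CohortBundle:
    beta: pd.DataFrame  # probes x samples, strictly in (0, 1)
    samples: pd.DataFrame  # sample sheet
    annotation: pd.DataFrame  # probe annotation
    reference: pd.DataFrame  # reference panel: probes x cell types
    truth: GroundTruth
    config: CohortConfig


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One child generator per named stage, all derived from the one seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def generate_probe_annotation(
    n_probes: int,
    island_freqs: Mapping[str, float] | None = None,
    gene_freqs: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Synthetic manifest-style probe annotation.

    Each probe gets one CpG-density context (island/shore/shelf/open_sea),
    one gene context, 0-based coordinates strictly increasing within each
    chromosome, and a semicolon-joined gene-symbol list (empty for
    intergenic probes).  QC mask flags default to False.
    """
    island_freqs = dict(DEFAULT_ISLAND_FREQS if island_freqs is None else island_freqs)
    gene_freqs = dict(DEFAULT_GENE_FREQS if gene_freqs is None else gene_freqs)
    _check_freqs("island_freqs", island_freqs, ISLAND_CONTEXTS)
    _check_freqs("gene_freqs", gene_freqs, GENE_CONTEXTS)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    chroms = np.sort(rng.integers(1, 23, size=n_probes))
    chromosome = np.array([f"chr{c}" for c in chroms])
    # strictly increasing positions per chromosome via positive gaps
    gaps = rng.integers(2, 20_000, size=n_probes)
    position = np.empty(n_probes, dtype=np.int64)
    for c in np.unique(chroms):
        mask = chroms == c
        position[mask] = np.cumsum(gaps[mask])

    island_context = rng.choice(
        ISLAND_CONTEXTS, size=n_probes, p=[island_freqs.get(c, 0.0) for c in ISLAND_CONTEXTS]
    )
    gene_context = rng.choice(
        GENE_CONTEXTS, size=n_probes, p=[gene_freqs.get(c, 0.0) for c in GENE_CONTEXTS]
    )

    pool_size = max(4, n_probes // 5)
    pool = np.array([f"GENE{i}" for i in range(pool_size)])
    n_symbols = rng.integers(1, 3, size=n_probes)
    sym_idx = rng.integers(0, pool_size, size=(n_probes, 2))
    gene_symbols = [
        ";".join(dict.fromkeys(pool[sym_idx[i, : n_symbols[i]]]))
        if gene_context[i] != "intergenic"
        else ""
        for i in range(n_probes)
    ]

    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chromosome,
            "position": position,
            "island_context": island_context,
            "gene_context": gene_context,
            "gene_symbols": gene_symbols,
            "snp_flag": np.zeros(n_probes, dtype=bool),
            "cross_hybridizing_flag": np.zeros(n_probes, dtype=bool),
        }
    )


def _baseline_betas(
    rng: np.random.Generator, n_probes: int, n_cell_types: int
) -> np.ndarray:
    """Per-probe, per-cell-type baseline betas with array-like bimodality.

    Each probe draws a Beta(a, b) shape from a low/high/intermediate
    mixture; each cell type then draws its own baseline from that shape, so
    cell types differ per probe (the signal deconvolution relies on).
    """
    state = rng.choice(3, size=n_probes, p=[0.45, 0.45, 0.10])
    a = np.where(state == 0, 2.0, np.where(state == 1, 10.0, 5.0))
    b = np.where(state == 0, 10.0, np.where(state == 1, 2.0, 5.0))
    base = rng.beta(a[:, None], b[:, None], size=(n_probes, n_cell_types))
    return np.clip(base, 1e-4, 1 - 1e-4)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw one full cohort with its ground-truth registry.

    The mixing model: mixed beta = composition-weighted cell-type baseline;
    chip shifts and probe noise are added on the M-scale, the planted EPDS
    effect (effect_stratum samples only) is added on the M-scale, and the
    result is mapped back to beta and clipped to (clip, 1-clip).
    """
    config.validate()
    rngs = _stage_rngs(config.seed)
    n, g, k = config.n_samples, config.n_probes, config.n_cell_types

    annotation = generate_probe_annotation(
        g, config.island_freqs, config.gene_freqs, rngs["annotation"]
    )
    probe_ids = annotation["probe_id"].to_numpy()
    sample_ids = np.array([f"S{i:04d}" for i in range(n)])

    baselines = _baseline_betas(rngs["baselines"], g, k)
    cell_types = [f"cell_{chr(ord('A') + i)}" for i in range(k)]

    # Dirichlet compositions around an uneven base profile
    base_props = 1.0 / np.arange(1, k + 1)
    base_props /= base_props.sum()
    comp = rngs["composition"].dirichlet(
        base_props * config.dirichlet_concentration, size=n
    )

    mixed = baselines @ comp.T  # g x n
    m = beta_to_m(mixed, epsilon=config.clip)

    # chip-level per-probe shifts + iid probe noise, both on the M-scale
    n_chips = int(np.ceil(n / config.chip_size))
    chip_idx = np.arange(n) // config.chip_size
    chip_labels = np.array([f"chip{c:03d}" for c in chip_idx])
    position_labels = np.array(
        [f"R{(i % config.chip_size) + 1:02d}" for i in range(n)]
    )
    chip_shifts = rngs["batch"].normal(0.0, config.batch_shift_sd, size=(g, n_chips))
    m += chip_shifts[:, chip_idx]
    m += rngs["noise"].normal(0.0, config.noise_sd, size=(g, n))

    # sample sheet
    rs = rngs["samplesheet"]
    epds = np.clip(np.rint(rs.normal(config.epds_mean, config.epds_sd, size=n)), 0, 30)
    fetal_sex = np.where(rs.random(n) < config.female_fraction, "female", "male")
    extraction = rs.choice(["method_A", "method_B"], size=n)
    bisulfite = np.round(np.clip(rs.normal(50.0, 10.0, size=n), 5.0, None), 2)
    group = rs.choice(np.asarray(config.groups, dtype=object), size=n)

    # planted effects
    re = rngs["effects"]
    n_effect = int(round(config.effect_fraction * g))
    if n_effect > 0:
        weights = np.ones(g)
        biased = annotation["island_context"].isin(
            config.biased_island_contexts
        ).to_numpy() | annotation["gene_context"].isin(
            config.biased_gene_contexts
        ).to_numpy()
        weights[biased] = config.context_bias
        effect_idx = re.choice(g, size=n_effect, replace=False, p=weights / weights.sum())
        effect_idx = np.sort(effect_idx)
        mag = config.effect_slope_magnitude()
        if mag is None:
            slopes = re.normal(0.0, config.effect_slope_sd, size=n_effect)
        else:
            slopes = mag * re.choice([-1.0, 1.0], size=n_effect)
        if config.effect_stratum == "both":
            in_stratum = np.ones(n, dtype=bool)
        else:
            in_stratum = fetal_sex == config.effect_stratum
        centered = (epds - config.epds_mean) * in_stratum
        m[effect_idx] += slopes[:, None] * centered[None, :]
        effect_probes = pd.DataFrame(
            {
                "probe_id": probe_ids[effect_idx],
                "stratum": config.effect_stratum,
                "slope": slopes,
            }
        )
    else:
        effect_probes = pd.DataFrame(columns=["probe_id", "stratum", "slope"])

    beta = m_to_beta(m)
    np.clip(beta, config.clip, 1 - config.clip, out=beta)
    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"),
                           columns=sample_ids)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "epds": epds.astype(int),
            "fetal_sex": fetal_sex,
            "chip": chip_labels,
            "chip_position": position_labels,
            "extraction_method": extraction,
            "bisulfite_concentration": bisulfite,
            "group": group,
        }
    )

    # reference panel: the true baselines at the probes where cell types
    # separate most (highest between-cell-type variance)
    n_ref = min(config.n_reference_probes, g)
    spread = baselines.var(axis=1)
    ref_idx = np.sort(np.argsort(spread)[::-1][:n_ref])
    reference = pd.DataFrame(
        baselines[ref_idx],
        index=pd.Index(probe_ids[ref_idx], name="probe_id"),
        columns=cell_types,
    )

    truth = GroundTruth(
        effect_probes=effect_probes,
        true_compositions=pd.DataFrame(
            comp, index=pd.Index(sample_ids, name="sample_id"), columns=cell_types
        ),
        batch_assignments=samples[["sample_id", "chip", "chip_position"]].copy(),
        category_of_probe=annotation[
            ["probe_id", "island_context", "gene_context"]
        ].copy(),
    )
    return CohortBundle(
        beta=beta_df,
        samples=samples,
        annotation=annotation,
        reference=reference,
        truth=truth,
        config=replace(config),
    )
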