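"""End-to-end orchestration of the stratified methylome-association analysis.

The chain reproduces the study design: probe QC -> M-value transform ->
empirical-Bayes chip adjustment -> back to beta -> variable-CpG filter ->
cell-composition estimation and its principal components -> per-stratum
mass univariate regression of beta on EPDS -> one-sided KS uniformity test
of the per-CpG p-values -> nominal-threshold selection of EPDS-associated
variable CpGs -> genomic-context enrichment, with every stage count logged
in a machine-readable run manifest.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from . import reports
from .association import (
    CovariateSpec,
    KSResult,
    fit_cpg_regressions,
    ks_uniformity_test,
    select_epds_vcpgs,
    summarize_counts,
)
from .enrichment import (
    GeneSetCollection,
    SCHEMES,
    feature_enrichment,
    geneset_hypergeometric,
    map_probes_to_genes,
)
from .errors import ConfigError, StratEwasError
from .preprocess import (
    ProbeQC,
    apply_probe_qc,
    beta_to_m,
    combat_adjust,
    composition_pcs,
    estimate_cell_composition,
    m_to_beta,
    select_variable_probes,
)

__version__ = "0.1.0"


@dataclass
class AnalysisOptions:
    """Tunable knobs of the stratified analysis (defaults follow the study)."""

    epsilon: float = 1e-6
    min_range: float = 0.05
    fence_multiplier: float = 1.5
    range_inclusive: bool = True
    qc_policy: str = "probe"
    run_combat: bool = True
    combat_protect_epds: bool = False
    n_ecc_pcs: int = 5
    categorical_covariates: tuple[str, ...] = ("chip_position", "chip", "extraction_method")
    numeric_covariates: tuple[str, ...] = ("bisulfite_concentration",)
    alpha: float = 0.005
    alpha_sensitivity: float = 0.001
    enrichment_alpha: float = 0.05
    strata: tuple[str, ...] = ("female", "male")
    ks_mode: str = "asymptotic"

    def validate(self) -> None:
        for name in ("alpha", "alpha_sensitivity", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")

    def covariate_spec(self, n_cell_types: int) -> CovariateSpec:
        return CovariateSpec(
            n_ecc_pcs=min(self.n_ecc_pcs, max(n_cell_types - 1, 0)),
            categorical=tuple(self.categorical_covariates),
            numeric=tuple(self.numeric_covariates),
        )


@dataclass
class StratumResult:
    association: pd.DataFrame
    ks: KSResult
    selected: list[str]
    selected_sensitivity: list[str]
    enrichment: dict[str, pd.DataFrame]


@dataclass
class PipelineResult:
    vcpg_ids: list[str]
    strata: dict[str, StratumResult]
    vcpg_enrichment: dict[str, pd.DataFrame]
    composition: pd.DataFrame
    ecc_pcs: pd.DataFrame
    summary: dict
    removal_log: dict | None
    counts: dict


def run_stratified_analysis(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    reference: pd.DataFrame,
    qc: ProbeQC | None = None,
    options: AnalysisOptions | None = None,
) -> PipelineResult:
    """Run the full in-memory analysis and return all stage outputs."""
    opt = options or AnalysisOptions()
    opt.validate()
    counts: dict = {"input_probes": int(beta.shape[0]), "input_samples": int(beta.shape[1])}

    removal_log = None
    if qc is not None:
        try:
            beta, removal_log = apply_probe_qc(beta, qc, annotation, policy=opt.qc_policy)
        except StratEwasError as exc:
            raise StratEwasError(f"[probe_qc] {exc}") from exc
        counts["post_qc_probes"] = int(beta.shape[0])

    sheet = samples.set_index("sample_id")
    if opt.run_combat and sheet["chip"].nunique() > 1:
        m = beta_to_m(beta, epsilon=opt.epsilon)
        design = None
        if opt.combat_protect_epds:
            epds = sheet.loc[beta.columns, "epds"].astype(float)
            design = epds.fillna(epds.mean()).to_numpy()[:, None]
        try:
            m = combat_adjust(m, sheet.loc[beta.columns, "chip"], design=design)
        except StratEwasError as exc:
            raise StratEwasError(f"[combat] {exc}") from exc
        beta = m_to_beta(m)
        beta = beta.clip(lower=opt.epsilon, upper=1 - opt.epsilon)

    vcpg_ids = select_variable_probes(
        beta, min_range=opt.min_range, fence_multiplier=opt.fence_multiplier,
        inclusive=opt.range_inclusive,
    )
    counts["vcpgs"] = len(vcpg_ids)
    vbeta = beta.loc[vcpg_ids]

    composition = estimate_cell_composition(beta, reference)
    cov_spec = opt.covariate_spec(reference.shape[1])
    pcs = composition_pcs(composition, k=cov_spec.n_ecc_pcs)

    # whole-array context profile of the variable CpGs
    vcpg_enrichment = {
        scheme: feature_enrichment(
            vcpg_ids, list(beta.index), annotation, scheme, alpha=opt.enrichment_alpha
        )
        for scheme in SCHEMES
    }

    strata: dict[str, StratumResult] = {}
    for stratum in opt.strata:
        try:
            table = fit_cpg_regressions(
                vbeta, samples, cov_spec, stratum=stratum, ecc_pcs=pcs.scores
            )
        except StratEwasError as exc:
            raise StratEwasError(f"[association:{stratum}] {exc}") from exc
        ok_p = table.loc[table["status"] == "ok", "p"]
        ks = ks_uniformity_test(ok_p, mode=opt.ks_mode)
        selected = select_epds_vcpgs(table, alpha=opt.alpha)
        selected_sens = select_epds_vcpgs(table, alpha=opt.alpha_sensitivity)
        enr = {
            scheme: feature_enrichment(
                selected, vcpg_ids, annotation, scheme, alpha=opt.enrichment_alpha
            )
            if selected
            else pd.DataFrame()
            for scheme in SCHEMES
        }
        strata[stratum] = StratumResult(
            association=table, ks=ks, selected=selected,
            selected_sensitivity=selected_sens, enrichment=enr,
        )
        counts[f"selected_{stratum}"] = len(selected)
        counts[f"selected_sensitivity_{stratum}"] = len(selected_sens)

    summary: dict = {"ks": {s: strata[s].ks.to_dict() for s in strata}}
    if "female" in strata and "male" in strata:
        summary["female_vs_male"] = summarize_counts(
            strata["female"].selected, vcpg_ids, strata["male"].selected
        ).to_dict()
        summary["male_vs_female"] = summarize_counts(
            strata["male"].selected, vcpg_ids, strata["female"].selected
        ).to_dict()

    return PipelineResult(
        vcpg_ids=vcpg_ids,
        strata=strata,
        vcpg_enrichment=vcpg_enrichment,
        composition=composition.proportions,
        ecc_pcs=pcs.scores,
        summary=summary,
        removal_log=removal_log,
        counts=counts,
    )


@dataclass
class PipelineConfig:
    """File-level configuration of one pipeline run."""

    beta_path: str
    annotation_path: str
    sample_sheet_path: str
    reference_path: str
    output_dir: str
    qc_detection_path: str | None = None
    qc_beads_path: str | None = None
    gmt_path: str | None = None
    seed: int = 0
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = sio.read_yaml_config(path)
        opt = AnalysisOptions(**raw.pop("options", {}))
        try:
            return cls(options=opt, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured run, write all result files, return the manifest."""
    started = datetime.datetime.now().isoformat(timespec="seconds")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    beta = sio.read_beta_tsv(config.beta_path)
    annotation = sio.read_annotation_csv(config.annotation_path)
    samples = sio.read_sample_sheet_csv(config.sample_sheet_path)
    reference = sio.read_reference_csv(config.reference_path)
    qc = None
    if config.qc_detection_path and config.qc_beads_path:
        qc = ProbeQC(
            detection_p=sio.read_beta_tsv(config.qc_detection_path),
            bead_count=sio.read_beta_tsv(config.qc_beads_path),
        )

    result = run_stratified_analysis(
        beta, annotation, samples, reference, qc=qc, options=config.options
    )

    sio.write_probe_set(result.vcpg_ids, out / "vcpgs.txt")
    sio.write_bed(result.vcpg_ids, annotation, out / "vcpgs.bed")
    for scheme, tab in result.vcpg_enrichment.items():
        tab.to_csv(out / f"vcpg_enrichment_{scheme}.tsv", sep="\t", index=False,
                   float_format=sio.FLOAT_FORMAT)
    for stratum, res in result.strata.items():
        res.association.rename_axis("probe_id").to_csv(
            out / f"association_{stratum}.tsv", sep="\t", float_format=sio.FLOAT_FORMAT
        )
        sio.write_json(res.ks.to_dict(), out / f"ks_{stratum}.json")
        sio.write_probe_set(res.selected, out / f"epds_vcpgs_{stratum}.txt")
        sio.write_probe_set(
            res.selected_sensitivity, out / f"epds_vcpgs_{stratum}_sensitivity.txt"
        )
        if res.selected:
            sio.write_bed(res.selected, annotation, out / f"epds_vcpgs_{stratum}.bed")
        for scheme, tab in res.enrichment.items():
            if len(tab):
                tab.to_csv(out / f"enrichment_{stratum}_{scheme}.tsv", sep="\t",
                           index=False, float_format=sio.FLOAT_FORMAT)
        ok_p = res.association.loc[res.association["status"] == "ok", "p"]
        reports.plot_pvalue_histogram(
            ok_p, out / f"pvalue_hist_{stratum}.png",
            title=f"{stratum} stratum (n={len(ok_p)} vCpGs)",
        )
    if {"female", "male"} <= set(result.strata):
        tables = {
            s: result.strata[s].enrichment["island_context"]
            for s in ("female", "male")
            if len(result.strata[s].enrichment["island_context"])
        }
        if tables:
            reports.plot_context_enrichment(
                tables, out / "enrichment_island_context.png",
                title="EPDS-vCpGs vs vCpG reference",
            )
    if result.removal_log is not None:
        sio.write_json(result.removal_log, out / "removal_log.json")
    sio.write_json(result.summary, out / "summary.json")

    if config.gmt_path:
        gmt_sets, _ = sio.read_gmt(config.gmt_path)
        universe = map_probes_to_genes(result.vcpg_ids, annotation)
        collection = GeneSetCollection.from_sets(gmt_sets, universe)
        for stratum, res in result.strata.items():
            if not res.selected:
                continue
            genes = map_probes_to_genes(res.selected, annotation)
            tab = geneset_hypergeometric(genes, collection)
            tab.to_csv(out / f"genesets_{stratum}.tsv", sep="\t", index=False,
                       float_format=sio.FLOAT_FORMAT)

    manifest = {
        "software": {"name": "stratewas", "version": __version__},
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "options"},
            "options": asdict(config.options),
        },
        "seed": config.seed,
        "counts": result.counts,
        "started": started,
        "finished": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    sio.write_json(manifest, out / "manifest.json")
    return manifest
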