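import numpy as np
import pandas as pd
import pytest

from stratewas import CohortConfig, generate_cohort
from stratewas.preprocess import (
    beta_to_m,
    combat_adjust,
    composition_pcs,
    estimate_cell_composition,
    m_to_beta,
    select_variable_probes,
)


@pytest.fixture(scope="session")
def ref_bundle():
    """Reference-scale cohort: 20k probes, 200 samples, female-only effects."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def ref_prepared(ref_bundle):
    """Chip-adjusted beta, variable-CpG ids and Ecc PCs for the reference cohort."""
    b = ref_bundle
    sheet = b.samples.set_index("sample_id")
    m = beta_to_m(b.beta)
    adj = combat_adjust(m, sheet.loc[m.columns, "chip"])
    beta_adj = m_to_beta(adj).clip(lower=1e-6, upper=1 - 1e-6)
    vcpgs = select_variable_probes(beta_adj)
    comp = estimate_cell_composition(beta_adj, b.reference)
    pcs = composition_pcs(comp, k=5)
    return {"beta": beta_adj, "vcpgs": vcpgs, "pcs": pcs.scores, "bundle": b}


@pytest.fixture()
def tiny_annotation():
    """Hand-built five-probe annotation covering both context schemes."""
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(5)],
            "chromosome": ["chr1", "chr1", "chr2", "chr2", "chr3"],
            "position": [100, 300, 50, 400, 7],
            "island_context": ["island", "shore", "open_sea", "open_sea", "shelf"],
            "gene_context": ["promoter", "exon", "intergenic", "intron", "intron"],
            "gene_symbols": ["a", "A;B", "", "C", "B"],
            "snp_flag": [False] * 5,
            "cross_hybridizing_flag": [False] * 5,
        }
    )
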