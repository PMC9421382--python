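"""Genomic-context enrichment of probe sets and gene-set over-representation.

Context enrichment compares a query probe set against a swappable reference
set (e.g. variable CpGs against the whole array, or EPDS-associated CpGs
against all variable CpGs) one annotation category at a time, with a
two-sided Fisher exact test and an enriched/depleted call from the odds
ratio.  Gene-set analysis maps probes to unique gene symbols and tests
overlap with user-supplied collections by the hypergeometric upper tail,
with Benjamini-Hochberg adjustment across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataIntegrityError

SCHEMES = {
    "island_context": ("island", "shore", "shelf", "open_sea"),
    "gene_context": (
        "promoter",
        "five_prime_utr",
        "exon",
        "intron",
        "three_prime_utr",
        "intergenic",
    ),
}

# relative tolerance for the probability-mass rule: tables whose probability
# does not exceed the observed one by more than this factor are summed
_TIE_TOL = 1.0 + 1e-7


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Probability-mass rule: the sum of hypergeometric probabilities of all
    tables with the observed margins whose probability is <= the observed
    table's (within a 1 + 1e-7 tie tolerance).
    """
    if min(a, b, c, d) < 0:
        raise ConfigError("table cells must be nonnegative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - kmin]
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_TOL].sum()))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def feature_enrichment(
    query,
    reference,
    annotation: pd.DataFrame,
    scheme: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category enrichment/depletion of ``query`` probes vs ``reference``.

    For each category of the scheme a 2x2 table (query in/out vs reference
    in/out) is tested two-sided; direction comes from the sample odds ratio
    (>1 enriched, <1 depleted).  Categories absent from both sets are
    omitted.  The query need not be a subset of the reference.
    """
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}")
    query = list(dict.fromkeys(query))
    reference = list(dict.fromkeys(reference))
    if not query or not reference:
        raise DataIntegrityError("query and reference probe sets must be nonempty")
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    for name, ids in (("query", query), ("reference", reference)):
        missing = pd.Index(ids).difference(ann.index)
        if len(missing):
            raise DataIntegrityError(f"{len(missing)} {name} probes lack annotation")
    q_cat = ann.loc[query, scheme]
    r_cat = ann.loc[reference, scheme]
    nq, nr = len(query), len(reference)
    rows = []
    for feature in SCHEMES[scheme]:
        a = int((q_cat == feature).sum())
        c = int((r_cat == feature).sum())
        if a == 0 and c == 0:
            continue
        b, d = nq - a, nr - c
        p = fisher_exact_two_sided(a, b, c, d)
        orat = _odds_ratio(a, b, c, d)
        if np.isnan(orat) or orat == 1.0:
            direction = "none"
        else:
            direction = "enriched" if orat > 1.0 else "depleted"
        rows.append(
            {
                "feature": feature,
                "query_in": a,
                "query_total": nq,
                "ref_in": c,
                "ref_total": nr,
                "odds_ratio": orat,
                "p": p,
                "direction": direction,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def map_probes_to_genes(probes, annotation: pd.DataFrame) -> list[str]:
    """Unique, case-normalized gene symbols mapped from a probe set.

    Intergenic probes (empty symbol list) contribute nothing.  Returns the
    sorted unique symbols.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    probes = list(dict.fromkeys(probes))
    missing = pd.Index(probes).difference(ann.index)
    if len(missing):
        raise DataIntegrityError(f"{len(missing)} probes lack annotation")
    symbols: set[str] = set()
    for entry in ann.loc[probes, "gene_symbols"]:
        if isinstance(entry, str):
            parts = entry.split(";")
        elif entry is None or (isinstance(entry, float) and np.isnan(entry)):
            parts = []
        else:
            parts = list(entry)
        for s in parts:
            s = s.strip().upper()
            if s:
                symbols.add(s)
    return sorted(symbols)


def harmonize_symbol(symbol: str) -> str:
    """Gene-symbol harmonization: uppercase, strip whitespace."""
    return symbol.strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets over a common symbol universe."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()

    @classmethod
    def from_sets(cls, sets: dict, universe) -> "GeneSetCollection":
        uni = frozenset(harmonize_symbol(g) for g in universe)
        harmonized = {}
        for name, genes in sets.items():
            if name in harmonized:
                raise DataIntegrityError(f"duplicate gene-set name {name!r}")
            harmonized[name] = frozenset(harmonize_symbol(g) for g in genes) & uni
        return cls(sets=harmonized, universe=uni)


def geneset_hypergeometric(
    query_genes, collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    p = P(X >= overlap) under Hypergeom(|universe|, |set|, |query|); the
    BH-adjusted value is reported per set.  Query genes outside the
    universe are dropped (their count is stored in ``attrs["n_dropped"]``).
    Rows are sorted by p ascending, ties broken by set name.
    """
    if not collection.universe:
        raise DataIntegrityError("empty gene universe")
    query = {harmonize_symbol(g) for g in query_genes}
    dropped = query - collection.universe
    query &= collection.universe
    N, n = len(collection.universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        K = len(genes)
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p": min(1.0, p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_dropped"] = len(dropped)
    return out
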