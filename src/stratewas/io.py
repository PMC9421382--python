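"""Readers and writers for the pipeline's plain-text formats.

Beta matrices travel as TSV (first column ``probe_id``, remaining columns
sample ids); annotation, sample sheets and reference panels as CSV; gene
sets as GMT; probe sets as one-id-per-line text or BED4 (0-based half-open,
a CpG site spanning 2 bases); results as JSON; configuration as YAML.
Numeric output uses 10 significant digits so write-then-read round-trips
below test tolerances.  All paths accept an optional ``.gz`` suffix
(pandas handles compression transparently).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError

FLOAT_FORMAT = "%.10g"

ANNOTATION_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "island_context",
    "gene_context",
    "gene_symbols",
    "snp_flag",
    "cross_hybridizing_flag",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "epds",
    "fetal_sex",
    "chip",
    "chip_position",
    "extraction_method",
    "bisulfite_concentration",
    "group",
]


def _check_unique(values, what: str, path) -> None:
    dup = pd.Index(values).duplicated()
    if dup.any():
        first = pd.Index(values)[dup][0]
        raise ParseError(f"duplicate {what} {first!r}", path=path)


def read_beta_tsv(path) -> pd.DataFrame:
    # pandas mangles duplicate column names, so vet the raw header first
    with pd.io.common.get_handle(path, "r") as handle:
        first_line = handle.handle.readline().rstrip("\n")
    _check_unique(first_line.split("\t")[1:], "sample id", path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "probe_id":
        raise ParseError(
            f"first column must be 'probe_id', got {df.columns[0]!r}", path=path, line=1
        )
    _check_unique(df["probe_id"], "probe id", path)
    _check_unique(df.columns[1:], "sample id", path)
    df = df.set_index("probe_id")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric beta value: {exc}", path=path) from None
    return values


def write_beta_tsv(beta: pd.DataFrame, path) -> None:
    out = beta.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_annotation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene_symbols": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"annotation lacks columns {missing}", path=path, line=1)
    _check_unique(df["probe_id"], "probe id", path)
    df["gene_symbols"] = df["gene_symbols"].fillna("")
    df["snp_flag"] = df["snp_flag"].astype(bool)
    df["cross_hybridizing_flag"] = df["cross_hybridizing_flag"].astype(bool)
    return df[ANNOTATION_COLUMNS]


def write_annotation_csv(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, index=False)


def read_sample_sheet_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"sample sheet lacks columns {missing}", path=path, line=1)
    _check_unique(df["sample_id"], "sample id", path)
    bad = df["epds"].dropna()
    if ((bad < 0) | (bad > 30)).any():
        raise ParseError("EPDS scores must lie in [0, 30]", path=path)
    return df[SAMPLE_COLUMNS]


def write_sample_sheet_csv(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, index=False)


def read_reference_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "probe_id":
        raise ParseError("first column must be 'probe_id'", path=path, line=1)
    _check_unique(df["probe_id"], "probe id", path)
    df = df.set_index("probe_id").astype(float)
    if df.shape[1] < 2:
        raise ParseError("reference panel needs >= 2 cell types", path=path)
    return df


def write_reference_csv(reference: pd.DataFrame, path) -> None:
    out = reference.copy()
    out.index.name = "probe_id"
    out.to_csv(path, float_format=FLOAT_FORMAT)


def read_gmt(path) -> tuple[dict[str, set], dict[str, str]]:
    """GMT gene sets: returns ({name: genes}, {name: description})."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and >= 1 gene",
                    path=path, line=lineno,
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", path=path, line=lineno)
            sets[name] = {g for g in fields[2:] if g.strip()}
            descriptions[name] = fields[1]
    return sets, descriptions


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_probe_set(path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    _check_unique(ids, "probe id", path)
    return ids


def write_probe_set(probes, path) -> None:
    with open(path, "w") as fh:
        for pid in probes:
            fh.write(f"{pid}\n")


def write_bed(probes, annotation: pd.DataFrame, path) -> None:
    """BED4 export: 0-based half-open, one CpG dinucleotide per probe."""
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    sub = ann.loc[list(probes)]
    with open(path, "w") as fh:
        for pid, row in sub.iterrows():
            start = int(row["position"])
            fh.write(f"{row['chromosome']}\t{start}\t{start + 2}\t{pid}\n")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError("YAML config must be a mapping", path=path)
    return cfg


def write_yaml_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
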