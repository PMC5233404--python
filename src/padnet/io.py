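"""Readers and writers for the standard text formats the pipeline speaks.

Formats: GMT gene sets, CLS phenotype labels, GCT v1.2 and plain TSV
expression matrices, two-column probe-to-gene maps, pathway x drug
enrichment-score matrices, validation-network edge lists, enrichment /
union / score tables, and flat key=value configuration files.  All
numeric round-trips preserve full precision (``repr`` formatting).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .enrichment import (
    CASE,
    CONTROL,
    DiseasePathwaySet,
    EnrichmentResult,
    ExpressionDataset,
    GeneSetCollection,
    collapse_probes,
)
from .network import PathwayDrugMatrix
from .validation import EDGE_COLUMNS, EDGE_TYPES

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} lists no genes")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(collection.sets[name])]) + "\n")


# ---------------------------------------------------------------------------
# CLS phenotype labels
# ---------------------------------------------------------------------------


def read_cls(path: str | Path) -> list[str]:
    """Class name per sample, in file order (categorical CLS dialect)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs 3 non-empty lines")
    head = lines[0].split()
    if len(head) != 3:
        raise FormatError(f"{path}:1: CLS header must be '<n_samples> <n_classes> 1'")
    n_samples, n_classes = int(head[0]), int(head[1])
    names_line = lines[1].split()
    if not names_line or names_line[0] != "#":
        raise FormatError(f"{path}:2: CLS class-name line must start with '#'")
    class_names = names_line[1:]
    if len(class_names) != n_classes:
        raise FormatError(f"{path}:2: declared {n_classes} classes but listed {len(class_names)}")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(f"{path}:3: declared {n_samples} samples but listed {len(tokens)} labels")
    labels = []
    for tok in tokens:
        if tok in class_names:
            labels.append(tok)
        elif tok.isdigit() and int(tok) < len(class_names):
            labels.append(class_names[int(tok)])
        else:
            raise FormatError(f"{path}:3: unknown sample label {tok!r}")
    return labels


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    classes = list(dict.fromkeys(labels))  # order of first appearance
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(str(classes.index(l)) for l in labels) + "\n")


# ---------------------------------------------------------------------------
# expression matrices (TSV and GCT v1.2)
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes/probes x samples matrix from TSV or GCT (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}:1: expected GCT version '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}:2: GCT dimension line must hold 2 integers")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
        df = df.drop(columns=df.columns[0])  # Description column
        if df.shape != (n_rows, n_cols):
            raise FormatError(f"{path}: declared {n_rows}x{n_cols} but found {df.shape[0]}x{df.shape[1]}")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.astype(float)


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def write_gct(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="Name")


def load_expression_dataset(
    expr_path: str | Path,
    cls_path: str | Path,
    *,
    case_class: str | None = None,
    probe_map: Mapping[str, str] | pd.Series | None = None,
    missing: str = "reject",
    name: str | None = None,
) -> ExpressionDataset:
    """Expression matrix + CLS labels -> a typed case/control dataset.

    CLS classes named ``case``/``control`` map directly; otherwise
    ``case_class`` must name the case class.  When ``probe_map`` is given
    the matrix is treated as probe-level and collapsed to gene symbols.
    """
    df = read_expression(expr_path)
    raw_labels = read_cls(cls_path)
    if len(raw_labels) != df.shape[1]:
        raise FormatError(
            f"{cls_path}: {len(raw_labels)} labels for {df.shape[1]} samples in {expr_path}"
        )
    classes = set(raw_labels)
    if classes == {CASE, CONTROL}:
        labels = raw_labels
    else:
        if case_class is None or case_class not in classes:
            raise ValueError(
                f"CLS classes {sorted(classes)} are not 'case'/'control'; pass case_class"
            )
        labels = [CASE if l == case_class else CONTROL for l in raw_labels]
    name = name or Path(expr_path).stem
    if probe_map is not None:
        return collapse_probes(df, probe_map, labels, missing=missing, name=name)
    if df.isna().any().any():
        if missing == "reject":
            df = df.dropna(axis=0)
        elif missing == "impute":
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            raise ValueError("missing policy must be 'reject' or 'impute'")
    return ExpressionDataset(list(df.index.astype(str)), df.to_numpy(), labels, name=name)


def read_probe_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: probe map needs two tab-separated columns")
    return pd.Series(df[1].values, index=df[0].values)


# ---------------------------------------------------------------------------
# enrichment-score matrix and edge lists
# ---------------------------------------------------------------------------


def read_es_matrix(path: str | Path) -> PathwayDrugMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return PathwayDrugMatrix.from_frame(df)


def write_es_matrix(m: PathwayDrugMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="pathway", float_format="%.17g")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: edge list missing columns {sorted(missing)}")
    bad = set(df["edge_type"]) - set(EDGE_TYPES)
    if bad:
        raise FormatError(f"{path}: unknown edge types {sorted(bad)}")
    df["weight"] = df["weight"].astype(float)
    return df[EDGE_COLUMNS]


def write_edge_list(df: pd.DataFrame, path: str | Path) -> None:
    df[EDGE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_enrichment_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    from .enrichment import results_to_frame

    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_enrichment_results(path: str | Path) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        EnrichmentResult(
            pathway_name=str(r.pathway),
            es=float(r.es),
            nes=float(r.nes),
            nominal_p=float(r.nominal_p),
            n_genes_matched=int(r.n_matched),
        )
        for r in df.itertuples()
    ]


def write_union(dps: DiseasePathwaySet, path: str | Path) -> None:
    rows = [(p, ",".join(dps.provenance[p])) for p in sorted(dps.pathway_names)]
    pd.DataFrame(rows, columns=["pathway", "datasets"]).to_csv(path, sep="\t", index=False)


def read_union(path: str | Path) -> DiseasePathwaySet:
    df = pd.read_csv(path, sep="\t")
    provenance = {str(r.pathway): str(r.datasets).split(",") for r in df.itertuples()}
    return DiseasePathwaySet(set(provenance), provenance)


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_drug_list(path: str | Path) -> list[str]:
    drugs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                drugs.append(line)
    return drugs


def write_drug_list(drugs: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{d}\n" for d in drugs))


# ---------------------------------------------------------------------------
# flat key=value configuration
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> tuple[RunConfig, dict[str, str]]:
    """Parse a flat key=value file into (RunConfig, full raw mapping)."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            raw[key.strip()] = value.strip()
    return RunConfig.from_mapping(raw), raw


def write_config(cfg: RunConfig, path: str | Path, extra: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.to_mapping().items():
            fh.write(f"{k}={v}\n")
        for k, v in (extra or {}).items():
            fh.write(f"{k}={v}\n")
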