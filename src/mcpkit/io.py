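"""Readers and writers for the pipeline's tabular formats.

Everything is plain text: TSV matrices (first column = row IDs, header =
sample IDs), TSV sample tables, GMT gene sets, JSON truth tables and models.
Readers reject invariant violations (duplicate IDs, out-of-range betas,
ragged or non-numeric rows) with specific diagnostics rather than coercing.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .containers import (
    AnnotationTable,
    BetaMatrix,
    ExpressionMatrix,
    MirnaMatrix,
    validate_sample_table,
)

log = logging.getLogger("mcpkit")

MATRIX_KINDS = ("expression", "beta", "mirna")


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {ncol})"
                )
            index.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})")
    df = pd.DataFrame(rows, index=index, columns=header[1:], dtype=float)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row IDs: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample IDs: {dups[:5]}")
    return df


def read_matrix(path, kind: str = "expression", detection_path=None):
    """Read a matrix TSV as the container matching ``kind``.

    kind='expression' returns :class:`ExpressionMatrix` (optionally with a
    parallel detection p-value TSV), 'beta' returns :class:`BetaMatrix`
    (values checked to lie in [0, 1]), 'mirna' returns :class:`MirnaMatrix`.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; valid: {MATRIX_KINDS}")
    df = _read_table(path)
    if kind == "beta":
        arr = df.to_numpy()
        if (arr < 0).any() or (arr > 1).any():
            bad = df.index[((df < 0) | (df > 1)).any(axis=1)].tolist()
            raise ValueError(
                f"{path}: beta values outside [0, 1] on probes {bad[:5]}"
            )
        return BetaMatrix(df)
    if kind == "mirna":
        return MirnaMatrix(df)
    det = _read_table(detection_path) if detection_path is not None else None
    if det is not None and (det.shape != df.shape):
        raise ValueError("detection p-value matrix shape differs from expression")
    return ExpressionMatrix(df, det)


def write_matrix(matrix, path, detection_path=None) -> None:
    """Write a matrix container to TSV (row IDs in the first column).

    Floats are written with ``repr`` precision so write→read round-trips are
    value-identical.
    """
    if isinstance(matrix, ExpressionMatrix):
        df = matrix.values
        if matrix.detection_pvals is not None and detection_path is not None:
            matrix.detection_pvals.to_csv(detection_path, sep="\t", index_label="id")
    elif isinstance(matrix, BetaMatrix):
        df = matrix.beta
    elif isinstance(matrix, MirnaMatrix):
        df = matrix.values
    else:
        df = matrix
    df.to_csv(path, sep="\t", index_label="id")


def read_gene_sets(path) -> AnnotationTable:
    """Read a GMT file (term, description, members...) into an AnnotationTable.

    Empty member lists are dropped with a logged warning; duplicate members
    within a line collapse to one (set semantics).  The universe is the union
    of all members.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (needs term and "
                    "description)"
                )
            term, members = parts[0], {m for m in parts[2:] if m}
            if not members:
                log.warning("GMT term %r at %s:%d has no members; dropped",
                            term, path, lineno)
                continue
            sets[term] = members
    universe = set().union(*sets.values()) if sets else set()
    return AnnotationTable(sets, universe)


def write_gene_sets(table: AnnotationTable, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for term in sorted(table.sets):
            members = "\t".join(sorted(table.sets[term]))
            fh.write(f"{term}\t{description}\t{members}\n")


def read_sample_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    problems = validate_sample_table(table)
    if problems:
        raise ValueError(f"{path}: invalid sample table: {problems}")
    return table


def write_sample_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def validate_bundle(matrices: dict, sample_table: pd.DataFrame) -> list:
    """Cross-check sample-ID alignment across matrices and the sample table.

    ``matrices`` maps a name to any matrix container.  Returns a list of
    mismatch descriptions; an aligned bundle yields an empty list.  Pipelines
    must refuse to run when the report is non-empty.
    """
    report = list(validate_sample_table(sample_table))
    if any("missing columns" in p for p in report):
        return report
    table_ids = set(sample_table["sample_id"])
    for name, matrix in matrices.items():
        if isinstance(matrix, ExpressionMatrix):
            ids = set(matrix.values.columns)
        elif isinstance(matrix, BetaMatrix):
            ids = set(matrix.beta.columns)
        elif isinstance(matrix, MirnaMatrix):
            ids = set(matrix.values.columns)
        else:
            ids = set(matrix.columns)
        for extra in sorted(ids - table_ids):
            report.append(f"{name}: sample {extra!r} absent from sample table")
    return report


# ---------------------------------------------------------------------------
# bundle and config round trips
# ---------------------------------------------------------------------------

def write_bundle(bundle, out_dir) -> None:
    """Write a synthetic cohort bundle as plain-text files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.expression, out / "expression.tsv",
                 detection_path=out / "detection.tsv")
    write_matrix(bundle.beta, out / "beta.tsv")
    write_matrix(bundle.mirna, out / "mirna.tsv")
    write_sample_table(bundle.samples, out / "samples.tsv")
    write_gene_sets(bundle.annotations, out / "annotations.gmt")
    targets = AnnotationTable(
        {f: set(g) for f, g in bundle.targets.items() if g},
        set().union(*bundle.targets.values()) if any(bundle.targets.values()) else set(),
    )
    write_gene_sets(targets, out / "targets.gmt", description="miRNA-family targets")
    (out / "truth.json").write_text(bundle.truth.to_json())
    maps = {
        "probe_to_gene": dict(bundle.beta.probe_to_gene),
        "mirna_family": dict(bundle.mirna.family_map),
    }
    (out / "maps.json").write_text(json.dumps(maps, indent=1, sort_keys=True))
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(bundle.config).items()}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_config(path) -> dict:
    """Read a YAML config file into a plain dict (flat keys)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "fold_range" in data and isinstance(data["fold_range"], list):
        data["fold_range"] = tuple(data["fold_range"])
    return data


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def read_json(path):
    return json.loads(Path(path).read_text())
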