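"""Readers, writers and preprocessing for the pipeline's file formats.

Formats are plain TSV throughout:

- expression: first column the gene id, remaining columns samples, with
  a header row of sample ids;
- labels: two columns (sample_id, class);
- state matrix: expression layout with entries in {-1, 0, 1} for D/N/U;
- pathways: SIF-style ``source<TAB>relation<TAB>target`` (one pathway
  per ``.sif`` file), a two-column edge list, or a multi-pathway table
  with a leading pathway-name column;
- results: pathway, n_links, DEP, p, q.

Writers prepend ``#`` header comments recording the package version,
seed and a configuration hash; readers skip ``#`` lines, so re-running
with identical inputs and configuration reproduces identical bodies.
The SIF relation column (activation/inhibition/...) is parsed and kept
on the side but does not enter the statistic, which is relation-
agnostic.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discretize import ExpressionMatrix, StateMatrix, _FILE_TO_CODE
from .pathway_analysis import Pathway, PathwayResult, RunConfig

logger = logging.getLogger("dynsig")

__all__ = ["read_expression", "read_labels", "write_expression",
           "write_labels", "read_state_matrix", "write_state_matrix",
           "read_pathways", "write_results", "collapse_probes", "cv_filter"]


def _config_hash(config) -> str:
    return hashlib.md5(repr(config).encode()).hexdigest()[:12]


def _header_lines(config=None, seed=None) -> str:
    lines = [f"# dynsig v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config={_config_hash(config)}")
    return "\n".join(lines) + "\n"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Two-column labels TSV (sample_id, class) -> (ids, labels)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: labels file needs two columns (sample, class)")
    return df.iloc[:, 0].tolist(), df.iloc[:, 1].to_numpy(dtype=object)


def _parse_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = _read_table(path)
    gene_ids = df.iloc[:, 0].tolist()
    sample_ids = df.columns[1:].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids")
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        try:
            values[:, j] = pd.to_numeric(body[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(body[col], errors="coerce")
            row = int(np.where(bad.isna())[0][0])
            raise ValueError(f"{path}: non-numeric value {body[col].iloc[row]!r} "
                             f"at gene {gene_ids[row]!r}, sample {col!r}")
    return values, gene_ids, sample_ids


def _align_labels(sample_ids, labels_path):
    ids, labels = read_labels(labels_path)
    mapping = dict(zip(ids, labels))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    return np.array([mapping[s] for s in sample_ids], dtype=object)


def read_expression(path, labels_path, on_duplicate: str = "error"
                    ) -> ExpressionMatrix:
    """Read an expression TSV plus its labels TSV.

    ``on_duplicate``: 'error' rejects duplicate gene ids, 'mean'
    collapses them by averaging (probe-style collapse).
    """
    values, gene_ids, sample_ids = _parse_matrix(path)
    if len(set(gene_ids)) != len(gene_ids):
        if on_duplicate == "mean":
            df = pd.DataFrame(values, index=gene_ids).groupby(level=0, sort=False).mean()
            gene_ids, values = df.index.tolist(), df.to_numpy()
        else:
            dups = pd.Index(gene_ids)
            raise ValueError(f"{path}: duplicate gene ids, e.g. "
                             f"{dups[dups.duplicated()][:3].tolist()}; "
                             "pass on_duplicate='mean' to average them")
    labels = _align_labels(sample_ids, labels_path)
    return ExpressionMatrix(values, gene_ids, sample_ids, labels)


def write_expression(expr: ExpressionMatrix, path, config=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df = pd.DataFrame(expr.values, index=expr.gene_ids,
                          columns=expr.sample_ids)
        df.index.name = "gene"
        df.to_csv(fh, sep="\t", float_format="%.10g")


def write_labels(sample_ids, labels, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines())
        fh.write("sample\tclass\n")
        for s, c in zip(sample_ids, labels):
            fh.write(f"{s}\t{c}\n")


def read_state_matrix(path, labels_path) -> StateMatrix:
    """State TSV in the -1/0/1 encoding -> :class:`StateMatrix`."""
    values, gene_ids, sample_ids = _parse_matrix(path)
    codes = np.empty(values.shape, dtype=np.int8)
    for enc, code in _FILE_TO_CODE.items():
        codes[values == enc] = code
    if not np.isin(values, list(_FILE_TO_CODE)).all():
        bad = sorted(set(values.ravel()) - set(_FILE_TO_CODE))
        raise ValueError(f"{path}: state entries must be -1/0/1, found {bad[:5]}")
    labels = _align_labels(sample_ids, labels_path)
    return StateMatrix(codes, gene_ids, sample_ids, labels)


def write_state_matrix(states: StateMatrix, path, config=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df = pd.DataFrame(states.to_file_encoding(), index=states.gene_ids,
                          columns=states.sample_ids)
        df.index.name = "gene"
        df.to_csv(fh, sep="\t")


def _pathway_from_edges(name, rows, path, relations=None) -> Pathway | None:
    links = [(s, t) for s, t in rows]
    dropped = sum(1 for s, t in links if s == t)
    if dropped:
        warnings.warn(f"{path}: {dropped} self-link(s) dropped in pathway {name!r}")
    links = [(s, t) for s, t in links if s != t]
    if not links:
        warnings.warn(f"{path}: pathway {name!r} empty after cleaning; skipped")
        return None
    pw = Pathway(name, links)
    logger.info("pathway %s: %d links", name, pw.L)
    return pw


def _read_single_pathway_file(path) -> Pathway | None:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:          # plain edge list
                rows.append((parts[0], parts[1]))
            elif len(parts) == 3:        # SIF: source relation target
                rows.append((parts[0], parts[2]))
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 (edge list) or "
                                 f"3 (SIF) tab-separated fields, got {len(parts)}")
    if not rows:
        warnings.warn(f"{path}: empty pathway file skipped")
        return None
    return _pathway_from_edges(path.stem, rows, path)


def read_pathways(path) -> list[Pathway]:
    """Read pathways from a directory or a single file.

    A directory yields one pathway per file (``.sif`` 3-column or
    2-column edge list), named by file stem. A single file with two
    columns is one pathway; with three or more columns the first column
    is the pathway name followed by (source, target) or
    (source, relation, target). Self-links are dropped with a warning
    and duplicate links collapsed.
    """
    path = Path(path)
    if path.is_dir():
        out = []
        for f in sorted(path.iterdir()):
            if f.suffix.lower() in (".sif", ".tsv", ".txt"):
                pw = _read_single_pathway_file(f)
                if pw is not None:
                    out.append(pw)
        if not out:
            raise ValueError(f"{path}: no pathway files found")
        return out
    if path.suffix.lower() == ".sif":
        pw = _read_single_pathway_file(path)
        return [pw] if pw is not None else []
    df = _read_table(path)
    if df.shape[1] == 2:
        pw = _pathway_from_edges(path.stem, list(df.itertuples(index=False)), path)
        return [pw] if pw is not None else []
    if df.shape[1] in (3, 4):
        # leading pathway-name column; optional relation column in between
        out = []
        for name, grp in df.groupby(df.columns[0], sort=False):
            rows = list(zip(grp.iloc[:, 1], grp.iloc[:, -1]))
            pw = _pathway_from_edges(str(name), rows, path)
            if pw is not None:
                out.append(pw)
        if not out:
            raise ValueError(f"{path}: no valid pathways")
        return out
    raise ValueError(f"{path}: unsupported pathway table with {df.shape[1]} columns")


def write_results(results: list[PathwayResult], path,
                  config: RunConfig | None = None) -> None:
    """Results TSV: pathway, n_links, DEP, p, q."""
    with open(path, "w") as fh:
        fh.write(_header_lines(config, seed=None if config is None else config.seed))
        fh.write("pathway\tn_links\tDEP\tp\tq\n")
        for r in results:
            q = "" if r.q is None else f"{r.q:.6g}"
            fh.write(f"{r.name}\t{r.n_links}\t{r.dep:.6g}\t{r.p:.6g}\t{q}\n")


def collapse_probes(expr: ExpressionMatrix, mapping) -> ExpressionMatrix:
    """Average multi-probe rows into one row per mapped gene.

    ``mapping`` is a probe -> gene dict or a two-column DataFrame
    (probe, gene). Unmapped probes are dropped (count logged).
    """
    if isinstance(mapping, pd.DataFrame):
        mapping = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    if not mapping:
        raise ValueError("probe mapping is empty")
    genes = [mapping.get(p) for p in expr.gene_ids]
    keep = [i for i, g in enumerate(genes) if g is not None]
    dropped = expr.n_genes - len(keep)
    if dropped:
        logger.info("collapse_probes: %d unmapped probe(s) dropped", dropped)
    if not keep:
        raise ValueError("no probe maps to a gene")
    df = pd.DataFrame(expr.values[keep],
                      index=[genes[i] for i in keep])
    df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df.to_numpy(), df.index.tolist(),
                            expr.sample_ids, expr.labels)


def cv_filter(expr: ExpressionMatrix, cutoff: float = 0.05) -> ExpressionMatrix:
    """Drop low-information genes by coefficient of variation.

    Retains genes with ``sd / |mean| >= cutoff``; genes with zero mean
    (CV undefined) are retained with a warning.
    """
    if not cutoff > 0:
        raise ValueError(f"CV cutoff must be positive, got {cutoff}")
    mean = expr.values.mean(axis=1)
    sd = expr.values.std(axis=1, ddof=1)
    zero_mean = mean == 0
    if zero_mean.any():
        warnings.warn(f"{int(zero_mean.sum())} gene(s) with zero mean retained "
                      "(CV undefined)")
    keep = zero_mean | (sd / np.where(zero_mean, 1.0, np.abs(mean)) >= cutoff)
    logger.info("cv_filter: %d of %d genes retained", int(keep.sum()), expr.n_genes)
    if not keep.any():
        raise ValueError("CV filter removed every gene")
    return ExpressionMatrix(expr.values[keep],
                            [g for g, k in zip(expr.gene_ids, keep) if k],
                            expr.sample_ids, expr.labels)
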