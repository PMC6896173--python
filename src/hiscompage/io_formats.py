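"""Readers, writers, and preprocessing filters for the standard inputs.

Supported formats:

* expression — TSV/CSV, one header row of gene ids, first column sample ids
  (or transposed, with ``orientation="genes_in_rows"``);
* pathways — GMT (Broad dialect): name, description, then member genes,
  tab-separated, one set per line;
* survival — TSV/CSV with columns ``sample_id``, ``time``, ``event``.

Filters implement the usual unsupervised preprocessing for expression data
ahead of pathway modelling: zero-proportion filtering, log2 transform, and
top-dispersion (variance or MAD) gene selection.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DataError, ExpressionMatrix, Pathway, PathwayCollection, SurvivalPhenotype


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path, orientation: str = "samples_in_rows") -> ExpressionMatrix:
    """Read an expression matrix from delimited text.

    Parameters
    ----------
    path : file path
        TSV or CSV with one header row and an id column.
    orientation : {"samples_in_rows", "genes_in_rows"}
        Layout of the file. The returned matrix is always samples x genes.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen, dup = set(), []
    for h in header:  # pandas mangles duplicate headers, so check them raw
        if h in seen and h not in dup:
            dup.append(h)
        seen.add(h)
    if dup:
        raise DataError(f"duplicate column ids in {path.name}: {', '.join(dup)}")
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    dup = frame.index[frame.index.duplicated()].unique().tolist()
    if dup:
        raise DataError(f"duplicate row ids in {path.name}: {', '.join(dup)}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell in {path.name} at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}: {frame.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(
            f"missing value in {path.name} at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    if orientation == "genes_in_rows":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_expression(X: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write samples x genes matrix with 12 significant digits (round-trip safe)."""
    X.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_gmt(path) -> PathwayCollection:
    """Read gene sets in GMT format, preserving pathway and gene order."""
    path = Path(path)
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path.name}:{lineno}: expected name, description and at "
                    f"least one gene ({len(fields)} fields found)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise DataError(f"{path.name}:{lineno}: pathway {name!r} lists no genes")
            pathways.append(Pathway(name=name, description=description, genes=genes))
    try:
        return PathwayCollection(pathways)
    except DataError as exc:
        raise DataError(f"{path.name}: {exc}") from exc


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.description, *p.genes]) + "\n")


def read_survival(path) -> SurvivalPhenotype:
    """Read a survival table with columns sample_id, time, event."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"sample_id", "time", "event"}
    if not required.issubset(frame.columns):
        raise DataError(
            f"{path.name}: survival table needs columns sample_id, time, event "
            f"(found {list(frame.columns)})"
        )
    return SurvivalPhenotype(
        sample_ids=frame["sample_id"].astype(str).tolist(),
        time=frame["time"].to_numpy(dtype=float),
        event=frame["event"].to_numpy(),
    )


def write_survival(surv: SurvivalPhenotype, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep=sep, index=False)


def log2_transform(X: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return log2(x + pseudocount); values below -pseudocount are an error."""
    shifted = X.values + pseudocount
    if np.any(shifted <= 0):
        raise DataError("log2 transform undefined: values <= -pseudocount present")
    return ExpressionMatrix(X.sample_ids, list(X.gene_ids), np.log2(shifted))


def filter_zero_proportion(X: ExpressionMatrix, max_zero_fraction: float = 0.8) -> ExpressionMatrix:
    """Drop genes whose fraction of exactly-zero entries exceeds the cutoff.

    Genes at exactly the cutoff are kept (the rule is strictly "larger than").
    """
    zero_frac = (X.values == 0).mean(axis=0)
    keep = np.flatnonzero(zero_frac <= max_zero_fraction)
    return X.subset_genes(keep)


def filter_top_dispersion(
    X: ExpressionMatrix, statistic: str = "variance", top_fraction: float = 0.25
) -> ExpressionMatrix:
    """Keep the ceil(top_fraction * K) genes with the largest dispersion.

    ``statistic`` is "variance" or "mad" (median absolute deviation). Ties are
    broken by original column order; survivors keep their original order.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if X.n_genes < 1:
        raise DataError("matrix has no genes")
    if statistic == "variance":
        disp = X.values.var(axis=0, ddof=1) if X.n_samples > 1 else np.zeros(X.n_genes)
    elif statistic == "mad":
        med = np.median(X.values, axis=0)
        disp = np.median(np.abs(X.values - med), axis=0)
    else:
        raise ValueError(f"unknown dispersion statistic {statistic!r}")
    n_keep = math.ceil(top_fraction * X.n_genes)
    # stable sort on -disp keeps original column order among ties
    ranked = np.argsort(-disp, kind="stable")[:n_keep]
    keep = np.sort(ranked)
    return X.subset_genes(keep)


def map_genes_to_pathways(
    X: ExpressionMatrix, collection: PathwayCollection, min_genes: int = 3
) -> tuple[PathwayCollection, ExpressionMatrix]:
    """Intersect pathways with the matrix's genes and prune small pathways.

    Each pathway keeps (in order) only genes present in ``X``; pathways with
    fewer than ``min_genes`` survivors are dropped. Returns the pruned
    collection and ``X`` restricted to genes belonging to >= 1 kept pathway
    (original column order; a column may be referenced by several pathways).
    """
    present = set(X.gene_ids)
    kept: list[Pathway] = []
    for p in collection:
        genes = [g for g in p.genes if g in present]
        if len(genes) >= min_genes:
            kept.append(Pathway(p.name, p.description, genes))
    if not kept:
        raise DataError(
            f"no pathway retains >= {min_genes} genes after intersection with the matrix"
        )
    used = set()
    for p in kept:
        used.update(p.genes)
    cols = [j for j, g in enumerate(X.gene_ids) if g in used]
    return PathwayCollection(kept), X.subset_genes(cols)
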