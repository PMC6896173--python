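"""Core in-memory containers: expression matrix, survival phenotype, pathways.

All containers validate their invariants on construction so that downstream
numerical code can assume clean inputs (no NaN, unique identifiers, aligned
shapes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


def _find_duplicates(ids) -> list[str]:
    seen, dups = set(), []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Samples x genes numeric expression matrix.

    Rows are samples (length I), columns are genes (length K). Values must be
    finite; duplicate sample or gene identifiers are rejected.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        for label, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise DataError(f"duplicate {label} ids: {', '.join(dups)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, columns) -> "ExpressionMatrix":
        """Restrict to the given column indices (order preserved as given)."""
        columns = np.asarray(columns, dtype=int)
        return ExpressionMatrix(
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[j] for j in columns],
            values=self.values[:, columns],
        )

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            sample_ids=list(map(str, frame.index)),
            gene_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class SurvivalPhenotype:
    """Per-sample right-censored survival outcome.

    ``time`` is the observed follow-up time (> 0, units as given) and
    ``event`` the death indicator (1 = event observed, 0 = censored).
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise DataError("sample_ids, time and event must have equal length")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise DataError(f"duplicate sample ids: {', '.join(dups)}")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise DataError("all survival times must be finite and > 0")
        ev = np.unique(self.event)
        if not np.all(np.isin(ev, [0, 1])):
            raise DataError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def align_to(self, X: ExpressionMatrix) -> "SurvivalPhenotype":
        """Reorder to match ``X.sample_ids``; error on any mismatch."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in X.sample_ids if s not in pos]
        extra = [s for s in self.sample_ids if s not in set(X.sample_ids)]
        if missing or extra:
            raise DataError(
                "sample ids do not align; "
                f"missing from survival: {missing[:5]}, extra: {extra[:5]}"
            )
        order = [pos[s] for s in X.sample_ids]
        return SurvivalPhenotype(
            sample_ids=list(X.sample_ids),
            time=self.time[order],
            event=self.event[order],
        )


@dataclass
class Pathway:
    name: str
    description: str
    genes: list[str]


@dataclass
class PathwayCollection:
    """Ordered set of named pathways; genes may appear in several pathways."""

    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        dups = _find_duplicates([p.name for p in self.pathways])
        if dups:
            raise DataError(f"duplicate pathway names: {', '.join(dups)}")
        for p in self.pathways:
            if len(p.genes) < 1:
                raise DataError(f"pathway {p.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, key):
        if isinstance(key, int):
            return self.pathways[key]
        for p in self.pathways:
            if p.name == key:
                return p
        raise KeyError(key)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]


@dataclass
class HierarchyDesign:
    """Gene-to-pathway column mapping bound to a specific expression matrix.

    ``pathway_index[j]`` holds the column indices (into the bound matrix)
    of the j-th pathway's member genes, in pathway order. Overlapping genes
    occur once per pathway membership.
    """

    pathway_names: list[str]
    pathway_index: list[np.ndarray]
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.pathway_names) != len(self.pathway_index):
            raise DataError("pathway_names and pathway_index lengths differ")
        self.pathway_index = [np.asarray(ix, dtype=int) for ix in self.pathway_index]
        for name, ix in zip(self.pathway_names, self.pathway_index):
            if len(ix) < 1:
                raise DataError(f"pathway {name!r} maps to no columns")
            if ix.min() < 0 or ix.max() >= self.n_genes:
                raise DataError(f"pathway {name!r} references columns outside the matrix")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_names)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(ix) for ix in self.pathway_index])

    @property
    def total_weight_count(self) -> int:
        return int(self.sizes.sum())

    @classmethod
    def from_collection(
        cls, collection: PathwayCollection, X: ExpressionMatrix
    ) -> "HierarchyDesign":
        gix = X.gene_index()
        names, index = [], []
        for p in collection:
            cols = [gix[g] for g in p.genes if g in gix]
            if not cols:
                raise DataError(f"pathway {p.name!r} shares no genes with the matrix")
            names.append(p.name)
            index.append(np.array(cols, dtype=int))
        return cls(pathway_names=names, pathway_index=index, n_genes=X.n_genes)
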