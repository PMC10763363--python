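"""In-memory containers for count data: bulk count tables and UMI matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class CountTable:
    """Non-negative counts, entities (genes/regions) x samples.

    ``counts`` is a pandas DataFrame indexed by entity id with sample ids
    as columns.  Every sample must have a condition label; replicate
    indices are optional bookkeeping.
    """

    counts: pd.DataFrame
    condition_of: dict[str, str]
    replicate_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate entity id: {dup!r}")
        if (self.counts.values < 0).any():
            raise ValueError("negative values in count table")
        missing = [s for s in self.counts.columns if s not in self.condition_of]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance (column) order."""
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]

    def subset_entities(self, keep: list[str]) -> "CountTable":
        return CountTable(self.counts.loc[keep], self.condition_of, self.replicate_of)


@dataclass
class UmiMatrix:
    """Sparse integer UMI counts, genes x cells, with per-cell cluster labels."""

    counts: sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.counts.data
        if data.size and (np.mod(data, 1) != 0).any():
            raise ValueError("UMI counts must be integers")
        if data.size and (data < 0).any():
            raise ValueError("negative UMI counts")
        missing = [c for c in self.cell_ids if c not in self.cluster_of]
        if missing:
            raise ValueError(f"cells missing from cluster map: {missing[:5]}")

    @property
    def clusters(self) -> list[str]:
        seen: list[str] = []
        for c in self.cell_ids:
            lab = self.cluster_of[c]
            if lab not in seen:
                seen.append(lab)
        return seen

    def cluster_cell_indices(self, cluster: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.cell_ids) if self.cluster_of[c] == cluster],
            dtype=int,
        )

    def gene_counts(self, gene_id: str, cluster: str | None = None) -> np.ndarray:
        """Dense count vector for one gene, optionally restricted to a cluster."""
        row = self.counts[self.gene_ids.index(gene_id)].toarray().ravel()
        if cluster is None:
            return row.astype(np.int64)
        return row[self.cluster_cell_indices(cluster)].astype(np.int64)
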