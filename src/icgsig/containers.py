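"""Core in-memory containers shared across the pipeline.

Expression data travel as a feature-by-sample matrix of log2-scale values
with optional per-feature annotation (gene symbol, chromosome, ion-channel
flag).  A signature is an ordered set of genes, each carrying a direction
weight of +1 (up-regulated in high-grade tumors) or -1 (down-regulated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"X", "Y"})

#: annotation columns recognized by the pipeline
ANNOTATION_COLUMNS = ("gene_symbol", "chromosome", "is_ion_channel")


def normalize_chromosome(label: object) -> str:
    """Map chromosome labels like 'chrX', ' x ', '23' → canonical 'X', '7', ...

    Empty / missing labels normalize to ''.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return ""
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    return text.upper()


@dataclass
class ExpressionMatrix:
    """Feature × sample matrix of log2 expression values.

    Parameters
    ----------
    values
        DataFrame with unique feature ids as index and unique sample ids as
        columns; all entries must be finite.
    annotation
        Optional per-feature DataFrame (same index) with any of the columns
        ``gene_symbol`` (str), ``chromosome`` (str), ``is_ion_channel`` (bool).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.annotation is not None:
            missing = self.values.index.difference(self.annotation.index)
            if len(missing):
                raise ValueError(
                    f"annotation missing {len(missing)} feature(s), e.g. {list(missing[:5])}"
                )
            # keep annotation aligned with the value matrix
            self.annotation = self.annotation.loc[self.values.index]

    # -- basic introspection -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_symbols(self) -> pd.Series:
        """Per-feature gene symbol ('' where unannotated)."""
        if self.annotation is None or "gene_symbol" not in self.annotation:
            return pd.Series("", index=self.feature_ids)
        return self.annotation["gene_symbol"].fillna("").astype(str)

    def ion_channel_genes(self) -> set[str]:
        """Gene symbols flagged as ion channels in the annotation."""
        if self.annotation is None or "is_ion_channel" not in self.annotation:
            return set()
        mask = self.annotation["is_ion_channel"].fillna(False).astype(bool)
        syms = self.gene_symbols()[mask]
        return {s for s in syms if s}

    # -- subsetting ----------------------------------------------------------

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(ids)
        ann = self.annotation.loc[ids] if self.annotation is not None else None
        return ExpressionMatrix(self.values.loc[ids], ann)

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(ids)
        return ExpressionMatrix(self.values.loc[:, ids], self.annotation)


@dataclass(frozen=True)
class Signature:
    """Direction-weighted gene signature: gene symbol → weight ∈ {+1, −1}."""

    weights: pd.Series

    def __post_init__(self) -> None:
        w = pd.Series(self.weights).astype(int)
        if w.index.has_duplicates:
            raise ValueError("signature contains duplicate genes")
        if len(w) and not w.isin([1, -1]).all():
            raise ValueError("signature weights must be +1 or -1")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, int]]) -> "Signature":
        entries = list(entries)
        genes = [g for g, _ in entries]
        return cls(pd.Series([w for _, w in entries], index=genes, dtype=int))

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def subset(self, direction: int) -> "Signature":
        """Entries whose weight equals ``direction`` (+1 or −1)."""
        if direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        return Signature(self.weights[self.weights == direction])

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.weights.items())

    def __contains__(self, gene: str) -> bool:
        return gene in self.weights.index
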