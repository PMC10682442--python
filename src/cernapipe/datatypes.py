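"""Typed in-memory containers shared across the pipeline.

The pipeline deals with four RNA classes measured on the same cohort:
messenger RNA (mRNA), long non-coding RNA (lncRNA), circular RNA
(circRNA) and microRNA (miRNA).  Expression is held per cancer subtype
as a genes x samples matrix of non-negative platform-agnostic values;
gene identity and RNA class travel together so downstream stages can
apply class-specific rules (e.g. which pairs may form sponge edges).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_SUBTYPES = ("basal-like", "luminal B", "normal-like", "luminal A", "HER2+")


class RNAClass(str, enum.Enum):
    """One of the four RNA classes a gene can belong to."""

    MRNA = "mRNA"
    LNCRNA = "lncRNA"
    CIRCRNA = "circRNA"
    MIRNA = "miRNA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: RNA classes eligible as network nodes (miRNAs mediate edges but are not nodes).
SPONGE_CLASSES = (RNAClass.MRNA, RNAClass.LNCRNA, RNAClass.CIRCRNA)


class FormatError(ValueError):
    """Malformed external file (duplicates, bad columns, unparseable cells)."""


@dataclass
class ExpressionDataset:
    """Expression of one subtype: genes (typed by RNA class) x samples.

    Parameters
    ----------
    subtype:
        Subtype label the samples belong to.
    values:
        ``pandas.DataFrame`` indexed by gene id with sample-id columns;
        finite, non-negative.
    classes:
        ``pandas.Series`` mapping every gene id in ``values.index`` to an
        :class:`RNAClass`.
    """

    subtype: str
    values: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        self.classes = self.classes.reindex(self.values.index)
        self.validate()

    def validate(self) -> None:
        if not self.subtype:
            raise ValueError("subtype label must be non-empty")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if arr.size and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.classes.isna().any():
            missing = self.classes.index[self.classes.isna()].tolist()
            raise ValueError(f"genes without an RNA class: {missing}")

    # -- convenience -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def genes_of_class(self, rna_class: RNAClass) -> list[str]:
        return self.classes.index[self.classes == rna_class].tolist()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        genes = [g for g in genes]
        return ExpressionDataset(self.subtype, self.values.loc[genes], self.classes.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.subtype, self.values.loc[:, list(samples)], self.classes)


@dataclass
class InteractionDB:
    """Experimentally supported miRNA -> target pairs (miRTarBase/TarBase-like)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    source: str = "unspecified"

    def __post_init__(self) -> None:
        for mirna, target in self.pairs:
            if mirna == target:
                raise ValueError(f"self-interaction {mirna!r} -> {target!r}")

    def targets_of(self, mirna: str) -> set[str]:
        return {t for m, t in self.pairs if m == mirna}

    def by_mirna(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for m, t in self.pairs:
            out.setdefault(m, set()).add(t)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ClinicalTable:
    """Per-sample overall survival: time, event indicator, subtype label."""

    records: pd.DataFrame  # columns: sample, time, event, subtype

    REQUIRED = ("sample", "time", "event", "subtype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        if self.records["sample"].duplicated().any():
            dupes = self.records.loc[self.records["sample"].duplicated(), "sample"].tolist()
            raise FormatError(f"duplicate clinical sample ids: {dupes}")
        if (self.records["time"] < 0).any():
            raise ValueError("survival times must be >= 0")
        if not self.records["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")

    def for_subtype(self, subtype: str) -> pd.DataFrame:
        return self.records[self.records["subtype"] == subtype].set_index("sample")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): name -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                # deduplicate silently preserving order
                seen: dict[str, None] = {}
                for g in members:
                    seen.setdefault(g)
                self.sets[name] = (self.sets[name][0], list(seen))

    def __len__(self) -> int:
        return len(self.sets)


def classes_from_mapping(genes: Iterable[str], class_map: Mapping[str, RNAClass]) -> pd.Series:
    """Build the gene->class series for *genes*, failing on unmapped ids."""
    genes = list(genes)
    missing = [g for g in genes if g not in class_map]
    if missing:
        raise ValueError(f"genes missing from class map: {missing[:10]}" +
                         (" ..." if len(missing) > 10 else ""))
    return pd.Series({g: RNAClass(class_map[g]) for g in genes}).reindex(genes)
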