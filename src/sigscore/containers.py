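"""In-memory containers for expression matrices, sample groupings and gene sets.

The central object is :class:`ExpressionMatrix`, a features x samples numeric
matrix carried as a pandas DataFrame together with two tags: the measurement
scale (``raw_linear`` intensities or ``log2`` values) and the feature level
(``probe`` or ``gene``).  All gene/probe symbols used for matching are
upper-cased at construction so that e.g. mouse ``Pgc1a`` and a human-array
``PGC1A`` row meet on equal terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

RAW_LINEAR = "raw_linear"
LOG2 = "log2"
SCALES = (RAW_LINEAR, LOG2)

PROBE = "probe"
GENE = "gene"
FEATURE_LEVELS = (PROBE, GENE)


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with scale and level tags.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    scale
        ``"raw_linear"`` (strictly positive intensities) or ``"log2"``.
    feature_level
        ``"probe"`` or ``"gene"``.
    """

    values: pd.DataFrame
    scale: str
    feature_level: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.feature_level not in FEATURE_LEVELS:
            raise ValidationError(
                f"unknown feature_level {self.feature_level!r}; expected one of {FEATURE_LEVELS}"
            )
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale == RAW_LINEAR and arr.size and arr.min() <= 0:
            raise ValidationError("raw_linear matrix contains non-positive values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.scale, self.feature_level)

    def reorder_samples(self, order) -> "ExpressionMatrix":
        order = list(order)
        if sorted(order) != sorted(self.sample_ids):
            raise ValidationError("sample order is not a permutation of the matrix samples")
        return ExpressionMatrix(self.values[order], self.scale, self.feature_level)


@dataclass
class SampleGroups:
    """Assignment of every sample to a group, with a designated reference group."""

    assignment: dict[str, str]
    reference_group: str

    def __post_init__(self) -> None:
        if self.reference_group not in set(self.assignment.values()):
            raise ValidationError(
                f"reference group {self.reference_group!r} has no samples assigned"
            )

    @property
    def groups(self) -> list[str]:
        """Group labels, reference first, then first-appearance order."""
        out = [self.reference_group]
        for g in self.assignment.values():
            if g not in out:
                out.append(g)
        return out

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def treated_group(self) -> str:
        """The single non-reference group; error if there is not exactly one."""
        others = [g for g in self.groups if g != self.reference_group]
        if len(others) != 1:
            raise ValidationError(
                f"expected exactly one non-reference group, found {len(others)}: {others}"
            )
        return others[0]

    def require_min_per_group(self, k: int) -> None:
        for g in self.groups:
            n = len(self.samples_in(g))
            if n < k:
                raise ValidationError(f"group {g!r} has {n} samples; at least {k} required")


@dataclass
class ProbeAnnotation:
    """Many-to-one probe -> gene-symbol mapping; symbols are upper-cased."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for probe, symbol in self.mapping.items():
            if symbol is None or str(symbol).strip() == "":
                raise ValidationError(f"probe {probe!r} maps to an empty symbol")
            clean[probe] = str(symbol).strip().upper()
        self.mapping = clean

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneSet:
    """A named set of gene symbols (upper-cased, duplicate-free)."""

    name: str
    description: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        self.members = {str(m).strip().upper() for m in self.members if str(m).strip()}
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no non-empty members")


@dataclass
class OrthologMap:
    """One-to-one symbol translation between species (source -> target).

    Rows that make a source ambiguous (two targets) or a target ambiguous
    (two sources) are rejected, so translation is deterministic.  The empty
    map is valid and means identity translation.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        seen_targets: dict[str, str] = {}
        for src, tgt in self.pairs.items():
            src_u, tgt_u = str(src).strip().upper(), str(tgt).strip().upper()
            if not src_u or not tgt_u:
                raise ValidationError("ortholog map contains an empty symbol")
            if src_u in clean and clean[src_u] != tgt_u:
                raise ValidationError(f"source symbol {src_u!r} maps to multiple targets")
            if tgt_u in seen_targets and seen_targets[tgt_u] != src_u:
                raise ValidationError(f"target symbol {tgt_u!r} is mapped from multiple sources")
            clean[src_u] = tgt_u
            seen_targets[tgt_u] = src_u
        self.pairs = clean

    def translate(self, symbol: str) -> str:
        s = str(symbol).strip().upper()
        return self.pairs.get(s, s)
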