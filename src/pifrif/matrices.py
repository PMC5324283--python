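"""Core in-memory containers: raw count matrices and normalised expression.

Both containers wrap a pandas DataFrame with genes as rows and samples as
columns, plus a per-sample group annotation (two-level, e.g. HFE / LFE).
Validation happens at construction so downstream stages can assume clean
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input matrix or annotation violates its contract."""


def _check_axes(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")


def _check_groups(samples: pd.Index, groups: pd.Series) -> pd.Series:
    groups = groups.reindex(samples)
    if groups.isna().any():
        missing = groups.index[groups.isna()].tolist()
        raise ValidationError(f"samples without a group label: {missing}")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(
            f"expected exactly two groups, found {levels}"
        )
    return groups.astype(str)


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples, with a two-group design."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        _check_axes(self.counts)
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.groups = _check_groups(self.counts.columns, self.groups)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.groups.equals(
            other.groups
        )


@dataclass
class ExpressionMatrix:
    """Normalised expression values (log2 quantile-normalised RPM).

    ``provenance`` records the ordered list of transforms that produced the
    matrix, e.g. ``["rpm", "filter_complete", "log2(+1)", "quantile"]``.
    """

    values: pd.DataFrame
    groups: pd.Series
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_axes(self.values)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression values must be finite")
        self.groups = _check_groups(self.values.columns, self.groups)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_means(self, group: str) -> pd.Series:
        return self.values[self.samples_in(group)].mean(axis=1)
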