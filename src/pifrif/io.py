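"""Plain-text readers and writers for all pipeline file formats.

Counts: tab-delimited, genes as rows, first column the gene id, header row
of sample ids. Groups: two-column TSV (sample_id, group). Gene sets:
newline-delimited identifiers, blank lines ignored. Errors cite 1-based
file line numbers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrices import CountMatrix, ExpressionMatrix, ValidationError


def read_counts(counts_path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Read and validate a count matrix plus its group annotation."""
    counts_path = Path(counts_path)
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    dup = df.index.duplicated(keep="first")
    if dup.any():
        line = int(dup.argmax()) + 2  # +1 header, +1 one-based
        raise ValidationError(
            f"{counts_path}: duplicate gene id {df.index[dup.argmax()]!r} on line {line}"
        )
    for j, col in enumerate(df.columns):
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            line = int(bad.isna().to_numpy().argmax()) + 2
            raise ValidationError(
                f"{counts_path}: non-numeric count in column {col!r} on line {line}"
            )
        if not (bad == bad.round()).all():
            line = int((bad != bad.round()).to_numpy().argmax()) + 2
            raise ValidationError(
                f"{counts_path}: non-integer count in column {col!r} on line {line}"
            )
    groups = read_groups(groups_path)
    missing = [s for s in df.columns if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without groups in {groups_path}: {missing}")
    return CountMatrix(counts=df.astype("int64"), groups=groups[df.columns])


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected two columns (sample_id, group)")
    sample_col, group_col = df.columns
    dup = df[sample_col].duplicated()
    if dup.any():
        line = int(dup.to_numpy().argmax()) + 2
        raise ValidationError(f"{path}: duplicate sample id on line {line}")
    if df[group_col].isna().any():
        line = int(df[group_col].isna().to_numpy().argmax()) + 2
        raise ValidationError(f"{path}: missing group on line {line}")
    return pd.Series(
        df[group_col].to_numpy(), index=df[sample_col].to_numpy(), name="group"
    )


def read_gene_set(path: str | Path) -> set[str]:
    """Read a newline-delimited gene-id file; blank lines are ignored."""
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            gid = raw.strip()
            if not gid:
                continue
            if gid in seen:
                raise ValidationError(f"{path}: duplicate id {gid!r} on line {lineno}")
            seen.add(gid)
            ids.append(gid)
    return set(ids)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_groups(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def write_gene_set(ids, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    df = em.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression(values_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = read_groups(groups_path)
    return ExpressionMatrix(values=df, groups=groups[df.columns], provenance=["file"])


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
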