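"""Per-gene MA statistics and Phenotypic Impact Factor (PIF) ranking.

For each gene, with group means x_hfe and x_lfe on the log2 scale:

    M   = x_hfe - x_lfe          (differential expression)
    A   = (x_hfe + x_lfe) / 2    (average abundance)
    PIF = A x M                  (abundance-weighted DE)

PIF de-emphasises lowly abundant, noisy genes and is used both to choose
the extreme target genes for the differential-wiring (RIF) analysis and
to build the small discrimination panel for sample clustering. Fold
changes are reported as signed linear ratios: 2^|M| carrying the sign of
M, so M = -2.16 prints as -4.46 (4.46-fold down in HFE).

No per-gene significance testing is performed here by design: with two
very similar groups of six, multiple-testing penalties make gene-by-gene
calls uninformative, so genes are ranked and interpreted at the systems
level instead.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .matrices import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

HFE = "HFE"
LFE = "LFE"


def compute_de(
    em: ExpressionMatrix, contrast: tuple[str, str] = (HFE, LFE)
) -> pd.DataFrame:
    """Build the per-gene DE table (columns x_hfe, x_lfe, a, m, fold_change,
    pif, rank_pif), indexed by gene id, for the ``contrast[0] - contrast[1]``
    comparison."""
    g_hi, g_lo = contrast
    for g in contrast:
        if g not in set(em.groups):
            raise ValidationError(f"group {g!r} absent from annotation")
    x_hi = em.group_means(g_hi)
    x_lo = em.group_means(g_lo)
    m = x_hi - x_lo
    a = (x_hi + x_lo) / 2
    fold = np.sign(m) * np.power(2.0, np.abs(m))
    fold = fold.where(m != 0, 1.0)  # no change -> ratio 1
    pif = a * m
    det = pd.DataFrame(
        {
            "x_hfe": x_hi,
            "x_lfe": x_lo,
            "a": a,
            "m": m,
            "fold_change": fold,
            "pif": pif,
        }
    )
    det["rank_pif"] = det["pif"].rank(method="dense", ascending=False).astype(int)
    det.index.name = "gene"
    return det


def _ordered_by_pif(det: pd.DataFrame, ascending: bool) -> pd.Index:
    # deterministic: PIF then gene id lexicographic
    tmp = det.reset_index()
    tmp = tmp.sort_values(["pif", "gene"], ascending=[ascending, True], kind="mergesort")
    return pd.Index(tmp["gene"])


def select_extreme_pif(
    det: pd.DataFrame, fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Extreme-PIF target sets: top and bottom floor(fraction/2 * n) genes.

    The nominal fraction is split symmetrically, e.g. 5% of 10,412 genes
    gives 260 up + 260 down = 520 targets.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    n = len(det)
    k = math.floor(fraction / 2 * n)
    if k == 0:
        raise ValidationError("fraction too small: selects zero genes")
    up = list(_ordered_by_pif(det, ascending=False)[:k])
    down = list(_ordered_by_pif(det, ascending=True)[:k])
    return up, down


def select_panel(det: pd.DataFrame, k: int = 20) -> list[str]:
    """Discrimination panel: top-k plus bottom-k genes by PIF (default 40)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if 2 * k > len(det):
        raise ValidationError(f"2k = {2 * k} exceeds the {len(det)} genes available")
    top = list(_ordered_by_pif(det, ascending=False)[:k])
    bottom = list(_ordered_by_pif(det, ascending=True)[:k])
    return top + bottom


def ma_table(det: pd.DataFrame, highlight: set[str] | None = None) -> pd.DataFrame:
    """(A, M) pairs per gene with a highlight flag for a gene set of interest."""
    highlight = set(highlight or ())
    missing = highlight - set(det.index)
    if missing:
        logger.warning(
            "%d highlight ids absent from DE table (e.g. %s)",
            len(missing),
            sorted(missing)[:5],
        )
    out = det[["a", "m"]].copy()
    out["highlight"] = out.index.isin(highlight)
    return out
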