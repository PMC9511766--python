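"""Expression-enrichment arithmetic for a positively-selected gene set.

Operations: merging tissue columns into organ categories, the inclusive
2-fold "highly expressed" rule, per-category flagged fractions, a one-sided
brain-vs-other rank-sum test, mouse-model phenotype fold enrichment, and the
elevation of differential-expression ratios within a gene set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

#: Default tissue -> category mapping: 6 merged organ groups plus 11
#: singleton organs = 17 categories over 28 tissue columns.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "CNS E11.5": "immature brain",
    "CNS E14": "immature brain",
    "CNS E18": "immature brain",
    "cerebellum": "brain",
    "cortex": "brain",
    "frontal lobe": "brain",
    "liver E14": "immature liver",
    "liver E14.5": "immature liver",
    "liver E18": "immature liver",
    "duodenum": "bowel",
    "small intestine": "bowel",
    "large intestine": "bowel",
    "colon": "bowel",
    "spleen": "immune system",
    "thymus": "immune system",
    "genital fat pad": "fat",
    "subcutaneous fat pad": "fat",
    "liver": "liver",
    "heart": "heart",
    "lung": "lung",
    "kidney": "kidney",
    "stomach": "stomach",
    "bladder": "bladder",
    "adrenal gland": "adrenal gland",
    "mammary gland": "mammary gland",
    "ovary": "ovary",
    "testis": "testis",
    "placenta": "placenta",
}

BRAIN_CATEGORIES = frozenset({"immature brain", "brain"})

#: Tissues profiled for wild-vs-inbred differential expression.
DE_TISSUES = ("hypothalamus", "hippocampus", "frontal lobe", "heart", "liver", "lung")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the reporting convention used throughout).

    Uses decimal arithmetic on repr(x) so printed halves like 1.65 round up
    despite binary floating point.
    """
    import decimal

    q = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def merge_categories(
    expr: pd.DataFrame, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Collapse tissue columns into category columns by arithmetic mean.

    Every column of ``expr`` (genes x tissues, RPKM) must be mapped.
    """
    mapping = DEFAULT_CATEGORY_MAP if mapping is None else mapping
    unmapped = [t for t in expr.columns if t not in mapping]
    if unmapped:
        raise KeyError(f"tissues without category mapping: {unmapped}")
    if (expr.to_numpy() < 0).any():
        raise ValueError("RPKM must be non-negative")
    cats = list(dict.fromkeys(mapping[t] for t in expr.columns))
    out = pd.DataFrame(index=expr.index, columns=cats, dtype=float)
    for cat in cats:
        members = [t for t in expr.columns if mapping[t] == cat]
        out[cat] = expr[members].mean(axis=1)
    return out


def flag_highly_expressed(merged: pd.DataFrame) -> pd.DataFrame:
    """flag(g, c) = value >= 2 x mean over the gene's categories (inclusive).

    A gene with all-zero expression receives no flags.
    """
    mean = merged.mean(axis=1)
    flags = merged.ge(2.0 * mean, axis=0)
    flags.loc[mean == 0] = False
    return flags


def category_ratio(flags: pd.DataFrame, gene_set) -> pd.Series:
    """Percent of ``gene_set`` flagged per category, to one decimal."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(flags.index)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)}")
    frac = flags.loc[gene_set].mean(axis=0)
    return frac.map(lambda f: round_half_up(100.0 * f, 1))


def ranksum_brain_vs_other(values: pd.Series | np.ndarray, brain_mask) -> tuple:
    """One-sided Mann-Whitney test that brain tissues exceed the others.

    Returns (U, p) with the tie-corrected normal approximation. All-tied
    input yields (n1*n2/2, 0.5): no evidence either way.
    """
    values = np.asarray(values, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    brain, other = values[brain_mask], values[~brain_mask]
    if len(brain) < 2 or len(other) < 2:
        raise ValueError("need >= 2 values on each side")
    if np.all(values == values[0]):
        return len(brain) * len(other) / 2.0, 0.5
    u, p = stats.mannwhitneyu(brain, other, alternative="greater", method="asymptotic")
    return float(u), float(p)


def phenotype_fold(k: int, m: int, K: float, M: float):
    """Fraction k/m as a percent and its fold enrichment over background K/M.

    Returns (percent, fold), each rounded half-up to one decimal.
    """
    if m == 0:
        raise ValueError("empty model set (m = 0)")
    if not (0 <= k <= m) or not (0 < K <= M):
        raise ValueError("require 0 <= k <= m and 0 < K <= M")
    percent = round_half_up(100.0 * k / m, 1)
    fold = round_half_up((k / m) / (K / M), 1)
    return percent, fold


def de_flags(table: pd.DataFrame) -> pd.Series:
    """Differential-expression flag: padj < 0.05 (strict) and FPKM > 1 (strict)."""
    return (table["padj"] < 0.05) & (table["fpkm"] > 1)


def de_ratio_elevation(de_tables: dict[str, pd.DataFrame], psg_set) -> pd.DataFrame:
    """Per tissue: DE fraction among all genes vs among the gene set.

    Columns: ratio_all, ratio_psg, delta_points (percentage points), fold
    (NaN when ratio_all = 0).
    """
    psg_set = set(psg_set)
    rows = {}
    for tissue, table in de_tables.items():
        flags = de_flags(table)
        in_psg = table["gene"].isin(psg_set)
        if not in_psg.any():
            raise ValueError(f"no gene-set members in table for {tissue!r}")
        ratio_all = float(flags.mean())
        ratio_psg = float(flags[in_psg].mean())
        rows[tissue] = {
            "ratio_all": ratio_all,
            "ratio_psg": ratio_psg,
            "delta_points": 100.0 * (ratio_psg - ratio_all),
            "fold": ratio_psg / ratio_all if ratio_all > 0 else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def common_de_genes(table_a: pd.DataFrame, table_b: pd.DataFrame) -> list[str]:
    """Sorted intersection of the two tables' differentially expressed genes."""
    a = set(table_a.loc[de_flags(table_a), "gene"])
    b = set(table_b.loc[de_flags(table_b), "gene"])
    return sorted(a & b)
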