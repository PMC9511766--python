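"""Candidate-SNP selection rules for mouse-model construction.

Two frequency rules over a wild vs classical-inbred contrast:

* **strict rule** — reference-allele homozygosity absent from every wild
  sample but present in every classical inbred sample; any missing genotype
  in either group makes the site ineligible (conservative).
* **relaxed rule** — the wild reference-allele frequency is strictly below
  ``factor`` (default 0.2) times the inbred reference-allele frequency,
  computed over called allele copies.

Plus allelicity (single/bi/tri) per group: the number of distinct alleles
observed among called genotypes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .variantio import INBRED, MISSING, WILD, GeneModel, GenotypeMatrix


def strict_rule(gm: GenotypeMatrix, site_idx: int, wild: str = WILD, inbred: str = INBRED):
    """(passes, reason). Reference allele is index 0."""
    gw = gm.gt[gm.group_indices(wild), site_idx, :]
    gi = gm.gt[gm.group_indices(inbred), site_idx, :]
    if (gw == MISSING).any() or (gi == MISSING).any():
        return False, "missing"
    wild_homref = np.all(gw == 0, axis=1)
    inbred_homref = np.all(gi == 0, axis=1)
    if wild_homref.any():
        return False, "hom-ref present in wild"
    if not inbred_homref.all():
        return False, "non-hom-ref present in inbred"
    return True, "pass"


def relaxed_rule(f_ref_wild: float, f_ref_inbred: float, factor: float = 0.2) -> bool:
    """Wild reference frequency strictly below factor x inbred reference frequency."""
    for f in (f_ref_wild, f_ref_inbred):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency {f} outside [0, 1]")
    if f_ref_inbred == 0:
        return False
    return f_ref_wild < factor * f_ref_inbred


def allelicity(gm: GenotypeMatrix, site_idx: int, group: str) -> str:
    """'single' / 'bi' / 'tri' by distinct called alleles; None if none called."""
    g = gm.gt[gm.group_indices(group), site_idx, :]
    observed = np.unique(g[g != MISSING])
    if observed.size == 0:
        warnings.warn(f"site {site_idx}: no called genotypes in {group!r}")
        return None
    return {1: "single", 2: "bi"}.get(observed.size, "tri")


def _ref_freq(gm: GenotypeMatrix, site_idx: int, group: str) -> float:
    g = gm.gt[gm.group_indices(group), site_idx, :]
    called = g != MISSING
    n = called.sum()
    return float((g[called] == 0).sum() / n) if n else np.nan


def scan_gene_candidates(
    gm: GenotypeMatrix,
    sites: pd.DataFrame,
    gene: GeneModel,
    factor: float = 0.2,
    wild: str = WILD,
    inbred: str = INBRED,
):
    """Evaluate both rules and allelicity for every site in the gene span.

    Returns (CandidateRecord table, summary dict). The gene span is 0-based
    half-open; VCF positions are 1-based.
    """
    pos0 = sites["pos"].to_numpy() - 1
    in_gene = (
        (sites["chrom"].to_numpy() == gene.chrom)
        & (pos0 >= gene.start)
        & (pos0 < gene.end)
    )
    idx = np.nonzero(in_gene)[0]
    if idx.size == 0:
        warnings.warn(f"gene {gene.gene_id} contains no sites")

    rows = []
    for j in idx:
        fw = _ref_freq(gm, j, wild)
        fi = _ref_freq(gm, j, inbred)
        sp, reason = strict_rule(gm, j, wild, inbred)
        rp = (
            relaxed_rule(fw, fi, factor)
            if np.isfinite(fw) and np.isfinite(fi)
            else False
        )
        rows.append(
            {
                "chrom": sites["chrom"].iloc[j],
                "pos": int(sites["pos"].iloc[j]),
                "ref": sites["ref"].iloc[j],
                "f_ref_wild": fw,
                "f_ref_inbred": fi,
                "strict_pass": sp,
                "strict_reason": reason,
                "relaxed_pass": rp,
                "allelicity_wild": allelicity(gm, j, wild),
                "allelicity_inbred": allelicity(gm, j, inbred),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "f_ref_wild", "f_ref_inbred",
            "strict_pass", "strict_reason", "relaxed_pass",
            "allelicity_wild", "allelicity_inbred",
        ],
    )
    summary = {
        "n_sites": len(table),
        "n_strict": int(table["strict_pass"].sum()) if len(table) else 0,
        "n_relaxed": int(table["relaxed_pass"].sum()) if len(table) else 0,
    }
    for grp in ("wild", "inbred"):
        col = f"allelicity_{grp}"
        counts = table[col].value_counts() if len(table) else {}
        for cls in ("single", "bi", "tri"):
            summary[f"n_{cls}_{grp}"] = int(counts.get(cls, 0))
    return table, summary
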