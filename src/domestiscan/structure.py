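"""Allele-sharing distances and neighbor-joining tree construction.

Used as a sanity check that the inbred panel separates from the wild group
before running the selection scan. The distance between two diploid
genotypes at a site is 1 minus the fraction of alleles shared under the
best pairing (0, 0.5 or 1), averaged over co-called sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .variantio import MISSING, GenotypeMatrix


def pairwise_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric allele-sharing distance matrix over all samples.

    Raises if some pair has no co-called sites (distance undefined).
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    gt = np.sort(gm.gt, axis=2)  # order alleles within genotype
    called = gt[:, :, 0] != MISSING
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            co = called[i] & called[j]
            if not co.any():
                raise ValueError(
                    f"no co-called sites for pair ({gm.samples[i]}, {gm.samples[j]})"
                )
            a, b = gt[i, co], gt[j, co]
            direct = (a[:, 0] == b[:, 0]).astype(np.int8) + (a[:, 1] == b[:, 1])
            crossed = (a[:, 0] == b[:, 1]).astype(np.int8) + (a[:, 1] == b[:, 0])
            shared = np.maximum(direct, crossed) / 2.0
            d[i, j] = d[j, i] = 1.0 - shared.mean()
    return pd.DataFrame(d, index=gm.samples, columns=gm.samples)


def neighbor_joining(dm: pd.DataFrame) -> str:
    """Classical Saitou-Nei neighbor joining; returns Newick with lengths.

    Ties in the Q-matrix are broken by the smallest (i, j) index pair in the
    current (insertion-ordered) node list, so output is deterministic.
    Negative branch lengths are clamped to 0 with a warning.
    """
    names = list(dm.index)
    if len(names) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = np.asarray(dm, dtype=float)
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distance matrix must be symmetric, zero-diagonal, non-negative")

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative branch length clamped to 0")
            return 0.0
        return x

    nodes = [str(n) for n in names]  # Newick fragment per active node
    d = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # argmin: first = smallest (i,j)
        i, j = min(best), max(best)
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - li)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]

    # final 3-node star with closed-form branch lengths
    la = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    lb = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    return f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"


def is_group_monophyletic(newick: str, group_samples: set[str], all_samples: set[str]) -> bool:
    """True if some edge of the (unrooted) tree bipartitions the taxa into
    exactly ``group_samples`` vs the rest."""
    target = frozenset(group_samples)
    rest = frozenset(all_samples) - target
    for clade in _clades(newick):
        if clade == target or clade == rest:
            return True
    return False


def _clades(newick: str):
    """Tip-label sets of every internal node of a Newick string."""
    stack: list[set[str]] = []
    clades: list[frozenset[str]] = []
    label = ""
    current: set[str] = set()
    for ch in newick:
        if ch == "(":
            stack.append(set())
        elif ch in ",)":
            if label:
                name = label.split(":")[0].strip()
                if name:
                    stack[-1].add(name)
                label = ""
            if ch == ")":
                done = stack.pop()
                clades.append(frozenset(done))
                if stack:
                    stack[-1] |= done
        elif ch == ";":
            break
        else:
            label += ch
    return clades
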