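"""Mirrortree coevolution scoring across gene-family distance matrices.

For each pair of families the two matrices are trimmed to the contigs
present in both (one representative sequence per contig), the strict upper
triangles are vectorised in a common contig order, and the vectors are
compared with Pearson correlation.  Pairs sharing fewer than five contigs
are discarded to avoid small-sample artefacts.  Summaries report the
all-pairs coefficient matrix, per-family mean coefficients, the histogram
of the coefficient distribution (a two-peak shape indicates a coevolving
core plus independently evolving accessory genes), and a one-tailed
Mann-Whitney U test of whether a focal functional category has higher
per-family means than the rest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .records import GAP, DistanceMatrix, MultipleAlignment, split_orf_id

#: Saturation cap for the Poisson-corrected distance.
D_MAX = 10.0

_P_LIMIT = 19.0 / 20.0


def distances_from_alignment(
    alignment: MultipleAlignment, d_max: float = D_MAX
) -> DistanceMatrix:
    """Poisson-corrected pairwise distances from an (indel-free) alignment.

    For each pair, ``p`` is the differing fraction over columns where
    neither row has a gap and ``d = -(19/20) ln(1 - (20/19) p)`` — the
    maximum-likelihood distance under the 20-state equal-rates model.
    Saturated pairs (``p >= 19/20``) are capped at ``d_max`` with a warning.
    """
    if len(alignment) < 2:
        raise DataError("need at least 2 rows to compute distances")
    arr = alignment.to_array()
    gaps = arr == GAP
    n = len(alignment)
    values = np.zeros((n, n))
    capped = 0
    ids = alignment.orf_ids()
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            m = int(ok.sum())
            if m == 0:
                raise DataError(
                    f"no shared ungapped columns between {ids[i]} and {ids[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).mean())
            if p >= _P_LIMIT:
                d = d_max
                capped += 1
            else:
                d = -_P_LIMIT * math.log(1.0 - p / _P_LIMIT)
            values[i, j] = values[j, i] = d
    if capped:
        warnings.warn(f"{capped} saturated pair(s) capped at d={d_max}")
    return DistanceMatrix(ids, alignment.contig_ids(), values)


@dataclass(frozen=True)
class PairCoevolution:
    cluster_a: str
    cluster_b: str
    n_shared: int
    r: float
    p_value: float
    status: str  # "ok" | "discarded" | "undefined"


def _orf_sort_key(orf_id: str):
    try:
        contig, idx = split_orf_id(orf_id)
        return (contig, idx)
    except DataError:
        return (orf_id, 0)


def _representatives(dm: DistanceMatrix, shared: list[str]) -> dict[str, int]:
    """Pick one row per shared contig: the copy with the smallest mean
    distance to all rows of the *other* shared contigs; ties broken by
    gene-order position."""
    idx_by_contig: dict[str, list[int]] = {}
    for i, c in enumerate(dm.contig_ids):
        if c in shared:
            idx_by_contig.setdefault(c, []).append(i)
    reps: dict[str, int] = {}
    for contig, idxs in idx_by_contig.items():
        if len(idxs) == 1:
            reps[contig] = idxs[0]
            continue
        others = [
            i for c2, lst in idx_by_contig.items() if c2 != contig for i in lst
        ]
        best = min(
            idxs,
            key=lambda i: (
                float(dm.values[i, others].mean()) if others else 0.0,
                _orf_sort_key(dm.orf_ids[i]),
            ),
        )
        reps[contig] = best
    return reps


def mirrortree_pair(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    min_shared: int = 5,
    cluster_a: str = "A",
    cluster_b: str = "B",
) -> PairCoevolution:
    """Mirrortree comparison of two family distance matrices.

    Rows/columns are trimmed to contigs present in both matrices (one
    representative per contig), the strict upper triangles are vectorised
    in a shared contig order and compared with Pearson correlation
    (two-sided t-based p).  Fewer than ``min_shared`` shared contigs gives
    a ``discarded`` result; zero variance gives ``undefined``.
    """
    shared = sorted(set(dm_a.contig_ids) & set(dm_b.contig_ids))
    if len(shared) < min_shared:
        return PairCoevolution(
            cluster_a, cluster_b, len(shared), float("nan"), float("nan"), "discarded"
        )
    reps_a = _representatives(dm_a, shared)
    reps_b = _representatives(dm_b, shared)
    ia = [reps_a[c] for c in shared]
    ib = [reps_b[c] for c in shared]
    sub_a = dm_a.values[np.ix_(ia, ia)]
    sub_b = dm_b.values[np.ix_(ib, ib)]
    iu = np.triu_indices(len(shared), k=1)
    va, vb = sub_a[iu], sub_b[iu]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return PairCoevolution(
            cluster_a, cluster_b, len(shared), float("nan"), float("nan"), "undefined"
        )
    r, p = stats.pearsonr(va, vb)
    return PairCoevolution(cluster_a, cluster_b, len(shared), float(r), float(p), "ok")


HISTOGRAM_EDGES = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.05), 10)


@dataclass
class CoevolutionSummary:
    pairs: list[PairCoevolution]
    r_matrix: pd.DataFrame                 # symmetric, NaN where discarded/undefined
    per_cluster_mean: dict[str, float]     # mean over non-missing partners
    histogram: np.ndarray                  # counts per 0.05 bin over [-1, 1]
    range_counts: dict[tuple[float, float], int]
    category_means: dict[str, float]       # mean of per-cluster means per category
    n_reported: int = 0
    n_discarded: int = 0
    n_undefined: int = 0
    categories: dict[str, str] = field(default_factory=dict)


def all_pairs_summary(
    dms: dict[str, DistanceMatrix],
    categories: dict[str, str] | None = None,
    min_shared: int = 5,
    ranges: tuple[tuple[float, float], ...] = ((0.7, 1.0), (-0.1, 0.4)),
) -> CoevolutionSummary:
    """Mirrortree over every unordered family pair, with distribution summaries."""
    if len(dms) < 2:
        raise ConfigError("need at least 2 distance matrices")
    ids = sorted(dms)
    categories = categories or {}
    r_matrix = pd.DataFrame(np.nan, index=ids, columns=ids)
    np.fill_diagonal(r_matrix.values, 1.0)
    pairs: list[PairCoevolution] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pc = mirrortree_pair(
                dms[a], dms[b], min_shared=min_shared, cluster_a=a, cluster_b=b
            )
            pairs.append(pc)
            if pc.status == "ok":
                r_matrix.loc[a, b] = r_matrix.loc[b, a] = pc.r
    rs = np.array([p.r for p in pairs if p.status == "ok"])
    hist, _ = np.histogram(rs, bins=HISTOGRAM_EDGES) if rs.size else (
        np.zeros(len(HISTOGRAM_EDGES) - 1, dtype=int),
        HISTOGRAM_EDGES,
    )
    range_counts = {
        (lo, hi): int(((rs >= lo) & (rs <= hi)).sum()) for lo, hi in ranges
    }
    per_cluster_mean: dict[str, float] = {}
    for a in ids:
        vals = [
            p.r
            for p in pairs
            if p.status == "ok" and a in (p.cluster_a, p.cluster_b)
        ]
        per_cluster_mean[a] = float(np.mean(vals)) if vals else float("nan")
    category_means: dict[str, float] = {}
    if categories:
        by_cat: dict[str, list[float]] = {}
        for cid, mean_r in per_cluster_mean.items():
            if not math.isnan(mean_r):
                by_cat.setdefault(categories.get(cid, "Uncharacterized"), []).append(
                    mean_r
                )
        category_means = {c: float(np.mean(v)) for c, v in sorted(by_cat.items())}
    return CoevolutionSummary(
        pairs=pairs,
        r_matrix=r_matrix,
        per_cluster_mean=per_cluster_mean,
        histogram=hist,
        range_counts=range_counts,
        category_means=category_means,
        n_reported=sum(p.status == "ok" for p in pairs),
        n_discarded=sum(p.status == "discarded" for p in pairs),
        n_undefined=sum(p.status == "undefined" for p in pairs),
        categories=dict(categories),
    )


def category_test(
    per_cluster_means: dict[str, float],
    categories: dict[str, str],
    focal: str,
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U: is the focal category's mean-r distribution
    stochastically greater than the rest?

    Exact p by enumeration when the smaller group has <= 8 values and there
    are no ties; tie-corrected normal approximation otherwise.
    """
    x = [
        v
        for cid, v in sorted(per_cluster_means.items())
        if categories.get(cid) == focal and not math.isnan(v)
    ]
    y = [
        v
        for cid, v in sorted(per_cluster_means.items())
        if categories.get(cid) != focal and not math.isnan(v)
    ]
    if not x or not y:
        raise ConfigError("both the focal group and its complement must be nonempty")
    if len(set(x + y)) == 1:
        # every value tied: no evidence either way
        return float(len(x) * len(y) / 2), 0.5
    no_ties = len(set(x + y)) == len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(u), float(p)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as a Newick string.

    Labels are sorted before agglomeration so ties resolve deterministically;
    negative branch lengths are clamped to zero with a warning.
    """
    import skbio
    from skbio.tree import nj

    if len(dm) < 3:
        raise ConfigError("neighbor joining needs at least 3 taxa")
    order = sorted(range(len(dm)), key=lambda i: dm.orf_ids[i])
    ids = [dm.orf_ids[i] for i in order]
    values = dm.values[np.ix_(order, order)]
    tree = nj(skbio.DistanceMatrix(values, ids=ids))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"{clamped} negative branch length(s) clamped to 0")
    return str(tree).strip()
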