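"""Per-cluster sequence conservation as average Shannon information content.

The information content of an alignment column is ``log2(20) - H`` bits,
where ``H`` is the Shannon entropy of the residue frequencies computed
over non-gap symbols.  A fully conserved column therefore scores
``log2(20) = 4.3219...`` bits and a column uniform over the 20 residues
scores 0.  Gaps carry no information: they are excluded from the
frequencies, and all-gap columns are excluded from the alignment average.

Conservation is then related to cluster ubiquity by the Pearson
correlation between ``log10(number of member sequences)`` and the mean
information content, computed per functional category and overall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError
from .records import GAP, MultipleAlignment, _AA_SET

LOG2_20 = math.log2(20)

#: Sentinel for undefined quantities (all-gap column, zero-variance correlation).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConservationRecord:
    cluster_id: str
    n_sequences: int
    mean_information: float
    category: str


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    r: float
    p_value: float
    n: int


def column_information(column: list[str]) -> float:
    """Shannon information content of one alignment column, in bits.

    Returns NaN for an all-gap column (excluded from averaging upstream).
    """
    if not column:
        raise DataError("empty column")
    counts: dict[str, int] = {}
    for sym in column:
        if sym == GAP:
            continue
        if sym not in _AA_SET:
            raise DataError(f"symbol {sym!r} outside the amino-acid alphabet")
        counts[sym] = counts.get(sym, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return UNDEFINED
    freqs = np.array(list(counts.values()), dtype=float) / total
    entropy = float(-(freqs * np.log2(freqs)).sum())
    return LOG2_20 - entropy


def alignment_information(alignment: MultipleAlignment) -> float:
    """Arithmetic mean of column information over non-all-gap columns."""
    values = [
        column_information(alignment.column(j)) for j in range(alignment.n_columns)
    ]
    defined = [v for v in values if not math.isnan(v)]
    if not defined:
        raise DataError("alignment has no non-all-gap columns")
    return float(np.mean(defined))


def conservation_size_correlation(
    records: list[ConservationRecord],
    group_by: str = "category",
    min_group_size: int = 5,
) -> list[CorrelationResult]:
    """Pearson correlation of mean information vs log10(cluster size).

    ``group_by`` is ``"category"`` (one result per functional category) or
    ``"all"`` (a single pooled result).  Groups smaller than
    ``min_group_size`` records are skipped with a warning — very small
    functional classes cannot support a meaningful fit.  Zero variance in
    either variable yields a NaN sentinel instead of an exception.  The
    p-value is two-sided, from the t distribution with n-2 df.
    """
    if group_by == "all":
        groups = {"all": list(records)}
    elif group_by == "category":
        groups = {}
        for rec in records:
            groups.setdefault(rec.category, []).append(rec)
    else:
        raise DataError(f"unknown grouping {group_by!r}")
    results = []
    for name in sorted(groups):
        recs = groups[name]
        if len(recs) < min_group_size:
            warnings.warn(
                f"category {name!r}: only {len(recs)} clusters, correlation skipped"
            )
            continue
        x = np.log10([r.n_sequences for r in recs])
        y = np.array([r.mean_information for r in recs])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(CorrelationResult(name, UNDEFINED, UNDEFINED, len(recs)))
            continue
        r, p = stats.pearsonr(x, y)
        results.append(CorrelationResult(name, float(r), float(p), len(recs)))
    return results
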