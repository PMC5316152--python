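"""Independent oracles used by the test suite.

These deliberately re-derive results by a different route than the
package (transcript-coordinate brute force, exhaustive permutation
enumeration, textbook formulas) so that agreement is informative.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import norm


def brute_count(bed, model, assay, offset=15, tss_exclusion=50):
    """Per-region weights by looping reads and using transcript coordinates."""
    utr5, cds, utr3 = model.utr5_len, model.cds_len, model.utr3_len
    totals = {"cds": 0, "utr5": 0, "utr3": 0}
    for row in bed.itertuples(index=False):
        if row.chrom != model.chrom or row.strand != model.strand:
            continue
        if row.strand == "+":
            pos = row.start
            if assay == "footprint":
                pos += offset
            t = pos - model.tss
        else:
            pos = row.end - 1
            if assay == "footprint":
                pos -= offset
            t = (model.tss - 1) - pos
        if 0 <= t < utr5:
            totals["utr5"] += row.score
        elif utr5 <= t < utr5 + cds:
            if t >= tss_exclusion:
                totals["cds"] += row.score
        elif utr5 + cds <= t < utr5 + cds + utr3:
            totals["utr3"] += row.score
    return totals["cds"], totals["utr5"], totals["utr3"]


def exact_rank_sum_z(values: np.ndarray, member_mask: np.ndarray) -> float:
    """Normal quantile of the exact permutation mid-p of the rank sum.

    Enumerates every way of choosing the member positions, computes the
    exact distribution of the members' rank sum, and converts the
    observed value's upper-tail mid-p (P[S > s] + P[S = s]/2) to a z via
    the standard normal quantile.  Only feasible for tiny instances.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    n1 = int(member_mask.sum())
    ranks = np.argsort(np.argsort(values)) + 1.0  # no ties expected in callers
    observed = ranks[member_mask].sum()
    sums = [sum(combo) for combo in combinations(ranks, n1)]
    greater = sum(1 for s in sums if s > observed)
    equal = sum(1 for s in sums if math.isclose(s, observed))
    mid_p_upper = (greater + 0.5 * equal) / len(sums)
    return float(norm.ppf(1.0 - mid_p_upper))


def sample_sd(values) -> float:
    """Textbook sample standard deviation (n-1 denominator)."""
    values = list(values)
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))


def pearson_brute(x, y) -> float:
    """Pearson r from the covariance formula, independent of scipy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
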