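"""Signed rank-sum scoring of gene modules.

A module (e.g. the targets of one transcription factor, or one pathway)
is scored by a Wilcoxon-Mann-Whitney comparison of its members' fold
changes against all non-members, reported as the normal-approximation z
with tie-corrected variance and no continuity correction.  The sign is
oriented so that members with systematically larger fold changes give
z > 0 (collective induction) and smaller give z < 0 (repression).  The z
depends on the fold changes only through their ranks, so scoring raw or
log fold changes is equivalent.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ScoringError

DEFAULT_MIN_SIZE = 15


def module_zscore(values: pd.Series, members: Iterable[str]) -> float:
    """Signed WMW z for the member genes of one module.

    ``values`` maps every scored gene to its fold change (any strictly
    monotone transform gives the same z).  Raises :class:`ScoringError`
    when either the member or non-member side is empty.
    """
    member_set = set(members)
    mask = values.index.isin(member_set)
    n1 = int(mask.sum())
    n2 = int(len(values) - n1)
    if n1 == 0 or n2 == 0:
        raise ScoringError(
            f"cannot score: {n1} members and {n2} non-members among scored genes"
        )
    x = values.to_numpy(dtype=float)
    ranks = rankdata(x)
    u_stat = float(ranks[mask].sum()) - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return 0.0
    return (u_stat - mean_u) / math.sqrt(var_u)


def score_all_modules(
    values: pd.Series,
    gene_sets: Mapping[str, set[str]],
    min_size: int = DEFAULT_MIN_SIZE,
    assay: str | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Score every module against the scored-gene universe.

    Memberships outside the universe (genes that failed the read filter)
    are dropped before the ``min_size`` check.  Modules that are too small
    or unscorable are returned in the skip log instead of raising.
    Results are sorted by |z| descending, ties by module_id.
    """
    universe = set(values.index)
    rows = []
    skipped: dict[str, str] = {}
    for module_id in sorted(gene_sets):
        members = gene_sets[module_id] & universe
        if len(members) < min_size:
            skipped[module_id] = f"only {len(members)} scorable members (< {min_size})"
            continue
        try:
            z = module_zscore(values, members)
        except ScoringError as exc:
            skipped[module_id] = str(exc)
            continue
        rows.append(
            {
                "module_id": module_id,
                "assay": assay if assay is not None else "",
                "n_members_scored": len(members),
                "z": z,
                "direction": "up" if z > 0 else "down",
            }
        )
    frame = pd.DataFrame(rows, columns=["module_id", "assay", "n_members_scored", "z", "direction"])
    if len(frame):
        frame = frame.sort_values(
            by=["z", "module_id"], key=lambda s: -s.abs() if s.name == "z" else s
        ).reset_index(drop=True)
    return frame, skipped
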