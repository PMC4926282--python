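"""Temporal response-group classification and heatmap ordering.

Bin abundances are summarized as arithmetic means per experimental
period (I: before the disturbance pulse, II: during, III: after), and
each bin is labelled by how its period means move relative to the
pre-pulse baseline:

* A — up during the pulse only (period II),
* B — up during and after (II and III),
* C — down after only (III),
* D — down during and after (II and III),
* NONE — no change beyond the fold threshold, or a discordant pattern
  the four groups do not cover (flagged for inspection).

Movement is measured on log2 ratios against period I with a pseudocount,
so the rule is scale-invariant. A deterministic average-linkage
clustering on correlation distance provides the row order used for
heatmap-style reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from binflux.abundance import BinAbundanceMatrix, auto_pseudocount
from binflux.io import PERIODS, SchemaError

GROUPS = ("A", "B", "C", "D", "NONE")


@dataclass
class PeriodProfile:
    """Mean abundance of one bin per period within one experimental set."""

    bin_id: str
    experimental_set: str
    m_I: float
    m_II: float
    m_III: float


@dataclass
class GroupAssignment:
    """Response-group label for one (bin, experimental set)."""

    bin_id: str
    experimental_set: str
    group: str
    log2_II_vs_I: float
    log2_III_vs_I: float


def period_means(
    abund: BinAbundanceMatrix, experimental_set: str
) -> list[PeriodProfile]:
    """Arithmetic mean abundance per period over all samples of a set."""
    design = abund.samples
    mask = design["experimental_set"] == experimental_set
    if not mask.any():
        raise SchemaError(f"no samples for experimental set {experimental_set!r}")
    sub = design[mask]
    per_period: dict[str, list[str]] = {}
    for period in PERIODS:
        ids = list(sub.loc[sub["period"] == period, "sample_id"])
        if not ids:
            raise SchemaError(
                f"period {period} has no samples in set {experimental_set!r}"
            )
        per_period[period] = ids
    means = {p: abund.abundance[ids].mean(axis=1) for p, ids in per_period.items()}
    return [
        PeriodProfile(
            bin_id=str(b),
            experimental_set=experimental_set,
            m_I=float(means["I"][b]),
            m_II=float(means["II"][b]),
            m_III=float(means["III"][b]),
        )
        for b in abund.abundance.index
    ]


def classify_bin(
    profile: PeriodProfile, theta: float = 2.0, pseudocount: float = 1e-6
) -> GroupAssignment:
    """Label one period profile with its response group.

    With u2 = log2((m_II+eps)/(m_I+eps)), u3 = log2((m_III+eps)/(m_I+eps))
    and t = log2(theta):

    A: u2 >= t, |u3| < t;  B: u2 >= t, u3 >= t;
    C: |u2| < t, u3 <= -t;  D: u2 <= -t, u3 <= -t;
    otherwise NONE (including discordant patterns, e.g. up in II but
    down in III beyond the threshold).
    """
    if theta <= 1:
        raise ValueError("theta must be > 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    eps = pseudocount
    u2 = float(np.log2((profile.m_II + eps) / (profile.m_I + eps)))
    u3 = float(np.log2((profile.m_III + eps) / (profile.m_I + eps)))
    t = float(np.log2(theta))
    if u2 >= t and u3 >= t:
        group = "B"
    elif u2 >= t and abs(u3) < t:
        group = "A"
    elif u2 <= -t and u3 <= -t:
        group = "D"
    elif abs(u2) < t and u3 <= -t:
        group = "C"
    else:
        group = "NONE"
    return GroupAssignment(
        bin_id=profile.bin_id,
        experimental_set=profile.experimental_set,
        group=group,
        log2_II_vs_I=u2,
        log2_III_vs_I=u3,
    )


def classify_all(
    abund: BinAbundanceMatrix,
    theta: float = 2.0,
    pseudocount: float | None = None,
    experimental_sets: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every bin in every experimental set.

    ``pseudocount=None`` selects the automatic scale-aware value (1% of
    the smallest nonzero abundance). Returns the assignment table
    (bin_id, experimental_set, group, log2_II_vs_I, log2_III_vs_I) and a
    summary with per-group counts plus ``responsive`` — the number of
    distinct bins with a non-NONE label in at least one set.
    """
    if experimental_sets is None:
        experimental_sets = sorted(abund.samples["experimental_set"].unique())
    if pseudocount is None:
        pseudocount = auto_pseudocount(abund.abundance)
    rows = []
    for eset in experimental_sets:
        for profile in period_means(abund, eset):
            a = classify_bin(profile, theta=theta, pseudocount=pseudocount)
            rows.append(
                {
                    "bin_id": a.bin_id,
                    "experimental_set": a.experimental_set,
                    "group": a.group,
                    "log2_II_vs_I": a.log2_II_vs_I,
                    "log2_III_vs_I": a.log2_III_vs_I,
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["bin_id", "experimental_set"], kind="stable"
    ).reset_index(drop=True)
    summary = {g: int((table["group"] == g).sum()) for g in GROUPS}
    responsive = table.loc[table["group"] != "NONE", "bin_id"].nunique()
    summary["responsive"] = int(responsive)
    return table, summary


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed distance 1 - Pearson r between rows.

    Rows with zero variance have undefined correlation; they are placed
    at distance 1 from every other row (neutral).
    """
    n = profiles.shape[0]
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    flat = norms <= 0
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[flat, :] = 1.0
    dist[:, flat] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    iu = np.triu_indices(n, k=1)
    return dist[iu]


def cluster_bins(
    abund: BinAbundanceMatrix,
    subset: list[str] | None = None,
    pseudocount: float | None = None,
) -> tuple[list[str], np.ndarray]:
    """Deterministic average-linkage clustering for heatmap row order.

    Distance is 1 - Pearson correlation between log2(abundance + eps)
    sample profiles. Bins are canonicalized to lexicographic order
    before linkage so the leaf order is independent of input
    permutation; ties in merge height resolve by that canonical order.
    Returns the ordered bin list and the linkage matrix (rows refer to
    the lexicographically sorted bin list).
    """
    bins = sorted(subset) if subset is not None else sorted(abund.abundance.index)
    missing = set(bins) - set(abund.abundance.index)
    if missing:
        raise KeyError(f"unknown bin(s) {sorted(missing)}")
    if len(bins) < 2:
        raise ValueError("clustering needs at least 2 bins")
    if pseudocount is None:
        pseudocount = auto_pseudocount(abund.abundance)
    profiles = np.log2(abund.abundance.loc[bins].to_numpy() + pseudocount)
    condensed = _correlation_distance(profiles)
    linkage = sch.linkage(condensed, method="average")
    order = sch.leaves_list(linkage)
    return [bins[i] for i in order], linkage
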