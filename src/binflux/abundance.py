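"""Scaffold coverage to normalized genome-bin abundance.

The quantification chain is: drop short scaffolds (reads were only
mapped to scaffolds longer than a minimum length), rescale each sample's
depths by aligned-read counts using the least-sequenced sample as the
reference, then aggregate scaffold depths into bin abundances as
length-weighted means (total aligned bases in the bin divided by bin
size). Relative abundance and between-condition log2 fold changes are
derived views of the same matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from binflux.io import CoverageMatrix, SchemaError

logger = logging.getLogger("binflux")


@dataclass
class BinAbundanceMatrix:
    """Normalized, length-weighted bin x sample abundances.

    ``normalization_reference`` records the sample with the fewest
    aligned reads (scaling factor exactly 1); ``None`` until
    :func:`normalize_coverage` has been applied upstream.
    """

    abundance: pd.DataFrame  # index bin_id, columns sample_id
    samples: pd.DataFrame
    normalization_reference: str | None = None
    is_relative: bool = False

    def __post_init__(self) -> None:
        if list(self.abundance.columns) != list(self.samples["sample_id"]):
            raise SchemaError("abundance columns do not match sample list")
        if (self.abundance.to_numpy() < 0).any():
            raise SchemaError("negative bin abundance")

    @property
    def bins(self) -> list[str]:
        return list(self.abundance.index)


def filter_scaffolds(cov: CoverageMatrix, min_length: int = 500) -> CoverageMatrix:
    """Keep scaffolds strictly longer than ``min_length`` bp.

    The inequality is strict: with the default 500, a 500 bp scaffold is
    removed and a 501 bp scaffold kept. Scaffold order is preserved.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    keep = (cov.scaffolds["length_bp"] > min_length).to_numpy()
    if not keep.any():
        raise SchemaError(
            f"length filter (> {min_length} bp) removed every scaffold"
        )
    scaffolds = cov.scaffolds.loc[keep].reset_index(drop=True)
    depth = cov.depth.loc[keep]
    return CoverageMatrix(scaffolds=scaffolds, samples=cov.samples, depth=depth)


def normalize_coverage(cov: CoverageMatrix) -> CoverageMatrix:
    """Rescale depths by aligned reads, lowest-read sample as reference.

    Each sample column s is multiplied by R_min / R_s where R_s is the
    sample's aligned-read count and R_min the minimum across all
    samples; the reference column is left unchanged. Normalization is
    global across every sample of the run, before any subsetting.
    """
    reads = cov.samples.set_index("sample_id")["aligned_reads"].astype(float)
    zero = reads[reads <= 0]
    if len(zero):
        raise SchemaError(f"sample {zero.index[0]!r} has no aligned reads")
    r_min = reads.min()
    factors = r_min / reads.reindex(cov.depth.columns)
    depth = cov.depth * factors
    out = CoverageMatrix(
        scaffolds=cov.scaffolds.reset_index(drop=True),
        samples=cov.samples,
        depth=depth,
    )
    return out


def normalization_reference(samples: pd.DataFrame) -> str:
    """sample_id of the minimum-aligned-reads sample (ties: first in design)."""
    reads = samples["aligned_reads"].to_numpy()
    return str(samples["sample_id"].iloc[int(np.argmin(reads))])


def aggregate_bin_abundance(
    cov: CoverageMatrix, bin_map: Mapping[str, str]
) -> BinAbundanceMatrix:
    """Aggregate scaffold depths into per-bin length-weighted mean depth.

    A(b, s) = sum_i length_i * depth_is / sum_i length_i over scaffolds
    i assigned to bin b — i.e. total aligned bases attributed to the bin
    divided by the bin's total assembled length. Scaffolds without a bin
    assignment are ignored (their count is logged). Expects coverage
    already filtered and normalized.
    """
    assigned = cov.scaffolds["scaffold_id"].map(bin_map)
    n_unassigned = int(assigned.isna().sum())
    if n_unassigned:
        logger.info("%d scaffolds without bin assignment ignored", n_unassigned)
    keep = assigned.notna().to_numpy()
    if not keep.any():
        raise SchemaError("no scaffold has a bin assignment")
    lengths = cov.scaffolds["length_bp"].to_numpy(dtype=float)[keep]
    bins = assigned.to_numpy()[keep]
    depth = cov.depth.to_numpy()[keep, :]

    bin_ids = sorted(set(bins))
    index = {b: i for i, b in enumerate(bin_ids)}
    rows = np.array([index[b] for b in bins])
    weighted = np.zeros((len(bin_ids), depth.shape[1]))
    total_len = np.zeros(len(bin_ids))
    np.add.at(weighted, rows, depth * lengths[:, None])
    np.add.at(total_len, rows, lengths)
    if (total_len <= 0).any():
        bad = bin_ids[int(np.argmin(total_len))]
        raise SchemaError(f"bin {bad!r} has zero total scaffold length")
    abundance = pd.DataFrame(
        weighted / total_len[:, None],
        index=pd.Index(bin_ids, name="bin_id"),
        columns=cov.depth.columns,
    )
    return BinAbundanceMatrix(
        abundance=abundance,
        samples=cov.samples,
        normalization_reference=normalization_reference(cov.samples),
    )


def relative_abundance(abund: BinAbundanceMatrix) -> BinAbundanceMatrix:
    """Column-normalize so each sample's bin abundances sum to 1."""
    sums = abund.abundance.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise SchemaError(f"sample {zero.index[0]!r} has zero total abundance")
    rel = abund.abundance / sums
    return BinAbundanceMatrix(
        abundance=rel,
        samples=abund.samples,
        normalization_reference=abund.normalization_reference,
        is_relative=True,
    )


def auto_pseudocount(abundance: pd.DataFrame) -> float:
    """Scale-aware pseudocount: 1% of the smallest nonzero abundance."""
    vals = abundance.to_numpy()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise SchemaError("abundance matrix is all zeros; no pseudocount scale")
    return float(nonzero.min()) * 0.01


def fold_change(
    abund: BinAbundanceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-bin log2 fold change between two disjoint sample groups.

    log2((mean_a + eps) / (mean_b + eps)) with arithmetic means over the
    samples of each group; ``pseudocount=None`` selects the automatic
    scale-aware value. Swapping the groups negates the result exactly.

    Returns a DataFrame with columns ``bin_id, log2_fold_change, mean_a,
    mean_b, pseudocount_used``.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("both sample groups must be nonempty")
    overlap = set_a & set_b
    if overlap:
        raise ValueError(f"sample groups overlap: {sorted(overlap)}")
    missing = (set_a | set_b) - set(abund.abundance.columns)
    if missing:
        raise KeyError(f"unknown sample(s) {sorted(missing)}")
    if pseudocount is None:
        pseudocount = auto_pseudocount(abund.abundance)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mean_a = abund.abundance[sorted(set_a)].mean(axis=1)
    mean_b = abund.abundance[sorted(set_b)].mean(axis=1)
    # log difference, not log-of-ratio: swapping groups negates exactly
    lfc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    return pd.DataFrame(
        {
            "bin_id": abund.abundance.index,
            "log2_fold_change": lfc.to_numpy(),
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "pseudocount_used": pseudocount,
        }
    ).reset_index(drop=True)
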