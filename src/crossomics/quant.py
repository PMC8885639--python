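"""Label-free quantification of count tables.

Implements the three normalizations used when comparing proteomes and
transcriptomes of production cell lines:

* **NSAF** (normalized spectral abundance factor) for protein spectral
  counts: ``NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)`` per sample, with
  ``L_i`` the protein length in amino acids.  NSAF is a *relative* measure —
  each sample's NSAF vector sums to one over the identified proteome.
* **FPKM** (fragments per kilobase of exon model per million mapped
  fragments) for RNA-seq fragment counts:
  ``FPKM_i = fragments_i * 1e9 / (total_mapped * L_i)`` with ``L_i`` the gene
  length in nucleotides.
* **Median-of-ratios size factors** for count normalization across
  sequencing libraries: each sample's factor is the median, over genes with a
  nonzero count in every sample, of the ratio of that sample's count to the
  gene's geometric mean across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "AbundanceTable",
    "compute_nsaf",
    "compute_fpkm",
    "size_factors",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CountTable:
    """A features × samples table of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by feature identifier (protein group or gene),
        one column per sample.  Values are spectral counts for proteomics
        or fragment counts for RNA-seq.
    lengths
        Feature lengths aligned to ``counts.index``: amino acids for
        proteins, nucleotides for genes.  Must be strictly positive.
    """

    counts: pd.DataFrame
    lengths: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate feature identifier {dup!r}")
        lengths = self.lengths.reindex(self.counts.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValidationError(f"no length for feature {missing!r}")
        bad = lengths <= 0
        if bad.any():
            feat = lengths.index[bad][0]
            raise ValidationError(
                f"feature {feat!r} has non-positive length {lengths[feat]}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "lengths", lengths.astype(float))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class AbundanceTable:
    """A features × samples table of non-negative abundances.

    ``measure`` tags the normalization that produced the values:
    ``"NSAF"``, ``"FPKM"`` or ``"size_factor_normalized"``.
    """

    values: pd.DataFrame
    measure: str

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("abundances must be non-negative")

    def sample(self, name: str) -> pd.Series:
        return self.values[name]


def compute_nsaf(table: CountTable) -> AbundanceTable:
    """Compute per-sample NSAF from spectral counts and protein lengths.

    Each sample's spectral abundance factors ``SAF_i = SpC_i / L_i`` are
    normalized to sum to one over all proteins present in the table (the
    identified proteome), so NSAF is invariant to per-sample scaling of the
    raw counts.

    Raises
    ------
    ValidationError
        If a sample has no nonzero spectral count (NSAF undefined) or a
        length is non-positive.
    """
    saf = table.counts.div(table.lengths, axis=0)
    totals = saf.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        sample = totals.index[zero][0]
        raise ValidationError(
            f"sample {sample!r} has no nonzero count; NSAF is undefined"
        )
    return AbundanceTable(values=saf.div(totals, axis=1), measure="NSAF")


def compute_fpkm(
    table: CountTable, total_mapped: int | Mapping[str, int] | pd.Series
) -> AbundanceTable:
    """Compute FPKM from fragment counts and gene lengths.

    Parameters
    ----------
    table
        Fragment counts with gene lengths in nucleotides.
    total_mapped
        Total mapped fragments per sample (library size).  A scalar applies
        to every sample.  By convention FPKM uses the library total, not the
        column sum of the (possibly filtered) table, so it is passed in
        explicitly.
    """
    if np.isscalar(total_mapped):
        totals = pd.Series(float(total_mapped), index=table.counts.columns)
    else:
        totals = pd.Series(total_mapped, dtype=float).reindex(table.counts.columns)
        if totals.isna().any():
            missing = totals.index[totals.isna()][0]
            raise ValidationError(f"no total_mapped for sample {missing!r}")
    if (totals <= 0).any():
        sample = totals.index[totals <= 0][0]
        raise ValidationError(f"total_mapped must be positive (sample {sample!r})")
    per_kb = table.counts.div(table.lengths / 1e3, axis=0)
    fpkm = per_kb.div(totals / 1e6, axis=1)
    return AbundanceTable(values=fpkm, measure="FPKM")


def size_factors(table: CountTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for a count matrix.

    The reference for each gene is its geometric mean across samples,
    computed in log space over genes whose counts are positive in every
    sample; a sample's factor is the median ratio of its counts to that
    reference.  Dividing each column by its factor equalizes the median
    count ratios between samples.

    Raises
    ------
    ValidationError
        If no gene has a nonzero count in every sample.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene has nonzero counts in every sample; "
            "filter low-coverage samples or genes before normalizing"
        )
    log_counts = np.log(arr[all_pos])
    log_ref = log_counts.mean(axis=1, keepdims=True)  # geometric mean, log space
    factors = np.exp(np.median(log_counts - log_ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")
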