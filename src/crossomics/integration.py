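"""Cross-layer and cross-species integration of detection and abundance.

Covers three steps of the comparative analysis:

* identifier mapping between species/namespaces (many-to-one allowed,
  with an explicit policy for unmapped identifiers);
* detection-overlap accounting between two datasets (genes seen at the
  mRNA level, the protein level, or both);
* differential flagging of per-gene abundance ratios by confidence-interval
  bands and a fold-change cutoff.  Each gene's log2 ratio (with pseudocount)
  is standardized against the bulk of the distribution — robust
  median/1.4826·MAD by default — and flagged when it falls outside the
  two-sided 90% or 95% normal band; a gene is fold-change selected when its
  linear ratio (either direction) reaches the threshold, 1.8-fold by
  default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .quant import AbundanceTable

__all__ = [
    "DetectionProfile",
    "OverlapResult",
    "MappingReport",
    "detect_from_abundance",
    "map_identifiers",
    "overlap",
    "compare_abundance",
]


@dataclass(frozen=True)
class DetectionProfile:
    """The set of gene identifiers detected in one dataset.

    ``label`` names the dataset (cell line × growth phase × omics layer);
    ``namespace`` guards against comparing profiles in different identifier
    spaces.
    """

    label: str
    genes: frozenset = field(default_factory=frozenset)
    namespace: str = "gene_symbol"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def detect_from_abundance(
    table: AbundanceTable | pd.DataFrame,
    sample: str,
    label: str | None = None,
    threshold: float = 0.0,
    namespace: str = "gene_symbol",
) -> DetectionProfile:
    """Detection profile of features whose abundance exceeds ``threshold``.

    The default threshold 0 implements "identified" as any positive signal
    (FPKM > 0 at the mRNA level, at least one spectral count at the protein
    level); both layers accept a stricter cutoff.
    """
    values = table.values if isinstance(table, AbundanceTable) else table
    col = values[sample]
    genes = frozenset(col.index[col > threshold].astype(str))
    return DetectionProfile(label or sample, genes, namespace)


class MappingReport(NamedTuple):
    profile: DetectionProfile
    unmapped_count: int


def map_identifiers(
    profile: DetectionProfile,
    mapping: Mapping[str, str],
    policy: str = "drop_unmapped",
    target_namespace: str | None = None,
) -> MappingReport:
    """Translate a detection profile into a target identifier namespace.

    Many-to-one mappings collapse to a single target entry.  ``policy``
    is ``"drop_unmapped"`` (unmapped identifiers are removed and counted)
    or ``"keep_unmapped"`` (kept untranslated).
    """
    if policy not in ("drop_unmapped", "keep_unmapped"):
        raise ValueError(f"unknown mapping policy {policy!r}")
    if not mapping:
        raise ValueError("empty identifier map")
    mapped = {mapping[g] for g in profile.genes if g in mapping}
    unmapped = {g for g in profile.genes if g not in mapping}
    if policy == "keep_unmapped":
        mapped |= unmapped
    out = replace(
        profile,
        genes=frozenset(mapped),
        namespace=target_namespace or profile.namespace,
    )
    return MappingReport(out, len(unmapped))


class OverlapResult(NamedTuple):
    only_a: frozenset
    both: frozenset
    only_b: frozenset

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.only_a), len(self.both), len(self.only_b))


def overlap(a: DetectionProfile, b: DetectionProfile) -> OverlapResult:
    """Partition two detection profiles into (only A, both, only B)."""
    if a.namespace != b.namespace:
        raise ValueError(
            f"namespace mismatch: {a.namespace!r} vs {b.namespace!r}"
        )
    return OverlapResult(
        frozenset(a.genes - b.genes),
        frozenset(a.genes & b.genes),
        frozenset(b.genes - a.genes),
    )


_ESTIMATORS = ("robust", "mean_sd")


def compare_abundance(
    a: pd.Series,
    b: pd.Series,
    ci_levels: Iterable[float] = (0.90, 0.95),
    fc_threshold: float = 1.8,
    pseudocount: float | None = None,
    estimator: str = "robust",
) -> pd.DataFrame:
    """Flag differential genes between two abundance vectors.

    Parameters
    ----------
    a, b
        Per-gene abundances (e.g. NSAF or FPKM) indexed by gene identifier;
        only shared genes are compared.
    ci_levels
        Two-sided confidence levels for the outlier bands.
    fc_threshold
        Linear fold-change cutoff (> 1); a gene is selected when
        ``max(r, 1/r) >= fc_threshold`` on the pseudocounted ratio.
    pseudocount
        Added to both abundances before the ratio so detection-limited zeros
        stay finite.  Default: half the smallest nonzero abundance in the
        pair.
    estimator
        ``"robust"`` standardizes log-ratios by median and 1.4826·MAD;
        ``"mean_sd"`` uses mean and standard deviation.

    Returns
    -------
    DataFrame
        Indexed by gene, columns ``abundance_a, abundance_b, log2_ratio, z,
        ci_flag, fc_selected, direction``.  ``ci_flag`` is ``"inside"`` or
        ``"outside_<level>"`` for the highest exceeded level; a degenerate
        spread of zero leaves every gene ``"inside"``.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if estimator not in _ESTIMATORS:
        raise ValueError(f"estimator must be one of {_ESTIMATORS}, got {estimator!r}")
    levels = sorted(float(c) for c in ci_levels)
    if any(not 0 < c < 1 for c in levels):
        raise ValueError("ci_levels must lie in (0, 1)")

    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared features; need at least 3")
    av = a.loc[shared].to_numpy(dtype=float)
    bv = b.loc[shared].to_numpy(dtype=float)
    if (av < 0).any() or (bv < 0).any():
        raise ValueError("abundances must be non-negative")

    if pseudocount is None:
        nz = np.concatenate([av[av > 0], bv[bv > 0]])
        if nz.size == 0:
            raise ValueError("all abundances are zero; cannot form ratios")
        pseudocount = float(nz.min()) / 2.0
    ratio = (av + pseudocount) / (bv + pseudocount)
    log2_ratio = np.log2(ratio)

    if estimator == "robust":
        center = float(np.median(log2_ratio))
        spread = float(stats.median_abs_deviation(log2_ratio, scale="normal"))
    else:
        center = float(np.mean(log2_ratio))
        spread = float(np.std(log2_ratio, ddof=1))

    if spread > 0:
        z = (log2_ratio - center) / spread
        flags = np.full(len(shared), "inside", dtype=object)
        for level in levels:  # ascending: the last exceeded level wins
            crit = stats.norm.ppf(0.5 + level / 2.0)
            flags[np.abs(z) > crit] = f"outside_{round(level * 100)}"
    else:
        z = np.zeros(len(shared))
        flags = np.full(len(shared), "inside", dtype=object)

    fc_selected = np.maximum(ratio, 1.0 / ratio) >= fc_threshold
    direction = np.where(log2_ratio < 0, "down", "up")

    return pd.DataFrame(
        {
            "abundance_a": av,
            "abundance_b": bv,
            "log2_ratio": log2_ratio,
            "z": z,
            "ci_flag": flags,
            "fc_selected": fc_selected,
            "direction": direction,
        },
        index=shared,
    )
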