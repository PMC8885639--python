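"""Exact hypergeometric enrichment and depletion testing of gene sets.

A detection profile (the genes identified in one dataset) is modeled as a
draw of ``n`` genes without replacement from a universe of ``N`` annotated
genes.  For a term annotating ``K`` universe genes of which ``k`` were
detected, the enrichment p-value is the inclusive upper tail
``P(X >= k)`` and the depletion p-value the inclusive lower tail
``P(X <= k)`` of the hypergeometric distribution — the same quantities as
MATLAB's ``hygecdf``/``hygepdf`` conventions.  Tails are accumulated in log
space via log-gamma so universes of tens of thousands of genes do not
overflow.

Multiple testing is controlled by Bonferroni within a family, defined as
the set of terms tested in one namespace for one direction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "HypergeomResult",
    "hypergeom_test",
    "test_collection",
    "shared_terms",
    "significance_matrix",
    "rank_terms",
    "kegg_map_number",
    "bonferroni",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "term_id", "name", "N", "K", "n", "k",
    "p_enrich", "p_deplete", "p_adj_enrich", "p_adj_deplete",
]


class GeneSet(NamedTuple):
    name: str
    genes: frozenset


@dataclass
class GeneSetCollection:
    """Namespace-tagged term → gene-set mapping (KEGG, GO:MF/BP/CC or custom)."""

    namespace: str
    species: str
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, gs in self.sets.items():
            if not gs.genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")
            if any(not g for g in gs.genes):
                raise ValueError(f"term {term_id!r} contains an empty identifier")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def all_genes(self) -> frozenset:
        out: set = set()
        for gs in self.sets.values():
            out |= gs.genes
        return frozenset(out)

    @classmethod
    def from_gmt(
        cls, path: str | Path, namespace: str = "custom", species: str = "NA"
    ) -> "GeneSetCollection":
        """Parse a GMT file (term_id TAB description TAB gene ...)."""
        sets: dict[str, GeneSet] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                term_id, name, genes = parts[0], parts[1], parts[2:]
                sets[term_id] = GeneSet(name, frozenset(g for g in genes if g))
        return cls(namespace=namespace, species=species, sets=sets)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term_id in sorted(self.sets):
                name, genes = self.sets[term_id]
                fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def kegg_map_number(term_id: str) -> str:
    """Species-agnostic KEGG map number: trailing digits of a pathway id.

    ``"cge00561"`` and ``"mmu00561"`` both key to ``"00561"`` so pathways can
    be matched across species.  Non-KEGG ids are returned unchanged.
    """
    m = re.search(r"(\d+)$", term_id)
    return m.group(1) if m else term_id


class HypergeomResult(NamedTuple):
    p_enrich: float
    p_deplete: float
    pmf_at_k: float


def _log_binom(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_test(N: int, K: int, n: int, k: int) -> HypergeomResult:
    """Inclusive hypergeometric tail probabilities.

    Parameters
    ----------
    N : universe size.
    K : term genes in the universe.
    n : detected genes in the universe (the draw).
    k : detected genes in the term (the overlap).

    Returns
    -------
    HypergeomResult
        ``p_enrich = P(X >= k)``, ``p_deplete = P(X <= k)`` and the point
        mass ``P(X = k)``; the identity
        ``p_enrich + p_deplete = 1 + P(X = k)`` holds exactly.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(K, n)
    if not (lo <= k <= hi):
        raise ValueError(
            f"k={k} outside feasible range [{lo}, {hi}] for N={N}, K={K}, n={n}"
        )
    j = np.arange(lo, hi + 1)
    log_pmf = (
        _log_binom(K, j) + _log_binom(N - K, n - j) - _log_binom(N, n)
    )
    pmf_at_k = float(np.exp(log_pmf[k - lo]))
    p_enrich = float(np.exp(logsumexp(log_pmf[j >= k])))
    p_deplete = float(np.exp(logsumexp(log_pmf[j <= k])))
    return HypergeomResult(min(p_enrich, 1.0), min(p_deplete, 1.0), pmf_at_k)


def bonferroni(p, m: int):
    """Bonferroni adjustment: ``min(1, m * p)`` for a family of ``m`` tests."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def test_collection(
    profile,
    collection: GeneSetCollection,
    universe_policy: str = "annotation_universe",
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every term of a collection against one detection profile.

    Parameters
    ----------
    profile
        A :class:`~crossomics.integration.DetectionProfile` (or any object
        with a ``genes`` set attribute).
    collection
        The gene sets to test.
    universe_policy
        ``"annotation_universe"`` (default) uses all genes annotated to at
        least one term of the collection; ``"detected_union"`` uses the
        union of detection across the datasets under comparison, which must
        be supplied via ``universe``; ``"explicit"`` uses ``universe`` as
        given.  The policy choice changes N and n and is recorded by the
        pipeline manifest.

    Returns
    -------
    DataFrame
        One row per term with ``K >= 1`` in the universe, columns
        ``term_id, name, N, K, n, k, p_enrich, p_deplete, p_adj_enrich,
        p_adj_deplete``.  The Bonferroni family size is the number of tested
        terms (enrichment and depletion adjusted as separate families of the
        same size).
    """
    detected = set(profile.genes)
    if not detected:
        raise ValueError(f"detection profile {getattr(profile, 'label', '')!r} is empty")
    if universe_policy == "annotation_universe":
        uni = set(collection.all_genes)
    elif universe_policy in ("detected_union", "explicit"):
        if universe is None:
            raise ValueError(f"universe_policy {universe_policy!r} requires a universe")
        uni = set(universe)
    else:
        raise ValueError(f"unknown universe_policy {universe_policy!r}")
    if not uni:
        raise ValueError("empty universe")

    N = len(uni)
    n = len(detected & uni)
    rows = []
    for term_id in sorted(collection.sets):
        name, genes = collection.sets[term_id]
        term_in_uni = genes & uni
        K = len(term_in_uni)
        if K == 0:
            continue
        k = len(term_in_uni & detected)
        res = hypergeom_test(N, K, n, k)
        rows.append((term_id, name, N, K, n, k, res.p_enrich, res.p_deplete))
    if not rows:
        raise ValueError("no term overlaps the universe")
    records = pd.DataFrame(
        rows, columns=["term_id", "name", "N", "K", "n", "k", "p_enrich", "p_deplete"]
    )
    m = len(records)
    records["p_adj_enrich"] = bonferroni(records["p_enrich"], m)
    records["p_adj_deplete"] = bonferroni(records["p_deplete"], m)
    return records


def shared_terms(
    records_by_dataset: Mapping[str, pd.DataFrame],
    key: Callable[[str], str] = kegg_map_number,
) -> tuple[dict[str, pd.DataFrame], int]:
    """Restrict per-dataset results to terms present in every dataset.

    Terms are matched by a species-agnostic key (by default the trailing
    KEGG map number, so ``cge00561`` in one species pairs with ``mmu00561``
    in another; GO ids map to themselves).  Returns the restricted records
    (with a ``shared_key`` column) and the number of shared terms.
    """
    if len(records_by_dataset) < 2:
        raise ValueError("shared_terms needs at least two datasets")
    keysets = []
    for rec in records_by_dataset.values():
        keysets.append({key(t) for t in rec["term_id"]})
    shared = set.intersection(*keysets)
    if not shared:
        logger.warning("no terms shared across the %d datasets", len(records_by_dataset))
    out: dict[str, pd.DataFrame] = {}
    for label, rec in records_by_dataset.items():
        keyed = rec.assign(shared_key=[key(t) for t in rec["term_id"]])
        out[label] = keyed[keyed["shared_key"].isin(shared)].reset_index(drop=True)
    return out, len(shared)


def significance_matrix(
    records_by_dataset: Mapping[str, pd.DataFrame],
    direction: str = "deplete",
    p_floor: float = 1e-16,
    adjusted: bool = False,
    term_key: str = "term_id",
) -> pd.DataFrame:
    """Heatmap-ready terms × datasets matrix of ``-log10(p)`` values.

    p-values are floored at ``p_floor`` so the matrix is finite; the
    implied ceiling is ``-log10(p_floor)``.  Terms absent from a dataset
    yield NaN cells.
    """
    if direction not in ("enrich", "deplete"):
        raise ValueError(f"direction must be 'enrich' or 'deplete', got {direction!r}")
    if not records_by_dataset:
        raise ValueError("no records")
    col = ("p_adj_" if adjusted else "p_") + direction
    series = {}
    for label, rec in records_by_dataset.items():
        p = np.maximum(rec[col].to_numpy(dtype=float), p_floor)
        series[label] = pd.Series(-np.log10(p), index=rec[term_key].to_numpy())
    return pd.DataFrame(series)


def rank_terms(records: pd.DataFrame, direction: str, top_k: int = 15) -> pd.DataFrame:
    """Top terms by ascending p in one direction.

    Ties at equal p are broken by the larger deviation of the observed
    overlap from its expectation ``|k - n*K/N|``, then lexicographically by
    term id, so the ordering is deterministic.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if direction not in ("enrich", "deplete"):
        raise ValueError(f"direction must be 'enrich' or 'deplete', got {direction!r}")
    dev = (records["k"] - records["n"] * records["K"] / records["N"]).abs()
    ordered = (
        records.assign(_dev=dev)
        .sort_values(
            ["p_" + direction, "_dev", "term_id"], ascending=[True, False, True]
        )
        .drop(columns="_dev")
        .reset_index(drop=True)
    )
    return ordered.head(top_k)
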