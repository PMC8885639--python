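"""Consensus membrane/secreted classification from localization predictors.

Upstream predictors (TMHMM, Phobius, SignalP, TargetP, WoLF PSORT) are run
outside this package; their outputs are normalized into one evidence table
with the schema below and combined by an inclusive union rule:

* membrane  — any of: TMHMM helices >= 1, Phobius helices >= 1,
  WoLF PSORT compartment ``plasma_membrane``;
* secreted  — any of: SignalP signal peptide, TargetP ``S``,
  Phobius signal peptide, WoLF PSORT ``extracellular``.

A protein may be both membrane and secreted.  A stricter consensus is
available through ``min_votes``.  Missing predictor output is recorded as
NA/zero and never counts as a vote.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "EVIDENCE_COLUMNS",
    "classify",
    "catalog_merge",
    "crosscheck_against_rna",
    "term_membership_report",
    "read_evidence",
    "write_calls",
]

EVIDENCE_COLUMNS = [
    "protein_id",
    "tmhmm_tm_count",
    "phobius_tm_count",
    "phobius_sp",
    "signalp_sp",
    "targetp_loc",
    "wolfpsort_loc",
]

TARGETP_VALUES = {"S", "M", "other", "NA"}
WOLFPSORT_VALUES = {"plasma_membrane", "extracellular", "other", "NA"}

# predictor name -> (column, test) per flag; order fixes evidence-list order
_MEMBRANE_RULES = (
    ("TMHMM", "tmhmm_tm_count"),
    ("Phobius-TM", "phobius_tm_count"),
    ("WolfPSort", "wolfpsort_loc"),
)
_SECRETED_RULES = (
    ("SignalP", "signalp_sp"),
    ("TargetP", "targetp_loc"),
    ("Phobius-SP", "phobius_sp"),
    ("WolfPSort", "wolfpsort_loc"),
)


def _validate(evidence: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table missing columns {missing}")
    ev = evidence.copy()
    for i, row in enumerate(ev.itertuples(index=False)):
        if row.tmhmm_tm_count < 0 or row.phobius_tm_count < 0:
            raise ValueError(f"row {i}: negative TM helix count")
        if row.targetp_loc not in TARGETP_VALUES:
            raise ValueError(
                f"row {i}: invalid targetp_loc {row.targetp_loc!r} "
                f"(expected one of {sorted(TARGETP_VALUES)})"
            )
        if row.wolfpsort_loc not in WOLFPSORT_VALUES:
            raise ValueError(
                f"row {i}: invalid wolfpsort_loc {row.wolfpsort_loc!r} "
                f"(expected one of {sorted(WOLFPSORT_VALUES)})"
            )
    return ev


def classify(
    evidence: pd.DataFrame, min_votes: int = 1, tm_threshold: int = 1
) -> pd.DataFrame:
    """Derive membrane/secreted calls from a normalized evidence table.

    Parameters
    ----------
    evidence
        One row per protein with the ``EVIDENCE_COLUMNS`` schema.
    min_votes
        Number of positive predictors required to fire a flag (1 = union
        rule, the default consensus).
    tm_threshold
        Minimum predicted transmembrane helices for a TM predictor to count.

    Returns
    -------
    DataFrame
        Columns ``protein_id, membrane, secreted, membrane_evidence,
        secreted_evidence``; evidence columns are semicolon-joined predictor
        names, deterministic per row and independent of row order.
    """
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    ev = _validate(evidence)

    mem_votes = {
        "TMHMM": ev["tmhmm_tm_count"] >= tm_threshold,
        "Phobius-TM": ev["phobius_tm_count"] >= tm_threshold,
        "WolfPSort": ev["wolfpsort_loc"] == "plasma_membrane",
    }
    sec_votes = {
        "SignalP": ev["signalp_sp"].astype(bool),
        "TargetP": ev["targetp_loc"] == "S",
        "Phobius-SP": ev["phobius_sp"].astype(bool),
        "WolfPSort": ev["wolfpsort_loc"] == "extracellular",
    }

    def tally(votes: dict[str, pd.Series]) -> tuple[pd.Series, list[str]]:
        count = sum(v.astype(int) for v in votes.values())
        names = [
            ";".join(name for name, v in votes.items() if bool(v.iloc[i]))
            for i in range(len(ev))
        ]
        return count >= min_votes, names

    membrane, mem_names = tally(mem_votes)
    secreted, sec_names = tally(sec_votes)
    return pd.DataFrame(
        {
            "protein_id": ev["protein_id"].to_numpy(),
            "membrane": membrane.to_numpy(),
            "secreted": secreted.to_numpy(),
            "membrane_evidence": mem_names,
            "secreted_evidence": sec_names,
        }
    )


class MergeResult(NamedTuple):
    merged: frozenset
    novel_counts: dict  # catalog label -> proteins new relative to earlier catalogs
    order: tuple


def catalog_merge(catalogs: Sequence[tuple[str, Iterable[str]]]) -> MergeResult:
    """Merge protein catalogs from successive enrichment experiments.

    Catalogs are combined in the supplied order (e.g. whole-cell proteome,
    then glycoproteome, biotinylation, ultracentrifugation); each catalog's
    ``novel`` count is the number of proteins absent from every earlier
    catalog, so the novel counts sum to the merged catalog size.
    """
    if not catalogs:
        raise ValueError("no catalogs to merge")
    merged: set = set()
    novel: dict = {}
    order = tuple(label for label, _ in catalogs)
    for label, members in catalogs:
        members = set(members)
        novel[label] = len(members - merged)
        merged |= members
    return MergeResult(frozenset(merged), novel, order)


def crosscheck_against_rna(catalog: Iterable[str], rna_profile) -> frozenset:
    """Proteins in a catalog with no transcript evidence.

    ``rna_profile`` is a DetectionProfile of the RNA-seq layer in the same
    identifier namespace; returns the set difference catalog − RNA.
    """
    catalog = frozenset(catalog)
    return catalog - set(rna_profile.genes)


class TermMembership(NamedTuple):
    found: frozenset
    missing: frozenset

    @property
    def counts(self) -> tuple[int, int]:
        return (len(self.found), len(self.missing))


def term_membership_report(
    catalog: Iterable[str], term_genes: Iterable[str]
) -> TermMembership:
    """Partition a term's genes into those present/absent from a catalog.

    Used to ask, e.g., how many of a secretory-granule gene set were ever
    observed in a merged membrane-enrichment catalog.
    """
    term = frozenset(term_genes)
    if not term:
        raise ValueError("empty term gene list")
    catalog = frozenset(catalog)
    return TermMembership(term & catalog, term - catalog)


def read_evidence(path) -> pd.DataFrame:
    """Read a normalized predictor TSV (booleans encoded as 0/1)."""
    ev = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein_id": str, "targetp_loc": str, "wolfpsort_loc": str},
    )
    for col in ("phobius_sp", "signalp_sp"):
        ev[col] = ev[col].astype(int).astype(bool)
    return _validate(ev)


def write_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out["membrane"] = out["membrane"].astype(int)
    out["secreted"] = out["secreted"].astype(int)
    out.to_csv(path, sep="\t", index=False)
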