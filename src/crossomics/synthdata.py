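"""Synthetic multi-omics data with planted, known ground truth.

The generator emulates the statistical structure the comparative analysis
assumes, without simulating raw spectra or reads:

* a gene universe with term annotations (a GMT-style collection of terms
  drawn uniformly within a size range);
* per-dataset detection: each gene is identified independently with a
  baseline probability, overridden for genes of *planted* terms so that
  depleted (or enriched) terms with a known identity exist for the
  hypergeometric tests to recover;
* log-normal per-gene abundance with planted log2 fold-changes between two
  simulated "cell lines", emitted both as true abundances and as Poisson
  spectral-count / fragment-count tables with expectation proportional to
  abundance × length × depth (so NSAF/FPKM are the natural estimators);
* localization-predictor evidence tables with known membrane/secreted
  labels and an independent per-predictor error rate.

One global seed expands into named independent substreams (universe,
detection, abundance, predictors), so adding or reconfiguring a later stage
never perturbs the draws of an earlier one, and a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .enrichment import GeneSet, GeneSetCollection
from .integration import DetectionProfile
from .localization import EVIDENCE_COLUMNS
from .quant import CountTable
from . import io as cio

__all__ = [
    "SimConfig",
    "SimConfigError",
    "PlantedTerm",
    "GroundTruth",
    "Universe",
    "AbundanceBundle",
    "generate_universe",
    "generate_detection",
    "generate_abundance",
    "generate_predictor_tables",
    "write_dataset",
]

_SUBSTREAMS = {"universe": 0, "detection": 1, "abundance": 2, "predictors": 3}


class SimConfigError(ValueError):
    """A SimConfig field violates its invariants."""


class PlantedTerm(NamedTuple):
    term_index: int
    direction: str  # "depleted" | "enriched"
    detect_prob: float  # overrides baseline for the term's genes


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic world, with defaults a desk-scale study
    would use: a 1,000-gene universe, 50 terms, 80% baseline detection and
    spectral/fragment depths giving tens to hundreds of counts per feature.
    """

    n_genes: int = 1000
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)
    baseline_detect_prob: float = 0.8
    planted_terms: tuple[PlantedTerm, ...] = ()
    n_datasets: int = 4
    abundance_log_mean: float = 1.0   # natural-log scale of the log-normal
    abundance_log_sd: float = 1.0
    condition_log_sd: float = 0.0     # biological noise between conditions
    planted_fc_genes: tuple[tuple[int, float], ...] = ()  # (gene_index, log2 FC)
    protein_length_range: tuple[int, int] = (100, 1000)
    gene_length_range: tuple[int, int] = (300, 3000)
    protein_depth: float = 0.01       # E[SpC] = abundance * aa length * depth
    rna_depth: float = 0.05           # E[fragments] = abundance * nt length * depth
    frac_membrane: float = 0.2
    frac_secreted: float = 0.2
    frac_both: float | None = None    # None -> independent: membrane*secreted
    predictor_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_terms < 0 or self.n_datasets < 1:
            raise SimConfigError("n_genes/n_datasets must be >= 1, n_terms >= 0")
        for name in ("baseline_detect_prob", "frac_membrane", "frac_secreted",
                     "predictor_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        for name in ("term_size_range", "protein_length_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise SimConfigError(f"{name}=({lo}, {hi}) must satisfy 1 <= min <= max")
        if self.term_size_range[1] > self.n_genes:
            raise SimConfigError(
                f"term size up to {self.term_size_range[1]} exceeds n_genes={self.n_genes}"
            )
        if self.abundance_log_sd < 0 or self.condition_log_sd < 0:
            raise SimConfigError("log-scale sd must be non-negative")
        for pt in self.planted_terms:
            pt = PlantedTerm(*pt)
            if not 0 <= pt.term_index < self.n_terms:
                raise SimConfigError(f"planted term index {pt.term_index} out of range")
            if pt.direction not in ("depleted", "enriched"):
                raise SimConfigError(f"planted direction {pt.direction!r} invalid")
            if not 0.0 <= pt.detect_prob <= 1.0:
                raise SimConfigError(f"planted detect_prob {pt.detect_prob} outside [0, 1]")
        for gi, _fc in self.planted_fc_genes:
            if not 0 <= gi < self.n_genes:
                raise SimConfigError(f"planted FC gene index {gi} out of range")
        fb = self.frac_both
        if fb is not None and not (
            0.0 <= fb <= min(self.frac_membrane, self.frac_secreted)
        ):
            raise SimConfigError(
                "frac_both must lie in [0, min(frac_membrane, frac_secreted)]"
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one named stage substream."""
        key = _SUBSTREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(key,))
        )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-term directions, per-gene log2 fold-changes,
    and per-protein membrane/secreted labels."""

    term_direction: dict          # term_id -> "baseline" | "depleted" | "enriched"
    term_detect_prob: dict        # term_id -> detection prob of its genes
    gene_log2_fc: pd.Series       # indexed by gene_id
    membrane: pd.Series           # bool, indexed by gene_id
    secreted: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_log2_fc.index,
                "log2_fc": self.gene_log2_fc.to_numpy(),
                "membrane": self.membrane.to_numpy().astype(int),
                "secreted": self.secreted.to_numpy().astype(int),
            }
        )


@dataclass(frozen=True)
class Universe:
    genes: pd.DataFrame               # gene_id, symbol, protein_length_aa, gene_length_nt
    gene_sets: GeneSetCollection
    truth: GroundTruth
    config: SimConfig

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index


def _term_id(j: int) -> str:
    return f"T{j:03d}"


def generate_universe(config: SimConfig) -> Universe:
    """Draw the gene catalog, the term annotations, and the ground truth."""
    rng = config.rng("universe")
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"SYN{i:05d}" for i in range(n)],
            "protein_length_aa": rng.integers(
                config.protein_length_range[0], config.protein_length_range[1] + 1, n
            ),
            "gene_length_nt": rng.integers(
                config.gene_length_range[0], config.gene_length_range[1] + 1, n
            ),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    lo, hi = config.term_size_range
    sizes = rng.integers(lo, hi + 1, config.n_terms)
    sets: dict[str, GeneSet] = {}
    for j, size in enumerate(sizes):
        members = rng.choice(n, size=int(size), replace=False)
        sets[_term_id(j)] = GeneSet(
            f"synthetic term {j}", frozenset(gene_ids[i] for i in members)
        )
    collection = GeneSetCollection(namespace="custom", species="synthetic", sets=sets)

    term_direction = {tid: "baseline" for tid in sets}
    term_detect_prob = {tid: config.baseline_detect_prob for tid in sets}
    for pt in config.planted_terms:
        pt = PlantedTerm(*pt)
        tid = _term_id(pt.term_index)
        term_direction[tid] = pt.direction
        term_detect_prob[tid] = pt.detect_prob

    log2_fc = pd.Series(0.0, index=genes.index, name="log2_fc")
    for gi, fc in config.planted_fc_genes:
        log2_fc.iloc[gi] = fc

    # membrane/secreted labels; frac_both defaults to the independence product
    fb = config.frac_both
    if fb is None:
        fb = config.frac_membrane * config.frac_secreted
    p_mem_only = config.frac_membrane - fb
    p_sec_only = config.frac_secreted - fb
    u = rng.random(n)
    both = u < fb
    mem_only = (u >= fb) & (u < fb + p_mem_only)
    sec_only = (u >= fb + p_mem_only) & (u < fb + p_mem_only + p_sec_only)
    membrane = pd.Series(both | mem_only, index=genes.index, name="membrane")
    secreted = pd.Series(both | sec_only, index=genes.index, name="secreted")

    truth = GroundTruth(term_direction, term_detect_prob, log2_fc, membrane, secreted)
    return Universe(genes=genes, gene_sets=collection, truth=truth, config=config)


def _detect_probs(universe: Universe) -> np.ndarray:
    """Per-gene detection probability: baseline, overridden by the lowest-
    indexed planted term containing the gene (plant disjoint terms)."""
    config = universe.config
    probs = np.full(config.n_genes, config.baseline_detect_prob)
    pos = {g: i for i, g in enumerate(universe.gene_ids)}
    assigned = np.zeros(config.n_genes, dtype=bool)
    for pt in sorted(config.planted_terms, key=lambda p: p[0]):
        pt = PlantedTerm(*pt)
        for g in universe.gene_sets.sets[_term_id(pt.term_index)].genes:
            i = pos[g]
            if not assigned[i]:
                probs[i] = pt.detect_prob
                assigned[i] = True
    return probs


def generate_detection(universe: Universe, config: SimConfig | None = None) -> list[DetectionProfile]:
    """Simulate per-dataset detection profiles (independent Bernoulli)."""
    config = config or universe.config
    rng = config.rng("detection")
    probs = _detect_probs(universe)
    ids = np.asarray(universe.gene_ids)
    profiles = []
    for d in range(config.n_datasets):
        hit = rng.random(config.n_genes) < probs
        profiles.append(
            DetectionProfile(
                label=f"dataset{d:02d}",
                genes=frozenset(ids[hit]),
                namespace="gene_id",
            )
        )
    return profiles


@dataclass(frozen=True)
class AbundanceBundle:
    """True abundances and sampled counts for two simulated cell lines."""

    true_abundance: pd.DataFrame      # genes × {A, B}
    spectral_counts: CountTable       # protein layer, samples A and B
    fragment_counts: CountTable       # mRNA layer, samples A and B


def generate_abundance(universe: Universe, config: SimConfig | None = None) -> AbundanceBundle:
    """Log-normal abundance with planted fold-changes, Poisson counts.

    Condition B multiplies the shared base abundance by ``2**log2_fc``;
    with ``condition_log_sd > 0`` each condition additionally receives
    independent log-normal biological noise.  Expected counts are
    abundance × length × depth, drawn Poisson per layer.
    """
    config = config or universe.config
    if config.abundance_log_sd < 0:
        raise SimConfigError("abundance_log_sd must be non-negative")
    rng = config.rng("abundance")
    n = config.n_genes
    base = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, n)
    fc = universe.truth.gene_log2_fc.to_numpy()
    noise_a = noise_b = 1.0
    if config.condition_log_sd > 0:
        noise_a = rng.lognormal(0.0, config.condition_log_sd, n)
        noise_b = rng.lognormal(0.0, config.condition_log_sd, n)
    abund_a = base * noise_a
    abund_b = base * (2.0 ** fc) * noise_b
    true_abund = pd.DataFrame(
        {"A": abund_a, "B": abund_b}, index=universe.gene_ids
    )

    aa_len = universe.genes["protein_length_aa"].to_numpy(dtype=float)
    nt_len = universe.genes["gene_length_nt"].to_numpy(dtype=float)
    spc = pd.DataFrame(
        {
            "A": rng.poisson(abund_a * aa_len * config.protein_depth),
            "B": rng.poisson(abund_b * aa_len * config.protein_depth),
        },
        index=universe.gene_ids,
    )
    frags = pd.DataFrame(
        {
            "A": rng.poisson(abund_a * nt_len * config.rna_depth),
            "B": rng.poisson(abund_b * nt_len * config.rna_depth),
        },
        index=universe.gene_ids,
    )
    return AbundanceBundle(
        true_abundance=true_abund,
        spectral_counts=CountTable(spc, universe.genes["protein_length_aa"]),
        fragment_counts=CountTable(frags, universe.genes["gene_length_nt"]),
    )


def generate_predictor_tables(
    universe: Universe, config: SimConfig | None = None
) -> pd.DataFrame:
    """Simulate the normalized localization-predictor evidence table.

    Each predictor reports independently and errs (misses a true signal or
    fires on a negative) with probability ``predictor_error_rate``.  True
    membrane proteins receive >= 1 TM helix from each non-erring TM
    predictor; true secreted proteins receive positive signal-peptide calls.
    WoLF PSORT emits a single compartment: for proteins that are both
    membrane and secreted it picks one of the two at random.
    """
    config = config or universe.config
    rng = config.rng("predictors")
    n = config.n_genes
    e = config.predictor_error_rate
    mem = universe.truth.membrane.to_numpy()
    sec = universe.truth.secreted.to_numpy()

    def err(size: int) -> np.ndarray:
        return rng.random(size) < e

    helix = lambda size: 1 + rng.poisson(1.0, size)  # >= 1 helices when firing

    tm_fire = np.where(mem, ~err(n), err(n))
    tmhmm = np.where(tm_fire, helix(n), 0)
    ph_fire = np.where(mem, ~err(n), err(n))
    phobius_tm = np.where(ph_fire, helix(n), 0)

    signalp = np.where(sec, ~err(n), err(n))
    phobius_sp = np.where(sec, ~err(n), err(n))
    targetp_fire = np.where(sec, ~err(n), err(n))
    targetp = np.where(targetp_fire, "S", "other")

    # single-compartment predictor: true compartment (one of two if both),
    # "other" on error or for cytosolic proteins
    wants_mem = mem & (~sec | (rng.random(n) < 0.5))
    wants_sec = sec & ~wants_mem
    wp_fire = np.where(mem | sec, ~err(n), err(n))
    wp = np.full(n, "other", dtype=object)
    wp[wp_fire & wants_mem] = "plasma_membrane"
    wp[wp_fire & wants_sec] = "extracellular"
    neg_fire = wp_fire & ~(mem | sec)  # false positives pick a compartment
    wp[neg_fire] = np.where(rng.random(int(neg_fire.sum())) < 0.5,
                            "plasma_membrane", "extracellular")

    return pd.DataFrame(
        {
            "protein_id": np.asarray(universe.gene_ids),
            "tmhmm_tm_count": tmhmm.astype(int),
            "phobius_tm_count": phobius_tm.astype(int),
            "phobius_sp": phobius_sp.astype(bool),
            "signalp_sp": signalp.astype(bool),
            "targetp_loc": targetp,
            "wolfpsort_loc": wp,
        },
        columns=EVIDENCE_COLUMNS,
    )


def scrambled_mapping(universe: Universe, prefix: str = "X") -> pd.DataFrame:
    """Two-column mapping table to an alternate namespace, for exercising
    the identifier mapper (identity is the default across simulated
    species, since symbols are shared)."""
    rng = universe.config.rng("universe")
    perm = rng.permutation(universe.config.n_genes)
    return pd.DataFrame(
        {
            "source_id": np.asarray(universe.gene_ids),
            "target_id": [f"{prefix}{i:05d}" for i in perm],
        }
    )


def write_dataset(
    outdir: str | Path,
    universe: Universe,
    profiles: list[DetectionProfile] | None = None,
    bundle: AbundanceBundle | None = None,
    evidence: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the generated world as the TSV/GMT files the pipeline reads.

    Returns the list of written paths (sorted, for manifests).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def note(p: Path) -> Path:
        written.append(p)
        return p

    cio.write_catalog(universe.genes, note(outdir / "gene_catalog.tsv"))
    universe.gene_sets.to_gmt(note(outdir / "gene_sets.gmt"))
    universe.truth.to_frame().to_csv(
        note(outdir / "ground_truth.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {
            "term_id": sorted(universe.truth.term_direction),
            "direction": [
                universe.truth.term_direction[t]
                for t in sorted(universe.truth.term_direction)
            ],
            "detect_prob": [
                universe.truth.term_detect_prob[t]
                for t in sorted(universe.truth.term_direction)
            ],
        }
    ).to_csv(note(outdir / "ground_truth_terms.tsv"), sep="\t", index=False)

    if profiles is not None:
        for p in profiles:
            cio.write_detection(p.genes, note(outdir / f"detection_{p.label}.tsv"))
    if bundle is not None:
        cio.write_matrix(
            bundle.spectral_counts.counts, note(outdir / "spectral_counts.tsv"),
            index_label="gene_id",
        )
        cio.write_matrix(
            bundle.fragment_counts.counts, note(outdir / "fragment_counts.tsv"),
            index_label="gene_id",
        )
        cio.write_matrix(
            bundle.true_abundance, note(outdir / "true_abundance.tsv"),
            index_label="gene_id",
        )
    if evidence is not None:
        ev = evidence.copy()
        ev["phobius_sp"] = ev["phobius_sp"].astype(int)
        ev["signalp_sp"] = ev["signalp_sp"].astype(int)
        ev.to_csv(note(outdir / "predictor_evidence.tsv"), sep="\t", index=False)
    return written


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["planted_terms"] = [list(PlantedTerm(*p)) for p in config.planted_terms]
    d["planted_fc_genes"] = [list(p) for p in config.planted_fc_genes]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "planted_terms" in d:
        d["planted_terms"] = tuple(PlantedTerm(*p) for p in d["planted_terms"])
    if "planted_fc_genes" in d:
        d["planted_fc_genes"] = tuple(
            (int(g), float(fc)) for g, fc in d["planted_fc_genes"]
        )
    for name in ("term_size_range", "protein_length_range", "gene_length_range"):
        if name in d:
            d[name] = tuple(d[name])
    return SimConfig(**d)
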