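"""End-to-end pipeline: simulate → quantify → integrate → enrich → localize → report.

Every stage writes plain TSV outputs under the run directory; the report
stage writes a machine-readable manifest (tool version, configuration echo
including every default the analysis depends on, SHA-256 checksums of all
inputs and outputs, per-stage row counts, timestamps).  Identical
configuration and inputs produce byte-identical data outputs.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .enrichment import (
    GeneSetCollection,
    rank_terms,
    shared_terms,
    significance_matrix,
    test_collection,
)
from .integration import compare_abundance, detect_from_abundance, overlap
from .localization import classify, catalog_merge, crosscheck_against_rna, write_calls
from .quant import compute_fpkm, compute_nsaf, size_factors
from .synthdata import (
    SimConfig,
    config_from_dict,
    config_to_dict,
    generate_abundance,
    generate_detection,
    generate_predictor_tables,
    generate_universe,
    write_dataset,
)

__all__ = ["RunConfig", "StageFailure", "run_pipeline", "render_heatmap"]

STAGES = ("simulate", "quantify", "integrate", "enrich", "localize", "report")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative run configuration; every analysis default is explicit
    so the manifest records the full decision surface."""

    outdir: Path
    seed: int = 0
    sim: SimConfig | None = None
    inputs: dict = field(default_factory=dict)  # used when not simulating
    stages: Sequence[str] = STAGES
    ci_levels: tuple[float, ...] = (0.90, 0.95)
    fc_threshold: float = 1.8
    estimator: str = "robust"
    pseudocount: float | None = None
    universe_policy: str = "annotation_universe"
    adjusted: bool = True
    p_floor: float = 1e-16
    min_votes: int = 1
    heatmap_direction: str = "deplete"
    top_k: int = 15

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")
        if self.sim is None and "simulate" in self.stages:
            self.sim = SimConfig(seed=self.seed)
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = config_from_dict({**config_to_dict(self.sim), "seed": self.seed})
        for label, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {label!r}: no such file {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "sim" in raw and raw["sim"] is not None and not isinstance(raw["sim"], SimConfig):
            raw["sim"] = config_from_dict(raw["sim"])
        for name in ("ci_levels",):
            if name in raw:
                raw[name] = tuple(raw[name])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(self.outdir)
        d["stages"] = list(self.stages)
        d["ci_levels"] = list(self.ci_levels)
        d["sim"] = config_to_dict(self.sim) if self.sim is not None else None
        return d


def render_heatmap(
    matrix: pd.DataFrame,
    ordering: str = "row_max",
    out_png: str | Path | None = None,
    out_tsv: str | Path | None = None,
    ceiling: float | None = None,
) -> pd.DataFrame:
    """Render a significance matrix as an image with a TSV twin.

    ``ordering`` is ``"row_max"`` (rows sorted by their maximum −log10 p,
    descending, ties by term id), a column name (sort by that dataset), or
    ``"none"``.  The TSV twin holds exactly the plotted values and is the
    testable artifact; cells above ``ceiling`` are clipped in both.
    """
    if matrix.empty:
        raise ValueError("empty significance matrix")
    mat = matrix.copy()
    if ceiling is not None:
        mat = mat.clip(upper=ceiling)
    if ordering == "row_max":
        key = pd.DataFrame({"_max": mat.max(axis=1), "_tid": mat.index})
        mat = mat.loc[key.sort_values(["_max", "_tid"], ascending=[False, True]).index]
    elif ordering in mat.columns:
        mat = mat.sort_values(ordering, ascending=False, kind="mergesort")
    elif ordering != "none":
        raise ValueError(f"unknown ordering {ordering!r}")

    if out_tsv is not None:
        mat.to_csv(out_tsv, sep="\t", index_label="term_id")
    if out_png is not None:
        fig, ax = plt.subplots(
            figsize=(2 + 0.5 * mat.shape[1], 1 + 0.12 * mat.shape[0])
        )
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="-log10 p")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120, metadata={"Software": "crossomics"})
        plt.close(fig)
    return mat


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict
    output_checksums: dict
    stage_rows: dict
    timestamps: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order and write all outputs.

    On a stage error a ``FAILED`` marker naming the stage is written next
    to whatever partial outputs exist, and :class:`StageFailure` is raised.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _dt.datetime.now().isoformat(timespec="seconds")
    stage_rows: dict = {}
    inputs_written: list[Path] = []
    outputs_written: list[Path] = []
    state: dict = {}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            fn()
        except Exception as exc:  # halt, name the stage, keep partial outputs
            (outdir / "FAILED").write_text(f"{name}: {exc}\n", encoding="utf-8")
            raise StageFailure(name, exc) from exc

    def stage_simulate():
        sim = config.sim
        universe = generate_universe(sim)
        profiles = generate_detection(universe)
        bundle = generate_abundance(universe)
        evidence = generate_predictor_tables(universe)
        inputs_written.extend(
            write_dataset(outdir / "inputs", universe, profiles, bundle, evidence)
        )
        state.update(
            universe=universe, profiles=profiles, bundle=bundle, evidence=evidence
        )
        stage_rows["simulate"] = {
            "genes": sim.n_genes,
            "terms": len(universe.gene_sets),
            "datasets": len(profiles),
        }

    def stage_quantify():
        bundle = state["bundle"]
        qdir = outdir / "quant"
        qdir.mkdir(exist_ok=True)
        nsaf = compute_nsaf(bundle.spectral_counts)
        totals = bundle.fragment_counts.counts.sum(axis=0)
        fpkm = compute_fpkm(bundle.fragment_counts, totals)
        sf = size_factors(bundle.fragment_counts)
        cio.write_matrix(nsaf.values, qdir / "nsaf.tsv", index_label="gene_id")
        cio.write_matrix(fpkm.values, qdir / "fpkm.tsv", index_label="gene_id")
        sf.to_frame().to_csv(qdir / "size_factors.tsv", sep="\t", index_label="sample")
        outputs_written.extend(qdir.glob("*.tsv"))
        state.update(nsaf=nsaf, fpkm=fpkm)
        stage_rows["quantify"] = {
            "proteins": nsaf.values.shape[0],
            "genes": fpkm.values.shape[0],
        }

    def stage_integrate():
        idir = outdir / "integrate"
        idir.mkdir(exist_ok=True)
        nsaf, fpkm = state["nsaf"], state["fpkm"]
        layer = {
            "protein": {
                s: detect_from_abundance(nsaf, s, f"protein_{s}", namespace="gene_id")
                for s in ("A", "B")
            },
            "mRNA": {
                s: detect_from_abundance(fpkm, s, f"mRNA_{s}", namespace="gene_id")
                for s in ("A", "B")
            },
        }
        rows = []
        pairs = [
            (layer["mRNA"]["A"], layer["protein"]["A"]),
            (layer["mRNA"]["B"], layer["protein"]["B"]),
            (layer["mRNA"]["A"], layer["mRNA"]["B"]),
            (layer["protein"]["A"], layer["protein"]["B"]),
        ]
        for pa, pb in pairs:
            only_a, both, only_b = overlap(pa, pb).counts
            rows.append((pa.label, pb.label, only_a, both, only_b))
        pd.DataFrame(
            rows, columns=["dataset_a", "dataset_b", "only_a", "both", "only_b"]
        ).to_csv(idir / "overlap_summary.tsv", sep="\t", index=False)

        comparison = compare_abundance(
            nsaf.sample("A"),
            nsaf.sample("B"),
            ci_levels=config.ci_levels,
            fc_threshold=config.fc_threshold,
            pseudocount=config.pseudocount,
            estimator=config.estimator,
        )
        comparison.to_csv(idir / "comparison.tsv", sep="\t", index_label="gene_id")
        outputs_written.extend(idir.glob("*.tsv"))
        state["comparison"] = comparison
        stage_rows["integrate"] = {
            "pairs": len(rows),
            "genes_compared": len(comparison),
            "fc_selected": int(comparison["fc_selected"].sum()),
        }

    def stage_enrich():
        edir = outdir / "enrich"
        edir.mkdir(exist_ok=True)
        collection: GeneSetCollection = state["universe"].gene_sets
        records = {}
        for profile in state["profiles"]:
            rec = test_collection(
                profile, collection, universe_policy=config.universe_policy
            )
            rec.to_csv(edir / f"enrichment_{profile.label}.tsv", sep="\t", index=False)
            records[profile.label] = rec
        shared, n_shared = shared_terms(records)
        for direction in ("enrich", "deplete"):
            ranked = rank_terms(
                records[state["profiles"][0].label], direction, config.top_k
            )
            ranked.to_csv(edir / f"top_{direction}.tsv", sep="\t", index=False)
        matrix = significance_matrix(
            records,
            direction=config.heatmap_direction,
            p_floor=config.p_floor,
            adjusted=config.adjusted,
        )
        render_heatmap(
            matrix,
            ordering="row_max",
            out_png=edir / "significance_heatmap.png",
            out_tsv=edir / "significance_matrix.tsv",
        )
        outputs_written.extend(edir.glob("*.tsv"))
        state.update(records=records, matrix=matrix)
        stage_rows["enrich"] = {
            "datasets": len(records),
            "terms_tested": len(next(iter(records.values()))),
            "shared_terms": n_shared,
        }

    def stage_localize():
        ldir = outdir / "localize"
        ldir.mkdir(exist_ok=True)
        calls = classify(state["evidence"], min_votes=config.min_votes)
        write_calls(calls, ldir / "localization_calls.tsv")
        merged = catalog_merge(
            [(p.label, p.genes) for p in state["profiles"]]
        )
        rna_a = detect_from_abundance(
            state["fpkm"], "A", "mRNA_A", namespace="gene_id"
        )
        membrane_catalog = set(calls.loc[calls["membrane"], "protein_id"])
        no_rna = crosscheck_against_rna(membrane_catalog, rna_a)
        summary = pd.DataFrame(
            {
                "metric": [
                    "proteins_classified",
                    "membrane_calls",
                    "secreted_calls",
                    "both_calls",
                    "merged_catalog_size",
                    "membrane_without_rna",
                ],
                "value": [
                    len(calls),
                    int(calls["membrane"].sum()),
                    int(calls["secreted"].sum()),
                    int((calls["membrane"] & calls["secreted"]).sum()),
                    len(merged.merged),
                    len(no_rna),
                ],
            }
        )
        summary.to_csv(ldir / "localization_summary.tsv", sep="\t", index=False)
        novel = pd.DataFrame(
            {"catalog": list(merged.order),
             "novel": [merged.novel_counts[c] for c in merged.order]}
        )
        novel.to_csv(ldir / "catalog_novel_counts.tsv", sep="\t", index=False)
        outputs_written.extend(ldir.glob("*.tsv"))
        state["calls"] = calls
        stage_rows["localize"] = {
            "proteins": len(calls),
            "membrane": int(calls["membrane"].sum()),
            "secreted": int(calls["secreted"].sum()),
        }

    manifest_path = outdir / "run_manifest.json"

    def stage_report():
        manifest = RunManifest(
            version=__version__,
            config=config.to_dict(),
            input_checksums={
                str(p.relative_to(outdir)): cio.sha256_file(p)
                for p in sorted(inputs_written)
            },
            output_checksums={
                str(p.relative_to(outdir)): cio.sha256_file(p)
                for p in sorted(set(outputs_written))
            },
            stage_rows=stage_rows,
            timestamps={
                "started": t0,
                "finished": _dt.datetime.now().isoformat(timespec="seconds"),
            },
        )
        manifest.write(manifest_path)
        state["manifest"] = manifest

    run_stage("simulate", stage_simulate)
    run_stage("quantify", stage_quantify)
    run_stage("integrate", stage_integrate)
    run_stage("enrich", stage_enrich)
    run_stage("localize", stage_localize)
    run_stage("report", stage_report)
    return state.get("manifest")
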