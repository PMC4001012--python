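"""One-config orchestration of the whole analysis.

Stages: simulate (or load files) -> annotate -> frequencies -> gene
differentiation -> enrichment -> MDS.  Every stage writes its TSV outputs
under the output directory and a manifest records versions, seed,
parameters and input checksums, so an identical config and seed reproduce
an identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation as ann
from . import enrichment as enr
from . import frequencies as frq
from . import genediff as gdf
from . import io as eio
from . import mds as emds
from . import simulate as sim

logger = logging.getLogger(__name__)

# fixed offsets for per-stage sub-seeds, recorded in the manifest
_SEED_OFFSETS = {"simulate": 0, "mds_reference": 1, "mds_runs_base": 2}


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults mirror the analysis constants
    (3000 bp flank, 0.3 divergence threshold, 10% deciles, 113-SNP MDS
    subsets, 10 null runs)."""

    outdir: str = "epidiff_out"
    seed: int = 0
    flank: int = ann.DEFAULT_FLANK
    divergence_threshold: float = 0.3
    decile: float = 0.10
    mds_subset_size: int = 113
    mds_runs: int = 10
    collapse_to_gene: bool = False
    rooted_metric: bool = False
    # file mode
    vcf: str | None = None
    gtf: str | None = None
    genes: str | None = None
    labels: str | None = None
    genotype_format: str = "vcf"
    # simulation mode
    simulation: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence_threshold < 1.0:
            raise PipelineConfigError("divergence_threshold must be in (0, 1)")
        if not 0.0 < self.decile < 1.0:
            raise PipelineConfigError("decile must be in (0, 1)")
        file_mode = self.simulation is None
        if file_mode:
            missing = [
                name for name in ("vcf", "gtf", "genes", "labels")
                if getattr(self, name) is None
            ]
            if missing:
                raise PipelineConfigError(
                    f"file-mode config lacks input paths: {missing}"
                )
            for name in ("vcf", "gtf", "genes", "labels"):
                p = Path(getattr(self, name))
                if not p.exists():
                    raise PipelineConfigError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineConfigError(f"bad config key: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory results plus written paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_file = outdir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("epidiff")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    written: dict[str, str] = {}
    inputs: dict[str, str] = {}
    try:
        stage = "inputs"
        if config.simulation is not None:
            sim_cfg = sim.SimulationConfig(
                **{**config.simulation, "seed": config.simulation.get(
                    "seed", config.seed + _SEED_OFFSETS["simulate"])}
            )
            dataset, transcripts, gene_list, truth = sim.simulate_dataset(sim_cfg)
            paths = sim.write_simulation(outdir / "simulated", dataset,
                                         transcripts, gene_list, truth)
            inputs = {k: str(p) for k, p in paths.items()}
        else:
            dataset = eio.read_genotypes(
                config.vcf, format=config.genotype_format, labels_path=config.labels
            )
            transcripts = eio.read_transcripts(config.gtf)
            gene_list = eio.read_gene_list(config.genes)
            inputs = {k: getattr(config, k) for k in ("vcf", "gtf", "genes", "labels")}

        stage = "annotate"
        annotations = ann.assign_snps(dataset.variants, transcripts, flank=config.flank)
        target_tx = set(gene_list)
        annotations = [
            a for a in annotations
            if a.transcript_id in target_tx or a.gene_id in target_tx
        ]
        eio.write_table(ann.annotations_to_frame(annotations),
                        outdir / "annotations.tsv")
        summary = ann.summarize_by_category(annotations, gene_list)
        eio.write_table(summary.to_frame(), outdir / "category_summary.tsv")
        for cat in ann.CATEGORIES:
            eio.write_bed6(ann.bed6_rows(annotations, dataset.variants, cat),
                           outdir / f"snps_{cat.lower()}.bed")
        written["annotations"] = "annotations.tsv"

        stage = "freqs"
        freqs = frq.compute_frequencies(dataset)
        eio.write_table(freqs.table, outdir / "frequencies.tsv")
        diffs = frq.frequency_differences(freqs)
        eio.write_table(diffs, outdir / "differences.tsv")
        epi_ids = {a.variant_id for a in annotations}
        density = frq.frequency_density(freqs, epi_ids)
        eio.write_table(density, outdir / "density.tsv")

        stage = "genediff"
        profiles = gdf.gene_profiles(annotations, freqs,
                                     collapse_to_gene=config.collapse_to_gene)
        ranked = gdf.rank_genes(
            gdf.diff_records(profiles, rooted=config.rooted_metric),
            decile=config.decile,
        )
        eio.write_table(gdf.records_to_frame(ranked), outdir / "gene_ranking.tsv")

        stage = "enrich"
        results = [enr.divergent_snp_enrichment(
            diffs, epi_ids, threshold=config.divergence_threshold,
            label="all_target_snps")]
        for cat in ann.CATEGORIES:
            ids = {a.variant_id for a in annotations if a.category == cat}
            if ids:
                results.append(enr.divergent_snp_enrichment(
                    diffs, ids, threshold=config.divergence_threshold, label=cat))
        for letter in sorted(set(gene_list.values())):
            tx = {t for t, c in gene_list.items() if c == letter}
            ids = {a.variant_id for a in annotations
                   if a.transcript_id in tx or a.gene_id in tx}
            if len(ids) > 10:  # only categories with more than 10 SNPs
                results.append(enr.divergent_snp_enrichment(
                    diffs, ids, threshold=config.divergence_threshold,
                    label=f"category:{letter}"))
        results.extend(enr.chromosome_enrichment(ranked, which="top"))
        results.extend(enr.chromosome_enrichment(ranked, which="bottom"))
        eio.write_table(enr.results_to_frame(results), outdir / "enrichment.tsv")

        stage = "mds"
        cat1_ids = [a.variant_id for a in annotations if a.category == ann.CAT1]
        if len(cat1_ids) >= config.mds_subset_size:
            rng = np.random.default_rng(config.seed + _SEED_OFFSETS["mds_reference"])
            reference = sorted(
                rng.choice(np.array(cat1_ids), size=config.mds_subset_size,
                           replace=False)
            )
        else:
            logger.warning(
                "only %d CAT1 SNPs (< %d); using all of them as the MDS "
                "reference subset", len(cat1_ids), config.mds_subset_size,
            )
            reference = cat1_ids
        if not reference:
            raise RuntimeError("no CAT1 SNPs available for MDS")
        base = config.seed + _SEED_OFFSETS["mds_runs_base"]
        comparison = emds.random_subset_comparison(
            dataset, reference,
            subset_size=min(config.mds_subset_size, dataset.n_variants),
            runs=config.mds_runs,
            run_seeds=[base + i for i in range(config.mds_runs)],
        )
        ref = comparison["reference"]
        coords = pd.DataFrame({
            "sample_id": ref.sample_ids,
            "population": [dataset.population_of[s] for s in ref.sample_ids],
            "component1": ref.component(0),
            "component2": ref.component(1) if ref.coordinates.shape[1] > 1 else 0.0,
        })
        eio.write_table(coords, outdir / "mds_coordinates.tsv")
        r2 = pd.DataFrame({
            "run": [*range(1, config.mds_runs + 1), "mean", "min",
                    "vs_mean_component"],
            "r2": [*comparison["per_run_r2"], comparison["mean_r2"],
                   comparison["min_r2"], comparison["r2_of_mean_component"]],
        })
        eio.write_table(r2, outdir / "mds_r2.tsv")
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from None
    finally:
        if handler in root.handlers:
            root.removeHandler(handler)
            handler.close()

    manifest = {
        "package": "epidiff",
        "version": __version__,
        "seed": config.seed,
        "seed_offsets": _SEED_OFFSETS,
        "parameters": {
            "flank": config.flank,
            "divergence_threshold": config.divergence_threshold,
            "decile": config.decile,
            "mds_subset_size": config.mds_subset_size,
            "mds_runs": config.mds_runs,
            "collapse_to_gene": config.collapse_to_gene,
            "rooted_metric": config.rooted_metric,
        },
        "simulation": config.simulation,
        "input_checksums": {k: _sha256(Path(p)) for k, p in inputs.items()},
        "outputs": sorted(
            str(p.relative_to(outdir))
            for p in outdir.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "dataset": dataset,
        "annotations": annotations,
        "summary": summary,
        "freqs": freqs,
        "differences": diffs,
        "ranked": ranked,
        "enrichment": results,
        "mds": comparison,
        "manifest": manifest,
        "outdir": outdir,
    }
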