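"""End-to-end driver: rollup -> filter -> ratios -> Znet -> S/N -> FDR -> summaries.

Given a :class:`~ticnet.io.RunConfig` the driver executes the analysis
steps in order, writes one result TSV per comparison plus the FDR curves
and annotation summaries, and finishes with a deterministic JSON manifest
(package version, seed, config hash, per-stage protein counts). Outputs are
byte-identical across runs with the same inputs, config and seed.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from . import diffstats, fdr, io, quantify
from .errors import PipelineError, TicnetError
from .summarize import cog_crosstab, overlap_counts

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("ticnet")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def run_pipeline(config: io.RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of artifacts.

    On any stage failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict[str, Path] = {}
    manifest: dict = {
        "ticnet_version": _package_version(),
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "comparisons": [c.label for c in config.comparisons],
        "counts": {},
    }

    def emit(name: str, path: Path) -> None:
        written.append(path)
        artifacts[name] = path

    stage = "load"
    try:
        if config.peptide_path:
            stage = "rollup"
            peptides = io.read_peptides(config.peptide_path)
            table = quantify.rollup_tic(peptides)
        else:
            table = io.read_tic_table(config.tic_path)
        for comp in config.comparisons:
            table.comparison_samples(comp)  # fail fast on missing samples

        stage = "detection_filter"
        counts = {}
        for state in table.states:
            counts[state] = quantify.detected_per_state(table, state)
            logger.info("proteins observed in both replicates of %s: %d",
                        state, counts[state])
        manifest["counts"]["detected_per_state"] = counts

        stage = "replicate_correlation"
        correlations = {
            state: round(quantify.replicate_correlation(table, state), 6)
            for state in table.states
        }
        manifest["replicate_correlations"] = correlations

        results = []
        for comp in config.comparisons:
            stage = f"ratios[{comp.label}]"
            filtered = quantify.filter_detected(table, comp)
            pops = diffstats.compute_ratio_populations(filtered, comp)
            manifest["counts"][comp.label] = len(pops)

            stage = f"znet[{comp.label}]"
            result = diffstats.merge_znet(pops)
            result = diffstats.classify_tiers(result, config.tier_thresholds)
            result.nd_proteins = quantify.nd_proteins(table, comp)

            stage = f"sn[{comp.label}]"
            scores = fdr.protein_sn(pops)
            result = fdr.apply_sn_filter(result, scores, config.sn_cutoff)

            if config.mc_enabled:
                stage = f"fdr[{comp.label}]"
                grid = np.round(
                    np.arange(0.0, config.mc_grid_max + 1e-9, config.mc_grid_step),
                    10,
                )
                curve = fdr.monte_carlo_fdr(
                    pops, grid=grid, reps=config.mc_reps, seed=config.seed
                )
                emit(f"fdr_curve[{comp.label}]",
                     io.write_fdr_curve(curve, outdir / f"fdr_{comp.label}.tsv"))
                written.append(Path(str(outdir / f"fdr_{comp.label}.tsv")
                                    + ".meta.json"))

            stage = f"write[{comp.label}]"
            emit(f"result[{comp.label}]",
                 io.write_result(result, outdir / f"result_{comp.label}.tsv"))
            results.append(result)

        if config.annotation_path:
            stage = "summaries"
            ann = io.read_annotation(config.annotation_path)
            crosstab = cog_crosstab(results, ann, config.tier_thresholds[1])
            p = outdir / "cog_crosstab.tsv"
            crosstab.to_csv(p, sep="\t")
            emit("cog_crosstab", p)
            if len(results) == 3:
                overlap = overlap_counts(results,
                                         threshold=config.tier_thresholds[1])
                p = outdir / "overlap_summary.tsv"
                overlap.to_csv(p, sep="\t")
                emit("overlap_summary", p)

        stage = "manifest"
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
        emit("manifest", p)
    except TicnetError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return artifacts
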