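"""End-to-end orchestration: count -> score -> call -> overlap/cluster -> enrich.

A single YAML config drives the run; every stage writes TSV/JSON artifacts
into the output directory, and a run manifest records the config snapshot,
input checksums and seed so any output is traceable to its inputs.
Re-running with identical config and inputs reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import clustering, counting, enrich, overlap, scoring

logger = logging.getLogger("barseqfit")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

SCREEN_MANIFEST_COLUMNS = ("screen_id", "compound", "doublings", "control", "treatment")


@dataclass
class PipelineConfig:
    catalog: Path
    sample_sheet: Path
    fastq_dir: Path
    screen_manifest: Path
    output_dir: Path
    gene_sets: Path | None = None
    seed: int = 0
    max_mismatch: int = 1
    tag_combination: str = "sum"
    spacer: str = counting.DEFAULT_SPACER
    barcode_length: int = 20
    read_length: int = counting.DEFAULT_READ_LENGTH
    pseudocount: float = 1.0
    fdr_cutoff: float = scoring.DEFAULT_FDR_CUTOFF
    expressivity_cutoffs: tuple[float, float] = scoring.DEFAULT_EXPRESSIVITY_CUTOFFS
    overlap_universe: int | None = None
    background: int | None = None
    alpha: float = enrich.DEFAULT_ALPHA

    def validate(self) -> None:
        for name in ("catalog", "sample_sheet", "fastq_dir", "screen_manifest"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"config.{name}: {path} does not exist")
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise FileNotFoundError(f"config.gene_sets: {self.gene_sets} does not exist")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in ("catalog", "sample_sheet", "fastq_dir", "screen_manifest", "gene_sets", "output_dir"):
            kwargs[key] = (base / value) if value is not None else None
        elif key == "expressivity_cutoffs":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory.

    A failing stage aborts the run with the stage named; partial outputs
    are retained alongside a FAILED marker file.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    inputs = [config.catalog, config.sample_sheet, config.screen_manifest]
    if config.gene_sets:
        inputs.append(config.gene_sets)
    manifest: dict[str, Any] = {
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in vars(config).items()},
        "seed": config.seed,
        "input_checksums": {str(p): _sha256(Path(p)) for p in inputs},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "count"
    try:
        catalog = counting.BarcodeCatalog.from_tsv(config.catalog)
        sheet = counting.load_sample_sheet(config.sample_sheet)
        layout = counting.ReadLayout(
            spacer=config.spacer,
            barcode_length=config.barcode_length,
            read_length=config.read_length,
        )
        fastqs = sorted(Path(config.fastq_dir).glob("*.fastq")) + sorted(
            Path(config.fastq_dir).glob("*.fastq.gz")
        )
        result = counting.count_barcodes(
            fastqs, catalog, sheet, layout, config.max_mismatch, config.tag_combination
        )
        result.counts.to_csv(out / "counts.tsv", sep="\t", index_label="mutant_id")
        result.file_qc.to_csv(out / "qc_files.tsv", sep="\t")
        result.sample_qc.to_csv(out / "qc_samples.tsv", sep="\t", index_label="sample_id")
        for fname, row in result.file_qc.iterrows():
            logger.info(
                "%s: %d reads, %d assigned, %d unassigned-index, %d unassigned-barcode, %d ambiguous",
                fname, row["total_reads"], row["assigned"], row["unassigned_index"],
                row["unassigned_barcode"], row["ambiguous"],
            )
        manifest["stages"].append(stage)

        stage = "score"
        screens_def = pd.read_csv(config.screen_manifest, sep="\t", dtype={"screen_id": str})
        missing = set(SCREEN_MANIFEST_COLUMNS) - set(screens_def.columns)
        if missing:
            raise ValueError(f"screen manifest missing columns: {sorted(missing)}")
        scores: dict[str, pd.DataFrame] = {}
        for row in screens_def.itertuples(index=False):
            table = scoring.score_screen(
                result.counts,
                control=row.control,
                treatment=row.treatment,
                doublings=float(row.doublings),
                pseudocount=config.pseudocount,
            )
            scores[row.screen_id] = table
            table.to_csv(out / f"scores_{row.screen_id}.tsv", sep="\t", index_label="mutant_id")
        manifest["stages"].append(stage)

        stage = "call"
        hit_lists: dict[str, list[str]] = {}
        for compound, grp in screens_def.groupby("compound"):
            calls = scoring.call_hits(
                {sid: scores[sid] for sid in grp["screen_id"]},
                fdr_cutoff=config.fdr_cutoff,
                expressivity_cutoffs=config.expressivity_cutoffs,
            )
            calls.hits.to_csv(out / f"hits_{compound}.tsv", sep="\t", index_label="mutant_id")
            calls.rescreen_candidates.to_csv(
                out / f"rescreen_{compound}.tsv", sep="\t", index_label="mutant_id"
            )
            hit_lists[compound] = list(calls.hits.index)
        manifest["stages"].append(stage)

        stage = "overlap"
        compounds = sorted(hit_lists)
        universe_n = config.overlap_universe or len(catalog.mutants)
        if len(compounds) >= 2:
            report = {}
            for i, a in enumerate(compounds):
                for b in compounds[i + 1 :]:
                    res = overlap.fisher_overlap(hit_lists[a], hit_lists[b], universe_n)
                    report[f"{a}_vs_{b}"] = {
                        "both": res.both,
                        f"{a}_only": res.a_only,
                        f"{b}_only": res.b_only,
                        "neither": res.neither,
                        "universe": universe_n,
                        "p_value": res.p_value,
                    }
            (out / "overlap.json").write_text(json.dumps(report, indent=2))
        manifest["stages"].append(stage)

        stage = "cluster"
        union_hits = sorted(set().union(*hit_lists.values())) if hit_lists else []
        if len(union_hits) >= 2:
            gi_matrix = pd.DataFrame({sid: scores[sid]["gi"] for sid in scores})
            dendro, ordered = clustering.cluster_gi_profiles(gi_matrix, union_hits)
            (out / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
            ordered.to_csv(out / "gi_matrix_ordered.tsv", sep="\t", index_label="mutant_id")
        manifest["stages"].append(stage)

        stage = "enrich"
        if config.gene_sets is not None:
            collection = enrich.GeneSetCollection.from_gmt(config.gene_sets)
            background = config.background or len(catalog.mutants)
            for compound, hits in hit_lists.items():
                if not hits:
                    continue
                table = enrich.enrich_table(hits, collection, background, config.alpha)
                table.to_csv(out / f"enrichment_{compound}.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:
        failed_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
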