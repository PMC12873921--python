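"""End-to-end orchestration: simulate, demultiplex, extract, collapse, filter, report.

Stages run in the order the wet-lab analysis dictates: demultiplex
pooled reads on the raw orientation, reverse-complement into template
orientation, extract anchored barcodes, collapse Levenshtein-1 error
variants, apply per-class read thresholds, remove template artifacts,
then normalize and summarize.  Every stage boundary is recorded in a run
manifest whose counts must reconcile (no silent read loss), and a fixed
seed makes the whole chain byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import io as mio
from .collapse import (
    FilterPolicy,
    collapse_barcodes,
    filter_counts,
    remove_template_artifacts,
)
from .extract import (
    DEFAULT_TEMPLATE,
    ReadTemplate,
    SampleSheet,
    SequencingRead,
    demultiplex,
    extract_barcode,
    reverse_complement,
    tally_observations,
)
from .simulate import (
    CloneSizeModel,
    LibrarySpec,
    MosaicSimConfig,
    ReadSimConfig,
    simulate_mosaic_fish,
    simulate_reads,
)
from .stats import diversity_metrics, rpm_normalize, unique_barcode_summary


class PipelineError(RuntimeError):
    pass


@dataclass
class StatsOptions:
    n_pairs: int = 20_000
    seed: int = 0
    hindbrain_total: int = 25_000


@dataclass
class SimulationOptions:
    """Simulation block: library/fish model plus per-sample read generation."""

    library_size: int = 1_000_000
    barcode_length: int = 15
    n_fish: int = 12
    n_integrations: int = 1600
    clone_size_model: CloneSizeModel = field(default_factory=CloneSizeModel)
    coverage_per_clone: float = 50.0  # mean reads per founder clone
    substitution_rate: float = 0.002
    insertion_rate: float = 0.0002
    deletion_rate: float = 0.0002


@dataclass
class PipelineConfig:
    """One config object for the whole run; round-trips through YAML."""

    fastq: List[str] = field(default_factory=list)
    sample_sheet: Optional[str] = None
    template: ReadTemplate = DEFAULT_TEMPLATE
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    sample_class: str = "fish"
    stats: StatsOptions = field(default_factory=StatsOptions)
    simulation: Optional[SimulationOptions] = None
    out_dir: str = "mosaicbc_out"
    seed: int = 0
    max_demux_mismatch: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "template" in data and isinstance(data["template"], dict):
            tmpl = dict(data["template"])
            if "conserved_regions" in tmpl:
                tmpl["conserved_regions"] = tuple(tmpl["conserved_regions"])
            data["template"] = ReadTemplate(**tmpl)
        if "policy" in data and isinstance(data["policy"], dict):
            data["policy"] = FilterPolicy(**data["policy"])
        if "stats" in data and isinstance(data["stats"], dict):
            data["stats"] = StatsOptions(**data["stats"])
        if data.get("simulation") is not None and isinstance(data["simulation"], dict):
            sim = dict(data["simulation"])
            if "clone_size_model" in sim and isinstance(sim["clone_size_model"], dict):
                sim["clone_size_model"] = CloneSizeModel(**sim["clone_size_model"])
            data["simulation"] = SimulationOptions(**sim)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)


def _sample_barcodes(n: int) -> List[str]:
    """Well-separated 5-nt multiplex barcodes (pairwise Hamming >= 3)."""
    pool = [
        "ATACC", "GTAGG", "ATTAG", "AGGGC", "GAGTT", "CTTCT", "TTCTT", "CTGTC",
        "AATCA", "CGTTA", "CGGAT", "GGGCA", "TATGC", "CAGCG", "CCCGC", "TCGAA",
    ]
    if n > len(pool):
        raise PipelineError(f"at most {len(pool)} samples supported by the default pool")
    return pool[:n]


def run_simulation(config: PipelineConfig) -> Dict[str, object]:
    """Generate synthetic FASTQ + ground truth consumable by :func:`run_pipeline`.

    Writes pooled FASTQ, per-fish truth TSV, sample sheet TSV and a config
    echo into ``out_dir``; returns a manifest dict.  ``n_fish == 0`` yields
    empty but valid outputs.
    """
    if config.simulation is None:
        raise PipelineError("config has no simulation block")
    sim = config.simulation
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mosaic = MosaicSimConfig(
        library=LibrarySpec(
            n_members=sim.library_size,
            barcode_length=sim.barcode_length,
            seed=config.seed,
        ),
        n_integrations=sim.n_integrations,
        clone_size_model=sim.clone_size_model,
        n_fish=sim.n_fish,
        seed=config.seed + 1,
    )
    fish_truths = simulate_mosaic_fish(mosaic) if sim.n_fish else []
    barcodes5 = _sample_barcodes(sim.n_fish) if sim.n_fish else []
    depth = max(1, int(round(sim.coverage_per_clone * sim.n_integrations)))

    records = []
    for k, truth in enumerate(fish_truths):
        rc = ReadSimConfig(
            template=config.template,
            sample_barcode=barcodes5[k],
            depth=depth,
            substitution_rate=sim.substitution_rate,
            insertion_rate=sim.insertion_rate,
            deletion_rate=sim.deletion_rate,
            seed=config.seed + 100 + k,
        )
        records.extend(simulate_reads(truth, rc))

    fastq_path = out / "reads.fastq"
    n_reads = mio.write_fastq(records, fastq_path)
    mio.write_truth_table(fish_truths, out / "truth.tsv")
    if fish_truths:
        sheet = SampleSheet(
            entries={t.fish_id: b for t, b in zip(fish_truths, barcodes5)},
            max_mismatch=config.max_demux_mismatch,
        )
        mio.write_sample_sheet(sheet, out / "sample_sheet.tsv")
    config.to_yaml(out / "config_echo.yaml")

    manifest = {
        "stage": "simulate",
        "seed": config.seed,
        "n_fish": sim.n_fish,
        "reads_written": n_reads,
        "depth_per_fish": depth if sim.n_fish else 0,
        "fastq": str(fastq_path),
        "truth": str(out / "truth.tsv"),
        "sample_sheet": str(out / "sample_sheet.tsv") if fish_truths else None,
    }
    with open(out / "simulation_manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    return manifest


def process_reads(
    reads: Sequence[SequencingRead],
    sheet: SampleSheet,
    template: ReadTemplate = DEFAULT_TEMPLATE,
    policy: FilterPolicy = FilterPolicy(),
    sample_class: str = "fish",
    apply_filters: bool = True,
) -> Dict[str, object]:
    """In-memory pipeline core: demux -> orient -> extract -> collapse -> filter.

    Returns a dict with the raw, collapsed and filtered count tables, the
    collapse map, the artifact-removal log, and stage-by-stage counts
    satisfying the read-accounting identity (assigned+extracted,
    assigned+unextractable, unassigned partition the input).
    """
    assigned, unassigned = demultiplex(reads, sheet, template)
    observations = []
    n_assigned = sum(len(v) for v in assigned.values())
    n_unextractable = 0
    stage_counts = {"exact": 0, "hamming": 0, "levenshtein": 0}
    for sample_id, sample_reads in assigned.items():
        for read in sample_reads:
            oriented = reverse_complement(read) if template.reverse_complement_reads else read
            obs = extract_barcode(oriented, template, sample_id=sample_id)
            if obs is None:
                n_unextractable += 1
            else:
                observations.append(obs)
                stage_counts[obs.match_stage] += 1

    raw_table = tally_observations(observations)
    if raw_table.empty:
        collapsed, cmap = raw_table, None
        filtered = artifact_filtered = raw_table
        removal_log = pd.DataFrame(columns=["barcode", "region", "distance"])
    else:
        collapsed, cmap = collapse_barcodes(raw_table)
        if apply_filters:
            filtered = filter_counts(collapsed, policy, sample_class)
            artifact_filtered, removal_log = remove_template_artifacts(
                filtered, template, policy.template_artifact_max_dist
            )
        else:
            filtered = artifact_filtered = collapsed
            removal_log = pd.DataFrame(columns=["barcode", "region", "distance"])

    counts = {
        "input_reads": len(reads),
        "unassigned": len(unassigned),
        "assigned": n_assigned,
        "extracted": len(observations),
        "unextractable": n_unextractable,
        "extracted_by_stage": stage_counts,
        "barcodes_pre_collapse": int(raw_table.shape[0]),
        "barcodes_post_collapse": int(collapsed.shape[0]),
        "barcodes_post_filter": int(filtered.shape[0]),
        "barcodes_post_artifact_filter": int(artifact_filtered.shape[0]),
        "artifact_removed": int(len(removal_log)),
    }
    assert counts["assigned"] + counts["unassigned"] == counts["input_reads"]
    assert counts["extracted"] + counts["unextractable"] == counts["assigned"]
    return {
        "raw_table": raw_table,
        "collapsed_table": collapsed,
        "filtered_table": artifact_filtered,
        "collapse_map": cmap,
        "removal_log": removal_log,
        "counts": counts,
    }


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """File-based pipeline: validate, process, write tables, stats and manifest."""
    for path in config.fastq:
        if not Path(path).exists():
            raise PipelineError(f"FASTQ path does not exist: {path}")
    if config.sample_sheet is None or not Path(config.sample_sheet).exists():
        raise PipelineError(f"sample sheet not found: {config.sample_sheet}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = mio.read_sample_sheet(config.sample_sheet, config.max_demux_mismatch)
    reads: List[SequencingRead] = []
    for path in config.fastq:
        reads.extend(mio.read_fastq(path))

    result = process_reads(
        reads, sheet, config.template, config.policy, config.sample_class
    )
    mio.write_count_table(result["raw_table"], out / "counts_raw.tsv")
    mio.write_count_table(result["collapsed_table"], out / "counts_collapsed.tsv")
    mio.write_count_table(result["filtered_table"], out / "counts_filtered.tsv")
    if result["collapse_map"] is not None:
        cmap = result["collapse_map"]
        with open(out / "collapse_map.tsv", "w") as handle:
            handle.write("child\tparent\n")
            for child in sorted(cmap.assignments):
                handle.write(f"{child}\t{cmap.assignments[child]}\n")
    result["removal_log"].to_csv(out / "artifact_removals.tsv", sep="\t", index=False)

    table = result["filtered_table"]
    manifest: Dict[str, object] = {"seed": config.seed, **result["counts"]}
    if not table.empty:
        rpm = rpm_normalize(table)
        rpm.to_csv(out / "abundance_rpm.tsv", sep="\t", index_label="barcode")
        metrics = diversity_metrics(rpm)
        metrics.to_csv(out / "diversity_metrics.tsv", sep="\t")
        summary = unique_barcode_summary(table)
        manifest["unique_barcodes"] = summary
    with open(out / "run_manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
    result["manifest"] = manifest
    return result
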