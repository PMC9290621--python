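"""End-to-end screening workflow: read -> assign -> criteria -> footprint -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .catalog import CoreFamilyCatalog, assign_families, load_default_catalog, read_catalog
from .criteria import HgtParams, evaluate_criteria, flags_from_arts_rows, write_criteria_table
from .footprint import ClassifierConfig, FootprintResult, IvttThresholds, compute_footprint
from .genome_io import read_arts_table, read_bgc_regions, read_genome, write_report

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Bad or missing input; the CLI maps this to exit code 2."""


@dataclass
class RunConfig:
    genome: Optional[Path] = None
    genome_format: str = "genbank"
    fasta: Optional[Path] = None
    regions: Optional[Path] = None
    regions_format: str = "gff3"
    arts_table: Optional[Path] = None
    catalog: Optional[Path] = None
    assignment_mode: str = "symbol"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    hgt: HgtParams = field(default_factory=HgtParams)
    overlap_rule: str = "any-overlap"
    ivtt: IvttThresholds = field(default_factory=IvttThresholds)
    out_dir: Path = Path(".")
    report_format: str = "tsv"
    export_criteria: bool = False
    strain_id: Optional[str] = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load key=value settings from a TOML config file."""
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        cfg = cls()
        for key in ("genome", "regions", "arts_table", "catalog", "fasta", "out_dir"):
            if key in doc:
                setattr(cfg, key, Path(doc[key]))
        for key in ("genome_format", "regions_format", "assignment_mode",
                    "overlap_rule", "report_format", "strain_id"):
            if key in doc:
                setattr(cfg, key, doc[key])
        if "min_hit_genes" in doc or "min_ri_genes" in doc:
            cfg.classifier = ClassifierConfig(
                min_hit_genes=int(doc.get("min_hit_genes", 20)),
                min_ri_genes=int(doc.get("min_ri_genes", 2)),
            )
        if "z_threshold" in doc:
            cfg.hgt = HgtParams(z_threshold=float(doc["z_threshold"]))
        if "ivtt_specific_max" in doc or "ivtt_strong_max" in doc:
            cfg.ivtt = IvttThresholds(
                specific_max=float(doc.get("ivtt_specific_max", 40)),
                strong_max=float(doc.get("ivtt_strong_max", 20)),
            )
        return cfg


def _load_catalog(config: RunConfig) -> CoreFamilyCatalog:
    if config.catalog is None:
        return load_default_catalog()
    if not Path(config.catalog).exists():
        raise InputError(f"catalog file not found: {config.catalog}")
    return read_catalog(config.catalog)


def screen_genome(config: RunConfig) -> FootprintResult:
    """Full per-genome screen; returns the strain's footprint result."""
    if config.genome is None:
        raise InputError("no genome given")
    if not Path(config.genome).exists():
        raise InputError(f"genome file not found: {config.genome}")
    catalog = _load_catalog(config)
    genome = read_genome(
        config.genome,
        format=config.genome_format,
        fasta=config.fasta,
        strain_id=config.strain_id,
    )
    logger.info("%s: %d contigs, %d genes", genome.strain_id, len(genome.contigs), len(genome.genes))
    regions = []
    if config.regions is not None:
        if not Path(config.regions).exists():
            raise InputError(f"regions file not found: {config.regions}")
        regions = read_bgc_regions(config.regions, format=config.regions_format)
        logger.info("%d BGC regions", len(regions))
    assignments = assign_families(genome, catalog, mode=config.assignment_mode)
    logger.info("%d core-gene assignments", len(assignments))
    flags = evaluate_criteria(
        genome, assignments, catalog,
        regions=regions, hgt_params=config.hgt, overlap_rule=config.overlap_rule,
    )
    result = compute_footprint(genome.strain_id, flags, catalog, config.classifier)
    logger.info(
        "%s: %d hit genes, %d RI genes, candidate=%s",
        result.strain_id, result.hit_genes, result.ri_count, result.candidate,
    )
    if config.export_criteria:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        write_criteria_table(flags, config.out_dir / f"{result.strain_id}.criteria.tsv")
    return result


def screen_arts_table(config: RunConfig) -> FootprintResult:
    """Footprint from a precomputed per-family criteria table (compat mode)."""
    if config.arts_table is None or not Path(config.arts_table).exists():
        raise InputError(f"criteria table not found: {config.arts_table}")
    catalog = _load_catalog(config)
    rows = read_arts_table(config.arts_table)
    flags = flags_from_arts_rows(rows)
    strain = config.strain_id or Path(config.arts_table).stem
    return compute_footprint(strain, flags, catalog, config.classifier)


def run_screen(config: RunConfig) -> tuple[int, list[FootprintResult]]:
    """Execute the configured workflow; returns (exit_code, results).

    Exit code 0 on success, 2 on any input error.
    """
    try:
        if config.arts_table is not None:
            results = [screen_arts_table(config)]
        else:
            results = [screen_genome(config)]
        config.out_dir.mkdir(parents=True, exist_ok=True)
        ext = "tsv" if config.report_format == "tsv" else "json"
        write_report(results, config.out_dir / f"footprint_report.{ext}", format=config.report_format)
        return 0, results
    except InputError as exc:
        logger.error("%s", exc)
        return 2, []
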