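"""End-to-end orchestration from a declarative YAML config.

Sequencing data is organised into *groups* (one per organ or condition in a
typical design); each group carries its own assembled transcripts, one or
more sRNA libraries, and optionally degradome libraries, and is processed
independently: preprocess -> conserved scan (if a reference registry is
given) -> discovery -> degradome validation (if degradome data is given)
-> reporting. Absent degradome data degrades gracefully: the candidate
tables are identical, only the validation outputs are missing.

All stage outputs are plain TSV/JSON with deterministic ordering, so two
runs with the same config and inputs produce byte-identical tables. A run
log records the package version, a hash of the resolved config, and every
parameter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .conservation import (
    classify_conservation,
    load_reference_matures,
    reference_stats,
    scan_conserved,
    write_conservation_table,
)
from .degradome import validate_pri, validation_tables
from .discovery import (
    HairpinRules,
    discover,
    load_transcripts,
    map_reads_exact,
)
from .preprocess import (
    load_degradome_library,
    load_srna_library,
    merge_libraries,
    write_expression_table,
)
from .reporting import (
    build_annotation_spec,
    build_coverage_profile,
    build_summary_table,
    render_outputs,
    summary_frame,
)

__all__ = ["PipelineConfig", "GroupSpec", "PipelineResult", "load_config", "run_pipeline"]

logger = logging.getLogger("plantmir")


class ConfigError(ValueError):
    """The configuration is invalid or references missing files."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class GroupSpec:
    label: str
    transcripts: Path
    srna: dict[str, Path]
    degradome: dict[str, Path] = field(default_factory=dict)


@dataclass
class Parameters:
    """Every adjustable knob of the pipeline, with its default."""

    min_len: int = 15
    max_len: int = 40
    tag_len: int = 20
    extension: int = 20
    flank: int = 230
    edge: int = 20
    max_dist: int = 3
    tolerance: int = 0
    min_rpm: float = 0.0
    species_prefix: str = "xxx"
    hairpin: HairpinRules = field(default_factory=HairpinRules)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "hairpin"}
        d["hairpin"] = dict(self.hairpin.__dict__)
        return d


@dataclass
class PipelineConfig:
    groups: list[GroupSpec]
    output_dir: Path
    reference_matures: Path | None = None
    seed: int = 0
    params: Parameters = field(default_factory=Parameters)

    def digest(self) -> str:
        payload = {
            "groups": [
                {
                    "label": g.label,
                    "transcripts": str(g.transcripts),
                    "srna": {k: str(v) for k, v in g.srna.items()},
                    "degradome": {k: str(v) for k, v in g.degradome.items()},
                }
                for g in self.groups
            ],
            "reference_matures": str(self.reference_matures) if self.reference_matures else None,
            "seed": self.seed,
            "params": self.params.as_dict(),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    output_dir: Path
    groups: dict[str, dict[str, pd.DataFrame]]
    merged_summary: pd.DataFrame
    manifest: list[str]


def _as_lib_map(entry, label: str) -> dict[str, Path]:
    if entry is None:
        return {}
    if isinstance(entry, dict):
        return {str(k): Path(v) for k, v in entry.items()}
    if isinstance(entry, list):
        return {Path(p).stem: Path(p) for p in entry}
    raise ConfigError(f"group {label!r}: library entry must be a mapping or list")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config (files must exist)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ConfigError("config must be a mapping with a 'groups' list")

    pdict = dict(raw.get("params") or {})
    hairpin = HairpinRules(**(pdict.pop("hairpin", None) or {}))
    try:
        params = Parameters(hairpin=hairpin, **pdict)
    except TypeError as exc:
        raise ConfigError(f"unknown parameter: {exc}") from exc
    if params.min_len > params.max_len:
        raise ConfigError("min_len must be <= max_len")

    groups = []
    labels = set()
    for g in raw["groups"]:
        label = str(g.get("label", ""))
        if not label or label in labels:
            raise ConfigError("every group needs a unique non-empty label")
        labels.add(label)
        spec = GroupSpec(
            label=label,
            transcripts=Path(g["transcripts"]),
            srna=_as_lib_map(g.get("srna"), label),
            degradome=_as_lib_map(g.get("degradome"), label),
        )
        if not spec.srna:
            raise ConfigError(f"group {label!r} has no sRNA libraries")
        groups.append(spec)

    config = PipelineConfig(
        groups=groups,
        output_dir=Path(raw.get("output_dir", "plantmir_out")),
        reference_matures=Path(raw["reference_matures"]) if raw.get("reference_matures") else None,
        seed=int(raw.get("seed", 0)),
        params=params,
    )
    missing = []
    for g in config.groups:
        for p in [g.transcripts, *g.srna.values(), *g.degradome.values()]:
            if not Path(p).exists():
                missing.append(str(p))
    if config.reference_matures and not config.reference_matures.exists():
        missing.append(str(config.reference_matures))
    if missing:
        raise ConfigError("missing input files: " + ", ".join(sorted(missing)))
    return config


def _format_of(path: Path) -> str:
    return "fastq" if path.suffix.lower().lstrip(".") in ("fastq", "fq") else "fasta"


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(logging.INFO)
    logger.handlers = [logging.StreamHandler(), logging.FileHandler(out_dir / "run.log", mode="w")]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in logger.handlers:
        h.setFormatter(fmt)


def run_group(
    group: GroupSpec,
    params: Parameters,
    out_dir: Path,
    refs=None,
) -> dict[str, pd.DataFrame]:
    """Process one group end-to-end; returns its result tables by name."""
    gdir = out_dir / group.label
    gdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    # --- preprocess ----------------------------------------------------
    stage = "preprocess"
    try:
        srna_tables = {}
        for lib_id in sorted(group.srna):
            p = group.srna[lib_id]
            table, lib = load_srna_library(
                p, _format_of(p), lib_id, min_len=params.min_len, max_len=params.max_len
            )
            logger.info("group %s: sRNA library %s: %d unique reads, %d retained",
                        group.label, lib_id, len(table), lib.total_retained)
            srna_tables[lib_id] = table
        expression = merge_libraries(srna_tables)
        write_expression_table(expression, gdir / "expression.tsv")
        tables["expression"] = expression
    except Exception as exc:
        raise StageError(f"stage {stage} failed for group {group.label}: {exc}") from exc

    # --- conserved scan ------------------------------------------------
    if refs:
        stage = "conserve"
        try:
            conserved = scan_conserved(expression, refs)
            conserved.to_csv(gdir / "conserved.tsv", sep="\t", index=False)
            tables["conserved"] = conserved
            logger.info("group %s: %d conserved miRNA candidates", group.label, len(conserved))
        except Exception as exc:
            raise StageError(f"stage {stage} failed for group {group.label}: {exc}") from exc

    # --- discovery -----------------------------------------------------
    stage = "discover"
    try:
        transcripts = load_transcripts(group.transcripts)
        mappings = map_reads_exact(expression, transcripts)
        candidates, pris = discover(
            expression,
            transcripts,
            rules=params.hairpin,
            flank=params.flank,
            edge=params.edge,
            extension=params.extension,
            mappings=mappings,
        )
        cand_rows = [
            {
                "transcript_id": c.window.transcript_id,
                "start": c.window.start,
                "end": c.window.end,
                "strand": c.window.strand,
                "verdict": int(c.verdict),
                "fail_reasons": ",".join(c.fail_reasons),
                "mature5p": _iv(c.mature5p),
                "mature3p": _iv(c.mature3p),
                "mfe": c.structure.mfe,
                "dot_bracket": c.structure.dot_bracket,
            }
            for c in candidates
        ]
        cand_table = pd.DataFrame(
            cand_rows,
            columns=["transcript_id", "start", "end", "strand", "verdict",
                     "fail_reasons", "mature5p", "mature3p", "mfe", "dot_bracket"],
        )
        cand_table.to_csv(gdir / "candidates.tsv", sep="\t", index=False)
        tables["candidates"] = cand_table
        pri_rows = [
            {
                "pri_id": p.pri_id,
                "transcript_id": p.transcript_id,
                "start": p.span[0],
                "end": p.span[1],
                "strand": p.strand,
                "extension_applied": p.extension_applied,
                "mature5p": _iv(p.mature5p),
                "mature3p": _iv(p.mature3p),
            }
            for p in pris
        ]
        pri_table = pd.DataFrame(
            pri_rows,
            columns=["pri_id", "transcript_id", "start", "end", "strand",
                     "extension_applied", "mature5p", "mature3p"],
        )
        pri_table.to_csv(gdir / "pri_mirnas.tsv", sep="\t", index=False)
        tables["pri_mirnas"] = pri_table
        with open(gdir / "precursors.fasta", "w") as fh:
            for p in pris:
                fh.write(f">{p.pri_id}\n{p.candidate.sequence}\n")
        logger.info("group %s: %d windows evaluated, %d passing pri-miRNAs",
                    group.label, len(candidates), len(pris))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage} failed for group {group.label}: {exc}") from exc

    # --- degradome validation -------------------------------------------
    validations = {}
    if group.degradome:
        stage = "validate"
        try:
            deg_tables = {}
            for lib_id in sorted(group.degradome):
                p = group.degradome[lib_id]
                table, lib = load_degradome_library(p, _format_of(p), lib_id, tag_len=params.tag_len)
                logger.info("group %s: degradome library %s: %d tags (%d reads)",
                            group.label, lib_id, len(table), lib.total_retained)
                deg_tables[lib_id] = table
            merged_tags = merge_libraries(deg_tables)
            results = []
            for p in pris:
                res = validate_pri(
                    p, merged_tags, tolerance=params.tolerance, min_rpm=params.min_rpm
                )
                validations[p.pri_id] = res
                results.append(res)
            site_table, summary = validation_tables(results)
            site_table.to_csv(gdir / "validation_sites.tsv", sep="\t", index=False)
            summary.to_csv(gdir / "validation_summary.tsv", sep="\t", index=False)
            tables["validation_sites"] = site_table
            tables["validation_summary"] = summary
            logger.info("group %s: %d/%d pri-miRNAs degradome-supported", group.label,
                        int((summary["n_supported"] > 0).sum()) if len(summary) else 0, len(pris))
        except Exception as exc:
            raise StageError(f"stage {stage} failed for group {group.label}: {exc}") from exc

    # --- reporting -----------------------------------------------------
    stage = "report"
    try:
        calls = {}
        if refs:
            for p in pris:
                for arm in ("5p", "3p"):
                    seq = p.candidate.arm_sequence(arm)
                    if seq and seq not in calls:
                        calls[seq] = classify_conservation(seq, refs, max_dist=params.max_dist)
        rows = build_summary_table(
            pris, calls, expression, group.label, species_prefix=params.species_prefix
        )
        summary = summary_frame(rows)
        summary.to_csv(gdir / "summary.tsv", sep="\t", index=False, float_format="%.2f")
        tables["summary"] = summary
        profiles = [build_coverage_profile(p, mappings) for p in pris]
        specs = [build_annotation_spec(p, validations.get(p.pri_id)) for p in pris]
        render_outputs(profiles, specs, gdir / "figures")
    except Exception as exc:
        raise StageError(f"stage {stage} failed for group {group.label}: {exc}") from exc

    return tables


def _iv(interval) -> str:
    return f"{interval[0]}-{interval[1]}" if interval else ""


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every group independently and merge the summary tables."""
    out_dir = Path(config.output_dir)
    _setup_logging(out_dir)
    logger.info("plantmir %s | config digest %s | seed %d",
                __version__, config.digest(), config.seed)
    for key, value in sorted(config.params.as_dict().items()):
        logger.info("parameter %s = %s", key, value)

    refs = None
    if config.reference_matures:
        refs = load_reference_matures(config.reference_matures)
        stats = reference_stats(refs)
        logger.info("reference registry: %(entries)d entries, %(unique_sequences)d unique "
                    "sequences, %(species)d species", stats)
        if not refs:
            logger.warning("reference registry is empty after species filtering")

    groups: dict[str, dict[str, pd.DataFrame]] = {}
    for group in config.groups:
        logger.info("processing group %s", group.label)
        groups[group.label] = run_group(group, config.params, out_dir, refs=refs)

    summaries = [t["summary"] for t in groups.values() if "summary" in t and len(t["summary"])]
    merged = (
        pd.concat(summaries, ignore_index=True).fillna(0.0)
        if summaries
        else pd.DataFrame(columns=["mature_id", "sequence", "conservation"])
    )
    merged.to_csv(out_dir / "summary_all_groups.tsv", sep="\t", index=False, float_format="%.2f")

    manifest = sorted(
        str(p.relative_to(out_dir)) for p in out_dir.rglob("*") if p.is_file()
    )
    (out_dir / "manifest.txt").write_text("\n".join(m for m in manifest if m != "manifest.txt") + "\n")
    return PipelineResult(
        output_dir=out_dir, groups=groups, merged_summary=merged, manifest=manifest
    )
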