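"""Shared fixtures: a seeded synthetic scenario and one full pipeline run.

The scenario (10 planted hairpins, 3 sRNA libraries at depth 50k with 80%
signal, degradome signal at 3 of the 4 processing sites per hairpin) is
built once per session and reused; the pipeline runs on it through the real
file interfaces (FASTA/FASTQ on disk, YAML config).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pytest
import yaml

from plantmir.pipeline import load_config, run_pipeline
from plantmir.simulate import build_scenario, populate_libraries, write_scenario

logging.getLogger("plantmir").setLevel(logging.WARNING)

SCENARIO_SEED = 42
LIBRARIES = ["lib1", "lib2", "lib3"]
DEPTH = 50000
SIGNAL_FRACTION = 0.8
SITES_PER_PRI = 3


@pytest.fixture(scope="session")
def scenario():
    sc = build_scenario(SCENARIO_SEED, n_hairpins=10)
    populate_libraries(
        sc,
        LIBRARIES,
        depth=DEPTH,
        signal_fraction=SIGNAL_FRACTION,
        sites_per_pri=SITES_PER_PRI,
    )
    return sc


def scenario_config(scenario, root: Path, with_degradome: bool = True) -> Path:
    """Write scenario files and a pipeline config under ``root``."""
    paths = write_scenario(scenario, root / "data")
    config = {
        "output_dir": str(root / "results"),
        "seed": SCENARIO_SEED,
        "groups": [
            {
                "label": "synthetic",
                "transcripts": paths["transcripts"],
                "srna": {lib: paths[f"srna_{lib}"] for lib in LIBRARIES},
                **(
                    {"degradome": {lib: paths[f"degradome_{lib}"] for lib in LIBRARIES}}
                    if with_degradome
                    else {}
                ),
            }
        ],
    }
    config_path = root / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path


@pytest.fixture(scope="session")
def pipeline_run(scenario, tmp_path_factory):
    root = tmp_path_factory.mktemp("e2e")
    config_path = scenario_config(scenario, root)
    result = run_pipeline(load_config(config_path))
    return scenario, result


@pytest.fixture()
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "reads.fasta") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
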