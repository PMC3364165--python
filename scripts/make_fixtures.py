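#!/usr/bin/env python
"""Regenerate the pinned-seed fixture libraries under tests/data/fixtures/.

Each fixture directory holds config.json plus the FASTA/TSV/truth emitted by
the simulator for that seed; a test asserts that regeneration from
config.json is byte-identical, pinning both the generator and the on-disk
formats.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from barcode_audit.simulate import SimulationConfig, simulate_reference_library

FIXTURE_ROOT = Path(__file__).resolve().parent.parent / "tests" / "data" / "fixtures"

SEEDS = (101, 102, 103)


def fixture_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_genera=2,
        species_per_genus=2,
        specimens_per_species=3,
        cryptic_fraction=0.25,
        fragment_fraction=0.2,
        ambiguity_rate=0.002,
        misid_count=1,
    )


def main() -> None:
    for seed in SEEDS:
        config = fixture_config(seed)
        outdir = FIXTURE_ROOT / f"seed{seed}"
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2) + "\n"
        )
        simulate_reference_library(config).write(outdir)
        print(f"wrote fixture {outdir}")


if __name__ == "__main__":
    main()
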