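"""Shared plumbing for the numbered analysis drivers: one working directory
(results/run) and one default configuration, overridable via --seed."""

import argparse
from pathlib import Path

from stratwas.simulate import SimulationConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--workdir", type=Path, default=RUN_DIR)
    return ap.parse_args()


def config_for(args: argparse.Namespace) -> SimulationConfig:
    return SimulationConfig(seed=args.seed)
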