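"""Command-line interface: validate configs, run simulations, run the
packaged experiments."""

from __future__ import annotations

import argparse
import logging
import sys
from typing import Optional, Sequence

log = logging.getLogger("spikewin")


def _cmd_validate(args) -> int:
    from .config import ConfigError, load_config

    try:
        load_config(args.config)
    except ConfigError as e:
        print("invalid configuration:", file=sys.stderr)
        for err in e.errors:
            print(f"  - {err}", file=sys.stderr)
        return 1
    print("OK")
    return 0


def _cmd_simulate(args) -> int:
    from .config import ConfigError, load_config, build_simulation
    from .outputs import write_outputs

    try:
        cfg = load_config(args.config)
    except ConfigError as e:
        print(str(e), file=sys.stderr)
        return 1
    seed = cfg.seed if args.seed is None else args.seed
    sim, _net = build_simulation(cfg, seed=seed)
    log.info("simulating %d ms (seed %d)", cfg.duration_ms, seed)
    rec = sim.run(cfg.duration_ms, seed=seed)
    files = write_outputs(rec, args.out, config_doc=cfg.raw)
    log.info("wrote %d files to %s", len(files), args.out)
    return 0


def _cmd_run_experiment(args) -> int:
    from ..experiments import EXPERIMENTS, run_experiment
    from .outputs import write_outputs

    if args.name not in EXPERIMENTS:
        print(f"unknown experiment {args.name!r}; choose from "
              f"{', '.join(sorted(EXPERIMENTS))}", file=sys.stderr)
        return 2
    log.info("running experiment %s (seed %d)", args.name, args.seed)
    result = run_experiment(args.name, seed=args.seed)
    files = write_outputs(result, args.out)
    log.info("wrote %d files to %s", len(files), args.out)
    return 0


def build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="spikewin",
        description="Spiking network simulation with windowed, batched plasticity.",
    )
    parser.add_argument("-v", "--verbose", action="store_true", help="debug logging")
    sub = parser.add_subparsers(dest="command", required=True)

    p_val = sub.add_parser("validate", help="validate a config file")
    p_val.add_argument("--config", required=True)
    p_val.set_defaults(func=_cmd_validate)

    p_sim = sub.add_parser("simulate", help="run a simulation from a config")
    p_sim.add_argument("--config", required=True)
    p_sim.add_argument("--seed", type=int, default=None)
    p_sim.add_argument("--out", required=True)
    p_sim.set_defaults(func=_cmd_simulate)

    p_exp = sub.add_parser("run-experiment", help="run a packaged experiment")
    p_exp.add_argument("name")
    p_exp.add_argument("--seed", type=int, default=0)
    p_exp.add_argument("--out", required=True)
    p_exp.set_defaults(func=_cmd_run_experiment)
    return parser


def main(argv: Optional[Sequence[str]] = None) -> int:
    parser = build_parser()
    args = parser.parse_args(argv)
    logging.basicConfig(
        level=logging.DEBUG if args.verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    return args.func(args)


if __name__ == "__main__":
    sys.exit(main())
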