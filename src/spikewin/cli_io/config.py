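"""Configuration schema: loading, validation and network construction.

Configs are YAML.  Validation aggregates every error it can find before
raising, so a broken file is reported in one pass.  Building a network from
a validated config plus a seed is a pure function: connectivity, initial
weights and stimuli each draw from named sub-streams of the global seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from typing import Any, Optional

import numpy as np
import yaml

from .. import stimuli
from ..engine import (
    LIFParams,
    Network,
    Population,
    Simulator,
    ValidationError,
    connect,
    rng_stream,
)
from ..rules import make_rule

__all__ = ["SimConfig", "ConfigError", "load_config", "build_simulation", "config_hash"]

_CONNECTIVITY_KINDS = ("one-to-one", "all-to-all", "bernoulli")
_MODELS = ("lif", "poisson", "spike_source")
_RULES = ("stdp_trace", "bcm", "vg_stdp")


class ConfigError(ValueError):
    """Aggregated validation failure; ``errors`` lists every problem."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass
class SimConfig:
    """A validated simulation description (plain dict payload plus schema
    guarantees)."""

    raw: dict
    duration_ms: int
    seed: int
    window_ms: int
    bin_ms: int

    @property
    def populations(self) -> list[dict]:
        return self.raw["populations"]

    @property
    def projections(self) -> list[dict]:
        return self.raw.get("projections", [])

    @property
    def runtime(self) -> dict:
        return self.raw["runtime"]


def _validate(doc: Any) -> list[str]:
    errors: list[str] = []
    if not isinstance(doc, dict):
        return ["top level must be a mapping"]
    rt = doc.get("runtime")
    if not isinstance(rt, dict):
        errors.append("missing 'runtime' section")
        rt = {}
    if not isinstance(rt.get("duration_ms", 0), int) or rt.get("duration_ms", 0) < 0:
        errors.append("runtime.duration_ms must be a non-negative integer")
    for key, dflt in (("window_ms", 128), ("bin_ms", 2)):
        v = rt.get(key, dflt)
        if not isinstance(v, int) or v < 1:
            errors.append(f"runtime.{key} must be a positive integer")
    if rt.get("ledger_mode", "batched") not in ("batched", "ded"):
        errors.append("runtime.ledger_mode must be 'batched' or 'ded'")

    pops = doc.get("populations")
    pop_names: dict[str, dict] = {}
    if not isinstance(pops, list) or not pops:
        errors.append("'populations' must be a non-empty list")
        pops = []
    for i, p in enumerate(pops):
        ctx = f"populations[{i}]"
        if not isinstance(p, dict):
            errors.append(f"{ctx}: must be a mapping")
            continue
        name = p.get("name")
        if not isinstance(name, str) or not name:
            errors.append(f"{ctx}: missing name")
            continue
        if name in pop_names:
            errors.append(f"{ctx}: duplicate population name {name!r}")
        pop_names[name] = p
        if not isinstance(p.get("size"), int) or p["size"] < 1:
            errors.append(f"{ctx} ({name}): size must be a positive integer")
        model = p.get("model", "lif")
        if model not in _MODELS:
            errors.append(f"{ctx} ({name}): unknown model {model!r}")
        if model == "poisson":
            if not isinstance(p.get("rate"), (int, float)) or p.get("rate", -1) < 0:
                errors.append(f"{ctx} ({name}): poisson model needs rate >= 0")
        if model == "lif" and p.get("params"):
            try:
                LIFParams(**p["params"])
            except (TypeError, ValidationError) as e:
                errors.append(f"{ctx} ({name}): bad lif params: {e}")

    for i, pr in enumerate(doc.get("projections", []) or []):
        ctx = f"projections[{i}]"
        if not isinstance(pr, dict):
            errors.append(f"{ctx}: must be a mapping")
            continue
        name = pr.get("name", f"proj{i}")
        for endpoint in ("source", "target"):
            ref = pr.get(endpoint)
            if ref not in pop_names:
                errors.append(f"{ctx} ({name}): {endpoint} references unknown population {ref!r}")
        conn = pr.get("connectivity", {})
        kind = conn.get("kind") if isinstance(conn, dict) else None
        if kind not in _CONNECTIVITY_KINDS:
            errors.append(f"{ctx} ({name}): connectivity.kind must be one of {_CONNECTIVITY_KINDS}")
        elif kind == "bernoulli":
            p_ = conn.get("p")
            if not isinstance(p_, (int, float)) or not 0.0 <= p_ <= 1.0:
                errors.append(f"{ctx} ({name}): bernoulli probability must be in [0, 1]")
        if pr.get("plastic"):
            rule = pr.get("rule")
            if not isinstance(rule, dict) or rule.get("name") not in _RULES:
                errors.append(f"{ctx} ({name}): plastic projection needs rule.name in {_RULES}")
            else:
                try:
                    make_rule(rule["name"], **{k: v for k, v in rule.items() if k != "name"})
                except (TypeError, ValueError) as e:
                    errors.append(f"{ctx} ({name}): bad rule params: {e}")
        if pr.get("target") in pop_names:
            tgt = pop_names[pr["target"]]
            if tgt.get("model", "lif") != "lif":
                errors.append(f"{ctx} ({name}): target must be a lif population")
    return errors


def load_config(path_or_dict) -> SimConfig:
    """Parse and validate a config file (or an already-parsed mapping).

    Raises :class:`ConfigError` carrying the full list of validation
    errors."""
    if isinstance(path_or_dict, dict):
        doc = copy.deepcopy(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            doc = yaml.safe_load(fh)
    errors = _validate(doc)
    if errors:
        raise ConfigError(errors)
    rt = doc["runtime"]
    return SimConfig(
        raw=doc,
        duration_ms=int(rt["duration_ms"]),
        seed=int(rt.get("seed", 0)),
        window_ms=int(rt.get("window_ms", 128)),
        bin_ms=int(rt.get("bin_ms", 2)),
    )


def _expand_value(spec, n, rng, integer=False):
    if isinstance(spec, dict):
        if "uniform" in spec:
            lo, hi = spec["uniform"]
            vals = rng.uniform(lo, hi, size=n)
            return np.round(vals).astype(np.int64) if integer else vals
        if "uniform_int" in spec:
            lo, hi = spec["uniform_int"]
            return rng.integers(lo, hi + 1, size=n)
        raise ConfigError([f"unknown value spec {spec!r}"])
    return np.full(n, spec, dtype=np.int64 if integer else np.float64)


def build_simulation(cfg: SimConfig, seed: Optional[int] = None) -> tuple[Simulator, Network]:
    """Instantiate populations, projections and stimuli from a validated
    config.  ``seed`` overrides the config seed."""
    seed = cfg.seed if seed is None else int(seed)
    record_v = set(cfg.runtime.get("record_v", []))
    pops: dict[str, Population] = {}
    for p in cfg.populations:
        model = p.get("model", "lif")
        if model == "lif":
            pops[p["name"]] = Population(
                p["name"], p["size"], kind="lif",
                params=LIFParams(**p.get("params", {}) or {}),
                record_v=p["name"] in record_v,
            )
        elif model == "poisson":
            spec = stimuli.PoissonSpec(
                rate=float(p["rate"]),
                start=int(p.get("start", 0)),
                stop=int(p.get("stop", cfg.duration_ms or 1)),
                n_sources=p["size"],
            )
            pops[p["name"]] = Population(
                p["name"], p["size"], kind="source",
                stimulus=lambda rng, d, spec=spec: stimuli.poisson_train(spec, rng),
            )
        else:  # spike_source
            trains = [np.asarray(t, dtype=np.int64) for t in p.get("spike_times", [])]
            trains += [np.empty(0, dtype=np.int64)] * (p["size"] - len(trains))
            pops[p["name"]] = Population(p["name"], p["size"], kind="source", trains=trains)

    projections = []
    for i, pr in enumerate(cfg.projections):
        name = pr.get("name", f"proj{i}")
        conn = pr["connectivity"]
        rule = None
        if pr.get("plastic"):
            rp = {k: v for k, v in pr["rule"].items() if k != "name"}
            rule = make_rule(pr["rule"]["name"], **rp)
        w_rng = rng_stream(seed, f"weights:{name}")
        d_rng = rng_stream(seed, f"delays:{name}")
        c_rng = rng_stream(seed, f"connectivity:{name}")
        pre, post = pops[pr["source"]], pops[pr["target"]]
        if conn["kind"] == "bernoulli":
            kw = {"p": float(conn["p"]), "rng": c_rng}
        else:
            kw = {}
        n_guess = {
            "one-to-one": pre.size,
            "all-to-all": pre.size * post.size,
        }.get(conn["kind"])

        def expand(spec, integer):
            rng = d_rng if integer else w_rng
            if n_guess is not None:
                return _expand_value(spec, n_guess, rng, integer=integer)
            # bernoulli: expand lazily once pair count is known
            return lambda pi, qi: _expand_value(spec, len(pi), rng, integer=integer)

        projections.append(
            connect(
                name, pre, post, conn["kind"],
                weight=expand(pr.get("weight", 0.0), False),
                delay=expand(pr.get("delay", 1), True),
                plastic=bool(pr.get("plastic", False)),
                rule=rule,
                **kw,
            )
        )
    net = Network(list(pops.values()), projections)
    sim = Simulator(
        net,
        window_ms=cfg.window_ms,
        bin_ms=cfg.bin_ms,
        snapshot_weights=cfg.runtime.get("snapshot_weights", "edges"),
    )
    return sim, net


def config_hash(doc: dict) -> str:
    """Stable hash of a config mapping (canonical JSON, sha256)."""
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, separators=(",", ":"), default=str).encode()
    ).hexdigest()
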