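"""File writers: spike rasters, membrane traces, weight snapshots, ledgers,
metrics and a self-describing run manifest.  All outputs are plain text;
re-running with identical inputs reproduces byte-identical files."""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np

from .. import __version__
from ..engine import RecordingSet
from .config import config_hash

__all__ = ["write_outputs", "write_recordings", "write_manifest"]


def _ensure_outdir(outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    probe = os.path.join(outdir, ".write_probe")
    try:
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as e:
        raise OSError(f"output directory {outdir!r} is not writable: {e}") from e


def write_recordings(rec: RecordingSet, outdir: str) -> list[str]:
    """Write spikes, optional membrane traces, weight snapshots and
    write-back ledgers.  Returns the list of files written."""
    _ensure_outdir(outdir)
    written = []
    for pop, (times, ids) in sorted(rec.spikes.items()):
        path = os.path.join(outdir, f"spikes_{pop}.csv")
        with open(path, "w") as fh:
            fh.write("time_ms,neuron_id\n")
            for t, i in zip(times, ids):
                fh.write(f"{int(t)},{int(i)}\n")
        written.append(path)
    for pop, trace in sorted(rec.v_traces.items()):
        path = os.path.join(outdir, f"v_{pop}.csv")
        with open(path, "w") as fh:
            fh.write("time_ms,neuron_id,v_mV\n")
            for t in range(trace.shape[0]):
                for i in range(trace.shape[1]):
                    fh.write(f"{t},{i},{trace[t, i]:.6f}\n")
        written.append(path)
    for proj, snaps in sorted(rec.weight_snapshots.items()):
        for t, w in snaps:
            path = os.path.join(outdir, f"weights_{proj}_{int(t)}.txt")
            np.savetxt(path, np.asarray(w)[None, :], fmt="%.12g")
            written.append(path)
    for proj, ledger in sorted(rec.ledgers.items()):
        path = os.path.join(outdir, f"writebacks_{proj}.csv")
        counts = ledger.counts()
        with open(path, "w") as fh:
            fh.write("row_id,writebacks\n")
            for r, cnt in enumerate(counts):
                fh.write(f"{r},{int(cnt)}\n")
        written.append(path)
    return written


def write_manifest(outdir: str, config_doc: dict, seed: int) -> str:
    path = os.path.join(outdir, "run_manifest.json")
    manifest = {
        "config": config_doc,
        "config_sha256": config_hash(config_doc),
        "seed": int(seed),
        "spikewin_version": __version__,
        "numpy_version": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def write_outputs(result, outdir: str, config_doc: Optional[dict] = None) -> list[str]:
    """Write an :class:`~spikewin.experiments.ExperimentResult` (or a bare
    :class:`RecordingSet`) to ``outdir``."""
    _ensure_outdir(outdir)
    rec = result if isinstance(result, RecordingSet) else result.recordings
    written = write_recordings(rec, outdir)
    metrics = getattr(result, "metrics", None)
    if metrics is not None:
        path = os.path.join(outdir, "metrics.json")
        with open(path, "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(path)
    doc = config_doc if config_doc is not None else {
        "experiment": getattr(result, "name", "recording"),
    }
    seed = getattr(result, "seed", 0)
    written.append(write_manifest(outdir, doc, seed))
    return written
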