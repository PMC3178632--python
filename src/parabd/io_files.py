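"""Observable tables, event logs and run manifests on disk."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_observables", "read_observables", "write_events",
           "read_events", "write_manifest", "write_profile"]


def write_observables(series, path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def read_observables(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events, path) -> None:
    with open(path, "w") as fh:
        fh.write("time\tkind\tsubunit_id\tfilament_id\n")
        for ev in events:
            fh.write(f"{ev.time!r}\t{ev.kind}\t{ev.subunit_id}\t{ev.filament_id}\n")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_profile(profile, path) -> None:
    pd.DataFrame({"x_rel_com": profile.bin_centers,
                  "density": profile.mean_density}).to_csv(path, index=False)


def write_manifest(config, path, extra: dict | None = None) -> None:
    """Full provenance: resolved config, its hash, seed and code version."""
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config_hash": config.config_hash(),
        "seed": config.integrator.seed,
        "config": json.loads(config.model_dump_json()),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
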