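"""Readers and writers for the pipeline's flat-file formats.

All tabular data travel as CSV, trees as Newick (one per line; NEXUS accepted
on read), the fitted environmental space and reports as JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .envspace import EnvRaster, OccurrenceTable
from .trees import Phylogeny

__all__ = [
    "read_raster", "write_raster", "read_occurrences", "write_occurrences",
    "read_metadata", "write_metadata", "read_trees", "write_trees",
]

_OCC_REQUIRED = ("species", "lon", "lat")


def read_raster(path) -> EnvRaster:
    table = pd.read_csv(path)
    missing = [c for c in ("pixel_id", "lon", "lat", "island")
               if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: raster CSV missing columns {missing}")
    return EnvRaster(table)


def write_raster(raster: EnvRaster, path):
    raster.table.to_csv(path, index=False)


def read_occurrences(path, metadata_path=None) -> OccurrenceTable:
    rec = pd.read_csv(path)
    missing = [c for c in _OCC_REQUIRED if c not in rec.columns]
    if missing:
        raise ValueError(f"{path}: occurrence CSV missing columns {missing}")
    meta = read_metadata(metadata_path) if metadata_path else pd.DataFrame()
    return OccurrenceTable(rec, meta)


def write_occurrences(occ: OccurrenceTable, path):
    occ.records.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "species" not in meta.columns:
        raise ValueError(f"{path}: metadata CSV missing 'species' column")
    return meta


def write_metadata(metadata: pd.DataFrame, path):
    metadata.to_csv(path, index=False)


def read_trees(path) -> list:
    """Trees from Newick (one per line) or NEXUS (translate tables honored)."""
    trees = Phylogeny.list_from_file(path)
    if not trees:
        raise ValueError(f"{path}: no trees found")
    return trees


def write_trees(trees, path):
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


def write_json(payload: dict, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default, sort_keys=True)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
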