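"""Environmental ordination and species niche summaries.

The background climate raster (pixels x environmental variables) is ordinated
with a correlation-matrix PCA; species presence records are projected onto the
first two axes using the *background* standardization constants and loadings.
Per species, the niche identity is the per-axis mean of its deduplicated pixel
scores and the niche breadth the per-axis sample standard deviation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

__all__ = [
    "EnvRaster", "EnvSpace", "OccurrenceTable", "SpeciesNiche",
    "fit_env_space", "apply_filters", "dedupe_per_pixel", "species_niche",
    "niches_to_frame",
]

_META_COLS = ("pixel_id", "lon", "lat", "island")
OCC_COLS = ("species", "lon", "lat", "coordinate_precision_km", "pixel_id", "island")


@dataclass
class EnvRaster:
    """Background raster as a pixel table.

    ``table`` columns: pixel_id, lon, lat, island, then one column per
    environmental variable.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _META_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"raster table missing columns {missing}")
        if self.table["pixel_id"].duplicated().any():
            raise ValueError("pixel_id values must be unique")
        if self.env.isna().any().any():
            raise ValueError("raster contains missing environmental values")
        self.table = self.table.reset_index(drop=True)

    @property
    def var_names(self):
        return [c for c in self.table.columns if c not in _META_COLS]

    @property
    def env(self) -> pd.DataFrame:
        return self.table[self.var_names]

    @property
    def n_pixels(self) -> int:
        return len(self.table)

    def pixel_size(self) -> float:
        """Grid spacing in degrees, inferred from coordinate gaps."""
        out = []
        for c in ("lon", "lat"):
            u = np.sort(self.table[c].unique())
            if len(u) > 1:
                out.append(np.median(np.diff(u)))
        return float(np.median(out)) if out else 1.0

    def env_for_pixels(self, pixel_ids) -> pd.DataFrame:
        t = self.table.set_index("pixel_id")
        return t.loc[list(pixel_ids), self.var_names]


@dataclass
class EnvSpace:
    """Fitted correlation-matrix PCA of the background raster."""

    means: pd.Series
    sds: pd.Series
    loadings: pd.DataFrame              # variables x all components
    explained_variance: np.ndarray      # percent, all components
    background_scores: np.ndarray       # pixels x 2
    n_components_kept: int = 2

    def project(self, env: pd.DataFrame) -> np.ndarray:
        """Project environmental vectors onto the first two background axes."""
        x = (env[self.means.index] - self.means) / self.sds
        return x.to_numpy() @ self.loadings.to_numpy()[:, : self.n_components_kept]

    def to_json(self, path):
        payload = {
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
            "variables": list(self.means.index),
            "loadings": self.loadings.to_numpy().tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "background_scores": np.asarray(self.background_scores).tolist(),
            "n_components_kept": self.n_components_kept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EnvSpace":
        with open(path) as fh:
            p = json.load(fh)
        variables = p["variables"]
        load = pd.DataFrame(np.array(p["loadings"]), index=variables,
                            columns=[f"PC{i+1}" for i in range(len(p["explained_variance"]))])
        return cls(
            means=pd.Series(p["means"])[variables],
            sds=pd.Series(p["sds"])[variables],
            loadings=load,
            explained_variance=np.array(p["explained_variance"]),
            background_scores=np.array(p["background_scores"]),
            n_components_kept=p["n_components_kept"],
        )


@dataclass
class OccurrenceTable:
    """Presence records plus species metadata.

    ``records``: one row per occurrence (see :data:`OCC_COLS`; pixel_id and
    island may be absent before assignment).  ``metadata``: one row per species
    with columns species, pollination_mode, mode_status, islands (a set).
    """

    records: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        req = ("species", "lon", "lat")
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"occurrence records missing columns {missing}")
        if "coordinate_precision_km" in self.records.columns:
            bad = self.records["coordinate_precision_km"] <= 0
            if bad.any():
                raise ValueError("coordinate_precision_km must be > 0")
        self.records = self.records.reset_index(drop=True)

    @property
    def species(self):
        return sorted(self.records["species"].unique())

    def subset_metadata(self) -> pd.DataFrame:
        if self.metadata.empty:
            return self.metadata
        return self.metadata[self.metadata["species"].isin(self.species)].reset_index(drop=True)


@dataclass
class SpeciesNiche:
    """Deduplicated per-pixel PC scores and their summary for one species."""

    species: str
    scores: np.ndarray       # n_pixels x 2
    identity: np.ndarray     # per-axis mean
    breadth: np.ndarray      # per-axis sample SD
    range: np.ndarray        # 2 x (min, max)
    n_pixels: int


def fit_env_space(raster: EnvRaster, n_components_kept: int = 2) -> EnvSpace:
    """Correlation-matrix PCA of the background raster.

    Variables are standardized to zero mean and unit (sample) SD, so every
    variable enters with the same weight.  The loading sign convention makes
    the largest-magnitude element of each column positive, which removes the
    eigenvector sign ambiguity across linear-algebra backends.
    """
    X = raster.env
    if raster.n_pixels < 3:
        raise ValueError("need at least 3 pixels to fit the environmental space")
    if raster.n_pixels < len(raster.var_names):
        raise ValueError("PCA degenerate: fewer pixels than environmental variables")
    sds = X.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"constant environmental variable(s): {list(zero.index)}")
    means = X.mean()
    Z = ((X - means) / sds).to_numpy()

    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()     # variables x components
    # sign convention: largest-|.| element of each loading column positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    explained = 100.0 * pca.explained_variance_ratio_
    cols = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return EnvSpace(
        means=means, sds=sds,
        loadings=pd.DataFrame(loadings, index=X.columns, columns=cols),
        explained_variance=explained,
        background_scores=scores[:, :n_components_kept],
        n_components_kept=n_components_kept,
    )


def assign_pixels(occ: OccurrenceTable, raster: EnvRaster) -> OccurrenceTable:
    """Attach pixel ids and island labels by nearest pixel center.

    Records farther than half a pixel diagonal from every center are marked
    outside the raster (pixel_id = NaN) and removed by :func:`apply_filters`.
    """
    rec = occ.records.copy()
    centers = raster.table[["lon", "lat"]].to_numpy()
    tree = cKDTree(centers)
    dist, idx = tree.query(rec[["lon", "lat"]].to_numpy())
    cutoff = 0.5 * raster.pixel_size() * np.sqrt(2.0) * (1 + 1e-9)
    inside = dist <= cutoff
    rec["pixel_id"] = np.where(inside, raster.table["pixel_id"].to_numpy()[idx], np.nan)
    rec["island"] = pd.array(
        [raster.table["island"].iat[i] if ok else pd.NA for i, ok in zip(idx, inside)]
    )
    return OccurrenceTable(rec, occ.metadata)


def apply_filters(
    occ: OccurrenceTable,
    raster: EnvRaster,
    precision_km: float = 10.0,
    min_records: int = 5,
    min_pixels: int = 5,
    enforce_min_counts: bool = True,
):
    """Apply the occurrence reliability filters.

    Drops records with coordinate precision strictly worse than
    ``precision_km``, records outside the raster, and (when
    ``enforce_min_counts``) species with fewer than ``min_records`` records or
    present in fewer than ``min_pixels`` distinct pixels.  Returns the filtered
    table and a log of counts dropped per rule.
    """
    rec = occ.records
    if "pixel_id" not in rec.columns or rec["pixel_id"].isna().any():
        occ = assign_pixels(occ, raster)
        rec = occ.records
    log = {"poor_precision": 0, "outside_raster": 0,
           "species_below_minimum": 0, "records_of_dropped_species": 0}

    if "coordinate_precision_km" in rec.columns:
        bad = rec["coordinate_precision_km"] > precision_km
        log["poor_precision"] = int(bad.sum())
        rec = rec[~bad]
    out = rec["pixel_id"].isna()
    log["outside_raster"] = int(out.sum())
    rec = rec[~out]

    if enforce_min_counts:
        grp = rec.groupby("species")
        n_rec = grp.size()
        n_pix = grp["pixel_id"].nunique()
        drop = set(n_rec[n_rec < min_records].index) | set(n_pix[n_pix < min_pixels].index)
        log["species_below_minimum"] = len(drop)
        dropped = rec["species"].isin(drop)
        log["records_of_dropped_species"] = int(dropped.sum())
        rec = rec[~dropped]
    return OccurrenceTable(rec.reset_index(drop=True), occ.metadata), log


def dedupe_per_pixel(occ: OccurrenceTable) -> OccurrenceTable:
    """Keep a single record per (species, pixel) to damp collector revisits."""
    rec = (occ.records.sort_values(["species", "pixel_id", "lon", "lat"],
                                   kind="mergesort")
           .drop_duplicates(subset=["species", "pixel_id"], keep="first")
           .reset_index(drop=True))
    return OccurrenceTable(rec, occ.metadata)


def species_niche(occ: OccurrenceTable, space: EnvSpace, raster: EnvRaster):
    """Project deduplicated records and summarize each species' niche.

    Identity is the per-axis mean score, breadth the per-axis sample SD
    (``ddof=1``), range the per-axis (min, max).
    """
    niches = []
    for sp, sub in occ.records.groupby("species", sort=True):
        env = raster.env_for_pixels(sub["pixel_id"])
        scores = space.project(env)
        if len(scores) < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 pixels; "
                             "breadth is undefined")
        niches.append(SpeciesNiche(
            species=sp,
            scores=scores,
            identity=scores.mean(axis=0),
            breadth=scores.std(axis=0, ddof=1),
            range=np.column_stack([scores.min(axis=0), scores.max(axis=0)]),
            n_pixels=len(scores),
        ))
    return niches


def niches_to_frame(niches) -> pd.DataFrame:
    rows = []
    for n in niches:
        rows.append({
            "species": n.species, "n_pixels": n.n_pixels,
            "identity_pc1": n.identity[0], "identity_pc2": n.identity[1],
            "breadth_pc1": n.breadth[0], "breadth_pc2": n.breadth[1],
            "min_pc1": n.range[0, 0], "max_pc1": n.range[0, 1],
            "min_pc2": n.range[1, 0], "max_pc2": n.range[1, 1],
        })
    return pd.DataFrame(rows)
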