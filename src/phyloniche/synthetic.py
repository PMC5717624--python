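"""Synthetic data with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here: a low-rank correlated
environmental raster whose first two principal components dominate, Gaussian
species niches in PC space producing presence records, birth-death trees with
pseudo-posterior branch-length perturbation, Mk character histories for
pollination mode and island, and regime-dependent BM/OU trait values drawn
from the exact model-implied Gaussian (the same moments the likelihood uses,
so simulator and fitted models share a single source of truth).
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from . import charmap, evomodels
from .envspace import EnvRaster, EnvSpace, OccurrenceTable, fit_env_space
from .trees import Phylogeny, SimmapTree

__all__ = [
    "SyntheticConfig", "TrueParameters", "SyntheticDataset",
    "generate_raster", "generate_tree", "perturb_trees", "simulate_mk",
    "simulate_traits", "generate_occurrences", "generate_dataset",
]

ISLAND_FRACTIONS = {"Cuba": 0.45, "Hispaniola": 0.35, "Jamaica": 0.11,
                    "PuertoRico": 0.09}

# fixed island positions in latent environmental space (units of the latent
# factor SD): guarantees every island pair is environmentally distinct, so
# "same island -> more similar available environments" is a known, stable
# property of the generated system rather than a per-seed accident
ISLAND_LATENT_OFFSETS = {
    "Cuba": (-1.0, 0.4), "Hispaniola": (1.0, 0.5),
    "Jamaica": (-0.4, -1.0), "PuertoRico": (0.7, -0.9),
}


@dataclass
class SyntheticConfig:
    """Shapes, rates and noise levels of the generated study system.

    Defaults mirror the Antillean study layout: a 3458-pixel raster of
    altitude plus 19 bioclimatic variables over four islands, 35 plant
    species with 6-116 presence records each, and a 35-taxon ultrametric
    tree with a pseudo-posterior sample of branch-length perturbations.
    """

    seed: int = 0
    n_pixels: int = 3458
    n_env_vars: int = 20
    latent_dim: int = 2
    noise_sd: float = 0.8
    n_species: int = 35
    n_occurrences_per_species: tuple = (6, 116)
    n_taxa: int = 35
    birth_rate: float = 1.0
    death_rate: float = 0.5
    tree_depth: float = 1.0
    branch_perturb_sd: float = 0.1
    n_trees: int = 50
    # pollinator side of the dataset
    n_hummingbird_species: int = 14
    n_bat_species: int = 8
    pollinator_occurrences: tuple = (8, 120)

    def __post_init__(self):
        counts = (self.n_pixels, self.n_env_vars, self.latent_dim,
                  self.n_species, self.n_taxa, self.n_trees)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.death_rate >= self.birth_rate:
            raise ValueError("death_rate must be < birth_rate")
        if self.branch_perturb_sd < 0:
            raise ValueError("branch_perturb_sd must be >= 0")
        lo, hi = self.n_occurrences_per_species
        if lo < 1 or hi < lo:
            raise ValueError("invalid occurrence count range")


@dataclass
class TrueParameters:
    """Generative counterparts of the fitted model parameters."""

    model_type: str = "OU1"
    sigma2: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    alpha: float = 0.0
    theta: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    root_state: float = 0.0
    Q: np.ndarray = None
    niche_centers: dict = field(default_factory=dict)
    niche_sds: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("sigma2 must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.Q is not None:
            q = np.asarray(self.Q, float)
            if not np.allclose(q.sum(axis=1), 0, atol=1e-8):
                raise ValueError("Q rows must sum to 0")
            if (q[~np.eye(len(q), dtype=bool)] < 0).any():
                raise ValueError("Q off-diagonals must be >= 0")


# ------------------------------------------------------------------- raster
def generate_raster(cfg: SyntheticConfig) -> EnvRaster:
    """Low-rank correlated pixel table over four contiguous island blocks.

    Environmental variables are linear mixtures of ``latent_dim`` latent
    factors plus independent noise, with island-specific offsets in latent
    space, so a correlation-matrix PCA concentrates variance on the first
    ``latent_dim`` axes and islands occupy (partly) distinct environments.
    """
    if cfg.n_pixels < cfg.n_env_vars:
        raise ValueError("PCA degenerate: n_pixels < n_env_vars")
    rng = np.random.default_rng([cfg.seed, 11])
    n, k, d = cfg.n_pixels, cfg.n_env_vars, cfg.latent_dim

    # contiguous island blocks of unequal size
    names = list(ISLAND_FRACTIONS)
    sizes = np.maximum(1, np.round(
        np.array(list(ISLAND_FRACTIONS.values())) * n).astype(int))
    while sizes.sum() > n:
        sizes[np.argmax(sizes)] -= 1
    sizes[0] += n - sizes.sum()
    island = np.repeat(names, sizes)

    offsets = np.zeros((len(names), d))
    fixed = np.array([ISLAND_LATENT_OFFSETS[i] for i in names]) * 1.2
    offsets[:, :min(d, 2)] = fixed[:, :min(d, 2)]
    offsets -= offsets.mean(axis=0)
    Z = rng.normal(size=(n, d)) + offsets[np.searchsorted(
        np.cumsum(sizes), np.arange(n), side="right")]
    A = rng.normal(size=(d, k))
    scale = np.exp(rng.normal(0.0, 1.0, size=k))     # per-variable units
    X = (Z @ A + cfg.noise_sd * rng.normal(size=(n, k))) * scale

    ncol = int(np.ceil(np.sqrt(n)))
    step = 1.0 / 12.0                                 # 5 arc-min grid
    lon = -80.0 + step * (np.arange(n) % ncol)
    lat = 18.0 + step * (np.arange(n) // ncol)
    if k == 20:
        var_names = ["altitude"] + [f"bio{i}" for i in range(1, 20)]
    else:
        var_names = [f"var_{i + 1:02d}" for i in range(k)]
    table = pd.DataFrame({"pixel_id": np.arange(n), "lon": lon, "lat": lat,
                          "island": island})
    table[var_names] = X
    return EnvRaster(table)


# -------------------------------------------------------------------- trees
def generate_tree(cfg: SyntheticConfig) -> Phylogeny:
    """Ultrametric birth-death tree with ``n_taxa`` extant tips, scaled to
    ``tree_depth``."""
    if cfg.birth_rate <= cfg.death_rate:
        raise ValueError("birth_rate must exceed death_rate")
    rng = _pyrandom.Random(int(cfg.seed) + 7919)
    dtree = birthdeath.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=cfg.death_rate,
        num_extant_tips=cfg.n_taxa, rng=rng,
        is_retain_extinct_tips=False, repeat_until_success=True)
    # the simulation stops exactly at the last speciation event, leaving
    # zero-length pendant edges; extend all tips by one extra waiting time
    total_rate = cfg.n_taxa * (cfg.birth_rate + cfg.death_rate)
    extra = rng.expovariate(total_rate)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree = Phylogeny.from_dendropy(dtree)
    width = len(str(cfg.n_taxa))
    counter = 0
    for i in tree.tip_indices:
        counter += 1
        tree.labels[i] = f"sp{counter:0{width}d}"
    return tree.scaled_to_depth(cfg.tree_depth)


def perturb_trees(tree: Phylogeny, cfg: SyntheticConfig) -> list:
    """Pseudo-posterior sample: branch lengths jittered by lognormal noise,
    then pendant edges adjusted to restore ultrametricity at ``tree_depth``."""
    rng = np.random.default_rng([cfg.seed, 13])
    sd = cfg.branch_perturb_sd
    out = []
    for _ in range(cfg.n_trees):
        t = tree.copy()
        if sd > 0:
            noise = np.exp(rng.normal(-0.5 * sd ** 2, sd, size=t.n_nodes))
            t.lengths = t.lengths * noise
            t = Phylogeny(t.parent, np.where(t.lengths > 0, t.lengths, 1e-9),
                          t.labels)
            # equalize tip depths at (at least) the deepest pendant parent,
            # then rescale uniformly to the target depth
            depth = t.depths()
            parent_depth = depth[t.tip_indices] - t.lengths[t.tip_indices]
            target = max(cfg.tree_depth, parent_depth.max() * (1 + 1e-6))
            for i, pd_ in zip(t.tip_indices, parent_depth):
                t.lengths[i] = target - pd_
            t = t.scaled_to_depth(cfg.tree_depth)
        out.append(t)
    return out


# ----------------------------------------------------------------- characters
def simulate_mk(tree: Phylogeny, Q: np.ndarray, root_freq, seed,
                states=None):
    """Forward CTMC character history along the tree.

    Returns ``(tip_states, history)``; the history records every transition
    time as branch segments.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    Q = np.asarray(Q, float)
    k = Q.shape[0]
    root_freq = np.asarray(root_freq, float)
    if not np.isclose(root_freq.sum(), 1.0):
        raise ValueError("root_freq must sum to 1")
    if states is None:
        states = tuple(range(k))
    node_states = np.zeros(tree.n_nodes, dtype=int)
    node_states[tree.root] = rng.choice(k, p=root_freq)
    segments = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder:
        if v == tree.root:
            continue
        path = charmap._sample_forward_path(Q, node_states[tree.parent[v]],
                                            float(tree.lengths[v]), rng)
        segments[v] = [(states[s], d) for s, d in path]
        node_states[v] = [s for s, _ in path][-1]
    history = SimmapTree(tree, segments, [states[s] for s in node_states])
    tips = {tree.labels[i]: states[node_states[i]] for i in tree.tip_indices}
    return tips, history


def simulate_traits(history: SimmapTree, spec, params: dict, seed):
    """Draw tip traits from the exact model-implied multivariate normal.

    Mean and covariance come from :func:`phyloniche.evomodels.model_moments`
    (no path discretization), so simulated data match the fitted likelihoods
    by construction.  Returns a DataFrame (tips x traits).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mean, cov, tip_order = evomodels.model_moments(history, spec, params)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    x = mean + L @ rng.standard_normal(len(mean))
    p = spec.n_traits
    Y = x.reshape(p, len(tip_order)).T
    return pd.DataFrame(Y, index=tip_order, columns=list(spec.traits))


# -------------------------------------------------------------- occurrences
def generate_occurrences(raster: EnvRaster, space: EnvSpace, niche_centers,
                         niche_sds, n_per_species, seed,
                         islands_by_species=None,
                         precision_km: float = 5.0) -> pd.DataFrame:
    """Presence records sampled from Gaussian niches in PC space.

    Pixels are drawn (with replacement) with probability proportional to an
    isotropic Gaussian density at each pixel's (PC1, PC2); optional island
    sets restrict each species to its islands' pixels.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    scores = np.asarray(space.background_scores)
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    rows = []
    for sp in sorted(niche_centers):
        c = np.asarray(niche_centers[sp], float)
        if (c < lo).any() or (c > hi).any():
            raise ValueError(f"niche center of {sp!r} lies outside the "
                             "background score hull")
        sd = float(niche_sds[sp])
        n = n_per_species[sp] if isinstance(n_per_species, dict) else int(n_per_species)
        if n < 1:
            raise ValueError("n_per_species must be >= 1")
        mask = np.ones(len(scores), bool)
        if islands_by_species is not None:
            isl = islands_by_species[sp]
            isl = set(isl) if not isinstance(isl, str) else {isl}
            mask = raster.table["island"].isin(isl).to_numpy()
        d2 = ((scores - c) ** 2).sum(axis=1)
        logw = np.where(mask, -0.5 * d2 / max(sd, 1e-12) ** 2, -np.inf)
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        pick = rng.choice(len(scores), size=n, replace=True, p=w)
        sub = raster.table.iloc[pick]
        for _, px in sub.iterrows():
            rows.append({"species": sp, "lon": px["lon"], "lat": px["lat"],
                         "coordinate_precision_km": precision_km,
                         "pixel_id": int(px["pixel_id"]),
                         "island": px["island"]})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ full dataset
@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    raster: EnvRaster
    space: EnvSpace
    tree: Phylogeny
    trees: list
    plant_occurrences: OccurrenceTable
    pollinator_occurrences: OccurrenceTable
    true_params: dict
    pollination_history: SimmapTree
    island_history: SimmapTree


def _status_assignment(species, rng):
    """Observed / inferred / unknown mix matching the 20:14:1 field ratio."""
    n = len(species)
    n_unknown = max(1, round(n / 35))
    n_observed = round(20 / 35 * n)
    flags = (["observed"] * n_observed
             + ["inferred"] * (n - n_observed - n_unknown)
             + ["unknown"] * n_unknown)
    perm = rng.permutation(n)
    return {species[i]: flags[j] for j, i in enumerate(perm)}


def generate_dataset(cfg: SyntheticConfig, trait_model: str = "OU1") -> SyntheticDataset:
    """Generate the full study-shaped dataset.

    Plant niche identities evolve on the tree under the ``trait_model``
    generating process (OU1 by default: one optimum at the center of the
    environmental space, half-life one fifth of the tree depth); log niche
    breadths evolve under the same process.  Occurrences are sampled from the
    implied Gaussian niches, restricted to each species' islands.
    """
    rng = np.random.default_rng([cfg.seed, 17])
    raster = generate_raster(cfg)
    space = fit_env_space(raster)
    tree = generate_tree(cfg)
    trees = perturb_trees(tree, cfg)
    species = tree.tip_labels

    # discrete characters on the tree
    q_isl = charmap.build_Q([0.3 / cfg.tree_depth] * 6, "SYM", 4)
    isl_tips, isl_history = simulate_mk(
        tree, q_isl, np.full(4, 0.25), rng, states=charmap.ISLAND_STATES)
    q_pol = charmap.build_Q(
        rng.uniform(0.3, 0.9, size=6) / cfg.tree_depth, "ARD", 3)
    pol_tips, pol_history = simulate_mk(
        tree, q_pol, np.array([0.6, 0.2, 0.2]), rng,
        states=charmap.POLLINATION_STATES)

    # niche identity / breadth evolving on the tree
    alpha = np.log(2.0) / (0.2 * cfg.tree_depth)
    if trait_model == "OU1":
        spec_c = evomodels.ModelSpec("OU", "none", ("c1", "c2"))
        params_c = {"alpha": np.array([alpha, alpha]),
                    "sigma2": 2.0 * alpha * np.diag([1.0, 1.0]),
                    "theta": np.zeros((1, 2))}
        spec_b = evomodels.ModelSpec("OU", "none", ("logsd",))
        params_b = {"alpha": alpha, "sigma2": 2.0 * alpha * 0.25 ** 2,
                    "theta": np.array([np.log(1.2)])}
    elif trait_model == "BM1":
        spec_c = evomodels.ModelSpec("BM", "none", ("c1", "c2"))
        params_c = {"sigma2": np.diag([1.0, 1.0]) / cfg.tree_depth,
                    "root_state": np.zeros(2)}
        spec_b = evomodels.ModelSpec("BM", "none", ("logsd",))
        params_b = {"sigma2": 0.25 ** 2 / cfg.tree_depth,
                    "root_state": np.log(1.2)}
    else:
        raise ValueError(f"unsupported trait model {trait_model!r}")
    single = SimmapTree.single_regime(tree, "all")
    centers_df = simulate_traits(single, spec_c, params_c, rng)
    logsd = simulate_traits(single, spec_b, params_b, rng)

    scores = np.asarray(space.background_scores)
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    span = hi - lo
    sds = {sp: float(np.exp(logsd.loc[sp, "logsd"])) for sp in species}

    # species metadata: island sets (a few two-island species) + modes
    islands = {sp: {isl_tips[sp]} for sp in species}
    n_two = min(4, max(0, cfg.n_species - 1))
    for sp in rng.choice(species, size=n_two, replace=False):
        others = [i for i in charmap.ISLAND_STATES if i not in islands[sp]]
        islands[sp].add(others[int(rng.integers(len(others)))])

    # realized centers are constrained by what each species' islands offer
    isl_col = raster.table["island"].to_numpy()
    island_box = {}
    for isl in charmap.ISLAND_STATES:
        s = scores[isl_col == isl]
        island_box[isl] = (s.min(axis=0), s.max(axis=0))
    centers = {}
    for sp in species:
        blo = np.min([island_box[i][0] for i in islands[sp]], axis=0)
        bhi = np.max([island_box[i][1] for i in islands[sp]], axis=0)
        pad = 0.05 * (bhi - blo)
        c = np.clip(centers_df.loc[sp].to_numpy(), blo + pad, bhi - pad)
        centers[sp] = np.clip(c, lo + 0.02 * span, hi - 0.02 * span)
    status = _status_assignment(species, rng)
    meta = pd.DataFrame({
        "species": species,
        "pollination_mode": [pol_tips[sp] if status[sp] != "unknown"
                             else "unknown" for sp in species],
        "mode_status": [status[sp] for sp in species],
        "islands": [";".join(sorted(islands[sp])) for sp in species],
    })

    n_occ = {sp: int(rng.integers(cfg.n_occurrences_per_species[0],
                                  cfg.n_occurrences_per_species[1] + 1))
             for sp in species}
    plant_rec = generate_occurrences(raster, space, centers, sds, n_occ, rng,
                                     islands_by_species=islands)
    plants = OccurrenceTable(plant_rec, meta)

    # pollinators: two functional groups with broadly overlapping niches
    pol_names = ([f"hummingbird{i + 1:02d}" for i in range(cfg.n_hummingbird_species)]
                 + [f"bat{i + 1:02d}" for i in range(cfg.n_bat_species)])
    group = {sp: ("hummingbird" if sp.startswith("hummingbird") else "bat")
             for sp in pol_names}
    group_center = {"hummingbird": np.array([0.0, 0.0]),
                    "bat": rng.normal(0.0, 0.3, size=2)}
    pol_centers, pol_sds, pol_islands, pol_n = {}, {}, {}, {}
    for sp in pol_names:
        c = group_center[group[sp]] + rng.normal(0.0, 0.8, size=2)
        pol_centers[sp] = np.clip(c, lo + 0.02 * span, hi - 0.02 * span)
        pol_sds[sp] = float(np.exp(rng.normal(np.log(1.0), 0.3)))
        k = int(rng.integers(1, 4))
        pol_islands[sp] = set(rng.choice(charmap.ISLAND_STATES, size=k,
                                         replace=False))
        pol_n[sp] = int(rng.integers(cfg.pollinator_occurrences[0],
                                     cfg.pollinator_occurrences[1] + 1))
    pol_rec = generate_occurrences(raster, space, pol_centers, pol_sds, pol_n,
                                   rng, islands_by_species=pol_islands)
    pol_meta = pd.DataFrame({
        "species": pol_names,
        "pollination_mode": [group[sp] for sp in pol_names],
        "mode_status": ["observed"] * len(pol_names),
        "islands": [";".join(sorted(pol_islands[sp])) for sp in pol_names],
    })
    pollinators = OccurrenceTable(pol_rec, pol_meta)

    true_params = {
        "trait_model": trait_model,
        "alpha": float(alpha) if trait_model == "OU1" else 0.0,
        "identity_params": {k: np.asarray(v).tolist() if k != "_structure"
                            else None for k, v in params_c.items()},
        "breadth_params": {k: np.asarray(v).tolist()
                           for k, v in params_b.items()},
        "Q_island": q_isl.tolist(), "Q_pollination": q_pol.tolist(),
        "niche_centers": {s: centers[s].tolist() for s in species},
        "niche_sds": sds,
    }
    return SyntheticDataset(
        config=cfg, raster=raster, space=space, tree=tree, trees=trees,
        plant_occurrences=plants, pollinator_occurrences=pollinators,
        true_params=true_params, pollination_history=pol_history,
        island_history=isl_history)
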