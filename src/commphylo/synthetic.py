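"""Synthetic phylogenies, traits and community data for the full pipeline.

The generators emulate the statistical structure the analysis assumes: a
dated regional phylogeny (pure-birth, depth rescaled to 1), continuous traits
evolved under Brownian motion (or white noise as a no-signal contrast), and
plots of contiguous quadrats whose species composition is drawn from the
pool under random, environmentally filtered, or competitively overdispersed
assembly.  The paper-scale fixture mirrors the study design: a 147-species
regional pool, a 51-species local pool, five plots of 5 × 5 contiguous
10 m × 10 m quadrats censused in tree and shrub layers.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix, SpeciesPool
from .errors import ValidationError
from .phylo import Phylogeny, cophenetic_distances

#: trait ranges used to place simulated values on a realistic measurement
#: scale (affine on the analysis scale, so dispersion and signal statistics
#: are unaffected): SLA 30.39–440.71 cm²/g, seed mass 0.05–11822.30 g
#: (mapped on log10), height 0.45–8.97 m
TRAIT_RANGES = {
    "sla_cm2_g": (30.39, 440.71, "identity"),
    "seed_mass_g": (0.05, 11822.30, "log10"),
    "height_m": (0.45, 8.97, "identity"),
}


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(n_tips: int, seed: int = 0,
                       rescale_depth: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree, ultrametric by construction.

    Lineages split at unit rate; a final exponential waiting time is added
    after the n-th speciation so no tip edge has zero length.  All branch
    lengths are rescaled so the root-to-tip depth equals ``rescale_depth``.
    Tips are labeled sp0001, sp0002, ... in birth order.
    """
    if n_tips < 2:
        raise ValidationError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # crown start: the root splits at time 0, so tree depth = elapsed time
    t = 0.0
    birth_time: dict[dendropy.Node, float] = {}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        birth_time[child] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent.edge.length = t - birth_time.pop(parent)
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / n_tips)
    for i, node in enumerate(active):
        node.edge.length = t - birth_time[node]
        node.taxon = taxa.new_taxon(f"sp{i + 1:04d}")
    scale = rescale_depth / t
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    return Phylogeny(tree)


def assign_genera(phy: Phylogeny, cut_depth_fraction: float = 0.3
                  ) -> dict[str, str]:
    """Genus labels by cutting the tree at a fraction of its depth.

    Every edge crossing the cut depth defines a clade; all tips below one
    crossing edge share a genus.  Lineages originating above the cut become
    monotypic genera.
    """
    if not 0 < cut_depth_fraction < 1:
        raise ValidationError("cut depth fraction must be in (0, 1)")
    cut = cut_depth_fraction * phy.depth
    phy.tree.calc_node_root_distances(return_leaf_distances_only=False)
    genera: dict[str, str] = {}
    counter = 0
    for node in phy.tree.preorder_node_iter():
        parent = node.parent_node
        start = parent.root_distance if parent is not None else 0.0
        if start <= cut < node.root_distance:
            counter += 1
            for leaf in ([node] if node.is_leaf() else node.leaf_iter()):
                genera[leaf.taxon.label] = f"gen{counter:03d}"
    for tip in phy.tip_labels:  # tips whose whole path lies above the cut
        if tip not in genera:
            counter += 1
            genera[tip] = f"gen{counter:03d}"
    return genera


# ---------------------------------------------------------------------------
# traits


def simulate_bm_traits(phy: Phylogeny, sigma2: float = 1.0, seed: int = 0,
                       root_value: float = 0.0) -> pd.Series:
    """Brownian-motion trait: root value plus Gaussian increments per branch
    with variance sigma2 × branch length; tip covariance is sigma2 × V."""
    if sigma2 < 0:
        raise ValidationError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    value = {phy.tree.seed_node: root_value}
    out = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is not None:
            step = rng.normal(0.0, np.sqrt(sigma2 * node.edge.length))
            value[node] = value[node.parent_node] + step
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return pd.Series(out).sort_index()


def white_noise_traits(species: list[str], sigma2: float = 1.0,
                       seed: int = 0, mean: float = 0.0) -> pd.Series:
    """iid normal trait values — the no-phylogenetic-signal contrast."""
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(mean, np.sqrt(sigma2), len(species)),
                     index=species).sort_index()


def _to_measurement_scale(x: pd.Series, lo: float, hi: float,
                          scale: str) -> pd.Series:
    """Affine-map simulated values onto a printed trait range (log10 scale
    for traits analysed on log10), preserving Brownian structure."""
    lo_t, hi_t = (np.log10(lo), np.log10(hi)) if scale == "log10" else (lo, hi)
    span = x.max() - x.min()
    z = (x - x.min()) / span if span > 0 else x * 0.0
    y = lo_t + z * (hi_t - lo_t)
    return 10.0 ** y if scale == "log10" else y


def simulate_trait_table(phy: Phylogeny, seed: int = 0,
                         sigma2: float = 1.0) -> pd.DataFrame:
    """Three BM traits on measurement scales matching field ranges."""
    cols = {}
    for i, (name, (lo, hi, scale)) in enumerate(TRAIT_RANGES.items()):
        x = simulate_bm_traits(phy, sigma2=sigma2, seed=seed * 7919 + i)
        cols[name] = _to_measurement_scale(x, lo, hi, scale)
    df = pd.DataFrame(cols)
    df.index.name = "species_id"
    return df


# ---------------------------------------------------------------------------
# community assembly


@dataclass(frozen=True)
class AssemblyScenario:
    """How quadrat composition is drawn from the pool.

    mode "random": uniform sampling without replacement.
    mode "filtering": weights ∝ exp(−strength × d(species, focal)), with one
    focal species per plot — an environmental-optimum proxy producing
    phylogenetic clustering (expected NRI > 0).
    mode "overdispersion": each next species weighted ∝ exp(+strength × min
    distance to those already selected), producing overdispersion (NRI < 0).
    strength = 0 reduces every mode to random.  Richness per quadrat is
    uniform on ``richness_range`` (woody-species counts typical of 10 m
    quadrats); abundances follow a geometric rank-abundance series with the
    given ratio, with Poisson noise, minimum 1.
    """

    mode: str = "random"
    strength: float = 5.0
    richness_range: tuple[int, int] = (6, 14)
    abundance_ratio: float = 0.7
    abundance_base: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "filtering", "overdispersion"):
            raise ValidationError(f"unknown assembly mode {self.mode!r}")
        if self.strength < 0:
            raise ValidationError("strength must be nonnegative")
        if self.richness_range[0] < 1 or \
                self.richness_range[1] < self.richness_range[0]:
            raise ValidationError("invalid richness range")


def _weighted_sample_without_replacement(weights: np.ndarray, k: int,
                                         rng: np.random.Generator
                                         ) -> list[int]:
    chosen: list[int] = []
    w = weights.astype(float).copy()
    for _ in range(k):
        p = w / w.sum()
        pick = rng.choice(len(w), p=p)
        chosen.append(pick)
        w[pick] = 0.0
    return chosen


def simulate_assembly(phy: Phylogeny, pool: SpeciesPool,
                      scenario: AssemblyScenario = AssemblyScenario(),
                      n_plots: int = 5, grid: tuple[int, int] = (5, 5),
                      layer: str = "tree", seed: int = 0,
                      dm=None) -> CommunityMatrix:
    """Draw a quadrat × species community matrix under an assembly scenario.

    Species are sampled sequentially without replacement per quadrat (see
    :class:`AssemblyScenario`); the distance matrix steering filtering and
    overdispersion is the tree's cophenetic matrix (precomputed ``dm`` may be
    passed to avoid recomputation).  Abundance of the i-th selected species
    is max(1, Poisson(base × ratio^i)).
    """
    members = sorted(pool.members)
    absent = sorted(set(members) - set(phy.tip_labels))
    if absent:
        raise ValidationError(f"pool members not in tree: {absent}")
    if scenario.richness_range[1] > len(members):
        raise ValidationError(
            f"richness up to {scenario.richness_range[1]} infeasible for a "
            f"{len(members)}-species pool")
    rng = np.random.default_rng(seed)
    need_dm = scenario.mode != "random" and scenario.strength > 0
    if need_dm:
        if dm is None:
            dm = cophenetic_distances(phy)
        pos = [dm.index(s) for s in members]
        D = dm.data[np.ix_(pos, pos)]
    n = len(members)
    lo, hi = scenario.richness_range
    rows = []
    for p in range(n_plots):
        plot = f"plot{p + 1}"
        if need_dm and scenario.mode == "filtering":
            focal = rng.integers(n)
            base_w = np.exp(-scenario.strength * D[focal])
        for r in range(grid[0]):
            for c in range(grid[1]):
                k = int(rng.integers(lo, hi + 1))
                if not need_dm:
                    chosen = list(rng.choice(n, size=k, replace=False))
                elif scenario.mode == "filtering":
                    chosen = _weighted_sample_without_replacement(
                        base_w, k, rng)
                else:  # overdispersion
                    chosen = [int(rng.integers(n))]
                    while len(chosen) < k:
                        mind = D[:, chosen].min(axis=1)
                        w = np.exp(scenario.strength * mind)
                        w[chosen] = 0.0
                        w = w / w.sum()
                        chosen.append(int(rng.choice(n, p=w)))
                counts = np.maximum(1, rng.poisson(
                    scenario.abundance_base
                    * scenario.abundance_ratio ** np.arange(k)))
                row = {"plot_id": plot, "grid_row": r, "grid_col": c,
                       "layer": layer}
                row.update({members[i]: 0 for i in range(n)})
                for i, idx in enumerate(chosen):
                    row[members[idx]] = int(counts[i])
                rows.append(row)
    return CommunityMatrix(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# fixture bundles


@dataclass
class FixtureBundle:
    """Tree + traits + communities + genus map + regional pool."""

    phylogeny: Phylogeny
    traits: pd.DataFrame
    communities: CommunityMatrix
    genus_map: dict[str, str]
    regional_pool: list[str]
    seed: int = 0

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "communities": outdir / "communities.csv",
            "traits": outdir / "traits.csv",
            "genus_map": outdir / "genus_map.csv",
            "regional_pool": outdir / "regional_pool.csv",
        }
        paths["tree"].write_text(self.phylogeny.as_newick() + "\n")
        self.communities.to_csv(paths["communities"])
        self.traits.reset_index().to_csv(paths["traits"], index=False)
        pd.DataFrame(sorted(self.genus_map.items()),
                     columns=["species_id", "genus_id"]
                     ).to_csv(paths["genus_map"], index=False)
        pd.DataFrame({"species_id": sorted(self.regional_pool)}
                     ).to_csv(paths["regional_pool"], index=False)
        return paths


def make_fixture(paper_scale: bool = False, seed: int = 0,
                 scenario: Optional[AssemblyScenario] = None) -> FixtureBundle:
    """Synthetic study bundle.

    paper_scale=True mirrors the study design: 147-species regional pool,
    a 51-species local candidate pool, 5 plots × 5 × 5 quadrats × 2 layers
    (250 census rows).  paper_scale=False is a fast 12-species, 2-plot,
    2 × 2-grid bundle for tests.  Identical seeds give identical bundles.
    """
    rng = np.random.default_rng(seed)
    if paper_scale:
        n_regional, n_local = 147, 51
        n_plots, grid = 5, (5, 5)
        richness = (6, 14)
    else:
        n_regional, n_local = 12, 8
        n_plots, grid = 2, (2, 2)
        richness = (2, 5)
    phy = simulate_yule_tree(n_regional, seed=int(rng.integers(2 ** 31)))
    traits = simulate_trait_table(phy, seed=int(rng.integers(2 ** 20)))
    genus_map = assign_genera(phy)
    local = sorted(rng.choice(phy.tip_labels, size=n_local, replace=False))
    local_pool = SpeciesPool("local", frozenset(local))
    if scenario is None:
        scenario = AssemblyScenario(mode="random", richness_range=richness)
    else:
        scenario = AssemblyScenario(
            mode=scenario.mode, strength=scenario.strength,
            richness_range=richness, abundance_ratio=scenario.abundance_ratio,
            abundance_base=scenario.abundance_base)
    dm = cophenetic_distances(phy) if scenario.mode != "random" else None
    frames = []
    for layer in ("tree", "shrub"):
        cm = simulate_assembly(
            phy, local_pool, scenario, n_plots=n_plots, grid=grid,
            layer=layer, seed=int(rng.integers(2 ** 31)), dm=dm)
        frames.append(cm.data)
    combined = pd.concat(frames, ignore_index=True)
    # regional pool columns absent from the local pool stay as explicit zeros
    for sp in phy.tip_labels:
        if sp not in combined.columns:
            combined[sp] = 0
    meta = ["plot_id", "grid_row", "grid_col", "layer"]
    combined = combined[meta + sorted(phy.tip_labels)]
    communities = CommunityMatrix(combined)
    return FixtureBundle(phy, traits, communities, genus_map,
                         sorted(phy.tip_labels), seed=seed)
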