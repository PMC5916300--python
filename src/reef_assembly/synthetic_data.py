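"""Seeded generators for every input the pipeline consumes.

Yule trees, Brownian quantitative traits with intraspecific replicates,
symmetric k-state Markov discrete traits, noisy gene-distance matrices,
and nested metacommunities assembled under neutral, environmental-
filtering or limiting-similarity regimes with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import NestedCommunity
from .distances import DistanceMatrix
from .tree import PhyloTree

__all__ = [
    "ScenarioConfig",
    "simulate_yule_tree",
    "simulate_bm_trait",
    "simulate_mk_discrete",
    "simulate_metacommunity",
    "perturbed_gene_distance",
    "simulate_scenario",
]


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def simulate_yule_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth tree with ``n`` tips, grown to ultrametric depth.

    Lineages split at exponential waiting times with total rate
    ``birth_rate * k``; after the (n-1)-th split all pending branches are
    extended by a final Exp(birth_rate * n) epoch so tips are contemporaneous.
    """
    if n < 3:
        raise ValueError("need n >= 3 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    class _Node:
        __slots__ = ("children", "born", "end", "label")

        def __init__(self, born: float):
            self.children: list["_Node"] = []
            self.born = born
            self.end = born
            self.label = ""

    root = _Node(0.0)
    active = [_Node(0.0), _Node(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        nd = active.pop(int(rng.integers(k)))
        nd.end = t
        nd.children = [_Node(t), _Node(t)]
        active.extend(nd.children)
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    for i, nd in enumerate(active):
        nd.end = t_end
        nd.label = f"sp{i + 1}"

    def _newick(nd: _Node) -> str:
        if not nd.children:
            return f"{nd.label}:{nd.end - nd.born:.12f}"
        inner = ",".join(_newick(c) for c in nd.children)
        return f"({inner}):{nd.end - nd.born:.12f}"

    inner = ",".join(_newick(c) for c in root.children)
    return PhyloTree.from_newick(f"({inner});")


# ----------------------------------------------------------------------
# traits
# ----------------------------------------------------------------------

def simulate_bm_trait(
    tree: PhyloTree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    intraspecific_sd: float = 0.0,
    n_individuals: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Brownian species means plus Gaussian individual noise.

    Returns a per-individual table ``species, value``; species means are
    recoverable by grouping.  ``sigma2`` is the Brownian rate per unit
    branch length.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    node_val = np.zeros(tree.n_nodes)
    node_val[tree.root] = root_value
    for i in tree.postorder[::-1]:
        p = tree.parent[i]
        if p >= 0:
            bl = tree.edge_len[i]
            node_val[i] = node_val[p] + rng.normal(0.0, np.sqrt(sigma2 * bl))
    rows = []
    for i, label in enumerate(tree.tip_labels):
        for _ in range(n_individuals):
            rows.append(
                (label, node_val[i] + rng.normal(0.0, intraspecific_sd))
            )
    return pd.DataFrame(rows, columns=["species", "value"])


def simulate_mk_discrete(
    tree: PhyloTree, k_states: int = 4, rate: float = 1.0, seed: int = 0
) -> dict[str, int]:
    """Symmetric k-state continuous-time Markov chain along the branches.

    ``rate`` is the total rate of leaving the current state; on a change
    the new state is uniform over the other k-1 states.  Returns tip
    states keyed by label.
    """
    if k_states < 2:
        raise ValueError("need k_states >= 2")
    rng = np.random.default_rng(seed)
    node_state = np.zeros(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = int(rng.integers(k_states))
    for i in tree.postorder[::-1]:
        p = tree.parent[i]
        if p < 0:
            continue
        state = node_state[p]
        remaining = tree.edge_len[i]
        if rate > 0:
            while True:
                wait = rng.exponential(1.0 / rate)
                if wait >= remaining:
                    break
                remaining -= wait
                jump = int(rng.integers(k_states - 1))
                state = jump if jump < state else jump + 1
        node_state[i] = state
    return {label: int(node_state[i]) for i, label in enumerate(tree.tip_labels)}


# ----------------------------------------------------------------------
# gene-distance proxies
# ----------------------------------------------------------------------

def perturbed_gene_distance(
    tree: PhyloTree,
    noise: float = 0.0,
    seed: int = 0,
    name: str = "gene",
) -> DistanceMatrix:
    """Noisy proxy for a per-gene distance matrix.

    The patristic matrix is rescaled to [0, 1] and each off-diagonal entry
    multiplied by a lognormal factor with spread ``noise`` (0 = exact copy),
    then resymmetrized and clipped.  Stands in for per-gene p-distance
    matrices in robustness sweeps; no substitution model is simulated.
    """
    rng = np.random.default_rng(seed)
    d = tree.patristic()
    mx = d.max()
    if mx > 0:
        d = d / mx
    if noise > 0:
        f = rng.lognormal(mean=0.0, sigma=noise, size=d.shape)
        f = (f + f.T) / 2.0
        d = np.clip(d * f, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tree.tip_labels, d, source=f"pdist:{name}")


# ----------------------------------------------------------------------
# metacommunities
# ----------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Design and assembly regime for a synthetic nested metacommunity."""

    n_atolls: int = 3
    sites_per_atoll: Sequence[int] | int = 4
    colonies_per_site: Sequence[int] | int = 3
    individuals_per_colony: int = 50
    assembly: str = "neutral"  # neutral | filtering | limiting
    filter_level: str = "site"  # atoll | site | colony
    optimum_spread: float = 2.0
    niche_width: float = 0.5
    repulsion: float = 5.0
    sad_mu: float = 0.0
    sad_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.assembly not in ("neutral", "filtering", "limiting"):
            raise ValueError(f"unknown assembly regime {self.assembly!r}")
        if self.filter_level not in ("atoll", "site", "colony"):
            raise ValueError(f"unknown filter level {self.filter_level!r}")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be > 0")
        if self.n_atolls < 1 or self.individuals_per_colony < 1:
            raise ValueError("dims must be >= 1")


def _design(config: ScenarioConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """(site_of_colony, atoll_of_site) arrays for the configured design."""
    A = config.n_atolls
    spa = config.sites_per_atoll
    if isinstance(spa, int):
        spa = [spa] * A
    if len(spa) != A:
        raise ValueError("sites_per_atoll length != n_atolls")
    atoll_of_site = np.repeat(np.arange(A), spa)
    n_sites = atoll_of_site.shape[0]
    cps = config.colonies_per_site
    if isinstance(cps, int):
        cps = [cps] * n_sites
    if len(cps) != n_sites:
        raise ValueError("colonies_per_site length != number of sites")
    site_of_colony = np.repeat(np.arange(n_sites), cps)
    return site_of_colony, atoll_of_site


def simulate_metacommunity(
    config: ScenarioConfig,
    tree: PhyloTree,
    trait: dict[str, float] | pd.Series,
) -> tuple[NestedCommunity, dict]:
    """Assemble a nested community under the configured regime.

    * neutral — every colony draws ``N`` individuals from one shared
      lognormal species-abundance distribution, independent of traits;
    * filtering — each unit at ``filter_level`` draws an environmental
      optimum (Normal(trait mean, optimum_spread)); species weights are the
      SAD times ``exp(-(trait - optimum)^2 / (2 h^2))`` with
      ``h = niche_width``;
    * limiting — colonies are filled one individual at a time; a species'
      weight is down-scaled by ``exp(-repulsion * max similarity to
      residents)`` where similarity is 1 minus the range-scaled trait gap.

    Returns the community and a ground-truth dict for power experiments.
    """
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    species = list(tree.tip_labels)
    missing = [s for s in species if s not in trait]
    if missing:
        raise ValueError(f"trait missing for species: {missing}")
    tvals = np.array([float(trait[s]) for s in species])
    rng = np.random.default_rng(config.seed)
    soc, aos = _design(config, rng)
    n_colonies = soc.shape[0]
    n_sites = aos.shape[0]
    n_sp = len(species)
    N = config.individuals_per_colony

    sad = rng.lognormal(config.sad_mu, config.sad_sigma, size=n_sp)
    sad /= sad.sum()

    X = np.zeros((n_colonies, n_sp), dtype=np.int64)
    truth: dict = {"assembly": config.assembly, "seed": config.seed}

    if config.assembly == "neutral":
        for c in range(n_colonies):
            X[c] = rng.multinomial(N, sad)
    elif config.assembly == "filtering":
        h = config.niche_width
        center, spread = tvals.mean(), config.optimum_spread
        if config.filter_level == "atoll":
            unit_of_colony = aos[soc]
            n_units = int(aos.max()) + 1
        elif config.filter_level == "site":
            unit_of_colony = soc
            n_units = n_sites
        else:
            unit_of_colony = np.arange(n_colonies)
            n_units = n_colonies
        optima = rng.normal(center, spread, size=n_units)
        truth["optima"] = optima.tolist()
        truth["filter_level"] = config.filter_level
        for c in range(n_colonies):
            opt = optima[unit_of_colony[c]]
            w = sad * np.exp(-((tvals - opt) ** 2) / (2.0 * h**2))
            if w.sum() == 0:
                w = sad
            X[c] = rng.multinomial(N, w / w.sum())
    else:  # limiting
        trange = np.ptp(tvals) or 1.0
        sim = 1.0 - np.abs(tvals[:, None] - tvals[None, :]) / trange
        rep = config.repulsion
        for c in range(n_colonies):
            present = np.zeros(n_sp, dtype=bool)
            for _ in range(N):
                if present.any():
                    max_sim = sim[:, present].max(axis=1)
                    w = sad * np.exp(-rep * max_sim)
                else:
                    w = sad
                j = rng.choice(n_sp, p=w / w.sum())
                X[c, j] += 1
                present[j] = True
        truth["repulsion"] = rep

    # guard: a colony can come out empty only if N = 0, which is rejected
    community = NestedCommunity.from_arrays(X, soc, aos, species)
    return community, truth


# ----------------------------------------------------------------------
# full scenario bundle
# ----------------------------------------------------------------------

def simulate_scenario(
    n_species: int,
    config: ScenarioConfig,
    bm_sigma2: float = 1.0,
    intraspecific_sd: float = 0.1,
    n_individuals: int = 5,
    seed: int | None = None,
):
    """Tree + individual trait table + community, all from one seed.

    Convenience wrapper used by the pipeline's ``simulate`` command and by
    the test-bed experiments.
    """
    seed = config.seed if seed is None else seed
    tree = simulate_yule_tree(n_species, seed=seed)
    indiv = simulate_bm_trait(
        tree,
        sigma2=bm_sigma2,
        intraspecific_sd=intraspecific_sd,
        n_individuals=n_individuals,
        seed=seed + 1,
    )
    means = indiv.groupby("species")["value"].mean()
    community, truth = simulate_metacommunity(config, tree, means)
    return tree, indiv, community, truth
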