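"""Synthetic trees and correlated gain/loss profiles with planted modules.

Real inputs to the screen are orthogroup presence/absence profiles over
hundreds to a thousand-plus genomes, where functionally linked genes (such
as the subunits of a sperm calcium channel) show a shared, discontinuous
pattern of lineage-specific gains and losses against a background of
independently evolving gene families.  This module emulates that situation
so the whole pipeline can be exercised and benchmarked without any
database access, and records the ground truth for recovery metrics.

Model.  Each gene evolves down a random rooted bifurcating tree as a
two-state (present/absent) process: the root state is Bernoulli(rho0), and
along every branch a present gene is lost with probability mu and an
absent gene is (re)gained with probability lambda.  Genes in a planted
coevolving module additionally share "event branches" — a fraction sigma
of branches drawn once per module — on which a single coin per module per
branch (probability kappa) flips every member together; that shared coin
is exactly what creates the concordant transitions the screen detects.
Branch lengths (exponential, mean 1) are generated for realism but do not
modulate the per-branch flip probabilities.

Randomness.  A single generator seeded from the config drives everything
in a fixed draw order: root states for all genes, then the event-branch
choice per module, then — branch by branch in preorder — the independent
flip draws for all genes followed by one co-event coin per module.
Identical config and seed give a bit-identical matrix and truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .profile_io import canonical_leaf_order

__all__ = [
    "ModuleSpec",
    "GainLossConfig",
    "SimulationTruth",
    "simulate_tree",
    "simulate_profiles",
    "evaluate_recovery",
    "RecoveryMetrics",
]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted coevolving module.

    ``n_members`` genes share ``sigma`` (fraction of branches) event
    branches, on each of which all members flip together with probability
    ``kappa``.
    """

    n_members: int = 10
    sigma: float = 0.15
    kappa: float = 0.9

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("a module needs >= 2 members")
        if not (0.0 <= self.sigma <= 1.0 and 0.0 <= self.kappa <= 1.0):
            raise ValueError("sigma and kappa must lie in [0, 1]")


@dataclass(frozen=True)
class GainLossConfig:
    """Configuration of the gain/loss simulation.

    Defaults reproduce the benchmark condition used throughout the test
    suite: a 300-genome tree, 200 independent background genes and one
    10-gene module with sigma=0.15, kappa=0.9 on top of per-branch loss
    and gain probabilities mu = lambda = 0.05 with every gene present at
    the root (rho0 = 1).
    """

    n_leaves: int = 300
    mu: float = 0.05  # per-branch loss probability (present -> absent)
    lam: float = 0.05  # per-branch gain probability (absent -> present)
    rho0: float = 1.0  # root presence probability
    n_background: int = 200
    modules: tuple[ModuleSpec, ...] = (ModuleSpec(),)
    seed: int = 20230317
    tree_seed: int | None = None  # defaults to seed

    def __post_init__(self) -> None:
        if self.n_leaves < 4:
            raise ValueError("need at least 4 leaves")
        for p, name in ((self.mu, "mu"), (self.lam, "lam"), (self.rho0, "rho0")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulation run."""

    module_members: dict[int, tuple[str, ...]]
    event_branches: dict[int, tuple[int, ...]]  # preorder edge indices

    def module_of(self, gene: str) -> int | None:
        for mid, members in self.module_members.items():
            if gene in members:
                return mid
        return None


def simulate_tree(n_leaves: int, seed: int) -> dendropy.Tree:
    """Random rooted bifurcating tree by recursive random splits.

    Leaf labels are ``sp0001`` ... ``sp{N}``; branch lengths are drawn
    from an exponential distribution with mean 1.  Deterministic under
    ``seed``.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"sp{i + 1:04d}" for i in range(n_leaves)]

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: dendropy.Node, members: list[str]) -> None:
        if len(members) == 1:
            node.taxon = taxa.get_taxon(members[0])
            return
        k = int(rng.integers(1, len(members)))  # uniform split point
        perm = rng.permutation(len(members))
        left = [members[i] for i in perm[:k]]
        right = [members[i] for i in perm[k:]]
        for part in (left, right):
            child = dendropy.Node(edge_length=float(rng.exponential(1.0)))
            node.add_child(child)
            build(child, part)

    build(tree.seed_node, labels)
    return tree


def _preorder_edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Child nodes of all edges, in preorder (root edge excluded)."""
    return [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]


def simulate_profiles(
    tree: dendropy.Tree, config: GainLossConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a phyletic profile matrix with planted modules.

    Returns the matrix (genes x genomes, columns in the canonical leaf
    order of ``tree``) and the ground truth.  Background genes are named
    ``bg0001``...; module genes ``mod<m>_g<i>``.
    """
    rng = np.random.default_rng(config.seed)
    edges = _preorder_edges(tree)
    n_edges = len(edges)

    gene_names = [f"bg{i + 1:04d}" for i in range(config.n_background)]
    module_members: dict[int, tuple[str, ...]] = {}
    module_index: list[np.ndarray] = []
    for mid, spec in enumerate(config.modules, start=1):
        members = [f"mod{mid}_g{i + 1:02d}" for i in range(spec.n_members)]
        idx = np.arange(len(gene_names), len(gene_names) + len(members))
        gene_names.extend(members)
        module_members[mid] = tuple(members)
        module_index.append(idx)
    n_genes = len(gene_names)

    # draw order: root states, event branches per module, then branch flips
    root_state = (rng.random(n_genes) < config.rho0).astype(np.int8)
    event_branches: dict[int, tuple[int, ...]] = {}
    event_sets: list[frozenset[int]] = []
    for mid, spec in enumerate(config.modules, start=1):
        n_events = int(round(spec.sigma * n_edges))
        chosen = rng.choice(n_edges, size=n_events, replace=False)
        chosen = tuple(sorted(int(e) for e in chosen))
        event_branches[mid] = chosen
        event_sets.append(frozenset(chosen))

    states: dict[int, np.ndarray] = {id(tree.seed_node): root_state}
    leaf_states: dict[str, np.ndarray] = {}
    for edge_idx, node in enumerate(edges):
        parent = states[id(node.parent_node)]
        flip_p = np.where(parent == 1, config.mu, config.lam)
        flips = rng.random(n_genes) < flip_p
        child = np.where(flips, 1 - parent, parent).astype(np.int8)
        for m, (spec, idx) in enumerate(zip(config.modules, module_index)):
            if edge_idx in event_sets[m]:
                coin = rng.random() < spec.kappa
                if coin:
                    child[idx] = 1 - parent[idx]  # co-flip overrides noise
        states[id(node)] = child
        if node.is_leaf():
            leaf_states[node.taxon.label] = child

    order = canonical_leaf_order(tree)
    matrix = pd.DataFrame(
        np.column_stack([leaf_states[g] for g in order]),
        index=gene_names,
        columns=order,
        dtype=np.int8,
    )
    truth = SimulationTruth(module_members=module_members, event_branches=event_branches)
    return matrix, truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """Recovery of one planted module by its best-matching cluster."""

    module_id: int
    precision: float
    recall: float
    jaccard: float
    best_cluster: tuple[str, ...] = field(default_factory=tuple)


def evaluate_recovery(clusters: ClusterSet, truth: SimulationTruth) -> list[RecoveryMetrics]:
    """Score each planted module against its best-matching cluster.

    The best match maximizes the Jaccard index; precision and recall are
    computed against that cluster.  With no clusters all metrics are 0.
    """
    out = []
    for mid, members in truth.module_members.items():
        mset = set(members)
        best_j, best_cl, best_p, best_r = 0.0, (), 0.0, 0.0
        for cl in clusters.clusters:
            cset = set(cl)
            inter = len(mset & cset)
            union = len(mset | cset)
            j = inter / union if union else 0.0
            if j > best_j:
                best_j = j
                best_cl = cl
                best_p = inter / len(cset)
                best_r = inter / len(mset)
        out.append(
            RecoveryMetrics(
                module_id=mid,
                precision=best_p,
                recall=best_r,
                jaccard=best_j,
                best_cluster=best_cl,
            )
        )
    return out
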