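"""Shared fixtures: tiny trees/matrices and the benchmark pipeline run."""

from __future__ import annotations

import dendropy
import pytest

import coevoscreen as cs
from coevoscreen.simulate import GainLossConfig


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


@pytest.fixture
def balanced_tree():
    return tree_from_string("((A,B),(C,D));")


@pytest.fixture
def small_matrix_tsv(tmp_path, balanced_tree):
    path = tmp_path / "profiles.tsv"
    path.write_text(
        "gene\tC\tA\tD\tB\n"  # columns deliberately shuffled vs tree order
        "g1\t1\t1\t0\t1\n"
        "g2\t0\t1\t1\t0\n"
        "g3\t1\t0\t1\t0\n"
    )
    return path


@pytest.fixture(scope="session")
def benchmark_run():
    """One full simulate -> screen -> graph -> MCL run at benchmark scale.

    300-genome tree, 200 background genes, one planted 10-gene module
    (sigma=0.15, kappa=0.9, mu=lam=0.05, rho0=1), shared by the recovery
    and clustering checks so the pipeline runs once per session.
    """
    config = GainLossConfig()
    tree = cs.simulate_tree(config.n_leaves, config.seed)
    matrix, truth = cs.simulate_profiles(tree, config)
    pairs = cs.screen_all_pairs(matrix)
    graph = cs.build_association_graph(pairs)
    clusters = cs.mcl(graph)
    return {
        "config": config,
        "tree": tree,
        "matrix": matrix,
        "truth": truth,
        "pairs": pairs,
        "graph": graph,
        "clusters": clusters,
    }
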