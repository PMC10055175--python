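"""Species trees and phyletic profile matrices.

The coevolution screen consumes a binary gene x genome matrix (a phyletic
profile: 1 if an orthogroup has at least one member in a genome, 0 if it is
absent) whose columns follow a single canonical, phylogeny-derived genome
ordering.  Fixing that ordering once is what makes "adjacent genome
boundaries" well defined for the transition statistic downstream, so every
reader in this module reindexes to it.

The canonical order is the left-to-right leaf sequence of the species tree
after deterministic ladderization: at every internal node children are
sorted by descending subtree leaf count, ties broken by the lexicographically
smallest leaf label in the subtree.  The order therefore depends only on the
tree topology, never on how the Newick string happened to be rotated.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "MatrixError",
    "read_newick",
    "canonical_leaf_order",
    "read_profile_matrix",
    "write_profile_matrix",
    "read_genome_order",
]


class TreeError(ValueError):
    """Malformed or invalid species tree."""


class MatrixError(ValueError):
    """Malformed or inconsistent phyletic profile matrix."""


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted species tree from a Newick file.

    Leaf labels are genome identifiers and must be unique and non-empty;
    the tree must have at least two leaves.  Branch lengths are read if
    present but are not used by the screen (the statistic is order-based,
    not rate-based).

    Raises
    ------
    TreeError
        On a parse error (with the parser's position information), on
        duplicate leaf labels, or on a tree with fewer than two leaves.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree, source=str(path))


def _validate_tree(tree: dendropy.Tree, source: str = "<tree>") -> dendropy.Tree:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None or lab == "" for lab in labels):
        raise TreeError(f"{source}: tree contains an unlabeled leaf")
    if len(labels) < 2:
        raise TreeError(f"{source}: tree has {len(labels)} leaves; need >= 2")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeError(f"{source}: duplicate leaf label {lab!r}")
        seen.add(lab)
    return tree


def canonical_leaf_order(tree: dendropy.Tree) -> list[str]:
    """Deterministic ladderized leaf order of a species tree.

    Children of each internal node are visited in order of descending
    subtree leaf count; ties are broken by the lexicographically smallest
    leaf label within the subtree.  Idempotent, and invariant under child
    rotations of the input Newick string.
    """
    _validate_tree(tree)

    # postorder pass: (leaf count, smallest label) per node
    stats: dict[int, tuple[int, str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[id(node)] = (1, node.taxon.label)
        else:
            counts = [stats[id(ch)] for ch in node.child_nodes()]
            stats[id(node)] = (
                sum(c for c, _ in counts),
                min(lab for _, lab in counts),
            )

    order: list[str] = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            order.append(node.taxon.label)
        else:
            children = sorted(
                node.child_nodes(),
                key=lambda ch: (-stats[id(ch)][0], stats[id(ch)][1]),
            )
            stack.extend(reversed(children))
    return order


def read_genome_order(path: str | Path) -> list[str]:
    """Read an explicit genome ordering (one genome identifier per line).

    Used to override the ladderized order, e.g. to reproduce a published
    linearization.  Blank lines are ignored; duplicates are an error.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    order = [ln for ln in lines if ln]
    if len(set(order)) != len(order):
        raise MatrixError(f"duplicate genome identifier in order file {path}")
    if not order:
        raise MatrixError(f"order file {path} is empty")
    return order


def read_profile_matrix(
    path: str | Path,
    tree: dendropy.Tree | None = None,
    order: Sequence[str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read a phyletic profile matrix (TSV) and reindex to canonical order.

    Format: header row of genome identifiers, first column gene identifiers,
    cells 0/1.  Lines starting with ``#`` are treated as comments.

    Exactly one of ``tree``/``order`` fixes the genome ordering.  Genomes in
    the TSV but not in the order are always an error.  Genomes in the order
    but missing from the TSV are an error in strict mode (default); in
    lenient mode they are dropped from the order with a logged warning.

    Returns a DataFrame with gene identifiers as index, genomes as columns
    in canonical order, dtype int8.
    """
    if (tree is None) == (order is None):
        raise ValueError("provide exactly one of tree= or order=")
    canon = list(order) if order is not None else canonical_leaf_order(tree)

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    df.index = df.index.astype(str)

    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise MatrixError(f"{path}: duplicate gene row(s): {dups}")

    unknown = [g for g in df.columns if g not in set(canon)]
    if unknown:
        raise MatrixError(f"{path}: genome(s) not in the tree/order: {sorted(unknown)}")

    missing = [g for g in canon if g not in set(df.columns)]
    if missing:
        if strict:
            raise MatrixError(
                f"{path}: genome(s) in the tree/order but absent from the "
                f"matrix: {sorted(missing)} (use lenient mode to drop them)"
            )
        logger.warning(
            "dropping %d genome(s) absent from %s: %s", len(missing), path, sorted(missing)
        )
        canon = [g for g in canon if g not in set(missing)]

    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell not in ("0", "1"):
                raise MatrixError(
                    f"{path}: non-binary cell {cell!r} at gene {df.index[i]!r}, "
                    f"genome {col!r}"
                )
            values[i, j] = int(cell)

    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    return out[canon]


def write_profile_matrix(matrix: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a profile matrix as TSV (gene rows, genome columns).

    ``header``, if given, is written as a leading ``#`` comment line.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        matrix.to_csv(fh, sep="\t", index_label="gene")
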