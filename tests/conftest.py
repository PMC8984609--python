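"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use a different computation path than the library:
PD by per-leaf root walks, module completeness by enumerating every
combination of one alternative per step.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phycofunc.module_catalog import ModuleDefinition, builtin_catalog
from phycofunc.phylo_metrics import read_tree
from phycofunc.synthetic_data import simulate_tree


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture()
def small_tree():
    # ((A:1,B:1):1,C:2); — total length 5
    return read_tree("((A:1,B:1):1,C:2);")


def brute_force_pd(tree, taxa: set[str]) -> float:
    """Union of per-leaf walks to the root; sums each edge once."""
    edges = set()
    for leaf in tree.leaf_nodes():
        if leaf.taxon.label not in taxa:
            continue
        node = leaf
        while node is not tree.seed_node:
            edges.add(id(node))
            node = node.parent_node
    by_id = {id(n): n for n in tree.preorder_node_iter()}
    total = sum(by_id[e].edge.length or 0.0 for e in edges)
    return total + (tree.seed_node.edge.length or 0.0)


def brute_force_completeness(definition: ModuleDefinition, ko_set: set[str]) -> float:
    """Max satisfied-step fraction over every combination of one alternative
    per step (equivalent to per-step independence, computed the long way)."""
    best = 0
    for combo in itertools.product(*[sorted(map(sorted, s)) for s in definition.steps]):
        sat = sum(1 for alt in combo if set(alt) <= ko_set)
        best = max(best, sat)
    return best / definition.n_steps


def brute_force_keys(definition: ModuleDefinition, ko_set: set[str]) -> bool:
    if not definition.key_requirements:
        return True
    for combo in itertools.product(
        *[sorted(map(sorted, c)) for c in definition.key_requirements]
    ):
        if all(set(alt) <= ko_set for alt in combo):
            return True
    return False


def random_module(rng: np.random.Generator, pool_size: int = 10) -> ModuleDefinition:
    """Random small module (≤ 4 steps, ≤ 3 alternatives, complexes ≤ 2)."""
    pool = [f"K{i:05d}" for i in range(1, pool_size + 1)]
    steps = []
    for _ in range(rng.integers(1, 5)):
        alts = []
        for _ in range(rng.integers(1, 4)):
            size = int(rng.integers(1, 3))
            alts.append(frozenset(rng.choice(pool, size=size, replace=False)))
        steps.append(frozenset(alts))
    step_idents = sorted({i for s in steps for a in s for i in a})
    keys = []
    if rng.random() < 0.5 and step_idents:
        size = int(rng.integers(1, min(3, len(step_idents)) + 1))
        keys.append(frozenset({frozenset(rng.choice(step_idents, size=size, replace=False))}))
    return ModuleDefinition(
        module_id="RND",
        name="random",
        category="nitrogen",
        steps=tuple(steps),
        key_requirements=tuple(keys),
    )


def random_trees(n_trees: int, max_leaves: int = 8, seed: int = 0):
    rng = np.random.default_rng(seed)
    for k in range(n_trees):
        n = int(rng.integers(2, max_leaves + 1))
        yield read_tree(simulate_tree(n, seed=int(rng.integers(0, 2**31 - 1))))
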