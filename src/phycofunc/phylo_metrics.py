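"""Faith's phylogenetic diversity (PD) and phylogenetic gain (PG).

PD of a taxon set on a rooted tree is the total branch length on the union
of paths from each taxon to the root, so PD(all leaves) equals the total
tree length exactly. PG of an ingroup is the additional branch length it
contributes::

    PG(ingroup) = PD(all leaves) − PD(leaves \\ ingroup)

which makes PG additive with the complement's PD by construction. An
unrooted variant (length of the minimal subtree spanning the taxa, root
path excluded) is available behind a flag for comparison with tools that
use that convention.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd

from phycofunc.util import round_half_away

PD_ROWS = ("full_tree", "outgroup_pd", "ingroup_pd", "ingroup_pg")


class TreeError(ValueError):
    pass


def read_tree(newick_text: str) -> dendropy.Tree:
    """Parse a rooted newick tree with branch lengths.

    Missing branch lengths default to 0 (with a warning); negative lengths
    and duplicate leaf labels are rejected; a single-leaf tree is
    degenerate and rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"unparseable newick: {exc}") from exc
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise TreeError(f"degenerate tree with {len(leaves)} leaf/leaves")
    labels = [leaf.taxon.label for leaf in leaves if leaf.taxon is not None]
    if len(labels) != len(leaves):
        raise TreeError("unlabeled leaf node")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            if edge.head_node is not tree.seed_node:
                missing += 1
            edge.length = 0.0
        elif edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    if missing:
        warnings.warn(f"{missing} branch length(s) missing; defaulted to 0")
    tree.is_rooted = True
    return tree


def read_tree_file(path: str | Path) -> dendropy.Tree:
    return read_tree(Path(path).read_text())


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_nodes())


def total_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def _check_taxa(tree: dendropy.Tree, taxa: frozenset[str]) -> None:
    unknown = taxa - leaf_labels(tree)
    if unknown:
        raise TreeError(f"unknown leaf ids: {sorted(unknown)}")


def faith_pd(
    tree: dendropy.Tree, taxa: Iterable[str], *, rooted: bool = True
) -> float:
    """Faith's PD of ``taxa`` on the tree.

    Rooted convention (default): an edge contributes iff its subtree holds
    at least one selected taxon. Unrooted: it must also separate selected
    taxa (at least one on each side), i.e. the minimal spanning subtree.
    """
    taxa = frozenset(taxa)
    if not taxa:
        raise TreeError("taxa set must be non-empty")
    _check_taxa(tree, taxa)
    n_total = len(taxa)
    # single postorder pass: count selected leaves below each edge
    below: dict[int, int] = {}
    pd_sum = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            count = 1 if node.taxon.label in taxa else 0
        else:
            count = sum(below[id(ch)] for ch in node.child_nodes())
        below[id(node)] = count
        if node is tree.seed_node:
            continue
        contributes = count >= 1 if rooted else 0 < count < n_total
        if contributes:
            pd_sum += node.edge.length or 0.0
    root_len = tree.seed_node.edge.length or 0.0
    if rooted and root_len:
        pd_sum += root_len  # root stem counts toward every rooted PD
    return pd_sum


def phylogenetic_gain(
    tree: dendropy.Tree, ingroup: Iterable[str], *, rooted: bool = True
) -> float:
    """Additional branch length contributed by ``ingroup``:
    PD(all leaves) − PD(complement)."""
    ingroup = frozenset(ingroup)
    _check_taxa(tree, ingroup)
    complement = leaf_labels(tree) - ingroup
    if not complement:
        raise TreeError("ingroup equals the full leaf set; complement is empty")
    full = faith_pd(tree, leaf_labels(tree), rooted=rooted)
    return full - faith_pd(tree, complement, rooted=rooted)


def pd_table_from_values(
    full_pd: float,
    outgroup_pd: float,
    ingroup_pd: float | None = None,
    *,
    n_full: int | None = None,
    n_outgroup: int | None = None,
    n_ingroup: int | None = None,
) -> pd.DataFrame:
    """Desk-scale PD/PG accounting from already-computed PD values.

    Returns the four-row summary (full tree, outgroup PD, ingroup PD,
    ingroup PG) with percent PD = 100 × pd / full_pd, unrounded; use
    :func:`format_pd_summary` for the printed 2-decimal form. The PG row is
    full − outgroup, computed from the (possibly rounded) inputs given.
    """
    if full_pd <= 0:
        raise ValueError("full_pd must be positive")
    pg = full_pd - outgroup_pd
    rows = {
        "full_tree": (n_full, full_pd),
        "outgroup_pd": (n_outgroup, outgroup_pd),
        "ingroup_pd": (n_ingroup, ingroup_pd),
        "ingroup_pg": (n_ingroup, pg),
    }
    df = pd.DataFrame(
        {
            "n_taxa": [rows[r][0] for r in PD_ROWS],
            "pd": [rows[r][1] for r in PD_ROWS],
        },
        index=list(PD_ROWS),
    )
    df["percent_pd"] = 100.0 * df["pd"] / full_pd
    return df


def pd_summary(
    tree: dendropy.Tree,
    ingroup: Iterable[str],
    outgroup: Iterable[str],
    *,
    rooted: bool = True,
) -> pd.DataFrame:
    """Full PD/PG summary for a disjoint ingroup/outgroup leaf partition.

    Percent PD is computed from unrounded internals; the full-tree row is
    100.00 by construction.
    """
    ingroup, outgroup = frozenset(ingroup), frozenset(outgroup)
    overlap = ingroup & outgroup
    if overlap:
        raise TreeError(f"ingroup/outgroup overlap: {sorted(overlap)[:5]}")
    all_leaves = leaf_labels(tree)
    if ingroup | outgroup != all_leaves:
        missing = all_leaves - (ingroup | outgroup)
        raise TreeError(f"partition does not cover all leaves; missing {sorted(missing)[:5]}")
    _check_taxa(tree, ingroup | outgroup)
    full = faith_pd(tree, all_leaves, rooted=rooted)
    out_pd = faith_pd(tree, outgroup, rooted=rooted)
    in_pd = faith_pd(tree, ingroup, rooted=rooted)
    df = pd_table_from_values(
        full,
        out_pd,
        in_pd,
        n_full=len(all_leaves),
        n_outgroup=len(outgroup),
        n_ingroup=len(ingroup),
    )
    return df


def format_pd_summary(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Printed form: pd and percent_pd rounded half-away-from-zero."""
    out = df.copy()
    out["pd"] = [round_half_away(v, ndigits) for v in out["pd"]]
    out["percent_pd"] = [round_half_away(v, ndigits) for v in out["percent_pd"]]
    return out


def write_pd_summary(df: pd.DataFrame, path: str | Path) -> None:
    format_pd_summary(df).to_csv(path, sep="\t", index_label="row")
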