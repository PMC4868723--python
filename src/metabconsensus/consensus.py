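"""Consensus of the three feature selectors and clustering of the result.

The default rule is the strict three-way intersection; a ``k_of_3``
majority vote is available because published consensus tables sometimes
contain entries missing from one selector. Selected metabolites are
hierarchically clustered (Euclidean distance on standardized level
vectors, average linkage, so merge heights are monotone non-decreasing).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .dataset import MetabolomicsDataset
from .decomposition import standardize

METHODS = ("splsda", "greedy", "genetic")


def _as_names(value) -> set[str]:
    names = getattr(value, "names", value)
    return set(names)


def consensus_select(
    sets: Mapping[str, Iterable[str]],
    rule: str = "strict",
    k: int = 2,
    attribution: Mapping[str, str] | None = None,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Combine per-method feature sets into a consensus table.

    Parameters
    ----------
    sets
        Mapping from method name (``splsda``, ``greedy``, ``genetic``) to
        the selected metabolite names (or ``FeatureSet``).
    rule
        ``"strict"`` keeps metabolites chosen by every method;
        ``"k_of_3"`` keeps those chosen by at least ``k`` methods.
    k
        Vote threshold for ``k_of_3``; must be 1, 2 or 3.
    attribution
        Optional sPLS-DA component attribution per metabolite; metabolites
        the sPLS-DA did not select are shown as ``"-"``.
    universe
        Optional metabolite ordering for the output rows.

    Returns a DataFrame with columns ``metabolite``, ``chosen_by`` and
    ``component``; an empty intersection yields an empty table.
    """
    if set(sets) != set(METHODS):
        raise ValueError(f"sets must be keyed by {METHODS}, got {sorted(sets)}")
    if rule not in ("strict", "k_of_3"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "k_of_3" and k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    by_method = {m: _as_names(sets[m]) for m in METHODS}
    need = 3 if rule == "strict" else k

    all_names = set().union(*by_method.values())
    if universe is None:
        ordered = sorted(all_names)
    else:
        ordered = [n for n in universe if n in all_names]
        leftover = all_names - set(universe)
        if leftover:
            raise ValueError(f"selected metabolites outside universe: {sorted(leftover)}")
    attribution = attribution or {}

    rows = []
    for name in ordered:
        chosen = [m for m in METHODS if name in by_method[m]]
        if len(chosen) < need:
            continue
        comp = attribution.get(name, "-") if "splsda" in chosen else "-"
        rows.append({"metabolite": name, "chosen_by": ",".join(chosen),
                     "component": comp})
    return pd.DataFrame(rows, columns=["metabolite", "chosen_by", "component"])


def cluster_selected(
    ds: MetabolomicsDataset, table: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage dendrogram of the consensus metabolites.

    Metabolites are points in standardized sample space (Euclidean
    distance). Returns the SciPy linkage matrix (merge list with heights)
    and the leaf names in input order.
    """
    names = list(table["metabolite"])
    if len(names) < 2:
        raise ValueError("need at least 2 selected metabolites to cluster")
    sub = ds.subset(names)
    Z = standardize(sub.values, sub.metabolite_names).T  # metabolites × samples
    linkage = hierarchy.linkage(Z, method="average", metric="euclidean")
    return linkage, names


def to_newick(linkage: np.ndarray, names: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def escape(name: str) -> str:
        return "'" + name.replace("'", "''") + "'"

    def recurse(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{escape(names[node.id])}:{parent_height:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"
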