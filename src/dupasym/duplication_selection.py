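"""Gene classification and duplication-topology filters.

A duplication enters the analysis only when it is directly preceded by a
speciation event in a singleton gene, so that a clean outgroup/paralog
triplet exists: the pre-duplication speciation ancestor (the reconstruction
reference), the two paralogous clades, and the sister singleton clade.
Three filters enforce this: (i) duplications ancestral to the whole
species set are dropped (no singleton outgroup exists); (ii) of nested
duplications only the outermost is kept (inner ones are not independent
data points); (iii) a duplication whose nearest outgroup is the remaining
paralog of a lost duplication is dropped (it is not a true singleton).

Gene types come from the reconciler's leaf annotations when present and
are otherwise derived structurally: a leaf below some duplication node
whose species occurs on both sides of that duplication is a ``paralog``;
below a duplication but never mirrored on the other side it is a
``remaining_paralog`` (its sister copy was lost in that species); with no
duplication ancestor it is a ``true_singleton``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .family import GENE_TYPES, leaf_label

DEFAULT_YOUNG_KS = 0.051
AGE_CLASSES = ("young", "mid", "old")


@dataclass
class DuplicationTriplet:
    """An eligible duplication and its reconstruction reference frame."""

    family_id: str
    speciation: object  # pre-duplication speciation node (the reference)
    duplication: object
    paralog1: object  # clade root nodes
    paralog2: object
    outgroup: object
    ks_depth: float
    age_class: Optional[str] = None

    def __post_init__(self):
        if self.ks_depth <= 0:
            raise ValueError("triplet ks_depth must be positive")

    def clade_leaves(self, clade: str, classification: Optional[dict] = None):
        """Leaf labels of one clade; paralog clades drop remaining paralogs."""
        root = {"paralog1": self.paralog1, "paralog2": self.paralog2,
                "singleton": self.outgroup}[clade]
        leaves = [root] if root.is_leaf() else list(root.leaf_iter())
        if clade != "singleton" and classification is not None:
            leaves = [lf for lf in leaves
                      if classification[leaf_label(lf)] == "paralog"]
        return [leaf_label(lf) for lf in leaves]


def _check_labelled(tree) -> None:
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and getattr(node, "is_duplication", None) is None:
            raise ValueError(
                f"internal node {node.label!r} lacks a speciation/duplication label"
            )


def classify_genes(tree) -> dict:
    """Per-leaf gene type derived from the duplication structure.

    Returns {leaf label: 'paralog' | 'true_singleton' | 'remaining_paralog'}.
    """
    _check_labelled(tree)
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf_label(leaf)
        species = leaf.species
        has_dup_anc = False
        is_paralog = False
        node, parent = leaf, leaf.parent_node
        while parent is not None:
            if parent.is_duplication:
                has_dup_anc = True
                for sib in parent.child_nodes():
                    if sib is node:
                        continue
                    sib_species = (
                        {sib.species} if sib.is_leaf()
                        else {lf.species for lf in sib.leaf_iter()}
                    )
                    if species in sib_species:
                        is_paralog = True
            node, parent = parent, parent.parent_node
        if is_paralog:
            out[label] = "paralog"
        elif has_dup_anc:
            out[label] = "remaining_paralog"
        else:
            out[label] = "true_singleton"
    return out


def _leaf_types(tree, classification) -> dict:
    """Reconciler leaf annotations where present, else structural classes."""
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf_label(leaf)
        gt = getattr(leaf, "gene_type", None)
        out[label] = gt if gt in GENE_TYPES else classification[label]
    return out


def select_duplications(tree, family_id: str = "") -> list:
    """Eligible duplication triplets of one reconciled gene tree.

    Applies the three topology filters; several triplets per family are
    allowed when duplications sit in parallel orthologous clades.  Returns
    an empty list when nothing qualifies.
    """
    _check_labelled(tree)
    classification = classify_genes(tree)
    types = _leaf_types(tree, classification)
    triplets = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or not node.is_duplication:
            continue
        parent = node.parent_node
        if parent is None:
            continue  # duplication ancestral to the whole species set
        anc = parent
        nested = False
        while anc is not None:
            if getattr(anc, "is_duplication", False):
                nested = True
                break
            anc = anc.parent_node
        if nested:
            continue  # only the outermost duplication is retained
        if parent.is_duplication:
            continue
        sisters = [c for c in parent.child_nodes() if c is not node]
        if len(sisters) != 1:
            continue
        sister = sisters[0]
        sister_nodes = [sister] if sister.is_leaf() else list(sister.preorder_iter())
        if any(getattr(n, "is_duplication", False) for n in sister_nodes
               if not n.is_leaf()):
            continue  # outgroup is not a singleton gene
        sister_leaves = [sister] if sister.is_leaf() else list(sister.leaf_iter())
        if any(types[leaf_label(lf)] != "true_singleton" for lf in sister_leaves):
            continue  # nearest outgroup is a remaining paralog
        children = node.child_nodes()
        if len(children) != 2:
            continue
        ks = parent.ks_depth
        if ks is None or ks <= 0:
            raise ValueError("speciation ancestor lacks a positive Ks depth")
        triplets.append(
            DuplicationTriplet(
                family_id=family_id,
                speciation=parent,
                duplication=node,
                paralog1=children[0],
                paralog2=children[1],
                outgroup=sister,
                ks_depth=float(ks),
            )
        )
    return triplets


def age_boundaries(ks_depths: Sequence[float],
                   young: Optional[float] = DEFAULT_YOUNG_KS) -> tuple:
    """(lower, upper) Ks boundaries of the three age classes.

    Tertiles of the cohort's depths; the young boundary is overridable
    (default 0.051, the only externally fixed boundary).
    """
    arr = np.asarray(list(ks_depths), dtype=float)
    if arr.size == 0:
        raise ValueError("no depths supplied")
    lo, hi = np.quantile(arr, [1 / 3, 2 / 3])
    if young is not None:
        lo = young
    if hi < lo:
        hi = lo
    return float(lo), float(hi)


def assign_age_class(triplet: DuplicationTriplet, boundaries: tuple) -> str:
    """young / mid / old by the duplication's upper-bound Ks depth.

    Half-open intervals: a depth exactly at a boundary falls in the upper
    class.
    """
    lo, hi = boundaries
    if triplet.ks_depth < 0:
        raise ValueError("negative ks_depth")
    if triplet.ks_depth < lo:
        cls = "young"
    elif triplet.ks_depth >= hi:
        cls = "old"
    else:
        cls = "mid"
    triplet.age_class = cls
    return cls


def triplets_table(triplets: Sequence[DuplicationTriplet]):
    """Triplets as a DataFrame (family, node labels, ks_depth, age_class)."""
    import pandas as pd

    def _lab(node):
        return getattr(node, "label", None) or leaf_label(node)

    return pd.DataFrame(
        {
            "family": [t.family_id for t in triplets],
            "speciation": [_lab(t.speciation) for t in triplets],
            "duplication": [_lab(t.duplication) for t in triplets],
            "paralog1": [_lab(t.paralog1) for t in triplets],
            "paralog2": [_lab(t.paralog2) for t in triplets],
            "outgroup": [_lab(t.outgroup) for t in triplets],
            "ks_depth": [t.ks_depth for t in triplets],
            "age_class": [t.age_class for t in triplets],
        }
    )
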