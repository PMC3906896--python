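"""Shared containers and reconciled gene-tree I/O.

A gene family is an amino-acid alignment bound to a reconciled gene tree
whose internal nodes are labelled as speciation or duplication events and
whose leaves carry a species and a gene type.  Trees travel as Newick with
NHX-style annotations::

    [&&NHX:D=Y]                     duplication node
    [&&NHX:D=N:KS=0.42]             speciation node with Ks depth
    [&&NHX:S=sp03:GT=paralog]       leaf: species + gene type

Ks depths are synonymous substitutions per 4-fold degenerate site and act
as node ages (leaves sit at depth 0, the root deepest).  dendropy is the
tree container; the NHX tags are kept in node comments and mirrored onto
plain node attributes (``is_duplication``, ``ks_depth``, ``species``,
``gene_type``) on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
#: residues treated as missing data in reconstruction (zero cost, any state)
MISSING = {GAP, "X", "?", "*", "."}

GENE_TYPES = ("paralog", "true_singleton", "remaining_paralog")


def parse_nhx(comment: str) -> dict:
    """Parse one ``&&NHX:k=v:k=v`` comment string into a dict."""
    body = comment.strip().lstrip("&")
    if not body.startswith("NHX"):
        return {}
    out = {}
    for item in body.split(":")[1:]:
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def format_nhx(tags: dict) -> str:
    return "&&NHX:" + ":".join(f"{k}={v}" for k, v in tags.items())


def _annotate_from_comments(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        tags: dict = {}
        for c in node.comments:
            tags.update(parse_nhx(c))
        if node.is_leaf():
            node.species = tags.get("S")
            node.gene_type = tags.get("GT")
            node.ks_depth = 0.0
            node.is_duplication = False
        else:
            d = tags.get("D")
            node.is_duplication = (d == "Y") if d is not None else None
            node.ks_depth = float(tags["KS"]) if "KS" in tags else None
            node.species = None
            node.gene_type = None


def _comments_from_attrs(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        tags = {}
        if node.is_leaf():
            if getattr(node, "species", None):
                tags["S"] = node.species
            if getattr(node, "gene_type", None):
                tags["GT"] = node.gene_type
        else:
            dup = getattr(node, "is_duplication", None)
            if dup is not None:
                tags["D"] = "Y" if dup else "N"
            ks = getattr(node, "ks_depth", None)
            if ks is not None and not dup:
                tags["KS"] = f"{ks:.6g}"
        node.comments = [format_nhx(tags)] if tags else []


def read_gene_tree(source: str, *, path: bool = True) -> dendropy.Tree:
    """Read an NHX-annotated Newick gene tree.

    ``source`` is a file path unless ``path=False`` (then raw Newick text).
    """
    kwargs = dict(
        schema="newick",
        extract_comment_metadata=False,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if path:
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    _annotate_from_comments(tree)
    resolve_duplication_depths(tree)
    return tree


def write_gene_tree(tree: dendropy.Tree, path: Optional[str] = None) -> str:
    """Serialise a gene tree to NHX Newick; writes to ``path`` if given."""
    _comments_from_attrs(tree)
    text = tree.as_string(
        schema="newick",
        suppress_item_comments=False,
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def resolve_duplication_depths(tree: dendropy.Tree) -> None:
    """Give duplication nodes the Ks depth of the nearest preceding speciation.

    The age of a duplication is unknowable more precisely than the flanking
    speciations, so the preceding speciation depth serves as the upper-bound
    estimate.  Speciation depths and leaf depths (0) are left untouched.
    """
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if getattr(node, "is_duplication", False):
            anc = node.parent_node
            while anc is not None and getattr(anc, "is_duplication", False):
                anc = anc.parent_node
            if anc is None or getattr(anc, "ks_depth", None) is None:
                raise ValueError(
                    "duplication node has no speciation ancestor with a Ks depth"
                )
            node.ks_depth = anc.ks_depth


@dataclass
class ReconciledFamily:
    """One gene family: aligned sequences + reconciled gene tree (+ mask).

    ``alignment`` maps leaf label -> aligned amino-acid string (all equal
    length, gap '-').  ``mask`` is the per-column exclusion vector filled in
    by :func:`dupasym.alignment_masking.mask_indels`.
    """

    family_id: str
    alignment: dict
    tree: dendropy.Tree
    mask: Optional[np.ndarray] = None
    focal_species: Optional[str] = None

    def __post_init__(self):
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment in family {self.family_id}")

    @property
    def length(self) -> int:
        return len(next(iter(self.alignment.values())))

    @property
    def leaf_labels(self) -> list:
        return [leaf_label(lf) for lf in self.tree.leaf_node_iter()]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReconciledFamily):
            return NotImplemented
        return (
            self.family_id == other.family_id
            and self.alignment == other.alignment
            and write_gene_tree(self.tree) == write_gene_tree(other.tree)
        )
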