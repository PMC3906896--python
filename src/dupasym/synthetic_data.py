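"""Synthetic gene families with known ground truth.

Generates the full input surface of the analysis — reconciled families
(alignment + NHX gene tree), expression tables, SNP tables and chromosomal
locations — from a species tree with Ks node depths, so that every
downstream stage has a parameter-recovery test target.

The evolution model is deliberately minimal: uniform 20-state amino-acid
exchange with per-site gamma rate multipliers, events Poisson-distributed
per branch at the Ks clock (branch Ka = Ks-depth span x ``ka_ks_scale``).
A duplication placed on one species-tree edge splits the lineage into two
paralog copies that inherit the species subtree below the edge; an imposed
``rate_ratio`` accelerates copy 1, ``concerted_until`` mirrors the first
stretch of post-duplication evolution into both copies (gene-conversion
style homogenisation), losses delete copy-2 leaves in chosen species, and
``indel_rate`` plants multi-residue gaps for the masking stage.

Expression values are log-normal per tissue; a signed ``coupling`` shifts
the log-mean of the faster-evolving copy (negative coupling = faster copy
expressed lower).  SNP tables carry synonymous / non-synonymous SNP and
site counts with an analogous ``kaks_coupling`` acting on the
non-synonymous SNP density of the faster copy.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .family import (
    AMINO_ACIDS,
    ReconciledFamily,
    leaf_label,
    resolve_duplication_depths,
    write_gene_tree,
)

ARMS = ("X", "2L", "2R", "3L", "3R")
LOCATION_CATEGORIES = (
    "different_arms",
    "same_arm_distant",
    "tandem_collinear",
    "tandem_inverted",
)


# ---------------------------------------------------------------------------
# species tree


def generate_species_tree(n_taxa: int, root_depth: float, seed: int) -> dendropy.Tree:
    """Random rooted bifurcating species tree with Ks node depths.

    Depths strictly decrease from the root (``root_depth``) to the leaves
    (0); each internal child sits at 0.55-0.85 of its parent's depth.
    Deterministic given the seed.  Requires n_taxa >= 3 so that a
    duplication below the root can still have a singleton outgroup.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3 (no outgroup triplet possible)")
    if root_depth <= 0:
        raise ValueError("root_depth must be positive")
    rng = np.random.default_rng(seed)
    taxa = [f"sp{i + 1:02d}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace()
    counter = itertools.count(1)

    def build(labels, depth):
        node = dendropy.Node()
        node.is_duplication = False
        node.gene_type = None
        if len(labels) == 1:
            node.taxon = ns.require_taxon(labels[0])
            node.label = labels[0]
            node.species = labels[0]
            node.ks_depth = 0.0
            return node
        node.label = f"n{next(counter):02d}"
        node.species = None
        node.ks_depth = depth
        k = int(rng.integers(1, len(labels)))
        for part in (labels[:k], labels[k:]):
            child_depth = (
                depth * float(rng.uniform(0.55, 0.85)) if len(part) > 1 else 0.0
            )
            node.add_child(build(part, child_depth))
        return node

    root = build(taxa, float(root_depth))
    tree = dendropy.Tree(seed_node=root, taxon_namespace=ns)
    return tree


def internal_edges(tree: dendropy.Tree) -> list:
    """Labels of non-root nodes usable as duplication edges."""
    return [
        nd.label or leaf_label(nd)
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    ]


# ---------------------------------------------------------------------------
# family simulation


@dataclass
class SimFamilySpec:
    """Parameters for one simulated family.

    length in codons (= aligned amino acids); gamma_shape controls
    site-rate heterogeneity (mean-1 gamma); dup_edge names the species
    tree node whose parent edge receives the duplication (None = pure
    speciation family); rate_ratio >= 1 accelerates paralog copy 1;
    concerted_until (Ka units) mirrors early post-duplication events into
    both copies; indel_rate is the per-site probability of planting a
    2-5 residue gap in one extant sequence; ka_ks_scale converts Ks depth
    spans into branch Ka (1 = amino-acid changes accrue at the Ks clock).
    """

    length: int = 200
    gamma_shape: float = 2.0
    dup_edge: Optional[str] = None
    rate_ratio: float = 1.0
    concerted_until: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0
    ka_ks_scale: float = 1.0
    lost_species: tuple = ()
    family_id: str = "fam"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.rate_ratio < 1:
            raise ValueError("rate_ratio must be >= 1 (copy 1 is the faster copy)")
        if self.concerted_until < 0:
            raise ValueError("concerted_until must be >= 0")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator actually did to one family."""

    family_id: str
    clade_counts: dict = field(default_factory=dict)
    path_sums: dict = field(default_factory=dict)
    rate_ratio: float = 1.0
    speciation_depth: Optional[float] = None
    dup_depth: Optional[float] = None
    dup_species: list = field(default_factory=list)
    lost_species: list = field(default_factory=list)
    focal_species: Optional[str] = None
    faster_copy: Optional[str] = None
    total_events: int = 0
    expression_sign: Optional[int] = None
    kaks_sign: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for nd in tree.preorder_node_iter():
        if (nd.label or (nd.taxon.label if nd.taxon else None)) == label:
            return nd
    raise ValueError(f"dup_edge node {label!r} not found in species tree")


def _copy_subtree(node, suffix, lost, ns):
    """Deep-copy a species subtree as one paralog copy, applying losses.

    Leaves get labels ``{species}_{suffix}``; species fully lost on this
    copy are skipped and unifurcations collapsed.  Returns None if the
    whole copy is lost.
    """
    if node.is_leaf():
        sp = node.species
        if sp in lost:
            return None
        new = dendropy.Node()
        new.taxon = ns.require_taxon(f"{sp}_{suffix}")
        new.label = f"{sp}_{suffix}"
        new.species = sp
        new.ks_depth = 0.0
        new.is_duplication = False
        new.gene_type = None
        return new
    children = [_copy_subtree(c, suffix, lost, ns) for c in node.child_nodes()]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    new = dendropy.Node()
    new.label = f"{node.label}_{suffix}"
    new.species = None
    new.ks_depth = node.ks_depth
    new.is_duplication = False
    new.gene_type = None
    for c in children:
        new.add_child(c)
    return new


def _build_gene_tree(species_tree, spec):
    """Species tree -> reconciled gene tree with one duplication planted."""
    ns = dendropy.TaxonNamespace()

    def copy_plain(node):
        new = dendropy.Node()
        new.is_duplication = False
        new.gene_type = None
        new.ks_depth = node.ks_depth
        new.species = node.species
        new.label = node.label
        if node.is_leaf():
            new.taxon = ns.require_taxon(node.species)
        for c in node.child_nodes():
            new.add_child(copy_plain(c))
        return new

    root = copy_plain(species_tree.seed_node)
    gene_tree = dendropy.Tree(seed_node=root, taxon_namespace=ns)
    if spec.dup_edge is None:
        return gene_tree, None

    target = _find_node(gene_tree, spec.dup_edge)
    if target.parent_node is None:
        raise ValueError("dup_edge on the root edge: no singleton outgroup exists")
    parent = target.parent_node
    dup_species = sorted(
        lf.species for lf in
        ([target] if target.is_leaf() else target.leaf_iter())
    )
    bad = set(spec.lost_species) - set(dup_species)
    if bad:
        raise ValueError(f"lost_species not below the duplication: {sorted(bad)}")
    if set(spec.lost_species) == set(dup_species):
        raise ValueError("cannot lose copy 2 in every species")

    src = _find_node(species_tree, spec.dup_edge)
    parent_depth = parent.ks_depth
    child_depth = src.ks_depth if not src.is_leaf() else 0.0
    dup = dendropy.Node()
    dup.label = "dup"
    dup.is_duplication = True
    dup.species = None
    dup.gene_type = None
    dup.sim_depth = 0.5 * (parent_depth + child_depth)
    dup.ks_depth = parent_depth  # upper-bound convention

    copy1 = _copy_subtree(src, "1", (), ns)
    copy2 = _copy_subtree(src, "2", set(spec.lost_species), ns)
    parent.remove_child(target)
    parent.add_child(dup)
    dup.add_child(copy1)
    dup.add_child(copy2)

    for side, node in (("p1", copy1), ("p2", copy2)):
        for nd in node.preorder_iter():
            nd._lineage = side
    dup._lineage = "pre_dup"
    for sib in parent.child_nodes():
        if sib is not dup:
            for nd in sib.preorder_iter():
                nd._lineage = "outgroup"
    info = {
        "dup": dup,
        "copy1": copy1,
        "copy2": copy2,
        "speciation": parent,
        "dup_species": dup_species,
        "dup_depth": dup.sim_depth,
    }
    return gene_tree, info


def _sim_depth(node) -> float:
    d = getattr(node, "sim_depth", None)
    return d if d is not None else node.ks_depth


def _evolve(gene_tree, spec, rng, info):
    """Simulate substitutions down the gene tree; return alignment + counts."""
    L = spec.length
    site_rates = rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_shape, size=L)
    aa = np.array(list(AMINO_ACIDS))
    root_seq = rng.integers(0, 20, size=L)
    edge_events = {}

    def substitute(seq, branch_ka):
        n_events = rng.poisson(branch_ka * spec.ka_ks_scale * site_rates)
        seq = seq.copy()
        count = 0
        for site in np.nonzero(n_events)[0]:
            for _ in range(int(n_events[site])):
                cur = seq[site]
                new = int(rng.integers(0, 19))
                seq[site] = new if new < cur else new + 1
                count += 1
        return seq, count

    concerted_events = 0
    seqs = {}

    def walk(node, seq):
        nonlocal concerted_events
        for child in node.child_nodes():
            span = max(0.0, _sim_depth(node) - _sim_depth(child))
            mult = spec.rate_ratio if getattr(child, "_lineage", None) == "p1" else 1.0
            branch = span * mult
            start = seq
            if (
                info is not None
                and node is info["dup"]
                and spec.concerted_until > 0
            ):
                # mirror the first `concerted_until` Ka of both stems
                shared = min(spec.concerted_until, span)
                if not hasattr(node, "_shared_seq"):
                    node._shared_seq, node._shared_n = substitute(seq, shared)
                    concerted_events += node._shared_n
                start = node._shared_seq
                branch = max(0.0, branch - shared)
            out, n = substitute(start, branch)
            edge_events[id(child)] = n
            if child.is_leaf():
                seqs[leaf_label(child)] = out
            else:
                walk(child, out)

    walk(gene_tree.seed_node, root_seq)
    alignment = {name: "".join(aa[s]) for name, s in seqs.items()}
    return alignment, edge_events, concerted_events


def _plant_indels(alignment, indel_rate, rng):
    if indel_rate <= 0:
        return alignment
    out = {}
    for name, seq in alignment.items():
        chars = list(seq)
        L = len(chars)
        j = 0
        while j < L:
            if rng.random() < indel_rate:
                run = int(rng.integers(2, 6))
                for k in range(j, min(L, j + run)):
                    chars[k] = "-"
                j += run
            j += 1
        out[name] = "".join(chars)
    return out


def generate_family(tree: dendropy.Tree, spec: SimFamilySpec):
    """Simulate one reconciled family on a species tree.

    Returns ``(ReconciledFamily, GroundTruth)``.  The ground truth records
    per-clade true event counts (disjoint partition: copy-1 subtree,
    copy-2 subtree, the speciation->duplication stem, the outgroup clade,
    everything above) and per-clade *path sums* — events summed over each
    ancestor->leaf path exactly as the clade-Ka numerator counts them.
    """
    rng = np.random.default_rng(spec.seed)
    gene_tree, info = _build_gene_tree(tree, spec)
    alignment, edge_events, concerted = _evolve(gene_tree, spec, rng, info)
    alignment = _plant_indels(alignment, spec.indel_rate, rng)

    truth = GroundTruth(family_id=spec.family_id, rate_ratio=spec.rate_ratio)
    clade_counts = {"paralog1": 0, "paralog2": 0, "pre_dup": 0,
                    "outgroup": 0, "other": 0, "concerted": concerted}
    for nd in gene_tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        lineage = getattr(nd, "_lineage", None) or "other"
        key = {"p1": "paralog1", "p2": "paralog2"}.get(lineage, lineage)
        clade_counts[key] += edge_events.get(id(nd), 0)
    truth.clade_counts = clade_counts
    truth.total_events = sum(clade_counts.values())

    # gene types
    if info is not None:
        sp1 = {lf.species for lf in info["copy1"].leaf_iter()} \
            if not info["copy1"].is_leaf() else {info["copy1"].species}
        sp2 = {lf.species for lf in info["copy2"].leaf_iter()} \
            if not info["copy2"].is_leaf() else {info["copy2"].species}
        both = sp1 & sp2
        for lf in gene_tree.leaf_node_iter():
            lin = getattr(lf, "_lineage", None)
            if lin in ("p1", "p2"):
                lf.gene_type = "paralog" if lf.species in both else "remaining_paralog"
            else:
                lf.gene_type = "true_singleton"
        truth.dup_species = info["dup_species"]
        truth.lost_species = sorted(spec.lost_species)
        truth.speciation_depth = info["speciation"].ks_depth
        truth.dup_depth = info["dup_depth"]
        truth.focal_species = min(both) if both else None

        def path_sum(leaves, stop):
            total = 0
            for lf in leaves:
                nd = lf
                while nd is not stop:
                    total += edge_events.get(id(nd), 0)
                    nd = nd.parent_node
            return total

        stop = info["speciation"]
        p1_leaves = [lf for lf in gene_tree.leaf_node_iter()
                     if getattr(lf, "_lineage", None) == "p1" and lf.species in both]
        p2_leaves = [lf for lf in gene_tree.leaf_node_iter()
                     if getattr(lf, "_lineage", None) == "p2" and lf.species in both]
        out_leaves = [lf for lf in gene_tree.leaf_node_iter()
                      if getattr(lf, "_lineage", None) == "outgroup"]
        truth.path_sums = {
            "paralog1": path_sum(p1_leaves, stop) + concerted * len(p1_leaves),
            "paralog2": path_sum(p2_leaves, stop) + concerted * len(p2_leaves),
            "singleton": path_sum(out_leaves, stop),
        }
        if spec.rate_ratio > 1:
            truth.faster_copy = "p1"
        elif truth.path_sums["paralog1"] >= truth.path_sums["paralog2"]:
            truth.faster_copy = "p1"
        else:
            truth.faster_copy = "p2"
    else:
        for lf in gene_tree.leaf_node_iter():
            lf.gene_type = "true_singleton"
        all_sp = sorted(lf.species for lf in gene_tree.leaf_node_iter())
        truth.focal_species = all_sp[0]
        truth.path_sums = {}

    family = ReconciledFamily(
        family_id=spec.family_id,
        alignment={leaf_label(lf): alignment[leaf_label(lf)]
                   for lf in gene_tree.leaf_node_iter()},
        tree=gene_tree,
        focal_species=truth.focal_species,
    )
    return family, truth


# ---------------------------------------------------------------------------
# planted topologies for the selection filters


def _mk(label=None, species=None, gene_type=None, dup=None, ks=None, children=()):
    nd = dendropy.Node()
    nd.label = label if label else species
    nd.species = species
    nd.gene_type = gene_type
    nd.is_duplication = dup
    nd.ks_depth = ks if ks is not None else (0.0 if species else None)
    for c in children:
        nd.add_child(c)
    return nd


def planted_gene_tree(kind: str) -> dendropy.Tree:
    """Small hand-built reconciled trees exercising the topology filters.

    kinds: ``eligible`` (one clean duplication with a singleton sister),
    ``nested`` (inner duplication below an eligible outer one),
    ``lost_outgroup`` (the candidate's sister leaf is a remaining paralog,
    as a reconciler infers after a duplication loss), ``root_duplication``
    (duplication ancestral to every species) and ``no_duplication``.
    """
    S = "true_singleton"
    P = "paralog"
    if kind == "eligible":
        dup = _mk("dup", dup=True, children=[
            _mk("na_1", dup=False, ks=0.2, children=[
                _mk(species="spA", gene_type=P, label="spA_1"),
                _mk(species="spB", gene_type=P, label="spB_1")]),
            _mk("na_2", dup=False, ks=0.2, children=[
                _mk(species="spA", gene_type=P, label="spA_2"),
                _mk(species="spB", gene_type=P, label="spB_2")])])
        root = _mk("n01", dup=False, ks=1.0, children=[
            _mk(species="spD", gene_type=S),
            _mk("n02", dup=False, ks=0.5, children=[
                _mk(species="spC", gene_type=S), dup])])
    elif kind == "nested":
        inner = _mk("dupi", dup=True, children=[
            _mk(species="spB", gene_type=P, label="spB_1a"),
            _mk(species="spB", gene_type=P, label="spB_1b")])
        outer = _mk("dupo", dup=True, children=[
            _mk("na_1", dup=False, ks=0.2, children=[
                _mk(species="spA", gene_type=P, label="spA_1"), inner]),
            _mk("na_2", dup=False, ks=0.2, children=[
                _mk(species="spA", gene_type=P, label="spA_2"),
                _mk(species="spB", gene_type=P, label="spB_2")])])
        root = _mk("n01", dup=False, ks=1.0, children=[
            _mk(species="spD", gene_type=S),
            _mk("n02", dup=False, ks=0.5, children=[
                _mk(species="spC", gene_type=S), outer])])
    elif kind == "lost_outgroup":
        # spC's sister copy was lost; the reconciler marks the survivor as
        # a remaining paralog, disqualifying it as an outgroup.
        dup = _mk("dup", dup=True, children=[
            _mk(species="spA", gene_type=P, label="spA_1"),
            _mk(species="spA", gene_type=P, label="spA_2")])
        root = _mk("n01", dup=False, ks=1.0, children=[
            _mk(species="spD", gene_type=S),
            _mk("n02", dup=False, ks=0.5, children=[
                _mk(species="spC", gene_type="remaining_paralog", label="spC_r"),
                dup])])
    elif kind == "root_duplication":
        root = _mk("dup", dup=True, ks=None, children=[
            _mk("na_1", dup=False, ks=0.5, children=[
                _mk(species="spA", gene_type=P, label="spA_1"),
                _mk(species="spB", gene_type=P, label="spB_1")]),
            _mk("na_2", dup=False, ks=0.5, children=[
                _mk(species="spA", gene_type=P, label="spA_2"),
                _mk(species="spB", gene_type=P, label="spB_2")])])
        root.ks_depth = 1.0
    elif kind == "no_duplication":
        root = _mk("n01", dup=False, ks=1.0, children=[
            _mk(species="spA", gene_type=S),
            _mk("n02", dup=False, ks=0.5, children=[
                _mk(species="spB", gene_type=S),
                _mk(species="spC", gene_type=S)])])
    else:
        raise ValueError(f"unknown planted topology kind: {kind}")
    ns = dendropy.TaxonNamespace()
    for lf in root.leaf_iter():
        lf.taxon = ns.require_taxon(lf.label)
    tree = dendropy.Tree(seed_node=root, taxon_namespace=ns)
    if kind != "root_duplication":
        resolve_duplication_depths(tree)
    return tree


# ---------------------------------------------------------------------------
# expression / SNP / location tables


def gene_id(family: ReconciledFamily, leaf: str) -> str:
    return f"{family.family_id}|{leaf}"


def focal_genes(family: ReconciledFamily) -> list:
    """Leaf labels of the family's focal species (the emulated reference
    genome whose genes carry expression/SNP/location data)."""
    return sorted(
        leaf_label(lf)
        for lf in family.tree.leaf_node_iter()
        if lf.species == family.focal_species
    )


def _focal_pair(family, truth):
    """(faster_gene, slower_gene) leaf labels of the focal paralog pair."""
    genes = focal_genes(family)
    pair = [g for g in genes if g.endswith(("_1", "_2"))]
    if len(pair) != 2:
        return None
    g1 = next(g for g in pair if g.endswith("_1"))
    g2 = next(g for g in pair if g.endswith("_2"))
    return (g1, g2) if truth.faster_copy == "p1" else (g2, g1)


def generate_expression_table(families: Sequence, coupling: float,
                              n_tissues: int = 26, seed: int = 0,
                              effect: float = 0.6, tissue_sd: float = 0.25,
                              profile_sd: float = 0.4) -> pd.DataFrame:
    """Per-gene expression across tissues, with optional imposed asymmetry.

    ``families`` is a sequence of (ReconciledFamily, GroundTruth) pairs.
    One row per extant focal-species gene.  Values are log-normal per
    tissue around a gene log10-mean; for a focal paralog pair, the
    faster-evolving copy's log-mean is shifted by ``coupling * effect / 2``
    and the slower copy by the opposite amount, so coupling < 0 gives the
    faster copy stochastically lower expression.  Paralogs share a family
    tissue profile, which makes within-pair tissue correlation positive.
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for family, truth in families:
        base = rng.normal(1.2, 0.4)
        profile = rng.normal(0.0, profile_sd, size=n_tissues)
        pair = _focal_pair(family, truth)
        if pair is not None:
            truth.expression_sign = int(np.sign(coupling))
        for g in focal_genes(family):
            gid = gene_id(family, g)
            shift = 0.0
            if pair is not None and g in pair:
                shift = 0.5 * coupling * effect if g == pair[0] else -0.5 * coupling * effect
            mu = base + shift
            vals = 10.0 ** (mu + profile + rng.normal(0.0, tissue_sd, size=n_tissues))
            rows.append([gid, *vals])
    cols = ["gene_id"] + [f"tissue_{i + 1}" for i in range(n_tissues)]
    return pd.DataFrame(rows, columns=cols)


def generate_snp_table(families: Sequence, kaks_coupling: float, seed: int = 0,
                       pi_syn: float = 0.05, pi_nonsyn: float = 0.015,
                       effect: float = 0.8) -> pd.DataFrame:
    """Per-gene synonymous / non-synonymous SNP and site counts.

    kaks_coupling > 0 gives the faster-evolving copy of each focal pair a
    higher non-synonymous SNP density (log-scale shift ``coupling *
    effect / 2``), emulating relaxed constraint in that copy.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for family, truth in families:
        L_nt = 3 * family.length
        sites_syn = int(round(0.25 * L_nt))
        sites_nonsyn = L_nt - sites_syn
        pair = _focal_pair(family, truth)
        if pair is not None:
            truth.kaks_sign = int(np.sign(kaks_coupling))
        for g in focal_genes(family):
            gid = gene_id(family, g)
            rate_n = pi_nonsyn
            if pair is not None and g in pair:
                s = 0.5 * effect * kaks_coupling
                rate_n = pi_nonsyn * np.exp(s if g == pair[0] else -s)
            rows.append([
                gid,
                int(rng.poisson(pi_syn * sites_syn)),
                int(rng.poisson(rate_n * sites_nonsyn)),
                sites_syn,
                sites_nonsyn,
            ])
    return pd.DataFrame(
        rows, columns=["gene_id", "n_syn", "n_nonsyn", "sites_syn", "sites_nonsyn"]
    )


def generate_location_table(families: Sequence, seed: int = 0,
                            tandem_threshold: int = 5000) -> pd.DataFrame:
    """Chromosomal locations with the four pair-placement categories
    planted uniformly at random for focal paralog pairs."""
    rng = np.random.default_rng(seed)
    rows = []
    for family, truth in families:
        span = 3 * family.length + int(rng.integers(500, 3000))
        pair = _focal_pair(family, truth)
        placed = set()
        if pair is not None:
            cat = LOCATION_CATEGORIES[int(rng.integers(4))]
            arm1 = ARMS[int(rng.integers(len(ARMS)))]
            start1 = int(rng.integers(10_000, 20_000_000))
            strand1 = "+" if rng.random() < 0.5 else "-"
            if cat == "different_arms":
                arm2 = ARMS[(ARMS.index(arm1) + 1) % len(ARMS)]
                start2 = int(rng.integers(10_000, 20_000_000))
                strand2 = strand1
            else:
                arm2 = arm1
                if cat == "same_arm_distant":
                    gap = int(rng.integers(2 * tandem_threshold, 100_000))
                else:
                    gap = int(rng.integers(200, tandem_threshold - 1))
                start2 = start1 + span + gap
                strand2 = strand1 if cat != "tandem_inverted" else (
                    "-" if strand1 == "+" else "+")
                if cat == "tandem_collinear":
                    strand2 = strand1
            for g, arm, start, strand in (
                (pair[0], arm1, start1, strand1),
                (pair[1], arm2, start2, strand2),
            ):
                rows.append([gene_id(family, g), arm, start, start + span, strand])
                placed.add(g)
        for g in focal_genes(family):
            if g not in placed:
                arm = ARMS[int(rng.integers(len(ARMS)))]
                start = int(rng.integers(10_000, 20_000_000))
                rows.append([gene_id(family, g), arm, start, start + span,
                             "+" if rng.random() < 0.5 else "-"])
    return pd.DataFrame(rows, columns=["gene_id", "arm", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# writers


def write_family(family: ReconciledFamily, truth: Optional[GroundTruth],
                 outdir: str) -> dict:
    """Write one family as aligned FASTA + NHX Newick (+ JSON ground truth)."""
    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, f"{family.family_id}.fasta")
    with open(fasta, "w") as fh:
        for name, seq in family.alignment.items():
            fh.write(f">{name}\n{seq}\n")
    nhx = os.path.join(outdir, f"{family.family_id}.nhx")
    write_gene_tree(family.tree, nhx)
    paths = {"fasta": fasta, "tree": nhx}
    if truth is not None:
        sidecar = os.path.join(outdir, f"{family.family_id}.truth.json")
        with open(sidecar, "w") as fh:
            fh.write(truth.to_json())
        paths["truth"] = sidecar
    return paths
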