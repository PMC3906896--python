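"""Per-clade substitution rates and radicality measures.

All rates are referenced to the pre-duplication speciation ancestor: the
clade Ka is the sum of posterior probabilities of substitutions lying on
any ancestor->leaf path of the clade, divided by the summed usable
alignment lengths of those paths (columns surviving the indel mask and
ungapped in the leaf).  Only paralog leaves count in paralog clades —
remaining paralogs from lost duplications are excluded.  Substitutions on
the stem between the speciation ancestor and the duplication node lie on
every paralog path and are therefore counted in *both* paralog clades;
that is deliberate, as it lets concerted evolution surface as shared
apparent substitutions.  relKa divides Ka by the ancestor's Ks depth (the
upper-bound age), so a neutrally evolving clade has relKa near 1.

Radicality of a clade's substitutions is summarised two ways: the
posterior-weighted mean absolute polarity change |dPolarity| (Grantham
polarity scale by default) and the posterior-weighted mean directional
exchangeability EX, where EX_ij is the chance that an i->j missense change
leaves protein function intact (EX_ij != EX_ji, so events are polarised by
the ancestral state).  The shipped EX table is a synthetic stand-in with
the published schema; pass your own TSV for real inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment_masking import MaskedAlignment
from .duplication_selection import DuplicationTriplet, classify_genes
from .family import AMINO_ACIDS

CLADES = ("paralog1", "paralog2", "singleton")


@dataclass
class PropertyTables:
    """Amino-acid polarity values and a directional 20x20 EX matrix."""

    polarity: dict
    ex: pd.DataFrame

    @classmethod
    def load_default(cls) -> "PropertyTables":
        base = resources.files("dupasym") / "data"
        return cls.from_files(
            str(base / "grantham_polarity.tsv"),
            str(base / "ex_matrix_synthetic.tsv"),
        )

    @classmethod
    def from_files(cls, polarity_path: str, ex_path: str) -> "PropertyTables":
        pol = pd.read_csv(polarity_path, sep="\t", comment="#", index_col=0)
        ex = pd.read_csv(ex_path, sep="\t", comment="#", index_col=0)
        ex.index.name = "from"
        ex.columns.name = "to"
        missing = set(AMINO_ACIDS) - set(pol.index)
        if missing or set(AMINO_ACIDS) - set(ex.index):
            raise ValueError(f"property tables incomplete (missing {sorted(missing)})")
        return cls(polarity=pol.iloc[:, 0].to_dict(), ex=ex)


@dataclass
class CladeRates:
    """Ka, relKa and radicality for one clade of one duplication."""

    ka: float
    rel_ka: float
    d_polarity: float
    ex: float
    n_events: float  # posterior sum over ancestor->leaf paths
    total_length: float  # summed usable lengths of those paths


def _path_nodes(leaf_node, stop):
    """Child nodes of the edges on the path stop -> leaf (leaf included)."""
    nodes = []
    nd = leaf_node
    while nd is not None and nd is not stop:
        nodes.append(nd)
        nd = nd.parent_node
    if nd is None:
        raise ValueError("leaf is not a descendant of the clade ancestor")
    return nodes


def _leaf_node(tree, label):
    from .family import leaf_label

    for lf in tree.leaf_node_iter():
        if leaf_label(lf) == label:
            return lf
    raise KeyError(label)


def clade_paths(triplet: DuplicationTriplet, tree, clade: str,
                classification: Optional[dict] = None):
    """Per-leaf path edge sets from the speciation ancestor to each
    retained leaf of the clade (paralog clades keep paralog leaves only)."""
    if classification is None:
        classification = classify_genes(tree)
    labels = triplet.clade_leaves(clade, classification)
    paths = {}
    for label in labels:
        leaf = _leaf_node(tree, label)
        paths[label] = {id(n) for n in _path_nodes(leaf, triplet.speciation)}
    return paths


def clade_events(events: Sequence, paths: dict) -> list:
    """Events lying on at least one ancestor->leaf path of the clade
    (each event once, regardless of how many paths share its edge)."""
    edge_ids = set().union(*paths.values()) if paths else set()
    return [e for e in events if id(e.child) in edge_ids]


def clade_ka(events: Sequence, triplet: DuplicationTriplet,
             masked: MaskedAlignment, clade: str,
             classification: Optional[dict] = None) -> CladeRates:
    """Posterior-weighted clade Ka (and event/length tallies).

    Numerator: for each retained leaf, the posterior sum of events on the
    ancestor->leaf path, summed over leaves (stem events count once per
    leaf path).  Denominator: summed usable alignment lengths of the same
    paths.  Radicality fields are filled by :func:`clade_radicality`.
    """
    paths = clade_paths(triplet, _as_tree(triplet), clade, classification)
    if not paths:
        raise ValueError(f"clade {clade} has no usable leaves")
    n = 0.0
    for path in paths.values():
        n += sum(e.posterior for e in events if id(e.child) in path)
    total_length = float(sum(masked.usable_length(label) for label in paths))
    if total_length == 0:
        raise ValueError(f"clade {clade} has zero usable alignment length")
    ka = n / total_length
    return CladeRates(ka=ka, rel_ka=rel_ka(ka, triplet.ks_depth),
                      d_polarity=np.nan, ex=np.nan,
                      n_events=n, total_length=total_length)


def _as_tree(triplet: DuplicationTriplet):
    """Wrap the triplet's tree for leaf iteration (the triplet stores
    nodes of the family tree; any node reaches the whole tree)."""
    root = triplet.speciation
    while root.parent_node is not None:
        root = root.parent_node

    class _View:
        seed_node = root

        @staticmethod
        def leaf_node_iter():
            return root.leaf_iter()

        @staticmethod
        def preorder_node_iter():
            return root.preorder_iter()

    return _View()


def rel_ka(ka: float, ks_depth: float) -> float:
    """Ka normalised by the ancestor's Ks depth (upper-bound age)."""
    if ks_depth <= 0:
        raise ValueError("ks_depth must be positive")
    if ka < 0:
        raise ValueError("ka must be non-negative")
    return ka / ks_depth


def clade_radicality(events: Sequence, tables: PropertyTables) -> tuple:
    """Posterior-weighted mean |dPolarity| and directional EX.

    ``events`` are the clade's events (each once).  Empty event sets are
    undefined: (nan, nan) is returned so missingness stays visible rather
    than collapsing to 0.
    """
    if not events:
        return (np.nan, np.nan)
    w = np.array([e.posterior for e in events])
    dpol = np.array([
        abs(tables.polarity[e.from_aa] - tables.polarity[e.to_aa]) for e in events
    ])
    ex = np.array([tables.ex.loc[e.from_aa, e.to_aa] for e in events])
    return (float(np.sum(w * dpol) / w.sum()), float(np.sum(w * ex) / w.sum()))


def compute_clade_rates(triplet: DuplicationTriplet, events: Sequence,
                        masked: MaskedAlignment,
                        tables: Optional[PropertyTables] = None,
                        classification: Optional[dict] = None) -> dict:
    """CladeRates for all three clades of a triplet."""
    if tables is None:
        tables = PropertyTables.load_default()
    tree = _as_tree(triplet)
    if classification is None:
        classification = classify_genes(tree)
    out = {}
    for clade in CLADES:
        rates = clade_ka(events, triplet, masked, clade, classification)
        paths = clade_paths(triplet, tree, clade, classification)
        dpol, ex = clade_radicality(clade_events(events, paths), tables)
        rates.d_polarity = dpol
        rates.ex = ex
        out[clade] = rates
    return out


def rates_table(all_rates: dict) -> pd.DataFrame:
    """{(family, dup): {clade: CladeRates}} flattened to a DataFrame."""
    rows = []
    for key, clades in all_rates.items():
        for clade, r in clades.items():
            rows.append({
                "duplication_id": key, "clade": clade, "ka": r.ka,
                "rel_ka": r.rel_ka, "d_polarity": r.d_polarity, "ex": r.ex,
                "n_events": r.n_events, "total_length": r.total_length,
            })
    return pd.DataFrame(rows)
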