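"""Parsimony ancestral reconstruction with posterior tie resolution.

For every alignment column carrying at least one substitution, ancestral
amino-acid states are reconstructed by maximum parsimony (Sankoff dynamic
programming with unit costs; gaps and ambiguity codes are missing data).
When several reconstructions are equally parsimonious, each is weighted by
the product, over its implied substitutions, of the empirical frequency of
that (ancestral, derived) amino-acid pair at the substitution's phylogeny
depth; normalising over the alternatives yields a posterior probability
per reconstruction, and hence per hypothesised substitution.  A uniquely
most parsimonious reconstruction has posterior 1, and posteriors over the
alternatives of a site always sum to 1.

The pair-frequency matrices are built from the *non-ambiguous* sites only,
binned into ``n_bins`` (default 10) classes of phylogeny depth (Ks units)
spanning the whole tree depth, because the relative likelihood of
different exchanges drifts with evolutionary time.  The depth of a
substitution is the Ks depth of the child node of its edge; duplication
nodes take the depth of the nearest preceding speciation (upper bound).
Empty bins fall back to the pooled matrix, and a 0.5 pseudo-count floor
replaces zero cells when a required pair was never observed, so posterior
weights are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .family import AA_INDEX, AMINO_ACIDS, MISSING, ReconciledFamily, leaf_label

DEFAULT_N_BINS = 10
DEFAULT_ENUM_CAP = 64
_INF = np.inf


@dataclass
class SubstitutionEvent:
    """One hypothesised substitution on one edge, with posterior weight."""

    site: int
    child: object  # dendropy Node at the lower end of the edge
    from_aa: str
    to_aa: str
    posterior: float


@dataclass
class Reconstruction:
    """One most-parsimonious assignment of internal states at a site."""

    states: dict  # id(node) -> amino acid (internal nodes)
    substitutions: list  # (child_node, from_aa, to_aa)

    @property
    def cost(self) -> int:
        return len(self.substitutions)


class ReconstructionSet(list):
    """Equally parsimonious reconstructions; ``capped`` marks truncation."""

    capped: bool = False


def _postorder(tree):
    return list(tree.postorder_node_iter())


def sankoff_costs(site_states: dict, tree) -> dict:
    """Unit-cost Sankoff dynamic programme: per-node 20-vectors of minimal
    subtree substitution counts.  Missing leaf states cost 0 everywhere."""
    costs = {}
    for node in _postorder(tree):
        if node.is_leaf():
            aa = site_states.get(leaf_label(node))
            v = np.zeros(20)
            if aa is not None and aa not in MISSING:
                v = np.full(20, _INF)
                v[AA_INDEX[aa]] = 0.0
        else:
            v = np.zeros(20)
            for child in node.child_nodes():
                c = costs[id(child)]
                v = v + np.minimum(c, c.min() + 1.0)
        costs[id(node)] = v
    return costs


def min_cost(site_states: dict, tree) -> int:
    """Minimal number of substitutions explaining the site pattern."""
    costs = sankoff_costs(site_states, tree)
    return int(costs[id(tree.seed_node)].min())


def enumerate_parsimonious(site_states: dict, tree,
                           cap: int = DEFAULT_ENUM_CAP) -> ReconstructionSet:
    """All equally most-parsimonious reconstructions of one site.

    ``site_states`` maps leaf label -> amino acid (gap characters are
    missing data).  Invariant sites (at most one distinct observed state)
    return an empty set — there is nothing to reconstruct.  Enumeration is
    exhaustive up to ``cap`` alternatives; beyond that the set is
    truncated and flagged ``capped`` (posterior assignment then falls back
    to uniform weights).
    """
    observed = {a for a in site_states.values() if a is not None and a not in MISSING}
    out = ReconstructionSet()
    if len(observed) <= 1:
        return out
    costs = sankoff_costs(site_states, tree)
    root = tree.seed_node
    best = costs[id(root)].min()

    # DFS over internal-state choices consistent with the minimal cost
    nodes = [n for n in tree.preorder_node_iter() if not n.is_leaf()]

    def allowed(child, parent_state: Optional[int]):
        c = costs[id(child)]
        if parent_state is None:
            target = c.min()
            return [s for s in range(20) if c[s] == target]
        with_par = np.minimum(c, c.min() + 1.0)[parent_state]
        return [s for s in range(20)
                if c[s] + (0.0 if s == parent_state else 1.0) == with_par]

    def expand(idx: int, states: dict):
        if out.capped:
            return
        if idx == len(nodes):
            subs = []
            for node in nodes:
                ps = states[id(node)]
                for child in node.child_nodes():
                    if child.is_leaf():
                        aa = site_states.get(leaf_label(child))
                        if aa is None or aa in MISSING:
                            continue
                        cs = AA_INDEX[aa]
                    else:
                        cs = states[id(child)]
                    if cs != ps:
                        subs.append((child, AMINO_ACIDS[ps], AMINO_ACIDS[cs]))
            if len(out) >= cap:
                out.capped = True
                return
            out.append(Reconstruction(states=dict(states), substitutions=subs))
            return
        node = nodes[idx]
        parent = node.parent_node
        pstate = states[id(parent)] if parent is not None else None
        for s in allowed(node, pstate):
            states[id(node)] = s
            expand(idx + 1, states)
            del states[id(node)]
        return

    expand(0, {})
    assert out, "divergent site must admit at least one reconstruction"
    assert all(r.cost == best for r in out)
    return out


# ---------------------------------------------------------------------------
# depth-binned pair-frequency matrices


class DepthBinnedMatrices:
    """Per-depth-bin 20x20 relative frequencies of (ancestral, derived)
    amino-acid pairs, estimated from unambiguous substitutions."""

    def __init__(self, n_bins: int = DEFAULT_N_BINS, max_depth: float = 1.0):
        if n_bins < 1 or max_depth <= 0:
            raise ValueError("n_bins >= 1 and max_depth > 0 required")
        self.n_bins = n_bins
        self.max_depth = float(max_depth)
        self.counts = np.zeros((n_bins, 20, 20))

    def bin_index(self, depth: float) -> int:
        b = int(depth / self.max_depth * self.n_bins)
        return min(max(b, 0), self.n_bins - 1)

    def add(self, depth: float, from_aa: str, to_aa: str, weight: float = 1.0):
        self.counts[self.bin_index(depth), AA_INDEX[from_aa], AA_INDEX[to_aa]] += weight

    @property
    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def frequency(self, b: int) -> np.ndarray:
        """Bin matrix normalised to sum 1 over off-diagonal cells; empty
        bins fall back to the pooled matrix."""
        c = self.counts[b]
        if c.sum() == 0:
            c = self.pooled_counts
        total = c.sum()
        if total == 0:
            raise ValueError("no unambiguous substitutions in the corpus")
        return c / total

    def weight(self, depth: float, from_aa: str, to_aa: str) -> float:
        """Pair frequency at a depth, with a 0.5 pseudo-count floor when
        the required cell was never observed (never zero)."""
        b = self.bin_index(depth)
        freq = self.frequency(b)
        w = freq[AA_INDEX[from_aa], AA_INDEX[to_aa]]
        if w > 0:
            return float(w)
        c = self.counts[b]
        if c.sum() == 0:
            c = self.pooled_counts
        c = c + 0.5
        np.fill_diagonal(c, 0.0)
        return float(c[AA_INDEX[from_aa], AA_INDEX[to_aa]] / c.sum())


def _site_states(family: ReconciledFamily, col: int) -> dict:
    return {name: seq[col] for name, seq in family.alignment.items()}


def _unmasked_columns(family: ReconciledFamily):
    if family.mask is None:
        return range(family.length)
    return np.nonzero(~family.mask)[0]


def _edge_depth(child) -> float:
    return child.ks_depth if not child.is_leaf() else 0.0


def build_matrices(families: Sequence[ReconciledFamily],
                   n_bins: int = DEFAULT_N_BINS,
                   max_depth: Optional[float] = None,
                   cap: int = DEFAULT_ENUM_CAP) -> DepthBinnedMatrices:
    """Estimate the depth-binned pair-frequency matrices from a corpus.

    Only sites with a *single* most parsimonious reconstruction
    contribute.  Families should be masked first.  Raises if the corpus
    yields no unambiguous substitution at all.
    """
    if max_depth is None:
        max_depth = max(f.tree.seed_node.ks_depth for f in families)
    mats = DepthBinnedMatrices(n_bins=n_bins, max_depth=max_depth)
    for family in families:
        for col in _unmasked_columns(family):
            recs = enumerate_parsimonious(_site_states(family, col), family.tree)
            if len(recs) == 1 and not recs.capped:
                for child, fr, to in recs[0].substitutions:
                    mats.add(_edge_depth(child), fr, to)
    if mats.pooled_counts.sum() == 0:
        raise ValueError("no unambiguous substitutions found in the corpus")
    return mats


def assign_posteriors(reconstructions: ReconstructionSet,
                      matrices: Optional[DepthBinnedMatrices],
                      site: int = 0) -> list:
    """Posterior-weighted substitution events for one site.

    Each reconstruction's weight is the product over its substitutions of
    the matrix frequency for that (from, to) pair at the edge's depth;
    posteriors are the normalised weights.  A single reconstruction gets
    posterior exactly 1; a capped enumeration (or absent matrices) gets
    uniform posteriors.  The posterior of an *event* is the sum over the
    reconstructions containing it.
    """
    if not reconstructions:
        return []
    n = len(reconstructions)
    if n == 1:
        post = np.array([1.0])
    elif matrices is None or reconstructions.capped:
        post = np.full(n, 1.0 / n)
    else:
        w = np.array([
            np.prod([matrices.weight(_edge_depth(child), fr, to)
                     for child, fr, to in rec.substitutions])
            for rec in reconstructions
        ])
        post = w / w.sum()
    events: dict = {}
    for rec, p in zip(reconstructions, post):
        for child, fr, to in rec.substitutions:
            key = (id(child), fr, to)
            if key in events:
                events[key].posterior += float(p)
            else:
                events[key] = SubstitutionEvent(
                    site=site, child=child, from_aa=fr, to_aa=to,
                    posterior=float(p))
    return list(events.values())


def reconstruct_family(family: ReconciledFamily,
                       matrices: Optional[DepthBinnedMatrices],
                       cap: int = DEFAULT_ENUM_CAP) -> list:
    """Substitution events (posterior-weighted) for every unmasked
    divergent site of one family."""
    events = []
    for col in _unmasked_columns(family):
        recs = enumerate_parsimonious(_site_states(family, col), family.tree, cap=cap)
        events.extend(assign_posteriors(recs, matrices, site=int(col)))
    return events


def events_table(events, family_id: str = ""):
    """Events as a DataFrame (family, site, edge child, from, to, posterior)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "family": family_id,
            "site": [e.site for e in events],
            "child": [getattr(e.child, "label", None) or leaf_label(e.child)
                      for e in events],
            "from_aa": [e.from_aa for e in events],
            "to_aa": [e.to_aa for e in events],
            "posterior": [e.posterior for e in events],
        }
    )
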