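"""Parsimony engine, depth-binned matrices and posterior weighting."""

import itertools

import numpy as np
import pytest

from dupasym.ancestral_reconstruction import (
    DepthBinnedMatrices,
    assign_posteriors,
    build_matrices,
    enumerate_parsimonious,
    min_cost,
    reconstruct_family,
)
from dupasym.family import AMINO_ACIDS, ReconciledFamily, leaf_label
from dupasym.synthetic_data import SimFamilySpec, generate_family, generate_species_tree


def brute_force_min_cost(site_states, tree, alphabet):
    """Independent oracle: exhaustive search over internal assignments."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = np.inf
    for combo in itertools.product(alphabet, repeat=len(internal)):
        states = dict(zip((id(n) for n in internal), combo))
        cost = 0
        for node in internal:
            for child in node.child_nodes():
                if child.is_leaf():
                    aa = site_states[leaf_label(child)]
                    if aa == "-":
                        continue
                    cs = aa
                else:
                    cs = states[id(child)]
                if cs != states[id(node)]:
                    cost += 1
        best = min(best, cost)
    return best


class TestParsimony:
    def test_textbook_two_state_tie(self, toy4_tree):
        recs = enumerate_parsimonious({"a": "A", "b": "A", "c": "V", "d": "V"},
                                      toy4_tree)
        assert len(recs) == 2
        assert all(r.cost == 1 for r in recs)
        subs = {(r.substitutions[0][1], r.substitutions[0][2]) for r in recs}
        assert subs == {("A", "V"), ("V", "A")}

    def test_invariant_site_yields_no_events(self, toy4_tree):
        assert enumerate_parsimonious({k: "A" for k in "abcd"}, toy4_tree) == []

    def test_missing_data_is_free(self, toy4_tree):
        recs = enumerate_parsimonious({"a": "A", "b": "-", "c": "A", "d": "A"},
                                      toy4_tree)
        assert recs == []

    def test_min_cost_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(11)
        alphabet = "ACDE"
        for rep in range(60):
            n = int(rng.integers(4, 7))
            tree = generate_species_tree(n, 1.0, int(rng.integers(1 << 16)))
            states = {
                leaf_label(lf): alphabet[int(rng.integers(4))]
                for lf in tree.leaf_node_iter()
            }
            assert min_cost(states, tree) == brute_force_min_cost(
                states, tree, alphabet)

    def test_enumeration_is_exhaustive_on_four_leaf_trees(self, toy4_tree):
        # oracle: all 20^3 internal assignments, keep the minimal-cost ones
        rng = np.random.default_rng(3)
        internal = [n for n in toy4_tree.preorder_node_iter() if not n.is_leaf()]
        for rep in range(10):
            states = {k: AMINO_ACIDS[int(rng.integers(4))] for k in "abcd"}
            if len(set(states.values())) < 2:
                continue
            best, solutions = np.inf, set()
            for combo in itertools.product(AMINO_ACIDS[:6], repeat=3):
                assign = dict(zip((id(n) for n in internal), combo))
                cost = 0
                for node in internal:
                    for child in node.child_nodes():
                        cs = (states[leaf_label(child)] if child.is_leaf()
                              else assign[id(child)])
                        cost += cs != assign[id(node)]
                if cost < best:
                    best, solutions = cost, {combo}
                elif cost == best:
                    solutions.add(combo)
            recs = enumerate_parsimonious(states, toy4_tree)
            got = {
                tuple(AMINO_ACIDS[r.states[id(n)]] for n in internal)
                for r in recs
            }
            assert got == solutions

    def test_enumeration_cap_flags_truncation(self):
        tree = generate_species_tree(8, 1.0, 5)
        states = {leaf_label(lf): AMINO_ACIDS[i]
                  for i, lf in enumerate(tree.leaf_node_iter())}
        recs = enumerate_parsimonious(states, tree, cap=4)
        assert recs.capped and len(recs) == 4
        events = assign_posteriors(recs, None)
        # uniform posteriors: total event mass equals the parsimony cost
        assert sum(e.posterior for e in events) == pytest.approx(recs[0].cost)


class TestPosteriors:
    def test_unique_reconstruction_gets_posterior_one(self, toy4_tree):
        recs = enumerate_parsimonious({"a": "V", "b": "A", "c": "A", "d": "A"},
                                      toy4_tree)
        assert len(recs) == 1
        events = assign_posteriors(recs, None)
        assert len(events) == 1 and events[0].posterior == 1.0

    def test_symmetric_tie_under_uniform_matrix(self, toy4_tree):
        mats = DepthBinnedMatrices(n_bins=1, max_depth=1.0)
        mats.counts[0] = 1.0
        np.fill_diagonal(mats.counts[0], 0.0)
        recs = enumerate_parsimonious({"a": "A", "b": "A", "c": "V", "d": "V"},
                                      toy4_tree)
        events = assign_posteriors(recs, mats)
        assert {round(e.posterior, 12) for e in events} == {0.5}

    def test_hand_normalised_frequency_ratio(self, toy4_tree):
        # bin frequencies f(A->V)=0.3, f(V->A)=0.1 -> posteriors 0.75 / 0.25
        mats = DepthBinnedMatrices(n_bins=1, max_depth=1.0)
        mats.counts[0, 0, AMINO_ACIDS.index("V")] = 3  # A->V
        mats.counts[0, AMINO_ACIDS.index("V"), 0] = 1  # V->A
        mats.counts[0, AMINO_ACIDS.index("L"), AMINO_ACIDS.index("I")] = 6
        recs = enumerate_parsimonious({"a": "A", "b": "A", "c": "V", "d": "V"},
                                      toy4_tree)
        events = {(e.from_aa, e.to_aa): e.posterior
                  for e in assign_posteriors(recs, mats)}
        assert events[("A", "V")] == pytest.approx(0.75)
        assert events[("V", "A")] == pytest.approx(0.25)

    def test_posterior_mass_per_site_equals_parsimony_cost(self, species_tree6):
        # reconstruction posteriors sum to 1 per site, so the total event
        # mass at a site equals the minimal substitution count; for
        # single-substitution sites the alternative events sum to exactly 1
        spec = SimFamilySpec(length=120, dup_edge="n03", seed=21,
                             ka_ks_scale=0.4, family_id="p")
        family, _ = generate_family(species_tree6, spec)
        mats = build_matrices([family])
        checked = 0
        for col in range(family.length):
            states = {n: s[col] for n, s in family.alignment.items()}
            recs = enumerate_parsimonious(states, family.tree)
            if not recs or recs.capped:
                continue
            events = assign_posteriors(recs, mats, site=col)
            assert sum(e.posterior for e in events) == pytest.approx(
                recs[0].cost, abs=1e-9)
            assert all(0.0 <= e.posterior <= 1.0 + 1e-12 for e in events)
            checked += 1
        assert checked > 30

    def test_total_expected_count_invariant_under_enumeration_order(
            self, toy4_tree):
        mats = DepthBinnedMatrices(n_bins=1, max_depth=1.0)
        mats.counts[0] = np.arange(400, dtype=float).reshape(20, 20)
        np.fill_diagonal(mats.counts[0], 0.0)
        recs = enumerate_parsimonious({"a": "A", "b": "V", "c": "L", "d": "L"},
                                      toy4_tree)
        fwd = assign_posteriors(recs, mats)
        rev_recs = type(recs)(reversed(recs))
        rev_recs.capped = recs.capped
        rev = assign_posteriors(rev_recs, mats)
        assert sum(e.posterior for e in fwd) == pytest.approx(
            sum(e.posterior for e in rev))


class TestMatrices:
    def _single_event_family(self, toy4_tree):
        # one divergent column: d carries V, everyone else A
        aln = {"a": "AAAA", "b": "AAAA", "c": "AAAA", "d": "AAVA"}
        return ReconciledFamily("deg", aln, toy4_tree)

    def test_degenerate_corpus_single_cell(self, toy4_tree):
        fam = self._single_event_family(toy4_tree)
        mats = build_matrices([fam], n_bins=10, max_depth=1.0)
        freq = mats.frequency(0)  # leaf-child edges have depth 0
        assert freq[0, AMINO_ACIDS.index("V")] == 1.0
        assert freq.sum() == pytest.approx(1.0)

    def test_all_bin_frequencies_normalised(self, species_tree6):
        fams = []
        for i in range(4):
            spec = SimFamilySpec(length=150, dup_edge="n03", seed=31 + i,
                                 ka_ks_scale=0.4, family_id=f"m{i}")
            fams.append(generate_family(species_tree6, spec)[0])
        mats = build_matrices(fams, n_bins=5)
        for b in range(5):
            assert mats.frequency(b).sum() == pytest.approx(1.0)

    def test_empty_corpus_rejected(self, toy4_tree):
        fam = ReconciledFamily("inv", {k: "AAAA" for k in "abcd"}, toy4_tree)
        with pytest.raises(ValueError, match="unambiguous"):
            build_matrices([fam], max_depth=1.0)

    def test_zero_cell_gets_pseudocount_floor(self, toy4_tree):
        fam = self._single_event_family(toy4_tree)
        mats = build_matrices([fam], max_depth=1.0)
        w = mats.weight(0.0, "L", "I")  # never observed
        assert 0 < w < mats.weight(0.0, "A", "V")

    def test_recovered_exchange_distribution_is_uniform(self, species_tree6):
        # the generator substitutes uniformly; the pooled recovered matrix
        # must be consistent with a uniform multinomial over ordered pairs
        fams = []
        for i in range(8):
            spec = SimFamilySpec(length=250, dup_edge="n03", seed=101 + i,
                                 ka_ks_scale=0.25, family_id=f"u{i}")
            fams.append(generate_family(species_tree6, spec)[0])
        mats = build_matrices(fams)
        counts = mats.pooled_counts
        observed = counts[~np.eye(20, dtype=bool)]
        n = observed.sum()
        from scipy import stats

        chi2 = ((observed - n / 380) ** 2 / (n / 380)).sum()
        p = stats.chi2.sf(chi2, 379)
        assert p > 1e-4


def test_family_reconstruction_counts_match_ground_truth(species_tree6):
    # low divergence: hardly any multiple hits, so posterior-weighted event
    # totals recover the generator's true counts closely
    spec = SimFamilySpec(length=400, dup_edge="n03", seed=55,
                         ka_ks_scale=0.1, family_id="gt")
    family, truth = generate_family(species_tree6, spec)
    mats = build_matrices([family])
    events = reconstruct_family(family, mats)
    inferred = sum(e.posterior for e in events)
    assert inferred == pytest.approx(truth.total_events, rel=0.12)
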