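"""Alignment quality masking and family input.

Regions of low alignment quality around indels are excluded before any
substitution counting: every gap run longer than ``max_indel`` residues in
*any* sequence is masked together with ``flank`` columns on each side
(defaults 1 and 5).  Masking is column-wise for the whole family, so a bad
region in one sequence removes the column from every pairwise comparison.
Terminal gap runs are treated like internal ones (the flank is clipped at
the alignment bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .family import GAP, ReconciledFamily, leaf_label, read_gene_tree

DEFAULT_MAX_INDEL = 1
DEFAULT_FLANK = 5


@dataclass
class MaskedAlignment:
    """Aligned sequences with a per-column exclusion mask.

    ``mask[j]`` is True when column j is excluded.  ``usable_length(name)``
    counts columns that are unmasked and ungapped in that sequence — the
    denominator L of the asymmetry statistic for one ancestor->leaf path.
    """

    names: list
    sequences: list
    mask: np.ndarray

    def __post_init__(self):
        if len(self.mask) != len(self.sequences[0]):
            raise ValueError("mask length does not match alignment length")

    @property
    def length(self) -> int:
        return len(self.mask)

    def sequence(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    def usable_length(self, name: str) -> int:
        seq = np.frombuffer(self.sequence(name).encode(), dtype="S1")
        return int(np.sum(~self.mask & (seq != GAP.encode())))

    def pair_usable_length(self, name1: str, name2: str) -> int:
        s1 = np.frombuffer(self.sequence(name1).encode(), dtype="S1")
        s2 = np.frombuffer(self.sequence(name2).encode(), dtype="S1")
        g = GAP.encode()
        return int(np.sum(~self.mask & (s1 != g) & (s2 != g)))


def _gap_runs(seq: str):
    """Yield (start, stop) half-open intervals of consecutive gaps."""
    start = None
    for j, ch in enumerate(seq):
        if ch == GAP:
            if start is None:
                start = j
        elif start is not None:
            yield start, j
            start = None
    if start is not None:
        yield start, len(seq)


def mask_indels(alignment, max_indel: int = DEFAULT_MAX_INDEL,
                flank: int = DEFAULT_FLANK) -> MaskedAlignment:
    """Mask columns around indels longer than ``max_indel`` residues.

    ``alignment`` is a mapping name -> aligned sequence (or a sequence of
    (name, seq) pairs).  For each gap run of length > max_indel in any
    sequence, the run plus ``flank`` columns on each side is masked,
    clipped at the alignment bounds.  Gap runs of length <= max_indel are
    left untouched.  Idempotent and independent of sequence order.
    """
    items = list(alignment.items()) if hasattr(alignment, "items") else list(alignment)
    names = [n for n, _ in items]
    seqs = [s.upper() for _, s in items]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    L = lengths.pop()
    mask = np.zeros(L, dtype=bool)
    for seq in seqs:
        for start, stop in _gap_runs(seq):
            if stop - start > max_indel:
                mask[max(0, start - flank):min(L, stop + flank)] = True
    return MaskedAlignment(names=names, sequences=seqs, mask=mask)


def mask_family(family: ReconciledFamily, max_indel: int = DEFAULT_MAX_INDEL,
                flank: int = DEFAULT_FLANK) -> MaskedAlignment:
    """Mask a family's alignment and record the mask on the family."""
    masked = mask_indels(family.alignment, max_indel=max_indel, flank=flank)
    family.mask = masked.mask
    family.alignment = dict(zip(masked.names, masked.sequences))
    return masked


def read_family(fasta_path: str, tree_path: str,
                family_id: str | None = None) -> ReconciledFamily:
    """Read a family from an aligned FASTA and an NHX gene tree.

    Leaf names must match FASTA headers exactly (after whitespace split);
    residues are uppercased.  Mismatches raise with the offending names.
    """
    alignment = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
    }
    tree = read_gene_tree(tree_path)
    leaves = {leaf_label(lf) for lf in tree.leaf_node_iter()}
    missing = sorted(leaves - alignment.keys())
    extra = sorted(alignment.keys() - leaves)
    if missing or extra:
        raise ValueError(
            f"alignment/tree name mismatch: tree-only={missing}, fasta-only={extra}"
        )
    if family_id is None:
        import os
        family_id = os.path.splitext(os.path.basename(fasta_path))[0]
    return ReconciledFamily(family_id=family_id, alignment=alignment, tree=tree)
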