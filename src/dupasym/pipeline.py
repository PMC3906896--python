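"""End-to-end orchestration: synthesize -> mask -> reconstruct -> select ->
rate -> asymmetry -> join -> battery.

A single :class:`RunConfig` drives a full, reproducible run.  Every stage
is a pure function of its inputs plus the global seed, so rerunning the
same config yields byte-identical outputs.  The manifest records the
seed, library versions and the funnel of counts through the filters
(families in, triplets selected, pairs with a focal paralog pair, pairs
with expression, pairs SNP-eligible), which must be monotone
non-increasing.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .alignment_masking import mask_family
from .ancestral_reconstruction import build_matrices, reconstruct_family
from .asymmetry_stats import AsymmetryRecord, adjust, records_table
from .clade_rates import PropertyTables, compute_clade_rates, rates_table
from .duplication_selection import (
    age_boundaries,
    assign_age_class,
    classify_genes,
    select_duplications,
    triplets_table,
)
from .expression_polymorphism import analysis_battery, build_pair_records
from .family import leaf_label
from .synthetic_data import (
    SimFamilySpec,
    gene_id,
    generate_expression_table,
    generate_family,
    generate_location_table,
    generate_snp_table,
    generate_species_tree,
    internal_edges,
    write_family,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the analysis defaults.

    Masking: indels longer than ``max_indel`` (1) plus ``flank`` (5)
    columns are excluded.  Reconstruction: ``n_bins`` (10) depth classes.
    Ages: young boundary at Ks ``young_ks`` (0.051), upper boundary from
    cohort tertiles.  Significance: Bonferroni ``alpha`` (0.05) and
    Benjamini-Yekutieli ``fdr_q`` (0.1).  Tandem threshold 5000 bp.
    """

    # synthesis
    n_families: int = 50
    n_taxa: int = 8
    root_depth: float = 0.8
    length: int = 200
    gamma_shape: float = 2.0
    rate_ratio: float = 1.0
    dup_fraction: float = 0.8
    indel_rate: float = 0.0
    concerted_until: float = 0.0
    ka_ks_scale: float = 0.15
    expression_coupling: float = 0.0
    kaks_coupling: float = 0.0
    n_tissues: int = 26
    with_expression: bool = True
    with_snp: bool = True
    with_locations: bool = True
    # masking
    max_indel: int = 1
    flank: int = 5
    # reconstruction
    n_bins: int = 10
    enum_cap: int = 64
    # ages / stats
    young_ks: float = 0.051
    alpha: float = 0.05
    fdr_q: float = 0.1
    tandem_threshold: int = 5000
    # bookkeeping
    seed: int = 0
    outdir: Optional[str] = None
    write_families: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _family_seed(seed: int, i: int) -> int:
    return int((seed * 1_000_003 + 9973 * i + 17) % (2 ** 31))


def synthesize(config: RunConfig):
    """Generate the cohort: species tree, families and data tables."""
    tree = generate_species_tree(config.n_taxa, config.root_depth, config.seed)
    edges = [e for e in internal_edges(tree)]
    rng = np.random.default_rng(config.seed)
    families = []
    for i in range(config.n_families):
        has_dup = rng.random() < config.dup_fraction
        dup_edge = edges[int(rng.integers(len(edges)))] if has_dup else None
        spec = SimFamilySpec(
            length=config.length,
            gamma_shape=config.gamma_shape,
            dup_edge=dup_edge,
            rate_ratio=config.rate_ratio if has_dup else 1.0,
            concerted_until=config.concerted_until,
            indel_rate=config.indel_rate,
            seed=_family_seed(config.seed, i),
            ka_ks_scale=config.ka_ks_scale,
            family_id=f"fam{i:04d}",
        )
        families.append(generate_family(tree, spec))
    tables = {}
    if config.with_expression:
        tables["expression"] = generate_expression_table(
            families, config.expression_coupling, n_tissues=config.n_tissues,
            seed=config.seed + 1)
    if config.with_snp:
        tables["snp"] = generate_snp_table(
            families, config.kaks_coupling, seed=config.seed + 2)
    if config.with_locations:
        tables["locations"] = generate_location_table(
            families, seed=config.seed + 3,
            tandem_threshold=config.tandem_threshold)
    return tree, families, tables


def analyse_families(families, config: RunConfig):
    """Mask, reconstruct and score every family; returns the per-stage
    frames (triplets, clade rates, asymmetry records, focal pairs)."""
    masked = {}
    fams = []
    for family, _truth in families:
        masked[family.family_id] = mask_family(
            family, max_indel=config.max_indel, flank=config.flank)
        fams.append(family)
    matrices = build_matrices(fams, n_bins=config.n_bins)
    tables = PropertyTables.load_default()

    all_triplets = []
    for family in fams:
        for t in select_duplications(family.tree, family.family_id):
            all_triplets.append((family, t))
    if all_triplets:
        bounds = age_boundaries([t.ks_depth for _, t in all_triplets],
                                young=config.young_ks)
        for _, t in all_triplets:
            assign_age_class(t, bounds)

    records, rates_by_dup, pair_rows = [], {}, []
    events_cache, class_cache = {}, {}
    for family, triplet in all_triplets:
        if family.family_id not in events_cache:
            events_cache[family.family_id] = reconstruct_family(
                family, matrices, cap=config.enum_cap)
            class_cache[family.family_id] = classify_genes(family.tree)
        events = events_cache[family.family_id]
        classification = class_cache[family.family_id]
        rates = compute_clade_rates(
            triplet, events, masked[family.family_id], tables, classification)
        dup_id = f"{family.family_id}:{triplet.duplication.label or 'dup'}"
        rates_by_dup[dup_id] = rates
        r1, r2 = rates["paralog1"], rates["paralog2"]
        rec = AsymmetryRecord(dup_id, r1.n_events, r1.total_length,
                              r2.n_events, r2.total_length)
        records.append(rec)
        pair = _focal_pair_genes(family, triplet, classification)
        if pair is not None:
            pair_rows.append({
                "duplication_id": dup_id,
                "gene1": gene_id(family, pair[0]),
                "gene2": gene_id(family, pair[1]),
                "ka1": r1.ka, "ka2": r2.ka,
            })
    adjust(records, method="both", alpha=config.alpha, q=config.fdr_q)
    rec_df = records_table(records)
    pairs = pd.DataFrame(pair_rows) if pair_rows else pd.DataFrame(
        columns=["duplication_id", "gene1", "gene2", "ka1", "ka2"])
    pairs = pairs.merge(
        rec_df[["duplication_id", "z2", "p_value", "bonferroni_sig",
                "fdr_sig", "fdr_q"]],
        on="duplication_id", how="left")
    trip_df = triplets_table([t for _, t in all_triplets])
    trip_df.insert(0, "duplication_id", list(rates_by_dup))
    return {
        "triplets": trip_df,
        "clade_rates": rates_table(rates_by_dup),
        "asymmetry": rec_df,
        "pairs": pairs,
    }


def _focal_pair_genes(family, triplet, classification):
    """Leaf labels of the focal-species gene in each paralog clade."""
    out = []
    for clade in ("paralog1", "paralog2"):
        labels = [
            lab for lab in triplet.clade_leaves(clade, classification)
            if _species_of(family, lab) == family.focal_species
        ]
        if len(labels) != 1:
            return None
        out.append(labels[0])
    return tuple(out)


def _species_of(family, label):
    for lf in family.tree.leaf_node_iter():
        if leaf_label(lf) == label:
            return lf.species
    return None


def run(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns all result frames + manifest.

    With ``config.outdir`` set, every stage output is written there as
    TSV/JSON (families as FASTA+NHX too when ``write_families``).
    """
    logger.info("synthesizing %d families (seed %d)", config.n_families, config.seed)
    tree, families, tables = synthesize(config)
    results = analyse_families(families, config)
    pairs = results["pairs"]
    joined = build_pair_records(
        pairs,
        expression=tables.get("expression"),
        snp=tables.get("snp"),
        locations=tables.get("locations"),
        tandem_threshold=config.tandem_threshold,
    )
    results["pair_records"] = joined
    battery = analysis_battery(joined, alpha=config.alpha)
    results["battery"] = battery

    n_expr = int(joined["mean_log_me"].notna().sum()) if "mean_log_me" in joined else 0
    n_snp = int(joined["snp_eligible"].sum()) if "snp_eligible" in joined else 0
    manifest = {
        "version": __version__,
        "versions": _versions(),
        "seed": config.seed,
        # outdir is where the manifest itself lives; not part of the record
        "config": {k: v for k, v in asdict(config).items() if k != "outdir"},
        "funnel": {
            "families_in": len(families),
            "triplets_selected": len(results["asymmetry"]),
            "pairs_focal": len(pairs),
            "pairs_with_expression": min(n_expr, len(pairs)),
            "pairs_snp_eligible": min(n_snp, n_expr if n_expr else len(pairs)),
        },
    }
    results["manifest"] = manifest
    if config.outdir:
        _write_outputs(config, families, tables, results)
    return results


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_outputs(config, families, tables, results) -> None:
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    if config.write_families:
        famdir = os.path.join(out, "families")
        for family, truth in families:
            write_family(family, truth, famdir)
    for name, df in tables.items():
        df.to_csv(os.path.join(out, f"{name}.tsv"), sep="\t", index=False)
    for name in ("triplets", "clade_rates", "asymmetry", "pairs", "pair_records"):
        results[name].to_csv(os.path.join(out, f"{name}.tsv"), sep="\t", index=False)
    for name, df in results["battery"].items():
        if df is not None and len(df):
            df.to_csv(os.path.join(out, f"battery_{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(results["manifest"], fh, indent=1, sort_keys=True)
    logger.info("results written to %s", out)
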