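"""Expression, polymorphism and location asymmetry of paralog pairs.

Joins per-duplication asymmetry records with per-gene expression profiles
(mean across tissues, coefficient of variation, Shannon evenness), SNP
counts (synonymous / non-synonymous densities -> a polymorphism Ka/Ks)
and chromosomal locations, for the duplications whose paralog pair is
present in the focal genome.

Signed differences between the members of a pair are *polarized by
divergence*: dE = E_faster - E_slower, where faster/slower is decided by
the paralogs' sequence Ka.  Pairs with exactly equal Ka carry no
direction and are excluded, consistently with the removal of Z^2 = 0
datapoints from log-scale analyses.  A negative mean polarized dME
therefore means the faster-evolving copy is the lower-expressed one — the
signature of relaxed constraint / unfinished pseudogenization.

Polymorphism eligibility follows the >=3 synonymous and >=3
non-synonymous SNP rule: with fewer, the SNP Ka/Ks ratio is dominated by
noise and the pair is dropped from polymorphism analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

MIN_SNPS = 3
DEFAULT_TANDEM_BP = 5000
LOCATION_CATEGORIES = (
    "different_arms",
    "same_arm_distant",
    "tandem_collinear",
    "tandem_inverted",
)


def expression_summary(values) -> tuple:
    """(log10 mean, CV, evenness) of one expression profile.

    CV = SD/mean across tissues measures non-uniformity; evenness is the
    Shannon entropy of the tissue shares divided by ln(n_tissues), so a
    perfectly uniform profile scores 1 and a single-tissue profile scores
    its minimum 0.  All-zero profiles are flagged missing (NaNs).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two tissues")
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    total = v.sum()
    if total == 0:
        return (np.nan, np.nan, np.nan)
    mean = v.mean()
    cv = v.std(ddof=0) / mean
    shares = v / total
    nz = shares[shares > 0]
    evenness = float(-(nz * np.log(nz)).sum() / np.log(v.size))
    return (float(np.log10(mean)), float(cv), evenness)


def polarize(value1: float, value2: float, ka1: float, ka2: float) -> float:
    """Signed difference (faster-evolving paralog) - (slower one).

    Polarized by the divergence Ka of each member; undefined when
    ka1 == ka2 (raises ValueError — such pairs are excluded, as Z^2 = 0
    pairs are from log-scale analyses).  Invariant to input order.
    """
    if ka1 == ka2:
        raise ValueError("polarized difference undefined for equal Ka")
    return value1 - value2 if ka1 > ka2 else value2 - value1


def tissue_correlation(profile1, profile2) -> float:
    """Product-moment correlation of two profiles over the same tissues.

    NaN (flagged missing) if either profile has zero variance.
    """
    a = np.asarray(profile1, dtype=float)
    b = np.asarray(profile2, dtype=float)
    if a.size != b.size:
        raise ValueError("profiles cover different tissue sets")
    if a.size < 3:
        raise ValueError("need at least three tissues for a correlation")
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def snp_kaks(n_nonsyn: int, n_syn: int, sites_nonsyn: float,
             sites_syn: float) -> tuple:
    """Polymorphism Ka/Ks and its eligibility flag.

    ratio = (n_nonsyn / sites_nonsyn) / (n_syn / sites_syn); eligible iff
    both SNP counts reach the minimum of 3.  Ineligible genes still get a
    ratio when computable (NaN when n_syn = 0).
    """
    if min(n_nonsyn, n_syn) < 0 or sites_nonsyn <= 0 or sites_syn <= 0:
        raise ValueError("counts must be >= 0 and site counts positive")
    eligible = n_nonsyn >= MIN_SNPS and n_syn >= MIN_SNPS
    if n_syn == 0:
        return (np.nan, False)
    ratio = (n_nonsyn / sites_nonsyn) / (n_syn / sites_syn)
    return (float(ratio), eligible)


def classify_location(loc1, loc2, tandem_threshold: int = DEFAULT_TANDEM_BP) -> str:
    """Relative placement of two genes: one of the four pair categories.

    ``loc``s expose arm, start, end, strand (mapping or attributes).
    Distance is the gap between the gene spans (overlap = 0, hence tandem
    by orientation); tandem means gap < ``tandem_threshold``.
    """
    def get(loc, key):
        return loc[key] if isinstance(loc, dict) else getattr(loc, key)

    if get(loc1, "arm") != get(loc2, "arm"):
        return "different_arms"
    a, b = sorted((loc1, loc2), key=lambda l: get(l, "start"))
    gap = max(0, get(b, "start") - get(a, "end"))
    if gap >= tandem_threshold:
        return "same_arm_distant"
    if get(loc1, "strand") == get(loc2, "strand"):
        return "tandem_collinear"
    return "tandem_inverted"


# ---------------------------------------------------------------------------
# joining


def _tissue_cols(expression: pd.DataFrame) -> list:
    return [c for c in expression.columns if c.startswith("tissue_")]


def build_pair_records(pairs: pd.DataFrame,
                       expression: Optional[pd.DataFrame] = None,
                       snp: Optional[pd.DataFrame] = None,
                       locations: Optional[pd.DataFrame] = None,
                       tandem_threshold: int = DEFAULT_TANDEM_BP) -> pd.DataFrame:
    """Join asymmetry pairs with expression / SNP / location tables.

    ``pairs`` needs columns duplication_id, gene1, gene2, ka1, ka2, z2,
    p_value (and any significance flags to carry through).  Pairs whose
    two members resolve to the *same* expression record (one gene under
    two identifiers) are dropped entirely.  Polarized differences are NaN
    when ka1 == ka2.  Missing tables leave their columns absent.
    """
    out = pairs.copy()
    if expression is not None:
        tissues = _tissue_cols(expression)
        expr = expression.set_index("gene_id")
        rows = []
        keep = []
        for _, rec in out.iterrows():
            g1, g2 = rec["gene1"], rec["gene2"]
            if g1 == g2:
                keep.append(False)  # duplicate-identifier collapse
                rows.append({})
                continue
            keep.append(True)
            row = {}
            have = g1 in expr.index and g2 in expr.index
            if have:
                p1 = expr.loc[g1, tissues].to_numpy(dtype=float)
                p2 = expr.loc[g2, tissues].to_numpy(dtype=float)
                lm1, cv1, ev1 = expression_summary(p1)
                lm2, cv2, ev2 = expression_summary(p2)
                row.update(
                    log_me1=lm1, cv1=cv1, evenness1=ev1,
                    log_me2=lm2, cv2=cv2, evenness2=ev2,
                    mean_log_me=0.5 * (lm1 + lm2), mean_cv=0.5 * (cv1 + cv2),
                    r_tissue=tissue_correlation(p1, p2),
                )
                if rec["ka1"] != rec["ka2"]:
                    row["d_me"] = polarize(lm1, lm2, rec["ka1"], rec["ka2"])
                    row["d_cve"] = polarize(cv1, cv2, rec["ka1"], rec["ka2"])
                    row["d_evenness"] = polarize(ev1, ev2, rec["ka1"], rec["ka2"])
            rows.append(row)
        out = out.loc[keep].reset_index(drop=True)
        extra = pd.DataFrame([r for r, k in zip(rows, keep) if k])
        out = pd.concat([out, extra], axis=1)
    if snp is not None:
        sn = snp.set_index("gene_id")
        kaks1, kaks2, elig, dk = [], [], [], []
        for _, rec in out.iterrows():
            vals = []
            ok = True
            for g in (rec["gene1"], rec["gene2"]):
                if g in sn.index:
                    r, e = snp_kaks(
                        int(sn.loc[g, "n_nonsyn"]), int(sn.loc[g, "n_syn"]),
                        float(sn.loc[g, "sites_nonsyn"]), float(sn.loc[g, "sites_syn"]))
                    vals.append(r)
                    ok = ok and e
                else:
                    vals.append(np.nan)
                    ok = False
            kaks1.append(vals[0])
            kaks2.append(vals[1])
            elig.append(ok)
            if ok and rec["ka1"] != rec["ka2"]:
                dk.append(polarize(vals[0], vals[1], rec["ka1"], rec["ka2"]))
            else:
                dk.append(np.nan)
        out["kaks1"], out["kaks2"] = kaks1, kaks2
        out["snp_eligible"], out["d_kaks"] = elig, dk
    if locations is not None:
        loc = locations.set_index("gene_id")
        cats = []
        for _, rec in out.iterrows():
            g1, g2 = rec["gene1"], rec["gene2"]
            if g1 in loc.index and g2 in loc.index:
                cats.append(classify_location(
                    loc.loc[g1].to_dict(), loc.loc[g2].to_dict(),
                    tandem_threshold=tandem_threshold))
            else:
                cats.append(None)
        out["location"] = cats
    with np.errstate(divide="ignore"):
        out["log10_z2"] = np.where(out["z2"] > 0, np.log10(out["z2"]), np.nan)
    return out


# ---------------------------------------------------------------------------
# the statistical battery


def _subsets(df: pd.DataFrame) -> dict:
    subs = {"all": df}
    subs["z2_gt_1"] = df[df["z2"] > 1]
    if "fdr_sig" in df:
        subs["fdr_sig"] = df[df["fdr_sig"].astype("boolean").fillna(False)]
    return subs


def analysis_battery(pairs: pd.DataFrame, alpha: float = 0.05,
                     min_n: int = 3) -> dict:
    """The paired statistical battery over joined pair records.

    Returns a dict of DataFrames: ``tests`` (one-sample two-tailed t, sign
    and Fisher exact tests of the polarized differences, per subset),
    ``regressions`` (log Z^2 on expression summaries; polarized
    differences and tissue correlation on log Z^2 for Z^2 > 1),
    ``anova`` (two-covariate + location linear model of log Z^2),
    ``binned`` (0.5-log10-unit binned means with SEs) and ``skipped``
    (tests not run, with reasons).
    """
    tests, skipped = [], []
    for sub_name, sub in _subsets(pairs).items():
        for var in ("d_me", "d_cve", "d_evenness", "d_kaks"):
            if var not in sub:
                continue
            d = sub[var].dropna().to_numpy()
            if d.size < min_n:
                skipped.append({"test": f"t:{var}:{sub_name}",
                                "reason": f"n={d.size} < {min_n}"})
                continue
            t = stats.ttest_1samp(d, 0.0)
            npos = int((d > 0).sum())
            nneg = int((d < 0).sum())
            sign_p = stats.binomtest(npos, npos + nneg, 0.5).pvalue \
                if npos + nneg else np.nan
            fisher_p = np.nan
            if var == "d_me" and npos + nneg >= min_n:
                fisher_p = stats.fisher_exact([[npos, nneg], [nneg, npos]])[1]
            tests.append({
                "variable": var, "subset": sub_name, "n": int(d.size),
                "mean": float(d.mean()), "t": float(t.statistic),
                "df": int(d.size - 1), "p_t": float(t.pvalue),
                "p_sign": float(sign_p), "p_fisher": float(fisher_p),
                "significant": bool(t.pvalue < alpha),
            })

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    regressions = []

    def add_reg(name, df, y, x):
        d = df[[y, x]].dropna()
        if len(d) < min_n:
            skipped.append({"test": f"reg:{name}", "reason": f"n={len(d)} < {min_n}"})
            return
        if d[x].nunique() < 2 or d[y].nunique() < 2:
            skipped.append({"test": f"reg:{name}", "reason": "no variance"})
            return
        model = sm.OLS(d[y], sm.add_constant(d[x])).fit()
        regressions.append({
            "regression": name, "n": int(len(d)),
            "coef": float(model.params[x]), "intercept": float(model.params["const"]),
            "p": float(model.pvalues[x]), "r2": float(model.rsquared),
        })

    add_reg("log_z2_on_mean_expression", pairs, "log10_z2", "mean_log_me") \
        if "mean_log_me" in pairs else None
    add_reg("log_z2_on_cv", pairs, "log10_z2", "mean_cv") \
        if "mean_cv" in pairs else None
    high = pairs[pairs["z2"] > 1]
    for name, y in (("d_me_on_log_z2", "d_me"), ("d_cve_on_log_z2", "d_cve"),
                    ("r_tissue_on_log_z2", "r_tissue"),
                    ("d_kaks_on_log_z2", "d_kaks")):
        if y in pairs:
            add_reg(name, high, y, "log10_z2")

    anova = None
    needed = {"log10_z2", "mean_log_me", "mean_cv", "location"}
    if needed <= set(pairs.columns):
        d = pairs[list(needed)].dropna()
        if len(d) >= min_n + 4 and d["location"].nunique() > 1:
            fit = smf.ols("log10_z2 ~ mean_log_me + mean_cv + C(location)", d).fit()
            anova = sm.stats.anova_lm(fit, typ=2).reset_index(names="source")
        else:
            skipped.append({"test": "anova", "reason": "insufficient data/levels"})

    binned = None
    if "log10_z2" in pairs:
        d = pairs.dropna(subset=["log10_z2"]).copy()
        if len(d):
            d["z2_bin"] = np.floor(d["log10_z2"] / 0.5) * 0.5
            cols = [c for c in ("r_tissue", "d_me", "d_cve", "d_kaks") if c in d]
            if cols:
                binned = d.groupby("z2_bin")[cols].agg(["mean", "sem", "count"])
                binned.columns = ["_".join(c) for c in binned.columns]
                binned = binned.reset_index()

    return {
        "tests": pd.DataFrame(tests),
        "regressions": pd.DataFrame(regressions),
        "anova": anova,
        "binned": binned,
        "skipped": pd.DataFrame(skipped),
    }
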