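"""Count tables and differential-translation analysis.

Per gene, footprint (RFP) and RNA counts across two conditions are modeled
with a negative-binomial log-linear model

    log E[count] = log(size factor) + b0 + b1*assay + b2*condition
                   + b3*(assay x condition)

where the interaction term b3 is the change in translational efficiency
(delta-TE) between conditions.  Wald z-tests on b3 (delta-TE), on the
condition effect within RNA (b2) and within RFP (b2 + b3) give per-gene
p-values, BH-adjusted separately per test family, and genes are classified
as translational regulation, buffering, mRNA-abundance regulation, or not
significant.

Size factors use the median-of-ratios estimator jointly across assays so
offsets are comparable between RFP and RNA libraries.  The NB dispersion is
estimated per gene by method-of-moments on normalized counts, pooled across
the four (assay, condition) groups and floored at 1e-8; no shrinkage is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import LibrarySet, fpkm
from .ranges import Annotation, ReadTable, count_in_region, extract_region

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0

CLASSES = ("translational_regulation", "buffering", "mRNA_abundance", "not_significant")


@dataclass
class CountTable:
    """Gene x library count matrix with library metadata.

    ``design`` has one row per library (index = library name) with columns
    assay ('RFP' or 'RNA'), condition, replicate.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("count columns must match design rows")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def count_table(
    libraries: Mapping[str, ReadTable],
    design: pd.DataFrame,
    annotation: Annotation,
    region: str = "cds",
    merge_replicates: bool = False,
    as_fpkm: bool = False,
) -> CountTable:
    """Gene-level count table over a named region (cds, mrna, leader).

    Reads are assigned to each gene's representative transcript region by
    the standard counting rule (P-sites by position, reads by overlap).
    ``merge_replicates`` sums columns sharing (assay, condition);
    ``as_fpkm`` converts cells with each library's total mapped weight.
    """
    from .metaplots import _representative_tx

    genes = sorted(annotation.gene_index)
    cols = {}
    for name in design.index:
        lib = libraries[name]
        vals = []
        for g in genes:
            tx = _representative_tx(annotation, g)
            if region == "mrna":
                reg = tx.exons
            elif region in ("cds", "leader"):
                if tx.cds is None or (region == "leader" and tx.cds[0] == 0):
                    vals.append(0)
                    continue
                reg = extract_region(tx, region)
            else:
                raise ValueError(f"unknown region {region!r}")
            vals.append(count_in_region(lib, reg))
        cols[name] = vals
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    if merge_replicates:
        groups: Dict[Tuple[str, str], List[str]] = {}
        for name, row in design.iterrows():
            groups.setdefault((row["assay"], row["condition"]), []).append(name)
        merged = {}
        meta = []
        for (assay, cond), names in sorted(groups.items()):
            label = f"{assay}_{cond}"
            merged[label] = counts[names].sum(axis=1)
            meta.append({"library": label, "assay": assay, "condition": cond, "replicate": 1})
        counts = pd.DataFrame(merged)
        design = pd.DataFrame(meta).set_index("library")

    if as_fpkm:
        from .metaplots import _representative_tx as _rep

        lens = {}
        for g in genes:
            tx = _rep(annotation, g)
            if region == "mrna" or tx.cds is None:
                lens[g] = tx.length
            elif region == "cds":
                lens[g] = tx.cds[1] - tx.cds[0]
            else:
                lens[g] = max(tx.cds[0], 1)
        totals = counts.sum(axis=0)
        counts = counts.apply(lambda col: [fpkm(c, lens[g], totals[col.name]) for g, c in col.items()])
        counts.index = pd.Index(genes, name="gene")
    else:
        counts = counts.round().astype(np.int64)
    return CountTable(counts, design.copy())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors, jointly across all libraries."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_geo = log_counts.mean(axis=1)
    ok = np.isfinite(log_geo)
    if not ok.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log_counts.loc[ok].sub(log_geo[ok], axis=0)
    sf = np.exp(ratios.median(axis=0))
    sf = sf.fillna(1.0)
    return sf / np.exp(np.log(sf).mean())  # normalize to geometric mean 1


def _mom_dispersion_raw(q: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Gene-wise method-of-moments NB dispersion on normalized counts.

    alpha = sum over (assay, condition) groups of (s^2 - m) divided by the
    sum of m^2.  May be negative for under-dispersed samples; the caller
    floors it.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        x = q[idx]
        if len(x) < 2:
            continue
        m = x.mean()
        s2 = x.var(ddof=1)
        num += s2 - m
        den += m * m
    if den <= 0:
        return 0.0
    return float(num / den)


def dte_fit(ct: CountTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene delta-TE analysis with Wald tests and regulatory classification.

    Requires both assays and at least two conditions with two replicates
    each.  Genes with all-zero counts are excluded (reported via the
    ``excluded`` attribute on the result).  Returns a DataFrame indexed by
    gene with log2 fold changes, Wald p-values and BH q-values for the
    interaction (te), the RFP condition effect and the RNA condition effect,
    plus the deltaTE class.
    """
    design = ct.design
    assays = sorted(design["assay"].unique())
    conds = sorted(design["condition"].unique())
    if set(assays) != {"RFP", "RNA"}:
        raise ValueError("both RFP and RNA assays are required")
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    for a in assays:
        for c in conds:
            n = ((design["assay"] == a) & (design["condition"] == c)).sum()
            if n < 2:
                raise ValueError(f"need >= 2 replicates for ({a}, {c})")

    cond_b = conds[1]
    is_rfp = (design["assay"] == "RFP").to_numpy().astype(float)
    is_b = (design["condition"] == cond_b).to_numpy().astype(float)
    X = np.column_stack([np.ones_like(is_rfp), is_rfp, is_b, is_rfp * is_b])
    group_idx = [
        np.where((is_rfp == a) & (is_b == b))[0] for a in (0.0, 1.0) for b in (0.0, 1.0)
    ]
    sf = size_factors(ct.counts).to_numpy()
    offset = np.log(sf)
    L_rfp = np.array([0.0, 0.0, 1.0, 1.0])  # condition effect within RFP

    # gene-wise moment dispersions, floored at the across-gene median
    # (DESeq-classic "maximum" sharing: with few replicates the per-gene
    # estimate is noisy downward, which would inflate Wald statistics)
    raw_disp: Dict[object, float] = {}
    for gene, y in ct.counts.iterrows():
        yv = y.to_numpy(dtype=float)
        if yv.sum() > 0:
            raw_disp[gene] = _mom_dispersion_raw(yv / sf, group_idx)
    common_disp = max(float(np.median(list(raw_disp.values()))), 0.0) if raw_disp else 0.0

    rows = []
    excluded = []
    ln2 = math.log(2.0)
    for gene, y in ct.counts.iterrows():
        y = y.to_numpy(dtype=float)
        if y.sum() == 0:
            excluded.append(gene)
            continue
        disp = float(np.clip(max(raw_disp[gene], common_disp), MIN_DISPERSION, MAX_DISPERSION))
        model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=disp), offset=offset)
        try:
            fit = model.fit(maxiter=100, tol=1e-8)
            beta = fit.params
            cov = fit.cov_params()
        except Exception:
            excluded.append(gene)
            continue
        se_te = math.sqrt(max(cov[3, 3], 0.0))
        se_rna = math.sqrt(max(cov[2, 2], 0.0))
        se_rfp = math.sqrt(max(float(L_rfp @ cov @ L_rfp), 0.0))
        est_rfp = float(L_rfp @ beta)
        rows.append(
            {
                "gene": gene,
                "log2fc_te": beta[3] / ln2,
                "log2fc_rfp": est_rfp / ln2,
                "log2fc_rna": beta[2] / ln2,
                "stat_te": beta[3] / se_te if se_te > 0 else 0.0,
                "stat_rfp": est_rfp / se_rfp if se_rfp > 0 else 0.0,
                "stat_rna": beta[2] / se_rna if se_rna > 0 else 0.0,
                "dispersion": disp,
            }
        )

    res = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    if len(res):
        for fam in ("te", "rfp", "rna"):
            z = res[f"stat_{fam}"].to_numpy()
            p = 2.0 * stats.norm.sf(np.abs(z))
            res[f"p_{fam}"] = p
            res[f"q_{fam}"] = multipletests(p, method="fdr_bh")[1]
        res["class"] = classify(res, alpha)
    res.attrs["excluded"] = excluded
    res.attrs["alpha"] = alpha
    return res


def classify(res: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """deltaTE regulatory classes from per-family significance calls.

    translational_regulation: delta-TE and RFP significant, RNA not.
    buffering: delta-TE and RNA significant, and RFP either not significant
    or changing in the opposite direction from RNA.
    mRNA_abundance: delta-TE not significant, RFP and RNA both significant
    with the same sign.  Everything else: not_significant.  Significance is
    on BH-adjusted q-values.  Classes are mutually exclusive and exhaustive.
    """
    sig_te = res["q_te"] < alpha
    sig_rfp = res["q_rfp"] < alpha
    sig_rna = res["q_rna"] < alpha
    same_sign = np.sign(res["log2fc_rfp"]) == np.sign(res["log2fc_rna"])

    out = pd.Series("not_significant", index=res.index, dtype=object)
    out[sig_te & sig_rfp & ~sig_rna] = "translational_regulation"
    out[sig_te & sig_rna & (~sig_rfp | ~same_sign)] = "buffering"
    out[~sig_te & sig_rfp & sig_rna & same_sign] = "mRNA_abundance"
    return out


def te_scatter_data(ct: CountTable, annotation: Annotation, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene mean TE vs mean RNA FPKM across replicates (log-scale exported).

    TE per replicate pair uses matched condition replicates; the table
    reports the across-replicate means for plotting TE against expression.
    """
    from .metaplots import _representative_tx

    design = ct.design
    lens = {}
    for g in ct.counts.index:
        tx = _representative_tx(annotation, g)
        lens[g] = (tx.cds[1] - tx.cds[0]) if tx.cds is not None else tx.length
    totals = ct.counts.sum(axis=0)

    rfp_cols = design.index[design["assay"] == "RFP"]
    rna_cols = design.index[design["assay"] == "RNA"]
    rows = []
    for g in ct.counts.index:
        L = lens[g]
        rfp_f = [fpkm(ct.counts.loc[g, c] + pseudocount, L, totals[c]) for c in rfp_cols]
        rna_f = [fpkm(ct.counts.loc[g, c] + pseudocount, L, totals[c]) for c in rna_cols]
        mean_rna = float(np.mean(rna_f))
        mean_te = float(np.mean(rfp_f)) / mean_rna
        rows.append(
            {
                "gene": g,
                "mean_te": mean_te,
                "mean_rna_fpkm": mean_rna,
                "log2_te": math.log2(mean_te),
                "log10_rna_fpkm": math.log10(mean_rna + 1e-12),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
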