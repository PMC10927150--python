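"""Gene-set enrichment and GWAS-locus annotation.

Chi-square tests of proportions (with Yates continuity correction) for
comparing annotation rates between response categories, a generic one-sided
Fisher over-representation test against a background universe, nearest-TSS
SNP-to-gene assignment, and the combined locus report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


def chisq_proportions(
    a_in: int, a_out: int, b_in: int, b_out: int, correction: bool = True
) -> tuple[float, float]:
    """2x2 chi-square test of proportions with Yates continuity correction.

    The correction term is min(0.5, |observed - expected|), so a table with
    exactly equal proportions yields statistic 0 and p = 1.
    """
    obs = np.array([[a_in, a_out], [b_in, b_out]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any():
        raise ValueError(f"zero row margin: rows = {rows.tolist()}")
    if (cols == 0).any():
        raise ValueError(f"zero column margin: columns = {cols.tolist()}")
    expected = np.outer(rows, cols) / total
    dev = np.abs(obs - expected)
    if correction:
        dev = dev - min(0.5, dev.min())
    statistic = float((dev**2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, 1))


@dataclass
class EnrichmentResult:
    annotation: str
    category_in: int
    category_out: int
    reference_in: int
    reference_out: int
    statistic: float
    p: float

    @property
    def category_fraction(self) -> float:
        return self.category_in / (self.category_in + self.category_out)

    @property
    def reference_fraction(self) -> float:
        return self.reference_in / (self.reference_in + self.reference_out)

    @property
    def neglog10_p(self) -> float:
        return float(-np.log10(self.p)) if self.p > 0 else np.inf


def enrichment_vs_reference(
    category_genes, reference_genes, annotation_name: str, annotation_genes
) -> EnrichmentResult:
    """Is an annotation over-represented in a response category relative to a
    reference (e.g. non-response) category? 2x2 chi-square of proportions."""
    cat = set(category_genes)
    ref = set(reference_genes)
    if cat & ref:
        raise ValueError("category and reference gene sets must be disjoint")
    if not cat or not ref:
        raise ValueError("category and reference must be non-empty")
    ann = set(annotation_genes)
    a_in = len(cat & ann)
    b_in = len(ref & ann)
    statistic, p = chisq_proportions(a_in, len(cat) - a_in, b_in, len(ref) - b_in)
    return EnrichmentResult(
        annotation=annotation_name,
        category_in=a_in,
        category_out=len(cat) - a_in,
        reference_in=b_in,
        reference_out=len(ref) - b_in,
        statistic=statistic,
        p=p,
    )


def overrepresentation_test(
    query_genes, universe, gene_sets: dict, fdr: float = 0.05
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of each gene set in the
    query, against the background universe; BH adjustment across sets."""
    universe = set(universe)
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            warnings.warn(f"gene set {name!r} has no universe members; skipped")
            continue
        k = len(query & in_universe)
        big_k = len(in_universe)
        n = len(universe)
        q = len(query)
        table = [[k, q - k], [big_k - k, n - q - (big_k - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"gene_set": name, "overlap": k, "set_size": big_k,
                     "query_size": q, "universe_size": n,
                     "odds_ratio": float(odds), "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < fdr
    return out


def tss_from_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware TSS from 0-based half-open gene intervals: the interval
    start on +, the interval end - 1 on -."""
    req = {"chrom", "start", "end", "gene_id", "strand"}
    missing = req - set(intervals.columns)
    if missing:
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    bad = ~intervals["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("strand must be '+' or '-'")
    pos = np.where(intervals["strand"] == "+", intervals["start"], intervals["end"] - 1)
    return pd.DataFrame(
        {"chrom": intervals["chrom"], "tss_pos": pos, "gene_id": intervals["gene_id"],
         "strand": intervals["strand"]}
    )


def nearest_tss(snps: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """For each SNP, the gene whose TSS minimizes |snp - tss| on the same
    chromosome; distance ties break to the lexicographically smaller gene id.
    SNPs on chromosomes without any TSS are returned unannotated."""
    req_snp = {"chrom", "pos", "id"}
    req_tss = {"chrom", "tss_pos", "gene_id"}
    if not req_snp <= set(snps.columns):
        raise ValueError(f"SNP table needs columns {sorted(req_snp)}")
    if not req_tss <= set(tss.columns):
        raise ValueError(f"TSS table needs columns {sorted(req_tss)}")
    out = []
    by_chrom = {
        chrom: grp.sort_values(["tss_pos", "gene_id"]).reset_index(drop=True)
        for chrom, grp in tss.groupby("chrom")
    }
    for _, snp in snps.iterrows():
        chrom, p = snp["chrom"], int(snp["pos"])
        grp = by_chrom.get(chrom)
        if grp is None:
            out.append({"id": snp["id"], "chrom": chrom, "pos": p,
                        "gene_id": None, "distance": np.nan})
            continue
        d = np.abs(grp["tss_pos"].to_numpy() - p)
        dmin = d.min()
        candidates = grp.loc[d == dmin, "gene_id"]
        out.append({"id": snp["id"], "chrom": chrom, "pos": p,
                    "gene_id": candidates.min(), "distance": int(dmin)})
    return pd.DataFrame(out)


def annotate_gwas_genes(
    snp_genes,
    eqtl_genes,
    expressed_universe,
    contrast_tables: dict,
    signatures: pd.Series,
    gene_sets: dict | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Locus report: union of nearest-TSS genes and eQTL genes restricted to
    the expressed universe, annotated with per-contrast log2 fold change and
    DE flags, the response-signature label, and gene-set memberships."""
    snp_genes = [g for g in set(snp_genes) if g is not None]
    eqtl_genes = set(eqtl_genes)
    universe = set(expressed_universe)
    genes = sorted((set(snp_genes) | eqtl_genes) & universe)
    rows = []
    for g in genes:
        row = {
            "gene_id": g,
            "sources": "+".join(
                s for s, present in
                (("nearest_tss", g in set(snp_genes)), ("eqtl", g in eqtl_genes))
                if present
            ),
            "signature": signatures.get(g, "unassigned"),
        }
        for name, table in contrast_tables.items():
            t = table.table if hasattr(table, "table") else table
            key = name if isinstance(name, str) else f"{name[0]}_{name[1]}"
            if g in t.index:
                row[f"log2fc_{key}"] = float(t.loc[g, "log2fc"])
                row[f"de_{key}"] = bool(t.loc[g, "p_adj"] < fdr)
            else:
                row[f"log2fc_{key}"] = np.nan
                row[f"de_{key}"] = False
        for set_name, members in (gene_sets or {}).items():
            row[f"in_{set_name}"] = g in set(members)
        rows.append(row)
    return pd.DataFrame(rows)
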