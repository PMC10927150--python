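"""Enrichment statistics, TSS assignment and the GWAS locus report."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from top2itox import enrichment
from top2itox.enrichment import (
    annotate_gwas_genes,
    chisq_proportions,
    enrichment_vs_reference,
    nearest_tss,
    overrepresentation_test,
    tss_from_intervals,
)


def _fisher_greater_oracle(k, q, big_k, n):
    """One-sided Fisher p via explicit hypergeometric tail (math.comb)."""
    denom = math.comb(n, q)
    p = 0.0
    for x in range(k, min(q, big_k) + 1):
        p += math.comb(big_k, x) * math.comb(n - big_k, q - x) / denom
    return p


def test_chisq_matches_scipy_on_random_tables(rng):
    for _ in range(300):
        table = rng.integers(0, 40, size=(2, 2)) + rng.integers(0, 2, size=(2, 2))
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        stat, p = chisq_proportions(*table.ravel())
        ref_stat, ref_p, _, _ = chi2_contingency(table, correction=True)
        assert stat == pytest.approx(ref_stat, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)


def test_chisq_equal_proportions_and_errors():
    stat, p = chisq_proportions(10, 30, 20, 60)
    assert stat == 0.0 and p == 1.0
    with pytest.raises(ValueError, match="row margin"):
        chisq_proportions(0, 0, 5, 5)
    with pytest.raises(ValueError, match="column margin"):
        chisq_proportions(0, 5, 0, 5)
    with pytest.raises(ValueError, match="non-negative"):
        chisq_proportions(-1, 5, 5, 5)


def test_enrichment_vs_reference_counts_and_disjointness():
    res = enrichment_vs_reference(
        ["a", "b", "c"], ["d", "e", "f", "g"], "anno", ["a", "b", "d"]
    )
    assert (res.category_in, res.category_out) == (2, 1)
    assert (res.reference_in, res.reference_out) == (1, 3)
    assert res.category_fraction == pytest.approx(2 / 3)
    with pytest.raises(ValueError, match="disjoint"):
        enrichment_vs_reference(["a"], ["a", "b"], "anno", [])


def test_overrepresentation_matches_comb_oracle(rng):
    universe = [f"g{i}" for i in range(60)]
    for _ in range(40):
        query = list(rng.choice(universe, size=rng.integers(3, 25), replace=False))
        members = set(rng.choice(universe, size=rng.integers(2, 30), replace=False))
        out = overrepresentation_test(query, universe, {"s": members})
        k = len(set(query) & members)
        expected = _fisher_greater_oracle(k, len(query), len(members), 60)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_overrepresentation_validation_and_bh():
    universe = [f"g{i}" for i in range(30)]
    with pytest.raises(ValueError, match="subset"):
        overrepresentation_test(["nope"], universe, {"s": {"g1"}})
    with pytest.warns(UserWarning, match="no universe members"):
        out = overrepresentation_test(
            ["g1", "g2"], universe, {"bad": {"x"}, "ok": {"g1", "g5"}}
        )
    assert list(out["gene_set"]) == ["ok"]
    assert "p_adj" in out.columns


def test_tss_strand_convention():
    intervals = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [100, 500],
            "end": [200, 700],
            "gene_id": ["plus", "minus"],
            "strand": ["+", "-"],
        }
    )
    tss = tss_from_intervals(intervals)
    assert tss.loc[tss["gene_id"] == "plus", "tss_pos"].iloc[0] == 100
    assert tss.loc[tss["gene_id"] == "minus", "tss_pos"].iloc[0] == 699
    intervals.loc[0, "strand"] = "x"
    with pytest.raises(ValueError, match="strand"):
        tss_from_intervals(intervals)


def _nearest_oracle(snps, tss):
    rows = []
    for _, s in snps.iterrows():
        best_d, best_g = None, None
        for _, t in tss.iterrows():
            if t["chrom"] != s["chrom"]:
                continue
            d = abs(int(t["tss_pos"]) - int(s["pos"]))
            if best_d is None or d < best_d or (d == best_d and t["gene_id"] < best_g):
                best_d, best_g = d, t["gene_id"]
        rows.append((s["id"], best_g, best_d))
    return rows


def test_nearest_tss_small_oracle_with_ties(rng):
    tss = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=40),
            "tss_pos": rng.integers(0, 2000, size=40),
            "gene_id": [f"gene{i:02d}" for i in range(40)],
        }
    )
    snps = pd.DataFrame(
        {
            "chrom": list(rng.choice(["chr1", "chr2"], size=60)) + ["chrX"],
            "pos": list(rng.integers(0, 2000, size=60)) + [5],
            "id": [f"rs{i}" for i in range(61)],
        }
    )
    out = nearest_tss(snps, tss)
    for (sid, gene, dist), (_, row) in zip(_nearest_oracle(snps, tss), out.iterrows()):
        assert row["id"] == sid
        if gene is None:
            assert row["gene_id"] is None and np.isnan(row["distance"])
        else:
            assert row["gene_id"] == gene and row["distance"] == dist


def test_nearest_tss_exact_tie_breaks_to_smaller_id():
    tss = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "tss_pos": [90, 110], "gene_id": ["b", "a"]}
    )
    snps = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "id": ["rs1"]})
    out = nearest_tss(snps, tss)
    assert out["gene_id"].iloc[0] == "a"


def test_annotate_gwas_genes_report():
    genes = ["g1", "g2", "g3"]
    table = pd.DataFrame(
        {"log2fc": [1.0, -2.0, 0.1], "p_adj": [0.01, 0.2, 0.5]}, index=genes
    )
    signatures = pd.Series({"g1": "LR", "g2": "NR"})
    report = annotate_gwas_genes(
        snp_genes=["g1", "g9", None],
        eqtl_genes=["g2"],
        expressed_universe=genes,
        contrast_tables={"DOX_24h": table},
        signatures=signatures,
        gene_sets={"myset": {"g1"}},
    )
    assert list(report["gene_id"]) == ["g1", "g2"]  # g9 not expressed
    g1 = report.set_index("gene_id").loc["g1"]
    assert g1["sources"] == "nearest_tss"
    assert g1["de_DOX_24h"] and g1["log2fc_DOX_24h"] == 1.0
    assert g1["signature"] == "LR" and g1["in_myset"]
    g2 = report.set_index("gene_id").loc["g2"]
    assert g2["sources"] == "eqtl" and not g2["de_DOX_24h"]
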