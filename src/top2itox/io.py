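"""Readers and writers for the pipeline's plain-text formats.

Counts as TSV (genes x samples) or MatrixMarket with row/column name files,
sample sheets and plate tables as CSV, gene sets as GMT, SNPs and gene
intervals as BED.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountExperiment


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet needs a sample_id column")
    return sheet.set_index("sample_id")


def read_counts(path, samples_path, genes_path=None, columns_path=None) -> CountExperiment:
    """Load a CountExperiment from TSV or MatrixMarket plus a sample sheet.

    For MatrixMarket, ``genes_path`` and ``columns_path`` give one row/column
    name per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or columns_path is None:
            raise ValueError("MatrixMarket input needs gene and column name files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(genes_path).read_text().split()
        cols = Path(columns_path).read_text().split()
        counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=cols)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = "gene"
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = counts.columns[[not np.issubdtype(counts[c].dtype, np.number)
                              for c in counts.columns]]
        raise ValueError(f"non-numeric count columns: {list(bad)}")
    if not np.allclose(vals, np.round(vals)):
        idx = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise ValueError(
            f"non-integer count at gene {counts.index[idx[0]]!r}, "
            f"sample {counts.columns[idx[1]]!r}"
        )
    counts = counts.astype(np.int64)
    samples = read_sample_sheet(samples_path)
    return CountExperiment(counts, samples)


def write_counts_tsv(experiment: CountExperiment, counts_path, samples_path) -> None:
    experiment.counts.to_csv(counts_path, sep="\t")
    experiment.samples.to_csv(samples_path, index_label="sample_id")


def write_counts_mtx(experiment: CountExperiment, mtx_path, genes_path, columns_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(experiment.counts.to_numpy()))
    Path(genes_path).write_text("\n".join(experiment.counts.index) + "\n")
    Path(columns_path).write_text("\n".join(experiment.counts.columns) + "\n")


def read_plate_csv(path) -> pd.DataFrame:
    plate = pd.read_csv(path)
    req = {"plate", "drug", "conc_uM", "rflu", "is_background"}
    missing = req - set(plate.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    return plate


def read_trace_csv(path) -> pd.DataFrame:
    """Wide trace CSV: time_s then one column per ROI (or one 'intensity')."""
    trace = pd.read_csv(path)
    if "time_s" not in trace.columns:
        raise ValueError("trace CSV needs a time_s column")
    return trace


def read_gmt(path) -> dict:
    """GMT gene sets: name, description, then member genes, tab-separated."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_bed_snps(path) -> pd.DataFrame:
    """SNP BED (0-based): chrom, start, end, id. Position = start."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError("SNP BED needs at least 4 columns (chrom start end id)")
    return pd.DataFrame({"chrom": bed[0], "pos": bed[1].astype(int), "id": bed[3]})


def read_bed_genes(path) -> pd.DataFrame:
    """Gene-interval BED (0-based half-open): chrom, start, end, gene_id,
    score, strand."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 6:
        raise ValueError("gene BED needs 6 columns (chrom start end name score strand)")
    return pd.DataFrame(
        {"chrom": bed[0], "start": bed[1].astype(int), "end": bed[2].astype(int),
         "gene_id": bed[3], "strand": bed[5]}
    )


def read_gene_list(path) -> list:
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]
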