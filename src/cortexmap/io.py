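"""Reading and writing the standard on-disk formats: 10x MatrixMarket
triplets, GWAS catalog tables, and plain TSV result tables.  No science
lives here.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import ExpressionMatrix, GWASCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_gwas_catalog",
    "EXONIC_CLASSES",
]

#: Variant functional classes counted as exonic.  The standard reading of
#: "exonic mutation" for catalog annotations: protein-coding-sequence
#: variants, whether or not they change the protein.
EXONIC_CLASSES = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "inframe_indel",
        "coding_sequence_variant",
    }
)


def _find_companion(path: Path, stems: list) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = path / (stem + suffix)
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"missing companion file in {path}: expected one of {stems} (optionally gzipped)"
    )


def _read_tsv_column(path: Path, column: int = 0) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            out.append(parts[min(column, len(parts) - 1)])
    return np.array(out, dtype=object)


def dedupe_gene_ids(gene_ids) -> np.ndarray:
    """Make gene symbols unique by appending ``-1``, ``-2``, ... to repeats."""
    seen: dict = {}
    out = []
    for g in gene_ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}-{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return np.array(out, dtype=object)


def read_10x_mtx(path) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket directory into an :class:`ExpressionMatrix`.

    The directory must contain ``matrix.mtx`` plus a gene table
    (``genes.tsv`` or ``features.tsv``) and ``barcodes.tsv``; each may be
    gzipped.  Orientation is normalized to genes x cells whichever way the
    matrix is stored on disk.  Duplicate gene symbols get a numeric suffix.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    mtx_path = _find_companion(path, ["matrix.mtx"])
    genes_path = _find_companion(path, ["genes.tsv", "features.tsv"])
    barcodes_path = _find_companion(path, ["barcodes.tsv"])

    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(mtx_path)
    mat = sp.csr_matrix(mat)

    # 10x gene tables may carry (id, symbol); use the symbol column when present
    raw_ids = _read_tsv_column(genes_path, column=1)
    barcodes = _read_tsv_column(barcodes_path, column=0)

    n_genes, n_cells = len(raw_ids), len(barcodes)
    if mat.shape == (n_genes, n_cells):
        pass
    elif mat.shape == (n_cells, n_genes) and n_genes != n_cells:
        logger.info("matrix stored cells x genes; transposing to genes x cells")
        mat = mat.T.tocsr()
    else:
        raise ValueError(
            f"dimension mismatch: matrix is {mat.shape} but gene table has "
            f"{n_genes} entries and barcode table {n_cells}"
        )

    gene_ids = dedupe_gene_ids(raw_ids)
    meta_path = path / "cell_meta.tsv"
    cell_meta = None
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        cell_meta = cell_meta.reindex(barcodes)
    return ExpressionMatrix(mat, gene_ids, barcodes, cell_meta)


def write_10x_mtx(matrix: ExpressionMatrix, path) -> None:
    """Write the 10x triplet (matrix.mtx, genes.tsv, barcodes.tsv) plus
    cell metadata when present."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = matrix.counts.tocoo()
    if matrix.integral:
        counts = counts.astype(np.int64)
    scipy.io.mmwrite(str(path / "matrix.mtx"), counts)
    with open(path / "genes.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(path / "barcodes.tsv", "w") as fh:
        for b in matrix.barcodes:
            fh.write(f"{b}\n")
    if matrix.cell_meta is not None and matrix.cell_meta.shape[1] > 0:
        matrix.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")


_GWAS_COLUMN_ALIASES = {
    "gene": {"gene", "gene_symbol", "mapped_gene", "reported gene(s)", "reported_gene"},
    "disease": {"disease", "trait", "disease/trait", "disease_trait", "mapped_trait"},
    "functional_class": {"functional_class", "context", "variant_class", "consequence"},
}


def read_gwas_catalog(path, diseases, exonic_classes=EXONIC_CLASSES) -> GWASCatalog:
    """Read a gene-disease association TSV and keep exonic records for the
    requested diseases.

    The table needs a gene column, a disease/trait column and a variant
    functional-class column (several conventional header spellings are
    accepted).  Only rows whose functional class is exonic AND whose
    disease is listed in ``diseases`` survive; (gene, disease) pairs are
    deduplicated.  Gene symbols are whitespace-stripped and matched
    case-sensitively downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for canon, aliases in _GWAS_COLUMN_ALIASES.items():
        hit = next((lower[a] for a in aliases if a in lower), None)
        if hit is None:
            raise ValueError(
                f"could not find a '{canon}' column; expected one of "
                f"{sorted(aliases)}, got columns {list(df.columns)}"
            )
        colmap[canon] = hit
    records = df[[colmap["gene"], colmap["disease"], colmap["functional_class"]]].copy()
    records.columns = ["gene", "disease", "functional_class"]
    for col in records.columns:
        records[col] = records[col].astype(str).str.strip()
    records["functional_class"] = records["functional_class"].str.lower()

    keep = records["functional_class"].isin(exonic_classes) & records["disease"].isin(
        set(diseases)
    )
    records = records[keep].drop_duplicates(subset=["gene", "disease"])
    return GWASCatalog(records.reset_index(drop=True))


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
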