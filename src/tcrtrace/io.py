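"""Readers, writers, QC and normalization for repertoire and expression data.

Handles the three tabular dialects the pipeline touches — 10x-style filtered
contig annotation CSVs, cell metadata tables, and VDJdb-style reference TSVs —
plus MatrixMarket gene×cell count matrices. Quality control follows the
conventional mitochondrial-fraction rule with separate cutoffs for blood
(>20% removed) and tumor (>30% removed) cells, and genes with zero counts
across all remaining cells are dropped. Normalization is the standard
log1p(counts-per-scale_total) transform in natural log.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
LOCI = ("TRA", "TRB")
TIMEPOINTS = ("pre", "post")
COMPARTMENTS = ("blood", "tumor")

#: canonical 10x filtered_contig_annotations.csv column names
CONTIG_COLUMNS = {
    "barcode": "barcode",
    "chain": "chain",
    "cdr3": "cdr3",
    "productive": "productive",
    "umis": "umis",
    "v_gene": "v_gene",
    "j_gene": "j_gene",
}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class ChainRecord:
    """One productive (or not) TCR chain observation in one cell."""

    barcode: str
    locus: str
    cdr3_aa: str
    v_gene: str | None = None
    j_gene: str | None = None
    productive: bool = True
    umis: int = 1

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"locus must be one of {LOCI}, got {self.locus!r}")
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be nonempty")
        bad = set(self.cdr3_aa) - AA_ALPHABET - {"*"}
        if bad:
            raise ValueError(f"cdr3_aa contains invalid characters {sorted(bad)}")
        if self.productive and "*" in self.cdr3_aa:
            raise ValueError("productive chain cannot contain a stop codon ('*')")
        if self.umis < 0:
            raise ValueError("umis must be nonnegative")


@dataclass(frozen=True)
class CellRecord:
    """One cell with its sample-of-origin annotations."""

    barcode: str
    patient: str
    timepoint: str
    compartment: str
    cluster: str | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )

    @property
    def sample(self) -> tuple[str, str, str]:
        return (self.patient, self.timepoint, self.compartment)


class RefEntry(NamedTuple):
    cdr3_beta_aa: str
    epitope: str
    antigen_species: str
    v_gene: str | None = None
    j_gene: str | None = None


@dataclass
class ReferenceDB:
    """TCRβ-chain reference of known antigen specificities (VDJdb dialect)."""

    entries: list[RefEntry]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpressionMatrix:
    """Gene × cell count matrix with an optional log-normalized layer.

    ``lognorm`` is only present after :func:`normalize` has run; both layers
    share the gene/barcode ordering.
    """

    genes: np.ndarray
    barcodes: np.ndarray
    counts: sp.csr_matrix
    lognorm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes × {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols in expression matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_indexer(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def cell_indexer(self, barcodes: Sequence[str]) -> np.ndarray:
        pos = {b: i for i, b in enumerate(self.barcodes)}
        missing = [b for b in barcodes if b not in pos]
        if missing:
            raise KeyError(f"barcodes not present in matrix: {missing[:5]}")
        return np.array([pos[b] for b in barcodes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            genes=self.genes.copy(),
            barcodes=self.barcodes[mask],
            counts=self.counts[:, mask].tocsr(),
            lognorm=None if self.lognorm is None else self.lognorm[:, mask].tocsr(),
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            genes=self.genes[mask],
            barcodes=self.barcodes.copy(),
            counts=self.counts[mask].tocsr(),
            lognorm=None if self.lognorm is None else self.lognorm[mask].tocsr(),
        )


# ---------------------------------------------------------------------------
# contig annotations
# ---------------------------------------------------------------------------

def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "t", "1", "yes"):
        return True
    if s in ("false", "f", "0", "no", "none", "nan", ""):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s and s.lower() not in ("none", "nan") else None


def read_contig_annotations(
    path: str | Path,
    productive_only: bool = True,
    column_map: dict[str, str] | None = None,
) -> list[ChainRecord]:
    """Read a 10x-style filtered contig annotation CSV into chain records.

    Rows from loci other than TRA/TRB, rows with an empty or ``"None"`` CDR3,
    and (when ``productive_only``) non-productive rows are dropped; drop
    counts are logged. ``column_map`` maps canonical column names (keys of
    :data:`CONTIG_COLUMNS`) onto this file's dialect.
    """
    colmap = dict(CONTIG_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path)
    for canon in ("barcode", "chain", "cdr3", "productive", "umis"):
        if colmap[canon] not in df.columns:
            raise FormatError(f"{path}: missing required column {colmap[canon]!r}")
    records: list[ChainRecord] = []
    dropped = {"locus": 0, "cdr3": 0, "nonproductive": 0}
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        d = dict(zip(df.columns, row))
        locus = str(d[colmap["chain"]]).strip()
        if locus not in LOCI:
            dropped["locus"] += 1
            continue
        cdr3 = _opt_str(d[colmap["cdr3"]])
        if cdr3 is None:
            dropped["cdr3"] += 1
            continue
        try:
            productive = _parse_bool(d[colmap["productive"]])
            if productive_only and not productive:
                dropped["nonproductive"] += 1
                continue
            rec = ChainRecord(
                barcode=str(d[colmap["barcode"]]),
                locus=locus,
                cdr3_aa=cdr3,
                v_gene=_opt_str(d.get(colmap["v_gene"])),
                j_gene=_opt_str(d.get(colmap["j_gene"])),
                productive=productive,
                umis=int(d[colmap["umis"]]),
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
        records.append(rec)
    log.info(
        "read %d chains from %s (dropped: %d off-locus, %d missing CDR3, %d non-productive)",
        len(records), path, dropped["locus"], dropped["cdr3"], dropped["nonproductive"],
    )
    return records


def write_contig_annotations(records: Iterable[ChainRecord], path: str | Path) -> None:
    """Write chain records in the 10x filtered contig annotation dialect."""
    rows = [
        {
            "barcode": r.barcode,
            "is_cell": "true",
            "high_confidence": "true",
            "chain": r.locus,
            "v_gene": r.v_gene or "",
            "j_gene": r.j_gene or "",
            "cdr3": r.cdr3_aa,
            "cdr3_nt": "",
            "productive": "true" if r.productive else "false",
            "umis": r.umis,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cell metadata
# ---------------------------------------------------------------------------

def read_cell_metadata(path: str | Path) -> list[CellRecord]:
    """Read a delimited cell metadata table (barcode, patient, timepoint,
    compartment, optional cluster); timepoint/compartment are matched
    case-insensitively against the canonical vocabularies."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    for col in ("barcode", "patient", "timepoint", "compartment"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_cluster = "cluster" in df.columns
    records: list[CellRecord] = []
    seen: set[tuple] = set()
    for d in df.to_dict("records"):
        tp = d["timepoint"].strip().lower()
        comp = d["compartment"].strip().lower()
        if tp not in TIMEPOINTS:
            raise FormatError(f"{path}: unmappable timepoint value {d['timepoint']!r}")
        if comp not in COMPARTMENTS:
            raise FormatError(f"{path}: unmappable compartment value {d['compartment']!r}")
        cluster = d["cluster"].strip() if has_cluster else ""
        rec = CellRecord(
            barcode=d["barcode"],
            patient=d["patient"],
            timepoint=tp,
            compartment=comp,
            cluster=cluster or None,
        )
        key = (rec.barcode, rec.patient, rec.timepoint, rec.compartment)
        if key in seen:
            raise FormatError(f"{path}: duplicate cell key {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_cell_metadata(cells: Iterable[CellRecord], path: str | Path) -> None:
    rows = [
        {
            "barcode": c.barcode,
            "patient": c.patient,
            "timepoint": c.timepoint,
            "compartment": c.compartment,
            "cluster": c.cluster or "",
        }
        for c in cells
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices (MatrixMarket trio)
# ---------------------------------------------------------------------------

def read_expression_mtx(directory: str | Path) -> ExpressionMatrix:
    """Read a MatrixMarket triplet directory (matrix.mtx + features.tsv +
    barcodes.tsv, genes × cells)."""
    d = Path(directory)
    mat = sp.csr_matrix(mmread(d / "matrix.mtx"))
    genes = (d / "features.tsv").read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g]
    barcodes = [b for b in (d / "barcodes.tsv").read_text().splitlines() if b]
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{d}: matrix is {mat.shape} but lists give "
            f"{len(genes)} genes × {len(barcodes)} barcodes"
        )
    return ExpressionMatrix(genes=np.array(genes, dtype=object),
                            barcodes=np.array(barcodes, dtype=object),
                            counts=mat.astype(np.int64))


def write_expression_mtx(expr: ExpressionMatrix, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(str(d / "matrix.mtx"), expr.counts.astype(np.int64).tocoo(), field="integer")
    (d / "features.tsv").write_text("".join(f"{g}\n" for g in expr.genes))
    (d / "barcodes.tsv").write_text("".join(f"{b}\n" for b in expr.barcodes))


# ---------------------------------------------------------------------------
# VDJdb reference
# ---------------------------------------------------------------------------

def read_vdjdb(path: str | Path) -> ReferenceDB:
    """Read a VDJdb-style TSV, retaining only β-chain (gene == "TRB") rows.

    Duplicate CDR3β sequences are retained (one entry per epitope record).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "cdr3" not in df.columns:
        raise FormatError(f"{path}: missing required column 'cdr3'")
    for col in ("gene", "antigen.epitope", "antigen.species"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    entries = [
        RefEntry(
            cdr3_beta_aa=d["cdr3"].strip().upper(),
            epitope=d["antigen.epitope"],
            antigen_species=d["antigen.species"],
            v_gene=_opt_str(d.get("v.segm", "")),
            j_gene=_opt_str(d.get("j.segm", "")),
        )
        for d in df.to_dict("records")
        if d["gene"].strip() == "TRB" and d["cdr3"].strip()
    ]
    return ReferenceDB(entries=entries)


def write_vdjdb(db: ReferenceDB, path: str | Path) -> None:
    rows = [
        {
            "gene": "TRB",
            "cdr3": e.cdr3_beta_aa,
            "antigen.epitope": e.epitope,
            "antigen.species": e.antigen_species,
            "v.segm": e.v_gene or "",
            "j.segm": e.j_gene or "",
        }
        for e in db.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter_cells(
    expr: ExpressionMatrix,
    cells: Sequence[CellRecord],
    mito_prefix: str = "MT-",
    blood_max_mito: float = 0.20,
    tumor_max_mito: float = 0.30,
) -> tuple[ExpressionMatrix, list[CellRecord]]:
    """Remove high-mitochondrial-fraction cells and then all-zero genes.

    Blood cells with mitochondrial count fraction strictly above
    ``blood_max_mito`` and tumor cells strictly above ``tumor_max_mito`` are
    discarded, then genes with zero total counts across the surviving cells
    are dropped. Idempotent. Cells present in ``cells`` but absent from the
    matrix are dropped from the returned list (they cannot be QC'd).
    """
    cell_by_bc = {c.barcode: c for c in cells}
    missing = [b for b in expr.barcodes if b not in cell_by_bc]
    if missing:
        raise ValueError(f"matrix barcodes missing from cell metadata: {missing[:5]}")
    mito_mask = np.array([str(g).startswith(mito_prefix) for g in expr.genes])
    totals = np.asarray(expr.counts.sum(axis=0)).ravel().astype(float)
    if not mito_mask.any():
        warnings.warn(
            f"no gene symbol starts with {mito_prefix!r}; "
            "no cell removed on the mitochondrial criterion",
            stacklevel=2,
        )
        frac = np.zeros(len(expr.barcodes))
    else:
        mito_tot = np.asarray(expr.counts[mito_mask].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_tot / np.maximum(totals, 1e-300), 0.0)
    limits = np.array(
        [
            blood_max_mito if cell_by_bc[b].compartment == "blood" else tumor_max_mito
            for b in expr.barcodes
        ]
    )
    keep_cells = frac <= limits
    out = expr.subset_cells(keep_cells)
    keep_genes = np.asarray(out.counts.sum(axis=1)).ravel() > 0
    out = out.subset_genes(keep_genes)
    kept_bcs = set(out.barcodes)
    kept_cells = [c for c in cells if c.barcode in kept_bcs]
    log.info(
        "QC: removed %d/%d cells (mito fraction), %d zero-count genes",
        int((~keep_cells).sum()), len(keep_cells), int((~keep_genes).sum()),
    )
    return out, kept_cells


def normalize(expr: ExpressionMatrix, scale_total: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and natural-log transform the counts.

    ``lognorm[g, c] = ln(1 + scale_total * counts[g, c] / total_counts[c])``.
    Cells with zero total counts are rejected (error names the barcode).
    The zero pattern of ``counts`` is preserved exactly.
    """
    totals = np.asarray(expr.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {expr.barcodes[zero[0]]!r} has zero total counts; cannot normalize"
        )
    scaled = expr.counts.astype(np.float64) @ sp.diags(scale_total / totals)
    scaled = scaled.tocsr()
    scaled.data = np.log1p(scaled.data)
    return replace(expr, lognorm=scaled)
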