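"""On-disk formats: MatrixMarket contact maps, TSV tables, JSON reports.

The contact map travels as a MatrixMarket coordinate file holding the upper
triangle only (1-based indices into an accompanying contig index TSV); the
full symmetric matrix is reconstructed on read.  Counts round-trip exactly;
normalized weights round-trip to full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .binning import BinSet
from .contact_map import ContactMap, ContigCatalog


def write_contact_map(cmap: ContactMap, mm_path: str | Path, index_path: str | Path,
                      catalog: ContigCatalog | None = None) -> None:
    """Write map as upper-triangle MatrixMarket + contig index TSV.

    When a catalog is given the index TSV carries the full attribute table
    (contig_id, length, coverage, sites, signal); otherwise just the ids.
    """
    upper = sp.triu(cmap.matrix, k=1).tocoo()
    field = "integer" if np.issubdtype(upper.dtype, np.integer) else "real"
    scipy.io.mmwrite(str(mm_path), upper, field=field, precision=17)
    if catalog is not None:
        catalog.subset(cmap.contig_ids).to_tsv(index_path)
    else:
        pd.Series(cmap.contig_ids, name="contig_id").to_csv(
            index_path, sep="\t", index=False
        )


def read_contact_map(mm_path: str | Path, index_path: str | Path) -> ContactMap:
    upper = sp.coo_matrix(scipy.io.mmread(str(mm_path)))
    index = pd.read_csv(index_path, sep="\t")
    ids = index["contig_id"].astype(str).tolist()
    m = sp.csr_matrix(
        (
            np.concatenate([upper.data, upper.data]),
            (
                np.concatenate([upper.row, upper.col]),
                np.concatenate([upper.col, upper.row]),
            ),
        ),
        shape=(len(ids), len(ids)),
    )
    return ContactMap(ids, m)


def read_labels(path: str | Path) -> pd.Series:
    """Partial contig -> species table (TSV: contig_id, species)."""
    df = pd.read_csv(path, sep="\t")
    if "contig_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, names=["contig_id", "species"])
    return df.set_index("contig_id")["species"].astype(str)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("species").to_csv(path, sep="\t", index_label="contig_id")


def read_quality(path: str | Path) -> pd.DataFrame:
    """CheckM-style CSV: bin_id, completeness, contamination."""
    df = pd.read_csv(path)
    required = {"bin_id", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quality table lacks column(s) {sorted(missing)}")
    return df


def write_bins(binset: BinSet, bins_path: str | Path, summary_path: str | Path) -> None:
    rows = [(c, b) for b, contigs in binset.bins.items() for c in contigs]
    rows += [(c, "unbinned") for c in binset.unbinned]
    pd.DataFrame(rows, columns=["contig_id", "bin_id"]).to_csv(
        bins_path, sep="\t", index=False
    )
    binset.summary.to_csv(summary_path, sep="\t", index=False)


def read_bins(path: str | Path) -> BinSet:
    df = pd.read_csv(path, sep="\t")
    bins: dict[str, list[str]] = {}
    unbinned: list[str] = []
    for contig, bin_id in zip(df["contig_id"].astype(str), df["bin_id"].astype(str)):
        if bin_id == "unbinned":
            unbinned.append(contig)
        else:
            bins.setdefault(bin_id, []).append(contig)
    summary = pd.DataFrame(
        [{"bin_id": b, "n_contigs": len(c), "total_bp": np.nan} for b, c in bins.items()],
        columns=["bin_id", "n_contigs", "total_bp"],
    )
    return BinSet(bins=bins, summary=summary, unbinned=unbinned)


def write_bin_fastas(binset: BinSet, fasta_path: str | Path, outdir: str | Path) -> None:
    """One FASTA per bin, given the assembly the contigs came from."""
    from Bio import SeqIO

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = SeqIO.to_dict(SeqIO.parse(str(fasta_path), "fasta"))
    for bin_id, contigs in binset.bins.items():
        records = [seqs[c] for c in contigs if c in seqs]
        SeqIO.write(records, str(outdir / f"{bin_id}.fasta"), "fasta")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")
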