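"""Hi-C alignment parsing, raw contact-map construction and contig filtering.

The clustering unit throughout the package is the assembled contig.  A Hi-C
read pair whose two mates align to *different* contigs is evidence that the
two contigs reside in the same cell (usually the same genome); this module
turns a stream of alignments into a sparse symmetric inter-contig count
matrix (:class:`ContactMap`), computes per-contig attributes
(:class:`ContigCatalog`) and applies the standard length/signal filters that
remove short, weakly connected contigs before normalization.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: SAM flag mask excluding unmapped (0x4), secondary (0x100) and
#: supplementary (0x800) records, mirroring ``samtools view -F 0x904``.
EXCLUDE_FLAG = 0x904

#: CIGAR operations that consume both query and reference (M, =, X).
_ALIGN_OPS = frozenset((0, 7, 8))

CATALOG_COLUMNS = ("length", "coverage", "sites", "signal")


@dataclass(frozen=True)
class HiCPair:
    """An unordered pair of distinct contigs bridged by one Hi-C read pair."""

    contig_a: str
    contig_b: str

    def __post_init__(self) -> None:
        if self.contig_a == self.contig_b:
            raise ValueError(f"self pair not allowed: {self.contig_a!r}")
        if self.contig_a > self.contig_b:  # canonical order
            a, b = self.contig_a, self.contig_b
            object.__setattr__(self, "contig_a", b)
            object.__setattr__(self, "contig_b", a)


class ContigCatalog:
    """Per-contig attribute table: length, coverage, restriction sites, signal.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by contig id with
    columns ``length`` (bp), ``coverage`` (mean per-base shotgun depth),
    ``sites`` (restriction-site count; NaN in LC mode where enzymes are
    unknown) and ``signal`` (number of Hi-C reads the contig contributes to
    inter-contig pairs).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate contig id: {dup!r}")
        for col in CATALOG_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        if (df["length"].dropna() < 1).any():
            raise ValueError("contig lengths must be >= 1 bp")
        self.df = df[list(CATALOG_COLUMNS)]

    @property
    def contig_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.df.index

    def subset(self, ids: Sequence[str]) -> "ContigCatalog":
        return ContigCatalog(self.df.loc[list(ids)])

    def require(self, ids: Iterable[str]) -> None:
        """Fail naming the first contig absent from the catalog."""
        missing = set(ids).difference(self.df.index)
        if missing:
            raise KeyError(f"contig {sorted(missing)[0]!r} missing from catalog")

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="contig_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContigCatalog":
        return cls(pd.read_csv(path, sep="\t", index_col="contig_id"))


class ContactMap:
    """Sparse symmetric inter-contig contact matrix.

    Stores either raw counts ``c_ij`` (positive integers) or normalized
    weights ``n_ij`` (positive reals).  The diagonal is structurally zero:
    same-contig read pairs are discarded upstream.
    """

    def __init__(self, contig_ids: Sequence[str], matrix: sp.spmatrix | np.ndarray):
        ids = list(contig_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique")
        m = sp.csr_matrix(matrix)
        if m.shape != (len(ids), len(ids)):
            raise ValueError(f"matrix shape {m.shape} does not match {len(ids)} contig ids")
        m.eliminate_zeros()
        if m.diagonal().any():
            raise ValueError("contact map diagonal must be zero")
        if abs(m - m.T).sum() != 0:
            raise ValueError("contact map must be symmetric")
        if len(m.data) and (m.data <= 0).any():
            raise ValueError("stored contact values must be > 0")
        self.contig_ids = ids
        self.index = {c: i for i, c in enumerate(ids)}
        self.matrix = m

    # ------------------------------------------------------------------ basic
    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)

    @property
    def n_entries(self) -> int:
        """Number of unordered contig pairs with a stored contact."""
        return self.matrix.nnz // 2

    def signal(self) -> pd.Series:
        """Row sums; for a raw map this is the per-contig Hi-C read signal."""
        return pd.Series(
            np.asarray(self.matrix.sum(axis=1)).ravel(), index=self.contig_ids, name="signal"
        )

    def value(self, a: str, b: str) -> float:
        return self.matrix[self.index[a], self.index[b]]

    def entries(self) -> Iterator[tuple[str, str, float]]:
        """Iterate upper-triangle entries as (contig_a, contig_b, value)."""
        coo = sp.triu(self.matrix, k=1).tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            yield self.contig_ids[i], self.contig_ids[j], v

    def total_weight(self) -> float:
        """Total edge weight m (each unordered pair counted once)."""
        return float(self.matrix.sum()) / 2.0

    # ------------------------------------------------------------- transforms
    def subset(self, keep_ids: Sequence[str]) -> "ContactMap":
        idx = np.array([self.index[c] for c in keep_ids], dtype=int)
        return ContactMap(list(keep_ids), self.matrix[np.ix_(idx, idx)])

    def with_values(self, values: np.ndarray) -> "ContactMap":
        """Same sparsity pattern, new values (given for the stored coo data)."""
        coo = self.matrix.tocoo()
        m = sp.csr_matrix((values, (coo.row, coo.col)), shape=coo.shape)
        return ContactMap(self.contig_ids, m)

    def drop_below(self, threshold: float) -> "ContactMap":
        coo = self.matrix.tocoo()
        keep = coo.data >= threshold
        m = sp.csr_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
        )
        return ContactMap(self.contig_ids, m)


# --------------------------------------------------------------------- parsing

def _match_length(rec: pysam.AlignedSegment) -> int:
    """Aligned-base length: reference-consuming matched bases (M/=/X)."""
    if rec.cigartuples is None:
        return 0
    return sum(n for op, n in rec.cigartuples if op in _ALIGN_OPS)


def extract_hic_pairs(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    min_match_len: int = 30,
    min_mapq: int = 30,
    drop_duplicates: bool = False,
) -> list[HiCPair]:
    """Extract inter-contig Hi-C pairs from SAM/BAM alignments.

    A read pair is retained iff *both* mates are mapped, primary,
    non-supplementary (flag mask ``0x904`` clear), have aligned match length
    >= ``min_match_len`` and mapping quality >= ``min_mapq``, and the two
    mates map to different contigs.  One :class:`HiCPair` is emitted per
    retained read pair.

    ``drop_duplicates`` optionally removes exact positional duplicates
    (contig_a, pos_a, contig_b, pos_b); PCR-duplicate marking is normally
    done upstream, so this defaults to off.
    """
    owned = None
    if isinstance(alignments, (str, Path)):
        owned = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable[pysam.AlignedSegment] = owned
    elif isinstance(alignments, pysam.AlignmentFile):
        records = alignments
    else:
        records = alignments

    # qname -> {1: (passes, contig, pos), 2: ...}; secondary/supplementary
    # records never occupy a mate slot.
    mates: dict[str, dict[int, tuple[bool, str, int]]] = {}
    try:
        for idx, rec in enumerate(records):
            try:
                if rec.flag & EXCLUDE_FLAG:
                    continue
                which = 1 if rec.is_read1 or not rec.is_read2 else 2
                ok = (
                    rec.mapping_quality >= min_mapq
                    and _match_length(rec) >= min_match_len
                )
                mates.setdefault(rec.query_name, {})[which] = (
                    ok,
                    rec.reference_name,
                    rec.reference_start,
                )
            except ValueError as exc:
                raise ValueError(f"unparseable alignment record {idx}: {exc}") from exc
    finally:
        if owned is not None:
            owned.close()

    pairs: list[HiCPair] = []
    seen: set[tuple[str, int, str, int]] = set()
    n_unpaired = 0
    for slots in mates.values():
        if len(slots) != 2:
            n_unpaired += 1
            continue
        (ok1, ref1, pos1), (ok2, ref2, pos2) = slots[1], slots[2]
        if not (ok1 and ok2) or ref1 == ref2:
            continue
        if drop_duplicates:
            key = min((ref1, pos1, ref2, pos2), (ref2, pos2, ref1, pos1))
            if key in seen:
                continue
            seen.add(key)
        pairs.append(HiCPair(ref1, ref2))
    if n_unpaired:
        logger.info("skipped %d reads without a usable mate", n_unpaired)
    return pairs


def build_contact_map(
    pairs: Sequence[HiCPair], contig_ids: Sequence[str] | None = None
) -> ContactMap:
    """Aggregate Hi-C pairs into a raw contact map.

    ``c_ij`` counts the read pairs bridging contigs i and j; the per-contig
    signal is the row sum, so each retained pair contributes one read to each
    of its two contigs and the signals total twice the pair count.
    """
    counts = Counter((p.contig_a, p.contig_b) for p in pairs)
    if contig_ids is None:
        ids = sorted({c for p in pairs for c in (p.contig_a, p.contig_b)})
    else:
        ids = list(contig_ids)
    index = {c: i for i, c in enumerate(ids)}
    rows, cols, data = [], [], []
    for (a, b), c in counts.items():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        data += [c, c]
    m = sp.csr_matrix((data, (rows, cols)), shape=(len(ids), len(ids)), dtype=np.int64)
    return ContactMap(ids, m)


def filter_contigs(
    cmap: ContactMap,
    catalog: ContigCatalog,
    min_len: int = 1000,
    min_signal: int = 2,
) -> tuple[ContactMap, ContigCatalog]:
    """Remove short or weak-signal contigs from the map and catalog.

    A contig is dropped when ``length < min_len`` OR ``signal < min_signal``,
    together with all its contacts.  This is a single pass: signals are taken
    from the full input map and not recomputed after removal, so surviving
    contigs may end up with fewer contacts than ``min_signal``.
    """
    catalog.require(cmap.contig_ids)
    signal = cmap.signal()
    lengths = catalog.df["length"].reindex(cmap.contig_ids)
    keep = [
        c
        for c in cmap.contig_ids
        if lengths[c] >= min_len and signal[c] >= min_signal
    ]
    sub = cmap.subset(keep)
    cat = catalog.subset(keep)
    cat.df["signal"] = signal.reindex(keep)
    return sub, cat


# --------------------------------------------------------------- contig attrs

def count_restriction_sites(sequence: str, motifs: Sequence[str]) -> int:
    """Count occurrences of restriction motifs on the forward strand.

    Overlapping matches are counted and counts for multiple enzymes are
    summed.  Positions containing N (or any non-ACGT symbol) never match.
    The four enzymes shipped with the package all have palindromic sites, so
    scanning a single strand is exact.
    """
    seq = sequence.upper()
    total = 0
    for motif in motifs:
        if not motif:
            raise ValueError("empty restriction motif")
        total += len(re.findall(f"(?={re.escape(motif.upper())})", seq))
    return total


def contig_lengths_from_fasta(path: str | Path) -> pd.Series:
    from Bio import SeqIO

    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return pd.Series(lengths, name="length", dtype=int)


def sites_from_fasta(path: str | Path, motifs: Sequence[str]) -> pd.Series:
    from Bio import SeqIO

    sites = {
        rec.id: count_restriction_sites(str(rec.seq), motifs)
        for rec in SeqIO.parse(str(path), "fasta")
    }
    return pd.Series(sites, name="sites", dtype=int)


def load_depth_table(path: str | Path) -> pd.Series:
    """Read per-contig mean depth from a TSV.

    Accepts either a plain two-column ``contig_id<TAB>mean_depth`` table or
    the wider table written by ``jgi_summarize_bam_contig_depths`` (columns
    ``contigName``/``totalAvgDepth``).
    """
    df = pd.read_csv(path, sep="\t")
    if "contigName" in df.columns and "totalAvgDepth" in df.columns:
        s = df.set_index("contigName")["totalAvgDepth"]
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        # tolerate an optional header row
        if not pd.api.types.is_numeric_dtype(df.iloc[:, 1]):
            df = df.iloc[1:]
        s = df.set_index(0)[1].astype(float)
    s.name = "coverage"
    s.index.name = "contig_id"
    return s.astype(float)


def coverage_from_bam(path: str | Path) -> pd.Series:
    """Mean per-base depth per contig from a sorted shotgun BAM/SAM."""
    cov = {}
    with pysam.AlignmentFile(str(path)) as bam:
        for ref, length in zip(bam.references, bam.lengths):
            depth = np.sum([np.asarray(c) for c in bam.count_coverage(ref)], axis=0)
            cov[ref] = float(depth.mean()) if length else 0.0
    return pd.Series(cov, name="coverage")


def compute_coverage(
    source: str | Path | pd.Series | Mapping[str, float],
    contigs: Sequence[str] | None = None,
) -> pd.Series:
    """Resolve per-contig coverage and apply the positive-coverage floor.

    Contigs reported with zero coverage are assigned the smallest positive
    coverage observed, so log-coverage covariates are always defined.  When
    ``contigs`` is given, every one of them must have a value.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        cov = (
            coverage_from_bam(path)
            if path.suffix.lower() in {".bam", ".sam", ".cram"}
            else load_depth_table(path)
        )
    elif isinstance(source, pd.Series):
        cov = source.astype(float)
    else:
        cov = pd.Series(dict(source), dtype=float)
    if (cov < 0).any():
        raise ValueError("negative coverage value encountered")
    if contigs is not None:
        missing = set(contigs).difference(cov.index)
        if missing:
            raise KeyError(f"contig {sorted(missing)[0]!r} missing from coverage table")
        cov = cov.reindex(list(contigs))
    positive = cov[cov > 0]
    if positive.empty:
        raise ValueError("no contig has positive coverage")
    cov = cov.where(cov > 0, positive.min())
    cov.name = "coverage"
    return cov
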