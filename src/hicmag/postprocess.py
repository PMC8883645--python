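"""Post-processing of partially contaminated genome bins.

Bins that are substantially complete yet contaminated (> 50% completeness,
> 10% contamination) typically merge a dominant genome with fragments of
another.  Such bins are re-clustered individually: the Leiden algorithm is
run at resolution 1 on the bin's induced subgraph of the despursed
normalized contact map — the expected number of sub-groups inside one bin
is small, so no resolution tuning is needed — and sub-bins passing the
minimum bin size are retained in place of the parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .binning import DEFAULT_MIN_BIN_SIZE, BinSet, leiden_cluster
from .contact_map import ContactMap, ContigCatalog

logger = logging.getLogger(__name__)


def find_partially_contaminated(quality: pd.DataFrame) -> list[str]:
    """Bin ids with completeness > 50% and contamination > 10% (both strict)."""
    mask = (quality["completeness"] > 50) & (quality["contamination"] > 10)
    return quality.loc[mask, "bin_id"].tolist()


@dataclass
class ReclusterResult:
    sub_bins: list[list[str]]  # retained (above min size)
    too_small: list[str] = field(default_factory=list)  # contigs in dropped sub-bins
    split: bool = True  # False when the bin could not be divided


def recluster_bin(
    cmap: ContactMap,
    contigs: list[str],
    catalog: ContigCatalog,
    seed: int = 0,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
) -> ReclusterResult:
    """Re-cluster one bin's contigs at resolution 1 on the induced subgraph.

    Returns retained sub-bins (total length > ``min_bin_size``) and the
    contigs of sub-bins that fell below the cutoff.  An edgeless induced
    subgraph, or a re-clustering that leaves the bin in one piece, returns
    the bin unchanged with ``split=False``.
    """
    if len(contigs) < 2:
        raise ValueError("re-clustering needs a bin with >= 2 contigs")
    catalog.require(contigs)
    sub = cmap.subset(contigs)
    if sub.matrix.nnz == 0:
        logger.warning("bin induces an edgeless subgraph; returned unchanged")
        return ReclusterResult(sub_bins=[sorted(contigs)], split=False)
    part = leiden_cluster(sub, gamma=1.0, seed=seed)
    clusters = part.communities()
    if len(clusters) == 1:
        return ReclusterResult(sub_bins=[sorted(contigs)], split=False)
    lengths = catalog.df["length"]
    retained: list[list[str]] = []
    too_small: list[str] = []
    for members in clusters.values():
        if int(lengths.loc[members].sum()) > min_bin_size:
            retained.append(sorted(members))
        else:
            too_small.extend(members)
    return ReclusterResult(sub_bins=retained, too_small=sorted(too_small), split=True)


def postprocess_bins(
    binset: BinSet,
    quality: pd.DataFrame,
    cmap: ContactMap,
    catalog: ContigCatalog,
    seed: int = 0,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
) -> tuple[BinSet, dict]:
    """One round of contaminated-bin cleanup over a whole bin set.

    Flagged parents that split are replaced by their retained sub-bins;
    flagged parents that cannot be divided are retained unchanged (and
    reported as unresolved).  Contigs from sub-bins below the size cutoff
    are reported as unbinned-after-post-processing, never silently lost.
    """
    flagged = set(find_partially_contaminated(quality))
    unknown = flagged - set(binset.bins)
    if unknown:
        raise KeyError(f"quality table flags unknown bin {sorted(unknown)[0]!r}")
    lengths = catalog.df["length"]
    new_bins: list[list[str]] = []
    unresolved: list[str] = []
    unbinned_after: list[str] = list(binset.unbinned)
    n_subbins = 0
    for bin_id, contigs in binset.bins.items():
        if bin_id not in flagged:
            new_bins.append(contigs)
            continue
        if len(contigs) < 2:
            unresolved.append(bin_id)
            new_bins.append(contigs)
            continue
        res = recluster_bin(
            cmap, contigs, catalog, seed=seed, min_bin_size=min_bin_size
        )
        if not res.split:
            unresolved.append(bin_id)
            new_bins.append(contigs)
            continue
        n_subbins += len(res.sub_bins)
        new_bins.extend(res.sub_bins)
        unbinned_after.extend(res.too_small)
    new_bins.sort(key=lambda c: (-int(lengths.loc[c].sum()), c[0]))
    bins = {f"bin_{i + 1:04d}": contigs for i, contigs in enumerate(new_bins)}
    summary = pd.DataFrame(
        [
            {
                "bin_id": b,
                "n_contigs": len(c),
                "total_bp": int(lengths.loc[c].sum()),
            }
            for b, c in bins.items()
        ],
        columns=["bin_id", "n_contigs", "total_bp"],
    )
    report = {
        "n_input_bins": binset.n_bins,
        "n_flagged": len(flagged),
        "n_unresolved": len(unresolved),
        "unresolved_bins": sorted(unresolved),
        "n_subbins_retained": n_subbins,
        "n_output_bins": len(bins),
    }
    return BinSet(bins=bins, summary=summary, unbinned=sorted(unbinned_after)), report
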