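"""Binning evaluation: pair-counting metrics, NMI, CheckM ranks, split-half.

Clustering quality against a (possibly partial) species ground truth is
scored with three standard external measures — the Fowlkes–Mallows score,
the Adjusted Rand Index and normalized mutual information — restricted to
contigs that carry both a truth label and a bin assignment.  Bin-level
quality tables (completeness/contamination, as produced by marker-gene
tools such as CheckM) are classified into the usual MAG quality ranks, and
a split-half protocol estimates performance when no external ground truth
exists: half of the labeled contigs drive calibration, the other half are
scored, repeated over random splits.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    normalized_mutual_info_score,
)

from .binning import Partition

logger = logging.getLogger(__name__)

RANKS = (
    "near-complete",
    "substantially complete",
    "moderately complete",
    "weak-complete",
    "contaminated",
    "unranked",
)


def _as_series(labeling: Mapping[str, object] | pd.Series | Partition) -> pd.Series:
    if isinstance(labeling, Partition):
        return labeling.as_series()
    if isinstance(labeling, pd.Series):
        return labeling
    return pd.Series(dict(labeling))


def _align(
    truth: Mapping[str, object] | pd.Series | Partition,
    pred: Mapping[str, object] | pd.Series | Partition,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Codes for contigs present in both labelings, plus the dropped fraction."""
    t = _as_series(truth)
    p = _as_series(pred)
    common = t.index.intersection(p.index)
    if len(common) < 2:
        raise ValueError("fewer than 2 contigs carry both a label and a bin")
    dropped = 1.0 - len(common) / len(t)
    if dropped > 0:
        logger.info("evaluation drops %.1f%% of labeled contigs (unbinned)", 100 * dropped)
    return (
        pd.factorize(t.loc[common])[0],
        pd.factorize(p.loc[common])[0],
        dropped,
    )


def pair_metrics(
    truth: Mapping[str, object] | pd.Series | Partition,
    pred: Mapping[str, object] | pd.Series | Partition,
) -> tuple[float, float]:
    """Fowlkes–Mallows score and Adjusted Rand Index over contig pairs.

    Counting unordered pairs of evaluable contigs, TP are pairs co-clustered
    in both labelings, FP co-clustered only in the prediction and FN only in
    the truth; the Fowlkes–Mallows score is TP / sqrt((TP+FP)(TP+FN)) and the
    ARI is the chance-adjusted pair-agreement index.  Contigs lacking either
    a truth label or a bin assignment are dropped first.
    """
    t, p, _ = _align(truth, pred)
    return float(fowlkes_mallows_score(t, p)), float(adjusted_rand_score(t, p))


def nmi(
    truth: Mapping[str, object] | pd.Series | Partition,
    pred: Mapping[str, object] | pd.Series | Partition,
) -> float:
    """Normalized mutual information, 2 I(U;V) / (H(U) + H(V)).

    Natural-log entropies over the contingency distribution, normalized by
    the arithmetic mean of the marginal entropies.  The degenerate case where
    both labelings have zero entropy (each a single cluster) is defined as 1
    if they are identical up to relabeling — which they necessarily are —
    with a warning.
    """
    t, p, _ = _align(truth, pred)
    if len(np.unique(t)) == 1 and len(np.unique(p)) == 1:
        warnings.warn("both labelings are single clusters; NMI defined as 1")
        return 1.0
    return float(normalized_mutual_info_score(t, p, average_method="arithmetic"))


def checkm_rank(completeness: float, contamination: float) -> str:
    """Classify a bin by completeness/contamination percentages.

    near-complete: >= 90% completeness, <= 10% contamination;
    substantially complete: >= 70% and < 90%, <= 10%;
    moderately complete: >= 50% and < 70%, <= 10%;
    weak-complete: >= 20% and < 50%, <= 10%;
    contaminated: >= 20% completeness, > 10% contamination;
    anything below 20% completeness is unranked.
    """
    if not 0 <= completeness <= 100:
        raise ValueError("completeness must be a percentage in [0, 100]")
    if contamination < 0:
        raise ValueError("contamination must be >= 0")
    if completeness < 20:
        return "unranked"
    if contamination > 10:
        return "contaminated"
    if completeness >= 90:
        return "near-complete"
    if completeness >= 70:
        return "substantially complete"
    if completeness >= 50:
        return "moderately complete"
    return "weak-complete"


def rank_quality_table(quality: pd.DataFrame) -> pd.DataFrame:
    """Add a ``rank`` column to a (bin_id, completeness, contamination) table."""
    out = quality.copy()
    out["rank"] = [
        checkm_rank(c, k)
        for c, k in zip(out["completeness"], out["contamination"])
    ]
    return out


def split_half_validation(
    labels: pd.Series | Mapping[str, str],
    run_fn: Callable[[pd.Series, int], Partition | pd.Series],
    n_reps: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split-half binning validation on labeled contigs.

    Each repetition randomly divides the labeled contigs into two equal
    halves (the odd contig, if any, goes to the calibration half).
    ``run_fn(calibration_labels, rep_seed)`` runs the binning pipeline using
    only the calibration half for normalization and resolution tuning and
    returns the resulting partition; the held-out half is then scored with
    the Fowlkes–Mallows score, ARI and NMI.  Species entirely absent from
    the held-out half are logged and the repetition is scored on the rest.

    Returns ``(per_rep, summary)`` where summary holds the mean and sd of
    each metric over repetitions.  Deterministic for a fixed seed.
    """
    labels = _as_series(labels).astype(str)
    if len(labels) < 4:
        raise ValueError("split-half validation needs >= 4 labeled contigs")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(n_reps) % (2**31)]
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        order = rng.permutation(len(labels))
        half = len(labels) // 2
        eval_ids = labels.index[order[:half]]
        calib_ids = labels.index[order[half:]]  # gets the extra contig if odd
        calib = labels.loc[calib_ids]
        held = labels.loc[eval_ids]
        missing = set(labels.unique()) - set(held.unique())
        if missing:
            logger.info(
                "repetition %d: %d species absent from evaluation half", rep, len(missing)
            )
        pred = run_fn(calib, rep_seed)
        fscore, ari = pair_metrics(held, pred)
        rows.append(
            {"rep": rep, "seed": rep_seed, "fscore": fscore, "ari": ari, "nmi": nmi(held, pred)}
        )
    per_rep = pd.DataFrame(rows)
    summary = per_rep[["fscore", "ari", "nmi"]].agg(["mean", "std"]).T
    summary["std"] = summary["std"].fillna(0.0)
    summary.columns = ["mean", "sd"]
    return per_rep, summary
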