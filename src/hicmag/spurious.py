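"""Detection and removal of spurious inter-species Hi-C contacts.

Cross-species ligation noise produces contacts between contigs from
different genomes.  After bias normalization these spurious contacts are
expected to be markedly weaker than genuine same-genome contacts, so they
are removed by thresholding the normalized map.  The threshold is
calibrated on the labeled non-zero intra-species contact samples ("valid
contacts"): it is chosen so that fewer than a preselected percentage
(default 5%) of those valid contacts fall below it and would be discarded
incorrectly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .contact_map import ContactMap


@dataclass(frozen=True)
class SpuriousThreshold:
    """Calibrated lower cutoff on normalized contacts.

    ``p`` is the acceptable percentage of valid contacts lost; ``t`` the
    resulting threshold; ``n_calibration`` the number of non-zero
    intra-species samples it was calibrated on.
    """

    p: float
    t: float
    n_calibration: int


def spurious_threshold(values: np.ndarray, p: float = 5.0) -> SpuriousThreshold:
    """Calibrate the spurious-contact threshold on valid-contact values.

    Uses the lower order statistic t = k-th smallest value with
    k = floor(p/100 * n) (t = 0 when k = 0) and strict-inequality
    discarding, which guarantees #{v < t} <= p/100 * n without any
    percentile-interpolation ambiguity.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no calibration values: need non-zero intra-species contacts")
    if (values <= 0).any():
        raise ValueError("calibration values must be > 0 (non-zero valid contacts)")
    if not 0 <= p < 100:
        raise ValueError("percentage p must be in [0, 100)")
    n = values.size
    k = math.floor(p / 100.0 * n)
    t = 0.0 if k == 0 else float(np.sort(values)[k - 1])
    assert (values < t).sum() <= p / 100.0 * n
    return SpuriousThreshold(p=float(p), t=t, n_calibration=int(n))


def remove_spurious(cmap: ContactMap, thr: SpuriousThreshold) -> ContactMap:
    """Drop all normalized entries strictly below the threshold.

    Removal is symmetric; contigs left without any contact stay in the map
    index and will surface downstream as unbinned singletons.
    """
    return cmap.drop_below(thr.t)


def intra_normalized_values(
    norm_map: ContactMap, labels: Mapping[str, str] | pd.Series
) -> np.ndarray:
    """Normalized values of observed same-species (valid) contacts.

    These are the calibration samples for :func:`spurious_threshold`; only
    stored (non-zero) entries between two contigs labeled with the same
    species qualify.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    out = [
        v
        for a, b, v in norm_map.entries()
        if a in labels.index and b in labels.index and labels[a] == labels[b]
    ]
    return np.asarray(out, dtype=float)
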