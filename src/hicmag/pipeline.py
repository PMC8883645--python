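"""End-to-end orchestration: map -> normalize -> despur -> cluster -> bins.

``run_pipeline`` drives the whole binning workflow on in-memory objects and
returns the bin set together with a report recording per-stage bookkeeping
and every decided convention (threshold rule, NMI variant, seed), since
several of those conventions are free choices a reader may want to audit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binning, hiczin, postprocess as pp, spurious
from .binning import DEFAULT_MIN_BIN_SIZE, DEFAULT_RESOLUTIONS, BinSet, Partition
from .contact_map import ContactMap, ContigCatalog, filter_contigs

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the binning pipeline (defaults throughout)."""

    mode: str = "full"  # "full" | "lc"
    min_len: int = 1000
    min_signal: int = 2
    spurious_pct: float = 5.0
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS
    min_intra_samples: int = 50
    seed: int = 0
    enzymes: Sequence[str] = ()


@dataclass
class PipelineResult:
    binset: BinSet
    partition: Partition
    model: hiczin.NormModel
    threshold: spurious.SpuriousThreshold
    gamma: float
    resolution_scores: pd.DataFrame
    norm_map: ContactMap  # despursed normalized map
    report: dict
    postprocessed: BinSet | None = None


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(
    cmap: ContactMap,
    catalog: ContigCatalog,
    labels: Mapping[str, str] | pd.Series,
    config: PipelineConfig | None = None,
    quality: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full binning workflow on a raw contact map.

    Stages, in order: contig filtering, intra-species sample construction,
    ZINB fit, normalization, spurious-threshold calibration and removal,
    resolution tuning, final Leiden clustering at the tuned resolution with
    the pipeline seed, valid-bin extraction, and — when a bin quality table
    is supplied — contaminated-bin post-processing.
    """
    config = config or PipelineConfig()
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    if config.mode == "lc" and config.enzymes:
        warnings.warn("LC mode ignores restriction enzymes; site counts unused")
    report: dict = {
        "config": {**asdict(config), "resolutions": list(config.resolutions),
                   "enzymes": list(config.enzymes)},
        "conventions": {
            "spurious_quantile_rule": "k = floor(p/100 * n) lower order statistic, strict-< discard",
            "nmi_normalization": "arithmetic mean of entropies, natural log",
            "normalized_contact": "count / fitted ZINB mean (ratio residual)",
            "seed": config.seed,
        },
        "stages": {},
    }
    report["stages"]["input"] = {
        "contigs": cmap.n_contigs,
        "contacts": cmap.n_entries,
        "total_bp": int(catalog.df["length"].reindex(cmap.contig_ids).sum()),
    }

    # ---- contig filtering
    fmap, fcat = _stage("contig filtering")(
        filter_contigs, cmap, catalog, config.min_len, config.min_signal
    )
    if fmap.n_contigs == 0 or fmap.matrix.nnz == 0:
        raise PipelineError("stage 'contig filtering' left an empty contact map")
    report["stages"]["filtered"] = {
        "contigs": fmap.n_contigs,
        "contacts": fmap.n_entries,
    }

    # ---- normalization
    samples = _stage("intra-species samples")(
        hiczin.build_intra_samples, fmap, fcat, labels, config.mode
    )
    model = _stage("ZINB fit")(
        hiczin.fit_hiczin, samples, config.mode, config.min_intra_samples
    )
    nmap = _stage("normalization")(hiczin.normalize, fmap, fcat, model)
    report["stages"]["normalization"] = {
        "intra_samples": len(samples),
        "intra_nonzero": int((samples["count"] > 0).sum()),
        "model": {
            "mode": model.mode,
            "beta": model.beta.tolist(),
            "theta": model.theta,
            "pi": model.pi,
            **model.fit_info,
        },
    }

    # ---- spurious removal
    valid_values = _stage("spurious threshold")(
        spurious.intra_normalized_values, nmap, labels
    )
    thr = _stage("spurious threshold")(
        spurious.spurious_threshold, valid_values, config.spurious_pct
    )
    dmap = _stage("spurious removal")(spurious.remove_spurious, nmap, thr)
    report["stages"]["spurious_removal"] = {
        "threshold": thr.t,
        "pct": thr.p,
        "n_calibration": thr.n_calibration,
        "contacts_before": nmap.n_entries,
        "contacts_after": dmap.n_entries,
    }

    # isolated contigs cannot be clustered into a meaningful community
    degree = np.asarray(dmap.matrix.getnnz(axis=1)).ravel()
    connected = [c for c, d in zip(dmap.contig_ids, degree) if d > 0]
    isolated = [c for c, d in zip(dmap.contig_ids, degree) if d == 0]
    if not connected:
        raise PipelineError("stage 'spurious removal' left an edgeless graph")
    gmap = dmap.subset(connected)

    # ---- clustering
    gamma, scores = _stage("resolution tuning")(
        binning.tune_resolution, gmap, labels, config.resolutions, config.seed
    )
    part = _stage("clustering")(binning.leiden_cluster, gmap, gamma, config.seed)
    binset = _stage("valid-bin extraction")(
        binning.extract_valid_bins, part, fcat, config.min_bin_size
    )
    binset.unbinned = sorted(set(binset.unbinned) | set(isolated))
    report["stages"]["clustering"] = {
        "gamma": gamma,
        "resolution_scores": scores,
        "communities": part.n_communities,
        "isolated_contigs": len(isolated),
    }
    total_bp = int(catalog.df["length"].reindex(cmap.contig_ids).sum())
    report["stages"]["bins"] = {
        "n_valid_bins": binset.n_bins,
        "binned_contigs": int(binset.summary["n_contigs"].sum()) if binset.n_bins else 0,
        "binned_bp": binset.total_bp(),
        "binned_fraction_of_assembly": binset.total_bp() / total_bp if total_bp else 0.0,
        "unbinned_contigs": len(binset.unbinned),
    }

    # ---- optional post-processing
    post = None
    if quality is not None:
        post, post_report = _stage("post-processing")(
            pp.postprocess_bins, binset, quality, dmap, fcat, config.seed,
            config.min_bin_size,
        )
        report["stages"]["postprocess"] = post_report

    return PipelineResult(
        binset=binset,
        partition=part,
        model=model,
        threshold=thr,
        gamma=gamma,
        resolution_scores=scores,
        norm_map=dmap,
        report=report,
        postprocessed=post,
    )
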