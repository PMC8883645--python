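"""Synthetic microbial communities with ZINB-biased Hi-C contacts.

Every pipeline stage is testable against ground truth by simulating a
community of species, each contributing a set of contigs with realistic
lengths, coverages and restriction-site counts.  Intra-species contact
counts follow the same zero-inflated negative binomial law the normalization
model assumes, with mean depending multiplicatively on site, length and
coverage biases; a small fraction of inter-species contig pairs receives
weaker "spurious" contacts mimicking cross-cell ligation noise.  A SAM
fixture writer exercises the alignment-parsing layer end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contact_map import ContactMap, ContigCatalog
from .hiczin import FULL_COVARIATES, LC_COVARIATES, effective_sites


@dataclass
class CommunitySpec:
    """Parameters of the simulated community.

    Defaults describe a modest 10-species community with lognormal contig
    lengths (median ~5 kbp, matching the length skew of short-read
    metagenome assemblies), species-level coverages around 20x, a
    restriction-site density of one six-cutter site per ~4 kbp, strongly
    structured intra-species contacts and a low spurious-contact rate.
    """

    n_species: int = 10
    contigs_per_species: int = 40
    length_meanlog: float = 8.5  # ln bp; e^8.5 ~ 4.9 kbp
    length_sdlog: float = 1.0
    min_length: int = 1000
    coverage_meanlog: float = 3.0  # ln depth; e^3 ~ 20x
    coverage_sdlog: float = 0.5
    coverage_jitter_sdlog: float = 0.1  # per-contig wobble around species depth
    site_rate: float = 2.5e-4  # sites per bp (~ 6-cutter density)
    beta0: float = -10.5
    beta_sites: float = 0.8
    beta_length: float = 0.6
    beta_coverage: float = 0.4
    theta: float = 2.0
    pi: float = 0.3
    spurious_rate: float = 0.05  # fraction of inter-species pairs hit
    spurious_scale: float = 0.15  # intensity of a spurious contact vs intra
    spurious_preferential: bool = True  # concentrate noise on few species pairs
    label_fraction: float = 0.5  # fraction of contigs with a species label
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.contigs_per_species < 2:
            raise ValueError("need >= 1 species with >= 2 contigs each")
        if not 0 <= self.spurious_rate < 1:
            raise ValueError("spurious_rate must be in [0, 1)")
        if not 0 < self.spurious_scale < 1:
            raise ValueError("spurious_scale must be in (0, 1)")
        if not 0 <= self.pi < 1:
            raise ValueError("pi must be in [0, 1)")
        if self.theta <= 0 or self.site_rate < 0:
            raise ValueError("theta must be > 0 and site_rate >= 0")
        if not 0 < self.label_fraction <= 1:
            raise ValueError("label_fraction must be in (0, 1]")


@dataclass
class SimulatedCommunity:
    """Simulation output: inputs for the pipeline plus full ground truth."""

    spec: CommunitySpec
    catalog: ContigCatalog
    truth: pd.Series  # every contig -> species
    labels: pd.Series  # the partial annotation subset
    cmap: ContactMap  # raw counts
    pair_truth: pd.DataFrame  # contig_a, contig_b, count, intra, spurious_draw


def _zinb_draws(rng: np.random.Generator, mu: np.ndarray, theta: float, pi: float) -> np.ndarray:
    """Vectorized ZINB sampling (structural zeros + NB2 counts)."""
    nb = rng.negative_binomial(theta, theta / (theta + mu))
    return np.where(rng.random(mu.shape) < pi, 0, nb)


def simulate_community(spec: CommunitySpec) -> SimulatedCommunity:
    """Draw one community: catalog, partial labels, raw contact map, truth.

    Intra-species pair counts are ZINB with
    ln mu = b0 + b1 ln(s_i s_j) + b2 ln(l_i l_j) + b3 ln(cov_i cov_j)
    on raw (unstandardized) covariates.  Each inter-species pair is
    independently selected with probability ``spurious_rate``; selected
    pairs draw from the same law with mu scaled by ``spurious_scale``.
    Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species * spec.contigs_per_species
    species = np.repeat([f"species_{s + 1:02d}" for s in range(spec.n_species)],
                        spec.contigs_per_species)
    ids = [f"ctg_{i + 1:05d}" for i in range(n)]

    lengths = np.maximum(
        rng.lognormal(spec.length_meanlog, spec.length_sdlog, n), spec.min_length
    ).astype(np.int64)
    depth = rng.lognormal(spec.coverage_meanlog, spec.coverage_sdlog, spec.n_species)
    coverage = np.repeat(depth, spec.contigs_per_species) * rng.lognormal(
        0.0, spec.coverage_jitter_sdlog, n
    )
    sites = rng.binomial(lengths, min(spec.site_rate, 1.0))

    s_eff = effective_sites(sites)
    log_s, log_l, log_c = np.log(s_eff), np.log(lengths), np.log(coverage)

    def log_mu(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
        return (
            spec.beta0
            + spec.beta_sites * (log_s[ia] + log_s[ib])
            + spec.beta_length * (log_l[ia] + log_l[ib])
            + spec.beta_coverage * (log_c[ia] + log_c[ib])
        )

    # intra-species pairs: every same-species pair is a candidate contact
    intra_a, intra_b = [], []
    for s in range(spec.n_species):
        base = s * spec.contigs_per_species
        for i, j in itertools.combinations(range(spec.contigs_per_species), 2):
            intra_a.append(base + i)
            intra_b.append(base + j)
    intra_a = np.array(intra_a)
    intra_b = np.array(intra_b)
    intra_counts = _zinb_draws(rng, np.exp(log_mu(intra_a, intra_b)), spec.theta, spec.pi)

    # inter-species pairs: a fraction spurious_rate gets a weak contact
    iu, ju = np.triu_indices(n, k=1)
    inter_mask = species[iu] != species[ju]
    inter_a, inter_b = iu[inter_mask], ju[inter_mask]
    if spec.spurious_preferential and spec.n_species > 1:
        # mimic closely-related-species noise: half the mass on a few pairs
        sp_pair = np.char.add(species[inter_a], species[inter_b])
        hot = set()
        all_sp_pairs = sorted(set(sp_pair.tolist()))
        n_hot = max(1, len(all_sp_pairs) // 5)
        hot = set(rng.choice(all_sp_pairs, size=n_hot, replace=False).tolist())
        rate = np.where(
            np.isin(sp_pair, list(hot)),
            min(3.0 * spec.spurious_rate, 0.99),
            spec.spurious_rate * (len(all_sp_pairs) - 3 * n_hot) / max(len(all_sp_pairs) - n_hot, 1),
        )
        rate = np.clip(rate, 0.0, 0.99)
        # keep the marginal selection probability equal to spurious_rate
        rate *= spec.spurious_rate / max(rate.mean(), 1e-12)
        rate = np.clip(rate, 0.0, 0.99)
    else:
        rate = np.full(inter_a.shape, spec.spurious_rate)
    chosen = rng.random(inter_a.shape) < rate
    spur_a, spur_b = inter_a[chosen], inter_b[chosen]
    spur_counts = _zinb_draws(
        rng,
        spec.spurious_scale * np.exp(log_mu(spur_a, spur_b)),
        spec.theta,
        spec.pi,
    )

    rows = np.concatenate([intra_a, spur_a])
    cols = np.concatenate([intra_b, spur_b])
    counts = np.concatenate([intra_counts, spur_counts])
    if counts.sum() == 0:
        raise ValueError("spec implies an empty contact map")
    keep = counts > 0
    m = sp.csr_matrix(
        (
            np.concatenate([counts[keep], counts[keep]]),
            (
                np.concatenate([rows[keep], cols[keep]]),
                np.concatenate([cols[keep], rows[keep]]),
            ),
        ),
        shape=(n, n),
        dtype=np.int64,
    )
    cmap = ContactMap(ids, m)

    pair_truth = pd.DataFrame(
        {
            "contig_a": [ids[i] for i in rows],
            "contig_b": [ids[j] for j in cols],
            "count": counts,
            "intra": np.concatenate(
                [np.ones(len(intra_a), bool), np.zeros(len(spur_a), bool)]
            ),
            "spurious_draw": np.concatenate(
                [np.zeros(len(intra_a), bool), np.ones(len(spur_a), bool)]
            ),
        }
    )
    pair_truth.attrs["n_inter_pairs"] = int(inter_mask.sum())

    truth = pd.Series(species, index=ids, name="species")
    labeled_idx = rng.choice(
        n, size=max(2, int(round(spec.label_fraction * n))), replace=False
    )
    labels = truth.iloc[np.sort(labeled_idx)]

    catalog = ContigCatalog(
        pd.DataFrame(
            {
                "length": lengths,
                "coverage": coverage,
                "sites": sites,
                "signal": cmap.signal().to_numpy(),
            },
            index=pd.Index(ids, name="contig_id"),
        )
    )
    return SimulatedCommunity(
        spec=spec,
        catalog=catalog,
        truth=truth,
        labels=labels,
        cmap=cmap,
        pair_truth=pair_truth,
    )


def simulate_intra_samples(
    beta: tuple[float, ...] = (1.5, 0.8, 0.6, 0.4),
    theta: float = 2.0,
    pi: float = 0.3,
    n: int = 5000,
    seed: int = 0,
    mode: str = "full",
) -> pd.DataFrame:
    """Simulate intra-species contact samples with known coefficients.

    Covariates are drawn standard normal (already on the fitter's
    standardized scale), so the fitted slopes are directly comparable to the
    ``beta`` used here.  Returns a frame consumable by ``fit_hiczin``.
    """
    rng = np.random.default_rng(seed)
    covnames = list(FULL_COVARIATES if mode == "full" else LC_COVARIATES)
    k = len(covnames)
    if len(beta) != k + 1:
        raise ValueError(f"beta must have {k + 1} entries for mode {mode!r}")
    z = rng.standard_normal((n, k))
    mu = np.exp(beta[0] + z @ np.asarray(beta[1:]))
    y = _zinb_draws(rng, mu, theta, pi)
    df = pd.DataFrame(z, columns=covnames)
    df.insert(0, "count", y.astype(np.int64))
    return df


# ------------------------------------------------------------- SAM fixtures

_POISON_KINDS = ("secondary", "supplementary", "low_mapq", "short_match",
                 "same_contig", "unmapped")


def write_sam_fixture(
    contig_lengths: dict[str, int],
    pairs: list[tuple[str, str]],
    poison: list[str] | None = None,
    path: str | Path | None = None,
    read_len: int = 50,
    mapq: int = 60,
) -> str:
    """Emit a small, syntactically valid SAM file for the extraction layer.

    Each entry of ``pairs`` becomes one clean read pair bridging the two
    contigs.  ``poison`` lists defective read pairs to interleave, one per
    keyword: ``secondary`` / ``supplementary`` (mate flagged 0x100/0x800),
    ``low_mapq`` (MAPQ 10), ``short_match`` (20 aligned bases),
    ``same_contig`` (both mates on one contig) and ``unmapped``.  Poisoned
    pairs must all be filtered out by the extractor.
    """
    if len(pairs) > 10_000:
        raise ValueError("fixture writer is for small inputs (<= 10^4 pairs)")
    contigs = list(contig_lengths)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in contigs:
        lines.append(f"@SQ\tSN:{c}\tLN:{contig_lengths[c]}")
    seq = "A" * read_len
    qual = "I" * read_len

    def rec(qname, flag, ref, pos, this_mapq, cigar, rnext, pnext, this_seq=seq, this_qual=qual):
        lines.append(
            "\t".join(
                [
                    qname,
                    str(flag),
                    ref,
                    str(pos),
                    str(this_mapq),
                    cigar,
                    rnext,
                    str(pnext),
                    "0",
                    this_seq,
                    this_qual,
                ]
            )
        )

    def emit_pair(qname, ref1, ref2, mapq1=mapq, mapq2=mapq, cigar1=None,
                  cigar2=None, extra_flag2=0, unmapped2=False):
        cigar1 = cigar1 or f"{read_len}M"
        cigar2 = cigar2 or f"{read_len}M"
        pos1 = max(1, contig_lengths[ref1] // 3)
        pos2 = max(1, contig_lengths[ref2] // 3)
        rec(qname, 0x1 | 0x40, ref1, pos1, mapq1, cigar1, ref2, pos2)
        if unmapped2:
            rec(qname, 0x1 | 0x80 | 0x4, "*", 0, 0, "*", ref1, pos1)
        else:
            rec(qname, 0x1 | 0x80 | extra_flag2, ref2, pos2, mapq2, cigar2, ref1, pos1)

    for k, (a, b) in enumerate(pairs):
        emit_pair(f"pair_{k:05d}", a, b)

    for k, kind in enumerate(poison or []):
        if kind not in _POISON_KINDS:
            raise ValueError(f"unknown poison kind {kind!r}")
        qname = f"poison_{k:03d}_{kind}"
        a = contigs[0]
        b = contigs[1] if len(contigs) > 1 else contigs[0]
        if kind == "secondary":
            emit_pair(qname, a, b, extra_flag2=0x100)
        elif kind == "supplementary":
            emit_pair(qname, a, b, extra_flag2=0x800)
        elif kind == "low_mapq":
            emit_pair(qname, a, b, mapq2=10)
        elif kind == "short_match":
            emit_pair(qname, a, b, cigar2=f"20M{read_len - 20}S")
        elif kind == "same_contig":
            emit_pair(qname, a, a)
        elif kind == "unmapped":
            emit_pair(qname, a, b, unmapped2=True)

    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
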