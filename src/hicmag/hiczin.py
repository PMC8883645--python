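"""Zero-inflated negative binomial normalization of raw Hi-C contact maps.

Raw inter-contig contact counts carry three multiplicative experimental
biases: the number of restriction sites on each contig, contig length, and
contig coverage.  Following the HiCzin approach, the bias model is fitted on
*intra-species* contact samples — all unordered pairs of contigs annotated to
the same species, including pairs with zero observed contacts — under a
zero-inflated negative binomial (ZINB) law:

    P(C = 0)     = pi + (1 - pi) * NB(0; mu, theta)
    P(C = c > 0) = (1 - pi) * NB(c; mu, theta)
    ln mu        = b0 + b1*z1 + b2*z2 + b3*z3

where z1 = standardized ln(s_i s_j) (restriction sites), z2 = standardized
ln(l_i l_j) (lengths), z3 = standardized ln(cov_i cov_j) (coverages), NB is
the NB2 parameterization (variance mu + mu^2/theta) and pi is an
intercept-only zero-inflation probability absorbing unobserved contacts.
In LC mode ("length-coverage", for experiments whose restriction enzymes
are unknown) the site covariate is dropped.

The normalized contact is the counting-part ratio residual
``n_ij = c_ij / mu_ij``, which is scale-free and directly comparable across
contig pairs; zero counts never produce stored normalized entries.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.special import expit, gammaln, logit

from .contact_map import ContactMap, ContigCatalog

logger = logging.getLogger(__name__)

FULL_COVARIATES = ("ln_sites", "ln_length", "ln_coverage")
LC_COVARIATES = ("ln_length", "ln_coverage")


def effective_sites(sites: np.ndarray | pd.Series) -> np.ndarray:
    """Site counts floored at 1 so log transforms stay finite."""
    return np.maximum(np.asarray(sites, dtype=float), 1.0)


@dataclass
class NormModel:
    """Fitted ZINB bias model plus the covariate standardization.

    ``beta`` holds the intercept followed by one slope per entry of
    ``covariates``; ``theta`` is the NB2 dispersion (> 0, larger = closer to
    Poisson); ``pi`` the zero-inflation probability.  ``mean``/``sd`` are the
    training-sample standardization applied to every later prediction, so
    contigs unseen during fitting are normalized on the same scale.
    """

    mode: str  # "full" | "lc"
    covariates: tuple[str, ...]
    beta: np.ndarray
    theta: float
    pi: float
    mean: np.ndarray
    sd: np.ndarray
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0 <= self.pi < 1:
            raise ValueError("pi must be in [0, 1)")
        if (self.sd <= 0).any():
            raise ValueError("covariate sd must be > 0")

    def expected_counts(self, u: np.ndarray) -> np.ndarray:
        """mu for raw (unstandardized) covariate rows ``u``."""
        z = (np.asarray(u, dtype=float) - self.mean) / self.sd
        return np.exp(self.beta[0] + z @ self.beta[1:])

    # ------------------------------------------------------------------- io
    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "covariates": list(self.covariates),
            "beta": self.beta.tolist(),
            "theta": self.theta,
            "pi": self.pi,
            "standardization": {"mean": self.mean.tolist(), "sd": self.sd.tolist()},
            "fit_info": self.fit_info,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mode=d["mode"],
            covariates=tuple(d["covariates"]),
            beta=np.array(d["beta"]),
            theta=d["theta"],
            pi=d["pi"],
            mean=np.array(d["standardization"]["mean"]),
            sd=np.array(d["standardization"]["sd"]),
            fit_info=d.get("fit_info", {}),
        )


# ----------------------------------------------------------------- samples

def raw_covariates(
    catalog: ContigCatalog,
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    mode: str = "full",
) -> np.ndarray:
    """Unstandardized covariate rows for contig index pairs.

    Columns are ln(s_i s_j) (full mode only), ln(l_i l_j), ln(cov_i cov_j).
    """
    df = catalog.df
    length = df["length"].to_numpy(dtype=float)
    coverage = df["coverage"].to_numpy(dtype=float)
    cols = []
    if mode == "full":
        sites = df["sites"].to_numpy(dtype=float)
        if np.isnan(sites).any():
            bad = df.index[np.isnan(sites)][0]
            raise ValueError(f"contig {bad!r} has no restriction-site count")
        s = effective_sites(sites)
        cols.append(np.log(s[pairs_a] * s[pairs_b]))
    if np.isnan(length).any():
        bad = df.index[np.isnan(length)][0]
        raise ValueError(f"contig {bad!r} has no length")
    if np.isnan(coverage).any() or (coverage <= 0).any():
        bad = df.index[np.isnan(coverage) | (coverage <= 0)][0]
        raise ValueError(f"contig {bad!r} has no positive coverage")
    cols.append(np.log(length[pairs_a] * length[pairs_b]))
    cols.append(np.log(coverage[pairs_a] * coverage[pairs_b]))
    return np.column_stack(cols)


def build_intra_samples(
    cmap: ContactMap,
    catalog: ContigCatalog,
    labels: Mapping[str, str] | pd.Series,
    mode: str = "full",
) -> pd.DataFrame:
    """Enumerate intra-species contact samples for model fitting.

    One row per unordered pair of same-species labeled contigs present in the
    map index; the contact count is read from the map and is 0 for
    unobserved pairs — zero-count pairs are what identify the zero-inflation
    mass.  Covariates are returned raw (columns ``ln_sites``/``ln_length``/
    ``ln_coverage``); :func:`fit_hiczin` standardizes them and records the
    standardization in the model.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    catalog.require(labels.index)
    catalog.require(cmap.contig_ids)
    labeled = [c for c in labels.index if c in cmap.index]
    by_species: dict[str, list[str]] = {}
    for c in labeled:
        by_species.setdefault(labels[c], []).append(c)
    rows_a: list[int] = []
    rows_b: list[int] = []
    species_col: list[str] = []
    for species, contigs in by_species.items():
        if len(contigs) < 2:
            continue
        for a, b in itertools.combinations(contigs, 2):
            rows_a.append(cmap.index[a])
            rows_b.append(cmap.index[b])
            species_col.append(species)
    if not rows_a:
        raise ValueError("insufficient labels: no species with >= 2 labeled contigs")
    ia = np.array(rows_a)
    ib = np.array(rows_b)
    # map catalog order onto map order for covariate lookup
    cat = catalog.subset(cmap.contig_ids)
    u = raw_covariates(cat, ia, ib, mode=mode)
    counts = np.asarray(cmap.matrix[ia, ib]).ravel()
    covnames = FULL_COVARIATES if mode == "full" else LC_COVARIATES
    df = pd.DataFrame(u, columns=list(covnames))
    df.insert(0, "contig_a", [cmap.contig_ids[i] for i in ia])
    df.insert(1, "contig_b", [cmap.contig_ids[i] for i in ib])
    df.insert(2, "species", species_col)
    df.insert(3, "count", counts.astype(np.int64))
    return df


# --------------------------------------------------------------------- fit

def _zinb_nll(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    p = X.shape[1]
    beta = params[:p]
    log_theta = np.clip(params[p], -10.0, 12.0)
    theta = np.exp(log_theta)
    pi_logit = np.clip(params[p + 1], -30.0, 8.0)
    pi = expit(pi_logit)
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    log_ratio = log_theta - np.logaddexp(log_theta, eta)  # ln(theta/(theta+mu))
    lognb = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * log_ratio
        + y * (eta - np.logaddexp(log_theta, eta))
    )
    zero = y == 0
    ll = np.empty_like(mu)
    # P(0) = pi + (1-pi) NB(0)
    ll[zero] = np.logaddexp(
        np.log(pi) if pi > 0 else -np.inf,
        np.log1p(-pi) + theta * log_ratio[zero],
    )
    ll[~zero] = np.log1p(-pi) + lognb[~zero]
    return -float(ll.sum())


def _poisson_init(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Poisson log-linear fit used to seed the ZINB betas."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
    return np.asarray(res.params, dtype=float)


def fit_hiczin(
    samples: pd.DataFrame,
    mode: str = "full",
    min_samples: int = 50,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> NormModel:
    """Fit the ZINB bias model by direct likelihood maximization.

    Initialization: betas from a Poisson log-linear fit, theta by method of
    moments on the sample counts, pi from the observed zero fraction.  On
    optimizer failure the model falls back to a plain negative binomial
    (pi = 0) and, failing that too, to the Poisson fit — both with a warning.

    Parameters
    ----------
    samples
        Output of :func:`build_intra_samples` (or any frame with a ``count``
        column and raw covariate columns).
    mode
        ``"full"`` uses sites+length+coverage; ``"lc"`` length+coverage only.
    min_samples
        Minimum number of intra-species samples required to attempt a fit.
    """
    covnames = FULL_COVARIATES if mode == "full" else LC_COVARIATES
    missing = [c for c in covnames if c not in samples.columns]
    if missing:
        raise ValueError(f"samples lack covariate column(s) {missing}")
    if len(samples) < min_samples:
        raise ValueError(
            f"need >= {min_samples} intra-species samples, got {len(samples)}"
        )
    u = samples[list(covnames)].to_numpy(dtype=float)
    y = samples["count"].to_numpy(dtype=float)
    mean = u.mean(axis=0)
    sd = u.std(axis=0, ddof=0)
    if (sd <= 0).any():
        const = covnames[int(np.flatnonzero(sd <= 0)[0])]
        raise ValueError(f"covariate {const!r} is constant across samples")
    z = (u - mean) / sd
    X = np.column_stack([np.ones(len(z)), z])
    p = X.shape[1]

    beta0 = _poisson_init(X, y)
    mu0 = np.exp(np.clip(X @ beta0, -30, 30))
    resid_var = np.mean((y - mu0) ** 2)
    mu2 = np.mean(mu0**2)
    theta0 = mu2 / max(resid_var - mu0.mean(), mu2 / 100.0)
    theta0 = float(np.clip(theta0, 0.05, 50.0))
    zero_frac = float(np.mean(y == 0))
    pi0 = float(np.clip(zero_frac * 0.5, 0.02, 0.9))

    x0 = np.concatenate([beta0, [np.log(theta0), logit(pi0)]])
    res = scipy.optimize.minimize(
        _zinb_nll,
        x0,
        args=(X, y),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol},
    )
    fit_info = {"family": "zinb", "converged": bool(res.success), "loglik": -float(res.fun)}
    if res.success and np.isfinite(res.fun):
        params = res.x
        beta = params[:p]
        theta = float(np.exp(np.clip(params[p], -10, 12)))
        pi = float(expit(np.clip(params[p + 1], -30, 8)))
    else:
        warnings.warn("ZINB fit did not converge; falling back to negative binomial")
        nb_nll = lambda q: _zinb_nll(np.concatenate([q, [-30.0]]), X, y)  # noqa: E731
        res_nb = scipy.optimize.minimize(
            nb_nll,
            np.concatenate([beta0, [np.log(theta0)]]),
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol},
        )
        if res_nb.success and np.isfinite(res_nb.fun):
            beta = res_nb.x[:p]
            theta = float(np.exp(np.clip(res_nb.x[p], -10, 12)))
            pi = 0.0
            fit_info = {
                "family": "nb",
                "converged": True,
                "loglik": -float(res_nb.fun),
            }
        else:
            warnings.warn("NB fallback failed; using Poisson coefficients")
            beta = beta0
            theta = 1e6  # effectively Poisson
            pi = 0.0
            fit_info = {"family": "poisson", "converged": False, "loglik": None}
    return NormModel(
        mode=mode,
        covariates=tuple(covnames),
        beta=beta,
        theta=theta,
        pi=pi,
        mean=mean,
        sd=sd,
        fit_info=fit_info,
    )


# --------------------------------------------------------------- normalize

def normalize(cmap: ContactMap, catalog: ContigCatalog, model: NormModel) -> ContactMap:
    """Normalize a raw contact map to ratio residuals ``n_ij = c_ij / mu_ij``.

    Every contig in the map — labeled during fitting or not — is normalized
    with the fitted model, standardizing its covariates with the stored
    training means/sds.  Absent (zero) entries stay absent and symmetry is
    preserved.
    """
    catalog.require(cmap.contig_ids)
    cat = catalog.subset(cmap.contig_ids)
    coo = sp.triu(cmap.matrix, k=1).tocoo()
    u = raw_covariates(cat, coo.row, coo.col, mode=model.mode)
    mu = model.expected_counts(u)
    vals = coo.data / mu
    rows = np.concatenate([coo.row, coo.col])
    cols = np.concatenate([coo.col, coo.row])
    data = np.concatenate([vals, vals])
    m = sp.csr_matrix((data, (rows, cols)), shape=cmap.matrix.shape)
    return ContactMap(cmap.contig_ids, m)
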