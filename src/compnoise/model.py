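"""Hierarchical Bayesian count model for expression mean and noise.

The model separates three sources of cell-to-cell variability in UMI counts
from a single strain with multiple biological replicates:

* Poisson sampling noise of the sequencer,
* technical variability specific to a replicate batch, and
* biological expression noise shared across replicates.

For gene ``i`` in cell ``j`` of replicate batch ``b(j)``::

    x_ij | nu_j, rho_ij ~ Poisson(nu_j * mu_i * rho_ij)
    rho_ij ~ Gamma(1/delta_i, rate=1/delta_i)        # mean 1, variance delta_i
    nu_j   ~ Gamma(1/theta_b, rate=1/(s_j theta_b))  # mean s_j, variance s_j^2 theta_b

so that marginally ``Var(x_ij) = m + delta_i m^2`` with ``m = nu_j mu_i``:
the Poisson term is subtracted and ``delta_i`` is the biological
over-dispersion, while variance that differs between replicate batches is
absorbed by the batch-specific ``theta_b``.  ``rho`` is integrated out
analytically, giving a negative-binomial likelihood.

Because over-dispersion trends with expression level, the model regresses
``log delta`` on ``log mu`` with an intercept, a linear term and Gaussian
radial basis functions::

    log delta_i = f(log mu_i) + eps_i,   eps_i ~ Normal(0, sigma^2)

``eps_i`` is the *residual over-dispersion*: a noise measure uncorrelated
with the mean, and the quantity compared between strains downstream.

Inference is Metropolis-within-Gibbs: vectorized per-gene random-walk
updates for ``log mu`` and ``log delta``, per-cell updates for ``log nu``,
per-batch updates for ``log theta``, and conjugate draws for the trend
coefficients and residual variance.  Proposal scales adapt during burn-in
toward a 0.44 acceptance rate.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg
from scipy.special import gammaln

from .io import CountMatrix, validate_cell_meta

__all__ = [
    "ModelSpec",
    "SizeFactors",
    "PosteriorSummary",
    "estimate_size_factors",
    "fit_noise_model",
    "residual_overdispersion",
    "rbf_basis",
    "fit_trend_map",
]

_STORE_VERSION = 1


@dataclass
class ModelSpec:
    """MCMC and prior settings for :func:`fit_noise_model`.

    Defaults target a desk-scale run with vague priors; shorter chains are
    appropriate for small simulated datasets.
    """

    n_iter: int = 20000
    burn_in: int = 10000
    thin: int = 10
    seed: int = 0
    n_basis: int = 10               # Gaussian RBFs (an intercept and linear term are always added)
    mu_prior_sd: float = 5.0        # sd of Normal prior on log mu, centred on the data
    coef_prior_var: float = 25.0    # prior variance of trend coefficients
    sigma2_prior_shape: float = 2.0
    sigma2_prior_rate: float = 0.5
    theta_prior_logmean: float = np.log(0.05)
    theta_prior_logsd: float = 2.0

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_basis < 2:
            raise ValueError("n_basis must be >= 2")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class SizeFactors:
    """Positive per-cell scaling factors, normalized to mean 1."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("size factors must be positive")
        if len(self.values) != len(self.cell_ids):
            raise ValueError("one size factor per cell required")

    def subset(self, cells) -> "SizeFactors":
        lookup = {c: j for j, c in enumerate(self.cell_ids)}
        idx = [lookup[c] for c in cells]
        vals = self.values[idx]
        return SizeFactors(vals / vals.mean(), [self.cell_ids[j] for j in idx])


def estimate_size_factors(cm: CountMatrix, pool_sizes=None) -> SizeFactors:
    """Pooling-and-deconvolution size factors (scran-style).

    Cells are ordered on a ring by library size.  For every pool size ``p``
    and every starting position, the counts of the ``p`` cells in the window
    are summed and compared with the average pseudo-cell (per-gene mean over
    all cells); the median ratio over genes expressed in the pseudo-cell
    estimates the *sum* of the pool members' size factors.  Low-weight
    anchor equations tie each cell to its relative library size so the
    linear system has full rank; it is solved by least squares and the
    solution rescaled to mean 1.

    With ``pool_sizes=None`` pooling is disabled and the factors degrade to
    plain library-size factors.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = [cm.cell_ids[j] for j in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(
            f"cells with zero total count (e.g. {bad}); filter these cells before "
            "size-factor estimation"
        )
    n = cm.n_cells
    lib = totals / totals.mean()
    if pool_sizes is None:
        return SizeFactors(lib, list(cm.cell_ids))

    pool_sizes = [int(p) for p in pool_sizes]
    if any(p < 1 or p > n for p in pool_sizes):
        raise ValueError(f"pool sizes must lie in [1, {n}]")
    order = np.argsort(totals, kind="stable")
    ref = cm.counts.mean(axis=1)
    expressed = ref > 0

    rows, cols, data, rhs = [], [], [], []
    eq = 0
    for p in pool_sizes:
        for start in range(n):
            members = order[(start + np.arange(p)) % n]
            pooled = cm.counts[:, members].sum(axis=1)
            ratio = np.median(pooled[expressed] / ref[expressed])
            rows.extend([eq] * p)
            cols.extend(members.tolist())
            data.extend([1.0] * p)
            rhs.append(ratio)
            eq += 1
    # low-weight anchors: s_j ~ library-size factor
    w = 0.1
    for j in range(n):
        rows.append(eq)
        cols.append(j)
        data.append(w)
        rhs.append(w * lib[j])
        eq += 1
    A = scipy.sparse.csr_matrix((data, (rows, cols)), shape=(eq, n))
    sol = scipy.sparse.linalg.lsqr(A, np.asarray(rhs), atol=1e-12, btol=1e-12)[0]
    sol = np.clip(sol, 1e-8, None)
    return SizeFactors(sol / sol.mean(), list(cm.cell_ids))


# ---------------------------------------------------------------------------
# trend basis
# ---------------------------------------------------------------------------

def rbf_basis(logmu: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    """Design matrix ``[1, logmu, RBF_1..RBF_K]`` evaluated at ``logmu``."""
    logmu = np.asarray(logmu, dtype=float)
    B = np.empty((logmu.size, centers.size + 2))
    B[:, 0] = 1.0
    B[:, 1] = logmu
    B[:, 2:] = np.exp(-((logmu[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))
    return B


def _basis_grid(logmu_init: np.ndarray, n_basis: int) -> tuple[np.ndarray, float]:
    lo, hi = float(np.min(logmu_init)), float(np.max(logmu_init))
    if hi - lo < 1e-6:
        hi = lo + 1e-6
    centers = np.linspace(lo, hi, n_basis)
    width = 1.2 * (centers[1] - centers[0])
    return centers, width


def fit_trend_map(
    logmu: np.ndarray,
    logdelta: np.ndarray,
    centers: np.ndarray,
    width: float,
    sigma2: float,
    coef_prior_var: float,
) -> np.ndarray:
    """Posterior-mean (ridge) trend coefficients at fixed ``sigma2``.

    Solves the penalized normal equations
    ``(B'B/sigma2 + I/coef_prior_var) beta = B'y/sigma2``.
    """
    B = rbf_basis(logmu, centers, width)
    K = B.shape[1]
    A = B.T @ B / sigma2 + np.eye(K) / coef_prior_var
    return np.linalg.solve(A, B.T @ np.asarray(logdelta) / sigma2)


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Stored MCMC draws for one strain fit."""

    gene_ids: list[str]
    cell_ids: list[str]
    batches: list[str]
    mu: np.ndarray        # (draws, genes), expression mean on the normalized scale
    delta: np.ndarray     # (draws, genes), biological over-dispersion
    eps: np.ndarray       # (draws, genes), residual over-dispersion
    nu: np.ndarray        # (draws, cells), cell-specific scalings
    theta: np.ndarray     # (draws, batches), technical variability per replicate batch
    beta: np.ndarray      # (draws, n_basis + 2), trend coefficients
    sigma2: np.ndarray    # (draws,), trend residual variance
    log_post: np.ndarray  # (draws,), joint log posterior (up to a constant)
    trend_centers: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trend_width: float = 1.0
    spec: ModelSpec | None = None

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def median_mu(self) -> pd.Series:
        return pd.Series(np.median(self.mu, axis=0), index=self.gene_ids, name="mu")

    def median_delta(self) -> pd.Series:
        return pd.Series(np.median(self.delta, axis=0), index=self.gene_ids, name="delta")

    def median_eps(self) -> pd.Series:
        return pd.Series(np.median(self.eps, axis=0), index=self.gene_ids, name="eps")

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mu": self.median_mu(),
                "delta": self.median_delta(),
                "eps": self.median_eps(),
            }
        ).rename_axis("gene")

    # -- serialization: TSV medians + versioned npz draw store ------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.summary_table().to_csv(path / "gene_medians.tsv", sep="\t")
        np.savez_compressed(
            path / "draws.npz",
            mu=self.mu, delta=self.delta, eps=self.eps, nu=self.nu,
            theta=self.theta, beta=self.beta, sigma2=self.sigma2,
            log_post=self.log_post, trend_centers=self.trend_centers,
        )
        manifest = {
            "version": _STORE_VERSION,
            "gene_ids": self.gene_ids,
            "cell_ids": self.cell_ids,
            "batches": self.batches,
            "trend_width": self.trend_width,
            "spec": asdict(self.spec) if self.spec else None,
        }
        (path / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def from_dir(cls, path) -> "PosteriorSummary":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest["version"] != _STORE_VERSION:
            raise ValueError(f"unsupported draw-store version {manifest['version']}")
        z = np.load(path / "draws.npz")
        spec = ModelSpec(**manifest["spec"]) if manifest["spec"] else None
        return cls(
            gene_ids=manifest["gene_ids"], cell_ids=manifest["cell_ids"],
            batches=manifest["batches"], mu=z["mu"], delta=z["delta"],
            eps=z["eps"], nu=z["nu"], theta=z["theta"], beta=z["beta"],
            sigma2=z["sigma2"], log_post=z["log_post"],
            trend_centers=z["trend_centers"], trend_width=manifest["trend_width"],
            spec=spec,
        )


def residual_overdispersion(ps: PosteriorSummary) -> pd.DataFrame:
    """Per-gene residual over-dispersion summaries.

    Returns median and central 90% interval of the ``eps`` draws per gene.
    """
    lo, med, hi = np.percentile(ps.eps, [5, 50, 95], axis=0)
    return pd.DataFrame(
        {"eps_median": med, "eps_lo90": lo, "eps_hi90": hi}, index=ps.gene_ids
    ).rename_axis("gene")


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

class _UniqueCounts:
    """Per-gene unique count values, for cheap ``sum_j gammaln(x_ij + r_i)``.

    UMI counts repeat heavily within a gene, so gammaln is evaluated once
    per distinct value and weighted by its multiplicity.
    """

    def __init__(self, x: np.ndarray):
        vals, gidx, wts = [], [], []
        for i in range(x.shape[0]):
            u, c = np.unique(x[i], return_counts=True)
            vals.append(u)
            wts.append(c)
            gidx.append(np.full(u.size, i))
        self.vals = np.concatenate(vals).astype(float)
        self.wts = np.concatenate(wts).astype(float)
        self.gidx = np.concatenate(gidx)
        self.n_genes = x.shape[0]

    def gl(self, r: np.ndarray) -> np.ndarray:
        """``GL_i = sum_j gammaln(x_ij + r_i)`` for all genes at once."""
        terms = gammaln(self.vals + r[self.gidx]) * self.wts
        return np.bincount(self.gidx, weights=terms, minlength=self.n_genes)


def _adapt(step: np.ndarray, acc: np.ndarray, tries: int, target: float = 0.44) -> None:
    rate = acc / max(tries, 1)
    step *= np.exp(np.clip(rate - target, -0.5, 0.5))
    np.clip(step, 1e-3, 5.0, out=step)


def fit_noise_model(
    cm: CountMatrix,
    meta: pd.DataFrame,
    s: SizeFactors,
    spec: ModelSpec,
) -> PosteriorSummary:
    """Fit the hierarchical noise model to the cells of a single strain.

    ``cm`` must contain cells of one strain only, covering at least two
    replicate batches (otherwise technical noise is not identifiable), with
    genes pre-filtered for expression.  ``s`` supplies per-cell size
    factors.  Returns stored posterior draws after burn-in and thinning;
    identical inputs and seed give identical draws.
    """
    validate_cell_meta(meta, cm)
    if cm.n_genes == 0 or cm.n_cells == 0:
        raise ValueError("empty count matrix")
    strain_of = dict(zip(meta["cell_id"], meta["strain"]))
    strains = {strain_of[c] for c in cm.cell_ids}
    if len(strains) != 1:
        raise ValueError(f"fit one strain at a time; got {sorted(strains)}")
    rep_of = dict(zip(meta["cell_id"], meta["replicate"]))
    batch_labels = [rep_of[c] for c in cm.cell_ids]
    batches = sorted(set(batch_labels))
    if len(batches) < 2:
        raise ValueError(
            "at least 2 replicate batches are required to identify technical noise"
        )
    batch_idx = np.array([batches.index(b) for b in batch_labels])
    n_batches = len(batches)

    sf = s.subset(cm.cell_ids)
    svals = sf.values
    x = cm.counts.astype(float)
    G, N = x.shape
    rng = np.random.default_rng(spec.seed)

    # sufficient statistics
    T = x.sum(axis=1)                  # per-gene totals
    Ccol = x.sum(axis=0)               # per-cell totals
    uniq = _UniqueCounts(cm.counts)

    # initial state
    mu = np.clip(T / svals.sum(), 1e-8, None)
    logmu = np.log(mu)
    y = x / svals[None, :]
    m_hat = y.mean(axis=1)
    v_hat = y.var(axis=1)
    delta = np.clip((v_hat - m_hat) / np.maximum(m_hat, 1e-12) ** 2, 1e-3, 50.0)
    logdelta = np.log(delta)
    nu = svals.copy()
    lognu = np.log(nu)
    theta = np.full(n_batches, 0.05)
    logtheta = np.log(theta)

    centers, width = _basis_grid(logmu, spec.n_basis)
    K = centers.size + 2
    sigma2 = 0.25
    B = rbf_basis(logmu, centers, width)
    beta = fit_trend_map(logmu, logdelta, centers, width, sigma2, spec.coef_prior_var)

    mu0 = float(np.mean(logmu))
    v0 = spec.mu_prior_sd**2

    # cached likelihood pieces
    r = 1.0 / delta
    def _pair_sums(logmu_, r_, lognu_):
        """S1_i = sum_j log(r_i + mu_i nu_j); S2_i = sum_j x_ij log(r_i + mu_i nu_j)."""
        L = np.log(r_[:, None] + np.exp(logmu_[:, None] + lognu_[None, :]))
        return L.sum(axis=1), (x * L).sum(axis=1)

    S1, S2 = _pair_sums(logmu, r, lognu)
    GL = uniq.gl(r)
    xdot_lognu = x @ lognu               # per-gene sum_j x_ij log nu_j
    gammaln_xp1 = float(gammaln(cm.counts + 1).sum())

    def _gene_ll(logmu_, r_, S1_, S2_, GL_):
        return (
            GL_
            - N * gammaln(r_)
            + r_ * (N * np.log(r_) - S1_)
            + T * logmu_
            + xdot_lognu
            - S2_
        )

    def _nu_prior_logpdf(lognu_, logtheta_):
        a = np.exp(-logtheta_)[batch_idx]
        scale = svals * np.exp(logtheta_)[batch_idx]
        nu_ = np.exp(lognu_)
        return (a - 1.0) * lognu_ - nu_ / scale - gammaln(a) - a * np.log(scale)

    # adaptive step sizes
    step_mu = np.full(G, 0.1)
    step_delta = np.full(G, 0.3)
    step_nu = np.full(N, 0.1)
    step_theta = np.full(n_batches, 0.3)
    acc_mu = np.zeros(G); acc_delta = np.zeros(G)
    acc_nu = np.zeros(N); acc_theta = np.zeros(n_batches)
    adapt_every = 50

    n_stored = spec.n_stored
    st_mu = np.empty((n_stored, G)); st_delta = np.empty((n_stored, G))
    st_eps = np.empty((n_stored, G)); st_nu = np.empty((n_stored, N))
    st_theta = np.empty((n_stored, n_batches)); st_beta = np.empty((n_stored, K))
    st_sigma2 = np.empty(n_stored); st_lp = np.empty(n_stored)
    stored = 0

    trend_mean = B @ beta

    for it in range(spec.n_iter):
        # --- trend coefficients and residual variance (conjugate) --------
        resid = logdelta - trend_mean
        shape = spec.sigma2_prior_shape + 0.5 * G
        rate = spec.sigma2_prior_rate + 0.5 * float(resid @ resid)
        sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)
        prec = B.T @ B / sigma2 + np.eye(K) / spec.coef_prior_var
        chol = np.linalg.cholesky(prec)
        mean_rhs = B.T @ logdelta / sigma2
        tmp = np.linalg.solve(chol, mean_rhs)
        beta_mean_w = np.linalg.solve(chol.T, tmp)
        z = rng.standard_normal(K)
        beta = beta_mean_w + np.linalg.solve(chol.T, z)
        trend_mean = B @ beta

        # --- log mu (vectorized per-gene Metropolis) ---------------------
        prop = logmu + step_mu * rng.standard_normal(G)
        S1p, S2p = _pair_sums(prop, r, lognu)
        Bp = rbf_basis(prop, centers, width)
        trend_p = Bp @ beta
        dll = (
            r * (S1 - S1p) + T * (prop - logmu) + (S2 - S2p)
            + ((logmu - mu0) ** 2 - (prop - mu0) ** 2) / (2 * v0)
            + ((logdelta - trend_mean) ** 2 - (logdelta - trend_p) ** 2) / (2 * sigma2)
        )
        accept = np.log(rng.random(G)) < dll
        logmu[accept] = prop[accept]
        S1[accept] = S1p[accept]; S2[accept] = S2p[accept]
        B[accept] = Bp[accept]; trend_mean[accept] = trend_p[accept]
        acc_mu += accept

        # --- log delta (vectorized per-gene Metropolis) -------------------
        propd = logdelta + step_delta * rng.standard_normal(G)
        rp = np.exp(-propd)
        S1p, S2p = _pair_sums(logmu, rp, lognu)
        GLp = uniq.gl(rp)
        ll_old = _gene_ll(logmu, r, S1, S2, GL)
        ll_new = _gene_ll(logmu, rp, S1p, S2p, GLp)
        dll = (
            ll_new - ll_old
            + ((logdelta - trend_mean) ** 2 - (propd - trend_mean) ** 2) / (2 * sigma2)
        )
        accept = np.log(rng.random(G)) < dll
        logdelta[accept] = propd[accept]
        r = np.exp(-logdelta)
        S1[accept] = S1p[accept]; S2[accept] = S2p[accept]; GL[accept] = GLp[accept]
        acc_delta += accept

        # --- log nu (vectorized per-cell Metropolis) ----------------------
        propn = lognu + step_nu * rng.standard_normal(N)
        Lold = np.log(r[:, None] + np.exp(logmu[:, None] + lognu[None, :]))
        Lnew = np.log(r[:, None] + np.exp(logmu[:, None] + propn[None, :]))
        w = r[:, None] + x
        dll_cell = (
            (w * (Lold - Lnew)).sum(axis=0)
            + Ccol * (propn - lognu)
            + _nu_prior_logpdf(propn, logtheta) + propn
            - _nu_prior_logpdf(lognu, logtheta) - lognu
        )
        accept_n = np.log(rng.random(N)) < dll_cell
        lognu[accept_n] = propn[accept_n]
        acc_nu += accept_n
        if accept_n.any():
            L = np.where(accept_n[None, :], Lnew, Lold)
            S1 = L.sum(axis=1)
            S2 = (x * L).sum(axis=1)
            xdot_lognu = x @ lognu

        # --- log theta per batch (Metropolis) -----------------------------
        propt = logtheta + step_theta * rng.standard_normal(n_batches)
        lp_old_cells = _nu_prior_logpdf(lognu, logtheta)
        lp_new_cells = _nu_prior_logpdf(lognu, propt)
        for b in range(n_batches):
            mask = batch_idx == b
            dlt = (
                lp_new_cells[mask].sum() - lp_old_cells[mask].sum()
                + ((logtheta[b] - spec.theta_prior_logmean) ** 2
                   - (propt[b] - spec.theta_prior_logmean) ** 2)
                / (2 * spec.theta_prior_logsd**2)
            )
            if np.log(rng.random()) < dlt:
                logtheta[b] = propt[b]
                acc_theta[b] += 1
        theta = np.exp(logtheta)

        # --- adaptation during burn-in ------------------------------------
        if it < spec.burn_in and (it + 1) % adapt_every == 0:
            _adapt(step_mu, acc_mu, adapt_every)
            _adapt(step_delta, acc_delta, adapt_every)
            _adapt(step_nu, acc_nu, adapt_every)
            _adapt(step_theta, acc_theta, adapt_every)
            acc_mu[:] = 0; acc_delta[:] = 0; acc_nu[:] = 0; acc_theta[:] = 0

        # --- storage -------------------------------------------------------
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and stored < n_stored:
            eps = logdelta - trend_mean
            ll = _gene_ll(logmu, r, S1, S2, GL).sum() - gammaln_xp1
            lp = (
                ll
                + _nu_prior_logpdf(lognu, logtheta).sum()
                - ((logmu - mu0) ** 2).sum() / (2 * v0)
                - ((logdelta - trend_mean) ** 2).sum() / (2 * sigma2)
                - 0.5 * G * np.log(2 * np.pi * sigma2)
                - (beta @ beta) / (2 * spec.coef_prior_var)
                - ((logtheta - spec.theta_prior_logmean) ** 2).sum()
                / (2 * spec.theta_prior_logsd**2)
                - (spec.sigma2_prior_shape + 1) * np.log(sigma2)
                - spec.sigma2_prior_rate / sigma2
            )
            st_mu[stored] = np.exp(logmu)
            st_delta[stored] = np.exp(logdelta)
            st_eps[stored] = eps
            st_nu[stored] = np.exp(lognu)
            st_theta[stored] = theta
            st_beta[stored] = beta
            st_sigma2[stored] = sigma2
            st_lp[stored] = lp
            stored += 1

    return PosteriorSummary(
        gene_ids=list(cm.gene_ids), cell_ids=list(cm.cell_ids), batches=batches,
        mu=st_mu, delta=st_delta, eps=st_eps, nu=st_nu, theta=st_theta,
        beta=st_beta, sigma2=st_sigma2, log_post=st_lp,
        trend_centers=centers, trend_width=width, spec=spec,
    )
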