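"""Gibbs sampler with closed-form full conditionals.

The model is a two-layer Bayesian supervised factor analysis:

    I = I0 + T W + A D' + E_I,      E_I ~ N(0, 1) elementwise,
    P = I Z + E_P,                  E_P,ik ~ N(0, sigma2_k),

with conjugate priors W_jj ~ N(1, tau_w), D_j ~ N(0, tau_d) (optionally a
spike-and-slab mixture), I0_j ~ N(m0, tau_i0), truncated-normal priors on the
on-support entries of Z, and Inverse-Gamma priors on the peptide noise
variances. Every full conditional is Gaussian, truncated Gaussian, or
Inverse-Gamma, so the sampler is a systematic-scan Gibbs sweep in the fixed
order I0 -> W -> D -> Z -> sigma2 -> I.

Because Z is block diagonal over connected components of the isoform-peptide
graph, the posterior factorizes over blocks: each block runs its complete
chain on its own random stream keyed by (seed, block index), which makes
block-parallel execution draw-for-draw identical to whole-matrix execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm as _truncnorm

from .data import ObservedDataset, PriorConfig
from .preprocess import decompose_blocks

__all__ = [
    "ChainConfig",
    "ModelState",
    "PosteriorDraws",
    "SamplingError",
    "BlockGibbsSampler",
    "Gaussian",
    "TruncatedGaussian",
    "InverseGamma",
    "SpikeSlab",
    "full_conditional_W",
    "full_conditional_D",
    "full_conditional_I0",
    "full_conditional_I_row",
    "full_conditional_Z",
    "full_conditional_noise",
    "sample_truncated_normal",
    "log_prior_density",
    "run_chain",
    "run_chains",
]


class SamplingError(RuntimeError):
    """Raised when a draw becomes non-finite; names the parameter and iteration."""


@dataclass
class ChainConfig:
    """MCMC run lengths. Defaults: 3000 iterations, 2000 burn-in, 10 chains."""

    n_iter: int = 3000
    burn_in: int = 2000
    n_chains: int = 10
    base_seed: int = 0
    thinning: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class ModelState:
    """One Gibbs configuration of all unknowns."""

    I0: np.ndarray  # (q,)
    W: np.ndarray  # (q,) diagonal of the conversion-weight matrix
    D: np.ndarray  # (q,)
    Z: np.ndarray  # (q, r), exactly zero off the mask support
    I: np.ndarray  # (n, q) latent isoform abundances
    sigma2: np.ndarray  # (r,) peptide noise variances
    gamma: np.ndarray | None = None  # (q,) spike indicators (spike_slab only)


class Gaussian(NamedTuple):
    mean: float
    variance: float


class TruncatedGaussian(NamedTuple):
    mean: float
    variance: float
    lower: float
    upper: float

    def moments(self) -> tuple[float, float]:
        """Mean and variance after truncation."""
        sd = np.sqrt(self.variance)
        a = (self.lower - self.mean) / sd
        b = (self.upper - self.mean) / sd
        m, v = _truncnorm.stats(a, b, loc=self.mean, scale=sd, moments="mv")
        return float(m), float(v)


class InverseGamma(NamedTuple):
    shape: float
    rate: float


class SpikeSlab(NamedTuple):
    """Spike-and-slab conditional: slab Gaussian plus inclusion probability."""

    slab: Gaussian
    p_include: float


# ---------------------------------------------------------------------------
# truncated-normal sampling (inverse CDF with tail-safe rejection fallback)
# ---------------------------------------------------------------------------


def _rejection_tail(a: float, b: float, rng: np.random.Generator) -> float:
    """Sample standard normal truncated to [a, b] when ndtr underflows.

    After the mirror flip applied by the caller, [a, b] lies in the lower
    tail, so mirror once more and sample x >= -b with Robert's exponential
    proposal, rejecting draws above -a.
    """
    lo, hi = -b, -a  # 0 <= lo <= hi
    alpha = 0.5 * (lo + np.sqrt(lo * lo + 4.0))
    for _ in range(10_000):
        x = lo + rng.exponential(1.0 / alpha)
        if x > hi:
            continue
        if rng.uniform() <= np.exp(-0.5 * (x - alpha) ** 2):
            return -x
    # interval so extreme that acceptance fails numerically
    return -lo


def sample_truncated_normal(mean, sd, lower, upper, rng: np.random.Generator):
    """Vectorized draws from N(mean, sd^2) truncated to [lower, upper].

    Uses the inverse-CDF transform; intervals whose normal mass underflows
    fall back to a rejection sampler. Degenerate intervals (lower == upper)
    return the bound exactly.
    """
    mean = np.asarray(mean, float)
    sd, lower, upper = (np.broadcast_to(np.asarray(x, float), mean.shape) for x in (sd, lower, upper))
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    flip = (a + b) > 0  # mirror so the interval is never deep in the upper tail
    a2 = np.where(flip, -b, a)
    b2 = np.where(flip, -a, b)
    pa, pb = ndtr(a2), ndtr(b2)
    u = rng.uniform(size=mean.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = ndtri(pa + u * (pb - pa))
    degenerate = (upper - lower) <= 0
    bad = (~np.isfinite(x) | (pb - pa < 1e-14)) & ~degenerate
    if np.any(bad):
        flat = x.reshape(-1)
        for idx in np.flatnonzero(bad.reshape(-1)):
            flat[idx] = _rejection_tail(a2.reshape(-1)[idx], b2.reshape(-1)[idx], rng)
    x = np.where(flip, -x, x)
    out = mean + sd * x
    out = np.clip(out, lower, upper)
    return np.where(degenerate, lower, out)


# ---------------------------------------------------------------------------
# full conditionals (scalar interfaces; the block sampler vectorizes the same
# algebra)
# ---------------------------------------------------------------------------


def _tau(value, j: int) -> float:
    return float(np.broadcast_to(np.asarray(value, float), (j + 1,))[j]) if np.ndim(value) else float(value)


def full_conditional_W(j: int, state: ModelState, data: ObservedDataset, config: PriorConfig) -> Gaussian:
    """Conditional of the conversion weight W_jj given everything else.

    With residual R_ij = I_ij - I0_j - A_i D_j and unit likelihood variance:
    precision = 1/tau_w + sum_i T_ij^2, mean = (1/tau_w + sum_i T_ij R_ij)/precision.
    """
    tau = _tau(config.tau_w, j)
    if tau <= 0:
        raise ValueError("tau_w must be positive")
    t = data.T[:, j] if data.T is not None else np.zeros(data.n)
    a_term = data.A * state.D[j] if data.A is not None else 0.0
    resid = state.I[:, j] - state.I0[j] - a_term
    prec = 1.0 / tau + float(t @ t)
    mean = (1.0 / tau + float(t @ resid)) / prec
    return Gaussian(mean, 1.0 / prec)


def full_conditional_D(
    j: int, state: ModelState, data: ObservedDataset, config: PriorConfig
) -> Gaussian | SpikeSlab:
    """Conditional of the condition effect D_j.

    Normal family: precision = 1/tau_d + sum_i A_i^2, mean = sum A_i R_ij / precision
    with R_ij = I_ij - I0_j - T_ij W_jj. Under the spike-and-slab prior the
    slab Gaussian is the same and the inclusion probability combines the
    prior odds theta/(1-theta) with the slab-vs-spike marginal likelihood
    ratio.
    """
    tau = _tau(config.tau_d, j)
    a = data.A if data.A is not None else np.zeros(data.n)
    t_term = data.T[:, j] * state.W[j] if data.T is not None else 0.0
    resid = state.I[:, j] - state.I0[j] - t_term
    s_aa = float(a @ a)
    s_ar = float(a @ resid)
    prec = 1.0 / tau + s_aa
    mean = s_ar / prec
    slab = Gaussian(mean, 1.0 / prec)
    if config.prior_family != "spike_slab":
        return slab
    theta = _tau(config.theta, j)
    if theta >= 1.0:
        return SpikeSlab(slab, 1.0)
    log_odds = (
        np.log(theta / (1.0 - theta))
        + 0.5 * (np.log(1.0 / tau) - np.log(prec))
        + 0.5 * mean * mean * prec
    )
    return SpikeSlab(slab, float(1.0 / (1.0 + np.exp(-log_odds))))


def full_conditional_I0(j: int, state: ModelState, data: ObservedDataset, config: PriorConfig) -> Gaussian:
    """Conditional of the baseline abundance I0_j.

    precision = 1/tau_i0 + n; mean = (m0/tau_i0 + sum_i residual_ij)/precision
    where the residual removes the transcript and condition terms from I.
    """
    tau = _tau(config.tau_i0, j)
    m0 = _tau(config.i0_mean, j)
    t_term = data.T[:, j] * state.W[j] if data.T is not None else 0.0
    a_term = data.A * state.D[j] if data.A is not None else 0.0
    resid = state.I[:, j] - t_term - a_term
    prec = 1.0 / tau + data.n
    mean = (m0 / tau + float(resid.sum())) / prec
    return Gaussian(mean, 1.0 / prec)


def full_conditional_I_row(
    i: int,
    block_isoforms: np.ndarray,
    block_peptides: np.ndarray,
    state: ModelState,
    data: ObservedDataset,
    config: PriorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional of one sample's latent abundances over a block's isoforms.

    Returns (mean, covariance) of the multivariate Gaussian with
    precision = Identity + Z_b diag(1/sigma2) Z_b', which is always
    positive definite.
    """
    iso = np.asarray(block_isoforms, int)
    pep = np.asarray(block_peptides, int)
    zb = state.Z[np.ix_(iso, pep)]
    inv_s = 1.0 / state.sigma2[pep]
    prec = np.eye(iso.size) + (zb * inv_s) @ zb.T
    prior_mean = state.I0[iso].copy()
    if data.T is not None:
        prior_mean = prior_mean + data.T[i, iso] * state.W[iso]
    if data.A is not None:
        prior_mean = prior_mean + data.A[i] * state.D[iso]
    rhs = prior_mean + (zb * inv_s) @ data.P[i, pep]
    c = cho_factor(prec, lower=True)
    mean = cho_solve(c, rhs)
    cov = cho_solve(c, np.eye(iso.size))
    return mean, cov


def full_conditional_Z(
    j: int,
    k: int,
    state: ModelState,
    data: ObservedDataset,
    config: PriorConfig,
    bounds: np.ndarray,
) -> TruncatedGaussian:
    """Conditional of the detectability coefficient Z_jk (on-support only).

    With partial residual Ptilde_ik = P_ik - sum_{j' != j} I_ij' Z_j'k:
    precision = 1/tau_z + sum_i I_ij^2 / sigma2_k,
    mean = (1/tau_z + sum_i I_ij Ptilde_ik / sigma2_k)/precision,
    truncated to the isoform's bounds [l_j, u_j].
    """
    if data.mask[j, k] == 0:
        raise ValueError(f"Z[{j},{k}] is off the detectability mask and is never sampled")
    tau = _tau(config.tau_z, j)
    ij = state.I[:, j]
    partial = data.P[:, k] - (state.I @ state.Z[:, k] - ij * state.Z[j, k])
    s2 = state.sigma2[k]
    prec = 1.0 / tau + float(ij @ ij) / s2
    mean = (1.0 / tau + float(ij @ partial) / s2) / prec
    lo, hi = bounds[j]
    return TruncatedGaussian(mean, 1.0 / prec, float(lo), float(hi))


def full_conditional_noise(
    k: int, state: ModelState, data: ObservedDataset, config: PriorConfig
) -> InverseGamma:
    """Conditional of the peptide noise variance sigma2_k (conjugate IG)."""
    resid = data.P[:, k] - state.I @ state.Z[:, k]
    shape = config.noise_a0 + data.n / 2.0
    rate = config.noise_b0 + 0.5 * float(resid @ resid)
    return InverseGamma(shape, rate)


# ---------------------------------------------------------------------------
# log prior density
# ---------------------------------------------------------------------------


def _normal_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def log_prior_density(
    state: ModelState, data: ObservedDataset, config: PriorConfig, bounds: np.ndarray
) -> float:
    """Joint log prior of (W, D, Z, I0, I) at the given state.

    Z entries outside their truncation interval (or nonzero off support)
    return -inf. The noise variances carry their own conjugate prior and are
    not included here.
    """
    cfg = config.broadcast(data.q)
    total = float(np.sum(_normal_logpdf(state.W, 1.0, cfg.tau_w)))
    if cfg.prior_family == "spike_slab":
        at_zero = state.D == 0
        with np.errstate(divide="ignore"):
            dens = np.where(
                at_zero,
                np.log(1.0 - np.minimum(cfg.theta, 1.0 - 1e-16)),
                np.log(cfg.theta) + _normal_logpdf(state.D, 0.0, cfg.tau_d),
            )
        total += float(dens.sum())
    else:
        total += float(np.sum(_normal_logpdf(state.D, 0.0, cfg.tau_d)))
    jj, kk = np.nonzero(data.mask)
    z = state.Z[jj, kk]
    lo, hi = bounds[jj, 0], bounds[jj, 1]
    if np.any((z < lo) | (z > hi)) or np.any(state.Z[data.mask == 0] != 0):
        return -np.inf
    sd = np.sqrt(cfg.tau_z[jj])
    total += float(
        np.sum(_truncnorm.logpdf(z, (lo - 1.0) / sd, (hi - 1.0) / sd, loc=1.0, scale=sd))
    )
    total += float(np.sum(_normal_logpdf(state.I0, cfg.i0_mean, cfg.tau_i0)))
    prior_mean = np.broadcast_to(state.I0, (data.n, data.q)).copy()
    if data.T is not None:
        prior_mean = prior_mean + data.T * state.W
    if data.A is not None:
        prior_mean = prior_mean + np.outer(data.A, state.D)
    total += float(np.sum(_normal_logpdf(state.I, prior_mean, 1.0)))
    return total


# ---------------------------------------------------------------------------
# block sampler
# ---------------------------------------------------------------------------


class BlockGibbsSampler:
    """Gibbs sweeps for one independent block of the model.

    Holds the block's data and current state; :meth:`sweep` performs one
    systematic scan (I0, W, D, Z, sigma2, I) drawing from the full
    conditionals above in vectorized form. ``P`` is a plain attribute so
    joint-distribution tests can regenerate data between sweeps.
    """

    def __init__(
        self,
        P: np.ndarray,
        mask: np.ndarray,
        bounds: np.ndarray,
        prior: PriorConfig,
        T: np.ndarray | None = None,
        A: np.ndarray | None = None,
    ) -> None:
        self.P = np.asarray(P, float)
        self.mask = (np.asarray(mask) != 0).astype(np.uint8)
        self.q, self.r = self.mask.shape
        self.n = self.P.shape[0]
        self.bounds = np.asarray(bounds, float).reshape(self.q, 2)
        self.prior = prior.broadcast(self.q)
        self.T = None if T is None else np.asarray(T, float)
        self.A = None if A is None else np.asarray(A, float)
        self.spike_slab = self.prior.prior_family == "spike_slab"
        self._nz = np.nonzero(self.mask)
        # initial state: prior modes / a valid mid-support configuration
        self.I0 = np.asarray(self.prior.i0_mean, float).copy()
        self.W = np.ones(self.q) if self.T is not None else np.zeros(self.q)
        self.D = np.zeros(self.q)
        self.gamma = np.ones(self.q, dtype=np.uint8)
        self.Z = np.zeros((self.q, self.r))
        mid = 0.5 * (self.bounds[:, 0] + self.bounds[:, 1])
        self.Z[self._nz] = mid[self._nz[0]]
        self.sigma2 = np.ones(self.r)
        self.I = self._prior_mean()
        self._it = 0

    # -- helpers -----------------------------------------------------------

    def _prior_mean(self) -> np.ndarray:
        m = np.broadcast_to(self.I0, (self.n, self.q)).copy()
        if self.T is not None:
            m += self.T * self.W
        if self.A is not None:
            m += np.outer(self.A, self.D)
        return m

    def _check(self, name: str, arr: np.ndarray) -> None:
        if not np.all(np.isfinite(arr)):
            raise SamplingError(f"non-finite draw in {name} at iteration {self._it}")

    # -- one systematic scan ----------------------------------------------

    def sweep(self, rng: np.random.Generator) -> None:
        p = self.prior
        # I0
        t_term = self.T * self.W if self.T is not None else 0.0
        a_term = np.outer(self.A, self.D) if self.A is not None else 0.0
        resid = self.I - t_term - a_term
        prec = 1.0 / p.tau_i0 + self.n
        mean = (p.i0_mean / p.tau_i0 + resid.sum(axis=0)) / prec
        self.I0 = mean + rng.standard_normal(self.q) / np.sqrt(prec)
        self._check("I0", self.I0)
        # W
        if self.T is not None:
            resid = self.I - self.I0 - (np.outer(self.A, self.D) if self.A is not None else 0.0)
            prec = 1.0 / p.tau_w + np.einsum("ij,ij->j", self.T, self.T)
            mean = (1.0 / p.tau_w + np.einsum("ij,ij->j", self.T, resid)) / prec
            self.W = mean + rng.standard_normal(self.q) / np.sqrt(prec)
            self._check("W", self.W)
        # D
        if self.A is not None:
            resid = self.I - self.I0 - (self.T * self.W if self.T is not None else 0.0)
            s_aa = float(self.A @ self.A)
            prec = 1.0 / p.tau_d + s_aa
            mean = (self.A @ resid) / prec
            noise = rng.standard_normal(self.q)
            if self.spike_slab:
                with np.errstate(over="ignore"):
                    log_odds = (
                        np.log(p.theta / np.maximum(1.0 - p.theta, 1e-300))
                        - 0.5 * np.log(p.tau_d * prec)
                        + 0.5 * mean * mean * prec
                    )
                    p_inc = 1.0 / (1.0 + np.exp(-log_odds))
                self.gamma = (rng.uniform(size=self.q) < p_inc).astype(np.uint8)
                self.D = np.where(self.gamma, mean + noise / np.sqrt(prec), 0.0)
            else:
                self.D = mean + noise / np.sqrt(prec)
            self._check("D", self.D)
        # Z (sequential scan over on-support entries, row-major)
        fitted = self.I @ self.Z
        jj, kk = self._nz
        for j, k in zip(jj, kk):
            ij = self.I[:, j]
            old = self.Z[j, k]
            partial = self.P[:, k] - (fitted[:, k] - ij * old)
            s2 = self.sigma2[k]
            prec_z = 1.0 / p.tau_z[j] + (ij @ ij) / s2
            mean_z = (1.0 / p.tau_z[j] + (ij @ partial) / s2) / prec_z
            new = float(
                sample_truncated_normal(
                    np.asarray(mean_z),
                    np.sqrt(1.0 / prec_z),
                    self.bounds[j, 0],
                    self.bounds[j, 1],
                    rng,
                )
            )
            self.Z[j, k] = new
            fitted[:, k] += ij * (new - old)
        self._check("Z", self.Z)
        # sigma2
        resid = self.P - fitted
        shape = p.noise_a0 + self.n / 2.0
        rate = p.noise_b0 + 0.5 * np.einsum("ik,ik->k", resid, resid)
        self.sigma2 = rate / rng.gamma(shape, 1.0, size=self.r)
        self._check("sigma2", self.sigma2)
        # I (all sample rows share the same precision matrix)
        inv_s = 1.0 / self.sigma2
        prec_mat = np.eye(self.q) + (self.Z * inv_s) @ self.Z.T
        rhs = self._prior_mean() + self.P @ (self.Z * inv_s).T
        chol = cholesky(prec_mat, lower=True)
        mean = cho_solve((chol, True), rhs.T).T
        noise = rng.standard_normal((self.n, self.q))
        self.I = mean + solve_triangular(chol, noise.T, lower=True, trans="T").T
        self._check("I", self.I)
        self._it += 1

    def simulate_data(self, rng: np.random.Generator) -> None:
        """Replace P with a draw from the likelihood at the current state
        (used by joint-distribution correctness tests)."""
        self.P = self.I @ self.Z + rng.standard_normal((self.n, self.r)) * np.sqrt(self.sigma2)

    def state(self) -> ModelState:
        return ModelState(
            I0=self.I0.copy(),
            W=self.W.copy(),
            D=self.D.copy(),
            Z=self.Z.copy(),
            I=self.I.copy(),
            sigma2=self.sigma2.copy(),
            gamma=self.gamma.copy() if self.spike_slab else None,
        )


# ---------------------------------------------------------------------------
# chain drivers
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws of one chain.

    Z draws are stored at the mask's nonzero coordinates only; latent
    abundances I are summarized by their running posterior mean and SD
    (``store_I="full"`` keeps every draw).
    """

    W: np.ndarray  # (S, q)
    D: np.ndarray  # (S, q)
    I0: np.ndarray  # (S, q)
    sigma2: np.ndarray  # (S, r)
    Z_rows: np.ndarray  # (nnz,)
    Z_cols: np.ndarray  # (nnz,)
    Z: np.ndarray  # (S, nnz)
    I_mean: np.ndarray  # (n, q)
    I_sd: np.ndarray  # (n, q)
    chain_id: int
    seed: int
    gamma: np.ndarray | None = None  # (S, q)
    I_draws: np.ndarray | None = None  # (S, n, q) when store_I="full"
    isoform_ids: list[str] = field(default_factory=list)
    peptide_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.W.shape[0]

    def z_mean(self, q: int | None = None, r: int | None = None) -> np.ndarray:
        q = q or (int(self.Z_rows.max()) + 1 if self.Z_rows.size else 0)
        r = r or (int(self.Z_cols.max()) + 1 if self.Z_cols.size else 0)
        out = np.zeros((q, r))
        out[self.Z_rows, self.Z_cols] = self.Z.mean(axis=0)
        return out

    def save(self, outdir) -> None:
        """Persist draws as gzip TSVs plus a JSON manifest."""
        import pandas as pd
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"chain{self.chain_id}"
        for name, arr, cols in (
            ("W", self.W, self.isoform_ids),
            ("D", self.D, self.isoform_ids),
            ("I0", self.I0, self.isoform_ids),
            ("sigma2", self.sigma2, self.peptide_ids),
        ):
            pd.DataFrame(arr, columns=cols or None).to_csv(
                outdir / f"{tag}_{name}.tsv.gz", sep="\t", index=False
            )
        zcols = [f"{int(j)}:{int(k)}" for j, k in zip(self.Z_rows, self.Z_cols)]
        pd.DataFrame(self.Z, columns=zcols).to_csv(
            outdir / f"{tag}_Z.tsv.gz", sep="\t", index=False
        )
        pd.DataFrame(self.I_mean, index=self.sample_ids or None, columns=self.isoform_ids or None).to_csv(
            outdir / f"{tag}_I_mean.tsv.gz", sep="\t"
        )
        manifest = {"chain_id": self.chain_id, "seed": int(self.seed), "n_draws": self.n_draws}
        (outdir / f"{tag}_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_chain(
    data: ObservedDataset,
    prior_config: PriorConfig,
    chain_config: ChainConfig,
    chain_id: int = 0,
    *,
    seed: int | None = None,
    bounds: np.ndarray | None = None,
    bounds_policy: str = "data",
    blocks=None,
    block_offset: int = 0,
    store_I: str = "mean",
) -> PosteriorDraws:
    """Run one Gibbs chain over all blocks of the dataset.

    Each block is sampled on its own random stream seeded by
    ``(seed, block_offset + block index)``, so running a chain on a subset of
    blocks (with the matching offset) reproduces the corresponding draws of a
    whole-matrix run exactly.
    """
    from .data import truncation_bounds_all

    if seed is None:
        seed = chain_config.base_seed + chain_id
    if bounds is None:
        bounds = truncation_bounds_all(data.P, data.mask, policy=bounds_policy)
    bounds = np.asarray(bounds, float).reshape(data.q, 2)
    if blocks is None:
        blocks = decompose_blocks(data.mask)
    prior_q = prior_config.broadcast(data.q)

    S = chain_config.n_retained
    n, q, r = data.n, data.q, data.r
    W = np.zeros((S, q))
    D = np.zeros((S, q))
    I0 = np.zeros((S, q))
    sig = np.zeros((S, r))
    jj, kk = np.nonzero(data.mask)
    Z = np.zeros((S, jj.size))
    gam = np.zeros((S, q)) if prior_q.prior_family == "spike_slab" else None
    i_sum = np.zeros((n, q))
    i_sumsq = np.zeros((n, q))
    i_full = np.zeros((S, n, q)) if store_I == "full" else None
    flat_pos = {(int(a), int(b)): idx for idx, (a, b) in enumerate(zip(jj, kk))}

    for bi, blk in enumerate(blocks):
        iso, pep = blk.isoforms, blk.peptides
        if iso.size == 0 or pep.size == 0:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(int(block_offset) + bi,))
        )
        sub_prior = _subset_prior(prior_q, iso)
        smp = BlockGibbsSampler(
            P=data.P[:, pep],
            mask=data.mask[np.ix_(iso, pep)],
            bounds=bounds[iso],
            prior=sub_prior,
            T=None if data.T is None else data.T[:, iso],
            A=data.A,
        )
        zsel = [flat_pos[(int(j), int(k))] for j in iso for k in pep if data.mask[j, k]]
        zsel = np.asarray(zsel, int)
        local_nz = np.nonzero(smp.mask)
        s = 0
        for it in range(chain_config.n_iter):
            try:
                smp.sweep(rng)
            except SamplingError as err:
                raise SamplingError(f"chain {chain_id}, block {blk.block_id}: {err}") from err
            if it >= chain_config.burn_in and (it - chain_config.burn_in) % chain_config.thinning == 0:
                W[s, iso] = smp.W
                D[s, iso] = smp.D
                I0[s, iso] = smp.I0
                sig[s, pep] = smp.sigma2
                Z[s, zsel] = smp.Z[local_nz]
                if gam is not None:
                    gam[s, iso] = smp.gamma
                i_sum[:, iso] += smp.I
                i_sumsq[:, iso] += smp.I**2
                if i_full is not None:
                    i_full[s][:, iso] = smp.I
                s += 1

    i_mean = i_sum / S
    i_var = np.maximum(i_sumsq / S - i_mean**2, 0.0)
    return PosteriorDraws(
        W=W,
        D=D,
        I0=I0,
        sigma2=sig,
        Z_rows=jj,
        Z_cols=kk,
        Z=Z,
        I_mean=i_mean,
        I_sd=np.sqrt(i_var),
        chain_id=chain_id,
        seed=int(seed),
        gamma=gam,
        I_draws=i_full,
        isoform_ids=list(data.isoform_ids),
        peptide_ids=list(data.peptide_ids),
        sample_ids=list(data.sample_ids),
    )


def _subset_prior(prior_q: PriorConfig, iso: np.ndarray) -> PriorConfig:
    import dataclasses as _dc

    kw = {}
    for name in ("tau_w", "tau_d", "tau_z", "tau_i0", "theta", "i0_mean"):
        kw[name] = np.asarray(getattr(prior_q, name), float)[iso]
    return _dc.replace(prior_q, **kw)


def run_chains(
    data: ObservedDataset,
    prior_config: PriorConfig,
    chain_config: ChainConfig,
    **kwargs,
) -> list[PosteriorDraws]:
    """Run ``n_chains`` independent chains; chain c is seeded base_seed + c."""
    out = []
    for c in range(chain_config.n_chains):
        try:
            out.append(
                run_chain(
                    data,
                    prior_config,
                    chain_config,
                    chain_id=c,
                    seed=chain_config.base_seed + c,
                    **kwargs,
                )
            )
        except SamplingError as err:
            raise SamplingError(f"chain {c} failed: {err}") from err
    return out
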