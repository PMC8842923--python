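"""Bayesian binomial spatial regression with a Matérn Gaussian-process effect.

Model
-----
    y_i ~ Binomial(n_i, p_i)
    logit(p_i) = x_i' beta + S(s_i)
    S ~ GP(0, sigma^2 * Matern_nu(d / range))

with weakly-informative hyperpriors: penalized-complexity-style priors
P(range < r0) = 0.1 (r0 defaulting to one tenth of the domain diameter) and
P(sigma > s0) = 0.1 with s0 = 1, and Normal(0, 10^2) coefficient priors after
internal covariate standardization.

Inference
---------
A Markov chain Monte Carlo sampler tailored to latent-Gaussian models:
elliptical slice sampling for the whitened latent field and for the
coefficient block (both have Gaussian priors, so the updates are
rejection-free), plus an adaptive random-walk Metropolis step on
(log sigma, log range). The latent field is represented exactly at the
cluster locations through a dense Cholesky factorization; no mesh or sparse
approximation is involved at the problem sizes this package targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from scipy.linalg import solve_triangular
from scipy.spatial.distance import pdist, squareform

from .kernels import correlation_matrix, cross_correlation, chol_with_jitter, \
    matern_correlation, JITTER
from .selection import ClusterDesign


@dataclass
class ModelSpec:
    """Model structure, hyperpriors and inference settings.

    ``prior_range`` is (r0, alpha) meaning P(range < r0) = alpha; ``None``
    sets r0 to one tenth of the data bounding-box diameter at fit time.
    ``prior_sigma`` is (s0, alpha) meaning P(sigma > s0) = alpha.
    ``fix_sigma`` / ``fix_range`` pin a hyperparameter instead of sampling it
    (useful for the non-spatial limit sigma -> 0).
    """

    covariates: list[str] | None = None
    nu: float = 1.0
    prior_range: tuple[float, float] | None = None
    prior_sigma: tuple[float, float] = (1.0, 0.1)
    prior_beta_sd: float = 10.0
    n_posterior_samples: int = 1000
    n_warmup: int = 1000
    thin: int = 1
    seed: int = 0
    fix_sigma: float | None = None
    fix_range: float | None = None
    n_hyper_sweeps: int = 2
    n_field_sweeps: int = 3

    def __post_init__(self) -> None:
        if self.n_posterior_samples < 1:
            raise ValueError("n_posterior_samples must be at least 1")
        if self.nu <= 0 or self.prior_beta_sd <= 0:
            raise ValueError("nu and prior_beta_sd must be positive")
        if self.prior_sigma[0] <= 0 or not (0 < self.prior_sigma[1] < 1):
            raise ValueError("prior_sigma must be (s0 > 0, 0 < alpha < 1)")
        if self.prior_range is not None and (
            self.prior_range[0] <= 0 or not (0 < self.prior_range[1] < 1)
        ):
            raise ValueError("prior_range must be (r0 > 0, 0 < alpha < 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior_range"] = list(self.prior_range) if self.prior_range else None
        d["prior_sigma"] = list(self.prior_sigma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if d.get("prior_range") is not None:
            d["prior_range"] = tuple(d["prior_range"])
        if d.get("prior_sigma") is not None:
            d["prior_sigma"] = tuple(d["prior_sigma"])
        return cls(**d)


def log_likelihood(design: ClusterDesign, beta: np.ndarray,
                   field_values: np.ndarray) -> float:
    """Binomial log-likelihood sum_i [log C(n_i, y_i) + y_i eta_i - n_i log(1 + e^eta_i)].

    ``beta`` includes the intercept first; ``field_values`` is the latent
    spatial effect per cluster.
    """
    beta = np.asarray(beta, dtype=float)
    s = np.asarray(field_values, dtype=float)
    y, n = design.n_sam, design.n_examined
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("counts must satisfy 0 <= y <= n")
    if beta.shape != (design.X.shape[1] + 1,) or s.shape != (design.n_clusters,):
        raise ValueError("dimension mismatch between design, beta and field")
    eta = beta[0] + design.X @ beta[1:] + s
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(const + y * eta - n * np.logaddexp(0.0, eta)))


def _binom_ll(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> float:
    """Likelihood kernel (binomial coefficient dropped) used inside the sampler."""
    return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))


def _ess_step(x: np.ndarray, prior_scale: float | np.ndarray, loglik,
              rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One elliptical slice sampling update for a Gaussian-prior vector."""
    nu = prior_scale * rng.standard_normal(x.shape)
    log_y = loglik(x) + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta
    while True:
        xp = x * np.cos(theta) + nu * np.sin(theta)
        ll = loglik(xp)
        if ll > log_y:
            return xp, ll
        if theta < 0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)


class _ClusterKernel:
    """Matérn correlation matrices over a fixed point set (distances cached)."""

    def __init__(self, coords: np.ndarray, nu: float):
        self.n = coords.shape[0]
        self.dvec = pdist(coords)
        self.nu = nu

    def corr(self, range_: float) -> np.ndarray:
        r = squareform(matern_correlation(self.dvec, range_, self.nu))
        np.fill_diagonal(r, 1.0 + JITTER)
        return r


def _gaussian_logpdf_chol(x: np.ndarray, chol: np.ndarray, sigma: float) -> float:
    """log N(x; 0, sigma^2 * C C') given the lower Cholesky factor C."""
    n = len(x)
    w = solve_triangular(chol, x, lower=True) / sigma
    logdet = 2.0 * np.sum(np.log(np.diag(chol))) + 2.0 * n * np.log(sigma)
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + w @ w))


def _pc_log_prior(log_sigma: float, log_range: float, lam_sigma: float,
                  lam_range: float) -> float:
    """Log hyperprior density on the log scale (Jacobians included).

    sigma has an exponential PC prior (lam = -log(alpha)/s0); range has the
    2-D PC prior pi(r) = lam r^-2 exp(-lam / r) with lam = -log(alpha) * r0.
    """
    sigma, rng_ = np.exp(log_sigma), np.exp(log_range)
    lp_sigma = np.log(lam_sigma) - lam_sigma * sigma + log_sigma
    lp_range = np.log(lam_range) - 2.0 * log_range - lam_range / rng_ + log_range
    return float(lp_sigma + lp_range)


@dataclass
class FittedModel:
    """Joint posterior draws from the spatial binomial regression.

    Coefficient draws are reported on the original covariate scale (the
    internal standardization transform is stored and inverted on output).
    ``latent`` holds the spatial effect S at the cluster locations, one row
    per draw.
    """

    spec: ModelSpec
    names: list[str]                 # covariate names (without intercept)
    coords: np.ndarray               # (n, 2) cluster locations
    beta: np.ndarray                 # (n_draws, p + 1), intercept first
    sigma: np.ndarray                # (n_draws,)
    range_: np.ndarray               # (n_draws,)
    latent: np.ndarray               # (n_draws, n)
    design: ClusterDesign
    standardization: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def linear_predictor(self) -> np.ndarray:
        """(n_draws, n_clusters) eta at the cluster locations."""
        cols = [self.design.names.index(n) for n in self.names]
        X = self.design.X[:, cols]
        return self.beta[:, :1] + self.beta[:, 1:] @ X.T + self.latent

    def cluster_probabilities(self) -> np.ndarray:
        return expit(self.linear_predictor())

    def summary(self) -> pd.DataFrame:
        cols = ["intercept", *self.names, "sigma", "range"]
        draws = np.column_stack([self.beta, self.sigma, self.range_])
        return pd.DataFrame({
            "parameter": cols,
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0),
            "q2.5": np.percentile(draws, 2.5, axis=0),
            "q97.5": np.percentile(draws, 97.5, axis=0),
        })

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cols = {"beta_intercept": self.beta[:, 0]}
        for j, name in enumerate(self.names):
            cols[f"beta_{name}"] = self.beta[:, j + 1]
        cols["sigma"] = self.sigma
        cols["range"] = self.range_
        for i in range(self.latent.shape[1]):
            cols[f"S_{i}"] = self.latent[:, i]
        pd.DataFrame(cols).to_csv(out / "draws.csv", index=False)
        meta = {
            "spec": self.spec.to_dict(),
            "names": self.names,
            "coords": self.coords.tolist(),
            "standardization": self.standardization,
            "diagnostics": self.diagnostics,
            "design": {
                "cluster_ids": self.design.cluster_ids,
                "coords": self.design.coords.tolist(),
                "n_sam": self.design.n_sam.tolist(),
                "n_examined": self.design.n_examined.tolist(),
                "X": self.design.X.tolist(),
                "names": self.design.names,
            },
        }
        (out / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, in_dir: str | Path) -> "FittedModel":
        src = Path(in_dir)
        meta = json.loads((src / "model.json").read_text())
        draws = pd.read_csv(src / "draws.csv")
        names = meta["names"]
        beta = draws[["beta_intercept", *(f"beta_{n}" for n in names)]].to_numpy()
        s_cols = [c for c in draws.columns if c.startswith("S_")]
        d = meta["design"]
        design = ClusterDesign(d["cluster_ids"], np.array(d["coords"]),
                               np.array(d["n_sam"]), np.array(d["n_examined"]),
                               np.array(d["X"]), d["names"])
        return cls(
            spec=ModelSpec.from_dict(meta["spec"]),
            names=names,
            coords=np.array(meta["coords"]),
            beta=beta,
            sigma=draws["sigma"].to_numpy(),
            range_=draws["range"].to_numpy(),
            latent=draws[s_cols].to_numpy(),
            design=design,
            standardization=meta["standardization"],
            diagnostics=meta.get("diagnostics", {}),
        )


def _check_design_rank(Z: np.ndarray, names: list[str]) -> None:
    sds = Z[:, 1:].std(axis=0)
    zero = [names[j] for j in np.nonzero(sds == 0)[0]]
    if zero:
        raise ValueError(f"singular design: zero-variance column(s) {zero}")
    if Z.shape[1] > 1:
        corr = np.corrcoef(Z[:, 1:], rowvar=False)
        if Z.shape[1] == 2:
            return
        iu = np.triu_indices_from(corr, k=1)
        dup = np.nonzero(np.abs(corr[iu]) > 1 - 1e-10)[0]
        if dup.size:
            a, b = iu[0][dup[0]], iu[1][dup[0]]
            raise ValueError(
                f"singular design: columns {names[a]!r} and {names[b]!r} are collinear"
            )


def fit(design: ClusterDesign, spec: ModelSpec) -> FittedModel:
    """Sample the joint posterior of (beta, sigma, range, S).

    Covariates are standardized internally; the transform is stored and the
    returned coefficient draws are on the original scale. Reproducible given
    ``spec.seed``.
    """
    if design.n_clusters < 2:
        raise ValueError("fit needs at least 2 clusters")
    rng = np.random.default_rng(spec.seed)
    names = list(spec.covariates) if spec.covariates is not None else list(design.names)
    cols = [design.names.index(n) for n in names]
    X = design.X[:, cols]
    n_clu, p = X.shape

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    Z = np.column_stack([np.ones(n_clu), (X - means) / sds_safe])
    _check_design_rank(Z, names)

    y = design.n_sam.astype(float)
    ntr = design.n_examined.astype(float)
    coords = design.coords
    diam = float(np.hypot(*(coords.max(axis=0) - coords.min(axis=0)))) or 1.0

    r0, a_r = spec.prior_range if spec.prior_range is not None else (diam / 10.0, 0.1)
    s0, a_s = spec.prior_sigma
    lam_range = -np.log(a_r) * r0
    lam_sigma = -np.log(a_s) / s0

    nu = spec.nu
    log_sigma = np.log(spec.fix_sigma) if spec.fix_sigma is not None else np.log(0.5)
    log_range = np.log(spec.fix_range) if spec.fix_range is not None else np.log(2.0 * r0)
    sample_hyper = spec.fix_sigma is None or spec.fix_range is None

    kernel = _ClusterKernel(coords, nu)
    L = chol_with_jitter(kernel.corr(np.exp(log_range)))
    beta = np.zeros(p + 1)
    pooled = np.clip(y.sum() / ntr.sum(), 1e-4, 1 - 1e-4)
    beta[0] = logit(pooled)
    v = np.zeros(n_clu)

    def ll_parts(beta_, v_, sigma_, L_) -> float:
        eta = Z @ beta_ + sigma_ * (L_ @ v_)
        return _binom_ll(eta, y, ntr)

    def hyper_prior(ls, lr) -> float:
        return _pc_log_prior(ls, lr, lam_sigma, lam_range)

    # adaptive joint proposal over the free hyperparameters: the posterior of
    # (log sigma, log range) is typically a correlated ridge, so an isotropic
    # walk mixes poorly; the proposal covariance is learned during warmup
    free = [i for i, fx in enumerate((spec.fix_sigma, spec.fix_range)) if fx is None]
    n_free = len(free)
    prop_chol = np.eye(n_free) if n_free else None
    w_count, w_mean, w_m2 = 0, np.zeros(n_free), np.zeros((n_free, n_free))

    def adapt_cov(theta_free: np.ndarray) -> None:
        nonlocal w_count, w_mean, w_m2, prop_chol
        w_count += 1
        d = theta_free - w_mean
        w_mean = w_mean + d / w_count
        w_m2 = w_m2 + np.outer(d, theta_free - w_mean)
        if w_count > 20 * n_free and w_count % 25 == 0:
            cov = w_m2 / (w_count - 1) + 1e-6 * np.eye(n_free)
            prop_chol = np.linalg.cholesky(cov)

    def propose(ls, lr, scale):
        z = scale * (prop_chol @ rng.standard_normal(n_free))
        theta = [ls, lr]
        for j, i in enumerate(free):
            theta[i] += z[j]
        return theta[0], theta[1]

    n_iter = spec.n_warmup + spec.n_posterior_samples * spec.thin
    step_w, step_c = 0.3, 0.3          # whitened / centered proposal scales
    acc_w = acc_c = n_mh = 0
    keep_beta = np.empty((spec.n_posterior_samples, p + 1))
    keep_sigma = np.empty(spec.n_posterior_samples)
    keep_range = np.empty(spec.n_posterior_samples)
    keep_S = np.empty((spec.n_posterior_samples, n_clu))
    kept = 0
    tau = spec.prior_beta_sd

    for it in range(n_iter):
        sigma = np.exp(log_sigma)
        # several cheap latent sweeps per iteration keep the field chain's
        # autocorrelation low relative to the costlier hyperparameter moves
        for _ in range(spec.n_field_sweeps):
            v, _ = _ess_step(v, 1.0, lambda vv: ll_parts(beta, vv, sigma, L), rng)
            beta, _ = _ess_step(beta, tau, lambda bb: ll_parts(bb, v, sigma, L), rng)

            # exact Gibbs move along the likelihood-invariant ridge
            # (beta0 -> beta0 + delta, S -> S - delta): resolves the
            # confounding of the intercept with the field's overall level
            a = solve_triangular(L, np.ones(n_clu), lower=True) / sigma
            prec = 1.0 / tau**2 + a @ a
            mu_d = (a @ v - beta[0] / tau**2) / prec
            delta = mu_d + rng.standard_normal() / np.sqrt(prec)
            beta[0] += delta
            v = v - delta * a

        if sample_hyper:
            for _ in range(spec.n_hyper_sweeps):
                n_mh += 1
                # whitened (non-centered) update: v fixed, S rescales
                prop_ls, prop_lr = propose(log_sigma, log_range, step_w)
                L_prop = L if prop_lr == log_range else \
                    chol_with_jitter(kernel.corr(np.exp(prop_lr)))
                cur = ll_parts(beta, v, np.exp(log_sigma), L) + \
                    hyper_prior(log_sigma, log_range)
                prop = ll_parts(beta, v, np.exp(prop_ls), L_prop) + \
                    hyper_prior(prop_ls, prop_lr)
                if np.log(rng.uniform()) < prop - cur:
                    log_sigma, log_range, L = prop_ls, prop_lr, L_prop
                    acc_w += 1

                # centered (interweaved) update: S fixed, likelihood
                # unchanged, acceptance driven by the GP prior density of the
                # realized field; lets sigma follow the field magnitude
                S_cur = np.exp(log_sigma) * (L @ v)
                prop_ls, prop_lr = propose(log_sigma, log_range, step_c)
                L_prop = L if prop_lr == log_range else \
                    chol_with_jitter(kernel.corr(np.exp(prop_lr)))
                cur = _gaussian_logpdf_chol(S_cur, L, np.exp(log_sigma)) + \
                    hyper_prior(log_sigma, log_range)
                prop = _gaussian_logpdf_chol(S_cur, L_prop, np.exp(prop_ls)) + \
                    hyper_prior(prop_ls, prop_lr)
                if np.log(rng.uniform()) < prop - cur:
                    log_sigma, log_range, L = prop_ls, prop_lr, L_prop
                    v = solve_triangular(L, S_cur, lower=True) / np.exp(log_sigma)
                    acc_c += 1

                if it < spec.n_warmup:
                    gain = 1.0 / np.sqrt(1.0 + it / 10.0)
                    step_w = float(np.clip(
                        step_w * np.exp((acc_w / n_mh - 0.3) * gain), 1e-3, 5.0))
                    step_c = float(np.clip(
                        step_c * np.exp((acc_c / n_mh - 0.3) * gain), 1e-3, 5.0))
                    adapt_cov(np.array([log_sigma, log_range])[free])

        if it >= spec.n_warmup and (it - spec.n_warmup) % spec.thin == 0:
            keep_beta[kept] = beta
            keep_sigma[kept] = np.exp(log_sigma)
            keep_range[kept] = np.exp(log_range)
            keep_S[kept] = np.exp(log_sigma) * (L @ v)
            kept += 1

    if sample_hyper and n_mh > 0 and max(acc_w, acc_c) / n_mh < 0.01:
        raise RuntimeError(
            "hyperparameter sampler failed to move (acceptance "
            f"{acc_w / n_mh:.4f}/{acc_c / n_mh:.4f} over {n_mh} proposals; "
            f"steps {step_w:.3g}/{step_c:.3g})"
        )

    # back-transform coefficients to the original covariate scale
    beta_orig = keep_beta.copy()
    beta_orig[:, 1:] = keep_beta[:, 1:] / sds_safe
    beta_orig[:, 0] = keep_beta[:, 0] - keep_beta[:, 1:] @ (means / sds_safe)

    diagnostics = {
        "mh_acceptance_whitened": acc_w / n_mh if n_mh else None,
        "mh_acceptance_centered": acc_c / n_mh if n_mh else None,
        "mh_steps": [step_w, step_c],
        "ess_sigma": _simple_ess(keep_sigma),
        "ess_range": _simple_ess(keep_range),
        "ess_intercept": _simple_ess(keep_beta[:, 0]),
    }
    sub_design = design.subset_covariates(names) if names != design.names else design
    return FittedModel(
        spec=spec, names=names, coords=coords.copy(), beta=beta_orig,
        sigma=keep_sigma, range_=keep_range, latent=keep_S,
        design=sub_design,
        standardization={"means": means.tolist(), "sds": sds_safe.tolist()},
        diagnostics=diagnostics,
    )


def _simple_ess(x: np.ndarray, max_lag: int | None = None) -> float:
    """Effective sample size from the initial-positive autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or x.var() <= 1e-14 * max(1.0, float(x.mean()) ** 2):
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var())
    max_lag = max_lag or n // 2
    tau = 1.0
    for k in range(1, max_lag):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


def predict_latent(model: FittedModel, points: np.ndarray,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Conditional GP draws of the latent field S at new points, per posterior draw.

    For each draw the kriging mean and conditional covariance are computed
    from that draw's (sigma, range) and field values; a multivariate normal
    realization is then added, so the output is a sample from the posterior
    of S at the points, with shape (n_draws, n_points).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    m = pts.shape[0]
    out = np.empty((model.n_draws, m))
    nu = model.spec.nu
    for i in range(model.n_draws):
        sig, rho = model.sigma[i], model.range_[i]
        R_oo = correlation_matrix(model.coords, rho, nu)
        L_oo = chol_with_jitter(R_oo)
        R_po = cross_correlation(pts, model.coords, rho, nu)
        # solve R_oo^{-1} via the Cholesky factor
        w = solve_triangular(L_oo, model.latent[i] / max(sig, 1e-300), lower=True)
        alpha = solve_triangular(L_oo.T, w, lower=False)
        mean = sig * (R_po @ alpha)
        half = solve_triangular(L_oo, R_po.T, lower=True)
        R_cond = correlation_matrix(pts, rho, nu) - half.T @ half
        R_cond[np.diag_indices_from(R_cond)] += JITTER
        L_c = chol_with_jitter(R_cond)
        out[i] = mean + sig * (L_c @ rng.standard_normal(m))
    return out
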