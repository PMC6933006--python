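"""Bayesian multilevel (mixed-effects) regression for smoothness records.

The observation model is a Gaussian linear mixed model

    y = X beta + Z_i b_i + e,   b_i ~ N(0, G),   e ~ N(0, sigma^2 I)

with one varying-coefficient block b_i per patient and
G = diag(tau) R diag(tau) (R = LKJ-distributed correlation matrix when
the block has >= 2 terms).  Because both the likelihood and the random
effects are Gaussian, the b_i are integrated out analytically and MCMC
runs on the low-dimensional marginal posterior of
(beta, log sigma, log tau, partial correlations) — an affine-invariant
ensemble sampler (emcee) with walker ensembles treated as chains for
split-R-hat / ESS diagnostics.  Partial pooling is exact: per-patient
coefficients are recovered from their Gaussian conditional given each
posterior draw, which also yields the pointwise log-likelihood matrix
for PSIS-LOO.

The model ladder used for the smoothness analysis (population terms ~
centred group / session / device codes and standardised pre-intervention
smoothness; varying terms per patient) is available via
:meth:`ModelSpec.ladder`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .priors import (PriorSpec, corr_param_layers, half_t_logpdf_from_log,
                     lkj_partial_logprior, partials_to_corr, student_t_logpdf)

__all__ = ["ModelSpec", "SamplerConfig", "SmoothnessMixedLM", "MixedLMResults",
           "LADDER"]

#: Table-style model ladder: (population terms, varying terms).
LADDER: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {
    1: (("Group.c",), ("intercept",)),
    2: (("Group.c", "Session.c", "Group.c:Session.c"), ("intercept",)),
    3: (("Group.c", "Session.c", "Group.c:Session.c"),
        ("intercept", "Session.c")),
    4: (("Group.c", "Session.c", "Group.c:Session.c", "pre.z"),
        ("intercept", "Session.c", "pre.z")),
    5: (("Group.c", "Session.c", "Group.c:Session.c", "pre.z", "MoCap.c"),
        ("intercept", "Session.c", "pre.z")),
    # post-hoc interaction models, additive extensions of #5
    6: (("Group.c", "Session.c", "Group.c:Session.c", "pre.z", "MoCap.c",
         "Group.c:MoCap.c"), ("intercept", "Session.c", "pre.z")),
    7: (("Group.c", "Session.c", "Group.c:Session.c", "pre.z", "MoCap.c",
         "pre.z:MoCap.c"), ("intercept", "Session.c", "pre.z")),
}


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "MedianLC"
    population_terms: tuple[str, ...] = ("Group.c",)
    varying_terms: tuple[str, ...] = ("intercept",)
    correlated: bool = True
    group: str = "IDanon"
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if "intercept" not in self.varying_terms and self.varying_terms:
            pass  # slopes-only varying blocks are allowed
        base = set(self.population_terms) | {"intercept"}
        if not set(self.varying_terms) <= base:
            raise ValueError("varying terms must be population terms or the "
                             "intercept")

    @classmethod
    def ladder(cls, number: int, **kw) -> "ModelSpec":
        """Smoothness model #1..#7 of the increasing-complexity ladder."""
        if number not in LADDER:
            raise ValueError(f"model number must be 1..7, got {number}")
        pop, varying = LADDER[number]
        return cls(population_terms=pop, varying_terms=varying, **kw)

    @property
    def n_corr_params(self) -> int:
        q = len(self.varying_terms)
        return q * (q - 1) // 2 if (self.correlated and q >= 2) else 0


@dataclass(frozen=True)
class SamplerConfig:
    n_walkers: int = 32
    n_steps: int = 1500       # post-warmup steps are n_steps - warmup
    warmup_fraction: float = 0.5
    n_chains: int = 4         # walker groups treated as chains in diagnostics
    thin_loglik: int = 20     # thinning for the pointwise log-lik matrix
    rhat_limit: float = 1.01
    progress: bool = False


def _column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Resolve a (possibly interaction) term to a design column."""
    if term == "intercept":
        return np.ones(len(df))
    parts = term.split(":")
    col = np.ones(len(df))
    for p in parts:
        if p not in df.columns:
            raise KeyError(f"term {term!r}: column {p!r} not in records")
        col = col * df[p].to_numpy(dtype=float)
    return col


class SmoothnessMixedLM:
    """Bayesian multilevel model fitted to a smoothness-record table.

    Parameters
    ----------
    records
        DataFrame with the outcome, covariate columns and a grouping
        (patient id) column.
    spec
        Model specification; see :meth:`ModelSpec.ladder`.
    """

    def __init__(self, records: pd.DataFrame, spec: ModelSpec) -> None:
        if records[spec.group].nunique() < 2:
            raise ValueError("need at least 2 patients")
        self.spec = spec
        self.records = records.reset_index(drop=True)
        self.y = self.records[spec.outcome].to_numpy(dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("outcome contains non-finite values")

        self.x_names = ["Intercept", *spec.population_terms]
        X = np.column_stack([_column(self.records, t)
                             for t in ["intercept", *spec.population_terms]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient (a predictor "
                             "is constant or collinear)")
        self.X = X
        self.z_names = list(spec.varying_terms)
        self.Z = (np.column_stack([_column(self.records, t)
                                   for t in spec.varying_terms])
                  if spec.varying_terms else np.empty((len(records), 0)))
        codes, self.group_ids = pd.factorize(self.records[spec.group])
        self.codes = codes

        # --- per-group sufficient statistics (likelihood is O(P) per eval)
        P, p, q = len(self.group_ids), X.shape[1], self.Z.shape[1]
        self.n_groups, self.p, self.q = P, p, q
        self.XtX = X.T @ X
        self.Xty = X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.N = len(self.y)
        self.ZtZ = np.zeros((P, q, q))
        self.ZtX = np.zeros((P, q, p))
        self.Zty = np.zeros((P, q))
        for g in range(P):
            m = codes == g
            Zg, Xg, yg = self.Z[m], X[m], self.y[m]
            self.ZtZ[g] = Zg.T @ Zg
            self.ZtX[g] = Zg.T @ Xg
            self.Zty[g] = Zg.T @ yg

        self.param_names = self._param_names()

    # ------------------------------------------------------------------
    def _param_names(self) -> list[str]:
        names = list(self.x_names) + ["sigma"]
        names += [f"sd({t})" for t in self.z_names]
        layers = corr_param_layers(self.q) if self.spec.n_corr_params else []
        names += [f"cor({self.z_names[i]},{self.z_names[j]})"
                  for i, j, _l in layers]
        return names

    @property
    def n_params(self) -> int:
        return self.p + 1 + self.q + self.spec.n_corr_params

    def _unpack(self, theta: np.ndarray):
        p, q = self.p, self.q
        beta = theta[:p]
        log_sigma = theta[p]
        log_tau = theta[p + 1:p + 1 + q]
        corr = theta[p + 1 + q:]
        return beta, log_sigma, log_tau, corr

    def log_prior(self, theta: np.ndarray) -> float:
        pr = self.spec.priors
        beta, log_sigma, log_tau, corr = self._unpack(theta)
        lp = float(student_t_logpdf(beta[0], pr.intercept_df, pr.intercept_scale))
        lp += float(np.sum(student_t_logpdf(beta[1:], pr.slope_df,
                                            pr.slope_scale)))
        lp += float(half_t_logpdf_from_log(log_sigma, pr.sd_df, pr.sd_scale))
        lp += float(np.sum(half_t_logpdf_from_log(log_tau, pr.sd_df,
                                                  pr.sd_scale)))
        if corr.size:
            lp += lkj_partial_logprior(corr, self.q, pr.lkj_eta)
        return lp

    # -- fast vectorised posterior (evaluated for all walkers at once) --
    @staticmethod
    def _t_logpdf(x, df, scale):
        from scipy.special import gammaln
        c = (gammaln((df + 1) / 2) - gammaln(df / 2)
             - 0.5 * np.log(df * np.pi) - np.log(scale))
        return c - (df + 1) / 2 * np.log1p((x / scale) ** 2 / df)

    def _log_posterior_batch(self, Theta: np.ndarray) -> np.ndarray:
        """Posterior log density for a (W, n_params) batch of states."""
        Theta = np.atleast_2d(np.asarray(Theta, float))
        W = Theta.shape[0]
        out = np.full(W, -np.inf)
        ok = np.all(np.abs(Theta) <= 50, axis=1)
        if not ok.any():
            return out
        Th = Theta[ok]
        p, q, pr = self.p, self.q, self.spec.priors
        beta = Th[:, :p]
        log_sigma = Th[:, p]
        log_tau = Th[:, p + 1:p + 1 + q]
        corr = Th[:, p + 1 + q:]
        sigma2 = np.exp(2.0 * log_sigma)

        lp = self._t_logpdf(beta[:, 0], pr.intercept_df, pr.intercept_scale)
        if p > 1:
            lp = lp + self._t_logpdf(beta[:, 1:], pr.slope_df,
                                     pr.slope_scale).sum(axis=1)
        sigma = np.exp(log_sigma)
        tau = np.exp(log_tau)
        lp = lp + (np.log(2.0) + self._t_logpdf(sigma, pr.sd_df, pr.sd_scale)
                   + log_sigma)
        if q:
            lp = lp + (np.log(2.0) + self._t_logpdf(tau, pr.sd_df, pr.sd_scale)
                       + log_tau).sum(axis=1)

        rr = (self.yty - 2.0 * beta @ self.Xty
              + np.einsum("wi,ij,wj->w", beta, self.XtX, beta))
        ll = -0.5 * self.N * np.log(2.0 * np.pi * sigma2)
        if q == 0:
            out[ok] = lp + ll - 0.5 * rr / sigma2
            return out

        # G = diag(tau) R diag(tau) per walker
        Wk = Th.shape[0]
        if corr.shape[1]:
            lp = lp + np.array([lkj_partial_logprior(c, q, pr.lkj_eta)
                                for c in corr])
            R = np.stack([partials_to_corr(c, q) for c in corr])
        else:
            R = np.broadcast_to(np.eye(q), (Wk, q, q))
        G = R * tau[:, :, None] * tau[:, None, :]
        u = self.Zty[None] - np.einsum("pqk,wk->wpq", self.ZtX, beta)
        A = np.einsum("wij,pjk->wpik", G, self.ZtZ) / sigma2[:, None, None, None]
        Iq = np.eye(q)
        sign, logdet = np.linalg.slogdet(Iq[None, None] + A)
        bad = np.any(sign <= 0, axis=1)
        Ginv = np.linalg.inv(G + 1e-300 * Iq)
        M = Ginv[:, None] + self.ZtZ[None] / sigma2[:, None, None, None]
        Mu = np.linalg.solve(M, u[..., None])[..., 0]
        quad = rr / sigma2 - np.einsum("wpq,wpq->w", u, Mu) / sigma2**2
        val = lp + ll - 0.5 * logdet.sum(axis=1) - 0.5 * quad
        val[bad] = -np.inf
        val[~np.isfinite(val)] = -np.inf
        res = out.copy()
        res[ok] = val
        return res

    def _G(self, log_tau: np.ndarray, corr: np.ndarray) -> np.ndarray:
        tau = np.exp(log_tau)
        if self.q == 0:
            return np.empty((0, 0))
        R = (partials_to_corr(corr, self.q) if corr.size else np.eye(self.q))
        return R * np.outer(tau, tau)

    def log_likelihood(self, theta: np.ndarray) -> float:
        """Marginal log likelihood with random effects integrated out."""
        beta, log_sigma, log_tau, corr = self._unpack(theta)
        sigma2 = np.exp(2.0 * log_sigma)
        rr = self.yty - 2.0 * beta @ self.Xty + beta @ self.XtX @ beta
        ll = -0.5 * self.N * np.log(2.0 * np.pi * sigma2)
        if self.q == 0:
            return float(ll - 0.5 * rr / sigma2)
        G = self._G(log_tau, corr)
        u = self.Zty - self.ZtX @ beta                   # (P, q)
        A = G[None] @ self.ZtZ / sigma2                  # (P, q, q)
        Iq = np.eye(self.q)
        sign, logdet = np.linalg.slogdet(Iq[None] + A)
        if np.any(sign <= 0):
            return -np.inf
        M = np.linalg.inv(G)[None] + self.ZtZ / sigma2   # (P, q, q)
        try:
            Mu = np.linalg.solve(M, u[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return -np.inf
        quad = rr / sigma2 - np.einsum("ij,ij->", u, Mu) / sigma2**2
        return float(ll - 0.5 * logdet.sum() - 0.5 * quad)

    def log_posterior(self, theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 50):
            return -np.inf
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(theta)

    # ------------------------------------------------------------------
    def _initial_state(self, rng: np.random.Generator,
                       n_walkers: int) -> np.ndarray:
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta0
        s = max(float(resid.std(ddof=self.p)), 1e-3)
        center = np.concatenate([
            beta0, [np.log(s)], np.full(self.q, np.log(max(s * 0.5, 1e-3))),
            np.zeros(self.spec.n_corr_params)])
        jitter = 0.05 * rng.standard_normal((n_walkers, self.n_params))
        return center[None, :] + jitter

    def sample_prior(self, n: int = 4000, seed: int = 0) -> pd.DataFrame:
        """Draws from the joint prior (prior-predictive sanity checks).

        Columns follow ``param_names``; SDs on the natural scale,
        correlations as matrix entries.
        """
        from scipy import stats as _st
        rng = np.random.default_rng(seed)
        pr = self.spec.priors
        cols: dict[str, np.ndarray] = {}
        cols["Intercept"] = _st.t.rvs(pr.intercept_df, scale=pr.intercept_scale,
                                      size=n, random_state=rng)
        for name in self.x_names[1:]:
            cols[name] = _st.t.rvs(pr.slope_df, scale=pr.slope_scale,
                                   size=n, random_state=rng)
        cols["sigma"] = np.abs(_st.t.rvs(pr.sd_df, scale=pr.sd_scale,
                                         size=n, random_state=rng))
        for t in self.z_names:
            cols[f"sd({t})"] = np.abs(_st.t.rvs(pr.sd_df, scale=pr.sd_scale,
                                                size=n, random_state=rng))
        if self.spec.n_corr_params:
            layers = corr_param_layers(self.q)
            raw = np.empty((n, len(layers)))
            for k, (_i, _j, l) in enumerate(layers):
                a = pr.lkj_eta + (self.q - 1 - l) / 2.0
                raw[:, k] = 2.0 * rng.beta(a, a, size=n) - 1.0
            for d in range(n):
                R = partials_to_corr(np.arctanh(np.clip(raw[d], -1 + 1e-12,
                                                        1 - 1e-12)), self.q)
                for name, (i, j, _l) in zip(
                        [nm for nm in self.param_names
                         if nm.startswith("cor(")], layers):
                    cols.setdefault(name, np.empty(n))[d] = R[i, j]
        return pd.DataFrame(cols)

    def fit(self, seed: int = 0,
            sampler: SamplerConfig | None = None) -> "MixedLMResults":
        """Run MCMC on the marginal posterior and return results."""
        import emcee

        cfg = sampler or SamplerConfig()
        rng = np.random.default_rng(seed)
        nw = max(cfg.n_walkers, 2 * self.n_params + 2)
        nw += nw % 2
        p0 = self._initial_state(rng, nw)
        es = emcee.EnsembleSampler(nw, self.n_params,
                                   self._log_posterior_batch, vectorize=True)
        es.random_state = np.random.RandomState(
            int(rng.integers(0, 2**31 - 1))).get_state()
        es.run_mcmc(p0, cfg.n_steps, progress=cfg.progress)
        burn = int(cfg.warmup_fraction * cfg.n_steps)
        chain = es.get_chain(discard=burn)       # (steps, walkers, dim)
        chain = np.moveaxis(chain, 0, 1)         # (walkers, steps, dim)
        return MixedLMResults(model=self, chain=chain, config=cfg, seed=seed)


class MixedLMResults:
    """Posterior draws, summaries and diagnostics of a fitted model."""

    def __init__(self, model: SmoothnessMixedLM, chain: np.ndarray,
                 config: SamplerConfig, seed: int) -> None:
        self.model = model
        self.config = config
        self.seed = seed
        # regroup walkers into n_chains pseudo-chains for diagnostics
        nw, steps, dim = chain.shape
        nc = min(config.n_chains, nw)
        per = nw // nc
        self.chain = (chain[:nc * per]
                      .reshape(nc, per, steps, dim)
                      .transpose(0, 2, 1, 3)
                      .reshape(nc, steps * per, dim))
        self.param_names = model.param_names
        self._idata = None
        self._diag = None

    # -------------------------------------------------- posterior access
    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    def draws(self, name: str) -> np.ndarray:
        """Flattened posterior draws of one parameter (natural scale)."""
        i = self.param_names.index(name)
        x = self.chain[..., i].ravel()
        if name == "sigma" or name.startswith("sd("):
            return np.exp(x)
        if name.startswith("cor("):
            return self._corr_draws()[name]
        return x

    def _corr_draws(self) -> dict[str, np.ndarray]:
        q = self.model.q
        k0 = self.model.p + 1 + q
        out: dict[str, np.ndarray] = {}
        flat = self.chain.reshape(-1, self.chain.shape[-1])
        names = [n for n in self.param_names if n.startswith("cor(")]
        if not names:
            return out
        Rs = np.stack([partials_to_corr(row[k0:], q) for row in flat])
        layers = corr_param_layers(q)
        for name, (i, j, _l) in zip(names, layers):
            out[name] = Rs[:, i, j]
        return out

    def to_inference_data(self):
        import arviz as az
        post = {}
        for k, name in enumerate(self.param_names):
            x = self.chain[..., k]
            if name == "sigma" or name.startswith("sd("):
                x = np.exp(x)
            post[name] = x
        corr = self._corr_draws()
        nc, nd = self.chain.shape[:2]
        for name, vals in corr.items():
            post[name] = vals.reshape(nc, nd)
        return az.from_dict(posterior=post)

    # -------------------------------------------------- diagnostics
    def diagnostics(self) -> pd.DataFrame:
        if self._diag is None:
            import arviz as az
            idata = self.to_inference_data()
            rhat = az.rhat(idata)
            ess = az.ess(idata)
            self._diag = pd.DataFrame({
                "rhat": {k: float(rhat[k]) for k in rhat.data_vars},
                "ess": {k: float(ess[k]) for k in ess.data_vars},
            })
        return self._diag

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics()["rhat"].max() < self.config.rhat_limit)

    # -------------------------------------------------- summaries
    def summary(self, prob: float = 0.9) -> pd.DataFrame:
        """Posterior summary shaped like a regression table.

        Columns: term, estimate (median), std.error (posterior SD),
        conf.low / conf.high (central ``prob`` interval), rhat, ess.
        """
        lo_q, hi_q = (1 - prob) / 2, 1 - (1 - prob) / 2
        diag = self.diagnostics()
        rows = []
        for name in self.param_names:
            d = self.draws(name)
            rows.append({
                "term": name,
                "estimate": float(np.median(d)),
                "std.error": float(d.std(ddof=1)),
                "conf.low": float(np.quantile(d, lo_q)),
                "conf.high": float(np.quantile(d, hi_q)),
                "rhat": float(diag["rhat"].get(name, np.nan)),
                "ess": float(diag["ess"].get(name, np.nan)),
            })
        return pd.DataFrame(rows)

    def intervals(self, name: str) -> dict[str, float]:
        """Median plus 50% and 90% central intervals (figure-style)."""
        d = self.draws(name)
        return {
            "median": float(np.median(d)),
            "l50": float(np.quantile(d, 0.25)),
            "u50": float(np.quantile(d, 0.75)),
            "l90": float(np.quantile(d, 0.05)),
            "u90": float(np.quantile(d, 0.95)),
        }

    # -------------------------------------------------- random effects
    def _theta_subset(self, max_draws: int, seed_offset: int = 1):
        flat = self.chain.reshape(-1, self.chain.shape[-1])
        rng = np.random.default_rng(self.seed + seed_offset)
        if len(flat) > max_draws:
            idx = rng.choice(len(flat), size=max_draws, replace=False)
            flat = flat[idx]
        return flat, rng

    def random_effects(self, max_draws: int = 500) -> pd.DataFrame:
        """Posterior means of the per-patient varying coefficients."""
        m = self.model
        if m.q == 0:
            raise ValueError("model has no varying terms")
        flat, _ = self._theta_subset(max_draws)
        acc = np.zeros((m.n_groups, m.q))
        for theta in flat:
            mean, _cov = self._b_conditional(theta)
            acc += mean
        acc /= len(flat)
        return pd.DataFrame(acc, columns=m.z_names,
                            index=pd.Index(m.group_ids, name=m.spec.group))

    def _b_conditional(self, theta: np.ndarray):
        """Gaussian conditional b_i | y, theta for every group (batched)."""
        m = self.model
        beta, log_sigma, log_tau, corr = m._unpack(theta)
        sigma2 = np.exp(2.0 * log_sigma)
        G = m._G(log_tau, corr)
        u = m.Zty - m.ZtX @ beta
        M = np.linalg.inv(G)[None] + m.ZtZ / sigma2
        cov = np.linalg.inv(M)
        mean = np.einsum("pij,pj->pi", cov, u) / sigma2
        return mean, cov

    # -------------------------------------------------- pointwise log-lik
    def pointwise_loglik(self, max_draws: int = 1000) -> np.ndarray:
        """Log-likelihood matrix (chains, draws, n_obs) for PSIS-LOO.

        Conditional on the varying coefficients, which are drawn from
        their exact Gaussian conditional for each retained posterior
        draw (the joint posterior of (theta, b) is sampled exactly).
        """
        m = self.model
        flat, rng = self._theta_subset(max_draws, seed_offset=2)
        n = len(flat)
        ll = np.empty((n, m.N))
        for d, theta in enumerate(flat):
            beta, log_sigma, log_tau, corr = m._unpack(theta)
            sigma2 = np.exp(2.0 * log_sigma)
            mu = m.X @ beta
            if m.q:
                mean, cov = self._b_conditional(theta)
                chol = np.linalg.cholesky(cov)
                b = mean + np.einsum("pij,pj->pi", chol,
                                     rng.standard_normal((m.n_groups, m.q)))
                mu = mu + np.einsum("ij,ij->i", m.Z, b[m.codes])
            ll[d] = (-0.5 * np.log(2 * np.pi * sigma2)
                     - 0.5 * (m.y - mu) ** 2 / sigma2)
        # split into 2 pseudo-chains for arviz
        half = n // 2
        return np.stack([ll[:half], ll[half:2 * half]])

    # -------------------------------------------------- plotting
    def plot_forest(self, terms: list[str] | None = None, ax=None):
        """Median / 50% / 90% interval forest plot of population terms."""
        import matplotlib.pyplot as plt
        terms = terms or self.model.x_names
        if ax is None:
            _fig, ax = plt.subplots(figsize=(6, 0.5 * len(terms) + 1))
        for k, t in enumerate(reversed(terms)):
            iv = self.intervals(t)
            ax.plot([iv["l90"], iv["u90"]], [k, k], lw=1, color="k")
            ax.plot([iv["l50"], iv["u50"]], [k, k], lw=3, color="k")
            ax.plot(iv["median"], k, "o", color="k")
        ax.axvline(0, color="0.6", ls=":")
        ax.set_yticks(range(len(terms)))
        ax.set_yticklabels(list(reversed(terms)))
        ax.set_xlabel("posterior")
        return ax
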