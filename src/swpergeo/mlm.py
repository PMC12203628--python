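"""Four-level random-intercept logistic model: PQL initialisation + MCMC.

The model for woman i in community j, district k, state l is

    logit P(Y_ijkl = 1) = beta0 + u_j + v_k + f_l,

with u ~ N(0, sigma2_community), v ~ N(0, sigma2_district),
f ~ N(0, sigma2_state). The level-1 (Bernoulli) variance is not freely
estimated. Because the model has no woman-level covariates, the likelihood
depends on the data only through per-community counts (n_j, y_j), so the
sampler and the quasi-likelihood initialiser operate on that exact collapse.

Estimation follows the two-stage convention of multilevel survey analysis:
an iterative generalised-least-squares / penalised-quasi-likelihood fit of
the linearised model provides starting values, then an MCMC run (default
burn-in 500, monitored 5000 iterations) yields posterior summaries for the
intercept, the three variance components and every unit-level residual.

Sampler kernels: vectorised single-site random-walk Metropolis for the
intercept and residuals, conjugate inverse-gamma Gibbs steps for the
variances, plus likelihood-invariant "translation" moves that shift mass
between adjacent levels (beta0<->f, f<->v, v<->u); these cost nothing in
likelihood evaluations and remove the slow random-walk behaviour of the
level-mean directions. Proposal scales adapt during burn-in only, so the
monitored chain is a valid Markov chain.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit, logit

from .errors import NestingViolationError, SchemaError, SeparationError

__all__ = [
    "NestedIndex",
    "MCMCSettings",
    "Summary",
    "VarianceComponents",
    "ModelFit",
    "build_index",
    "init_quasilikelihood",
    "run_mcmc",
    "diagnose",
]

logger = logging.getLogger(__name__)

LEVELS = ("community", "district", "state")


def _log1pexp(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# index


@dataclass
class NestedIndex:
    """Dense 0-based contiguous codes for the four-level nesting.

    Communities are canonically sorted by (state, district, community) label,
    so the communities of a district — and the districts of a state — occupy
    contiguous code ranges.
    """

    community_labels: np.ndarray  # (J,) community id per community code
    district_labels: np.ndarray  # (K,)
    state_labels: np.ndarray  # (L,)
    community_district: np.ndarray  # (J,) district code of each community
    district_state: np.ndarray  # (K,) state code of each district
    woman_community: np.ndarray  # (N,) community code per input row

    @property
    def n_communities(self) -> int:
        return len(self.community_labels)

    @property
    def n_districts(self) -> int:
        return len(self.district_labels)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_women(self) -> int:
        return len(self.woman_community)

    @property
    def community_state(self) -> np.ndarray:
        return self.district_state[self.community_district]

    def community_sizes(self) -> np.ndarray:
        return np.bincount(self.woman_community, minlength=self.n_communities)


def build_index(records: pd.DataFrame) -> NestedIndex:
    """Validate strict nesting and assign dense canonical codes.

    Raises :class:`NestingViolationError` listing any community that appears
    under more than one district (or district under more than one state).
    """
    for col in ("state_id", "district_id", "community_id"):
        if col not in records.columns:
            raise SchemaError(f"records lack key column {col!r}")

    keys = records[["state_id", "district_id", "community_id"]].astype(str)
    cd = keys.drop_duplicates(["community_id", "district_id"])
    offenders = cd["community_id"][cd["community_id"].duplicated(keep=False)].unique()
    if len(offenders):
        raise NestingViolationError(
            f"communities under multiple districts: {sorted(offenders.tolist())}"
        )
    dsu = keys.drop_duplicates(["district_id", "state_id"])
    offenders = dsu["district_id"][dsu["district_id"].duplicated(keep=False)].unique()
    if len(offenders):
        raise NestingViolationError(
            f"districts under multiple states: {sorted(offenders.tolist())}"
        )

    units = (
        keys.drop_duplicates("community_id")
        .sort_values(["state_id", "district_id", "community_id"], kind="stable")
        .reset_index(drop=True)
    )
    community_labels = units["community_id"].to_numpy()
    district_labels, dist_first = np.unique(units["district_id"].to_numpy(), return_index=True)
    order = np.argsort(dist_first)
    district_labels = district_labels[order]  # keep canonical order
    dist_code = {d: i for i, d in enumerate(district_labels)}
    state_labels_all = units["state_id"].to_numpy()
    state_labels, st_first = np.unique(state_labels_all, return_index=True)
    state_labels = state_labels[np.argsort(st_first)]
    state_code = {s: i for i, s in enumerate(state_labels)}

    community_district = np.array([dist_code[d] for d in units["district_id"]])
    dist_state_pairs = units.drop_duplicates("district_id")
    district_state = np.empty(len(district_labels), dtype=int)
    for row in dist_state_pairs.itertuples():
        district_state[dist_code[row.district_id]] = state_code[row.state_id]

    comm_code = {c: i for i, c in enumerate(community_labels)}
    woman_community = records["community_id"].astype(str).map(comm_code).to_numpy()
    return NestedIndex(
        community_labels=community_labels,
        district_labels=district_labels,
        state_labels=state_labels,
        community_district=community_district,
        district_state=district_state,
        woman_community=woman_community,
    )


def _collapse(records: pd.DataFrame, index: NestedIndex, outcome: str):
    """Per-community success/total counts (exact sufficient statistics)."""
    if outcome not in records.columns:
        raise SchemaError(f"records lack outcome column {outcome!r}")
    y = records[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise SchemaError(f"outcome column {outcome!r} must be binary 0/1")
    J = index.n_communities
    y_j = np.bincount(index.woman_community, weights=y, minlength=J)
    n_j = np.bincount(index.woman_community, minlength=J).astype(float)
    return y_j, n_j


# ---------------------------------------------------------------------------
# quasi-likelihood initialisation


@dataclass
class StartingValues:
    beta0: float
    sigma2_community: float
    sigma2_district: float
    sigma2_state: float
    converged: bool = True
    method: str = "pql"

    def as_tuple(self):
        return (self.sigma2_state, self.sigma2_district, self.sigma2_community)


def init_quasilikelihood(
    records: pd.DataFrame,
    index: NestedIndex,
    outcome: str = "y",
    max_iter: int = 30,
    tol: float = 1e-4,
) -> StartingValues:
    """Iterative linearised (PQL-style) fit giving finite starting values.

    Each pass linearises the Bernoulli likelihood around the current linear
    predictor, forming a community-level working response with known
    heteroscedastic sampling variance, then fits the nested linear mixed
    model exactly (per-state block ML) and updates the predictor from its
    BLUPs. Falls back to a method-of-moments decomposition of empirical
    logits if the inner optimiser fails (logged).
    """
    y_j, n_j = _collapse(records, index, outcome)
    total_y = y_j.sum()
    if total_y == 0 or total_y == n_j.sum():
        raise SeparationError(
            "outcome is constant (all 0 or all 1); the intercept-only logistic "
            "model is degenerate and no variance components are identified"
        )
    cd = index.community_district
    ds = index.district_state
    active_v = index.n_districts > 1
    active_f = index.n_states > 1

    p_tilde = (y_j + 0.5) / (n_j + 1.0)
    eta = logit(p_tilde)
    beta0 = float(np.average(eta, weights=n_j))
    theta = None
    fell_back = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y_j / n_j - mu) / w
        d = 1.0 / (n_j * w)
        try:
            beta0, theta = _fit_nested_lmm(z, d, cd, ds, active_v, active_f)
        except Exception:  # noqa: BLE001 - any numerical failure triggers fallback
            logger.warning("PQL inner fit failed; falling back to method of moments")
            beta0, theta = _moment_start(z, d, cd, ds, active_v, active_f)
            fell_back = True
        u, v, f = _blup(z, d, cd, ds, beta0, theta)
        eta_new = beta0 + u + v[cd] + f[ds[cd]]
        if np.max(np.abs(eta_new - eta)) < tol:
            eta = eta_new
            break
        if fell_back:
            eta = eta_new
            break
        eta = eta_new
    s2f, s2v, s2u = theta
    return StartingValues(
        beta0=float(beta0),
        sigma2_community=float(max(s2u, 0.0)),
        sigma2_district=float(max(s2v, 0.0)),
        sigma2_state=float(max(s2f, 0.0)),
        converged=not fell_back,
        method="moments" if fell_back else "pql",
    )


def _state_blocks(cd, ds):
    cs = ds[cd]
    L = int(cs.max()) + 1 if len(cs) else 0
    return [np.flatnonzero(cs == l) for l in range(L)]


def _fit_nested_lmm(z, d, cd, ds, active_v, active_f):
    """Exact ML for the nested linear model z_j = b0 + u + v + f + e, e~N(0,d_j).

    Optimises the profile (over b0) log-likelihood in log-variance space,
    one dense Cholesky per state block per evaluation.
    """
    blocks = _state_blocks(cd, ds)

    def unpack(x):
        s2u = np.exp(x[0])
        s2v = np.exp(x[1]) if active_v else 0.0
        s2f = np.exp(x[-1]) if active_f else 0.0
        return s2f, s2v, s2u

    def negll(x):
        s2f, s2v, s2u = unpack(x)
        logdet = 0.0
        A = B = C = 0.0
        for idx in blocks:
            dl = d[idx]
            zl = z[idx]
            cdl = cd[idx]
            V = s2v * (cdl[:, None] == cdl[None, :]) + s2f
            V = V + np.diag(dl + s2u)
            try:
                cf = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                return 1e12
            logdet += 2.0 * np.sum(np.log(np.diag(cf[0])))
            Vi1 = cho_solve(cf, np.ones(len(idx)))
            Viz = cho_solve(cf, zl)
            A += Vi1.sum()
            B += Viz.sum()
            C += zl @ Viz
        return 0.5 * (logdet + C - B * B / A)

    n_par = 1 + int(active_v) + int(active_f)
    x0 = np.full(n_par, np.log(0.2))
    res = minimize(
        negll, x0, method="L-BFGS-B", bounds=[(-12.0, 4.0)] * n_par
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("nested LMM likelihood optimisation failed")
    s2f, s2v, s2u = unpack(res.x)
    # recover the profiled intercept at the optimum
    A = B = 0.0
    for idx in blocks:
        V = s2v * (cd[idx][:, None] == cd[idx][None, :]) + s2f
        V = V + np.diag(d[idx] + s2u)
        cf = cho_factor(V, lower=True)
        A += cho_solve(cf, np.ones(len(idx))).sum()
        B += cho_solve(cf, z[idx]).sum()
    beta0 = B / A
    # treat tiny boundary solutions as zero
    floor = 1e-4
    return float(beta0), (
        s2f if s2f > floor else 0.0,
        s2v if s2v > floor else 0.0,
        max(s2u, floor),
    )


def _blup(z, d, cd, ds, beta0, theta):
    """Joint BLUPs of (u, v, f) per state block by solving the mixed-model equations."""
    s2f, s2v, s2u = theta
    J = len(z)
    K = int(cd.max()) + 1
    L = int(ds.max()) + 1
    u = np.zeros(J)
    v = np.zeros(K)
    f = np.zeros(L)
    for l, idx in enumerate(_state_blocks(cd, ds)):
        m = len(idx)
        r = z[idx] - beta0
        winv = 1.0 / d[idx]
        cols = []
        ginv = []
        # community effects
        if s2u > 0:
            Zu = np.eye(m)
            cols.append(Zu)
            ginv.extend([1.0 / s2u] * m)
        dist_local, dist_inv = np.unique(cd[idx], return_inverse=True)
        if s2v > 0:
            Zv = np.zeros((m, len(dist_local)))
            Zv[np.arange(m), dist_inv] = 1.0
            cols.append(Zv)
            ginv.extend([1.0 / s2v] * len(dist_local))
        if s2f > 0:
            cols.append(np.ones((m, 1)))
            ginv.append(1.0 / s2f)
        if not cols:
            continue
        Z = np.hstack(cols)
        A = (Z.T * winv) @ Z + np.diag(ginv)
        b = np.linalg.solve(A, (Z.T * winv) @ r)
        pos = 0
        if s2u > 0:
            u[idx] = b[pos : pos + m]
            pos += m
        if s2v > 0:
            v[dist_local] = b[pos : pos + len(dist_local)]
            pos += len(dist_local)
        if s2f > 0:
            f[l] = b[pos]
    return u, v, f


def _moment_start(z, d, cd, ds, active_v, active_f):
    """ANOVA-type moment decomposition of the working response (fallback)."""
    beta0 = float(np.mean(z))
    dist_means = np.array([z[cd == k].mean() for k in range(int(cd.max()) + 1)])
    state_means = np.array([dist_means[ds == l].mean() for l in range(int(ds.max()) + 1)])
    s2f = float(np.var(state_means, ddof=1)) if active_f and len(state_means) > 1 else 0.0
    s2v = (
        float(np.var(dist_means - state_means[ds], ddof=1)) if active_v and len(dist_means) > 1 else 0.0
    )
    s2u = float(max(np.var(z - dist_means[cd], ddof=1) - np.mean(d), 0.01))
    return beta0, (max(s2f, 0.0), max(s2v, 0.0), s2u)


# ---------------------------------------------------------------------------
# MCMC


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration.

    Defaults mirror the study's stated run: burn-in 500, monitored 5000.
    Priors: improper flat on the intercept, inverse-gamma(prior_shape,
    prior_scale) on each variance (default 0.001/0.001, i.e. close to
    log-uniform). If ``init_as_prior`` the quasi-likelihood estimates are
    turned into weakly informative inverse-gamma priors (prior mean at the
    starting value, shape 3); otherwise they only set the chain's start.
    """

    burnin: int = 500
    monitor: int = 5000
    seed: int = 0
    thinning: int = 1
    prior_shape: float = 0.001
    prior_scale: float = 0.001
    init_as_prior: bool = False

    def validate(self) -> None:
        if self.burnin < 0 or self.monitor < 1 or self.thinning < 1:
            raise ValueError("burnin >= 0, monitor >= 1 and thinning >= 1 required")
        if self.monitor < 100:
            warnings.warn(
                f"monitoring only {self.monitor} iterations; posterior summaries "
                "will be noisy",
                stacklevel=2,
            )


@dataclass
class Summary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_chain(cls, x: np.ndarray) -> "Summary":
        return cls(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            ci_low=float(np.percentile(x, 2.5)),
            ci_high=float(np.percentile(x, 97.5)),
        )

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "ci_low": self.ci_low, "ci_high": self.ci_high}


@dataclass
class VarianceComponents:
    """Posterior summaries of the three latent-scale geographic variances."""

    sigma2_state: Summary
    sigma2_district: Summary
    sigma2_community: Summary

    def means(self) -> tuple[float, float, float]:
        return (
            self.sigma2_state.mean,
            self.sigma2_district.mean,
            self.sigma2_community.mean,
        )


@dataclass
class ModelFit:
    """Posterior of the four-level model: intercept, variances, all residuals."""

    beta0: Summary
    variances: VarianceComponents
    residuals: dict[str, pd.DataFrame]  # level -> (label, post_mean, post_sd)
    chains: dict[str, np.ndarray]
    index: NestedIndex
    settings: MCMCSettings
    start: StartingValues
    acceptance: dict[str, float]
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "beta0": self.beta0.as_dict(),
            "sigma2_state": self.variances.sigma2_state.as_dict(),
            "sigma2_district": self.variances.sigma2_district.as_dict(),
            "sigma2_community": self.variances.sigma2_community.as_dict(),
            "settings": {
                "burnin": self.settings.burnin,
                "monitor": self.settings.monitor,
                "seed": self.settings.seed,
                "thinning": self.settings.thinning,
            },
            "acceptance": self.acceptance,
            "diagnostics": self.diagnostics,
            "residuals": {
                level: df.to_dict(orient="list") for level, df in self.residuals.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_mcmc(
    records: pd.DataFrame,
    index: NestedIndex,
    settings: MCMCSettings | None = None,
    outcome: str = "y",
    start: StartingValues | None = None,
) -> ModelFit:
    """Sample the posterior of the four-level random-intercept logit.

    Degenerate levels (a single district or a single state) have their
    variance fixed at zero with a logged warning, which reduces the model to
    three (or two) levels. A fixed seed yields identical draws.
    """
    settings = settings or MCMCSettings()
    settings.validate()
    if start is None:
        try:
            start = init_quasilikelihood(records, index, outcome=outcome)
        except SeparationError:
            raise
    y_j, n_j = _collapse(records, index, outcome)
    cd = index.community_district
    ds = index.district_state
    cs = ds[cd]
    J, K, L = index.n_communities, index.n_districts, index.n_states
    active_v = K > 1
    active_f = L > 1
    if not active_v:
        logger.warning("single district: sigma2_district fixed at 0")
    if not active_f:
        logger.warning("single state: sigma2_state fixed at 0")

    rng = np.random.default_rng(settings.seed)
    a0, b0 = settings.prior_shape, settings.prior_scale
    priors = {"community": (a0, b0), "district": (a0, b0), "state": (a0, b0)}
    if settings.init_as_prior:
        for name, s2 in (
            ("community", start.sigma2_community),
            ("district", start.sigma2_district),
            ("state", start.sigma2_state),
        ):
            s2 = max(s2, 0.01)
            priors[name] = (3.0, 2.0 * s2)  # prior mean = scale/(shape-1) = s2

    beta0 = start.beta0
    s2u = max(start.sigma2_community, 1e-3)
    s2v = max(start.sigma2_district, 1e-3) if active_v else 0.0
    s2f = max(start.sigma2_state, 1e-3) if active_f else 0.0
    u = np.zeros(J)
    v = np.zeros(K)
    f = np.zeros(L)
    eta = np.full(J, beta0)

    scales = {"u": 0.5, "v": 0.5, "f": 0.5, "b": 0.1, "t1": 0.2, "t2": 0.2, "t3": 0.2}
    acc_count = {k: 0.0 for k in scales}
    prop_count = {k: 0.0 for k in scales}

    n_iter = settings.burnin + settings.monitor
    kept = settings.monitor // settings.thinning
    chains = {
        "beta0": np.empty(kept),
        "sigma2_community": np.empty(kept),
        "sigma2_district": np.empty(kept),
        "sigma2_state": np.empty(kept),
    }
    sums = {"u": np.zeros(J), "v": np.zeros(K), "f": np.zeros(L)}
    sqsums = {"u": np.zeros(J), "v": np.zeros(K), "f": np.zeros(L)}
    n_kept = 0

    ll_eta = y_j * eta - n_j * _log1pexp(eta)

    def adapt(key, rate, t):
        step = min(0.25, 2.0 / np.sqrt(t + 1.0))
        scales[key] = float(np.clip(scales[key] * np.exp(step * (rate - 0.44)), 1e-4, 20.0))

    for t in range(n_iter):
        adapting = t < settings.burnin

        # community residuals (element-wise RW Metropolis)
        prop = scales["u"] * rng.standard_normal(J)
        eta_new = eta + prop
        ll_new = y_j * eta_new - n_j * _log1pexp(eta_new)
        logacc = (ll_new - ll_eta) - ((u + prop) ** 2 - u**2) / (2 * s2u)
        acc = np.log(rng.random(J)) < logacc
        u += prop * acc
        eta += prop * acc
        ll_eta = np.where(acc, ll_new, ll_eta)
        if adapting:
            adapt("u", acc.mean(), t)

        # district residuals
        if active_v:
            delta = scales["v"] * rng.standard_normal(K)
            prop_j = delta[cd]
            eta_new = eta + prop_j
            ll_new = y_j * eta_new - n_j * _log1pexp(eta_new)
            dll_k = np.bincount(cd, weights=ll_new - ll_eta, minlength=K)
            logacc = dll_k - ((v + delta) ** 2 - v**2) / (2 * s2v)
            acc_k = np.log(rng.random(K)) < logacc
            v += delta * acc_k
            move = (delta * acc_k)[cd]
            eta += move
            upd = acc_k[cd]
            ll_eta = np.where(upd, ll_new, ll_eta)
            if adapting:
                adapt("v", acc_k.mean(), t)

        # state residuals
        if active_f:
            delta = scales["f"] * rng.standard_normal(L)
            prop_j = delta[cs]
            eta_new = eta + prop_j
            ll_new = y_j * eta_new - n_j * _log1pexp(eta_new)
            dll_l = np.bincount(cs, weights=ll_new - ll_eta, minlength=L)
            logacc = dll_l - ((f + delta) ** 2 - f**2) / (2 * s2f)
            acc_l = np.log(rng.random(L)) < logacc
            f += delta * acc_l
            eta += (delta * acc_l)[cs]
            upd = acc_l[cs]
            ll_eta = np.where(upd, ll_new, ll_eta)
            if adapting:
                adapt("f", acc_l.mean(), t)

        # intercept (flat prior)
        d0 = scales["b"] * rng.standard_normal()
        eta_new = eta + d0
        ll_new = y_j * eta_new - n_j * _log1pexp(eta_new)
        if np.log(rng.random()) < ll_new.sum() - ll_eta.sum():
            beta0 += d0
            eta = eta_new
            ll_eta = ll_new
            if adapting:
                adapt("b", 1.0, t)
        elif adapting:
            adapt("b", 0.0, t)

        # translation moves (likelihood-invariant level-mean exchanges)
        top = f if active_f else (v if active_v else u)
        top_s2 = s2f if active_f else (s2v if active_v else s2u)
        d1 = scales["t1"] * rng.standard_normal()
        logacc = -(np.sum((top - d1) ** 2) - np.sum(top**2)) / (2 * top_s2)
        if np.log(rng.random()) < logacc:
            beta0 += d1
            top -= d1
            if adapting:
                adapt("t1", 1.0, t)
        elif adapting:
            adapt("t1", 0.0, t)

        if active_f and active_v:
            dl = scales["t2"] * rng.standard_normal(L)
            pen_f = ((f + dl) ** 2 - f**2) / (2 * s2f)
            v_shift = dl[ds]
            pen_v = np.bincount(ds, weights=((v - v_shift) ** 2 - v**2), minlength=L) / (2 * s2v)
            acc_l = np.log(rng.random(L)) < -(pen_f + pen_v)
            f += dl * acc_l
            v -= (dl * acc_l)[ds]
            if adapting:
                adapt("t2", acc_l.mean(), t)
        if active_v:
            dk = scales["t3"] * rng.standard_normal(K)
            pen_v = ((v + dk) ** 2 - v**2) / (2 * s2v)
            u_shift = dk[cd]
            pen_u = np.bincount(cd, weights=((u - u_shift) ** 2 - u**2), minlength=K) / (2 * s2u)
            acc_k = np.log(rng.random(K)) < -(pen_v + pen_u)
            v += dk * acc_k
            u -= (dk * acc_k)[cd]
            if adapting:
                adapt("t3", acc_k.mean(), t)

        # conjugate variance updates
        a, b = priors["community"]
        s2u = 1.0 / rng.gamma(a + J / 2.0, 1.0 / (b + 0.5 * np.sum(u**2)))
        if active_v:
            a, b = priors["district"]
            s2v = 1.0 / rng.gamma(a + K / 2.0, 1.0 / (b + 0.5 * np.sum(v**2)))
        if active_f:
            a, b = priors["state"]
            s2f = 1.0 / rng.gamma(a + L / 2.0, 1.0 / (b + 0.5 * np.sum(f**2)))

        if not adapting:
            k = t - settings.burnin
            if k % settings.thinning == 0 and n_kept < kept:
                chains["beta0"][n_kept] = beta0
                chains["sigma2_community"][n_kept] = s2u
                chains["sigma2_district"][n_kept] = s2v
                chains["sigma2_state"][n_kept] = s2f
                sums["u"] += u
                sqsums["u"] += u**2
                sums["v"] += v
                sqsums["v"] += v**2
                sums["f"] += f
                sqsums["f"] += f**2
                n_kept += 1

    if not np.isfinite(ll_eta).all():
        raise RuntimeError(
            f"non-finite likelihood at end of sampling; state: beta0={beta0}, "
            f"s2=({s2f}, {s2v}, {s2u})"
        )

    def resid_frame(level_key, labels):
        m = sums[level_key] / n_kept
        var = np.maximum(sqsums[level_key] / n_kept - m**2, 0.0)
        return pd.DataFrame({"label": labels, "post_mean": m, "post_sd": np.sqrt(var)})

    fit = ModelFit(
        beta0=Summary.from_chain(chains["beta0"]),
        variances=VarianceComponents(
            sigma2_state=Summary.from_chain(chains["sigma2_state"]),
            sigma2_district=Summary.from_chain(chains["sigma2_district"]),
            sigma2_community=Summary.from_chain(chains["sigma2_community"]),
        ),
        residuals={
            "community": resid_frame("u", index.community_labels),
            "district": resid_frame("v", index.district_labels),
            "state": resid_frame("f", index.state_labels),
        },
        chains=chains,
        index=index,
        settings=settings,
        start=start,
        acceptance={k: float(scales[k]) for k in scales},
    )
    return fit


# ---------------------------------------------------------------------------
# diagnostics


def diagnose(fit: ModelFit) -> dict:
    """Effective sample size and split-chain convergence per scalar parameter.

    Constant chains are flagged (ESS undefined) rather than raising. The
    result is stored on ``fit.diagnostics`` and returned.
    """
    import arviz as az

    report: dict[str, dict] = {}
    for name, chain in fit.chains.items():
        chain = np.asarray(chain, dtype=float)
        entry: dict = {"n_draws": int(chain.size)}
        if chain.size < 4 or np.std(chain) == 0.0:
            entry.update(ess=None, rhat=None, flag="constant-or-too-short")
        else:
            entry["ess"] = float(az.ess(chain[None, :]))
            half = chain.size // 2
            entry["rhat"] = float(az.rhat(chain[: 2 * half].reshape(2, half)))
            entry["flag"] = None
        report[name] = entry
    fit.diagnostics = report
    return report
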