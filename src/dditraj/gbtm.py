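"""Censored-normal group-based trajectory model (GBTM).

The model: each subject i belongs to one of G latent groups; conditional on
group g, the biomarker at day t is a polynomial mean curve plus Gaussian
noise, observed only within detection bounds [lo, hi].  Values recorded at a
bound contribute tail probability mass (Tobit likelihood) instead of
density.  Group membership probabilities pi_g are the mixing proportions of
the finite mixture; occasions are conditionally independent given group.

Estimation is maximum likelihood by an expectation-maximisation scheme with
two layers of latent data: the group labels and, for bound-valued
observations, the latent uncensored measurements.  Both E-step expectations
are available in closed form (posterior responsibilities; truncated-normal
moments), so every M-step is a set of weighted least-squares solves — no
inner numerical optimisation — and the observed-data log-likelihood is
non-decreasing across iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp
from sklearn.cluster import KMeans

from dditraj.errors import ValidationError

logger = logging.getLogger(__name__)

_MAX_ORDER = 4
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(z):
    return -0.5 * z * z - _LOG_SQRT_2PI


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Panel:
    """Long-format measurement panel in array form.

    ``ids`` holds one entry per subject; ``day``/``value`` are flat
    observation arrays and ``subject_index[j]`` maps observation j to its
    subject's position in ``ids``.
    """

    ids: np.ndarray
    day: np.ndarray
    value: np.ndarray
    subject_index: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return len(self.value)

    @classmethod
    def from_long(cls, df: pd.DataFrame, id_col: str = "patient_id",
                  day_col: str = "day", value_col: str = "value") -> "Panel":
        for col in (id_col, day_col, value_col):
            if col not in df.columns:
                raise ValidationError(f"measurement table lacks column {col!r}")
        if len(df) == 0:
            raise ValidationError("empty measurement table")
        df = df.sort_values([id_col, day_col], kind="mergesort")
        ids, idx = np.unique(df[id_col].to_numpy(), return_inverse=True)
        return cls(
            ids=ids,
            day=df[day_col].to_numpy(dtype=float),
            value=df[value_col].to_numpy(dtype=float),
            subject_index=idx.astype(np.int64),
        )


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Structural specification: group count, polynomial orders, bounds.

    Time enters the polynomials as day / ``time_scale`` (default 10) for
    numerical conditioning; coefficients are reported on the scaled axis by
    :class:`GbtmParams` and on the per-day axis via
    :meth:`GbtmParams.beta_per_day`.
    """

    n_groups: int
    poly_orders: tuple[int, ...]
    censor_lo: float = 0.0
    censor_hi: float = 40.0
    time_scale: float = 10.0

    def __post_init__(self):
        if not 1 <= self.n_groups <= 6:
            raise ValidationError(f"n_groups must be in 1..6, got {self.n_groups}")
        if len(self.poly_orders) != self.n_groups:
            raise ValidationError("poly_orders length must equal n_groups")
        if any(o not in (2, 3, 4) for o in self.poly_orders):
            raise ValidationError("polynomial orders must be 2, 3 or 4")
        if not self.censor_lo < self.censor_hi:
            raise ValidationError("censor_lo must be < censor_hi")
        if self.time_scale <= 0:
            raise ValidationError("time_scale must be positive")

    @property
    def n_params(self) -> int:
        # per-group coefficients + free mixing proportions + shared sigma
        return sum(o + 1 for o in self.poly_orders) + (self.n_groups - 1) + 1


@dataclass(frozen=True)
class GbtmParams:
    """Mixture parameters: per-group coefficients, shared sigma, proportions."""

    beta: tuple[np.ndarray, ...]
    sigma: float
    pi: np.ndarray

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValidationError("pi must be non-negative and sum to 1")
        if len(self.beta) != len(pi):
            raise ValidationError("beta and pi must have equal length")

    def beta_per_day(self, time_scale: float) -> tuple[np.ndarray, ...]:
        """Coefficients re-expressed for time in raw days."""
        return tuple(
            b / time_scale ** np.arange(len(b)) for b in self.beta
        )


@dataclass
class GbtmFit:
    """A fitted trajectory model with classification diagnostics."""

    spec: TrajectorySpec
    params: GbtmParams
    loglik: float
    posterior: np.ndarray          # n_subjects x G, rows sum to 1
    assignment: np.ndarray         # modal group per subject (0-based)
    bic: float
    entropy: float
    appa: np.ndarray               # per group; NaN for empty groups
    group_props: np.ndarray        # assigned-membership fractions
    n_params: int
    converged: bool
    n_starts: int
    seed: int | None
    n_iter: int = 0
    warnings: list[str] = field(default_factory=list)
    start_logliks: list[float] = field(default_factory=list)
    loglik_trace: np.ndarray | None = None
    ids: np.ndarray | None = None


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------

def censored_normal_logdensity(y, mu, sigma, lo, hi):
    """Log density/mass of a normal observed subject to censoring at [lo, hi].

    Interior values contribute the normal log-density; a value exactly at
    ``lo`` contributes log Phi((lo-mu)/sigma) and a value exactly at ``hi``
    contributes the upper-tail log mass log(1 - Phi((hi-mu)/sigma)).  All
    branches are evaluated in log space so the result is finite for any
    finite mu.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValidationError("sigma must be positive")
    if not lo < hi:
        raise ValidationError("censor_lo must be < censor_hi")
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape) if y.shape else mu
    z = (y - mu) / sigma
    out = -0.5 * z * z - _LOG_SQRT_2PI - np.log(sigma)
    out = np.where(y <= lo, log_ndtr((lo - mu) / sigma), out)
    out = np.where(y >= hi, log_ndtr(-(hi - mu) / sigma), out)
    return out if out.shape else float(out)


def _design(day: np.ndarray, order: int, time_scale: float) -> np.ndarray:
    t = day / time_scale
    return np.vander(t, order + 1, increasing=True)


def _subject_group_logliks(panel: Panel, spec: TrajectorySpec,
                           params: GbtmParams) -> np.ndarray:
    """n_subjects x G matrix of conditional log-likelihoods log L_ig."""
    G = spec.n_groups
    n = panel.n_subjects
    out = np.zeros((n, G))
    for g in range(G):
        Xg = _design(panel.day, spec.poly_orders[g], spec.time_scale)
        mu = Xg @ params.beta[g]
        ll_obs = censored_normal_logdensity(
            panel.value, mu, params.sigma, spec.censor_lo, spec.censor_hi)
        out[:, g] = np.bincount(panel.subject_index, weights=ll_obs, minlength=n)
    return out


def mixture_loglik(panel: Panel, spec: TrajectorySpec, params: GbtmParams) -> float:
    """Observed-data log-likelihood of the censored-normal mixture.

    Sum over subjects of log sum_g pi_g * prod_t f(y_it | beta_g, sigma),
    evaluated with log-sum-exp.
    """
    if panel.n_obs == 0:
        raise ValidationError("empty panel")
    ll_ig = _subject_group_logliks(panel, spec, params)
    return float(logsumexp(ll_ig + np.log(params.pi), axis=1).sum())


def posterior_probabilities(panel: Panel, spec: TrajectorySpec,
                            params: GbtmParams) -> np.ndarray:
    """Posterior probability of group membership, one row per subject."""
    ll_ig = _subject_group_logliks(panel, spec, params)
    logpost = ll_ig + np.log(params.pi)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return np.exp(logpost)


def assign_groups(posterior: np.ndarray) -> np.ndarray:
    """Modal assignment; ties resolve to the lowest group index."""
    posterior = np.asarray(posterior)
    labels = np.argmax(posterior, axis=1)
    row_max = posterior[np.arange(len(labels)), labels]
    n_tied = int(np.sum(np.isclose(posterior, row_max[:, None]).sum(axis=1) > 1))
    if n_tied:
        logger.info("assign_groups: %d tied rows resolved to lowest index", n_tied)
    return labels


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def bic(loglik: float, k: int, n_subjects: int) -> float:
    """Penalised log-likelihood, larger-is-better orientation.

    BIC = loglik - (k/2) ln(n); model comparison maximises this quantity,
    which is equivalent to minimising the classical -2*loglik + k*ln(n).
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    return float(loglik - 0.5 * k * np.log(n_subjects))


def entropy(posterior: np.ndarray) -> float:
    """Relative entropy of the classification, 1 = crisp, 0 = uninformative.

    E = 1 - [-sum_i sum_g p_ig ln p_ig] / (n ln G), with 0 ln 0 := 0.
    """
    posterior = np.asarray(posterior, dtype=float)
    n, G = posterior.shape
    if G == 1:
        logger.info("entropy of a one-group model is 1.0 by convention")
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(posterior > 0, posterior * np.log(posterior), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(G)))


def appa(posterior: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Average posterior probability of assignment per group.

    APPA_g averages p_ig over subjects assigned to g; empty groups yield NaN.
    """
    posterior = np.asarray(posterior, dtype=float)
    labels = np.asarray(labels)
    G = posterior.shape[1]
    out = np.full(G, np.nan)
    for g in range(G):
        mask = labels == g
        if mask.any():
            out[g] = posterior[mask, g].mean()
        else:
            logger.warning("appa: group %d has no assigned members", g + 1)
    return out


def predict_mean_curves(params: GbtmParams, spec: TrajectorySpec,
                        days: np.ndarray | None = None,
                        panel: Panel | None = None,
                        assignment: np.ndarray | None = None) -> pd.DataFrame:
    """Per-group latent mean curves, clipped to the censoring bounds.

    When a panel and its assignment are supplied the table also carries the
    day-wise observed group means with pointwise normal-theory 95% bands.
    """
    if days is None:
        days = np.arange(51)
    days = np.asarray(days, dtype=float)
    frames = []
    for g in range(spec.n_groups):
        X = _design(days, spec.poly_orders[g], spec.time_scale)
        latent = X @ params.beta[g]
        clipped = np.clip(latent, spec.censor_lo, spec.censor_hi)
        if np.any(latent != clipped):
            logger.info("group %d mean curve clipped to bounds for display", g + 1)
        frames.append(pd.DataFrame({
            "group": g + 1, "day": days, "mean": clipped, "latent_mean": latent,
        }))
    out = pd.concat(frames, ignore_index=True)
    if panel is not None and assignment is not None:
        obs = pd.DataFrame({
            "group": np.asarray(assignment)[panel.subject_index] + 1,
            "day": panel.day,
            "value": panel.value,
        })
        summ = (obs.groupby(["group", "day"])["value"]
                   .agg(obs_mean="mean", obs_sd="std", obs_n="count")
                   .reset_index())
        half = 1.96 * summ["obs_sd"] / np.sqrt(summ["obs_n"])
        summ["obs_lo"] = summ["obs_mean"] - half
        summ["obs_hi"] = summ["obs_mean"] + half
        out = out.merge(summ, on=["group", "day"], how="left")
    return out


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------

def _censored_moments(value, mu, sigma, lo, hi):
    """First and second conditional moments of the latent uncensored value.

    Interior observations are their own moments.  For an observation at the
    upper bound the latent value is normal truncated to [hi, inf); at the
    lower bound, to (-inf, lo].  Hazard ratios are computed via log pdf/cdf
    differences for tail stability.
    """
    m1 = value.copy()
    m2 = value ** 2
    at_hi = value >= hi
    at_lo = value <= lo
    if at_hi.any():
        a = (hi - mu[at_hi]) / sigma
        lam = np.exp(_norm_logpdf(a) - log_ndtr(-a))
        e = mu[at_hi] + sigma * lam
        v = sigma ** 2 * np.clip(1.0 + a * lam - lam ** 2, 0.0, None)
        m1[at_hi] = e
        m2[at_hi] = v + e ** 2
    if at_lo.any():
        b = (lo - mu[at_lo]) / sigma
        h = np.exp(_norm_logpdf(b) - log_ndtr(b))
        e = mu[at_lo] - sigma * h
        v = sigma ** 2 * np.clip(1.0 - b * h - h ** 2, 0.0, None)
        m1[at_lo] = e
        m2[at_lo] = v + e ** 2
    return m1, m2


def _m_step(panel: Panel, spec: TrajectorySpec, params: GbtmParams,
            post: np.ndarray) -> GbtmParams:
    """Closed-form conditional M-step given responsibilities ``post``."""
    G = spec.n_groups
    w_obs = post[panel.subject_index, :]          # n_obs x G
    new_beta = []
    sse = 0.0
    designs = []
    for g in range(G):
        Xg = _design(panel.day, spec.poly_orders[g], spec.time_scale)
        designs.append(Xg)
        mu = Xg @ params.beta[g]
        m1, m2 = _censored_moments(panel.value, mu, params.sigma,
                                   spec.censor_lo, spec.censor_hi)
        w = w_obs[:, g]
        XtW = Xg.T * w
        beta_g, *_ = np.linalg.lstsq(XtW @ Xg, XtW @ m1, rcond=None)
        new_beta.append(beta_g)
        mu_new = Xg @ beta_g
        sse += float(np.sum(w * (m2 - 2.0 * m1 * mu_new + mu_new ** 2)))
    sigma_new = float(np.sqrt(max(sse / panel.n_obs, 1e-12)))
    pi_new = post.mean(axis=0)
    pi_new = np.clip(pi_new, 1e-12, None)
    pi_new /= pi_new.sum()
    return GbtmParams(beta=tuple(new_beta), sigma=sigma_new, pi=pi_new)


def _subject_features(panel: Panel) -> np.ndarray:
    """Per-subject summary features used by the k-means initialiser."""
    n = panel.n_subjects
    feats = np.zeros((n, 3))
    for i in range(n):
        mask = panel.subject_index == i
        d, v = panel.day[mask], panel.value[mask]
        feats[i, 0] = v.mean()
        early = d <= 5
        if early.sum() >= 2 and np.ptp(d[early]) > 0:
            feats[i, 1] = np.polyfit(d[early], v[early], 1)[0]
        feats[i, 2] = v.max()
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    return (feats - feats.mean(axis=0)) / sd


def _initial_params(panel: Panel, spec: TrajectorySpec, labels: np.ndarray
                    ) -> GbtmParams:
    """Parameters from hard initial labels: per-group OLS, pooled sigma."""
    G = spec.n_groups
    betas, resid_ss = [], 0.0
    for g in range(G):
        mask = labels[panel.subject_index] == g
        if mask.sum() <= max(spec.poly_orders) + 1:
            mask = np.ones(panel.n_obs, dtype=bool)   # degenerate start
        Xg = _design(panel.day[mask], spec.poly_orders[g], spec.time_scale)
        beta_g, *_ = np.linalg.lstsq(Xg, panel.value[mask], rcond=None)
        betas.append(beta_g)
        resid_ss += float(np.sum((panel.value[mask] - Xg @ beta_g) ** 2))
    sigma = float(np.sqrt(max(resid_ss / panel.n_obs, 1e-6)))
    counts = np.bincount(labels, minlength=G).astype(float)
    counts = np.clip(counts, 1.0, None)
    return GbtmParams(beta=tuple(betas), sigma=sigma, pi=counts / counts.sum())


def _relabel_ascending(spec: TrajectorySpec, params: GbtmParams) -> np.ndarray:
    """Permutation putting groups in ascending mean fitted level, days 0-10."""
    days = np.arange(11, dtype=float)
    levels = []
    for g in range(spec.n_groups):
        X = _design(days, spec.poly_orders[g], spec.time_scale)
        levels.append(float(np.mean(X @ params.beta[g])))
    return np.argsort(levels, kind="stable")


def fit_gbtm(panel: Panel, spec: TrajectorySpec, n_starts: int = 20,
             max_iter: int = 500, tol: float = 1e-6,
             seed: int | None = None,
             init_params: GbtmParams | None = None) -> GbtmFit:
    """Fit the censored-normal GBTM by multi-start EM.

    Start 1 initialises from k-means on per-subject summary features
    (mean, early slope, max); the remaining starts use random hard
    assignments.  The best start by log-likelihood is kept.  An explicit
    ``init_params`` adds a warm start (useful when refining shapes around a
    previously fitted model).  After fitting, groups are relabelled in
    ascending order of mean fitted level over days 0-10 so that group 1 is
    the lowest trajectory for every seed.
    """
    if panel.n_obs == 0:
        raise ValidationError("cannot fit an empty panel")
    if panel.n_subjects < spec.n_groups:
        raise ValidationError("need at least as many subjects as groups")
    rng = np.random.default_rng(seed)
    G = spec.n_groups

    starts: list[GbtmParams] = []
    if init_params is not None:
        starts.append(init_params)
    if G == 1:
        starts.append(_initial_params(panel, spec, np.zeros(panel.n_subjects, int)))
    else:
        feats = _subject_features(panel)
        km = KMeans(n_clusters=G, n_init=5,
                    random_state=int(rng.integers(2 ** 31)))
        starts.append(_initial_params(panel, spec, km.fit_predict(feats)))
        while len(starts) < n_starts + (init_params is not None):
            labels = rng.integers(G, size=panel.n_subjects)
            starts.append(_initial_params(panel, spec, labels))

    best = None
    start_logliks = []
    fit_warnings: list[str] = []
    for params in starts:
        cur_spec = spec
        ll_prev = -np.inf
        converged = False
        it = 0
        trace: list[float] = []
        for it in range(1, max_iter + 1):
            post = posterior_probabilities(panel, cur_spec, params)
            # prune components that collapsed below one subject of mass
            weak = params.pi < 1.0 / panel.n_subjects
            if weak.any() and cur_spec.n_groups > 1:
                keep = ~weak
                msg = (f"pruned {int(weak.sum())} degenerate component(s) "
                       f"with pi < 1/n")
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
                fit_warnings.append(msg)
                cur_spec = TrajectorySpec(
                    n_groups=int(keep.sum()),
                    poly_orders=tuple(o for o, k in
                                      zip(cur_spec.poly_orders, keep) if k),
                    censor_lo=cur_spec.censor_lo, censor_hi=cur_spec.censor_hi,
                    time_scale=cur_spec.time_scale)
                pi = params.pi[keep]
                params = GbtmParams(
                    beta=tuple(b for b, k in zip(params.beta, keep) if k),
                    sigma=params.sigma, pi=pi / pi.sum())
                post = posterior_probabilities(panel, cur_spec, params)
            params = _m_step(panel, cur_spec, params, post)
            ll = mixture_loglik(panel, cur_spec, params)
            trace.append(ll)
            if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * abs(ll_prev):
                ll_prev = ll
                converged = True
                break
            ll_prev = ll
        start_logliks.append(ll_prev)
        if best is None or ll_prev > best[0]:
            best = (ll_prev, params, cur_spec, converged, it, np.array(trace))

    loglik, params, fitted_spec, converged, n_iter, best_trace = best
    if not converged:
        msg = f"EM did not converge within {max_iter} iterations"
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        fit_warnings.append(msg)

    # canonical ordering: group 1 = lowest early trajectory
    perm = _relabel_ascending(fitted_spec, params)
    params = GbtmParams(beta=tuple(params.beta[p] for p in perm),
                        sigma=params.sigma, pi=params.pi[perm])
    fitted_spec = TrajectorySpec(
        n_groups=fitted_spec.n_groups,
        poly_orders=tuple(fitted_spec.poly_orders[p] for p in perm),
        censor_lo=fitted_spec.censor_lo, censor_hi=fitted_spec.censor_hi,
        time_scale=fitted_spec.time_scale)

    post = posterior_probabilities(panel, fitted_spec, params)
    labels = assign_groups(post)
    props = np.bincount(labels, minlength=fitted_spec.n_groups) / panel.n_subjects
    k = fitted_spec.n_params
    return GbtmFit(
        spec=fitted_spec,
        params=params,
        loglik=loglik,
        posterior=post,
        assignment=labels,
        bic=bic(loglik, k, panel.n_subjects),
        entropy=entropy(post),
        appa=appa(post, labels),
        group_props=props,
        n_params=k,
        converged=converged,
        n_starts=len(starts),
        seed=seed,
        n_iter=n_iter,
        warnings=fit_warnings,
        start_logliks=start_logliks,
        loglik_trace=best_trace,
        ids=panel.ids,
    )
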