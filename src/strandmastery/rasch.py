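"""Per-strand Rasch model: MML item estimation, MAP person scoring, outfit fit.

The Rasch item response function is

    P(X_ij = 1 | theta_j, b_i) = exp(theta_j - b_i) / (1 + exp(theta_j - b_i)).

Item difficulties are estimated by marginal maximum likelihood with the
latent density fixed at N(0, 1) — the standard Bock–Aitkin EM over a fixed
quadrature grid. Fixing the latent density identifies the scale and makes
the mastery cut theta > 0 the population median. Person abilities are
scored by the posterior mode (MAP) under the same N(0, 1) prior, which is
finite for every response pattern including zero and perfect scores.

Item fit is the outfit mean-square: the average over persons of the squared
standardized residual (X_ij - P_ij)^2 / [P_ij (1 - P_ij)], with expectation
1 under model fit; values outside [0.6, 1.4] are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import norm

__all__ = [
    "RaschFit",
    "fit_rasch_mml",
    "map_theta",
    "rasch_mastery",
    "outfit",
    "marginal_deviance",
    "quadrature_grid",
    "OUTFIT_ACCEPTABLE",
]

#: Acceptable outfit band; items outside it are flagged as misfitting.
OUTFIT_ACCEPTABLE = (0.6, 1.4)


def quadrature_grid(n_nodes: int = 61, bound: float = 6.0):
    """Equally spaced quadrature nodes on [-bound, bound] with renormalized
    standard-normal weights."""
    nodes = np.linspace(-bound, bound, n_nodes)
    weights = norm.pdf(nodes)
    return nodes, weights / weights.sum()


@dataclass
class RaschFit:
    """Fitted per-strand Rasch model."""

    difficulties: np.ndarray
    deviance: float
    n_iterations: int
    converged: bool
    final_change: float
    item_names: list[str] = field(default=None)
    dropped_items: list[int] = field(default_factory=list)
    theta_map: np.ndarray = None
    outfit: np.ndarray = None
    outfit_flags: np.ndarray = None

    def item_table(self) -> pd.DataFrame:
        names = self.item_names or [f"item{i + 1}" for i in range(len(self.difficulties))]
        df = pd.DataFrame({"item": names, "difficulty": self.difficulties})
        if self.outfit is not None:
            df["outfit"] = self.outfit
            df["flagged"] = self.outfit_flags
        return df

    def summary(self) -> dict:
        return {
            "model": "rasch",
            "deviance": float(self.deviance),
            "n_items": int(len(self.difficulties)),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "final_change": float(self.final_change),
            "dropped_items": [int(i) for i in self.dropped_items],
        }


def _pattern_loglik(x: np.ndarray, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Log-likelihood of each person's pattern at each quadrature node.

    Returns an (n_persons, n_nodes) matrix; computed from the sufficient
    structure log P and log(1-P) with a single pair of matrix products.
    """
    logits = nodes[None, :] - b[:, None]  # items x nodes
    log_p = -np.logaddexp(0.0, -logits)
    log_q = -np.logaddexp(0.0, logits)
    return x @ log_p + (1 - x) @ log_q


def marginal_deviance(responses, difficulties, n_nodes: int = 61) -> float:
    """-2 x log marginal likelihood under theta ~ N(0,1), by quadrature."""
    from .containers import as_values

    x = as_values(responses).astype(float)
    b = np.asarray(difficulties, dtype=float)
    nodes, weights = quadrature_grid(n_nodes)
    ll = _pattern_loglik(x, b, nodes)
    return float(-2.0 * logsumexp(ll + np.log(weights)[None, :], axis=1).sum())


def fit_rasch_mml(
    responses,
    n_nodes: int = 61,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> RaschFit:
    """Estimate Rasch difficulties by marginal maximum likelihood (EM).

    E-step: posterior weight of each quadrature node per person.
    M-step: per-item Newton solve of the expected-complete-data score
    equation (a logistic regression in the intercept -b_i with node
    abilities as offsets).

    Items answered all-correct or all-incorrect carry no information about
    their difficulty under MML; they are excluded from estimation with a
    warning and reported as NaN, never silently.
    """
    from .containers import as_values

    x_all = as_values(responses)
    if not np.isin(x_all, (0, 1)).all():
        raise ValueError("responses must be binary")
    x_all = x_all.astype(float)
    n_persons, n_items_all = x_all.shape
    if n_items_all < 2:
        raise ValueError("Rasch MML needs at least 2 items")

    p_obs = x_all.mean(axis=0)
    keep = (p_obs > 0.0) & (p_obs < 1.0)
    dropped = np.flatnonzero(~keep).tolist()
    if dropped:
        warnings.warn(
            f"items {dropped} have zero observed variance and are excluded "
            "from Rasch estimation",
            stacklevel=2,
        )
    x = x_all[:, keep]
    n_items = x.shape[1]
    if n_items < 2:
        raise ValueError("fewer than 2 items with observed variance")

    nodes, weights = quadrature_grid(n_nodes)
    b = -np.log(x.mean(axis=0) / (1.0 - x.mean(axis=0)))  # logit-of-p start

    converged = False
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior over nodes for each person
        ll = _pattern_loglik(x, b, nodes)
        log_post = ll + np.log(weights)[None, :]
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        post = np.exp(log_post)
        n_q = post.sum(axis=0)  # expected persons at node q
        r_iq = x.T @ post  # expected correct per item x node

        # M-step: per-item Newton (2-3 steps suffice; the objective is concave).
        # Root of d(loglik)/db_i = sum_q (N_q P_iq - R_iq); steps clamped for
        # safety far from the optimum.
        b_new = b.copy()
        for _ in range(5):
            p_iq = expit(nodes[None, :] - b_new[:, None])
            grad = (n_q[None, :] * p_iq - r_iq).sum(axis=1)
            curv = (n_q[None, :] * p_iq * (1.0 - p_iq)).sum(axis=1)
            step = np.clip(grad / np.maximum(curv, 1e-12), -2.0, 2.0)
            b_new += step
            if np.abs(step).max() < 0.1 * tol:
                break
        change = float(np.abs(b_new - b).max())
        b = b_new
        if change < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"Rasch EM did not converge in {max_iter} iterations "
            f"(last max |db| = {change:.2e})",
            stacklevel=2,
        )

    deviance = marginal_deviance(x, b, n_nodes)
    b_full = np.full(n_items_all, np.nan)
    b_full[keep] = b

    names = getattr(responses, "item_names", None)
    return RaschFit(
        difficulties=b_full,
        deviance=deviance,
        n_iterations=it,
        converged=converged,
        final_change=change,
        item_names=list(names) if names is not None else None,
        dropped_items=dropped,
    )


def map_theta(responses, difficulties, tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """MAP ability per person: mode of N(0,1)-prior posterior under the Rasch model.

    The log-posterior is strictly concave in theta, so a vectorized Newton
    iteration with step-halving safeguards converges for every response
    pattern; the proper prior keeps zero and perfect scores finite.
    """
    from .containers import as_values

    x = as_values(responses).astype(float)
    b = np.asarray(difficulties, dtype=float)
    used = np.isfinite(b)
    x, b = x[:, used], b[used]

    def grad_hess(theta):
        p = expit(theta[:, None] - b[None, :])
        g = (x - p).sum(axis=1) - theta
        h = -(p * (1.0 - p)).sum(axis=1) - 1.0
        return g, h

    def log_post(theta):
        logits = theta[:, None] - b[None, :]
        ll = (x * -np.logaddexp(0.0, -logits) + (1 - x) * -np.logaddexp(0.0, logits)).sum(axis=1)
        return ll - 0.5 * theta**2

    theta = np.zeros(x.shape[0])
    f = log_post(theta)
    for _ in range(max_iter):
        g, h = grad_hess(theta)
        step = -g / h
        # safeguarded: halve steps that do not improve the log-posterior
        new_theta = theta + step
        new_f = log_post(new_theta)
        for _ in range(30):
            worse = new_f < f - 1e-12
            if not worse.any():
                break
            step = np.where(worse, 0.5 * step, step)
            new_theta = theta + step
            new_f = log_post(new_theta)
        theta, f = new_theta, new_f
        if np.abs(step).max() < tol:
            break
    return theta


def rasch_mastery(theta, cut: float = 0.0) -> np.ndarray:
    """Master iff the ability estimate is strictly above the cut (default 0)."""
    return (np.asarray(theta) > cut).astype(np.int8)


def outfit(responses, theta, difficulties, flag_band=OUTFIT_ACCEPTABLE):
    """Outfit mean-square per item, with flags for values outside the band.

    outfit_i = (1/N) sum_j (X_ij - P_ij)^2 / (P_ij (1 - P_ij)), expectation
    1 under model fit. Cells with numerically degenerate probabilities are
    excluded with a warning.
    """
    from .containers import as_values

    x = as_values(responses).astype(float)
    th = np.asarray(theta, dtype=float)
    b = np.asarray(difficulties, dtype=float)
    if x.shape[0] != th.shape[0] or x.shape[1] != b.shape[0]:
        raise ValueError("responses, theta and difficulties have inconsistent shapes")

    p = expit(th[:, None] - b[None, :])
    ok = (p > 1e-12) & (p < 1.0 - 1e-12)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} person-item cells with degenerate probabilities "
            "excluded from outfit",
            stacklevel=2,
        )
    z2 = np.where(ok, (x - p) ** 2 / np.where(ok, p * (1.0 - p), 1.0), np.nan)
    values = np.nanmean(z2, axis=0)
    lo, hi = flag_band
    flags = (values < lo) | (values > hi)
    return values, flags
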