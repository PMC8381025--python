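"""DINA model: EM estimation over 2^K latent classes, MAP classification, RMSEA fit.

The DINA ("deterministic inputs, noisy AND-gate") model is a conjunctive
latent-class model. Each examinee holds a binary mastery profile alpha over
K attributes; the ideal response to item i is

    eta_ij = prod_k alpha_jk ^ q_ik,

1 only when every attribute the item requires is mastered. Observed
responses deviate through the item's guess and slip probabilities:

    P(X_ij = 1 | eta_ij) = g_i^(1 - eta_ij) * (1 - s_i)^eta_ij.

Estimation is marginal maximum likelihood by EM over the full set of 2^K
profiles with saturated mixing weights pi_c: the E-step computes each
person's posterior over profiles in log space, and the M-step updates g_i,
s_i and pi_c from expected counts in closed form. Persons are classified by
the largest posterior (MAP profile); per-attribute marginal mastery
probabilities are posterior sums over the profiles mastering the attribute.

Item fit is an RMSEA-type index: the pi-weighted root mean square gap
between the model-implied success probability of each latent class and the
posterior-weighted observed proportion correct in that class; values above
0.08 are flagged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import MasteryMatrix, QMatrix, as_values

__all__ = [
    "DinaFit",
    "eta",
    "dina_irf",
    "profile_space",
    "fit_dina_em",
    "dina_posteriors",
    "dina_item_rmsea",
    "RMSEA_ACCEPTABLE",
]

#: Items with RMSEA above this are flagged as misfitting.
RMSEA_ACCEPTABLE = 0.08

_PARAM_FLOOR = 1e-4  # g, s clipped to [floor, 1 - floor]


def eta(alpha, q_row) -> int:
    """Ideal response: 1 iff every attribute required by the item is mastered.

    eta = prod_k alpha_k^{q_k}; an all-zero q row yields 1 (empty product).
    """
    a = np.asarray(alpha)
    q = np.asarray(q_row)
    if a.shape != q.shape:
        raise ValueError("alpha and q_row must have equal length")
    if not (np.isin(a, (0, 1)).all() and np.isin(q, (0, 1)).all()):
        raise ValueError("alpha and q_row must be binary")
    return int(np.all(a >= q))


def dina_irf(eta_val: int, g: float, s: float) -> float:
    """P(X=1 | eta) = 1 - s if eta = 1, else g."""
    if not (0.0 <= g <= 1.0 and 0.0 <= s <= 1.0):
        raise ValueError("guess and slip must lie in [0, 1]")
    return (1.0 - s) if eta_val else g


def profile_space(n_attributes: int) -> np.ndarray:
    """All 2^K binary mastery profiles in lexicographic order (first attribute
    varies slowest): row c is the K-bit big-endian expansion of c."""
    return np.array(list(itertools.product((0, 1), repeat=n_attributes)), dtype=np.int8)


def _eta_matrix(profiles: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Classes x items ideal-response matrix."""
    # eta_ci = 1 iff profile c covers every attribute of item i
    return (profiles @ q.T == q.sum(axis=1)[None, :]).astype(np.int8)


@dataclass
class DinaFit:
    """Fitted DINA model: item parameters, class weights, and diagnostics."""

    guess: np.ndarray
    slip: np.ndarray
    profiles: np.ndarray
    weights: np.ndarray
    deviance: float
    n_iterations: int
    converged: bool
    final_change: float
    q: QMatrix = None
    item_names: list[str] = field(default=None)
    posteriors: np.ndarray = None
    map_profiles: MasteryMatrix = None
    marginal_mastery: np.ndarray = None
    rmsea: np.ndarray = None
    rmsea_flags: np.ndarray = None

    @property
    def n_classes(self) -> int:
        return self.profiles.shape[0]

    def item_table(self) -> pd.DataFrame:
        names = self.item_names or [f"item{i + 1}" for i in range(len(self.guess))]
        df = pd.DataFrame({"item": names, "guess": self.guess, "slip": self.slip})
        if self.rmsea is not None:
            df["rmsea"] = self.rmsea
            df["flagged"] = self.rmsea_flags
        return df

    def summary(self) -> dict:
        return {
            "model": "dina",
            "deviance": float(self.deviance),
            "n_items": int(len(self.guess)),
            "n_classes": int(self.n_classes),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "final_change": float(self.final_change),
        }


def _class_log_probs(x: np.ndarray, eta_ci: np.ndarray, g: np.ndarray, s: np.ndarray):
    """Persons x classes log P(pattern | class), computed in log space."""
    p_ci = np.where(eta_ci == 1, 1.0 - s[None, :], g[None, :])  # classes x items
    log_p = np.log(p_ci)
    log_q = np.log1p(-p_ci)
    return x @ log_p.T + (1.0 - x) @ log_q.T


def fit_dina_em(
    responses,
    q: QMatrix,
    tol: float = 1e-5,
    max_iter: int = 1000,
    g_init: float = 0.2,
    s_init: float = 0.2,
) -> DinaFit:
    """Estimate DINA guess/slip and saturated class weights by EM.

    E-step: posterior over the 2^K profiles per person (log-space, stable
    for long tests). M-step: closed-form expected-count ratios for g_i and
    s_i and the posterior mean for pi_c. Guess and slip are clipped to
    [1e-4, 1 - 1e-4]; monotonicity (g_i < 1 - s_i) is checked and warned
    about but not imposed.
    """
    x = as_values(responses)
    if not np.isin(x, (0, 1)).all():
        raise ValueError("responses must be binary")
    x = x.astype(float)
    if (q.entries.sum(axis=1) == 0).any():
        raise ValueError("every item must require at least one attribute")
    k = q.n_attributes
    if k > 16:
        raise ValueError(f"K={k} attributes would need 2^{k} classes; guard is K <= 16")
    if x.shape[1] != q.n_items:
        raise ValueError("response columns do not match Q-matrix items")

    profiles = profile_space(k)
    eta_ci = _eta_matrix(profiles, q.entries)
    n_persons, n_items = x.shape
    n_classes = profiles.shape[0]

    g = np.full(n_items, float(g_init))
    s = np.full(n_items, float(s_init))
    log_pi = np.full(n_classes, -np.log(n_classes))

    converged = False
    change = np.inf
    it = 0
    eta_f = eta_ci.astype(float)
    for it in range(1, max_iter + 1):
        # E-step
        ll = _class_log_probs(x, eta_ci, g, s)
        log_post = ll + log_pi[None, :]
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        post = np.exp(log_post)

        # M-step: expected counts among eta=1 and eta=0 classes per item
        class_mass = post.sum(axis=0)  # expected persons per class
        correct_ci = x.T @ post  # items x classes expected correct
        n1 = class_mass @ eta_f  # persons facing eta=1, per item
        r1 = (correct_ci * eta_f.T).sum(axis=1)
        n0 = n_persons - n1
        r0 = correct_ci.sum(axis=1) - r1

        g_new = np.clip(r0 / np.maximum(n0, 1e-300), _PARAM_FLOOR, 1.0 - _PARAM_FLOOR)
        s_new = np.clip(1.0 - r1 / np.maximum(n1, 1e-300), _PARAM_FLOOR, 1.0 - _PARAM_FLOOR)
        pi_new = class_mass / n_persons

        change = float(
            max(
                np.abs(g_new - g).max(),
                np.abs(s_new - s).max(),
                np.abs(pi_new - np.exp(log_pi)).max(),
            )
        )
        g, s = g_new, s_new
        log_pi = np.log(np.maximum(pi_new, 1e-300))
        if change < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"DINA EM did not converge in {max_iter} iterations "
            f"(last max parameter change = {change:.2e})",
            stacklevel=2,
        )
    non_monotone = np.flatnonzero(g >= 1.0 - s)
    if non_monotone.size:
        warnings.warn(
            f"items {non_monotone.tolist()} estimated with g >= 1 - s "
            "(non-masters outscore masters); interpret with care",
            stacklevel=2,
        )

    ll = _class_log_probs(x, eta_ci, g, s)
    deviance = float(-2.0 * logsumexp(ll + log_pi[None, :], axis=1).sum())

    names = getattr(responses, "item_names", None)
    fit = DinaFit(
        guess=g,
        slip=s,
        profiles=profiles,
        weights=np.exp(log_pi),
        deviance=deviance,
        n_iterations=it,
        converged=converged,
        final_change=change,
        q=q,
        item_names=list(names) if names is not None else None,
    )
    return fit


def dina_posteriors(responses, fit: DinaFit):
    """Posterior over profiles, MAP profile, and marginal mastery per person.

    posterior_jc is proportional to pi_c * P(pattern_j | profile_c). The MAP
    profile is the argmax row; exact ties resolve to the lowest class index
    (logged). Marginal mastery of attribute k is the posterior mass of the
    profiles with alpha_k = 1. The fit object is updated in place and
    returned.
    """
    x = as_values(responses).astype(float)
    eta_ci = _eta_matrix(fit.profiles, fit.q.entries)
    ll = _class_log_probs(x, eta_ci, fit.guess, fit.slip)
    log_post = ll + np.log(np.maximum(fit.weights, 1e-300))[None, :]
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)

    best = post.argmax(axis=1)
    ties = (post == post[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} persons with tied MAP profiles; "
            "resolved to the lowest class index",
            stacklevel=2,
        )
    fit.posteriors = post
    fit.map_profiles = MasteryMatrix(values=fit.profiles[best])
    fit.marginal_mastery = post @ fit.profiles.astype(float)
    return fit


def dina_item_rmsea(responses, fit: DinaFit, threshold: float = RMSEA_ACCEPTABLE):
    """RMSEA-type item fit: pi-weighted RMS gap between model-implied and
    posterior-weighted observed class success rates.

    RMSEA_i = sqrt( sum_c pi_c (P_i(alpha_c) - Ptilde_ic)^2 ), with
    Ptilde_ic = sum_j posterior_jc X_ij / sum_j posterior_jc. Classes with
    negligible posterior mass are skipped and the weights renormalized.
    The fit object gains ``rmsea`` and ``rmsea_flags`` and is returned.
    """
    if fit.posteriors is None:
        dina_posteriors(responses, fit)
    x = as_values(responses).astype(float)
    post = fit.posteriors
    eta_ci = _eta_matrix(fit.profiles, fit.q.entries)
    p_model = np.where(eta_ci == 1, 1.0 - fit.slip[None, :], fit.guess[None, :])  # classes x items

    mass = post.sum(axis=0)
    occupied = mass > 1e-8
    if not occupied.all():
        warnings.warn(
            f"{int((~occupied).sum())} latent classes with negligible posterior "
            "mass skipped in RMSEA; weights renormalized",
            stacklevel=2,
        )
    p_obs = (x.T @ post)[:, occupied] / mass[None, occupied]  # items x occupied classes
    w = fit.weights[occupied]
    w = w / w.sum()
    gap2 = (p_model[occupied, :].T - p_obs) ** 2
    fit.rmsea = np.sqrt(gap2 @ w)
    fit.rmsea_flags = fit.rmsea > threshold
    return fit
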