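"""Classification accuracy, pairwise consistency, and the simulation engine.

Accuracy of a mastery rule is the exact-match proportion between true and
estimated mastery per attribute — the diagonal sum of the 2x2
(true x observed) contingency table divided by the number of examinees.
Consistency is the same exact-match proportion between two estimated
mastery matrices. ``run_condition`` replicates one design cell: it
generates forms, classifies every examinee with the CTT percent-correct
rule, per-strand Rasch MAP, and joint DINA MAP, and averages per-strand
accuracy over forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import as_values
from .ctt import ctt_subscores, threshold_mastery
from .dina import dina_posteriors, fit_dina_em
from .rasch import fit_rasch_mml, map_theta, rasch_mastery
from .simulate import SimulationCondition, generate_form

__all__ = [
    "AccuracyResult",
    "ConditionResult",
    "accuracy",
    "consistency",
    "score_correlations",
    "classify_form",
    "run_condition",
    "MODELS",
]

MODELS = ("ctt", "rasch", "dina")


@dataclass
class AccuracyResult:
    """Per-attribute 2x2 agreement tables and diagonal proportions."""

    tables: np.ndarray  # attributes x 2 x 2, [true][observed] counts
    accuracy: np.ndarray  # per-attribute proportion in [0, 1]

    @property
    def n_persons(self) -> int:
        return int(self.tables[0].sum())


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"matrices have different shapes: {a.shape} vs {b.shape}")


def accuracy(true, observed) -> AccuracyResult:
    """Agreement of an estimated mastery matrix with the truth, per attribute."""
    t = as_values(true)
    o = as_values(observed)
    _check_same_shape(t, o)
    n_persons, n_attr = t.shape
    tables = np.zeros((n_attr, 2, 2), dtype=int)
    for a in range(2):
        for b in range(2):
            tables[:, a, b] = ((t == a) & (o == b)).sum(axis=0)
    acc = (tables[:, 0, 0] + tables[:, 1, 1]) / n_persons
    return AccuracyResult(tables=tables, accuracy=acc)


def consistency(m_a, m_b) -> np.ndarray:
    """Exact-match proportion between two mastery matrices, per attribute."""
    a = as_values(m_a)
    b = as_values(m_b)
    _check_same_shape(a, b)
    return (a == b).mean(axis=0)


def score_correlations(s_a, s_b) -> np.ndarray:
    """Pearson correlation of two person-score matrices, per attribute column."""
    a = np.asarray(as_values(s_a), dtype=float)
    b = np.asarray(as_values(s_b), dtype=float)
    _check_same_shape(a, b)
    out = np.empty(a.shape[1])
    for k in range(a.shape[1]):
        sda, sdb = a[:, k].std(), b[:, k].std()
        if sda == 0.0 or sdb == 0.0:
            raise ValueError(f"attribute column {k} has zero variance; correlation undefined")
        out[k] = np.corrcoef(a[:, k], b[:, k])[0, 1]
    return out


def classify_form(form, theta_cut: float = 0.0, ctt_cut: float = 0.5):
    """Classify one form's examinees under all three engines.

    Returns ``(mastery, scores)``: two dicts keyed by model name. Mastery
    holds persons x attributes binary matrices; scores holds the person
    estimates behind them (CTT proportion correct, Rasch MAP theta, DINA
    marginal mastery probability).
    """
    q = form.q
    x = form.responses
    n_attr = q.n_attributes

    sub = ctt_subscores(x, q)
    ctt_m = threshold_mastery(sub, cut=ctt_cut).values

    theta = np.empty((x.n_persons, n_attr))
    for k in range(n_attr):
        strand = x.subset_items(q.attribute_items(k))
        fit = fit_rasch_mml(strand)
        theta[:, k] = map_theta(strand, fit.difficulties)
    rasch_m = np.column_stack([rasch_mastery(theta[:, k], cut=theta_cut) for k in range(n_attr)])

    dfit = fit_dina_em(x, q)
    dina_posteriors(x, dfit)
    dina_m = dfit.map_profiles.values

    mastery = {"ctt": ctt_m, "rasch": rasch_m, "dina": dina_m}
    scores = {"ctt": sub, "rasch": theta, "dina": dfit.marginal_mastery}
    return mastery, scores


@dataclass
class ConditionResult:
    """Per-model, per-strand accuracy of one design cell, aggregated over forms."""

    condition: SimulationCondition
    mean_accuracy: dict  # model -> per-strand mean over forms
    sd_accuracy: dict  # model -> per-strand across-form SD
    per_form: dict  # model -> forms x strands matrix
    failed_forms: list

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per model x strand."""
        rows = []
        for model in MODELS:
            for k, size in enumerate(self.condition.strand_sizes):
                rows.append(
                    {
                        "rho": self.condition.rho,
                        "strand": k + 1,
                        "strand_size": size,
                        "model": model,
                        "mean_accuracy": self.mean_accuracy[model][k],
                        "sd_accuracy": self.sd_accuracy[model][k],
                        "n_forms": self.per_form[model].shape[0],
                    }
                )
        return pd.DataFrame(rows)


def run_condition(condition: SimulationCondition) -> ConditionResult:
    """Replicate one design cell: generate ``n_forms`` forms, classify with all
    three engines, and average per-strand accuracy against true mastery.

    A form whose fit raises is recorded in ``failed_forms`` and excluded
    from the averages, never dropped silently.
    """
    per_form = {m: [] for m in MODELS}
    failed = []
    for f in range(condition.n_forms):
        form = generate_form(condition, f)
        try:
            mastery, _ = classify_form(form)
        except Exception as exc:  # pragma: no cover - defensive bookkeeping
            failed.append({"form": f, "error": repr(exc)})
            warnings.warn(f"form {f} failed: {exc!r}", stacklevel=2)
            continue
        for m in MODELS:
            per_form[m].append(accuracy(form.true_mastery, mastery[m]).accuracy)
    per_form = {m: np.array(v) for m, v in per_form.items()}
    mean = {m: per_form[m].mean(axis=0) for m in MODELS}
    sd = {m: per_form[m].std(axis=0, ddof=1) if per_form[m].shape[0] > 1 else np.zeros(condition.n_attributes) for m in MODELS}
    return ConditionResult(
        condition=condition,
        mean_accuracy=mean,
        sd_accuracy=sd,
        per_form=per_form,
        failed_forms=failed,
    )
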