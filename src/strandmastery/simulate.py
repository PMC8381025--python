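"""Synthetic response-data generator for the mastery-classification study.

Responses are generated under a simple-structure multidimensional IRT model:
each item i loads a single attribute k(i) with unit slope, so

    logit P(X_ij = 1) = theta_{j,k(i)} - b_i,

with abilities theta_j drawn multivariate normal (zero mean, unit variances,
common pairwise correlation ``rho``) and difficulties b_i uniform on a
configurable range. True mastery of attribute k is defined as
theta_jk > 0, the population median cut, mirroring the estimated-mastery
rules used downstream.

The default :class:`SimulationCondition` is the factorial study design:
1,000 examinees per form, 50 items per form in four strands of 5/10/15/20
items, difficulties uniform on [-3, 3], 50 replicate forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AbilityMatrix, MasteryMatrix, QMatrix, ResponseMatrix, as_values

__all__ = [
    "SimulationCondition",
    "GeneratedForm",
    "build_simple_q",
    "draw_difficulties",
    "draw_abilities",
    "simulate_responses",
    "true_mastery",
    "generate_form",
    "form_rng",
    "exam_strand_sizes",
]

#: Item counts of the 8 content domains of a 360-item licensing-exam form.
EXAM_STRAND_SIZES = [45, 45, 45, 25, 154, 20, 20, 6]


def exam_strand_sizes(scale: float = 1.0) -> list[int]:
    """Strand sizes of the 8-domain, 360-item exam layout, optionally scaled down.

    ``scale < 1`` shrinks every strand proportionally (minimum 2 items per
    strand) for quick runs that keep the original shape.
    """
    if scale == 1.0:
        return list(EXAM_STRAND_SIZES)
    return [max(2, round(s * scale)) for s in EXAM_STRAND_SIZES]


@dataclass
class SimulationCondition:
    """One cell of the simulation design: a correlation level plus the form layout."""

    n_persons: int = 1000
    strand_sizes: list[int] = field(default_factory=lambda: [5, 10, 15, 20])
    rho: float = 0.0
    difficulty_low: float = -3.0
    difficulty_high: float = 3.0
    n_forms: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.n_forms < 1:
            raise ValueError("n_forms must be >= 1")
        if not self.strand_sizes or any(s < 1 for s in self.strand_sizes):
            raise ValueError("strand_sizes must be a non-empty list of positive counts")
        if self.difficulty_low >= self.difficulty_high:
            raise ValueError("difficulty_low must be below difficulty_high")
        _check_rho(self.rho, len(self.strand_sizes))

    @property
    def n_items(self) -> int:
        return int(sum(self.strand_sizes))

    @property
    def n_attributes(self) -> int:
        return len(self.strand_sizes)


@dataclass
class GeneratedForm:
    """A single simulated test form with its generating truth."""

    difficulties: np.ndarray
    abilities: AbilityMatrix
    q: QMatrix
    responses: ResponseMatrix
    true_mastery: MasteryMatrix


def build_simple_q(strand_sizes: list[int]) -> QMatrix:
    """Block simple-structure Q-matrix: strand k contributes ``strand_sizes[k]``
    consecutive items, each loading attribute k only."""
    if not strand_sizes or any(int(s) < 1 for s in strand_sizes):
        raise ValueError("strand_sizes must be a non-empty list of positive counts")
    sizes = [int(s) for s in strand_sizes]
    n_items, n_attr = sum(sizes), len(sizes)
    entries = np.zeros((n_items, n_attr), dtype=np.int8)
    row = 0
    for k, size in enumerate(sizes):
        entries[row : row + size, k] = 1
        row += size
    return QMatrix(entries=entries)


def draw_difficulties(n_items: int, low: float, high: float, rng: np.random.Generator) -> np.ndarray:
    """Item difficulties b_i ~ Uniform(low, high) on the logit scale."""
    if low >= high:
        raise ValueError("difficulty range must satisfy low < high")
    return rng.uniform(low, high, size=int(n_items))


def _check_rho(rho: float, n_attributes: int) -> None:
    # Compound-symmetric correlation matrix is PD iff -1/(K-1) < rho < 1.
    lower = -1.0 / (n_attributes - 1) if n_attributes > 1 else -np.inf
    if not (lower < rho < 1.0):
        raise ValueError(
            f"rho={rho} makes the {n_attributes}-attribute compound-symmetric "
            f"correlation matrix non-positive-definite (need {lower:.3f} < rho < 1)"
        )


def draw_abilities(
    n_persons: int, n_attributes: int, rho: float, rng: np.random.Generator
) -> AbilityMatrix:
    """Abilities theta_j ~ MVN(0, R) with unit variances and common correlation rho."""
    _check_rho(rho, n_attributes)
    corr = np.full((n_attributes, n_attributes), float(rho))
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal(size=(int(n_persons), n_attributes))
    return AbilityMatrix(values=z @ chol.T)


def simulate_responses(
    abilities, difficulties, q: QMatrix, rng: np.random.Generator
) -> ResponseMatrix:
    """Bernoulli responses under the unit-slope simple-structure MIRT model."""
    theta = as_values(abilities)
    b = np.asarray(difficulties, dtype=float)
    if not q.is_simple_structure:
        raise ValueError("response generator is defined for simple-structure Q-matrices only")
    if q.n_items != b.shape[0]:
        raise ValueError("difficulties length does not match Q-matrix items")
    if theta.shape[1] != q.n_attributes:
        raise ValueError("ability columns do not match Q-matrix attributes")
    k_of_item = q.item_attribute()
    logits = theta[:, k_of_item] - b[None, :]
    p = 1.0 / (1.0 + np.exp(-logits))
    x = (rng.random(size=p.shape) < p).astype(np.int8)
    return ResponseMatrix(values=x, item_names=list(q.item_names))


def true_mastery(abilities) -> MasteryMatrix:
    """True mastery alpha_jk = 1 iff theta_jk > 0 (strict; 0 is non-mastery)."""
    theta = as_values(abilities)
    return MasteryMatrix(values=(theta > 0.0).astype(np.int8))


def form_rng(seed: int, form_index: int) -> np.random.Generator:
    """Deterministic per-form random stream: child ``form_index`` of master ``seed``.

    Any single form of a study is reproducible in isolation from the study
    seed and the form's index.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(int(form_index),)))


def generate_form(condition: SimulationCondition, form_index: int = 0) -> GeneratedForm:
    """Generate one complete form under a simulation condition."""
    rng = form_rng(condition.seed, form_index)
    q = build_simple_q(condition.strand_sizes)
    b = draw_difficulties(q.n_items, condition.difficulty_low, condition.difficulty_high, rng)
    theta = draw_abilities(condition.n_persons, q.n_attributes, condition.rho, rng)
    x = simulate_responses(theta, b, q, rng)
    return GeneratedForm(
        difficulties=b, abilities=theta, q=q, responses=x, true_mastery=true_mastery(theta)
    )
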