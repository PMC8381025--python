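"""Classical-test-theory subscores and the percent-correct mastery rule."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MasteryMatrix, QMatrix, as_values

__all__ = ["ctt_subscores", "threshold_mastery", "write_subscores"]


def ctt_subscores(responses, q: QMatrix) -> np.ndarray:
    """Per-person, per-attribute proportion correct over the attribute's items.

    Entry (j, k) is the fraction of the items loading attribute k that
    person j answered correctly. Requires a simple-structure Q-matrix so
    each item contributes to exactly one strand subscore.
    """
    x = as_values(responses)
    if not q.is_simple_structure:
        raise ValueError("CTT subscores require a simple-structure Q-matrix")
    if x.shape[1] != q.n_items:
        raise ValueError("response columns do not match Q-matrix items")
    counts = q.entries.sum(axis=0)
    if (counts == 0).any():
        k = int(np.argwhere(counts == 0)[0][0])
        raise ValueError(f"attribute {q.attribute_names[k]} has no items")
    # x @ q gives per-strand raw scores in one pass
    return (x @ q.entries) / counts[None, :]


def threshold_mastery(scores, cut: float = 0.5, strict: bool = True) -> MasteryMatrix:
    """Classify mastery by thresholding scores at ``cut``.

    The default is the strict rule: a person masters a strand only when the
    score is strictly above the cut, so a 50% score on an even-length strand
    is non-mastery.
    """
    s = as_values(scores)
    mastered = (s > cut) if strict else (s >= cut)
    return MasteryMatrix(values=mastered.astype(np.int8))


def write_subscores(scores: np.ndarray, path, attribute_names=None) -> None:
    """Write a persons x attributes score table in the shared CSV dialect."""
    s = np.asarray(scores)
    cols = attribute_names or [f"A{k + 1}" for k in range(s.shape[1])]
    df = pd.DataFrame(s, columns=cols)
    df.index = [f"p{j + 1}" for j in range(s.shape[0])]
    df.index.name = "person"
    df.to_csv(path)
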