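"""Plant-functional-type (PFT) affinity scoring of pollen assemblages.

Biomization-style scoring: each taxon's proportion p contributes
``w * sqrt(max(0, p - theta))`` to every PFT it is assigned to, where w
is the taxa-PFT weight and theta a small screening threshold (default
0.5%) that suppresses trace occurrences.  Proportions are computed on the
sum of taxa present in the regional matrix (the terrestrial pollen sum);
fossil taxa absent from the matrix contribute nothing and are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PollenCounts, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THETA = 0.005


@dataclass
class PftScores:
    sample_ids: list[str]
    pfts: list[str]
    scores: np.ndarray          # samples x PFT, non-negative

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.pfts)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def to_proportions(counts: PollenCounts, taxa_subset: list[str] | None = None) -> np.ndarray:
    """Row-normalize counts to proportions, optionally on a taxon subset sum.

    With ``taxa_subset`` the denominator is the summed count of the listed
    taxa only (the pollen-sum definition), and columns are restricted to
    that subset in its given order.
    """
    if counts.is_proportions and taxa_subset is None:
        return counts.counts.copy()
    values = counts.counts
    if taxa_subset is not None:
        idx = [counts.taxa.index(t) for t in taxa_subset if t in counts.taxa]
        values = values[:, idx]
    sums = values.sum(axis=1)
    if np.any(sums <= 0):
        bad = counts.sample_ids[int(np.argmax(sums <= 0))]
        raise ValidationError(f"sample {bad!r} has zero pollen sum")
    return values / sums[:, None]


def compute_pft_scores(props: np.ndarray, taxa: list[str], matrix: pd.DataFrame,
                       theta: float = DEFAULT_THETA,
                       sample_ids: list[str] | None = None) -> PftScores:
    """Score samples on PFTs: score = sum_taxa w * sqrt(max(0, p - theta)).

    ``matrix`` is a taxa x PFT weight table; taxa in ``taxa`` but not in
    the matrix are skipped (and logged), so they contribute nothing.
    """
    if theta < 0:
        raise ValidationError("theta must be >= 0")
    props = np.asarray(props, dtype=float)
    if props.shape[1] != len(taxa):
        raise ValidationError("proportions/taxa mismatch")
    known = [t for t in taxa if t in matrix.index]
    missing = [t for t in taxa if t not in matrix.index]
    if missing:
        logger.info("taxa without PFT assignment skipped: %s", missing)
    pfts = list(matrix.columns)
    w = matrix.loc[known].to_numpy(dtype=float)           # known-taxa x PFT
    cols = [taxa.index(t) for t in known]
    clipped = np.sqrt(np.clip(props[:, cols] - theta, 0.0, None))
    scores = clipped @ w
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(props.shape[0])]
    return PftScores(sample_ids=list(ids), pfts=pfts, scores=scores)


def scores_from_counts(counts: PollenCounts, matrix: pd.DataFrame,
                       theta: float = DEFAULT_THETA) -> PftScores:
    """Convenience: restrict to matrix taxa, re-normalize, then score."""
    subset = [t for t in counts.taxa if t in matrix.index]
    if not subset:
        raise ValidationError("no fossil taxa covered by the taxa-PFT matrix")
    props = to_proportions(counts, taxa_subset=subset)
    return compute_pft_scores(props, subset, matrix, theta=theta,
                              sample_ids=counts.sample_ids)
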