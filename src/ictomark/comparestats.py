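"""Friedman comparison of biomarkers' three-way classification outcomes.

Each subject contributes one ordinal outcome per biomarker (correct = 2,
uncertain = 1, misclassified = 0; any strictly monotone coding gives the
same ranks), so biomarkers are compared with the Friedman test — a
rank-based repeated-measures ANOVA — computed separately within the IGE
and control cohorts.  Because three-way outcomes are massively tied, the
mid-rank tie-corrected statistic is the default; a Monte-Carlo
within-row permutation variant is available for exactness at small n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Ordinal coding of a three-way outcome given the true class.
OUTCOME_SCORES = {"correct": 2, "uncertain": 1, "misclassified": 0}


class FriedmanUndefinedError(ValueError):
    """All rows fully tied: the rank variance is zero and the statistic undefined."""


@dataclass
class OutcomeMatrix:
    """Subjects x biomarkers ordinal scores for one cohort.

    Entries are in {0, 1, 2}; ``cohort`` tags whether the rows are IGE
    subjects or controls (the two cohorts are never pooled).
    """

    scores: np.ndarray
    biomarkers: tuple
    cohort: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2:
            raise ValueError("scores must be subjects x biomarkers")
        if not np.isin(self.scores, (0, 1, 2)).all():
            raise ValueError("scores must be in {0, 1, 2}")
        if self.scores.shape[1] != len(self.biomarkers):
            raise ValueError("one column per biomarker required")
        if self.cohort not in ("ige", "control"):
            raise ValueError("cohort must be 'ige' or 'control'")

    @classmethod
    def from_outcomes(cls, outcome_columns: dict, labels, cohort: str) -> "OutcomeMatrix":
        """Score three-way outcomes against the true labels of one cohort.

        ``outcome_columns`` maps biomarker name -> per-subject outcomes in
        {"ige", "normal", "uncertain"}; only subjects of ``cohort`` are kept.
        """
        from .classify import _ige_mask

        is_ige = _ige_mask(labels)
        keep = is_ige if cohort == "ige" else ~is_ige
        correct = "ige" if cohort == "ige" else "normal"
        names = tuple(outcome_columns)
        cols = []
        for name in names:
            out = np.asarray(outcome_columns[name], object)[keep]
            score = np.where(out == correct, 2, np.where(out == "uncertain", 1, 0))
            cols.append(score)
        return cls(np.column_stack(cols), names, cohort)

    def column(self, name: str) -> int:
        try:
            return self.biomarkers.index(name)
        except ValueError:
            raise KeyError(f"unknown biomarker {name!r}") from None


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float
    method: str


def _midranks(scores: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, scores.astype(float))


def _chi2_from_ranks(r: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from within-row mid-ranks."""
    n, k = r.shape
    col_sums = r.sum(axis=0)
    a2 = (r**2).sum()
    c = n * k * (k + 1) ** 2 / 4.0
    if a2 - c <= 0:
        raise FriedmanUndefinedError(
            "every row is fully tied: Friedman statistic undefined"
        )
    return float((k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum() / (a2 - c))


def friedman(
    om,
    method: str = "chi2",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> FriedmanResult:
    """Friedman test across the columns of an outcome matrix.

    With ``method="chi2"`` the tie-corrected statistic is referred to the
    chi-square distribution with k-1 degrees of freedom; with
    ``method="permutation"`` the p-value instead comes from ``n_resamples``
    independent within-row permutations of the raw scores (seeded), which
    is preferable for small cohorts.
    """
    scores = om.scores if isinstance(om, OutcomeMatrix) else np.asarray(om)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 biomarkers")
    n, k = scores.shape
    obs = _chi2_from_ranks(_midranks(scores))
    if method == "chi2":
        p = float(stats.chi2.sf(obs, k - 1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_resamples):
            perm = np.array([rng.permutation(row) for row in scores])
            try:
                val = _chi2_from_ranks(_midranks(perm))
            except FriedmanUndefinedError:  # pragma: no cover - impossible if obs defined
                val = 0.0
            hits += val >= obs - 1e-12
        p = (hits + 1) / (n_resamples + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FriedmanResult(statistic=obs, df=k - 1, pvalue=float(p), method=method)


def pairwise_friedman(om: OutcomeMatrix, col_a: str, col_b: str, **kwargs) -> FriedmanResult:
    """Friedman test restricted to two biomarkers (df = 1)."""
    ia, ib = om.column(col_a), om.column(col_b)
    return friedman(om.scores[:, [ia, ib]], **kwargs)
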