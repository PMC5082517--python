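"""Dual-threshold three-outcome classification with leave-one-out evaluation.

For a scalar biomarker with known polarity, two cuts are optimized on a
training set:

* ``th1`` — the cut giving the highest sensitivity subject to 100%
  specificity (no control on the IGE side), and
* ``th2`` — the cut giving the highest specificity subject to 100%
  sensitivity (no IGE subject on the control side).

A test subject is called ``ige`` when its value is on the IGE side of both
cuts, ``normal`` when on the control side of both, and ``uncertain``
otherwise.  Cuts are placed at the midpoint between the two adjacent order
statistics that realize each optimum; when a control and an IGE value tie
exactly at a boundary, the 100% requirement is enforced strictly, so the
cut moves past the tied value.

For the model-based local-coupling biomarker the free parameters (scored
channel, coupling scale K) are re-optimized inside every leave-one-out
fold, independently for each of the two objectives, from a precomputed
value table over the (channel, K) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OUTCOMES = ("ige", "uncertain", "normal")

#: Biomarker polarities: which side of a cut is the IGE side.
DIRECTIONS = {
    "alpha_peak": "lower_is_ige",
    "mean_degree": "higher_is_ige",
    "local_coupling": "higher_is_ige",
}


class ClassifierError(ValueError):
    pass


@dataclass
class ThresholdPair:
    """The two optimized cuts (original biomarker scale) and their context.

    ``params1`` / ``params2`` record the (channel, K) optimized for the
    sensitivity and specificity objectives when the biomarker has free
    parameters; None otherwise.
    """

    th1: float
    th2: float
    direction: str
    train_sensitivity: float  # at th1, where training specificity = 1
    train_specificity: float  # at th2, where training sensitivity = 1
    params1: tuple | None = None
    params2: tuple | None = None


def _signed(values, direction):
    """Map values onto a scale where larger always means more IGE-like."""
    s = 1.0 if direction == "higher_is_ige" else -1.0
    return s * np.asarray(values, float), s


def _pad(sorted_unique):
    """Offset used to place a cut beyond the data range in degenerate cases."""
    if sorted_unique.size > 1:
        return 0.5 * float(np.median(np.diff(sorted_unique)))
    return 1.0


def _optimize_signed(ige, ctrl):
    """Midpoint cuts on the signed scale (larger = IGE side).

    Returns (th1, sens_at_th1, th2, spec_at_th2).
    """
    allv = np.unique(np.concatenate([ige, ctrl]))
    pad = _pad(allv)

    # th1: all controls at or below the cut (specificity 1); maximal count
    # of IGE strictly above it.
    a = ctrl.max()
    above = allv[allv > a]
    if above.size:
        th1 = 0.5 * (a + above.min())
    else:
        th1 = a + pad
    sens1 = float((ige > th1).mean())

    # th2: all IGE strictly above the cut (sensitivity 1); maximal count of
    # controls strictly below it.
    c = ige.min()
    below = allv[allv < c]
    if below.size:
        th2 = 0.5 * (c + below.max())
    else:
        th2 = c - pad
    spec2 = float((ctrl < th2).mean())
    return float(th1), sens1, float(th2), spec2


def optimize_thresholds(values, labels, direction) -> ThresholdPair:
    """Optimize th1 and th2 on a training set.

    ``labels`` holds "patient"/"ige" vs "control" strings (or booleans,
    True = IGE).  Both classes must be present and all values finite.
    """
    values = np.asarray(values, float)
    if not np.isfinite(values).all():
        raise ClassifierError("biomarker values must be finite")
    is_ige = _ige_mask(labels)
    if is_ige.all() or (~is_ige).all():
        raise ClassifierError("both classes must be present to optimize thresholds")
    if direction not in ("higher_is_ige", "lower_is_ige"):
        raise ClassifierError(f"unknown direction {direction!r}")
    sv, s = _signed(values, direction)
    th1, sens1, th2, spec2 = _optimize_signed(sv[is_ige], sv[~is_ige])
    return ThresholdPair(
        th1=s * th1, th2=s * th2, direction=direction,
        train_sensitivity=sens1, train_specificity=spec2,
    )


def _ige_mask(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, (bool, np.bool_)):
            out.append(bool(lab))
        else:
            out.append(str(lab).lower() in ("ige", "patient", "1", "true"))
    return np.asarray(out, bool)


def classify(value, thresholds: ThresholdPair, value2=None) -> str:
    """Three-way outcome of one subject.

    ``value`` is judged against th1 and ``value2`` (defaulting to
    ``value``) against th2 — they differ only when the two objectives were
    optimized with different biomarker parameters.
    """
    v1 = float(value)
    v2 = v1 if value2 is None else float(value2)
    if not (np.isfinite(v1) and np.isfinite(v2)):
        raise ClassifierError("cannot classify a non-finite value")
    s = 1.0 if thresholds.direction == "higher_is_ige" else -1.0
    ige_side1 = s * v1 > s * thresholds.th1
    ige_side2 = s * v2 > s * thresholds.th2
    ctrl_side1 = s * v1 < s * thresholds.th1
    ctrl_side2 = s * v2 < s * thresholds.th2
    if ige_side1 and ige_side2:
        return "ige"
    if ctrl_side1 and ctrl_side2:
        return "normal"
    return "uncertain"


# ---------------------------------------------------------------------------
# Leave-one-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    subject: int
    outcome: str
    value1: float
    value2: float
    thresholds: ThresholdPair


@dataclass
class ClassificationResult:
    """Per-subject three-way outcomes with full fold metadata.

    Produced by :func:`loocv` / :class:`LeaveOneOutClassifier.fit`; one
    fold per subject, the subject classified by thresholds (and, for the
    parametric biomarker, channel/K choices) optimized without it.
    """

    outcomes: list
    labels: np.ndarray
    folds: list = field(default_factory=list)
    biomarker: str = ""

    def __post_init__(self):
        if len(self.outcomes) != len(self.labels):
            raise ClassifierError("one outcome per subject required")

    def performance(self) -> dict:
        return performance(self)

    def counts(self) -> pd.DataFrame:
        is_ige = _ige_mask(self.labels)
        out = np.asarray(self.outcomes)
        rows = {}
        for name, mask in (("ige", is_ige), ("control", ~is_ige)):
            rows[name] = [int((out[mask] == o).sum()) for o in OUTCOMES]
        return pd.DataFrame(rows, index=list(OUTCOMES)).T

    def summary(self) -> str:
        perf = self.performance()
        tab = self.counts()
        lines = [
            f"Leave-one-out dual-threshold classification"
            + (f" — {self.biomarker}" if self.biomarker else ""),
            f"subjects: {len(self.outcomes)} "
            f"(IGE {int(_ige_mask(self.labels).sum())}, "
            f"control {int((~_ige_mask(self.labels)).sum())})",
            "",
            tab.to_string(),
            "",
            f"sensitivity (unequivocal IGE among IGE):      {perf['sensitivity']:.1%}",
            f"specificity (unequivocal normal among ctrl):  {perf['specificity']:.1%}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for f in self.folds:
            tp = f.thresholds
            recs.append(
                dict(
                    subject=f.subject,
                    label=self.labels[f.subject],
                    outcome=f.outcome,
                    value1=f.value1,
                    value2=f.value2,
                    th1=tp.th1,
                    th2=tp.th2,
                    params1=tp.params1,
                    params2=tp.params2,
                )
            )
        return pd.DataFrame(recs)


def performance(result) -> dict:
    """Sensitivity / specificity and the 2x3 outcome count table.

    Accepts a :class:`ClassificationResult` or an ``(outcomes, labels)``
    pair.  Sensitivity is the fraction of true IGE subjects called
    unequivocally IGE; specificity the fraction of controls called
    unequivocally normal; uncertain outcomes count against both.
    """
    if isinstance(result, ClassificationResult):
        outcomes, labels = np.asarray(result.outcomes), result.labels
    else:
        outcomes, labels = result
        outcomes = np.asarray(outcomes)
    is_ige = _ige_mask(labels)
    n_ige = int(is_ige.sum())
    n_ctrl = int((~is_ige).sum())
    sens = float((outcomes[is_ige] == "ige").sum() / n_ige) if n_ige else np.nan
    spec = float((outcomes[~is_ige] == "normal").sum() / n_ctrl) if n_ctrl else np.nan
    counts = {
        "ige": {o: int((outcomes[is_ige] == o).sum()) for o in OUTCOMES},
        "control": {o: int((outcomes[~is_ige] == o).sum()) for o in OUTCOMES},
    }
    return {"sensitivity": sens, "specificity": spec, "counts": counts}


def _objective_grid(table, is_ige, direction):
    """Training objectives for every (channel, K) cell of a value table.

    ``table``: (n_subjects, n_channels, n_K).  Returns two arrays of shape
    (n_channels, n_K): sensitivity at 100% specificity, and specificity at
    100% sensitivity.
    """
    n_s, n_ch, n_k = table.shape
    sv, _ = _signed(table.reshape(n_s, -1), direction)
    ige = sv[is_ige]
    ctrl = sv[~is_ige]
    # th1 region: strictly above max control
    a = ctrl.max(axis=0)
    sens = (ige > a[None, :]).mean(axis=0)
    above = np.where(ige > a[None, :], ige, np.inf).min(axis=0)
    m1 = np.where(np.isfinite(above), above - a, ige.max(axis=0) - a)
    # th2 region: strictly below min IGE
    c = ige.min(axis=0)
    spec = (ctrl < c[None, :]).mean(axis=0)
    below = np.where(ctrl < c[None, :], ctrl, -np.inf).max(axis=0)
    m2 = np.where(np.isfinite(below), c - below, ctrl.min(axis=0) - c)
    shape = (n_ch, n_k)
    return sens.reshape(shape), spec.reshape(shape), m1.reshape(shape), m2.reshape(shape)


def _best_cell(grid, margin):
    """Deterministic argmax with a max-margin tie-break.

    Among cells tying the best training objective, prefer the one whose
    threshold sits in the widest gap between the classes (better expected
    transfer to the held-out subject); remaining ties resolve toward lower
    channel then lower K index.
    """
    best = grid.max()
    tied = np.argwhere(grid == best)
    if len(tied) == 1:
        return tuple(tied[0])
    margins = margin[tuple(tied.T)]
    return tuple(tied[int(np.argmax(margins))])


def loocv(
    values,
    labels,
    biomarker: str,
    channels=None,
    K_grid=None,
) -> ClassificationResult:
    """Leave-one-out evaluation of one biomarker over a cohort.

    Parameters
    ----------
    values : array
        Either shape (n_subjects,) for the scalar biomarkers
        (``alpha_peak``, ``mean_degree``) or (n_subjects, n_channels, n_K)
        for ``local_coupling``, giving the precomputed seizure likelihood
        of every subject at every candidate (channel, K).
    labels : sequence
        "patient"/"ige" vs "control" per subject.
    biomarker : str
        Name, fixing the polarity via :data:`DIRECTIONS`.
    channels, K_grid :
        Axis labels of the parametric table (required with a 3-D table).
    """
    values = np.asarray(values, float)
    direction = DIRECTIONS.get(biomarker)
    if direction is None:
        raise ClassifierError(f"unknown biomarker {biomarker!r}")
    is_ige = _ige_mask(labels)
    n = len(is_ige)
    if values.shape[0] != n:
        raise ClassifierError("values and labels disagree in length")
    if is_ige.sum() < 2 or (~is_ige).sum() < 2:
        raise ClassifierError("need >= 2 subjects per class for leave-one-out")
    parametric = values.ndim == 3
    if parametric and (channels is None or K_grid is None):
        raise ClassifierError("channels and K_grid required for a parametric table")
    if parametric and (len(channels) != values.shape[1] or len(K_grid) != values.shape[2]):
        raise ClassifierError("table shape does not match channels/K_grid")

    outcomes = []
    folds = []
    for i in range(n):
        train = np.ones(n, bool)
        train[i] = False
        t_labels = is_ige[train]
        if t_labels.all() or (~t_labels).all():
            raise ClassifierError(f"fold {i}: a class is missing from the training set")
        if parametric:
            sens_grid, spec_grid, m1, m2 = _objective_grid(values[train], t_labels, direction)
            c1, k1 = _best_cell(sens_grid, m1)
            c2, k2 = _best_cell(spec_grid, m2)
            tp1 = optimize_thresholds(values[train, c1, k1], t_labels, direction)
            tp2 = optimize_thresholds(values[train, c2, k2], t_labels, direction)
            tp = ThresholdPair(
                th1=tp1.th1, th2=tp2.th2, direction=direction,
                train_sensitivity=tp1.train_sensitivity,
                train_specificity=tp2.train_specificity,
                params1=(channels[c1], float(K_grid[k1])),
                params2=(channels[c2], float(K_grid[k2])),
            )
            v1 = float(values[i, c1, k1])
            v2 = float(values[i, c2, k2])
        else:
            tp = optimize_thresholds(values[train], t_labels, direction)
            v1 = v2 = float(values[i])
        outcome = classify(v1, tp, v2)
        outcomes.append(outcome)
        folds.append(FoldResult(subject=i, outcome=outcome, value1=v1, value2=v2, thresholds=tp))
    return ClassificationResult(
        outcomes=outcomes, labels=np.asarray(labels, object), folds=folds,
        biomarker=biomarker,
    )


class LeaveOneOutClassifier:
    """Model-object interface over :func:`loocv`.

    Holds the cohort's biomarker values and labels; ``fit()`` runs the
    leave-one-out protocol and returns a :class:`ClassificationResult`.
    """

    def __init__(self, values, labels, biomarker, channels=None, K_grid=None):
        self.values = np.asarray(values, float)
        self.labels = np.asarray(labels, object)
        self.biomarker = biomarker
        self.channels = channels
        self.K_grid = K_grid

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str, label_col: str, biomarker: str):
        """Build from a tidy per-subject table (scalar biomarkers)."""
        return cls(df[value_col].to_numpy(float), df[label_col].to_numpy(), biomarker)

    def fit(self) -> ClassificationResult:
        return loocv(
            self.values, self.labels, self.biomarker,
            channels=self.channels, K_grid=self.K_grid,
        )
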