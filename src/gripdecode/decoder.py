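"""Multi-movement decoding with bounded scores and argmax arbitration.

One nonlinear (Gaussian-kernel SVM) scorer is trained per movement against
all other states including rest; raw decision values are squashed through
tanh so every score lies in [-1, 1].  At run time a movement is a candidate
when its score exceeds zero; if several candidates exist the highest score
wins, otherwise the state is rest.  Accuracy statistics follow the
100 ms-bin conventions of the closed-loop system: individual accuracy is
the per-bin agreement between a movement's activation indicator and its cue
indicator over a whole block, and response probabilities tally, within each
cue, the share of decoder-active bins claimed by each movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from gripdecode.features import FeatureMatrix, StandardizationParams
from gripdecode.synth import REST, CueSchedule


class DecoderError(ValueError):
    pass


@dataclass
class LabeledBins:
    features: FeatureMatrix
    labels: np.ndarray               # per-bin state label (object dtype)

    def __post_init__(self):
        if len(self.labels) != self.features.n_bins:
            raise DecoderError("one label required per feature bin")


@dataclass
class DecoderModel:
    """Per-movement bounded scoring functions (no scorer exists for rest)."""

    movements: tuple
    scorers: dict                     # movement -> fitted sklearn SVC
    gamma: float
    C: float
    params: StandardizationParams | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return next(iter(self.scorers.values())).shape_fit_[1]


@dataclass
class DecodeTrace:
    bin_starts_s: np.ndarray
    scores: np.ndarray               # bins x movements, in [-1, 1]
    states: np.ndarray               # per-bin active state (movement or rest)
    movements: tuple


@dataclass
class ConfusionSummary:
    individual_accuracy_pct: dict    # movement -> percent
    response_probability: pd.DataFrame   # cue x predicted movement
    undefined_cues: tuple = ()


def assemble_training_set(
    features: FeatureMatrix, schedule: CueSchedule
) -> LabeledBins:
    """Label each bin by the cue interval containing its start time.

    Intervals are half-open [start, end); bins outside the schedule are
    labeled rest.
    """
    labels = schedule.labels_for_times(features.bin_starts_s)
    return LabeledBins(features, labels)


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    sub = X if len(X) <= 1000 else X[rng.choice(len(X), 1000, replace=False)]
    med = np.median(pdist(sub))
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med**2)


def train(
    bins: LabeledBins,
    movements: tuple | None = None,
    C: float = 10.0,
    gamma: float | None = None,
    seed: int = 0,
) -> DecoderModel:
    """Fit one one-vs-rest Gaussian-kernel scorer per movement.

    Rest bins (and all other movements' bins) are the negative class of each
    scorer.  The kernel width defaults to the median heuristic on the
    training features.  Deterministic for a given seed.
    """
    X = bins.features.values
    y = bins.labels
    present = [m for m in dict.fromkeys(y) if m != REST]
    if movements is None:
        movements = tuple(present)
    missing = [m for m in movements if m not in present]
    if missing:
        raise DecoderError(f"movements missing from training data: {missing}")
    if len(set(y)) < 2:
        raise DecoderError("need at least 2 distinct labels to train")
    for m in movements:
        if np.sum(y == m) < 10:
            raise DecoderError(f"fewer than 10 training bins for {m!r}")

    rng = np.random.default_rng(seed)
    if gamma is None:
        gamma = _median_heuristic_gamma(X, rng)
    scorers = {}
    for m in movements:
        clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=int(seed))
        clf.fit(X, (y == m).astype(int))
        scorers[m] = clf
    return DecoderModel(tuple(movements), scorers, gamma, C,
                        bins.features.params,
                        {"seed": int(seed), "n_train_bins": int(len(y))})


def score_bins(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Bounded per-movement scores for a batch of MWP vectors.

    tanh of the SVM decision value; every entry lies in [-1, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise DecoderError("non-finite feature input")
    if X.shape[1] != model.n_features:
        raise DecoderError(
            f"feature width {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    out = np.empty((X.shape[0], len(model.movements)))
    for k, m in enumerate(model.movements):
        out[:, k] = np.tanh(model.scorers[m].decision_function(X))
    return out


def score_bin(model: DecoderModel, mwp: np.ndarray) -> np.ndarray:
    """Scores for a single 96-dim MWP vector."""
    return score_bins(model, mwp[None, :])[0]


def arbitrate(scores: np.ndarray, movements: tuple) -> str:
    """Highest-scoring movement among those with score > 0, else rest.

    Exact ties go to the earlier label in the model's canonical order.
    """
    scores = np.asarray(scores, dtype=float)
    if not (scores > 0).any():
        return REST
    masked = np.where(scores > 0, scores, -np.inf)
    return movements[int(np.argmax(masked))]   # argmax takes first on ties


def decode(model: DecoderModel, features: FeatureMatrix) -> DecodeTrace:
    """Score and arbitrate every bin of a feature matrix."""
    scores = score_bins(model, features.values)
    states = np.array(
        [arbitrate(s, model.movements) for s in scores], dtype=object
    )
    return DecodeTrace(features.bin_starts_s, scores, states, model.movements)


def individual_accuracy(
    trace: DecodeTrace, schedule: CueSchedule, movement: str,
    cue_restricted: bool = False,
) -> float:
    """Percent of bins where activation of ``movement`` matches its cue.

    Whole-block binary agreement between indicator(active == movement) and
    indicator(cue == movement); with ``cue_restricted`` the denominator is
    limited to that movement's cue bins.
    """
    if movement not in set(schedule.labels):
        raise DecoderError(f"{movement!r} not present in schedule")
    cue = schedule.labels_for_times(trace.bin_starts_s)
    pred_on = trace.states == movement
    cue_on = cue == movement
    if cue_restricted:
        if not cue_on.any():
            raise DecoderError(f"no bins cued {movement!r}")
        return 100.0 * np.mean(pred_on[cue_on])
    return 100.0 * np.mean(pred_on == cue_on)


def response_probabilities(
    trace: DecodeTrace, schedule: CueSchedule
) -> ConfusionSummary:
    """Confusion matrix of response probabilities.

    For each cue label, over the bins of that cue in which *some* movement
    is active, the fraction attributed to each movement; defined rows sum
    to 1.  Cues with zero active bins are flagged and excluded.
    """
    cue = schedule.labels_for_times(trace.bin_starts_s)
    movements = trace.movements
    rows, undefined = {}, []
    for m in movements:
        in_cue = cue == m
        active = in_cue & (trace.states != REST)
        if not active.any():
            undefined.append(m)
            rows[m] = np.full(len(movements), np.nan)
            continue
        rows[m] = np.array(
            [np.mean(trace.states[active] == p) for p in movements]
        )
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=list(movements))
    mat.index.name = "cue"
    acc = {m: individual_accuracy(trace, schedule, m)
           for m in movements if m in set(schedule.labels)}
    return ConfusionSummary(acc, mat, tuple(undefined))
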