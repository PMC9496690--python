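"""Cross-validated evaluation: leave-one-out, leave-one-group-out,
majority-vote scoring and cohort summaries.

Spectra mapped from one CSF sample are statistically dependent, so the
sample-level protocol holds out one whole mapping group per round, trains
on the remaining groups (with augmentation applied to training folds only),
and predicts every spectrum of the held-out group.  The per-sample **vote
score** is 100 x the fraction of the group's spectra predicted as the
sample's clinically expected class; a score above 50 is a confident correct
call, below 50 an incorrect one, exactly 50 indeterminate.

FAD samples never enter training: the binary model is trained on the
normal-vs-dementia groups only, and mutation carriers (fad_pos) are
expected to score as diseased, non-carriers (fad_neg) as normal.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier as _clf
from .augment import AugmentConfig, augment_dataset
from .classifier import GroupLeakageError, ModelConfig, PredictionSet
from .preprocess import PreprocessConfig, integration_normalize, preprocess_spectrum
from .spectra_io import MappingGroup

__all__ = [
    "EvaluationResult",
    "GroupSummary",
    "EXPECTED_CLASS",
    "TRAIN_CLASSES",
    "vote_score",
    "classify",
    "leave_one_group_out",
    "leave_one_out",
    "summarize",
    "load_reference_scores",
    "results_from_scores",
    "CNNBackend",
]

#: Clinically expected class of each diagnostic label under the binary
#: normal-vs-dementia model.
EXPECTED_CLASS = {
    "normal": "normal",
    "dementia": "dementia",
    "fad_pos": "dementia",
    "fad_neg": "normal",
}

#: Labels whose groups may enter training.
TRAIN_CLASSES = ("normal", "dementia")


@dataclass(frozen=True)
class EvaluationResult:
    """Outcome of one held-out sample."""

    sample_id: str
    true_label: str
    expected_label: str
    predicted_label: str | None
    score: float  # percent in [0, 100], anchored to the expected class
    n_test_spectra: int
    call: str  # correct / incorrect / indeterminate

    def __post_init__(self):
        if not 0.0 <= self.score <= 100.0:
            raise ValueError("score must be in [0, 100]")
        if self.call not in ("correct", "incorrect", "indeterminate"):
            raise ValueError(f"bad call {self.call!r}")


@dataclass(frozen=True)
class GroupSummary:
    """Per-label accuracy and mean vote score."""

    group_label: str
    n: int
    n_correct: int
    accuracy: float  # percent
    mean_score: float


def vote_score(predictions: PredictionSet, expected_label: str):
    """Majority vote over one test group's spectrum predictions.

    Returns ``(predicted_label, score)``: the modal argmax class (ties
    broken conservatively toward a non-expected label) and 100 x the
    fraction of spectra whose argmax equals the *expected* class.  Anchoring
    the score to the expected class lets it fall below 50 when the vote goes
    against the clinical label.
    """
    labels = predictions.labels
    if labels.size == 0:
        raise ValueError("empty prediction set")
    gids = set(predictions.group_ids)
    if len(gids) > 1:
        raise ValueError(f"predictions span several groups: {sorted(gids)}")
    counts = Counter(labels.tolist())
    top = max(counts.values())
    modal = sorted(l for l, c in counts.items() if c == top)
    non_expected = [l for l in modal if l != expected_label]
    predicted = non_expected[0] if non_expected else modal[0]
    score = 100.0 * counts.get(expected_label, 0) / labels.size
    return predicted, score


def classify(score: float, threshold: float = 50.0) -> str:
    """The 50-threshold call rule on a vote score."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("score must be in [0, 100]")
    if score > threshold:
        return "correct"
    if score < threshold:
        return "incorrect"
    return "indeterminate"


# ---------------------------------------------------------------------------
# classifier backends

class CNNBackend:
    """Default backend: the package's 1D CNN behind the fit/predict
    interface the evaluation drivers expect."""

    def __init__(self, model_config: ModelConfig | None = None):
        self.config = model_config or ModelConfig()
        self.model: _clf.CNNModel | None = None

    def fit(self, X, labels, groups, forbidden_groups=frozenset()):
        classes = tuple(sorted(set(labels)))
        self.model = _clf.build_model(self.config, X.shape[1], classes)
        _clf.train(self.model, X, labels, groups, forbidden_groups=forbidden_groups)
        return self

    def predict(self, X, group_ids=None) -> PredictionSet:
        assert self.model is not None, "fit before predict"
        return _clf.predict(self.model, X, group_ids)


def _prepare_group(group: MappingGroup, config: PreprocessConfig) -> MappingGroup:
    cleaned = [
        integration_normalize(preprocess_spectrum(s, config)) for s in group.spectra
    ]
    return MappingGroup(group.sample_id, cleaned, group.step_size)


def leave_one_group_out(
    groups: Sequence[MappingGroup],
    labels: Mapping[str, str],
    model_config: ModelConfig | None = None,
    augment_config: AugmentConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    backend_factory: Callable[[], object] | None = None,
    preprocess: bool = True,
) -> list[EvaluationResult]:
    """One evaluation round per mapping group.

    Per round, the held-out group's spectra are the test set; training uses
    all *other* normal/dementia groups, augmented (originals plus synthetic
    spectra that never mix groups).  FAD groups are never part of any
    training set, so every FAD round shares the model trained on all
    normal/dementia groups; it is trained once and reused.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ids = [g.sample_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group ids")
    unknown = [i for i in ids if i not in labels]
    if unknown:
        raise ValueError(f"groups without labels: {unknown}")
    augment_config = augment_config or AugmentConfig()
    preprocess_config = preprocess_config or PreprocessConfig()
    if backend_factory is None:
        backend_factory = lambda: CNNBackend(model_config)  # noqa: E731

    prepared = [
        _prepare_group(g, preprocess_config) if preprocess else g for g in groups
    ]
    eligible = [g for g in prepared if labels[g.sample_id] in TRAIN_CLASSES]
    if len({labels[g.sample_id] for g in eligible}) < 2:
        raise ValueError("training pool must contain at least two classes")

    def run_round(test_group: MappingGroup, round_idx: int) -> PredictionSet:
        train_groups = [g for g in eligible if g.sample_id != test_group.sample_id]
        train_labels = {labels[g.sample_id] for g in train_groups}
        if len(train_labels) < 2:
            raise ValueError(
                f"round for {test_group.sample_id!r} leaves a single-class training set"
            )
        acfg = AugmentConfig(
            **{
                **augment_config.__dict__,
                "seed": augment_config.seed + 997 * round_idx,
            }
        )
        spectra, spec_labels, gids = augment_dataset(
            train_groups, {g.sample_id: labels[g.sample_id] for g in train_groups}, acfg
        )
        if test_group.sample_id in set(gids):  # pragma: no cover - defensive audit
            raise GroupLeakageError(f"test group {test_group.sample_id!r} leaked into training")
        X = np.stack([s.intensities for s in spectra])
        backend = backend_factory()
        backend.fit(X, spec_labels, gids, forbidden_groups={test_group.sample_id})
        Xt = test_group.intensity_matrix()
        return backend.predict(Xt, [test_group.sample_id] * len(test_group))

    results: list[EvaluationResult] = []
    fad_predictions: dict[str, PredictionSet] = {}
    fad_groups = [g for g in prepared if labels[g.sample_id] not in TRAIN_CLASSES]
    if fad_groups:
        # identical training set for every FAD round: train once, reuse
        acfg = AugmentConfig(**{**augment_config.__dict__})
        spectra, spec_labels, gids = augment_dataset(
            eligible, {g.sample_id: labels[g.sample_id] for g in eligible}, acfg
        )
        X = np.stack([s.intensities for s in spectra])
        backend = backend_factory()
        backend.fit(
            X, spec_labels, gids,
            forbidden_groups={g.sample_id for g in fad_groups},
        )
        for g in fad_groups:
            fad_predictions[g.sample_id] = backend.predict(
                g.intensity_matrix(), [g.sample_id] * len(g)
            )

    for round_idx, g in enumerate(prepared):
        true_label = labels[g.sample_id]
        expected = EXPECTED_CLASS[true_label]
        preds = (
            fad_predictions[g.sample_id]
            if true_label not in TRAIN_CLASSES
            else run_round(g, round_idx)
        )
        predicted, score = vote_score(preds, expected)
        results.append(
            EvaluationResult(
                sample_id=g.sample_id,
                true_label=true_label,
                expected_label=expected,
                predicted_label=predicted,
                score=score,
                n_test_spectra=len(g),
                call=classify(score),
            )
        )
    return results


def leave_one_out(
    X: np.ndarray,
    labels: Sequence[str],
    backend_factory: Callable[[], object],
    folds: int | None = None,
    seed: int = 0,
) -> float:
    """Spectrum-level leave-one-out accuracy (percent).

    The default holds out every spectrum once, training on the rest — the
    low-bias protocol suited to small spectral datasets.  ``folds=k`` is a
    cheaper k-fold approximation for larger inputs.  Group dependence is
    deliberately ignored here; see :func:`leave_one_group_out` for the
    sample-level protocol.
    """
    X = np.asarray(X)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two spectra")
    if folds is None:
        fold_assign = np.arange(n)
        n_folds = n
    else:
        rng = np.random.default_rng(seed)
        fold_assign = rng.permutation(n) % folds
        n_folds = folds
    correct = 0
    for f in range(n_folds):
        test = fold_assign == f
        if not test.any():
            continue
        backend = backend_factory()
        gids = [f"spec{i}" for i in np.flatnonzero(~test)]
        backend.fit(X[~test], labels[~test].tolist(), gids)
        preds = backend.predict(X[test], ["held_out"] * int(test.sum()))
        correct += int((preds.labels == labels[test]).sum())
    return 100.0 * correct / n


def summarize(
    results: Sequence[EvaluationResult], by: str = "true_label"
) -> list[GroupSummary]:
    """Per-label n, correct calls, accuracy percent and mean vote score,
    plus an ``overall`` row.  Indeterminate calls count as not correct."""
    if not results:
        raise ValueError("no results to summarize")
    order: list[str] = []
    buckets: dict[str, list[EvaluationResult]] = {}
    for r in results:
        key = getattr(r, by)
        if key not in buckets:
            order.append(key)
            buckets[key] = []
        buckets[key].append(r)
    out = []
    for key in order:
        rs = buckets[key]
        n_corr = sum(r.call == "correct" for r in rs)
        out.append(
            GroupSummary(
                group_label=key,
                n=len(rs),
                n_correct=n_corr,
                accuracy=100.0 * n_corr / len(rs),
                mean_score=float(np.mean([r.score for r in rs])),
            )
        )
    n_corr = sum(r.call == "correct" for r in results)
    out.append(
        GroupSummary(
            group_label="overall",
            n=len(results),
            n_correct=n_corr,
            accuracy=100.0 * n_corr / len(results),
            mean_score=float(np.mean([r.score for r in results])),
        )
    )
    return out


# ---------------------------------------------------------------------------
# packaged reference scores

def load_reference_scores() -> pd.DataFrame:
    """Published per-sample vote scores of the reference CSF cohorts
    (17 non-FAD samples and 9 FAD-related samples), as a DataFrame with
    columns sample_id, cohort, label, score."""
    with importlib.resources.files("sersdx").joinpath(
        "data/reference_scores.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def results_from_scores(df: pd.DataFrame) -> list[EvaluationResult]:
    """Re-express a score table as :class:`EvaluationResult` rows so the
    summary statistics can be recomputed from the printed scores alone."""
    results = []
    for row in df.itertuples():
        expected = EXPECTED_CLASS[row.label]
        call = classify(float(row.score))
        results.append(
            EvaluationResult(
                sample_id=str(row.sample_id),
                true_label=row.label,
                expected_label=expected,
                predicted_label=expected if call == "correct" else None,
                score=float(row.score),
                n_test_spectra=0 if not hasattr(row, "n") else int(row.n),
                call=call,
            )
        )
    return results
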