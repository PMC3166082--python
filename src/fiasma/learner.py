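"""Binary classification of functional ASM inhibition.

Workflow: a labelled descriptor matrix (class 1 = active, residual ASM
activity <= 50 %; class 0 = inactive) is filtered (near-zero-variance
columns dropped), candidate descriptors are ranked by several label-
relevance weightings, a beam search over descriptor combinations is scored
by bootstrap-validated Youden index, and the surviving model is challenged
with a response-permutation (Y-scrambling) null.

The Youden index (sensitivity + specificity - 1) is the primary performance
measure because the class distribution is unbalanced (roughly 1:3); plain
accuracy would reward the majority-class ("zero rule") baseline.

Validation is bootstrap resampling: the forest is refit on a
with-replacement sample of the rows and evaluated on the out-of-bag rows;
means and standard deviations are reported across resamples.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._forest import RandomForest
from ._rng import derive_seed
from .errors import PipelineError, ValidationError
from .descriptors import MODEL_DESCRIPTORS

__all__ = [
    "ForestSpec",
    "ValidationReport",
    "ModelArtifact",
    "youden",
    "zero_rule",
    "variance_filter",
    "weight_features",
    "candidate_pool",
    "fit_forest",
    "bootstrap_validate",
    "beam_search",
    "y_scramble",
]


def youden(tp: int, fp: int, tn: int, fn: int) -> float:
    """Youden index J = sensitivity + specificity - 1, in [-1, 1].

    Requires at least one positive (tp+fn) and one negative (tn+fp) truth.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValidationError("confusion-matrix counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("Youden index undefined: one truth class is empty")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def zero_rule(labels: Sequence[int]) -> float:
    """Accuracy of the majority-class baseline classifier."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValidationError("zero_rule requires non-empty labels")
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / y.size)


@dataclass
class ForestSpec:
    """Random-forest hyperparameters.

    ``mtry`` defaults to floor(log_base(m)) + 1 features per split, with
    base 2 (``mtry_log_base``); natural log is available for comparison.
    """

    ntree: int = 51
    nodesize: int = 1
    maxdepth: int = 8
    mtry: int | None = None
    mtry_log_base: float = 2.0
    seed: int = 0

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return max(1, min(self.mtry, n_features))
        return max(1, min(int(math.log(n_features, self.mtry_log_base)) + 1, n_features))


def fit_forest(x, y, spec: ForestSpec | None = None) -> RandomForest:
    """Fit the forest on the full matrix (final, non-validated model)."""
    spec = spec or ForestSpec()
    x = np.asarray(x, dtype=float)
    forest = RandomForest(
        ntree=spec.ntree,
        nodesize=spec.nodesize,
        mtry=spec.resolve_mtry(x.shape[1]),
        maxdepth=spec.maxdepth,
        seed=spec.seed,
    )
    return forest.fit(x, np.asarray(y))


# --- feature filtering and weighting ----------------------------------------

def variance_filter(matrix: pd.DataFrame, threshold: float = 1e-8) -> list[str]:
    """Names of columns whose range-scaled variance is >= ``threshold``.

    Columns are scaled to unit range before computing the variance, so the
    filter is insensitive to descriptor units; constant columns always fall.
    """
    retained = []
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        rng_ = v.max() - v.min()
        if rng_ <= 0:
            continue
        if ((v - v.min()) / rng_).var() >= threshold:
            retained.append(col)
    if not retained:
        raise PipelineError("variance filter removed every column")
    return retained


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _information_gain(v: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    vals, inverse = np.unique(v, return_inverse=True)
    if vals.size < 2:
        return 0.0
    if vals.size <= bins:  # few-valued column: one bin per distinct value
        which = inverse
    else:
        edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)))
        which = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, edges.size - 2)
    h_y = _entropy(np.bincount(y))
    h_cond = 0.0
    for b in np.unique(which):
        mask = which == b
        h_cond += mask.mean() * _entropy(np.bincount(y[mask], minlength=2))
    return h_y - h_cond


def _relief(x: np.ndarray, y: np.ndarray, k: int = 10, rng: np.random.Generator | None = None) -> np.ndarray:
    """Basic ReliefF weights for binary labels on range-scaled features."""
    rng = rng or np.random.default_rng(0)
    n, m = x.shape
    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0
    xs = (x - x.min(axis=0)) / span
    w = np.zeros(m)
    for i in range(n):
        d = np.abs(xs - xs[i]).sum(axis=1)
        d[i] = np.inf
        for target, sign in ((y == y[i], -1.0), (y != y[i], +1.0)):
            idx = np.where(target)[0]
            idx = idx[idx != i]
            if idx.size == 0:
                continue
            near = idx[np.argsort(d[idx])[: min(k, idx.size)]]
            w += sign * np.abs(xs[near] - xs[i]).mean(axis=0)
    return w / n


def weight_features(
    matrix: pd.DataFrame, labels, method: str = "correlation"
) -> dict[str, float]:
    """Label-relevance weight per column; higher = more relevant.

    Methods: ``correlation`` (|Pearson r|), ``information_gain`` (entropy
    reduction over quantile bins), ``relief`` (ReliefF nearest-hit/miss
    margins). Requires both classes with at least two rows each.
    """
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2 or min(np.bincount(y)) < 2:
        raise ValidationError("feature weighting requires >= 2 rows per class")
    x = matrix.to_numpy(dtype=float)
    if method == "correlation":
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore"):
            r = np.where(denom > 0, np.abs(xc.T @ yc) / denom, 0.0)
        weights = r
    elif method == "information_gain":
        weights = np.array([_information_gain(x[:, j], y) for j in range(x.shape[1])])
    elif method == "relief":
        weights = _relief(x, y)
    else:
        raise ValidationError(f"unknown weighting method {method!r}")
    return dict(zip(matrix.columns, weights.tolist()))


def candidate_pool(
    matrix: pd.DataFrame,
    labels,
    methods: Iterable[str] = ("correlation", "information_gain", "relief"),
    top_q: int = 30,
    redundancy_r: float | None = 0.90,
) -> list[str]:
    """Union of the top-q columns under each weighting method.

    With ``redundancy_r`` set (default 0.90), the union is additionally
    pruned for collinearity: candidates are visited in order of decreasing
    combined rank weight and dropped when their |Pearson r| to an already
    kept candidate exceeds the bound, so each signal axis enters the beam
    search once, represented by its best-weighted descriptor. Returned in
    matrix column order.
    """
    per_method: list[dict[str, float]] = []
    chosen: set[str] = set()
    for method in methods:
        w = weight_features(matrix, labels, method)
        per_method.append(w)
        ranked = sorted(w, key=lambda c: (-w[c], c))
        chosen.update(ranked[:top_q])
    if redundancy_r is not None and len(chosen) > 1:
        # combined weight: mean of per-method ranks normalised to [0, 1]
        combined: dict[str, float] = {}
        for c in chosen:
            scores = []
            for w in per_method:
                ranked = sorted(w, key=lambda col: (-w[col], col))
                scores.append(1.0 - ranked.index(c) / max(len(ranked) - 1, 1))
            combined[c] = float(np.mean(scores))
        corr = matrix[sorted(chosen)].corr().abs()
        kept: list[str] = []
        for c in sorted(chosen, key=lambda col: (-combined[col], col)):
            if all(corr.loc[c, k] <= redundancy_r for k in kept):
                kept.append(c)
        chosen = set(kept)
    return [c for c in matrix.columns if c in chosen]


# --- bootstrap validation ----------------------------------------------------

@dataclass
class ValidationReport:
    """Out-of-bag bootstrap performance summary."""

    youden_values: np.ndarray
    accuracy_values: np.ndarray
    sensitivity_values: np.ndarray
    specificity_values: np.ndarray
    n_resamples: int
    seed: int
    n_redrawn: int = 0

    @property
    def youden_mean(self) -> float:
        return float(self.youden_values.mean())

    @property
    def youden_sd(self) -> float:
        return float(self.youden_values.std(ddof=1))

    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracy_values.mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.accuracy_values.std(ddof=1))

    @property
    def sensitivity_mean(self) -> float:
        return float(self.sensitivity_values.mean())

    @property
    def specificity_mean(self) -> float:
        return float(self.specificity_values.mean())

    def summary(self) -> dict[str, float]:
        return {
            "youden_mean": self.youden_mean,
            "youden_sd": self.youden_sd,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity_mean": self.sensitivity_mean,
            "specificity_mean": self.specificity_mean,
            "n_resamples": self.n_resamples,
            "n_redrawn": self.n_redrawn,
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


def bootstrap_validate(
    x,
    y,
    spec: ForestSpec | None = None,
    n_resamples: int = 200,
    seed: int = 0,
    estimator: str = "oob",
) -> ValidationReport:
    """Bootstrap-validate the forest: fit on in-bag rows, score out-of-bag.

    ``estimator="oob"`` (default) reports plain out-of-bag scores;
    ``".632"`` blends them with the resubstitution score
    (0.368 x resubstitution + 0.632 x out-of-bag), the classical
    optimism-corrected bootstrap estimate.

    A resample whose out-of-bag set contains only one truth class is
    redrawn (counted); more than 50 % redraws abort with an error.
    """
    if estimator not in ("oob", ".632"):
        raise ValidationError(f"unknown estimator {estimator!r}")
    spec = spec or ForestSpec()
    x = np.ascontiguousarray(np.asarray(x, dtype=np.float32))
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValidationError("bootstrap validation requires both classes")
    n = len(y)
    rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
    js, accs, sens, specs = [], [], [], []
    n_redrawn = 0
    max_redraws = max(1, n_resamples // 2)
    for _ in range(n_resamples):
        while True:
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size and np.unique(y[oob]).size == 2 and np.unique(y[idx]).size == 2:
                break
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise PipelineError("more than 50% of bootstrap resamples redrawn")
        forest = RandomForest(
            ntree=spec.ntree,
            nodesize=spec.nodesize,
            mtry=spec.resolve_mtry(x.shape[1]),
            maxdepth=spec.maxdepth,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).fit(x[idx], y[idx])
        pred = forest.predict(x[oob])
        tp, fp, tn, fn = _confusion(y[oob], pred)
        j = youden(tp, fp, tn, fn)
        acc = (tp + tn) / oob.size
        if estimator == ".632":
            pred_in = forest.predict(x)
            tpi, fpi, tni, fni = _confusion(y, pred_in)
            j = 0.368 * youden(tpi, fpi, tni, fni) + 0.632 * j
            acc = 0.368 * ((tpi + tni) / len(y)) + 0.632 * acc
        js.append(j)
        accs.append(acc)
        sens.append(tp / (tp + fn))
        specs.append(tn / (tn + fp))
    return ValidationReport(
        youden_values=np.array(js),
        accuracy_values=np.array(accs),
        sensitivity_values=np.array(sens),
        specificity_values=np.array(specs),
        n_resamples=n_resamples,
        seed=seed,
        n_redrawn=n_redrawn,
    )


# --- beam search over descriptor combinations -------------------------------

@dataclass
class BeamResult:
    """Winner for one combination size."""

    combination: tuple[str, ...]
    report: ValidationReport


def beam_search(
    matrix: pd.DataFrame,
    labels,
    candidates: Sequence[str] | None = None,
    beam_width: int = 10,
    max_size: int = 5,
    spec: ForestSpec | None = None,
    seed: int = 0,
    score_resamples: int = 200,
    final_resamples: int | None = None,
    refine_top: int = 1,
) -> dict[int, BeamResult]:
    """Greedy beam search over descriptor combinations, sizes 1..max_size.

    Each candidate combination is scored by the mean bootstrap-validated
    Youden index (``score_resamples`` resamples). Per size, the top
    ``refine_top`` beam members are re-validated at ``final_resamples``
    (two-stage selection: a cheap screen followed by a high-resolution
    paired comparison of the shortlist) and the best becomes the reported
    winner. Ties are broken by fewer descriptors, then lexicographic name
    order.
    """
    spec = spec or ForestSpec()
    candidates = list(candidates) if candidates is not None else list(matrix.columns)
    if not candidates:
        raise PipelineError("beam search needs a non-empty candidate pool")
    y = np.asarray(labels).astype(int)
    cache: dict[tuple[str, ...], float] = {}

    # common random numbers: every combination is scored on the same
    # bootstrap resamples, so combination comparisons are paired and small
    # true performance differences are not drowned by resampling noise
    score_seed = derive_seed(seed, "beam-score")

    def score(combo: tuple[str, ...]) -> float:
        if combo not in cache:
            rep = bootstrap_validate(
                matrix[list(combo)], y, spec,
                n_resamples=score_resamples,
                seed=score_seed,
            )
            cache[combo] = rep.youden_mean
        return cache[combo]

    def ranked(combos: Iterable[tuple[str, ...]]) -> list[tuple[str, ...]]:
        return sorted(set(combos), key=lambda c: (-score(c), len(c), c))

    final_seed = derive_seed(seed, "beam-final")

    def finalize(combos: list[tuple[str, ...]]) -> BeamResult:
        shortlist = combos[: max(1, refine_top)]
        reports = {
            c: bootstrap_validate(
                matrix[list(c)], y, spec,
                n_resamples=final_resamples or score_resamples,
                seed=final_seed,
            )
            for c in shortlist
        }
        best = min(shortlist, key=lambda c: (-reports[c].youden_mean, len(c), c))
        return BeamResult(best, reports[best])

    results: dict[int, BeamResult] = {}
    beam = ranked((c,) for c in candidates)[:beam_width]
    size = 1
    while True:
        results[size] = finalize(beam)
        if size == max_size:
            break
        expansions = [
            tuple(sorted(c + (extra,)))
            for c in beam
            for extra in candidates
            if extra not in c
        ]
        beam = ranked(expansions)[:beam_width]
        size += 1
    return results


# --- Y-scrambling ------------------------------------------------------------

@dataclass
class YScrambleResult:
    """Response-permutation null distribution for a fixed combination."""

    null_youden: np.ndarray  # mean bootstrap Youden per permutation
    null_accuracy: np.ndarray
    reference: ValidationReport  # unpermuted-labels validation

    @property
    def null_youden_mean(self) -> float:
        return float(self.null_youden.mean())

    @property
    def null_youden_sd(self) -> float:
        return float(self.null_youden.std(ddof=1))

    @property
    def null_accuracy_mean(self) -> float:
        return float(self.null_accuracy.mean())

    @property
    def null_accuracy_sd(self) -> float:
        return float(self.null_accuracy.std(ddof=1))

    @property
    def z_youden(self) -> float:
        """Standard deviations separating the true score from the null."""
        sd = self.null_youden_sd
        return (self.reference.youden_mean - self.null_youden_mean) / sd if sd > 0 else math.inf

    @property
    def z_accuracy(self) -> float:
        sd = self.null_accuracy_sd
        return (self.reference.accuracy_mean - self.null_accuracy_mean) / sd if sd > 0 else math.inf


def y_scramble(
    matrix: pd.DataFrame,
    labels,
    combination: Sequence[str],
    spec: ForestSpec | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    n_resamples: int = 200,
) -> YScrambleResult:
    """Refit-and-validate under uniformly permuted labels.

    Each permutation runs the full bootstrap validation; the distribution of
    per-permutation mean Youden/accuracy estimates the chance-correlation
    baseline for the fixed descriptor combination.
    """
    spec = spec or ForestSpec()
    y = np.asarray(labels).astype(int)
    sub = matrix[list(combination)]
    reference = bootstrap_validate(
        sub, y, spec, n_resamples=n_resamples, seed=derive_seed(seed, "reference")
    )
    rng = np.random.default_rng(derive_seed(seed, "permutation"))
    null_j, null_a = [], []
    for i in range(n_permutations):
        perm = rng.permutation(y)
        rep = bootstrap_validate(
            sub, perm, spec, n_resamples=n_resamples, seed=derive_seed(seed, "scramble", i)
        )
        null_j.append(rep.youden_mean)
        null_a.append(rep.accuracy_mean)
    return YScrambleResult(np.array(null_j), np.array(null_a), reference)


# --- model artifact ----------------------------------------------------------

ARTIFACT_VERSION = 1


@dataclass
class ModelArtifact:
    """A trained classifier plus everything needed to apply it to new data."""

    forest: RandomForest
    spec: ForestSpec
    descriptor_names: list[str] = field(default_factory=lambda: list(MODEL_DESCRIPTORS))
    activity_threshold: float = 50.0
    version: int = ARTIFACT_VERSION

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.descriptor_names if c not in matrix.columns]
        if missing:
            raise ValidationError(f"matrix lacks model descriptors: {missing}")
        return self.forest.predict(matrix[self.descriptor_names].to_numpy(dtype=float))

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "ModelArtifact":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls) or obj.version != ARTIFACT_VERSION:
            raise ValidationError("incompatible model artifact")
        return obj


def train_model(
    matrix: pd.DataFrame,
    labels,
    combination: Sequence[str] | None = None,
    spec: ForestSpec | None = None,
) -> ModelArtifact:
    """Fit the final (non-validated) model on the whole labelled set."""
    combination = list(combination) if combination is not None else list(MODEL_DESCRIPTORS)
    spec = spec or ForestSpec()
    forest = fit_forest(matrix[combination].to_numpy(dtype=float), labels, spec)
    return ModelArtifact(forest=forest, spec=spec, descriptor_names=combination)
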