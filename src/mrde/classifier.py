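"""Tumour-Normal-Difference features and the trial-ensemble MLP classifier.

Each tumour sample, paired with its patient's adjacent-normal sample on a
normalized log2 scale, yields one Tumour-Normal-Difference (TND) instance;
patient baselines cancel in the subtraction, which is what lets a model
trained on one cohort transfer to another.  A feed-forward network (four
linear layers — three ReLU-activated with Kaiming initialization, a final
softmax layer with Xavier initialization — trained with SGD, learning rate
0.01, momentum 0.9, cross-entropy loss, batch size 32) is fitted on a fresh
random 70/30 instance split in each of ``n_trials`` trials; every trial also
predicts the label of each instance of the unlabelled cohort.  Per-instance
label counts over trials are then tested against the uniform expectation
(n_trials / k per group) with a chi-square goodness-of-fit test; after BH
correction across instances, significant instances receive the label with
the highest standardized residual, the rest stay unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import NormalizedMatrix
from .io import NORMAL, TUMOUR, SampleTable
from .survstats import bh_fdr, chisq_gof

UNASSIGNED = "unassigned"


@dataclass
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (200, 100, 50)
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 500
    batch_size: int = 32
    train_fraction: float = 0.7
    n_trials: int = 1000

    def validate(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if min(self.learning_rate, self.epochs, self.batch_size, self.n_trials) <= 0:
            raise ValueError("learning_rate, epochs, batch_size, n_trials must be positive")


@dataclass
class TNDMatrix:
    """One instance per tumour sample: tumour minus matched normal expression."""

    instance_ids: list[str]
    patient_ids: list[str]
    gene_ids: list[str]
    x: np.ndarray  # (n_instances, n_genes)
    labels: np.ndarray | None = None  # integer group per instance, or None

    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)


def build_tnd(
    norm: NormalizedMatrix,
    samples: SampleTable,
    gene_subset,
    patient_labels: dict[str, int] | None = None,
) -> TNDMatrix:
    """TND feature matrix over ``gene_subset`` from a normalized matrix.

    Every tumour sample must have a normal sample of the same patient in the
    matrix; a patient's label (training cohort) is copied to each of its
    instances.
    """
    frame = norm.to_frame()
    missing = [g for g in gene_subset if g not in frame.index]
    if missing:
        raise ValueError(f"genes absent from normalized matrix: {missing[:5]}...")
    frame = frame.loc[list(gene_subset)]
    sub = samples.subset(norm.sample_ids)
    instance_ids, patient_ids, rows, labels = [], [], [], []
    for p in sub.patient_ids:
        tumours = sub.samples_of(p, TUMOUR)
        normals = sub.samples_of(p, NORMAL)
        if tumours and not normals:
            raise ValueError(f"patient {p!r} has tumour samples but no normal sample")
        if not tumours:
            continue
        normal_col = frame[normals[0]].to_numpy()
        for t in tumours:
            instance_ids.append(t)
            patient_ids.append(p)
            rows.append(frame[t].to_numpy() - normal_col)
            if patient_labels is not None:
                labels.append(patient_labels[p])
    return TNDMatrix(
        instance_ids=instance_ids,
        patient_ids=patient_ids,
        gene_ids=list(gene_subset),
        x=np.vstack(rows) if rows else np.empty((0, len(list(gene_subset)))),
        labels=np.asarray(labels, dtype=int) if patient_labels is not None else None,
    )


class _MLP:
    """Feed-forward net: Kaiming-initialized ReLU layers + Xavier softmax head."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        last = len(sizes) - 2
        for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            if i < last:
                scale = np.sqrt(2.0 / fan_in)  # Kaiming for ReLU layers
            else:
                scale = np.sqrt(2.0 / (fan_in + fan_out))  # Xavier for softmax head
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.v_w = [np.zeros_like(w) for w in self.weights]
        self.v_b = [np.zeros_like(b) for b in self.biases]

    def _forward(self, x: np.ndarray):
        acts = [x]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ w + b
            if i < len(self.weights) - 1:
                z = np.maximum(z, 0.0)
            acts.append(z)
        return acts

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._softmax(self._forward(x)[-1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def fit(self, x: np.ndarray, y: np.ndarray, config: MLPConfig,
            rng: np.random.Generator) -> None:
        n, k = x.shape[0], self.biases[-1].size
        onehot = np.eye(k)[y]
        lr, mom = config.learning_rate, config.momentum
        for _ in range(config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                acts = self._forward(x[idx])
                probs = self._softmax(acts[-1])
                delta = (probs - onehot[idx]) / len(idx)  # softmax + CE gradient
                for layer in range(len(self.weights) - 1, -1, -1):
                    grad_w = acts[layer].T @ delta
                    grad_b = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
                    self.v_w[layer] = mom * self.v_w[layer] - lr * grad_w
                    self.v_b[layer] = mom * self.v_b[layer] - lr * grad_b
                    self.weights[layer] += self.v_w[layer]
                    self.biases[layer] += self.v_b[layer]


def train_trial(
    tnd: TNDMatrix, config: MLPConfig, trial_seed: int, n_classes: int | None = None
) -> tuple[np.ndarray, np.ndarray, float, _MLP]:
    """One trial: random 70/30 split, train, score the held-out instances.

    Returns (test indices, predicted labels on the test split, test accuracy,
    fitted model).  A split leaving a class out of the training set is
    resampled (with a note) up to 100 times.
    """
    config.validate()
    if tnd.labels is None:
        raise ValueError("training TND matrix has no labels")
    k = int(n_classes if n_classes is not None else tnd.labels.max() + 1)
    if len(np.unique(tnd.labels)) < 2:
        raise ValueError("need >=2 classes in the training data")
    rng = np.random.default_rng(trial_seed)
    n = tnd.n_instances
    n_train = max(1, int(round(config.train_fraction * n)))
    classes = np.unique(tnd.labels)
    for attempt in range(100):
        order = rng.permutation(n)
        train_idx, test_idx = order[:n_train], order[n_train:]
        if np.isin(classes, tnd.labels[train_idx]).all() and test_idx.size:
            break
        if attempt == 99:
            raise ValueError("could not draw a split containing every class")
        warnings.warn("resampling split: a class was missing from the training set",
                      stacklevel=2)
    model = _MLP([tnd.x.shape[1], *config.hidden_sizes, k], rng)
    model.fit(tnd.x[train_idx], tnd.labels[train_idx], config, rng)
    preds = model.predict(tnd.x[test_idx])
    accuracy = float((preds == tnd.labels[test_idx]).mean())
    return test_idx, preds, accuracy, model


@dataclass
class TrialPredictions:
    """Accumulated ensemble output: per-trial accuracy and label counts."""

    accuracies: np.ndarray  # (n_trials,)
    counts: pd.DataFrame  # instances x groups, counts summing to n_trials
    n_trials: int


def run_trials(
    tnd_train: TNDMatrix,
    tnd_predict: TNDMatrix,
    config: MLPConfig,
    seed: int = 0,
) -> TrialPredictions:
    """Trial ensemble: fresh split + fit per trial, predicting the target cohort."""
    if tnd_train.gene_ids != tnd_predict.gene_ids:
        raise ValueError("train and predict matrices must share the same gene features")
    if tnd_train.labels is None:
        raise ValueError("training TND matrix has no labels")
    k = int(tnd_train.labels.max() + 1)
    root = np.random.default_rng(seed)
    trial_seeds = root.integers(0, 2**31 - 1, size=config.n_trials)
    accuracies = np.empty(config.n_trials)
    counts = np.zeros((tnd_predict.n_instances, k), dtype=int)
    for trial in range(config.n_trials):
        _, _, acc, model = train_trial(tnd_train, config, int(trial_seeds[trial]), n_classes=k)
        accuracies[trial] = acc
        preds = model.predict(tnd_predict.x)
        counts[np.arange(len(preds)), preds] += 1
    frame = pd.DataFrame(counts, index=tnd_predict.instance_ids,
                         columns=[f"PG{j}" for j in range(k)])
    return TrialPredictions(accuracies=accuracies, counts=frame, n_trials=config.n_trials)


def expected_uniform_counts(n_trials: int, k_groups: int) -> np.ndarray:
    """Uniform-null expectation: n_trials / k predicted labels per group."""
    if n_trials < 1 or k_groups < 1:
        raise ValueError("n_trials and k_groups must be positive")
    return np.full(k_groups, n_trials / k_groups)


def aggregate_predictions(
    tp: TrialPredictions, k_groups: int | None = None, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """Final per-instance label via chi-square goodness of fit vs uniform.

    Instances whose label counts deviate from the uniform expectation
    (BH-adjusted GoF p < ``fdr_alpha``) get the label with the highest
    standardized residual (ties broken toward the lowest group index); the
    rest are left unassigned.
    """
    counts = tp.counts
    k = k_groups if k_groups is not None else counts.shape[1]
    expected = expected_uniform_counts(tp.n_trials, k)
    stats_, pvals, residuals = [], [], []
    for _, row in counts.iterrows():
        res = chisq_gof(row.to_numpy(), expected)
        stats_.append(res.statistic)
        pvals.append(res.p)
        residuals.append(res.extras["residuals"])
    fdr = bh_fdr(np.asarray(pvals))
    labels = []
    for i, resid in enumerate(residuals):
        if fdr[i] < fdr_alpha:
            labels.append(counts.columns[int(np.argmax(resid))])  # argmax: lowest index on ties
        else:
            labels.append(UNASSIGNED)
    out = pd.DataFrame(
        {
            "instance_id": counts.index,
            "gof_statistic": stats_,
            "p": pvals,
            "fdr": fdr,
            "label": labels,
        }
    )
    for j, col in enumerate(counts.columns):
        out[f"residual_{col}"] = [r[j] for r in residuals]
    return out.reset_index(drop=True)
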