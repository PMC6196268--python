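"""Stability selection via nested cross-validation.

The outer loop draws B stratified Monte-Carlo learning/test splits.  For each
split an inner stratified K-fold cross-validation picks the (tau, mu) pair
minimizing mean classification error (ties resolved toward smaller tau, then
smaller mu); the model is refit on the whole learning
set, its non-zero features recorded as that split's list and its test error
stored.  Features appearing in at least a fraction phi of the B lists form
the aggregated stable signature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, SampleMetadata
from .l1l2 import auto_tau_grid, fit_l1l2, predict

__all__ = [
    "SelectionRun",
    "nested_cv_select",
    "aggregate_by_frequency",
    "subset_matrix",
    "stratified_mc_splits",
]

# The l2 weight is fixed by default at 1e-2 x the spectral scale of the
# learning matrix, following the convention of cross-validating only the
# sparsity parameter: with strongly separable data every mu in a wide grid
# ties at zero inner error, so CV cannot identify mu, and any fixed tie
# preference lands on an extreme (too little l2 destabilizes which
# correlated feature is kept; too much selects most of the matrix).  A grid
# may still be supplied via mu_ratios.
DEFAULT_MU_RATIOS = (1e-2,)


@dataclass
class SplitResult:
    learning_ids: list[str]
    test_ids: list[str]
    tau: float
    mu: float
    selected: list[str]
    test_error: float
    beta: dict[str, float] = field(default_factory=dict)


@dataclass
class SelectionRun:
    B: int
    phi: float
    seed: int
    splits: list[SplitResult]
    frequency: dict[str, float]        # feature -> fraction of lists containing it
    signature: list[str]               # aggregated stable signature at phi
    mean_accuracy: float

    @property
    def mean_error(self) -> float:
        return 1.0 - self.mean_accuracy

    def frequency_curve(self) -> list[tuple[float, int]]:
        """(frequency threshold, #features at or above it) — the slope
        diagnostic used to justify the 50% cutoff."""
        freqs = sorted({round(i / self.B, 10) for i in range(1, self.B + 1)})
        return [(f, sum(1 for v in self.frequency.values() if v >= f - 1e-12))
                for f in freqs]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "B": self.B, "phi": self.phi, "seed": self.seed,
            "mean_accuracy": self.mean_accuracy,
            "signature": self.signature,
            "frequency": self.frequency,
            "splits": [
                {
                    "learning_ids": s.learning_ids, "test_ids": s.test_ids,
                    "tau": s.tau, "mu": s.mu, "selected": s.selected,
                    "test_error": s.test_error, "beta": s.beta,
                }
                for s in self.splits
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def stratified_mc_splits(
    labels: np.ndarray,
    B: int,
    test_fraction: float,
    rng: np.random.Generator,
    donors: np.ndarray | None = None,
):
    """B stratified random learning/test index splits.

    Each split draws ceil(test_fraction * n_g) samples per class without
    replacement.  With ``donors`` given, whole donors are assigned to the
    test side so paired samples never straddle the split.
    """
    n = len(labels)
    classes = np.unique(labels)
    splits = []
    for _ in range(B):
        test_idx: list[int] = []
        if donors is None:
            for c in classes:
                idx = np.flatnonzero(labels == c)
                k = int(np.ceil(test_fraction * len(idx)))
                if k >= len(idx):
                    raise ValueError("test fraction leaves an empty class")
                test_idx.extend(rng.choice(idx, size=k, replace=False))
        else:
            uniq = np.unique(donors)
            k = max(1, int(np.ceil(test_fraction * len(uniq))))
            chosen = rng.choice(uniq, size=k, replace=False)
            test_idx = list(np.flatnonzero(np.isin(donors, chosen)))
            train_labels = labels[~np.isin(np.arange(n), test_idx)]
            if len(np.unique(train_labels)) < len(classes):
                raise ValueError("donor-paired split leaves an empty class")
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
        splits.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return splits


def _inner_select(
    X: np.ndarray,
    y: np.ndarray,
    tau_grid: np.ndarray,
    mu_ratios,
    inner_folds: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Pick (tau, mu) by inner stratified K-fold error; ties resolve to
    smaller tau, then smaller mu."""
    n = len(y)
    smax2 = float(np.linalg.eigvalsh(
        (X - X.mean(0)) @ (X - X.mean(0)).T if n <= X.shape[1]
        else (X - X.mean(0)).T @ (X - X.mean(0))
    )[-1])
    spectral = max(smax2 / n, 1e-12)
    mu_grid = [r * spectral for r in mu_ratios]

    n_folds = min(inner_folds, int(np.bincount(((y + 1) / 2).astype(int)).min()))
    if n_folds < 2:
        raise ValueError("inner CV needs at least 2 samples per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    folds = list(skf.split(X, y))

    # error[mu][tau] averaged over folds; tau path warm-started per fold.
    # Ties in error resolve toward smaller tau (the denser model), then
    # smaller mu: with a strong signal the error floor is reached by many
    # (tau, mu) pairs, and preferring sparsity would discard the correlated
    # feature groups the frequency aggregation is meant to stabilize over.
    n_tau = len(tau_grid)
    best = None
    for mu in mu_grid:
        errors = np.zeros(n_tau)
        for tr, te in folds:
            beta0 = None
            for ti, tau in enumerate(tau_grid):
                m = fit_l1l2(X[tr], y[tr], tau=float(tau), mu=float(mu),
                             beta0=beta0)
                beta0 = m.beta
                errors[ti] += float(np.mean(predict(m, X[te]) != y[te]))
        errors /= len(folds)
        for ti, tau in enumerate(tau_grid):
            key = (errors[ti], float(tau), float(mu))
            if best is None or key < best:
                best = key
    return best[1], best[2]


def nested_cv_select(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    B: int = 5,
    test_fraction: float = 0.25,
    inner_folds: int = 4,
    tau_grid=None,
    mu_ratios=DEFAULT_MU_RATIOS,
    phi: float = 0.5,
    seed: int = 0,
    pair_by_donor: bool = False,
    groups: tuple[str, str] = ("bright", "dim"),
) -> SelectionRun:
    """Run the full nested-CV variable selection and aggregate the signature."""
    matrix.require_log2()
    md = metadata.align(matrix)
    samples = matrix.sample_ids
    y = md.two_group_labels(samples, positive=groups[1], negative=groups[0])
    for c in (-1.0, 1.0):
        if (y == c).sum() < B:
            raise ValueError(
                f"each group needs at least B={B} samples for stratified "
                f"splitting; reduce B"
            )
    X_full = matrix.values.T  # samples x features
    feature_names = matrix.feature_ids

    # constant features carry no information and break standardization
    sd = X_full.std(axis=0)
    if (sd == 0).any():
        dropped = [f for f, s in zip(feature_names, sd) if s == 0]
        warnings.warn(f"dropping {len(dropped)} constant feature(s)")
        keep = sd > 0
        X_full = X_full[:, keep]
        feature_names = [f for f, k in zip(feature_names, keep) if k]

    rng = np.random.default_rng(seed)
    donors = md.table["donor"].to_numpy() if pair_by_donor else None
    splits = stratified_mc_splits(y, B, test_fraction, rng, donors)

    results: list[SplitResult] = []
    counts: dict[str, int] = {}
    betas: dict[str, list[float]] = {}
    for train_idx, test_idx in splits:
        X_tr, y_tr = X_full[train_idx], y[train_idx]
        X_te, y_te = X_full[test_idx], y[test_idx]
        grid = (np.asarray(tau_grid, dtype=float) if tau_grid is not None
                else auto_tau_grid(X_tr, y_tr))
        tau, mu = _inner_select(X_tr, y_tr, grid, mu_ratios, inner_folds, rng)
        model = fit_l1l2(X_tr, y_tr, tau=tau, mu=mu, feature_names=feature_names)
        err = float(np.mean(predict(model, X_te) != y_te))
        sel = model.selected
        for f, b in zip(model.feature_names, model.beta):
            if b != 0.0:
                counts[f] = counts.get(f, 0) + 1
                betas.setdefault(f, []).append(abs(float(b)))
        results.append(SplitResult(
            learning_ids=[samples[i] for i in train_idx],
            test_ids=[samples[i] for i in test_idx],
            tau=float(tau), mu=float(mu), selected=sel, test_error=err,
            beta={f: float(b) for f, b in zip(model.feature_names, model.beta)
                  if b != 0.0},
        ))

    frequency = {f: c / B for f, c in counts.items()}
    mean_acc = 1.0 - float(np.mean([r.test_error for r in results]))
    run = SelectionRun(
        B=B, phi=phi, seed=seed, splits=results,
        frequency=frequency, signature=[], mean_accuracy=mean_acc,
    )
    run.signature = aggregate_by_frequency(run, phi, mean_abs_beta=betas)
    return run


def aggregate_by_frequency(
    run: SelectionRun,
    phi: float = 0.5,
    mean_abs_beta: dict[str, list[float]] | None = None,
) -> list[str]:
    """Features selected in at least a fraction phi of the B lists, ordered by
    (frequency desc, mean |beta| desc, name)."""
    if not 0 < phi <= 1:
        raise ValueError(f"phi must be in (0, 1], got {phi}")
    if not run.splits:
        raise ValueError("SelectionRun has no splits")
    if mean_abs_beta is None:
        mean_abs_beta = {}
        for s in run.splits:
            for f, b in s.beta.items():
                mean_abs_beta.setdefault(f, []).append(abs(b))
    scored = [
        (f, freq, float(np.mean(mean_abs_beta.get(f, [0.0]))))
        for f, freq in run.frequency.items()
        if freq >= phi - 1e-12
    ]
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [f for f, _, _ in scored]


def subset_matrix(matrix: ExpressionMatrix, signature) -> ExpressionMatrix:
    """Restrict the matrix to the signature's features, in signature order."""
    return matrix.subset_features(list(signature))
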