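"""Supervised core: nested feature selection + Naive Bayes under LOOCV.

The modeling chain is: equal-frequency discretization of each spectral
feature (training-fold-fitted cuts), symmetric-uncertainty (SU) scoring
against the class label, feature selection by FCBF (default) or top-k
univariate ranking, then a Gaussian Naive Bayes classifier on the
selected continuous features.  Everything that learns from data —
discretization cuts, SU ranking, FCBF pruning, NB parameters — is fitted
inside each leave-one-out fold, so the held-out sample never contributes
to feature ranking or classifier fitting.

Validity checks: a label-permutation test (nested pipeline rerun under
shuffled labels), quantile-binned reliability with the Brier score, and a
discriminant-band report aggregating per-fold selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, xlogy
from sklearn.metrics import roc_auc_score

from .preprocess import PreprocessConfig, apply_preprocess_pipeline, get_variant
from .spectra import SpectrumSet

_LN2 = np.log(2.0)


@dataclass
class ModelConfig:
    """Selector and classifier settings.

    selector: ``"fcbf"`` (default), ``"rank_top_k"`` or ``"none"``.
    """

    selector: str = "fcbf"
    k: int = 10
    fcbf_delta: float = 0.0
    n_bins: int = 4
    threshold: float = 0.5

    def __post_init__(self):
        if self.selector not in ("fcbf", "rank_top_k", "none"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.selector == "rank_top_k" and self.k < 1:
            raise ValueError("k must be >= 1 for rank_top_k")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.fcbf_delta < 0:
            raise ValueError("fcbf_delta must be >= 0")


# ---------------------------------------------------------------------------
# Discretization


def fit_equal_frequency_cuts(values: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Interior cut points = equal-frequency quantiles of the fit data.

    Uses the midpoint quantile convention (numpy ``method="midpoint"``):
    for values 1..8 with 4 bins the cuts are (2.5, 4.5, 6.5).  Works on a
    vector (returns shape ``(n_bins-1,)``) or a matrix fit column-wise
    (returns ``(n_bins-1, p)``).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < n_bins:
        raise ValueError(f"need >= {n_bins} fit values for {n_bins} bins")
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    return np.quantile(values, qs, axis=0, method="midpoint")


def apply_cuts(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Assign bin codes: code = number of cuts strictly below the value.

    Intervals are half-open, ``(c_{i-1}, c_i]``, right-closed at +inf:
    values at or below the first cut get code 0; values above all cuts get
    the top code.  Duplicate cuts (quantile ties) collapse bins.
    """
    values = np.asarray(values, dtype=float)
    cuts = np.asarray(cuts, dtype=float)
    if cuts.ndim == 1:
        return np.searchsorted(cuts, values, side="left").astype(np.int64)
    # matrix: values (n, p), cuts (b, p)
    return (values[:, None, :] > cuts[None, :, :]).sum(axis=1).astype(np.int64)


def equal_frequency_discretize(
    values: np.ndarray, n_bins: int = 4, fit_values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper: fit cuts (on *fit_values* or *values*) and code.

    Returns ``(codes, cuts)``; the cuts are reusable on unseen data via
    :func:`apply_cuts`.  A constant feature collapses to a single bin.
    """
    fit = values if fit_values is None else fit_values
    cuts = fit_equal_frequency_cuts(fit, n_bins)
    return apply_cuts(values, cuts), cuts


# ---------------------------------------------------------------------------
# Symmetric uncertainty


def _entropy_from_counts(counts: np.ndarray, axis=0) -> np.ndarray:
    """Plug-in entropy (bits) from a count array along *axis*."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.log2(np.where(n > 0, n, 1.0)) - (
            xlogy(counts, counts).sum(axis=axis) / _LN2
        ) / np.where(n > 0, n, 1.0)
    return h


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(X;Y) = 2 I(X;Y) / (H(X) + H(Y)), plug-in entropies in bits.

    Bounded in [0, 1]; defined as 0 when both variables are constant.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    return float(su_profile(x[:, None], y)[0])


def su_profile(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SU of every column of *codes* against the discrete vector *y*.

    Vectorized over columns via one-hot contingency counts; the workhorse
    for per-fold feature ranking and FCBF redundancy checks.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if codes.ndim == 1:
        codes = codes[:, None]
    y = np.asarray(y, dtype=np.int64).ravel()
    n, p = codes.shape
    if n != y.size:
        raise ValueError("length mismatch between codes and y")
    lx = int(codes.max()) + 1 if codes.size else 1
    ly = int(y.max()) + 1
    x1 = (codes[:, None, :] == np.arange(lx)[None, :, None]).astype(float)
    y1 = (y[:, None] == np.arange(ly)[None, :]).astype(float)
    joint = np.einsum("na,nbp->abp", y1, x1)  # (ly, lx, p)
    hx = _entropy_from_counts(x1.sum(axis=0), axis=0)  # (p,)
    hy = float(_entropy_from_counts(y1.sum(axis=0)))
    hxy = _entropy_from_counts(joint.reshape(ly * lx, p), axis=0)
    denom = hx + hy
    mi = np.clip(hx + hy - hxy, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        su = np.where(denom > 0, 2.0 * mi / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(su, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Feature selection


def fcbf_select(
    codes: np.ndarray, y: np.ndarray, delta: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fast Correlation-Based Filter.

    (i) keep features with SU(f, label) > delta; (ii) order descending by
    label SU, ties by smallest feature index; (iii) predominance scan: a
    candidate f is removed if some retained higher-ranked feature g has
    SU(f, g) >= SU(f, label).  Returns ``(selected_indices_in_rank_order,
    su_with_label_for_all_features)``.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
    su_label = su_profile(codes, y)
    cand = np.nonzero(su_label > delta)[0]
    order = cand[np.lexsort((cand, -su_label[cand]))]
    selected: list[int] = []
    redundancy_rows: list[np.ndarray] = []  # SU(g, all features) per selected g
    for f in order:
        dominated = any(
            row[f] >= su_label[f] for row in redundancy_rows
        )
        if dominated:
            continue
        selected.append(int(f))
        redundancy_rows.append(su_profile(codes, codes[:, f]))
    return np.array(selected, dtype=int), su_label


def rank_top_k(
    codes: np.ndarray, y: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate ranking: top-k features by label SU, ties by index."""
    codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
    su_label = su_profile(codes, y)
    idx = np.arange(su_label.size)
    order = idx[np.lexsort((idx, -su_label))]
    return order[: min(k, order.size)], su_label


def _select(codes, y, cfg: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    if cfg.selector == "fcbf":
        return fcbf_select(codes, y, cfg.fcbf_delta)
    if cfg.selector == "rank_top_k":
        return rank_top_k(codes, y, cfg.k)
    su_label = su_profile(codes, y)
    return np.arange(codes.shape[1]), su_label


# ---------------------------------------------------------------------------
# Gaussian Naive Bayes

_VAR_EPS = 1e-9


def gaussian_nb_train_predict(
    train: np.ndarray, train_labels: np.ndarray, test: np.ndarray
) -> np.ndarray:
    """Train a Gaussian NB on continuous features; return test posteriors.

    Per class and feature a Gaussian is fitted (MLE variance), with every
    variance floored at ``1e-9 * max(pooled variance)`` for numerical
    safety; priors are training class frequencies; posteriors computed in
    log space via log-sum-exp.  Output rows sum to 1, columns ordered
    (class 0, class 1).
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    test = np.atleast_2d(np.asarray(test, dtype=float))
    y = np.asarray(train_labels, dtype=int).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    pooled = train.var(axis=0)
    floor = _VAR_EPS * max(float(pooled.max()), np.finfo(float).tiny)
    log_post = np.empty((test.shape[0], classes.size))
    for ci, c in enumerate(classes):
        sub = train[y == c]
        mu = sub.mean(axis=0)
        var = np.maximum(sub.var(axis=0), floor)
        log_prior = np.log(sub.shape[0] / train.shape[0])
        ll = -0.5 * (
            np.log(2 * np.pi * var) + (test - mu) ** 2 / var
        ).sum(axis=1)
        log_post[:, ci] = log_prior + ll
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


# ---------------------------------------------------------------------------
# Metrics


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC via the rank (Mann-Whitney) statistic with midrank ties."""
    labels = np.asarray(labels, dtype=int).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).ravel()))


def classification_metrics(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict:
    """AUC plus thresholded confusion metrics.

    F1/precision/recall are computed per class and macro-averaged; the
    headline ``f1``/``precision``/``recall`` fields are the macro values
    and ``specificity`` is the true-negative rate (= recall of class 0).
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if np.unique(y).size < 2:
        raise ValueError("metrics need both classes present")
    pred = (probs >= threshold).astype(int)
    per_class = {}
    for c in (0, 1):
        tp = int(np.sum((pred == c) & (y == c)))
        fp = int(np.sum((pred == c) & (y != c)))
        fn = int(np.sum((pred != c) & (y == c)))
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1}
    return {
        "auc": auc_mann_whitney(probs, y),
        "accuracy": float(np.mean(pred == y)),
        "f1": (per_class[0]["f1"] + per_class[1]["f1"]) / 2,
        "precision": (per_class[0]["precision"] + per_class[1]["precision"]) / 2,
        "recall": (per_class[0]["recall"] + per_class[1]["recall"]) / 2,
        "specificity": per_class[0]["recall"],
        "per_class": per_class,
    }


# ---------------------------------------------------------------------------
# Nested LOOCV


@dataclass
class CVResult:
    sample_ids: list[str]
    labels: np.ndarray
    oof_prob: np.ndarray                 # P(class 1) for each held-out sample
    fold_selected: list[np.ndarray]      # selected feature indices per fold
    fold_su: list[np.ndarray]            # label SU of the selected features
    wavenumbers: np.ndarray
    metrics: dict
    train_metrics: dict
    seed: int | None = None
    provenance: str = ""


def _fit_and_score_fold(x_tr, y_tr, x_te, cfg: ModelConfig):
    """One fold: discretize on training data, select, train NB, score test.

    Returns (positive-class probabilities, selected indices, their SU).
    With an empty selection the fold falls back to the training prior.
    """
    cuts = fit_equal_frequency_cuts(x_tr, cfg.n_bins)
    codes_tr = apply_cuts(x_tr, cuts)
    sel, su_label = _select(codes_tr, y_tr, cfg)
    if sel.size == 0:
        prior = float(np.mean(y_tr == 1))
        return np.full(np.atleast_2d(x_te).shape[0], prior), sel, su_label[sel]
    probs = gaussian_nb_train_predict(x_tr[:, sel], y_tr, np.atleast_2d(x_te)[:, sel])
    return probs[:, 1], sel, su_label[sel]


def nested_loocv(
    x: np.ndarray, y: np.ndarray, cfg: ModelConfig
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Array-level nested LOOCV: returns out-of-fold positive-class
    probabilities plus per-fold selections and their label-SU values."""
    n = x.shape[0]
    oof = np.empty(n)
    fold_sel, fold_su = [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            raise ValueError(f"class absent from training fold {i}")
        p, sel, su = _fit_and_score_fold(x[mask], y[mask], x[i : i + 1], cfg)
        oof[i] = p[0]
        fold_sel.append(sel)
        fold_su.append(su)
    return oof, fold_sel, fold_su


def resubstitution_metrics(
    x: np.ndarray, y: np.ndarray, cfg: ModelConfig
) -> dict:
    """Train on all samples, predict all samples (optimistic reference)."""
    p, _, _ = _fit_and_score_fold(x, y, x, cfg)
    return classification_metrics(p, y, cfg.threshold)


def loocv_run(
    sset: SpectrumSet,
    preprocess_cfg: PreprocessConfig | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int | None = None,
    feature_subset: np.ndarray | None = None,
) -> CVResult:
    """Leakage-safe leave-one-out evaluation of the full pipeline.

    Preprocessing steps are per-sample transforms (no cross-sample
    fitting), so they are applied once up front; discretization cuts,
    feature ranking/FCBF and NB parameters are fitted per fold on the
    n-1 training samples only.  ``feature_subset`` restricts the feature
    matrix to the given column indices *before* cross-validation — it
    exists so tests can demonstrate the selection-leakage effect and is
    not part of the nested protocol.
    """
    model_cfg = model_cfg or ModelConfig()
    if sset.labels is None:
        raise ValueError("LOOCV requires labeled data")
    if sset.n_samples < 4:
        raise ValueError("LOOCV needs n >= 4")
    pp = (
        apply_preprocess_pipeline(sset, preprocess_cfg)
        if preprocess_cfg is not None
        else sset
    )
    x, y, grid = pp.intensities, pp.labels, pp.wavenumbers
    if feature_subset is not None:
        feature_subset = np.asarray(feature_subset, dtype=int)
        x = x[:, feature_subset]
        grid = grid[feature_subset]
    oof, fold_sel, fold_su = nested_loocv(x, y, model_cfg)
    return CVResult(
        sample_ids=list(sset.sample_ids),
        labels=y.copy(),
        oof_prob=oof,
        fold_selected=fold_sel,
        fold_su=fold_su,
        wavenumbers=grid.copy(),
        metrics=classification_metrics(oof, y, model_cfg.threshold),
        train_metrics=resubstitution_metrics(x, y, model_cfg),
        seed=seed,
        provenance=pp.meta.get("preprocess", "raw"),
    )


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    n_permutations: int
    perm_loocv_auc: np.ndarray
    perm_train_auc: np.ndarray
    true_loocv_auc: float
    true_train_auc: float
    seed: int


def permutation_test(
    sset: SpectrumSet,
    preprocess_cfg: PreprocessConfig | None = None,
    model_cfg: ModelConfig | None = None,
    n_permutations: int = 10,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation validity test.

    Each permutation shuffles the class labels (preserving class counts —
    a permutation, not a resample) and reruns the *entire* nested pipeline
    including per-fold feature selection, recording both the LOOCV AUC and
    the resubstitution (training) AUC.  Deterministic under *seed*.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    model_cfg = model_cfg or ModelConfig()
    if sset.labels is None:
        raise ValueError("permutation test requires labeled data")
    pp = (
        apply_preprocess_pipeline(sset, preprocess_cfg)
        if preprocess_cfg is not None
        else sset
    )
    x, y = pp.intensities, pp.labels
    oof, _, _ = nested_loocv(x, y, model_cfg)
    true_loocv = auc_mann_whitney(oof, y)
    true_train = resubstitution_metrics(x, y, model_cfg)["auc"]
    rng = np.random.default_rng(seed)
    perm_loocv = np.empty(n_permutations)
    perm_train = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        oof_b, _, _ = nested_loocv(x, y_perm, model_cfg)
        perm_loocv[b] = auc_mann_whitney(oof_b, y_perm)
        perm_train[b] = resubstitution_metrics(x, y_perm, model_cfg)["auc"]
    return PermutationResult(
        n_permutations=n_permutations,
        perm_loocv_auc=perm_loocv,
        perm_train_auc=perm_train,
        true_loocv_auc=true_loocv,
        true_train_auc=true_train,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reliability / Brier


def reliability_and_brier(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 5
) -> tuple[pd.DataFrame, float]:
    """Quantile-binned reliability table and the Brier score.

    Bins are quantiles of the predicted probabilities (duplicate edges
    collapse to fewer bins); each row reports the bin's mean predicted
    probability and observed positive fraction.  Note: under 1:1 matched
    case-control sampling these probabilities are internal discriminative
    scores, not population risks — the table carries that caveat in its
    attrs.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if probs.size < n_bins:
        raise ValueError(f"need >= {n_bins} predictions for {n_bins} bins")
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        bin_idx = np.zeros(probs.size, dtype=int)
        n_eff = 1
    else:
        bin_idx = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, edges.size - 2)
        n_eff = edges.size - 1
    rows = []
    for b in range(n_eff):
        m = bin_idx == b
        if not m.any():
            continue
        rows.append(
            {
                "bin": b,
                "n": int(m.sum()),
                "mean_predicted": float(probs[m].mean()),
                "observed_positive_fraction": float(y[m].mean()),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["note"] = (
        "Scores are internal discriminative probabilities under matched "
        "case-control sampling, not population-level risks."
    )
    brier = float(np.mean((probs - y) ** 2))
    return table, brier


# ---------------------------------------------------------------------------
# Discriminant bands


def discriminant_band_summary(cv: CVResult, max_gap_steps: int = 2) -> pd.DataFrame:
    """Aggregate per-fold selections into ranked wavenumber bands.

    Per-wavenumber selection frequency = fraction of folds in which the
    feature was selected; contiguous selected wavenumbers (gap at most
    ``max_gap_steps`` grid steps) merge into one band reported with
    min-max bounds.  Bands are sorted by their mean label-SU (descending),
    ties by selection frequency.
    """
    n_folds = len(cv.fold_selected)
    grid = cv.wavenumbers
    counts = np.zeros(grid.size)
    su_sum = np.zeros(grid.size)
    for sel, su in zip(cv.fold_selected, cv.fold_su):
        counts[sel] += 1
        su_sum[sel] += su
    selected = np.nonzero(counts > 0)[0]
    if selected.size == 0:
        return pd.DataFrame(
            columns=["low_cm1", "high_cm1", "n_points", "selection_frequency", "mean_su"]
        )
    freq = counts / n_folds
    mean_su = np.zeros(grid.size)
    mean_su[selected] = su_sum[selected] / counts[selected]
    diffs = np.diff(grid)
    step = diffs[diffs > 0].min() if diffs.size else 1.0
    bands = []
    start = prev = selected[0]
    members = [selected[0]]
    for idx in selected[1:]:
        if grid[idx] - grid[prev] <= max_gap_steps * step + 1e-9:
            members.append(idx)
            prev = idx
        else:
            bands.append((start, prev, members))
            start = prev = idx
            members = [idx]
    bands.append((start, prev, members))
    rows = [
        {
            "low_cm1": float(grid[a]),
            "high_cm1": float(grid[b]),
            "n_points": len(mem),
            "selection_frequency": float(freq[mem].max()),
            "mean_su": float(mean_su[mem].mean()),
        }
        for a, b, mem in bands
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["mean_su", "selection_frequency"], ascending=False
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Variant grid


def variant_grid(
    sset: SpectrumSet,
    variant_names: list[str] | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """LOOCV metrics for each named preprocessing variant (sensitivity grid).

    Emits one row per variant with the six headline metrics, mirroring the
    published sensitivity table layout.
    """
    from .preprocess import VARIANTS

    names = variant_names if variant_names is not None else list(VARIANTS)
    rows = []
    for name in names:
        cfg = get_variant(name)  # raises with valid names listed
        cv = loocv_run(sset, cfg, model_cfg, seed=seed)
        rows.append(
            {
                "variant": name,
                "auc": cv.metrics["auc"],
                "accuracy": cv.metrics["accuracy"],
                "f1": cv.metrics["f1"],
                "precision": cv.metrics["precision"],
                "recall": cv.metrics["recall"],
                "specificity": cv.metrics["specificity"],
            }
        )
    return pd.DataFrame(rows)
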