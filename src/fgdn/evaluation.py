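"""Training protocol and evaluation harness.

Covers model training with early stopping on a held-out monitoring set,
stratified k-fold cross-validation, leave-one-site-out evaluation, the
learning-curve experiment (growing training fraction at a fixed validation
fold), and the region-discriminability analysis (masking all but one region's
node features, fine-tuning, and ranking regions by masked validation
accuracy with paired t-tests).

Leakage discipline: within every fold, the tangent reference, the class
graph templates, and the model parameters are functions of that fold's
training subjects only; the evaluation step asserts the id sets are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import chebnet, connectivity, graph_template
from .chebnet import Adam, FgdnParams, forward_batch, backward_batch, init_params
from .data_io import RoiTimeSeries
from .reports import EvalReport, FoldResult


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol.

    Optimizer settings follow the published protocol (Adam, learning rate
    1e-4, weight decay 5e-4, mini-batches of 16, dropout 0.1 after each graph
    convolution, 10% of the training subjects held out as a monitoring set
    for early stopping). The stopping horizon (patience/max_epochs) and the
    dense hidden width are package defaults.
    """

    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    batch_size: int = 16
    dropout: float = 0.1
    monitor_fraction: float = 0.10
    patience: int = 20
    max_epochs: int = 300
    seed: int = 0
    feature_kind: str = "tangent"  # "tangent" | "correlation"
    tangent_mean: str = "geometric"
    graph_k: int = 20
    cheb_order: int = 3
    channels: int = 64
    hidden: int = 128
    finetune_epochs: int = 30
    finetune_lr_factor: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.monitor_fraction < 0.5:
            raise ValueError("monitor_fraction must lie in (0, 0.5)")
        for name in ("learning_rate", "weight_decay", "batch_size", "patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedModel:
    """A trained network plus everything needed to embed and score new subjects."""

    params: FgdnParams
    asd_template: graph_template.GraphTemplate
    hc_template: graph_template.GraphTemplate
    tangent_ref: connectivity.TangentReference | None
    lt_asd: np.ndarray
    lt_hc: np.ndarray
    history: dict
    cfg: TrainConfig
    fitted_on: set[str] = field(default_factory=set)  # subjects that shaped ref/templates/params
    monitor_ids: set[str] = field(default_factory=set)

    @property
    def training_ids(self) -> set[str]:
        return self.fitted_on | self.monitor_ids


def _as_pairs(train_set) -> list[tuple[RoiTimeSeries, str]]:
    pairs = []
    for item in train_set:
        if isinstance(item, RoiTimeSeries):
            pairs.append((item, item.diagnosis))
        else:
            pairs.append((item[0], item[1]))
    return pairs


def subject_features(
    ts_list: list[RoiTimeSeries],
    cfg: TrainConfig,
    ref: connectivity.TangentReference | None,
) -> list[connectivity.ConnectivityMatrix]:
    """Connectivity features of the configured kind for each subject."""
    if cfg.feature_kind == "correlation":
        return [connectivity.pearson_correlation(ts) for ts in ts_list]
    if cfg.feature_kind == "tangent":
        if ref is None:
            raise ValueError("tangent features need a fitted reference")
        covs = [connectivity.ledoit_wolf_covariance(ts) for ts in ts_list]
        return [connectivity.tangent_embed(c, ref) for c in covs]
    raise ValueError(f"unknown feature kind {cfg.feature_kind!r}")


def _stratified_holdout(
    labels: list[str], fraction: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """(fit indices, holdout indices), stratified by class, original order kept."""
    labels_arr = np.asarray(labels)
    holdout: list[int] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels_arr == cls)
        n_hold = int(round(fraction * idx.size))
        if idx.size > 1:
            n_hold = max(1, min(n_hold, idx.size - 1))
        else:
            n_hold = 0
        chosen = rng.permutation(idx.size)[:n_hold]
        holdout.extend(idx[chosen])
    holdout_set = set(holdout)
    fit = [i for i in range(len(labels)) if i not in holdout_set]
    return fit, sorted(holdout_set)


def _predict_arrays(
    x: np.ndarray, model: TrainedModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    p_asd, p_hc, _ = forward_batch(x, model.lt_asd, model.lt_hc, model.params,
                                   training=False)
    scores = p_asd - p_hc
    preds = [chebnet.classify(a, h) for a, h in zip(p_asd, p_hc)]
    return p_asd, p_hc, scores, preds


def train_fgdn(
    train_set,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> TrainedModel:
    """Fit the full pipeline on a training set.

    Steps: stratified monitor holdout; Ledoit-Wolf covariances and tangent
    reference on the non-monitor portion; class-mean connectivity and KNN
    templates (k clamped to N-1 for small atlases) from the same portion;
    then minibatch Adam on the summed cross-entropy, stopping once the
    monitoring accuracy has not improved for ``cfg.patience`` epochs and
    restoring the best-monitor parameters.
    """
    pairs = _as_pairs(train_set)
    labels = [lab for _, lab in pairs]
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    fit_idx, mon_idx = _stratified_holdout(labels, cfg.monitor_fraction, rng)
    fit_ts = [pairs[i][0] for i in fit_idx]
    fit_labels = [pairs[i][1] for i in fit_idx]
    mon_ts = [pairs[i][0] for i in mon_idx]
    mon_labels = [pairs[i][1] for i in mon_idx]

    ref = None
    if cfg.feature_kind == "tangent":
        covs = [connectivity.ledoit_wolf_covariance(ts) for ts in fit_ts]
        ref = connectivity.fit_tangent_reference(covs, mean_kind=cfg.tangent_mean)
    fit_feats = subject_features(fit_ts, cfg, ref)
    mon_feats = subject_features(mon_ts, cfg, ref) if mon_ts else []

    n_rois = fit_feats[0].n_rois
    k_eff = min(cfg.graph_k, n_rois - 1)
    asd_mean = graph_template.class_mean_connectivity(
        [f for f, lab in zip(fit_feats, fit_labels) if lab == "ASD"], "ASD"
    )
    hc_mean = graph_template.class_mean_connectivity(
        [f for f, lab in zip(fit_feats, fit_labels) if lab == "HC"], "HC"
    )
    asd_t = graph_template.build_template(asd_mean, k_eff, "ASD")
    hc_t = graph_template.build_template(hc_mean, k_eff, "HC")
    lt_asd = chebnet.normalized_laplacian(asd_t.weights).rescaled
    lt_hc = chebnet.normalized_laplacian(hc_t.weights).rescaled

    x_fit = np.stack([f.values for f in fit_feats])
    y_fit = np.array([1.0 if lab == "ASD" else 0.0 for lab in fit_labels])
    x_mon = np.stack([f.values for f in mon_feats]) if mon_feats else None

    params = init_params(n_rois, rng, order=cfg.cheb_order,
                         channels=cfg.channels, hidden=cfg.hidden)
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    history = {"train_loss": [], "monitor_acc": [], "monitor_auc": []}
    best_acc, best_params, since_best = -np.inf, params.copy(), 0
    n_fit = x_fit.shape[0]
    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(n_fit)
        epoch_loss = 0.0
        for start in range(0, n_fit, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = x_fit[idx], y_fit[idx]
            p_asd, p_hc, caches = forward_batch(
                xb, lt_asd, lt_hc, params,
                dropout=cfg.dropout, training=True, rng=rng,
            )
            grads = backward_batch(caches, params, yb)
            opt.step(params, grads)
            pa = np.clip(p_asd, chebnet.EPS_PROB, 1 - chebnet.EPS_PROB)
            ph = np.clip(p_hc, chebnet.EPS_PROB, 1 - chebnet.EPS_PROB)
            epoch_loss += float(
                -(yb * np.log(pa) + (1 - yb) * np.log(1 - pa)).sum()
                - ((1 - yb) * np.log(ph) + yb * np.log(1 - ph)).sum()
            )
        history["train_loss"].append(epoch_loss / n_fit)

        if x_mon is None:
            continue
        p_asd, p_hc, _ = forward_batch(x_mon, lt_asd, lt_hc, params, training=False)
        preds = [chebnet.classify(a, h) for a, h in zip(p_asd, p_hc)]
        acc = float(np.mean([p == t for p, t in zip(preds, mon_labels)])) * 100.0
        auc = None
        if len(set(mon_labels)) == 2:
            y_bin = [1 if lab == "ASD" else 0 for lab in mon_labels]
            auc = float(roc_auc_score(y_bin, p_asd - p_hc)) * 100.0
        history["monitor_acc"].append(acc)
        history["monitor_auc"].append(auc)
        if acc > best_acc:
            best_acc, best_params, since_best = acc, params.copy(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if x_mon is not None:
        params = best_params

    return TrainedModel(
        params=params,
        asd_template=asd_t,
        hc_template=hc_t,
        tangent_ref=ref,
        lt_asd=lt_asd,
        lt_hc=lt_hc,
        history=history,
        cfg=cfg,
        fitted_on={ts.subject_id for ts in fit_ts},
        monitor_ids={ts.subject_id for ts in mon_ts},
    )


def predict(
    model: TrainedModel, ts_list: list[RoiTimeSeries]
) -> tuple[list[str], np.ndarray]:
    """Labels and ranking scores (p_asd - p_hc) for new subjects."""
    feats = subject_features(ts_list, model.cfg, model.tangent_ref)
    x = np.stack([f.values for f in feats])
    _, _, scores, preds = _predict_arrays(x, model)
    return preds, scores


def compute_metrics(
    truth: list[str], pred: list[str], scores
) -> tuple[float, float | None, float | None, float | None]:
    """(ACC, AUC, sensitivity, specificity) on a 0-100 scale; ASD positive.

    AUC is the Mann-Whitney rank statistic of the scores (ties count half),
    undefined (None) when the truth holds a single class. Sensitivity/
    specificity are None when there are no positives/negatives.
    """
    truth = list(truth)
    pred = list(pred)
    scores = np.asarray(list(scores), dtype=float)
    if not truth or len(truth) != len(pred) or len(truth) != len(scores):
        raise ValueError("truth, predictions and scores must be aligned and nonempty")
    correct = sum(t == p for t, p in zip(truth, pred))
    acc = 100.0 * correct / len(truth)
    tp = sum(1 for t, p in zip(truth, pred) if t == "ASD" and p == "ASD")
    fn = sum(1 for t, p in zip(truth, pred) if t == "ASD" and p == "HC")
    tn = sum(1 for t, p in zip(truth, pred) if t == "HC" and p == "HC")
    fp = sum(1 for t, p in zip(truth, pred) if t == "HC" and p == "ASD")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    if len(set(truth)) == 2:
        y = [1 if t == "ASD" else 0 for t in truth]
        auc = 100.0 * float(roc_auc_score(y, scores))
    else:
        auc = None
    return acc, auc, sens, spec


def _evaluate_fold(
    fold_id: str, model: TrainedModel, test_ts: list[RoiTimeSeries]
) -> FoldResult:
    test_ids = {ts.subject_id for ts in test_ts}
    overlap = test_ids & model.training_ids
    if overlap:
        raise AssertionError(f"leakage: test subjects seen in training: {sorted(overlap)}")
    preds, scores = predict(model, test_ts)
    truth = [ts.diagnosis for ts in test_ts]
    acc, auc, sens, spec = compute_metrics(truth, preds, scores)
    return FoldResult(fold_id, acc, auc, sens, spec, n_test=len(test_ts))


def _fold_rng(cfg: TrainConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *key]))


def _cv_folds(cohort: list[RoiTimeSeries], n_folds: int, cfg: TrainConfig):
    labels = [ts.diagnosis for ts in cohort]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=cfg.seed % (2**32 - 1))
    return list(skf.split(np.zeros(len(cohort)), labels))


def cross_validate(
    cohort: list[RoiTimeSeries],
    n_folds: int,
    cfg: TrainConfig,
    return_models: bool = False,
) -> EvalReport | tuple[EvalReport, list]:
    """Stratified k-fold cross-validation; every pipeline stage refits per fold."""
    folds = []
    models = []
    for f, (tr_idx, te_idx) in enumerate(_cv_folds(cohort, n_folds, cfg)):
        train_ts = [cohort[i] for i in tr_idx]
        test_ts = [cohort[i] for i in te_idx]
        if len({ts.diagnosis for ts in test_ts}) < 2:
            raise ValueError(f"fold {f} has a single-class test set")
        model = train_fgdn(train_ts, cfg, rng=_fold_rng(cfg, f))
        folds.append(_evaluate_fold(f"fold{f}", model, test_ts))
        if return_models:
            models.append({"model": model, "train": train_ts, "test": test_ts})
    report = EvalReport(experiment="cv", folds=folds, seed=cfg.seed,
                        extra={"n_folds": n_folds})
    return (report, models) if return_models else report


def leave_one_site_out(cohort: list[RoiTimeSeries], cfg: TrainConfig) -> EvalReport:
    """One fold per acquisition site: train on the other sites, test on it."""
    sites = sorted({ts.site for ts in cohort})
    if len(sites) < 2:
        raise ValueError("leave-one-site-out needs at least two sites")
    folds = []
    for s, site in enumerate(sites):
        test_ts = [ts for ts in cohort if ts.site == site]
        train_ts = [ts for ts in cohort if ts.site != site]
        model = train_fgdn(train_ts, cfg, rng=_fold_rng(cfg, s))
        folds.append(_evaluate_fold(site, model, test_ts))
    return EvalReport(experiment="loso", folds=folds, seed=cfg.seed,
                      extra={"sites": sites})


def _stratified_subsample(
    train_ts: list[RoiTimeSeries], fraction: float, rng: np.random.Generator
) -> list[RoiTimeSeries]:
    if fraction >= 1.0:
        return list(train_ts)
    labels = np.array([ts.diagnosis for ts in train_ts])
    chosen: list[int] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels == cls)
        n_take = int(round(fraction * idx.size))
        if n_take < 1:
            raise ValueError(
                f"fraction {fraction} leaves no training subjects of class {cls}"
            )
        chosen.extend(idx[rng.permutation(idx.size)[:n_take]])
    return [train_ts[i] for i in sorted(chosen)]


def learning_curve(
    cohort: list[RoiTimeSeries],
    fractions: list[float],
    cfg: TrainConfig,
    n_folds: int = 10,
) -> EvalReport:
    """Training-set-size experiment at a fixed validation fold.

    For each fraction, each fold's training set is subsampled (stratified,
    seeded) while the held-out fold is unchanged; fraction 1.0 reproduces
    :func:`cross_validate` exactly under the same seed.
    """
    if sorted(fractions) != list(fractions):
        raise ValueError("fractions must be sorted ascending")
    cv_splits = _cv_folds(cohort, n_folds, cfg)
    folds = []
    by_fraction: dict[str, list[float]] = {}
    for fi, frac in enumerate(fractions):
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        accs = []
        for f, (tr_idx, te_idx) in enumerate(cv_splits):
            train_ts = [cohort[i] for i in tr_idx]
            test_ts = [cohort[i] for i in te_idx]
            sub = _stratified_subsample(train_ts, frac, _fold_rng(cfg, 7919, fi, f))
            model = train_fgdn(sub, cfg, rng=_fold_rng(cfg, f))
            res = _evaluate_fold(f"frac{frac:g}_fold{f}", model, test_ts)
            folds.append(res)
            accs.append(res.acc)
        by_fraction[f"{frac:g}"] = accs
    return EvalReport(
        experiment="learning_curve", folds=folds, seed=cfg.seed,
        extra={"fractions": [float(f) for f in fractions], "acc_by_fraction": by_fraction},
    )


# ---------------------------------------------------------------------------
# Region discriminability
# ---------------------------------------------------------------------------

@dataclass
class RegionScore:
    region_id: int
    mean_acc: float
    mean_auc: float | None
    sd: float
    pct_exceeded: float
    fold_accs: list[float] = field(default_factory=list)


def _mask_features(x: np.ndarray, region: int, mask_columns: bool) -> np.ndarray:
    """Zero every node-feature row except ``region``'s (templates untouched)."""
    out = np.zeros_like(x)
    out[:, region, :] = x[:, region, :]
    if mask_columns:
        col = out[:, region, region].copy()
        out[:, region, :] = 0.0
        out[:, region, region] = col
    return out


def region_discriminability(
    cohort: list[RoiTimeSeries],
    cfg: TrainConfig,
    n_folds: int = 10,
    mask_columns: bool = False,
) -> list[RegionScore]:
    """Rank regions by the validation accuracy they sustain alone.

    For each region, the trained CV fold models are fine-tuned (reduced
    epochs, one-tenth learning rate) on training features where every other
    region's rows are zeroed, then scored on the equally masked validation
    fold. A region's discriminative weight is its mean masked validation
    accuracy; ``pct_exceeded`` is the share of other regions it beats with a
    paired two-sided t-test at p < 0.05.
    """
    _, fold_models = cross_validate(cohort, n_folds, cfg, return_models=True)
    n_rois = fold_models[0]["model"].params.n_rois

    # Per-fold cached arrays (features computed once with the fold's reference)
    fold_data = []
    for rec in fold_models:
        model = rec["model"]
        train_feats = subject_features(rec["train"], cfg, model.tangent_ref)
        test_feats = subject_features(rec["test"], cfg, model.tangent_ref)
        fold_data.append({
            "model": model,
            "x_tr": np.stack([f.values for f in train_feats]),
            "y_tr": np.array([1.0 if ts.diagnosis == "ASD" else 0.0 for ts in rec["train"]]),
            "x_te": np.stack([f.values for f in test_feats]),
            "truth": [ts.diagnosis for ts in rec["test"]],
        })

    acc_by_region = np.zeros((n_rois, len(fold_data)))
    auc_by_region: list[list[float | None]] = [[] for _ in range(n_rois)]
    for r in range(n_rois):
        for f, data in enumerate(fold_data):
            model = data["model"]
            params = model.params.copy()
            opt = Adam(params, lr=cfg.learning_rate * cfg.finetune_lr_factor,
                       weight_decay=cfg.weight_decay)
            rng = _fold_rng(cfg, 104729, f, r)
            x_tr = _mask_features(data["x_tr"], r, mask_columns)
            y_tr = data["y_tr"]
            n = x_tr.shape[0]
            for _ in range(cfg.finetune_epochs):
                perm = rng.permutation(n)
                for start in range(0, n, cfg.batch_size):
                    idx = perm[start:start + cfg.batch_size]
                    _, _, caches = forward_batch(
                        x_tr[idx], model.lt_asd, model.lt_hc, params,
                        dropout=cfg.dropout, training=True, rng=rng,
                    )
                    opt.step(params, backward_batch(caches, params, y_tr[idx]))
            x_te = _mask_features(data["x_te"], r, mask_columns)
            p_asd, p_hc, _ = forward_batch(x_te, model.lt_asd, model.lt_hc,
                                           params, training=False)
            preds = [chebnet.classify(a, h) for a, h in zip(p_asd, p_hc)]
            acc, auc, _, _ = compute_metrics(data["truth"], preds, p_asd - p_hc)
            acc_by_region[r, f] = acc
            auc_by_region[r].append(auc)

    scores = []
    for r in range(n_rois):
        others = [s for s in range(n_rois) if s != r]
        beaten = 0
        for s in others:
            a, b = acc_by_region[r], acc_by_region[s]
            if a.mean() <= b.mean() or np.allclose(a, b):
                continue
            _, p = stats.ttest_rel(a, b)
            if np.isfinite(p) and p < 0.05:
                beaten += 1
        aucs = [v for v in auc_by_region[r] if v is not None]
        scores.append(RegionScore(
            region_id=r,
            mean_acc=float(acc_by_region[r].mean()),
            mean_auc=float(np.mean(aucs)) if aucs else None,
            sd=float(acc_by_region[r].std(ddof=1)) if acc_by_region.shape[1] > 1 else 0.0,
            pct_exceeded=100.0 * beaten / (n_rois - 1),
            fold_accs=acc_by_region[r].tolist(),
        ))
    scores.sort(key=lambda s: (-s.mean_acc, s.region_id))
    return scores


def shuffle_labels(cohort: list[RoiTimeSeries], seed: int) -> list[RoiTimeSeries]:
    """Return a copy of the cohort with diagnoses randomly permuted (null control)."""
    rng = np.random.default_rng(seed)
    labels = [ts.diagnosis for ts in cohort]
    perm = rng.permutation(len(labels))
    return [
        RoiTimeSeries(ts.subject_id, ts.site, labels[perm[i]], ts.signal, ts.atlas_name)
        for i, ts in enumerate(cohort)
    ]
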