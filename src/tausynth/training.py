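"""ROI-weighted objective, balanced folds, optimization and cross-validation.

The generative loss is a voxel MSE in which residuals inside ROI r are scaled
by a user-specified weight w_r (background weight 1), averaged over voxels
and then over the batch; a loss of zero means the synthetic and actual
volumes agree exactly. Optimization follows AdamW (lr 1e-3, weight decay
1e-3, batch size 2) with a reduce-on-plateau schedule on validation loss and
early stopping after five flat epochs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .atlas import Atlas, meta_temp_tau, regional_suvr
from .model import (NetworkConfig, RegionalPromptInputs, SynthesisModel,
                    build_regional_tensors, conditioning_matrix)
from .nn.autodiff import Tensor
from .nn.optim import AdamW, ReduceLROnPlateau
from .tabular import (FeatureTable, LeakageError, cohort_feature_table,
                      cohort_targets, fit_auxiliary, knn_impute,
                      predict_auxiliary)


@dataclass
class RoiWeights:
    """Per-ROI multiplicative loss weights; background is fixed at 1."""

    weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for r, w in self.weights.items():
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"ROI {r}: weight must be finite and > 0, got {w}")

    @classmethod
    def meta_temporal_emphasis(cls, atlas: Atlas, w_meta: float = 2.0) -> "RoiWeights":
        return cls({r: (w_meta if r in atlas.meta_temp_members else 1.0)
                    for r in atlas.roi_ids})

    def voxel_map(self, atlas: Atlas) -> np.ndarray:
        w = np.ones(atlas.grid)
        for r, wr in self.weights.items():
            w[atlas.label_volume == r] = wr
        return w


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 2
    scheduler_factor: float = 0.5
    scheduler_patience: int = 2
    early_stop_patience: int = 5
    early_stop_rel_tol: float = 1e-4
    validation_fraction: float = 0.1
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience < 1 or self.scheduler_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def roi_weighted_mse(pred, truth, atlas: Atlas, weights: RoiWeights):
    """Mean over voxels (and batch) of w(v) * (P_v - P_hat_v)^2.

    Accepts numpy arrays (returns float) or an autodiff Tensor prediction
    (returns a Tensor for backprop). Volumes may be (D,H,W) or batched.
    """
    wmap = weights.voxel_map(atlas)
    truth = np.asarray(truth, dtype=float)
    if isinstance(pred, Tensor):
        diff = pred - Tensor(truth.reshape(pred.shape))
        return (diff * diff * Tensor(np.broadcast_to(wmap, pred.shape).copy())).mean()
    pred = np.asarray(pred, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    per_vox = wmap * (pred - truth) ** 2 if pred.ndim == 3 else wmap[None] * (pred - truth) ** 2
    if pred.ndim == 3:
        return float(per_vox.mean())
    return float(per_vox.reshape(pred.shape[0], -1).mean(axis=1).mean())


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    fold_of: dict            # subject id -> fold index
    k: int
    summary: pd.DataFrame    # per-fold mean MetaTempTau and amyloid-positive fraction

    def train_ids(self, fold: int) -> list:
        return [s for s, f in self.fold_of.items() if f != fold]

    def test_ids(self, fold: int) -> list:
        return [s for s, f in self.fold_of.items() if f == fold]


def make_folds(subjects: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Partition subjects into k folds balanced on amyloid status and
    MetaTempTau burden (stratified on status x tau-quantile bin).

    ``subjects`` needs columns subject_id, meta_temp, abeta; repeated
    subject ids (longitudinal visits) stay in one fold.
    """
    per_subj = subjects.drop_duplicates("subject_id").reset_index(drop=True)
    n = len(per_subj)
    if k > n:
        raise ValueError(f"k={k} folds but only {n} subjects")
    n_bins = max(1, min(k, n // (2 * k)))
    if n_bins > 1:
        bins = pd.qcut(per_subj["meta_temp"], q=n_bins, labels=False, duplicates="drop")
    else:
        bins = pd.Series(np.zeros(n, dtype=int))
    strata = per_subj["abeta"].astype(int) * (int(bins.max()) + 1) + bins.astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = {}
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), strata)):
        for i in test_idx:
            fold_of[per_subj.loc[i, "subject_id"]] = f
    rows = []
    for f in range(k):
        sub = per_subj[per_subj["subject_id"].map(fold_of) == f]
        rows.append({"fold": f, "n": len(sub),
                     "mean_meta_temp": float(sub["meta_temp"].mean()),
                     "abeta_pos_fraction": float(sub["abeta"].mean())})
    return FoldAssignment(fold_of, k, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# sample assembly
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    subject_id: object
    mri: np.ndarray          # (1, D, H, W)
    tau: np.ndarray          # (1, D, H, W)
    conditioning: np.ndarray  # (cond_dim,) raw scale
    gamma: np.ndarray        # (1, D, H, W)
    s_hat: np.ndarray        # (1, D, H, W)
    cov_idx: int
    visit_time: float = 0.0


def assemble_samples(cohort, estimates, atlas: Atlas, imputer=None) -> list[TrainingSample]:
    """Pair each phantom visit with its stage-1 estimates as network inputs.

    ``imputer``: a fitted covariate imputer (from the auxiliary bundle); when
    omitted the cohort's own table is imputed self-contained.
    """
    table = cohort_feature_table(cohort)
    feats = imputer.transform(table) if imputer is not None else knn_impute(table)
    cond = conditioning_matrix(feats.df, estimates)
    prompts = build_regional_tensors(estimates, atlas)
    out = []
    for i, s in enumerate(cohort):
        out.append(TrainingSample(
            subject_id=s.subject_id, mri=s.mri[None], tau=s.tau[None],
            conditioning=cond[i], gamma=prompts.gamma_hat[i],
            s_hat=prompts.s_hat[i], cov_idx=int(prompts.covariate_index[i]),
            visit_time=float(s.truth.visit_time)))
    return out


def _batch(samples: list[TrainingSample]):
    mri = np.stack([s.mri for s in samples])
    tau = np.stack([s.tau for s in samples])
    cond = np.stack([s.conditioning for s in samples])
    pr = RegionalPromptInputs(np.stack([s.gamma for s in samples]),
                              np.stack([s.s_hat for s in samples]),
                              np.array([s.cov_idx for s in samples]))
    return mri, tau, cond, pr


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def _epoch_loss(model, samples, atlas, weights, batch_size) -> float:
    model.eval()
    tot = 0.0
    for i in range(0, len(samples), batch_size):
        mri, tau, cond, pr = _batch(samples[i:i + batch_size])
        pred = model.forward(mri, cond if not model.config.ablated else None,
                             pr if not model.config.ablated else None)
        tot += roi_weighted_mse(pred.data, tau, atlas, weights) * len(samples[i:i + batch_size])
    return tot / len(samples)


def train(model: SynthesisModel, train_samples: list[TrainingSample], atlas: Atlas,
          weights: RoiWeights, config: TrainConfig,
          val_samples: list[TrainingSample] | None = None,
          val_loss_override=None,
          allow_val_overlap: bool = False) -> tuple[SynthesisModel, pd.DataFrame]:
    """AdamW training with plateau schedule and early stopping.

    Returns the best-validation checkpoint and a per-epoch history
    (epoch, train_loss, val_loss, lr). ``val_loss_override`` replaces the
    validation computation (used to exercise the stopping rule).
    """
    rng = np.random.default_rng(config.seed)
    if val_samples is None:
        n_val = max(1, int(round(config.validation_fraction * len(train_samples))))
        if n_val >= len(train_samples):
            raise ValueError("validation split leaves no training subjects")
        perm = rng.permutation(len(train_samples))
        val_samples = [train_samples[i] for i in perm[:n_val]]
        train_samples = [train_samples[i] for i in perm[n_val:]]
    if not val_samples:
        raise ValueError("empty validation subset")

    train_ids = {s.subject_id for s in train_samples}
    if not allow_val_overlap and train_ids & {s.subject_id for s in val_samples}:
        raise LeakageError("validation subjects overlap training subjects")

    # conditioning standardization from the training split only
    conds = np.stack([s.conditioning for s in train_samples])
    model.set_conditioning_stats(conds.mean(axis=0), conds.std(axis=0))

    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=config.scheduler_factor,
                              patience=config.scheduler_patience)
    best_val, best_state, bad = np.inf, None, 0
    history = []
    order = np.arange(len(train_samples))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        model.train()
        ep_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            mri, tau, cond, pr = _batch([train_samples[j] for j in idx])
            pred = model.forward(mri, cond if not model.config.ablated else None,
                                 pr if not model.config.ablated else None)
            loss = roi_weighted_mse(pred, tau, atlas, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(idx)
        ep_loss /= len(order)

        if val_loss_override is not None:
            val_loss = float(val_loss_override(epoch))
        else:
            val_loss = _epoch_loss(model, val_samples, atlas, weights, config.batch_size)
        history.append({"epoch": epoch, "train_loss": ep_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        sched.step(val_loss)
        if val_loss < best_val * (1.0 - config.early_stop_rel_tol):
            best_val = val_loss
            best_state = copy.deepcopy(model.state_arrays())
            bad = 0
        else:
            bad += 1
            if bad >= config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(cohort, atlas: Atlas, folds: FoldAssignment,
                   net_config: NetworkConfig, train_config: TrainConfig,
                   weights: RoiWeights | None = None, model_factory=None,
                   aux_seed: int = 0) -> dict:
    """Strict out-of-fold synthesis: stage-1 models and the network are fit on
    k-1 folds, predictions and metrics computed only on the held-out fold.

    ``model_factory(fold) -> object with .predict(mri, cond, prompts)`` lets
    tests substitute a mock network. Returns out-of-fold predictions keyed by
    (subject_id, visit_time) and a per-fold metric table.
    """
    from .metrics import evaluate_volumes

    weights = weights or RoiWeights.meta_temporal_emphasis(atlas)
    by_id = {}
    for s in cohort:
        by_id.setdefault(s.subject_id, []).append(s)

    oof_pred, fold_rows = {}, []
    for f in range(folds.k):
        tr_ids = set(folds.train_ids(f))
        te_ids = set(folds.test_ids(f))
        if tr_ids & te_ids:
            raise LeakageError(f"fold {f}: train/test subject overlap {sorted(tr_ids & te_ids)[:5]}")
        tr = [s for s in cohort if s.subject_id in tr_ids]
        te = [s for s in cohort if s.subject_id in te_ids]

        aux = fit_auxiliary(cohort_feature_table(tr), cohort_targets(tr, atlas),
                            atlas.roi_ids, atlas=atlas, seed=aux_seed,
                            min_rows=min(20, len(tr)))
        est_te = predict_auxiliary(aux, cohort_feature_table(te), forbid_train_overlap=True)
        te_samples = assemble_samples(te, est_te, atlas, imputer=aux.imputer)

        if model_factory is not None:
            net = model_factory(f)
        else:
            est_tr = predict_auxiliary(aux, cohort_feature_table(tr))
            tr_samples = assemble_samples(tr, est_tr, atlas, imputer=aux.imputer)
            net = SynthesisModel(net_config, seed=train_config.seed + f)
            net, _ = train(net, tr_samples, atlas, weights, train_config)

        preds, trues = [], []
        for s in te_samples:
            vol = net.predict(s.mri, s.conditioning[None], RegionalPromptInputs(
                s.gamma[None], s.s_hat[None], np.array([s.cov_idx])))[0]
            oof_pred[(s.subject_id, s.visit_time)] = vol
            preds.append(vol)
            trues.append(s.tau[0])
        rep = evaluate_volumes(preds, trues, atlas)
        fold_rows.append({"fold": f, "n": len(te), "corr_avg": rep.corr_avg,
                          "mape_percent": rep.mape_percent, "mae": rep.mae,
                          "ssim": rep.ssim})
    return {"oof_predictions": oof_pred, "fold_metrics": pd.DataFrame(fold_rows)}
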