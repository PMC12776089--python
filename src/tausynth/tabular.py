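"""Stage-1 auxiliary estimators on the covariate table.

KNN imputation of missing covariates (k = round(sqrt(#features)), uniform
weights, Euclidean distance on standardized columns), gradient-boosted
per-ROI tau regression with a Gaussian (mean, SD) output, a boosted amyloid
classifier, and a KNN MMSE regressor. Their predictions condition the
synthesis network.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.impute import KNNImputer
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from .atlas import Atlas, meta_temp_tau

DEFAULT_CATEGORICAL = ("marital_status", "race")

_LGBM_KW = dict(n_estimators=150, learning_rate=0.07, num_leaves=15,
                min_child_samples=5, verbose=-1, deterministic=True,
                force_row_wise=True)


class LeakageError(RuntimeError):
    """Raised when prediction rows overlap the training partition in CV mode."""


@dataclass
class FeatureTable:
    """Numeric covariate table (NaN = missing) with row identifiers."""

    df: pd.DataFrame
    ids: list = None
    categorical: tuple = DEFAULT_CATEGORICAL

    def __post_init__(self):
        if self.ids is None:
            self.ids = list(self.df.index)
        if len(self.ids) != len(self.df):
            raise ValueError("ids length does not match table")
        self.df = self.df.reset_index(drop=True).astype(float)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    def knn_k(self) -> int:
        """Neighbour count: square root of the number of features, rounded."""
        return max(1, int(round(np.sqrt(len(self.columns)))))

    # CSV I/O with a declared missing-token convention ("" and "NA")
    def to_csv(self, path):
        self.df.assign(_row_id=self.ids).to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path, categorical: tuple = DEFAULT_CATEGORICAL) -> "FeatureTable":
        df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
        ids = list(df.pop("_row_id")) if "_row_id" in df.columns else None
        bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if bad:
            for c in bad:
                row = int(df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()][0])
                raise ValueError(f"mixed-type column '{c}' (first offending row {row})")
        return cls(df, ids=ids, categorical=categorical)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def _design(table: FeatureTable):
    """Standardized continuous columns + one-hot categoricals, for distances."""
    df = table.df
    cont = [c for c in df.columns if c not in table.categorical]
    blocks, meta = [], []
    for c in cont:
        col = df[c].to_numpy(float)
        mu = np.nanmean(col)
        sd = np.nanstd(col)
        sd = sd if sd > 0 else 1.0
        blocks.append(((col - mu) / sd)[:, None])
        meta.append(("cont", c, mu, sd, None))
    for c in table.categorical:
        if c not in df.columns:
            continue
        col = df[c].to_numpy(float)
        cats = np.unique(col[~np.isnan(col)])
        onehot = np.full((len(col), len(cats)), np.nan)
        obs = ~np.isnan(col)
        onehot[obs] = (col[obs, None] == cats[None, :]).astype(float)
        blocks.append(onehot)
        meta.append(("cat", c, None, None, cats))
    return np.hstack(blocks), meta, cont


def _apply_design(table: FeatureTable, meta) -> np.ndarray:
    """Build the standardized design matrix for new rows under stored stats."""
    df = table.df
    blocks = []
    for kind, c, mu, sd, cats in meta:
        col = df[c].to_numpy(float)
        if kind == "cont":
            blocks.append(((col - mu) / sd)[:, None])
        else:
            onehot = np.full((len(col), len(cats)), np.nan)
            obs = ~np.isnan(col)
            onehot[obs] = (col[obs, None] == cats[None, :]).astype(float)
            blocks.append(onehot)
    return np.hstack(blocks)


def _fill_from_design(table: FeatureTable, Xf: np.ndarray, meta) -> FeatureTable:
    out = table.df.copy()
    j = 0
    for kind, c, mu, sd, cats in meta:
        if kind == "cont":
            filled = Xf[:, j] * sd + mu
            miss = out[c].isna()
            out.loc[miss, c] = filled[miss.to_numpy()]
            j += 1
        else:
            block = Xf[:, j:j + len(cats)]
            miss = out[c].isna()
            if miss.any():
                out.loc[miss, c] = cats[block[miss.to_numpy()].argmax(axis=1)]
            j += len(cats)
    return FeatureTable(out, ids=list(table.ids), categorical=table.categorical)


def knn_impute(table: FeatureTable) -> FeatureTable:
    """Fill missing entries with the unweighted mean of the k nearest rows.

    k = round(sqrt(number of features)); distances are Euclidean over
    mutually observed standardized columns; observed entries are unchanged.
    """
    all_missing = [c for c in table.columns if table.df[c].isna().all()]
    if all_missing:
        raise ValueError(f"columns missing in every row: {all_missing}")
    if not table.missing_mask.to_numpy().any():
        return FeatureTable(table.df.copy(), ids=list(table.ids), categorical=table.categorical)

    X, meta, _ = _design(table)
    k = min(table.knn_k(), len(table.df) - 1)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    Xf = imputer.fit_transform(X)
    return _fill_from_design(table, Xf, meta)


class FittedImputer:
    """KNN imputation fit on a training table and applied to new rows.

    New rows borrow donors from the training partition, so prediction-time
    tables may have whole columns missing (e.g. plasma panels absent in a
    validation cohort).
    """

    def __init__(self):
        self.meta = None
        self.imputer = None
        self.columns = None

    def fit(self, table: FeatureTable) -> "FittedImputer":
        all_missing = [c for c in table.columns if table.df[c].isna().all()]
        if all_missing:
            raise ValueError(f"columns missing in every training row: {all_missing}")
        X, self.meta, _ = _design(table)
        self.columns = table.columns
        k = min(table.knn_k(), len(table.df) - 1)
        self.imputer = KNNImputer(n_neighbors=k, weights="uniform").fit(X)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if table.columns != self.columns:
            raise ValueError(f"schema mismatch: {sorted(set(table.columns) ^ set(self.columns))}")
        if not table.missing_mask.to_numpy().any():
            return FeatureTable(table.df.copy(), ids=list(table.ids),
                                categorical=table.categorical)
        X = _apply_design(table, self.meta)
        Xf = self.imputer.transform(X)
        return _fill_from_design(table, Xf, self.meta)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

@dataclass
class AuxiliaryEstimates:
    """Per-subject stage-1 outputs conditioning the network."""

    tau_hat: dict[int, float]
    sigma_hat: dict[int, float]
    meta_temp_hat: float
    abeta_prob: float
    abeta_status: int
    mmse_hat: float


def _matrix(table: FeatureTable) -> pd.DataFrame:
    return table.df


class RegionalTauModel:
    """Per-ROI boosted regressors with a Gaussian (mean, SD) output head.

    The mean is an L2-boosted fit; the SD is the square root of a second
    boosted model predicting the squared residual (out-of-fold residuals when
    the sample allows), floored at ``sigma_floor``.
    """

    def __init__(self, roi_ids: list[int], meta_mode: str = "direct",
                 atlas: Atlas | None = None, min_rows: int = 20,
                 sigma_floor: float = 1e-3, seed: int = 0,
                 imputer: FittedImputer | None = None):
        if meta_mode not in ("direct", "derived"):
            raise ValueError("meta_mode must be 'direct' or 'derived'")
        if meta_mode == "derived" and atlas is None:
            raise ValueError("derived meta mode needs the atlas for ROI weights")
        self.roi_ids = [int(r) for r in roi_ids]
        self.meta_mode = meta_mode
        self.atlas = atlas
        self.min_rows = min_rows
        self.sigma_floor = sigma_floor
        self.seed = seed
        self.imputer = imputer
        self.mean_models: dict = {}
        self.var_models: dict = {}
        self.meta_model = None
        self.columns: list[str] | None = None
        self.train_ids: set = set()

    def _fit_one(self, X, y, seed):
        mean = LGBMRegressor(random_state=seed, **_LGBM_KW).fit(X, y)
        if len(y) >= 40:
            res = np.empty_like(y)
            for tr, te in KFold(5, shuffle=True, random_state=seed).split(X):
                m = LGBMRegressor(random_state=seed, **_LGBM_KW).fit(X.iloc[tr], y[tr])
                res[te] = y[te] - m.predict(X.iloc[te])
        else:
            res = y - mean.predict(X)
        var = LGBMRegressor(random_state=seed + 1, **_LGBM_KW).fit(X, res ** 2)
        return mean, var

    def fit(self, features: FeatureTable, targets: pd.DataFrame) -> "RegionalTauModel":
        if len(features.df) < self.min_rows:
            raise ValueError(f"need >= {self.min_rows} rows, got {len(features.df)}")
        if self.imputer is None:
            self.imputer = FittedImputer().fit(features)
        features = self.imputer.transform(features)
        X = _matrix(features)
        self.columns = features.columns
        self.train_ids = set(features.ids)
        for i, rid in enumerate(self.roi_ids):
            y = targets[f"roi_{rid}"].to_numpy(float)
            self.mean_models[rid], self.var_models[rid] = self._fit_one(X, y, self.seed + 17 * i)
        if self.meta_mode == "direct":
            ymeta = targets["meta_temp"].to_numpy(float)
            self.meta_model, _ = self._fit_one(X, ymeta, self.seed + 1000)
        return self

    def predict(self, features: FeatureTable) -> tuple[list[dict], list[dict], np.ndarray]:
        if features.columns != self.columns:
            raise ValueError(f"schema mismatch: {sorted(set(features.columns) ^ set(self.columns))}")
        features = self.imputer.transform(features)
        X = _matrix(features)
        n = len(X)
        tau = [dict() for _ in range(n)]
        sig = [dict() for _ in range(n)]
        for rid in self.roi_ids:
            mu = self.mean_models[rid].predict(X)
            s2 = self.var_models[rid].predict(X)
            s = np.sqrt(np.clip(s2, self.sigma_floor ** 2, None))
            for i in range(n):
                tau[i][rid] = float(mu[i])
                sig[i][rid] = float(s[i])
        if self.meta_mode == "direct":
            meta = self.meta_model.predict(X)
        else:
            meta = np.array([meta_temp_tau(tau[i], self.atlas) for i in range(n)])
        return tau, sig, meta


def fit_regional_tau(features: FeatureTable, targets: pd.DataFrame, roi_ids: list[int],
                     **kw) -> RegionalTauModel:
    return RegionalTauModel(roi_ids, **kw).fit(features, targets)


class AbetaModel:
    def __init__(self, seed: int = 0, imputer: FittedImputer | None = None):
        self.clf = LGBMClassifier(random_state=seed, **_LGBM_KW)
        self.columns = None
        self.imputer = imputer

    def fit(self, features: FeatureTable, labels: np.ndarray) -> "AbetaModel":
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < 2:
            raise ValueError("amyloid classifier requires both classes in training labels")
        if self.imputer is None:
            self.imputer = FittedImputer().fit(features)
        features = self.imputer.transform(features)
        self.columns = features.columns
        self.clf.fit(_matrix(features), labels)
        return self

    def predict_prob(self, features: FeatureTable) -> np.ndarray:
        features = self.imputer.transform(features)
        return self.clf.predict_proba(_matrix(features))[:, 1]


def fit_abeta(features: FeatureTable, abeta_labels) -> AbetaModel:
    return AbetaModel().fit(features, abeta_labels)


class MmseModel:
    """Nearest-neighbour mean regressor with the same k rule as imputation."""

    def __init__(self, imputer: FittedImputer | None = None):
        self.knn = None
        self.mu = None
        self.sd = None
        self.imputer = imputer

    def fit(self, features: FeatureTable, mmse: np.ndarray) -> "MmseModel":
        mmse = np.asarray(mmse, dtype=float)
        if ((mmse < 0) | (mmse > 30)).any():
            raise ValueError("MMSE targets must lie in [0, 30]")
        if self.imputer is None:
            self.imputer = FittedImputer().fit(features)
        features = self.imputer.transform(features)
        X = _matrix(features)
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        k = min(features.knn_k(), len(X))
        self.knn = KNeighborsRegressor(n_neighbors=k, weights="uniform")
        self.knn.fit((X - self.mu) / self.sd, mmse)
        return self

    def predict(self, features: FeatureTable) -> np.ndarray:
        features = self.imputer.transform(features)
        X = (_matrix(features) - self.mu) / self.sd
        return np.clip(self.knn.predict(X), 0.0, 30.0)


def fit_mmse(features: FeatureTable, mmse) -> MmseModel:
    return MmseModel().fit(features, mmse)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class AuxiliaryModels:
    regional: RegionalTauModel
    abeta: AbetaModel
    mmse: MmseModel
    train_ids: set = field(default_factory=set)

    @property
    def imputer(self) -> FittedImputer:
        return self.regional.imputer

    def save(self, outdir: str | Path):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"columns": self.regional.columns, "roi_ids": self.regional.roi_ids,
                    "meta_mode": self.regional.meta_mode,
                    "n_train": len(self.train_ids)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with open(outdir / "models.pkl", "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, outdir: str | Path) -> "AuxiliaryModels":
        with open(Path(outdir) / "models.pkl", "rb") as fh:
            return pickle.load(fh)


def fit_auxiliary(features: FeatureTable, targets: pd.DataFrame, roi_ids: list[int],
                  meta_mode: str = "direct", atlas: Atlas | None = None,
                  seed: int = 0, min_rows: int = 20) -> AuxiliaryModels:
    """Fit all stage-1 models on one training partition.

    ``targets`` columns: roi_<id> per ROI, meta_temp, abeta, mmse.
    """
    imputer = FittedImputer().fit(features)
    regional = RegionalTauModel(roi_ids, meta_mode=meta_mode, atlas=atlas, seed=seed,
                                min_rows=min_rows, imputer=imputer).fit(features, targets)
    abeta = AbetaModel(seed=seed, imputer=imputer).fit(features, targets["abeta"].to_numpy())
    mmse = MmseModel(imputer=imputer).fit(features, targets["mmse"].to_numpy())
    return AuxiliaryModels(regional, abeta, mmse, train_ids=set(features.ids))


def predict_auxiliary(models: AuxiliaryModels, table: FeatureTable,
                      forbid_train_overlap: bool = False) -> list[AuxiliaryEstimates]:
    """One AuxiliaryEstimates per row; imputation handles missing covariates.

    With ``forbid_train_overlap`` (cross-validation hygiene) any row id seen
    during fitting raises LeakageError.
    """
    if forbid_train_overlap:
        overlap = set(table.ids) & models.train_ids
        if overlap:
            raise LeakageError(f"predict-on-train refused for ids: {sorted(overlap)[:5]}...")
    tau, sig, meta = models.regional.predict(table)
    prob = models.abeta.predict_prob(table)
    mm = models.mmse.predict(table)
    return [AuxiliaryEstimates(tau_hat=tau[i], sigma_hat=sig[i],
                               meta_temp_hat=float(meta[i]),
                               abeta_prob=float(prob[i]),
                               abeta_status=int(prob[i] >= 0.5),
                               mmse_hat=float(mm[i]))
            for i in range(len(table.df))]


# ---------------------------------------------------------------------------
# phantom-cohort adapters
# ---------------------------------------------------------------------------

def cohort_feature_table(cohort) -> FeatureTable:
    rows = [s.covariates.to_dict() for s in cohort]
    ids = [(s.subject_id, s.truth.visit_time) for s in cohort]
    return FeatureTable(pd.DataFrame(rows), ids=ids)


def cohort_targets(cohort, atlas: Atlas) -> pd.DataFrame:
    rows = []
    for s in cohort:
        r = {f"roi_{rid}": m for rid, m in s.truth.regional_tau.items()}
        r["meta_temp"] = s.truth.meta_temp
        r["abeta"] = s.truth.abeta_status
        r["mmse"] = s.truth.mmse
        rows.append(r)
    return pd.DataFrame(rows)
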