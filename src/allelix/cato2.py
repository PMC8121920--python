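"""Two-stage regulatory-variant scoring (CATO2-style).

Stage 1 is a logistic model of imbalance on genomic-context annotations
(cell-type activity, gene context, distance to TSS, DHS strength and
width, footprint presence, nearby binding sites, conservation; squared
terms enter as extra columns). Stage 2 trains one logistic model per TF
motif on SNVs overlapping that motif — features are the stage-1 fitted
probability, the (log) match score and its square, the ref-vs-alt
log-odds difference, and per-position indicators — using imbalance calls
from the cell types where the motif shows >2-fold core enrichment.
Per-SNV best scores per TF cluster are finally combined by a
lasso-penalized logistic model selected by cross-validated AUC, yielding
a variant-impact score in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "QUANTITATIVE_ANNOTATIONS",
    "AnnotationStandardizer",
    "standardize_annotations",
    "GlobalModel",
    "fit_global_model",
    "TFModel",
    "fit_tf_model",
    "Combiner",
    "fit_combiner",
    "Cato2ModelBundle",
    "gated_tf_labels",
    "train_bundle",
    "score_variants",
    "precision_recall",
]

QUANTITATIVE_ANNOTATIONS = (
    "mcv", "dist_tss", "dhs_strength", "dhs_width", "nearby_sites",
    "conservation",
)
_GLOBAL_FEATURES = (
    "mcv", "mcv_sq", "intron", "intergenic", "log_dist_tss", "log_dist_tss_sq",
    "dhs_strength", "dhs_strength_sq", "log_dhs_width", "footprint",
    "nearby_sites", "nearby_sites_sq", "conservation",
)


@dataclass
class AnnotationStandardizer:
    """Persisted standardization: cross-cohort mean-ratio scaling followed
    by z-scoring with the training cohort's mean/SD. Scoring must reuse
    the training-time parameters, so they live on this object."""

    scale: dict[str, float] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def transform(self, annotations: pd.DataFrame) -> pd.DataFrame:
        df = annotations.copy()
        for col, s in self.scale.items():
            df[col] = df[col] * s
        df = _expand_global_features(df)
        for col in _GLOBAL_FEATURES:
            m, s = self.mean[col], self.sd[col]
            df[col] = (df[col] - m) / s if s > 0 else 0.0
        return df


def _expand_global_features(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns: logs (guarded by +1) and squared terms."""
    df = df.copy()
    df["mcv_sq"] = df["mcv"] ** 2
    df["log_dist_tss"] = np.log(df["dist_tss"].astype(float) + 1.0)
    df["log_dist_tss_sq"] = df["log_dist_tss"] ** 2
    df["dhs_strength_sq"] = df["dhs_strength"] ** 2
    df["log_dhs_width"] = np.log(df["dhs_width"].astype(float) + 1.0)
    df["nearby_sites_sq"] = df["nearby_sites"].astype(float) ** 2
    df["intron"] = df["intron"].astype(float)
    df["intergenic"] = df["intergenic"].astype(float)
    df["footprint"] = df["footprint"].astype(float)
    return df


def standardize_annotations(annotations: pd.DataFrame,
                            reference: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, AnnotationStandardizer]:
    """Standardize a training cohort, returning the fitted parameters.

    Step 1: each quantitative column is multiplied by
    mean(reference)/mean(annotations) so the two cohorts share scales
    (skipped when no reference cohort is given). Step 2: all model
    features are z-scored with the training cohort's mean/SD.
    """
    std = AnnotationStandardizer()
    df = annotations.copy()
    if reference is not None:
        for col in QUANTITATIVE_ANNOTATIONS:
            m_a = float(df[col].mean())
            if m_a == 0:
                raise ValueError(f"column {col!r} has zero mean; cannot scale")
            std.scale[col] = float(reference[col].mean()) / m_a
            df[col] = df[col] * std.scale[col]
    df = _expand_global_features(df)
    for col in _GLOBAL_FEATURES:
        std.mean[col] = float(df[col].mean())
        std.sd[col] = float(df[col].std(ddof=0))
        s = std.sd[col]
        df[col] = (df[col] - std.mean[col]) / s if s > 0 else 0.0
    return df, std


@dataclass
class GlobalModel:
    coef: np.ndarray
    intercept: float
    features: tuple[str, ...] = _GLOBAL_FEATURES

    def predict_proba(self, standardized: pd.DataFrame) -> np.ndarray:
        X = standardized[list(self.features)].to_numpy(dtype=float)
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def fit_global_model(standardized: pd.DataFrame, labels) -> GlobalModel:
    """Unpenalized logistic regression of imbalance on genomic context."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = standardized[list(_GLOBAL_FEATURES)].to_numpy(dtype=float)
    clf = LogisticRegression(penalty=None, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(f"global model failed to converge: {exc}") from exc
    return GlobalModel(coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]))


@dataclass
class TFModel:
    motif_id: str
    coef: np.ndarray
    intercept: float
    features: tuple[str, ...]
    positions: tuple[int, ...]       # positions with their own indicator
    trained_cell_types: tuple[str, ...]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        M = X[list(self.features)].to_numpy(dtype=float)
        z = M @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def tf_feature_frame(rows: pd.DataFrame, positions: tuple[int, ...]
                     ) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Build the per-TF design: global fit, log(score) and its square,
    allele log-odds difference, and per-position indicators."""
    X = pd.DataFrame(index=rows.index)
    X["global_fit"] = rows["global_fit"].astype(float)
    logscore = np.log(np.clip(rows["score"].astype(float), 1e-6, None))
    X["log_score"] = logscore
    X["log_score_sq"] = logscore ** 2
    X["logodds_diff"] = rows["logodds_diff"].astype(float)
    feats = ["global_fit", "log_score", "log_score_sq", "logodds_diff"]
    for p in positions:
        col = f"pos_{p}"
        X[col] = (rows["position"] == p).astype(float)
        feats.append(col)
    return X, tuple(feats)


def fit_tf_model(motif_id: str, rows: pd.DataFrame, labels,
                 trained_cell_types: tuple[str, ...] = (),
                 min_rows: int = 50,
                 min_per_position: int = 7) -> TFModel | None:
    """Per-TF logistic model on SNVs overlapping this motif.

    `rows` must carry global_fit, score, logodds_diff, position; `labels`
    are imbalance calls from the gated cell types. Position indicators
    are included only for positions with >= `min_per_position` rows.
    Constant feature columns are dropped with a warning. Returns None
    (with a warning) when fewer than `min_rows` rows are available.
    """
    y = np.asarray(labels).astype(int)
    if len(rows) < min_rows or len(np.unique(y)) < 2:
        warnings.warn(f"motif {motif_id}: insufficient training data "
                      f"({len(rows)} rows); skipped")
        return None
    pos_counts = rows["position"].value_counts()
    positions = tuple(sorted(int(p) for p in pos_counts.index[pos_counts >= min_per_position]))
    X, feats = tf_feature_frame(rows, positions)
    keep = []
    for f in feats:
        if X[f].nunique() > 1:
            keep.append(f)
        else:
            warnings.warn(f"motif {motif_id}: constant feature {f!r} dropped")
    M = X[keep].to_numpy(dtype=float)
    clf = LogisticRegression(penalty=None, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(M, y)
    return TFModel(motif_id=motif_id, coef=clf.coef_[0].copy(),
                   intercept=float(clf.intercept_[0]), features=tuple(keep),
                   positions=tuple(p for p in positions if f"pos_{p}" in keep),
                   trained_cell_types=tuple(trained_cell_types))


@dataclass
class Combiner:
    """Lasso-penalized logistic combiner over per-cluster TF scores."""

    coef: np.ndarray
    intercept: float
    features: tuple[str, ...]
    cv_auc: float
    C: float

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.coef != 0))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        M = X[list(self.features)].to_numpy(dtype=float)
        z = M @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def fit_combiner(features: pd.DataFrame, labels, folds: int = 50,
                 seed: int = 0, Cs: int = 10) -> Combiner:
    """L1-penalized logistic fit; penalty chosen by CV-AUC maximum.

    `features` holds per-TF-cluster scores (0 where the SNV overlaps no
    motif of the cluster) plus any extra columns such as the global-model
    probability. Folds exceeding n/2 are reduced with a warning; CV is
    stratified by label with a seeded shuffle.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if folds > n // 2:
        folds = max(2, n // 2)
        warnings.warn(f"folds reduced to {folds} for n={n}")
    folds = min(folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    X = features.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegressionCV(
            penalty="l1", solver="liblinear", scoring="roc_auc", cv=cv,
            Cs=Cs, max_iter=500, refit=True, random_state=seed % (2**31),
        )
        clf.fit(X, y)
    best_idx = int(np.argmax(clf.scores_[1].mean(axis=0)))
    cv_auc = float(clf.scores_[1].mean(axis=0)[best_idx])
    return Combiner(coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]),
                    features=tuple(features.columns), cv_auc=cv_auc,
                    C=float(clf.C_[0]))


@dataclass
class Cato2ModelBundle:
    """Everything needed to score variants: stage-1 model, per-TF models,
    combiner, standardization parameters, and the motif->cluster map."""

    standardizer: AnnotationStandardizer
    global_model: GlobalModel
    tf_models: dict[str, TFModel]
    combiner: Combiner
    cluster_of: dict[str, str]

    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()
        payload = {
            "version": 1,
            "standardizer": {"scale": self.standardizer.scale,
                             "mean": self.standardizer.mean,
                             "sd": self.standardizer.sd},
            "global_model": {"coef": arr(self.global_model.coef),
                             "intercept": self.global_model.intercept,
                             "features": list(self.global_model.features)},
            "tf_models": {
                m: {"coef": arr(t.coef), "intercept": t.intercept,
                    "features": list(t.features), "positions": list(t.positions),
                    "trained_cell_types": list(t.trained_cell_types)}
                for m, t in self.tf_models.items()
            },
            "combiner": {"coef": arr(self.combiner.coef),
                         "intercept": self.combiner.intercept,
                         "features": list(self.combiner.features),
                         "cv_auc": self.combiner.cv_auc, "C": self.combiner.C},
            "cluster_of": self.cluster_of,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Cato2ModelBundle":
        d = json.loads(text)
        std = AnnotationStandardizer(scale=d["standardizer"]["scale"],
                                     mean=d["standardizer"]["mean"],
                                     sd=d["standardizer"]["sd"])
        gm = GlobalModel(coef=np.array(d["global_model"]["coef"]),
                         intercept=d["global_model"]["intercept"],
                         features=tuple(d["global_model"]["features"]))
        tms = {
            m: TFModel(motif_id=m, coef=np.array(t["coef"]),
                       intercept=t["intercept"], features=tuple(t["features"]),
                       positions=tuple(t["positions"]),
                       trained_cell_types=tuple(t["trained_cell_types"]))
            for m, t in d["tf_models"].items()
        }
        cb = Combiner(coef=np.array(d["combiner"]["coef"]),
                      intercept=d["combiner"]["intercept"],
                      features=tuple(d["combiner"]["features"]),
                      cv_auc=d["combiner"]["cv_auc"], C=d["combiner"]["C"])
        return cls(standardizer=std, global_model=gm, tf_models=tms,
                   combiner=cb, cluster_of=d["cluster_of"])


def cluster_score_frame(snv_ids, tf_scores: pd.DataFrame,
                        cluster_of: dict[str, str],
                        global_fit: np.ndarray) -> pd.DataFrame:
    """Per-SNV combiner features: global probability plus the best per-TF
    score within each cluster (0 where the SNV overlaps no motif)."""
    clusters = sorted(set(cluster_of.values()))
    out = pd.DataFrame(0.0, index=pd.Index(snv_ids, name="snv_id"),
                       columns=[f"cluster_{c}" for c in clusters])
    if not tf_scores.empty:
        tf_scores = tf_scores.copy()
        tf_scores["cluster"] = tf_scores["motif_id"].map(cluster_of)
        best = (tf_scores.groupby(["snv_id", "cluster"])["tf_score"].max()
                .reset_index())
        for row in best.itertuples(index=False):
            col = f"cluster_{row.cluster}"
            if row.snv_id in out.index and col in out.columns:
                out.loc[row.snv_id, col] = row.tf_score
    out.insert(0, "global_fit", global_fit)
    return out


def score_variants(bundle: Cato2ModelBundle, annotations: pd.DataFrame,
                   assignments: pd.DataFrame) -> pd.DataFrame:
    """Score SNVs in [0, 1] with a trained bundle.

    `annotations` is raw (unstandardized); `assignments` carries per-SNV
    motif overlaps with score, logodds_diff and position columns. SNVs
    overlapping no motif fall back to the combiner applied to the
    global-model probability alone (all cluster features zero).
    """
    needed = {"snv_id", *QUANTITATIVE_ANNOTATIONS, "intron", "intergenic", "footprint"}
    missing = needed - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation columns missing: {sorted(missing)}")
    std = bundle.standardizer.transform(annotations)
    gfit = bundle.global_model.predict_proba(std)
    gfit_of = pd.Series(gfit, index=annotations["snv_id"].to_numpy())

    tf_rows = []
    for motif_id, model in bundle.tf_models.items():
        sub = assignments[assignments["motif_id"] == motif_id]
        if sub.empty:
            continue
        sub = sub.copy()
        sub["global_fit"] = gfit_of.reindex(sub["snv_id"]).to_numpy()
        sub = sub.dropna(subset=["global_fit"])
        if sub.empty:
            continue
        X, _ = tf_feature_frame(sub, model.positions)
        proba = model.predict_proba(X)
        tf_rows.append(pd.DataFrame({
            "snv_id": sub["snv_id"].to_numpy(),
            "motif_id": motif_id,
            "tf_score": proba,
        }))
    tf_scores = (pd.concat(tf_rows, ignore_index=True) if tf_rows
                 else pd.DataFrame(columns=["snv_id", "motif_id", "tf_score"]))
    feats = cluster_score_frame(annotations["snv_id"].to_numpy(), tf_scores,
                                bundle.cluster_of, gfit)
    score = bundle.combiner.predict_proba(feats)
    return pd.DataFrame({"snv_id": annotations["snv_id"], "score": score})


def gated_tf_labels(assignments: pd.DataFrame, snvs: pd.DataFrame,
                    calls_by_celltype: dict[str, pd.DataFrame],
                    motifs: pd.DataFrame, gate_log2: float = 1.0
                    ) -> dict[str, tuple[pd.Series, tuple[str, ...]]]:
    """Per-motif training labels from enrichment-gated cell types.

    A cell type trains a motif's TF model only when imbalance is more
    than twofold enriched over the motif core relative to flanks in that
    cell type. The motif's label for an SNV is "imbalanced in any gated
    cell type". Motifs with no gated cell type are omitted (callers may
    fall back to aggregate labels).
    """
    from .motif_profiles import celltype_enrichment

    out = {}
    for m in motifs.itertuples(index=False):
        enr = celltype_enrichment(
            assignments, snvs, calls_by_celltype, m.motif_id,
            core=(int(m.core_start), int(m.core_end)), gate_log2=gate_log2)
        gated = tuple(enr.loc[enr["gate"], "cell_type"])
        if not gated:
            continue
        frames = [calls_by_celltype[ct][["snv_id", "imbalanced"]] for ct in gated]
        lab = (pd.concat(frames).groupby("snv_id")["imbalanced"].any())
        out[m.motif_id] = (lab, gated)
    return out


def train_bundle(annotations: pd.DataFrame, assignments: pd.DataFrame,
                 labels: pd.Series, cluster_of: dict[str, str] | None = None,
                 tf_labels: dict[str, tuple[pd.Series, tuple[str, ...]]] | None = None,
                 reference: pd.DataFrame | None = None, seed: int = 0,
                 folds: int = 50, min_tf_rows: int = 50) -> Cato2ModelBundle:
    """Fit the full two-stage model on one cohort.

    `labels` is a boolean Series indexed by snv_id (the combiner's and
    global model's target). `tf_labels` optionally overrides per-motif
    training labels (e.g. from gated_tf_labels); motifs without an entry
    train on `labels`. Motifs default to singleton clusters.
    """
    std_df, std = standardize_annotations(annotations, reference)
    y = labels.reindex(annotations["snv_id"]).fillna(False).to_numpy()
    gm = fit_global_model(std_df, y)
    gfit = gm.predict_proba(std_df)
    gfit_of = pd.Series(gfit, index=annotations["snv_id"].to_numpy())

    if cluster_of is None:
        cluster_of = {m: m for m in assignments["motif_id"].unique()}
    tf_models: dict[str, TFModel] = {}
    tf_rows = []
    for motif_id, sub in assignments.groupby("motif_id"):
        sub = sub.copy()
        sub["global_fit"] = gfit_of.reindex(sub["snv_id"]).to_numpy()
        sub = sub.dropna(subset=["global_fit"]).reset_index(drop=True)
        if tf_labels is not None and motif_id in tf_labels:
            lab_src, cts = tf_labels[motif_id]
        else:
            lab_src, cts = labels, ()
        y_m = lab_src.reindex(sub["snv_id"]).fillna(False).to_numpy()
        model = fit_tf_model(str(motif_id), sub, y_m, trained_cell_types=cts,
                             min_rows=min_tf_rows)
        if model is None:
            continue
        tf_models[str(motif_id)] = model
        X, _ = tf_feature_frame(sub, model.positions)
        tf_rows.append(pd.DataFrame({
            "snv_id": sub["snv_id"].to_numpy(), "motif_id": str(motif_id),
            "tf_score": model.predict_proba(X),
        }))
    tf_scores = (pd.concat(tf_rows, ignore_index=True) if tf_rows
                 else pd.DataFrame(columns=["snv_id", "motif_id", "tf_score"]))
    feats = cluster_score_frame(annotations["snv_id"].to_numpy(), tf_scores,
                                cluster_of, gfit)
    combiner = fit_combiner(feats, y, folds=folds, seed=seed)
    return Cato2ModelBundle(standardizer=std, global_model=gm,
                            tf_models=tf_models, combiner=combiner,
                            cluster_of=cluster_of)


def precision_recall(scores, labels) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve over all score thresholds + trapezoid area.

    Direct numpy threshold sweep: thresholds at every distinct score,
    descending; area integrates precision over the recall grid. The
    positive-class prevalence is the random-score baseline.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # threshold boundaries: last index of each distinct score
    distinct = np.flatnonzero(np.diff(s_sorted))
    idx = np.concatenate([distinct, [len(s) - 1]])
    precision = tp[idx] / (tp[idx] + fp[idx])
    recall = tp[idx] / tp[-1]
    # prepend the (recall=0) anchor with the first threshold's precision
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    area = float(np.trapezoid(precision, recall))
    curve = pd.DataFrame({"recall": recall, "precision": precision})
    return curve, area
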