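"""Regularized mutability modelling.

Fits a penalized (elastic-net) logistic regression of mutated vs
non-mutated callable sites on standardized genomic-context predictors,
with the penalty strength chosen by cross-validation and the whole fit
repeated over independent training replicates to yield coefficient
medians and 95% CIs. Calibration bins predicted mutability (rounded to
one decimal) against the observed mutation rate of the same sites, with
a site-count-weighted linear fit. A model trained on one dataset can be
applied to another's features (cross-dataset prediction), and a binary
C→T-vs-other classifier with optional class balancing covers the
spectrum-prediction task.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .seqcontext import canonical_triplets
from .spectrum import fold_snm

FEATURE_CLASSES = ("CDS", "UTR5", "UTR3", "intron", "intergenic")
REPEAT_CLASSES = ("none", "low_complexity", "microsatellite", "TE")
CONTEXT_SLOTS = ("up_ctx", "mid_ctx", "down_ctx")

DEFAULT_CS = np.logspace(-3, 2, 8)


def encode_features(features: pd.DataFrame,
                    drop_gc: bool = False,
                    context_slots: tuple[str, ...] = CONTEXT_SLOTS
                    ) -> pd.DataFrame:
    """Encode a context-feature table as a numeric predictor frame.

    Categorical predictors become indicator columns over fixed category
    lists (32 canonical triplets per context slot; feature and repeat
    classes), so independently encoded datasets share a column schema.
    Rows with missing values (NaN or empty context) are dropped.
    """
    df = features.copy()
    parts = []
    numeric = df.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("pos",) if c in df], errors="ignore")
    if drop_gc:
        numeric = numeric.drop(columns=[c for c in numeric.columns
                                        if c.startswith(("GC_", "dGC_"))])
    parts.append(numeric)
    for slot in context_slots:
        if slot not in df:
            continue
        cat = pd.Categorical(df[slot].replace("", np.nan),
                             categories=canonical_triplets(
                                 slot.split("_")[0]))
        dummies = pd.get_dummies(cat, prefix=slot, dtype=float)
        dummies.index = df.index
        dummies[np.asarray(cat.isna())] = np.nan
        parts.append(dummies)
    for col, cats in (("feature_class", FEATURE_CLASSES),
                      ("repeat_class", REPEAT_CLASSES)):
        if col in df:
            cat = pd.Categorical(df[col], categories=cats)
            dummies = pd.get_dummies(cat, prefix=col, dtype=float)
            dummies.index = df.index
            dummies[np.asarray(cat.isna())] = np.nan
            parts.append(dummies)
    out = pd.concat(parts, axis=1)
    return out.dropna(axis=0)


@dataclass
class FeatureMatrix:
    """Encoded predictor frame plus labels, pre-standardization."""

    frame: pd.DataFrame
    y: np.ndarray

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def build_feature_matrix(features: pd.DataFrame, labels,
                         drop_gc: bool = False) -> FeatureMatrix:
    """Pair encoded features with 0/1 labels, dropping incomplete rows."""
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("labels must align with feature rows")
    frame = encode_features(features.reset_index(drop=True), drop_gc=drop_gc)
    if frame.empty:
        raise ValueError("no rows left after missing-value filtering")
    y = labels[frame.index.to_numpy()]
    return FeatureMatrix(frame=frame.reset_index(drop=True),
                         y=np.asarray(y).astype(int))


@dataclass
class Scaler:
    """Per-column training means/SDs; near-zero-variance columns dropped."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, frame: pd.DataFrame, min_minority_freq: float = 1e-4
            ) -> "Scaler":
        keep = []
        for col in frame.columns:
            x = frame[col].to_numpy()
            uniq, counts = np.unique(x, return_counts=True)
            if len(uniq) < 2:
                continue
            if counts.min() / len(x) < min_minority_freq:
                continue
            keep.append(col)
        sub = frame[keep]
        mean = sub.mean().to_numpy()
        sd = sub.std(ddof=0).to_numpy()
        return cls(columns=keep, mean=mean, sd=sd)

    def transform(self, frame: pd.DataFrame,
                  missing_ok: bool = False) -> np.ndarray:
        missing = [c for c in self.columns if c not in frame.columns]
        if missing and not missing_ok:
            raise KeyError(f"features lack trained columns: {missing[:5]}")
        x = np.empty((len(frame), len(self.columns)))
        for j, col in enumerate(self.columns):
            if col in frame.columns:
                x[:, j] = frame[col].to_numpy(dtype=float)
            else:  # impute at the training mean => standardized zero
                x[:, j] = self.mean[j]
        return (x - self.mean) / self.sd


@dataclass
class ReplicateFit:
    scaler: Scaler
    coef: pd.Series
    intercept: float
    C: float
    seed: int

    def predict_proba(self, frame: pd.DataFrame,
                      missing_ok: bool = False) -> np.ndarray:
        z = self.scaler.transform(frame, missing_ok) @ self.coef.to_numpy() \
            + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class MutabilityModel:
    l1_ratio: float
    replicates: list[ReplicateFit]
    n_mutated: int
    n_nonmutated: int
    seed: int

    def coefficient_summary(self) -> pd.DataFrame:
        table = pd.DataFrame({i: r.coef for i, r in
                              enumerate(self.replicates)})
        return pd.DataFrame({
            "median": table.median(axis=1),
            "ci_low": table.quantile(0.025, axis=1),
            "ci_high": table.quantile(0.975, axis=1),
            "n_replicates": table.notna().sum(axis=1),
        })

    def predict_proba(self, frame: pd.DataFrame,
                      missing_ok: bool = False) -> np.ndarray:
        return np.mean([r.predict_proba(frame, missing_ok)
                        for r in self.replicates], axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Plain-text serializable coefficient + scaling table."""
        rows = []
        for i, rep in enumerate(self.replicates):
            rows.append({"replicate": i, "column": "__intercept__",
                         "coef": rep.intercept, "mean": 0.0, "sd": 1.0,
                         "C": rep.C, "l1_ratio": self.l1_ratio})
            for col, m, s in zip(rep.scaler.columns, rep.scaler.mean,
                                 rep.scaler.sd):
                rows.append({"replicate": i, "column": col,
                             "coef": rep.coef[col], "mean": m, "sd": s,
                             "C": rep.C, "l1_ratio": self.l1_ratio})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_mutated: int = 0,
                   n_nonmutated: int = 0, seed: int = 0) -> "MutabilityModel":
        reps = []
        for i, g in df.groupby("replicate"):
            inter = g[g["column"] == "__intercept__"]
            body = g[g["column"] != "__intercept__"]
            scaler = Scaler(columns=list(body["column"]),
                            mean=body["mean"].to_numpy(),
                            sd=body["sd"].to_numpy())
            reps.append(ReplicateFit(
                scaler=scaler,
                coef=pd.Series(body["coef"].to_numpy(),
                               index=body["column"]),
                intercept=float(inter["coef"].iloc[0]),
                C=float(g["C"].iloc[0]), seed=seed))
        return cls(l1_ratio=float(df["l1_ratio"].iloc[0]), replicates=reps,
                   n_mutated=n_mutated, n_nonmutated=n_nonmutated, seed=seed)


def _fit_enet(x: np.ndarray, y: np.ndarray, l1_ratio: float, cs,
              cv_folds: int, seed: int, max_iter: int = 3000):
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=cs, cv=cv, solver="saga", l1_ratios=[l1_ratio],
        scoring="neg_log_loss", max_iter=max_iter, tol=1e-3, n_jobs=1,
        random_state=seed, use_legacy_attributes=False)
    model.fit(x, y)
    c_sel = model.C_
    c_val = float(np.ravel(c_sel)[0])
    return model.coef_.ravel(), float(model.intercept_[0]), c_val


def train_mutability(matrix: FeatureMatrix, n_nonmutated: int = 100_000,
                     cv_folds: int = 10, replicates: int = 10,
                     l1_ratio: float = 0.5, cs=DEFAULT_CS,
                     seed: int = 0) -> MutabilityModel:
    """Fit the replicate ensemble of elastic-net mutability models.

    Each replicate trains on all mutated rows plus ``n_nonmutated``
    non-mutated rows sampled without replacement from the matrix, with
    standardization and near-zero-variance filtering recomputed on that
    replicate's training rows only (no information leakage). The penalty
    strength is selected at minimum cross-validated deviance within the
    replicate; folds are stratified by label.
    """
    y = matrix.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    mut_idx = np.flatnonzero(y == 1)
    non_idx = np.flatnonzero(y == 0)
    n_non = min(int(n_nonmutated), len(non_idx))
    rng = np.random.default_rng(seed)
    reps = []
    for r in range(replicates):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        rows = np.concatenate([
            mut_idx, rep_rng.choice(non_idx, size=n_non, replace=False)])
        frame = matrix.frame.iloc[rows]
        scaler = Scaler.fit(frame)
        x = scaler.transform(frame)
        coef, intercept, c = _fit_enet(x, y[rows], l1_ratio, cs,
                                       cv_folds, rep_seed)
        reps.append(ReplicateFit(
            scaler=scaler, coef=pd.Series(coef, index=scaler.columns),
            intercept=intercept, C=c, seed=rep_seed))
    return MutabilityModel(l1_ratio=l1_ratio, replicates=reps,
                           n_mutated=len(mut_idx), n_nonmutated=n_non,
                           seed=seed)


@dataclass
class CalibrationResult:
    table: pd.DataFrame   # bin, mean predicted, observed rate, n
    slope: float
    intercept: float
    r2: float
    p: float


def calibrate_predictions(model: MutabilityModel, frame: pd.DataFrame,
                          y, missing_ok: bool = False) -> CalibrationResult:
    """Binned predicted-vs-observed mutability with a weighted linear fit.

    Sites are grouped by ensemble-mean predicted mutability rounded to
    one decimal; the observed rate is the mutated fraction per bin. The
    linear fit is weighted by the number of sites in each bin. With fewer
    than two occupied bins the fit is reported missing (NaN).
    """
    y = np.asarray(y).astype(int)
    p = model.predict_proba(frame, missing_ok)
    bins = np.round(p, 1)
    df = pd.DataFrame({"bin": bins, "p": p, "y": y})
    table = df.groupby("bin").agg(
        predicted=("p", "mean"), observed=("y", "mean"),
        n=("y", "size")).reset_index()
    if len(table) < 2:
        return CalibrationResult(table=table, slope=np.nan,
                                 intercept=np.nan, r2=np.nan, p=np.nan)
    wls = sm.WLS(table["observed"], sm.add_constant(table["bin"]),
                 weights=table["n"]).fit()
    return CalibrationResult(table=table,
                             slope=float(wls.params.iloc[1]),
                             intercept=float(wls.params.iloc[0]),
                             r2=float(wls.rsquared),
                             p=float(wls.pvalues.iloc[1]))


def cross_predict(model: MutabilityModel, frame_b: pd.DataFrame, y_b
                  ) -> tuple[CalibrationResult, list[str]]:
    """Apply a trained model to another dataset's encoded features.

    Only columns shared with the training schema are used; training
    columns absent from the target are reported (and treated as zero
    after standardization, i.e. at the training mean). Disjoint schemas
    are an error.
    """
    mismatches = sorted({c for rep in model.replicates
                         for c in rep.scaler.columns} - set(frame_b.columns))
    shared = [c for rep in model.replicates for c in rep.scaler.columns
              if c in frame_b.columns]
    if not shared:
        raise ValueError("no shared feature columns between datasets")
    return calibrate_predictions(model, frame_b, y_b,
                                 missing_ok=True), mismatches


# ---------------------------------------------------------------------------
# binary C→T spectrum classifier

def _smote(x: np.ndarray, n_new: int, rng, k: int = 5) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(x))).fit(x)
    _, idx = nn.kneighbors(x)
    picks = rng.integers(0, len(x), size=n_new)
    out = np.empty((n_new, x.shape[1]))
    for i, p in enumerate(picks):
        neigh = idx[p][1:] if len(idx[p]) > 1 else idx[p]
        q = neigh[rng.integers(0, len(neigh))]
        u = rng.random()
        out[i] = x[p] + u * (x[q] - x[p])
    return out


def _balance(x: np.ndarray, y: np.ndarray, how: str, rng):
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if how == "none" or n1 == n0:
        return x, y
    minority = 1 if n1 < n0 else 0
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    if how == "down":
        keep = rng.choice(maj_idx, size=len(min_idx), replace=False)
        rows = np.concatenate([min_idx, keep])
        return x[rows], y[rows]
    if how == "up":
        extra = rng.choice(min_idx, size=len(maj_idx) - len(min_idx),
                           replace=True)
        rows = np.concatenate([np.arange(len(y)), extra])
        return x[rows], y[rows]
    if how == "smote":
        new = _smote(x[min_idx], len(maj_idx) - len(min_idx), rng)
        return (np.vstack([x, new]),
                np.concatenate([y, np.full(len(new), minority)]))
    raise ValueError(f"unknown balancing {how!r}")


@dataclass
class CtClassifierResult:
    accuracy: float
    baseline: float      # majority-class rate in the test split
    p: float             # exact binomial test vs the baseline
    n_test: int
    balancing: str
    coef: pd.Series


def train_ct_classifier(features: pd.DataFrame, refs, alts,
                        balancing: str = "none", split: float = 0.75,
                        l1_ratio: float = 0.5, cs=DEFAULT_CS,
                        cv_folds: int = 5, seed: int = 0
                        ) -> CtClassifierResult:
    """Binary classifier: is an SNM a C→T transition?

    Works on SNM-site features only. GC-content predictors are excluded
    and trinucleotide contexts are reduced to the flanking dinucleotides
    (the mutated base itself is removed from its own predictors, since
    C→T status is deterministic given the centre base). A random
    ``split`` fraction trains (with optional down/up/SMOTE balancing);
    accuracy on the held-out remainder is compared against the
    majority-class baseline with an exact binomial test.
    """
    labels = np.array([1 if fold_snm(r, a) == "C>T" else 0
                       for r, a in zip(refs, alts)])
    df = features.copy().reset_index(drop=True)
    df["up2"] = [c[:2] if c else "" for c in df.get("up_ctx", [""] * len(df))]
    df["down2"] = [c[1:] if c else ""
                   for c in df.get("down_ctx", [""] * len(df))]
    dinucs = [a + b for a in "ACGT" for b in "ACGT"]
    frame_parts = [encode_features(
        df.drop(columns=[c for c in CONTEXT_SLOTS if c in df]),
        drop_gc=True, context_slots=())]
    for col in ("up2", "down2"):
        cat = pd.Categorical(df[col].replace("", np.nan), categories=dinucs)
        dummies = pd.get_dummies(cat, prefix=col, dtype=float)
        dummies[np.asarray(cat.isna())] = np.nan
        frame_parts.append(dummies)
    frame = pd.concat(frame_parts, axis=1, join="inner").dropna(axis=0)
    y = labels[frame.index.to_numpy()]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n = len(frame)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    train_rows, test_rows = perm[:n_train], perm[n_train:]
    if len(test_rows) == 0 or len(np.unique(y[train_rows])) < 2:
        raise ValueError("degenerate train/test split")
    scaler = Scaler.fit(frame.iloc[train_rows])
    x_train = scaler.transform(frame.iloc[train_rows])
    y_train = y[train_rows]
    x_train, y_train = _balance(x_train, y_train, balancing, rng)
    if len(np.unique(y_train)) < 2:
        raise ValueError("a class vanished during balancing")
    coef, intercept, _c = _fit_enet(x_train, y_train, l1_ratio, cs,
                                    cv_folds, int(rng.integers(2 ** 31 - 1)))
    x_test = scaler.transform(frame.iloc[test_rows])
    pred = (x_test @ coef + intercept) > 0
    y_test = y[test_rows]
    acc = float((pred == y_test).mean())
    baseline = float(max(y_test.mean(), 1 - y_test.mean()))
    k = int((pred == y_test).sum())
    p = float(stats.binomtest(k, len(y_test), baseline,
                              alternative="greater").pvalue)
    return CtClassifierResult(accuracy=acc, baseline=baseline, p=p,
                              n_test=len(y_test), balancing=balancing,
                              coef=pd.Series(coef, index=scaler.columns))
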