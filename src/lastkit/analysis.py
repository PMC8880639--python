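"""Group statistics and the proof-of-concept three-group classifier.

Because the clinical groups are small and unbalanced, features are compared
across PD, PSP and control with the Kruskal–Wallis rank test; features that
reject are followed up with Dunn's pairwise mean-rank z-tests to locate the
differing group.  Classification reduces the three-class problem to three
one-vs-one Gaussian-kernel SVM dichotomizers combined by error-correcting
output codes: each dichotomizer votes, and the class whose codeword is
nearest in Hamming distance (zeros excluded) wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .scan_io import GROUPS, FeatureTable, ValidationError

logger = logging.getLogger(__name__)

PAIRS = (("PD", "PSP"), ("PD", "CON"), ("PSP", "CON"))

#: one-vs-one codewords: rows = classes, columns = dichotomizers (PAIRS);
#: +1 = the row class is the pair's first member, 0 = class not involved
CODEBOOK = pd.DataFrame(
    [[+1, +1, 0],
     [-1, 0, +1],
     [0, -1, -1]],
    index=["PD", "PSP", "CON"],
    columns=[f"{a}_vs_{b}" for a, b in PAIRS],
)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

@dataclass
class FeatureSignificance:
    feature: str
    H: float
    p: float
    significant: bool
    dunn_p: dict[str, float] = field(default_factory=dict)
    dunn_significant: dict[str, bool] = field(default_factory=dict)


@dataclass
class SignificanceReport:
    alpha: float
    features: dict[str, FeatureSignificance]
    skipped: list[str] = field(default_factory=list)

    @property
    def significant_features(self) -> list[str]:
        return [n for n, f in self.features.items() if f.significant]


def _dunn_pairwise(samples: dict[str, np.ndarray], alpha: float,
                   correction: str | None = None) -> tuple[dict, dict]:
    """Dunn's multiple-comparison z-tests on mean ranks, tie-corrected."""
    pooled = np.concatenate(list(samples.values()))
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for g, v in samples.items():
        mean_ranks[g] = ranks[i:i + len(v)].mean()
        i += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term

    pvals = {}
    for a, b in PAIRS:
        if a not in samples or b not in samples:
            continue
        se = np.sqrt(base_var * (1.0 / len(samples[a]) + 1.0 / len(samples[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pvals[f"{a}_vs_{b}"] = 2 * stats.norm.sf(abs(z))
    if correction == "holm":
        names = sorted(pvals, key=pvals.get)
        m = len(names)
        adj_prev = 0.0
        for k, name in enumerate(names):
            adj = min(max((m - k) * pvals[name], adj_prev), 1.0)
            pvals[name] = adj
            adj_prev = adj
    flags = {k: p < alpha for k, p in pvals.items()}
    return pvals, flags


def kruskal_dunn(table: FeatureTable, alpha: float = 0.05,
                 correction: str | None = None) -> SignificanceReport:
    """Kruskal–Wallis per feature, gate-kept Dunn post-hocs on rejections.

    Missing values are dropped per feature; features observed in fewer than
    two groups (or constant everywhere) are skipped and logged.  Dunn
    pairwise tests run only for features whose omnibus test rejects at
    ``alpha`` (no multiplicity correction by default; ``correction="holm"``
    adjusts the three pairwise p-values).
    """
    df = table.frame
    if "group" not in df.columns:
        raise ValidationError("feature table lacks a 'group' column")
    report = SignificanceReport(alpha=alpha, features={})
    for name in table.feature_columns:
        col = pd.to_numeric(df[name], errors="coerce")
        samples = {g: col[(df["group"] == g) & col.notna()].to_numpy()
                   for g in GROUPS}
        samples = {g: v for g, v in samples.items() if len(v) >= 2}
        if len(samples) < 2:
            report.skipped.append(name)
            logger.info("feature %s skipped: fewer than 2 groups", name)
            continue
        try:
            with np.errstate(invalid="ignore"):
                H, p = stats.kruskal(*samples.values())
        except ValueError:
            H, p = np.nan, np.nan
        if not np.isfinite(H):  # all values identical: H undefined
            report.skipped.append(name)
            logger.info("feature %s skipped: constant across groups", name)
            continue
        sig = bool(p < alpha)
        entry = FeatureSignificance(feature=name, H=float(H), p=float(p),
                                    significant=sig)
        if sig:
            entry.dunn_p, entry.dunn_significant = _dunn_pairwise(
                samples, alpha, correction)
        report.features[name] = entry
    return report


# ---------------------------------------------------------------------------
# ECOC Gaussian-SVM
# ---------------------------------------------------------------------------

@dataclass
class EcocModel:
    dichotomizers: dict[str, SVC]
    mean: np.ndarray
    sd: np.ndarray
    medians: np.ndarray  # imputation values, pre-standardization
    gamma: float
    class_counts: dict[str, int]
    feature_names: list[str]


def _resolve_gamma(n_features: int, gamma_mode: str) -> float:
    """Kernel coefficient of k(x, x') = exp(-gamma |x - x'|^2).

    ``medium``: the conventional medium-Gaussian preset, kernel scale
    sqrt(n) i.e. gamma = 1/n; ``paper``: literally gamma = n, which on
    standardized features is a near-degenerate, very narrow kernel.
    """
    if gamma_mode == "medium":
        return 1.0 / n_features
    if gamma_mode == "paper":
        return float(n_features)
    raise ValidationError("gamma_mode must be 'medium' or 'paper'")


def train_ecoc_svm(X: np.ndarray, y: np.ndarray,
                   gamma_mode: str = "medium",
                   feature_names: list[str] | None = None) -> EcocModel:
    """Fit the three one-vs-one Gaussian-SVM dichotomizers.

    Features are median-imputed and standardized with statistics computed
    from the training data; each dichotomizer sees only its two classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    present = set(y)
    if present != set(GROUPS):
        raise ValidationError(f"all three groups required, got {present}")
    medians = np.nanmedian(X, axis=0)
    if np.isnan(X).any():
        logger.info("median-imputing %d missing values", int(np.isnan(X).sum()))
    Xi = np.where(np.isnan(X), medians, X)
    mean = Xi.mean(axis=0)
    sd = Xi.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xi - mean) / sd
    gamma = _resolve_gamma(X.shape[1], gamma_mode)
    dichos = {}
    for a, b in PAIRS:
        sel = (y == a) | (y == b)
        svc = SVC(kernel="rbf", gamma=gamma, C=1.0)
        svc.fit(Xs[sel], y[sel])
        dichos[f"{a}_vs_{b}"] = svc
    return EcocModel(dichotomizers=dichos, mean=mean, sd=sd, medians=medians,
                     gamma=gamma,
                     class_counts={g: int((y == g).sum()) for g in GROUPS},
                     feature_names=feature_names or
                     [f"f{i}" for i in range(X.shape[1])])


def predict_ecoc(model: EcocModel, X: np.ndarray) -> np.ndarray:
    """Decode dichotomizer votes to group labels by Hamming distance.

    Each dichotomizer votes +1 (its pair's first class) or -1; the class
    with the nearest codeword (zero entries excluded) wins.  Exact ties go
    to the class with more training samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.mean):
        raise ValidationError(
            f"expected {len(model.mean)} features, got {X.shape[1]}")
    Xi = np.where(np.isnan(X), model.medians, X)
    Xs = (Xi - model.mean) / model.sd
    votes = np.zeros((len(Xs), len(PAIRS)))
    for j, (a, b) in enumerate(PAIRS):
        pred = model.dichotomizers[f"{a}_vs_{b}"].predict(Xs)
        votes[:, j] = np.where(pred == a, +1, -1)
    out = []
    for v in votes:
        dists = {}
        for cls in CODEBOOK.index:
            code = CODEBOOK.loc[cls].to_numpy()
            active = code != 0
            dists[cls] = int(np.sum(v[active] != code[active]))
        dmin = min(dists.values())
        tied = [c for c, d in dists.items() if d == dmin]
        if len(tied) > 1:
            tied.sort(key=lambda c: -model.class_counts[c])
            logger.info("ECOC tie %s resolved to %s", dists, tied[0])
        out.append(tied[0])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    accuracy: float
    per_fold: list[float]
    confusion: pd.DataFrame
    selected_features: list[list[str]]

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "per_fold": self.per_fold,
                "confusion_matrix": self.confusion.to_dict(),
                "selected_features": self.selected_features}


def cross_validate(table: FeatureTable, k: int = 5, seed: int = 0,
                   gamma_mode: str = "medium", alpha: float = 0.05,
                   nested_selection: bool = True,
                   features: list[str] | None = None) -> CvReport:
    """Stratified k-fold accuracy of the ECOC classifier.

    Imputation, standardization and (by default) the significance-based
    feature selection are all fitted inside each training fold.  With
    ``nested_selection=False`` the feature set is fixed up front (all
    columns, or ``features`` when given).
    """
    from sklearn.model_selection import StratifiedKFold

    df = table.frame
    y = df["group"].to_numpy()
    for g in GROUPS:
        if (y == g).sum() < k:
            raise ValidationError(f"group {g} smaller than k={k}")
    all_feats = features or table.feature_columns
    X_full = df[all_feats].apply(pd.to_numeric, errors="coerce").to_numpy()

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    sel_log: list[list[str]] = []
    conf = pd.DataFrame(0, index=list(GROUPS), columns=list(GROUPS))
    correct = total = 0
    for tr, te in skf.split(X_full, y):
        feats = all_feats
        if nested_selection:
            sub = FeatureTable(df.iloc[tr][["subject", "group"] + all_feats]
                               if "subject" in df.columns
                               else df.iloc[tr][["group"] + all_feats])
            rep = kruskal_dunn(sub, alpha=alpha)
            sig = rep.significant_features
            if sig:
                feats = sig
        sel_log.append(list(feats))
        idx = [all_feats.index(f) for f in feats]
        model = train_ecoc_svm(X_full[np.ix_(tr, idx)], y[tr],
                               gamma_mode=gamma_mode, feature_names=feats)
        pred = predict_ecoc(model, X_full[np.ix_(te, idx)])
        hits = int((pred == y[te]).sum())
        per_fold.append(hits / len(te) * 100.0)
        correct += hits
        total += len(te)
        for t, p in zip(y[te], pred):
            conf.loc[t, p] += 1
    return CvReport(accuracy=correct / total * 100.0, per_fold=per_fold,
                    confusion=conf, selected_features=sel_log)
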