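"""Radiomics baseline: hand-crafted RoI features, Boruta selection, random forest.

Features are intensity (first-order histogram statistics) and texture
descriptors from gray-level co-occurrence (GLCM) and gray-level
run-length (GLRLM) matrices, computed on the un-augmented RoI after
quantization to a fixed number of gray levels.  Shape features are
deliberately absent (no pixel-level masks, only boxes).  The feature
inventory is configurable through the extraction settings; selection
makes the exact count non-critical.

Boruta is the all-relevant selection scheme: each iteration appends a
permuted "shadow" copy of every column, fits a random forest, scores a
hit for every real feature whose importance exceeds the best shadow's,
and accumulates two-sided binomial tests (Bonferroni-corrected) until
each feature is confirmed or rejected, or the iteration budget ends —
undecided features are reported as tentative, never silently confirmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix, graycoprops
from sklearn.ensemble import RandomForestClassifier

_GLCM_PROPS = ("contrast", "dissimilarity", "homogeneity", "energy", "correlation", "ASM")


@dataclass
class RadiomicsSettings:
    """Extraction provenance: quantization and texture-matrix geometry."""

    n_gray: int = 32
    distances: tuple[int, ...] = (1, 2, 3)
    angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class RFSettings:
    """Random-forest settings; the depth cap of 300 is effectively unbounded
    for RoI-sized data and is exposed alongside the tree count."""

    n_estimators: int = 300
    max_depth: int = 300
    seed: int = 0


@dataclass
class BorutaResult:
    confirmed: list[str] = field(default_factory=list)
    tentative: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)
    n_iterations: int = 0


def quantize(image: np.ndarray, n_gray: int) -> np.ndarray:
    """Map [0, 255] intensities onto n_gray equal-width levels 0..n_gray-1."""
    img = np.asarray(image, dtype=float)
    return np.minimum((img / 256.0 * n_gray).astype(int), n_gray - 1)


def first_order_features(image: np.ndarray, n_gray: int = 32) -> dict[str, float]:
    x = np.asarray(image, dtype=float).ravel()
    hist = np.bincount(quantize(x, n_gray).ravel(), minlength=n_gray).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    pct = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var())
    feats = {
        "fo_mean": float(x.mean()),
        "fo_variance": var,
        "fo_skewness": float(stats.skew(x)) if var > 0 else 0.0,
        "fo_kurtosis": float(stats.kurtosis(x)) if var > 0 else 0.0,
        "fo_energy": float((p ** 2).sum()),
        "fo_entropy": float(-(nz * np.log2(nz)).sum()),
        "fo_min": float(x.min()),
        "fo_max": float(x.max()),
        "fo_range": float(x.max() - x.min()),
        "fo_p10": float(pct[0]),
        "fo_p25": float(pct[1]),
        "fo_median": float(pct[2]),
        "fo_p75": float(pct[3]),
        "fo_p90": float(pct[4]),
        "fo_iqr": float(pct[3] - pct[1]),
        "fo_mad": float(np.abs(x - x.mean()).mean()),
        "fo_rms": float(np.sqrt((x ** 2).mean())),
    }
    return feats


def glcm_features(image: np.ndarray, settings: RadiomicsSettings) -> dict[str, float]:
    q = quantize(image, settings.n_gray).astype(np.uint8)
    glcm = graycomatrix(q, distances=settings.distances, angles=settings.angles,
                        levels=settings.n_gray, symmetric=True, normed=True)
    feats: dict[str, float] = {}
    for prop in _GLCM_PROPS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = graycoprops(glcm, prop)  # (n_dist, n_angle)
        for di, d in enumerate(settings.distances):
            v = float(np.nanmean(vals[di]))
            if not np.isfinite(v):
                warnings.warn(f"GLCM {prop} undefined (constant image); imputing 0", stacklevel=2)
                v = 0.0
            feats[f"glcm_{prop.lower()}_d{d}"] = v
    for di, d in enumerate(settings.distances):
        pm = glcm[:, :, di, :]
        ent = []
        for ai in range(pm.shape[-1]):
            nz = pm[:, :, ai][pm[:, :, ai] > 0]
            ent.append(float(-(nz * np.log2(nz)).sum()))
        feats[f"glcm_entropy_d{d}"] = float(np.mean(ent))
    return feats


def glcm_matrix(image: np.ndarray, n_gray: int, distance: int, angle: float,
                symmetric: bool = True, normed: bool = True) -> np.ndarray:
    """Single co-occurrence matrix (convenience wrapper used for inspection)."""
    q = quantize(image, n_gray).astype(np.uint8)
    return graycomatrix(q, [distance], [angle], levels=n_gray,
                        symmetric=symmetric, normed=normed)[:, :, 0, 0]


def _run_length_matrix(q: np.ndarray, n_gray: int, direction: tuple[int, int]) -> np.ndarray:
    """GLRLM for one direction; rows = gray level, cols = run length - 1."""
    h, w = q.shape
    max_len = max(h, w)
    mat = np.zeros((n_gray, max_len), dtype=float)
    dy, dx = direction
    lines: list[np.ndarray] = []
    if (dy, dx) == (0, 1):
        lines = [q[i, :] for i in range(h)]
    elif (dy, dx) == (1, 0):
        lines = [q[:, j] for j in range(w)]
    else:  # diagonals
        flipped = q[:, ::-1] if dx < 0 else q
        lines = [np.diagonal(flipped, offset=k) for k in range(-h + 1, w)]
    for line in lines:
        if line.size == 0:
            continue
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [line.size]])
        for s, e in zip(starts, ends):
            mat[line[s], min(e - s, max_len) - 1] += 1
    return mat


def glrlm_features(image: np.ndarray, settings: RadiomicsSettings) -> dict[str, float]:
    q = quantize(image, settings.n_gray)
    directions = [(0, 1), (1, 0), (1, 1), (1, -1)]
    acc: dict[str, list[float]] = {}
    n_pixels = q.size
    for d in directions:
        r = _run_length_matrix(q, settings.n_gray, d)
        n_runs = r.sum()
        j = np.arange(1, r.shape[1] + 1, dtype=float)
        i = np.arange(1, r.shape[0] + 1, dtype=float)
        rj = r.sum(axis=0)  # runs by length
        ri = r.sum(axis=1)  # runs by gray level
        vals = {
            "glrlm_sre": (rj / j ** 2).sum() / n_runs,
            "glrlm_lre": (rj * j ** 2).sum() / n_runs,
            "glrlm_gln": (ri ** 2).sum() / n_runs,
            "glrlm_rln": (rj ** 2).sum() / n_runs,
            "glrlm_rp": n_runs / n_pixels,
            "glrlm_lgre": (ri / i ** 2).sum() / n_runs,
            "glrlm_hgre": (ri * i ** 2).sum() / n_runs,
            "glrlm_srlge": (r / np.outer(i ** 2, j ** 2)).sum() / n_runs,
            "glrlm_srhge": (r * np.outer(i ** 2, 1.0 / j ** 2)).sum() / n_runs,
            "glrlm_lrlge": (r * np.outer(1.0 / i ** 2, j ** 2)).sum() / n_runs,
            "glrlm_lrhge": (r * np.outer(i ** 2, j ** 2)).sum() / n_runs,
        }
        for k, v in vals.items():
            acc.setdefault(k, []).append(float(v))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def extract_features(roi: np.ndarray, settings: RadiomicsSettings | None = None,
                     ) -> dict[str, float]:
    """Deterministic feature vector of one RoI (no augmentation involved)."""
    if roi.size == 0:
        raise ValueError("cannot extract features from an empty RoI")
    settings = settings or RadiomicsSettings()
    feats = first_order_features(roi, settings.n_gray)
    feats.update(glcm_features(roi, settings))
    feats.update(glrlm_features(roi, settings))
    return feats


def build_feature_table(records, roi_margin: float = 0.2,
                        settings: RadiomicsSettings | None = None) -> pd.DataFrame:
    """FeatureTable: one row per image, indexed by image_id; stable columns."""
    from sonomtl.augment import extract_roi

    rows = {r.image_id: extract_features(extract_roi(r, roi_margin), settings)
            for r in records}
    df = pd.DataFrame.from_dict(rows, orient="index")
    assert not df.isna().any().any(), "feature table contains missing values"
    return df


def boruta_select(X: pd.DataFrame, y, max_iter: int = 50, alpha: float = 0.01,
                  n_estimators: int = 100, seed: int = 0) -> BorutaResult:
    """All-relevant feature selection with shadow features and binomial tests."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("Boruta requires at least two classes")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    result = BorutaResult()
    constant = [n for j, n in enumerate(names) if np.ptp(Xv[:, j]) == 0.0]
    result.rejected.extend(constant)
    undecided = [n for n in names if n not in constant]
    hits = {n: 0 for n in undecided}
    n_trials = 0
    n_total = len(names)

    while undecided and n_trials < max_iter:
        cols = [names.index(n) for n in undecided]
        Xa = Xv[:, cols]
        shadow = np.column_stack([rng.permutation(Xa[:, j]) for j in range(Xa.shape[1])])
        Z = np.hstack([Xa, shadow])
        rf = RandomForestClassifier(n_estimators=n_estimators, max_depth=7,
                                    random_state=int(rng.integers(2 ** 31)), n_jobs=1)
        rf.fit(Z, y)
        imp = rf.feature_importances_
        shadow_max = imp[Xa.shape[1]:].max()
        for j, n in enumerate(undecided):
            if imp[j] > shadow_max:
                hits[n] += 1
        n_trials += 1
        thr = alpha / n_total  # Bonferroni over the feature inventory
        still = []
        for n in undecided:
            k = hits[n]
            if stats.binom.sf(k - 1, n_trials, 0.5) < thr:
                result.confirmed.append(n)
            elif stats.binom.cdf(k, n_trials, 0.5) < thr:
                result.rejected.append(n)
            else:
                still.append(n)
        undecided = still
    result.tentative = undecided
    result.n_iterations = n_trials
    return result


def rf_classify(X: pd.DataFrame, y, settings: RFSettings | None = None,
                ) -> RandomForestClassifier:
    """Fit the baseline random forest; scores come from ``predict_proba``."""
    settings = settings or RFSettings()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("random-forest baseline requires two classes in y")
    rf = RandomForestClassifier(n_estimators=settings.n_estimators,
                                max_depth=settings.max_depth,
                                random_state=settings.seed, n_jobs=1)
    rf.fit(X.to_numpy(dtype=float), y)
    return rf


def radiomics_baseline(records, task: str = "bm", roi_margin: float = 0.2,
                       settings: RadiomicsSettings | None = None,
                       rf_settings: RFSettings | None = None,
                       boruta_max_iter: int = 50, boruta_alpha: float = 0.01,
                       seed: int = 0) -> dict:
    """End-to-end baseline for one task; returns metrics, scores and selection.

    Trains on the train+val splits and evaluates on the test split of
    the given records.  ``task`` is ``bm``, ``alnm`` or ``burden_geN``;
    nodal tasks use only ALNM-defined records.
    """
    from sonomtl.evalmetrics import evaluate_scores
    from sonomtl.train import _labels_for

    def subset(split_names):
        recs = [r for r in records if r.split in split_names]
        if task != "bm":
            recs = [r for r in recs if r.alnm_defined]
        return recs

    train_recs = subset(("train", "val"))
    test_recs = subset(("test",))
    X_train = build_feature_table(train_recs, roi_margin, settings)
    X_test = build_feature_table(test_recs, roi_margin, settings)
    y_train = _labels_for(task, train_recs)
    y_test = _labels_for(task, test_recs)

    sel = boruta_select(X_train, y_train, max_iter=boruta_max_iter,
                        alpha=boruta_alpha, seed=seed)
    keep = sel.confirmed
    if not keep:
        warnings.warn("Boruta confirmed no feature; falling back to all features",
                      stacklevel=2)
        keep = list(X_train.columns)
    rf_settings = rf_settings or RFSettings(seed=seed)
    rf = rf_classify(X_train[keep], y_train, rf_settings)
    scores = rf.predict_proba(X_test[keep].to_numpy(dtype=float))[:, 1]
    return {
        "task": task,
        "metrics": evaluate_scores(scores, y_test),
        "selection": sel,
        "scores": scores,
        "labels": y_test,
        "n_features_selected": len(keep),
    }
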