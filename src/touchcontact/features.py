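"""Trial summarization, feature extraction, selection and classification.

Implements the analysis used to discern gestures, messages and touchers
from contact attributes: per-trial attribute means (signed velocities
enter as absolute values), a time/frequency feature set per channel,
relevance selection by rank tests with Benjamini-Hochberg control,
random-forest classification on a stratified 75/25 split at three feature
granularities (mean / relevant / timeseries), permutation importance, and
pairwise Mann-Whitney U comparisons across gestures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import train_test_split
from statsmodels.tsa.stattools import acf, pacf

from .kinematics import ContactAttributeSeries

__all__ = [
    "MESSAGES",
    "TrialRecord",
    "FeatureTable",
    "ClassificationResult",
    "summarize_trial",
    "extract_feature_set",
    "build_feature_table",
    "select_relevant_features",
    "benjamini_hochberg",
    "classify_trials",
    "permutation_importance",
    "compare_gestures",
    "chance_level",
]

#: The seven cued emotional messages of the communication task.
MESSAGES = ("anger", "attention", "calm", "fear", "gratitude", "happiness", "sympathy")

#: The seven contact attributes summarized per trial.
ATTRIBUTES = ("Vabs", "Vlg", "Vlt", "Vvt", "area", "depth", "duration")

_VELOCITY_CHANNELS = ("Vabs", "Vlg", "Vlt", "Vvt")
_CHANNELS = ("Vabs", "Vlg", "Vlt", "Vvt", "area", "depth")


@dataclass
class TrialRecord:
    """One trial's attribute series plus its task labels."""

    series: ContactAttributeSeries
    gesture: str | None = None
    message: str | None = None
    toucher_id: str | None = None

    def label(self, task: str):
        return {"gesture": self.gesture, "message": self.message,
                "toucher": self.toucher_id}[task]


@dataclass
class FeatureTable:
    """Trials-by-features design matrix with deterministic column naming."""

    matrix: pd.DataFrame
    granularity: str = "mean"

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.matrix.isna().any().any():
            raise ValueError("feature table must contain no missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class ClassificationResult:
    """Test accuracy (percent), row-normalized confusion (percent) and splits."""

    accuracy: float
    confusion: pd.DataFrame
    classes: list
    n_train: int
    n_test: int
    importances: pd.DataFrame | None = None


def chance_level(n_classes: int) -> float:
    """Uniform-guessing accuracy for a balanced task, percent."""
    return 100.0 / n_classes


def summarize_trial(series: ContactAttributeSeries, *, contact_only: bool = True) -> dict:
    """Seven attribute scalars: contact-frame means and the duration.

    Velocity channels are averaged as absolute values (they are signed);
    velocity means skip frames whose backward difference is undefined.
    With zero contact frames an all-zero summary is returned with a
    warning.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    mask = series.contact_flags if contact_only else np.ones(len(series), bool)
    out = {}
    if not mask.any():
        warnings.warn("trial has no contact frames; summary is all zeros",
                      RuntimeWarning, stacklevel=2)
        return {a: 0.0 for a in ATTRIBUTES}
    vmask = mask & series.velocity_valid
    for name, channel in (("Vabs", series.v_abs), ("Vlg", series.v_lg),
                          ("Vlt", series.v_lt), ("Vvt", series.v_vt)):
        vals = np.abs(channel[vmask]) if vmask.any() else np.array([0.0])
        out[name] = float(vals.mean())
    out["area"] = float(series.area[mask].mean())
    out["depth"] = float(series.depth[mask].mean())
    out["duration"] = float(series.duration)
    return out


def _shannon_entropy(x: np.ndarray, bins: int = 10) -> float:
    hist, _ = np.histogram(x, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _channel_features(x: np.ndarray) -> dict:
    """Time- and frequency-domain descriptors of one channel."""
    n = len(x)
    with warnings.catch_warnings():
        # near-constant channels trip scipy's skew precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        skewness = float(stats.skew(x)) if x.std() > 0 else 0.0
    feats = {
        "mean": x.mean(),
        "absmean": np.abs(x).mean(),
        "max": x.max(),
        "min": x.min(),
        "q25": np.quantile(x, 0.25),
        "median": np.quantile(x, 0.50),
        "q75": np.quantile(x, 0.75),
        "std": x.std(),
        "skewness": skewness,
        "entropy": _shannon_entropy(x),
        "energy": float(np.sum(x**2)),
        "trend": float(np.polyfit(np.arange(n), x, 1)[0]) if n > 1 else 0.0,
    }
    # autocorrelations (lags 1-5) and partial autocorrelations (lags 1-3)
    if x.std() > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ac = acf(x, nlags=5, fft=True)
            try:
                pc = pacf(x, nlags=3, method="ywm")
            except Exception:
                pc = np.zeros(4)
    else:
        ac = np.zeros(6)
        pc = np.zeros(4)
    for lag in range(1, 6):
        feats[f"acf{lag}"] = float(ac[lag]) if lag < len(ac) else 0.0
    for lag in range(1, 4):
        feats[f"pacf{lag}"] = float(pc[lag]) if lag < len(pc) else 0.0
    # Fourier: leading amplitude coefficients and spectrum shape
    amp = np.abs(np.fft.rfft(x - x.mean()))
    for k in range(1, 6):
        feats[f"fourier{k}"] = float(amp[k]) if k < len(amp) else 0.0
    spec = amp[1:]
    if spec.sum() > 0:
        freqs = np.arange(1, len(amp))
        w = spec / spec.sum()
        mu = float((freqs * w).sum())
        var = float(((freqs - mu) ** 2 * w).sum())
        sk = float(((freqs - mu) ** 3 * w).sum() / var**1.5) if var > 0 else 0.0
    else:
        mu = var = sk = 0.0
    feats["spec_mean"] = mu
    feats["spec_var"] = var
    feats["spec_skew"] = sk
    # wavelet decomposition energies (Haar, 3 levels)
    coeffs = pywt.wavedec(x, "haar", level=min(3, pywt.dwt_max_level(n, "haar")))
    for lvl in range(1, 4):
        feats[f"wavelet_e{lvl}"] = (
            float(np.sum(coeffs[lvl] ** 2)) if lvl < len(coeffs) else 0.0
        )
    return feats


def extract_feature_set(series: ContactAttributeSeries) -> pd.Series:
    """Deterministically named ``channel__feature`` vector for one trial.

    Requires at least 8 frames. Non-finite results (e.g. undefined
    autocorrelation of a constant channel) are reported as 0 so the table
    has no missing values.
    """
    if len(series) < 8:
        raise ValueError(f"feature extraction requires >= 8 frames, got {len(series)}")
    channels = {
        "Vabs": series.v_abs, "Vlg": series.v_lg, "Vlt": series.v_lt,
        "Vvt": series.v_vt, "area": series.area, "depth": series.depth,
    }
    out = {}
    for ch, x in channels.items():
        for name, val in _channel_features(np.asarray(x, float)).items():
            out[f"{ch}__{name}"] = val
    out["duration"] = series.duration
    vec = pd.Series(out)
    return vec.where(np.isfinite(vec), 0.0)


def _resample_channel(x: np.ndarray, length: int) -> np.ndarray:
    if len(x) == length:
        return np.asarray(x, float)
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, x)


def build_feature_table(
    trials: list[TrialRecord], granularity: str = "mean", length: int = 100
) -> FeatureTable:
    """Assemble the design matrix at one of the three granularities.

    mean : the seven per-trial attribute summaries.
    relevant : the full time/frequency feature set (selection is applied
        separately against the labels of a chosen task).
    timeseries : every channel linearly resampled to ``length`` points
        and concatenated, plus the duration scalar.
    """
    rows = []
    if granularity == "mean":
        for tr in trials:
            rows.append(pd.Series(summarize_trial(tr.series)))
    elif granularity == "relevant":
        for tr in trials:
            rows.append(extract_feature_set(tr.series))
    elif granularity == "timeseries":
        for tr in trials:
            s = tr.series
            parts = {}
            for ch, x in (("Vabs", s.v_abs), ("Vlg", s.v_lg), ("Vlt", s.v_lt),
                          ("Vvt", s.v_vt), ("area", s.area), ("depth", s.depth)):
                r = _resample_channel(x, length)
                parts.update({f"{ch}__{i:03d}": r[i] for i in range(length)})
            parts["duration"] = s.duration
            rows.append(pd.Series(parts))
    else:
        raise ValueError("granularity must be 'mean', 'relevant' or 'timeseries'")
    matrix = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureTable(matrix=matrix, granularity=granularity)


def benjamini_hochberg(pvalues, q: float = 0.05) -> np.ndarray:
    """Step-up FDR control: keep the largest k with p_(k) <= k q / m."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    keep = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        keep[order[: k + 1]] = True
    return keep


def feature_pvalues(table: FeatureTable, labels) -> pd.Series:
    """Kruskal-Wallis association p-value of each feature with the labels.

    Constant features get p = 1 (no evidence of association).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("relevance selection needs >= 2 classes")
    pvals = {}
    for col in table.matrix.columns:
        x = table.matrix[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            pvals[col] = 1.0
            continue
        groups = [x[labels == c] for c in classes]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                pvals[col] = float(stats.kruskal(*groups).pvalue)
            except ValueError:  # all-identical within the test's tolerance
                pvals[col] = 1.0
    return pd.Series(pvals)


def select_relevant_features(
    table: FeatureTable, labels, q: float = 0.05
) -> FeatureTable:
    """Benjamini-Hochberg selection of label-associated features at level q."""
    pvals = feature_pvalues(table, labels)
    keep = benjamini_hochberg(pvals.to_numpy(), q=q)
    kept = table.matrix.loc[:, pvals.index[keep]]
    return FeatureTable(matrix=kept, granularity=table.granularity)


def _make_forest(seed, n_estimators=500):
    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )


def classify_trials(
    table: FeatureTable,
    labels,
    train_fraction: float = 0.75,
    seed: int = 0,
    n_estimators: int = 500,
) -> ClassificationResult:
    """Random-forest classification on a stratified random split.

    Returns the test accuracy (percent) and the row-normalized confusion
    matrix (rows sum to 100%).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    singles = classes[counts < 2]
    if len(singles):
        raise ValueError(f"class {singles[0]!r} has fewer than 2 trials")
    X = table.matrix.to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, train_size=train_fraction, stratify=labels, random_state=seed
    )
    clf = _make_forest(seed, n_estimators)
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    acc = 100.0 * accuracy_score(y_te, pred)
    cm = confusion_matrix(y_te, pred, labels=classes).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, row_sums, out=np.zeros_like(cm), where=row_sums > 0) * 100.0
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    return ClassificationResult(
        accuracy=float(acc),
        confusion=confusion,
        classes=list(classes),
        n_train=len(y_tr),
        n_test=len(y_te),
    )


def _attribute_groups(columns) -> dict[str, list]:
    """Group feature columns by the contact attribute they derive from."""
    groups: dict[str, list] = {}
    for col in columns:
        attr = col.split("__")[0]
        groups.setdefault(attr, []).append(col)
    return groups


def permutation_importance(
    table: FeatureTable,
    labels,
    repetitions: int = 100,
    permutations: int = 10,
    seed: int = 0,
    train_fraction: float = 0.75,
    n_estimators: int = 100,
) -> pd.DataFrame:
    """Attribute importance as mean test-accuracy drop under permutation.

    Each repetition refits the forest on a fresh stratified split, then
    permutes each attribute's columns in the test set ``permutations``
    times; the attribute's importance for that repetition is the mean
    accuracy drop (fraction). Rows are repetitions, columns attributes;
    plot-ready, with the final importance being the column mean.
    """
    labels = np.asarray(labels)
    groups = _attribute_groups(table.matrix.columns)
    rng = np.random.default_rng(seed)
    records = []
    X = table.matrix
    for rep in range(repetitions):
        split_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, labels, train_size=train_fraction, stratify=labels,
            random_state=split_seed,
        )
        clf = _make_forest(split_seed, n_estimators)
        clf.fit(X_tr.to_numpy(float), y_tr)
        base = accuracy_score(y_te, clf.predict(X_te.to_numpy(float)))
        row = {}
        for attr, cols in groups.items():
            drops = []
            for _ in range(permutations):
                shuffled = X_te.copy()
                perm = rng.permutation(len(X_te))
                shuffled[cols] = X_te[cols].to_numpy()[perm]
                drops.append(
                    base - accuracy_score(y_te, clf.predict(shuffled.to_numpy(float)))
                )
            row[attr] = float(np.mean(drops))
        records.append(row)
    return pd.DataFrame.from_records(records)


_STARS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for thresh, mark in _STARS:
        if p < thresh:
            return mark
    return "ns"


def compare_gestures(summaries: pd.DataFrame, attribute: str,
                     group_col: str = "gesture") -> pd.DataFrame:
    """Pairwise two-sample Mann-Whitney U tests on per-trial attribute means.

    U is exact for group sizes <= 20 without ties, otherwise the normal
    approximation with tie correction. The returned table annotates each
    pair with significance stars at 0.05 / 0.01 / 0.001 / 0.0001.
    """
    groups = {g: df[attribute].to_numpy(float)
              for g, df in summaries.groupby(group_col)}
    for g, x in groups.items():
        if len(x) == 0:
            raise ValueError(f"empty group {g!r}")
        if len(x) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 trials")
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = groups[a], groups[b]
            exact = (len(x) <= 20 and len(y) <= 20
                     and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided",
                method="exact" if exact else "asymptotic",
            )
            rows.append({"group_a": a, "group_b": b, "U": float(res.statistic),
                         "p": float(res.pvalue), "stars": _stars(float(res.pvalue))})
    return pd.DataFrame(rows)
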