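"""Validation suite: spike-train matching, PSTH and tuning comparison,
time-resolved population decoding, neuron-dropping curves and their
asymptote fits, and the paired statistics.

Match score between two spike trains is ``1 - FP - FM`` (false-positive
rate relative to the test train, false-miss rate relative to the
reference); a score of at least 0.8 defines a matched unit. Direction
tuning is fit with a von Mises curve ``r(theta) = b + a * exp(kappa *
(cos(theta - mu) - 1))``; fits with r^2 <= 0.6 are flagged not-well-fit.
Decoding uses multinomial logistic regression (lbfgs, C = 1.0, max 1000
iterations) with stratified cross-validation, per-fold class balancing
and train-fit standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "MatchResult",
    "VonMisesFit",
    "TuningCurve",
    "DroppingCurve",
    "AsymptoteFit",
    "match_units",
    "match_trains",
    "psth_compare",
    "bin_counts",
    "fit_tuning",
    "decode_timecourse",
    "dropping_curve",
    "fit_asymptote",
    "asymptote_model",
    "compare_methods",
]

MATCH_SCORE_CUTOFF = 0.8
WELL_FIT_R2 = 0.6
CHANCE_12WAY = 1.0 / 12.0


# ---------------------------------------------------------------------------
# unit matching


def match_trains(train_a: np.ndarray, train_b: np.ndarray, tol_samples: int):
    """Greedy one-to-one nearest matching of two sorted spike trains.

    Returns ``(FP, FM, score)`` where FP is the fraction of the test train
    ``a`` left unmatched and FM the fraction of the reference ``b`` left
    unmatched; score = 1 - FP - FM. Empty trains force FP or FM to 1.
    """
    a = np.asarray(train_a, np.int64)
    b = np.asarray(train_b, np.int64)
    if len(a) == 0 and len(b) == 0:
        return 0.0, 0.0, 1.0  # vacuously identical
    if len(a) == 0:
        return 0.0, 1.0, 0.0  # every reference spike missed
    if len(b) == 0:
        return 1.0, 0.0, 0.0  # every test spike is a false positive
    # candidate pairs sorted by |dt|: greedy nearest-first one-to-one
    pairs = []
    for i, t in enumerate(a):
        lo = np.searchsorted(b, t - tol_samples, side="left")
        hi = np.searchsorted(b, t + tol_samples, side="right")
        for jj in range(lo, hi):
            pairs.append((abs(int(b[jj]) - int(t)), i, jj))
    pairs.sort()
    used_a = np.zeros(len(a), bool)
    used_b = np.zeros(len(b), bool)
    n_matched = 0
    for _, i, j in pairs:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            n_matched += 1
    fp = 1.0 - n_matched / len(a)
    fm = 1.0 - n_matched / len(b)
    return fp, fm, 1.0 - fp - fm


@dataclass
class MatchResult:
    """Pairwise match scores between two unit sets."""

    pairs: pd.DataFrame  # unit_a, unit_b, FP, FM, score (one row per paired unit)
    matched: pd.DataFrame = field(init=False)  # rows with score >= 0.8

    def __post_init__(self):
        self.matched = self.pairs[self.pairs["score"] >= MATCH_SCORE_CUTOFF].reset_index(
            drop=True
        )


def match_units(
    trains_a: dict, trains_b: dict, tol_samples: int = 15
) -> MatchResult:
    """Pair units across two sorted outputs by maximal match score.

    Scores every (a, b) pair, then pairs greedily by descending score,
    one-to-one. ``trains_*`` map unit id -> sorted spike-time array.
    """
    if tol_samples < 0:
        raise ValueError("tol_samples must be >= 0")
    rows = []
    for ua, ta in trains_a.items():
        for ub, tb in trains_b.items():
            fp, fm, score = match_trains(ta, tb, tol_samples)
            rows.append((ua, ub, fp, fm, score))
    all_pairs = pd.DataFrame(rows, columns=["unit_a", "unit_b", "FP", "FM", "score"])
    all_pairs = all_pairs.sort_values("score", ascending=False, kind="stable")
    used_a: set = set()
    used_b: set = set()
    chosen = []
    for _, r in all_pairs.iterrows():
        if r["unit_a"] in used_a or r["unit_b"] in used_b:
            continue
        used_a.add(r["unit_a"])
        used_b.add(r["unit_b"])
        chosen.append(r)
    pairs = pd.DataFrame(chosen).reset_index(drop=True)
    return MatchResult(pairs=pairs)


# ---------------------------------------------------------------------------
# PSTH

def _sliding_rate(
    train: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    window_ms: tuple,
    bin_ms: float,
    step_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged sliding-window firing rate (Hz) and bin centers (ms)."""
    t0, t1 = window_ms
    centers = np.arange(t0 + bin_ms / 2, t1 - bin_ms / 2 + 1e-9, step_ms)
    rates = np.zeros(len(centers))
    half = bin_ms / 2
    for onset in onsets:
        rel_ms = (train - onset) / fs * 1e3
        rel_ms = rel_ms[(rel_ms >= t0) & (rel_ms < t1)]
        for i, c in enumerate(centers):
            rates[i] += np.count_nonzero((rel_ms >= c - half) & (rel_ms < c + half))
    rates /= len(onsets) * (bin_ms / 1e3)
    return rates, centers


def psth_compare(
    train_a: np.ndarray,
    train_b: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    window_ms: tuple = (-500.0, 1500.0),
    bin_ms: float = 100.0,
    step_ms: float = 10.0,
):
    """Sliding-window PSTHs (bin 100 ms, step 10 ms) and their Pearson r.

    A zero-variance PSTH makes the correlation undefined; it is reported
    as NaN so summaries can exclude it.
    """
    onsets = np.asarray(onsets)
    if len(onsets) < 1:
        raise ValueError("need at least one stimulus onset")
    psth_a, centers = _sliding_rate(train_a, onsets, fs, window_ms, bin_ms, step_ms)
    psth_b, _ = _sliding_rate(train_b, onsets, fs, window_ms, bin_ms, step_ms)
    if len(centers) < 2:
        raise ValueError("need at least two time bins")
    if psth_a.std() == 0 or psth_b.std() == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(psth_a, psth_b)[0])
    return psth_a, psth_b, r


def bin_counts(
    trains: dict,
    onsets: np.ndarray,
    fs: float,
    window_ms: tuple = (-500.0, 1500.0),
    bin_ms: float = 100.0,
    step_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window spike counts: (n_trials, n_units, n_bins) plus bin
    centers in ms relative to onset."""
    t0, t1 = window_ms
    centers = np.arange(t0 + bin_ms / 2, t1 - bin_ms / 2 + 1e-9, step_ms)
    half = bin_ms / 2
    unit_ids = sorted(trains)
    counts = np.zeros((len(onsets), len(unit_ids), len(centers)))
    for u_i, u in enumerate(unit_ids):
        t = np.asarray(trains[u])
        for tr_i, onset in enumerate(np.asarray(onsets)):
            rel = (t - onset) / fs * 1e3
            rel = rel[(rel >= t0) & (rel < t1)]
            if len(rel) == 0:
                continue
            lo = np.searchsorted(rel, centers - half, side="left")
            hi = np.searchsorted(rel, centers + half, side="left")
            counts[tr_i, u_i] = hi - lo
    return counts, centers


# ---------------------------------------------------------------------------
# tuning

@dataclass
class TuningCurve:
    directions_deg: np.ndarray
    mean_rate_hz: np.ndarray
    sem_hz: np.ndarray


@dataclass
class VonMisesFit:
    """b + a*exp(kappa*(cos(theta-mu)-1)) fit to a 12-point tuning curve."""

    baseline: float
    amplitude: float
    preferred_deg: float
    kappa: float
    r_squared: float
    well_fit: bool


def _von_mises(theta_deg, b, a, mu_deg, kappa):
    return b + a * np.exp(kappa * (np.cos(np.deg2rad(theta_deg - mu_deg)) - 1.0))


def fit_tuning(
    train: np.ndarray,
    trials: pd.DataFrame,
    fs: float,
    response_window_ms: tuple = (50.0, 250.0),
) -> tuple[TuningCurve, VonMisesFit]:
    """Direction tuning curve and its von Mises fit.

    Rates are counted in ``response_window_ms`` after each stimulus onset;
    all 12 directions must be present. mu is initialized at the argmax
    direction; fits with r^2 <= 0.6 (or failures/degenerate curves) carry
    ``well_fit=False``.
    """
    dirs = np.sort(trials["direction_deg"].unique())
    if len(dirs) != 12:
        raise ValueError("all 12 directions must be present")
    t0, t1 = response_window_ms
    win_s = (t1 - t0) / 1e3
    train = np.asarray(train)
    means, sems = [], []
    for d in dirs:
        onsets = trials.loc[trials["direction_deg"] == d, "onset_sample"].to_numpy()
        rates = np.array(
            [
                np.count_nonzero(
                    (train >= o + t0 * fs / 1e3) & (train < o + t1 * fs / 1e3)
                )
                / win_s
                for o in onsets
            ]
        )
        means.append(rates.mean())
        sems.append(rates.std(ddof=1) / np.sqrt(len(rates)) if len(rates) > 1 else 0.0)
    means = np.asarray(means)
    sems = np.asarray(sems)
    curve = TuningCurve(directions_deg=dirs, mean_rate_hz=means, sem_hz=sems)

    bad = VonMisesFit(np.nan, np.nan, np.nan, np.nan, 0.0, False)
    ss_tot = float(np.sum((means - means.mean()) ** 2))
    if ss_tot == 0:
        return curve, bad
    mu0 = float(dirs[np.argmax(means)])
    p0 = [max(means.min(), 0.0), max(means.max() - means.min(), 1e-6), mu0, 2.0]
    try:
        popt, _ = optimize.curve_fit(
            _von_mises,
            dirs,
            means,
            p0=p0,
            bounds=([0.0, 0.0, -360.0, 0.0], [np.inf, np.inf, 720.0, 50.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return curve, bad
    b, a, mu, kappa = popt
    pred = _von_mises(dirs, *popt)
    r2 = 1.0 - float(np.sum((means - pred) ** 2)) / ss_tot
    if a <= 1e-9:  # mu unidentifiable
        return curve, VonMisesFit(b, a, np.nan, kappa, r2, False)
    mu = float(mu % 360.0)
    return curve, VonMisesFit(
        baseline=float(b),
        amplitude=float(a),
        preferred_deg=mu,
        kappa=float(kappa),
        r_squared=r2,
        well_fit=bool(r2 > WELL_FIT_R2),
    )


# ---------------------------------------------------------------------------
# decoding

def _balanced_fit_predict(X_tr, y_tr, X_va, rng) -> np.ndarray:
    """Class-balanced downsampling of the training fold, train-fit
    standardization, multinomial logistic regression; returns predictions."""
    classes, counts = np.unique(y_tr, return_counts=True)
    n_min = counts.min()
    keep = np.concatenate(
        [rng.choice(np.flatnonzero(y_tr == c), size=n_min, replace=False) for c in classes]
    )
    X_tr, y_tr = X_tr[keep], y_tr[keep]
    scaler = StandardScaler().fit(X_tr)
    clf = LogisticRegression(solver="lbfgs", max_iter=1000, C=1.0)
    clf.fit(scaler.transform(X_tr), y_tr)
    return clf.predict(scaler.transform(X_va))


def _cv_accuracy(X, y, n_folds, seed) -> tuple[float, float]:
    """Stratified k-fold CV accuracy: (fold mean, across-fold SEM)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    accs = []
    for tr, va in skf.split(X, y):
        pred = _balanced_fit_predict(X[tr], y[tr], X[va], rng)
        accs.append(float(np.mean(pred == y[va])))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1) / np.sqrt(len(accs)))


def decode_timecourse(
    counts: np.ndarray, labels: np.ndarray, seed: int = 42, n_folds: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin 12-way decoding accuracy with 5-fold stratified CV.

    ``counts`` is (n_trials, n_units, n_bins). Within each training fold,
    classes are downsampled to the smallest class and features
    standardized on the training split only. Returns per-bin fold-mean
    accuracy and across-fold SEM.
    """
    counts = np.asarray(counts, float)
    labels = np.asarray(labels)
    classes, class_n = np.unique(labels, return_counts=True)
    if len(classes) != 12:
        raise ValueError("12 direction classes required")
    if class_n.min() < n_folds:
        raise ValueError(
            f"every class needs at least {n_folds} trials "
            f"(smallest has {class_n.min()})"
        )
    n_bins = counts.shape[2]
    acc = np.zeros(n_bins)
    sem = np.zeros(n_bins)
    for b in range(n_bins):
        acc[b], sem[b] = _cv_accuracy(counts[:, :, b], labels, n_folds, seed)
    return acc, sem


@dataclass
class DroppingCurve:
    """Decoding accuracy vs unit count (10, 20, ...)."""

    unit_counts: np.ndarray
    mean_accuracy: np.ndarray
    sem: np.ndarray

    def __post_init__(self):
        self.unit_counts = np.asarray(self.unit_counts, int)
        if np.any(np.diff(self.unit_counts) <= 0):
            raise ValueError("unit counts must be strictly increasing")
        if np.any((self.mean_accuracy < 0) | (self.mean_accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


def dropping_curve(
    counts: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_draws: int = 5,
    n_folds: int = 20,
    step: int = 10,
) -> DroppingCurve:
    """Neuron-dropping curve: units subsampled in increments of ``step``
    from ``step`` up to all units; ``n_draws`` seeded draws per count;
    per-draw z-scoring across trials, 12-way logistic regression with
    ``n_folds``-fold stratified CV and class-balanced training folds."""
    counts = np.asarray(counts, float)
    n_units = counts.shape[1]
    if n_units < step:
        raise ValueError(f"need at least {step} units, got {n_units}")
    ks = list(range(step, n_units + 1, step))
    if ks[-1] != n_units:
        ks.append(n_units)
    rng = np.random.default_rng(seed)
    means, sems = [], []
    for k in ks:
        accs = []
        for _ in range(n_draws):
            sel = rng.choice(n_units, size=k, replace=False)
            X = counts[:, sel]
            mu = X.mean(axis=0, keepdims=True)
            sd = X.std(axis=0, keepdims=True)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
            a, _ = _cv_accuracy(X, labels, n_folds, int(rng.integers(2**31 - 1)))
            accs.append(a)
        accs = np.asarray(accs)
        means.append(accs.mean())
        sems.append(accs.std(ddof=1) / np.sqrt(len(accs)))
    return DroppingCurve(
        unit_counts=np.asarray(ks), mean_accuracy=np.asarray(means), sem=np.asarray(sems)
    )


# ---------------------------------------------------------------------------
# asymptote fits

@dataclass
class AsymptoteFit:
    """Two-term saturating exponential fit of a dropping curve."""

    A: float
    w: float
    tau1: float
    tau2: float
    c: float = CHANCE_12WAY
    converged: bool = True
    fallback_used: bool = False


def asymptote_model(k, A, w, tau1, tau2, c=CHANCE_12WAY):
    """y(k) = c + (A - c) * (1 - w*exp(-k/tau1) - (1-w)*exp(-k/tau2))."""
    k = np.asarray(k, float)
    return c + (A - c) * (1.0 - w * np.exp(-k / tau1) - (1.0 - w) * np.exp(-k / tau2))


def fit_asymptote(curve: DroppingCurve) -> AsymptoteFit:
    """Weighted nonlinear least squares with fixed chance level c = 1/12.

    Initial guesses: observed maximum accuracy, 0.5, 10 and 200 units;
    bounds A in [chance, 1], w in [0, 1], taus in [1e-6, 1e6]; dropping-
    curve SEMs serve as inverse weights. On failure the asymptote falls
    back to the mean of the last 3 curve points.
    """
    k = curve.unit_counts.astype(float)
    y = curve.mean_accuracy
    if len(k) < 5:
        raise ValueError("need at least 5 curve points")
    sem = curve.sem
    sigma = sem if np.all(sem > 0) else None
    p0 = [float(y.max()), 0.5, 10.0, 200.0]
    p0[0] = min(max(p0[0], CHANCE_12WAY), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            lambda kk, A, w, t1, t2: asymptote_model(kk, A, w, t1, t2),
            k,
            y,
            p0=p0,
            sigma=sigma,
            bounds=([CHANCE_12WAY, 0.0, 1e-6, 1e-6], [1.0, 1.0, 1e6, 1e6]),
            maxfev=20000,
        )
        return AsymptoteFit(A=float(popt[0]), w=float(popt[1]), tau1=float(popt[2]),
                            tau2=float(popt[3]))
    except (RuntimeError, ValueError):
        return AsymptoteFit(
            A=float(y[-3:].mean()), w=np.nan, tau1=np.nan, tau2=np.nan,
            converged=False, fallback_used=True,
        )


def compare_methods(asymptotes_a, asymptotes_b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-session values."""
    a = np.asarray(asymptotes_a, float)
    b = np.asarray(asymptotes_b, float)
    if a.shape != b.shape or len(a) < 5:
        raise ValueError("need equal-length paired lists with n >= 5")
    diff = b - a
    if np.all(diff == 0):
        return {"statistic": np.nan, "p_value": 1.0, "mean_difference": 0.0,
                "all_zero": True}
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_difference": float(diff.mean()),
        "all_zero": False,
    }
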