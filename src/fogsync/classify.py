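"""FOG vs non-FOG classification with a mixed-effects random forest (MERF).

From each analyzable trial, 2 two-second FOG epochs and 4 same-length
non-FOG epochs are drawn at random (without overlap, non-FOG with a 1 s
guard band around freeze boundaries). Each epoch yields per-channel band
powers from 512-point FFT Welch averages over six bands (delta 1-3, theta
3-8, alpha 8-13, beta 13-30, gamma 30-60, HFO 60-300 Hz).

Repeated epochs from the same subject are not independent, so the classifier
is a mixed-effects random forest: a random-forest fixed-effects learner on
the 0/1 label plus per-subject random intercepts, fit by EM-style
alternation (fit the forest to the intercept-adjusted target, then update
the intercepts and the variance components from the forest residuals) until
the generalized log-likelihood stabilizes. Scores are thresholded at 0.5;
subjects unseen at prediction time get a zero intercept.

Validation: trial-grouped 70/30 split, subject-grouped k-fold
cross-validation inside the training set, and a label-permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from fogsync.session import ChannelRole, SyncedSession
from fogsync.spectral import CLASSIFIER6, BandScheme, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "extract_epochs",
    "epoch_features",
    "build_feature_table",
    "MerfClassifier",
    "evaluate",
]


@dataclass
class Epoch:
    """One fixed-length labelled epoch of preprocessed neural data."""

    subject_id: str
    trial_id: str
    label: str  # "FOG" | "nFOG"
    start: float  # session clock, seconds
    data: np.ndarray  # channels x samples
    channel_labels: list[str]
    rate_hz: float


def _sample_starts(
    regions: list[tuple[float, float]],
    k: int,
    epoch_s: float,
    taken: list[tuple[float, float]],
    rng: np.random.Generator,
    max_tries: int = 500,
) -> list[float] | None:
    """k non-overlapping epoch starts uniform over the feasible region union."""
    feas = [(a, b - epoch_s) for a, b in regions if b - a >= epoch_s]
    if not feas:
        return None
    lengths = np.array([b - a for a, b in feas])
    chosen: list[float] = []
    for _ in range(max_tries):
        if len(chosen) == k:
            break
        u = rng.uniform(0, lengths.sum())
        idx = min(int(np.searchsorted(np.cumsum(lengths), u, side="right")), len(feas) - 1)
        start = feas[idx][0] + (u - np.concatenate([[0], np.cumsum(lengths)])[idx])
        span = (start, start + epoch_s)
        clash = any(span[0] < e and s < span[1] for s, e in chosen_spans(chosen, epoch_s))
        clash |= any(span[0] < e and s < span[1] for s, e in taken)
        if not clash:
            chosen.append(start)
    return sorted(chosen) if len(chosen) == k else None


def chosen_spans(starts: Sequence[float], epoch_s: float) -> list[tuple[float, float]]:
    return [(s, s + epoch_s) for s in starts]


def extract_epochs(
    sessions: Sequence[SyncedSession],
    epoch_s: float = 2.0,
    n_fog: int = 2,
    n_nfog: int = 4,
    seed: int = 0,
    guard_s: float = 1.0,
    channels: str = "all",
) -> list[Epoch]:
    """Draw labelled epochs from every qualifying session.

    FOG epochs lie fully inside annotated intervals; non-FOG epochs lie fully
    outside them with a ``guard_s`` buffer around every freeze boundary, and
    no two epochs of a trial overlap. Sessions whose eligible regions cannot
    host the requested epochs are skipped with a logged reason. Sampling is
    uniform within the eligible regions and fully determined by ``seed``.

    ``channels`` is ``"all"`` or ``"depth"`` (STN-LFP only). Referential
    recordings are preprocessed (decimate/notch/bipolar) on the fly.
    """
    rng = np.random.default_rng(seed)
    epochs: list[Epoch] = []
    for session in sessions:
        if session.neural is None:
            logger.warning("extract_epochs: %s has no neural stream; skipped", session.trial_id)
            continue
        rec = session.neural
        if rec.montage == "referential":
            rec = preprocess(rec)
        if channels == "depth":
            keep = [
                i
                for i, r in enumerate(rec.roles)
                if r in (ChannelRole.DEPTH_LEFT, ChannelRole.DEPTH_RIGHT)
            ]
            labels = [rec.labels[i] for i in keep]
            data = rec.data[keep]
        elif channels == "all":
            labels, data = list(rec.labels), rec.data
        else:
            raise ValueError(f"channels must be 'all' or 'depth', got {channels!r}")

        t0 = rec.start_time
        t1 = rec.start_time + rec.duration
        ann = session.annotation
        fog_regions = [(max(a, t0), min(b, t1)) for a, b in ann.intervals]
        guard = [(a - guard_s, b + guard_s) for a, b in ann.intervals]
        from fogsync.session import FogAnnotation

        non_regions = FogAnnotation(guard, source="ground_truth").complement(t0, t1)

        fog_starts = _sample_starts(fog_regions, n_fog, epoch_s, [], rng)
        if fog_starts is None:
            logger.warning(
                "extract_epochs: %s skipped (cannot place %d FOG epochs of %.1f s "
                "in %.1f s of freezing)",
                session.trial_id,
                n_fog,
                epoch_s,
                ann.total_duration,
            )
            continue
        non_starts = _sample_starts(
            non_regions, n_nfog, epoch_s, chosen_spans(fog_starts, epoch_s), rng
        )
        if non_starts is None:
            logger.warning(
                "extract_epochs: %s skipped (cannot place %d non-FOG epochs)",
                session.trial_id,
                n_nfog,
            )
            continue
        for label, starts in (("FOG", fog_starts), ("nFOG", non_starts)):
            for s in starts:
                i0 = int(round((s - rec.start_time) * rec.rate_hz))
                i1 = i0 + int(round(epoch_s * rec.rate_hz))
                epochs.append(
                    Epoch(
                        subject_id=session.subject_id,
                        trial_id=session.trial_id,
                        label=label,
                        start=float(s),
                        data=data[:, i0:i1].copy(),
                        channel_labels=labels,
                        rate_hz=rec.rate_hz,
                    )
                )
    return epochs


def epoch_features(
    data: np.ndarray,
    rate_hz: float,
    n_fft: int = 512,
    scheme: BandScheme = CLASSIFIER6,
) -> np.ndarray:
    """Band-power features of one epoch: (n_channels, n_bands).

    Welch average of ``n_fft``-point Hann windows at 50% overlap per channel;
    band power is the sum of PSD bins whose centre lies in the half-open band
    ``[low, high)``. Bands reaching beyond Nyquist are truncated there (the
    60-300 Hz HFO band at a 1000 Hz rate is complete; at 500 Hz it would not
    be, which is logged).
    """
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape[1] < n_fft:
        raise ValueError(f"epoch of {data.shape[1]} samples shorter than n_fft={n_fft}")
    freqs, psd = scipy.signal.welch(
        data, fs=rate_hz, window="hann", nperseg=n_fft, noverlap=n_fft // 2, axis=-1
    )
    nyq = rate_hz / 2.0
    out = np.empty((data.shape[0], len(scheme.bands)))
    for j, (lab, low, high) in enumerate(scheme):
        if high > nyq:
            logger.info("band %s truncated at Nyquist (%g Hz)", lab, nyq)
        mask = (freqs >= low) & (freqs < min(high, nyq + 1e-9))
        out[:, j] = psd[:, mask].sum(axis=-1)
    return out


def build_feature_table(
    epochs: Sequence[Epoch],
    n_fft: int = 512,
    scheme: BandScheme = CLASSIFIER6,
) -> pd.DataFrame:
    """Tidy epoch-by-feature table: subject_id, trial_id, label, then features."""
    rows = []
    for ep in epochs:
        feats = epoch_features(ep.data, ep.rate_hz, n_fft=n_fft, scheme=scheme)
        row: dict = {
            "subject_id": ep.subject_id,
            "trial_id": ep.trial_id,
            "label": ep.label,
        }
        for ci, ch in enumerate(ep.channel_labels):
            for bi, (band, _lo, _hi) in enumerate(scheme):
                row[f"{ch}__{band}"] = feats[ci, bi]
        rows.append(row)
    df = pd.DataFrame(rows)
    feat_cols = [c for c in df.columns if "__" in c]
    if not np.isfinite(df[feat_cols].to_numpy()).all():
        raise ValueError("non-finite feature values")
    return df


class MerfClassifier:
    """Random-forest fixed effects + per-subject random intercepts.

    Fit by EM-style alternation: (i) fit the forest to the target minus the
    current intercepts, (ii) update each subject's intercept by its BLUP
    shrinkage of the mean forest residual and re-estimate the residual and
    random-effect variances, iterating until the generalized log-likelihood
    (GLL) change falls below ``tol`` (relative) or ``max_iter`` is reached.
    With a single subject the model degenerates to a plain forest (warned).
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_iter: int = 10,
        tol: float = 1e-3,
        random_state: int = 0,
        **forest_kwargs,
    ) -> None:
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.forest_kwargs = forest_kwargs
        self.forest_: RandomForestRegressor | None = None
        self.intercepts_: dict = {}
        self.sigma2_b_: float = np.nan
        self.sigma2_e_: float = np.nan
        self.gll_trace_: list[float] = []
        self.converged_: bool = False

    def fit(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> "MerfClassifier":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        single = len(uniq) == 1
        if single:
            logger.warning("MERF with a single subject degenerates to a plain forest")
        idx = {g: np.flatnonzero(groups == g) for g in uniq}

        b = {g: 0.0 for g in uniq}
        sigma2_e, sigma2_b = 1.0, (0.0 if single else 1.0)
        self.gll_trace_ = []
        self.converged_ = False
        for it in range(self.max_iter):
            offset = np.array([b[g] for g in groups])
            forest = RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=self.random_state,
                **self.forest_kwargs,
            )
            forest.fit(X, y - offset)
            f = forest.predict(X)
            eps = y - f  # residual before intercepts

            if not single:
                new_b = {}
                for g in uniq:
                    i = idx[g]
                    n_i = len(i)
                    new_b[g] = sigma2_b * eps[i].sum() / (sigma2_e + n_i * sigma2_b)
                b = new_b
                resid_sq = 0.0
                d_acc = 0.0
                N = len(y)
                for g in uniq:
                    i = idx[g]
                    n_i = len(i)
                    r = eps[i] - b[g]
                    shrink = n_i * sigma2_b / (sigma2_e + n_i * sigma2_b)
                    resid_sq += float(r @ r) + sigma2_e * shrink
                    d_acc += b[g] ** 2 + sigma2_b * sigma2_e / (sigma2_e + n_i * sigma2_b)
                sigma2_e = resid_sq / N
                sigma2_b = d_acc / len(uniq)
            else:
                sigma2_e = float(np.mean(eps**2))

            gll = 0.0
            for g in uniq:
                i = idx[g]
                r = eps[i] - b[g]
                gll += float(r @ r) / max(sigma2_e, 1e-12)
                gll += len(i) * np.log(max(sigma2_e, 1e-12))
                if not single and sigma2_b > 1e-12:
                    gll += b[g] ** 2 / sigma2_b + np.log(sigma2_b)
            self.gll_trace_.append(gll)
            self.forest_ = forest
            self.intercepts_ = dict(b)
            self.sigma2_e_ = float(sigma2_e)
            self.sigma2_b_ = float(sigma2_b)
            if it > 0 and abs(self.gll_trace_[-2] - gll) < self.tol * abs(
                self.gll_trace_[-2]
            ):
                self.converged_ = True
                break
        if not self.converged_:
            logger.info("MERF reached max_iter=%d without GLL convergence", self.max_iter)
        return self

    def predict_score(self, X: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
        if self.forest_ is None:
            raise RuntimeError("fit the model first")
        score = self.forest_.predict(np.asarray(X, float))
        if groups is not None:
            score = score + np.array([self.intercepts_.get(g, 0.0) for g in groups])
        return score

    def predict(self, X: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
        return (self.predict_score(X, groups) >= 0.5).astype(int)


def _trial_split(
    df: pd.DataFrame, split: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/test masks keeping every trial's epochs on one side."""
    trials = df["trial_id"].unique()
    trials = rng.permutation(trials)
    n_train = max(1, int(round(split * len(trials))))
    if n_train == len(trials):
        n_train -= 1
    train_trials = set(trials[:n_train])
    train_mask = df["trial_id"].isin(train_trials).to_numpy()
    return train_mask, ~train_mask


def evaluate(
    table: pd.DataFrame,
    split: float = 0.7,
    cv_folds: int = 10,
    n_permutations: int = 1000,
    seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 5,
) -> dict:
    """Split / cross-validate / permutation-test the MERF FOG classifier.

    The 70/30 split is grouped by trial (all of a trial's epochs stay on one
    side; every trial carries both labels so the split is label-balanced by
    construction). Cross-validation folds group by subject within the
    training set, reduced with a warning when there are fewer subjects than
    folds. The permutation p-value is ``(1 + #{permuted acc >= observed}) /
    (1 + n_permutations)``; with ``n_permutations=0`` it is reported as None.
    """
    rng = np.random.default_rng(seed)
    feat_cols = [c for c in table.columns if "__" in c]
    X = table[feat_cols].to_numpy(float)
    X = np.log10(np.maximum(X, 1e-30))  # band powers span decades
    y = (table["label"] == "FOG").to_numpy(int)
    groups = table["subject_id"].to_numpy()

    train, test = _trial_split(table, split, rng)

    def fit_score(y_vec: np.ndarray) -> float:
        model = MerfClassifier(
            n_estimators=n_estimators,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.fit(X[train], y_vec[train], groups[train])
        pred = model.predict(X[test], groups[test])
        return float(np.mean(pred == y_vec[test]))

    model = MerfClassifier(
        n_estimators=n_estimators, max_iter=max_iter, random_state=seed % (2**31)
    )
    model.fit(X[train], y[train], groups[train])
    score = model.predict_score(X[test], groups[test])
    pred = (score >= 0.5).astype(int)
    accuracy = float(np.mean(pred == y[test]))
    auc = float(roc_auc_score(y[test], score)) if len(np.unique(y[test])) == 2 else np.nan

    # subject-grouped CV inside the training set
    tr_groups = groups[train]
    n_groups = len(np.unique(tr_groups))
    folds = min(cv_folds, n_groups)
    if folds < cv_folds:
        logger.warning("reducing CV folds from %d to %d (subjects available)", cv_folds, folds)
    cv_acc = []
    if folds >= 2:
        gkf = GroupKFold(n_splits=folds)
        Xt, yt = X[train], y[train]
        for tr_i, te_i in gkf.split(Xt, yt, tr_groups):
            m = MerfClassifier(
                n_estimators=n_estimators, max_iter=max_iter, random_state=seed % (2**31)
            )
            m.fit(Xt[tr_i], yt[tr_i], tr_groups[tr_i])
            cv_acc.append(float(np.mean(m.predict(Xt[te_i], tr_groups[te_i]) == yt[te_i])))

    perm_p = None
    perm_acc = []
    if n_permutations > 0:
        for _ in range(n_permutations):
            perm_acc.append(fit_score(rng.permutation(y)))
        perm_acc_arr = np.asarray(perm_acc)
        perm_p = float((1 + np.sum(perm_acc_arr >= accuracy)) / (1 + n_permutations))

    return {
        "accuracy": accuracy,
        "auc": auc,
        "cv_accuracy_mean": float(np.mean(cv_acc)) if cv_acc else np.nan,
        "cv_accuracies": cv_acc,
        "permutation_p": perm_p,
        "n_train_epochs": int(train.sum()),
        "n_test_epochs": int(test.sum()),
        "model": model,
    }
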