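"""Single-trial hit/miss decoding from fiber fluorescence.

Per-trial feature vectors are mean ΔF/F₀ in consecutive 10 ms bins taken
either from the 1 s preceding tone onset or the 400 ms following it (100 or
40 bins per fiber, concatenated across the selected fibers).  Decoding uses
PCA retaining the components that explain 90% of the variance followed by a
linear SVM under leave-one-out cross-validation.  Because hit trials
typically outnumber misses, each of 50 iterations randomly downsamples the
majority class to balance the design (chance = 0.5 exactly); the session
accuracy is the mean over iterations.  A label-randomization control
permutes outcome labels once per iteration before balancing.

PCA is fit inside each training fold by default (no test-row leakage); a
whole-matrix mode is available for comparison with analyses that reduce
dimensionality once per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .behavior import TrialRecord
from .traces import DffTrace

__all__ = ["DecodingConfig", "DecodingResult", "build_feature_matrix", "decode_session"]

WINDOWS_S = {"pre_1s": (-1.0, 0.0), "post_400ms": (0.0, 0.4)}


@dataclass
class DecodingConfig:
    window: str = "pre_1s"  # pre_1s | post_400ms
    bin_ms: float = 10.0
    var_explained: float = 0.90
    n_iterations: int = 50
    fibers: tuple[str, ...] = ("HDB", "GP/SI")
    randomize_labels: bool = False
    seed: int = 0
    pca_per_fold: bool = True
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.var_explained <= 1:
            raise ValueError("var_explained must lie in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.window not in WINDOWS_S:
            raise ValueError(f"window must be one of {sorted(WINDOWS_S)}")


@dataclass
class DecodingResult:
    accuracy: float
    accuracy_per_iteration: np.ndarray
    n_trials_used: int
    n_skipped_iterations: int
    config: DecodingConfig


def build_feature_matrix(
    traces: dict[str, DffTrace],
    trials: list[TrialRecord],
    cfg: DecodingConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial binned-fluorescence features and hit/miss labels.

    Only hit and miss trials enter the matrix.  Each row concatenates, for
    every selected fiber, the mean ΔF/F₀ in consecutive ``bin_ms`` bins over
    the configured peri-cue window.  Labels are 1 for hit, 0 for miss.

    Raises
    ------
    ValueError
        If a class has fewer than 2 trials (session should be skipped) or a
        trial window falls outside a trace.
    """
    w0, w1 = WINDOWS_S[cfg.window]
    n_bins = int(round((w1 - w0) * 1000.0 / cfg.bin_ms))
    used = [t for t in trials if t.outcome in ("hit", "miss")]
    labels = np.array([1 if t.outcome == "hit" else 0 for t in used])
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 hit and 2 miss trials")

    rows = []
    for t in used:
        feats = []
        for fiber in cfg.fibers:
            tr = traces[fiber]
            start = t.onset_s + w0
            edges_s = start + np.arange(n_bins + 1) * (cfg.bin_ms / 1000.0)
            idx = np.round((edges_s - tr.t0) * tr.fs).astype(int)
            if idx[0] < 0 or idx[-1] > len(tr):
                raise ValueError("trial window outside trace support")
            sums = np.add.reduceat(tr.dff[idx[0] : idx[-1]], idx[:-1] - idx[0])
            counts = np.diff(idx)
            feats.append(sums / counts)
        rows.append(np.concatenate(feats))
    return np.asarray(rows), labels


def _loo_accuracy(X: np.ndarray, y: np.ndarray, cfg: DecodingConfig) -> float | None:
    n = len(y)
    correct = 0
    if not cfg.pca_per_fold:
        pca_all = PCA(n_components=cfg.var_explained, svd_solver="full")
        Xr_all = pca_all.fit_transform(X)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if cfg.pca_per_fold:
            Xtr = X[tr]
            if np.allclose(Xtr, Xtr[0]):
                return None  # singular fold: all-identical training rows
            pca = PCA(n_components=cfg.var_explained, svd_solver="full")
            Ztr = pca.fit_transform(Xtr)
            Zte = pca.transform(X[i : i + 1])
        else:
            Ztr, Zte = Xr_all[tr], Xr_all[i : i + 1]
        clf = SVC(kernel="linear", C=cfg.svm_c)
        clf.fit(Ztr, y[tr])
        correct += int(clf.predict(Zte)[0] == y[i])
    return correct / n


def decode_session(
    X: np.ndarray, labels: np.ndarray, cfg: DecodingConfig
) -> DecodingResult:
    """Balanced leave-one-out decoding accuracy for one session.

    Each iteration: (optionally permute labels,) downsample the majority
    class to the minority count, then run leave-one-out with PCA + linear
    SVM fit per training fold.  Iterations with singular training folds are
    skipped and counted.  Identical seeds reproduce identical downsampling,
    permutations and accuracies.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("matrix rows must match labels length")
    rng = np.random.default_rng(cfg.seed)
    accs = []
    skipped = 0
    n_used = 0
    for _ in range(cfg.n_iterations):
        y = labels.copy()
        if cfg.randomize_labels:
            y = rng.permutation(y)
        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        k = min(idx0.size, idx1.size)
        maj = idx1 if idx1.size > idx0.size else idx0
        mino = idx0 if idx1.size > idx0.size else idx1
        keep = np.sort(np.concatenate([mino, rng.choice(maj, size=k, replace=False)]))
        n_used = 2 * k
        acc = _loo_accuracy(X[keep], y[keep], cfg)
        if acc is None:
            skipped += 1
        else:
            accs.append(acc)
    accs = np.asarray(accs)
    return DecodingResult(
        accuracy=float(accs.mean()) if accs.size else float("nan"),
        accuracy_per_iteration=accs,
        n_trials_used=n_used,
        n_skipped_iterations=skipped,
        config=cfg,
    )
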