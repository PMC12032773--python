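"""Two-class decoding: CSP + LDA and a compact CNN, with the study's CV schemes.

CSP solves the generalized eigenproblem of the two class covariances and keeps
the eigenvector pair with extreme eigenvalues; features are log-transformed
normalized band-power (variance) of the spatially filtered trials, classified
with LDA.  Evaluation: within-subject repeated 90/10 holdout (10 repeats) and
cross-subject splits (healthy: 10 random 18-train/2-test repeats; patients:
leave-one-subject-out over the 10 subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .config import CNNConfig, CSPConfig, DecodingConfig
from .io_prep import EpochSet


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

def _class_covariance(X: np.ndarray, ridge: float) -> np.ndarray:
    """Average trace-normalized spatial covariance over trials + ridge."""
    n_ch = X.shape[1]
    cov = np.zeros((n_ch, n_ch))
    for trial in X:
        c = trial @ trial.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("zero-variance trial in covariance estimate")
        cov += c / tr
    cov /= X.shape[0]
    return cov + ridge * np.eye(n_ch)


@dataclass
class CSPModel:
    filters: np.ndarray            # (n_filters, channels)
    eigenvalues: np.ndarray        # of C0 w = lambda (C0 + C1) w, full spectrum
    classes: np.ndarray
    lda: LinearDiscriminantAnalysis | None = None
    meta: dict = field(default_factory=dict)


def csp_fit(X: np.ndarray, y: np.ndarray, cfg: CSPConfig | None = None,
            fit_lda: bool = True) -> CSPModel:
    """Fit CSP spatial filters (and LDA on the training features).

    X: (trials, channels, times), already band-filtered and windowed.
    Keeps n_filters/2 eigenvectors from each end of the eigenvalue spectrum.
    """
    cfg = cfg or CSPConfig()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("CSP requires exactly two classes")
    c0 = _class_covariance(X[y == classes[0]], 0.0)
    c1 = _class_covariance(X[y == classes[1]], 0.0)
    comp = c0 + c1 + cfg.ridge * np.trace(c0 + c1) * np.eye(c0.shape[0])
    try:
        evals, evecs = linalg.eigh(c0, comp)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "rank-deficient covariance; increase CSPConfig.ridge"
        ) from exc
    order = np.argsort(evals)
    m = cfg.n_filters // 2
    pick = np.concatenate([order[:m], order[-m:]])
    filters = evecs[:, pick].T
    model = CSPModel(filters=filters, eigenvalues=evals[order], classes=classes)
    if fit_lda:
        feats = csp_features(model, X)
        model.lda = LinearDiscriminantAnalysis().fit(feats, y)
    return model


def csp_features(model: CSPModel, X: np.ndarray) -> np.ndarray:
    """Log of the sum-normalized variance of each spatially filtered trial."""
    proj = np.einsum("fc,nct->nft", model.filters, X)
    var = proj.var(axis=2)
    total = var.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero-variance trial; cannot form CSP features")
    return np.log(var / total)


def csp_predict(model: CSPModel, X: np.ndarray) -> np.ndarray:
    return model.lda.predict(csp_features(model, X))


class CSPLDADecoder:
    """sklearn-style wrapper: fit(X, y) / predict(X) on (trials, ch, time) arrays."""

    def __init__(self, cfg: CSPConfig | None = None):
        self.cfg = cfg or CSPConfig()
        self.model_: CSPModel | None = None

    def fit(self, X, y):
        self.model_ = csp_fit(np.asarray(X), np.asarray(y), self.cfg)
        return self

    def predict(self, X):
        return csp_predict(self.model_, np.asarray(X))


def make_cnn_decoder(cfg: CNNConfig, n_channels: int, n_times: int, seed: int = 0):
    from .cnn import CompactCNNDecoder

    return CompactCNNDecoder(cfg, n_channels=n_channels, n_times=n_times, seed=seed)


# ---------------------------------------------------------------------------
# epoch windowing helpers
# ---------------------------------------------------------------------------

def extract_window(epochs: EpochSet, window_s: tuple[float, float],
                   channels: list[str] | None = None) -> np.ndarray:
    """(trials, channels, times) slice for a decoder's window/channel subset."""
    t = epochs.time_axis
    mask = (t >= window_s[0] - 1e-9) & (t < window_s[1] - 1e-9)
    idx = ([epochs.ch_index(c) for c in channels] if channels
           else np.arange(len(epochs.channel_labels)))
    return epochs.data[:, idx, :][:, :, mask]


# ---------------------------------------------------------------------------
# cross-validation schemes
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    scheme: str                    # within | cross
    population: str                # HS | SP
    task: str
    decoder: str
    fold_accuracies: list[float]   # percent
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _accuracy(y_true, y_pred) -> float:
    return 100.0 * float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def within_subject_cv(X: np.ndarray, y: np.ndarray, decoder_factory,
                      k: int = 10, test_fraction: float = 0.1, seed: int = 0,
                      mode: str = "shuffle", population: str = "", task: str = "",
                      decoder_name: str = "") -> CVResult:
    """k repeated stratified 90/10 holdouts (or strict k-fold with mode='kfold')."""
    from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

    y = np.asarray(y)
    if mode == "kfold":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedShuffleSplit(n_splits=k, test_size=test_fraction,
                                          random_state=seed)
    accs = []
    for tr, te in splitter.split(np.zeros(len(y)), y):
        if np.unique(y[tr]).size < 2:  # resample-safe guard
            continue
        dec = decoder_factory()
        dec.fit(X[tr], y[tr])
        accs.append(_accuracy(y[te], dec.predict(X[te])))
    return CVResult("within", population, task, decoder_name, accs, seed)


def cross_subject_cv(subject_data: dict[str, tuple[np.ndarray, np.ndarray]],
                     decoder_factory, population: str, seed: int = 0,
                     n_repeats: int = 10, n_test_subjects: int = 2,
                     task: str = "", decoder_name: str = "") -> CVResult:
    """Cross-subject evaluation.

    HS: ``n_repeats`` random splits holding out ``n_test_subjects`` subjects.
    SP: leave-one-subject-out over all subjects (one fold per subject).
    Subject identity never leaks between train and test.
    """
    ids = sorted(subject_data.keys())
    rng = np.random.default_rng(seed)
    if population == "SP":
        folds = [[sid] for sid in ids]
    else:
        if len(ids) <= n_test_subjects:
            raise ValueError("population too small for the cross-subject scheme")
        folds = [list(rng.choice(ids, size=n_test_subjects, replace=False))
                 for _ in range(n_repeats)]
    accs = []
    for test_ids in folds:
        train_ids = [s for s in ids if s not in test_ids]
        assert not set(train_ids) & set(test_ids)
        Xtr = np.concatenate([subject_data[s][0] for s in train_ids])
        ytr = np.concatenate([subject_data[s][1] for s in train_ids])
        Xte = np.concatenate([subject_data[s][0] for s in test_ids])
        yte = np.concatenate([subject_data[s][1] for s in test_ids])
        dec = decoder_factory()
        dec.fit(Xtr, ytr)
        accs.append(_accuracy(yte, dec.predict(Xte)))
    return CVResult("cross", population, task, decoder_name, accs, seed)
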