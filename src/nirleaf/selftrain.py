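"""Rebalanced self-training: iterative pseudo-labeling with per-iteration
class rebalancing.

The procedure:

1. optionally balance the labeled set once (SMOTE) before any learning;
2. inject an unlabeled pool whose size is set by the labeled/unlabeled
   ratio beta = D_labeled / D_unlabeled (beta = 1/4 means four unlabeled
   samples per labeled one);
3. iterate: fit the base classifier on labeled + current pseudo-labeled
   data, predict the unlabeled pool, keep predictions whose top class
   probability reaches the confidence threshold tau, and rebalance that
   high-confidence set with the configured resampling scheme to form the
   next pseudo-labeled set;
4. stop when the pseudo-labels stabilise (changed fraction < stop_eps)
   or after max_iter iterations.

The pseudo set is rebuilt from the full injected pool every iteration, so
per-iteration class histograms can grow and rebalance.  With the MES or
SMOTE pseudo-samplers the rebalanced pseudo set is exactly balanced
(mu = 1) at every iteration.

Organised as a model/results pair: build a :class:`SelfTrainingModel`
from the data and a :class:`SelfTrainConfig`, call ``fit()``, and read
estimates, history and diagnostics off the returned
:class:`SelfTrainingResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

from nirleaf.rebalance import SamplerSpec, imbalance_ratio, resample
from nirleaf.spectra_io import LabeledSet, SpectrumMatrix

__all__ = ["SelfTrainConfig", "SelfTrainState", "PLSDAClassifier",
           "SelfTrainingModel", "SelfTrainingResults",
           "subsample_unlabeled", "fit_base", "pseudo_label", "self_train"]

_BASES = ("PLSDA", "LDA", "RFC")


@dataclass
class SelfTrainConfig:
    """Configuration of the rebalanced self-training loop.

    Parameters
    ----------
    base : {"PLSDA", "LDA", "RFC"}
        Base classifier.
    beta : float
        Labeled/unlabeled ratio; the injected pool holds round(n_labeled
        / beta) samples (typical values 1/2, 1/4, 1/6, 1/8).
    tau : float
        Pseudo-label confidence threshold in (0, 1]; a pool sample is
        accepted when its top class probability is >= tau.
    labeled_sampler : {"none", "smote"}
        One-off balancing of the labeled data before the loop.
    pseudo_sampler : {"RAS", "MES", "SMOTE", "RES"}
        Per-iteration rebalancing of the high-confidence pseudo set.
    stop_eps : float
        Convergence tolerance on the fraction of pool predictions that
        changed between iterations.
    n_components : int
        PLSDA latent variables (ignored by LDA/RFC).
    """

    base: str = "RFC"
    beta: float = 0.25
    tau: float = 0.8
    max_iter: int = 10
    labeled_sampler: str = "smote"
    pseudo_sampler: str = "MES"
    stop_eps: float = 0.01
    k_neighbors: int = 5
    n_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.base = self.base.upper()
        self.labeled_sampler = self.labeled_sampler.lower()
        self.pseudo_sampler = self.pseudo_sampler.upper()
        if self.base not in _BASES:
            raise ValueError(f"base must be one of {_BASES}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 < self.tau:
            raise ValueError("tau must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.labeled_sampler not in ("none", "smote"):
            raise ValueError("labeled_sampler must be 'none' or 'smote'")
        if self.pseudo_sampler not in ("RAS", "MES", "SMOTE", "RES"):
            raise ValueError("pseudo_sampler must be RAS/MES/SMOTE/RES")
        if self.labeled_sampler == "smote" and self.pseudo_sampler == "RES":
            warnings.warn(
                "RES pseudo-sampling is normally paired with *no* labeled "
                "balancing (RES self-balances from the start); "
                "labeled_sampler='smote' + pseudo_sampler='RES' is unusual")


@dataclass
class SelfTrainState:
    """Snapshot of one self-training iteration.

    ``mu`` is the imbalance ratio of the rebalanced pseudo set P_t (the
    quantity that equals 1 throughout for MES/SMOTE); ``train_mu`` is the
    ratio of the combined training set L' + P_t.
    """

    iteration: int
    pseudo_counts: np.ndarray
    mu: float
    train_mu: float
    n_high_confidence: int
    changed_fraction: float
    converged: bool


# ---------------------------------------------------------------------------
# base classifiers


class PLSDAClassifier:
    """Partial least squares discriminant analysis.

    PLS2 regression of one-hot class indicators on the spectra, with an
    argmax decision (ties resolve to the lowest class index).  Class
    scores are clipped at zero and normalised to serve as probabilities;
    a well-separated sample yields a score vector close to a one-hot
    indicator, hence a confidence near 1.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_, yi = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("PLSDA needs at least 2 classes")
        Y = np.eye(self.classes_.size)[yi]
        n_comp = int(min(self.n_components, X.shape[1], X.shape[0] - 1))
        self._pls = PLSRegression(n_components=n_comp, scale=False)
        self._pls.fit(X, Y)
        return self

    def decision_function(self, X):
        return self._pls.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        scores = np.clip(self.decision_function(X), 1e-9, None)
        return scores / scores.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def fit_base(base: str, X: SpectrumMatrix, y, seed: int = 0,
             n_components: int = 10):
    """Fit one of the base classifiers; returns a model with ``classes_``,
    ``predict`` and ``predict_proba``."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data contain a single class")
    base = base.upper()
    if base == "RFC":
        model = RandomForestClassifier(n_estimators=100, random_state=seed,
                                       n_jobs=1)
    elif base == "LDA":
        model = LinearDiscriminantAnalysis()
    elif base == "PLSDA":
        model = PLSDAClassifier(n_components=n_components)
    else:
        raise ValueError(f"unknown base classifier {base!r}")
    return model.fit(X.values, y)


# ---------------------------------------------------------------------------
# loop primitives


def subsample_unlabeled(pool: SpectrumMatrix, beta: float, n_labeled: int,
                        seed: int = 0) -> SpectrumMatrix:
    """Draw the injected unlabeled pool: round(n_labeled / beta) samples
    without replacement (the whole pool, with a warning, if smaller)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if pool.n_samples < 1:
        raise ValueError("empty unlabeled pool")
    quota = int(round(n_labeled / beta))
    if quota >= pool.n_samples:
        if quota > pool.n_samples:
            warnings.warn(
                f"unlabeled pool ({pool.n_samples}) smaller than the "
                f"beta quota ({quota}); using the whole pool")
        return pool
    rows = np.random.default_rng(seed).choice(pool.n_samples, size=quota,
                                              replace=False)
    return SpectrumMatrix(pool.values[rows], pool.wavelengths)


def pseudo_label(model, U: SpectrumMatrix, tau: float,
                 ) -> tuple[SpectrumMatrix, np.ndarray, np.ndarray]:
    """High-confidence pseudo-labels: samples whose top class probability
    is >= tau, labelled by argmax (ties to the lowest class index)."""
    proba = model.predict_proba(U.values)
    conf = proba.max(axis=1)
    y_hat = np.asarray(model.classes_)[np.argmax(proba, axis=1)]
    keep = conf >= tau
    return (SpectrumMatrix(U.values[keep], U.wavelengths),
            y_hat[keep], conf[keep])


# ---------------------------------------------------------------------------
# model / results


class SelfTrainingModel:
    """Rebalanced self-training model over a labeled set and an unlabeled pool.

    Parameters
    ----------
    labeled : LabeledSet
        Mean-spectrum samples with 5-level status labels.
    unlabeled : SpectrumMatrix
        Screened pixel spectra on the same band grid.
    config : SelfTrainConfig
    """

    def __init__(self, labeled: LabeledSet, unlabeled: SpectrumMatrix,
                 config: SelfTrainConfig | None = None):
        if len(labeled) == 0:
            raise ValueError("empty labeled set")
        if (labeled.spectra.n_bands != unlabeled.n_bands
                or not np.allclose(labeled.spectra.wavelengths,
                                   unlabeled.wavelengths, atol=0.1)):
            # 0.1 nm slack: table columns round wavelengths to one decimal
            raise ValueError("labeled and unlabeled band grids differ")
        self.labeled = labeled
        self.unlabeled = unlabeled
        self.config = config or SelfTrainConfig()

    @classmethod
    def from_cube(cls, labeled: LabeledSet, cube, config=None, **screen_kw):
        """Build the model from a leaf cube by screening its pixels."""
        from nirleaf.preprocess import screen_pixels
        pool, _ = screen_pixels(cube, **screen_kw)
        return cls(labeled, pool, config)

    def fit(self) -> "SelfTrainingResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        s_labeled, s_pool, s_model, s_iter = (
            int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4))

        # (1) one-off balancing of the labeled data
        L = self.labeled
        if cfg.labeled_sampler == "smote":
            Lx, Ly = resample(L.spectra, L.labels,
                              SamplerSpec("SMOTE", k_neighbors=cfg.k_neighbors,
                                          seed=s_labeled))
        else:
            Lx, Ly = L.spectra, L.labels

        # (2) the injected unlabeled pool, sized by beta
        U = subsample_unlabeled(self.unlabeled, cfg.beta, len(L), seed=s_pool)

        history: list[SelfTrainState] = []
        model = fit_base(cfg.base, Lx, Ly, seed=s_model,
                         n_components=cfg.n_components)
        if cfg.max_iter == 0:
            return SelfTrainingResults(self, model, history, (Lx, Ly))

        iter_rng = np.random.default_rng(s_iter)
        prev_pool_labels = None
        Px = Py = None
        n_empty = 0
        for t in range(1, cfg.max_iter + 1):
            if t > 1:  # iteration 1 reuses the supervised fit on L'
                if Py is not None and Py.size:
                    Tx = SpectrumMatrix(np.vstack([Lx.values, Px.values]),
                                        Lx.wavelengths)
                    Ty = np.concatenate([Ly, Py])
                else:
                    Tx, Ty = Lx, Ly
                model = fit_base(cfg.base, Tx, Ty, seed=s_model,
                                 n_components=cfg.n_components)

            X_hc, y_hc, _conf = pseudo_label(model, U, cfg.tau)
            pool_labels = np.asarray(model.classes_)[
                np.argmax(model.predict_proba(U.values), axis=1)]
            if prev_pool_labels is None:
                changed = 1.0
            else:
                changed = float(np.mean(pool_labels != prev_pool_labels))
            prev_pool_labels = pool_labels

            if y_hc.size == 0:
                n_empty += 1
                history.append(SelfTrainState(
                    t, np.zeros(5, dtype=int), float("nan"),
                    imbalance_ratio(Ly), 0, changed, False))
                if n_empty >= 3:
                    warnings.warn(
                        "no high-confidence pseudo-labels for 3 consecutive "
                        "iterations; returning the supervised model")
                    sup = fit_base(cfg.base, Lx, Ly, seed=s_model,
                                   n_components=cfg.n_components)
                    return SelfTrainingResults(self, sup, history, (Lx, Ly))
                Px = Py = None
                continue
            n_empty = 0

            # (3) rebalance the high-confidence set into P_t
            seed_t = int(iter_rng.integers(2 ** 31))
            budget = min(Lx.n_samples, y_hc.size)
            if cfg.pseudo_sampler == "MES":
                # exact per-class quotas: round the budget down to a
                # multiple of the number of classes present
                k_present = np.unique(y_hc).size
                budget = k_present * (budget // k_present)
            if cfg.pseudo_sampler != "SMOTE" and budget == 0:
                Px, Py = None, None
                history.append(SelfTrainState(
                    t, np.zeros(5, dtype=int), float("nan"),
                    imbalance_ratio(Ly), int(y_hc.size), changed, False))
                continue
            spec = SamplerSpec(cfg.pseudo_sampler,
                               target_n=max(budget, 1),
                               k_neighbors=cfg.k_neighbors, seed=seed_t)
            Px, Py = resample(X_hc, y_hc, spec)

            train_labels = np.concatenate([Ly, Py])
            state = SelfTrainState(
                iteration=t,
                pseudo_counts=np.bincount(Py, minlength=5),
                mu=imbalance_ratio(Py),
                train_mu=imbalance_ratio(train_labels),
                n_high_confidence=int(y_hc.size),
                changed_fraction=changed,
                converged=changed < cfg.stop_eps,
            )
            history.append(state)
            if state.converged:
                break

        # final refit on labeled + last pseudo set
        if Py is not None and Py.size:
            Tx = SpectrumMatrix(np.vstack([Lx.values, Px.values]),
                                Lx.wavelengths)
            Ty = np.concatenate([Ly, Py])
            model = fit_base(cfg.base, Tx, Ty, seed=s_model,
                             n_components=cfg.n_components)
            return SelfTrainingResults(self, model, history, (Tx, Ty))
        return SelfTrainingResults(self, model, history, (Lx, Ly))


class SelfTrainingResults:
    """Fitted self-training results: final classifier, iteration history,
    and evaluation helpers."""

    def __init__(self, model: SelfTrainingModel, classifier, history,
                 train_data):
        self.model = model
        self.config = model.config
        self.classifier_ = classifier
        self.history = list(history)
        self.train_X_, self.train_y_ = train_data

    # -- inference ---------------------------------------------------------
    def predict(self, X: SpectrumMatrix | np.ndarray) -> np.ndarray:
        values = X.values if isinstance(X, SpectrumMatrix) else np.asarray(X)
        return self.classifier_.predict(values)

    def predict_proba(self, X: SpectrumMatrix | np.ndarray) -> np.ndarray:
        values = X.values if isinstance(X, SpectrumMatrix) else np.asarray(X)
        return self.classifier_.predict_proba(values)

    # -- diagnostics -------------------------------------------------------
    @property
    def n_iterations(self) -> int:
        return len(self.history)

    @property
    def converged(self) -> bool:
        return bool(self.history) and self.history[-1].converged

    @property
    def mu_trajectory(self) -> np.ndarray:
        """Imbalance ratio of the rebalanced pseudo set, per iteration."""
        return np.array([s.mu for s in self.history])

    def evaluate(self, test: LabeledSet, balanced: bool = False,
                 seed: int = 0):
        """Metrics report on a test set (optionally balanced first)."""
        from nirleaf.evaluate import balance_test_set, compute_metrics
        if balanced:
            test = balance_test_set(test, seed=seed)
        return compute_metrics(test.labels, self.predict(test.spectra))

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self.config
        lines = [
            "Rebalanced self-training results",
            "=" * 54,
            f"base classifier   : {cfg.base}",
            f"beta (L/U ratio)  : {cfg.beta:g}",
            f"tau (confidence)  : {cfg.tau:g}",
            f"labeled sampler   : {cfg.labeled_sampler}",
            f"pseudo sampler    : {cfg.pseudo_sampler}",
            f"labeled samples   : {len(self.model.labeled)}",
            f"unlabeled pool    : {self.model.unlabeled.n_samples}",
            f"iterations run    : {self.n_iterations} "
            f"(converged: {self.converged})",
            "-" * 54,
            "iter  n_hc   pseudo counts (VL..VH)      mu    train_mu",
        ]
        for s in self.history:
            counts = ":".join(str(c) for c in s.pseudo_counts)
            mu = f"{s.mu:.2f}" if np.isfinite(s.mu) else "  - "
            lines.append(f"{s.iteration:4d}  {s.n_high_confidence:5d}  "
                         f"{counts:<26s}  {mu:>5s}  {s.train_mu:8.2f}")
        lines.append("=" * 54)
        return "\n".join(lines)


def self_train(L: LabeledSet, U: SpectrumMatrix, config: SelfTrainConfig,
               ) -> tuple[object, list[SelfTrainState]]:
    """Functional wrapper: fit and return (final classifier, history)."""
    results = SelfTrainingModel(L, U, config).fit()
    return results.classifier_, results.history
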