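"""Class-imbalance quantification and the four resampling schemes.

The imbalance ratio of a label vector is mu = C_max / C_min, the largest
class count over the smallest (non-empty classes only); mu = 1 is
perfectly balanced.

Four schemes rebalance a labeled pool.  The first three draw a class
first, then a sample uniformly with replacement within the class:

* RAS (random sampling)  — class j chosen with p_j = C_j / sum_j C_j,
  i.e. the original distribution is preserved in expectation;
* MES (mean sampling)    — every non-empty class receives exactly
  floor(target_n / k) samples (remainder to the smallest classes first),
  so the output is balanced by construction;
* RES (reverse sampling) — class j chosen with p_j proportional to
  1 / C_j, aggressively over-weighting minority classes.

* SMOTE synthesises new minority samples as convex combinations of
  nearest minority neighbours until every class reaches the majority
  count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from nirleaf.spectra_io import SpectrumMatrix

__all__ = ["SamplerSpec", "ImbalanceReport", "imbalance_ratio", "class_counts",
           "class_probabilities", "resample", "smote_synthesize"]

_METHODS = ("RAS", "MES", "SMOTE", "RES")


@dataclass
class SamplerSpec:
    """Resampling request: method, size target, SMOTE neighbourhood, seed.

    ``target_n`` is the total draw for RAS/RES and the total (split evenly
    across classes) for MES; SMOTE ignores it and fills every class up to
    the majority count.
    """

    method: str
    target_n: int = 0
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.method != "SMOTE" and self.target_n <= 0:
            raise ValueError("target_n must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class ImbalanceReport:
    """Per-class counts and the imbalance ratio mu = C_max / C_min."""

    counts: np.ndarray
    mu: float


def class_counts(labels, n_classes: int = 5) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label vector")
    return np.bincount(labels, minlength=n_classes)


def imbalance_ratio(labels, n_classes: int = 5) -> float:
    """mu = C_max / C_min over the non-empty classes (mu >= 1)."""
    counts = class_counts(labels, n_classes)
    nonzero = counts[counts > 0]
    return float(nonzero.max() / nonzero.min())


def imbalance_report(labels, n_classes: int = 5) -> ImbalanceReport:
    counts = class_counts(labels, n_classes)
    nonzero = counts[counts > 0]
    return ImbalanceReport(counts=counts, mu=float(nonzero.max() / nonzero.min()))


def class_probabilities(method: str, counts) -> np.ndarray:
    """Per-class selection probability under RAS, MES or RES.

    Empty classes receive probability 0 and the rest renormalise.  With k
    non-empty classes: RAS gives C_j / sum C, MES gives 1/k, RES gives
    (1/C_j) / sum(1/C).
    """
    method = method.upper()
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    nonzero = counts > 0
    if not nonzero.any():
        raise ValueError("all classes empty")
    p = np.zeros_like(counts)
    if method == "RAS":
        p[nonzero] = counts[nonzero]
    elif method == "MES":
        p[nonzero] = 1.0
    elif method == "RES":
        p[nonzero] = 1.0 / counts[nonzero]
    else:
        raise ValueError(f"no probability rule for method {method!r}")
    return p / p.sum()


def resample(data: SpectrumMatrix, labels, spec: SamplerSpec,
             ) -> tuple[SpectrumMatrix, np.ndarray]:
    """Rebalance (data, labels) according to ``spec``; order is shuffled.

    Deterministic given (data, labels, spec) including the seed.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("cannot resample an empty set")
    rng = np.random.default_rng(spec.seed)
    counts = class_counts(labels)
    present = np.where(counts > 0)[0]
    idx_by_class = {c: np.where(labels == c)[0] for c in present}

    if spec.method in ("RAS", "RES"):
        p = class_probabilities(spec.method, counts)
        drawn_classes = rng.choice(counts.size, size=spec.target_n, p=p)
        rows = np.array([rng.choice(idx_by_class[c]) for c in drawn_classes],
                        dtype=int)
        out_x, out_y = data.values[rows], labels[rows]
    elif spec.method == "MES":
        k = present.size
        quota = np.full(k, spec.target_n // k)
        # remainder goes to the smallest classes first
        remainder = spec.target_n - quota.sum()
        order = np.argsort(counts[present], kind="stable")
        quota[order[:remainder]] += 1
        rows = np.concatenate([
            rng.choice(idx_by_class[c], size=q, replace=True)
            for c, q in zip(present, quota)]) if quota.sum() else np.empty(0, int)
        out_x, out_y = data.values[rows.astype(int)], labels[rows.astype(int)]
    else:  # SMOTE: fill every minority class up to the majority count
        majority = counts[present].max()
        xs = [data.values]
        ys = [labels]
        for c in present:
            n_new = int(majority - counts[c])
            if n_new == 0:
                continue
            minority = SpectrumMatrix(data.values[idx_by_class[c]],
                                      data.wavelengths)
            child_seed = int(rng.integers(2 ** 31))
            xs.append(smote_synthesize(minority, n_new, spec.k_neighbors,
                                       child_seed).values)
            ys.append(np.full(n_new, c, dtype=int))
        out_x = np.vstack(xs)
        out_y = np.concatenate(ys)

    perm = rng.permutation(out_y.size)
    return SpectrumMatrix(out_x[perm], data.wavelengths), out_y[perm]


def smote_synthesize(X_minority: SpectrumMatrix, n_new: int,
                     k_neighbors: int = 5, seed: int = 0) -> SpectrumMatrix:
    """Synthesise ``n_new`` minority samples by neighbour interpolation.

    Each synthetic point is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1)
    and x_nn one of the ``k_neighbors`` nearest minority neighbours
    (Euclidean), so every band value lies between its two parents'.  A
    single-sample class cannot be interpolated and falls back to
    duplication with a warning.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    X = X_minority.values
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if n_new == 0:
        return SpectrumMatrix(np.empty((0, X.shape[1])), X_minority.wavelengths)
    if n == 0:
        raise ValueError("cannot synthesise from an empty class")
    if n == 1:
        warnings.warn("SMOTE on a single-sample class: duplicating it")
        return SpectrumMatrix(np.repeat(X, n_new, axis=0),
                              X_minority.wavelengths)
    k = k_neighbors
    if k > n - 1:
        warnings.warn(f"k_neighbors reduced from {k} to {n - 1} "
                      f"(class has only {n} samples)")
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self

    base = rng.integers(n, size=n_new)
    pick = rng.integers(k, size=n_new)
    partner = neigh[base, pick]
    u = rng.uniform(0.0, 1.0, size=n_new)[:, None]
    synth = X[base] + u * (X[partner] - X[base])
    return SpectrumMatrix(synth, X_minority.wavelengths)
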