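"""Time-resolved pairwise decoding of conditions from sensor patterns.

For every pair of conditions and every timepoint, a linear soft-margin
SVM is trained and tested on *pseudo-trials* — averages of ``group_size``
raw trials — using leave-one-pseudo-trial-per-class-out cross-validation
over the K pseudo-trials, the whole permute / average / cross-validate
cycle repeated ``n_reps`` times with fresh random partitions. The mean
accuracy fills the symmetric cell of a per-timepoint condition x
condition decoding RDM (diagonal undefined, stored NaN).

Two classifier engines solve the identical optimisation (linear kernel,
soft margin, default C = 1):

* ``"batched"`` (default) — an in-package SMO solver for the SVM dual
  that treats every timepoint as one tiny QP and solves them all in
  vectorised sweeps; orders of magnitude faster than per-timepoint
  library calls at these problem sizes (a handful of training samples).
* ``"sklearn"`` — ``sklearn.svm.SVC(kernel="linear")``, one fit per
  timepoint; used in the test suite as the independent reference the
  batched engine is checked against.

Condition pairs are independent work units seeded individually from the
root seed, so results are bit-identical regardless of execution order or
parallelism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .containers import EpochSet, RDMSeries

__all__ = [
    "PseudoTrialSet",
    "make_pseudotrials",
    "resolve_group_size",
    "decode_pair_timecourse",
    "decode_pair_timepoint",
    "decoding_rdm_series",
]

log = logging.getLogger(__name__)

K_GROUPS = 4
GROUP_SIZE = 10
N_REPS = 100
SVM_C = 1.0


@dataclass
class PseudoTrialSet:
    """K sub-averaged pattern series for one condition.

    Each pseudo-trial is the mean of exactly ``group_size`` distinct raw
    trials; the raw trials used across the K groups are disjoint
    (``provenance`` records which raw-trial indices entered each average).
    """

    patterns: np.ndarray  # (K, ...) — same trailing shape as one raw trial
    provenance: list[np.ndarray]
    K: int
    group_size: int


def resolve_group_size(n_trials: int, K: int, group_size: int) -> int:
    """Shortfall policy: shrink the group size to floor(n/K), minimum 1.

    Returns 0 if fewer than K raw trials are available (condition must be
    excluded).
    """
    if n_trials < K:
        return 0
    return max(1, min(group_size, n_trials // K))


def make_pseudotrials(
    trials: np.ndarray,
    K: int = K_GROUPS,
    group_size: int = GROUP_SIZE,
    rng: np.random.Generator | None = None,
) -> PseudoTrialSet:
    """Randomly partition raw trials into K groups and average within groups.

    ``trials`` holds one condition's raw trials along axis 0 (e.g. shape
    ``(n_trials, channel, time)``). The assignment is a uniformly random
    partition of ``K * group_size`` trials drawn without replacement.
    """
    rng = rng or np.random.default_rng()
    n = trials.shape[0]
    gs = resolve_group_size(n, K, group_size)
    if gs == 0:
        raise ValueError(f"need at least K={K} raw trials; got {n}")
    if gs < group_size:
        log.warning("group size reduced from %d to %d (only %d trials)", group_size, gs, n)
    perm = rng.permutation(n)[: K * gs]
    groups = perm.reshape(K, gs)
    patterns = trials[groups].mean(axis=1)
    return PseudoTrialSet(patterns=patterns, provenance=list(groups), K=K, group_size=gs)


# ---------------------------------------------------------------------------
# linear SVM engines
# ---------------------------------------------------------------------------

def _batched_svm_predict(
    train: np.ndarray,
    y: np.ndarray,
    test: np.ndarray,
    C: float = SVM_C,
    tol: float = 1e-8,
    max_sweeps: int = 200,
) -> np.ndarray:
    """Batch-solve T independent linear soft-margin SVMs and predict.

    ``train``: (T, n, f) training samples, ``y``: (n,) labels in {-1, +1}
    shared across problems, ``test``: (T, m, f). Solves the SVM dual per
    problem by SMO-style pairwise coordinate updates swept in a fixed
    order, vectorised over the T problems; the bias is recovered from the
    free support vectors (fallback: all support vectors). Returns (T, m)
    predictions in {-1, +1}; ties (decision value 0) go to +1.
    """
    T, n, _ = train.shape
    K = np.einsum("tif,tjf->tij", train, train)
    alpha = np.zeros((T, n))
    F = np.zeros((T, n))  # sum_l alpha_l y_l K(l, k), per problem
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for _ in range(max_sweeps):
        max_step = 0.0
        for i, j in pairs:
            Eij = (F[:, i] - y[i]) - (F[:, j] - y[j])
            eta = K[:, i, i] + K[:, j, j] - 2.0 * K[:, i, j]
            ok = eta > 1e-12
            aj_new = alpha[:, j] + np.where(ok, y[j] * Eij / np.maximum(eta, 1e-12), 0.0)
            if y[i] == y[j]:
                lo = np.maximum(0.0, alpha[:, i] + alpha[:, j] - C)
                hi = np.minimum(C, alpha[:, i] + alpha[:, j])
            else:
                lo = np.maximum(0.0, alpha[:, j] - alpha[:, i])
                hi = np.minimum(C, C + alpha[:, j] - alpha[:, i])
            aj_new = np.where(ok, np.clip(aj_new, lo, hi), alpha[:, j])
            dj = aj_new - alpha[:, j]
            di = -y[i] * y[j] * dj
            alpha[:, j] = aj_new
            alpha[:, i] = alpha[:, i] + di
            F += (di * y[i])[:, None] * K[:, i, :] + (dj * y[j])[:, None] * K[:, j, :]
            step = np.abs(dj).max(initial=0.0)
            max_step = max(max_step, step)
        if max_step < tol:
            break
    free = (alpha > 1e-9) & (alpha < C - 1e-9)
    sv = alpha > 1e-9
    resid = y[None, :] - F
    n_free = free.sum(axis=1)
    b_free = (resid * free).sum(axis=1) / np.maximum(n_free, 1)
    b_sv = (resid * sv).sum(axis=1) / np.maximum(sv.sum(axis=1), 1)
    b = np.where(n_free > 0, b_free, b_sv)
    Kt = np.einsum("tmf,tnf->tmn", test, train)
    dec = np.einsum("tmn,tn->tm", Kt, alpha * y[None, :]) + b[:, None]
    return np.where(dec >= 0, 1, -1)


def _sklearn_svm_predict(train, y, test, C: float = SVM_C) -> np.ndarray:
    from sklearn.svm import SVC

    preds = np.empty(test.shape[:2], dtype=int)
    for t in range(train.shape[0]):
        clf = SVC(kernel="linear", C=C)
        clf.fit(train[t], y)
        preds[t] = clf.predict(test[t])
    return preds


_ENGINES = {"batched": _batched_svm_predict, "sklearn": _sklearn_svm_predict}


# ---------------------------------------------------------------------------
# pairwise decoding
# ---------------------------------------------------------------------------

def decode_pair_timecourse(
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    *,
    K: int = K_GROUPS,
    group_size: int = GROUP_SIZE,
    n_reps: int = N_REPS,
    C: float = SVM_C,
    rng: np.random.Generator | None = None,
    all_folds: bool = True,
    engine: str = "batched",
) -> np.ndarray:
    """Pairwise decoding accuracy at every timepoint.

    ``raw_a`` / ``raw_b`` are ``(n_trials, n_channels, n_time)`` arrays of
    the two conditions' valid raw trials. Per repetition, fresh pseudo-
    trial partitions are drawn; the classifier is trained on K-1 pseudo-
    trials per class and tested on the held-out pair, across all K folds
    (``all_folds=False`` tests a single random fold per repetition).
    Returns the accuracy time series, values in [0, 1].
    """
    if engine not in _ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {sorted(_ENGINES)}")
    predict = _ENGINES[engine]
    rng = rng or np.random.default_rng()
    if raw_a.shape[1:] != raw_b.shape[1:]:
        raise ValueError("condition trials must share channel/time dimensions")
    if K < 2:
        raise ValueError("K must be >= 2")
    n_time = raw_a.shape[2]
    n_ch = raw_a.shape[1]
    labels = np.array([-1] * (K - 1) + [1] * (K - 1))
    test_labels = np.array([-1, 1])
    # gather every (repetition, fold, timepoint) as one independent problem
    # so the batched engine solves them in large vectorised sweeps
    trains, tests = [], []
    for _ in range(n_reps):
        pa = make_pseudotrials(raw_a, K, group_size, rng).patterns  # (K, ch, T)
        pb = make_pseudotrials(raw_b, K, group_size, rng).patterns
        folds = range(K) if all_folds else (int(rng.integers(K)),)
        for k in folds:
            tr = np.concatenate([np.delete(pa, k, axis=0), np.delete(pb, k, axis=0)])
            te = np.stack([pa[k], pb[k]])
            trains.append(tr.transpose(2, 0, 1))  # (T, samples, ch)
            tests.append(te.transpose(2, 0, 1))
    n_units = len(trains)
    train = np.concatenate(trains)  # (units * T, samples, ch)
    test = np.concatenate(tests)
    # chunk to keep the working set bounded at full problem sizes
    chunk = max(n_time, int(5e7 / (labels.size * n_ch)))
    preds = np.concatenate([
        predict(train[i : i + chunk], labels, test[i : i + chunk], C)
        for i in range(0, train.shape[0], chunk)
    ])
    correct = (preds == test_labels[None, :]).mean(axis=1)
    return correct.reshape(n_units, n_time).mean(axis=0)


def decode_pair_timepoint(
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    *,
    n_reps: int = N_REPS,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> float:
    """Decoding accuracy for a single timepoint (``(n_trials, n_channels)`` inputs)."""
    acc = decode_pair_timecourse(
        raw_a[:, :, None], raw_b[:, :, None], n_reps=n_reps, rng=rng, **kwargs
    )
    return float(acc[0])


def _valid_trials(epochs: EpochSet, s: int, c: int) -> np.ndarray:
    return epochs.data[s, c][epochs.valid[s, c]]


def _decode_unit(raw_a, raw_b, seed_key, K, group_size, n_reps, C, all_folds, engine):
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    return decode_pair_timecourse(
        raw_a, raw_b, K=K, group_size=group_size, n_reps=n_reps, C=C,
        rng=rng, all_folds=all_folds, engine=engine,
    )


def decoding_rdm_series(
    epochs: EpochSet,
    *,
    K: int = K_GROUPS,
    group_size: int = GROUP_SIZE,
    n_reps: int = N_REPS,
    C: float = SVM_C,
    seed: int = 0,
    all_folds: bool = True,
    engine: str = "batched",
    n_jobs: int = 1,
) -> RDMSeries:
    """Per-subject, per-timepoint pairwise decoding RDMs.

    Conditions with fewer than K valid trials are excluded: their RDM rows
    and columns are NaN and a warning is logged. Each (subject, pair) unit
    draws its random stream from ``SeedSequence([seed, subject, i, j])``,
    making the output independent of scheduling.
    """
    ns, nc = epochs.n_subjects, epochs.n_conditions
    nt = epochs.n_time
    rdms = np.full((ns, nt, nc, nc), np.nan)

    jobs, keys = [], []
    for s in range(ns):
        ok = [resolve_group_size(int(epochs.valid[s, c].sum()), K, group_size) > 0
              for c in range(nc)]
        for c, good in enumerate(ok):
            if not good:
                log.warning("subject %d condition %d excluded (too few valid trials)", s, c)
        for i in range(nc):
            for j in range(i + 1, nc):
                if ok[i] and ok[j]:
                    jobs.append((_valid_trials(epochs, s, i), _valid_trials(epochs, s, j),
                                 [seed, s, i, j]))
                    keys.append((s, i, j))
    results = Parallel(n_jobs=n_jobs)(
        delayed(_decode_unit)(a, b, key, K, group_size, n_reps, C, all_folds, engine)
        for a, b, key in jobs
    )
    for (s, i, j), acc in zip(keys, results):
        rdms[s, :, i, j] = acc
        rdms[s, :, j, i] = acc
    return RDMSeries(data=rdms, times=epochs.times, condition_labels=epochs.condition_labels)
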