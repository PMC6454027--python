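"""Significance and latency machinery for RSA time-courses.

Significance is assessed nonparametrically: under the null hypothesis of
no signal, each subject's time-course is symmetric around zero, so a
null distribution of the group mean is built by randomly multiplying
subjects by +1 or -1. Multiple comparisons over time are handled by
cluster correction: contiguous runs of timepoints below the
cluster-defining threshold form candidate clusters, and a cluster is
significant when its size (count of contiguous supra-threshold
timepoints) exceeds what the same sign-flip permutations produce for
their maximum cluster.

Peak and onset latencies are estimated by bootstrapping the subject
sample: per draw, subjects are resampled with replacement, averaged, and
the latency extracted (peak = argmax within a search window; onset =
first timepoint of the earliest significant cluster at or after stimulus
onset, recomputed per draw). The bootstrap distribution supplies the
mean, SEM and percentile 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SignificanceMask",
    "LatencyEstimate",
    "sign_permutation_test",
    "cluster_correct",
    "significance_mask",
    "bootstrap_latency",
    "trim_outliers",
    "latency_histogram_filter",
    "count_significant",
]

log = logging.getLogger(__name__)

N_PERMUTATIONS = 1000
N_BOOTSTRAP = 1000
CLUSTER_DEFINING_P = 0.05
CLUSTER_ALPHA = 0.05
TRIM_PCT = 5.0
LATENCY_CUTOFF_MS = 150.0
PEAK_WINDOW_MS = (0.0, 600.0)


@dataclass
class SignificanceMask:
    """Cluster-corrected per-timepoint significance."""

    mask: np.ndarray  # bool per timepoint
    clusters: list[tuple[int, int, int]]  # (start_idx, stop_idx inclusive, size)
    cdt: float
    alpha: float
    n_permutations: int
    cluster_p: list[float] = field(default_factory=list)

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class LatencyEstimate:
    """Bootstrap latency summary (all times in ms)."""

    point: float
    mean: float
    sem: float
    ci95: tuple[float, float]
    n_bootstrap: int
    kind: str  # "peak" or "onset"
    samples: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    missing_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "point_ms": self.point,
            "mean_ms": self.mean,
            "sem_ms": self.sem,
            "ci95_ms": list(self.ci95),
            "n_bootstrap": self.n_bootstrap,
            "missing_fraction": self.missing_fraction,
        }


def _check_timecourses(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("timecourses must be (subject, time)")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not np.isfinite(x).all():
        raise ValueError("timecourses contain non-finite values")
    return x


def _sign_flip_null(x: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_time) null group means under random per-subject sign flips."""
    n_sub = x.shape[0]
    signs = rng.integers(0, 2, size=(n_perm, n_sub)) * 2 - 1
    return (signs @ x) / n_sub


def sign_permutation_test(
    timecourses: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-sided sign-permutation p-value per timepoint.

    The statistic is the mean over subjects; p is the proportion of
    sign-flip draws whose |statistic| reaches the observed one, with the
    observed statistic counted among the permutations (so p is never
    below 1 / (n_perm + 1)).
    """
    x = _check_timecourses(timecourses)
    if n_perm < 100:
        log.warning("n_perm=%d gives coarse p-value resolution (minimum p = %.3g)",
                    n_perm, 1.0 / (n_perm + 1))
    rng = rng or np.random.default_rng()
    null = _sign_flip_null(x, n_perm, rng)
    obs = x.mean(axis=0)
    exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of True as (start, stop_inclusive, size)."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks], idx[-1]]
    for a, b in zip(starts, stops):
        out.append((int(a), int(b), int(b - a + 1)))
    return out


def _max_run(mask_row: np.ndarray) -> int:
    runs = _runs(mask_row)
    return max((r[2] for r in runs), default=0)


def cluster_correct(
    p_values: np.ndarray,
    timecourses: np.ndarray,
    cdt: float = CLUSTER_DEFINING_P,
    alpha: float = CLUSTER_ALPHA,
    n_perm: int = N_PERMUTATIONS,
    rng: np.random.Generator | None = None,
) -> SignificanceMask:
    """Cluster-size correction of a per-timepoint p-map.

    Candidate clusters are maximal runs with ``p < cdt``. The null
    distribution of the maximum cluster size is built from sign-flip
    permutations of the same time-courses (each permutation's p-map is
    computed by ranking it within the permutation distribution, then
    thresholded at ``cdt``). A candidate is significant when the
    proportion of null maxima at least as large is <= ``alpha``.
    """
    x = _check_timecourses(timecourses)
    p_values = np.asarray(p_values, dtype=float)
    if p_values.shape != (x.shape[1],):
        raise ValueError("p_values must align with the time axis of timecourses")
    rng = rng or np.random.default_rng()

    null = _sign_flip_null(x, n_perm, rng)
    # permutation p-maps: fraction of permutation |means| >= this one's, per column
    perm_p = rankdata(-np.abs(null), method="max", axis=0) / n_perm
    null_max = np.array([_max_run(row) for row in (perm_p < cdt)])

    mask = np.zeros(x.shape[1], dtype=bool)
    clusters, cluster_p = [], []
    for start, stop, size in _runs(p_values < cdt):
        pc = (1.0 + (null_max >= size).sum()) / (n_perm + 1.0)
        if pc <= alpha:
            mask[start : stop + 1] = True
            clusters.append((start, stop, size))
            cluster_p.append(float(pc))
    return SignificanceMask(mask=mask, clusters=clusters, cdt=cdt, alpha=alpha,
                            n_permutations=n_perm, cluster_p=cluster_p)


def significance_mask(
    timecourses: np.ndarray,
    cdt: float = CLUSTER_DEFINING_P,
    alpha: float = CLUSTER_ALPHA,
    n_perm: int = N_PERMUTATIONS,
    rng: np.random.Generator | None = None,
) -> SignificanceMask:
    """Sign-permutation p-map followed by cluster correction, one call."""
    rng = rng or np.random.default_rng()
    p = sign_permutation_test(timecourses, n_perm, rng)
    return cluster_correct(p, timecourses, cdt, alpha, n_perm, rng)


def _onset_ms(mask: np.ndarray, times: np.ndarray) -> float | None:
    """First timepoint of the earliest significant cluster at/after 0 ms."""
    post = mask & (times >= 0)
    idx = np.flatnonzero(post)
    return float(times[idx[0]]) if idx.size else None


def bootstrap_latency(
    timecourses: np.ndarray,
    times: np.ndarray,
    window_ms: tuple[float, float] = PEAK_WINDOW_MS,
    n_boot: int = N_BOOTSTRAP,
    kind: str = "peak",
    rng: np.random.Generator | None = None,
    *,
    cdt: float = CLUSTER_DEFINING_P,
    alpha: float = CLUSTER_ALPHA,
    n_perm_onset: int = 200,
) -> LatencyEstimate:
    """Bootstrap the subject sample and extract a latency per draw.

    ``kind="peak"``: argmax of the subject-average within ``window_ms``
    (first occurrence on ties). ``kind="onset"``: first timepoint of the
    earliest cluster-significant run at or after 0 ms, recomputed per
    draw (draws with no significant cluster are recorded as missing and
    reported via ``missing_fraction``). The point estimate uses the full
    (unresampled) subject sample; mean, SEM and the percentile 2.5/97.5
    CI come from the bootstrap distribution.
    """
    x = _check_timecourses(timecourses)
    times = np.asarray(times, dtype=float)
    if times.size != x.shape[1]:
        raise ValueError("times must align with timecourses")
    if kind not in ("peak", "onset"):
        raise ValueError(f"kind must be 'peak' or 'onset'; got {kind!r}")
    lo, hi = window_ms
    win = (times >= lo) & (times <= hi)
    if not win.any():
        raise ValueError(f"window {window_ms} ms contains no samples of the time axis")
    rng = rng or np.random.default_rng()
    n_sub = x.shape[0]

    def extract(avg: np.ndarray, draw_rng: np.random.Generator) -> float | None:
        if kind == "peak":
            return float(times[win][np.argmax(avg[win])])
        return None  # onset handled below (needs the resampled matrix)

    # point estimate on the full sample
    if kind == "peak":
        point = extract(x.mean(axis=0), rng)
    else:
        sm = significance_mask(x, cdt, alpha, n_perm_onset, rng)
        point = _onset_ms(sm.mask, times)
        if point is None:
            log.warning("no significant cluster in the full sample; onset point undefined")
            point = float("nan")

    draws = []
    n_missing = 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_sub, size=n_sub)
        xb = x[pick]
        if kind == "peak":
            draws.append(float(times[win][np.argmax(xb.mean(axis=0)[win])]))
        else:
            sm = significance_mask(xb, cdt, alpha, n_perm_onset, rng)
            onset = _onset_ms(sm.mask, times)
            if onset is None:
                n_missing += 1
            else:
                draws.append(onset)
    samples = np.asarray(draws, dtype=float)
    if samples.size == 0:
        return LatencyEstimate(point=point, mean=float("nan"), sem=float("nan"),
                               ci95=(float("nan"), float("nan")), n_bootstrap=n_boot,
                               kind=kind, samples=samples, missing_fraction=1.0)
    sem = float(samples.std(ddof=1)) if samples.size > 1 else 0.0
    ci = (float(np.percentile(samples, 2.5)), float(np.percentile(samples, 97.5)))
    return LatencyEstimate(
        point=point, mean=float(samples.mean()), sem=sem, ci95=ci,
        n_bootstrap=n_boot, kind=kind, samples=samples,
        missing_fraction=n_missing / n_boot,
    )


def trim_outliers(values: np.ndarray, pct: float = TRIM_PCT) -> np.ndarray:
    """Drop values strictly outside the [pct, 100 - pct] percentile range.

    Percentiles use linear interpolation between order statistics.
    Samples smaller than 100 / pct are returned unchanged with a warning
    (the trim would be ill-resolved).
    """
    v = np.asarray(values, dtype=float)
    if pct <= 0 or pct >= 50:
        raise ValueError("pct must be in (0, 50)")
    if v.size < 100.0 / pct:
        log.warning("sample of %d too small to trim %g%% tails; returned unchanged",
                    v.size, pct)
        return v
    lo, hi = np.percentile(v, [pct, 100.0 - pct])
    return v[(v >= lo) & (v <= hi)]


def latency_histogram_filter(values: np.ndarray, cutoff_ms: float = LATENCY_CUTOFF_MS) -> np.ndarray:
    """Keep latencies at or below the cutoff (boundary inclusive)."""
    v = np.asarray(values, dtype=float)
    return v[v <= cutoff_ms]


def count_significant(
    masks: dict[str, SignificanceMask],
    meta: dict[str, tuple[int, str]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-descriptor significant-timepoint counts and orientation sums.

    ``meta`` maps descriptor id -> (level, band). Returns a table with
    columns (descriptor, level, band, n_significant) and the per-
    orientation sums over levels for the detail bands H, V, D.
    """
    rows = []
    for did, sm in masks.items():
        level, band = meta[did]
        rows.append({"descriptor": did, "level": level, "band": band,
                     "n_significant": sm.count()})
    table = pd.DataFrame(rows, columns=["descriptor", "level", "band", "n_significant"])
    sums = {
        band: int(table.loc[table["band"] == band, "n_significant"].sum())
        for band in ("H", "V", "D")
    }
    return table, sums
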