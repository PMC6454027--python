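"""Descriptor RDMs (1 - Pearson) and their Spearman comparison with
neural decoding RDMs over time (representational similarity analysis).

A model RDM cell (i, j) is ``1 - Pearson r`` between the descriptor
vectors of stimuli i and j, giving values in [0, 2] with an undefined
(NaN) diagonal. RDM-to-RDM comparison is Spearman rank correlation over
the vectorised strict upper triangle (the symmetric lower half and the
diagonal carry no extra information), with average ranks for ties and
pairwise exclusion of missing cells. Correlating one model RDM with a
neural RDM series yields one RSA time-course per subject; the grand
average is the plain mean over subjects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sst

from .containers import RDMSeries
from .wavelet import WaveletDescriptor

__all__ = [
    "model_rdm",
    "model_rdms",
    "rdm_spearman",
    "rsa_timecourse",
    "timecourse_frame",
]

log = logging.getLogger(__name__)


def model_rdm(vectors: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """1 - Pearson dissimilarity matrix over per-stimulus descriptor vectors.

    Zero-variance vectors cannot be correlated; their cells are NaN
    (flagged with a warning). The diagonal is stored NaN (undefined).
    """
    mat = np.asarray(vectors, dtype=float)
    if mat.ndim != 2:
        raise ValueError("need a (n_stimuli, n_features) stack of equal-length vectors")
    n, m = mat.shape
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    if m < 2:
        raise ValueError("descriptor vectors must have length >= 2")
    sd = mat.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d zero-variance descriptor vector(s): cells set to NaN",
                    int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    rdm = 1.0 - r
    rdm = 0.5 * (rdm + rdm.T)  # exact bitwise symmetry
    rdm[degenerate, :] = np.nan
    rdm[:, degenerate] = np.nan
    np.fill_diagonal(rdm, np.nan)
    return rdm


def model_rdms(descriptors: list[list[WaveletDescriptor]]) -> dict[str, np.ndarray]:
    """One 1 - Pearson RDM per descriptor id (W1..W25 for 5 levels)."""
    ids = [d.id for d in descriptors[0]]
    out = {}
    for k, did in enumerate(ids):
        out[did] = model_rdm([stim[k].vector for stim in descriptors])
    return out


def _utri(rdm: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(rdm.shape[0], k=1)
    return rdm[iu]


def rdm_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation between two RDMs' strict upper triangles.

    Cells missing (NaN) in either matrix are excluded pairwise; ties get
    average ranks. Raises if fewer than 3 usable cell pairs remain or if
    either triangle is constant (ranks undefined).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"RDMs must be square and same shape; got {a.shape} vs {b.shape}")
    va, vb = _utri(a), _utri(b)
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 usable cell pairs; got {int(ok.sum())}")
    va, vb = va[ok], vb[ok]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant RDM upper triangle: ranks undefined")
    return float(sst.spearmanr(va, vb).statistic)


def rsa_timecourse(neural: RDMSeries, model: np.ndarray) -> np.ndarray:
    """Per-subject Spearman rho(t) between a model RDM and the neural series.

    Returns a ``(n_subjects, n_time)`` array; the grand average is its
    mean over axis 0. A constant model triangle has no rank information
    and is rejected; a neural triangle that is constant at an isolated
    timepoint (possible pre-stimulus, where decoding accuracies are
    quantised) is flagged and scored rho = 0 so downstream statistics
    stay finite.
    """
    model = np.asarray(model, dtype=float)
    if model.shape != (neural.n_conditions, neural.n_conditions):
        raise ValueError(
            f"model RDM is {model.shape} but neural RDMs are "
            f"{neural.n_conditions}x{neural.n_conditions}"
        )
    ns, nt = neural.n_subjects, neural.times.size
    iu = np.triu_indices(neural.n_conditions, k=1)
    vm = model[iu]
    if np.ptp(vm[np.isfinite(vm)]) == 0:
        raise ValueError("constant model RDM: ranks undefined")
    out = np.empty((ns, nt))
    n_degenerate = 0
    for s in range(ns):
        tri = neural.data[s][:, iu[0], iu[1]]  # (time, n_pairs)
        for t in range(nt):
            vn = tri[t]
            ok = np.isfinite(vm) & np.isfinite(vn)
            if ok.sum() < 3 or np.ptp(vm[ok]) == 0 or np.ptp(vn[ok]) == 0:
                out[s, t] = 0.0
                n_degenerate += 1
                continue
            out[s, t] = sst.spearmanr(vm[ok], vn[ok]).statistic
    if n_degenerate:
        log.warning("%d degenerate (constant/under-determined) timepoints scored rho=0",
                    n_degenerate)
    return out


def timecourse_frame(rho: np.ndarray, times: np.ndarray) -> pd.DataFrame:
    """Tidy per-subject time-course table (time_ms, subject_*, grand_mean)."""
    ns = rho.shape[0]
    cols = {"time_ms": np.asarray(times, dtype=float)}
    for s in range(ns):
        cols[f"subject_{s + 1}"] = rho[s]
    cols["grand_mean"] = rho.mean(axis=0)
    return pd.DataFrame(cols)
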