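"""Epoch-level cleaning: baseline removal, amplitude-based trial
rejection, zero-phase low-pass smoothing and a PCA eyeblink projector.

All operations are pure (they return a new :class:`EpochSet`) and
preserve array shape and metadata; only the validity flags change, and
only in :func:`reject_bad_trials`.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .containers import EpochSet

__all__ = [
    "baseline_correct",
    "reject_bad_trials",
    "lowpass_filter",
    "remove_eyeblinks",
    "preprocess_pipeline",
    "rejection_report",
]

log = logging.getLogger(__name__)

PTP_THRESHOLD_FT = 6000.0  # peak-to-peak rejection threshold, femtotesla
LOWPASS_CUTOFF_HZ = 30.0
BLINK_Z_THRESHOLD = 4.0


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial's per-channel pre-stimulus mean.

    The baseline window is the full pre-stimulus interval
    ``[t_start_ms, 0)``; after correction the pre-stimulus mean of every
    trial and channel is zero to machine precision.
    """
    pre = epochs.times < 0
    if not pre.any():
        raise ValueError("no pre-stimulus samples: epoch must start before 0 ms")
    baseline = epochs.data[..., pre].mean(axis=-1, keepdims=True)
    return epochs.with_data(epochs.data - baseline)


def reject_bad_trials(epochs: EpochSet, ptp_threshold: float = PTP_THRESHOLD_FT) -> EpochSet:
    """Flag trials whose worst-channel peak-to-peak range strictly exceeds the threshold.

    The comparison is strict (``>``): a trial spanning exactly the
    threshold is kept. Sample values are untouched; only validity flags
    change.
    """
    if ptp_threshold <= 0:
        raise ValueError("ptp_threshold must be > 0")
    ptp = np.ptp(epochs.data, axis=-1).max(axis=-1)  # (subject, cond, trial)
    bad = ptp > ptp_threshold
    valid = epochs.valid & ~bad
    if not valid.any():
        log.warning("all trials flagged invalid at peak-to-peak threshold %g", ptp_threshold)
    return epochs.with_data(epochs.data, valid=valid)


def lowpass_filter(epochs: EpochSet, cutoff_hz: float = LOWPASS_CUTOFF_HZ, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth low-pass along the time axis.

    Applied forward-backward (``filtfilt``) so the smoothing introduces no
    latency bias — peak latency is a headline quantity downstream.
    """
    fs = 1000.0 / epochs.step_ms  # Hz
    nyquist = fs / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return epochs.with_data(sps.sosfiltfilt(sos, epochs.data, axis=-1))


def remove_eyeblinks(
    epochs: EpochSet,
    frontal_channels: list[str] | None = None,
    z_threshold: float = BLINK_Z_THRESHOLD,
) -> EpochSet:
    """Detect blinks on the frontal channel mean and project out their first PC.

    Per trial, the mean frontal signal is robustly z-scored over time
    (median / scaled MAD, so a blink occupying a sizeable fraction of the
    epoch cannot mask itself by inflating the spread estimate); samples
    with ``|z| > z_threshold`` mark a blink. For trials with a detection,
    the first principal component (over channels) of the blink-segment
    data is projected out of all channels. Trials without a detection are
    returned numerically unchanged.
    """
    labels = frontal_channels if frontal_channels is not None else epochs.frontal_channels
    if not labels:
        raise ValueError("frontal channel subset must be non-empty")
    missing = set(labels) - set(epochs.channel_labels)
    if missing:
        raise ValueError(f"frontal channels not found in channel labels: {sorted(missing)}")
    idx_map = {c: i for i, c in enumerate(epochs.channel_labels)}
    fidx = np.array([idx_map[c] for c in labels], dtype=int)

    data = epochs.data.copy()
    n_detected = 0
    for s in range(epochs.n_subjects):
        for c in range(epochs.n_conditions):
            for t in range(epochs.n_trials):
                trial = data[s, c, t]  # (channel, time)
                frontal = trial[fidx].mean(axis=0)
                med = np.median(frontal)
                mad = np.median(np.abs(frontal - med))
                scale = 1.4826 * mad if mad > 0 else frontal.std()
                if scale == 0:
                    continue
                z = (frontal - med) / scale
                mask = np.abs(z) > z_threshold
                if not mask.any():
                    continue
                seg = trial[:, mask]  # (channel, n_blink_samples)
                seg = seg - seg.mean(axis=1, keepdims=True)
                u, sv, _ = np.linalg.svd(seg, full_matrices=False)
                pc = u[:, 0]
                data[s, c, t] = trial - np.outer(pc, pc @ trial)
                n_detected += 1
    if n_detected:
        log.info("eyeblink projector applied to %d trials", n_detected)
    return epochs.with_data(data)


def preprocess_pipeline(
    epochs: EpochSet,
    *,
    ptp_threshold: float = PTP_THRESHOLD_FT,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    blink_z_threshold: float = BLINK_Z_THRESHOLD,
    remove_blinks: bool = True,
) -> EpochSet:
    """The standard cleaning chain: baseline -> reject -> low-pass -> blinks.

    Rejection uses the raw (baseline-corrected) peak-to-peak range, so its
    outcome does not depend on whether it runs before or after baseline
    correction (a constant offset cancels in a peak-to-peak range).
    """
    out = baseline_correct(epochs)
    out = reject_bad_trials(out, ptp_threshold)
    out = lowpass_filter(out, cutoff_hz)
    if remove_blinks and out.frontal_channels:
        out = remove_eyeblinks(out, z_threshold=blink_z_threshold)
    return out


def rejection_report(epochs: EpochSet) -> dict:
    """Per-subject kept/flagged trial counts, JSON-serialisable."""
    report = {}
    for s in range(epochs.n_subjects):
        v = epochs.valid[s]
        report[f"subject_{s:03d}"] = {
            "kept": int(v.sum()),
            "flagged": int((~v).sum()),
            "total": int(v.size),
        }
    return report
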