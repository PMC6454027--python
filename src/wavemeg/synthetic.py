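"""Synthetic stimuli and MEG-like epochs with known ground truth.

Every downstream stage of the pipeline (descriptor extraction, decoding,
RSA, latency statistics) is exercised against data generated here, where
the representational geometry and its latency are injected by
construction and can therefore be recovered and checked.

Stimuli are composed of oriented sinusoidal gratings (horizontal /
vertical / diagonal stripes) whose contrasts are set by an
:class:`OrientationProfile`, plus smooth band-limited noise; this gives
direct control over the horizontal, vertical and diagonal wavelet detail
energy of each image.

Epochs carry condition-mean sensor patterns whose pairwise 1 - Pearson
geometry matches a target model RDM *exactly in rank order*: the target
RDM is turned into a correlation Gram matrix ``G = I - s * RDM`` (``s``
scaled so G stays positive semi-definite), eigen-factored, and the
resulting unit-norm condition vectors are rotated into channel space by
a seeded random orthonormal map chosen orthogonal to the constant
channel vector (so every pattern has zero mean across channels, making
1 - Pearson between patterns proportional to the injected
dissimilarity). The patterns are modulated by a smooth compact-support
Gaussian envelope centred on ``signal_peak_ms`` and buried in i.i.d.
Gaussian sensor noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, time_axis

__all__ = [
    "OrientationProfile",
    "GroundTruth",
    "SignalComponent",
    "generate_stimuli",
    "generate_epochs",
    "generate_multicomponent_epochs",
    "signal_envelope",
    "correlation_geometry_patterns",
    "inject_blinks",
]

MIN_STIMULUS_SIZE = 32


@dataclass(frozen=True)
class OrientationProfile:
    """Nonnegative weights setting the oriented edge content of one image."""

    horizontal_energy: float = 0.0
    vertical_energy: float = 0.0
    diagonal_energy: float = 0.0

    def __post_init__(self) -> None:
        w = (self.horizontal_energy, self.vertical_energy, self.diagonal_energy)
        if not all(np.isfinite(w)):
            raise ValueError("orientation weights must be finite")
        if any(x < 0 for x in w):
            raise ValueError("orientation weights must be nonnegative")
        if all(x == 0 for x in w):
            raise ValueError("at least one orientation weight must be > 0")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.horizontal_energy, self.vertical_energy, self.diagonal_energy)


@dataclass
class GroundTruth:
    """The injected representational geometry and its temporal profile.

    ``model_rdm`` drives the pairwise dissimilarity of the condition-mean
    sensor patterns; ``signal_peak_ms`` / ``signal_width_ms`` place and
    scale (FWHM, ms) the temporal envelope; ``noise_sd`` is the standard
    deviation of the additive Gaussian sensor noise (same units as the
    unit-norm signal patterns).
    """

    model_rdm: np.ndarray
    signal_peak_ms: float = 120.0
    signal_width_ms: float = 60.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.model_rdm, dtype=float).copy()
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("model_rdm must be square")
        np.fill_diagonal(r, 0.0)  # diagonal is undefined; treat as zero
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("model_rdm must be symmetric")
        if not np.isfinite(r).all() or (r < 0).any():
            raise ValueError("model_rdm must be finite and nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.signal_width_ms <= 0:
            raise ValueError("signal_width_ms must be > 0")
        self.model_rdm = r

    def to_json(self, path) -> None:
        payload = {
            "model_rdm": self.model_rdm.tolist(),
            "signal_peak_ms": self.signal_peak_ms,
            "signal_width_ms": self.signal_width_ms,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model_rdm=np.asarray(d["model_rdm"], dtype=float),
            signal_peak_ms=d["signal_peak_ms"],
            signal_width_ms=d["signal_width_ms"],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# stimulus generation
# ---------------------------------------------------------------------------

def _grating(size: int, orientation: str, cycles: float, phase: float) -> np.ndarray:
    """Unit-amplitude sinusoidal grating; orientation names the stripe axis."""
    u = np.arange(size, dtype=float) / size
    yy, xx = np.meshgrid(u, u, indexing="ij")
    if orientation == "horizontal":  # stripes run horizontally: varies down rows
        arg = yy
    elif orientation == "vertical":
        arg = xx
    elif orientation == "diagonal":
        arg = (xx + yy) / np.sqrt(2.0)
    else:  # pragma: no cover - internal
        raise ValueError(orientation)
    return np.sin(2.0 * np.pi * cycles * arg + phase)


def _smooth_noise(size: int, rng: np.random.Generator, cutoff_frac: float = 0.05) -> np.ndarray:
    """Band-limited (low-frequency) Gaussian noise field, unit max-abs."""
    spec = np.fft.rfft2(rng.standard_normal((size, size)))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    spec[np.hypot(fy, fx) > cutoff_frac] = 0.0
    field = np.fft.irfft2(spec, s=(size, size))
    m = np.abs(field).max()
    return field / m if m > 0 else field


def generate_stimuli(
    n_conditions: int,
    size: int,
    profiles: list[OrientationProfile],
    seed: int,
    *,
    noise_amplitude: float = 0.08,
) -> list[np.ndarray]:
    """Grayscale images in [0, 1] whose oriented detail energy follows the profiles.

    Each image sums three gratings (horizontal, vertical, diagonal stripes)
    with contrasts proportional to the profile weights, at per-condition
    jittered spatial frequencies, plus a low-frequency noise field; the
    result is affinely mapped into [0, 1] (an affine map leaves the ratio
    of detail-band energies unchanged).
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2")
    if size < MIN_STIMULUS_SIZE:
        raise ValueError(f"size must be >= {MIN_STIMULUS_SIZE} pixels; got {size}")
    if len(profiles) != n_conditions:
        raise ValueError("need exactly one OrientationProfile per condition")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5717]))
    images = []
    for profile in profiles:
        img = np.zeros((size, size))
        for w, orient in zip(profile.weights, ("horizontal", "vertical", "diagonal")):
            if orient == "diagonal":
                # the diagonal Haar detail atom is a 2x2 checkerboard: diagonal
                # energy must sit near that scale (axis period ~2.0-2.5 px) or
                # it lands in the H/V bands instead
                cycles = size * rng.uniform(0.57, 0.70)
            else:
                # period 4-8 px: well inside the level-1/2 detail pass-band
                cycles = size / rng.uniform(4.0, 8.0)
            img += w * _grating(size, orient, cycles, rng.uniform(0, 2 * np.pi))
        img += noise_amplitude * max(profile.weights) * _smooth_noise(size, rng)
        lo, hi = img.min(), img.max()
        images.append((img - lo) / (hi - lo) if hi > lo else np.full_like(img, 0.5))
    return images


# ---------------------------------------------------------------------------
# epoch generation
# ---------------------------------------------------------------------------

def correlation_geometry_patterns(
    model_rdm: np.ndarray, n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """Equal-norm zero-mean channel patterns realising the target geometry.

    Builds the correlation Gram matrix ``G = ones - s * RDM`` (all
    conditions share a strong common component, as evoked responses do,
    with pairwise correlation decreasing affinely in the target
    dissimilarity; ``s`` scales the largest dissimilarity to a 0.5
    correlation drop). A ridge ``eps * I`` restores positive
    semi-definiteness where needed. G is eigen-factored into condition
    vectors, which are rotated into channel space with a seeded random
    orthonormal map orthogonal to the constant channel vector (so every
    pattern has zero channel mean). The resulting 1 - Pearson
    dissimilarity between patterns a and b is
    ``(eps + s * model_rdm[a, b]) / (1 + eps)`` — strictly increasing in
    the target, hence a rank-perfect copy of it — and the squared
    pairwise distance ``2 * (eps + s * model_rdm[a, b])`` keeps a large
    relative spread, so pairwise decodability varies across pairs.
    """
    r = np.asarray(model_rdm, dtype=float).copy()
    np.fill_diagonal(r, 0.0)
    C = r.shape[0]
    rmax = r.max()
    s = 0.5 / rmax if rmax > 0 else 1.0
    gram = np.ones((C, C)) - s * r
    np.fill_diagonal(gram, 1.0)
    lam_min = np.linalg.eigvalsh(gram).min()
    if lam_min < 0:
        gram += (-lam_min + 1e-12) * np.eye(C)
    w, v = np.linalg.eigh(gram)
    coords = v * np.sqrt(np.clip(w, 0.0, None))  # (C, C)
    d = coords.shape[1]
    if n_channels <= d:
        raise ValueError(
            f"need more channels than conditions to embed patterns: {n_channels} <= {d}"
        )
    basis = rng.standard_normal((n_channels, d))
    ones = np.full(n_channels, 1.0 / np.sqrt(n_channels))
    basis -= np.outer(ones, ones @ basis)
    q, _ = np.linalg.qr(basis)
    return coords @ q[:, :d].T  # (C, n_channels)


def signal_envelope(times_ms: np.ndarray, peak_ms: float, width_ms: float) -> np.ndarray:
    """Smooth single-peaked envelope, exactly zero outside ``peak +- width``.

    A Gaussian of nominal FWHM ``width_ms`` with its value at the support
    edge subtracted and rescaled, giving unit peak, compact support and
    an effective FWHM of about 0.96 * width_ms.
    """
    sigma = width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-0.5 * ((times_ms - peak_ms) / sigma) ** 2)
    edge = np.exp(-0.5 * (width_ms / sigma) ** 2)
    return np.clip((g - edge) / (1.0 - edge), 0.0, None)


def random_orthogonal_rdms(
    n_conditions: int, n_rdms: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random symmetric RDMs whose upper triangles are mutually orthogonal.

    Gaussian upper-triangle vectors are Gram-Schmidt orthogonalised and
    shifted to be positive, so the resulting dissimilarity structures are
    mutually uncorrelated (near-zero pairwise Spearman) — useful for
    injecting several independent geometries into one recording without
    cross-talk between their RSA time-courses.
    """
    n_pairs = n_conditions * (n_conditions - 1) // 2
    if n_rdms > n_pairs:
        raise ValueError(f"at most {n_pairs} orthogonal RDMs exist for {n_conditions} conditions")
    vecs = rng.standard_normal((n_rdms, n_pairs))
    vecs -= vecs.mean(axis=1, keepdims=True)
    for i in range(n_rdms):
        for j in range(i):
            vecs[i] -= (vecs[i] @ vecs[j]) * vecs[j]
        vecs[i] /= np.linalg.norm(vecs[i])
    iu = np.triu_indices(n_conditions, k=1)
    out = []
    for v in vecs:
        r = np.zeros((n_conditions, n_conditions))
        vals = v - v.min() + 0.1 * (v.max() - v.min())
        r[iu] = vals
        r += r.T
        out.append(r)
    return out


@dataclass(frozen=True)
class SignalComponent:
    """One latency-localised representational component of a synthetic signal."""

    model_rdm: np.ndarray
    peak_ms: float
    width_ms: float = 60.0
    amplitude: float = 1.0


def generate_multicomponent_epochs(
    components: list[SignalComponent],
    *,
    noise_sd: float,
    seed: int,
    n_subjects: int,
    n_trials: int,
    n_channels: int,
    window_ms: tuple[float, float] = (-100.0, 400.0),
    step_ms: float = 1.0,
    n_frontal: int = 4,
) -> EpochSet:
    """Epochs whose signal is a sum of latency-localised geometry components.

    Each component contributes ``amplitude * envelope(t) * pattern[cond]``;
    components get independent (per-subject-rotated) channel embeddings, so
    distinct model RDMs occupy near-orthogonal channel subspaces. A single
    component reproduces the plain :func:`generate_epochs` behaviour.
    """
    if not components:
        raise ValueError("at least one signal component required")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    t0, t1 = window_ms
    times = time_axis(t0, t1, step_ms)
    n_cond = components[0].model_rdm.shape[0]
    for comp in components:
        r = np.asarray(comp.model_rdm, dtype=float)
        if r.shape != (n_cond, n_cond):
            raise ValueError("all component RDMs must share one condition count")
        rr = r.copy()
        np.fill_diagonal(rr, 0.0)
        if not np.allclose(rr, rr.T, atol=1e-10):
            raise ValueError("model_rdm must be symmetric")
        if not (t0 <= comp.peak_ms <= t1):
            raise ValueError(
                f"signal peak {comp.peak_ms} ms outside epoch window {window_ms}"
            )
    root = np.random.SeedSequence([seed, 0xE90C])
    subj_seeds = root.spawn(n_subjects)
    data = np.empty((n_subjects, n_cond, n_trials, n_channels, times.size))
    for s in range(n_subjects):
        rng = np.random.default_rng(subj_seeds[s])
        signal = np.zeros((n_cond, n_channels, times.size))
        for comp in components:
            patterns = correlation_geometry_patterns(comp.model_rdm, n_channels, rng)
            env = signal_envelope(times, comp.peak_ms, comp.width_ms)
            signal += comp.amplitude * patterns[:, :, None] * env[None, None, :]
        noise = rng.normal(0.0, noise_sd, size=(n_cond, n_trials, n_channels, times.size))
        data[s] = signal[:, None, :, :] + noise
    labels = [f"CH{i:03d}" for i in range(n_channels)]
    return EpochSet(
        data=data,
        t_start_ms=t0,
        step_ms=step_ms,
        channel_labels=labels,
        frontal_channels=labels[:n_frontal],
    )


def generate_epochs(
    truth: GroundTruth,
    n_subjects: int,
    n_conditions: int,
    n_trials: int,
    n_channels: int,
    window_ms: tuple[float, float] = (-150.0, 1000.0),
    step_ms: float = 1.0,
    **kwargs,
) -> EpochSet:
    """Epoch set carrying the single geometry described by ``truth``.

    Deterministic given ``truth.seed``; the time axis has
    ``floor((stop - start) / step) + 1`` samples, endpoints inclusive.
    """
    if truth.model_rdm.shape[0] != n_conditions:
        raise ValueError(
            f"model_rdm is {truth.model_rdm.shape[0]}x{truth.model_rdm.shape[0]} "
            f"but n_conditions={n_conditions}"
        )
    comp = SignalComponent(
        model_rdm=truth.model_rdm,
        peak_ms=truth.signal_peak_ms,
        width_ms=truth.signal_width_ms,
    )
    return generate_multicomponent_epochs(
        [comp],
        noise_sd=truth.noise_sd,
        seed=truth.seed,
        n_subjects=n_subjects,
        n_trials=n_trials,
        n_channels=n_channels,
        window_ms=window_ms,
        step_ms=step_ms,
        **kwargs,
    )


def inject_blinks(
    epochs: EpochSet,
    *,
    amplitude: float,
    rate_per_trial: float = 0.5,
    blink_width_ms: float = 80.0,
    frontal_gain: float = 1.0,
    other_gain: float = 0.05,
    seed: int = 0,
) -> tuple[EpochSet, np.ndarray]:
    """Add a rank-1 frontal-dominant blink artifact to random trials.

    The blink has a fixed spatial loading (``frontal_gain`` on the frontal
    subset, ``other_gain`` elsewhere) times a Gaussian temporal bump at a
    random latency. Returns the contaminated epochs and a boolean
    ``(subject, condition, trial)`` mask of affected trials. Used to test
    the preprocessing eyeblink projector against a known template.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB117]))
    loading = np.full(epochs.n_channels, other_gain)
    loading[epochs.frontal_indices] = frontal_gain
    loading /= np.linalg.norm(loading)
    times = epochs.times
    data = epochs.data.copy()
    hit = np.zeros(epochs.valid.shape, dtype=bool)
    sigma = blink_width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for s in range(epochs.n_subjects):
        for c in range(epochs.n_conditions):
            for t in range(epochs.n_trials):
                if rng.random() < rate_per_trial:
                    center = rng.uniform(times[0] + blink_width_ms, times[-1] - blink_width_ms)
                    bump = np.exp(-0.5 * ((times - center) / sigma) ** 2)
                    data[s, c, t] += amplitude * loading[:, None] * bump[None, :]
                    hit[s, c, t] = True
    return epochs.with_data(data), hit
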