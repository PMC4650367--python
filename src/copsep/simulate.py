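"""Synthetic maternal/fetal ECG mixtures.

The generator produces the study conditions end to end: two ECG-like
sources (a stronger, slower maternal beat train and a weaker, faster
fetal one), optional cross-source dependence imposed through an AMH or
Clayton copula, linear 2x2 mixing, per-channel normalization of the
mixtures to unit max-abs, and additive centered Gaussian noise.

ECG morphology is a phase-domain model: each beat is a sum of five
Gaussian bumps (P, Q, R, S, T) placed at fixed phases within the beat,
with seeded beat-to-beat timing jitter making the train quasi-periodic.
This is deliberately simpler than an ODE-based ECG simulator — it is
deterministic under a seed and reproduces the QRS-dominated, spiky
amplitude distribution that the separation stage exploits.

Dependence between the sources is injected by rank remapping
(Iman-Conover style): a sample is drawn from the requested copula and
the fetal samples are permuted so that the joint ranks of the pair
follow the copula's ranks.  Both marginal sample multisets are preserved
exactly; the fetal channel's temporal smoothness is partially destroyed,
which is a known limitation of this fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from copsep.copula_models import CopulaSpec, copula_sample

__all__ = [
    "ECGTemplateParams",
    "MixtureConfig",
    "MixResult",
    "maternal_preset",
    "fetal_preset",
    "synth_ecg",
    "couple_sources",
    "mix",
    "make_sources",
    "detect_beat_rate",
]

# P, Q, R, S, T bump phases (radians within a beat, R wave at pi),
# relative amplitudes and widths.  Loosely follows the standard
# phase-domain ECG parameterization used by dynamical ECG models.
_WAVE_CENTERS = np.pi + np.array([-np.pi / 3, -np.pi / 12, 0.0, np.pi / 12, np.pi / 2])
_WAVE_AMPLITUDES = np.array([0.12, -0.12, 1.0, -0.18, 0.25])
_WAVE_WIDTHS = np.array([0.25, 0.10, 0.10, 0.10, 0.40])


@dataclass
class ECGTemplateParams:
    """Phase-domain PQRST template for one quasi-periodic beat train.

    ``wave_centers``/``wave_widths`` are in radians of beat phase (one
    beat spans 2*pi, R wave at pi); ``wave_amplitudes`` are in signal
    units, and the synthesized signal is rescaled so its max-abs equals
    ``max(|wave_amplitudes|)`` — i.e. the R amplitude sets the output
    scale.  ``jitter`` is the relative standard deviation of
    beat-to-beat interval fluctuations.
    """

    beat_rate: float
    wave_amplitudes: np.ndarray = field(default_factory=lambda: _WAVE_AMPLITUDES.copy())
    wave_widths: np.ndarray = field(default_factory=lambda: _WAVE_WIDTHS.copy())
    wave_centers: np.ndarray = field(default_factory=lambda: _WAVE_CENTERS.copy())
    jitter: float = 0.02

    def __post_init__(self) -> None:
        if self.beat_rate <= 0:
            raise ValueError("beat_rate must be positive")
        if np.any(np.asarray(self.wave_widths) <= 0):
            raise ValueError("wave widths must be positive")
        if not (0.0 <= self.jitter <= 0.2):
            raise ValueError("jitter must be in [0, 0.2]")


def maternal_preset(jitter: float = 0.02) -> ECGTemplateParams:
    """Maternal ECG: ~85 bpm, R amplitude 1.0."""
    return ECGTemplateParams(beat_rate=85.0, jitter=jitter)


def fetal_preset(jitter: float = 0.02) -> ECGTemplateParams:
    """Fetal ECG: ~140 bpm, R amplitude 0.25 (weaker and faster)."""
    amps = _WAVE_AMPLITUDES * 0.25
    return ECGTemplateParams(beat_rate=140.0, wave_amplitudes=amps, jitter=jitter)


@dataclass
class MixtureConfig:
    """Generative side of the observation model x = A s + n."""

    A: np.ndarray
    noise_sigma: float = 0.1
    N: int = 2500
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("mixing matrix must be nonsingular")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        object.__setattr__(self, "A", A)


@dataclass
class MixResult:
    """Observed mixtures plus the bookkeeping metrics need.

    ``A_eff`` absorbs the per-channel normalization of the noise-free
    mixtures into the mixing matrix, so ``X_clean = A_eff @ S`` exactly
    and ``X = X_clean + noise``.  Separation quality is judged against
    ``A_eff``.
    """

    X: np.ndarray
    X_clean: np.ndarray
    A_eff: np.ndarray


def synth_ecg(params: ECGTemplateParams, N: int, fs: float, seed: int) -> np.ndarray:
    """Synthesize one ECG-like channel of ``N`` samples at ``fs`` Hz.

    Beat onsets follow intervals ``60/beat_rate * (1 + jitter * eps_k)``
    with seeded standard-normal ``eps_k``; within each beat the phase
    ramps linearly over 2*pi and the PQRST bumps are evaluated at the
    wrapped phase distance to their centers.  With ``jitter=0`` the
    signal is exactly periodic.
    """
    if fs <= 2.0 * params.beat_rate / 60.0:
        raise ValueError("sampling rate too low for the requested beat rate")
    rng = np.random.default_rng(seed)
    T_beat = 60.0 / params.beat_rate
    duration = N / fs
    n_beats = int(np.ceil(duration / T_beat)) + 3
    eps = rng.standard_normal(n_beats)
    intervals = T_beat * (1.0 + params.jitter * eps)
    intervals = np.maximum(intervals, 0.2 * T_beat)
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])

    t = np.arange(N) / fs
    k = np.searchsorted(onsets, t, side="right") - 1
    phase = 2.0 * np.pi * (t - onsets[k]) / intervals[k]

    x = np.zeros(N)
    for a, c, w in zip(params.wave_amplitudes, params.wave_centers, params.wave_widths):
        d = np.angle(np.exp(1j * (phase - c)))  # wrapped phase distance
        x += a * np.exp(-0.5 * (d / w) ** 2)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= np.max(np.abs(params.wave_amplitudes)) / peak
    return x


def couple_sources(
    s1: np.ndarray, s2: np.ndarray, spec: CopulaSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Impose a copula on the joint ranks of two signals by permuting s2.

    Draws ``N`` pairs from ``spec`` and reorders the samples of ``s2``
    so that the joint ranks of ``(s1, s2')`` follow the copula sample's
    ranks.  ``s1`` is returned unchanged; ``s2'`` is an exact
    permutation of ``s2`` (marginals preserved).
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sources must be equal-length 1-D signals")
    n = s1.size
    uv = copula_sample(spec, n, seed)
    order_u = np.argsort(uv[:, 0], kind="stable")
    v_rank = np.empty(n, dtype=int)
    v_rank[np.argsort(uv[:, 1], kind="stable")] = np.arange(n)
    s2_sorted = np.sort(s2)
    out = np.empty(n)
    idx1 = np.argsort(s1, kind="stable")
    # the k-th smallest s1 sample gets the s2 value whose rank matches
    # the v-rank paired with the k-th smallest u
    out[idx1] = s2_sorted[v_rank[order_u]]
    return s1.copy(), out


def mix(S: np.ndarray, cfg: MixtureConfig) -> MixResult:
    """Mix sources, normalize each mixture to unit max-abs, add noise.

    Normalization happens before noise addition, so the noise standard
    deviation is on the normalized-mixture scale.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != cfg.A.shape[0]:
        raise ValueError("S must be p x N with p matching the mixing matrix")
    M = cfg.A @ S
    peaks = np.max(np.abs(M), axis=1, keepdims=True)
    if np.any(peaks == 0):
        raise ValueError("a mixture channel is identically zero")
    X_clean = M / peaks
    A_eff = cfg.A / peaks
    rng = np.random.default_rng(cfg.seed)
    noise = cfg.noise_sigma * rng.standard_normal(X_clean.shape)
    return MixResult(X=X_clean + noise, X_clean=X_clean, A_eff=A_eff)


def make_sources(
    case: str,
    N: int = 2500,
    fs: float = 250.0,
    seed: int = 0,
    theta: float | None = None,
    jitter: float = 0.02,
) -> np.ndarray:
    """Build the 2 x N source matrix for a named experimental case.

    ``case`` is ``"independent"``, ``"amh"`` (default theta 0.4) or
    ``"clayton"`` (default theta 0.5).  Row 0 is maternal, row 1 fetal.
    """
    s_m = synth_ecg(maternal_preset(jitter), N, fs, seed=seed * 2 + 1)
    s_f = synth_ecg(fetal_preset(jitter), N, fs, seed=seed * 2 + 2)
    if case == "independent":
        return np.vstack([s_m, s_f])
    if case == "amh":
        spec = CopulaSpec("amh", 0.4 if theta is None else theta)
    elif case == "clayton":
        spec = CopulaSpec("clayton", 0.5 if theta is None else theta)
    else:
        raise ValueError(f"unknown case {case!r}")
    s_m, s_f = couple_sources(s_m, s_f, spec, seed=seed * 2 + 3)
    return np.vstack([s_m, s_f])


def detect_beat_rate(
    x: np.ndarray, fs: float, min_bpm: float = 40.0, max_bpm: float = 220.0
) -> float:
    """Dominant beat rate (bpm) from the autocorrelation peak lag.

    Searches lags corresponding to ``[min_bpm, max_bpm]`` and refines
    the peak by parabolic interpolation.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    lo = max(int(fs * 60.0 / max_bpm), 1)
    hi = min(int(fs * 60.0 / min_bpm), n - 2)
    if hi <= lo:
        raise ValueError("signal too short for the requested bpm range")
    k = lo + int(np.argmax(ac[lo : hi + 1]))
    # parabolic refinement around the peak
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    lag = k + float(np.clip(delta, -0.5, 0.5))
    return 60.0 * fs / lag
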