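"""Formant-specified stimulus synthesis and pitch-period shuffling.

Targets are an 11-step [ga]-to-[da] consonant-vowel continuum whose
steps differ only in the third-formant (F3) onset, rising in 100 Hz
increments from 1800 to 2800 Hz and gliding linearly to a 2500 Hz
steady state.  Contexts are 375 ms [al]/[aɹ]-like syllables (or tone
analogs at the liquid's F3 offset: about 2600 Hz for [al], 1820 Hz for
[aɹ]).  "Simulated speech" variants are made by cutting 11 pitch
periods out of the vowel portion of a context and resorting them over
the same span of time, which preserves duration, intensity, the sample
multiset, and the formant offsets while destroying fine-grained
sequence.

Synthesis uses impulse-train excitation through cascaded second-order
resonators (one per formant) with linearly interpolated center
frequencies -- the simplest source-filter architecture that yields
genuine pitch periods for the shuffling procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import Waveform

__all__ = [
    "ContinuumSpec",
    "ContextSpec",
    "ShufflePlan",
    "synthesize_continuum",
    "synthesize_context",
    "plan_shuffle",
    "shuffle_resynthesize",
    "assemble_trial_audio",
]

F3_OFFSET_BY_PRECURSOR = {"al": 2600.0, "ar": 1820.0}

# vowel [a] formants used for the speech-like context (Hz)
_VOWEL_FORMANTS = (750.0, 1200.0, 2500.0, 3500.0)
_FORMANT_BANDWIDTHS = (90.0, 110.0, 170.0, 250.0)


@dataclass
class ContinuumSpec:
    """The 11-step [ga]-to-[da] target continuum."""

    n_steps: int = 11
    f3_onset_start: float = 1800.0
    f3_onset_step: float = 100.0
    f3_offset: float = 2500.0
    f1: tuple = (500.0, 800.0)
    f2: tuple = (1600.0, 1200.0)
    f4: float = 3500.0
    duration: float = 0.215
    rate: int = 22050
    f0: float = 100.0

    def f3_onset(self, step: int) -> float:
        if not 0 <= step < self.n_steps:
            raise ValueError(f"step {step} outside 0..{self.n_steps - 1}")
        return self.f3_onset_start + self.f3_onset_step * step


@dataclass
class ContextSpec:
    """A 375-ms context stimulus: speech-like, tone, or simulated speech."""

    kind: str = "real_speech_like"
    precursor: str = "al"
    duration: float = 0.375
    rate: int = 22050
    f0: float = 100.0
    vowel_fraction: float = 0.6  # vowel [a] portion preceding the liquid

    def __post_init__(self) -> None:
        if self.kind not in ("real_speech_like", "tone", "simulated_speech"):
            raise ValueError(f"unknown context kind: {self.kind}")
        if self.precursor not in F3_OFFSET_BY_PRECURSOR:
            raise ValueError(f"precursor must be 'al' or 'ar', got {self.precursor}")

    @property
    def f3_offset(self) -> float:
        return F3_OFFSET_BY_PRECURSOR[self.precursor]

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.rate)

    @property
    def vowel_region(self) -> tuple:
        """Sample interval (start, end) of the [a] portion."""
        return (0, int(self.n_samples * self.vowel_fraction))


@dataclass
class ShufflePlan:
    """Segment boundaries and the permutations defining shuffle variants."""

    segment_boundaries: np.ndarray  # 12 strictly increasing sample indices
    permutations: list  # 8 distinct non-identity permutations of 0..10
    seed: int = 0

    def __post_init__(self) -> None:
        self.segment_boundaries = np.asarray(self.segment_boundaries, dtype=np.int64)
        if np.any(np.diff(self.segment_boundaries) <= 0):
            raise ValueError("segment boundaries must be strictly increasing")
        n_seg = self.segment_boundaries.size - 1
        identity = tuple(range(n_seg))
        seen = set()
        for perm in self.permutations:
            tp = tuple(perm)
            if sorted(tp) != list(identity):
                raise ValueError("each permutation must reorder 0..n_segments-1")
            if tp == identity:
                raise ValueError("identity permutation not allowed among variants")
            if tp in seen:
                raise ValueError("permutations must be distinct")
            seen.add(tp)

    @property
    def n_segments(self) -> int:
        return self.segment_boundaries.size - 1


def _resonator(x: np.ndarray, freqs: np.ndarray, bandwidth: float, rate: int) -> np.ndarray:
    """Time-varying two-pole resonator (Klatt-style coefficients)."""
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2.0 * np.pi * freqs / rate
    b = 2.0 * r * np.cos(theta)
    c = -r * r
    a = 1.0 - b - c  # unity gain at DC
    y = np.empty_like(x)
    y1 = 0.0
    y2 = 0.0
    for n in range(x.size):
        yn = a[n] * x[n] + b[n] * y1 + c * y2
        y2 = y1
        y1 = yn
        y[n] = yn
    return y


def _impulse_train(n: int, rate: int, f0: float) -> np.ndarray:
    src = np.zeros(n)
    positions = np.round(np.arange(0.0, n, rate / f0)).astype(np.int64)
    src[positions[positions < n]] = 1.0
    return src


def _source_filter(tracks: list, bandwidths, n: int, rate: int, f0: float) -> np.ndarray:
    y = _impulse_train(n, rate, f0)
    for track, bw in zip(tracks, bandwidths):
        y = _resonator(y, track, bw, rate)
    return y


def _set_rms(x: np.ndarray, target: float = 0.1) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return x
    return x * (target / rms)


def synthesize_continuum(spec: ContinuumSpec | None = None) -> list:
    """Synthesize the 11 CV targets, identical except in F3 onset."""
    spec = spec or ContinuumSpec()
    highest = max(spec.f4, spec.f3_onset(spec.n_steps - 1), spec.f3_offset)
    if spec.rate < 4 * highest:
        raise ValueError("sampling rate too low for the requested formants (aliasing)")
    n = round(spec.duration * spec.rate)
    out = []
    for step in range(spec.n_steps):
        tracks = [
            np.linspace(spec.f1[0], spec.f1[1], n),
            np.linspace(spec.f2[0], spec.f2[1], n),
            np.linspace(spec.f3_onset(step), spec.f3_offset, n),
            np.full(n, spec.f4),
        ]
        y = _source_filter(tracks, _FORMANT_BANDWIDTHS, n, spec.rate, spec.f0)
        out.append(Waveform(_set_rms(y), spec.rate, label=f"target_step{step:02d}"))
    return out


def synthesize_context(spec: ContextSpec) -> Waveform:
    """Synthesize one context stimulus (tone or speech-like)."""
    n = spec.n_samples
    label = f"ctx_{spec.kind}_{spec.precursor}"
    if spec.kind == "tone":
        t = np.arange(n) / spec.rate
        y = np.sin(2.0 * np.pi * spec.f3_offset * t)
        return Waveform(_set_rms(y), spec.rate, label=label)

    # speech-like: steady vowel [a], then a liquid whose F3 glides to the offset
    v_end = spec.vowel_region[1]
    f1v, f2v, f3v, f4v = _VOWEL_FORMANTS
    liquid_len = n - v_end
    f1 = np.concatenate([np.full(v_end, f1v), np.linspace(f1v, 420.0, liquid_len)])
    f2 = np.concatenate([np.full(v_end, f2v), np.linspace(f2v, 1100.0, liquid_len)])
    f3 = np.concatenate([np.full(v_end, f3v), np.linspace(f3v, spec.f3_offset, liquid_len)])
    f4 = np.full(n, f4v)
    y = _source_filter([f1, f2, f3, f4], _FORMANT_BANDWIDTHS, n, spec.rate, spec.f0)
    return Waveform(_set_rms(y), spec.rate, label=label)


def _estimate_period(x: np.ndarray, rate: int) -> int:
    """Pitch period in samples from the autocorrelation peak (50-400 Hz)."""
    lo = max(2, rate // 400)
    hi = min(x.size // 2, rate // 50)
    if hi <= lo:
        raise ValueError("region too short for period estimation")
    x0 = x - x.mean()
    denom = float(np.dot(x0, x0))
    if denom == 0:
        raise ValueError("aperiodic region (silent)")
    ac = np.array([np.dot(x0[:-lag], x0[lag:]) / denom for lag in range(lo, hi)])
    best = int(np.argmax(ac))
    if ac[best] < 0.3:
        raise ValueError("aperiodic region (no consistent periodicity)")
    return lo + best


def plan_shuffle(
    w: Waveform,
    region: tuple,
    n_segments: int = 11,
    n_variants: int = 8,
    seed: int = 0,
) -> ShufflePlan:
    """Locate pitch-period boundaries and draw the shuffle permutations.

    Boundaries are positive-going zero crossings nearest integer
    multiples of the estimated pitch period inside ``region``; the
    permutations are ``n_variants`` distinct non-identity permutations
    of 0..n_segments-1, drawn uniformly without replacement.
    """
    start, end = region
    x = w.samples[start:end]
    period = _estimate_period(x, w.rate)
    if end - start < (n_segments + 1) * period:
        raise ValueError(
            f"region of {end - start} samples cannot hold {n_segments} "
            f"periods of {period} samples"
        )
    rising = np.flatnonzero((x[:-1] <= 0) & (x[1:] > 0))
    if rising.size < n_segments + 1:
        raise ValueError("aperiodic region (no consistent zero crossings)")

    boundaries = []
    for k in range(n_segments + 1):
        target = k * period
        boundaries.append(start + int(rising[np.argmin(np.abs(rising - target))]))
    boundaries = np.asarray(boundaries, dtype=np.int64)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("could not place strictly increasing period boundaries")

    rng = np.random.default_rng(seed)
    identity = tuple(range(n_segments))
    chosen: list = []
    seen = set()
    while len(chosen) < n_variants:
        perm = tuple(rng.permutation(n_segments).tolist())
        if perm == identity or perm in seen:
            continue
        seen.add(perm)
        chosen.append(perm)
    return ShufflePlan(segment_boundaries=boundaries, permutations=chosen, seed=seed)


def shuffle_resynthesize(w: Waveform, plan: ShufflePlan) -> list:
    """Apply each planned permutation to the pitch-period segments.

    Within the shuffled span the output's sample multiset equals the
    original's; all samples outside the span are bit-identical.
    """
    b = plan.segment_boundaries
    if b[-1] > len(w):
        raise ValueError("shuffle plan extends past the waveform")
    segments = [w.samples[b[i]: b[i + 1]] for i in range(plan.n_segments)]
    out = []
    for v, perm in enumerate(plan.permutations):
        samples = w.samples.copy()
        samples[b[0]: b[-1]] = np.concatenate([segments[i] for i in perm])
        out.append(Waveform(samples, w.rate, label=f"{w.label}_ss{v + 1}"))
    return out


def assemble_trial_audio(context: Waveform, target: Waveform) -> Waveform:
    """Context, 50 ms of silence, then target."""
    if context.rate != target.rate:
        raise ValueError("context and target sampling rates differ")
    gap = np.zeros(round(0.050 * context.rate))
    samples = np.concatenate([context.samples, gap, target.samples])
    return Waveform(samples, context.rate, label=f"{context.label}+{target.label}")
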