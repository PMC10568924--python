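"""Seeded generators for ultrasonic audio with ground truth and for
cohort-structured behavioural tables.

Audio
-----
The background is Gaussian noise shaped in the frequency domain so that
amplitude falls off as ``f**-alpha`` (default ``alpha = 1``, a pink-like
tilt typical of ultrasonic recording noise floors).  Calls are
phase-continuous FM tones with raised-cosine on/off ramps: *flat* (constant
carrier), *sweep* (linear chirp) and *trill* (sinusoidal FM) in the
35-68 kHz range for the 50-kHz class, and *long22* (long narrowband calls
at 18-26 kHz) for the 22-kHz class.  Per-call SNR is defined in-band:
RMS of the call divided by the RMS of the background restricted to the
call class's detection band, in dB.

Tables
------
Received pinnings are Poisson with a log-link linear predictor over
treatment and batch; rats whose play partner cannot pin them (the
kinematically reduced group) receive exactly zero.  Per-session 50-kHz
counts follow a Gaussian linear mixed model with rat and litter random
intercepts and day/order covariates, floored at zero and rounded;
22-kHz counts follow a log-link Poisson analogue with rat and litter
random intercepts on the latent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import TruthAnnotation
from .spectral import AudioRecording, DEFAULT_FS

__all__ = [
    "CallSpec",
    "RecordingPlan",
    "CohortDesign",
    "GenerativeParams",
    "synth_call_waveform",
    "synth_noise",
    "synth_recording",
    "default_benchmark_plan",
    "simulate_play_bouts",
    "simulate_usv_counts",
    "make_contact_schedule",
]

CLASS_BANDS = {"usv50": (35_000.0, 68_000.0), "usv22": (18_000.0, 26_000.0)}
CALL_CLASS_OF_TYPE = {"flat": "usv50", "sweep": "usv50", "trill": "usv50", "long22": "usv22"}


@dataclass(frozen=True)
class CallSpec:
    """One synthetic call.

    ``jitter_hz`` is the SD of a slow (~1 ms correlation time) random
    walk added to the instantaneous frequency.  Real calls — including
    the nominally "flat" ones — have an instantaneous bandwidth of a few
    hundred Hz from cycle-to-cycle phonation jitter; a mathematically
    pure tone is narrower than one analysis band and is not a realistic
    stand-in.  Zero by default so the deterministic closed-form examples
    (dominant band of a tone, etc.) hold exactly.
    """

    call_type: str  # flat | sweep | trill | long22
    f0: float
    duration_s: float
    amplitude: float
    onset_s: float = 0.0
    sweep_rate: float = 0.0  # Hz/s, sweep only
    fm_depth: float = 0.0  # Hz, trill only
    fm_rate: float = 0.0  # Hz, trill only
    jitter_hz: float = 0.0  # SD of frequency jitter
    jitter_seed: int = 0

    def __post_init__(self):
        if self.call_type not in CALL_CLASS_OF_TYPE:
            raise ValueError(f"unknown call_type {self.call_type!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        lo, hi = CLASS_BANDS[self.call_class]
        fmin, fmax = self.freq_range
        if fmin < lo - 1e-6 or fmax > hi + 1e-6:
            raise ValueError(
                f"instantaneous frequency [{fmin:.0f}, {fmax:.0f}] Hz outside "
                f"the {self.call_class} band [{lo:.0f}, {hi:.0f}] Hz"
            )

    @property
    def call_class(self) -> str:
        return CALL_CLASS_OF_TYPE[self.call_type]

    @property
    def freq_range(self) -> tuple[float, float]:
        if self.call_type == "sweep":
            f1 = self.f0 + self.sweep_rate * self.duration_s
            return min(self.f0, f1), max(self.f0, f1)
        if self.call_type == "trill":
            return self.f0 - self.fm_depth, self.f0 + self.fm_depth
        return self.f0, self.f0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class RecordingPlan:
    duration_s: float
    fs: float = DEFAULT_FS
    noise_sigma: float = 0.01
    noise_tilt_alpha: float = 1.0
    calls: tuple[CallSpec, ...] = ()
    seed: int = 0
    min_gap_s: float = 0.01

    def __post_init__(self):
        for c in self.calls:
            if c.onset_s < 0 or c.offset_s > self.duration_s:
                raise ValueError(f"call at {c.onset_s}s does not fit the recording")
        ordered = sorted(self.calls, key=lambda c: c.onset_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.onset_s < a.offset_s + self.min_gap_s:
                raise ValueError(
                    f"call collision: onsets {a.onset_s:.3f}s and {b.onset_s:.3f}s"
                )


def synth_call_waveform(spec: CallSpec, fs: float) -> np.ndarray:
    """Phase-continuous FM tone with raised-cosine ramps (>= 2 ms each,
    shortened to a quarter of the call for very short calls)."""
    fmax = spec.freq_range[1]
    if fs <= 2 * fmax:
        raise ValueError(f"aliasing risk: fs={fs} too low for {fmax} Hz")
    n = max(int(round(spec.duration_s * fs)), 1)
    t = np.arange(n) / fs
    if spec.call_type == "sweep":
        f_inst = spec.f0 + spec.sweep_rate * t
    elif spec.call_type == "trill":
        f_inst = spec.f0 + spec.fm_depth * np.sin(2 * np.pi * spec.fm_rate * t)
    else:
        f_inst = np.full(n, spec.f0)
    if spec.jitter_hz > 0:
        jrng = np.random.default_rng(spec.jitter_seed)
        w = jrng.standard_normal(n)
        m = max(int(round(0.001 * fs)), 1)  # ~1 ms correlation time
        w = np.convolve(w, np.ones(m) / m, mode="same")
        f_inst = f_inst + spec.jitter_hz * w / w.std()
        lo, hi = CLASS_BANDS[spec.call_class]
        f_inst = np.clip(f_inst, lo, hi)  # keep within the class band
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    x = np.sin(phase)
    ramp_n = min(int(round(0.002 * fs)), n // 4)
    if ramp_n > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        x[:ramp_n] *= r
        x[-ramp_n:] *= r[::-1]
    return spec.amplitude * x


#: tilt reference: the f**-alpha amplitude roll-off flattens below this
#: frequency so the spectral shape (and hence the in-band noise share) is
#: independent of recording length.
NOISE_TILT_FLOOR_HZ = 1000.0


def synth_noise(n: int, fs: float, sigma: float, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with amplitude spectrum shaped as ``f**-alpha``
    (flat below :data:`NOISE_TILT_FLOOR_HZ`), scaled to overall RMS
    ``sigma``."""
    w = rng.standard_normal(n)
    if alpha == 0.0:
        return sigma * w / w.std()
    F = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = (np.maximum(f, NOISE_TILT_FLOOR_HZ) / NOISE_TILT_FLOOR_HZ) ** (-alpha)
    x = np.fft.irfft(F * shape, n)
    return sigma * x / x.std()


def band_rms(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """RMS of ``x`` restricted to the band [lo, hi] Hz (FFT masking)."""
    F = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    F = np.where((f >= lo) & (f <= hi), F, 0.0)
    y = np.fft.irfft(F, x.size)
    return float(np.sqrt(np.mean(y**2)))


def synth_recording(plan: RecordingPlan) -> tuple[AudioRecording, list[TruthAnnotation]]:
    """Render a plan to audio plus exact ground-truth annotations.

    Deterministic for a fixed plan (the seed drives the noise).  Each
    annotation carries the realized in-band SNR: call RMS over its active
    interval divided by the RMS of the background noise restricted to the
    call class's detection band.
    """
    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration_s * plan.fs))
    x = synth_noise(n, plan.fs, plan.noise_sigma, plan.noise_tilt_alpha, rng)
    noise_band_rms = {
        cls: band_rms(x, plan.fs, lo, hi) for cls, (lo, hi) in CLASS_BANDS.items()
    }
    truth: list[TruthAnnotation] = []
    for spec in sorted(plan.calls, key=lambda c: c.onset_s):
        wave = synth_call_waveform(spec, plan.fs)
        i0 = int(round(spec.onset_s * plan.fs))
        i1 = min(i0 + wave.size, n)
        x[i0:i1] += wave[: i1 - i0]
        call_rms = float(np.sqrt(np.mean(wave**2)))
        nref = noise_band_rms[spec.call_class]
        snr_db = 20.0 * np.log10(call_rms / nref) if nref > 0 else np.inf
        truth.append(
            TruthAnnotation(
                onset_s=spec.onset_s,
                offset_s=spec.offset_s,
                call_class=spec.call_class,
                call_type=spec.call_type,
                snr_db=snr_db,
            )
        )
    return AudioRecording(x, plan.fs, id=f"synth-{plan.seed}"), truth


# ---------------------------------------------------------------------------
# Benchmark plan

#: default call-type mix for 50-kHz plans
CALL_TYPE_MIX = (("flat", 0.4), ("sweep", 0.3), ("trill", 0.3))


def _draw_call(rng: np.random.Generator, call_class: str, onset: float, amplitude: float) -> CallSpec:
    jit = dict(
        jitter_hz=rng.uniform(250.0, 600.0),
        jitter_seed=int(rng.integers(0, 2**31 - 1)),
    )
    if call_class == "usv22":
        dur = rng.uniform(0.3, 2.0)
        f0 = rng.uniform(19_000, 25_000)
        return CallSpec("long22", f0=f0, duration_s=dur, amplitude=amplitude,
                        onset_s=onset, **jit)
    types, probs = zip(*CALL_TYPE_MIX)
    ct = rng.choice(types, p=probs)
    dur = rng.uniform(0.015, 0.120)
    if ct == "flat":
        return CallSpec("flat", f0=rng.uniform(38_000, 65_000), duration_s=dur,
                        amplitude=amplitude, onset_s=onset, **jit)
    if ct == "sweep":
        f0 = rng.uniform(38_000, 55_000)
        rate = rng.uniform(20_000, 120_000)  # Hz/s upward
        rate = min(rate, (66_000 - f0) / dur)
        return CallSpec("sweep", f0=f0, sweep_rate=rate, duration_s=dur,
                        amplitude=amplitude, onset_s=onset, **jit)
    f0 = rng.uniform(45_000, 58_000)
    depth = rng.uniform(2_000, 6_000)
    return CallSpec("trill", f0=f0, fm_depth=depth, fm_rate=rng.uniform(40, 90),
                    duration_s=dur, amplitude=amplitude, onset_s=onset, **jit)


def default_benchmark_plan(
    seed: int = 1,
    n_calls: int = 200,
    snr_db_range: tuple[float, float] = (15.0, 30.0),
    call_class: str = "usv50",
    noise_sigma: float = 0.01,
    noise_tilt_alpha: float = 1.0,
    min_gap_s: float = 0.08,
    fs: float = DEFAULT_FS,
) -> RecordingPlan:
    """The standard detector benchmark: ``n_calls`` calls of mixed type at
    in-band SNR drawn from ``snr_db_range`` over tilted noise.

    The recording is sized so calls plus gaps fit comfortably; amplitudes
    are set from the in-band RMS of a reference noise realisation so the
    realized SNR matches the target closely (a tone's RMS is amp/sqrt(2)).
    The default minimum inter-call gap (80 ms) exceeds the detector's
    40 ms grouping window plus the analysis-window smearing on each side:
    calls closer than that are merged into one detection by construction
    of the algorithm, which is a resolution limit of the method, not a
    detection failure, and is tested separately.
    """
    rng = np.random.default_rng(seed)
    # expected in-band noise RMS for the f^-alpha shape, from the PSD integral
    lo, hi = CLASS_BANDS[call_class]
    probe = synth_noise(2**18, fs, noise_sigma, noise_tilt_alpha, np.random.default_rng(12345))
    rms_band = band_rms(probe, fs, lo, hi)

    # place calls sequentially with random gaps
    calls: list[CallSpec] = []
    t = 0.25
    for _ in range(n_calls):
        snr = rng.uniform(*snr_db_range)
        amp = np.sqrt(2.0) * rms_band * 10 ** (snr / 20.0)
        t += rng.uniform(min_gap_s, 5 * min_gap_s)
        c = _draw_call(rng, call_class, onset=t, amplitude=amp)
        calls.append(c)
        t = c.offset_s
    duration = t + 0.25
    return RecordingPlan(
        duration_s=float(np.ceil(duration * 2) / 2),
        fs=fs,
        noise_sigma=noise_sigma,
        noise_tilt_alpha=noise_tilt_alpha,
        calls=tuple(calls),
        seed=seed,
        min_gap_s=min_gap_s * 0.99,
    )


# ---------------------------------------------------------------------------
# Cohort tables

TREATMENTS = ("control", "kinematic_reduced", "social_reduced")


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: three batches of rats from several litters, each rat
    with a fixed treatment, litter, batch and tickling-order position,
    tested daily.

    Defaults mirror the study: batches A (17 rats, 10 days), B (18, 7)
    and C (18, 10) — 53 rats, 476 sessions — with four litters per batch
    and treatments balanced within batch.
    """

    batch_sizes: tuple[tuple[str, int], ...] = (("A", 17), ("B", 18), ("C", 18))
    days_per_batch: tuple[tuple[str, int], ...] = (("A", 10), ("B", 7), ("C", 10))
    litters_per_batch: int = 4
    seed: int = 0

    def rats(self) -> pd.DataFrame:
        """One row per rat: rat_id, litter_id, treatment, batch, order."""
        rng = np.random.default_rng(self.seed)
        rows = []
        for batch, n in self.batch_sizes:
            treatments = [TREATMENTS[i % 3] for i in range(n)]
            rng.shuffle(treatments)
            order = rng.permutation(n) + 1  # tickling order within batch
            for i in range(n):
                rows.append(
                    dict(
                        rat_id=f"{batch}R{i + 1:02d}",
                        litter_id=f"{batch}L{i % self.litters_per_batch + 1}",
                        treatment=treatments[i],
                        batch=batch,
                        order=int(order[i]),
                    )
                )
        return pd.DataFrame(rows)

    def sessions(self) -> pd.DataFrame:
        """One row per rat x day."""
        rats = self.rats()
        days = dict(self.days_per_batch)
        out = []
        for _, r in rats.iterrows():
            for day in range(1, days[r.batch] + 1):
                rec = r.to_dict()
                rec["day"] = day
                rec["session_id"] = f"{r.rat_id}-d{day:02d}"
                out.append(rec)
        return pd.DataFrame(out)


@dataclass(frozen=True)
class GenerativeParams:
    """Generating coefficients for the behavioural tables.

    Defaults are the study-scale values: pinning GLM on the log scale
    (intercept 3.20 for control/batch A, social-reduction -0.45, batch C
    -0.82); 50-kHz Gaussian LMM (intercept 136.27, day slope 3.09, order
    slope 4.31, treatment/batch shifts as fitted) with variance components
    chosen to give rat repeatability ~0.52 and litter repeatability ~0.14;
    22-kHz log-link Poisson analogue (intercept -0.72, day 0.17, batch B
    2.13, batch C -0.01) with latent rat/litter intercepts.
    """

    # received-pinning Poisson GLM (log link); reference control / batch A
    pin_intercept: float = 3.20
    pin_social: float = -0.45
    pin_batch: tuple[tuple[str, float], ...] = (("A", 0.0), ("C", -0.82))
    pin_delivered_shift: float = 0.35  # log-scale asymmetry for social_reduced

    # 50-kHz Gaussian LMM
    usv_intercept: float = 136.27
    usv_social: float = -33.35
    usv_kinematic: float = -8.59
    usv_day: float = 3.09
    usv_order: float = 4.31
    usv_batch: tuple[tuple[str, float], ...] = (("A", 0.0), ("B", -25.56), ("C", -23.58))
    sd_rat: float = 51.6
    sd_litter: float = 26.5
    sd_resid: float = 42.0

    # 22-kHz Poisson analogue (log link, latent random intercepts)
    usv22_intercept: float = -0.72
    usv22_day: float = 0.17
    usv22_batch: tuple[tuple[str, float], ...] = (("A", 0.0), ("B", 2.13), ("C", -0.01))
    # latent-scale SDs calibrated so that, with the distribution-specific
    # variance ln(1 + 1/lambda_bar) =~ 0.37 implied by the fixed effects,
    # rat repeatability =~ 0.38 and litter repeatability =~ 0.02
    sd_rat_22: float = 0.48
    sd_litter_22: float = 0.10

    def __post_init__(self):
        for s in (self.sd_rat, self.sd_litter, self.sd_resid, self.sd_rat_22, self.sd_litter_22):
            if s < 0:
                raise ValueError("sd components must be >= 0")

    @property
    def true_repeatability_rat(self) -> float:
        v = self.sd_rat**2 + self.sd_litter**2 + self.sd_resid**2
        return self.sd_rat**2 / v

    @property
    def true_repeatability_litter(self) -> float:
        v = self.sd_rat**2 + self.sd_litter**2 + self.sd_resid**2
        return self.sd_litter**2 / v


def simulate_play_bouts(
    design: CohortDesign,
    params: GenerativeParams | None = None,
    seed: int | None = None,
    batches: tuple[str, ...] = ("A", "C"),
) -> pd.DataFrame:
    """Per-rat pinning counts over the play observation block.

    Received pinnings are Poisson with mean ``exp(intercept + treatment +
    batch)``; kinematically reduced rats receive exactly 0 (their low
    ceiling precludes pinning).  Delivered pinnings use the same predictor
    plus a positive shift for socially reduced rats, whose less playful
    partners rarely pin back.
    """
    if params is None:
        params = GenerativeParams()
    rats = design.rats()
    rats = rats[rats.batch.isin(batches)].reset_index(drop=True)
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    pin_batch = dict(params.pin_batch)
    rows = []
    for _, r in rats.iterrows():
        eta = params.pin_intercept + pin_batch.get(r.batch, 0.0)
        if r.treatment == "social_reduced":
            eta += params.pin_social
        if r.treatment == "kinematic_reduced":
            received = 0
        else:
            received = int(rng.poisson(np.exp(eta)))
        eta_d = params.pin_intercept + pin_batch.get(r.batch, 0.0)
        if r.treatment == "social_reduced":
            eta_d += params.pin_delivered_shift
        delivered = int(rng.poisson(np.exp(eta_d)))
        rows.append(
            dict(
                rat_id=r.rat_id,
                litter_id=r.litter_id,
                treatment=r.treatment,
                batch=r.batch,
                pinnings_delivered=delivered,
                pinnings_received=received,
            )
        )
    return pd.DataFrame(rows)


def simulate_usv_counts(
    design: CohortDesign,
    params: GenerativeParams | None = None,
    seed: int | None = None,
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """Per-session 50-kHz and 22-kHz call counts with cohort covariates.

    50-kHz: Gaussian linear predictor + rat/litter Normal intercepts +
    Normal residual, floored at 0 and rounded (``floor_at_zero=False``
    yields the exact Gaussian model, useful for estimator validation).
    22-kHz: Poisson with log-link predictor + latent rat/litter intercepts.
    """
    if params is None:
        params = GenerativeParams()
    rng = np.random.default_rng(design.seed + 2 if seed is None else seed)
    sess = design.sessions()
    usv_batch = dict(params.usv_batch)
    usv22_batch = dict(params.usv22_batch)

    rats = sess.rat_id.unique()
    litters = sess.litter_id.unique()
    rat_b = dict(zip(rats, rng.normal(0, params.sd_rat, rats.size)))
    lit_b = dict(zip(litters, rng.normal(0, params.sd_litter, litters.size)))
    rat_b22 = dict(zip(rats, rng.normal(0, params.sd_rat_22, rats.size)))
    lit_b22 = dict(zip(litters, rng.normal(0, params.sd_litter_22, litters.size)))

    treat_eff = {"control": 0.0, "social_reduced": params.usv_social,
                 "kinematic_reduced": params.usv_kinematic}

    mu = (
        params.usv_intercept
        + sess.treatment.map(treat_eff).to_numpy()
        + sess.batch.map(usv_batch).to_numpy()
        + params.usv_day * sess.day.to_numpy()
        + params.usv_order * sess.order.to_numpy()
        + sess.rat_id.map(rat_b).to_numpy()
        + sess.litter_id.map(lit_b).to_numpy()
    )
    y = mu + rng.normal(0, params.sd_resid, len(sess))
    if floor_at_zero:
        n50 = np.round(np.maximum(y, 0.0)).astype(int)
    else:
        n50 = y

    eta22 = (
        params.usv22_intercept
        + params.usv22_day * sess.day.to_numpy()
        + sess.batch.map(usv22_batch).to_numpy()
        + sess.rat_id.map(rat_b22).to_numpy()
        + sess.litter_id.map(lit_b22).to_numpy()
    )
    n22 = rng.poisson(np.exp(eta22))

    out = sess.copy()
    out["n50"] = n50
    out["n22"] = n22
    return out


def make_contact_schedule(
    session_duration_s: float,
    block_s: float = 15.0,
    ventral_fraction: float = 0.5,
) -> pd.DataFrame:
    """Alternating hover / tickle schedule tiling the session.

    Blocks alternate ``none`` (hand hovering) and tickle; each tickle block
    is split into a dorsal then a ventral sub-period (default 50/50).
    Returns a frame with columns period_type, start_s, end_s.
    """
    if session_duration_s < 2 * block_s:
        raise ValueError(f"session must be at least {2 * block_s} s")
    rows = []
    t = 0.0
    tickle = False
    while t < session_duration_s - 1e-9:
        end = min(t + block_s, session_duration_s)
        if tickle:
            split = t + (end - t) * (1.0 - ventral_fraction)
            rows.append(dict(period_type="dorsal", start_s=t, end_s=split))
            rows.append(dict(period_type="ventral", start_s=split, end_s=end))
        else:
            rows.append(dict(period_type="none", start_s=t, end_s=end))
        tickle = not tickle
        t = end
    return pd.DataFrame(rows)
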