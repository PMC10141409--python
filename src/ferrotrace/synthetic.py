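"""Physics-based synthetic transmission-trace generator.

Generates seeded, ground-truth-annotated traces with the statistical
structure of plasmonic-nanotweezer recordings of single trapped ferritins:

* a baseline phase at transmission ``T0``;
* a dielectric-loading step of fractional height ``delta = DeltaT/T0`` when a
  protein is trapped (Clausius-Mossotti polarizability sets the contrast:
  the iron-oxide core of holo-ferritin raises both size and conductivity,
  hence the larger step);
* hydrodynamic motion of the trapped particle, modelled as an
  Ornstein-Uhlenbeck process in a harmonic trap and coupled to the signal
  through a position responsivity ``c`` (V/m);
* band-limited (3-150 Hz) Gaussian conformational fluctuation noise whose
  amplitude encodes protein flexibility;
* an optional two-state Markov gating process (folding/unfolding of the
  3-fold ion channels during Fe(2+) loading) that switches the fluctuation
  amplitude between an "on" (unfolded, high) and "off" (folded, low) level,
  with exponential dwell times;
* a slow exponential decay of the fluctuation amplitude as the mineral core
  grows (biomineralization stiffens the cage);
* white Gaussian instrument noise.

Signal model::

    T(t) = T0 * (1 + delta * o(t)) + o(t) * [c * x(t) + A(t) * zeta(t)] + n(t)

with occupancy ``o``, OU position ``x``, unit-RMS band-limited noise
``zeta``, amplitude schedule ``A(t) = conf_amp * amp(state) * decay(t)``,
and instrument noise ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.constants import Boltzmann as K_B
from scipy.constants import c as C_LIGHT
from scipy.constants import epsilon_0 as EPS0

from .trace import Trace

__all__ = [
    "ProteinPreset", "TrapPhysics", "GatingKinetics", "TraceConfig",
    "SyntheticTrace", "polarizability", "delta_from_polarizability",
    "simulate_ou", "simulate_gating", "band_limited_noise", "synthesize",
    "apo_preset", "holo_preset", "ferric_control_preset",
    "trapped_experiment", "loading_experiment", "gating_experiment",
    "control_experiment",
]

# --- calibrated preset constants (see docs/methods.md, "Calibration") -------
# Solved once with the package's own analysis chain (1 kHz Gaussian filter,
# 0.1 s sliding-RMS window, T0 = 1 V, fs = 10 kHz) so that:
#   apo trapped trace          -> median sliding RMS 6.8 mV
#   mineralized endpoint floor -> median sliding RMS 5.4 mV
#   ferric control             -> 14 mV before / 15 mV after exposure
APO_CONF_AMP_V = 4.2348e-3
INSTRUMENT_NOISE_V = 1.17209e-2
CONTROL_AMP_PRE_V = 1.32251e-2
CONTROL_AMP_POST_V = 1.43297e-2
HOLO_CONF_RATIO = 5.4 / 6.8       # holo conformational amplitude vs apo
DELTA_APO = 0.05                  # fractional step DeltaT/T0, apo
DELTA_HOLO = 0.05 * 1.41          # holo step is 41% larger


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinPreset:
    """Physical and signal parameters of one ferritin isoform."""

    name: str
    radius_nm: float
    eps_particle: float
    eps_medium: float
    core_conductivity: float       # S/m; 0 for the iron-free (apo) form
    step_contrast: float           # delta = DeltaT/T0
    conf_amp_trapped: float        # conformational fluctuation RMS at detector, V
    conf_band: tuple[float, float] = (3.0, 150.0)   # Hz

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")
        if self.eps_medium <= 0:
            raise ValueError("medium permittivity must be positive")
        if self.step_contrast < 0:
            raise ValueError("step contrast must be non-negative")
        f_lo, f_hi = self.conf_band
        if not (0 < f_lo < f_hi):
            raise ValueError("conf_band must satisfy 0 < f_lo < f_hi")


@dataclass(frozen=True)
class TrapPhysics:
    """Harmonic-trap hydrodynamics of the trapped particle."""

    stiffness: float = 2e-6            # N/m
    temperature: float = 298.0         # K
    viscosity: float = 8.9e-4          # Pa s (water, ~25 C)
    drag: float = 1.0e-10              # kg/s, Stokes 6 pi eta r
    position_responsivity: float = 2.0e4   # V/m

    @classmethod
    def for_radius(cls, radius_nm: float, **kwargs) -> "TrapPhysics":
        """Build with Stokes drag for a sphere of the given radius."""
        base = cls(**kwargs)
        drag = 6.0 * math.pi * base.viscosity * radius_nm * 1e-9
        return cls(stiffness=base.stiffness, temperature=base.temperature,
                   viscosity=base.viscosity, drag=drag,
                   position_responsivity=base.position_responsivity)

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.drag <= 0 or self.temperature <= 0:
            raise ValueError("stiffness, drag and temperature must be positive")

    @property
    def corner_frequency(self) -> float:
        """Trap corner frequency kappa / (2 pi gamma), Hz."""
        return self.stiffness / (2.0 * math.pi * self.drag)


@dataclass(frozen=True)
class GatingKinetics:
    """Two-state Markov gating of the conformational fluctuation amplitude."""

    tau_on: float = 3.5                # s, mean dwell in the unfolded state
    tau_off: float = 3.5               # s, mean dwell in the folded state
    amp_on: float = 1.0                # fluctuation multiplier, on state
    amp_off: float = 0.3               # fluctuation multiplier, off state
    mineralization_tau: float = 600.0  # s; inf disables the slow decay
    loading_start: float = 0.0         # s, absolute time Fe(2+) reaches the trap

    def __post_init__(self) -> None:
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("dwell means must be positive")
        if not self.amp_off < self.amp_on:
            raise ValueError("amp_off must be below amp_on")


@dataclass
class TraceConfig:
    """Timeline and instrument parameters of one synthetic recording."""

    fs: float = 10_000.0
    duration: float = 12.0
    baseline: float = 1.0              # T0, volts
    instrument_noise: float = INSTRUMENT_NOISE_V   # V RMS per raw sample
    seed: int | np.random.SeedSequence = 0
    t_trap: float = 2.0
    t_release: float | None = None
    # optional piecewise-constant extra amplitude multiplier: list of
    # (start_time_s, multiplier); 1.0 before the first entry
    amp_schedule: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        end = self.duration if self.t_release is None else self.t_release
        if not (0 <= self.t_trap < end <= self.duration):
            raise ValueError("need 0 <= t_trap < t_release <= duration")

    def phase_schedule(self, kinetics: "GatingKinetics | None") -> list[tuple[float, str]]:
        """Ordered (time, phase) list over {baseline, trapped, loading}."""
        sched = [(0.0, "baseline"), (self.t_trap, "trapped")]
        if kinetics is not None and kinetics.loading_start < (
                self.t_release or self.duration):
            sched.append((kinetics.loading_start, "loading"))
        if self.t_release is not None:
            sched.append((self.t_release, "baseline"))
        return sched


@dataclass
class SyntheticTrace:
    """Generated trace plus its ground-truth channels."""

    trace: Trace
    occupancy: np.ndarray              # {0,1} per sample
    gating_state: np.ndarray           # {0 off, 1 on} per sample
    true_boundaries: np.ndarray        # gating transition times, s, on grid
    position: np.ndarray               # OU position, m

    def truth_dict(self) -> dict[str, np.ndarray]:
        return {"occupancy": self.occupancy, "gating_state": self.gating_state,
                "boundaries": self.true_boundaries, "position": self.position}


# ---------------------------------------------------------------------------
# optical contrast
# ---------------------------------------------------------------------------

def polarizability(radius: float, eps_particle: float, eps_medium: float,
                   core_conductivity: float = 0.0,
                   wavelength: float = 852e-9) -> complex:
    """Clausius-Mossotti polarizability of a (possibly conductive) sphere.

    ``alpha = 4 pi eps0 r^3 (eps_p~ - eps_m) / (eps_p~ + 2 eps_m)`` with the
    Drude-style complex permittivity ``eps_p~ = eps_p + i sigma/(omega eps0)``.
    Radius and wavelength in metres; returns C m^2 / V.
    """
    if radius <= 0 or wavelength <= 0:
        raise ValueError("radius and wavelength must be positive")
    omega = 2.0 * math.pi * C_LIGHT / wavelength
    eps_tilde = eps_particle + 1j * core_conductivity / (omega * EPS0)
    return (4.0 * math.pi * EPS0 * radius ** 3
            * (eps_tilde - eps_medium) / (eps_tilde + 2.0 * eps_medium))


def delta_from_polarizability(alpha: complex, loading_responsivity: float) -> float:
    """Fractional transmission step from the real part of the polarizability.

    Dielectric loading is linear in Re(alpha); the polarizability is reduced
    by ``4 pi eps0 (1 nm)^3`` so the responsivity is a dimensionless gain.
    """
    if loading_responsivity <= 0:
        raise ValueError("loading responsivity must be positive")
    return loading_responsivity * alpha.real / (4.0 * math.pi * EPS0 * 1e-27)


# ---------------------------------------------------------------------------
# stochastic building blocks
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ou(stiffness: float, drag: float, temperature: float, fs: float,
                n_samples: int, seed) -> np.ndarray:
    """Exact-discretization Ornstein-Uhlenbeck position series (metres).

    ``x[k+1] = a x[k] + s xi``, ``a = exp(-theta/fs)``, ``theta = kappa/gamma``,
    ``s = sqrt(kB T / kappa * (1 - a^2))``; the initial sample is drawn from
    the stationary distribution, so the whole series is stationary.
    """
    if min(stiffness, drag, temperature, fs) <= 0:
        raise ValueError("stiffness, drag, temperature and fs must be positive")
    rng = _rng(seed)
    theta = stiffness / drag
    a = math.exp(-theta / fs)
    sigma_stat = math.sqrt(K_B * temperature / stiffness)
    innov = rng.standard_normal(n_samples) * (sigma_stat * math.sqrt(1.0 - a * a))
    innov[0] = rng.standard_normal() * sigma_stat
    # AR(1) recursion via an IIR filter: x[k] = a x[k-1] + innov[k]
    x = _signal.lfilter([1.0], [1.0, -a], innov)
    return x


def simulate_gating(kinetics: GatingKinetics, duration: float, fs: float,
                    seed, start_state: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Alternating two-state renewal process with exponential dwells.

    Returns ``(state_series, boundaries)``: the per-sample state in {0, 1}
    (1 = "on", high fluctuation) and the exact switching times in seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    taus = {1: kinetics.tau_on, 0: kinetics.tau_off}
    t, state = 0.0, int(start_state)
    boundaries: list[float] = []
    states: list[int] = []
    dwell_starts: list[float] = []
    while t < duration:
        dwell_starts.append(t)
        states.append(state)
        tau = taus[state]
        dwell = float("inf") if math.isinf(tau) else rng.exponential(tau)
        t += dwell
        if t < duration:
            boundaries.append(t)
        state = 1 - state
    n = int(round(duration * fs))
    series = np.empty(n, dtype=np.uint8)
    edges = np.array(dwell_starts + [duration])
    idx = np.minimum((edges * fs).round().astype(np.int64), n)
    for s, i0, i1 in zip(states, idx[:-1], idx[1:]):
        series[i0:i1] = s
    return series, np.asarray(boundaries)


def band_limited_noise(f_lo: float, f_hi: float, fs: float, n_samples: int,
                       seed) -> np.ndarray:
    """Unit-RMS Gaussian noise with power confined to ``[f_lo, f_hi]``.

    Spectral synthesis: independent complex-Gaussian Fourier coefficients in
    the band, zero elsewhere, inverse-transformed and normalized to RMS 1.
    """
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError("need 0 < f_lo < f_hi < fs/2")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    spectrum = np.zeros(len(freqs), dtype=np.complex128)
    m = int(band.sum())
    spectrum[band] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.irfft(spectrum, n_samples)
    rms = math.sqrt(float(np.mean(x * x)))
    if rms == 0:
        raise ValueError("empty band at this length/sampling rate")
    return x / rms


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def synthesize(config: TraceConfig, preset: ProteinPreset,
               physics: TrapPhysics | None = None,
               kinetics: GatingKinetics | None = None) -> SyntheticTrace:
    """Generate one annotated transmission trace from the signal model."""
    if physics is None:
        physics = TrapPhysics.for_radius(preset.radius_nm)
    f_lo, f_hi = preset.conf_band
    if f_hi >= config.fs / 2:
        raise ValueError("conformational band exceeds Nyquist at this fs")
    if physics.corner_frequency >= config.fs / 2:
        raise ValueError("trap corner frequency exceeds Nyquist at this fs")

    ss = (config.seed if isinstance(config.seed, np.random.SeedSequence)
          else np.random.SeedSequence(config.seed))
    # derive child streams statelessly (no spawn-counter side effect), so the
    # same (config, seed) pair always yields bit-identical output
    seed_ou, seed_gate, seed_conf, seed_inst = (
        np.random.SeedSequence(entropy=ss.entropy,
                               spawn_key=tuple(ss.spawn_key) + (j,))
        for j in range(4))

    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    i_trap = int(round(config.t_trap * config.fs))
    i_rel = n if config.t_release is None else int(round(config.t_release * config.fs))

    occupancy = np.zeros(n, dtype=np.uint8)
    occupancy[i_trap:i_rel] = 1

    # gating state: "on" everywhere except where the loading-phase Markov
    # process says otherwise
    state = np.ones(n, dtype=np.uint8)
    boundaries = np.empty(0)
    decay = np.ones(n)
    if kinetics is not None:
        i_load = int(round(kinetics.loading_start * config.fs))
        i_load = max(i_trap, min(i_load, i_rel))
        span = (i_rel - i_load) / config.fs
        if span > 0:
            sub, b = simulate_gating(kinetics, span, config.fs, seed_gate)
            state[i_load:i_load + len(sub)] = sub
            # snap transition times onto the sample grid, absolute time
            b_abs = kinetics.loading_start + b
            boundaries = np.round(b_abs * config.fs) / config.fs
            boundaries = boundaries[(boundaries > config.t_trap)
                                    & (boundaries < (config.t_release or config.duration))]
        if math.isfinite(kinetics.mineralization_tau):
            age = np.maximum(0.0, t - kinetics.loading_start)
            decay = np.exp(-age / kinetics.mineralization_tau)
        amp_state = np.where(state == 1, kinetics.amp_on, kinetics.amp_off)
    else:
        amp_state = np.ones(n)

    sched_mult = np.ones(n)
    if config.amp_schedule:
        for t_start, mult in sorted(config.amp_schedule):
            sched_mult[t >= t_start] = mult

    x = simulate_ou(physics.stiffness, physics.drag, physics.temperature,
                    config.fs, n, np.random.default_rng(seed_ou))
    zeta = band_limited_noise(f_lo, f_hi, config.fs, n,
                              np.random.default_rng(seed_conf))
    inst = (np.random.default_rng(seed_inst).standard_normal(n)
            * config.instrument_noise if config.instrument_noise > 0
            else np.zeros(n))

    amp = preset.conf_amp_trapped * amp_state * decay * sched_mult
    values = (config.baseline * (1.0 + preset.step_contrast * occupancy)
              + occupancy * (physics.position_responsivity * x + amp * zeta)
              + inst)

    trace = Trace(values=values, fs=config.fs,
                  metadata={"source": "ferrotrace.synthetic",
                            "preset": preset.name,
                            "t_trap": config.t_trap,
                            "t_release": config.t_release,
                            "baseline": config.baseline})
    return SyntheticTrace(trace=trace, occupancy=occupancy, gating_state=state,
                          true_boundaries=boundaries, position=x)


# ---------------------------------------------------------------------------
# shipped presets and experiment builders
# ---------------------------------------------------------------------------

def apo_preset() -> ProteinPreset:
    """Iron-free ferritin: ~12 nm cage, insulating, flexible (large 3-150 Hz
    conformational fluctuations), step contrast ``delta0 = 0.05``."""
    return ProteinPreset(name="apo", radius_nm=6.0, eps_particle=2.1,
                         eps_medium=1.77, core_conductivity=0.0,
                         step_contrast=DELTA_APO,
                         conf_amp_trapped=APO_CONF_AMP_V)


def holo_preset() -> ProteinPreset:
    """Iron-loaded ferritin: ~2 nm larger, conductive mineral core, 41%
    larger step contrast, stiffer cage (reduced fluctuation amplitude)."""
    return ProteinPreset(name="holo", radius_nm=7.0, eps_particle=2.06,
                         eps_medium=1.77, core_conductivity=100.0,
                         step_contrast=DELTA_HOLO,
                         conf_amp_trapped=APO_CONF_AMP_V * HOLO_CONF_RATIO)


def ferric_control_preset() -> ProteinPreset:
    """Apo-ferritin exposed to Fe(3+) (no loading): gating disabled, constant
    fluctuation amplitude calibrated to 14 mV median sliding RMS."""
    return ProteinPreset(name="ferric-control", radius_nm=6.0, eps_particle=2.1,
                         eps_medium=1.77, core_conductivity=0.0,
                         step_contrast=DELTA_APO,
                         conf_amp_trapped=CONTROL_AMP_PRE_V)


def trapped_experiment(preset: ProteinPreset, seed, duration: float = 12.0,
                       t_trap: float = 2.0, fs: float = 10_000.0) -> SyntheticTrace:
    """Plain trapping recording: baseline, step, steady trapped phase."""
    config = TraceConfig(fs=fs, duration=duration, seed=seed, t_trap=t_trap)
    return synthesize(config, preset, TrapPhysics.for_radius(preset.radius_nm))


def loading_experiment(seed, duration: float = 1420.0, t_trap: float = 10.0,
                       loading_delay: float = 60.0,
                       fs: float = 10_000.0) -> tuple[SyntheticTrace, GatingKinetics]:
    """Iron-loading recording: apo trapped, Fe(2+) arrives ``loading_delay``
    seconds later, on-off gating plus slow mineralization decay."""
    kin = GatingKinetics(loading_start=t_trap + loading_delay)
    config = TraceConfig(fs=fs, duration=duration, seed=seed, t_trap=t_trap)
    out = synthesize(config, apo_preset(), TrapPhysics.for_radius(6.0), kin)
    return out, kin


def gating_experiment(seed, duration: float = 130.0, t_trap: float = 2.0,
                      loading_start: float = 10.0, tau_on: float = 3.5,
                      tau_off: float = 3.5,
                      fs: float = 10_000.0) -> tuple[SyntheticTrace, GatingKinetics]:
    """Gating-kinetics recording: on-off switching without the slow
    mineralization decay, for dwell-time studies."""
    kin = GatingKinetics(tau_on=tau_on, tau_off=tau_off,
                         mineralization_tau=math.inf, loading_start=loading_start)
    config = TraceConfig(fs=fs, duration=duration, seed=seed, t_trap=t_trap)
    out = synthesize(config, apo_preset(), TrapPhysics.for_radius(6.0), kin)
    return out, kin


def control_experiment(seed, duration: float = 1320.0, t_trap: float = 10.0,
                       exposure_time: float = 70.0,
                       fs: float = 10_000.0) -> tuple[SyntheticTrace, float]:
    """Ferric-solution control: no gating, amplitude steps slightly at the
    exposure time (14 -> 15 mV calibration)."""
    preset = ferric_control_preset()
    config = TraceConfig(
        fs=fs, duration=duration, seed=seed, t_trap=t_trap,
        amp_schedule=[(exposure_time, CONTROL_AMP_POST_V / CONTROL_AMP_PRE_V)])
    out = synthesize(config, preset, TrapPhysics.for_radius(preset.radius_nm))
    return out, exposure_time
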