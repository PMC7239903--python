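"""Synthetic session generator.

Produces ground-truth-annotated recordings with the statistical structure the
downstream analyses assume: a latent ring trajectory driving von Mises HD
units, non-HD units with parameterized refractoriness / burstiness / slow
log-rate fluctuations / SWR-coupling kernels / theta modulation, NREM UP-DOWN
gain modulation, and an LFP with ripple bursts and theta oscillation.

All randomness flows from a single seed through named streams (`rng.stream`),
so every stage is reproducible and independently perturbable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .core import EpochSet, EventSeries, LfpTrace, SpikeTrain
from .rng import stream

__all__ = [
    "Stabilization",
    "LatentTrajectory",
    "UnitSpec",
    "GroundTruth",
    "SessionConfig",
    "make_latent_trajectory",
    "theta_phase_truth",
    "simulate_unit",
    "synthesize_lfp",
    "generate_session",
]

#: period (s) of the oscillatory SWR-coupling kernel; one pseudo-cycle of the
#: fast modulation around ripple peaks.
SWR_KERNEL_PERIOD = 0.25
#: e-fold timescale (s) of the post-spike self-excitation producing bursts.
BURST_KERNEL_TAU = 0.004
#: hard cap on the burst branching ratio (keeps the cascade subcritical).
BURST_BRANCHING_CAP = 0.9


@dataclass
class Stabilization:
    """Pre-SWR stabilization of the latent ring signal.

    In the `lead_s` window before each planned SWR the angular velocity is
    suppressed to zero and the population gain is transiently raised by a
    Gaussian bump of peak `gain` centered `lead_s` before the event with
    s.d. `hold_s / 2`.
    """

    lead_s: float = 0.020
    hold_s: float = 0.050
    gain: float = 2.0


@dataclass
class LatentTrajectory:
    times: np.ndarray  # uniform grid, seconds
    angle: np.ndarray  # radians in [0, 2pi)
    gain: np.ndarray  # >= 0; exactly 0 inside DOWN epochs

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def angle_at(self, t) -> np.ndarray:
        idx = np.clip(np.round((np.asarray(t, float) - self.times[0]) / self.dt).astype(int), 0, self.times.size - 1)
        return self.angle[idx]


@dataclass
class UnitSpec:
    unit_id: int
    kind: str  # "hd" | "nonhd"
    shank_id: int = 0
    preferred_direction: float = 0.0  # hd only, radians
    kappa: float = 2.0  # hd only, von Mises concentration
    peak_rate: float = 10.0  # Hz
    refractory: float = 0.002  # s, absolute
    recovery_tau: float = 0.0  # s; soft relative-refractory recovery (0 = off)
    burst_propensity: float = 0.0
    burst_tau: float = BURST_KERNEL_TAU  # s; e-fold of the offspring delay
    slow_tau: float = 0.0  # s; 0 disables the slow log-rate process
    slow_sigma: float = 0.0
    swr_amplitude: float = 0.0  # fractional rate modulation around SWRs
    swr_phase: float = 0.0  # radians within the kernel pseudo-cycle
    swr_width: float = 0.05  # s, Gaussian envelope s.d.
    theta_depth: float = 0.0  # in [0, 1]
    theta_phase: float = 0.0  # radians

    def __post_init__(self):
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be > 0")
        if self.kind == "hd" and self.kappa <= 0:
            raise ValueError("kappa must be > 0 for hd units")
        if self.swr_width <= 0:
            raise ValueError("swr_width must be > 0")


@dataclass
class GroundTruth:
    trajectory: LatentTrajectory
    swr_times: np.ndarray
    down_epochs: EpochSet
    up_epochs: EpochSet
    unit_specs: list[UnitSpec]
    epochs: dict[str, EpochSet]
    seed: int
    theta_freq_hz: float = 7.0


def _plan_to_epochs(state_plan) -> dict[str, EpochSet]:
    """Validate a [(label, start, end), ...] plan and group it by label."""
    rows = sorted((float(s), float(e), str(lbl)) for lbl, s, e in state_plan)
    for (s0, e0, l0), (s1, e1, l1) in zip(rows, rows[1:]):
        if s1 < e0 - 1e-9:
            raise ValueError(f"overlapping states in state_plan: ({l0},{s0},{e0}) and ({l1},{s1},{e1})")
    by_label: dict[str, list] = {}
    for s, e, lbl in rows:
        by_label.setdefault(lbl, []).append((s, e))
    return {lbl: EpochSet(lbl, np.array(iv)) for lbl, iv in by_label.items()}


def make_latent_trajectory(
    duration_s: float,
    state_plan,
    diffusion_wake: float = 0.5,
    diffusion_nrem: float = 3.0,
    stabilization: Stabilization | None = None,
    swr_times=(),
    down_epochs: EpochSet | None = None,
    seed: int = 0,
    dt: float = 0.001,
) -> LatentTrajectory:
    """Angular random walk with state-dependent diffusion and gain plan.

    `state_plan` is a list of (label, start_s, end_s) covering the session;
    wake/rem states use `diffusion_wake`, nrem uses `diffusion_nrem`
    (rad^2/s). Gain is 1 everywhere except exactly 0 inside `down_epochs`
    and transiently raised before each planned SWR when `stabilization` is
    given (stabilization is OFF by default so null sessions exist).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if diffusion_wake < 0 or diffusion_nrem < 0:
        raise ValueError("diffusion coefficients must be >= 0")
    epochs = _plan_to_epochs(state_plan)
    rng = stream(seed, "trajectory")
    times = np.arange(0.0, duration_s, dt)
    n = times.size

    diffusion = np.full(n, diffusion_wake)
    if "nrem" in epochs:
        diffusion[epochs["nrem"].contains(times)] = diffusion_nrem

    incr = rng.standard_normal(n) * np.sqrt(2.0 * diffusion * dt)
    swr_times = np.asarray(swr_times, dtype=float)
    if stabilization is not None and swr_times.size:
        # suppress angular velocity in the lead window before each SWR
        for t_e in swr_times:
            i0 = max(0, int(np.ceil((t_e - stabilization.lead_s) / dt)))
            i1 = min(n, int(np.floor(t_e / dt)) + 1)
            incr[i0:i1] = 0.0
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    angle = np.mod(theta0 + np.cumsum(incr), 2.0 * np.pi)

    gain = np.ones(n)
    if stabilization is not None and swr_times.size:
        sd = max(stabilization.hold_s / 2.0, dt)
        for t_e in swr_times:
            c = t_e - stabilization.lead_s
            i0 = max(0, int((c - 4 * sd) / dt))
            i1 = min(n, int((c + 4 * sd) / dt) + 1)
            bump = (stabilization.gain - 1.0) * np.exp(-((times[i0:i1] - c) ** 2) / (2.0 * sd**2))
            gain[i0:i1] = np.maximum(gain[i0:i1], 1.0 + bump)
    if down_epochs is not None and len(down_epochs):
        gain[down_epochs.contains(times)] = 0.0
    return LatentTrajectory(times=times, angle=angle, gain=gain)


def theta_phase_truth(times, epochs: dict[str, EpochSet], freq_hz: float) -> np.ndarray:
    """Ground-truth theta phase at `times`; NaN outside wake/REM epochs.

    Within each wake or REM interval the phase advances linearly from 0 at
    the interval start: phase = 2*pi*f*(t - start) mod 2*pi. The synthetic
    LFP theta component is cos(phase), so a wavelet phase estimate should
    recover this quantity directly.
    """
    t = np.asarray(times, dtype=float)
    phase = np.full(t.shape, np.nan)
    for label in ("wake", "rem"):
        ep = epochs.get(label)
        if ep is None:
            continue
        for s, e in ep.intervals:
            m = (t >= s) & (t < e)
            phase[m] = np.mod(2.0 * np.pi * freq_hz * (t[m] - s), 2.0 * np.pi)
    return phase


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    if times.size == 0 or refractory <= 0:
        return times
    keep = np.zeros(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= refractory:
            keep[i] = True
            last = t
    return times[keep]


def simulate_unit(spec: UnitSpec, truth: GroundTruth, rng: np.random.Generator | None = None) -> SpikeTrain:
    """Simulate one unit as an inhomogeneous point process on the latent grid.

    HD units: rate = peak_rate * exp(kappa*(cos(angle - pd) - 1)) * gain.
    Non-HD units: rate = peak_rate * gain * exp(OU) * (1 + theta mod) *
    (1 + SWR kernel), clamped at 0. Refractoriness is enforced by thinning;
    burst_propensity > 0 spawns a capped Hawkes-like cascade of offspring
    spikes with ISIs concentrated in the 2-9 ms band.
    """
    traj = truth.trajectory
    if rng is None:
        rng = stream(truth.seed, f"unit-{spec.unit_id}")
    t = traj.times
    dt = traj.dt
    n = t.size

    if spec.kind == "hd":
        rate = spec.peak_rate * np.exp(spec.kappa * (np.cos(traj.angle - spec.preferred_direction) - 1.0))
        rate = rate * traj.gain
    else:
        rate = np.full(n, spec.peak_rate) * traj.gain
        if spec.slow_tau > 0 and spec.slow_sigma > 0:
            # AR(1) discretization of a log-rate OU process, run via lfilter
            a = np.exp(-dt / spec.slow_tau)
            noise = rng.standard_normal(n) * spec.slow_sigma * np.sqrt(1.0 - a**2)
            x0 = rng.standard_normal() * spec.slow_sigma
            x, _ = signal.lfilter([1.0], [1.0, -a], noise, zi=np.array([a * x0]))
            rate = rate * np.exp(x - spec.slow_sigma**2 / 2.0)
        if spec.theta_depth > 0:
            phase = theta_phase_truth(t, truth.epochs, truth.theta_freq_hz)
            mod = np.ones(n)
            ok = np.isfinite(phase)
            mod[ok] = 1.0 + spec.theta_depth * np.cos(phase[ok] - spec.theta_phase)
            rate = rate * mod
        if spec.swr_amplitude != 0 and truth.swr_times.size:
            kern = np.zeros(n)
            half = 4.0 * spec.swr_width
            for t_e in truth.swr_times:
                i0 = max(0, int((t_e - half) / dt))
                i1 = min(n, int((t_e + half) / dt) + 1)
                lag = t[i0:i1] - t_e
                kern[i0:i1] += np.exp(-(lag**2) / (2.0 * spec.swr_width**2)) * np.cos(
                    2.0 * np.pi * lag / SWR_KERNEL_PERIOD - spec.swr_phase
                )
            rate = rate * (1.0 + spec.swr_amplitude * kern)
    if np.any(rate < 0):
        warnings.warn(f"unit {spec.unit_id}: modulated intensity below 0, clamped", RuntimeWarning)
        rate = np.clip(rate, 0.0, None)

    p = np.clip(rate * dt, 0.0, 1.0)
    hits = np.flatnonzero(rng.random(n) < p)
    spikes = t[hits] + rng.uniform(0.0, dt, hits.size)

    if spec.burst_propensity > 0 and spikes.size:
        branching = min(spec.burst_propensity, BURST_BRANCHING_CAP)
        parents = spikes
        extra = []
        for _ in range(5):  # generation cap keeps the cascade bounded
            n_off = rng.poisson(branching, parents.size)
            tot = int(n_off.sum())
            if tot == 0:
                break
            kids = np.repeat(parents, n_off) + spec.refractory + rng.exponential(spec.burst_tau, tot)
            kids = kids[kids < t[-1] + dt]
            if kids.size:
                g = traj.gain[np.clip((kids / dt).astype(int), 0, n - 1)]
                kids = kids[g > 0]
            if kids.size == 0:
                break
            extra.append(kids)
            parents = kids
        if extra:
            spikes = np.sort(np.concatenate([spikes] + extra))

    spikes = _enforce_refractory(np.sort(spikes), spec.refractory)
    if spec.recovery_tau > 0 and spikes.size > 1:
        # soft relative refractoriness: thin spikes with probability
        # exp(-(isi - refractory)/recovery_tau), shaping the fast rise of
        # the auto-correlogram
        u = rng.random(spikes.size)
        kept = [0]
        for i in range(1, spikes.size):
            gap = spikes[i] - spikes[kept[-1]] - spec.refractory
            if u[i] >= np.exp(-max(gap, 0.0) / spec.recovery_tau):
                kept.append(i)
        spikes = spikes[kept]
    return SpikeTrain(unit_id=spec.unit_id, times=spikes, shank_id=spec.shank_id, kind=spec.kind)


def synthesize_lfp(
    truth: GroundTruth,
    fs_hz: float = 1250.0,
    ripple_freq_hz: float = 150.0,
    theta_band_hz: tuple[float, float] = (5.0, 12.0),
    noise_sd: float = 1.0,
    seed: int = 0,
    ripple_amp: float | None = None,
    theta_amp: float | None = None,
    ripple_duration_range: tuple[float, float] = (0.05, 0.12),
) -> LfpTrace:
    """White-noise background + windowed ripple bursts at each SWR time +
    continuous theta (cos of the ground-truth phase) during wake/REM."""
    if fs_hz < 1250:
        raise ValueError("fs_hz must be >= 1250")
    if not (80.0 < ripple_freq_hz < 300.0):
        raise ValueError("ripple_freq_hz must lie in (80, 300)")
    rng = stream(seed, "lfp")
    duration = float(truth.trajectory.times[-1] + truth.trajectory.dt)
    n = int(round(duration * fs_hz))
    t = np.arange(n) / fs_hz
    x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    if ripple_amp is None:
        ripple_amp = 8.0 * noise_sd if noise_sd > 0 else 1.0
    lo, hi = ripple_duration_range
    for t_e in np.asarray(truth.swr_times, float):
        dur = rng.uniform(lo, hi)
        i0 = max(0, int((t_e - dur / 2) * fs_hz))
        i1 = min(n, int((t_e + dur / 2) * fs_hz) + 1)
        if i1 <= i0:
            continue
        tt = t[i0:i1] - t_e
        envelope = np.cos(np.pi * tt / dur) ** 2
        x[i0:i1] += ripple_amp * envelope * np.sin(2.0 * np.pi * ripple_freq_hz * tt + rng.uniform(0, 2 * np.pi))

    if theta_amp is None:
        theta_amp = 2.0 * noise_sd if noise_sd > 0 else 1.0
    phase = theta_phase_truth(t, truth.epochs, truth.theta_freq_hz)
    ok = np.isfinite(phase)
    x[ok] += theta_amp * np.cos(phase[ok])
    return LfpTrace(fs_hz=fs_hz, samples=x, start_s=0.0)


@dataclass
class SessionConfig:
    """Knobs of `generate_session`; defaults give a moderate null session
    (no pre-SWR stabilization)."""

    n_hd: int = 24
    n_nonhd: int = 24
    wake_s: float = 600.0
    nrem_s: float = 600.0
    rem_s: float = 120.0
    swr_rate_hz: float = 0.6  # rate within UP states
    swr_min_gap_s: float = 0.25  # thin events closer than this
    stabilization: Stabilization | None = None
    diffusion_wake: float = 0.5
    diffusion_nrem: float = 3.0
    down_duration_range: tuple[float, float] = (0.06, 0.3)
    up_duration_range: tuple[float, float] = (0.5, 2.0)
    hd_kappa: float = 2.0
    hd_peak_rate_range: tuple[float, float] = (15.0, 40.0)
    nonhd_rate_range: tuple[float, float] = (5.0, 20.0)
    refractory_s: float = 0.002
    hd_recovery_tau: float = 0.008
    nonhd_recovery_tau_range: tuple[float, float] = (0.001, 0.012)
    burst_range: tuple[float, float] = (0.0, 0.8)
    burst_tau_range: tuple[float, float] = (0.003, 0.006)
    slow_tau_range: tuple[float, float] = (0.3, 1.5)
    slow_sigma: float = 0.5
    swr_amplitude_range: tuple[float, float] = (0.0, 2.0)
    swr_width_s: float = 0.05
    theta_depth_range: tuple[float, float] = (0.0, 0.8)
    theta_freq_hz: float = 7.0
    couple_theta_swr_phase: bool = True
    couple_theta_swr_strength: bool = False
    couple_burst_slow: bool = False
    n_shanks_hd: int = 3
    n_shanks_nonhd: int = 5
    lfp_fs_hz: float = 1250.0
    lfp_noise_sd: float = 1.0
    ripple_freq_hz: float = 150.0
    with_lfp: bool = True
    lfp_format: str = "dat"  # "dat" (int16 little-endian) or "tsv"
    dt_s: float = 0.001


def build_ground_truth(config: SessionConfig, seed: int) -> GroundTruth:
    """Plan epochs, UP/DOWN alternation, SWR times, unit specs and the
    latent trajectory — everything except the spikes and the LFP."""
    cfg = config
    t_nrem0 = cfg.wake_s
    t_nrem1 = cfg.wake_s + cfg.nrem_s
    duration = t_nrem1 + cfg.rem_s
    state_plan = [("wake", 0.0, t_nrem0), ("nrem", t_nrem0, t_nrem1)]
    if cfg.rem_s > 0:
        state_plan.append(("rem", t_nrem1, duration))
    epochs = _plan_to_epochs(state_plan)

    rng_plan = stream(seed, "epoch-plan")
    downs, t_cur = [], t_nrem0 + rng_plan.uniform(*cfg.up_duration_range)
    while True:
        d = rng_plan.uniform(*cfg.down_duration_range)
        if t_cur + d >= t_nrem1 - cfg.up_duration_range[0]:
            break
        downs.append((t_cur, t_cur + d))
        t_cur = t_cur + d + rng_plan.uniform(*cfg.up_duration_range)
    down_epochs = EpochSet("down", np.array(downs, float).reshape(-1, 2))
    bounds = [t_nrem0] + [b for iv in downs for b in iv] + [t_nrem1]
    ups = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
    up_epochs = EpochSet("up", np.array(ups, float).reshape(-1, 2))

    rng_swr = stream(seed, "swr-times")
    swr = []
    for s, e in up_epochs.intervals:
        k = rng_swr.poisson(cfg.swr_rate_hz * (e - s))
        swr.extend(rng_swr.uniform(s, e, k))
    swr_times = np.sort(np.asarray(swr, float))
    if cfg.swr_min_gap_s > 0 and swr_times.size > 1:
        keep = [0]
        for i in range(1, swr_times.size):
            if swr_times[i] - swr_times[keep[-1]] >= cfg.swr_min_gap_s:
                keep.append(i)
        swr_times = swr_times[keep]

    rng_u = stream(seed, "units")
    specs: list[UnitSpec] = []
    uid = 0
    for i in range(cfg.n_hd):
        specs.append(
            UnitSpec(
                unit_id=uid,
                kind="hd",
                shank_id=i % max(cfg.n_shanks_hd, 1),
                preferred_direction=rng_u.uniform(0, 2 * np.pi),
                kappa=cfg.hd_kappa,
                peak_rate=rng_u.uniform(*cfg.hd_peak_rate_range),
                refractory=cfg.refractory_s,
                recovery_tau=cfg.hd_recovery_tau,
            )
        )
        uid += 1
    for i in range(cfg.n_nonhd):
        u = rng_u.uniform()
        burst = cfg.burst_range[0] + (cfg.burst_range[1] - cfg.burst_range[0]) * rng_u.uniform()
        tau = rng_u.uniform(*cfg.slow_tau_range)
        if cfg.couple_burst_slow:
            burst = cfg.burst_range[0] + (cfg.burst_range[1] - cfg.burst_range[0]) * u
            tau = cfg.slow_tau_range[1] - (cfg.slow_tau_range[1] - cfg.slow_tau_range[0]) * u
        phase = rng_u.uniform(0, 2 * np.pi)
        v = rng_u.uniform()
        amp = cfg.swr_amplitude_range[0] + (cfg.swr_amplitude_range[1] - cfg.swr_amplitude_range[0]) * v
        if cfg.couple_theta_swr_strength:
            depth = cfg.theta_depth_range[0] + (cfg.theta_depth_range[1] - cfg.theta_depth_range[0]) * v
        else:
            depth = rng_u.uniform(*cfg.theta_depth_range)
        specs.append(
            UnitSpec(
                unit_id=uid,
                kind="nonhd",
                shank_id=cfg.n_shanks_hd + i % max(cfg.n_shanks_nonhd, 1),
                peak_rate=rng_u.uniform(*cfg.nonhd_rate_range),
                refractory=cfg.refractory_s,
                recovery_tau=rng_u.uniform(*cfg.nonhd_recovery_tau_range),
                burst_propensity=burst,
                burst_tau=rng_u.uniform(*cfg.burst_tau_range),
                slow_tau=tau,
                slow_sigma=cfg.slow_sigma,
                swr_amplitude=amp,
                swr_phase=phase,
                swr_width=cfg.swr_width_s,
                theta_depth=depth,
                theta_phase=phase if cfg.couple_theta_swr_phase else rng_u.uniform(0, 2 * np.pi),
            )
        )
        uid += 1

    traj = make_latent_trajectory(
        duration,
        state_plan,
        diffusion_wake=cfg.diffusion_wake,
        diffusion_nrem=cfg.diffusion_nrem,
        stabilization=cfg.stabilization,
        swr_times=swr_times,
        down_epochs=down_epochs,
        seed=seed,
        dt=cfg.dt_s,
    )
    return GroundTruth(
        trajectory=traj,
        swr_times=swr_times,
        down_epochs=down_epochs,
        up_epochs=up_epochs,
        unit_specs=specs,
        epochs=epochs,
        seed=seed,
        theta_freq_hz=cfg.theta_freq_hz,
    )


def simulate_units(truth: GroundTruth) -> list[SpikeTrain]:
    return [simulate_unit(spec, truth) for spec in truth.unit_specs]


def generate_session(config: SessionConfig, outdir, seed: int):
    """Generate a full session and write it to `outdir`.

    Returns (manifest_path, GroundTruth). Writing the same (config, seed)
    twice produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_ground_truth(config, seed)
    units = simulate_units(truth)

    # spikes.tsv
    rows = []
    for u in units:
        for t in u.times:
            rows.append((u.unit_id, u.shank_id, t))
    rows.sort(key=lambda r: (r[2], r[0]))
    with open(outdir / "spikes.tsv", "w") as f:
        f.write("unit_id\tshank_id\ttime_s\n")
        for uid, sid, t in rows:
            f.write(f"{uid}\t{sid}\t{t:.6f}\n")

    with open(outdir / "epochs.tsv", "w") as f:
        f.write("label\tstart_s\tend_s\n")
        for label in ("wake", "nrem", "rem"):
            ep = truth.epochs.get(label)
            if ep is None:
                continue
            for s, e in ep.intervals:
                f.write(f"{label}\t{s:.6f}\t{e:.6f}\n")

    with open(outdir / "events.tsv", "w") as f:
        f.write("start_s\tpeak_s\tend_s\n")
        for t in truth.swr_times:
            f.write(f"{t:.6f}\t{t:.6f}\t{t:.6f}\n")

    manifest = {
        "session": f"synthetic-seed{seed}",
        "files": {"spikes": "spikes.tsv", "epochs": "epochs.tsv", "events": "events.tsv"},
        "units": [{"unit_id": s.unit_id, "shank_id": s.shank_id, "kind": s.kind} for s in truth.unit_specs],
    }
    if config.with_lfp:
        lfp = synthesize_lfp(
            truth,
            fs_hz=config.lfp_fs_hz,
            ripple_freq_hz=config.ripple_freq_hz,
            noise_sd=config.lfp_noise_sd,
            seed=seed,
        )
        if config.lfp_format == "dat":
            scale = float(np.max(np.abs(lfp.samples))) / 32000.0 or 1.0
            (outdir / "lfp.dat").write_bytes(
                np.round(lfp.samples / scale).astype("<i2").tobytes()
            )
            manifest["files"]["lfp"] = "lfp.dat"
            manifest["lfp"] = {"fs_hz": lfp.fs_hz, "format": "int16", "scale": scale, "start_s": 0.0}
        else:
            with open(outdir / "lfp.tsv", "w") as f:
                f.write("sample\n")
                for v in lfp.samples:
                    f.write(f"{v:.6f}\n")
            manifest["files"]["lfp"] = "lfp.tsv"
            manifest["lfp"] = {"fs_hz": lfp.fs_hz, "format": "tsv", "scale": 1.0, "start_s": 0.0}

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path, truth
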