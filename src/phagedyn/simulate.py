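"""Mechanistic phage-bacterium coculture simulator with an OD observation model.

The population model tracks susceptible cells S, phage-resistant cells R,
latently infected cells I, free phage P and cumulative lysed cells D
(all per mL)::

    dS/dt = r S (1 - N/K) - delta S P
    dR/dt = c_r r R (1 - N/K) + mu r S (1 - N/K)
    dI/dt = delta S P - I / tau
    dP/dt = (beta / tau) I - delta S P
    dD/dt = I / tau,            N = S + R + I

Adsorption is mass-action (rate ``delta``), the latent period is an
exponential stage of mean ``tau`` (a Markovian approximation of the fixed
delay), and each lysis releases ``beta`` phage.  Resistant cells arise at
an effective per-division probability ``mu`` and grow with relative fitness
``c_r``; because phage cannot adsorb to them, they are the mechanism behind
the killing-then-regrowth patterns.  The plate reader sees

    OD(t) = alpha_od * (S + R + I + debris_frac * D)

clipped at a saturation ceiling: optical density counts intact biomass and
a fraction ``debris_frac`` of lysed-cell debris, and does not distinguish
live from dead cells.

Archetype presets packaged here are calibrated once so that the noise-free
curves reproduce the seven canonical growth-dynamics patterns (logistic
growth; full killing; three killing-then-regrowth variants; two
impaired-growth variants); ``scripts/calibrate_presets.py`` re-derives them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .curves import (
    NONE_TOKEN,
    CombinationKey,
    GrowthCurve,
    PlateExperiment,
    TimeGrid,
    VALID_MOIS,
)

__all__ = [
    "SimulationParams",
    "NoiseModel",
    "ARCHETYPE_PRESETS",
    "PATTERN_IDS",
    "simulate_dynamics",
    "generate_archetype_curve",
    "StudyConfig",
    "default_pattern_map",
    "generate_study",
]

PATTERN_IDS = ("G1", "G2", "G3.1", "G3.2", "G3.3", "G3.4", "G3.5")


@dataclass(frozen=True)
class SimulationParams:
    """Coculture model parameters (rates in per hour, densities per mL)."""

    r: float = 0.85            # susceptible growth rate (1/h)
    K: float = 2.0e9           # carrying capacity (cells/mL)
    delta: float = 0.0         # adsorption rate (mL/(cell*h))
    tau: float = 0.5           # mean latent period (h)
    beta: float = 100.0        # burst size (phage per lysed cell)
    mu: float = 0.0            # effective per-division resistance probability
    c_r: float = 1.0           # relative fitness of resistant cells (0, 1]
    S0: float = 1.0e8          # initial susceptible density (CFU/mL)
    moi: float = 1.0           # initial phage:bacteria ratio
    alpha_od: float = 3.5e-10  # OD600 per cell (absorbance*mL/cell)
    debris_frac: float = 0.1   # fraction of lysed-cell OD that persists
    t_end: float = 22.0        # h
    dt_out: float = 0.5        # output step (h)
    od_ceiling: float = 1.2    # reader saturation (absorbance)

    def __post_init__(self):
        for name in ("r", "K", "delta", "tau", "beta", "moi", "alpha_od"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must lie in [0, 1]")
        if not 0 <= self.debris_frac <= 1:
            raise ValueError("debris_frac must lie in [0, 1]")
        if not 0 < self.c_r <= 1:
            raise ValueError("c_r must lie in (0, 1]")
        if self.S0 <= 0:
            raise ValueError("S0 must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: od * exp(N(0, sd_mult)) + N(0, sd_add), clipped at 0."""

    sd_add: float = 0.005
    sd_mult: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sd_add < 0 or self.sd_mult < 0:
            raise ValueError("noise sds must be >= 0")

    def apply(self, od: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed)
        eps_m = rng.normal(0.0, self.sd_mult, size=od.shape) if self.sd_mult else 0.0
        eps_a = rng.normal(0.0, self.sd_add, size=od.shape) if self.sd_add else 0.0
        return np.clip(od * np.exp(eps_m) + eps_a, 0.0, None)


def _default_key(moi: float) -> CombinationKey:
    key_moi = moi if moi in VALID_MOIS else 1.0
    if moi == 0:
        return CombinationKey(NONE_TOKEN, "SIM", 0.0, 1, "bacteria_control")
    return CombinationKey("SIM", "SIM", key_moi, 1, "treatment")


def simulate_dynamics(params: SimulationParams,
                      key: CombinationKey | None = None) -> GrowthCurve:
    """Integrate the coculture model and return the noise-free OD curve.

    The returned curve is flagged ``adjusted``: it is the pure biological
    signal with no media background (the study generator adds background
    and noise when emitting raw plate files).
    """
    p = params
    grid = TimeGrid.default(p.t_end, p.dt_out)
    y0 = np.array([p.S0, 0.0, 0.0, p.moi * p.S0, 0.0])

    def rhs(t, y):
        S, R, I, P, D = np.maximum(y, 0.0)
        N = S + R + I
        growth = p.r * (1.0 - N / p.K)
        ads = p.delta * S * P
        lysis = I / p.tau
        return (
            growth * S - ads,
            p.c_r * growth * R + p.mu * growth * S,
            ads - lysis,
            p.beta * lysis - ads,
            lysis,
        )

    sol = solve_ivp(
        rhs,
        (0.0, p.t_end),
        y0,
        method="LSODA",
        t_eval=grid.times,
        rtol=1e-8,
        atol=1e-6 * p.S0,
    )
    if not sol.success:
        raise RuntimeError(f"coculture integration failed for params {p}: {sol.message}")
    y = sol.y
    if np.min(y) < -1e-3 * p.S0:
        raise RuntimeError(f"negative state beyond tolerance for params {p}")
    y = np.maximum(y, 0.0)
    S, R, I, _, D = y
    od = p.alpha_od * (S + R + I + p.debris_frac * D)
    od = np.clip(od, 0.0, p.od_ceiling)
    return GrowthCurve(key=key or _default_key(p.moi), grid=grid, od=od, adjusted=True)


# ---------------------------------------------------------------------------
# Archetype presets
# ---------------------------------------------------------------------------
# Calibrated so the noise-free curves hit the canonical pattern features
# (final OD, lag, regrowth onset, time-to-stationary); see
# scripts/calibrate_presets.py for the derivation.

ARCHETYPE_PRESETS: dict[str, SimulationParams] = {
    # unimpeded logistic growth, stationary ~7 h, final OD ~0.7
    "G1": SimulationParams(r=0.85, K=2.0e9, delta=0.0, beta=0.0, moi=1.0),
    # full killing, never recovers, endpoint < 0.2
    "G2": SimulationParams(r=0.85, K=2.0e9, delta=1.0e-8, beta=150.0,
                           mu=0.0, debris_frac=0.05, moi=1.0),
    # killing then slow regrowth from ~9 h to final OD ~0.45
    "G3.1": SimulationParams(r=0.85, K=1.286e9, delta=1.0e-8, beta=100.0,
                             mu=0.20, c_r=0.60, debris_frac=0.05, moi=1.0),
    # killing then sharp regrowth after ~7 h to final OD ~0.5
    "G3.2": SimulationParams(r=0.85, K=1.43e9, delta=1.0e-8, beta=100.0,
                             mu=0.06, c_r=1.0, debris_frac=0.05, moi=1.0),
    # like G3.2 with the highest final OD (~0.75)
    "G3.3": SimulationParams(r=0.85, K=2.14e9, delta=1.0e-8, beta=100.0,
                             mu=0.06, c_r=1.0, debris_frac=0.05, moi=1.0),
    # impaired growth (host-side: slower rate, lower ceiling, phage inert),
    # stationary ~9.5 h, final OD ~0.26
    "G3.4": SimulationParams(r=0.525, K=7.43e8, delta=0.0, beta=0.0, moi=1.0),
    # impaired growth, stationary ~12 h, final OD ~0.45
    "G3.5": SimulationParams(r=0.465, K=1.286e9, delta=0.0, beta=0.0, moi=1.0),
}


def generate_archetype_curve(pattern_id: str, noise: NoiseModel | None = None,
                             key: CombinationKey | None = None,
                             moi: float | None = None) -> GrowthCurve:
    """Simulate one packaged archetype, optionally with measurement noise
    and/or an overriding MOI (P0 = moi * S0)."""
    if pattern_id not in ARCHETYPE_PRESETS:
        raise KeyError(f"unknown pattern_id {pattern_id!r}; valid: {PATTERN_IDS}")
    params = ARCHETYPE_PRESETS[pattern_id]
    if moi is not None:
        params = replace(params, moi=moi)
    curve = simulate_dynamics(params, key=key)
    if noise is not None:
        curve = replace(curve, od=noise.apply(curve.od))
    return curve


# ---------------------------------------------------------------------------
# Full-study generator
# ---------------------------------------------------------------------------

def default_pattern_map(phage_id: str, bacterium_id: str, moi: float) -> str:
    """Deterministic qualitative pattern assignment mirroring the study's
    endpoint-infectivity structure: phages P10-P18 never infect (pure
    growth); P1 is the strongest killer; B1/B4 are broadly resistant hosts;
    the remaining combinations cycle through the in-between patterns."""
    pn = int(phage_id[1:])
    bn = int(bacterium_id[1:])
    if pn >= 10:
        return "G1"
    if pn == 1:
        return "G2" if moi >= 1 else "G3.1"
    if bn in (1, 4):
        return "G1"
    cycle = ("G2", "G3.1", "G3.2", "G3.3", "G3.4", "G3.5")
    moi_off = {10.0: 0, 1.0: 1, 0.1: 2}.get(moi, 0)
    return cycle[(pn + bn + moi_off) % len(cycle)]


@dataclass(frozen=True)
class StudyConfig:
    """Layout of a synthetic plate-reader study.

    One plate per (bacterium, replicate): all phage x MOI treatments for
    that strain plus a phage-free bacterial control, a bacteria-free phage
    control and a media blank, as on the real plates.
    """

    phages: tuple = tuple(f"P{i}" for i in range(1, 19))
    bacteria: tuple = tuple(f"B{i}" for i in range(1, 11))
    mois: tuple = (10.0, 1.0, 0.1)
    replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    background_od: float = 0.04    # media absorbance added to every well
    pattern_map: Callable[[str, str, float], str] = default_pattern_map

    def __post_init__(self):
        n_wells = len(self.phages) * len(self.mois) + 3
        if n_wells > 96:
            raise ValueError(f"plate layout needs {n_wells} wells (> 96)")


def generate_study(config: StudyConfig | None = None, seed: int = 0
                   ) -> tuple[list[PlateExperiment], pd.DataFrame]:
    """Emit raw (unadjusted) synthetic plates plus the truth table.

    Raw well ODs are ``background + signal`` with measurement noise; blank
    wells carry background only, so blank-timewise baseline adjustment
    recovers the biological signal.  The truth table maps each
    (phage, bacterium, MOI) combination to its generating pattern.
    Identical seeds produce identical studies.
    """
    config = config or StudyConfig()
    grid = TimeGrid.default()
    rng_root = np.random.SeedSequence(seed)

    # noise-free dynamics depend only on (pattern, moi): cache them
    signal_cache: dict[tuple, np.ndarray] = {}

    def signal(pattern: str, moi: float) -> np.ndarray:
        k = (pattern, moi)
        if k not in signal_cache:
            signal_cache[k] = generate_archetype_curve(pattern, moi=moi).od
        return signal_cache[k]

    control_signal = simulate_dynamics(replace(ARCHETYPE_PRESETS["G1"], moi=0.0)).od
    flat = np.zeros(len(grid))

    plates: list[PlateExperiment] = []
    truth_rows = []
    seen_truth = set()
    plate_seeds = rng_root.spawn(len(config.bacteria) * config.replicates)
    i_plate = 0
    for bact in config.bacteria:
        for rep in range(1, config.replicates + 1):
            rng = np.random.default_rng(plate_seeds[i_plate])
            i_plate += 1
            curves = []

            def well(key, sig):
                noisy = config.noise.apply(config.background_od + sig, rng)
                curves.append(GrowthCurve(key=key, grid=grid, od=noisy))

            well(CombinationKey(NONE_TOKEN, NONE_TOKEN, 0.0, rep, "blank"), flat)
            well(CombinationKey(NONE_TOKEN, bact, 0.0, rep, "bacteria_control"),
                 control_signal)
            well(CombinationKey("P1", NONE_TOKEN, 1.0, rep, "phage_control"), flat)
            for phage in config.phages:
                for moi in config.mois:
                    pattern = config.pattern_map(phage, bact, moi)
                    if pattern not in ARCHETYPE_PRESETS:
                        raise KeyError(
                            f"pattern map returned unknown pattern {pattern!r} "
                            f"for ({phage},{bact},{moi})"
                        )
                    key = CombinationKey(phage, bact, moi, rep, "treatment")
                    well(key, signal(pattern, moi))
                    if (phage, bact, moi) not in seen_truth:
                        seen_truth.add((phage, bact, moi))
                        truth_rows.append(
                            {"phage_id": phage, "bacterium_id": bact,
                             "moi": moi, "pattern": pattern,
                             "group": 1 if pattern == "G1"
                                      else 2 if pattern == "G2" else 3}
                        )
            plates.append(
                PlateExperiment(curves=curves, grid=grid,
                                provenance=f"sim:{bact}:rep{rep}").validate()
            )
    truth = pd.DataFrame(truth_rows).sort_values(
        ["phage_id", "bacterium_id", "moi"]).reset_index(drop=True)
    return plates, truth
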