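"""Agent-based simulation of single-season avian detection histories.

Simulates a surveyor (point count or autonomous recorder) at the center of a
square landscape populated with territorial birds.  Each bird holds a fixed
territory center ("nest"); within a visit it relocates at exponentially
distributed intervals, each new position an independent bivariate-normal draw
around the nest, and produces auditory cues as a Poisson process.  A cue
produced at distance ``d`` from the survey point is detected with half-normal
perceptibility ``g(d) = exp(-(d/tau)**2)`` where ``tau`` is the effective
detection radius (EDR).  A visit records a detection iff at least one cue from
any bird is detected.

A site counts as *occupied* when the core territory (radius ``2*sigma_m``
around the nest) of at least one bird overlaps the sampling range of the
surveyor -- the disc in which a single cue has more than a 6% chance of
detection (100 m for a 60-m EDR).  Occupied-site layouts are rejection-sampled
until this holds, so every occupied site has at least one plausibly
detectable individual.

The module doubles as the synthetic-data generator for the whole package:
besides the agent-based simulator it provides simple parametric history
generators (zero-inflated binomial, zero-inflated beta-binomial,
Royle-Nichols) used for calibration and parameter-recovery checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ScenarioConfig",
    "Bird",
    "VisitRecord",
    "DetectionHistory",
    "perceptibility",
    "sampling_radius",
    "place_territories",
    "site_occupied",
    "simulate_visit",
    "simulate_site",
    "simulate_scenario",
    "simulate_zib_history",
    "simulate_betabinomial_history",
    "simulate_rn_history",
]

#: single-cue perceptibility defining the edge of the sampling range
SAMPLING_RANGE_THRESHOLD = 0.06

#: max territory-layout rejections before simulate_site gives up
MAX_LAYOUT_REJECTIONS = 100_000

#: max placement attempts per bird under spatial inhibition
MAX_INHIBITION_ATTEMPTS = 1_000


class DegenerateHistoryError(ValueError):
    """Raised when a detection history cannot support the requested operation."""


@dataclass
class ScenarioConfig:
    """All parameters of one simulation scenario.

    Parameters
    ----------
    landscape_edge : float
        Side of the square landscape in meters (default 1500).
    density : float
        Birds per hectare.  Ignored when ``exactly_one`` is set.
    exactly_one : bool
        Populate each occupied site with exactly one detectable individual
        instead of a Poisson number at ``density``.
    movement_sd : float
        Per-axis SD (m) of the bivariate-normal within-territory relocation
        kernel; 0 means a stationary bird.
    movement_rate : float
        Relocations per minute (default 1).
    cue_rate : float
        Auditory cues per minute (default 0.25).
    duration : float
        Visit length in minutes (default 10).
    n_visits : int
        Number of independent visits per site (default 20).
    edr : float
        Effective detection radius tau in meters (default 60; 90 and 120 are
        the higher-perceptibility variants).
    psi : float
        Target proportion of occupied sites.
    n_sites : int
        Total number of sites in a detection history (default 200).
    seed : int, optional
        Scenario-level seed; per-site and per-visit streams are spawned
        from it.
    """

    landscape_edge: float = 1500.0
    density: float = 1.0
    exactly_one: bool = False
    movement_sd: float = 25.0
    movement_rate: float = 1.0
    cue_rate: float = 0.25
    duration: float = 10.0
    n_visits: int = 20
    edr: float = 60.0
    psi: float = 0.5
    n_sites: int = 200
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("landscape_edge", "density", "movement_sd", "movement_rate",
                     "cue_rate", "duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.edr <= 0:
            raise ValueError(f"edr must be > 0, got {self.edr}")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi must be in [0, 1], got {self.psi}")
        if self.n_visits < 1:
            raise ValueError(f"n_visits must be >= 1, got {self.n_visits}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")

    @property
    def area_ha(self) -> float:
        return self.landscape_edge ** 2 / 1e4

    @property
    def center(self) -> np.ndarray:
        return np.array([self.landscape_edge / 2.0, self.landscape_edge / 2.0])

    @property
    def n_occupied(self) -> int:
        """Number of sites flagged occupied: round(psi * n_sites)."""
        return int(round(self.psi * self.n_sites))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class Bird:
    """A territorial individual: fixed nest plus movement scale."""

    nest: np.ndarray
    movement_sd: float

    def __post_init__(self) -> None:
        self.nest = np.asarray(self.nest, dtype=float)
        if self.nest.shape != (2,):
            raise ValueError("nest must be a 2-D coordinate")


@dataclass
class VisitRecord:
    """Outcome of one visit: detection flag plus optional per-cue log."""

    detected: int
    cue_log: Optional[list] = None


@dataclass
class DetectionHistory:
    """M x N binary detection matrix with optional per-site truth flags."""

    y: np.ndarray
    z: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 2:
            raise ValueError("y must be an M x N matrix")
        finite = self.y[~np.isnan(self.y.astype(float))] if self.y.dtype.kind == "f" else self.y
        if not np.isin(finite, (0, 1)).all():
            raise ValueError("detection matrix must be binary")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=bool)
            if self.z.shape != (self.y.shape[0],):
                raise ValueError("z must have one flag per site")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    @property
    def D(self) -> np.ndarray:
        """Per-site detection counts D_i = sum_j y_ij."""
        return self.y.sum(axis=1).astype(int)

    @property
    def has_missing(self) -> bool:
        return self.y.dtype.kind == "f" and bool(np.isnan(self.y).any())

    def require_complete(self) -> np.ndarray:
        """Return the integer matrix, refusing histories with missing visits."""
        if self.has_missing:
            raise ValueError(
                "history contains missing visits; the occupancy models assume "
                "complete N-visit histories -- drop incomplete sites or visits first"
            )
        return self.y.astype(int)


def perceptibility(distance, edr: float):
    """Half-normal single-cue detection probability ``g(d) = exp(-(d/tau)^2)``.

    ``edr`` is the effective detection radius tau (m).  Vectorized in
    ``distance``.
    """
    if edr <= 0:
        raise ValueError(f"edr must be > 0, got {edr}")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = np.exp(-((d / edr) ** 2))
    return float(out) if np.isscalar(distance) else out


def sampling_radius(edr: float, threshold: float = SAMPLING_RANGE_THRESHOLD) -> float:
    """Radius at which a single cue's perceptibility drops to ``threshold``.

    For the default 6% threshold and a 60-m EDR this is ~100 m; it scales
    linearly with the EDR.
    """
    if edr <= 0:
        raise ValueError(f"edr must be > 0, got {edr}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return edr * float(np.sqrt(np.log(1.0 / threshold)))


def core_territory_area_ha(movement_sd: float) -> float:
    """Area (ha) of the core territory: disc of radius 2 movement-SD.

    About 86% of bivariate-normal relocations fall inside this disc; a
    100-m movement SD gives a 12.57-ha core.
    """
    if movement_sd < 0:
        raise ValueError("movement_sd must be >= 0")
    return float(np.pi * (2.0 * movement_sd) ** 2 / 1e4)


def inhibition_radius(density_per_ha: float) -> float:
    """Minimum nest spacing under sequential spatial inhibition.

    Half the mean grid spacing at the given density: ``0.5 * sqrt(1/density)``
    with density in birds per square meter.
    """
    if density_per_ha <= 0:
        return 0.0
    density_m2 = density_per_ha / 1e4
    return 0.5 / np.sqrt(density_m2)


def place_territories(config: ScenarioConfig, rng: np.random.Generator) -> list[Bird]:
    """Place territory centers on the landscape.

    Abundance is Poisson(density x area); nests are laid down one at a time by
    sequential spatial inhibition, retrying until the candidate is at least the
    inhibition radius from every accepted nest (semi-regular spacing typical
    of territorial songbirds).  If a nest cannot be placed within the attempt
    cap, remaining birds fall back to unconstrained placement with a warning.
    In ``exactly_one`` mode a single nest is placed uniformly at random.
    """
    edge = config.landscape_edge
    if config.exactly_one:
        nest = rng.uniform(0.0, edge, size=2)
        return [Bird(nest, config.movement_sd)]
    if config.density == 0:
        return []
    n = rng.poisson(config.density * config.area_ha)
    if n == 0:
        return []
    r_inh = inhibition_radius(config.density)
    accepted = np.empty((n, 2))
    n_accepted = 0
    fallback = False
    for _ in range(n):
        placed = False
        for _ in range(MAX_INHIBITION_ATTEMPTS):
            cand = rng.uniform(0.0, edge, size=2)
            if n_accepted == 0 or (
                np.min(np.hypot(*(accepted[:n_accepted] - cand).T)) >= r_inh
            ):
                accepted[n_accepted] = cand
                n_accepted += 1
                placed = True
                break
        if not placed:
            accepted[n_accepted] = rng.uniform(0.0, edge, size=2)
            n_accepted += 1
            fallback = True
    if fallback:
        warnings.warn(
            f"spatial inhibition infeasible at density {config.density}/ha; "
            "some nests placed without the spacing constraint",
            RuntimeWarning,
        )
    return [Bird(accepted[i].copy(), config.movement_sd) for i in range(n_accepted)]


def site_occupied(birds: Sequence[Bird], config: ScenarioConfig) -> bool:
    """True iff at least one bird's core territory overlaps the sampling range.

    Core territory = disc of radius ``2*movement_sd`` around the nest;
    sampling range = disc of radius ``sampling_radius(edr)`` around the survey
    point at the landscape center.  Partial overlap means the nest lies closer
    than the sum of the two radii.
    """
    if not birds:
        return False
    nests = np.array([b.nest for b in birds])
    dist = np.hypot(*(nests - config.center).T)
    limit = sampling_radius(config.edr) + 2.0 * config.movement_sd
    return bool(np.any(dist < limit))


def _simulate_visit_core(
    nests: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
    collect_log: bool = False,
):
    """Simulate one visit for all birds at once.

    Event streams (relocations at ``movement_rate``, cues at ``cue_rate``) are
    generated as flattened arrays across birds; the position active at each
    cue time is the bird's latest relocation draw (all positions iid
    bivariate-normal around the nest).  Returns the binary detection flag and,
    optionally, a per-cue log of (time, position, distance, detected).
    """
    t = config.duration
    nb = len(nests)
    if nb == 0:
        return 0, ([] if collect_log else None)
    n_moves = rng.poisson(config.movement_rate * t, nb)
    n_cues = rng.poisson(config.cue_rate * t, nb)
    total_cues = int(n_cues.sum())
    if total_cues == 0:
        return 0, ([] if collect_log else None)

    # per-bird event times (unsorted uniforms are a Poisson process given count)
    move_times = rng.uniform(0.0, t, int(n_moves.sum()))
    cue_times = rng.uniform(0.0, t, total_cues)
    move_bird = np.repeat(np.arange(nb), n_moves)
    cue_bird = np.repeat(np.arange(nb), n_cues)

    # number of relocations before each cue, computed without a per-bird loop:
    # key = bird * (t + 1) + time sorts by bird then time
    span = t + 1.0
    move_keys = np.sort(move_bird * span + move_times)
    cue_keys = cue_bird * span + cue_times
    cum_moves = np.concatenate(([0], np.cumsum(n_moves)))
    pos_index = np.searchsorted(move_keys, cue_keys) - cum_moves[cue_bird]

    # positions: initial + one per relocation, all iid N(nest, sigma^2 I)
    n_pos = n_moves + 1
    cum_pos = np.concatenate(([0], np.cumsum(n_pos)))
    total_pos = int(cum_pos[-1])
    sigma = config.movement_sd
    if sigma > 0:
        positions = np.repeat(nests, n_pos, axis=0) + rng.normal(
            0.0, sigma, size=(total_pos, 2)
        )
    else:
        positions = np.repeat(nests, n_pos, axis=0)

    cue_pos = positions[cum_pos[cue_bird] + pos_index]
    dist = np.hypot(cue_pos[:, 0] - config.center[0], cue_pos[:, 1] - config.center[1])
    detected_cue = rng.random(total_cues) < np.exp(-((dist / config.edr) ** 2))
    detected = int(detected_cue.any())
    if collect_log:
        log = [
            (float(cue_times[k]), (float(cue_pos[k, 0]), float(cue_pos[k, 1])),
             float(dist[k]), bool(detected_cue[k]))
            for k in range(total_cues)
        ]
        return detected, log
    return detected, None


def simulate_visit(
    birds: Sequence[Bird],
    config: ScenarioConfig,
    rng: np.random.Generator,
    collect_log: bool = False,
) -> VisitRecord:
    """Simulate one independent visit and return its :class:`VisitRecord`."""
    if config.duration <= 0:
        raise ValueError("duration must be > 0")
    nests = np.array([b.nest for b in birds]).reshape(-1, 2)
    detected, log = _simulate_visit_core(nests, config, rng, collect_log)
    return VisitRecord(detected=detected, cue_log=log)


def _prune_radius(config: ScenarioConfig) -> float:
    """Nest distance beyond which a bird is effectively undetectable.

    Caps the expected number of detected cues from one bird across all visits
    at 1e-7, allowing for movement excursions up to 7 movement SDs.
    """
    budget = max(config.cue_rate * config.duration * config.n_visits, 1.0)
    return (config.edr * np.sqrt(np.log(budget / 1e-7))
            + 7.0 * config.movement_sd)


def simulate_site(
    config: ScenarioConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[list[Bird], list[VisitRecord]]:
    """Simulate one occupied site: rejection-sample a layout, then N visits.

    Territory layouts are re-drawn until the site satisfies the occupancy
    criterion; the accepted layout is fixed across the ``n_visits`` visits,
    whose movement and cue realizations are independent (each visit has its
    own child RNG stream).
    """
    place_ss, visits_ss = seed_seq.spawn(2)
    place_rng = np.random.default_rng(place_ss)
    for _ in range(MAX_LAYOUT_REJECTIONS):
        birds = place_territories(config, place_rng)
        if site_occupied(birds, config):
            break
    else:
        raise RuntimeError(
            f"could not generate an occupied layout after {MAX_LAYOUT_REJECTIONS} "
            f"attempts for config {config}"
        )
    nests = np.array([b.nest for b in birds]).reshape(-1, 2)
    # drop birds too distant to be detected (expected detections < 1e-7)
    if len(nests):
        dist = np.hypot(*(nests - config.center).T)
        nests = nests[dist <= _prune_radius(config)]
    records = []
    for visit_ss in visits_ss.spawn(config.n_visits):
        detected, _ = _simulate_visit_core(
            nests, config, np.random.default_rng(visit_ss)
        )
        records.append(VisitRecord(detected=detected))
    return birds, records


def simulate_scenario(config: ScenarioConfig) -> DetectionHistory:
    """Simulate a full detection history for one scenario.

    ``round(psi * n_sites)`` occupied sites are simulated independently, each
    on its own landscape; the remaining sites are unoccupied all-zero rows.
    Per-site RNG streams are spawned from the scenario seed, so the same
    config + seed reproduces the history bit for bit.
    """
    n_occ = config.n_occupied
    m, n = config.n_sites, config.n_visits
    y = np.zeros((m, n), dtype=np.int8)
    z = np.zeros(m, dtype=bool)
    z[:n_occ] = True
    root = np.random.SeedSequence(config.seed)
    for i, site_ss in enumerate(root.spawn(n_occ)):
        _, records = simulate_site(config, site_ss)
        y[i] = [r.detected for r in records]
    return DetectionHistory(
        y=y, z=z, metadata={"config": config.to_dict(), "seed": config.seed}
    )


# ---------------------------------------------------------------------------
# Parametric history generators (calibration / recovery / worked examples)
# ---------------------------------------------------------------------------

def _zero_inflate(p_site: np.ndarray, psi: float, n_sites: int,
                  n_visits: int, rng: np.random.Generator) -> DetectionHistory:
    z = rng.random(n_sites) < psi
    y = (rng.random((n_sites, n_visits)) < p_site[:, None]) & z[:, None]
    return DetectionHistory(y=y.astype(np.int8), z=z)


def simulate_zib_history(psi: float, p: float, n_sites: int, n_visits: int,
                         rng: np.random.Generator) -> DetectionHistory:
    """History from the homogeneous zero-inflated binomial model."""
    return _zero_inflate(np.full(n_sites, p), psi, n_sites, n_visits, rng)


def simulate_betabinomial_history(psi: float, alpha: float, beta: float,
                                  n_sites: int, n_visits: int,
                                  rng: np.random.Generator) -> DetectionHistory:
    """History with per-site detection probability drawn from Beta(alpha, beta)."""
    p_site = rng.beta(alpha, beta, n_sites)
    return _zero_inflate(p_site, psi, n_sites, n_visits, rng)


def simulate_rn_history(lam: float, r: float, n_sites: int, n_visits: int,
                        rng: np.random.Generator) -> DetectionHistory:
    """History from the Royle-Nichols abundance model.

    Site abundance B_i ~ Poisson(lam); per-visit detection probability
    ``1 - (1-r)**B_i``; occupancy truth is B_i > 0.
    """
    b = rng.poisson(lam, n_sites)
    p_site = 1.0 - (1.0 - r) ** b
    y = rng.random((n_sites, n_visits)) < p_site[:, None]
    return DetectionHistory(y=y.astype(np.int8), z=b > 0)


def fixed_occupancy_history(p_site: np.ndarray, n_occupied: int, n_sites: int,
                            n_visits: int, rng: np.random.Generator
                            ) -> DetectionHistory:
    """History with exactly ``n_occupied`` occupied rows (first rows occupied).

    ``p_site`` gives the per-visit detection probability of each occupied site
    (length ``n_occupied``); the remaining rows are unoccupied and all-zero.
    """
    if len(p_site) != n_occupied:
        raise ValueError("p_site must have one entry per occupied site")
    z = np.zeros(n_sites, dtype=bool)
    z[:n_occupied] = True
    y = np.zeros((n_sites, n_visits), dtype=np.int8)
    y[:n_occupied] = (
        rng.random((n_occupied, n_visits)) < np.asarray(p_site)[:, None]
    ).astype(np.int8)
    return DetectionHistory(y=y, z=z)
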