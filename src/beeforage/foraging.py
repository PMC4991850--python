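"""Single-day foraging simulators with hourly resource dynamics.

The colony forages for ``day_hours`` hourly steps.  Each hour the set of
feasible patches is determined (flowers open, within range, positive trip
energy balance, detected), foragers are allocated, deliveries of nectar
and sugar are recorded, and open-flower densities are updated for
depletion by the colony, by background competitors ``Z``, and for nectar
renewal ``r``.

Two allocation rules are implemented:

* **SO (single-optimal)** — the colony's self-organisation is assumed fast
  enough that all foragers exploit the one patch with the highest net
  energetic efficiency each hour (ties broken by smaller distance, then
  patch id).
* **RL (recruitment-limited)** — forager recruitment via the dance floor
  limits how fast effort can be redirected, so several high-NEE patches
  are exploited simultaneously.  Employed foragers abandon a patch with a
  probability that grows as its NEE falls below the current best, and a
  fraction of the unemployed pool is recruited each hour in proportion to
  per-patch dance strength.  The functional forms and rate constants
  (``kappa_a``, ``rho``, ``eps``) are a documented stand-in for this
  mechanism and are all exposed in :class:`SimulationConfig`.

Forager numbers and trips are continuous (fractional): the delivery
equation is a rate equation and integer truncation would introduce
artificial discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import energetics as en
from .params import BeeParameters, ResourceType

__all__ = [
    "Patch",
    "SimulationConfig",
    "RecruitmentState",
    "ForagingDayResult",
    "trips_per_hour",
    "hourly_delivery",
    "update_flower_density",
    "feasible_patches",
    "simulate_day",
    "simulate_day_so",
    "simulate_day_rl",
    "patches_for_sugar_fraction",
]


@dataclass
class Patch:
    """One internally homogeneous resource patch as seen from a focal hive.

    ``F`` is the current open-flower density and is mutated by the
    simulators; ``C`` is the chemical concentration in the patch's nectar
    (μg per mg nectar, 0 for untreated patches).
    """

    id: str
    rt: ResourceType
    A: float  # area, m^2
    D: float  # distance from the focal hive, m
    F: Optional[float] = None  # open-flower density, m^-2
    C: float = 0.0  # chemical concentration in nectar, ug/mg
    treated: bool = False
    category: str = "target-field"
    sigma: float = 1.0  # per-scout encounter probability

    def __post_init__(self) -> None:
        if self.F is None:
            self.F = self.rt.F0
        if self.A <= 0:
            raise ValueError(f"patch {self.id}: area must be positive")
        if self.C < 0 or self.D < 0:
            raise ValueError(f"patch {self.id}: D and C must be non-negative")
        if not 0 <= self.F <= self.rt.F0 * (1 + 1e-12):
            raise ValueError(f"patch {self.id}: F must lie in [0, F0]")


@dataclass
class SimulationConfig:
    """Run-level knobs shared by both allocation models.

    ``Z`` is a constant background density of competing nectar foragers
    (m⁻²) exploiting flowers with the same functional response.  With
    ``perfect_knowledge`` the hive is assumed to know every patch
    (detection probability 1); otherwise patch detection is drawn once per
    day from the scout model.  The RL stand-in parameters are the
    abandonment slope ``kappa_a``, the per-hour recruited fraction ``rho``
    of the unemployed pool and the dance-floor weight ``eps`` given to
    attractive but not-yet-occupied patches.  By default RL transitions
    use deterministic expected-value updates; ``stochastic_recruitment``
    switches to binomial sampling.
    """

    Z: float = 0.0
    perfect_knowledge: bool = True
    seed: Optional[int] = None
    model: str = "so"
    kappa_a: float = 0.3
    rho: float = 0.3
    eps: float = 0.01
    stochastic_recruitment: bool = False

    def __post_init__(self) -> None:
        if self.Z < 0:
            raise ValueError("competitor density Z must be non-negative")
        if self.model not in ("so", "rl"):
            raise ValueError("model must be 'so' or 'rl'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class RecruitmentState:
    """Forager bookkeeping for the RL model (conserved every hour)."""

    employed: Dict[str, float] = field(default_factory=dict)
    unemployed: float = 0.0

    def total(self) -> float:
        return sum(self.employed.values()) + self.unemployed


@dataclass
class ForagingDayResult:
    """Hour-by-patch record of a simulated foraging day.

    One row per (hour, patch) with positive forager allocation.  Rows
    carry everything the exposure module needs: forager count ``n``, trips
    per forager ``b``, return-flight energy ``E_c``, the patch's nectar
    energy density ``e_R`` and contamination ``C``, and the realised
    nectar/sugar deliveries.
    """

    hours: List[int] = field(default_factory=list)
    patch_ids: List[str] = field(default_factory=list)
    n: List[float] = field(default_factory=list)
    b: List[float] = field(default_factory=list)
    D: List[float] = field(default_factory=list)
    E_c: List[float] = field(default_factory=list)
    e_R: List[float] = field(default_factory=list)
    C: List[float] = field(default_factory=list)
    treated: List[bool] = field(default_factory=list)
    nectar_mg: List[float] = field(default_factory=list)
    sugar_mg: List[float] = field(default_factory=list)
    #: RL only: total foragers (employed + unemployed) after each hour
    rl_forager_totals: List[float] = field(default_factory=list)

    def add(self, hour, pid, n, b, D, E_c, e_R, C, treated, nectar, sugar) -> None:
        self.hours.append(int(hour))
        self.patch_ids.append(pid)
        self.n.append(float(n))
        self.b.append(float(b))
        self.D.append(float(D))
        self.E_c.append(float(E_c))
        self.e_R.append(float(e_R))
        self.C.append(float(C))
        self.treated.append(bool(treated))
        self.nectar_mg.append(float(nectar))
        self.sugar_mg.append(float(sugar))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per hour × exploited patch."""
        return pd.DataFrame(
            {
                "hour": self.hours,
                "patch_id": self.patch_ids,
                "n": self.n,
                "b": self.b,
                "D": self.D,
                "E_c": self.E_c,
                "e_R": self.e_R,
                "C": self.C,
                "treated": self.treated,
                "nectar_mg": self.nectar_mg,
                "sugar_mg": self.sugar_mg,
            }
        )

    @property
    def total_sugar(self) -> float:
        return float(sum(self.sugar_mg))

    @property
    def total_nectar(self) -> float:
        return float(sum(self.nectar_mg))

    def sugar_by_patch(self) -> Dict[str, float]:
        totals: Dict[str, float] = {}
        for pid, s in zip(self.patch_ids, self.sugar_mg):
            totals[pid] = totals.get(pid, 0.0) + s
        return totals

    @property
    def exploited_patches(self) -> set:
        """Patches with a positive nectar delivery at any hour."""
        return {
            pid for pid, mg in zip(self.patch_ids, self.nectar_mg) if mg > 0
        }

    def summary(self) -> dict:
        return {
            "total_sugar_mg": self.total_sugar,
            "total_nectar_mg": self.total_nectar,
            "n_exploited_patches": len(self.exploited_patches),
            "patches_for_90pct_sugar": patches_for_sugar_fraction(self, 0.9),
        }


# -- hourly building blocks --------------------------------------------------

def trips_per_hour(D: float, F: float, rt: ResourceType, bee: BeeParameters) -> float:
    """Foraging trips per forager per time step, ``b = Δt/(t_trip + t_UD)``.

    Kept continuous; zero is returned only in the degenerate ``F = 0``
    limit where the trip never completes.
    """
    t_trip = en.trip_duration(D, F, rt, bee)
    if not np.isfinite(t_trip):
        return 0.0
    return bee.dt / (t_trip + bee.t_UD)


def hourly_delivery(
    n: float, D: float, F: float, rt: ResourceType, bee: BeeParameters
) -> tuple[float, float, float]:
    """Nectar and sugar (mg) arriving at the hive this hour from one patch.

    Per trip a full load ``γ`` is collected but the return flight burns
    ``E_c = e_L D/v`` joules of it, so ``n (γ − E_c/e_R) b`` mg of nectar
    and ``n (γ e_R − E_c)/e_SUGAR b`` mg of sugar arrive.  Returns
    ``(nectar_mg, sugar_mg, b)``; infeasible patches deliver zero.
    """
    if n < 0:
        raise ValueError("forager count must be non-negative")
    if n == 0 or not en.is_feasible(D, F, rt, bee):
        return 0.0, 0.0, 0.0
    b = trips_per_hour(D, F, rt, bee)
    e_c, _ = en.return_consumption(D, rt, bee)
    nectar = n * (bee.gamma - e_c / rt.e_R) * b
    sugar = n * (bee.gamma * rt.e_R - e_c) / bee.e_sugar * b
    return nectar, sugar, b


def update_flower_density(
    patch: Patch, n: float, b: float, bee: BeeParameters, Z: float = 0.0
) -> float:
    """Synchronous hourly update of a patch's open-flower density.

    ``F' = F − (nγ/(gA)) b − f(F) Z + r (F0 − F)`` clamped to
    ``[0, F0]``: colony depletion (a full load always empties ``γ/g``
    flowers), competitor consumption through the same functional response,
    and renewal of the visited-flower pool.
    """
    rt = patch.rt
    depletion = n * bee.gamma / (rt.g * patch.A) * b
    competition = en.visit_rate(patch.F, rt) * Z
    renewal = rt.r * (rt.F0 - patch.F)
    new_F = patch.F - depletion - competition + renewal
    return float(min(max(new_F, 0.0), rt.F0))


def feasible_patches(
    patches: Sequence[Patch],
    hour: int,
    bee: BeeParameters,
    cfg: SimulationConfig,
    detected: Optional[Dict[str, bool]] = None,
) -> List[Patch]:
    """Patches exploitable this hour.

    A patch qualifies when its flowers are open (anthesis), it was
    detected, it lies within ``D_max``, it still has flowers, and the trip
    energy balance at its current density is positive.
    """
    out = []
    for p in patches:
        if not p.rt.is_open(hour):
            continue
        if detected is not None and not detected.get(p.id, True):
            continue
        if en.is_feasible(p.D, p.F, p.rt, bee):
            out.append(p)
    return out


def _draw_detection(
    patches: Sequence[Patch], bee: BeeParameters, cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Optional[Dict[str, bool]]:
    """Per-day detection draw from the scout model; None = all detected."""
    if cfg.perfect_knowledge:
        return None
    probs = en.detection_probability(
        np.array([p.sigma for p in patches]), bee.s_scouts
    )
    draws = rng.random(len(patches)) < np.asarray(probs)
    return {p.id: bool(d) for p, d in zip(patches, draws)}


def _record_and_deplete(
    result: ForagingDayResult,
    patches: Sequence[Patch],
    alloc: Dict[str, float],
    hour: int,
    bee: BeeParameters,
    cfg: SimulationConfig,
) -> None:
    """Record deliveries for this hour's allocation, then update every patch."""
    trips: Dict[str, float] = {}
    for p in patches:
        n = alloc.get(p.id, 0.0)
        if n <= 0:
            continue
        nectar, sugar, b = hourly_delivery(n, p.D, p.F, p.rt, bee)
        trips[p.id] = b
        if b > 0:
            e_c, _ = en.return_consumption(p.D, p.rt, bee)
            result.add(
                hour, p.id, n, b, p.D, e_c, p.rt.e_R, p.C, p.treated, nectar, sugar
            )
    for p in patches:
        p.F = update_flower_density(
            p, alloc.get(p.id, 0.0), trips.get(p.id, 0.0), bee, cfg.Z
        )


# -- day simulators ----------------------------------------------------------

def _sorted_copy(patches: Iterable[Patch]) -> List[Patch]:
    # stable order: the documented argmax tie-break is (NEE desc, D asc, id asc)
    return sorted(patches, key=lambda p: (p.D, p.id))


def simulate_day_so(
    patches: Sequence[Patch], bee: BeeParameters, cfg: Optional[SimulationConfig] = None
) -> ForagingDayResult:
    """Single-optimal day: all foragers on the max-NEE patch each hour.

    Deterministic given the inputs (detection is the only stochastic
    element and defaults to perfect knowledge).  Hours with no feasible
    patch contribute nothing.  Patch ``F`` attributes are mutated in
    place.
    """
    cfg = cfg or SimulationConfig(model="so")
    rng = cfg.rng()
    patches = _sorted_copy(patches)
    detected = _draw_detection(patches, bee, cfg, rng)
    result = ForagingDayResult()
    for hour in range(bee.day_hours):
        feas = feasible_patches(patches, hour, bee, cfg, detected)
        alloc: Dict[str, float] = {}
        if feas:
            # patches are pre-sorted by (D, id); max() keeps the first of
            # any exactly-tied NEE values, realising the tie-break rule
            best = max(feas, key=lambda p: en.nee(p.D, p.F, p.rt, bee))
            alloc[best.id] = float(bee.n_foragers)
        _record_and_deplete(result, patches, alloc, hour, bee, cfg)
    return result


def simulate_day_rl(
    patches: Sequence[Patch], bee: BeeParameters, cfg: Optional[SimulationConfig] = None
) -> ForagingDayResult:
    """Recruitment-limited day: dance-driven allocation over many patches.

    Hourly cycle: (1) employed foragers abandon patch *i* with probability
    ``clamp(kappa_a (1 − NEE_i/NEE*), 0, 1)`` where ``NEE*`` is the best
    current efficiency; foragers on infeasible or depleted patches abandon
    with probability 1; (2) a fraction ``rho`` of the unemployed pool is
    recruited, split across feasible patches proportionally to dance
    strength ``n_i · NEE_i⁺`` (unoccupied patches get a floor weight
    ``eps · NEE_i⁺`` so exploitation can begin); (3) deliveries and
    depletion are computed with each patch's forager count.  The forager
    budget is conserved exactly every hour.

    All foragers start the day unemployed.
    """
    cfg = cfg or SimulationConfig(model="rl")
    rng = cfg.rng()
    patches = _sorted_copy(patches)
    detected = _draw_detection(patches, bee, cfg, rng)
    state = RecruitmentState(
        employed={p.id: 0.0 for p in patches}, unemployed=float(bee.n_foragers)
    )
    result = ForagingDayResult()
    for hour in range(bee.day_hours):
        feas = feasible_patches(patches, hour, bee, cfg, detected)
        feas_ids = {p.id for p in feas}
        nee_by_id = {p.id: float(en.nee(p.D, p.F, p.rt, bee)) for p in feas}
        nee_star = max(nee_by_id.values(), default=0.0)

        # (1) abandonment
        for p in patches:
            n_i = state.employed[p.id]
            if n_i <= 0:
                continue
            if p.id not in feas_ids:
                p_ab = 1.0
            else:
                p_ab = min(max(cfg.kappa_a * (1.0 - nee_by_id[p.id] / nee_star), 0.0), 1.0)
            if cfg.stochastic_recruitment and 0 < p_ab < 1:
                leaving = float(rng.binomial(int(round(n_i)), p_ab))
                leaving = min(leaving, n_i)
            else:
                leaving = n_i * p_ab
            state.employed[p.id] = n_i - leaving
            state.unemployed += leaving

        # (2) recruitment from the dance floor
        weights = {}
        for p in feas:
            n_i = state.employed[p.id]
            w = (n_i if n_i > 0 else cfg.eps) * max(nee_by_id[p.id], 0.0)
            if w > 0:
                weights[p.id] = w
        if weights and state.unemployed > 0:
            recruits = cfg.rho * state.unemployed
            total_w = sum(weights.values())
            if cfg.stochastic_recruitment:
                ids = list(weights)
                probs = np.array([weights[i] for i in ids]) / total_w
                counts = rng.multinomial(int(round(recruits)), probs)
                for pid, k in zip(ids, counts):
                    state.employed[pid] += float(k)
                state.unemployed -= float(counts.sum())
            else:
                for pid, w in weights.items():
                    state.employed[pid] += recruits * w / total_w
                state.unemployed -= recruits

        # (3) deliveries and depletion
        _record_and_deplete(result, patches, dict(state.employed), hour, bee, cfg)
        result.rl_forager_totals.append(state.total())
    return result


def simulate_day(
    patches: Sequence[Patch], bee: BeeParameters, cfg: Optional[SimulationConfig] = None
) -> ForagingDayResult:
    """Dispatch to the SO or RL simulator according to ``cfg.model``."""
    cfg = cfg or SimulationConfig()
    if cfg.model == "rl":
        return simulate_day_rl(patches, bee, cfg)
    return simulate_day_so(patches, bee, cfg)


def patches_for_sugar_fraction(result: ForagingDayResult, q: float) -> int:
    """Smallest number of top patches covering a fraction ``q`` of the sugar.

    The field-comparable statistic "patches accounting for 90% of the
    sugar brought to the hive"; returns 0 when no sugar was collected.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    totals = sorted(result.sugar_by_patch().values(), reverse=True)
    grand = sum(totals)
    if grand <= 0:
        return 0
    acc = 0.0
    for k, s in enumerate(totals, start=1):
        acc += s
        if acc >= q * grand - 1e-12 * grand:
            return k
    return len(totals)
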