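"""Per-trip central-place foraging energetics.

A nectar-foraging trip is travel from the hive to a patch at distance
``D``, collection of a full crop load while visiting flowers under a
Holling type-II functional response, and the return flight.  The module
provides the closed-form components of that trip — visitation rate, load
time, trip duration, field and travel energy expenditure, energy intake —
and the derived decision quantities: net energetic efficiency (NEE, the
currency on which patch choice is based), the EI/EE ratio, the threshold
distance beyond which a resource can no longer be exploited with a
positive energy balance, and its mass-flowering simplification.

All rates are per second and all distances in metres; hour-level
conversions live in :mod:`beeforage.foraging`.  Every function accepts
scalars or NumPy arrays for ``F`` and ``D`` and broadcasts.

The energetic cost of sitting on flowers while drinking is ignored — it is
roughly an order of magnitude below flight cost — so handling time affects
trip *duration* but cancels out of the energy budget.
"""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np

from .params import BeeParameters, ResourceType

__all__ = [
    "visit_rate",
    "load_time",
    "trip_duration",
    "field_energy",
    "travel_energy",
    "total_energy",
    "energy_intake",
    "nee",
    "ei_ee_ratio",
    "return_consumption",
    "arriving_load",
    "threshold_distance",
    "threshold_distance_massflowering",
    "detection_probability",
    "is_feasible",
]

ArrayLike = Union[float, np.ndarray]


def _check_nonneg(x: ArrayLike, name: str) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be non-negative")


def visit_rate(F: ArrayLike, rt: ResourceType) -> ArrayLike:
    """Flowers visited per second at open-flower density ``F`` (m⁻²).

    Type-II functional response ``f = aF / (1 + ahF)``; saturates at
    ``1/h`` as flower density grows.
    """
    _check_nonneg(F, "flower density F")
    F = np.asarray(F, dtype=float)
    out = rt.a * F / (1.0 + rt.a * rt.h * F)
    return out if out.ndim else float(out)


def load_time(F: ArrayLike, rt: ResourceType, bee: BeeParameters) -> ArrayLike:
    """Seconds to fill the crop (``γ / (f g)``); infinite at ``F == 0``."""
    f = np.asarray(visit_rate(F, rt), dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(f > 0, bee.gamma / (f * rt.g), np.inf)
    return out if out.ndim else float(out)


def trip_duration(
    D: ArrayLike, F: ArrayLike, rt: ResourceType, bee: BeeParameters
) -> ArrayLike:
    """Round-trip travel plus load time: ``2D/v + γ/(fg)`` seconds."""
    _check_nonneg(D, "distance D")
    out = 2.0 * np.asarray(D, dtype=float) / bee.v + load_time(F, rt, bee)
    return out if np.ndim(out) else float(out)


def field_energy(F: ArrayLike, rt: ResourceType, bee: BeeParameters) -> ArrayLike:
    """Energy spent searching within the patch, J.

    ``(t_L − (γ/g)h) e_F`` simplifies to ``γ e_F / (g a F)``: handling time
    cancels because sitting on flowers is taken as energetically free.
    """
    _check_nonneg(F, "flower density F")
    F = np.asarray(F, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(F > 0, bee.gamma * bee.e_F / (rt.g * rt.a * F), np.inf)
    return out if out.ndim else float(out)


def travel_energy(D: ArrayLike, bee: BeeParameters) -> ArrayLike:
    """Out-and-back flight cost ``(D/v)(e_U + e_L) = 2 (D/v) e_F``, J."""
    _check_nonneg(D, "distance D")
    out = 2.0 * np.asarray(D, dtype=float) / bee.v * bee.e_F
    return out if out.ndim else float(out)


def total_energy(
    D: ArrayLike, F: ArrayLike, rt: ResourceType, bee: BeeParameters
) -> ArrayLike:
    """Total trip energy expenditure ``EE_total = EE_field + EE_travel``, J."""
    out = field_energy(F, rt, bee) + travel_energy(D, bee)
    return out if np.ndim(out) else float(out)


def energy_intake(rt: ResourceType, bee: BeeParameters) -> float:
    """Energy content of one full load, ``EI = γ e_R`` J (distance-free)."""
    return bee.gamma * rt.e_R


def nee(D: ArrayLike, F: ArrayLike, rt: ResourceType, bee: BeeParameters) -> ArrayLike:
    """Net energetic efficiency ``(EI − EE_total) / EE_total``.

    The patch-selection currency: positive exactly when the trip's energy
    balance is positive, i.e. when ``D`` is below the threshold distance.
    """
    ee = np.asarray(total_energy(D, F, rt, bee), dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isfinite(ee), (energy_intake(rt, bee) - ee) / ee, -1.0)
    return out if out.ndim else float(out)


def ei_ee_ratio(
    D: ArrayLike, F: ArrayLike, rt: ResourceType, bee: BeeParameters
) -> ArrayLike:
    """Intake-to-expenditure ratio ``gaF/(1 + c·gaF) · e_R/e_F``, ``c = 2D/(γv)``.

    Algebraically identical to ``nee + 1``; increases asymptotically with
    the nectar acquisition rate ``gaF`` toward ``(1/c) e_R/e_F``.
    """
    gaF = rt.g * rt.a * np.asarray(F, dtype=float)
    c = 2.0 * np.asarray(D, dtype=float) / (bee.gamma * bee.v)
    out = gaF / (1.0 + c * gaF) * rt.e_R / bee.e_F
    return out if np.ndim(out) else float(out)


def return_consumption(
    D: ArrayLike, rt: ResourceType, bee: BeeParameters
) -> Tuple[ArrayLike, ArrayLike]:
    """Energy burned on the return flight and its nectar equivalent.

    Returns ``(E_c, E_c / e_R)``: joules of loaded flight over ``D/v``
    seconds, and the mg of nectar metabolised to pay for it.
    """
    _check_nonneg(D, "distance D")
    e_c = bee.e_L * np.asarray(D, dtype=float) / bee.v
    nectar_mg = e_c / rt.e_R
    if np.ndim(e_c):
        return e_c, nectar_mg
    return float(e_c), float(nectar_mg)


def arriving_load(D: ArrayLike, rt: ResourceType, bee: BeeParameters) -> ArrayLike:
    """Nectar reaching the hive per trip, ``γ − E_c/e_R`` mg.

    Not clamped: a non-positive value marks the patch infeasible (the full
    load would be burned on the way home), which :func:`is_feasible`
    reports.
    """
    _, nectar_mg = return_consumption(D, rt, bee)
    out = bee.gamma - nectar_mg
    return out if np.ndim(out) else float(out)


def threshold_distance(
    rt: ResourceType, bee: BeeParameters, F: ArrayLike | None = None
) -> ArrayLike:
    """Distance at which the trip energy balance reaches zero, m.

    ``D_T = (vγ/2) [e_R/e_F − 1/(gaF)]`` evaluated at the undepleted
    density ``F0`` unless ``F`` is given.  May be negative for resources
    that are never profitable; the value is returned unclamped.
    """
    F = rt.F0 if F is None else F
    gaF = rt.g * rt.a * np.asarray(F, dtype=float)
    out = (bee.v * bee.gamma / 2.0) * (rt.e_R / bee.e_F - 1.0 / gaF)
    return out if np.ndim(out) else float(out)


def threshold_distance_massflowering(rt: ResourceType, bee: BeeParameters) -> float:
    """Mass-flowering limit of the threshold distance, ``[γv/(2e_F)] e_R`` m.

    As flower density saturates the functional response, field costs vanish
    and the threshold grows linearly with nectar energy content, with a
    slope that depends only on the bee constants.
    """
    return (bee.gamma * bee.v / (2.0 * bee.e_F)) * rt.e_R


def detection_probability(sigma: ArrayLike, s: int) -> ArrayLike:
    """Probability a patch is found by at least one of ``s`` scouts.

    ``P = 1 − (1 − σ)^s`` where ``σ`` is the per-scout encounter
    probability.
    """
    sigma_arr = np.asarray(sigma, dtype=float)
    if np.any(sigma_arr < 0) or np.any(sigma_arr > 1):
        raise ValueError("sigma must lie in [0, 1]")
    if s < 0:
        raise ValueError("scout count must be non-negative")
    out = 1.0 - (1.0 - sigma_arr) ** s
    return out if out.ndim else float(out)


def is_feasible(
    D: ArrayLike, F: ArrayLike, rt: ResourceType, bee: BeeParameters
) -> ArrayLike:
    """Whether a patch can be profitably exploited from the hive.

    Requires flowers present, the patch within the foraging range, and a
    strictly positive trip energy balance (which also guarantees a positive
    arriving load, since the return cost is part of total expenditure).
    """
    D = np.asarray(D, dtype=float)
    F = np.asarray(F, dtype=float)
    out = (F > 0) & (D <= bee.D_max) & (np.asarray(nee(D, F, rt, bee)) > 0)
    return out if out.ndim else bool(out)
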