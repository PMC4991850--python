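"""Sugar-based hive-entry concentrations and dilution factors.

A foraging day determines, per hour and patch, how many foragers made how
many trips.  When some patches carry a chemical at nectar concentration
``C_i`` (μg per mg nectar), the day's deliveries translate into a total
chemical mass and a total sugar mass entering the hive, and hence a
sugar-based daily-averaged concentration ``X`` (μg chemical per mg
sugar).  Two bookkeeping variants exist:

* the chemical is **metabolised** together with the sugar burned on the
  return flight — amount reduced, concentration preserved (``X_m``);
* it is **not metabolised** — the full collected amount arrives in a
  partially consumed load, so the nectar is *enriched* (``X_e``).

Dividing by the sugar-based reference concentration ``X_P = C_P
e_SUGAR/e_R`` on a treated reference field yields dilution factors
``φ_m = X_m/X_P`` and ``φ_e = X_e/X_P``: 1 means no dilution, 0 no
exposure, and ``φ_e`` may exceed 1 (enrichment).  A day on which no sugar
is collected has no defined concentration; this is reported as an
explicit no-exposure marker rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .foraging import ForagingDayResult
from .params import BeeParameters, ResourceType

__all__ = [
    "ExposureConfig",
    "ExposureResult",
    "chemical_influx",
    "sugar_influx",
    "hive_concentration",
    "reference_concentration",
    "dilution_factor",
    "exposure_summary",
]


@dataclass(frozen=True)
class ExposureConfig:
    """Reference treatment and metabolisation assumption.

    ``C_P`` is the nectar concentration on a treated reference field
    (μg mg⁻¹; the predicted environmental concentration).  ``metabolized``
    selects ``X_m``/``φ_m`` (default) versus the enrichment variant
    ``X_e``/``φ_e``.  ``reference`` is the resource whose ``e_R`` converts
    ``C_P`` to a sugar base.
    """

    C_P: float
    reference: ResourceType
    metabolized: bool = True

    def __post_init__(self) -> None:
        if self.C_P <= 0:
            raise ValueError("C_P must be strictly positive")


@dataclass
class ExposureResult:
    """Daily exposure bookkeeping for one hive.

    ``concentration`` and ``dilution`` are ``None`` when no sugar entered
    the hive (``no_exposure`` is then True): the day had no foraging, so
    an exposure concentration is undefined rather than zero.
    """

    chemical_ug: float
    sugar_mg: float
    concentration: Optional[float]
    dilution: Optional[float]
    metabolized: bool
    per_patch: List[dict] = field(default_factory=list)

    @property
    def no_exposure(self) -> bool:
        return self.concentration is None


def _per_patch_terms(result: ForagingDayResult):
    """Row-wise arrays (n, b, E_c, e_R, C) over the day's records."""
    n = np.asarray(result.n, dtype=float)
    b = np.asarray(result.b, dtype=float)
    e_c = np.asarray(result.E_c, dtype=float)
    e_r = np.asarray(result.e_R, dtype=float)
    c = np.asarray(result.C, dtype=float)
    return n, b, e_c, e_r, c


def chemical_influx(
    result: ForagingDayResult, bee: BeeParameters, metabolized: bool = True
) -> float:
    """Total chemical mass entering the hive over the day, μg.

    Metabolised: ``Σ n_i (γ − E_c,i/e_R,i) b_i C_i`` — the chemical is
    consumed in proportion to the sugar burned on the return flight.
    Not metabolised: ``Σ n_i γ b_i C_i`` — the full collected amount
    arrives.
    """
    n, b, e_c, e_r, c = _per_patch_terms(result)
    if metabolized:
        load = bee.gamma - e_c / e_r
    else:
        load = np.full_like(np.asarray(result.n, dtype=float), bee.gamma)
    return float(np.sum(n * load * b * c))


def sugar_influx(result: ForagingDayResult, bee: BeeParameters) -> float:
    """Total sugar entering the hive, ``Σ n_i (γ e_R,i − E_c,i)/e_SUGAR b_i`` mg."""
    n, b, e_c, e_r, _ = _per_patch_terms(result)
    return float(np.sum(n * (bee.gamma * e_r - e_c) / bee.e_sugar * b))


def reference_concentration(cfg: ExposureConfig, bee: BeeParameters) -> float:
    """Sugar-based reference concentration ``X_P = C_P e_SUGAR / e_R`` (μg mg⁻¹).

    The factor ``e_SUGAR/e_R = 1/sugar_share`` exceeds 1 whenever nectar is
    not pure sugar: concentrating nectar to a minimum sugar content raises
    the chemical concentration correspondingly.
    """
    return cfg.C_P * bee.e_sugar / cfg.reference.e_R


def hive_concentration(
    result: ForagingDayResult, cfg: ExposureConfig, bee: BeeParameters
) -> Optional[float]:
    """Sugar-based daily-averaged concentration ``X`` (μg chemical / mg sugar).

    Returns ``None`` when no sugar was delivered (no-exposure marker).
    """
    sugar = sugar_influx(result, bee)
    if sugar <= 0:
        return None
    return chemical_influx(result, bee, cfg.metabolized) / sugar


def dilution_factor(
    result: ForagingDayResult, cfg: ExposureConfig, bee: BeeParameters
) -> Optional[float]:
    """Dilution factor ``φ = X / X_P``; ``None`` when X is undefined.

    For a single-resource landscape this reduces to the treated-trip
    weighted fraction ``Σ δ_i w_i / Σ w_i`` and is independent of ``C_P``;
    ``φ_m = 1`` exactly when every exploited patch is treated at ``C_P``
    with the reference resource.
    """
    x = hive_concentration(result, cfg, bee)
    if x is None:
        return None
    return x / reference_concentration(cfg, bee)


def exposure_summary(
    result: ForagingDayResult, cfg: ExposureConfig, bee: BeeParameters
) -> ExposureResult:
    """Full exposure record for a day, with per-patch contributions."""
    chem = chemical_influx(result, bee, cfg.metabolized)
    sugar = sugar_influx(result, bee)
    x = hive_concentration(result, cfg, bee)
    phi = None if x is None else x / reference_concentration(cfg, bee)

    per_patch: dict[str, dict] = {}
    n, b, e_c, e_r, c = _per_patch_terms(result)
    load = (bee.gamma - e_c / e_r) if cfg.metabolized else np.full(len(n), bee.gamma)
    row_chem = n * load * b * c
    row_sugar = n * (bee.gamma * e_r - e_c) / bee.e_sugar * b
    for pid, ch, su, conc in zip(result.patch_ids, row_chem, row_sugar, c):
        rec = per_patch.setdefault(
            pid, {"patch_id": pid, "chemical_ug": 0.0, "sugar_mg": 0.0, "C": float(conc)}
        )
        rec["chemical_ug"] += float(ch)
        rec["sugar_mg"] += float(su)
    return ExposureResult(
        chemical_ug=chem,
        sugar_mg=sugar,
        concentration=x,
        dilution=phi,
        metabolized=cfg.metabolized,
        per_patch=list(per_patch.values()),
    )
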