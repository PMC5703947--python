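"""Deterministic dynamical core: Lotka-Volterra competition among three
prostate-cancer phenotypes plus serum-PSA kinetics.

Three phenotypes compete within a metastatic lesion during continuous
androgen-deprivation therapy (ADT):

* ``T_PLUS`` (i=1)  -- androgen-dependent cells that survive ADT only by
  "cheating" on testosterone produced by their neighbours; their carrying
  capacity is proportional to the TP abundance.
* ``TP`` (i=2)      -- CYP17A1-expressing, testosterone-producing cells;
  abiraterone collapses their carrying capacity.
* ``T_MINUS`` (i=3) -- androgen-independent, abiraterone-resistant cells.

Cell dynamics follow standard Lotka-Volterra competition,

    dx_i/dt = r_i x_i (1 - sum_j a_ij x_j / K_i),

with a unit-diagonal competition matrix ``a_ij`` (the per-capita effect of
type *j* on type *i*) and drug- and state-dependent carrying capacities.
Serum PSA is produced at one unit per cell per day and cleared at rate
0.5/day,

    dPSA/dt = sum_i x_i - 0.5 * PSA,

so at any cell-population equilibrium PSA converges to exactly twice the
total cell count.  PSA units are arbitrary; time is measured in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Phenotype",
    "PatientParams",
    "TumorState",
    "DrugStatus",
    "DEFAULT_GROWTH_RATES",
    "K_FLOOR",
    "PSA_CLEARANCE",
    "carrying_capacities",
    "lv_rhs",
]

#: In-vitro doubling-time-derived growth rates (per day) for the
#: T+, TP and T- cell lines, scaled to 10% for in-vivo realism.
DEFAULT_GROWTH_RATES = (0.0278, 0.0355, 0.0665)

#: Serum clearance rate of PSA (per day).
PSA_CLEARANCE = 0.5

#: Carrying capacities below this are treated as extinct niches: the
#: logistic bracket is replaced by -1, giving maximal per-capita decline
#: -r_i x_i.  This keeps the vector field Lipschitz when x_2 -> 0 drags
#: K_1 = c * x_2 to zero.
K_FLOOR = 1e-9


class Phenotype(IntEnum):
    """The three modelled phenotypes, indexed as i = 1, 2, 3."""

    T_PLUS = 1
    TP = 2
    T_MINUS = 3

    @property
    def idx(self) -> int:
        """Zero-based position in state vectors."""
        return int(self) - 1


@dataclass(frozen=True)
class DrugStatus:
    """Whether abiraterone is administered at this instant (on/off, no
    pharmacokinetics: the effect on carrying capacities is immediate)."""

    on: bool = False


@dataclass(frozen=True)
class PatientParams:
    """Growth rates, competition matrix and carrying-capacity policy for one
    (virtual) patient.

    Parameters
    ----------
    growth_rates
        Intrinsic per-day growth rates ``r_i`` for (T+, TP, T-).
    competition
        Unit-diagonal 3x3 matrix ``a_ij`` with off-diagonals in (0, 1);
        row = affected type, column = acting type.
    k2_off, k2_on
        TP carrying capacity without / under abiraterone (cells).
    k3
        T- carrying capacity (cells); unaffected by the drug.
    cheater_factor_off, cheater_factor_on
        T+ cells supported per TP cell (K_1 = factor * x_2) without / under
        abiraterone.
    """

    growth_rates: tuple[float, float, float] = DEFAULT_GROWTH_RATES
    competition: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    k2_off: float = 10_000.0
    k2_on: float = 100.0
    k3: float = 10_000.0
    cheater_factor_off: float = 1.5
    cheater_factor_on: float = 0.5

    def __post_init__(self) -> None:
        r = np.asarray(self.growth_rates, dtype=float)
        if r.shape != (3,) or np.any(r <= 0):
            raise ValueError("growth_rates must be 3 positive reals")
        object.__setattr__(self, "growth_rates", tuple(r))

        a = np.array(self.competition, dtype=float)
        if a.shape != (3, 3):
            raise ValueError("competition must be a 3x3 matrix")
        if not np.allclose(np.diag(a), 1.0, rtol=0, atol=0):
            raise ValueError("competition diagonal must be exactly 1")
        off = a[~np.eye(3, dtype=bool)]
        if np.any(off <= 0) or np.any(off >= 1):
            raise ValueError("off-diagonal competition entries must lie in (0, 1)")
        a.setflags(write=False)
        object.__setattr__(self, "competition", a)

        for name in ("k2_off", "k2_on", "k3", "cheater_factor_off", "cheater_factor_on"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.k2_on < self.k2_off:
            raise ValueError("k2_on must be smaller than k2_off")

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.growth_rates)

    def cheater_factor(self, drug_on: bool) -> float:
        return self.cheater_factor_on if drug_on else self.cheater_factor_off

    def k2(self, drug_on: bool) -> float:
        return self.k2_on if drug_on else self.k2_off

    def with_rescaled_capacities(self, c: float) -> "PatientParams":
        """All carrying-capacity constants multiplied by ``c`` (equilibrium
        abundances scale by ``c``; frequencies are unchanged)."""
        return PatientParams(
            growth_rates=self.growth_rates,
            competition=self.competition.copy(),
            k2_off=c * self.k2_off,
            k2_on=c * self.k2_on,
            k3=c * self.k3,
            cheater_factor_off=self.cheater_factor_off,
            cheater_factor_on=self.cheater_factor_on,
        )


@dataclass
class TumorState:
    """Cell abundances of the three phenotypes plus serum PSA at time t."""

    x: np.ndarray
    psa: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape != (3,):
            raise ValueError("x must hold the three phenotype abundances")
        if np.any(x < 0) or self.psa < 0:
            raise ValueError("abundances and PSA must be non-negative")
        self.x = x

    @property
    def total(self) -> float:
        return float(self.x.sum())

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.x.sum()
        return self.x / tot if tot > 0 else np.zeros(3)

    def as_vector(self) -> np.ndarray:
        """(x1, x2, x3, PSA) solver state."""
        return np.append(self.x, self.psa)


def _as_cells_psa(state) -> tuple[np.ndarray, float]:
    if isinstance(state, TumorState):
        return state.x, state.psa
    y = np.asarray(state, dtype=float)
    if y.shape == (4,):
        return y[:3], float(y[3])
    if y.shape == (3,):
        return y, 0.0
    raise ValueError("state must be a TumorState or a 3-/4-vector")


def carrying_capacities(state, params: PatientParams, drug: DrugStatus | bool) -> np.ndarray:
    """Carrying capacities (K_1, K_2, K_3) at the given state and drug status.

    K_1 = cheater_factor(drug) * x_2 (zero when no TP cells remain),
    K_2 switches between ``k2_off`` and ``k2_on``, K_3 is constant.
    """
    x, _ = _as_cells_psa(state)
    on = drug.on if isinstance(drug, DrugStatus) else bool(drug)
    return np.array(
        [params.cheater_factor(on) * x[1], params.k2(on), params.k3]
    )


def lv_rhs(state, params: PatientParams, drug: DrugStatus | bool,
           k_floor: float = K_FLOOR) -> np.ndarray:
    """Time derivatives (dx1, dx2, dx3, dPSA)/dt of the cell/PSA system.

    A carrying capacity below ``k_floor`` marks a vanished niche; the
    logistic bracket is then replaced by -1 (maximal per-capita decline).
    """
    x, psa = _as_cells_psa(state)
    K = carrying_capacities(x, params, drug)
    r = params.r
    ax = params.competition @ x
    dx = np.empty(4)
    for i in range(3):
        if K[i] < k_floor:
            dx[i] = -r[i] * x[i]
        else:
            dx[i] = r[i] * x[i] * (1.0 - ax[i] / K[i])
    dx[3] = x.sum() - PSA_CLEARANCE * psa
    return dx
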