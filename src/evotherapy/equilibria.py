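"""Untreated equilibrium communities, invasion analysis, and the responder
taxonomy.

Because the T+ carrying capacity is proportional to the TP abundance
(K_1 = 1.5 x_2 without drug), every steady state of the untreated system
solves a *linear* system: for each present type i,

    sum_j a_ij x_j = K_i,      with K_1 replaced by 1.5 x_2.

Communities are subsets of the three phenotypes; T+ can never persist
without TP (its niche vanishes).  The evolutionarily stable community (ESS)
is the feasible equilibrium that no absent phenotype can invade and whose
community Jacobian is non-expanding.  Patients are classified by the fate
of the resistant clone at that ESS:

* ``BEST_RESPONDER`` -- T- is strictly excluded (negative invasion fitness);
* ``RESPONDER``      -- T- persists below 20% of cells (including the
  knife-edge case of exactly neutral invasion fitness, where T- is not
  driven absent);
* ``NON_RESPONDER``  -- T- holds at least 20% of cells before any
  abiraterone is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .lv_model import PatientParams, Phenotype, TumorState, lv_rhs

__all__ = [
    "EquilibriumCommunity",
    "ResponderClass",
    "EssNotFoundError",
    "CANDIDATE_COMMUNITIES",
    "solve_community",
    "invasion_fitness",
    "untreated_ess",
    "classify_patient",
    "initialize_patient",
]

#: Tolerance below which an invasion fitness is treated as non-positive
#: (uninvadable) and above whose negation it is treated as non-negative
#: (not excluded).  Decides the knife-edge neutral cases on the default
#: coefficient grid.
FITNESS_TOL = 1e-9

#: Frequency threshold separating responders from non-responders.
NON_RESPONDER_FREQ = 0.20

#: Communities that can support every member: T+ requires TP.
CANDIDATE_COMMUNITIES = (
    frozenset({Phenotype.TP}),
    frozenset({Phenotype.T_MINUS}),
    frozenset({Phenotype.TP, Phenotype.T_MINUS}),
    frozenset({Phenotype.T_PLUS, Phenotype.TP}),
    frozenset({Phenotype.T_PLUS, Phenotype.TP, Phenotype.T_MINUS}),
)


class ResponderClass(Enum):
    BEST_RESPONDER = "best_responder"
    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"


class EssNotFoundError(RuntimeError):
    """No feasible, uninvadable community exists (model-violation signal)."""


@dataclass(frozen=True)
class EquilibriumCommunity:
    """A feasible untreated equilibrium: which phenotypes are present, their
    abundances (zeros for absent types), frequencies, and the associated
    steady-state PSA (exactly twice the total cell count)."""

    present: frozenset[Phenotype]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.abundances, dtype=float)
        x.setflags(write=False)
        object.__setattr__(self, "abundances", x)

    @property
    def total(self) -> float:
        return float(self.abundances.sum())

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.total
        return self.abundances / tot if tot > 0 else np.zeros(3)

    @property
    def psa_star(self) -> float:
        return 2.0 * self.total

    def contains(self, phenotype: Phenotype) -> bool:
        return phenotype in self.present


def solve_community(params: PatientParams,
                    present: frozenset[Phenotype] | set[Phenotype]):
    """Solve the untreated steady-state linear system for the given
    community; ``None`` if the community is infeasible (a present type
    would need non-positive abundance, T+ lacks TP, or the system is
    singular)."""
    present = frozenset(present)
    if not present:
        raise ValueError("present must be a non-empty set of phenotypes")
    if Phenotype.T_PLUS in present and Phenotype.TP not in present:
        return None  # K_1 = 1.5 x_2 vanishes without TP

    idx = sorted(p.idx for p in present)
    a = params.competition
    k_rhs = {0: 0.0, 1: params.k2_off, 2: params.k3}
    m = np.zeros((len(idx), len(idx)))
    b = np.zeros(len(idx))
    for row, i in enumerate(idx):
        for col, j in enumerate(idx):
            m[row, col] = a[i, j]
            if i == 0 and j == 1:
                # move K_1 = cheater_factor_off * x_2 to the left-hand side
                m[row, col] -= params.cheater_factor_off
        b[row] = k_rhs[i]
    try:
        sol = np.linalg.solve(m, b)
    except np.linalg.LinAlgError:
        return None
    if np.any(sol <= 0):
        return None
    x = np.zeros(3)
    x[idx] = sol
    return EquilibriumCommunity(present=present, abundances=x)


def invasion_fitness(params: PatientParams,
                     resident: EquilibriumCommunity,
                     invader: Phenotype) -> float:
    """Per-capita growth sign of a rare invader at the resident equilibrium,
    up to the positive factor r_i: the bracket 1 - sum_j a_ij x_j / K_i.

    Returns -1 when the invader's niche is absent (T+ invading a community
    with no TP cells).  An empty resident gives +1 for any viable invader.
    """
    if resident.contains(invader):
        raise ValueError("invader must be absent from the resident community")
    x = resident.abundances
    i = invader.idx
    if invader is Phenotype.T_PLUS:
        k = params.cheater_factor_off * x[1]
        if k <= 0:
            return -1.0
    elif invader is Phenotype.TP:
        k = params.k2_off
    else:
        k = params.k3
    return float(1.0 - params.competition[i] @ x / k)


def _community_jacobian(params: PatientParams, x: np.ndarray,
                        eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the untreated cell dynamics at x;
    the K_1 = 1.5 x_2 coupling is differentiated through automatically."""
    jac = np.empty((3, 3))
    for j in range(3):
        h = max(eps, eps * abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        fp = lv_rhs(np.append(xp, 0.0), params, False)[:3]
        fm = lv_rhs(np.append(xm, 0.0), params, False)[:3]
        jac[:, j] = (fp - fm) / (xp[j] - xm[j])
    return jac


def _is_stable(params: PatientParams, community: EquilibriumCommunity) -> bool:
    eig = np.linalg.eigvals(_community_jacobian(params, community.abundances))
    scale = max(params.r.max(), 1e-12)
    return bool(np.all(eig.real <= FITNESS_TOL * scale + 1e-7 * scale))


def _settle(params: PatientParams, horizon: float = 20_000.0) -> np.ndarray:
    """Long-run untreated integration from a 25% start seeded with one cell
    of every type; used to arbitrate between multiple uninvadable
    communities and as an independent cross-check."""
    from scipy.integrate import solve_ivp

    start = np.array([1.0, 1.0, 1.0])
    for comm in (solve_community(params, c) for c in CANDIDATE_COMMUNITIES):
        if comm is not None:
            start = np.maximum(start, 0.25 * comm.abundances)
    sol = solve_ivp(
        lambda t, y: lv_rhs(y, params, False),
        (0.0, horizon),
        np.append(start, 2.0 * start.sum()),
        method="LSODA", rtol=1e-8, atol=1e-10,
    )
    return sol.y[:3, -1]


def untreated_ess(params: PatientParams) -> EquilibriumCommunity:
    """The evolutionarily stable untreated community: feasible, uninvadable
    by every absent phenotype, and internally stable.

    Raises :class:`EssNotFoundError` if no candidate qualifies.  If several
    qualify (possible only on degenerate parameter sets) the one reached by
    forward integration from an all-types inoculum is returned.
    """
    qualifying = []
    for candidate in CANDIDATE_COMMUNITIES:
        comm = solve_community(params, candidate)
        if comm is None:
            continue
        absent = [p for p in Phenotype if not comm.contains(p)]
        if any(invasion_fitness(params, comm, p) > FITNESS_TOL for p in absent):
            continue
        if not _is_stable(params, comm):
            continue
        qualifying.append(comm)
    if not qualifying:
        raise EssNotFoundError(
            "no uninvadable feasible community on this parameter set"
        )
    if len(qualifying) == 1:
        return qualifying[0]
    import warnings

    warnings.warn(
        "multiple uninvadable communities; choosing the one reached by "
        "forward integration", stacklevel=2,
    )
    final = _settle(params)
    tot = final.sum()
    best, best_err = None, np.inf
    for comm in qualifying:
        err = np.abs(comm.abundances - final).sum() / tot
        if err < best_err:
            best, best_err = comm, err
    return best


def classify_patient(params: PatientParams) -> ResponderClass:
    """Responder taxonomy from the untreated ESS.

    T- absent with strictly negative invasion fitness -> BEST_RESPONDER;
    T- at or above 20% of cells -> NON_RESPONDER; otherwise RESPONDER.
    A neutrally invading T- (fitness within :data:`FITNESS_TOL` of zero)
    is counted as present at marginal frequency, i.e. RESPONDER.
    """
    ess = untreated_ess(params)
    if ess.contains(Phenotype.T_MINUS):
        freq = ess.frequencies[Phenotype.T_MINUS.idx]
        if freq >= NON_RESPONDER_FREQ - 1e-9:
            return ResponderClass.NON_RESPONDER
        return ResponderClass.RESPONDER
    fitness = invasion_fitness(params, ess, Phenotype.T_MINUS)
    if fitness < -FITNESS_TOL:
        return ResponderClass.BEST_RESPONDER
    return ResponderClass.RESPONDER


def initialize_patient(params: PatientParams,
                       tminus_inoculum: float = 1.0,
                       fraction: float = 0.25) -> TumorState:
    """Pre-abiraterone initial state: ESS frequencies at ``fraction``
    (default 25%) of the untreated equilibrium size, PSA at the same
    fraction of the equilibrium PSA.

    When the ESS contains no T- cells, a fixed inoculum (default one cell)
    is planted at t = 0; it decays while therapy is off (negative invasion
    fitness) and is competitively released under treatment.  An inoculum of
    zero keeps T- identically zero for all time.
    """
    if tminus_inoculum < 0:
        raise ValueError("tminus_inoculum must be non-negative")
    ess = untreated_ess(params)
    x = fraction * ess.abundances
    if not ess.contains(Phenotype.T_MINUS):
        x[Phenotype.T_MINUS.idx] = tminus_inoculum
    return TumorState(x=x, psa=fraction * ess.psa_star, t=0.0)
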