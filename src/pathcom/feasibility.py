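"""Linear-feasibility oracle for mechanism compatibility.

A mechanism is compatible with an occupancy vector exactly when nonnegative
steady-state dwell fractions can be placed on its occupied DNA states so
that, for every factor, the dwell summed over states containing it equals
the observed percent occupancy.  That is a linear feasibility problem; a
phase-1 LP (minimize the total artificial slack on the per-factor equality
constraints) decides it exactly up to solver tolerance, independently of
the two compatibility rules, and therefore serves as their oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .mechanisms import FactorOrder, Mechanism, StateCycle, build_state_cycle, enumerate_dissociations

__all__ = ["FeasibilityResult", "lp_feasible", "oracle_matrix", "divergence_report"]

logger = logging.getLogger(__name__)

#: Phase-1 optimum below which the system is declared feasible.
FEASIBILITY_TOL = 1e-7


@dataclass(frozen=True)
class FeasibilityResult:
    """Outcome of the dwell-fraction feasibility test.

    ``residual`` is the squared equality violation (percent^2) at the
    phase-1 optimum; ``certificate`` — present only when infeasible — maps
    each factor to a dual weight y with y.occ > 0 while y restricted to any
    occupied state sums to <= 0 (a Farkas witness that no dwell assignment
    can reproduce the data).
    """

    feasible: bool
    residual: float
    certificate: dict[str, float] | None = None


def lp_feasible(
    cycle: StateCycle,
    occ: Mapping[str, float],
    cap_total: bool = False,
) -> FeasibilityResult:
    """Decide whether nonnegative dwell fractions can reproduce ``occ``.

    Solves: does there exist f(S) >= 0 for every occupied state S with
    sum_{S containing i} f(S) = occ(i) for each factor i (and, when
    ``cap_total``, sum_S f(S) <= 100)?

    Implemented as a phase-1 LP minimizing the total artificial slack
    u + v with  A f + u - v = occ;  feasible iff the optimum is at most
    :data:`FEASIBILITY_TOL`.
    """
    codes = sorted({c for s in cycle.occupied_states for c in s} | set(occ))
    occ_vec = np.array([float(occ[c]) for c in codes])
    states = cycle.occupied_states
    m = len(states)
    k = len(codes)

    if m == 0:
        # No occupied states at all: only the all-zero occupancy is attainable.
        resid = float(np.sum(occ_vec**2))
        if resid <= FEASIBILITY_TOL:
            return FeasibilityResult(feasible=True, residual=resid)
        cert = {c: 1.0 if occ[c] > 0 else 0.0 for c in codes}
        return FeasibilityResult(feasible=False, residual=resid, certificate=cert)

    A = np.zeros((k, m))
    for j, s in enumerate(states):
        for c in s:
            A[codes.index(c), j] = 1.0

    # Variables: [f (m), u (k), v (k)]; minimize sum(u) + sum(v).
    c_obj = np.concatenate([np.zeros(m), np.ones(2 * k)])
    A_eq = np.hstack([A, np.eye(k), -np.eye(k)])
    b_eq = occ_vec
    A_ub = b_ub = None
    if cap_total:
        A_ub = np.concatenate([np.ones(m), np.zeros(2 * k)])[None, :]
        b_ub = np.array([100.0])

    res = linprog(
        c_obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=(0, None), method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"phase-1 LP failed: {res.message}")

    f = res.x[:m]
    viol = A @ f - occ_vec
    residual = float(viol @ viol)
    if res.fun <= FEASIBILITY_TOL:
        return FeasibilityResult(feasible=True, residual=residual)
    # Dual of the equality constraints is a Farkas-type infeasibility witness.
    marginals = np.asarray(res.eqlin.marginals, dtype=float)
    cert = dict(zip(codes, marginals.tolist()))
    return FeasibilityResult(feasible=False, residual=residual, certificate=cert)


def oracle_matrix(
    assoc: FactorOrder,
    table: pd.DataFrame,
    cap_total: bool = False,
) -> pd.DataFrame:
    """Groups x mechanisms chart decided cell-by-cell by the LP oracle.

    Mirrors :func:`pathcom.compatibility.compatibility_matrix` (-1/0
    encoding, same labels) but answers each cell with :func:`lp_feasible`.
    """
    if len(table) == 0:
        raise ValueError("empty occupancy table")
    missing = set(assoc.codes) - set(table.columns)
    if missing:
        raise ValueError(f"occupancy table lacks factor columns {sorted(missing)}")
    mechs = enumerate_dissociations(assoc)
    cycles = [build_state_cycle(m) for m in mechs]
    data = {}
    for group, row in table.iterrows():
        occ = {c: float(row[c]) for c in assoc.codes}
        data[group] = [
            -1 if lp_feasible(cyc, occ, cap_total=cap_total).feasible else 0
            for cyc in cycles
        ]
    out = pd.DataFrame.from_dict(
        data, orient="index", columns=[m.mechanism_id for m in mechs]
    )
    out.index.name = table.index.name
    return out


def divergence_report(
    assoc: FactorOrder,
    vectors: Sequence[Mapping[str, float]],
    mechanisms: Sequence[Mechanism] | None = None,
) -> list[dict]:
    """Compare the rule-based verdict with the LP oracle over given vectors.

    Every (vector, mechanism) cell where the two disagree is logged and
    returned; an empty list means exact agreement on the tested cells.
    Divergences are surfaced, never silently discarded — for four or more
    factors the equivalence of the two routes is an empirical claim that
    this report is designed to probe.
    """
    from .compatibility import is_compatible

    if mechanisms is None:
        mechanisms = enumerate_dissociations(assoc)
    cycles = {m.mechanism_id: build_state_cycle(m) for m in mechanisms}
    out: list[dict] = []
    for vi, occ in enumerate(vectors):
        for mech in mechanisms:
            rules = is_compatible(mech, occ)
            lp = lp_feasible(cycles[mech.mechanism_id], occ).feasible
            if rules != lp:
                rec = {
                    "vector_index": vi,
                    "occ": dict(occ),
                    "mechanism_id": mech.mechanism_id,
                    "dissociation": "".join(mech.dissociation),
                    "rules": rules,
                    "lp": lp,
                }
                logger.warning("rule/LP divergence: %s", rec)
                out.append(rec)
    return out
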