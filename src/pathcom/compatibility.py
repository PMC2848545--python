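"""Rule-based compatibility of occupancy data with dissociation mechanisms.

ChIP occupancy is taken to measure the fraction of DNA molecules bound by a
factor, i.e. the summed steady-state dwell of all cycle states containing
that factor.  Two rules decide whether a percent-occupancy vector can arise
under a given mechanism:

Rule 1 (pairwise nesting).  If every occupied state containing factor *i*
also contains factor *j* — which happens exactly when *j* associates before
*i* and dissociates after *i* — then the mechanism forces
``occ(i) <= occ(j)``.  Data with ``occ(i) > occ(j)`` reject it.

Rule 2 (triple sums).  A middle factor *m* whose occupancy strictly exceeds
``occ(a) + occ(b)`` for some earlier-associating *a* and later-associating
*b* must at some point sit on DNA without either, which requires *m* to
dissociate after both.  Mechanisms in which it does not are rejected.

Together the rules produce the groups x mechanisms compatibility chart,
encoded -1 (compatible) / 0 (incompatible).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .mechanisms import FactorOrder, Mechanism, enumerate_dissociations

__all__ = [
    "EPS",
    "rule1_allows",
    "rule2_allows",
    "is_compatible",
    "compatibility_matrix",
]

#: Numeric tolerance on the percent scale; preprocessing round-off must not
#: flip a compatibility decision, so all strict comparisons use this slack.
EPS = 1e-9

OccupancyVector = Mapping[str, float]


def _check_occ(mech: Mechanism, occ: OccupancyVector) -> None:
    if set(occ) != set(mech.association.codes):
        raise ValueError(
            f"occupancy factors {sorted(occ)} do not match mechanism factors "
            f"{sorted(mech.association.codes)}"
        )
    for code, v in occ.items():
        v = float(v)
        if not (v == v) or v in (float("inf"), float("-inf")):
            raise ValueError(f"occupancy for {code!r} is not finite")
        if v < -EPS or v > 100 + EPS:
            raise ValueError(f"occupancy for {code!r} outside [0, 100]: {v}")


def rule1_allows(mech: Mechanism, occ: OccupancyVector) -> bool:
    """Pairwise rule: no factor may out-occupy a factor whose presence it implies.

    Returns ``False`` iff some pair (i, j) has j associating before i and
    dissociating after i while ``occ(i) > occ(j)`` (strictly, beyond
    :data:`EPS`).  Equal occupancies are always allowed.
    """
    _check_occ(mech, occ)
    codes = mech.association.codes
    for i in codes:
        for j in codes:
            if i == j:
                continue
            nested = (
                mech.association.rank(j) < mech.association.rank(i)
                and mech.dissociation_rank(j) > mech.dissociation_rank(i)
            )
            if nested and occ[i] > occ[j] + EPS:
                return False
    return True


def rule2_allows(mech: Mechanism, occ: OccupancyVector) -> bool:
    """Triple rule: a dominant middle factor must dissociate after its neighbours.

    Returns ``False`` iff some triple (a, m, b) — a associating before m, b
    after m — has ``occ(m) > occ(a) + occ(b)`` (strictly) while m does not
    dissociate after both a and b.  Vacuously ``True`` for fewer than three
    factors.
    """
    _check_occ(mech, occ)
    codes = mech.association.codes
    n = len(codes)
    if n < 3:
        return True
    for mi in range(1, n - 1):
        m = codes[mi]
        for a in codes[:mi]:
            for b in codes[mi + 1 :]:
                if occ[m] > occ[a] + occ[b] + EPS:
                    if not (
                        mech.dissociation_rank(m) > mech.dissociation_rank(a)
                        and mech.dissociation_rank(m) > mech.dissociation_rank(b)
                    ):
                        return False
    return True


def is_compatible(mech: Mechanism, occ: OccupancyVector) -> bool:
    """Both rules must allow the mechanism."""
    return rule1_allows(mech, occ) and rule2_allows(mech, occ)


def compatibility_matrix(assoc: FactorOrder, table: pd.DataFrame) -> pd.DataFrame:
    """Compatibility chart of every group (row) against every mechanism.

    Parameters
    ----------
    assoc
        Fixed association order.
    table
        Occupancy table: one row per gene group, one column per factor code
        (percent occupancies in [0, 100]); the index holds group names.

    Returns
    -------
    DataFrame of shape ``(len(table), n!)`` with mechanism ids as columns
    and cells -1 (compatible) or 0 (incompatible).
    """
    if len(table) == 0:
        raise ValueError("empty occupancy table")
    missing = set(assoc.codes) - set(table.columns)
    if missing:
        raise ValueError(f"occupancy table lacks factor columns {sorted(missing)}")
    mechs = enumerate_dissociations(assoc)
    data = {}
    for group, row in table.iterrows():
        occ = {c: float(row[c]) for c in assoc.codes}
        data[group] = [-1 if is_compatible(m, occ) else 0 for m in mechs]
    out = pd.DataFrame.from_dict(
        data, orient="index", columns=[m.mechanism_id for m in mechs]
    )
    out.index.name = table.index.name
    return out
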