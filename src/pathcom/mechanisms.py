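"""Association/dissociation mechanisms and the DNA-state cycles they imply.

A *mechanism* is a fixed order in which factors associate onto DNA paired
with one order in which they dissociate.  For ``n`` factors and a fixed
association order there are ``n!`` candidate dissociation orders; each
mechanism determines a cycle of DNA-bound factor subsets, from the empty
promoter up through the full complex and back down to empty.  Everything
downstream (the compatibility rules, the linear-feasibility oracle and the
kinetic models) is phrased in terms of these state cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterator, Sequence

__all__ = [
    "FactorOrder",
    "Mechanism",
    "StateCycle",
    "enumerate_dissociations",
    "build_state_cycle",
    "mechanism_key",
]

#: Practical bound on the number of factors (n! mechanisms are enumerated).
MAX_FACTORS = 8


class MechanismError(ValueError):
    """Invalid factor order or mechanism definition."""


@dataclass(frozen=True)
class FactorOrder:
    """An ordered set of factor codes defining the association pathway.

    Parameters
    ----------
    codes
        Distinct single-character factor codes in the order the factors
        assemble onto DNA (position = association rank, 1-based).
    """

    codes: tuple[str, ...]

    def __init__(self, codes: Sequence[str]) -> None:
        codes = tuple(codes)
        if len(codes) == 0:
            raise MechanismError("empty factor order: at least one factor required")
        if len(codes) > MAX_FACTORS:
            raise MechanismError(
                f"{len(codes)} factors exceeds the practical bound of {MAX_FACTORS}"
            )
        for c in codes:
            if len(c) != 1 or c.isspace() or not c.isprintable():
                raise MechanismError(
                    f"factor code {c!r} is not a single printable non-whitespace character"
                )
        if len(set(codes)) != len(codes):
            raise MechanismError(f"duplicate factor codes in {codes!r}")
        object.__setattr__(self, "codes", codes)

    @property
    def n(self) -> int:
        return len(self.codes)

    def rank(self, code: str) -> int:
        """1-based association rank of ``code``."""
        try:
            return self.codes.index(code) + 1
        except ValueError:
            raise MechanismError(f"unknown factor code {code!r}") from None

    def __str__(self) -> str:
        return "".join(self.codes)


@dataclass(frozen=True)
class Mechanism:
    """A fixed association order paired with one dissociation order.

    ``mechanism_id`` is the 1-based position of the dissociation permutation
    in the canonical enumeration: lexicographic over dissociation sequences
    expressed in association-rank indices (so id 1 is always "factors leave
    in the order they arrived", and id n! is the fully last-in-first-out
    reversal).
    """

    association: FactorOrder
    dissociation: tuple[str, ...]
    mechanism_id: int

    def __post_init__(self) -> None:
        if sorted(self.dissociation) != sorted(self.association.codes):
            raise MechanismError(
                f"dissociation {self.dissociation!r} is not a permutation of "
                f"association codes {self.association.codes!r}"
            )
        if self.mechanism_id < 1:
            raise MechanismError("mechanism_id must be >= 1")

    @property
    def n(self) -> int:
        return self.association.n

    def dissociation_rank(self, code: str) -> int:
        """1-based position of ``code`` in the dissociation order."""
        try:
            return self.dissociation.index(code) + 1
        except ValueError:
            raise MechanismError(f"unknown factor code {code!r}") from None

    def __str__(self) -> str:
        return f"{self.association}|{''.join(self.dissociation)}#{self.mechanism_id}"


@dataclass(frozen=True)
class StateCycle:
    """The chain of DNA-bound factor subsets a mechanism traverses.

    ``states`` runs from the first assembly intermediate through the full
    complex, down the disassembly intermediates, and ends with the empty
    set: 2n entries in total, consecutive entries differing by exactly one
    factor.  ``occupied_states`` are the distinct non-empty subsets (the
    assembly and disassembly legs may share subsets, e.g. a lone first
    factor both before the second arrives and after it has left).
    """

    states: tuple[frozenset[str], ...]
    occupied_states: tuple[frozenset[str], ...] = field(init=False)

    def __post_init__(self) -> None:
        seen: list[frozenset[str]] = []
        for s in self.states:
            if s and s not in seen:
                seen.append(s)
        object.__setattr__(self, "occupied_states", tuple(seen))

    def states_containing(self, code: str) -> tuple[frozenset[str], ...]:
        return tuple(s for s in self.occupied_states if code in s)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.states)


def enumerate_dissociations(assoc: FactorOrder) -> list[Mechanism]:
    """Enumerate all ``n!`` dissociation orders for a fixed association order.

    The ordering is canonical and deterministic: lexicographic over the
    dissociation permutations written in association-rank indices, with
    ``mechanism_id`` equal to the 1-based position.  Changing the
    association order permutes which sequence carries which id but never
    the set of sequences.
    """
    mechs = []
    for i, perm in enumerate(permutations(assoc.codes), start=1):
        mechs.append(Mechanism(association=assoc, dissociation=perm, mechanism_id=i))
    return mechs


def build_state_cycle(mech: Mechanism) -> StateCycle:
    """Construct the cycle of bound-factor subsets implied by a mechanism.

    Assembly adds factors in association order (n states, ending at the
    full complex); disassembly removes them in dissociation order (n - 1
    further occupied states, then the empty set).
    """
    states: list[frozenset[str]] = []
    bound: set[str] = set()
    for code in mech.association.codes:
        bound.add(code)
        states.append(frozenset(bound))
    for code in mech.dissociation[:-1]:
        bound.discard(code)
        states.append(frozenset(bound))
    states.append(frozenset())
    return StateCycle(states=tuple(states))


def mechanism_key(assoc: FactorOrder) -> list[tuple[int, str]]:
    """Map each mechanism id to its dissociation sequence string.

    Returns one ``(id, sequence)`` row per mechanism, ids ascending and
    matching :func:`enumerate_dissociations`.
    """
    return [
        (m.mechanism_id, "".join(m.dissociation))
        for m in enumerate_dissociations(assoc)
    ]
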