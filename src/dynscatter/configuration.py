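"""Per-atom electronic configurations.

A configuration is the ordered occupation vector over the non-relativistic
subshells (1s, 2s, 2p, 3s, 3p, 3d, ...).  It is the state label ``C_j(t)``
that every rate and form factor in the dynamic-scattering model depends on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .constants import ATOMIC_NUMBER

# subshell ladder in filling order used for ground states of the light
# elements and argon handled here (no transition metals -> simple Aufbau)
SUBSHELLS = ("1s", "2s", "2p", "3s", "3p", "3d", "4s", "4p")
_L_OF = {"s": 0, "p": 1, "d": 2, "f": 3}


def subshell_n_l(name: str) -> tuple[int, int]:
    return int(name[:-1]), _L_OF[name[-1]]


def subshell_capacity(name: str) -> int:
    _, l = subshell_n_l(name)
    return 2 * (2 * l + 1)


class InvalidConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ElectronicConfiguration:
    """Occupation vector of an atom/ion.

    Parameters
    ----------
    element:
        Chemical symbol ("H", "C", "O", "Ar").
    occupations:
        Integer occupation per subshell in the order of :data:`SUBSHELLS`,
        truncated at the last non-empty subshell.
    """

    element: str
    occupations: tuple[int, ...]

    def __post_init__(self):
        if self.element not in ATOMIC_NUMBER:
            raise InvalidConfigurationError(f"unknown element {self.element!r}")
        occ = tuple(int(o) for o in self.occupations)
        if len(occ) > len(SUBSHELLS):
            raise InvalidConfigurationError("occupation vector longer than subshell ladder")
        for name, o in zip(SUBSHELLS, occ):
            if o < 0 or o > subshell_capacity(name):
                raise InvalidConfigurationError(
                    f"occupation {o} outside [0, {subshell_capacity(name)}] for {name}"
                )
        if sum(occ) > self.atomic_number:
            raise InvalidConfigurationError(
                f"{sum(occ)} electrons exceed Z={self.atomic_number} for {self.element}"
            )
        object.__setattr__(self, "occupations", occ)

    # -- basic bookkeeping -------------------------------------------------
    @property
    def atomic_number(self) -> int:
        return ATOMIC_NUMBER[self.element]

    @property
    def n_electrons(self) -> int:
        return sum(self.occupations)

    @property
    def charge(self) -> int:
        return self.atomic_number - self.n_electrons

    def occupation(self, subshell: str) -> int:
        try:
            i = SUBSHELLS.index(subshell)
        except ValueError:
            raise InvalidConfigurationError(f"unknown subshell {subshell!r}") from None
        return self.occupations[i] if i < len(self.occupations) else 0

    def holes(self, subshell: str) -> int:
        return subshell_capacity(subshell) - self.occupation(subshell)

    @property
    def occupied_subshells(self) -> tuple[str, ...]:
        return tuple(s for s, o in zip(SUBSHELLS, self.occupations) if o > 0)

    # -- derived configurations -------------------------------------------
    def remove(self, subshell: str) -> "ElectronicConfiguration":
        return self._shift(subshell, -1)

    def add(self, subshell: str) -> "ElectronicConfiguration":
        return self._shift(subshell, +1)

    def excite(self, src: str, dst: str) -> "ElectronicConfiguration":
        return self.remove(src).add(dst)

    def _shift(self, subshell: str, delta: int) -> "ElectronicConfiguration":
        try:
            i = SUBSHELLS.index(subshell)
        except ValueError:
            raise InvalidConfigurationError(f"unknown subshell {subshell!r}") from None
        occ = list(self.occupations) + [0] * (i + 1 - len(self.occupations))
        occ[i] += delta
        while occ and occ[-1] == 0:
            occ.pop()
        return ElectronicConfiguration(self.element, tuple(occ))

    def __str__(self) -> str:
        if not self.occupations:
            return f"{self.element}(bare)"
        body = "".join(
            f"{s}{o}" for s, o in zip(SUBSHELLS, self.occupations) if o > 0
        )
        return f"{self.element}[{body}]"


@lru_cache(maxsize=None)
def ground_state(element: str) -> ElectronicConfiguration:
    """Aufbau ground-state configuration of the neutral atom."""
    z = ATOMIC_NUMBER.get(element)
    if z is None:
        raise InvalidConfigurationError(f"unknown element {element!r}")
    occ = []
    left = z
    for name in SUBSHELLS:
        cap = subshell_capacity(name)
        take = min(cap, left)
        occ.append(take)
        left -= take
        if left == 0:
            break
    return ElectronicConfiguration(element, tuple(occ))
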