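"""Closed-form overall stoichiometry of CO (+ H2) conversion to ethanol.

For an ethanol-only product spectrum the overall conversion per mol CO is
fixed by carbon and electron conservation alone. With r = mol H2 consumed
per mol CO consumed, the electron balance 2 + 2r = 12*E (E = ethanol per CO,
ethanol carrying 12 available electrons) gives

    ethanol yield      Y(r) = (1 + r) / 6          for r <= 2
    CO2 loss fraction  f(r) = 1 - 2*Y(r) = (2 - r)/3 for r <= 2

At r = 2 every carbon is retained (f = 0); beyond r = 2 the ethanol-only
spectrum cannot consume the surplus H2, so f stays 0 and Y is capped at the
carbon limit 1/2. Limiting cases: 6 CO + 3 H2O -> C2H5OH + 4 CO2 (r = 0)
and 2 CO + 4 H2 -> C2H5OH + H2O (r = 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "OverallStoichiometry",
    "co2_loss_fraction",
    "ethanol_yield",
    "overall_stoichiometry",
]

#: Elemental composition of the species in the overall equation.
_ELEMENTS: Mapping[str, Mapping[str, float]] = {
    "co": {"C": 1, "O": 1},
    "h2": {"H": 2},
    "h2o": {"H": 2, "O": 1},
    "ethanol": {"C": 2, "H": 6, "O": 1},
    "co2": {"C": 1, "O": 2},
}


@dataclass(frozen=True)
class OverallStoichiometry:
    """Balanced overall equation per mol CO consumed.

    Sign convention: consumption positive, production negative (so the CO
    coefficient is +1 and ethanol's is negative).
    """

    co: float
    h2: float
    h2o: float
    ethanol: float
    co2: float

    @property
    def coefficients(self) -> dict[str, float]:
        return {
            "co": self.co,
            "h2": self.h2,
            "h2o": self.h2o,
            "ethanol": self.ethanol,
            "co2": self.co2,
        }

    def element_imbalance(self) -> dict[str, float]:
        """Net atoms consumed minus produced per element (zero if balanced)."""
        out: dict[str, float] = {"C": 0.0, "H": 0.0, "O": 0.0}
        for species, coeff in self.coefficients.items():
            for element, count in _ELEMENTS[species].items():
                out[element] += coeff * count
        return out

    def is_balanced(self, tol: float = 1e-12) -> bool:
        return all(abs(v) <= tol for v in self.element_imbalance().values())

    def equation(self) -> str:
        """Human-readable equation with integer-friendly formatting."""
        lhs = [(s, c) for s, c in self.coefficients.items() if c > 0]
        rhs = [(s, -c) for s, c in self.coefficients.items() if c < 0]
        fmt = lambda side: " + ".join(f"{c:.4g} {s}" for s, c in side)  # noqa: E731
        return f"{fmt(lhs)} -> {fmt(rhs)}"


def co2_loss_fraction(r: float) -> float:
    """Fraction of consumed CO carbon lost as CO2 at H2/CO uptake ratio r.

    f = (2 - r)/3 on [0, 2], and 0 beyond (continuous at r = 2).
    """
    if r < 0:
        raise ValueError("H2/CO uptake ratio must be non-negative")
    if r > 2.0:
        return 0.0
    return (2.0 - r) / 3.0


def ethanol_yield(r: float) -> float:
    """Mol ethanol per mol CO at H2/CO uptake ratio r.

    Y = (1 + r)/6 on [0, 2]; carbon-limited at 1/2 beyond.
    """
    if r < 0:
        raise ValueError("H2/CO uptake ratio must be non-negative")
    if r > 2.0:
        return 0.5
    return (1.0 + r) / 6.0


def overall_stoichiometry(r: float) -> OverallStoichiometry:
    """Balanced overall equation per mol CO at uptake ratio r in [0, 2].

    The water coefficient follows from the oxygen balance: (1 - r)/2, i.e.
    water is consumed below r = 1 and produced above. r > 2 is rejected
    (the surplus H2 cannot be consumed by an ethanol-only spectrum);
    callers wanting the clamped behaviour should use
    :func:`co2_loss_fraction` / :func:`ethanol_yield`.
    """
    if r < 0:
        raise ValueError("H2/CO uptake ratio must be non-negative")
    if r > 2.0:
        raise ValueError(
            "r > 2 leaves H2 unconsumed in an ethanol-only stoichiometry; "
            "clamp to 2 for the zero-CO2-loss limit"
        )
    st = OverallStoichiometry(
        co=1.0,
        h2=r,
        h2o=(1.0 - r) / 2.0,
        ethanol=-ethanol_yield(r),
        co2=-co2_loss_fraction(r),
    )
    assert st.is_balanced(1e-9)
    return st
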