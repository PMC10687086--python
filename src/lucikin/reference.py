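"""Published kinetic constants for NanoLuc luciferase variants.

Steady-state constants (mean ± s.d., n = 3) for the wild-type enzyme and
three allosteric-site mutants with the two imidazopyrazinone luciferins,
coelenterazine (CTZ) and furimazine (FMZ).  Values are stored together with
their printed specificity constants (k_cat/K_m) as strings so the printed
decimal precision is recoverable; one row (the triple mutant with CTZ) is
known to be internally inconsistent — its printed ratio differs from
k_cat ÷ K_m beyond printing precision — and consistency checks flag it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetic_core import KineticParams

__all__ = [
    "ReferenceRow",
    "TABLE_ROWS",
    "reference_params",
    "printed_decimals",
    "ratio_consistent_with_printed",
]

WILD_TYPE = "NanoLuc"
TRIPLE_MUTANT = "NanoLuc-D9R/H57A/K89R"


@dataclass(frozen=True)
class ReferenceRow:
    variant: str
    luciferin: str  # "CTZ" or "FMZ"
    K_m: float
    se_K_m: float
    k_cat: float
    se_k_cat: float
    K_p: float
    se_K_p: float
    printed_specificity: str  # k_cat/K_m as printed, string keeps precision
    se_specificity: float

    @property
    def params(self) -> KineticParams:
        return KineticParams(k_cat=self.k_cat, K_m=self.K_m, K_p=self.K_p)


TABLE_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow(WILD_TYPE, "CTZ", 0.57, 0.02, 2.48, 0.05, 0.256, 0.005, "4.4", 0.2),
    ReferenceRow("NanoLuc-Y94A", "CTZ", 3.74, 0.09, 0.225, 0.004, 0.79, 0.04, "0.060", 0.001),
    ReferenceRow("NanoLuc-D9R/K89R", "CTZ", 0.46, 0.01, 16.8, 0.6, 0.163, 0.006, "37", 1.0),
    ReferenceRow(TRIPLE_MUTANT, "CTZ", 0.77, 0.07, 40.0, 4.0, 0.23, 0.02, "70", 7.0),
    ReferenceRow(WILD_TYPE, "FMZ", 0.123, 0.004, 7.88, 0.03, 0.56, 0.01, "64", 2.0),
    ReferenceRow("NanoLuc-Y94A", "FMZ", 1.29, 0.02, 0.519, 0.007, 0.85, 0.02, "0.402", 0.006),
    ReferenceRow("NanoLuc-D9R/K89R", "FMZ", 0.157, 0.009, 5.2, 0.1, 0.39, 0.03, "33", 2.0),
    ReferenceRow(TRIPLE_MUTANT, "FMZ", 0.098, 0.005, 2.74, 0.03, 0.34, 0.02, "28", 1.0),
)


def reference_params() -> dict[tuple[str, str], KineticParams]:
    """All published parameter sets keyed by (variant, luciferin)."""
    return {(r.variant, r.luciferin): r.params for r in TABLE_ROWS}


def printed_decimals(printed: str) -> int:
    """Number of decimal places in a printed numeric string."""
    return len(printed.split(".")[1]) if "." in printed else 0


def ratio_consistent_with_printed(computed: float, printed: str) -> bool:
    """True when ``computed`` rounds to the printed value within half an ulp
    of the printed decimal precision."""
    return abs(computed - float(printed)) <= 0.5 * 10.0 ** (-printed_decimals(printed))
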