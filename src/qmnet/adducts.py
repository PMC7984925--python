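"""ESI adduct m/z arithmetic for SIM monitoring-ion tables.

Single-charge adducts only. The m/z of an adduct is the neutral monoisotopic
mass plus a fixed delta that accounts for the attached/removed particle and
the electron:

======================  ============  =========
adduct                  delta (Da)    polarity
======================  ============  =========
[M + H]+                +1.007276     positive
[M - H]-                -1.007276     negative
[M + HCOO]- (formate)   +44.998204    negative
======================  ============  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CompoundRecord, IonMode

#: Signed mass deltas in Da (electron mass included).
MASS_DELTA = {
    IonMode.M_PLUS_H: 1.007276,
    IonMode.M_MINUS_H: -1.007276,
    IonMode.M_PLUS_FORMATE: 44.998204,
}

POLARITY = {
    IonMode.M_PLUS_H: "positive",
    IonMode.M_MINUS_H: "negative",
    IonMode.M_PLUS_FORMATE: "negative",
}

#: Default consistency tolerance in Da. SIM monitoring ions are typically
#: configured as low-resolution nominal targets (often ~0.1 Da from the
#: exact adduct mass), so exact-mass matching is inappropriate.
DEFAULT_TOLERANCE = 0.2


@dataclass(frozen=True)
class AdductSpec:
    """Adduct mode together with its mass delta and polarity."""

    mode: IonMode
    mass_delta: float = field(init=False)
    polarity: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_delta", MASS_DELTA[self.mode])
        object.__setattr__(self, "polarity", POLARITY[self.mode])


def adduct_mz(neutral_mass: float, mode: IonMode) -> float:
    """Expected m/z of a singly charged adduct of a neutral molecule.

    Full machine precision is used internally; round only for display.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    try:
        delta = MASS_DELTA[mode]
    except KeyError:
        raise ValueError(f"unknown ion mode {mode!r}") from None
    return neutral_mass + delta


@dataclass
class SimCheckRow:
    """Per-compound consistency verdict for a monitoring-ion table."""

    compound_id: str
    rt_min: float
    mode: IonMode
    observed_mz: float
    expected_mz: float | None  # None when no neutral mass was supplied
    delta: float | None
    status: str  # "pass" | "fail" | "unchecked"


def check_sim_table(
    records: list[CompoundRecord],
    masses: dict[str, float],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[SimCheckRow]:
    """Audit a monitoring-ion table against supplied neutral masses.

    A row passes iff |observed - expected| <= tolerance; rows without a
    supplied neutral mass are marked ``unchecked`` (never failed). The
    report order follows the input record order, and the result is
    independent of the order of ``masses``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rows: list[SimCheckRow] = []
    for rec in records:
        mass = masses.get(rec.compound_id)
        if mass is None:
            rows.append(
                SimCheckRow(
                    compound_id=rec.compound_id,
                    rt_min=rec.rt_min,
                    mode=rec.ion_mode,
                    observed_mz=rec.mz_monitored,
                    expected_mz=None,
                    delta=None,
                    status="unchecked",
                )
            )
            continue
        expected = adduct_mz(mass, rec.ion_mode)
        delta = rec.mz_monitored - expected
        rows.append(
            SimCheckRow(
                compound_id=rec.compound_id,
                rt_min=rec.rt_min,
                mode=rec.ion_mode,
                observed_mz=rec.mz_monitored,
                expected_mz=expected,
                delta=delta,
                status="pass" if abs(delta) <= tolerance else "fail",
            )
        )
    return rows


def sim_check_table(rows: list[SimCheckRow]):
    """Report rows as a pandas DataFrame (expected m/z shown to 4 dp)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "rt_min": r.rt_min,
                "ion_mode": r.mode.value,
                "observed_mz": r.observed_mz,
                "expected_mz": round(r.expected_mz, 4) if r.expected_mz is not None else None,
                "delta": round(r.delta, 4) if r.delta is not None else None,
                "status": r.status,
            }
            for r in rows
        ]
    )
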