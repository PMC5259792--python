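"""PAMPA effective permeability from donor/acceptor well concentrations.

Parallel artificial membrane permeability assay: a compound diffuses from a
donor well (volume V_D) across an artificial membrane of area A into an
acceptor well (V_A).  First-order mass transfer gives the effective
permeability

    P (cm/s) = -ln(1 - C_A(t)/C_eq) / (A * (1/V_D + 1/V_A) * t)

with the no-loss equilibrium concentration

    C_eq = (C_D(t)*V_D + C_A(t)*V_A) / (V_D + V_A).

Volumes in mL are treated as cm^3, so A in cm^2 and t in s give cm/s
directly.  Defaults follow the pre-coated 96-well plate format:
A = 0.3 cm^2, V_D = 0.3 mL, V_A = 0.2 mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class PampaMeasurement:
    """One well pair: concentrations (any common unit), time and geometry."""

    c_donor: float
    c_acceptor: float
    t: float
    area: float = 0.3
    v_donor: float = 0.3
    v_acceptor: float = 0.2

    def __post_init__(self) -> None:
        if self.area <= 0 or self.v_donor <= 0 or self.v_acceptor <= 0:
            raise ValueError("area and well volumes must be positive")
        if self.c_donor <= 0 or self.c_acceptor < 0:
            raise ValueError("need C_D > 0 and C_A >= 0")


def equilibrium_concentration(m: PampaMeasurement) -> float:
    """Mass-balance equilibrium C_eq = (C_D*V_D + C_A*V_A)/(V_D + V_A)."""
    return (m.c_donor * m.v_donor + m.c_acceptor * m.v_acceptor) / (
        m.v_donor + m.v_acceptor
    )


def permeability(m: PampaMeasurement) -> float:
    """Effective permeability in cm/s; undefined once C_A reaches C_eq."""
    if m.t <= 0:
        raise ValueError("incubation time must be positive")
    c_eq = equilibrium_concentration(m)
    if m.c_acceptor >= c_eq:
        raise ValueError("equilibrium reached, P undefined")
    num = -math.log(1.0 - m.c_acceptor / c_eq)
    den = m.area * (1.0 / m.v_donor + 1.0 / m.v_acceptor) * m.t
    return num / den


def permeability_table(
    wells: pd.DataFrame,
    average_concentrations: bool = False,
) -> pd.DataFrame:
    """Per-compound permeability from a well table.

    ``wells`` needs columns compound, c_donor, c_acceptor, t and optionally
    area, v_donor, v_acceptor.  Duplicate wells of a compound are averaged at
    the P level (the range across replicates is reported); pass
    ``average_concentrations=True`` to average the concentrations first and
    compute a single P instead.
    """
    rows = []
    opt = ("area", "v_donor", "v_acceptor")
    for compound, grp in wells.groupby("compound", sort=False):
        extras = {k: float(grp[k].iloc[0]) for k in opt if k in grp}
        if average_concentrations:
            m = PampaMeasurement(
                c_donor=float(grp["c_donor"].mean()),
                c_acceptor=float(grp["c_acceptor"].mean()),
                t=float(grp["t"].iloc[0]),
                **extras,
            )
            p_values = [permeability(m)]
        else:
            p_values = [
                permeability(
                    PampaMeasurement(
                        c_donor=float(r.c_donor),
                        c_acceptor=float(r.c_acceptor),
                        t=float(r.t),
                        **extras,
                    )
                )
                for r in grp.itertuples()
            ]
        rows.append(
            {
                "compound": compound,
                "P_cm_per_s": sum(p_values) / len(p_values),
                "P_range": max(p_values) - min(p_values),
                "n_wells": len(p_values),
            }
        )
    return pd.DataFrame(rows)
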