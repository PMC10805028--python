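"""Porewater dissolved CH4 from headspace equilibration.

Field porewater is equilibrated against a helium headspace and the CH4
concentration of that headspace measured by GC-FID.  The dissolved
concentration is recovered by a headspace mass balance divided by an
extraction efficiency (default 0.95) that folds in the residual dissolved
fraction, so no explicit Henry's-law partitioning term appears:

    dissolved [uM] = n_headspace [umol] / (V_water [L] * efficiency)

Headspace CH4 may be supplied directly as a molar concentration (uM of
headspace) or as a dry mol fraction, converted with the ideal gas law at
1 atm and 25 degC.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: L atm / (mol K)
_R = 0.082057366
_T_K = 298.15
_P_ATM = 1.0


@dataclass
class PorewaterSample:
    """One equilibrated porewater sample.

    ``headspace_ch4`` is interpreted per ``concentration_unit``: "uM"
    (umol per litre of headspace) or "mol_fraction" (converted assuming
    ideal gas at 1 atm, 298.15 K).
    """

    headspace_ch4: float
    headspace_volume_ml: float
    water_volume_ml: float
    extraction_efficiency: float = 0.95
    concentration_unit: str = "uM"

    def __post_init__(self) -> None:
        if self.headspace_volume_ml <= 0 or self.water_volume_ml <= 0:
            raise ValueError("volumes must be positive")
        if not 0 < self.extraction_efficiency <= 1:
            raise ValueError("extraction efficiency must be in (0, 1]")
        if self.concentration_unit not in ("uM", "mol_fraction"):
            raise ValueError(f"unknown concentration unit {self.concentration_unit!r}")


def dissolved_ch4(sample: PorewaterSample) -> float:
    """Dissolved porewater CH4 concentration in uM.

    Linear in the measured headspace concentration and inversely
    proportional to the extraction efficiency.
    """
    v_head_l = sample.headspace_volume_ml / 1000.0
    if sample.concentration_unit == "uM":
        umol = sample.headspace_ch4 * v_head_l
    else:  # mol fraction, ideal gas
        mol = sample.headspace_ch4 * _P_ATM * v_head_l / (_R * _T_K)
        umol = mol * 1e6
    v_water_l = sample.water_volume_ml / 1000.0
    return umol / (v_water_l * sample.extraction_efficiency)


def dissolved_ch4_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Vectorized table form: input columns mirror :class:`PorewaterSample`.

    Required: headspace_ch4, headspace_volume_ml, water_volume_ml; optional
    extraction_efficiency (default 0.95) and concentration_unit
    (default uM).  Returns the table with a ``dissolved_ch4_uM`` column.
    """
    out = samples.copy()
    eff = out.get("extraction_efficiency", pd.Series(0.95, index=out.index))
    unit = out.get("concentration_unit", pd.Series("uM", index=out.index))
    values = []
    for i in out.index:
        values.append(
            dissolved_ch4(
                PorewaterSample(
                    headspace_ch4=float(out.loc[i, "headspace_ch4"]),
                    headspace_volume_ml=float(out.loc[i, "headspace_volume_ml"]),
                    water_volume_ml=float(out.loc[i, "water_volume_ml"]),
                    extraction_efficiency=float(eff.loc[i]),
                    concentration_unit=str(unit.loc[i]),
                )
            )
        )
    out["dissolved_ch4_uM"] = values
    return out
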