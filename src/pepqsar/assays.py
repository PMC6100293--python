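"""Free-radical antioxidant assay quantitation from plate absorbances.

Three single-electron-transfer assays are supported:

- DPPH radical scavenging, read at 517 nm and reported as a percentage:
  ``100 * (A_control - A_sample) / A_control``.
- TEAC (ABTS radical-cation decolorization), read at 734 nm: the sample
  response is converted to an equivalent trolox concentration via a
  trolox standard curve (typically 150-1500 uM) and divided by the
  peptide molar concentration to give uM TE per uM peptide. The same
  percent-scavenging formula applies at 734 nm.
- FRAP (TPTZ-Fe(III) reduction), read at 593 nm: identical read-off
  against an FeSO4 standard curve (typically 200-1200 uM), reported as
  FeSO4 uM per uM peptide.

Standard curves are ordinary least-squares lines of absorbance on
concentration; read-off inverts the fitted line (never nearest-standard
lookup). Peptide molar concentrations come from mass concentration and
the average-isotopic molar mass (sum of residue masses plus one water).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Average (not monoisotopic) residue masses, g/mol.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01528

#: Conventional read wavelengths, nm.
WAVELENGTHS = {"dpph": 517, "teac": 734, "frap": 593}


@dataclass(frozen=True)
class StandardCurve:
    """Fitted calibration line: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    concentration_range: tuple[float, float]  # uM
    analyte: str  # "trolox" or "FeSO4"

    def absorbance(self, concentration_uM: float) -> float:
        return self.slope * concentration_uM + self.intercept

    def concentration(self, absorbance: float) -> float:
        if self.slope == 0:
            raise ValueError("standard curve has zero slope")
        return (absorbance - self.intercept) / self.slope

    def in_range(self, concentration_uM: float) -> bool:
        lo, hi = self.concentration_range
        return lo <= concentration_uM <= hi


@dataclass(frozen=True)
class QuantResult:
    """A converted assay value with its extrapolation status."""

    value: float
    extrapolated: bool = False


def dpph_scavenging(a_control: float, a_sample: float) -> float:
    """Percent radical scavenging: 100 * (A_c - A_s) / A_c.

    May be negative (pro-oxidant behaviour); the value is returned as-is.
    """
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    if a_sample < 0:
        raise ValueError("absorbances must be non-negative")
    return 100.0 * (a_control - a_sample) / a_control


def fit_standard_curve(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    analyte: str,
    min_r_squared: float = 0.98,
) -> StandardCurve:
    """OLS calibration line of absorbance on concentration.

    Requires at least 3 strictly increasing concentrations and refuses
    curves whose r^2 falls below ``min_r_squared``.
    """
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if len(conc) < 3:
        raise ValueError("standard curve needs at least 3 points")
    if len(conc) != len(absb):
        raise ValueError("concentration/absorbance length mismatch")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing (no duplicates)")
    fit = stats.linregress(conc, absb)
    r2 = float(fit.rvalue) ** 2
    if r2 < min_r_squared:
        raise ValueError(
            f"calibration r^2 = {r2:.4f} below the acceptance floor {min_r_squared}"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        concentration_range=(float(conc.min()), float(conc.max())),
        analyte=analyte,
    )


def peptide_molar_mass(sequence: str) -> float:
    """Average-isotopic molar mass of a peptide, g/mol."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return sum(RESIDUE_MASS[r] for r in sequence) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {sequence!r}") from None


def molar_concentration_uM(mass_mg_per_ml: float, sequence: str) -> float:
    """Convert a mass concentration (mg/mL) to uM for a given peptide."""
    if mass_mg_per_ml <= 0:
        raise ValueError("peptide mass concentration must be positive")
    return mass_mg_per_ml / peptide_molar_mass(sequence) * 1e6


def _equivalent_value(
    absorbance: float,
    curve: StandardCurve,
    peptide_conc_mass: float,
    sequence: str,
) -> QuantResult:
    equivalent_uM = curve.concentration(absorbance)
    peptide_uM = molar_concentration_uM(peptide_conc_mass, sequence)
    return QuantResult(
        value=equivalent_uM / peptide_uM,
        extrapolated=not curve.in_range(equivalent_uM),
    )


def teac_value(
    absorbance: float,
    curve: StandardCurve,
    peptide_conc_mass: float,
    sequence: str,
) -> QuantResult:
    """Trolox-equivalent antioxidant capacity, uM TE per uM peptide.

    The sample absorbance is inverted through the trolox calibration line
    to an equivalent trolox concentration, then divided by the peptide
    molar concentration. Read-offs outside the calibrated concentration
    range are flagged as extrapolated.
    """
    if curve.analyte.lower() != "trolox":
        raise ValueError(f"TEAC needs a trolox curve, got {curve.analyte!r}")
    return _equivalent_value(absorbance, curve, peptide_conc_mass, sequence)


def frap_value(
    absorbance: float,
    curve: StandardCurve,
    peptide_conc_mass: float,
    sequence: str,
) -> QuantResult:
    """Ferric reducing antioxidant power, FeSO4 uM per uM peptide."""
    if curve.analyte.lower() not in ("feso4", "fe2+"):
        raise ValueError(f"FRAP needs an FeSO4 curve, got {curve.analyte!r}")
    return _equivalent_value(absorbance, curve, peptide_conc_mass, sequence)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, standard deviation (ddof=1; 0 for a single value) and n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def analyze_plate(
    plate: pd.DataFrame,
    assay: str,
    min_r_squared: float = 0.98,
) -> pd.DataFrame:
    """Quantify a plate table into per-sample assay values.

    ``plate`` columns: ``well, role, analyte, concentration, absorbance,
    replicate`` where role is ``standard``/``sample``/``control``; for
    standards ``concentration`` is the analyte concentration in uM, for
    samples it is the peptide mass concentration in mg/mL and ``analyte``
    holds the peptide sequence.

    Returns one row per sample sequence: ``sequence, assay, value, sd, n,
    extrapolated``. DPPH needs control wells instead of standards.
    """
    assay = assay.lower()
    if assay not in WAVELENGTHS:
        raise ValueError(f"unknown assay {assay!r}")
    samples = plate[plate["role"] == "sample"]
    if samples.empty:
        raise ValueError("plate has no sample wells")

    rows = []
    if assay == "dpph":
        controls = plate.loc[plate["role"] == "control", "absorbance"]
        if controls.empty:
            raise ValueError("DPPH plate needs control wells")
        a_control = float(controls.mean())
        for seq, grp in samples.groupby("analyte", sort=True):
            vals = [dpph_scavenging(a_control, a) for a in grp["absorbance"]]
            mean, sd, n = aggregate_replicates(vals)
            rows.append((seq, assay, mean, sd, n, False))
    else:
        standards = plate[plate["role"] == "standard"]
        if standards.empty:
            raise ValueError(f"{assay} plate needs standard wells")
        by_conc = standards.groupby("concentration", sort=True)["absorbance"].mean()
        analyte = "trolox" if assay == "teac" else "FeSO4"
        curve = fit_standard_curve(
            by_conc.index.to_numpy(), by_conc.to_numpy(), analyte, min_r_squared
        )
        convert = teac_value if assay == "teac" else frap_value
        for seq, grp in samples.groupby("analyte", sort=True):
            mass_conc = float(grp["concentration"].iloc[0])
            results = [
                convert(a, curve, mass_conc, seq) for a in grp["absorbance"]
            ]
            mean, sd, n = aggregate_replicates([r.value for r in results])
            rows.append((seq, assay, mean, sd, n, any(r.extrapolated for r in results)))
    return pd.DataFrame(
        rows, columns=["sequence", "assay", "value", "sd", "n", "extrapolated"]
    )
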