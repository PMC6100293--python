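"""Synthetic data with the statistical structure the pipeline assumes.

Two generators make every stage testable offline:

- :func:`generate_peptide_dataset` draws distinct random tripeptides and
  assigns activities from a sparse linear model over a few descriptor
  columns plus Gaussian noise, mapped affinely to the TEAC scale. The
  default ground truth emulates the empirical activity distribution of
  published antioxidant tripeptide panels: most activities between about
  0.03 and 1.0 uM TE/uM with a small high-activity tail reaching ~2.3,
  driven by aromatic/thiol residues at the C-terminus.
- :func:`generate_assay_plate` forward-simulates microplate absorbances
  (standards on a calibration line, samples at the equivalent-analyte
  concentration implied by known true values), so assay quantitation can
  be validated by round-trip.

All randomness flows through an explicit seeded generator; no global
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aaindex import AAIndexEntry, STANDARD_RESIDUES, filter_complete, load_bundled
from .assays import StandardCurve, molar_concentration_uM
from .encoding import PeptideRecord, autoscale, encode_peptides

#: Internal seed for the fixed synthetic property panel; independent of the
#: dataset seed so the candidate descriptor pool is the same across runs.
_PROPERTY_PANEL_SEED = 314159


@dataclass
class GroundTruth:
    """Sparse linear ground truth for synthetic peptide datasets.

    ``true_coefficients`` act on autoscaled descriptor columns; the
    standardized response is then mapped to uM TE/uM through
    ``activity = offset + scale * (X beta + noise)``.
    """

    true_variables: list[str]
    true_coefficients: list[float]
    noise_sd: float = 0.15
    n_peptides: int = 91
    seed: int = 0
    activity_offset: float = 0.55
    activity_scale: float = 0.42

    def __post_init__(self) -> None:
        if len(self.true_variables) != len(self.true_coefficients):
            raise ValueError("one coefficient per true variable")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticDataset:
    """A generated peptide panel together with its generating truth."""

    peptides: list[PeptideRecord]
    truth: GroundTruth
    properties: list[AAIndexEntry]
    matrix: pd.DataFrame = field(repr=False)  # autoscaled descriptors
    linear_part: np.ndarray = field(repr=False)  # X beta, standardized scale


def synthetic_properties(m: int, seed: int = _PROPERTY_PANEL_SEED) -> list[AAIndexEntry]:
    """Generate ``m`` complete synthetic property scales (seeded).

    Each scale draws one value per residue from a normal distribution with
    a property-specific location and spread, mimicking the heterogeneity
    of curated physicochemical scales.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(m):
        loc = rng.normal(0.0, 2.0)
        spread = rng.uniform(0.3, 3.0)
        values = {r: float(rng.normal(loc, spread)) for r in STANDARD_RESIDUES}
        entries.append(
            AAIndexEntry(
                accession=f"SYN{i:05d}01",
                description=f"Synthetic property scale {i}",
                values=values,
            )
        )
    return entries


def default_properties(n_extra: int = 13) -> list[AAIndexEntry]:
    """Default descriptor panel: the bundled complete scales plus seeded
    synthetic ones (20 scales in total by default -> 60 tripeptide columns)."""
    return filter_complete(load_bundled()) + synthetic_properties(n_extra)


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """The reference study conditions: 91 tripeptides, 3 true variables,
    noise sd 0.15 on the standardized scale.

    The dominant effect sits on the C-terminal solution-free-energy
    column (aromatic/thiol residues high), which is what produces the
    high-activity tail; a smaller steric effect at position 1 and a
    negative-charge penalty at position 2 complete the support.
    """
    return GroundTruth(
        true_variables=["CHAM820102_p3", "LEVM760107_p1", "FAUJ880112_p2"],
        true_coefficients=[1.1, 0.35, -0.25],
        noise_sd=0.15,
        n_peptides=91,
        seed=seed,
    )


def _random_tripeptides(n: int, rng: np.random.Generator) -> list[str]:
    if n > 20**3:
        raise ValueError(f"cannot draw {n} distinct tripeptides (max 8000)")
    residues = np.array(list(STANDARD_RESIDUES))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(residues, size=3))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def generate_peptide_dataset(
    truth: GroundTruth | None = None,
    properties: Sequence[AAIndexEntry] | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Draw distinct tripeptides and simulate activities from the truth.

    The descriptor matrix of the drawn peptides is autoscaled; the
    standardized response ``X beta + N(0, noise_sd)`` is mapped to the
    activity scale through the truth's affine parameters.
    """
    truth = truth if truth is not None else default_ground_truth(seed=seed or 0)
    if seed is not None:
        truth.seed = seed
    properties = list(properties) if properties is not None else default_properties()
    accessions = {p.accession for p in properties}
    rng = np.random.default_rng(truth.seed)

    sequences = _random_tripeptides(truth.n_peptides, rng)
    raw = encode_peptides(sequences, properties)
    for var in truth.true_variables:
        if var.rpartition("_p")[0] not in accessions:
            raise ValueError(f"true variable {var} not covered by the property panel")
    scaled, _ = autoscale(raw)
    missing = [v for v in truth.true_variables if v not in scaled.columns]
    if missing:
        raise ValueError(
            f"true variables dropped as constant in this draw: {missing}; "
            "use a larger panel or another seed"
        )
    beta = np.asarray(truth.true_coefficients, dtype=float)
    linear = scaled[truth.true_variables].to_numpy(dtype=float) @ beta
    noise = rng.normal(0.0, truth.noise_sd, size=len(sequences))
    activity = truth.activity_offset + truth.activity_scale * (linear + noise)
    peptides = [
        PeptideRecord(sequence=s, activity=float(a))
        for s, a in zip(sequences, activity)
    ]
    return SyntheticDataset(
        peptides=peptides,
        truth=truth,
        properties=properties,
        matrix=scaled,
        linear_part=linear,
    )


#: Default forward-simulation calibration lines.
DEFAULT_TROLOX_CURVE = StandardCurve(
    slope=-4.5e-4, intercept=0.72, r_squared=1.0,
    concentration_range=(150.0, 1500.0), analyte="trolox",
)
DEFAULT_FESO4_CURVE = StandardCurve(
    slope=8.0e-4, intercept=0.05, r_squared=1.0,
    concentration_range=(200.0, 1200.0), analyte="FeSO4",
)


def generate_assay_plate(
    sequences: Sequence[str],
    true_values: Sequence[float],
    curve: StandardCurve,
    noise_sd_absorbance: float = 0.0,
    seed: int = 0,
    peptide_conc_mass: float = 0.1,
    n_standards: int = 7,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Forward-simulate a plate from known per-peptide assay values.

    Standards lie exactly on the curve (plus absorbance noise); each
    sample's absorbance is the curve evaluated at the equivalent-analyte
    concentration implied by its true value (uM analyte per uM peptide)
    and the peptide molar concentration at ``peptide_conc_mass`` mg/mL.
    Triplicate wells are emitted by default. The output is the plate CSV
    dialect :func:`pepqsar.assays.analyze_plate` consumes.
    """
    if len(sequences) != len(true_values):
        raise ValueError("one true value per sequence")
    if any(v < 0 for v in true_values):
        raise ValueError("true values must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    lo, hi = curve.concentration_range
    for conc in np.linspace(lo, hi, n_standards):
        for rep in range(1, n_replicates + 1):
            well += 1
            absorbance = curve.absorbance(conc) + rng.normal(0, noise_sd_absorbance)
            rows.append((f"W{well:03d}", "standard", curve.analyte, conc, absorbance, rep))
    for seq, value in zip(sequences, true_values):
        peptide_uM = molar_concentration_uM(peptide_conc_mass, seq)
        equivalent_uM = value * peptide_uM
        for rep in range(1, n_replicates + 1):
            well += 1
            absorbance = curve.absorbance(equivalent_uM) + rng.normal(0, noise_sd_absorbance)
            rows.append((f"W{well:03d}", "sample", seq, peptide_conc_mass, absorbance, rep))
    return pd.DataFrame(
        rows,
        columns=["well", "role", "analyte", "concentration", "absorbance", "replicate"],
    )
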