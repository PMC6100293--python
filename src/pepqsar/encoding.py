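"""Position-wise descriptor encoding of peptides and autoscaling.

A peptide of ``n`` residues described by ``m`` property scales becomes a
row of ``n x m`` descriptors: column ``<accession>_p<j>`` holds property
``<accession>``'s value for the residue at position ``j`` (1-based,
position 1 = N-terminus; for tripeptides position 3 is the C-terminus).
Columns are ordered position-major: all properties of position 1, then
position 2, and so on.

Before modelling, descriptor columns (and, optionally, the activity) are
autoscaled to zero mean and unit standard deviation. Fitting on
standardized variables makes the regression intercept vanish and makes
the fitted coefficients directly comparable as normalized regression
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aaindex import AAIndexEntry, STANDARD_RESIDUES

_STANDARD = set(STANDARD_RESIDUES)


@dataclass
class PeptideRecord:
    """A peptide sequence with an optional measured activity.

    Activity is expressed in uM Trolox equivalents per uM peptide (TEAC
    units). ``subset_label`` tracks train/test membership after splitting.
    """

    sequence: str
    activity: float | None = None
    subset_label: str = "unassigned"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _STANDARD
        if bad or not self.sequence:
            raise ValueError(
                f"sequence {self.sequence!r} contains non-standard residues "
                f"{sorted(bad)}" if bad else "empty sequence"
            )
        if self.activity is not None and not math.isfinite(self.activity):
            raise ValueError(f"{self.sequence}: activity must be finite")


def read_peptide_csv(path) -> list[PeptideRecord]:
    """Read a peptide table (columns: sequence, activity[, subset])."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        activity = row.get("activity")
        records.append(
            PeptideRecord(
                sequence=str(row["sequence"]).strip().upper(),
                activity=None if pd.isna(activity) else float(activity),
                subset_label=str(row.get("subset", "unassigned")),
            )
        )
    return records


def write_peptide_csv(records: Iterable[PeptideRecord], path) -> None:
    pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "activity": [r.activity for r in records],
            "subset": [r.subset_label for r in records],
        }
    ).to_csv(path, index=False)


def variable_name(accession: str, position: int) -> str:
    return f"{accession}_p{position}"


def split_variable_name(name: str) -> tuple[str, int]:
    """Inverse of :func:`variable_name`: ``"ACC_p2" -> ("ACC", 2)``."""
    accession, _, pos = name.rpartition("_p")
    if not accession or not pos.isdigit():
        raise ValueError(f"not a position-tagged variable name: {name!r}")
    return accession, int(pos)


def encode_peptides(
    peptides: Sequence[PeptideRecord] | Sequence[str],
    properties: Sequence[AAIndexEntry],
) -> pd.DataFrame:
    """Build the peptides x (n_positions x n_properties) descriptor matrix.

    Rows are indexed by sequence; cell ``(i, <acc>_pj)`` is property
    ``acc``'s value for residue ``j`` of peptide ``i``.
    """
    sequences = [p.sequence if isinstance(p, PeptideRecord) else str(p) for p in peptides]
    if not sequences:
        raise ValueError("no peptides to encode")
    n = len(sequences[0])
    for seq in sequences:
        if len(seq) != n:
            raise ValueError(
                f"mixed-length peptides: {sequences[0]!r} has {n} residues, "
                f"{seq!r} has {len(seq)}"
            )
    columns: list[str] = []
    data: dict[str, list[float]] = {}
    for j in range(1, n + 1):
        for prop in properties:
            col = variable_name(prop.accession, j)
            columns.append(col)
            values = []
            for seq in sequences:
                residue = seq[j - 1]
                if residue not in prop.values:
                    raise ValueError(
                        f"peptide {seq}: residue {residue} at position {j} has "
                        f"no value in property {prop.accession}"
                    )
                values.append(prop.values[residue])
            data[col] = values
    return pd.DataFrame(data, index=pd.Index(sequences, name="sequence"), columns=columns)


@dataclass
class ScalingParams:
    """Column-wise autoscaling statistics (and optional response scaling).

    ``mean``/``sd`` cover the retained columns only; ``dropped`` lists
    zero-variance columns removed before modelling. ``col_min``/``col_max``
    record the raw training range per retained column, used to flag
    extrapolation when scoring new peptides.
    """

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)
    col_min: pd.Series | None = None
    col_max: pd.Series | None = None
    y_mean: float | None = None
    y_sd: float | None = None

    @property
    def retained(self) -> list[str]:
        return list(self.mean.index)

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.retained if c not in matrix.columns]
        if missing:
            raise ValueError(f"matrix lacks scaled columns: {missing[:5]}")
        return (matrix[self.retained] - self.mean) / self.sd

    def scale_y(self, y) -> np.ndarray:
        if self.y_mean is None or self.y_sd is None:
            raise ValueError("no response scaling stored")
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def unscale_y(self, y_scaled) -> np.ndarray:
        if self.y_mean is None or self.y_sd is None:
            raise ValueError("no response scaling stored")
        return np.asarray(y_scaled, dtype=float) * self.y_sd + self.y_mean


def autoscale(
    matrix: pd.DataFrame,
    activities: Sequence[float] | None = None,
    scale_response: bool = False,
) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardize columns to mean 0 / sd 1, dropping constant columns.

    Standard deviations use ``ddof=1``. When ``scale_response`` is set,
    ``activities`` are standardized with the same convention and the
    parameters stored for back-transformation of predictions.
    """
    if len(matrix) < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    dropped = list(sd.index[sd <= 0.0])
    retained = [c for c in matrix.columns if c not in set(dropped)]
    mean, sd = mean[retained], sd[retained]
    params = ScalingParams(
        mean=mean,
        sd=sd,
        dropped=dropped,
        col_min=matrix[retained].min(axis=0),
        col_max=matrix[retained].max(axis=0),
    )
    if scale_response:
        if activities is None:
            raise ValueError("scale_response=True requires activities")
        y = np.asarray(activities, dtype=float)
        params.y_mean = float(y.mean())
        params.y_sd = float(y.std(ddof=1))
        if params.y_sd <= 0:
            raise ValueError("activities have zero variance")
    scaled = (matrix[retained] - mean) / sd
    return scaled, params
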