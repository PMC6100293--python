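"""Model-guided enumeration and scoring of candidate tripeptides.

The contribution analysis points at favourable residues per position
(e.g. aromatic/thiol residues at the C-terminus); this module turns that
into a screen: enumerate every sequence allowed by per-position residue
constraints, encode and score each with a fitted model, and rank the
candidates for synthesis. Candidates whose selected descriptors fall
outside the training range are flagged as extrapolations.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aaindex import AAIndexEntry, STANDARD_RESIDUES
from .encoding import encode_peptides
from .models import FittedModel, r2_pearson

#: The designed tripeptides named in the study this package operationalizes
#: (11 with Trp at the C-terminus or His at position 2 among them); five of
#: the nineteen designed sequences are not named in the main text and are
#: not listed here. ECG (glutathione) was the positive control, not a
#: designed peptide.
DESIGNED_TRIPEPTIDES = (
    "GKW", "GVR", "PYW", "NKW", "YHW", "KHW", "QHW",
    "NHW", "KVW", "KHR", "GHT", "GHG", "LVG", "GHP",
)


def enumerate_candidates(
    constraints: Sequence[Iterable[str] | None] | None = None,
    n_positions: int = 3,
) -> list[str]:
    """Cartesian product of per-position allowed residue sets.

    ``constraints[j]`` is the residue set allowed at position j+1; ``None``
    (or a missing entry) means all 20 residues. Output is in lexicographic
    order with no duplicates.
    """
    if constraints is None:
        constraints = [None] * n_positions
    if len(constraints) != n_positions:
        raise ValueError(f"need one constraint set per position ({n_positions})")
    pools = []
    for j, allowed in enumerate(constraints, start=1):
        residues = sorted(set(allowed)) if allowed is not None else list(STANDARD_RESIDUES)
        if not residues:
            raise ValueError(f"empty residue set at position {j}")
        bad = set(residues) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"non-standard residues at position {j}: {sorted(bad)}")
        pools.append(residues)
    return ["".join(combo) for combo in itertools.product(*pools)]


def score_candidates(
    sequences: Sequence[str],
    model: FittedModel,
    properties: Sequence[AAIndexEntry],
) -> pd.DataFrame:
    """Encode, scale and predict candidates; rank by predicted activity.

    Returns a frame with columns ``sequence, predicted_activity, rank,
    extrapolation_flag``, sorted by rank. Ties in predicted activity are
    broken lexicographically; ranks are 1..N with 1 the most active.
    The extrapolation flag marks candidates with any selected-variable
    value outside the training min/max.
    """
    if not sequences:
        raise ValueError("no candidate sequences")
    needed = {v.rpartition("_p")[0] for v in model.variables}
    available = {p.accession for p in properties}
    missing = needed - available
    if missing:
        raise ValueError(f"properties missing for accessions: {sorted(missing)}")
    raw = encode_peptides(list(sequences), properties)
    scaled = model.scaling.transform(raw)
    predicted = model.predict(scaled)
    flags = np.zeros(len(sequences), dtype=bool)
    if model.scaling.col_min is not None:
        for var in model.variables:
            lo = float(model.scaling.col_min[var])
            hi = float(model.scaling.col_max[var])
            vals = raw[var].to_numpy(dtype=float)
            flags |= (vals < lo) | (vals > hi)
    frame = pd.DataFrame(
        {
            "sequence": list(sequences),
            "predicted_activity": predicted,
            "extrapolation_flag": flags,
        }
    )
    frame = frame.sort_values(
        ["predicted_activity", "sequence"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame[["sequence", "predicted_activity", "rank", "extrapolation_flag"]]


def compare_predictions_to_observed(
    predicted: Mapping[str, Sequence[float]],
    observed: Sequence[float],
) -> dict[str, float]:
    """Squared Pearson correlation between each model's predictions and a
    common set of observed activities (the external-validation scatter)."""
    obs = np.asarray(observed, dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    if obs.std() == 0:
        raise ValueError("observed activities have zero variance")
    out = {}
    for name, pred in predicted.items():
        pred = np.asarray(pred, dtype=float)
        if len(pred) != len(obs):
            raise ValueError(f"{name}: prediction/observation length mismatch")
        out[name] = r2_pearson(obs, pred)
    return out
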