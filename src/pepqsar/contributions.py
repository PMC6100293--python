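"""Residue-contribution analysis of linear QSAR models.

Because fitting is done on autoscaled descriptors and response, the
stored linear coefficients are already normalized regression coefficients
(NRCs). The total contribution of residue ``a`` at position ``j`` is

    contribution(a, j) = sum over selected variables v = <acc>_pj of
                         NRC(v) * z_acc(a)

where ``z_acc(a)`` is property ``acc``'s value for residue ``a``,
standardized with the same column statistics used for the descriptor
matrix. Under this definition the standardized prediction for any
peptide decomposes exactly into the sum of its per-position residue
contributions, which is what makes the table usable for rational design:
residues with the most positive contributions at a position are
predominant, those with the most negative are deleterious.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aaindex import AAIndexEntry, STANDARD_RESIDUES
from .encoding import split_variable_name
from .models import FittedModel


def normalized_coefficients(
    model: FittedModel | None = None,
    raw_coefficients: Mapping[str, float] | None = None,
    x_sds: Mapping[str, float] | None = None,
    y_sd: float | None = None,
) -> dict[str, float]:
    """Return the normalized regression coefficients of a linear model.

    For a model fitted on standardized X and y the stored coefficients
    are the NRCs and are returned as-is. Alternatively, raw-scale
    coefficients can be converted via ``beta * sd_x / sd_y``.
    """
    if raw_coefficients is not None:
        if x_sds is None or y_sd is None:
            raise ValueError("raw-scale conversion needs x_sds and y_sd")
        return {v: float(b) * float(x_sds[v]) / float(y_sd) for v, b in raw_coefficients.items()}
    if model is None:
        raise ValueError("provide a model or raw coefficients")
    if model.coefficients is None:
        raise ValueError(
            f"{model.method} model has no linear coefficients; NRCs are "
            "defined for MLR/PLS only"
        )
    return {v: float(c) for v, c in zip(model.variables, model.coefficients)}


def residue_contributions(
    model: FittedModel,
    properties: Sequence[AAIndexEntry],
    n_positions: int = 3,
) -> pd.DataFrame:
    """20 x n_positions table of per-residue, per-position contributions.

    Rows are the standard residues (alphabetical); columns are 1-based
    positions. Positions with no selected variable contribute zero.
    """
    nrc = normalized_coefficients(model)
    by_accession = {p.accession: p for p in properties}
    table = pd.DataFrame(
        0.0,
        index=pd.Index(STANDARD_RESIDUES, name="residue"),
        columns=pd.RangeIndex(1, n_positions + 1, name="position"),
    )
    for var, coef in nrc.items():
        accession, position = split_variable_name(var)
        if accession not in by_accession:
            raise ValueError(f"property {accession} (variable {var}) not supplied")
        prop = by_accession[accession]
        mean = float(model.scaling.mean[var])
        sd = float(model.scaling.sd[var])
        for residue in STANDARD_RESIDUES:
            z = (prop.value(residue) - mean) / sd
            table.loc[residue, position] += coef * z
    return table


def rank_residues(
    table: pd.DataFrame, top_k: int = 3
) -> dict[int, dict[str, list[str] | bool]]:
    """Per position: top-k predominant and bottom-k deleterious residues.

    Residues are sorted by contribution descending, ties broken
    alphabetically. An all-tied (e.g. all-zero) position is flagged
    degenerate; its ordering is then purely alphabetical.
    """
    if top_k > len(table.index):
        raise ValueError("top_k exceeds the number of residues")
    out: dict[int, dict[str, list[str] | bool]] = {}
    for position in table.columns:
        scores = table[position]
        order = sorted(scores.index, key=lambda a: (-scores[a], a))
        out[int(position)] = {
            "predominant": order[:top_k],
            "deleterious": list(reversed(order[-top_k:])),
            "degenerate": bool(scores.nunique() == 1),
        }
    return out


def peptide_contribution_sum(table: pd.DataFrame, sequence: str) -> float:
    """Sum of per-position contributions for one peptide; equals the
    model's standardized prediction for a linear model."""
    return float(sum(table.loc[res, j + 1] for j, res in enumerate(sequence)))


def write_contributions_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.columns = [f"position_{c}" for c in out.columns]
    out.to_csv(path)


def plot_contributions(table: pd.DataFrame, path) -> None:
    """Bar chart of per-position residue contributions (optional render)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(table.columns)
    fig, axes = plt.subplots(n, 1, figsize=(8, 2.6 * n), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, position in zip(axes, table.columns):
        scores = table[position]
        colors = ["tab:blue" if v >= 0 else "tab:red" for v in scores]
        ax.bar(scores.index, scores.values, color=colors)
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_ylabel(f"position {position}")
    axes[-1].set_xlabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
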