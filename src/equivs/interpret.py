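"""Attention-based optimal-conformer discovery.

The attention coefficients alpha express how much each conformer contributes
to the molecule-level prediction; ranking conformers by alpha identifies the
geometry the model considers most consistent with the measured bioactivity.
Coefficients below the uniform average 1/M mark conformers the model treats
as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AttentionUnavailableError
from .model import PredictionResult


@dataclass
class ConformerRanking:
    """Conformers of one molecule ordered by attention, descending.

    `entries` rows are (conformer index, alpha, conformer-level prediction);
    `below_uniform` flags entries whose alpha falls below 1/M.
    """

    molecule_id: str
    entries: list[tuple[int, float, float]]
    below_uniform: list[bool]

    @property
    def top_conformer(self) -> int:
        return self.entries[0][0]


def rank_conformers(result: PredictionResult) -> ConformerRanking:
    """Rank a molecule's conformers by attention coefficient.

    Stable descending order; ties break toward the lower conformer index.
    Raises AttentionUnavailableError for results from the no-attention
    variant.
    """
    if result.alpha is None:
        raise AttentionUnavailableError(
            "conformer ranking needs attention coefficients; this prediction "
            "came from a variant that aggregates by unweighted sum"
        )
    alpha = np.asarray(result.alpha, dtype=np.float64)
    M = alpha.shape[0]
    order = sorted(range(M), key=lambda m: (-alpha[m], m))
    entries = [(m, float(alpha[m]), float(result.yGm[m])) for m in order]
    uniform = 1.0 / M
    return ConformerRanking(
        molecule_id=result.molecule_id,
        entries=entries,
        below_uniform=[a < uniform for _, a, _ in entries],
    )


def interpretation_report(
    results: list[PredictionResult],
    labels: dict[str, float] | None = None,
    external_scores: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-conformer table: attention, prediction, absolute error.

    `labels` maps molecule_id to the measured -logM value (falls back to the
    label stored on each result); `external_scores` optionally attaches a
    user-supplied score column (e.g. docking scores) per molecule, aligned
    by original conformer index.
    """
    rows = []
    for res in results:
        ranking = rank_conformers(res)
        label = None
        if labels is not None and res.molecule_id in labels:
            label = labels[res.molecule_id]
        elif res.label is not None:
            label = res.label
        ext = external_scores.get(res.molecule_id) if external_scores else None
        for rank, ((m, a, y_m), below) in enumerate(
            zip(ranking.entries, ranking.below_uniform)
        ):
            rows.append(
                {
                    "molecule_id": res.molecule_id,
                    "rank": rank,
                    "conformer_index": m,
                    "alpha": a,
                    "y_conformer": y_m,
                    "y_molecule": res.yG,
                    "label_logM": label,
                    "abs_error": abs(y_m - label) if label is not None else np.nan,
                    "below_uniform": below,
                    "external_score": (
                        float(ext[m]) if ext is not None else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
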