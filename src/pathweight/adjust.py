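"""Weighted p-value adjustment of a base enrichment method's results.

Pathway-level scores (appearance-frequency or density) become p-value
weights: scores are shifted to be positive (minimum maps to a small floor)
and normalised to mean 1, which keeps the monotone order of the scores.
The base method's per-pathway p-values are then divided by the weights and
clipped to 1 — the standard weighted Benjamini–Hochberg construction, whose
mean-1 weight constraint preserves FDR control while shifting power toward
high-scoring pathways. q-values and ranks are recomputed on the adjusted
p-values.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ValidationError, validate_result_table
from .enrichment import bh_fdr, rank_table


def scores_to_weights(
    scores: Mapping[str, float], floor: float = 0.01
) -> dict[str, float]:
    """Turn real-valued pathway scores into positive, mean-1 p-value weights.

    Scores are shifted by ``-min(score) + floor`` and divided by their mean,
    so the weight order matches the score order and the mean is exactly 1
    (all-equal scores give all-1 weights).
    """
    if not scores:
        raise ValidationError("no pathway scores supplied")
    if floor <= 0:
        raise ValidationError(f"floor must be > 0; got {floor}")
    ids = list(scores)
    vals = np.array([float(scores[i]) for i in ids])
    shifted = vals - vals.min() + floor
    weights = shifted / shifted.mean()
    return dict(zip(ids, weights.tolist()))


def weighted_pvalues(
    table: pd.DataFrame,
    weights: Mapping[str, float],
    missing_weight: float | None = None,
) -> pd.DataFrame:
    """Divide each pathway's p-value by its weight (clipped to 1), then
    recompute BH q-values and p-ascending ranks.

    A pathway without a weight is an error unless ``missing_weight`` (e.g.
    1.0) is supplied — the hard default surfaces id mismatches between the
    base table and the score source.
    """
    validate_result_table(table)
    if "p_value" not in table.columns or table["p_value"].isna().any():
        raise ValidationError("table must carry a p_value for every pathway")
    ids = list(table["pathway_id"])
    missing = [i for i in ids if i not in weights]
    if missing and missing_weight is None:
        raise ValidationError(
            f"no weight for pathway id(s): {missing}; pass missing_weight=1.0 "
            "to default them"
        )
    w = np.array(
        [float(weights.get(i, missing_weight)) for i in ids]
    )
    if np.any(w <= 0):
        bad = [i for i, v in zip(ids, w) if v <= 0]
        raise ValidationError(f"non-positive weight for pathway id(s): {bad}")
    out = table.copy().reset_index(drop=True)
    base_p = out["p_value"].to_numpy(dtype=float)
    adjusted = np.minimum(1.0, base_p / w)
    out["base_p"] = base_p
    out["weight"] = w
    out["adjusted_p"] = adjusted
    out["p_value"] = adjusted
    out["q_value"] = bh_fdr(adjusted)
    return rank_table(out, key="p_asc")


def adjust_base_method(
    base_table: pd.DataFrame,
    scores: Mapping[str, float],
    method_tag: str = "ds",
    floor: float = 0.01,
    missing_weight: float | None = None,
) -> pd.DataFrame:
    """Adjust any base method's result table with pathway scores.

    ``method_tag`` ('af' or 'ds') labels the provenance of the scores in a
    ``method`` column; the output keeps base_p, weight and adjusted_p
    alongside the recomputed q-values and ranks.
    """
    if method_tag not in ("af", "ds"):
        raise ValidationError(
            f"method_tag must be 'af' or 'ds'; got {method_tag!r}"
        )
    weights = scores_to_weights(scores, floor=floor)
    out = weighted_pvalues(base_table, weights, missing_weight=missing_weight)
    out["method"] = method_tag
    return out
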