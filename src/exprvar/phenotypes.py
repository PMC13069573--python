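"""Expression phenotypes derived from a condition atlas.

Two per-gene scores, plus a correlation helper to relate them to NEV:

* **Environmental responsiveness** — the summed log2 ratio of
  expression between each treatment sample and its linked baseline.
  Signed log ratios cancel across opposing responses, so the default
  convention sums absolute log2 ratios (the score is a magnitude of
  transcriptional plasticity); the literal signed sum is available via
  ``signed=True``.

* **Tissue specificity τ** — τ = Σ_j (1 − log2 S_j / log2 S_max) / (n − 1)
  over n tissues, 0 for uniform expression, → 1 as expression
  concentrates in one tissue.  Values below 1 expression unit are
  floored at 1 before the log so every term lies in [0, 1]; a gene
  expressed in a single tissue then gives τ = 1 exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ConditionAtlas, ValidationError

__all__ = ["responsiveness", "tau", "tau_table", "correlate"]

PSEUDOCOUNT = 1.0
DETECTION_FLOOR = 1.0
TAU_FLOOR = 1.0


def responsiveness(atlas: ConditionAtlas, ecotype: str | None = None,
                   tissue: str | None = None, signed: bool = False,
                   pseudocount: float = PSEUDOCOUNT,
                   detection_floor: float = DETECTION_FLOOR) -> pd.DataFrame:
    """Per-gene responsiveness across treatment–baseline contrasts.

    Contrasts where both the treatment and baseline values are below the
    detection floor are skipped and counted per gene.  Filters restrict
    to one ecotype / tissue (e.g. Col-0 seedlings) before scoring.

    Returns a DataFrame indexed by gene with columns ``responsiveness``,
    ``n_contrasts`` and ``n_skipped``.
    """
    samples = atlas.treatment_samples()
    if ecotype is not None:
        samples = samples[samples["ecotype"] == ecotype]
    if tissue is not None:
        samples = samples[samples["tissue"] == tissue]
    if samples.empty:
        raise ValidationError("no treatment samples match the requested filters")

    score = np.zeros(len(atlas.genes))
    n_used = np.zeros(len(atlas.genes), dtype=int)
    n_skipped = np.zeros(len(atlas.genes), dtype=int)
    for sid, row in samples.iterrows():
        expr = atlas.values[sid].to_numpy(dtype=float)
        base = atlas.values[row["baseline"]].to_numpy(dtype=float)
        undetected = (expr < detection_floor) & (base < detection_floor)
        ratio = np.log2((expr + pseudocount) / (base + pseudocount))
        contrib = ratio if signed else np.abs(ratio)
        score += np.where(undetected, 0.0, contrib)
        n_used += ~undetected
        n_skipped += undetected
    return pd.DataFrame({
        "responsiveness": score,
        "n_contrasts": n_used,
        "n_skipped": n_skipped,
    }, index=atlas.genes)


def tau(expression, floor: float = TAU_FLOOR) -> float:
    """Tissue-specificity index τ of one gene's per-tissue expression.

    Requires ≥ 2 tissues.  Returns NaN when every tissue is at or below
    the floor (τ undefined: no expression signal).
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector of >= 2 tissue values")
    x = np.where(np.isnan(x), floor, x)
    x = np.maximum(x, floor)
    lg = np.log2(x / floor)  # floor maps to 0 on the log scale
    lmax = lg.max()
    if lmax == 0:
        return float("nan")
    return float(np.sum(1.0 - lg / lmax) / (x.size - 1))


def tau_table(atlas: ConditionAtlas, floor: float = TAU_FLOOR) -> pd.DataFrame:
    """τ for every gene from the atlas's untreated tissue samples."""
    tissues = atlas.tissue_samples()
    if len(tissues) < 2:
        raise ValidationError("atlas has fewer than 2 untreated tissue samples")
    mat = atlas.values[tissues.index].to_numpy(dtype=float)
    vals = np.array([tau(row, floor=floor) for row in mat])
    return pd.DataFrame({"tau": vals, "n_tissues": len(tissues)},
                        index=atlas.genes)


def correlate(score_x: pd.Series, score_y: pd.Series,
              method: str = "pearson") -> tuple[float, float]:
    """Correlate two per-gene scores on their common defined genes."""
    df = pd.concat({"x": score_x, "y": score_y}, axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 paired values, got {len(df)}")
    if method == "pearson":
        r, p = sps.pearsonr(df["x"], df["y"])
    elif method == "spearman":
        r, p = sps.spearmanr(df["x"], df["y"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
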