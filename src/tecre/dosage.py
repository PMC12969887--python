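"""Combined two-TF dosage statistics for a target gene.

Two transcription factors expressed on different scales are made comparable
by per-gene Z-standardization across samples; their per-sample sum is the
combined dosage score, which is then Pearson-correlated with the target's
expression. Fisher's method combines the two individual correlation
p-values as a complementary summary.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - v.mean()) / sd


def log2_tpm(raw: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log2(TPM + offset) preprocessing for raw abundance matrices."""
    return np.log2(raw + offset)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r*sqrt((n-2)/(1-r^2)),
    df = n-2. |r| = 1 is reported with the 0-limit marker p = 0.0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for inference")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return math.copysign(1.0, r), 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def combined_dosage_correlation(
    matrix: pd.DataFrame, tf1: str, tf2: str, target: str
) -> dict:
    """Correlate the target with each TF and with the summed Z score.

    ``matrix`` is genes x samples on the log2 scale. The combined dosage
    score per sample is Z(tf1) + Z(tf2); standardization makes the result
    invariant to affine rescaling of either TF's raw values.
    """
    for gene in (tf1, tf2, target):
        if gene not in matrix.index:
            raise KeyError(f"gene {gene!r} absent from the matrix")
    y = matrix.loc[target].to_numpy(dtype=float)
    z1 = zscore(matrix.loc[tf1])
    z2 = zscore(matrix.loc[tf2])
    r1, p1 = pearson_with_p(matrix.loc[tf1], y)
    r2, p2 = pearson_with_p(matrix.loc[tf2], y)
    rc, pc = pearson_with_p(z1 + z2, y)
    return {
        "r_tf1": r1, "p_tf1": p1,
        "r_tf2": r2, "p_tf2": p2,
        "r_combined": rc, "p_combined": pc,
        "n": matrix.shape[1],
        "dosage_score": z1 + z2,
    }


def fishers_combined(pvals) -> float:
    """Fisher's combined probability: X = -2*sum(ln p), upper chi-square
    tail with 2k df, evaluated by the even-df closed form
    exp(-X/2) * sum_{j<k} (X/2)^j / j!."""
    ps = [float(p) for p in pvals]
    if not ps:
        raise ValueError("need at least one p-value")
    for p in ps:
        if not 0 < p <= 1:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    x_half = -sum(math.log(p) for p in ps)  # X/2
    k = len(ps)
    term = 1.0
    total = 1.0
    for j in range(1, k):
        term *= x_half / j
        total += term
    return min(1.0, math.exp(-x_half) * total)
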