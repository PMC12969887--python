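"""Per-family repeat enrichment across peak datasets, and the downstream
matrix / clustering / co-occupancy / activity-classification chain.

The enrichment statistic is a one-sided Fisher's exact test on TE-instance
counts: instances of the family overlapped by >= 1 qualifying peak versus the
same count over all other TE instances (the background). P-values are
Benjamini-Hochberg adjusted within each dataset. The counting unit is the TE
instance, not the peak, because family sizes differ by orders of magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .intervals import Peak, TEInstance, overlap_join

logger = logging.getLogger(__name__)

NEGLOG10_CAP = 300.0


def family_enrichment(
    peaks: Sequence[Peak],
    te_instances: Sequence[TEInstance],
    overlap_mode: str = "any",
    min_instances: int = 10,
    peak_mask: Optional[Sequence] = None,
) -> pd.DataFrame:
    """One dataset's per-family enrichment table.

    ``overlap_mode`` is ``"any"`` or ``"frac:F"`` requiring fraction F of the
    peak to lie inside the repeat (``frac:0.7`` reproduces the 70%-of-peak
    rule). Families with fewer than ``min_instances`` copies are reported
    with NaN statistics but untested. ``peak_mask`` optionally excludes
    blacklisted intervals: any peak overlapping the mask is dropped before
    counting.
    """
    if overlap_mode == "any":
        frac = 0.0
    elif overlap_mode.startswith("frac:"):
        frac = float(overlap_mode.split(":", 1)[1])
    else:
        raise ValueError(f"unknown overlap mode {overlap_mode!r}")
    datasets = {p.dataset for p in peaks}
    if len(datasets) > 1:
        raise ValueError(f"peaks must come from a single dataset, got {datasets}")
    if peak_mask:
        masked = {i for i, _, _ in overlap_join(peaks, peak_mask)}
        peaks = [p for i, p in enumerate(peaks) if i not in masked]
    overlapped_te = {j for _, j, _ in overlap_join(peaks, te_instances, frac)}
    fam_n: dict[str, int] = {}
    fam_hit: dict[str, int] = {}
    for j, te in enumerate(te_instances):
        fam_n[te.family] = fam_n.get(te.family, 0) + 1
        if j in overlapped_te:
            fam_hit[te.family] = fam_hit.get(te.family, 0) + 1
    total_n = len(te_instances)
    total_hit = len(overlapped_te)
    rows = []
    for fam in sorted(fam_n):
        n, k = fam_n[fam], fam_hit.get(fam, 0)
        bg_n, bg_k = total_n - n, total_hit - k
        row = {
            "family": fam,
            "dataset": next(iter(datasets)) if datasets else "",
            "n_instances": n,
            "n_overlapped": k,
            "n_background_instances": bg_n,
            "n_background_overlapped": bg_k,
            "tested": n >= min_instances,
        }
        if n >= min_instances:
            fam_rate = k / n
            bg_rate = bg_k / bg_n if bg_n else np.nan
            row["fold"] = fam_rate / bg_rate if bg_rate else np.inf
            _, row["p"] = stats.fisher_exact(
                [[k, n - k], [bg_k, bg_n - bg_k]], alternative="greater"
            )
        else:
            row["fold"] = np.nan
            row["p"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["tested"]
    if not tested.any():
        raise ValueError("no family has enough instances to test")
    adj = pd.Series(np.nan, index=table.index)
    adj[tested] = multipletests(table.loc[tested, "p"], method="fdr_bh")[1]
    table["adj_p"] = adj
    return table


@dataclass
class EnrichmentMatrix:
    """Families x datasets matrix of -log10(adj_p) plus significance flags."""

    values: pd.DataFrame
    significant: pd.DataFrame
    alpha: float

    @property
    def families(self) -> list[str]:
        return list(self.values.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.values.columns)

    def significant_subset(self) -> "EnrichmentMatrix":
        """Restrict to families significant in >= 1 dataset."""
        keep = self.significant.any(axis=1)
        return EnrichmentMatrix(
            self.values.loc[keep], self.significant.loc[keep], self.alpha
        )


def build_enrichment_matrix(
    tables: Sequence[pd.DataFrame], alpha: float = 0.05
) -> EnrichmentMatrix:
    """Assemble per-dataset enrichment tables into one matrix.

    Rows are the union of families; cells missing from a table (or untested)
    are 0. -log10 values are capped to avoid infinities before clustering.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 dataset tables")
    names = [t["dataset"].iloc[0] for t in tables]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicated dataset names: {names}")
    families = sorted(set().union(*(set(t["family"]) for t in tables)))
    values = pd.DataFrame(0.0, index=families, columns=names)
    sig = pd.DataFrame(False, index=families, columns=names)
    for name, t in zip(names, tables):
        t = t.set_index("family")
        adj = t["adj_p"].dropna()
        scores = -np.log10(np.maximum(adj, 10.0**-NEGLOG10_CAP))
        values.loc[adj.index, name] = scores.clip(upper=NEGLOG10_CAP)
        sig.loc[adj.index, name] = adj < alpha
    return EnrichmentMatrix(values=values, significant=sig, alpha=alpha)


def cluster_enrichment(matrix: EnrichmentMatrix, k: int, seed: int = 0) -> pd.Series:
    """K-means on the -log10(adj_p) row vectors; labels are relabelled
    canonically by descending cluster mean so runs are comparable."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(matrix.families):
        raise ValueError(f"k={k} exceeds the {len(matrix.families)} families")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(matrix.values.to_numpy())
    means = [matrix.values.to_numpy()[raw == c].mean() for c in range(k)]
    order = np.argsort(means)[::-1]
    remap = {int(old): new for new, old in enumerate(order)}
    return pd.Series([remap[int(c)] for c in raw], index=matrix.families, name="cluster")


def dataset_correlation(matrix: EnrichmentMatrix) -> pd.DataFrame:
    """Spearman rank correlation between dataset columns (average ranks for
    ties). A constant column yields NaN entries, not an exception."""
    if len(matrix.datasets) < 2 or len(matrix.families) < 3:
        raise ValueError("need >= 2 datasets and >= 3 families")
    cols = matrix.datasets
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    X = matrix.values
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            if X[ci].nunique() == 1 or X[cj].nunique() == 1:
                rho = np.nan
            else:
                rho = stats.spearmanr(X[ci], X[cj]).statistic
            out.loc[ci, cj] = out.loc[cj, ci] = rho
    return out


def cooccupancy_summary(
    matrix: EnrichmentMatrix,
    factor_a: str,
    factor_b: str,
    enhancer_marks: Sequence[str] = (),
    alpha: Optional[float] = None,
) -> dict:
    """Set algebra on the two factors' significant family sets, plus the
    fraction of shared families that also carry enhancer-mark enrichment."""
    for ds in [factor_a, factor_b, *enhancer_marks]:
        if ds not in matrix.datasets:
            raise KeyError(f"dataset {ds!r} absent from the matrix")
    sig = matrix.significant
    a_set = set(sig.index[sig[factor_a]])
    b_set = set(sig.index[sig[factor_b]])
    shared = a_set & b_set
    if shared and enhancer_marks:
        with_marks = {
            f for f in shared if sig.loc[f, list(enhancer_marks)].any()
        }
        frac = len(with_marks) / len(shared)
    else:
        frac = np.nan
    return {
        "A_only": len(a_set - b_set),
        "B_only": len(b_set - a_set),
        "shared": len(shared),
        "shared_families": sorted(shared),
        "shared_with_enhancer_marks": frac,
    }


@dataclass
class ActivityRules:
    """Which datasets play each regulatory role in activity classification.

    An empty role list disables that rule; a role naming a dataset absent
    from the matrix is an error. Precedence: promoter > enhancer > repressed.
    """

    promoter_marks: Sequence[str] = ("H3K4me3",)
    pioneer: Sequence[str] = ("TFAP2C",)
    enhancer_marks: Sequence[str] = ("H3K4me1", "H3K27ac")
    enhancer_coactivators: Sequence[str] = ("P300", "MED1")
    repressive_marks: Sequence[str] = ("H3K9me3",)


def classify_family_activity(
    matrix: EnrichmentMatrix, rules: Optional[ActivityRules] = None
) -> pd.Series:
    """Label each family promoter-like / enhancer-like / repressed /
    unclassified from its significance pattern.

    promoter-like: significant for a promoter mark AND the pioneer factor;
    enhancer-like: an enhancer mark AND a coactivator; repressed: a
    repressive mark and neither of the above.
    """
    rules = rules or ActivityRules()
    sig = matrix.significant
    for role in (
        rules.promoter_marks, rules.pioneer, rules.enhancer_marks,
        rules.enhancer_coactivators, rules.repressive_marks,
    ):
        for ds in role:
            if ds not in sig.columns:
                raise KeyError(f"activity rule references absent dataset {ds!r}")

    def any_sig(fam: str, role: Sequence[str]) -> bool:
        return bool(role) and bool(sig.loc[fam, list(role)].any())

    labels = {}
    for fam in matrix.families:
        if any_sig(fam, rules.promoter_marks) and any_sig(fam, rules.pioneer):
            labels[fam] = "promoter-like"
        elif any_sig(fam, rules.enhancer_marks) and any_sig(
            fam, rules.enhancer_coactivators
        ):
            labels[fam] = "enhancer-like"
        elif any_sig(fam, rules.repressive_marks):
            labels[fam] = "repressed"
        else:
            labels[fam] = "unclassified"
    return pd.Series(labels, name="activity")


def shortlist_candidates(
    matrix: EnrichmentMatrix,
    required: Sequence[str] = ("GATA3", "DLX5", "TFAP2C"),
    allowed_labels: Sequence[str] = ("promoter-like", "enhancer-like"),
    rules: Optional[ActivityRules] = None,
) -> pd.DataFrame:
    """Families significant in ALL required datasets with an allowed activity
    label, ranked by summed -log10(adj_p) over the required datasets (ties by
    family name). An empty shortlist is a valid result."""
    for ds in required:
        if ds not in matrix.datasets:
            raise KeyError(f"required dataset {ds!r} absent from the matrix")
    labels = classify_family_activity(matrix, rules)
    sig = matrix.significant
    rows = []
    for fam in matrix.families:
        if sig.loc[fam, list(required)].all() and labels[fam] in allowed_labels:
            rows.append(
                {
                    "family": fam,
                    "activity": labels[fam],
                    "score": float(matrix.values.loc[fam, list(required)].sum()),
                }
            )
    out = pd.DataFrame(rows, columns=["family", "activity", "score"])
    if len(out):
        out = out.sort_values(
            ["score", "family"], ascending=[False, True]
        ).reset_index(drop=True)
        out.index = out.index + 1
        out.index.name = "rank"
    return out
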