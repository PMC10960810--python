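"""Summary statistics and visual outputs of repair-outcome profiles.

Rank-ordered allelic landscapes, the Class Fraction index (summed read
fractions per repair class over the top-N alleles), common-allele
extraction across samples (the input matrix for external UMAP embedding),
replicate Pearson correlation, and per-cluster deletion-size summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .locus import parse_allele_id
from .npclassifier import CLASS_LABELS
from .saclassifier import SampleProfile

__all__ = [
    "CLASS_COLORS",
    "ClassFraction",
    "AlleleFeatureMatrix",
    "CorrelationResult",
    "landscape",
    "class_fraction",
    "common_alleles",
    "replicate_correlation",
    "deletion_size_summary",
    "plot_landscape",
]

# Color code used in all rendered outputs.
CLASS_COLORS = {
    "MMEJ": "#C71585",   # dark pink
    "PEPPR": "#87CEEB",  # sky blue
    "DELET": "#FF8C00",  # orange
    "INSRT": "#800080",  # purple
    "WT": "#000000",     # black
}


def _ranked(profile: SampleProfile, include_wt: bool = True) -> list[tuple[str, str, float]]:
    fr = profile.fractions
    rows = [
        (a, profile.allele_class[a], fr[a])
        for a in profile.allele_counts
        if include_wt or profile.allele_class[a] != "WT"
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows


def landscape(profile: SampleProfile, top_n: int = 50) -> pd.DataFrame:
    """Rank-ordered allelic landscape: the top-N alleles by read fraction.

    Returns a DataFrame (rank, allele_id, class, fraction) with fractions
    monotone non-increasing in rank.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not profile.allele_counts:
        raise ValueError("empty profile")
    rows = _ranked(profile)[:top_n]
    df = pd.DataFrame(rows, columns=["allele_id", "class", "fraction"])
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


@dataclass(frozen=True)
class ClassFraction:
    """Summed read fraction per repair class over the top-N alleles."""

    fractions: dict[str, float]
    top_n: int | None
    include_wt: bool
    renormalized: bool

    def as_dict(self) -> dict[str, float]:
        return dict(self.fractions)


def class_fraction(
    profile: SampleProfile,
    top_n: int | None = None,
    include_wt: bool = True,
    renormalize: bool = False,
) -> ClassFraction:
    """Class Fraction index of a profile.

    Sums read fractions per class over the top-N ranked alleles
    (``top_n=None`` means all alleles).  With ``include_wt=False`` the WT
    allele is removed before ranking.  ``renormalize`` rescales the sums to
    total 1 over the top-N subset (raw summed fractions by default).
    """
    if not profile.allele_counts:
        raise ValueError("empty profile")
    rows = _ranked(profile, include_wt)
    if top_n is not None:
        rows = rows[:top_n]
    sums = {label: 0.0 for label in CLASS_LABELS}
    for _, label, frac in rows:
        sums[label] += frac
    if renormalize:
        total = sum(sums.values())
        if total > 0:
            sums = {k: v / total for k, v in sums.items()}
    return ClassFraction(sums, top_n, include_wt, renormalize)


@dataclass
class AlleleFeatureMatrix:
    """Shared alleles x samples read-fraction matrix with row annotations.

    Every row's allele appears in every column's profile; this is the input
    matrix for external embedding/clustering (e.g. UMAP), which is consumed
    back through :func:`deletion_size_summary`.
    """

    fractions: pd.DataFrame              # rows: allele_id, cols: sample_id
    classes: dict[str, str]              # allele_id -> class label
    del_lengths: dict[str, int]          # allele_id -> deletion length
    ins_lengths: dict[str, int]          # allele_id -> insertion length

    @property
    def allele_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def empty(self) -> bool:
        return self.fractions.shape[0] == 0


def common_alleles(profiles: Sequence[SampleProfile]) -> tuple[set[str], AlleleFeatureMatrix]:
    """Alleles shared by every profile, as a set and a feature matrix.

    An empty intersection yields an empty (flagged via ``matrix.empty``)
    matrix rather than an error.  Row order is deterministic (descending
    mean fraction, then allele id).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    shared = set(profiles[0].allele_counts)
    for p in profiles[1:]:
        shared &= set(p.allele_counts)
    fracs = {p.sample_id: p.fractions for p in profiles}
    order = sorted(
        shared,
        key=lambda a: (-float(np.mean([fracs[p.sample_id][a] for p in profiles])), a),
    )
    data = {
        p.sample_id: [fracs[p.sample_id][a] for a in order] for p in profiles
    }
    matrix = pd.DataFrame(data, index=order)
    classes = {a: profiles[0].allele_class[a] for a in order}
    del_lengths = {}
    ins_lengths = {}
    for a in order:
        edit = parse_allele_id(a)
        del_lengths[a] = edit.del_len
        ins_lengths[a] = len(edit.insertion)
    return shared, AlleleFeatureMatrix(matrix, classes, del_lengths, ins_lengths)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    n: int
    undefined: bool = False


def replicate_correlation(
    matrix: AlleleFeatureMatrix | pd.DataFrame, sample_a: str, sample_b: str
) -> CorrelationResult:
    """Pearson correlation of two samples' fraction vectors over shared
    alleles (r, r^2, two-sided p from the t transform).

    A zero-variance vector makes the coefficient undefined; the result is
    flagged (NaN values, ``undefined=True``) rather than raising.
    """
    df = matrix.fractions if isinstance(matrix, AlleleFeatureMatrix) else matrix
    x = np.asarray(df[sample_a], dtype=float)
    y = np.asarray(df[sample_b], dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 shared alleles")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, math.nan, n, undefined=True)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r, r * r, float(res.pvalue), n)


def deletion_size_summary(
    matrix: AlleleFeatureMatrix, cluster_assignment: Mapping[str, object]
) -> pd.DataFrame:
    """Mean deletion length per externally supplied cluster.

    Insertion alleles contribute to a separate mean insertion length; a
    cluster with no deletion alleles reports NaN with ``no_deletions=True``.
    """
    rows = []
    clusters: dict[object, list[str]] = {}
    for allele, cluster in cluster_assignment.items():
        clusters.setdefault(cluster, []).append(allele)
    for cluster in sorted(clusters, key=str):
        alleles = clusters[cluster]
        dels = [matrix.del_lengths[a] for a in alleles if matrix.del_lengths[a] > 0]
        inss = [matrix.ins_lengths[a] for a in alleles if matrix.ins_lengths[a] > 0]
        rows.append(
            {
                "cluster": cluster,
                "n_alleles": len(alleles),
                "mean_del_len": float(np.mean(dels)) if dels else math.nan,
                "no_deletions": not dels,
                "mean_ins_len": float(np.mean(inss)) if inss else math.nan,
            }
        )
    return pd.DataFrame(rows)


def plot_landscape(profiles, top_n: int = 50, ax=None, include_wt: bool = True):
    """Overlayed rank-ordered landscapes, one line per sample, with the
    class of each sample's top allele coloring its line.  Requires
    matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for profile in profiles:
        rows = _ranked(profile, include_wt)[:top_n]
        fracs = [f for _, _, f in rows]
        top_class = rows[0][1] if rows else "WT"
        ax.plot(
            range(1, len(fracs) + 1),
            fracs,
            marker="o",
            markersize=2.5,
            linewidth=1,
            label=profile.sample_id,
            color=CLASS_COLORS.get(top_class, "gray"),
            alpha=0.8,
        )
    ax.set_xlabel(f"allele rank (top {top_n})")
    ax.set_ylabel("read fraction")
    ax.legend(fontsize=7)
    return ax
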