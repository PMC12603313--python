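"""Expression normalisation and group statistics.

Implements the normalisations used for the RNA-Seq and small-RNA-Seq
matrices (FPKM for transcripts, RPM for miRNAs, per-row Z-scores for
heatmaps), relative qPCR quantification by the 2^-ddCt method with a
reference gene and calibrator condition, and the group comparisons used
on the drought series (one-way ANOVA with Tukey HSD and a compact letter
display; two-group designs fall back to a two-sided t test).

Conventions: technical replicates are averaged on the Ct scale before
dCt; the calibrator baseline is the mean dCt over calibrator biological
replicates; Z-scores use the population standard deviation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountMatrix:
    counts: pd.DataFrame                    # features x samples, non-negative
    feature_lengths: pd.Series | None = None  # nt, required for FPKM

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(self.counts.index)
            if self.feature_lengths.isna().any():
                missing = self.counts.index[self.feature_lengths.isna()].tolist()
                raise ValueError(f"missing feature lengths for {missing[:5]}")
            if (self.feature_lengths <= 0).any():
                raise ValueError("feature lengths must be > 0")


@dataclass
class RelativeExpression:
    gene: str
    group: str
    fold_change: float          # mean 2^-ddCt over biological replicates
    sd: float                   # dispersion across biological replicates
    n_bio: int
    rep_folds: list[float] = field(default_factory=list)


@dataclass
class GroupTestResult:
    method: str                 # anova_tukey | t_test
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float]
    letters: dict[str, str]
    flagged: str = ""


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def fpkm(m: CountMatrix) -> pd.DataFrame:
    """FPKM[f,s] = counts / (library total / 1e6) / (length / 1e3)."""
    if m.feature_lengths is None:
        raise ValueError("FPKM requires feature lengths")
    totals = m.counts.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"zero library total in samples {empty}")
    per_million = m.counts / (totals / 1e6)
    return per_million.div(m.feature_lengths / 1e3, axis=0)


def rpm(m: CountMatrix) -> pd.DataFrame:
    """RPM[f,s] = counts / (library total / 1e6)."""
    totals = m.counts.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"zero library total in samples {empty}")
    return m.counts / (totals / 1e6)


def zscore_rows(x: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-row Z-scores (population sd); constant rows flagged, emitted as 0."""
    values = x.values.astype(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    flagged = [str(x.index[i]) for i in np.nonzero(flat)[0]]
    return pd.DataFrame(z, index=x.index, columns=x.columns), flagged


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

REQUIRED_QPCR_COLUMNS = ["gene", "group", "bio_rep", "tech_rep", "ct"]


def ddct(qpcr: pd.DataFrame, reference_gene: str, calibrator_group: str,
         ) -> list[RelativeExpression]:
    """Relative expression by the 2^-ddCt method.

    Per (gene, group, bio_rep): Ct averaged over technical replicates;
    dCt = Ct(gene) - Ct(reference); ddCt = dCt - mean dCt of the
    calibrator group's biological replicates; fold = 2^-ddCt, summarised
    as mean +/- sd over biological replicates.  Replicates without a
    reference-gene measurement are excluded with a warning.
    """
    missing_cols = [c for c in REQUIRED_QPCR_COLUMNS if c not in qpcr.columns]
    if missing_cols:
        raise ValueError(f"qPCR table lacks columns {missing_cols}")
    if (qpcr["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    mean_ct = (qpcr.groupby(["gene", "group", "bio_rep"])["ct"]
               .mean().rename("ct"))
    if reference_gene not in qpcr["gene"].unique():
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = mean_ct.xs(reference_gene, level="gene")

    out: list[RelativeExpression] = []
    genes = [g for g in qpcr["gene"].unique() if g != reference_gene]
    for gene in genes:
        gct = mean_ct.xs(gene, level="gene")
        dct = {}
        for (group, rep), ct in gct.items():
            if (group, rep) not in ref_ct.index:
                warnings.warn(f"{gene}/{group}/rep{rep}: no reference-gene Ct; "
                              "replicate excluded")
                continue
            dct[(group, rep)] = ct - ref_ct.loc[(group, rep)]
        calib = [v for (g, _), v in dct.items() if g == calibrator_group]
        if not calib:
            raise ValueError(f"calibrator group {calibrator_group!r} absent for {gene!r}")
        baseline = float(np.mean(calib))
        by_group: dict[str, list[float]] = {}
        for (group, _rep), v in sorted(dct.items()):
            by_group.setdefault(group, []).append(2.0 ** -(v - baseline))
        for group, folds in by_group.items():
            arr = np.array(folds)
            out.append(RelativeExpression(gene=gene, group=group,
                                          fold_change=float(arr.mean()),
                                          sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                                          n_bio=arr.size, rep_folds=list(map(float, arr))))
    return out


def read_qpcr_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compact_letter_display(groups: list[str], means: dict[str, float],
                           significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insertion method over the pairwise significance matrix.

    Groups ordered by mean descending; letter sets are split on each
    significant pair and absorbed, giving the usual a/b/c display where
    groups sharing a letter are not significantly different.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    sets: list[set[str]] = [set(order)]
    for g1, g2 in sorted(significant):
        new_sets: list[set[str]] = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.extend([s - {g1}, s - {g2}])
            else:
                new_sets.append(s)
        # absorb subsets, deterministically
        new_sets = [s for s in new_sets if s]
        keep: list[set[str]] = []
        for s in sorted(new_sets, key=lambda s: (-len(s), sorted(s))):
            if not any(s <= k for k in keep):
                keep.append(s)
        sets = keep
    # letters assigned in order of the highest-mean member
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        symbol = chr(ord("a") + i)
        for g in order:
            if g in s:
                letters[g] += symbol
    return letters


def group_tests(values_by_group: dict[str, list[float]], alpha: float = 0.05,
                ) -> GroupTestResult:
    """One-way ANOVA + Tukey HSD with compact letters; t test for 2 groups."""
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least two replicates per group")
    means = {g: float(a.mean()) for g, a in zip(groups, arrays)}

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return GroupTestResult(method="degenerate", statistic=float("nan"),
                               p_value=float("nan"), pairwise={},
                               letters={}, flagged="zero variance in all groups")

    if len(groups) == 2:
        stat, p = stats.ttest_ind(arrays[0], arrays[1])
        pair = {(groups[0], groups[1]): float(p)}
        sig = {(groups[0], groups[1])} if p < alpha else set()
        letters = compact_letter_display(groups, means, sig)
        return GroupTestResult(method="t_test", statistic=float(stat),
                               p_value=float(p), pairwise=pair, letters=letters)

    f_stat, f_p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairwise: dict[tuple[str, str], float] = {}
    significant: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(range(len(groups)), 2):
        p = float(hsd.pvalue[i, j])
        pairwise[(groups[i], groups[j])] = p
        if p < alpha:
            significant.add((groups[i], groups[j]))
    letters = compact_letter_display(groups, means, significant)
    return GroupTestResult(method="anova_tukey", statistic=float(f_stat),
                           p_value=float(f_p), pairwise=pairwise, letters=letters)
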