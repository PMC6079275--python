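"""Stress-expression profiling of an FPKM matrix.

Fold change is the ratio of mean treatment FPKM to mean time-matched control
FPKM (a symmetric pseudocount on both means guards against near-zero control
denominators, which extreme inductions in the 10^3-10^4-fold range make
unavoidable).  Significance uses an ordinary least-squares fit of
``log2(FPKM + 1)`` on a two-group indicator — the simplest linear-model test
over the six samples of a (treatment, control) pair at one time point — with
no multiple-testing adjustment by default (raw ``P < 0.05``).  Per-time-point
PCA treats samples as observations and genes as variables on centered,
unscaled FPKM.  DEG overlap between stresses is computed over genes
significant at >= 1 time point under each condition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FoldChangeRecord",
    "PCAResult",
    "read_expression",
    "fold_change",
    "de_test",
    "fold_change_table",
    "heatmap_matrix",
    "pca_by_time",
    "overlap_analysis",
    "significant_sets",
]

TREATMENTS = ("LT", "HT", "LS", "HS")
CONTROL = "C"
TIMES_H = (1, 24, 48)


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) with condition/time/replicate metadata."""

    values: pd.DataFrame
    samples: pd.DataFrame  # sample_id, condition, time_h, replicate

    def __post_init__(self) -> None:
        self.samples = self.samples.set_index(
            self.samples["sample_id"].astype(str), drop=False
        )
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet lacks entries for {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        times = sorted(self.samples["time_h"].unique())
        for t in times:
            at_t = self.samples[self.samples["time_h"] == t]
            if CONTROL not in set(at_t["condition"]):
                raise ValueError(f"no control group at time {t} h")

    def group(self, condition: str, time_h: int) -> list[str]:
        mask = (self.samples["condition"] == condition) & (
            self.samples["time_h"] == time_h
        )
        ids = [s for s in self.samples.index[mask] if s in self.values.columns]
        if not ids:
            raise ValueError(f"no samples for ({condition}, {time_h} h)")
        return ids

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class FoldChangeRecord:
    gene_id: str
    condition: str
    time_h: int
    fc: float
    log2fc: float
    p_value: float | None = None
    significant: bool | None = None


@dataclass
class PCAResult:
    """Per-sample scores on the first two components and variance fractions."""

    time_h: int
    scores: pd.DataFrame  # samples x (PC1, PC2) with condition column
    variance_fractions: np.ndarray  # all components, sums to 1


def read_expression(fpkm_tsv: str | Path, samples_tsv: str | Path) -> ExpressionMatrix:
    """Load an FPKM TSV (first column gene ids) plus a sample sheet."""
    values = pd.read_csv(fpkm_tsv, sep="\t", index_col=0)
    samples = pd.read_csv(samples_tsv, sep="\t")
    return ExpressionMatrix(values, samples)


def fold_change(
    matrix: ExpressionMatrix,
    gene: str,
    condition: str,
    time_h: int,
    pseudocount: float = 0.01,
) -> FoldChangeRecord:
    """Mean-treatment over mean-control FPKM ratio for one gene/condition/time."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    treat = matrix.values.loc[gene, matrix.group(condition, time_h)].to_numpy(float)
    ctrl = matrix.values.loc[gene, matrix.group(CONTROL, time_h)].to_numpy(float)
    denom = ctrl.mean() + pseudocount
    numer = treat.mean() + pseudocount
    if denom == 0.0:
        raise ZeroDivisionError(
            f"{gene}: control mean is zero and pseudocount is 0"
        )
    fc = numer / denom
    return FoldChangeRecord(gene, condition, time_h, fc, float(np.log2(fc)))


def _ttest_rows(
    treat: np.ndarray, ctrl: np.ndarray
) -> np.ndarray:
    """Row-wise two-sided pooled-variance t-test p-values on log2(x+1).

    Equivalent to the slope t-test of an OLS fit of log2(FPKM + 1) on a
    two-group indicator.  Degenerate rows (zero variance in both groups)
    get p = 1 when the means agree and p = 0 otherwise.
    """
    a = np.log2(treat + 1.0)
    b = np.log2(ctrl + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
        log.warning("%d degenerate zero-variance tests", int(degenerate.sum()))
    return p


def de_test(
    matrix: ExpressionMatrix, gene: str, condition: str, time_h: int
) -> float:
    """Two-sided p-value of the two-group linear-model test for one gene."""
    t_ids = matrix.group(condition, time_h)
    c_ids = matrix.group(CONTROL, time_h)
    if len(t_ids) < 2 or len(c_ids) < 2:
        raise ValueError("need >= 2 replicates per group")
    treat = matrix.values.loc[[gene], t_ids].to_numpy(float)
    ctrl = matrix.values.loc[[gene], c_ids].to_numpy(float)
    return float(_ttest_rows(treat, ctrl)[0])


def fold_change_table(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    pseudocount: float = 0.01,
    conditions: Sequence[str] = TREATMENTS,
    times: Sequence[int] = TIMES_H,
) -> pd.DataFrame:
    """Fold change + significance for every gene x condition x time cell."""
    rows = []
    for condition in conditions:
        for time_h in times:
            t_ids = matrix.group(condition, time_h)
            c_ids = matrix.group(CONTROL, time_h)
            treat = matrix.values[t_ids].to_numpy(float)
            ctrl = matrix.values[c_ids].to_numpy(float)
            fc = (treat.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount)
            p = _ttest_rows(treat, ctrl)
            for gi, gene in enumerate(matrix.genes):
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": condition,
                        "time_h": time_h,
                        "fc": fc[gi],
                        "log2fc": float(np.log2(fc[gi])),
                        "p_value": p[gi],
                        "significant": bool(p[gi] < alpha),
                    }
                )
    return pd.DataFrame(rows)


def heatmap_matrix(
    fc_table: pd.DataFrame,
    conditions: Sequence[str] = TREATMENTS,
    times: Sequence[int] = TIMES_H,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x (condition, time) log2FC matrix plus significance mask.

    Columns are ordered condition-major (LT, HT, LS, HS x 1, 24, 48 h).
    Missing cells become NA (logged) with a False mask.
    """
    columns = [f"{c}_{t}h" for c in conditions for t in times]
    key = fc_table.assign(col=fc_table["condition"] + "_" + fc_table["time_h"].astype(str) + "h")
    log2fc = key.pivot_table(index="gene_id", columns="col", values="log2fc", sort=False)
    sig = key.pivot_table(index="gene_id", columns="col", values="significant", sort=False)
    log2fc = log2fc.reindex(columns=columns)
    sig = sig.reindex(columns=columns)
    n_missing = int(log2fc.isna().sum().sum())
    if n_missing:
        log.warning("heatmap matrix has %d missing cells", n_missing)
    mask = sig.eq(True)  # NA cells count as not significant
    return log2fc, mask


def pca_by_time(
    matrix: ExpressionMatrix, time_h: int, scale: bool = False
) -> PCAResult:
    """PCA of samples at one time point (samples = observations, genes = variables).

    Data are centered; genes are not unit-scaled unless ``scale`` is set, so
    dominant genes dominate the axes.  Scores are sign-fixed (the largest-
    magnitude gene loading of each component is made positive).
    """
    from sklearn.decomposition import PCA

    at_t = matrix.samples[matrix.samples["time_h"] == time_h]
    ids = [s for s in at_t.index if s in matrix.values.columns]
    if len(ids) < 3:
        raise ValueError(f"need >= 3 samples at {time_h} h")
    x = matrix.values[ids].to_numpy(float).T  # samples x genes
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("constant matrix: no variance to decompose")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd == 0, 1.0, sd)
    pca = PCA()
    scores = pca.fit_transform(x)
    components = pca.components_
    for k in range(components.shape[0]):
        j = int(np.abs(components[k]).argmax())
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    frac = pca.explained_variance_ratio_
    df = pd.DataFrame(
        scores[:, :2], index=ids, columns=["PC1", "PC2"]
    )
    df["condition"] = at_t.loc[ids, "condition"].to_numpy()
    return PCAResult(time_h=time_h, scores=df, variance_fractions=frac)


def significant_sets(
    fc_table: pd.DataFrame, conditions: Sequence[str] = TREATMENTS
) -> dict[str, set[str]]:
    """Genes significant at >= 1 time point, per condition (the DEG sets)."""
    out: dict[str, set[str]] = {}
    for condition in conditions:
        sub = fc_table[(fc_table["condition"] == condition) & fc_table["significant"]]
        out[condition] = set(sub["gene_id"])
    return out


def overlap_analysis(
    sets_by_condition: Mapping[str, set[str]]
) -> dict[tuple[str, ...], set[str]]:
    """Exclusive Venn regions over the given condition sets.

    Returns every non-empty combination key (tuple of condition names, in the
    input order) mapped to the genes belonging to exactly those conditions.
    Region counts sum to the size of the union.
    """
    names = list(sets_by_condition)
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets_by_condition[c] for c in combo)) if combo else set()
            outside = set().union(
                *(sets_by_condition[c] for c in names if c not in combo)
            )
            regions[combo] = inside - outside
    return regions
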