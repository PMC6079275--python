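"""Short time-series profile clustering with permutation enrichment.

Gene expression time courses (log2 fold change versus the time-matched
control at 1, 24 and 48 h, with an implicit 0 at t = 0) are assigned to an
exhaustively enumerated set of model temporal profiles: every unit-step
vector in {-c..+c}^(T-1) anchored at 0, giving (2c+1)^(T-1) profiles (27 for
the default c = 1 over four time points).  Assignment maximizes the Pearson
correlation between the 0-prepended series and the profile vector, with
correlation defined as 0 whenever either vector is constant and ties broken
toward the lowest profile id.

Enrichment of a profile compares its observed gene count with the count
expected when the order of the post-baseline time points carries no
information: genes are re-assigned under each of the 6 exhaustive
permutations of the three post-baseline time labels (the baseline stays
fixed) and the expected count is the mean over permutations.  Significance
of the excess is a binomial tail test of the observed count against the
permutation-derived expected rate, Bonferroni-corrected across profiles.
The raw permutation exceedance fraction is reported alongside, but with only
six exhaustive permutations it is too coarse to grade significance on its
own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelProfile",
    "build_model_profiles",
    "assign_genes",
    "permutation_enrichment",
    "series_from_fc_table",
]

#: Above this many profiles the exhaustive set is thinned greedily.
PROFILE_CAP = 200


@dataclass(frozen=True)
class ModelProfile:
    """One model temporal profile: unit steps and the cumulative value track."""

    profile_id: int
    steps: tuple[int, ...]

    @property
    def values(self) -> tuple[int, ...]:
        out = [0]
        for s in self.steps:
            out.append(out[-1] + s)
        return tuple(out)


def build_model_profiles(
    n_timepoints: int = 4, c: int = 1, max_profiles: int = PROFILE_CAP
) -> list[ModelProfile]:
    """Enumerate all (2c+1)^(T-1) profiles anchored at 0, lexicographically.

    When the exhaustive set exceeds ``max_profiles`` a greedy maximally
    distinct subset of that size is selected instead (farthest-first on
    profile-value correlation distance, seeded with the flat profile).
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if n_timepoints < 2:
        raise ValueError("need >= 2 time points")
    steps = list(itertools.product(range(-c, c + 1), repeat=n_timepoints - 1))
    steps.sort()
    profiles = [ModelProfile(i, s) for i, s in enumerate(steps)]
    if len(profiles) <= max_profiles:
        return profiles
    return _select_distinct(profiles, max_profiles)


def _select_distinct(profiles: list[ModelProfile], n: int) -> list[ModelProfile]:
    values = np.array([p.values for p in profiles], dtype=float)
    dist = 1.0 - _corr_matrix(values, values)
    flat = next(i for i, p in enumerate(profiles) if all(s == 0 for s in p.steps))
    chosen = [flat]
    while len(chosen) < n:
        min_d = dist[:, chosen].min(axis=1)
        min_d[chosen] = -np.inf
        chosen.append(int(min_d.argmax()))
    return [ModelProfile(rank, profiles[i].steps) for rank, i in enumerate(sorted(chosen))]


def _corr_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation rows-of-x vs rows-of-y.

    A constant row against a non-constant one correlates 0 (no shape
    information); two constant rows correlate 1, so a flat series matches the
    flat profile rather than an arbitrary one.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    yn = np.linalg.norm(yc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xc @ yc.T) / np.outer(xn, yn)
    corr[~np.isfinite(corr)] = 0.0
    both_const = np.outer(xn == 0, yn == 0)
    corr[both_const] = 1.0
    return corr


def _series_matrix(
    series: Mapping[str, Sequence[float]] | pd.DataFrame, n_post: int
) -> tuple[list[str], np.ndarray]:
    if isinstance(series, pd.DataFrame):
        genes = list(series.index)
        mat = series.to_numpy(float)
    else:
        genes = list(series)
        mat = np.array([list(series[g]) for g in genes], dtype=float)
    if mat.ndim != 2 or mat.shape[1] != n_post:
        raise ValueError(
            f"each series must have {n_post} post-baseline values, got shape {mat.shape}"
        )
    return genes, mat


def assign_genes(
    series: Mapping[str, Sequence[float]] | pd.DataFrame,
    profiles: Sequence[ModelProfile],
) -> pd.DataFrame:
    """Assign each gene's log2FC series to its best-correlated model profile.

    ``series`` holds the post-baseline values (e.g. at 1, 24, 48 h); a 0 is
    prepended before correlating against the profile value tracks.  A
    constant series correlates 0 with every changing profile and 1 with the
    flat one, so flat genes land on the flat profile; remaining ties break
    toward the lowest profile id.
    """
    pvals = np.array([p.values for p in profiles], dtype=float)
    n_post = pvals.shape[1] - 1
    genes, mat = _series_matrix(series, n_post)
    full = np.hstack([np.zeros((len(genes), 1)), mat])
    corr = _corr_matrix(full, pvals)
    best = corr.argmax(axis=1)  # argmax takes the lowest index on ties
    return pd.DataFrame(
        {
            "gene_id": genes,
            "profile_id": [profiles[i].profile_id for i in best],
            "correlation": corr[np.arange(len(genes)), best],
        }
    )


def permutation_enrichment(
    assignments: pd.DataFrame,
    series: Mapping[str, Sequence[float]] | pd.DataFrame,
    profiles: Sequence[ModelProfile],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Profile enrichment against the exhaustive time-label permutation null.

    For each of the 6 permutations of the post-baseline time labels (baseline
    fixed) genes are re-assigned and per-profile counts recorded; ``expected``
    is the mean count.  ``p_value`` is the binomial tail probability of the
    observed count at the permutation-derived expected rate; ``significant``
    applies Bonferroni across profiles.  ``perm_p`` is the raw permutation
    exceedance fraction ``(#perms with count >= observed + 1) / (N + 1)``.
    Exhaustive enumeration makes the whole computation deterministic.
    """
    pvals = np.array([p.values for p in profiles], dtype=float)
    n_post = pvals.shape[1] - 1
    genes, mat = _series_matrix(series, n_post)
    n_genes = len(genes)
    profile_ids = [p.profile_id for p in profiles]
    id_to_pos = {pid: i for i, pid in enumerate(profile_ids)}

    observed = np.zeros(len(profiles), dtype=int)
    for pid in assignments["profile_id"]:
        observed[id_to_pos[pid]] += 1

    perms = list(itertools.permutations(range(n_post)))
    counts = np.zeros((len(perms), len(profiles)), dtype=int)
    for k, perm in enumerate(perms):
        permuted = mat[:, list(perm)]
        full = np.hstack([np.zeros((n_genes, 1)), permuted])
        best = _corr_matrix(full, pvals).argmax(axis=1)
        counts[k] = np.bincount(best, minlength=len(profiles))
    expected = counts.mean(axis=0)

    rate = np.clip(expected / max(n_genes, 1), 1e-12, 1.0)
    p_value = stats.binom.sf(observed - 1, n_genes, rate)
    perm_p = ((counts >= observed[None, :]).sum(axis=0) + 1) / (len(perms) + 1)
    bonf = alpha / len(profiles)
    rows = []
    for i, profile in enumerate(profiles):
        members = assignments.loc[
            assignments["profile_id"] == profile.profile_id, "gene_id"
        ].tolist()
        rows.append(
            {
                "profile_id": profile.profile_id,
                "steps": profile.steps,
                "observed": int(observed[i]),
                "expected": float(expected[i]),
                "p_value": float(p_value[i]),
                "perm_p": float(perm_p[i]),
                "significant": bool(p_value[i] < bonf),
                "genes": members,
            }
        )
    return pd.DataFrame(rows)


def series_from_fc_table(
    fc_table: pd.DataFrame, condition: str, times: Sequence[int] = (1, 24, 48)
) -> pd.DataFrame:
    """Gene x time log2FC series for one condition, ordered by time."""
    sub = fc_table[fc_table["condition"] == condition]
    wide = sub.pivot_table(index="gene_id", columns="time_h", values="log2fc", sort=False)
    return wide.reindex(columns=list(times))
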