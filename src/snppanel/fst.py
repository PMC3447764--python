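"""Weir-Cockerham Fst (theta) between accession groups.

Implements the full diploid variance-components estimator: per locus the
among-population (a), among-individuals-within-population (b) and
within-individual (c) components are computed from genotype counts,
honouring observed heterozygosity; the multilocus estimate combines loci
as a ratio of sums, theta = sum(a) / sum(a + b + c).  Significance is
assessed by permuting accessions between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HET, HOM_ALT, HOM_REF, MISSING, PanelError, SnpPanel, SubpopulationScheme

__all__ = [
    "weir_cockerham_theta",
    "theta_from_summaries",
    "fst_permutation_test",
    "pairwise_fst_matrix",
    "balanced_resample_fst",
    "FstMatrix",
]


def _group_summaries(g: np.ndarray):
    """Per-locus (n called individuals, ref-allele freq, het proportion)."""
    n_aa = (g == HOM_REF).sum(axis=0)
    n_ab = (g == HET).sum(axis=0)
    n_bb = (g == HOM_ALT).sum(axis=0)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_aa + n_ab) / np.maximum(2 * n, 1)
        h = n_ab / np.maximum(n, 1)
    return n.astype(float), p, h


def theta_components(nA, pA, hA, nB, pB, hB):
    """Weir-Cockerham variance components (a, b, c) for two populations.

    Vectorised over loci.  Loci where either sample has fewer than one
    called individual, or where n_c degenerates, yield NaN components and
    are skipped by the multilocus combiner.
    """
    r = 2.0
    nA = np.asarray(nA, float)
    nB = np.asarray(nB, float)
    valid = (nA > 0) & (nB > 0) & (nA + nB > 2)
    nbar = (nA + nB) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def theta_from_summaries(nA, pA, hA, nB, pB, hB):
    """Multilocus theta (ratio of sums) from per-group locus summaries."""
    a, b, c = theta_components(nA, pA, hA, nB, pB, hB)
    denom = np.nansum(a + b + c)
    if denom == 0 or not np.isfinite(denom):
        return np.nan, a, b, c
    return float(np.nansum(a) / denom), a, b, c


@dataclass
class ThetaResult:
    theta: float
    per_locus_theta: np.ndarray
    components: pd.DataFrame  # a, b, c per locus (NaN where undefined)


def weir_cockerham_theta(
    panel: SnpPanel, group_a: list[str], group_b: list[str], markers=None
) -> ThetaResult:
    """Pairwise theta between two accession groups.

    Per-locus theta values (a / (a+b+c)) are reported for the outlier scan;
    the headline multilocus estimate is the ratio of summed components.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise PanelError("each group needs at least 2 accessions")
    if set(group_a) & set(group_b):
        raise PanelError("groups overlap")
    mids = panel.marker_ids if markers is None else list(markers)
    if len(mids) == 0:
        raise PanelError("empty marker set")
    ga = panel.calls(group=group_a, markers=mids)
    gb = panel.calls(group=group_b, markers=mids)
    nA, pA, hA = _group_summaries(ga)
    nB, pB, hB = _group_summaries(gb)
    theta, a, b, c = theta_from_summaries(nA, pA, hA, nB, pB, hB)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
    comp = pd.DataFrame(
        {"a": a, "b": b, "c": c, "theta": per_locus},
        index=pd.Index(mids, name="marker_id"),
    )
    return ThetaResult(theta=theta, per_locus_theta=per_locus, components=comp)


def fst_permutation_test(
    panel: SnpPanel,
    group_a: list[str],
    group_b: list[str],
    markers=None,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation p-value for theta > 0.

    Accessions are shuffled between the two groups holding group sizes
    fixed; p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    Returns (observed theta, p-value).
    """
    if n_perm < 1:
        raise PanelError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    mids = panel.marker_ids if markers is None else list(markers)
    obs = weir_cockerham_theta(panel, group_a, group_b, markers=mids).theta
    pooled = list(group_a) + list(group_b)
    g = panel.calls(group=pooled, markers=mids)
    nA = len(group_a)
    n_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        sa = _group_summaries(g[perm[:nA]])
        sb = _group_summaries(g[perm[nA:]])
        t, *_ = theta_from_summaries(*sa, *sb)
        if np.isfinite(t) and t >= obs:
            n_exceed += 1
    p = (1 + n_exceed) / (n_perm + 1)
    return obs, p


@dataclass
class FstMatrix:
    """Symmetric multilocus theta matrix with permutation significance."""

    theta: pd.DataFrame
    p_values: pd.DataFrame
    stars: pd.DataFrame  # 'NS', '*', '**' after Bonferroni adjustment
    per_locus: dict[tuple[str, str], pd.Series]


def pairwise_fst_matrix(
    panel: SnpPanel,
    scheme: SubpopulationScheme,
    markers=None,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> FstMatrix:
    """All pairwise theta estimates with Bonferroni-corrected stars.

    Significance codes: '**' when the Bonferroni-adjusted p is below 0.005,
    '*' below 0.05, else 'NS'.  The Bonferroni factor is the number of
    unordered group pairs tested.
    """
    rng = np.random.default_rng() if rng is None else rng
    groups = scheme.groups()
    labels = [lab for lab in groups if len(groups[lab]) >= 2]
    if len(labels) < 2:
        raise PanelError("need at least 2 groups of size >= 2")
    n_tests = len(labels) * (len(labels) - 1) // 2
    theta = pd.DataFrame(0.0, index=labels, columns=labels)
    pvals = pd.DataFrame(np.nan, index=labels, columns=labels)
    stars = pd.DataFrame("", index=labels, columns=labels)
    per_locus = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            if n_perm > 0:
                t, p = fst_permutation_test(
                    panel, groups[la], groups[lb], markers=markers, n_perm=n_perm, rng=rng
                )
            else:
                t = weir_cockerham_theta(panel, groups[la], groups[lb], markers=markers).theta
                p = np.nan
            res = weir_cockerham_theta(panel, groups[la], groups[lb], markers=markers)
            per_locus[(la, lb)] = pd.Series(res.per_locus_theta, index=res.components.index)
            theta.loc[la, lb] = theta.loc[lb, la] = t
            pvals.loc[la, lb] = pvals.loc[lb, la] = p
            p_adj = min(p * n_tests, 1.0) if np.isfinite(p) else np.nan
            code = "NS"
            if np.isfinite(p_adj):
                if p_adj < 0.005:
                    code = "**"
                elif p_adj < 0.05:
                    code = "*"
            stars.loc[la, lb] = stars.loc[lb, la] = code
    return FstMatrix(theta=theta, p_values=pvals, stars=stars, per_locus=per_locus)


def balanced_resample_fst(
    panel: SnpPanel,
    scheme: SubpopulationScheme,
    groups_to_resample: list[str],
    markers=None,
    n: int = 40,
    iterations: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Theta matrices under balanced subsampling of the named groups.

    Each iteration draws ``n`` accessions without replacement from every
    group in ``groups_to_resample`` (other groups enter whole) and
    recomputes all pairwise theta values.  Returns the per-iteration
    matrices and a dispersion summary (min/max/range per pair).
    """
    rng = np.random.default_rng() if rng is None else rng
    all_groups = scheme.groups()
    for lab in groups_to_resample:
        if lab not in all_groups:
            raise PanelError(f"unknown group {lab!r}")
        if len(all_groups[lab]) < n:
            raise PanelError(f"group {lab!r} has fewer than n={n} accessions")
    mats = []
    for _ in range(iterations):
        assignment = {}
        for lab, ids in all_groups.items():
            chosen = (
                list(rng.choice(ids, size=n, replace=False))
                if lab in groups_to_resample
                else ids
            )
            for a in chosen:
                assignment[a] = lab
        sub_scheme = SubpopulationScheme(assignment, labels=tuple(all_groups))
        m = pairwise_fst_matrix(panel, sub_scheme, markers=markers, n_perm=0, rng=rng)
        mats.append(m.theta)
    stacked = np.stack([m.to_numpy() for m in mats])
    labels = mats[0].index
    summary_rows = []
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if j <= i:
                continue
            vals = stacked[:, i, j]
            summary_rows.append(
                {
                    "group_a": la,
                    "group_b": lb,
                    "theta_min": float(np.nanmin(vals)),
                    "theta_max": float(np.nanmax(vals)),
                    "theta_range": float(np.nanmax(vals) - np.nanmin(vals)),
                }
            )
    return mats, pd.DataFrame(summary_rows)
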