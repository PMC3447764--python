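"""Population structure by PCA on proportionally coded genotypes.

Genotypes are coded 2 / 1 / 0 (homozygous for the common allele /
heterozygous / homozygous for the rare allele, with the common allele
fixed from a reference accession set), missing cells are completed by the
iterative low-rank SVD imputation scheme, and structure is summarised by
a centred singular value decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .panel import HET, HOM_ALT, HOM_REF, MISSING, PanelError, SnpPanel, SubpopulationScheme
from .panel import allele_frequencies

logger = logging.getLogger(__name__)


@dataclass
class CodedMatrix:
    """Accession x marker matrix of {2,1,0}/NaN proportional codes."""

    values: np.ndarray  # float, NaN for missing
    accession_ids: list[str]
    marker_ids: list[str]


def proportional_coding(
    panel: SnpPanel,
    reference_group: list[str],
    group: list[str] | None = None,
    markers=None,
) -> CodedMatrix:
    """Code calls as copies of the common allele (2/1/0; NaN = missing).

    The common allele at each marker is fixed from ``reference_group``
    (ties at 0.5 resolve to the reference/A allele, consistent with the
    minor-allele tie-break elsewhere).  Markers whose reference frequency
    is undefined (all calls missing) are excluded with a warning.
    """
    if len(reference_group) == 0:
        raise PanelError("reference group is empty")
    mids = panel.marker_ids if markers is None else list(markers)
    ref = allele_frequencies(panel, group=reference_group, markers=mids)
    defined = ~ref["undefined"].to_numpy()
    if not defined.all():
        logger.warning(
            "proportional_coding: %d markers with undefined reference frequency excluded",
            int((~defined).sum()),
        )
    mids = [m for m, d in zip(mids, defined) if d]
    common_is_ref = ref.loc[defined, "p"].to_numpy() >= 0.5

    acc = panel.accession_ids if group is None else list(group)
    g = panel.calls(group=acc, markers=mids).astype(float)
    coded = np.full(g.shape, np.nan)
    # dosage of the reference allele, then flip where ALT is the common allele
    coded[g == HOM_REF] = 2.0
    coded[g == HET] = 1.0
    coded[g == HOM_ALT] = 0.0
    coded[:, ~common_is_ref] = 2.0 - coded[:, ~common_is_ref]
    return CodedMatrix(values=coded, accession_ids=list(acc), marker_ids=mids)


def svd_impute(
    coded: CodedMatrix | np.ndarray,
    rank: int = 10,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Complete missing cells by iterative rank-k SVD reconstruction.

    Missing cells start at their column means; the matrix is repeatedly
    approximated by its best rank-``rank`` reconstruction and the missing
    cells overwritten with the approximation, until the relative change of
    the imputed values falls below ``tol``.  Observed cells are never
    altered.
    """
    x = coded.values if isinstance(coded, CodedMatrix) else np.asarray(coded, float)
    x = x.copy()
    mask = np.isnan(x)
    if not mask.any():
        return x
    if mask.mean() >= 0.5:
        raise PanelError("more than 50% missing cells; refusing to impute")
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), np.nanmean(x), col_mean)
    x[mask] = np.broadcast_to(col_mean, x.shape)[mask]
    rank = min(rank, min(x.shape) - 1) or 1
    prev = x[mask].copy()
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        approx = (u[:, :rank] * s[:rank]) @ vt[:rank]
        x[mask] = approx[mask]
        delta = np.linalg.norm(x[mask] - prev) / max(np.linalg.norm(prev), 1e-12)
        if delta < tol:
            break
        prev = x[mask].copy()
    else:
        logger.warning("svd_impute: no convergence after %d iterations", max_iter)
    return x


@dataclass
class PcaResult:
    """Scores, unit-norm loadings and variance explained per component."""

    scores: pd.DataFrame  # accessions x PCs
    loadings: pd.DataFrame  # markers x PCs (unit-norm columns)
    variance_explained: np.ndarray  # fraction per PC, non-increasing


def pca(
    matrix: np.ndarray,
    accession_ids: list[str] | None = None,
    marker_ids: list[str] | None = None,
    n_components: int | None = None,
    center: bool = True,
) -> PcaResult:
    """Column-centred SVD of a completed coded matrix.

    Scores are the projections U*S; loadings are the right-singular vectors
    (unit column norm); variance_explained_j = sigma_j^2 / sum sigma^2.
    """
    x = np.asarray(matrix, float)
    if np.isnan(x).any():
        raise PanelError("matrix contains missing values; impute first")
    n, m = x.shape
    k = min(n, m) if n_components is None else n_components
    if m < k:
        raise PanelError("more components requested than markers")
    if center:
        x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    var = (s**2) / total if total > 0 else np.zeros_like(s)
    k = min(k, len(s))
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=accession_ids if accession_ids is not None else range(n),
        columns=pcs,
    )
    loadings = pd.DataFrame(
        vt[:k].T,
        index=marker_ids if marker_ids is not None else range(m),
        columns=pcs,
    )
    return PcaResult(scores=scores, loadings=loadings, variance_explained=var[:k])


def loading_screen(
    result: PcaResult,
    markers: pd.DataFrame,
    pc: str = "PC1",
    threshold: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Markers with |loading| strictly above the threshold, by chromosome.

    ``markers`` must be indexed by marker_id with a ``chrom`` column.
    Returns (selected-marker table, per-chromosome count/percentage table).
    """
    lo = result.loadings[pc]
    selected = lo[lo.abs() > threshold]
    tab = pd.DataFrame({"loading": selected})
    tab["chrom"] = markers.loc[tab.index, "chrom"].to_numpy()
    total = max(len(tab), 1)
    counts = tab.groupby("chrom").size()
    summary = pd.DataFrame(
        {"n_markers": counts, "percentage": 100.0 * counts / total}
    ).sort_index()
    return tab, summary


def eigen_anova(
    result: PcaResult,
    scheme: SubpopulationScheme,
    pc_set: tuple[str, ...] = ("PC1", "PC2"),
) -> pd.DataFrame:
    """One-way ANOVA of subpopulation label on PC scores, per component."""
    groups = {
        lab: [a for a in ids if a in result.scores.index]
        for lab, ids in scheme.groups().items()
    }
    groups = {lab: ids for lab, ids in groups.items() if len(ids) >= 2}
    if len(groups) < 2:
        raise PanelError("need at least 2 groups with >= 2 scored accessions")
    rows = []
    for pc in pc_set:
        samples = [result.scores.loc[ids, pc].to_numpy() for ids in groups.values()]
        if np.ptp(np.concatenate(samples)) == 0:
            rows.append({"pc": pc, "F": 0.0, "p_value": 1.0})
            continue
        stat = f_oneway(*samples)
        f = float(stat.statistic)
        p = float(stat.pvalue)
        if not np.isfinite(f):
            f, p = 0.0, 1.0
        rows.append({"pc": pc, "F": f, "p_value": p})
    return pd.DataFrame(rows).set_index("pc")
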