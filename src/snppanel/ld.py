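"""Chromosome-wise linkage-disequilibrium decay.

Pairwise r-squared between markers is computed on haploidised calls
(heterozygotes dropped pairwise, defensible for panels that are >= 95%
homozygous), plotted against genetic map distance, and summarised by two
decay fits -- LOESS smoothing and nonlinear least squares on the Hill-Weir
drift expectation E[r^2](C) with C proportional to distance -- against two
baselines: a fixed r^2 of 0.2 and the parametric 95th percentile of
unlinked (inter-chromosomal) pairs.  The decay distance is the first
distance at which the fitted curve falls to the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.nonparametric.smoothers_lowess import lowess

from .panel import HET, HOM_ALT, HOM_REF, MISSING, PanelError, SnpPanel

logger = logging.getLogger(__name__)

NOT_DETERMINED = None
GRID_STEP_CM = 0.01


@dataclass
class LdPointSet:
    """(distance, r^2) pairs for one chromosome and accession group."""

    pairs: pd.DataFrame  # marker_a, marker_b, distance_cM, r2, n_obs
    chromosome: str
    group_label: str
    n_accessions: int
    n_pairs_dropped: int  # pairs with too few joint observations


def _haploidize(g: np.ndarray) -> np.ndarray:
    """Calls as haploid alleles: 1 = ref, 0 = alt, NaN = missing or HET."""
    h = np.full(g.shape, np.nan)
    h[g == HOM_REF] = 1.0
    h[g == HOM_ALT] = 0.0
    return h


def r2_matrix(h: np.ndarray, min_obs: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs haplotypic r^2 = D^2/(pA qA pB qB) with pairwise deletion.

    Returns (r2, n_obs) square matrices; entries with fewer than ``min_obs``
    joint observations or a monomorphic member are NaN.
    """
    n_acc, n_m = h.shape
    obs = (~np.isnan(h)).astype(float)
    x = np.nan_to_num(h)
    n_joint = obs.T @ obs
    s_a = x.T @ obs  # sum of allele a over jointly observed
    s_ab = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = s_a / n_joint
        p_b = s_a.T / n_joint
        p_ab = s_ab / n_joint
        d = p_ab - p_a * p_b
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = d**2 / denom
    r2[(n_joint < min_obs) | ~np.isfinite(r2)] = np.nan
    return r2, n_joint


def pairwise_r2(
    panel: SnpPanel,
    group: list[str],
    chromosome: str,
    markers: list[str],
    min_obs: int = 10,
    group_label: str = "",
) -> LdPointSet:
    """Within-chromosome pairwise r^2 for the given markers and group.

    ``markers`` should already be filtered (typically MAF >= 0.1 within the
    group); only those on ``chromosome`` with genetic positions are used.
    """
    sub = panel.markers.set_index("marker_id").loc[markers]
    on_chrom = sub[(sub["chrom"] == chromosome) & sub["cM"].notna()]
    mids = list(on_chrom.index)
    if len(mids) < 2:
        logger.warning("pairwise_r2: <2 eligible markers on chromosome %s", chromosome)
        return LdPointSet(
            pairs=pd.DataFrame(
                columns=["marker_a", "marker_b", "distance_cM", "r2", "n_obs"]
            ),
            chromosome=chromosome,
            group_label=group_label,
            n_accessions=len(group),
            n_pairs_dropped=0,
        )
    h = _haploidize(panel.calls(group=group, markers=mids))
    r2, n_joint = r2_matrix(h, min_obs=min_obs)
    pos = on_chrom["cM"].to_numpy(float)
    iu, ju = np.triu_indices(len(mids), k=1)
    vals = r2[iu, ju]
    keep = np.isfinite(vals)
    n_dropped = int((~keep).sum())
    pairs = pd.DataFrame(
        {
            "marker_a": np.array(mids)[iu[keep]],
            "marker_b": np.array(mids)[ju[keep]],
            "distance_cM": np.abs(pos[ju[keep]] - pos[iu[keep]]),
            "r2": vals[keep],
            "n_obs": n_joint[iu[keep], ju[keep]].astype(int),
        }
    )
    return LdPointSet(
        pairs=pairs,
        chromosome=chromosome,
        group_label=group_label,
        n_accessions=len(group),
        n_pairs_dropped=n_dropped,
    )


@dataclass
class DecayFit:
    """A fitted r^2-vs-distance curve evaluable on a grid."""

    method: str  # 'LOESS' or 'NLR'
    grid: np.ndarray  # cM
    curve: np.ndarray  # fitted r^2, clipped to [0, 1]
    span: float | None = None  # LOESS span
    rho: float | None = None  # NLR: C = rho * d
    n: int | None = None  # NLR: sample size in the Hill-Weir expectation

    def evaluate(self, d) -> np.ndarray:
        return np.interp(np.asarray(d, float), self.grid, self.curve)


def _fit_grid(distances: np.ndarray) -> np.ndarray:
    d_max = float(distances.max())
    return np.arange(0.0, d_max + GRID_STEP_CM, GRID_STEP_CM)


def loess_decay(points: LdPointSet, span: float = 0.3) -> DecayFit:
    """LOESS (locally weighted linear, tricube) fit of r^2 on distance."""
    d = points.pairs["distance_cM"].to_numpy(float)
    r2 = points.pairs["r2"].to_numpy(float)
    if len(d) < 20:
        raise PanelError("need at least 20 (distance, r^2) points for LOESS")
    if np.ptp(d) == 0:
        raise PanelError("degenerate distances: all pairs at the same distance")
    grid = _fit_grid(d)
    fitted = lowess(r2, d, frac=span, xvals=grid)
    return DecayFit(
        method="LOESS", grid=grid, curve=np.clip(fitted, 0.0, 1.0), span=span
    )


def hill_weir_expected_r2(c, n):
    """Drift expectation of r^2 at scaled recombination C and sample size n.

    E[r^2] = [(10+C)/((2+C)(11+C))] * [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))].
    """
    c = np.asarray(c, float)
    base = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    corr = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c**2)) / (n * (2.0 + c) * (11.0 + c))
    return base * corr


def hill_weir_fit(points: LdPointSet, n: int | None = None) -> DecayFit:
    """Nonlinear least squares of the Hill-Weir expectation with C = rho*d.

    ``n`` defaults to the number of accessions used for the point set.
    """
    d = points.pairs["distance_cM"].to_numpy(float)
    r2 = points.pairs["r2"].to_numpy(float)
    if len(d) < 20:
        raise PanelError("need at least 20 points for the Hill-Weir fit")
    n = points.n_accessions if n is None else n
    if n < 10:
        raise PanelError("Hill-Weir fit needs sample size n >= 10")

    def resid(log_rho):
        return hill_weir_expected_r2(np.exp(log_rho[0]) * d, n) - r2

    best = None
    for rho0 in (0.01, 0.1, 1.0, 10.0):
        sol = least_squares(resid, x0=[np.log(rho0)], method="lm", max_nfev=200)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise PanelError(
            f"Hill-Weir optimiser failed; residual diagnostics: {best}"
        )
    rho = float(np.exp(best.x[0]))
    grid = _fit_grid(d)
    curve = np.clip(hill_weir_expected_r2(rho * grid, n), 0.0, 1.0)
    return DecayFit(method="NLR", grid=grid, curve=curve, rho=rho, n=n)


def baseline_r2(
    panel: SnpPanel,
    group: list[str],
    markers: list[str],
    method: str = "percentile_95_unlinked",
    fixed: float = 0.2,
    min_pairs: int = 500,
    max_pairs: int = 20000,
    parametric: bool = True,
    min_obs: int = 10,
    rng: np.random.Generator | None = None,
) -> float:
    """Background r^2 level against which decay is measured.

    ``fixed``: return the fixed value (default 0.2).  ``percentile_95_unlinked``:
    the 95th percentile of r^2 between markers on different chromosomes; by
    convention it is computed parametrically on square-root-transformed
    values (mean + 1.645 sd of sqrt(r^2), squared back), with the plain
    empirical percentile available via ``parametric=False``.  Unlinked pairs
    are subsampled to ``max_pairs`` when necessary (seeded rng).
    """
    if method == "fixed_0.2" or method == "fixed":
        return float(fixed)
    if method != "percentile_95_unlinked":
        raise PanelError(f"unknown baseline method {method!r}")
    rng = np.random.default_rng() if rng is None else rng
    sub = panel.markers.set_index("marker_id").loc[markers]
    sub = sub[sub["chrom"] != "unknown"]
    chroms = sub["chrom"].unique()
    if len(chroms) < 2:
        raise PanelError("percentile baseline needs markers on >= 2 chromosomes")
    mids = list(sub.index)
    h = _haploidize(panel.calls(group=group, markers=mids))
    chrom_arr = sub["chrom"].to_numpy()
    iu, ju = np.triu_indices(len(mids), k=1)
    unlinked = chrom_arr[iu] != chrom_arr[ju]
    iu, ju = iu[unlinked], ju[unlinked]
    if len(iu) > max_pairs:
        pick = rng.choice(len(iu), size=max_pairs, replace=False)
        iu, ju = iu[pick], ju[pick]
    r2, _ = r2_matrix(h, min_obs=min_obs)
    vals = r2[iu, ju]
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_pairs:
        raise PanelError(
            f"only {len(vals)} unlinked pairs available; need >= {min_pairs}"
        )
    root = np.sqrt(vals)
    if parametric:
        q95 = root.mean() + 1.6449 * root.std(ddof=1)
    else:
        q95 = np.quantile(root, 0.95)
    return float(np.clip(q95, 0.0, 1.0) ** 2)


def decay_distance(fit: DecayFit, baseline: float) -> tuple[float | None, bool]:
    """First distance at which the fitted curve falls to <= baseline.

    Returns (distance_cM, started_below).  If the curve starts at or below
    the baseline the distance is 0.0 with ``started_below=True``; if it
    never reaches the baseline within the fitted range the distance is
    ``None`` (not determined).
    """
    below = fit.curve <= baseline
    if not below.any():
        return NOT_DETERMINED, False
    first = int(np.argmax(below))
    if first == 0:
        return 0.0, True
    return float(fit.grid[first]), False
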