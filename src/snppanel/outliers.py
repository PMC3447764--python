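"""Fst-outlier detection conditioned on heterozygosity.

A neutral joint distribution of (He, theta) between two samples is built
by simulating loci under a symmetric island model realised through
Balding-Nichols frequency draws: the expected Fst is the controlled
quantity, and the observed statistics (Weir-Cockerham theta and pooled
gene diversity He) are computed on simulated samples exactly as for real
loci, including the panel's selfing-style inbreeding.  Loci whose theta
falls outside the He-conditional envelope are candidates for positive
(above) or balancing (below) selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelError
from .fst import theta_from_summaries, theta_components

POSITIVE = "positive_selection"
BALANCING = "balancing"
NEUTRAL = "neutral"


def _sample_deme_genotypes(p, n, f_is, rng):
    """Genotype summaries for one deme, vectorised over loci.

    With probability ``f_is`` an individual is autozygous (one allele drawn,
    doubled); otherwise its two alleles are drawn independently.  Returns
    (n_called, sample allele freq, sample het proportion) arrays.
    """
    p = np.asarray(p, float)
    m = p.shape[0]
    n_ibd = rng.binomial(n, f_is, size=m) if f_is > 0 else np.zeros(m, dtype=int)
    n_out = n - n_ibd
    aa_ibd = rng.binomial(n_ibd, p)
    p_sq = p**2
    aa_out = rng.binomial(n_out, p_sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(p_sq < 1.0, 2 * p * (1 - p) / np.maximum(1 - p_sq, 1e-300), 0.0)
    ab_out = rng.binomial(n_out - aa_out, np.clip(cond, 0.0, 1.0))
    n_aa = aa_ibd + aa_out
    n_ab = ab_out
    p_s = (2 * n_aa + n_ab) / (2.0 * n)
    h_s = n_ab / float(n)
    return np.full(m, float(n)), p_s, h_s


def simulate_island_loci(
    n_loci: int,
    target_fst: float,
    sample_sizes: tuple[int, int] = (50, 50),
    f_is: float = 0.0,
    mutation: str = "infinite_alleles",
    n_ancestral_alleles: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw neutral loci and return (He, theta, components).

    Two demes diverge from an ancestral allele pool at divergence
    ``target_fst`` (Balding-Nichols / Dirichlet draws).  Under the
    infinite-alleles mutation model the ancestral locus carries several
    alleles (Dirichlet-distributed frequencies) which are reduced to a
    biallelic state by pooling everything but the ancestrally most common
    allele; ``mutation="biallelic"`` draws a two-allele ancestral frequency
    from a broad Uniform law directly.  He is the pooled-sample gene
    diversity 2*p*(1-p); theta is the two-population Weir-Cockerham
    estimator applied to the sampled genotypes.
    """
    if not 0.0 < target_fst < 1.0:
        raise PanelError("target Fst must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    nA, nB = sample_sizes
    if nA < 2 or nB < 2:
        raise PanelError("need at least 2 sampled individuals per deme")
    scale = (1.0 - target_fst) / target_fst
    if mutation == "infinite_alleles":
        anc = rng.dirichlet(np.ones(n_ancestral_alleles), size=n_loci)
        # Balding-Nichols generalised to K alleles: Dirichlet(anc * scale)
        gamma_a = rng.standard_gamma(anc * scale)
        gamma_b = rng.standard_gamma(anc * scale)
        deme_a = gamma_a / np.maximum(gamma_a.sum(axis=1, keepdims=True), 1e-300)
        deme_b = gamma_b / np.maximum(gamma_b.sum(axis=1, keepdims=True), 1e-300)
        ref = np.argmax(anc, axis=1)
        rows = np.arange(n_loci)
        pA = deme_a[rows, ref]
        pB = deme_b[rows, ref]
    elif mutation == "biallelic":
        p_anc = rng.uniform(0.02, 0.98, n_loci)
        pA = rng.beta(p_anc * scale, (1 - p_anc) * scale)
        pB = rng.beta(p_anc * scale, (1 - p_anc) * scale)
    else:
        raise PanelError(f"unknown mutation model {mutation!r}")

    sA = _sample_deme_genotypes(pA, nA, f_is, rng)
    sB = _sample_deme_genotypes(pB, nB, f_is, rng)
    a, b, c = theta_components(*sA, *sB)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    he = pooled_he(sA[0], sA[1], sB[0], sB[1])
    comp = pd.DataFrame({"a": a, "b": b, "c": c})
    return he, theta, comp


def simulate_divergent_loci(
    n_loci: int,
    target_fst: float,
    sample_sizes: tuple[int, int] = (50, 50),
    f_is: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Loci under divergent selection between the two demes.

    Unlike the neutral draws, where per-locus divergence is a noisy
    Balding-Nichols realisation around the target, selection is emulated by
    pushing the two deme frequencies deterministically apart around a
    mid-range mean, pA,B = pbar +/- delta with delta chosen so that the
    two-population Weir-Cockerham parameter of every planted locus equals
    ``target_fst`` (for two demes theta = 2 delta^2 / (pbar qbar + delta^2),
    hence delta^2 = theta pbar qbar / (2 - theta)).  Returns (He, theta)
    computed from sampled genotypes exactly as for neutral loci.
    """
    if not 0.0 < target_fst < 1.0:
        raise PanelError("target Fst must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    pbar = rng.uniform(0.4, 0.6, n_loci)
    delta = np.sqrt(target_fst * pbar * (1.0 - pbar) / (2.0 - target_fst))
    pA = np.clip(pbar + delta, 0.0, 1.0)
    pB = np.clip(pbar - delta, 0.0, 1.0)
    swap = rng.random(n_loci) < 0.5
    pA, pB = np.where(swap, pB, pA), np.where(swap, pA, pB)
    nA, nB = sample_sizes
    sA = _sample_deme_genotypes(pA, nA, f_is, rng)
    sB = _sample_deme_genotypes(pB, nB, f_is, rng)
    a, b, c = theta_components(*sA, *sB)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    he = pooled_he(sA[0], sA[1], sB[0], sB[1])
    return he, theta


def pooled_he(nA, pA, nB, pB) -> np.ndarray:
    """Gene diversity 2p(1-p) of the size-weighted pooled sample frequency."""
    pbar = (np.asarray(nA) * pA + np.asarray(nB) * pB) / (np.asarray(nA) + np.asarray(nB))
    return 2.0 * pbar * (1.0 - pbar)


@dataclass
class NeutralEnvelope:
    """He-conditional theta quantile bounds from neutral simulation."""

    he_centers: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    ci: float
    target_mean_fst: float
    calibrated_f: float
    n_sims: int
    sample_sizes: tuple[int, int]
    he_range: tuple[float, float]

    def bounds_at(self, he) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (lower, upper) bounds at the given He values.

        He outside the simulated range clamps to the nearest bin.
        """
        he = np.asarray(he, float)
        lo = np.interp(he, self.he_centers, self.lower)
        hi = np.interp(he, self.he_centers, self.upper)
        return lo, hi


def _running_median(x: np.ndarray, window: int = 3) -> np.ndarray:
    if len(x) < window:
        return x.copy()
    out = x.copy()
    half = window // 2
    for i in range(len(x)):
        out[i] = np.median(x[max(0, i - half) : i + half + 1])
    return out


def _mean_theta(f, sample_sizes, f_is, mutation, n_loci, seed):
    rng = np.random.default_rng(seed)
    he, theta, comp = simulate_island_loci(
        n_loci, f, sample_sizes, f_is=f_is, mutation=mutation, rng=rng
    )
    denom = np.nansum(comp["a"] + comp["b"] + comp["c"])
    return float(np.nansum(comp["a"]) / denom)


def build_envelope(
    target_mean_fst: float,
    sample_sizes: tuple[int, int] = (50, 50),
    f_is: float = 0.0,
    mutation: str = "infinite_alleles",
    n_sims: int = 50000,
    n_runs: int = 5,
    ci: float = 0.95,
    n_bins: int = 25,
    tol: float = 0.005,
    rng: np.random.Generator | None = None,
) -> NeutralEnvelope:
    """Simulate the neutral (He, theta) cloud and extract quantile bounds.

    The divergence parameter is calibrated by bisection (forced mean) so
    that the pooled simulated multilocus theta matches ``target_mean_fst``
    within ``tol``; the cloud is pooled over ``n_runs`` independent runs.
    He bins contain equal numbers of simulated loci; the per-bin empirical
    quantiles are smoothed by a running median over adjacent bins.
    """
    if not 0.0 < target_mean_fst < 1.0:
        raise PanelError("target mean Fst must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    calib_seed = int(rng.integers(2**31))
    n_calib = min(max(n_sims // 4, 2000), 20000)

    def f_of(x):
        return _mean_theta(x, sample_sizes, f_is, mutation, n_calib, calib_seed)

    lo, hi = 1e-4, 0.995
    if not (f_of(lo) <= target_mean_fst <= f_of(hi)):
        raise PanelError("target mean Fst outside achievable range")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if f_of(mid) < target_mean_fst:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    f_cal = 0.5 * (lo + hi)

    per_run = max(n_sims // n_runs, 1)
    for attempt in range(5):
        he_all, th_all, comps, run_means = [], [], [], []
        for _ in range(n_runs):
            he, theta, comp = simulate_island_loci(
                per_run, f_cal, sample_sizes, f_is=f_is, mutation=mutation, rng=rng
            )
            he_all.append(he)
            th_all.append(theta)
            comps.append(comp)
            run_means.append(
                float(np.nansum(comp["a"]) / np.nansum(comp["a"] + comp["b"] + comp["c"]))
            )
        he = np.concatenate(he_all)
        theta = np.concatenate(th_all)
        comp = pd.concat(comps, ignore_index=True)
        pooled = float(
            np.nansum(comp["a"]) / np.nansum(comp["a"] + comp["b"] + comp["c"])
        )
        # accept within tol, widened to the Monte-Carlo standard error of
        # the pooled mean when few loci are simulated
        se = float(np.std(run_means, ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
        if abs(pooled - target_mean_fst) <= max(tol, 2.5 * se):
            break
        # one-step proportional correction, then re-simulate
        f_cal = float(np.clip(f_cal * target_mean_fst / max(pooled, 1e-6), 1e-4, 0.995))
    else:
        raise PanelError(
            f"forced-mean calibration failed: pooled mean {pooled:.4f} "
            f"vs target {target_mean_fst:.4f}"
        )

    ok = np.isfinite(theta) & np.isfinite(he)
    he, theta = he[ok], theta[ok]
    order = np.argsort(he, kind="stable")
    he, theta = he[order], theta[order]
    bins = np.array_split(np.arange(len(he)), n_bins)
    q_lo = (1.0 - ci) / 2.0
    centers, lower, upper = [], [], []
    for idx in bins:
        if len(idx) == 0:
            continue
        centers.append(float(he[idx].mean()))
        lower.append(float(np.quantile(theta[idx], q_lo)))
        upper.append(float(np.quantile(theta[idx], 1.0 - q_lo)))
    lower = _running_median(np.array(lower))
    upper = _running_median(np.array(upper))
    return NeutralEnvelope(
        he_centers=np.array(centers),
        lower=lower,
        upper=upper,
        ci=ci,
        target_mean_fst=target_mean_fst,
        calibrated_f=f_cal,
        n_sims=len(he),
        sample_sizes=tuple(sample_sizes),
        he_range=(float(he.min()), float(he.max())),
    )


def neutral_mean_fst(
    components: pd.DataFrame,
    he: np.ndarray,
    sample_sizes: tuple[int, int],
    f_is: float = 0.0,
    trim_level: float = 0.95,
    n_sims: int = 20000,
    rng: np.random.Generator | None = None,
) -> float:
    """One-round trimmed ("neutral") mean Fst.

    A provisional envelope is built at the raw multilocus mean; observed
    loci falling outside it are dropped and the ratio-of-sums mean of the
    retained loci is returned.  This reduces the pull of selected loci on
    the target mean used for the final envelope.
    """
    if len(components) < 50:
        raise PanelError("need at least 50 loci for a neutral-mean estimate")
    a = components["a"].to_numpy(float)
    bc = components["b"].to_numpy(float) + components["c"].to_numpy(float)
    raw = float(np.nansum(a) / np.nansum(a + bc))
    env = build_envelope(
        raw,
        sample_sizes,
        f_is=f_is,
        n_sims=n_sims,
        ci=trim_level,
        rng=rng,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + bc)
    lo, hi = env.bounds_at(he)
    keep = np.isfinite(theta) & (theta >= lo) & (theta <= hi)
    if not keep.any():
        raise PanelError("all loci trimmed in neutral-mean estimation")
    return float(np.nansum(a[keep]) / np.nansum((a + bc)[keep]))


def detect_outliers(
    he: np.ndarray,
    theta: np.ndarray,
    envelope: NeutralEnvelope,
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call each locus against the envelope at its He.

    ``positive_selection`` when theta is strictly above the upper bound,
    ``balancing`` strictly below the lower bound, else ``neutral``.  Loci
    with He outside the simulated range use nearest-bin bounds and are
    flagged.  Pass ``markers`` (with chrom / positions) to carry map
    columns into the output.
    """
    he = np.asarray(he, float)
    theta = np.asarray(theta, float)
    if len(he) == 0:
        cols = ["he", "theta", "lower", "upper", "call", "he_out_of_range"]
        return pd.DataFrame(columns=cols)
    lo, hi = envelope.bounds_at(he)
    call = np.full(len(he), NEUTRAL, dtype=object)
    finite = np.isfinite(theta)
    call[finite & (theta > hi)] = POSITIVE
    call[finite & (theta < lo)] = BALANCING
    out_of_range = (he < envelope.he_range[0]) | (he > envelope.he_range[1])
    out = pd.DataFrame(
        {
            "he": he,
            "theta": theta,
            "lower": lo,
            "upper": hi,
            "call": call,
            "he_out_of_range": out_of_range,
        }
    )
    if markers is not None:
        out.index = markers.index
        for col in ("chrom", "cM", "bp"):
            if col in markers.columns:
                out[col] = markers[col].to_numpy()
    return out


def outlier_chromosome_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Count and percentage of positive-selection candidates per chromosome."""
    if "chrom" not in calls.columns:
        raise PanelError("calls table has no chromosome column")
    pos = calls[calls["call"] == POSITIVE]
    counts = pos.groupby("chrom").size()
    total = max(len(pos), 1)
    return pd.DataFrame(
        {"n_outliers": counts, "percentage": 100.0 * counts / total}
    ).sort_index()
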