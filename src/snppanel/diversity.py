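"""Within-population diversity descriptors and rarefaction.

Implements the classical descriptive statistics for marker panels:
rarefied allelic richness A (expected number of distinct alleles in a
standardized draw of g gene copies), Nei's unbiased expected
heterozygosity He, Botstein's polymorphism information content PIC, and
polymorphic-marker accumulation curves estimated by repeated random
subsampling of accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import HET, HOM_ALT, HOM_REF, MISSING, PanelError, SnpPanel, SubpopulationScheme
from .panel import CHROMOSOMES, UNKNOWN_CHROM


def pic(freqs) -> float:
    """Polymorphism information content.

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.  For a biallelic locus
    this reduces to 2pq(1 - pq).
    """
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise PanelError("negative allele frequency")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise PanelError("allele frequencies must sum to 1")
    sq = p**2
    cross = (sq.sum() ** 2 - (sq**2).sum()) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - sq.sum() - 2.0 * cross)


def expected_het(freqs, n_copies: int, unbiased: bool = True) -> float:
    """Expected heterozygosity (gene diversity), optionally Nei-corrected.

    The unbiased form is He = n/(n-1) * (1 - sum p_i^2) with n the number of
    sampled gene copies.
    """
    if n_copies < 2:
        raise PanelError("need at least 2 gene copies")
    p = np.asarray(freqs, dtype=float)
    h = 1.0 - float((p**2).sum())
    if unbiased:
        h *= n_copies / (n_copies - 1)
    return h


def allelic_richness(allele_counts, g: int) -> float:
    """Rarefied allelic richness: expected distinct alleles in g copies.

    A = sum_alleles [1 - C(N - N_i, g) / C(N, g)] for a locus with N
    sampled gene copies of which N_i carry allele i (draw without
    replacement).  Computed with log-gamma for numerical stability.
    """
    counts = np.asarray(allele_counts, dtype=float)
    n_total = counts.sum()
    if g < 1:
        raise PanelError("rarefaction size g must be >= 1")
    if g > n_total:
        raise PanelError(f"rarefaction size g={g} exceeds sampled copies N={n_total}")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    a = 0.0
    for n_i in counts:
        rest = n_total - n_i
        if rest < g:
            a += 1.0  # allele i must appear in any draw of g
        else:
            a += 1.0 - np.exp(log_comb(rest, g) - log_comb(n_total, g))
    return float(a)


@dataclass
class DiversitySummary:
    """Per-group multilocus diversity descriptors."""

    table: pd.DataFrame  # index group; sample_size, A, He, PIC, n_polymorphic
    per_chromosome: pd.DataFrame  # long: group, chrom, n_polymorphic, percentage
    rarefaction_g: int


def _allele_counts(panel: SnpPanel, group, markers):
    g = panel.calls(group=group, markers=markers)
    n_ref = 2 * (g == HOM_REF).sum(axis=0) + (g == HET).sum(axis=0)
    n_alt = 2 * (g == HOM_ALT).sum(axis=0) + (g == HET).sum(axis=0)
    return n_ref, n_alt


def _polymorphic_mask(g: np.ndarray) -> np.ndarray:
    """Markers with both alleles observed (HET counts toward both)."""
    has_a = ((g == HOM_REF) | (g == HET)).any(axis=0)
    has_b = ((g == HOM_ALT) | (g == HET)).any(axis=0)
    return has_a & has_b


def group_diversity(
    panel: SnpPanel, scheme: SubpopulationScheme, markers=None
) -> DiversitySummary:
    """Multilocus A, He, PIC and polymorphic-marker counts per subpopulation.

    Statistics are unweighted means over the analysis marker set.  The
    rarefaction size g is the smallest non-missing gene-copy count found at
    any (group, marker) cell with data, so A is comparable across groups of
    unequal size.  Per-chromosome polymorphic counts include an 'unknown'
    row; percentages sum to 100 per group.
    """
    scheme.validate_against(panel)
    mids = panel.marker_ids if markers is None else list(markers)
    groups = scheme.groups()
    counts = {lab: _allele_counts(panel, ids, mids) for lab, ids in groups.items()}

    # rarefaction size: smallest positive copy count across groups/markers
    g_min = None
    for n_ref, n_alt in counts.values():
        tot = n_ref + n_alt
        pos = tot[tot > 0]
        if len(pos):
            g_min = int(pos.min()) if g_min is None else min(g_min, int(pos.min()))
    if g_min is None:
        raise PanelError("no called markers in any group")
    g_min = max(g_min, 2)

    rows = []
    chrom_rows = []
    chrom_of = panel.markers.set_index("marker_id")["chrom"].loc[mids]
    for lab, ids in groups.items():
        n_ref, n_alt = counts[lab]
        tot = n_ref + n_alt
        ok = tot >= g_min
        a_vals = np.array(
            [allelic_richness((r, q), g_min) for r, q in zip(n_ref[ok], n_alt[ok])]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, n_ref / np.maximum(tot, 1), np.nan)
        he_vals = np.array(
            [
                expected_het((pp, 1 - pp), int(t))
                for pp, t in zip(p[ok], tot[ok])
            ]
        )
        pic_vals = np.array([pic((pp, 1 - pp)) for pp in p[ok]])
        gmat = panel.calls(group=ids, markers=mids)
        poly = _polymorphic_mask(gmat)
        rows.append(
            {
                "group": lab,
                "sample_size": len(ids),
                "A": float(a_vals.mean()) if len(a_vals) else np.nan,
                "He": float(he_vals.mean()) if len(he_vals) else np.nan,
                "PIC": float(pic_vals.mean()) if len(pic_vals) else np.nan,
                "n_polymorphic": int(poly.sum()),
            }
        )
        n_poly_total = max(int(poly.sum()), 1)
        for chrom in CHROMOSOMES + [UNKNOWN_CHROM]:
            in_chrom = (chrom_of == chrom).to_numpy()
            n_c = int((poly & in_chrom).sum())
            chrom_rows.append(
                {
                    "group": lab,
                    "chrom": chrom,
                    "n_polymorphic": n_c,
                    "percentage": 100.0 * n_c / n_poly_total,
                }
            )
    return DiversitySummary(
        table=pd.DataFrame(rows).set_index("group"),
        per_chromosome=pd.DataFrame(chrom_rows),
        rarefaction_g=g_min,
    )


@dataclass
class AccumulationCurve:
    """Mean/sd of polymorphic-marker count vs number of sampled accessions."""

    sizes: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def accumulation_curve(
    panel: SnpPanel,
    group: list[str],
    markers=None,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> AccumulationCurve:
    """Polymorphic-marker accumulation by random subsampling.

    For each subset size k = 1..n the number of markers polymorphic within
    the first k accessions of a random ordering is recorded; mean and sd are
    taken over ``n_perm`` orderings drawn without replacement.
    """
    if len(group) < 2:
        raise PanelError("need at least 2 accessions for an accumulation curve")
    rng = np.random.default_rng() if rng is None else rng
    g = panel.calls(group=group, markers=markers)
    n = g.shape[0]
    counts = np.empty((n_perm, n))
    for it in range(n_perm):
        perm = rng.permutation(n)
        gp = g[perm]
        has_a = np.maximum.accumulate((gp == HOM_REF) | (gp == HET), axis=0)
        has_b = np.maximum.accumulate((gp == HOM_ALT) | (gp == HET), axis=0)
        counts[it] = (has_a & has_b).sum(axis=1)
    return AccumulationCurve(
        sizes=np.arange(1, n + 1),
        mean=counts.mean(axis=0),
        sd=counts.std(axis=0, ddof=1),
    )
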