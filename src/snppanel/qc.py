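"""Marker-level quality control and filtering.

Classification follows array-QC practice for inbred diploid panels: a
marker is *polymorphic* when both homozygous allele states are observed;
markers whose alternate allele appears only in heterozygous calls, or that
look monomorphic but have >=10% missing data, cannot be classified
unambiguously and are set aside as *undetermined*.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import HET, HOM_ALT, HOM_REF, MISSING, PanelError, SnpPanel, SubpopulationScheme
from .panel import allele_frequencies

logger = logging.getLogger(__name__)

CLASS_POLYMORPHIC = "polymorphic"
CLASS_MONOMORPHIC = "monomorphic"
CLASS_UNDET_MISSING = "undetermined_missing"
CLASS_UNDET_HET_ONLY = "undetermined_het_only"
CLASS_NO_CALL = "no_call"

#: Missing-data strata reported for polymorphic markers.
MISSING_STRATA = ("<10%", "10-20%", ">20%")


def classify_markers(panel: SnpPanel, inbreds_only: bool = True) -> pd.DataFrame:
    """Classify every marker by call pattern.

    Returns a DataFrame indexed by marker_id with columns ``marker_class``,
    ``missing_fraction``, ``maf_overall`` and ``missing_stratum`` (only for
    polymorphic markers).  Classes are mutually exclusive and exhaustive:

    - ``no_call``: zero non-missing calls;
    - ``undetermined_het_only``: the alternate allele is seen only in
      heterozygous calls (at most one homozygous state observed, HETs present);
    - ``undetermined_missing``: monomorphic pattern with >= 10% missing data;
    - ``monomorphic``: one allele only, < 10% missing data;
    - ``polymorphic``: both homozygous states observed.
    """
    group = panel.inbred_ids() if inbreds_only else None
    g = panel.calls(group=group)
    n = g.shape[0]
    n_aa = (g == HOM_REF).sum(axis=0)
    n_ab = (g == HET).sum(axis=0)
    n_bb = (g == HOM_ALT).sum(axis=0)
    n_called = n_aa + n_ab + n_bb
    missing_frac = (n - n_called) / n  # exact at the 10% boundary

    cls = np.empty(panel.n_markers, dtype=object)
    no_call = n_called == 0
    het_only = ~no_call & (n_ab > 0) & ((n_aa == 0) | (n_bb == 0))
    mono_pattern = ~no_call & (n_ab == 0) & ((n_aa == 0) | (n_bb == 0))
    poly = ~no_call & (n_aa > 0) & (n_bb > 0)
    cls[no_call] = CLASS_NO_CALL
    cls[het_only] = CLASS_UNDET_HET_ONLY
    cls[mono_pattern & (missing_frac >= 0.10)] = CLASS_UNDET_MISSING
    cls[mono_pattern & (missing_frac < 0.10)] = CLASS_MONOMORPHIC
    cls[poly] = CLASS_POLYMORPHIC

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, (2 * n_aa + n_ab) / np.maximum(2 * n_called, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)

    stratum = np.full(panel.n_markers, "", dtype=object)
    stratum[poly & (missing_frac < 0.10)] = MISSING_STRATA[0]
    stratum[poly & (missing_frac >= 0.10) & (missing_frac <= 0.20)] = MISSING_STRATA[1]
    stratum[poly & (missing_frac > 0.20)] = MISSING_STRATA[2]

    return pd.DataFrame(
        {
            "marker_class": cls,
            "missing_fraction": missing_frac,
            "maf_overall": maf,
            "missing_stratum": stratum,
        },
        index=pd.Index(panel.marker_ids, name="marker_id"),
    )


def class_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Marker-classification summary (count and percentage per class)."""
    counts = table["marker_class"].value_counts()
    order = [
        CLASS_POLYMORPHIC,
        CLASS_MONOMORPHIC,
        CLASS_UNDET_MISSING,
        CLASS_UNDET_HET_ONLY,
        CLASS_NO_CALL,
    ]
    counts = counts.reindex(order, fill_value=0)
    out = pd.DataFrame({"n_markers": counts})
    out["percentage"] = 100.0 * out["n_markers"] / len(table)
    return out


def maf_table(
    panel: SnpPanel,
    scheme: SubpopulationScheme,
    minor_allele_reference: list[str],
    markers=None,
) -> pd.DataFrame:
    """Per-marker, per-group frequency of a panel-wide minor allele.

    The minor allele is fixed once from ``minor_allele_reference`` (the
    allele with frequency < 0.5 there; an exact tie is broken toward the
    alternate allele).  Each subpopulation's "MAF" is then the frequency of
    that same allele within the group, so values above 0.5 flag divergence
    from the reference pool.
    """
    if len(minor_allele_reference) == 0:
        raise PanelError("minor-allele reference subset is empty")
    scheme.validate_against(panel)
    ref = allele_frequencies(panel, group=minor_allele_reference, markers=markers)
    # minor allele is ALT when p_ref(A) >= 0.5 (tie included), else REF
    minor_is_alt = ref["p"] >= 0.5
    cols = {"minor_is_alt": minor_is_alt, "undefined_in_reference": ref["undefined"]}
    for label, ids in scheme.groups().items():
        grp = allele_frequencies(panel, group=ids, markers=markers)
        p_minor = np.where(minor_is_alt, 1.0 - grp["p"], grp["p"])
        cols[label] = p_minor
    return pd.DataFrame(cols, index=ref.index)


def heterozygosity_observed(
    panel: SnpPanel, group: list[str], markers=None, polymorphic_within_group: bool = False
) -> float:
    """Mean per-accession proportion of heterozygous calls.

    With ``polymorphic_within_group`` the proportion is computed only over
    markers segregating within the group (both homozygous states or a HET
    observed), which is how within-population heterozygosity is usually
    quoted for inbred panels.
    """
    if len(group) == 0:
        raise PanelError("empty accession group")
    g = panel.calls(group=group, markers=markers)
    if g.shape[1] == 0:
        raise PanelError("empty marker set")
    if polymorphic_within_group:
        has_a = ((g == HOM_REF) | (g == HET)).any(axis=0)
        has_b = ((g == HOM_ALT) | (g == HET)).any(axis=0)
        g = g[:, has_a & has_b]
        if g.shape[1] == 0:
            return float("nan")
    n_called = (g != MISSING).sum(axis=1)
    n_het = (g == HET).sum(axis=1)
    ok = n_called > 0
    if not ok.all():
        logger.warning(
            "heterozygosity_observed: %d accession(s) with zero calls excluded",
            int((~ok).sum()),
        )
    if not ok.any():
        return float("nan")
    return float((n_het[ok] / n_called[ok]).mean())


def filter_markers(
    panel: SnpPanel,
    max_missing: float | None = None,
    min_maf: float | None = None,
    require_map: bool = False,
    group: list[str] | None = None,
    markers=None,
) -> list[str]:
    """Marker ids satisfying all requested criteria.

    ``max_missing`` is exclusive (< threshold retained), ``min_maf`` is
    inclusive (>= threshold retained), matching the conventions "<10%
    missing data" and "MAF >= 0.1".  Frequencies are computed within
    ``group`` when given, else over the inbred panel.
    """
    ids = panel.marker_ids if markers is None else list(markers)
    acc = group if group is not None else panel.inbred_ids()
    freq = allele_frequencies(panel, group=acc, markers=ids)
    g = panel.calls(group=acc, markers=ids)
    keep = np.ones(len(ids), dtype=bool)
    if max_missing is not None:
        missing_frac = (g == MISSING).mean(axis=0)
        keep &= missing_frac < max_missing
    if min_maf is not None:
        maf = np.minimum(freq["p"].to_numpy(), 1.0 - freq["p"].to_numpy())
        # tolerance so a MAF of exactly the threshold survives rounding
        keep &= ~np.isnan(maf) & (maf >= min_maf - 1e-9)
    if require_map:
        sub = panel.markers.set_index("marker_id").loc[ids]
        keep &= (
            (sub["chrom"] != "unknown") & sub["cM"].notna()
        ).to_numpy()
    result = [m for m, k in zip(ids, keep) if k]
    if not result:
        logger.warning("filter_markers: no markers satisfy the criteria")
    return result
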