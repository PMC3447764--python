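"""Core data model and I/O for diploid biallelic SNP panels.

A panel couples three tables: a genotype call matrix (accessions x markers),
a marker map (chromosome, genetic position in cM, physical position in bp)
and an accession table (subpopulation labels, hybrid flags, duplicate links).
Calls are normalised internally to the four states HOM_REF / HET / HOM_ALT /
MISSING; the Illumina A/B convention maps AA -> HOM_REF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Internal call codes (int8).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

#: Known genotype alphabets, mapping text codes to internal call states.
ALPHABETS: dict[str, dict[str, int]] = {
    "AB": {"AA": HOM_REF, "AB": HET, "BA": HET, "BB": HOM_ALT, "NC": MISSING},
    "012": {"0": HOM_ALT, "1": HET, "2": HOM_REF, "NA": MISSING},
}

_CODE_TO_AB = {HOM_REF: "AA", HET: "AB", HOM_ALT: "BB", MISSING: "NC"}

CHROMOSOMES = [str(i) for i in range(1, 13)]
UNKNOWN_CHROM = "unknown"


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel inputs."""


@dataclass
class SnpPanel:
    """Genotype matrix plus marker map and accession metadata.

    Parameters
    ----------
    genotypes : ndarray of int8, shape (n_accessions, n_markers)
        Call codes ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``.
    markers : DataFrame
        Columns ``marker_id``, ``chrom`` (str, '1'..'12' or 'unknown'),
        ``cM`` (float, NaN if unmapped), ``bp`` (float, NaN if unplaced).
    accessions : DataFrame
        Columns ``accession_id``, ``subpopulation`` (str or NaN),
        ``is_hybrid`` (bool), ``duplicate_of`` (str or NaN).
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    accessions: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise PanelError("genotype matrix must be 2-dimensional")
        n_acc, n_mrk = self.genotypes.shape
        if len(self.accessions) != n_acc:
            raise PanelError(
                f"accession table has {len(self.accessions)} rows, "
                f"genotype matrix has {n_acc}"
            )
        if len(self.markers) != n_mrk:
            raise PanelError(
                f"marker table has {len(self.markers)} rows, "
                f"genotype matrix has {n_mrk} columns"
            )
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers["marker_id"][self.markers["marker_id"].duplicated()]
            raise PanelError(f"duplicate marker ids: {sorted(set(dup))[:5]}")
        if self.accessions["accession_id"].duplicated().any():
            dup = self.accessions["accession_id"][
                self.accessions["accession_id"].duplicated()
            ]
            raise PanelError(f"duplicate accession ids: {sorted(set(dup))[:5]}")
        bad = ~np.isin(self.genotypes, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise PanelError(f"{int(bad.sum())} genotype cells outside call alphabet")
        self._sort_markers()
        self.markers = self.markers.reset_index(drop=True)
        self.accessions = self.accessions.reset_index(drop=True)
        self._acc_pos = {a: i for i, a in enumerate(self.accessions["accession_id"])}
        self._mrk_pos = {m: j for j, m in enumerate(self.markers["marker_id"])}

    def _sort_markers(self) -> None:
        # Within each chromosome markers are kept sorted by genetic, then
        # physical position; ordering across chromosomes is numeric with
        # 'unknown' last. Stable, so unmapped markers keep input order.
        chrom_rank = self.markers["chrom"].map(
            {c: i for i, c in enumerate(CHROMOSOMES + [UNKNOWN_CHROM])}
        )
        if chrom_rank.isna().any():
            bad = self.markers.loc[chrom_rank.isna(), "chrom"].unique()
            raise PanelError(f"unknown chromosome labels: {list(bad)[:5]}")
        order = np.lexsort(
            (
                self.markers["bp"].fillna(np.inf).to_numpy(float),
                self.markers["cM"].fillna(np.inf).to_numpy(float),
                chrom_rank.to_numpy(),
            )
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order]
            self.genotypes = self.genotypes[:, order]

    # -- indexing helpers -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def accession_ids(self) -> list[str]:
        return list(self.accessions["accession_id"])

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["marker_id"])

    def accession_indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._acc_pos[a] for a in ids], dtype=np.intp)
        except KeyError as e:
            raise PanelError(f"unknown accession id {e.args[0]!r}") from None

    def marker_indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._mrk_pos[m] for m in ids], dtype=np.intp)
        except KeyError as e:
            raise PanelError(f"unknown marker id {e.args[0]!r}") from None

    def inbred_ids(self) -> list[str]:
        """Accessions that are neither hybrids nor duplicate re-samples.

        Frequency-based analyses use this set by default so that duplicated
        samples and heterozygous hybrids do not distort allele counts.
        """
        acc = self.accessions
        keep = (~acc["is_hybrid"].astype(bool)) & acc["duplicate_of"].isna()
        return list(acc.loc[keep, "accession_id"])

    def calls(self, group=None, markers=None) -> np.ndarray:
        """Genotype sub-matrix for accession ids `group` x marker ids `markers`."""
        g = self.genotypes
        if group is not None:
            g = g[self.accession_indices(group), :]
        if markers is not None:
            g = g[:, self.marker_indices(markers)]
        return g


@dataclass
class SubpopulationScheme:
    """Accession -> subpopulation labelling, with optional finer subgroups."""

    assignment: dict[str, str]
    labels: tuple[str, ...] = ()
    subgroup: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = tuple(sorted(set(self.assignment.values())))
        bad = set(self.assignment.values()) - set(self.labels)
        if bad:
            raise PanelError(f"labels outside declared set: {sorted(bad)}")

    @classmethod
    def from_panel(cls, panel: SnpPanel, inbreds_only: bool = True) -> "SubpopulationScheme":
        acc = panel.accessions
        if inbreds_only:
            acc = acc[acc["accession_id"].isin(panel.inbred_ids())]
        acc = acc.dropna(subset=["subpopulation"])
        return cls({r.accession_id: r.subpopulation for r in acc.itertuples()})

    def validate_against(self, panel: SnpPanel) -> None:
        missing = set(self.assignment) - set(panel.accession_ids)
        if missing:
            raise PanelError(f"scheme names unknown accessions: {sorted(missing)[:5]}")

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {lab: [] for lab in self.labels}
        for acc, lab in self.assignment.items():
            out[lab].append(acc)
        return {lab: ids for lab, ids in out.items() if ids}


# -- I/O -------------------------------------------------------------------


def _parse_marker_table(marker_tsv) -> pd.DataFrame:
    mt = pd.read_csv(marker_tsv, sep="\t", dtype={"marker_id": str, "chrom": str})
    required = {"marker_id", "chrom"}
    if not required <= set(mt.columns):
        raise PanelError(f"marker table needs columns {sorted(required)}")
    for col in ("cM", "bp"):
        if col not in mt.columns:
            mt[col] = np.nan
        mt[col] = pd.to_numeric(mt[col], errors="coerce")
    if ((mt["cM"] < 0) | (mt["bp"] < 0)).any():
        raise PanelError("negative map positions in marker table")
    return mt[["marker_id", "chrom", "cM", "bp"]]


def _parse_accession_table(accession_tsv) -> pd.DataFrame:
    at = pd.read_csv(accession_tsv, sep="\t", dtype=str)
    if "accession_id" not in at.columns:
        raise PanelError("accession table needs an accession_id column")
    for col in ("subpopulation", "duplicate_of"):
        if col not in at.columns:
            at[col] = np.nan
    if "is_hybrid" in at.columns:
        at["is_hybrid"] = (
            at["is_hybrid"].str.lower().isin(("1", "true", "yes", "y"))
        )
    else:
        at["is_hybrid"] = False
    return at[["accession_id", "subpopulation", "is_hybrid", "duplicate_of"]]


def read_panel(genotype_tsv, marker_tsv, accession_tsv, alphabet: str = "AB") -> SnpPanel:
    """Read the TSV triple (genotypes, marker map, accessions) into a panel.

    The genotype table has accessions as rows (first column ``accession_id``)
    and one column per marker.  Cells are decoded through `alphabet`
    (``"AB"``: AA/AB/BB/NC, or ``"012"``: 2/1/0/NA).
    """
    if alphabet not in ALPHABETS:
        raise PanelError(f"unknown genotype alphabet {alphabet!r}")
    code = ALPHABETS[alphabet]
    markers = _parse_marker_table(marker_tsv)
    accessions = _parse_accession_table(accession_tsv)

    gt = pd.read_csv(genotype_tsv, sep="\t", dtype=str)
    if gt.columns[0] != "accession_id":
        raise PanelError("genotype table must start with an accession_id column")
    gt_markers = list(gt.columns[1:])
    unknown_m = set(gt_markers) - set(markers["marker_id"])
    if unknown_m:
        raise PanelError(f"genotype table markers not in marker table: {sorted(unknown_m)[:5]}")
    unknown_a = set(gt["accession_id"]) - set(accessions["accession_id"])
    if unknown_a:
        raise PanelError(
            f"genotype table accessions not in accession table: {sorted(unknown_a)[:5]}"
        )
    # Align metadata tables to genotype table order.
    markers = (
        markers.set_index("marker_id").loc[gt_markers].reset_index()
    )
    accessions = (
        accessions.set_index("accession_id").loc[gt["accession_id"]].reset_index()
    )

    raw = gt[gt_markers].to_numpy(dtype=str)
    geno = np.full(raw.shape, np.iinfo(np.int8).min, dtype=np.int8)
    for text, value in code.items():
        geno[raw == text] = value
    bad_cells = geno == np.iinfo(np.int8).min
    if bad_cells.any():
        i, j = np.argwhere(bad_cells)[0]
        raise PanelError(
            f"unrecognised genotype code {raw[i, j]!r} at accession "
            f"{gt['accession_id'].iloc[i]!r}, marker {gt_markers[j]!r}"
        )
    return SnpPanel(geno, markers, accessions)


def write_panel(panel: SnpPanel, genotype_tsv, marker_tsv, accession_tsv) -> None:
    """Write a panel back to the TSV triple (A/B alphabet, NC for missing)."""
    text = np.empty(panel.genotypes.shape, dtype=object)
    for value, code in _CODE_TO_AB.items():
        text[panel.genotypes == value] = code
    gt = pd.DataFrame(text, columns=panel.marker_ids)
    gt.insert(0, "accession_id", panel.accession_ids)
    gt.to_csv(genotype_tsv, sep="\t", index=False)
    panel.markers.to_csv(marker_tsv, sep="\t", index=False)
    panel.accessions.to_csv(accession_tsv, sep="\t", index=False)


def import_vcf(path) -> SnpPanel:
    """Import a VCF (4.x) of biallelic SNPs as a panel.

    Multi-allelic and non-SNP records are skipped (count logged).  Genotypes
    are read from GT; half-missing calls are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    geno_cols = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        chrom = str(var.CHROM).removeprefix("chr")
        if chrom not in CHROMOSOMES:
            chrom = UNKNOWN_CHROM
        mid = var.ID if var.ID else f"{var.CHROM}_{var.POS}"
        rows.append((mid, chrom, np.nan, float(var.POS)))
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        geno_cols.append(g)
    if n_skipped:
        logger.info("import_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not geno_cols:
        raise PanelError(f"no biallelic SNP records in {path}")
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "cM", "bp"])
    accessions = pd.DataFrame(
        {
            "accession_id": samples,
            "subpopulation": np.nan,
            "is_hybrid": False,
            "duplicate_of": np.nan,
        }
    )
    return SnpPanel(np.column_stack(geno_cols), markers, accessions)


# -- basic per-locus primitives -------------------------------------------


def allele_frequencies(panel: SnpPanel, group=None, markers=None) -> pd.DataFrame:
    """Reference-allele frequencies per marker within an accession group.

    Returns a DataFrame indexed by marker_id with columns ``p`` (frequency of
    the reference/A allele among non-missing gene copies), ``n_copies``,
    ``n_het`` and ``undefined`` (True when every call is missing).
    """
    if group is not None and len(group) == 0:
        raise PanelError("empty accession group")
    mids = panel.marker_ids if markers is None else list(markers)
    if len(mids) == 0:
        raise PanelError("empty marker set")
    g = panel.calls(group=group, markers=mids)
    n_ref = 2 * (g == HOM_REF).sum(axis=0) + (g == HET).sum(axis=0)
    n_het = (g == HET).sum(axis=0)
    n_copies = 2 * (g != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, n_ref / np.maximum(n_copies, 1), np.nan)
    return pd.DataFrame(
        {
            "p": p,
            "n_copies": n_copies,
            "n_het": n_het,
            "undefined": n_copies == 0,
        },
        index=pd.Index(mids, name="marker_id"),
    )


@dataclass
class ConcordanceResult:
    prop_consistent: float
    n_compared: int
    no_call_rate: dict[str, float]
    het_rate: dict[str, float]


def duplicate_concordance(panel: SnpPanel, a: str, b: str) -> ConcordanceResult:
    """Proportion of identical calls between two accessions.

    Consistency is assessed over markers where both samples produced a call
    (pairwise-complete); each sample's no-call and heterozygote rates are
    reported alongside, as sample-quality diagnostics.
    """
    ga = panel.calls(group=[a])[0]
    gb = panel.calls(group=[b])[0]
    both = (ga != MISSING) & (gb != MISSING)
    n = int(both.sum())
    if n == 0:
        raise PanelError(f"no jointly called markers for {a!r} and {b!r}")
    prop = float((ga[both] == gb[both]).mean())
    return ConcordanceResult(
        prop_consistent=prop,
        n_compared=n,
        no_call_rate={
            a: float((ga == MISSING).mean()),
            b: float((gb == MISSING).mean()),
        },
        het_rate={
            a: float((ga == HET).sum() / max((ga != MISSING).sum(), 1)),
            b: float((gb == HET).sum() / max((gb != MISSING).sum(), 1)),
        },
    )
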