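"""Synthetic SNP-panel generator with known truth.

Emulates an inbred crop germplasm panel genotyped on a fixed SNP array:
subpopulations diverge from a common ancestral allele-frequency pool under
the Balding-Nichols model, accessions are highly selfed (excess
homozygosity), calls fail at a small uniform rate, and linkage
disequilibrium decays with genetic map distance.  LD is induced by a
Gaussian copula: a latent exponential-covariance process along each
chromosome is thresholded marker-by-marker at the quantile matching the
target allele frequency, which gives an analytically checkable decay scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .panel import HET, HOM_ALT, HOM_REF, MISSING, SnpPanel, PanelError
import pandas as pd


@dataclass
class SubpopSpec:
    label: str
    n_accessions: int
    divergence_f: float  # Balding-Nichols F, expected Fst to the ancestral pool


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults mirror the scale and structure of a tomato germplasm panel:
    ~410 inbred accessions in 7 subpopulations of unequal size and
    divergence, ~7,720 SNPs on 12 chromosomes, residual heterozygosity in
    the 0.01-0.05 range (selfing F_IS = 0.96), ~1% missing calls, and LD
    decaying over a few cM.
    """

    seed: int = 0
    subpops: list[SubpopSpec] = field(
        default_factory=lambda: [
            SubpopSpec("processing", 141, 0.35),
            SubpopSpec("fresh_market", 110, 0.30),
            SubpopSpec("vintage", 61, 0.40),
            SubpopSpec("cultivated_cherry", 27, 0.15),
            SubpopSpec("landrace", 12, 0.20),
            SubpopSpec("wild_cherry", 43, 0.15),
            SubpopSpec("pimpinellifolium", 16, 0.65),
        ]
    )
    n_markers_per_chrom: list[int] = field(
        default_factory=lambda: [500, 780, 560, 780, 700, 640, 360, 330, 420, 380, 900, 370]
    )
    map_length_cM: list[float] = field(default_factory=lambda: [120.0] * 12)
    phys_length_bp: list[float] = field(default_factory=lambda: [70e6] * 12)
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    selfing_inbreeding: float = 0.96  # F_IS
    missing_rate: float = 0.01
    ld_scale_cM: float = 5.0  # latent correlation e^{-d/lambda}
    n_duplicates: int = 0
    duplicate_error_rate: float = 0.013

    def validate(self) -> None:
        if len(self.subpops) < 2:
            raise PanelError("need at least 2 subpopulations")
        for sp in self.subpops:
            if not 0.0 <= sp.divergence_f < 1.0:
                raise PanelError(f"divergence F for {sp.label} outside [0,1)")
            if sp.n_accessions < 1:
                raise PanelError(f"empty subpopulation {sp.label}")
        if len(self.n_markers_per_chrom) != len(self.map_length_cM):
            raise PanelError("chromosome count mismatch between markers and map")
        if not 0.0 <= self.missing_rate < 1.0:
            raise PanelError("missing_rate outside [0,1)")
        if not 0.0 <= self.selfing_inbreeding <= 1.0:
            raise PanelError("selfing_inbreeding outside [0,1]")
        if self.ld_scale_cM <= 0:
            raise PanelError("ld_scale_cM must be positive")
        if not 0.0 < self.ancestral_freq_low < self.ancestral_freq_high < 1.0:
            raise PanelError("ancestral frequency bounds must satisfy 0 < lo < hi < 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "subpops" in d:
            d["subpops"] = [
                sp if isinstance(sp, SubpopSpec) else SubpopSpec(**sp)
                for sp in d["subpops"]
            ]
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated panel."""

    divergence_f: dict[str, float]
    ancestral_freq: np.ndarray  # (n_markers,)
    subpop_freq: dict[str, np.ndarray]  # target (drawn) frequencies per subpop
    realized_freq: dict[str, np.ndarray]  # frequencies recomputed from haplotypes
    ld_scale_cM: float

    def to_json(self, path) -> None:
        obj = {
            "divergence_f": self.divergence_f,
            "ancestral_freq": np.asarray(self.ancestral_freq).tolist(),
            "subpop_freq": {k: np.asarray(v).tolist() for k, v in self.subpop_freq.items()},
            "realized_freq": {
                k: np.asarray(v).tolist() for k, v in self.realized_freq.items()
            },
            "ld_scale_cM": self.ld_scale_cM,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def balding_nichols_freqs(p_anc: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Draw subpopulation frequencies around ancestral `p_anc` at divergence `f`.

    Beta(p(1-F)/F, (1-p)(1-F)/F); F=0 returns the ancestral frequencies
    exactly.  Degenerate ancestral frequencies (0 or 1) stay fixed.
    """
    if not 0.0 <= f < 1.0:
        raise PanelError("divergence F must lie in [0, 1)")
    p_anc = np.asarray(p_anc, dtype=float)
    if f == 0.0:
        return p_anc.copy()
    scale = (1.0 - f) / f
    out = np.empty_like(p_anc)
    interior = (p_anc > 0.0) & (p_anc < 1.0)
    out[~interior] = p_anc[~interior]
    if interior.any():
        a = p_anc[interior] * scale
        b = (1.0 - p_anc[interior]) * scale
        out[interior] = rng.beta(a, b)
    return out


def simulate_frequencies(config: SimConfig, rng: np.random.Generator):
    """Ancestral and per-subpopulation allele frequencies for all markers."""
    config.validate()
    n_markers = int(sum(config.n_markers_per_chrom))
    p_anc = rng.uniform(config.ancestral_freq_low, config.ancestral_freq_high, n_markers)
    freqs = {
        sp.label: balding_nichols_freqs(p_anc, sp.divergence_f, rng)
        for sp in config.subpops
    }
    return p_anc, freqs


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for ci, (n, l_cm, l_bp) in enumerate(
        zip(config.n_markers_per_chrom, config.map_length_cM, config.phys_length_bp)
    ):
        cm = np.sort(rng.uniform(0.0, l_cm, n))
        bp = np.round(np.sort(rng.uniform(1.0, l_bp, n)))
        for k in range(n):
            rows.append((f"snp_c{ci + 1:02d}_{k:05d}", str(ci + 1), cm[k], bp[k]))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "cM", "bp"])


def simulate_haplotypes_with_ld(
    freqs: np.ndarray,
    marker_map: pd.DataFrame,
    ld_scale_cM: float,
    n_haplotypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotypes (n_haplotypes x n_markers, values 1 = reference allele).

    Along each chromosome a latent standard-normal process with correlation
    exp(-d/lambda) between markers at genetic distance d is generated by the
    Markov (AR-1 in distance) recursion; each marker is thresholded so that
    P(allele = reference) equals its target frequency.  Chromosomes are
    independent.
    """
    if ld_scale_cM <= 0:
        raise PanelError("ld_scale_cM must be positive")
    freqs = np.asarray(freqs, dtype=float)
    n_m = len(freqs)
    if len(marker_map) != n_m:
        raise PanelError("frequency vector does not match marker map")
    hap = np.empty((n_haplotypes, n_m), dtype=np.int8)
    thresholds = norm.ppf(np.clip(freqs, 0.0, 1.0))
    for _, idx in marker_map.groupby("chrom", sort=False).indices.items():
        idx = np.sort(np.asarray(idx))
        pos = marker_map["cM"].to_numpy(float)[idx]
        if np.any(np.diff(pos) < 0):
            raise PanelError("genetic map positions not monotone within chromosome")
        d = np.diff(pos)
        a = np.exp(-d / ld_scale_cM)
        z = np.empty((n_haplotypes, len(idx)))
        z[:, 0] = rng.standard_normal(n_haplotypes)
        noise = rng.standard_normal((n_haplotypes, len(idx) - 1))
        for j in range(1, len(idx)):
            z[:, j] = a[j - 1] * z[:, j - 1] + np.sqrt(1.0 - a[j - 1] ** 2) * noise[:, j - 1]
        hap[:, idx] = (z < thresholds[idx]).astype(np.int8)
    return hap


def assemble_panel(config: SimConfig) -> tuple[SnpPanel, TruthRecord]:
    """Simulate a full diploid panel plus its truth record.

    Each accession carries two haplotypes from its subpopulation; with
    probability F_IS the second is a copy of the first (selfing-style excess
    homozygosity).  Missing calls are injected uniformly; optional duplicate
    re-samples receive symmetric random call flips at the duplicate error
    rate.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_anc, freqs = simulate_frequencies(config, rng)
    mmap = _marker_map(config, rng)

    geno_blocks = []
    acc_rows = []
    realized = {}
    for sp in config.subpops:
        n = sp.n_accessions
        hap = simulate_haplotypes_with_ld(
            freqs[sp.label], mmap, config.ld_scale_cM, 2 * n, rng
        )
        h1, h2 = hap[:n], hap[n:]
        # per-(individual, locus) autozygosity: residual heterozygosity in a
        # selfing lineage is scattered along the genome
        selfed = rng.random(h1.shape) < config.selfing_inbreeding
        h2 = np.where(selfed, h1, h2)
        dosage = h1 + h2  # reference-allele count 0/1/2
        g = np.full(dosage.shape, HET, dtype=np.int8)
        g[dosage == 2] = HOM_REF
        g[dosage == 0] = HOM_ALT
        realized[sp.label] = (h1.mean(axis=0) + h2.mean(axis=0)) / 2.0
        geno_blocks.append(g)
        for k in range(n):
            acc_rows.append((f"{sp.label}_{k:04d}", sp.label, False, np.nan))

    geno = np.vstack(geno_blocks)
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = MISSING

    # Duplicate re-samples of randomly chosen accessions, with call errors.
    if config.n_duplicates > 0:
        src = rng.choice(len(acc_rows), size=config.n_duplicates, replace=False)
        dup_rows = []
        dup_geno = []
        for i in src:
            g = geno[i].copy()
            flip = (rng.random(g.shape) < config.duplicate_error_rate) & (g != MISSING)
            # symmetric flip among the two other non-missing states
            alt = np.where(
                rng.random(g.shape) < 0.5, (g + 1) % 3, (g + 2) % 3
            ).astype(np.int8)
            g[flip] = alt[flip]
            dup_geno.append(g)
            src_id, src_pop = acc_rows[i][0], acc_rows[i][1]
            dup_rows.append((f"{src_id}_dup", src_pop, False, src_id))
        geno = np.vstack([geno, np.vstack(dup_geno)])
        acc_rows.extend(dup_rows)

    accessions = pd.DataFrame(
        acc_rows, columns=["accession_id", "subpopulation", "is_hybrid", "duplicate_of"]
    )
    panel = SnpPanel(geno, mmap, accessions)
    truth = TruthRecord(
        divergence_f={sp.label: sp.divergence_f for sp in config.subpops},
        ancestral_freq=p_anc,
        subpop_freq=freqs,
        realized_freq=realized,
        ld_scale_cM=config.ld_scale_cM,
    )
    return panel, truth


def small_config(
    seed: int = 0,
    subpops=None,
    n_markers_per_chrom=(60, 60),
    map_length_cM=(100.0, 100.0),
    **kwargs,
) -> SimConfig:
    """Reduced-size config for tests and examples (two chromosomes)."""
    if subpops is None:
        subpops = [SubpopSpec("popA", 40, 0.3), SubpopSpec("popB", 40, 0.3)]
    n_chrom = len(n_markers_per_chrom)
    return SimConfig(
        seed=seed,
        subpops=list(subpops),
        n_markers_per_chrom=list(n_markers_per_chrom),
        map_length_cM=list(map_length_cM),
        phys_length_bp=[50e6] * n_chrom,
        **kwargs,
    )
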