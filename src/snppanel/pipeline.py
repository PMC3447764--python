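"""Configuration-driven end-to-end analysis pipeline.

Runs the stages (simulate/load -> qc -> diversity -> pca -> fst ->
outliers -> ld) in dependency order, writing flat TSV outputs plus a JSON
run manifest (inputs, seeds, stage outputs, counts).  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import ld as ldmod
from . import outliers as out
from . import pca as pcamod
from . import qc as qcmod
from .fst import pairwise_fst_matrix, weir_cockerham_theta
from .panel import PanelError, SnpPanel, SubpopulationScheme, read_panel, import_vcf, write_panel
from .simulate import SimConfig, assemble_panel

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "diversity", "pca", "fst", "outliers", "ld")


@dataclass
class PipelineConfig:
    """Everything a run needs; see `load_config` for the YAML form."""

    out_dir: str = "snppanel_run"
    seed: int = 0
    # exactly one input source: simulate block, TSV triple, or VCF
    simulate: dict | None = None
    genotype_tsv: str | None = None
    marker_tsv: str | None = None
    accession_tsv: str | None = None
    alphabet: str = "AB"
    vcf: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    # analysis parameters
    max_missing: float = 0.10
    pca_rank: int = 10
    loading_threshold: float = 0.02
    fst_n_perm: int = 1000
    outlier_pairs: list[tuple[str, str]] | None = None
    outlier_ci: float = 0.95
    outlier_n_sims: int = 50000
    ld_groups: list[str] | None = None
    ld_min_maf: float = 0.10
    loess_span: float = 0.3
    baseline_method: str = "percentile_95_unlinked"

    def validate(self) -> None:
        sources = [
            self.simulate is not None,
            self.genotype_tsv is not None,
            self.vcf is not None,
        ]
        if sum(sources) != 1:
            raise PanelError("config must declare exactly one input source")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PanelError(f"unknown stages: {sorted(unknown)}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "outlier_pairs" in raw and raw["outlier_pairs"] is not None:
        raw["outlier_pairs"] = [tuple(p) for p in raw["outlier_pairs"]]
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _get_panel(config: PipelineConfig, out_dir: Path, manifest: dict) -> SnpPanel:
    if config.simulate is not None:
        sim = SimConfig.from_dict({"seed": config.seed, **config.simulate})
        panel, truth = assemble_panel(sim)
        write_panel(
            panel,
            out_dir / "panel_genotypes.tsv",
            out_dir / "panel_markers.tsv",
            out_dir / "panel_accessions.tsv",
        )
        truth.to_json(out_dir / "truth.json")
        manifest["input"] = {"source": "simulate", "seed": config.seed}
        manifest["outputs"].extend(
            ["panel_genotypes.tsv", "panel_markers.tsv", "panel_accessions.tsv", "truth.json"]
        )
    elif config.vcf is not None:
        panel = import_vcf(config.vcf)
        manifest["input"] = {"source": "vcf", "path": str(config.vcf)}
    else:
        panel = read_panel(
            config.genotype_tsv,
            config.marker_tsv,
            config.accession_tsv,
            alphabet=config.alphabet,
        )
        manifest["input"] = {"source": "tsv", "genotypes": str(config.genotype_tsv)}
    manifest["n_accessions"] = panel.n_accessions
    manifest["n_markers"] = panel.n_markers
    return panel


def _write(df: pd.DataFrame, out_dir: Path, name: str, manifest: dict, index=True):
    path = out_dir / name
    df.to_csv(path, sep="\t", index=index)
    manifest["outputs"].append(name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": list(config.stages), "outputs": []}
    rng = np.random.default_rng(config.seed)

    panel = _get_panel(config, out_dir, manifest)
    scheme = SubpopulationScheme.from_panel(panel)
    inbreds = panel.inbred_ids()

    stage = None
    try:
        # markers passing the analysis filter, shared by downstream stages
        analysis_markers = qcmod.filter_markers(
            panel, max_missing=config.max_missing, require_map=True, group=inbreds
        )
        poly = div._polymorphic_mask(panel.calls(group=inbreds, markers=analysis_markers))
        analysis_markers = [m for m, p in zip(analysis_markers, poly) if p]
        manifest["n_analysis_markers"] = len(analysis_markers)

        if "qc" in config.stages:
            stage = "qc"
            classes = qcmod.classify_markers(panel)
            _write(classes, out_dir, "marker_classes.tsv", manifest)
            _write(qcmod.class_counts(classes), out_dir, "marker_class_counts.tsv", manifest)
            maf = qcmod.maf_table(panel, scheme, minor_allele_reference=inbreds)
            _write(maf, out_dir, "maf_by_group.tsv", manifest)
            het_rows = [
                {
                    "group": lab,
                    "het_all_markers": qcmod.heterozygosity_observed(panel, ids),
                    "het_polymorphic_within": qcmod.heterozygosity_observed(
                        panel, ids, polymorphic_within_group=True
                    ),
                }
                for lab, ids in scheme.groups().items()
            ]
            _write(
                pd.DataFrame(het_rows).set_index("group"),
                out_dir,
                "heterozygosity.tsv",
                manifest,
            )

        if "diversity" in config.stages:
            stage = "diversity"
            summary = div.group_diversity(panel, scheme, markers=analysis_markers)
            _write(summary.table, out_dir, "diversity_summary.tsv", manifest)
            _write(
                summary.per_chromosome, out_dir, "diversity_per_chromosome.tsv",
                manifest, index=False,
            )
            curves = []
            for lab, ids in scheme.groups().items():
                if len(ids) < 2:
                    continue
                c = div.accumulation_curve(panel, ids, n_perm=100, rng=rng)
                curves.append(
                    pd.DataFrame(
                        {"group": lab, "size": c.sizes, "mean": c.mean, "sd": c.sd}
                    )
                )
            _write(
                pd.concat(curves, ignore_index=True), out_dir,
                "accumulation_curves.tsv", manifest, index=False,
            )

        pca_result = None
        if "pca" in config.stages:
            stage = "pca"
            coded = pcamod.proportional_coding(
                panel, reference_group=inbreds, group=inbreds, markers=analysis_markers
            )
            completed = pcamod.svd_impute(coded, rank=config.pca_rank)
            pca_result = pcamod.pca(
                completed, coded.accession_ids, coded.marker_ids, n_components=10
            )
            _write(pca_result.scores, out_dir, "pca_scores.tsv", manifest)
            _write(pca_result.loadings, out_dir, "pca_loadings.tsv", manifest)
            _write(
                pd.DataFrame(
                    {
                        "pc": [f"PC{i+1}" for i in range(len(pca_result.variance_explained))],
                        "variance_explained": pca_result.variance_explained,
                    }
                ),
                out_dir, "pca_variance.tsv", manifest, index=False,
            )
            mk = panel.markers.set_index("marker_id")
            for pc in ("PC1", "PC2"):
                _tab, screen = pcamod.loading_screen(
                    pca_result, mk, pc=pc, threshold=config.loading_threshold
                )
                _write(screen, out_dir, f"loading_screen_{pc}.tsv", manifest)
            _write(
                pcamod.eigen_anova(pca_result, scheme), out_dir,
                "pca_anova.tsv", manifest,
            )

        if "fst" in config.stages:
            stage = "fst"
            fst = pairwise_fst_matrix(
                panel, scheme, markers=analysis_markers,
                n_perm=config.fst_n_perm, rng=rng,
            )
            _write(fst.theta.round(4), out_dir, "fst_matrix.tsv", manifest)
            _write(fst.stars, out_dir, "fst_significance.tsv", manifest)
            _write(fst.p_values, out_dir, "fst_pvalues.tsv", manifest)

        if "outliers" in config.stages:
            stage = "outliers"
            groups = scheme.groups()
            pairs = config.outlier_pairs
            if pairs is None:
                labs = [l for l, ids in groups.items() if len(ids) >= 10][:3]
                pairs = [(a, b) for i, a in enumerate(labs) for b in labs[i + 1 :]]
            for ga, gb in pairs:
                res = weir_cockerham_theta(
                    panel, groups[ga], groups[gb], markers=analysis_markers
                )
                fa = panel.calls(group=groups[ga], markers=analysis_markers)
                fb = panel.calls(group=groups[gb], markers=analysis_markers)
                from .fst import _group_summaries

                nA, pA, hA = _group_summaries(fa)
                nB, pB, hB = _group_summaries(fb)
                he = out.pooled_he(nA, pA, nB, pB)
                f_is = _panel_f_is(panel, groups[ga] + groups[gb], analysis_markers)
                sizes = (len(groups[ga]), len(groups[gb]))
                target = out.neutral_mean_fst(
                    res.components, he, sizes, f_is=f_is,
                    n_sims=max(config.outlier_n_sims // 5, 2000), rng=rng,
                )
                env = out.build_envelope(
                    target, sizes, f_is=f_is, ci=config.outlier_ci,
                    n_sims=config.outlier_n_sims, rng=rng,
                )
                calls = out.detect_outliers(
                    he, res.per_locus_theta, env,
                    markers=panel.markers.set_index("marker_id").loc[analysis_markers],
                )
                tag = f"{ga}_vs_{gb}"
                _write(calls, out_dir, f"outliers_{tag}.tsv", manifest)
                _write(
                    out.outlier_chromosome_summary(calls), out_dir,
                    f"outliers_{tag}_by_chrom.tsv", manifest,
                )

        if "ld" in config.stages:
            stage = "ld"
            groups = scheme.groups()
            labels = config.ld_groups or [
                l for l, ids in groups.items() if len(ids) >= 20
            ]
            rows = []
            pair_tabs = []
            for lab in labels:
                ids = groups[lab]
                mids = qcmod.filter_markers(
                    panel, min_maf=config.ld_min_maf, require_map=True,
                    group=ids, markers=analysis_markers,
                )
                base_fixed = 0.2
                try:
                    base_pct = ldmod.baseline_r2(
                        panel, ids, mids, method="percentile_95_unlinked", rng=rng
                    )
                except PanelError as e:
                    logger.warning("percentile baseline unavailable for %s: %s", lab, e)
                    base_pct = None
                chroms = [
                    c for c in panel.markers["chrom"].unique() if c != "unknown"
                ]
                for chrom in chroms:
                    pts = ldmod.pairwise_r2(panel, ids, chrom, mids, group_label=lab)
                    if len(pts.pairs) < 20:
                        continue
                    pair_tabs.append(pts.pairs.assign(group=lab, chrom=chrom))
                    fits = [ldmod.loess_decay(pts, span=config.loess_span)]
                    try:
                        fits.append(ldmod.hill_weir_fit(pts))
                    except PanelError as e:
                        logger.warning("NLR fit failed (%s, chr %s): %s", lab, chrom, e)
                    for fit in fits:
                        for bname, bval in (
                            ("fixed_0.2", base_fixed),
                            ("percentile_95", base_pct),
                        ):
                            if bval is None:
                                continue
                            dd, started_below = ldmod.decay_distance(fit, bval)
                            rows.append(
                                {
                                    "group": lab,
                                    "chrom": chrom,
                                    "method": fit.method,
                                    "baseline_method": bname,
                                    "baseline_r2": bval,
                                    "decay_cM": "n.d." if dd is None else round(dd, 1),
                                    "started_below": started_below,
                                    "n_pairs": len(pts.pairs),
                                }
                            )
            _write(
                pd.concat(pair_tabs, ignore_index=True)
                if pair_tabs else pd.DataFrame(),
                out_dir, "ld_pairs.tsv", manifest, index=False,
            )
            _write(
                pd.DataFrame(rows), out_dir, "ld_decay_summary.tsv", manifest,
                index=False,
            )
    except Exception:
        manifest["failed_stage"] = stage
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _panel_f_is(panel: SnpPanel, group: list[str], markers) -> float:
    """Crude within-panel inbreeding estimate: 1 - Hobs/Hexp over loci."""
    from .panel import allele_frequencies

    freq = allele_frequencies(panel, group=group, markers=markers)
    p = freq["p"].to_numpy(float)
    n = freq["n_copies"].to_numpy(float)
    het_obs = freq["n_het"].to_numpy(float) / np.maximum(n / 2.0, 1.0)
    he = 2.0 * p * (1.0 - p)
    ok = np.isfinite(he) & (he > 0.05)
    if not ok.any():
        return 0.0
    f = 1.0 - het_obs[ok].sum() / he[ok].sum()
    return float(np.clip(f, 0.0, 1.0))
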