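"""End-to-end orchestration of the four-step workflow.

Step order: (i) diversity — per-sample indices, pooled accumulation
curves and richness estimators; (ii) chemometrics — normalization, PCA,
correlation and clustering; (iii) differential screening — fold-change
volcano comparisons and consolidation into the unique differential list;
(iv) annotation — ppm adduct matching against the compound reference and
pathway over-representation.  Each step writes tabular outputs into the
run directory and contributes a summary section to ``report.json``.  All
randomness flows from a single global seed via fixed per-step offsets,
so a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotation as ann
from . import chemometrics as chem
from . import differential as diff
from . import diversity as div
from .feature_io import FeatureMatrix, pool_units, read_feature_table, to_incidence
from .stat_tests import anova_oneway

logger = logging.getLogger(__name__)

# per-step seed offsets derived from the single global seed
_STEP_SEED = {"diversity": 11, "chemometrics": 23, "differential": 37, "annotation": 53}


@dataclass
class PipelineConfig:
    """Everything one run needs; serialized verbatim into the report."""

    features: str | None = None          # feature table path (CSV/TSV/XLSX)
    meta: str | None = None              # sample metadata CSV
    mode: str = "ESI+"
    transform: str = "none"              # chemometrics normalization
    scaling: str = "autoscale"
    n_components: int | str = "elbow"
    pool_by: tuple[str, ...] = ("concentration", "time")
    sac_permutations: int = 100
    bootstrap_B: int = 100
    comparisons: list[tuple[str, str]] | None = None
    fc_threshold: float = 2.0
    p_threshold: float | None = 0.05
    min_frequency: int = 2
    tol_ppm: float = 5.0
    adducts: tuple[str, ...] | None = None   # default: polarity of `mode`
    compounds: str | None = None             # reference TSV (None = bundled)
    pathways: str | None = None              # GMT (None = bundled)
    n_perm: int = 200                        # enrichment permutations
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if cfg.comparisons is not None:
            cfg.comparisons = [tuple(c) for c in cfg.comparisons]
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pool_by"] = list(self.pool_by)
        if self.adducts is not None:
            d["adducts"] = list(self.adducts)
        if self.comparisons is not None:
            d["comparisons"] = [list(c) for c in self.comparisons]
        return d


class StepError(RuntimeError):
    def __init__(self, step: str, cause: Exception):
        super().__init__(f"pipeline step {step!r} failed: {cause}")
        self.step = step
        self.cause = cause


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    fm: FeatureMatrix | None = None,
) -> dict:
    """Run the four steps in order, writing tables + report.json.

    ``fm`` may be passed directly (e.g. a simulated matrix); otherwise
    the configured input files are read.  A step failure aborts the run
    with a :class:`StepError` after writing the partial report, leaving
    earlier steps' outputs intact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "steps": {},
    }

    def _fail(step: str, exc: Exception):
        report["failed_step"] = step
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise StepError(step, exc) from exc

    # ---- input ------------------------------------------------------------
    try:
        if fm is None:
            if config.features is None or config.meta is None:
                raise ValueError("no feature matrix given and no input paths configured")
            fm = read_feature_table(config.features, config.meta, mode=config.mode)
        report["n_samples"] = fm.n_samples
        report["n_features"] = fm.n_features
    except StepError:
        raise
    except Exception as exc:  # noqa: BLE001 - report then abort
        _fail("input", exc)

    # ---- step i: diversity ------------------------------------------------
    try:
        seed = config.seed + _STEP_SEED["diversity"]
        idx = div.sample_indices(fm)
        idx.to_csv(out / "diversity_indices.csv")
        im = to_incidence(fm)
        pooled = pool_units(im, by=config.pool_by)
        sac = div.species_accumulation(pooled, n_perm=config.sac_permutations, seed=seed)
        div.sac_table(sac).to_csv(out / "sac.csv", index=False)
        pooled_richness = pooled.unit_richness.sort_values(ascending=False)
        pooled_richness.rename("richness").to_csv(out / "pooled_richness.csv")
        h_by_conc = {
            str(c): idx.loc[idx["concentration"] == c, "H"].values
            for c in idx["concentration"].unique()
        }
        an = anova_oneway(h_by_conc)
        report["steps"]["diversity"] = {
            "total_richness": int(sac.mean_richness[-1]),
            "estimators": {k: float(v) for k, v in sac.estimators.items()},
            "max_pooled_unit": str(pooled_richness.index[0]),
            "max_pooled_richness": int(pooled_richness.iloc[0]),
            "anova_H_by_concentration": {"F": an.F, "p": an.p},
        }
    except Exception as exc:  # noqa: BLE001
        _fail("diversity", exc)

    # ---- step ii: chemometrics -------------------------------------------
    try:
        spec = chem.NormalizationSpec(transform=config.transform, scaling=config.scaling)
        fm_norm = chem.normalize(fm, spec)
        pc = chem.pca(fm_norm, n_components=config.n_components)
        pc.scores.to_csv(out / "pca_scores.csv")
        pc.loadings.to_csv(out / "pca_loadings.csv")
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(pc.var_explained.size)],
             "var_explained_pct": pc.var_explained}
        ).to_csv(out / "pca_variance.csv", index=False)
        clust = chem.hierarchical_cluster(fm_norm.abundance)
        (out / "sample_dendrogram_order.json").write_text(json.dumps(clust.leaf_order))
        report["steps"]["chemometrics"] = {
            "normalization": {"transform": spec.transform, "scaling": spec.scaling},
            "n_components": pc.n_components,
            "pc1_var_pct": float(pc.var_explained[0]),
            "pc2_var_pct": float(pc.var_explained[1]) if pc.var_explained.size > 1 else None,
        }
    except Exception as exc:  # noqa: BLE001
        _fail("chemometrics", exc)

    # ---- step iii: differential screening --------------------------------
    try:
        sets = diff.run_comparisons(
            fm,
            comparisons=config.comparisons,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
        )
        for s in sets:
            name = f"{s.comparison[0]}_vs_{s.comparison[1]}"
            s.table.to_csv(out / f"volcano_{name}.csv")
        freq, hist = diff.comparison_frequency(sets)
        hist.rename("n_features").to_csv(out / "frequency_histogram.csv")
        dmes = diff.consolidate_dmes(sets, min_frequency=config.min_frequency)
        dmes_all = diff.consolidate_dmes(sets, mode="dedup_all")
        dmes.table.to_csv(out / "dmes.csv")
        dmes_all.table.to_csv(out / "dmes_dedup_all.csv")
        report["steps"]["differential"] = {
            "comparisons": {
                f"{s.comparison[0]}_vs_{s.comparison[1]}": s.n_differential for s in sets
            },
            "total_differential": int(sum(s.n_differential for s in sets)),
            "n_consolidated": len(dmes),
            "n_dedup_all": len(dmes_all),
        }
    except Exception as exc:  # noqa: BLE001
        _fail("differential", exc)

    # ---- step iv: annotation + enrichment --------------------------------
    try:
        seed = config.seed + _STEP_SEED["annotation"]
        reference = ann.load_compounds(config.compounds)
        pathways = ann.load_pathways(config.pathways)
        adducts = config.adducts
        if adducts is None:
            adducts = ann.POSITIVE_ADDUCTS if config.mode == "ESI+" else ann.NEGATIVE_ADDUCTS
        candidates, unmatched = ann.match_features(
            dmes.features, reference, adducts=adducts, tol_ppm=config.tol_ppm
        )
        candidates.to_csv(out / "tme_annotations.csv", index=False)
        universe = {c.kegg_id for c in reference}
        hit_ids = set(candidates["kegg_id"]) if len(candidates) else set()
        enrich_results: list = []
        if hit_ids:
            from .feature_io import parse_feature_id

            all_mzs = {lbl: parse_feature_id(lbl).mz for lbl in fm.feature_labels}
            enrich_results = ann.pathway_enrichment(
                hit_ids,
                pathways,
                universe,
                feature_mzs=all_mzs,
                n_features_sig=len(dmes),
                reference=reference,
                adducts=adducts,
                tol_ppm=config.tol_ppm,
                n_perm=config.n_perm,
                seed=seed,
            )
            ann.enrichment_table(enrich_results).to_csv(out / "enrichment.csv", index=False)
            ann.build_report(candidates, pathways).to_csv(
                out / "pathway_tme_map.csv", index=False
            )
        report["steps"]["annotation"] = {
            "n_dmes": len(dmes),
            "n_annotated_features": int(candidates["feature"].nunique()) if len(candidates) else 0,
            "n_unmatched": len(unmatched),
            "n_kegg_ids": len(hit_ids),
            "top_pathway": enrich_results[0].pathway_id if enrich_results else None,
        }
    except Exception as exc:  # noqa: BLE001
        _fail("annotation", exc)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
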