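"""End-to-end pipeline: simulate -> correct -> featurize -> ESOM -> associate.

A single :class:`PipelineConfig` drives every stage; with fixed seeds the
whole run is bit-reproducible, and every stage writes its artifacts (CSV
tables, JSON models/metadata) under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from olfcluster import cluster_stats, io
from olfcluster.cohort import default_config, generate_cohort, scaled_config
from olfcluster.esom import Esom, export_heightmap
from olfcluster.mixture import MixtureFeaturizer
from olfcluster.preprocess import DEFAULT_TDI_CUTOFFS, AgeSexCorrector, diagnose_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run.

    Defaults follow the reference analysis: m = 3 Gaussians per subtest,
    a 50 x 80 toroidal grid and 30 training epochs.
    """

    seed: int = 0
    n_subjects: int = 10_714
    cohort_path: str | None = None  # None -> simulate
    out_dir: str = "olfcluster_run"

    m_gaussians: int = 3
    pde_quantile: float = 0.18
    rows: int = 50
    cols: int = 80
    epochs: int = 30
    threshold_quantile: float = 0.5
    min_basin_units: int = 5
    tdi_cutoffs: tuple[float, float] = DEFAULT_TDI_CUTOFFS
    sign_convention: str = "exp_minus_obs"
    exclude_etiologies: tuple[str, ...] = ()
    export_png: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tdi_cutoffs" in raw:
            raw["tdi_cutoffs"] = tuple(raw["tdi_cutoffs"])
        if "exclude_etiologies" in raw:
            raw["exclude_etiologies"] = tuple(raw["exclude_etiologies"])
        return cls(**raw)


@dataclass
class RunReport:
    """Summary of one pipeline run: parameters, seeds, counts, clusters."""

    config: dict
    n_subjects: int
    k_clusters: int
    cluster_sizes: dict[int, int]
    cluster_medians: dict[int, dict[str, float]]
    chi2: float
    df: int
    p: float
    diagnosis_counts: dict[str, int]
    ari_vs_planted: float | None = None
    quantization_errors: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write all artifacts.

    Stage order: cohort (simulate or load) -> sex-specific age correction ->
    mixture featurization -> ESOM training and U/P/U* landscapes ->
    watershed clustering -> association statistics.  Identical config and
    seeds produce byte-identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- cohort -------------------------------------------------------------
    if config.cohort_path is None:
        cohort_cfg = (
            default_config(seed=config.seed)
            if config.n_subjects == 10_714
            else scaled_config(config.n_subjects, seed=config.seed)
        )
        records = generate_cohort(cohort_cfg)
        logger.info("simulated %d subjects (seed=%d)", len(records), config.seed)
        io.write_cohort(out / "cohort.csv", records)
        frame = io.records_to_frame(records)
    else:
        frame = io.read_cohort_frame(config.cohort_path)
        logger.info("loaded %d subjects from %s", len(frame), config.cohort_path)

    # -- preprocess -----------------------------------------------------------
    corrector = AgeSexCorrector()
    corrected = corrector.fit(frame).transform(frame)
    corrected = diagnose_frame(corrected, cutoffs=config.tdi_cutoffs)
    corrected.to_csv(out / "cohort_corrected.csv", index=False, lineterminator="\n")
    with open(out / "correction_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "slopes": {f"{s}:{c}": v for (s, c), v in corrector.slopes_.items()},
                "intercepts": {f"{s}:{c}": v for (s, c), v in corrector.intercepts_.items()},
                "grand_means": corrector.grand_means_,
                "tdi_cutoffs": list(config.tdi_cutoffs),
            },
            fh,
            indent=2,
        )

    # -- mixture featurization ------------------------------------------------
    logger.info("fitting m=%d Gaussian mixtures per subtest", config.m_gaussians)
    featurizer = MixtureFeaturizer(
        m=config.m_gaussians,
        pde_quantile=config.pde_quantile,
        random_state=config.seed,
    )
    features = featurizer.fit(corrected).transform(corrected)
    featurizer.save_models(out / "models.json")
    features.to_csv(out / "features.csv", index=False, lineterminator="\n")

    # -- ESOM -----------------------------------------------------------------
    logger.info(
        "training %dx%d toroidal ESOM, %d epochs (seed=%d)",
        config.rows,
        config.cols,
        config.epochs,
        config.seed,
    )
    som = Esom(
        rows=config.rows,
        cols=config.cols,
        epochs=config.epochs,
        random_state=config.seed,
    )
    X = features.to_numpy()
    som.fit(X)
    U, P, Ustar = som.landscape(X, q=config.pde_quantile)
    bmus = som.bmus(X)
    for name, mat in (("umatrix", U), ("pmatrix", P), ("ustar", Ustar)):
        np.savetxt(out / f"{name}.csv", mat, delimiter=",")
        if config.export_png:
            export_heightmap(mat, out / f"{name}.png")
    with open(out / "esom_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "rows": config.rows,
                "cols": config.cols,
                "epochs": config.epochs,
                "seed": config.seed,
                "pareto_radius": som.pareto_radius_,
                "quantization_errors": som.quantization_errors_,
                "orientation": "row 0 = top",
            },
            fh,
            indent=2,
        )

    # -- clustering + association --------------------------------------------
    assignment = cluster_stats.cluster_landscape(
        Ustar,
        bmus,
        som.weights_,
        threshold_quantile=config.threshold_quantile,
        min_basin_units=config.min_basin_units,
    )
    analysis = corrected.loc[features.index].copy()
    analysis["cluster"] = assignment.subject_labels
    analysis[["subject_id", "cluster"]].to_csv(out / "clusters.csv", index=False, lineterminator="\n")

    assoc = cluster_stats.associate(
        analysis,
        assignment.subject_labels,
        exclude=list(config.exclude_etiologies) or None,
        sign_convention=config.sign_convention,
    )
    table = cluster_stats.contingency(
        analysis, assignment.subject_labels, exclude=list(config.exclude_etiologies) or None
    )
    table.observed.to_csv(out / "contingency.csv", lineterminator="\n")
    assoc.reldiff.to_csv(out / "reldiff.csv", lineterminator="\n")
    with open(out / "association.json", "w", encoding="utf-8") as fh:
        json.dump({"chi2": assoc.chi2, "df": assoc.df, "p": assoc.p, "p_text": assoc.p_text()}, fh, indent=2)

    correlations = cluster_stats.spearman_by_group(analysis, grouping="cluster")
    correlations = pd.concat(
        [correlations, cluster_stats.spearman_by_group(analysis, grouping="etiology").iloc[3:]],
        ignore_index=True,
    )
    correlations.to_csv(out / "correlations.csv", index=False, lineterminator="\n")

    # -- report ---------------------------------------------------------------
    medians = {
        int(cid): {
            "thr": float(sub["thr"].median()),
            "disc": float(sub["disc"].median()),
            "ident": float(sub["ident"].median()),
        }
        for cid, sub in analysis.groupby("cluster")
    }
    ari = None
    if "latent_profile" in analysis.columns:
        from sklearn.metrics import adjusted_rand_score

        ari = float(adjusted_rand_score(analysis["latent_profile"], analysis["cluster"]))

    report = RunReport(
        config=dataclasses.asdict(config),
        n_subjects=len(analysis),
        k_clusters=assignment.k,
        cluster_sizes={int(c): int(s) for c, s in assignment.sizes.items()},
        cluster_medians=medians,
        chi2=assoc.chi2,
        df=assoc.df,
        p=assoc.p,
        diagnosis_counts=analysis["diagnosis"].value_counts().to_dict(),
        ari_vs_planted=ari,
        quantization_errors=[float(q) for q in som.quantization_errors_],
    )
    report.to_json(out / "report.json")
    logger.info(
        "pipeline done: k=%d clusters, chi2=%.1f (df=%d, p %s)",
        report.k_clusters,
        report.chi2,
        report.df,
        assoc.p_text(),
    )
    return report
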