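"""End-to-end analysis pipeline with config, logging and report bundle.

Stages: synthesize (or ingest) call data -> spectrogram features ->
correlation pruning -> per-bird subsampling -> PERMANOVA (single factors
and the sequential sex + age + variant + sex:variant design with birds as
the exchangeable units) -> unsupervised random-forest similarity ->
within/between-individual t-test -> PCoA / NMDS with group ellipses ->
similarity heatmap.  Every statistic in the summary carries its metric,
permutation count and seed so the bundle is self-describing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    batch_features,
    feature_columns,
    load_feature_table,
    prune_correlated,
    subsample_calls,
)
from .ordination import nmds, pcoa, plot_ordination, plot_similarity_heatmap
from .permanova import Permanova, distance_matrix, permanova_single
from .similarity import ProximityForest, similarity_to_distance, SimilarityMatrix
from .synth import PopulationConfig, generate_clips

__all__ = ["run_pipeline", "PipelineError", "DEFAULT_CONFIG"]

log = logging.getLogger("redstartcalls")

DEFAULT_CONFIG: dict = {
    "simulate": {},  # PopulationConfig overrides; omit and set input.features_csv
    #                  to skip the audio stages entirely
    "input": {},  # {"features_csv": path, "column_map": {...}}
    "features": {"prune_threshold": 0.95, "n_per_bird": 5, "min_calls": 5},
    "stats": {
        "metric": "euclidean",
        "standardize": "zscore",
        "n_perm": 999,
        "n_trees": 4999,
        "factors": ["sex", "age", "variant"],
        "interactions": [["sex", "variant"]],
        "nest": "bird_id",
    },
    "report": {"plots": True, "nmds_restarts": 20, "ordination": True},
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and completed artifacts."""

    def __init__(self, stage: str, artifacts: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.artifacts = artifacts


def _merge(base: dict, override: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None, out_dir=None, seed: int | None = None):
    """Run the full analysis; return the summary bundle as a dict.

    If ``out_dir`` is given, CSV artifacts, plots and ``summary.json`` are
    written there.  ``seed`` overrides both the generator seed and the
    statistical seeds for a fully reproducible run.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is None:
        seed = cfg.get("simulate", {}).get("seed", 0)
    rng_seeds = np.random.SeedSequence(seed).spawn(5)
    stat_seed = int(rng_seeds[1].generate_state(1)[0] % (2**31 - 1))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    summary: dict = {"version": __version__, "seed": int(seed)}

    def _save_df(df: pd.DataFrame, name: str):
        if out is not None:
            path = out / name
            df.to_csv(path, index=False)
            artifacts[name] = str(path)

    stage = "generate"
    try:
        if cfg["input"].get("features_csv"):
            log.info("stage ingest: loading features from %s",
                     cfg["input"]["features_csv"])
            table = load_feature_table(
                cfg["input"]["features_csv"], cfg["input"].get("column_map")
            )
            manifest = None
        else:
            sim_kwargs = dict(cfg["simulate"])
            sim_kwargs["seed"] = seed
            pop = PopulationConfig(**sim_kwargs)
            log.info("stage generate: %d birds, seed %d", pop.n_birds, seed)
            clips, manifest = generate_clips(pop)
            _save_df(manifest, "manifest.csv")
            stage = "features"
            log.info("stage features: %d clips", len(clips))
            table, errors = batch_features(clips)
            if errors:
                log.warning("feature extraction failures: %s", errors)
            summary["feature_errors"] = len(errors)
        summary["n_calls_raw"] = int(len(table))
        summary["n_features"] = len(feature_columns(table))
        _save_df(table, "features.csv")

        stage = "prune"
        pruned, report = prune_correlated(
            table, threshold=cfg["features"]["prune_threshold"]
        )
        log.info("stage prune: %d -> %d features",
                 summary["n_features"], len(feature_columns(pruned)))
        summary["n_features_pruned"] = len(feature_columns(pruned))
        summary["prune_threshold"] = cfg["features"]["prune_threshold"]
        _save_df(report, "prune_report.csv")
        _save_df(pruned, "features_pruned.csv")

        stage = "subsample"
        analysis = subsample_calls(
            pruned,
            n_per_bird=cfg["features"]["n_per_bird"],
            min_calls=cfg["features"]["min_calls"],
            seed=stat_seed,
        )
        summary["n_calls"] = int(len(analysis))
        summary["n_birds"] = int(analysis["bird_id"].nunique())
        _save_df(analysis, "features_analysis.csv")
        if manifest is not None:
            kept = manifest[manifest["file"].isin(analysis["file"])]
            summary["mean_duration_ms"] = float(kept["realized_duration_ms"].mean())
            by_sex = kept.groupby("sex")["realized_duration_ms"].mean()
            summary["mean_duration_male_ms"] = float(by_sex.get("M", np.nan))
            summary["mean_duration_female_ms"] = float(by_sex.get("F", np.nan))

        stage = "permanova"
        st = cfg["stats"]
        dist = distance_matrix(analysis, metric=st["metric"],
                               standardize=st["standardize"])
        summary["permanova"] = {
            "metric": st["metric"],
            "standardize": st["standardize"],
            "n_perm": st["n_perm"],
            "seed": stat_seed,
            "single": {},
        }
        for factor in st["factors"]:
            labels = analysis[factor]
            if labels.value_counts().min() < 2 or labels.nunique() < 2:
                log.warning(
                    "factor %s has a level with < 2 calls; single-factor "
                    "test skipped", factor,
                )
                continue
            res = permanova_single(dist, labels.to_numpy(), n_perm=st["n_perm"],
                                   seed=stat_seed)
            row = res.table.iloc[0]
            summary["permanova"]["single"][factor] = {
                "df": int(row["df"]),
                "SumOfSqs": float(row["SumOfSqs"]),
                "F": float(row["F"]),
                "R2": float(row["R2"]),
                "p": float(row["p"]),
            }
            log.info("pMANOVA %s: F=%.3f R2=%.4f p=%.4f",
                     factor, row["F"], row["R2"], row["p"])
        model = Permanova.from_dataframe(
            analysis,
            factors=st["factors"],
            interactions=[tuple(t) for t in st["interactions"]],
            nest=st.get("nest"),
            metric=st["metric"],
            standardize=st["standardize"],
        )
        try:
            terms_res = model.fit(n_perm=st["n_perm"], seed=stat_seed)
        except ValueError as exc:
            # aliasing can occur in small subsets (e.g. a variant produced by
            # one sex only); retry without interaction terms
            log.warning("sequential design failed (%s); dropping interactions", exc)
            model = Permanova.from_dataframe(
                analysis, factors=st["factors"], interactions=[],
                nest=st.get("nest"), metric=st["metric"],
                standardize=st["standardize"],
            )
            terms_res = model.fit(n_perm=st["n_perm"], seed=stat_seed)
        summary["permanova"]["terms"] = {
            str(term): {
                "df": int(r["df"]),
                "SumOfSqs": float(r["SumOfSqs"]),
                "F": float(r["F"]) if np.isfinite(r["F"]) else None,
                "R2": float(r["R2"]),
                "p": float(r["p"]) if np.isfinite(r["p"]) else None,
            }
            for term, r in terms_res.table.iterrows()
        }
        summary["permanova"]["schemes"] = terms_res.schemes

        stage = "similarity"
        prox = ProximityForest(analysis, n_trees=st["n_trees"]).fit(seed=stat_seed)
        wb = prox.within_between()
        summary["similarity"] = {
            "n_trees": st["n_trees"],
            "seed": stat_seed,
            "within_mean": float(wb.within_means.mean()),
            "between_mean": float(wb.between_means.mean()),
            "t_welch": wb.t_statistic,
            "df_welch": wb.df,
            "p_welch": wb.p_value,
            "t_pooled": wb.t_pooled,
            "df_pooled": wb.df_pooled,
            "p_pooled": wb.p_pooled,
            "within_pairs_per_bird": wb.pair_counts[
                next(iter(wb.pair_counts))
            ]["within_pairs"],
            "between_entries_per_bird": wb.pair_counts[
                next(iter(wb.pair_counts))
            ]["between_entries"],
        }
        log.info("within/between: t=%.2f p=%.3g", wb.t_statistic, wb.p_value)
        if out is not None:
            prox.matrix.to_frame().to_csv(out / "similarity.csv")
            artifacts["similarity.csv"] = str(out / "similarity.csv")

        stage = "ordination"
        if not cfg["report"].get("ordination", True):
            summary["artifacts"] = artifacts
            if out is not None:
                with open(out / "summary.json", "w") as fh:
                    json.dump(summary, fh, indent=2, default=str)
            return summary
        from .permanova import DistanceMatrix

        rf_dist = DistanceMatrix(
            similarity_to_distance(prox.matrix),
            labels=prox.matrix.call_ids,
            metric="1 - rf proximity",
        )
        pc_feat = pcoa(dist, k=2)
        pc_rf = pcoa(rf_dist, k=2)
        nm = nmds(rf_dist, k=2, restarts=cfg["report"]["nmds_restarts"],
                  seed=stat_seed)
        ev = pc_feat.eigenvalues
        pos = ev[ev > 0]
        summary["ordination"] = {
            "pcoa_feature_var2_pct": float(100 * ev[:2].sum() / pos.sum()),
            "pcoa_rf_var2_pct": float(
                100 * pc_rf.eigenvalues[:2].sum()
                / pc_rf.eigenvalues[pc_rf.eigenvalues > 0].sum()
            ),
            "nmds_stress": nm.stress,
            "nmds_restarts": cfg["report"]["nmds_restarts"],
            "seed": stat_seed,
        }
        if out is not None and cfg["report"].get("plots", True):
            plot_ordination(pc_feat, analysis["sex"], out / "pcoa_sex.png",
                            title="PCoA by sex")
            plot_ordination(pc_feat, analysis["variant"], out / "pcoa_variant.png",
                            title="PCoA by variant")
            plot_ordination(nm, analysis["bird_id"], out / "nmds_birds.png")
            plot_similarity_heatmap(prox.matrix, out / "similarity_heatmap.png")
            artifacts.update(
                {p: str(out / p) for p in
                 ("pcoa_sex.png", "pcoa_variant.png", "nmds_birds.png",
                  "similarity_heatmap.png")}
            )
    except Exception as exc:
        raise PipelineError(stage, artifacts, exc) from exc

    summary["artifacts"] = artifacts
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
    return summary
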