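"""End-to-end orchestration: cohort → PCA → selectors → consensus → RF → ROC.

By default the three selectors run once per measurement panel (platforms
are analyzed separately to avoid platform-specific biases) and the
per-method results are unioned before the consensus vote; ``pooled=True``
runs each selector once on the combined matrix. Random forest and ROC
always see the full matrix. Every stochastic stage receives a seed
derived deterministically from the global seed, and the manifest written
with the outputs suffices to reproduce every table bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import cluster_selected, consensus_select, to_newick
from .data_io import read_dataset, write_dataset
from .dataset import PANELS, MetabolomicsDataset
from .decomposition import pca, standardize
from .random_forest import RfConfig, fit_forest, oob_error, permutation_importance, top_importance
from .roc import roc_table
from .splsda import fit_splsda, selected_features
from .synthetic_data import CohortConfig, MetaboliteSpec, generate_cohort
from .wrapper_selection import GaParams, genetic_search, greedy_stepwise

logger = logging.getLogger("metabconsensus")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Full pipeline configuration; see ``PipelineConfig.from_yaml``."""

    cohort: CohortConfig | None = None
    values_path: str | None = None
    meta_path: str | None = None
    pca_components: int = 3
    splsda_h: int = 3
    splsda_keep: tuple[int, ...] = (10, 10, 10)
    greedy_direction: str = "forward"
    ga: GaParams = field(default_factory=GaParams)
    consensus_rule: str = "strict"
    consensus_k: int = 2
    rf: RfConfig = field(default_factory=RfConfig)
    pooled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.values_path is not None and self.meta_path is not None
        if (self.cohort is None) == (not from_files):
            raise ValueError(
                "configure exactly one input source: a synthetic cohort or "
                "a values/meta file pair"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "metabolites" in c:
                c["metabolites"] = tuple(
                    MetaboliteSpec(**m) for m in c["metabolites"]
                )
            kwargs["cohort"] = CohortConfig(**c)
        for key in ("values_path", "meta_path", "pca_components", "splsda_h",
                    "greedy_direction", "consensus_rule", "consensus_k",
                    "pooled", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "splsda_keep" in raw:
            kwargs["splsda_keep"] = tuple(raw["splsda_keep"])
        if "ga" in raw:
            kwargs["ga"] = GaParams(**raw["ga"])
        if "rf" in raw:
            kwargs["rf"] = RfConfig(**raw["rf"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            "values_path": self.values_path,
            "meta_path": self.meta_path,
            "pca_components": self.pca_components,
            "splsda_h": self.splsda_h,
            "splsda_keep": list(self.splsda_keep),
            "greedy_direction": self.greedy_direction,
            "ga": asdict(self.ga),
            "consensus_rule": self.consensus_rule,
            "consensus_k": self.consensus_k,
            "rf": {**asdict(self.rf)},
            "pooled": self.pooled,
            "seed": self.seed,
        }
        if self.cohort is not None:
            out["cohort"] = {
                "n_cases": self.cohort.n_cases,
                "n_controls": self.cohort.n_controls,
                "distribution": self.cohort.distribution,
                "seed": self.cohort.seed,
                "metabolites": [asdict(m) for m in self.cohort.metabolites],
            }
        return out


@dataclass
class ReportBundle:
    dataset: MetabolomicsDataset
    pca_scores: pd.DataFrame
    splsda_selected: pd.DataFrame
    greedy_set: list[str]
    genetic_set: list[str]
    consensus_table: pd.DataFrame
    dendrogram: str | None
    importance: pd.DataFrame
    importance_top25: pd.DataFrame
    roc: pd.DataFrame
    oob: tuple[float, float]
    manifest: dict


def _stage_seed(root: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=root, spawn_key=(index,))
               .generate_state(1)[0] % 2**31)


def _hash_values(ds: MetabolomicsDataset) -> str:
    return hashlib.sha256(
        np.nan_to_num(ds.values, nan=-1.0).tobytes()
    ).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> ReportBundle:
    """Execute every stage in order; any failure aborts with the stage name.

    When ``out_dir`` is given all tables are written there as TSV, the
    dendrogram as Newick and the manifest as JSON; a partial manifest is
    written on failure.
    """
    manifest: dict = {
        "package": "metabconsensus",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def log_stage(name: str, started: float, **info) -> None:
        entry = {"stage": name, **info}
        manifest["stages"].append(entry)
        logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - started, info)

    def fail(stage: str, exc: Exception) -> PipelineError:
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return PipelineError(stage, exc)

    # ---- load / simulate -------------------------------------------------
    t0 = time.time()
    try:
        if config.cohort is not None:
            ds = generate_cohort(config.cohort)
            source = "synthetic"
        else:
            ds = read_dataset(config.values_path, config.meta_path)
            source = "files"
    except Exception as exc:
        raise fail("input", exc) from exc
    input_hash = _hash_values(ds)
    log_stage("input", t0, source=source, n_samples=ds.n_samples,
              n_metabolites=ds.n_metabolites, values_sha256=input_hash)

    # ---- PCA -------------------------------------------------------------
    t0 = time.time()
    try:
        Z = standardize(ds.values, ds.metabolite_names)
        res = pca(Z, config.pca_components)
        pca_scores = pd.DataFrame(
            res.scores,
            columns=[f"PC{i + 1}" for i in range(res.k)],
        )
        pca_scores.insert(0, "sample_id", ds.sample_ids)
        pca_scores.insert(1, "group",
                          ["tumor" if v else "control" for v in ds.case_mask])
    except Exception as exc:
        raise fail("pca", exc) from exc
    log_stage("pca", t0, k=config.pca_components,
              explained=[float(v) for v in res.explained_variance])

    # ---- selectors (per panel by default) ---------------------------------
    def blocks() -> list[MetabolomicsDataset]:
        if config.pooled:
            return [ds]
        present = [q for q in PANELS if (ds.panel == q).any()]
        return [ds.panel_subset(q) for q in present]

    t0 = time.time()
    try:
        splsda_tables = []
        greedy_names: list[str] = []
        ga_names: list[str] = []
        for i, block in enumerate(blocks()):
            keep = tuple(min(k, block.n_metabolites) for k in config.splsda_keep)
            model = fit_splsda(block, H=config.splsda_h, keep=keep)
            splsda_tables.append(selected_features(model))
            greedy_names += list(greedy_stepwise(block, config.greedy_direction).names)
            ga = GaParams(
                population_size=config.ga.population_size,
                generations=config.ga.generations,
                p_crossover=config.ga.p_crossover,
                p_mutation=config.ga.p_mutation,
                report_frequency=config.ga.report_frequency,
                seed=_stage_seed(config.seed, 10 + i),
            )
            ga_names += list(genetic_search(block, ga).names)
        splsda_selected = pd.concat(splsda_tables, ignore_index=True)
    except Exception as exc:
        raise fail("selectors", exc) from exc
    log_stage("selectors", t0, pooled=config.pooled,
              splsda=len(splsda_selected), greedy=len(greedy_names),
              genetic=len(ga_names))

    # ---- consensus ---------------------------------------------------------
    t0 = time.time()
    try:
        attribution = dict(
            zip(splsda_selected["metabolite"], splsda_selected["components"])
        )
        table = consensus_select(
            {
                "splsda": list(splsda_selected["metabolite"]),
                "greedy": greedy_names,
                "genetic": ga_names,
            },
            rule=config.consensus_rule,
            k=config.consensus_k,
            attribution=attribution,
            universe=ds.metabolite_names,
        )
        dendrogram = None
        if len(table) >= 2:
            linkage, leaf_names = cluster_selected(ds, table)
            dendrogram = to_newick(linkage, leaf_names)
    except Exception as exc:
        raise fail("consensus", exc) from exc
    log_stage("consensus", t0, rule=config.consensus_rule, size=len(table))

    # ---- random forest ------------------------------------------------------
    t0 = time.time()
    try:
        rf_config = RfConfig(
            n_trees=config.rf.n_trees,
            mtry=config.rf.mtry,
            seed=_stage_seed(config.seed, 20),
            min_node_size=config.rf.min_node_size,
        )
        forest = fit_forest(ds, rf_config)
        oob = oob_error(forest)
        importance = permutation_importance(forest, ds)
        top25 = top_importance(importance, 25)
    except Exception as exc:
        raise fail("random_forest", exc) from exc
    log_stage("random_forest", t0, n_trees=rf_config.n_trees, mtry=forest.mtry,
              oob_aggregate=oob[0], oob_mean_tree=oob[1])

    # ---- ROC -----------------------------------------------------------------
    t0 = time.time()
    try:
        roc_df = roc_table(ds)
    except Exception as exc:
        raise fail("roc", exc) from exc
    log_stage("roc", t0, rows=len(roc_df))

    if _hash_values(ds) != input_hash:
        raise fail("integrity", RuntimeError("a stage mutated the input dataset"))

    bundle = ReportBundle(
        dataset=ds,
        pca_scores=pca_scores,
        splsda_selected=splsda_selected,
        greedy_set=greedy_names,
        genetic_set=ga_names,
        consensus_table=table,
        dendrogram=dendrogram,
        importance=importance,
        importance_top25=top25,
        roc=roc_df,
        oob=oob,
        manifest=manifest,
    )
    if out is not None:
        _write_bundle(bundle, out, ds)
    return bundle


def _write_bundle(bundle: ReportBundle, out: Path, ds: MetabolomicsDataset) -> None:
    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")

    write_dataset(ds, str(out / "dataset"))
    tsv(bundle.pca_scores, "pca_scores.tsv")
    tsv(bundle.splsda_selected, "selected_splsda.tsv")
    (out / "selected_greedy.txt").write_text(
        "\n".join(bundle.greedy_set) + "\n" if bundle.greedy_set else ""
    )
    (out / "selected_genetic.txt").write_text(
        "\n".join(bundle.genetic_set) + "\n" if bundle.genetic_set else ""
    )
    tsv(bundle.consensus_table, "consensus.tsv")
    if bundle.dendrogram is not None:
        (out / "dendrogram.nwk").write_text(bundle.dendrogram + "\n")
    tsv(bundle.importance, "importance.tsv")
    tsv(bundle.importance_top25, "importance_top25.tsv")
    tsv(bundle.roc, "roc_table.tsv")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
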