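"""File formats, configuration, and the pipeline driver.

Cell tables travel as CSV (one row per segmented cell: identifiers,
centroid coordinates in um, one column per raw marker count); gene sets as
GMT; configuration as a single YAML/JSON document that is validated before
any stage runs; every run writes a manifest recording parameters, seeds and
SHA-256 hashes of its outputs so results are reproducible bit-identically
from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import outcomes, signatures, spatial
from .panel import FINAL_LABELS, MARKERS
from .phenotype import PhenotypingConfig, run_phenotyping
from .simulate import NicheParams, SimulationConfig, generate_bulk, \
    generate_cohort, generate_st

log = logging.getLogger("sgctme")

REQUIRED_CELL_COLUMNS = ("cell_id", "patient_id", "roi_id", "x_um", "y_um")


def read_cell_table(path) -> pd.DataFrame:
    """Read a segmented single-cell CSV and validate its schema."""
    cells = pd.read_csv(path)
    for col in REQUIRED_CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"missing column {col}")
    markers = [m for m in MARKERS if m in cells.columns]
    if not markers:
        raise ValueError("no panel marker columns found")
    for m in markers:
        if (cells[m] < 0).any():
            raise ValueError(f"negative counts in marker column {m}")
    return cells


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_gmt(path) -> dict:
    """Read gene sets from GMT (name, description, genes; tab-separated).

    Duplicate genes within a set are stored once (first occurrence).
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno} "
                    f"(need name, description, >= 1 gene)")
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass
class SpatialConfig:
    k: int = 20
    n_neighborhoods: int = 9
    min_patch_size: int = 10
    n_perm: int = 1000
    alpha: float = 0.01

    def __post_init__(self):
        if self.k <= 0 or self.n_neighborhoods <= 0 or self.n_perm <= 0:
            raise ValueError("spatial parameters must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclasses.dataclass
class SignatureConfig:
    q_sel: float = 0.2
    q_spot: float = 0.2
    n_bins: int = 24
    n_ctrl: int = 100
    log_transform_bulk: bool = False


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    seed: int = 0
    out_dir: str = "sgctme_out"
    simulate: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    phenotype: PhenotypingConfig = dataclasses.field(
        default_factory=PhenotypingConfig)
    spatial: SpatialConfig = dataclasses.field(default_factory=SpatialConfig)
    signatures: SignatureConfig = dataclasses.field(
        default_factory=SignatureConfig)
    five_year_months: float = 60.0


def _build_section(cls, data: dict, path: str):
    allowed = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config keys under {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = allowed[key].type
        if isinstance(value, dict) and ftype in (
                "SimulationConfig", "PhenotypingConfig", "SpatialConfig",
                "SignatureConfig", "NicheParams"):
            sub = {"SimulationConfig": SimulationConfig,
                   "PhenotypingConfig": PhenotypingConfig,
                   "SpatialConfig": SpatialConfig,
                   "SignatureConfig": SignatureConfig,
                   "NicheParams": NicheParams}[ftype]
            kwargs[key] = _build_section(sub, value, f"{path}.{key}")
        else:
            if key == "niche_params" and isinstance(value, dict):
                value = _build_section(NicheParams, value,
                                       f"{path}.{key}")
            if key in ("som_grid",) and isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config; unknown keys reject."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return _build_section(PipelineConfig, data, "config")


# ---------------------------------------------------------------------------
# pipeline driver


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_spatial_stage(labeled: pd.DataFrame, config: PipelineConfig,
                      out: Path) -> pd.DataFrame:
    """Per-ROI graphs, pooled CN assignment, patches, interactions."""
    profiles, itabs, extra_cols = [], [], []
    for _, roi_cells in labeled.groupby("roi_id", sort=True):
        graph = spatial.build_knn_graph(roi_cells, k=config.spatial.k)
        labels = roi_cells.set_index("cell_id")["label_final"]
        profiles.append(
            spatial.neighbor_fractions(graph, labels.loc[graph.cell_ids]))
        patches = spatial.detect_patches(graph, labels.loc[graph.cell_ids],
                                         config.spatial.min_patch_size)
        extra_cols.append(spatial.distance_to_border(
            roi_cells.set_index("cell_id"), patches,
            labels.loc[graph.cell_ids]))
        itabs.append(spatial.test_interactions(
            graph, labels.loc[graph.cell_ids], config.spatial.n_perm,
            config.spatial.alpha, seed=config.seed + 7))
    profiles = pd.concat(profiles)
    cn = spatial.assign_neighborhoods(
        profiles, config.spatial.n_neighborhoods, seed=config.seed + 3)
    labeled = labeled.set_index("cell_id")
    labeled["cn"] = cn.cn_of_cell
    dist_all = pd.concat(extra_cols)
    labeled["dist_to_tumor_border"] = dist_all["dist_to_tumor_border"]
    labeled["infiltrating"] = dist_all["infiltrating"]
    labeled = labeled.reset_index()
    labeled.to_csv(out / "cells_spatial.csv", index=False)
    pd.concat(itabs, ignore_index=True).to_csv(out / "interactions.csv",
                                               index=False)
    spatial.summarize_interactions(itabs).to_csv(
        out / "interaction_summary.csv", index=False)
    return labeled


def run_survival_stage(labeled: pd.DataFrame, clinical: pd.DataFrame,
                       config: PipelineConfig, out: Path) -> dict:
    """Per-patient frequencies, mCAF dichotomization, KM/log-rank/Cox."""
    freq = outcomes.per_patient_frequencies(labeled, vocabulary=FINAL_LABELS)
    freq.to_csv(out / "patient_frequencies.csv")
    surv = clinical.set_index("patient_id").loc[freq.index]
    groups = outcomes.dichotomize_median(freq["mCAF"])
    hi, lo = groups == "high", groups == "low"
    _, p_rfp = outcomes.logrank(
        surv.loc[hi, "time_rfp"], surv.loc[hi, "event_rfp"],
        surv.loc[lo, "time_rfp"], surv.loc[lo, "event_rfp"], sidedness="one")
    km_rows = {}
    for name, m in (("mCAF_high", hi), ("mCAF_low", lo)):
        _, at = outcomes.km_estimate(surv.loc[m, "time_rfp"],
                                     surv.loc[m, "event_rfp"],
                                     (config.five_year_months,))
        km_rows[name] = at[config.five_year_months]
    cox = outcomes.cox_fit(
        pd.DataFrame({"mcaf_high": (groups == "high").astype(int)},
                     index=groups.index),
        surv["time_rfp"], surv["event_rfp"])
    summary = {
        "logrank_one_sided_p_rfp": p_rfp,
        "five_year_rfp": km_rows,
        "cox": cox.table.reset_index().to_dict(orient="records"),
        "cox_excluded": cox.excluded,
    }
    (out / "outcome_summary.json").write_text(json.dumps(summary, indent=1,
                                                         default=str))
    return summary


def run_signature_stage(config: PipelineConfig, out: Path) -> dict:
    """Signature construction, bulk scoring, ST scoring and categories."""
    sim = config.simulate.replace(seed=config.seed)
    rng = np.random.default_rng(config.seed + 11)
    n_de = 490
    de_table = pd.DataFrame({
        "gene": [f"MCAFG{i:03d}" for i in range(n_de)],
        "log2FC": np.sort(rng.uniform(0.05, 4.0, n_de))[::-1],
    })
    sig = signatures.build_weighted_signature(de_table,
                                              config.signatures.q_sel)
    bulk, _ = generate_bulk(sim, n_samples=40, signature=sig,
                            effect=4.0, seed=config.seed + 13)
    scores = signatures.score_matrix(bulk, sig,
                                     config.signatures.log_transform_bulk)
    strata = signatures.stratify_by_signature(scores)
    pd.DataFrame({"score": scores, "group": strata}).to_csv(
        out / "bulk_scores.csv")

    st_expr, st_coords, _ = generate_st(
        sim, n_spots_per_sample=1500, seed=config.seed + 17, n_samples=3,
        mcaf_genes=tuple(sig.genes))
    ms_cfg = signatures.ModuleScoreConfig(config.signatures.n_bins,
                                          config.signatures.n_ctrl,
                                          seed=config.seed + 19)
    mcaf_ms = signatures.module_score(st_expr, sig.genes, ms_cfg)
    endo_ms = signatures.module_score(
        st_expr, ["PECAM1", "VWF", "CDH5", "KDR", "MCAM"], ms_cfg)
    cats = signatures.categorize_spots(mcaf_ms, endo_ms,
                                       st_coords["sample_id"],
                                       config.signatures.q_spot)
    r, p = signatures.score_correlation(mcaf_ms, endo_ms)
    st_out = st_coords.copy()
    st_out["mcaf_score"], st_out["endo_score"] = mcaf_ms, endo_ms
    st_out["category"] = cats
    st_out.to_csv(out / "st_spots.csv")
    signatures.rank_sum_de(
        st_expr, cats == "mCAF_high_endothelia_high").to_csv(out / "st_de.csv")
    return {"n_signature_genes": len(sig.genes), "st_pearson_r": r,
            "st_pearson_p": p,
            "category_counts": cats.value_counts().to_dict()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> phenotype -> spatial -> signatures -> outcomes.

    Returns the manifest (also written as JSON in the output directory).
    Each stage writes its tables as CSV; any stage error aborts with the
    stage name in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "outputs": {},
                "parameters": _config_dict(config)}

    log.info("[simulate] generating cohort")
    sim = config.simulate.replace(seed=config.seed)
    cells, clinical, truth = generate_cohort(sim)
    write_cell_table(cells, out / "cells.csv")
    clinical.to_csv(out / "clinical.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=1))

    log.info("[phenotype] %d cells", len(cells))
    labeled, audit = run_phenotyping(cells, config.phenotype,
                                     seed=config.seed + 1)
    labeled.to_csv(out / "cells_labeled.csv", index=False)
    (out / "phenotype_audit.json").write_text(json.dumps(audit, indent=1,
                                                         default=str))

    log.info("[spatial] graphs, neighborhoods, interactions")
    labeled = run_spatial_stage(labeled, config, out)

    log.info("[signatures] bulk + spatial transcriptomics")
    run_signature_stage(config, out)

    log.info("[outcomes] frequencies + survival")
    run_survival_stage(labeled, clinical, config, out)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_dict(config) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj
    return enc(config)
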