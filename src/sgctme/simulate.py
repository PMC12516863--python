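"""Seeded synthetic cohorts with planted ground truth.

Emulates the data a multiplexed imaging-mass-cytometry study of salivary
gland carcinoma produces after segmentation: per-ROI single-cell tables with
raw marker counts and spatial structure (tumor patches, vessel-tropic mCAFs,
lymphocyte aggregates), per-patient clinical tables whose recurrence hazard
is log-linear in the true mCAF fraction, TPM-like bulk expression matrices,
and spot-level spatial-transcriptomics samples with a tunable
mCAF–endothelia co-localization.

Every generator is deterministic given the config seed; the cohort-level
seed fans out to per-ROI child seeds by stable hashing of the (patient, roi)
indices, so individual ROIs can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .panel import FINAL_LABELS, MARKERS

ENTITIES = ("SDC", "ACC", "MEC", "Sec")

ROI_SIZE_UM = 500.0  # square ablation field side length

#: Lymphocyte-lineage labels that co-locate in immune aggregates.
_LYMPHOID = (
    "plasma cell",
    "CD8 T",
    "CD4 T",
    "proliferating CD4 T",
    "CD4+CD74+ T",
    "other CD4+",
    "other immune",
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# marker archetypes

# raw-count lognormal parameters on three intensity tiers; on the asinh
# scale (cofactor 1) "high" and "low" tiers sit ~11 SD apart, comfortably
# beyond the 4-SD separation the recovery guarantees assume
_HIGH = (math.log(60.0), 0.35)
_MID = (math.log(12.0), 0.35)
_LOW = (0.0, 0.5)

#: markers elevated per phenotype; ("marker", tier) pairs; DNA high for all
_ARCHETYPE_HIGHS: dict[str, tuple] = {
    "tumor": (("CKAE13", _HIGH),),
    "endothelia": (("CD31", _HIGH), ("CD34", _HIGH), ("Vimentin", _MID)),
    "plasma cell": (("CD138", _HIGH), ("CD45", _MID)),
    "CD8 T": (("CD45", _HIGH), ("CD8a", _HIGH)),
    "CD4 T": (("CD45", _HIGH), ("CD4", _HIGH)),
    "proliferating CD4 T": (("CD45", _HIGH), ("CD4", _HIGH), ("Ki67", _HIGH)),
    "CD4+CD74+ T": (("CD45", _HIGH), ("CD4", _HIGH), ("CD74", _HIGH)),
    "other CD4+": (("CD45", _HIGH), ("CD4", _MID)),
    "other immune": (("CD45", _HIGH),),
    "mCAF": (("aSMA", _HIGH), ("Collagen1", _HIGH), ("Vimentin", _HIGH)),
    "Collagen CAF": (("Collagen1", _HIGH), ("Vimentin", _HIGH)),
    "SMA CAF": (("aSMA", _HIGH), ("Vimentin", _HIGH)),
    "dCAF": (("Ki67", _HIGH), ("Vimentin", _HIGH)),
    "apCAF": (("CD74", _HIGH), ("Vimentin", _HIGH)),
    "other CAF (Vimentin+)": (("Vimentin", _HIGH),),
}


def default_marker_model() -> dict:
    """Per-type, per-marker (meanlog, sigma) for lognormal raw counts."""
    model = {}
    for label in FINAL_LABELS:
        params = {m: _LOW for m in MARKERS}
        params["DNA"] = _HIGH
        for marker, tier in _ARCHETYPE_HIGHS[label]:
            params[marker] = tier
        model[label] = params
    return model


def _entity_composition(nontumor: dict) -> dict:
    total = sum(nontumor.values())
    if total >= 1.0:
        raise ConfigError("non-tumor fractions exceed 1")
    comp = {"tumor": 1.0 - total}
    comp.update(nontumor)
    return comp


def default_compositions() -> dict:
    """Entity-specific cell-type probability vectors.

    SDC is mCAF/Collagen-CAF rich; ACC carries the strongest lymphoid
    infiltrate (CD4/CD8 T cells, apCAFs); MEC and Sec are tumor-dominated.
    """
    return {
        "SDC": _entity_composition({
            "endothelia": 0.010, "plasma cell": 0.020, "CD8 T": 0.030,
            "CD4 T": 0.030, "proliferating CD4 T": 0.005,
            "CD4+CD74+ T": 0.005, "other CD4+": 0.030, "other immune": 0.020,
            "mCAF": 0.120, "Collagen CAF": 0.100, "SMA CAF": 0.050,
            "dCAF": 0.005, "apCAF": 0.005, "other CAF (Vimentin+)": 0.040,
        }),
        "ACC": _entity_composition({
            "endothelia": 0.010, "plasma cell": 0.030, "CD8 T": 0.070,
            "CD4 T": 0.070, "proliferating CD4 T": 0.010,
            "CD4+CD74+ T": 0.010, "other CD4+": 0.060, "other immune": 0.040,
            "mCAF": 0.030, "Collagen CAF": 0.040, "SMA CAF": 0.030,
            "dCAF": 0.005, "apCAF": 0.015, "other CAF (Vimentin+)": 0.030,
        }),
        "MEC": _entity_composition({
            "endothelia": 0.010, "plasma cell": 0.020, "CD8 T": 0.030,
            "CD4 T": 0.030, "proliferating CD4 T": 0.005,
            "CD4+CD74+ T": 0.005, "other CD4+": 0.020, "other immune": 0.020,
            "mCAF": 0.040, "Collagen CAF": 0.050, "SMA CAF": 0.040,
            "dCAF": 0.005, "apCAF": 0.005, "other CAF (Vimentin+)": 0.030,
        }),
        "Sec": _entity_composition({
            "endothelia": 0.010, "plasma cell": 0.020, "CD8 T": 0.040,
            "CD4 T": 0.040, "proliferating CD4 T": 0.005,
            "CD4+CD74+ T": 0.005, "other CD4+": 0.030, "other immune": 0.020,
            "mCAF": 0.050, "Collagen CAF": 0.050, "SMA CAF": 0.040,
            "dCAF": 0.005, "apCAF": 0.005, "other CAF (Vimentin+)": 0.030,
        }),
    }


@dataclass
class NicheParams:
    """Planted spatial structure of one ROI."""

    n_tumor_patches: int = 3
    patch_radius_um: float = 80.0
    n_vessel_lines: int = 3
    vessel_buffer_um: float = 20.0
    mcaf_vessel_affinity: float = 0.8
    n_lymphocyte_aggregates: int = 2
    lymphocyte_aggregate_sd_um: float = 40.0
    lymphocyte_aggregate_prob: float = 0.8


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``hazard_log_hr_mcaf`` is the log hazard ratio for recurrence per unit
    true mCAF fraction.  ``mcaf_fraction_dist`` optionally overrides the
    per-patient mCAF fraction: ``("bimodal", f_lo, f_hi, jitter_sd)`` draws
    each patient from one of two tight clusters (so a dichotomized group
    contrast has a well-defined planted hazard ratio), ``("jitter", sd)``
    perturbs the entity baseline on the logit scale.
    """

    n_patients: int = 20
    rois_per_patient: int = 2
    cells_per_roi: int = 1000
    entity_mix: dict = field(default_factory=lambda: {
        "SDC": 23 / 54, "ACC": 13 / 54, "MEC": 12 / 54, "Sec": 6 / 54})
    composition: dict = field(default_factory=default_compositions)
    marker_model: dict = field(default_factory=default_marker_model)
    niche_params: NicheParams = field(default_factory=NicheParams)
    hazard_log_hr_mcaf: float = math.log(6.0) / 0.3
    base_hazard_rfp: float = 0.008   # events / month at mCAF fraction 0
    base_hazard_os: float = 0.006
    p_distant: float = 0.6           # distant spread given recurrence
    censor_rate: float = 0.2
    follow_up_months: float = 120.0
    mcaf_fraction_dist: tuple | None = None
    st_colocalization: float = 0.8
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("n_patients", "rois_per_patient", "cells_per_roi"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        _check_probvec(self.entity_mix, "entity_mix")
        for entity, comp in self.composition.items():
            _check_probvec(comp, f"composition[{entity}]")
        np_ = self.niche_params
        if not 0.0 <= np_.mcaf_vessel_affinity <= 1.0:
            raise ConfigError("mcaf_vessel_affinity must be in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigError("censor_rate must be in [0, 1]")
        if not -1.0 <= self.st_colocalization <= 1.0:
            raise ConfigError("st_colocalization must be in [-1, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _check_probvec(vec: dict, name: str) -> None:
    vals = np.asarray(list(vec.values()), dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ConfigError(f"{name}: probabilities must be in [0, 1]")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {vals.sum()}, not 1")


@dataclass
class GroundTruth:
    """Planted truth for a generated cohort (or single ROI)."""

    cell_types: pd.Series                 # cell_id -> true final label
    niches: dict                          # roi_id -> planted geometry
    mcaf_fraction: pd.Series              # patient_id -> true mCAF fraction
    hazard_log_hr_mcaf: float

    def to_json_dict(self) -> dict:
        return {
            "cell_types": self.cell_types.to_dict(),
            "niches": {
                roi: {k: np.asarray(v).tolist() for k, v in geo.items()}
                for roi, geo in self.niches.items()
            },
            "mcaf_fraction": self.mcaf_fraction.to_dict(),
            "hazard_log_hr_mcaf": self.hazard_log_hr_mcaf,
        }


def child_seed(root_seed: int, *indices: int) -> int:
    """Stable per-(patient, roi) child seed below 2**31."""
    ss = np.random.SeedSequence([int(root_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# ROI generation


def _point_on_segment(rng, seg):
    (x0, y0), (x1, y1) = seg
    t = rng.uniform()
    return x0 + t * (x1 - x0), y0 + t * (y1 - y0)


def generate_roi(
    config: SimulationConfig,
    entity: str,
    seed: int,
    *,
    patient_id: str = "P000",
    roi_id: str = "P000_R000",
    composition: dict | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one 500x500 um ROI.

    Tumor cells concentrate in planted circular patches, endothelia lie on
    vessel line segments, mCAFs sit within the vessel attraction buffer with
    probability ``mcaf_vessel_affinity``, lymphoid cells cluster in
    aggregates, and everything else is uniform.  Raw marker counts are drawn
    from the per-type lognormal marker model.
    """
    if config.cells_per_roi < 50:
        raise ConfigError("cells_per_roi must be >= 50")
    comp = dict(composition if composition is not None else
                config.composition[entity])
    _check_probvec(comp, "composition")
    rng = np.random.default_rng(seed)
    n = config.cells_per_roi
    labels = list(comp)
    types = rng.choice(len(labels), size=n, p=list(comp.values()))
    nich = config.niche_params
    size = ROI_SIZE_UM

    patch_centers = rng.uniform(0, size, size=(nich.n_tumor_patches, 2))
    vessels = rng.uniform(0, size, size=(nich.n_vessel_lines, 2, 2))
    aggregates = rng.uniform(0, size, size=(nich.n_lymphocyte_aggregates, 2))

    xy = np.empty((n, 2))
    for i, ti in enumerate(types):
        label = labels[ti]
        if label == "tumor" and nich.n_tumor_patches > 0:
            c = patch_centers[rng.integers(nich.n_tumor_patches)]
            r = abs(rng.normal(0.0, nich.patch_radius_um / 2.0))
            theta = rng.uniform(0, 2 * np.pi)
            xy[i] = c + r * np.array([np.cos(theta), np.sin(theta)])
        elif label == "endothelia" and nich.n_vessel_lines > 0:
            px, py = _point_on_segment(rng, vessels[rng.integers(len(vessels))])
            xy[i] = (px + rng.normal(0, 3.0), py + rng.normal(0, 3.0))
        elif (label == "mCAF" and nich.n_vessel_lines > 0
              and rng.uniform() < nich.mcaf_vessel_affinity):
            px, py = _point_on_segment(rng, vessels[rng.integers(len(vessels))])
            r = rng.uniform(0, nich.vessel_buffer_um)
            theta = rng.uniform(0, 2 * np.pi)
            xy[i] = (px + r * np.cos(theta), py + r * np.sin(theta))
        elif (label in _LYMPHOID and nich.n_lymphocyte_aggregates > 0
              and rng.uniform() < nich.lymphocyte_aggregate_prob):
            c = aggregates[rng.integers(len(aggregates))]
            xy[i] = c + rng.normal(0, nich.lymphocyte_aggregate_sd_um, 2)
        else:
            xy[i] = rng.uniform(0, size, 2)
    np.clip(xy, 0.0, size, out=xy)

    counts = np.empty((n, len(MARKERS)))
    for j, marker in enumerate(MARKERS):
        mu = np.array([config.marker_model[labels[t]][marker][0] for t in types])
        sg = np.array([config.marker_model[labels[t]][marker][1] for t in types])
        counts[:, j] = rng.lognormal(mu, sg)

    cell_ids = [f"{roi_id}_c{i:05d}" for i in range(n)]
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "patient_id": patient_id,
        "roi_id": roi_id,
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
    })
    for j, marker in enumerate(MARKERS):
        cells[marker] = counts[:, j]

    truth = GroundTruth(
        cell_types=pd.Series([labels[t] for t in types], index=cell_ids,
                             name="true_label"),
        niches={roi_id: {
            "tumor_patch_centers": patch_centers,
            "patch_radius_um": [nich.patch_radius_um],
            "vessel_segments": vessels,
            "vessel_buffer_um": [nich.vessel_buffer_um],
            "lymphocyte_aggregates": aggregates,
        }},
        mcaf_fraction=pd.Series({patient_id: comp.get("mCAF", 0.0)}),
        hazard_log_hr_mcaf=config.hazard_log_hr_mcaf,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# cohort generation


def _patient_composition(config, entity, rng, patient_index: int = 0) -> dict:
    comp = dict(config.composition[entity])
    dist = config.mcaf_fraction_dist
    if dist is None:
        return comp
    if dist[0] == "bimodal":
        # balanced by construction (index parity): the cohort median then
        # falls exactly between the clusters and the dichotomized contrast
        # carries the planted group hazard ratio
        _, f_lo, f_hi, jitter = dist
        f = (f_lo if patient_index % 2 == 0 else f_hi) + rng.normal(0, jitter)
        f = float(np.clip(f, 1e-4, 0.95))
    elif dist[0] == "jitter":
        _, sd = dist
        base = comp.get("mCAF", 0.05)
        logit = math.log(base / (1 - base)) + rng.normal(0, sd)
        f = 1.0 / (1.0 + math.exp(-logit))
    else:
        raise ConfigError(f"unknown mcaf_fraction_dist kind {dist[0]!r}")
    rest = 1.0 - comp.get("mCAF", 0.0)
    scale = (1.0 - f) / rest
    comp = {k: v * scale for k, v in comp.items() if k != "mCAF"}
    comp["mCAF"] = f
    total = sum(comp.values())
    comp = {k: v / total for k, v in comp.items()}
    return comp


_T34_RATE = {"SDC": 0.52, "ACC": 0.50, "MEC": 0.25, "Sec": 0.20}
_NPOS_RATE = {"SDC": 0.78, "ACC": 0.25, "MEC": 0.08, "Sec": 0.0}
_HER2_PROBS = (0.227, 0.182, 0.227, 0.364)  # scores 0..3+ among SDC


def generate_cohort(
    config: SimulationConfig,
    with_cells: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate cells + clinical outcomes for a whole cohort.

    Recurrence times are exponential with hazard
    ``base_hazard_rfp * exp(hazard_log_hr_mcaf * mcaf_fraction)``; death
    times are exponential with hazard independent of mCAF fraction; distant
    recurrence occurs with probability ``p_distant`` at the recurrence time.
    Censoring is administrative at ``follow_up_months`` plus an independent
    exponential whose rate yields ``censor_rate`` mass before the horizon.

    ``with_cells=False`` skips cell synthesis (clinical table and ground
    truth only) — the fast path for survival replicate studies.
    """
    rng = np.random.default_rng(child_seed(config.seed, 777))
    entities = rng.choice(ENTITIES, size=config.n_patients,
                          p=[config.entity_mix[e] for e in ENTITIES])

    all_cells, clin_rows = [], []
    cell_truth, niches, frac = [], {}, {}
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        entity = str(entities[p])
        prng = np.random.default_rng(child_seed(config.seed, p, 999_000))
        comp = _patient_composition(config, entity, prng, p)
        frac[pid] = comp.get("mCAF", 0.0)
        for r in range(config.rois_per_patient if with_cells else 0):
            rid = f"{pid}_R{r:03d}"
            cells, truth = generate_roi(
                config, entity, child_seed(config.seed, p, r),
                patient_id=pid, roi_id=rid, composition=comp)
            all_cells.append(cells)
            cell_truth.append(truth.cell_types)
            niches.update(truth.niches)
        clin_rows.append(_clinical_record(config, pid, entity, frac[pid], prng))

    cells = (pd.concat(all_cells, ignore_index=True) if all_cells
             else pd.DataFrame())
    clinical = pd.DataFrame(clin_rows)
    truth = GroundTruth(
        cell_types=(pd.concat(cell_truth) if cell_truth
                    else pd.Series(dtype=object)),
        niches=niches,
        mcaf_fraction=pd.Series(frac, name="mcaf_fraction"),
        hazard_log_hr_mcaf=config.hazard_log_hr_mcaf,
    )
    return cells, clinical, truth


def _censor_time(config, rng) -> float:
    if config.censor_rate >= 1.0:
        return 0.0
    if config.censor_rate <= 0.0:
        return config.follow_up_months
    rate = -math.log(1.0 - config.censor_rate) / config.follow_up_months
    return min(config.follow_up_months, rng.exponential(1.0 / rate))


def _clinical_record(config, pid, entity, mcaf_frac, rng) -> dict:
    lam_rfp = config.base_hazard_rfp * math.exp(
        config.hazard_log_hr_mcaf * mcaf_frac)
    t_rec = rng.exponential(1.0 / lam_rfp) if lam_rfp > 0 else math.inf
    t_death = (rng.exponential(1.0 / config.base_hazard_os)
               if config.base_hazard_os > 0 else math.inf)
    distant = rng.uniform() < config.p_distant
    t_dist = t_rec if distant else math.inf
    cens = _censor_time(config, rng)

    def endpoint(t_event):
        t = min(t_event, cens)
        return t, bool(t_event <= cens)

    t_os, e_os = endpoint(t_death)
    t_rfp, e_rfp = endpoint(t_rec)
    t_rfs, e_rfs = endpoint(min(t_rec, t_death))
    t_dcr, e_dcr = endpoint(t_dist)

    is_sdc = entity == "SDC"
    ar_percent = (float(rng.uniform(70, 100)) if rng.uniform() < 0.545
                  else float(rng.uniform(0, 70))) if is_sdc else float("nan")
    her2 = int(rng.choice(4, p=_HER2_PROBS)) if is_sdc else 0
    return {
        "patient_id": pid,
        "entity": entity,
        "ar_percent": ar_percent,
        "her2_score": her2,
        "t_stage": "T3/4" if rng.uniform() < _T34_RATE[entity] else "T1/2",
        "n_stage": "N+" if rng.uniform() < _NPOS_RATE[entity] else "N0",
        "time_os": t_os, "event_os": e_os,
        "time_rfs": t_rfs, "event_rfs": e_rfs,
        "time_rfp": t_rfp, "event_rfp": e_rfp,
        "time_dcr": t_dcr, "event_dcr": e_dcr,
    }


def group_log_hr(config: SimulationConfig) -> float:
    """Planted log hazard ratio between the two bimodal mCAF clusters."""
    dist = config.mcaf_fraction_dist
    if dist is None or dist[0] != "bimodal":
        raise ConfigError("group_log_hr requires a bimodal mcaf_fraction_dist")
    _, f_lo, f_hi, _ = dist
    return config.hazard_log_hr_mcaf * (f_hi - f_lo)


# ---------------------------------------------------------------------------
# bulk expression


def generate_bulk(
    config: SimulationConfig,
    n_samples: int,
    signature,
    effect: float,
    seed: int,
    *,
    n_background: int = 1000,
    total: float = 1e6,
) -> tuple[pd.DataFrame, pd.Series]:
    """TPM-like genes x samples matrix with a planted signature contrast.

    Half the samples ("high") have every signature gene scaled by
    ``effect``; each column is renormalized to a constant total so the
    matrix stays TPM-like.
    """
    if effect <= 0:
        raise ConfigError("effect must be > 0")
    sig_genes = list(signature.genes)
    if not sig_genes:
        raise ConfigError("signature is empty")
    rng = np.random.default_rng(seed)
    genes = sig_genes + [f"BG{i:05d}" for i in range(n_background)]
    base = rng.lognormal(mean=3.0, sigma=1.0, size=len(genes))
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(len(genes), n_samples))
    expr = base[:, None] * noise
    labels = pd.Series(
        ["high" if i < n_samples // 2 else "low" for i in range(n_samples)],
        index=[f"S{i:03d}" for i in range(n_samples)], name="group")
    high_cols = np.arange(n_samples) < n_samples // 2
    expr[: len(sig_genes), high_cols] *= effect
    expr = expr / expr.sum(axis=0, keepdims=True) * total
    mat = pd.DataFrame(expr, index=genes, columns=labels.index)
    return mat, labels


# ---------------------------------------------------------------------------
# spatial transcriptomics


ENDOTHELIAL_GENES = ("PECAM1", "VWF", "CDH5", "KDR", "MCAM")


def _smooth_field(rng, side: int, smooth: float = 0.8) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=(side, side)), smooth,
                                mode="wrap")
    return (f - f.mean()) / f.std()


def generate_st(
    config: SimulationConfig,
    n_spots_per_sample: int,
    seed: int,
    *,
    n_samples: int = 1,
    mcaf_genes: tuple | None = None,
    n_background: int = 300,
    noise_sigma: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spot-level expression mixing cell-type profiles over a spatial field.

    The latent mCAF and endothelia abundance fields are correlated at
    ``config.st_colocalization``; each spot's expression is the
    composition-weighted mix of type profiles times lognormal noise.

    Returns (expression spots x genes, coordinates, true composition).
    """
    rho = config.st_colocalization
    rng = np.random.default_rng(seed)
    if mcaf_genes is None:
        mcaf_genes = tuple(f"MCAFG{i:03d}" for i in range(98))
    genes = (list(mcaf_genes) + list(ENDOTHELIAL_GENES)
             + [f"STBG{i:04d}" for i in range(n_background)])

    # cell-type gene profiles: signature genes high in mCAF, endothelial
    # canon high in endothelia, everything expressed at a background level
    profiles = pd.DataFrame(1.0, index=["mCAF", "endothelia", "other"],
                            columns=genes)
    profiles.loc["mCAF", list(mcaf_genes)] = 8.0
    profiles.loc["endothelia", list(ENDOTHELIAL_GENES)] = 8.0

    side = int(np.ceil(np.sqrt(n_spots_per_sample)))
    rows = []
    exprs, coords, comps = [], [], []
    for s in range(n_samples):
        z1 = _smooth_field(rng, side)
        z2 = _smooth_field(rng, side)
        endo_f = rho * z1 + math.sqrt(max(0.0, 1 - rho**2)) * z2
        idx = np.arange(n_spots_per_sample)
        gx, gy = idx % side, idx // side
        # bounded logistic abundances: no shared normalization, so the
        # mCAF-endothelia correlation is exactly the latent-field one
        a_m = 0.4 / (1.0 + np.exp(-1.5 * z1[gy, gx]))
        a_e = 0.2 / (1.0 + np.exp(-1.5 * endo_f[gy, gx]))
        comp = np.stack([a_m, a_e, 1.0 - a_m - a_e], axis=1)
        mix = comp @ profiles.to_numpy()
        noise = rng.lognormal(0.0, noise_sigma, size=mix.shape)
        spot_ids = [f"ST{s}_s{i:05d}" for i in idx]
        exprs.append(pd.DataFrame(mix * noise, index=spot_ids, columns=genes))
        coords.append(pd.DataFrame(
            {"sample_id": f"ST{s}", "x": gx * 100.0, "y": gy * 100.0},
            index=spot_ids))
        comps.append(pd.DataFrame(
            comp, index=spot_ids, columns=["mCAF", "endothelia", "other"]))
        rows.append(spot_ids)

    return (pd.concat(exprs), pd.concat(coords), pd.concat(comps))
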