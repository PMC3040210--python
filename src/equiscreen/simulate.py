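"""Synthetic multi-platform substantial-equivalence studies with ground truth.

The generator emulates the statistical structure of a multi-genotype,
two-stage, multi-platform tomato study: a control line, transgenic lines
carrying planted GM effects on a known subset of metabolites, and a panel
of reference cultivars whose per-metabolite effects calibrate the safety
margins.  Latent metabolites shared across platforms produce redundant,
cross-correlated peaks; abundances are log-normal with smooth harvest
drift, random missingness and low-abundance censoring.  Every generated
peak is described in a ground-truth ledger so each pipeline stage can be
validated against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import DESCRIPTORS, PropertyMatrix, ScalingRecord, standardize_properties
from .io import AnnotationMap, EquiscreenError, PeakTable, StudyDesign


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults emulate a hydroponic-culture style experiment: one control
    line, two transgenic lines, five reference cultivars (8 genotypes),
    two ripening stages, 8 replicates, and 600 peaks spread over three
    platforms.  Effect sizes are on the log10-abundance scale.
    """

    n_transgenic: int = 2
    n_reference: int = 5
    n_stages: int = 2
    n_replicates: int = 8
    n_treatments: int = 1
    peaks_per_platform: dict = field(
        default_factory=lambda: {"GC-MS": 250, "LC-MS": 200, "CE-MS": 150})
    n_shared_metabolites: int = 40     # latent metabolites detected on all platforms
    cross_platform_rho: float = 0.8    # shared fraction of each peak's noise variance
    annotated_fraction: float = 0.30   # platform-specific peaks with an annotation
    stage_effect_sd: float = 0.5
    cultivar_effect_sd: float = 0.4
    treatment_effect_sd: float = 0.2
    harvest_drift_sd: float = 0.2
    noise_sd: float = 0.25
    n_gm_peaks: int = 50               # latent metabolites given a planted GM shift
    gm_margin_multiple: float = 1.5    # shift size relative to the expected margin
    baseline_mean: float = 5.0         # log10 abundance
    baseline_sd: float = 1.0
    random_missing: float = 0.02
    censor_quantile: float = 0.05      # lowest raw abundances become missing
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cross_platform_rho", "annotated_fraction",
                     "random_missing", "censor_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise EquiscreenError(f"{name}={v} must be in [0, 1]")
        for name in ("n_transgenic", "n_reference", "n_stages", "n_replicates",
                     "n_treatments"):
            if getattr(self, name) < 1:
                raise EquiscreenError(f"{name} must be positive")
        if min(self.peaks_per_platform.values()) < self.n_shared_metabolites:
            raise EquiscreenError(
                "n_shared_metabolites exceeds the peak count of some platform")
        total_latents = (sum(self.peaks_per_platform.values())
                         - self.n_shared_metabolites * (len(self.peaks_per_platform) - 1))
        if self.n_gm_peaks > total_latents:
            raise EquiscreenError("n_gm_peaks exceeds the number of latent metabolites")


@dataclass
class GroundTruth:
    """What was planted: one row per generated peak plus effect tables."""

    peaks: pd.DataFrame             # peak_id, platform, latent, shared, gm_effect, rho
    cultivar_effects: pd.DataFrame  # latent x genotype log-scale shifts
    gm_latents: list                # latent keys carrying the planted GM shift

    def planted_peak_ids(self) -> list:
        return list(self.peaks.loc[self.peaks["gm_effect"] != 0.0, "peak_id"])


def generate_study(config: SimulationConfig):
    """Generate per-platform peak tables, design, annotations, ground truth.

    Log-scale abundance = baseline + stage effect + cultivar effect +
    GM effect (transgenic lines, planted latents only) + smooth harvest
    drift + noise; for latents shared across platforms a fraction ``rho``
    of the noise variance is common to all platforms, planting the
    cross-platform correlation.  Raw abundances are ``10**value`` with
    random missingness plus censoring below a platform abundance quantile.
    Identical seeds give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    platforms = list(cfg.peaks_per_platform)

    genotypes = (["CTRL"]
                 + [f"TG{i + 1}" for i in range(cfg.n_transgenic)]
                 + [f"REF{i + 1}" for i in range(cfg.n_reference)])
    roles = (["control"] + ["transgenic"] * cfg.n_transgenic
             + ["reference"] * cfg.n_reference)
    stages = [f"stage{i + 1}" for i in range(cfg.n_stages)]
    treatments = [f"trt{i + 1}" for i in range(cfg.n_treatments)]

    rows = []
    for geno, role in zip(genotypes, roles):
        for stage in stages:
            for trt in treatments:
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append({"sample_id": f"{geno}_{stage}_{trt}_r{rep}",
                                 "genotype": geno, "role": role, "stage": stage,
                                 "treatment": trt, "replicate": rep})
    design_df = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(design_df)
    design_df["harvest_order"] = rng.permutation(n_samples) + 1
    design = StudyDesign(design_df)

    # latent metabolites: shared ones appear on every platform
    shared_latents = [f"M{i + 1:04d}" for i in range(cfg.n_shared_metabolites)]
    latents_by_platform: dict[str, list] = {}
    next_id = cfg.n_shared_metabolites
    for pl in platforms:
        n_specific = cfg.peaks_per_platform[pl] - cfg.n_shared_metabolites
        specific = [f"M{next_id + i + 1:04d}" for i in range(n_specific)]
        next_id += n_specific
        latents_by_platform[pl] = shared_latents + specific
    all_latents = shared_latents + [
        lat for pl in platforms for lat in latents_by_platform[pl]
        if lat not in shared_latents]

    # planted effects
    baseline = pd.Series(rng.normal(cfg.baseline_mean, cfg.baseline_sd,
                                    len(all_latents)), index=all_latents)
    stage_eff = pd.DataFrame(0.0, index=all_latents, columns=stages)
    for stage in stages[1:]:
        stage_eff[stage] = rng.normal(0.0, cfg.stage_effect_sd, len(all_latents))
    trt_eff = pd.DataFrame(0.0, index=all_latents, columns=treatments)
    for trt in treatments[1:]:
        trt_eff[trt] = rng.normal(0.0, cfg.treatment_effect_sd, len(all_latents))
    cult_eff = pd.DataFrame(0.0, index=all_latents, columns=genotypes)
    for geno, role in zip(genotypes, roles):
        if role == "reference":
            cult_eff[geno] = rng.normal(0.0, cfg.cultivar_effect_sd, len(all_latents))
    drift_slope = pd.Series(rng.normal(0.0, cfg.harvest_drift_sd, len(all_latents)),
                            index=all_latents)

    gm_latents = sorted(rng.choice(all_latents, size=cfg.n_gm_peaks, replace=False))
    # shift sized relative to the margin the panel will imply for that peak:
    # the largest absolute cultivar effect plus the CI slack expected at the
    # configured noise level and replicate count
    gm_eff = pd.Series(0.0, index=all_latents)
    ci_slack = 2.0 * cfg.noise_sd * np.sqrt(2.0 / cfg.n_replicates)
    for lat in gm_latents:
        margin_proxy = float(cult_eff.loc[lat].abs().max()) + ci_slack
        gm_eff[lat] = cfg.gm_margin_multiple * margin_proxy * rng.choice([-1.0, 1.0])

    # latent signal per (sample, latent) plus the shared noise component
    h = design_df["harvest_order"].to_numpy(dtype=float)
    h = (h - h.mean()) / h.std(ddof=0)
    signal = (baseline.to_numpy()[None, :]
              + stage_eff.to_numpy()[:, :].T[
                  [stages.index(s) for s in design_df["stage"]], :]
              + trt_eff.to_numpy().T[[treatments.index(t)
                                      for t in design_df["treatment"]], :]
              + cult_eff.to_numpy().T[[genotypes.index(g)
                                       for g in design_df["genotype"]], :]
              + np.outer(h, drift_slope.to_numpy()))
    is_tg = design_df["role"].to_numpy() == "transgenic"
    signal = signal + np.outer(is_tg.astype(float), gm_eff.to_numpy())
    shared_noise = rng.normal(0.0, 1.0, size=(n_samples, len(all_latents)))

    latent_index = {lat: i for i, lat in enumerate(all_latents)}
    tables: dict[str, PeakTable] = {}
    maps: dict[str, AnnotationMap] = {}
    gt_rows = []
    prefix = {"GC-MS": "gc", "LC-MS": "lc", "CE-MS": "ce"}
    for pl in platforms:
        lat_ids = latents_by_platform[pl]
        idx = [latent_index[lat] for lat in lat_ids]
        shared_flags = np.array([lat in shared_latents for lat in lat_ids])
        rho = np.where(shared_flags, cfg.cross_platform_rho, 0.0)
        eps = rng.normal(0.0, 1.0, size=(n_samples, len(lat_ids)))
        values = (signal[:, idx]
                  + cfg.noise_sd * (np.sqrt(rho) * shared_noise[:, idx]
                                    + np.sqrt(1.0 - rho) * eps))
        raw = np.power(10.0, values)
        # missingness: censoring of the lowest raw abundances + random dropout
        if cfg.censor_quantile > 0:
            threshold = np.quantile(raw, cfg.censor_quantile)
            raw[raw < threshold] = np.nan
        if cfg.random_missing > 0:
            raw[rng.random(raw.shape) < cfg.random_missing] = np.nan
        peak_ids = [f"{prefix.get(pl, pl.lower())}_{lat}" for lat in lat_ids]
        df = pd.DataFrame(raw, index=design_df.index, columns=peak_ids)
        tables[pl] = PeakTable(df, platform=pl)

        entries: dict = {}
        for lat, peak in zip(lat_ids, peak_ids):
            if lat in shared_latents:
                entries[peak] = {("KEGG", f"C{latent_index[lat] + 10000:05d}")}
            elif rng.random() < cfg.annotated_fraction:
                entries[peak] = {("KEGG", f"C{latent_index[lat] + 10000:05d}")}
        maps[pl] = AnnotationMap(entries)
        for lat, peak in zip(lat_ids, peak_ids):
            gt_rows.append({"peak_id": peak, "platform": pl, "latent": lat,
                            "shared": lat in shared_latents,
                            "gm_effect": float(gm_eff[lat]),
                            "noise_rho": float(cfg.cross_platform_rho
                                               if lat in shared_latents else 0.0),
                            "annotated": peak in entries})

    truth = GroundTruth(peaks=pd.DataFrame(gt_rows),
                        cultivar_effects=cult_eff,
                        gm_latents=list(gm_latents))
    return tables, design, maps, truth


# ---------------------------------------------------------------------------
# physicochemical descriptor tables
# ---------------------------------------------------------------------------

def generate_property_tables(
    seed: int,
    n_reference: int = 300,
    descriptors=DESCRIPTORS,
    subsets: dict | None = None,
    variance_decay: float = 0.7,
):
    """Reference descriptor matrix plus subsets spanning known subspaces.

    The reference metabolome is sampled from a low-rank-dominated Gaussian
    (geometrically decaying eigenvalues, random orthogonal loadings) and
    emitted on the raw scale (the vapor-pressure column exponentiated so
    the standard log transform applies).  Each subset draws metabolites
    exactly inside the span of chosen principal components of the
    *standardized* reference, so its true chemical coverage is the summed
    variance share of those components — returned in the info dict.

    ``subsets`` maps a name to ``{"components": tuple of PC indices,
    "n": number of metabolites}``.
    """
    rng = np.random.default_rng(seed)
    p = len(descriptors)
    if subsets is None:
        subsets = {"plane12": {"components": (0, 1), "n": 60}}

    lam = variance_decay ** np.arange(p)
    q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    z = rng.standard_normal((n_reference, p))
    x = z * np.sqrt(lam) @ q.T

    def _to_raw(values: np.ndarray, index) -> pd.DataFrame:
        df = pd.DataFrame(values, index=index, columns=list(descriptors))
        if "LgPVap" in df.columns:
            df["LgPVap"] = np.power(10.0, df["LgPVap"])
        return df

    ref_index = [f"ref{i + 1:04d}" for i in range(n_reference)]
    reference_raw = PropertyMatrix(_to_raw(x, ref_index))
    reference = standardize_properties(reference_raw)

    xs = reference.data.to_numpy(dtype=float)
    _, svals, vt = np.linalg.svd(xs - xs.mean(axis=0), full_matrices=False)
    shares = svals**2 / np.sum(svals**2)

    record: ScalingRecord = reference.scaling
    out_subsets: dict[str, PropertyMatrix] = {}
    info = {"singular_values": svals, "variance_shares": shares, "plane_share": {}}
    for name, params in subsets.items():
        comps = tuple(params["components"])
        n_sub = int(params["n"])
        directions = vt[list(comps)]                       # k x p
        spread = svals[list(comps)] / np.sqrt(n_reference)
        scores = rng.standard_normal((n_sub, len(comps))) * spread
        sub_std = scores @ directions + xs.mean(axis=0)
        # back to the raw scale so the subset can be standardized with the
        # reference's record like a real input table
        sub_raw = sub_std * record.scale.to_numpy() + record.center.to_numpy()
        sub_index = [f"{name}_{i + 1:03d}" for i in range(n_sub)]
        out_subsets[name] = PropertyMatrix(_to_raw(sub_raw, sub_index))
        info["plane_share"][name] = float(np.sum(shares[list(comps)]))
    return reference, out_subsets, info
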