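"""Synthetic study generator with known ground truth.

Emulates a two-modality intratumoral-heterogeneity study design:
n patients, k tumour samples (luminal localisations) per patient, five
target miRNAs plus three stably expressed reference miRNAs measured by
RT-qPCR in triplicate, and four of the targets additionally quantified
by chromogenic ISH as area fractions.

qPCR model (Cq scale, where noise is approximately Gaussian):

    dCq_ij(m) = mu_m + b_i(m) + e_ij(m)
    b_i ~ N(0, sigma_b^2)   patient effect
    e_ij ~ N(0, sigma_w^2)  within-patient (sampling) effect
    replicate Cq = dCq_ij + normaliser level + N(0, tech_sd^2)

so the implied single-sample reliability on the Cq scale is
sigma_b^2 / (sigma_b^2 + sigma_w^2). Because the chain is Gaussian on
the Cq scale, the observable triplicate-mean *linear* value 2^-dCq is
exactly lognormal and the population ICC on the linear analysis scale
has a closed form (:func:`true_linear_icc`), reported with every truth
record as the recovery target. Replicates above the detection ceiling
are blanked; an all-blank triplicate is an undetected sample.

ISH model: each miRNA's per-patient signal mixes the standardized qPCR
patient effect (sign-flipped: low Cq = high expression) with an
independent component, controlled by the latent-sharing weight w in
[0, 1]; log area fractions then get within-patient noise and are clipped
to that miRNA's observed plausibility band. ROI areas are lognormal, so
a realistic minority fall under the small-ROI exclusion limit.

Synthetic images are hard-edged coloured ellipses at the class centroid
colours on a counterstain background, placed without overlap until each
class's pixel share matches its target; realized fractions are returned
exactly from the pixel bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ish import DEFAULT_CENTROIDS
from .qpcr import DEFAULT_NORMALISERS

LN2 = math.log(2.0)


@dataclass(frozen=True)
class MirnaParams:
    """Per-miRNA generative parameters.

    ``mean_cq`` / SDs are on the Cq scale; ``ish_band`` is the (lo, hi)
    plausibility band for the TBp (wpB for the iB-split miRNA) area
    fraction; ``ish_ib_max`` is the ceiling of the separate intense-blue
    fraction for the miRNA whose iB class is analysed separately.
    """

    mean_cq: float
    sigma_b: float
    sigma_w: float
    ish_band: tuple[float, float] | None = None
    ish_ib_max: float = 0.0

    @property
    def icc_cq(self) -> float:
        return self.sigma_b**2 / (self.sigma_b**2 + self.sigma_w**2)


def _params_from_range(lo: float, hi: float, icc: float,
                       ish_band=None, ish_ib_max=0.0) -> MirnaParams:
    """Anchor mean/total-SD to an observed raw-Cq range (~ mean +/- 2 SD)."""
    mean = (lo + hi) / 2.0
    total_sd = (hi - lo) / 4.0
    return MirnaParams(
        mean_cq=mean,
        sigma_b=total_sd * math.sqrt(icc),
        sigma_w=total_sd * math.sqrt(1.0 - icc),
        ish_band=ish_band,
        ish_ib_max=ish_ib_max,
    )


# Defaults anchored to the study conditions: observed raw-Cq ranges,
# Cq-scale reliabilities near the reported per-miRNA ICCs, and observed
# area-fraction bands. miR-31 has no ISH channel (not detectable by ISH).
DEFAULT_MIRNA_PARAMS: dict[str, MirnaParams] = {
    "miR-21": _params_from_range(17.4, 21.6, 0.65, ish_band=(0.0091, 0.5751)),
    "miR-31": _params_from_range(20.9, 28.7, 0.78),
    "miR-125b": _params_from_range(20.4, 26.3, 0.45,
                                   ish_band=(0.0004, 0.0818), ish_ib_max=0.0030),
    "miR-145": _params_from_range(15.9, 24.4, 0.134, ish_band=(0.0002, 0.1141)),
    "miR-630": _params_from_range(28.5, 36.7, 0.284, ish_band=(0.0012, 0.1302)),
}

DEFAULT_NORMALISER_MEANS = {"miR-193a-5p": 20.0, "miR-27a": 21.0, "let-7g": 19.5}


@dataclass
class SyntheticConfig:
    """Study-design and noise configuration for the generator."""

    n_patients: int = 27
    k: int = 3
    mirna_params: dict[str, MirnaParams] = field(
        default_factory=lambda: dict(DEFAULT_MIRNA_PARAMS)
    )
    normaliser_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NORMALISER_MEANS)
    )
    normaliser_sigma_b: float = 0.30   # reference genes are stable by selection
    normaliser_sigma_w: float = 0.15
    tech_sd: float = 0.15              # replicate-to-replicate noise, cycles
    detection_ceiling: float = 37.0    # replicates above this Cq are blanked
    latent_weight: float = 0.5         # cross-modality patient-latent sharing
    # log-area-fraction components anchored so the patient share of
    # variance (~0.45) sits mid-range of the observed ISH reliabilities
    ish_within_sd: float = 0.72        # within-patient SD of log area fraction
    ish_patient_scale: float = 0.65    # patient-latent SD of log area fraction
    roi_log_mean: float = math.log(5.0)  # lognormal ROI area, mm^2
    roi_log_sd: float = 0.55
    image_size: tuple[int, int] = (192, 192)
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def true_linear_icc(sigma_b: float, sigma_w: float, tech_sd: float = 0.0,
                    n_replicates: int = 3) -> float:
    """Population ICC_single of triplicate-mean linear values 2^-dCq.

    With Gaussian components on the Cq scale the observable is lognormal:
    X | b = exp(a (mu + b + e + t)), a = -ln 2, t the mean technical
    noise with variance tech_sd^2 / n_replicates. Then

        Var_between = E[X|b] variance over b = m^2 (exp(a^2 s_b^2) - 1)
        Var_within  = E[Var(X|b)] = m^2 exp(a^2 s_b^2) (exp(a^2 s_e^2) - 1)

    with s_e^2 = sigma_w^2 + tech_sd^2/n and a common factor m^2, so

        ICC = (e^{a^2 s_b^2} - 1) /
              (e^{a^2 s_b^2} - 1 + e^{a^2 s_b^2} (e^{a^2 s_e^2} - 1))
    """
    a2 = LN2**2
    s_b2 = sigma_b**2
    s_e2 = sigma_w**2 + tech_sd**2 / n_replicates
    eb = math.exp(a2 * s_b2)
    ew = math.exp(a2 * s_e2)
    return (eb - 1.0) / ((eb - 1.0) + eb * (ew - 1.0))


def _patient_sample_effects(rng, n, k, sigma_b, sigma_w):
    b = rng.normal(0.0, sigma_b, size=(n, 1))
    e = rng.normal(0.0, sigma_w, size=(n, k))
    return b, e


def gen_qpcr_dataset(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Generate an S1-style triplicate Cq table plus a truth record.

    Returns ``(table, truth)``. The table has one row per patient x
    sample x miRNA with columns patient_id, sample_id, deepest_flag,
    mirna_id, rep1_cq..rep3_cq (NaN = undetected replicate). The truth
    record carries, per miRNA, the patient effects, the noiseless dCq
    matrix, and the implied Cq-scale and linear-scale ICCs.
    """
    rng = cfg.rng() if rng is None else rng
    n, k = cfg.n_patients, cfg.k
    patients = [f"P{i + 1:02d}" for i in range(n)]
    samples = [f"S{j + 1}" for j in range(k)]
    deepest_idx = rng.integers(0, k, size=n)

    # per-channel normaliser levels; their mean is the per-sample
    # normalisation baseline that dCq generation is anchored to
    norm_levels = {}
    for name, mu in cfg.normaliser_means.items():
        b, e = _patient_sample_effects(
            rng, n, k, cfg.normaliser_sigma_b, cfg.normaliser_sigma_w
        )
        norm_levels[name] = mu + b + e
    baseline = np.mean([norm_levels[name] for name in cfg.normaliser_means], axis=0)

    norm_baseline_mu = float(np.mean(list(cfg.normaliser_means.values())))
    rows = []
    truth: dict = {
        "seed": cfg.seed,
        "n_patients": n,
        "k": k,
        "deepest_sample": {
            patients[i]: samples[deepest_idx[i]] for i in range(n)
        },
        "mirnas": {},
    }

    def emit(mirna, level_matrix):
        reps = level_matrix[..., None] + rng.normal(0.0, cfg.tech_sd, size=(n, k, 3))
        reps = np.where(reps > cfg.detection_ceiling, np.nan, reps)
        for i in range(n):
            for j in range(k):
                rows.append(
                    {
                        "patient_id": patients[i],
                        "sample_id": samples[j],
                        "deepest_flag": int(j == deepest_idx[i]),
                        "mirna_id": mirna,
                        "rep1_cq": reps[i, j, 0],
                        "rep2_cq": reps[i, j, 1],
                        "rep3_cq": reps[i, j, 2],
                    }
                )

    target_truth_b = {}
    for mirna, p in cfg.mirna_params.items():
        b, e = _patient_sample_effects(rng, n, k, p.sigma_b, p.sigma_w)
        mu_delta = p.mean_cq - norm_baseline_mu
        delta_cq = mu_delta + b + e
        raw_cq = delta_cq + baseline
        emit(mirna, raw_cq)
        target_truth_b[mirna] = b[:, 0]
        truth["mirnas"][mirna] = {
            "sigma_b": p.sigma_b,
            "sigma_w": p.sigma_w,
            "icc_cq": p.icc_cq,
            "icc_linear": true_linear_icc(p.sigma_b, p.sigma_w, cfg.tech_sd),
            "patient_effects": b[:, 0].tolist(),
            "delta_cq": delta_cq.tolist(),
        }
    for name in cfg.normaliser_means:
        emit(name, norm_levels[name])

    table = pd.DataFrame(rows)
    truth["_patient_effects_arrays"] = target_truth_b
    return table, truth


# fixed split of the weak/purple blue area between the wB and pB classes
_WB_SHARE, _PB_SHARE = 0.7, 0.3


def gen_ish_dataset(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    patient_effects: dict[str, np.ndarray],
    deepest_sample: dict[str, str],
):
    """Generate the S2-style ISH area table tied to the qPCR patient effects.

    The per-patient ISH latent is w * z + sqrt(1 - w^2) * independent,
    with z the standardized qPCR patient effect sign-flipped so that
    high expression (low Cq) means more stained area.
    """
    n, k = cfg.n_patients, cfg.k
    patients = [f"P{i + 1:02d}" for i in range(n)]
    samples = [f"S{j + 1}" for j in range(k)]
    w = cfg.latent_weight
    rows = []
    truth: dict = {"latent_weight": w, "mirnas": {}}
    for mirna, p in cfg.mirna_params.items():
        if p.ish_band is None:
            continue
        lo, hi = p.ish_band
        log_mid = (math.log(lo) + math.log(hi)) / 2.0
        z = -patient_effects[mirna] / p.sigma_b  # high expression -> high z
        eta = rng.normal(0.0, 1.0, size=n)
        latent = w * z + math.sqrt(max(0.0, 1.0 - w**2)) * eta
        log_frac = (
            log_mid
            + cfg.ish_patient_scale * latent[:, None]
            + rng.normal(0.0, cfg.ish_within_sd, size=(n, k))
        )
        main_frac = np.clip(np.exp(log_frac), lo, hi)
        if p.ish_ib_max > 0:
            # separate intense-blue compartment (cancer-independent signal)
            ib_frac = rng.uniform(0.0, p.ish_ib_max, size=(n, k))
            tbp = main_frac + ib_frac  # main band models wpB here
        else:
            ib_frac = 0.2 * main_frac
            tbp = main_frac
        wpb = tbp - ib_frac
        roi = np.exp(rng.normal(cfg.roi_log_mean, cfg.roi_log_sd, size=(n, k)))
        for i in range(n):
            for j in range(k):
                area_ib = ib_frac[i, j] * roi[i, j]
                area_wpb = wpb[i, j] * roi[i, j]
                rows.append(
                    {
                        "patient_id": patients[i],
                        "sample_id": samples[j],
                        "deepest_flag": int(samples[j] == deepest_sample[patients[i]]),
                        "mirna_id": mirna,
                        "area_iB": area_ib,
                        "area_wB": _WB_SHARE * area_wpb,
                        "area_pB": _PB_SHARE * area_wpb,
                        "roi_area_mm2": roi[i, j],
                    }
                )
        truth["mirnas"][mirna] = {
            "latent": latent.tolist(),
            "tbp_fraction": tbp.tolist(),
            "roi_area_mm2": roi.tolist(),
        }
    return pd.DataFrame(rows), truth


def gen_ish_image(
    targets: dict[str, float],
    size: tuple[int, int] = (192, 192),
    rng: np.random.Generator | int | None = None,
    tol: float = 0.005,
    max_blob_radius: int = 14,
):
    """Compose an RGB image of class-coloured blobs with known fractions.

    ``targets`` maps blue class names (iB/wB/pB) to target area
    fractions of the ROI (here the full frame); the remainder is
    nuclear-red counterstain. Non-overlapping hard-edged ellipses are
    placed until each class's pixel share is within ``tol`` (0.5
    percentage points by default) of its target. Returns
    ``(image, roi_mask, realized_fractions)`` where the realized
    fractions come from exact pixel counts.
    """
    from skimage.draw import ellipse

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    total = sum(targets.values())
    if total > 1.0:
        raise ValueError(f"target fractions sum to {total} > 1")
    h, wdt = size
    n_px = h * wdt
    image = np.empty((h, wdt, 3), dtype=np.uint8)
    image[...] = DEFAULT_CENTROIDS["nuclear_red"]
    roi_mask = np.ones((h, wdt), dtype=bool)
    occupied = np.zeros((h, wdt), dtype=bool)
    realized = {}
    # split the fraction tolerance across classes so the summed (TBp)
    # fraction also lands within tol of the summed target
    tol_px = max(1, int(tol * n_px / (2 * max(1, len(targets)))))
    for cls, frac in targets.items():
        if cls not in ("iB", "wB", "pB"):
            raise ValueError(f"unknown blue class {cls!r}")
        color = DEFAULT_CENTROIDS[cls]
        target_px = int(round(frac * n_px))
        placed = 0
        attempts = 0
        while target_px - placed > tol_px and attempts < 40000:
            attempts += 1
            remaining = target_px - placed
            r_max = min(max_blob_radius, max(1, int(math.sqrt(remaining / math.pi))))
            ra = rng.integers(1, r_max + 1)
            rb = rng.integers(1, r_max + 1)
            cy = rng.integers(ra, h - ra) if h > 2 * ra else h // 2
            cx = rng.integers(rb, wdt - rb) if wdt > 2 * rb else wdt // 2
            yy, xx = ellipse(cy, cx, ra, rb, shape=(h, wdt))
            if occupied[yy, xx].any():
                continue
            if len(yy) > remaining + tol_px:
                continue
            occupied[yy, xx] = True
            image[yy, xx] = color
            placed += len(yy)
        realized[cls] = placed / n_px
    realized["TBp"] = sum(realized.values())
    return image, roi_mask, realized


def gen_paired_study(cfg: SyntheticConfig, render_images: bool = False):
    """Full synthetic study: qPCR table, ISH table, optional images, truth.

    All randomness flows from ``cfg.seed``; the same seed reproduces the
    study bit-identically. The ISH side reuses the qPCR patient effects
    through the latent-sharing weight, so cross-modality concordance is
    tunable ground truth.
    """
    rng = cfg.rng()
    qpcr_table, qpcr_truth = gen_qpcr_dataset(cfg, rng)
    effects = qpcr_truth.pop("_patient_effects_arrays")
    ish_table, ish_truth = gen_ish_dataset(
        cfg, rng, effects, qpcr_truth["deepest_sample"]
    )
    images = {}
    if render_images:
        for _, row in ish_table.iterrows():
            roi = row["roi_area_mm2"]
            targets = {
                "iB": row["area_iB"] / roi,
                "wB": row["area_wB"] / roi,
                "pB": row["area_pB"] / roi,
            }
            key = (row["patient_id"], row["sample_id"], row["mirna_id"])
            images[key] = gen_ish_image(targets, size=cfg.image_size, rng=rng)
    return {
        "qpcr_table": qpcr_table,
        "ish_table": ish_table,
        "images": images,
        "truth": {"qpcr": qpcr_truth, "ish": ish_truth},
    }


def simulate_icc_recovery(
    icc_cq: float,
    n_reps: int,
    seed: int,
    n_patients: int = 27,
    k: int = 3,
    total_cq_sd: float = 1.0,
    tech_sd: float = 0.15,
):
    """Vectorized replicate engine for ICC parameter-recovery studies.

    Simulates ``n_reps`` independent studies under the generator's qPCR
    model (patient + sample effects on the Cq scale, triplicate
    technical noise folded into the observable as tech_sd^2/3), analyses
    each on the linear 2^-dCq scale with the one-way ANOVA estimator,
    and returns ``(estimates, true_linear)`` where ``true_linear`` is
    the closed-form population ICC of the linear observable.
    """
    rng = np.random.default_rng(seed)
    sigma_b = total_cq_sd * math.sqrt(icc_cq)
    sigma_w = total_cq_sd * math.sqrt(1.0 - icc_cq)
    b = rng.normal(0.0, sigma_b, size=(n_reps, n_patients, 1))
    e = rng.normal(0.0, sigma_w, size=(n_reps, n_patients, k))
    t = rng.normal(0.0, tech_sd / math.sqrt(3), size=(n_reps, n_patients, k))
    x = 2.0 ** (-(b + e + t))
    group_means = x.mean(axis=2)
    ms_between = k * group_means.var(axis=1, ddof=1)
    ms_within = x.var(axis=2, ddof=1).mean(axis=1)
    estimates = (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)
    return estimates, true_linear_icc(sigma_b, sigma_w, tech_sd)
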