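"""Synthetic paired MRI / tau-PET cohort generator.

Phantoms reproduce the statistical structure the downstream analyses assume:
an ordinal Braak-group latent (0, I/II, III/IV, V/VI) controlling which ROIs
carry tau above baseline, tau-coupled atrophy in the MRI channel, plasma
p-tau217 linear in temporal meta-ROI tau, MMSE anti-correlated with
neocortical tau, APOE4 shifting the stage distribution, per-covariate
missingness, and optional within-subject longitudinal tau accumulation.
They make no claim to anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import Atlas, meta_temp_tau, regional_suvr

COVARIATE_FIELDS = [
    "age", "sex", "education", "marital_status", "race", "height", "weight",
    "systolic_bp", "diastolic_bp", "pulse", "respiratory_rate", "temperature",
    "apoe4_count", "ptau217", "nfl", "gfap", "abeta40", "abeta42",
]

NEVER_MISSING = {"age", "sex"}


@dataclass
class CovariateRecord:
    """One subject's tabular covariates; np.nan marks a missing value."""

    age: float
    sex: float
    education: float
    marital_status: float
    race: float
    height: float
    weight: float
    systolic_bp: float
    diastolic_bp: float
    pulse: float
    respiratory_rate: float
    temperature: float
    apoe4_count: float
    ptau217: float
    nfl: float
    gfap: float
    abeta40: float
    abeta42: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CovariateCoupling:
    """Coefficients tying covariates to the latent disease process."""

    apoe_stage_shift: float = 0.6      # log-odds increment per allele per stage step
    abeta_probs_by_stage: tuple = (0.20, 0.65, 0.90, 0.98)
    abeta_apoe_shift: float = 0.5      # log-odds per APOE4 allele
    ptau_intercept: float = -0.05
    ptau_slope: float = 0.35           # per unit MetaTempTau (SUVR)
    ptau_noise: float = 0.06
    mmse_ceiling: float = 29.5
    mmse_slope_neocortical: float = 9.0  # points per unit neocortical tau excess
    mmse_slope_temporal: float = 2.0     # points per unit meta-temporal tau excess
    mmse_noise: float = 1.0


@dataclass
class LongitudinalDesign:
    n_visits: int = 1
    slope_mean: float = 0.05   # annual SUVR accumulation in affected ROIs
    slope_sd: float = 0.02
    visit_interval: float = 1.0  # years


def _default_missingness() -> dict[str, float]:
    rates = {f: 0.02 for f in COVARIATE_FIELDS}
    for f in ("systolic_bp", "diastolic_bp", "pulse", "respiratory_rate", "temperature"):
        rates[f] = 0.05
    for f in ("ptau217", "nfl", "gfap", "abeta40", "abeta42"):
        rates[f] = 0.30
    rates["apoe4_count"] = 0.05
    for f in NEVER_MISSING:
        rates[f] = 0.0
    return rates


@dataclass
class PhantomParams:
    """Study conditions for the synthetic cohort."""

    stage_probs: tuple = (0.40, 0.25, 0.20, 0.15)  # groups 0, I/II, III/IV, V/VI
    baseline_suvr: float = 1.0
    stage_increments: tuple = (0.9, 0.7, 0.5)      # onset tiers 1-2, 3-4, 5-6
    severity_sd: float = 0.25                      # subject-level increment multiplier spread
    noise_sd: float = 0.08                         # tau voxel noise (SUVR)
    mri_noise_sd: float = 0.05
    atrophy_gain: float = 0.25                     # MRI intensity loss per unit tau excess
    tau_floor: float = 0.05
    covariate_coupling: CovariateCoupling = field(default_factory=CovariateCoupling)
    missingness_rates: dict = field(default_factory=_default_missingness)
    longitudinal: LongitudinalDesign = field(default_factory=LongitudinalDesign)

    def __post_init__(self):
        probs = np.asarray(self.stage_probs, dtype=float)
        if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("stage_probs must be 4 non-negative values summing to 1")
        if any(i < 0 for i in self.stage_increments):
            raise ValueError("tau increments must be >= 0")
        if self.baseline_suvr <= 0:
            raise ValueError("baseline SUVR must be > 0")
        if not all(0.0 <= r <= 1.0 for r in self.missingness_rates.values()):
            raise ValueError("missingness rates must be in [0, 1]")


@dataclass
class SubjectTruth:
    braak_group: int                  # 0..3 for groups 0, I/II, III/IV, V/VI
    regional_tau: dict[int, float]    # noise-free per-ROI mean SUVR
    diagnosis: str                    # CN / MCI / Dem
    abeta_status: int
    mmse: float                       # observed (noisy, clipped) MMSE
    mmse_noisefree: float
    visit_time: float
    meta_temp: float = 0.0


@dataclass
class PhantomSubject:
    subject_id: int
    mri: np.ndarray
    tau: np.ndarray
    covariates: CovariateRecord
    truth: SubjectTruth


# ---------------------------------------------------------------------------


def _onset_tier(stage: int) -> int:
    return (stage - 1) // 2  # 1-2 -> 0, 3-4 -> 1, 5-6 -> 2


def _roi_onsets(atlas: Atlas) -> dict[int, int]:
    return {int(r["id"]): int(r["braak_onset_stage"]) for _, r in atlas.roi_table.iterrows()}


def _draw_latents(atlas: Atlas, params: PhantomParams, rng: np.random.Generator) -> dict:
    c = params.covariate_coupling
    apoe = int(rng.choice(3, p=[0.55, 0.37, 0.08]))

    # APOE shifts the Braak-group distribution toward higher stages
    base = np.asarray(params.stage_probs, dtype=float)
    logits = np.log(np.clip(base, 1e-12, None)) + c.apoe_stage_shift * apoe * np.arange(4)
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    group = int(rng.choice(4, p=probs))

    severity = float(np.clip(rng.normal(1.0, params.severity_sd), 0.5, 1.8))
    slope = float(rng.normal(params.longitudinal.slope_mean, params.longitudinal.slope_sd)) \
        if params.longitudinal.n_visits > 1 else 0.0

    # amyloid positivity: stage-dependent probability with an APOE bump
    p0 = c.abeta_probs_by_stage[group]
    logit = np.log(p0 / (1 - p0)) + c.abeta_apoe_shift * apoe
    abeta = int(rng.random() < 1.0 / (1.0 + np.exp(-logit)))

    return {"apoe": apoe, "group": group, "severity": severity,
            "slope": slope, "abeta": abeta}


def _regional_truth(atlas: Atlas, params: PhantomParams, lat: dict, t: float) -> dict[int, float]:
    onsets = _roi_onsets(atlas)
    out = {}
    for rid, onset in onsets.items():
        affected = onset <= 2 * lat["group"]
        mean = params.baseline_suvr
        if affected:
            mean += lat["severity"] * params.stage_increments[_onset_tier(onset)]
            mean += lat["slope"] * t
        out[rid] = float(mean)
    return out


def _render_fields(atlas: Atlas, params: PhantomParams, regional: dict[int, float],
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (noise-free tau field, tau volume, mri volume)."""
    lab = atlas.label_volume
    lut = np.zeros(max(regional) + 1)
    for rid, m in regional.items():
        lut[rid] = m
    field_ = lut[lab]                      # 0 outside brain
    mask = atlas.brain_mask

    tau = field_ + rng.normal(0.0, params.noise_sd, size=lab.shape) * mask
    tau = np.clip(tau, params.tau_floor, None)

    # tissue template: bright interior with a smooth gradient toward the rim
    p1, p2, p3 = atlas.grid
    center = np.array([(p1 - 1) / 2, (p2 - 1) / 2, (p3 - 1) / 2])
    semi = np.array([0.42 * p1, 0.45 * p2, 0.42 * p3])
    ii = np.indices(atlas.grid).astype(float)
    rho2 = sum(((ii[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    template = (0.8 + 0.4 * np.clip(1.0 - rho2, 0.0, None)) * mask

    excess = np.clip(field_ - params.baseline_suvr, 0.0, None) * mask
    mri = template - params.atrophy_gain * excess + rng.normal(0.0, params.mri_noise_sd, size=lab.shape) * mask
    return field_, tau, np.clip(mri, 0.0, None)


def _draw_covariates(params: PhantomParams, lat: dict, meta_true: float, neo_excess: float,
                     temp_excess: float, rng: np.random.Generator) -> tuple[CovariateRecord, float, float]:
    c = params.covariate_coupling
    sex = float(rng.integers(0, 2))
    height = rng.normal(176, 7) if sex else rng.normal(163, 6)
    weight = rng.normal(82, 12) if sex else rng.normal(68, 11)

    mmse_nf = c.mmse_ceiling - c.mmse_slope_neocortical * neo_excess - c.mmse_slope_temporal * temp_excess
    mmse_nf = float(np.clip(mmse_nf, 0.0, 30.0))
    mmse_obs = float(np.clip(mmse_nf + rng.normal(0.0, c.mmse_noise), 0.0, 30.0))

    rec = CovariateRecord(
        age=float(np.clip(rng.normal(73, 7), 55, 95)),
        sex=sex,
        education=float(np.clip(rng.normal(16.4, 2.6), 8, 22)),
        marital_status=float(rng.choice(4, p=[0.62, 0.18, 0.14, 0.06])),
        race=float(rng.choice(5, p=[0.78, 0.10, 0.06, 0.04, 0.02])),
        height=float(height),
        weight=float(weight),
        systolic_bp=float(rng.normal(132, 16)),
        diastolic_bp=float(rng.normal(74, 10)),
        pulse=float(rng.normal(68, 10)),
        respiratory_rate=float(rng.normal(16, 2)),
        temperature=float(rng.normal(36.7, 0.3)),
        apoe4_count=float(lat["apoe"]),
        ptau217=float(c.ptau_intercept + c.ptau_slope * meta_true + rng.normal(0.0, c.ptau_noise)),
        nfl=float(rng.normal(18 + 6 * lat["group"], 4)),
        gfap=float(rng.normal(140 + 40 * lat["group"], 30)),
        abeta40=float(rng.normal(220, 25)),
        abeta42=float(rng.normal(40 - 8 * lat["abeta"], 4)),
    )
    return rec, mmse_nf, mmse_obs


def _diagnosis(mmse_noisefree: float) -> str:
    if mmse_noisefree >= 27.0:
        return "CN"
    if mmse_noisefree >= 24.0:
        return "MCI"
    return "Dem"


def _make_visit(atlas: Atlas, params: PhantomParams, lat: dict, covs: CovariateRecord | None,
                subject_id: int, t: float, rng: np.random.Generator) -> PhantomSubject:
    regional = _regional_truth(atlas, params, lat, t)
    _, tau, mri = _render_fields(atlas, params, regional, rng)

    sizes = atlas.roi_sizes
    onsets = _roi_onsets(atlas)
    meta_true = meta_temp_tau(regional, atlas)
    neo = [rid for rid, o in onsets.items() if o >= 5]
    temp = sorted(atlas.meta_temp_members)
    neo_excess = float(np.mean([regional[r] for r in neo]) - params.baseline_suvr) if neo else 0.0
    w = np.array([sizes[r] for r in temp], dtype=float)
    temp_excess = float((w * np.array([regional[r] for r in temp])).sum() / w.sum() - params.baseline_suvr)

    if covs is None:
        covs, mmse_nf, mmse_obs = _draw_covariates(params, lat, meta_true, neo_excess, temp_excess, rng)
        covs = _apply_missingness(covs, params.missingness_rates, rng)
    else:  # longitudinal follow-up: identity-stable covariates, refreshed cognition
        c = params.covariate_coupling
        mmse_nf = float(np.clip(c.mmse_ceiling - c.mmse_slope_neocortical * neo_excess
                                - c.mmse_slope_temporal * temp_excess, 0.0, 30.0))
        mmse_obs = float(np.clip(mmse_nf + rng.normal(0.0, c.mmse_noise), 0.0, 30.0))

    truth = SubjectTruth(
        braak_group=lat["group"], regional_tau=regional, diagnosis=_diagnosis(mmse_nf),
        abeta_status=lat["abeta"], mmse=mmse_obs, mmse_noisefree=mmse_nf,
        visit_time=t, meta_temp=meta_true,
    )
    return PhantomSubject(subject_id=subject_id, mri=mri, tau=tau, covariates=covs, truth=truth)


def _apply_missingness(rec: CovariateRecord, rates: dict[str, float],
                       rng: np.random.Generator) -> CovariateRecord:
    d = rec.to_dict()
    for f in COVARIATE_FIELDS:
        if f in NEVER_MISSING:
            continue
        if rng.random() < rates.get(f, 0.0):
            d[f] = np.nan
    return CovariateRecord(**d)


def simulate_subject(atlas: Atlas, params: PhantomParams, seed: int,
                     subject_id: int = 0) -> PhantomSubject:
    """Simulate a single baseline visit; deterministic in (atlas, params, seed)."""
    rng = np.random.default_rng(seed)
    lat = _draw_latents(atlas, params, rng)
    return _make_visit(atlas, params, lat, None, subject_id, 0.0, rng)


def simulate_cohort(atlas: Atlas, params: PhantomParams, n: int, seed: int) -> list[PhantomSubject]:
    """Simulate n independent subjects (flat list; longitudinal visits share subject_id).

    With ``params.longitudinal.n_visits > 1`` each subject contributes one
    PhantomSubject per visit at times 0, dt, 2*dt, ..., with affected-ROI tau
    means incremented by the subject's annual slope times visit time.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out: list[PhantomSubject] = []
    children = np.random.SeedSequence(seed).spawn(n)
    for sid, child in enumerate(children):
        rng = np.random.default_rng(child)
        lat = _draw_latents(atlas, params, rng)
        first = _make_visit(atlas, params, lat, None, sid, 0.0, rng)
        out.append(first)
        for k in range(1, params.longitudinal.n_visits):
            t = k * params.longitudinal.visit_interval
            out.append(_make_visit(atlas, params, lat, first.covariates, sid, t, rng))
    return out


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[PhantomSubject], atlas: Atlas, outdir: str | Path):
    """Per-visit NIfTI pairs plus one covariates CSV and one truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas.save(outdir / "atlas_labels.nii.gz", outdir / "atlas_rois.csv")
    cov_rows, truth_rows = [], []
    visit_counter: dict[int, int] = {}
    for s in cohort:
        v = visit_counter.get(s.subject_id, 0)
        visit_counter[s.subject_id] = v + 1
        stem = f"sub-{s.subject_id:04d}_v{v:02d}"
        nib.save(nib.Nifti1Image(s.mri.astype(np.float32), np.eye(4)), str(outdir / f"{stem}_mri.nii.gz"))
        nib.save(nib.Nifti1Image(s.tau.astype(np.float32), np.eye(4)), str(outdir / f"{stem}_tau.nii.gz"))
        cov_rows.append({"subject_id": s.subject_id, "visit_index": v,
                         "visit_time": s.truth.visit_time, **s.covariates.to_dict()})
        tr = {"subject_id": s.subject_id, "visit_index": v, "visit_time": s.truth.visit_time,
              "braak_group": s.truth.braak_group, "diagnosis": s.truth.diagnosis,
              "abeta_status": s.truth.abeta_status, "mmse": s.truth.mmse,
              "mmse_noisefree": s.truth.mmse_noisefree, "meta_temp": s.truth.meta_temp}
        tr.update({f"roi_{rid}": m for rid, m in s.truth.regional_tau.items()})
        truth_rows.append(tr)
    pd.DataFrame(cov_rows).to_csv(outdir / "covariates.csv", index=False, na_rep="NA")
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)


def read_cohort(indir: str | Path) -> tuple[Atlas, list[PhantomSubject]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    atlas = Atlas.load(indir / "atlas_labels.nii.gz", indir / "atlas_rois.csv")
    covs = pd.read_csv(indir / "covariates.csv", na_values=["", "NA"])
    truth = pd.read_csv(indir / "truth.csv")
    roi_cols = [c for c in truth.columns if c.startswith("roi_")]
    out = []
    for (crow, trow) in zip(covs.itertuples(index=False), truth.itertuples(index=False)):
        c = crow._asdict()
        t = trow._asdict()
        sid, v = int(c.pop("subject_id")), int(c.pop("visit_index"))
        c.pop("visit_time")
        stem = f"sub-{sid:04d}_v{v:02d}"
        mri = np.asarray(nib.load(str(indir / f"{stem}_mri.nii.gz")).dataobj)
        tau = np.asarray(nib.load(str(indir / f"{stem}_tau.nii.gz")).dataobj)
        regional = {int(col[4:]): float(t[col]) for col in roi_cols}
        tr = SubjectTruth(braak_group=int(t["braak_group"]), regional_tau=regional,
                          diagnosis=str(t["diagnosis"]), abeta_status=int(t["abeta_status"]),
                          mmse=float(t["mmse"]), mmse_noisefree=float(t["mmse_noisefree"]),
                          visit_time=float(t["visit_time"]), meta_temp=float(t["meta_temp"]))
        out.append(PhantomSubject(subject_id=sid, mri=mri.astype(float),
                                  tau=tau.astype(float),
                                  covariates=CovariateRecord(**c), truth=tr))
    return atlas, out
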