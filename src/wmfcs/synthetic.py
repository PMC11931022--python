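"""Synthetic cohorts with the statistical structure the FCS analysis assumes.

No patient data ship with this package.  This module generates complete
stand-in cohorts — subject metadata, rigid-motion traces, region time series,
optional voxel volumes and radiation-dose variables — whose summary behaviour
is matched to the published group statistics (two groups of 47 and 64
subjects, 164 regions, 240 frames at TR 2.4 s, group FCS reductions on the
Fisher-z scale, and prescribed dose partial correlations).  All distributional
choices are stand-ins for testing the pipeline, not a model of the study's
data-generating truth.

Generative model
----------------
Region signals are zero-mean Gaussian with a stationary target correlation
matrix built block-wise from three baseline correlations (WM-WM, GM-WM,
GM-GM).  The baselines are hierarchical — within-tissue correlation (0.35)
above cross-tissue correlation (0.28) — both because resting-state FC shows
stronger within-tissue coupling and because the geometry requires it: with a
single global correlation level, decoupling a region from one tissue family
while preserving its coupling to the other leaves the positive-definite
cone.  Group effects subtract a configured amount from the Fisher-z values
of the affected region's family edges, so the region's population
family-mean z drops by exactly the configured amount.  Between-subject
heterogeneity adds a subject-level offset to every off-diagonal z, drawn
from a Gaussian (SD ``subject_z_sd``) winsorised at two SDs so every
subject's matrix stays positive definite; together with
correlation-estimation noise over 235 usable frames this yields a
subject-level FCS standard deviation of about 0.105 — the scale of the
published group SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import subject_fcs
from .parcellation import ParcellationScheme, generic_scheme
from .preprocess import RegionTimeSeries
from .qc import MotionTrace, compute_fd

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "SyntheticCohort",
    "SimulatedFCS",
    "build_target_correlation",
    "simulate_motion",
    "simulate_dose",
    "simulate_cohort",
    "simulate_fcs_cohort",
    "render_voxel_data",
    "records_to_frame",
    "write_cohort",
]

#: group FCS reductions (Fisher-z scale) matched to the published group
#: summary means (pre minus post), used as the default effect map
DEFAULT_EFFECT_MAP: tuple[tuple[str, float], ...] = (
    ("lh_Superior_cerebellar_peduncle", 0.06),
    ("rh_Anterior_limb_of_internal_capsule", 0.06),
    ("rh_Posterior_thalamic_radiation", 0.08),
    ("lh_Posterior_thalamic_radiation", 0.08),
    ("lh_Tapetum", 0.06),
    ("rh_Caudate", 0.07),
    ("lh_Vis_4", 0.07),
    ("lh_Vis_5", 0.06),
    ("lh_Vis_8", 0.08),
    ("rh_Vis_4", 0.06),
    ("rh_Default_PFCv_2", 0.08),
)

#: default dose targets: (GM region, dose variable, target partial r),
#: matched to the published dose associations
DEFAULT_DOSE_TARGETS: tuple[tuple[str, str, float], ...] = (
    ("lh_Vis_8", "mdrt_brainstem", -0.35),
    ("lh_Vis_8", "mdrt_left_temporal", -0.46),
)


@dataclass
class SubjectRecord:
    """One subject's metadata row."""

    subject_id: str
    group: str  # "pre" or "post" (radiation therapy)
    age: float
    sex: str  # "male" or "female"
    euler_number: int
    mean_fd: float | None = None
    mdrt_brainstem: float | None = None
    mdrt_left_temporal: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("pre", "post"):
            raise ValueError(f"group must be 'pre' or 'post', got {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.mean_fd is not None and self.mean_fd < 0:
            raise ValueError("mean FD must be non-negative")


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Defaults reproduce the study conditions: 47 pre-RT and 64 post-RT
    subjects, 164 regions (100 cortical + 14 subcortical + 50 WM), 240 frames
    at TR 2.4 s, Table-matched group effects on the Fisher-z scale, and dose
    variables with the published partial correlations for 37 post-RT
    subjects.
    """

    n_pre: int = 47
    n_post: int = 64
    n_frames: int = 240
    tr: float = 2.4
    n_cortical: int = 100
    n_subcortical: int = 14
    n_wm: int = 50
    baseline_wm_corr: float = 0.35
    baseline_gw_corr: float = 0.28
    baseline_gm_corr: float | None = None  # defaults to baseline_wm_corr
    effect_map: tuple[tuple[str, float], ...] = DEFAULT_EFFECT_MAP
    dose_targets: tuple[tuple[str, str, float], ...] = DEFAULT_DOSE_TARGETS
    motion_spike_rate: float = 0.02
    subject_z_sd: float = 0.103
    motion_subject_sd: float = 0.4
    n_dose: int = 37
    # group demographics (years; male fraction per group)
    age_mean_pre: float = 46.70
    age_sd_pre: float = 9.55
    age_mean_post: float = 43.39
    age_sd_post: float = 9.93
    male_frac_pre: float = 36 / 47
    male_frac_post: float = 47 / 64
    euler_mean: float = -45.0
    euler_sd: float = 15.0
    # dose scales in Gray
    dose_means: Mapping[str, float] = field(
        default_factory=lambda: {"mdrt_brainstem": 62.0, "mdrt_left_temporal": 66.0}
    )
    dose_sds: Mapping[str, float] = field(
        default_factory=lambda: {"mdrt_brainstem": 6.0, "mdrt_left_temporal": 7.0}
    )
    seed: int = 0

    @property
    def n_regions(self) -> int:
        return self.n_cortical + self.n_subcortical + self.n_wm

    def validate(self) -> None:
        if self.n_pre + self.n_post <= 5 + 2:  # covariates (group/age/sex/FD + 1) + 2
            raise ValueError("cohort too small for the covariate model")
        if min(self.n_pre, self.n_post, self.n_frames) < 1:
            raise ValueError("counts must be positive")
        for name, value in (
            ("baseline_wm_corr", self.baseline_wm_corr),
            ("baseline_gw_corr", self.baseline_gw_corr),
        ):
            if not 0 <= value < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {value}")
        if self.baseline_gm_corr is not None and not 0 <= self.baseline_gm_corr < 1:
            raise ValueError("baseline_gm_corr must lie in [0, 1)")
        if not 0 <= self.motion_spike_rate < 1:
            raise ValueError("motion_spike_rate must lie in [0, 1)")
        for _, _, r in self.dose_targets:
            if not -1 < r < 1:
                raise ValueError("dose target partial correlations must lie in (-1, 1)")
        dose_vars = [v for _, v, _ in self.dose_targets]
        if len(set(dose_vars)) != len(dose_vars):
            raise ValueError(
                "each dose variable may target a single region; shared dose "
                "variables cannot satisfy two exact partial correlations"
            )

    def scheme(self) -> ParcellationScheme:
        return generic_scheme(self.n_cortical, self.n_subcortical, self.n_wm)


def _target_z(
    scheme: ParcellationScheme,
    baseline_wm_corr: float,
    baseline_gw_corr: float,
    effect_map: Sequence[tuple[str, float]],
    group: str,
    baseline_gm_corr: float | None = None,
) -> np.ndarray:
    """Off-diagonal Fisher-z target matrix (diagonal zero)."""
    if group not in ("pre", "post"):
        raise ValueError("group must be 'pre' or 'post'")
    n = len(scheme)
    wm = scheme.wm_indices
    gm = scheme.gm_indices
    if baseline_gm_corr is None:
        baseline_gm_corr = baseline_wm_corr
    z = np.zeros((n, n))
    z[np.ix_(gm, gm)] = np.arctanh(baseline_gm_corr)
    z[np.ix_(wm, wm)] = np.arctanh(baseline_wm_corr)
    z[np.ix_(gm, wm)] = np.arctanh(baseline_gw_corr)
    z[np.ix_(wm, gm)] = np.arctanh(baseline_gw_corr)
    np.fill_diagonal(z, 0.0)

    if group == "post" and effect_map:
        idx = {}
        for name, dz in effect_map:
            idx[scheme.index_of(name)] = float(dz)  # KeyError -> unknown region
        wm_set = set(wm.tolist())
        wm_affected = sorted(i for i in idx if i in wm_set)
        gm_affected = sorted(i for i in idx if i not in wm_set)
        # GM effects: each GM region's edges to WM are disjoint across GM
        # regions, so the family mean drops by exactly dz per region.
        for g in gm_affected:
            z[g, wm] -= idx[g]
            z[wm, g] -= idx[g]
        # WM effects interact (an edge between two affected WM regions belongs
        # to both families).  Decompose the per-edge reduction as a_k + a_j
        # and solve exactly so each affected region's family mean drops by its
        # configured dz:  (m-1) a_k + sum_{j in A, j != k} a_j = (m-1) dz_k
        # with m = |WM family| and a_j = 0 outside the affected set A.
        if wm_affected:
            m = wm.size
            k = len(wm_affected)
            A = (m - 2) * np.eye(k) + np.ones((k, k))
            dz_vec = np.array([idx[i] for i in wm_affected])
            a = np.linalg.solve(A, (m - 1) * dz_vec)
            a_full = np.zeros(n)
            a_full[wm_affected] = a
            a_wm = a_full[wm]
            delta = a_wm[:, None] + a_wm[None, :]
            z[np.ix_(wm, wm)] -= delta
            np.fill_diagonal(z, 0.0)
    return z


#: minimum eigenvalue a target correlation matrix must keep: below this the
#: matrix is effectively degenerate for simulation (subject-level offsets and
#: Cholesky factorisation need headroom inside the positive-definite cone)
PD_FLOOR = 0.01


def build_target_correlation(
    scheme: ParcellationScheme,
    baseline_wm_corr: float,
    baseline_gw_corr: float,
    effect_map: Sequence[tuple[str, float]] = (),
    group: str = "pre",
    baseline_gm_corr: float | None = None,
    pd_floor: float = PD_FLOOR,
) -> np.ndarray:
    """Target correlation matrix for one group (symmetric, unit diagonal, PD).

    Baselines are correlations in [0, 1); effects are Fisher-z reductions
    applied to the post group's affected-family edges.  The result is checked
    for positive definiteness with an eigenvalue floor ``pd_floor``; failure
    raises with the offending construction named.
    """
    for name, value in (
        ("baseline_wm_corr", baseline_wm_corr),
        ("baseline_gw_corr", baseline_gw_corr),
    ):
        if not 0 <= value < 1:
            raise ValueError(f"{name} must lie in [0, 1), got {value}")
    z = _target_z(
        scheme, baseline_wm_corr, baseline_gw_corr, effect_map, group, baseline_gm_corr
    )
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    _check_pd(r, scheme, effect_map, group, pd_floor)
    return r


def _check_pd(
    r: np.ndarray,
    scheme: ParcellationScheme,
    effect_map: Sequence[tuple[str, float]],
    group: str,
    pd_floor: float = PD_FLOOR,
) -> None:
    min_eig = float(np.linalg.eigvalsh(r)[0])
    if min_eig < pd_floor:
        affected = ", ".join(name for name, _ in effect_map) or "none"
        raise ValueError(
            f"target correlation for group '{group}' is degenerate "
            f"(smallest eigenvalue {min_eig:.2e} < {pd_floor:g}; "
            f"WM/GM baseline blocks with effect regions: {affected}); "
            "reduce the baselines or the configured effects"
        )


def simulate_motion(
    n_frames: int,
    spike_rate: float,
    rng: np.random.Generator | int,
    trans_sd: float = 0.0292,
    rot_sd: float = 0.000584,
    scale: float = 1.0,
    spike_min: float = 0.7,
    spike_max: float = 1.5,
) -> MotionTrace:
    """Random-walk rigid motion with censorable spikes.

    Baseline jitter is a Gaussian random walk whose increments produce a mean
    FD of about 0.14 mm — well below the 0.5 mm censoring threshold.  With
    probability ``spike_rate`` a frame (never the first) receives a persistent
    offset of at least ``spike_min`` mm on one translation axis, guaranteeing
    FD > 0.5 mm at exactly that frame; the spiked frame indices are stored on
    the returned trace as a test oracle.
    """
    if not 0 <= spike_rate < 1:
        raise ValueError("spike rate must lie in [0, 1)")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    sds = np.array([trans_sd] * 3 + [rot_sd] * 3) * scale
    steps = rng.standard_normal((n_frames, 6)) * sds
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    spikes = (
        np.flatnonzero(rng.random(n_frames - 1) < spike_rate) + 1
        if n_frames > 1
        else np.array([], dtype=int)
    )
    for t in spikes:
        axis = rng.integers(0, 3)
        jump = rng.uniform(spike_min, spike_max) * rng.choice([-1.0, 1.0])
        params[t:, axis] += jump
    return MotionTrace(params, spike_frames=spikes)


def simulate_dose(
    fcs_values: np.ndarray,
    covariates: np.ndarray,
    target_partial_r: float,
    rng: np.random.Generator | int,
    dose_mean: float = 62.0,
    dose_sd: float = 6.0,
) -> np.ndarray:
    """Dose values (Gray) with a prescribed partial correlation to FCS.

    The dose is an affine combination of the covariate-residualised FCS and
    covariate-residualised independent noise, weighted rho and sqrt(1-rho^2),
    so the population partial correlation given the covariates equals
    ``target_partial_r``; the sample estimate fluctuates around it with
    SD ~ (1 - rho^2)/sqrt(n).
    """
    if not -1 < target_partial_r < 1:
        raise ValueError("target partial correlation must lie in (-1, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    x = np.asarray(fcs_values, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, g = len(x), C.shape[1]
    if n < g + 3:
        raise ValueError(f"need at least {g + 3} subjects for {g} covariates")
    X = np.column_stack([np.ones(n), C])
    proj = lambda v: v - X @ np.linalg.lstsq(X, v, rcond=None)[0]
    xr = proj(x)
    if xr.std() <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError("FCS is constant after residualisation; partial "
                         "correlation undefined")
    er = proj(rng.standard_normal(n))
    zx = xr / xr.std()
    ze = er / er.std()
    rho = target_partial_r
    core = rho * zx + np.sqrt(1 - rho**2) * ze
    return dose_mean + dose_sd * core


@dataclass
class SyntheticCohort:
    """A full simulated cohort: metadata, motion, region series, scheme."""

    records: list[SubjectRecord]
    motion: dict[str, MotionTrace]
    series: dict[str, RegionTimeSeries]
    scheme: ParcellationScheme
    config: CohortConfig


def _subject_offset(
    rng: np.random.Generator, sd: float, size: int | None = None
) -> float | np.ndarray:
    """Subject-level connectivity offset: N(0, sd) winsorised at 2 sd.

    The winsorisation keeps every subject's correlation matrix inside the
    positive-definite cone (a large negative common offset would push all
    cross-region correlations uniformly negative, which is infeasible at
    n = 164 regions).
    """
    return np.clip(rng.normal(0.0, sd, size=size), -2 * sd, 2 * sd)


def _draw_subject_series(
    z_base: np.ndarray,
    u: float,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject's regions x frames Gaussian draw at z-offset ``u``."""
    r = np.tanh(z_base + u)
    np.fill_diagonal(r, 1.0)
    L = np.linalg.cholesky(r)
    return (rng.standard_normal((n_frames, z_base.shape[0])) @ L.T).T


def _demographics(
    config: CohortConfig, rng: np.random.Generator
) -> list[SubjectRecord]:
    records = []
    specs = [
        ("pre", config.n_pre, config.age_mean_pre, config.age_sd_pre, config.male_frac_pre),
        ("post", config.n_post, config.age_mean_post, config.age_sd_post, config.male_frac_post),
    ]
    i = 0
    for group, n, age_mean, age_sd, male_frac in specs:
        for _ in range(n):
            i += 1
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{i:04d}",
                    group=group,
                    age=float(np.clip(rng.normal(age_mean, age_sd), 18, 80)),
                    sex="male" if rng.random() < male_frac else "female",
                    euler_number=int(round(rng.normal(config.euler_mean, config.euler_sd))),
                )
            )
    return records


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a complete cohort, deterministic given ``config.seed``.

    Returns subject records, per-subject motion traces and raw region time
    series (before any cleaning), plus the parcellation scheme.  Dose
    variables are attached to a random subset of post-group subjects and are
    constructed against each target region's GW-FCS computed from the raw
    series, with age, sex and (motion-derived) mean FD as covariates.
    """
    config = config or CohortConfig()
    config.validate()
    scheme = config.scheme()
    z_pre = _target_z(
        scheme, config.baseline_wm_corr, config.baseline_gw_corr,
        config.effect_map, "pre", config.baseline_gm_corr,
    )
    z_post = _target_z(
        scheme, config.baseline_wm_corr, config.baseline_gw_corr,
        config.effect_map, "post", config.baseline_gm_corr,
    )
    # fail fast on a non-PD construction before drawing subjects
    build_target_correlation(
        scheme, config.baseline_wm_corr, config.baseline_gw_corr,
        config.effect_map, "post", config.baseline_gm_corr,
    )
    rng = np.random.default_rng(config.seed)
    records = _demographics(config, rng)
    motion: dict[str, MotionTrace] = {}
    series: dict[str, RegionTimeSeries] = {}
    for rec in records:
        z_base = z_pre if rec.group == "pre" else z_post
        u = _subject_offset(rng, config.subject_z_sd)
        data = _draw_subject_series(z_base, u, config.n_frames, rng)
        series[rec.subject_id] = RegionTimeSeries(data, scheme.ids, config.tr)
        scale = float(np.exp(rng.normal(0.0, config.motion_subject_sd)))
        motion[rec.subject_id] = simulate_motion(
            config.n_frames, config.motion_spike_rate, rng, scale=scale
        )
    _attach_doses(config, scheme, records, motion, series, rng)
    return SyntheticCohort(records, motion, series, scheme, config)


def _attach_doses(
    config: CohortConfig,
    scheme: ParcellationScheme,
    records: list[SubjectRecord],
    motion: Mapping[str, MotionTrace],
    series: Mapping[str, RegionTimeSeries],
    rng: np.random.Generator,
) -> None:
    if not config.dose_targets:
        return
    post = [r for r in records if r.group == "post"]
    n_dose = min(config.n_dose, len(post))
    dosed = list(rng.choice(len(post), size=n_dose, replace=False))
    dosed_recs = [post[i] for i in sorted(dosed)]
    if n_dose < 6:
        warnings.warn("too few dosed subjects; skipping dose simulation")
        return
    cov = np.column_stack(
        [
            [r.age for r in dosed_recs],
            [1.0 if r.sex == "male" else 0.0 for r in dosed_recs],
            [compute_fd(motion[r.subject_id]).mean_fd for r in dosed_recs],
        ]
    )
    fcs_cache: dict[str, pd.DataFrame] = {}
    for region, dose_var, rho in config.dose_targets:
        vals = []
        for r in dosed_recs:
            if r.subject_id not in fcs_cache:
                fcs_cache[r.subject_id] = subject_fcs(
                    series[r.subject_id], scheme
                ).set_index("region")
            vals.append(float(fcs_cache[r.subject_id].loc[region, "value"]))
        doses = simulate_dose(
            np.array(vals), cov, rho, rng,
            dose_mean=config.dose_means.get(dose_var, 62.0),
            dose_sd=config.dose_sds.get(dose_var, 6.0),
        )
        for r, d in zip(dosed_recs, doses):
            setattr(r, dose_var, float(d))


@dataclass
class SimulatedFCS:
    """Subject-level FCS drawn directly from the generative model.

    ``ww`` is subjects x n_wm and ``gw`` subjects x n_gm, with subjects
    ordered as in ``records``.  This is the fast region-level path used for
    calibration and recovery studies: series are simulated and correlated but
    motion and voxel rendering are skipped.
    """

    records: pd.DataFrame
    ww: np.ndarray
    gw: np.ndarray
    scheme: ParcellationScheme


def simulate_fcs_cohort(
    config: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_frames: int | None = None,
    chunk: int = 128,
) -> SimulatedFCS:
    """Draw per-subject WW/GW-FCS values from the generative model.

    Simulates each subject's multivariate-normal region series (with the
    subject-level z offset), computes the Fisher-z correlation matrix and the
    two family means.  ``n_frames`` defaults to the config's frame count
    minus the five dropped volumes, matching what the cleaning pipeline
    analyses.
    """
    config = config or CohortConfig()
    config.validate()
    scheme = config.scheme()
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    F = n_frames if n_frames is not None else max(config.n_frames - 5, 8)
    wm = scheme.wm_indices
    gm = scheme.gm_indices
    n = len(scheme)
    off = ~np.eye(n, dtype=bool)
    ww_rows, gw_rows = [], []
    rec_rows = []
    for group, n_sub in (("pre", config.n_pre), ("post", config.n_post)):
        z_base = _target_z(
            scheme, config.baseline_wm_corr, config.baseline_gw_corr,
            config.effect_map, group, config.baseline_gm_corr,
        )
        done = 0
        while done < n_sub:
            c = min(chunk, n_sub - done)
            u = _subject_offset(rng, config.subject_z_sd, size=c)
            Z = z_base[None, :, :] + u[:, None, None] * off
            R = np.tanh(Z)
            R[:, np.arange(n), np.arange(n)] = 1.0
            try:
                L = np.linalg.cholesky(R)
            except np.linalg.LinAlgError:
                raise ValueError(
                    "subject-level correlation matrix not positive definite; "
                    "reduce subject_z_sd or the baselines"
                ) from None
            E = rng.standard_normal((c, F, n))
            Y = E @ L.transpose(0, 2, 1)
            Y -= Y.mean(axis=1, keepdims=True)
            Y /= np.linalg.norm(Y, axis=1, keepdims=True)
            C = Y.transpose(0, 2, 1) @ Y
            zhat = np.arctanh(np.clip(C, -(1 - 1e-7), 1 - 1e-7))
            zhat[:, np.arange(n), np.arange(n)] = 0.0
            ww_block = zhat[:, wm[:, None], wm[None, :]]
            ww_rows.append(ww_block.sum(axis=2) / (wm.size - 1))
            gw_block = zhat[:, gm[:, None], wm[None, :]]
            gw_rows.append(gw_block.mean(axis=2))
            done += c
        for _ in range(n_sub):
            rec_rows.append(group)
    rng_demo = np.random.default_rng(rng.integers(2**31))
    records = _demographics(config, rng_demo)
    rec = records_to_frame(records)
    # mean FD stand-in: lognormal around the typical 0.15 mm
    rec["mean_fd"] = np.exp(rng_demo.normal(np.log(0.15), 0.35, size=len(rec)))
    assert list(rec["group"]) == rec_rows
    return SimulatedFCS(rec, np.vstack(ww_rows), np.vstack(gw_rows), scheme)


def render_voxel_data(
    region_ts: RegionTimeSeries,
    scheme: ParcellationScheme,
    grid_shape: tuple[int, int, int],
    voxel_noise_sd: float = 0.0,
    rng: np.random.Generator | int = 0,
    voxel_size: float = 3.0,
) -> tuple[nib.Nifti1Image, nib.Nifti1Image]:
    """Render region series onto a voxel grid as 4D BOLD plus labels.

    Voxels are assigned to regions in equal contiguous blocks (every region
    gets at least one); each voxel's series is its region's series plus
    independent Gaussian noise.  BOLD and label volumes share grid, affine
    and orientation.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = len(scheme)
    if region_ts.n_regions != n:
        raise ValueError("time series rows do not match scheme size")
    V = int(np.prod(grid_shape))
    if V < n:
        raise ValueError(
            f"grid of {V} voxels cannot host {n} regions (needs >= 1 voxel each)"
        )
    per = V // n
    labels = np.zeros(V, dtype=np.int32)
    for i in range(n):
        labels[i * per : (i + 1) * per] = i + 1
    T = region_ts.n_frames
    bold = np.zeros((V, T))
    assigned = labels > 0
    bold[assigned] = region_ts.data[labels[assigned] - 1]
    if voxel_noise_sd > 0:
        bold[assigned] += rng.normal(0.0, voxel_noise_sd, size=(assigned.sum(), T))
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    bold_img = nib.Nifti1Image(bold.reshape(*grid_shape, T), affine)
    bold_img.header.set_zooms((voxel_size,) * 3 + (region_ts.tr,))
    label_img = nib.Nifti1Image(labels.reshape(grid_shape), affine)
    return bold_img, label_img


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject records as a participants table (None becomes NaN)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "euler": [r.euler_number for r in records],
            "mean_fd": [np.nan if r.mean_fd is None else r.mean_fd for r in records],
            "mdrt_brainstem": [
                np.nan if r.mdrt_brainstem is None else r.mdrt_brainstem for r in records
            ],
            "mdrt_left_temporal": [
                np.nan if r.mdrt_left_temporal is None else r.mdrt_left_temporal
                for r in records
            ],
        }
    )


def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    voxel_grid: tuple[int, int, int] | None = None,
    voxel_noise_sd: float = 0.0,
) -> Path:
    """Write a cohort to disk: participants and scheme TSVs, per-subject
    motion TSVs and time-series TSVs (NIfTI volumes only when ``voxel_grid``
    is given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(cohort.records).to_csv(
        out / "participants.tsv", sep="\t", index=False
    )
    cohort.scheme.to_tsv(out / "scheme.tsv")
    motion_dir = out / "motion"
    ts_dir = out / "timeseries"
    motion_dir.mkdir(exist_ok=True)
    ts_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(cohort.config.seed + 1)
    for rec in cohort.records:
        sid = rec.subject_id
        cohort.motion[sid].to_tsv(motion_dir / f"{sid}_motion.tsv")
        cohort.series[sid].to_tsv(ts_dir / f"{sid}_ts.tsv")
        if voxel_grid is not None:
            bold, labels = render_voxel_data(
                cohort.series[sid], cohort.scheme, voxel_grid, voxel_noise_sd, rng
            )
            nib.save(bold, out / f"{sid}_bold.nii.gz")
            if not (out / "labels.nii.gz").exists():
                nib.save(labels, out / "labels.nii.gz")
    return out
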