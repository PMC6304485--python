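"""Synthetic rat cohort generator for a radiation-induced liver-fibrosis study.

Emulates the statistical structure of a longitudinal irradiation experiment:
30 rats imaged at baseline; the right liver lobe irradiated; follow-up MRI of
8, 8 and 7 surviving rats at one, two and three months; METAVIR fibrosis
staging of the irradiated lobe (all one-month rats F0, all two-month rats F1,
the three-month rats split 5 F2 : 2 F1, i.e. stage counts 8/10/5); the
shielded left lobe of every rat serves as its own control.

Per-lobe ground-truth parameters (D*, D, f, R2*, plus relative T1/T2 signal
ratios) are drawn from stage- and group-wise normal distributions whose means
and SDs are the module defaults below, truncated at physical bounds.  Left
and right lobes of one rat are coupled through a Gaussian copula with a
configurable rank correlation (default 0.3) reflecting shared physiology.

Two downstream modes exist: a fast *tabular* mode in which the ROI
measurement equals the ground-truth draw (plus optional measurement noise),
and an *imaging* mode that renders per-lobe voxel phantoms through the
forward models with Rician noise for end-to-end map fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import warnings
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .models import (
    AcquisitionProtocol,
    IvimParameters,
    RelaxometryParameters,
    SignalCurve,
    add_rician_noise,
    ivim_signal,
    r2star_signal,
)

__all__ = [
    "StageDistributionTable",
    "CohortConfig",
    "LobeTruth",
    "RatRecord",
    "Cohort",
    "STAGES",
    "TIMEPOINTS",
    "sample_rat_parameters",
    "generate_cohort",
    "tabular_mode",
    "render_rat_phantom",
]

STAGES = ("control", "F0", "F1", "F2")
TIMEPOINTS = ("baseline", "1m", "2m", "3m")
PARAMS = ("D_star", "D", "f", "R2_star")

# Stage-wise (mean, SD) on the conventional reporting scales:
# D*, D in 1e-3 mm^2/s, f as a fraction, R2* in Hz.
DEFAULT_STAGE_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "control": {"D_star": (81.2, 34.8), "D": (0.760, 0.133), "f": (0.276, 0.070), "R2_star": (38.42, 5.69)},
    "F0":      {"D_star": (85.4, 39.2), "D": (0.660, 0.103), "f": (0.264, 0.053), "R2_star": (50.75, 6.12)},
    "F1":      {"D_star": (85.2, 41.0), "D": (0.637, 0.108), "f": (0.298, 0.094), "R2_star": (58.73, 6.40)},
    "F2":      {"D_star": (84.4, 37.1), "D": (0.581, 0.121), "f": (0.241, 0.077), "R2_star": (64.34, 5.87)},
}

# Baseline (pre-irradiation) right-lobe distributions by time-point cohort.
DEFAULT_BASELINE_RIGHT: dict[str, tuple[float, float]] = {
    "D_star": (80.3, 75.9), "D": (0.684, 0.174), "f": (0.275, 0.079), "R2_star": (36.43, 7.64),
}

# Left-lobe (shielded control) distributions per follow-up time point.
DEFAULT_LEFT_BY_TIMEPOINT: dict[str, dict[str, tuple[float, float]]] = {
    "baseline": {"D_star": (77.8, 27.4), "D": (0.719, 0.127), "f": (0.269, 0.058), "R2_star": (37.77, 4.90)},
    "1m":       {"D_star": (78.2, 33.4), "D": (0.704, 0.153), "f": (0.279, 0.081), "R2_star": (37.10, 5.25)},
    "2m":       {"D_star": (79.0, 36.9), "D": (0.737, 0.125), "f": (0.270, 0.088), "R2_star": (37.64, 6.11)},
    "3m":       {"D_star": (84.6, 36.4), "D": (0.749, 0.182), "f": (0.283, 0.079), "R2_star": (38.24, 4.92)},
}

# Relative T1/T2 liver-to-muscle signal ratios, (mean, SD) per time point and lobe.
DEFAULT_RELATIVE_SIGNAL: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "T1": {
        "right": {"baseline": (1.38, 0.07), "1m": (1.33, 0.07), "2m": (1.27, 0.12), "3m": (1.43, 0.13)},
        "left":  {"baseline": (1.38, 0.07), "1m": (1.24, 0.12), "2m": (1.29, 0.12), "3m": (1.40, 0.16)},
    },
    "T2": {
        "right": {"baseline": (1.04, 0.20), "1m": (1.10, 0.23), "2m": (0.96, 0.03), "3m": (1.22, 0.08)},
        "left":  {"baseline": (1.04, 0.17), "1m": (1.12, 0.17), "2m": (1.01, 0.07), "3m": (1.23, 0.13)},
    },
}

# Truncation bounds on the reporting scales: rates/diffusivities non-negative,
# the perfusion fraction in [0, 1].  D* additionally carries a physiological
# floor of 20 (1e-3 mm^2/s): pseudo-diffusion must stay well separated from
# tissue diffusion (D ~ 0.7) for the biexponential compartments to be
# meaningful — below that floor the perfusion term no longer decays out by
# b = 200 s/mm^2 and f is unidentifiable for any segmented estimator.
_BOUNDS = {"D_star": (20.0, np.inf), "D": (0.0, np.inf), "f": (0.0, 1.0), "R2_star": (0.0, np.inf)}


@dataclass(frozen=True)
class StageDistributionTable:
    """Stage-wise normal (mean, SD) of each parameter on the reporting scales."""

    rows: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_STAGE_TABLE.items()}
    )

    def __post_init__(self) -> None:
        for stage, row in self.rows.items():
            for p, (mean, sd) in row.items():
                if sd <= 0:
                    raise ValueError(f"SD must be positive ({stage}/{p})")
                if p == "f" and not 0 < mean < 1:
                    raise ValueError("perfusion-fraction mean must lie in (0, 1)")

    def mean_sd(self, stage: str, param: str) -> tuple[float, float]:
        if stage not in self.rows:
            raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(self.rows)}")
        return self.rows[stage][param]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Group sizes default to the study design: 30 rats at baseline, 8/8/7
    survivors at one/two/three months, stage mapping 1m -> F0, 2m -> F1,
    3m -> 5 F2 + 2 F1.  ``snr`` is the b=0 / TE=0 signal-to-noise ratio of
    rendered phantoms; ``lobe_correlation`` the within-rat left-right copula
    correlation; ``measurement_noise_sd`` an additive relative ROI-measurement
    error in tabular mode (0 = measurements equal ground truth);
    ``heterogeneity`` the relative voxel-to-voxel parameter SD within a lobe.
    """

    n_baseline: int = 30
    group_sizes: tuple[int, int, int] = (8, 8, 7)
    n_f2_in_3m: int = 5
    lobe_correlation: float = 0.3
    left_lobe_from_control_row: bool = True
    snr: float = 50.0
    measurement_noise_sd: float = 0.0
    heterogeneity: float = 0.02
    lobe_grid: tuple[int, int, int] = (32, 32, 3)
    voxel_size_mm: tuple[float, float, float] = (0.625, 0.625, 3.0)

    def __post_init__(self) -> None:
        if not -1 < self.lobe_correlation < 1:
            raise ValueError("lobe correlation must be in (-1, 1)")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.n_f2_in_3m > self.group_sizes[2]:
            raise ValueError("more F2 rats than three-month survivors")
        if min(self.group_sizes) < 1 or sum(self.group_sizes) > self.n_baseline:
            raise ValueError("invalid group sizes")


@dataclass(frozen=True)
class LobeTruth:
    """Ground-truth parameters of one lobe, on the reporting scales."""

    D_star: float
    D: float
    f: float
    R2_star: float
    t1_ratio: float
    t2_ratio: float

    @property
    def ivim(self) -> IvimParameters:
        """IVIM triple in internal units (mm^2/s)."""
        return IvimParameters(D=self.D * 1e-3, D_star=self.D_star * 1e-3, f=self.f)

    @property
    def relaxometry(self) -> RelaxometryParameters:
        return RelaxometryParameters(R2_star=self.R2_star)


@dataclass(frozen=True)
class RatRecord:
    """One animal: time-point group, right-lobe stage, per-lobe ground truth."""

    rat_id: int
    timepoint: str
    right_stage: str  # METAVIR stage of the irradiated lobe at follow-up
    baseline_right: LobeTruth
    left: Optional[LobeTruth] = None  # follow-up control lobe (None for attrition)
    right: Optional[LobeTruth] = None  # follow-up irradiated lobe

    def __post_init__(self) -> None:
        allowed = {"1m": {"F0"}, "2m": {"F1"}, "3m": {"F1", "F2"}, "baseline": {"none"}}
        if self.right_stage not in allowed.get(self.timepoint, set()):
            raise ValueError(
                f"stage {self.right_stage!r} inconsistent with time point {self.timepoint!r}"
            )


@dataclass(frozen=True)
class Cohort:
    rats: tuple[RatRecord, ...]
    config: CohortConfig
    table: StageDistributionTable
    seed: int

    @property
    def survivors(self) -> tuple[RatRecord, ...]:
        return tuple(r for r in self.rats if r.right is not None)

    def stage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.survivors:
            counts[r.right_stage] = counts.get(r.right_stage, 0) + 1
        return counts


@lru_cache(maxsize=None)
def _calibrated_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose truncation to [lo, hi] has the requested moments.

    Printed study tables report the mean and SD of the *observed* (physical,
    hence bounded) quantities, so the truncated distribution — not the parent
    normal — must carry those moments.  When the bounds are many sigma away
    the correction is skipped.
    """
    p_lo = sps.norm.cdf((lo - mean) / sd) if np.isfinite(lo) else 0.0
    p_hi = sps.norm.sf((hi - mean) / sd) if np.isfinite(hi) else 0.0
    if p_lo < 1e-10 and p_hi < 1e-10:
        return mean, sd

    def eqs(x: np.ndarray) -> list[float]:
        mu, log_sigma = x
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol, _info, ier, _msg = optimize.fsolve(
            eqs, np.array([mean, np.log(sd)]), full_output=True
        )
    if ier != 1:  # moments unattainable under truncation: plain truncated normal
        return mean, sd
    return float(sol[0]), float(np.exp(sol[1]))


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    mu, sigma = _calibrated_parent(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return sps.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _draw(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    return float(_truncnorm_ppf(rng.uniform(), mean, sd, lo, hi))


def sample_rat_parameters(
    stage: str,
    table: StageDistributionTable | None = None,
    seed: int | np.random.Generator | None = None,
    size: Optional[int] = None,
) -> dict[str, float] | dict[str, np.ndarray]:
    """Draw one lobe's (D*, D, f, R2*) from the stage's truncated normals.

    Values are on the reporting scales (1e-3 mm^2/s, fraction, Hz);
    deterministic under a fixed seed.  With ``size`` given, returns arrays of
    independent draws instead of scalars.
    """
    tab = table or StageDistributionTable()
    if stage not in tab.rows:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(tab.rows)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict = {}
    for p in PARAMS:
        mean, sd = tab.mean_sd(stage, p)
        lo, hi = _BOUNDS[p]
        if size is None:
            out[p] = _draw(rng, mean, sd, lo, hi)
        else:
            out[p] = _truncnorm_ppf(rng.uniform(size=size), mean, sd, lo, hi)
    return out


def _paired_lobe_truth(
    rng: np.random.Generator,
    left_row: dict[str, tuple[float, float]],
    right_row: dict[str, tuple[float, float]],
    ratio_tp: str,
    rho: float,
) -> tuple[LobeTruth, LobeTruth]:
    """Draw correlated left/right parameters via a Gaussian copula.

    Each parameter uses its own bivariate standard normal with correlation
    ``rho``; marginals are the truncated normals of each lobe's row, so the
    stage-wise means and SDs are preserved exactly regardless of pairing.
    """
    cov = np.array([[1.0, rho], [rho, 1.0]])
    vals: dict[str, tuple[float, float]] = {}
    for p in PARAMS:
        z = rng.multivariate_normal(np.zeros(2), cov, method="cholesky")
        u = sps.norm.cdf(z)
        lo, hi = _BOUNDS[p]
        lv = float(_truncnorm_ppf(u[0], *left_row[p], lo, hi))
        rv = float(_truncnorm_ppf(u[1], *right_row[p], lo, hi))
        vals[p] = (lv, rv)
    ratios = {}
    for w in ("T1", "T2"):
        ratios[w] = (
            _draw(rng, *DEFAULT_RELATIVE_SIGNAL[w]["left"][ratio_tp], 0.0, np.inf),
            _draw(rng, *DEFAULT_RELATIVE_SIGNAL[w]["right"][ratio_tp], 0.0, np.inf),
        )
    left = LobeTruth(vals["D_star"][0], vals["D"][0], vals["f"][0], vals["R2_star"][0],
                     ratios["T1"][0], ratios["T2"][0])
    right = LobeTruth(vals["D_star"][1], vals["D"][1], vals["f"][1], vals["R2_star"][1],
                      ratios["T1"][1], ratios["T2"][1])
    return left, right


def generate_cohort(
    config: CohortConfig | None = None,
    table: StageDistributionTable | None = None,
    seed: int = 0,
) -> Cohort:
    """Build the full paired-lobe cohort.

    The structure (rat ids, group membership, stage labels, attrition) is
    fixed by the config and identical for every seed; only the parameter
    draws vary.  Rats 1..8 form the one-month group (F0), 9..16 the two-month
    group (F1), 17..23 the three-month group (the first ``n_f2_in_3m`` staged
    F2, the rest F1); the remaining rats up to ``n_baseline`` have baseline
    measurements only (attrition).
    """
    cfg = config or CohortConfig()
    tab = table or StageDistributionTable()
    rng = np.random.default_rng(seed)

    n1, n2, n3 = cfg.group_sizes
    groups: list[tuple[str, str]] = (
        [("1m", "F0")] * n1
        + [("2m", "F1")] * n2
        + [("3m", "F2")] * cfg.n_f2_in_3m
        + [("3m", "F1")] * (n3 - cfg.n_f2_in_3m)
    )
    rats: list[RatRecord] = []
    for rid in range(1, cfg.n_baseline + 1):
        base = LobeTruth(
            *(_draw(rng, *DEFAULT_BASELINE_RIGHT[p], *_BOUNDS[p]) for p in PARAMS),
            _draw(rng, *DEFAULT_RELATIVE_SIGNAL["T1"]["right"]["baseline"], 0.0, np.inf),
            _draw(rng, *DEFAULT_RELATIVE_SIGNAL["T2"]["right"]["baseline"], 0.0, np.inf),
        )
        if rid <= len(groups):
            tp, stage = groups[rid - 1]
            left_row = (
                tab.rows["control"]
                if cfg.left_lobe_from_control_row
                else DEFAULT_LEFT_BY_TIMEPOINT[tp]
            )
            left, right = _paired_lobe_truth(
                rng, left_row, tab.rows[stage], tp, cfg.lobe_correlation
            )
            rats.append(RatRecord(rid, tp, stage, base, left, right))
        else:
            rats.append(RatRecord(rid, "baseline", "none", base))
    return Cohort(tuple(rats), cfg, tab, seed)


def tabular_mode(
    cohort: Cohort,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Flatten a cohort to one ROI-measurement row per lobe.

    Columns carry the reporting scales (D*, D in 1e-3 mm^2/s, f as a
    fraction, R2* in Hz, T1/T2 as liver-to-muscle ratios).  The measurement
    equals the ground-truth draw plus a relative Gaussian measurement error of
    SD ``config.measurement_noise_sd`` (default 0).  Baseline rows describe
    the pre-irradiation right lobe of all rats; follow-up rows the paired
    left (control) and right (staged) lobes of survivors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = cohort.config.measurement_noise_sd

    def measure(v: float) -> float:
        return v if noise == 0 else v * (1.0 + rng.normal(0.0, noise))

    rows = []
    for rat in cohort.rats:
        rows.append(_row(rat.rat_id, "baseline", "right", "control", rat.baseline_right, measure))
        if rat.right is not None:
            rows.append(_row(rat.rat_id, rat.timepoint, "left", "control", rat.left, measure))
            rows.append(_row(rat.rat_id, rat.timepoint, "right", rat.right_stage, rat.right, measure))
    return pd.DataFrame(rows)


def _row(rid, timepoint, lobe, stage, truth: LobeTruth, measure) -> dict:
    return {
        "rat_id": rid,
        "timepoint": timepoint,
        "lobe": lobe,
        "stage": stage,
        "D_star": measure(truth.D_star),
        "D": measure(truth.D),
        "f": measure(truth.f),
        "R2_star": measure(truth.R2_star),
        "t1_ratio": measure(truth.t1_ratio),
        "t2_ratio": measure(truth.t2_ratio),
    }


def render_rat_phantom(
    rat: RatRecord,
    protocol: AcquisitionProtocol,
    config: CohortConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Render follow-up left/right lobe phantoms of one rat as 4-D volumes.

    The two lobes sit side by side on one grid (left half / right half).
    Per-voxel parameters equal the lobe truth perturbed by the configured
    relative heterogeneity; signals follow the forward models and carry
    Rician noise of scale SI0 / SNR.  Returns ``dwi`` (x, y, z, b),
    ``gre`` (x, y, z, TE) and the boolean masks ``left_mask``/``right_mask``.
    """
    if rat.right is None or rat.left is None:
        raise ValueError("cannot render a baseline-only rat (no follow-up lobes)")
    cfg = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gx, gy, gz = cfg.lobe_grid
    shape = (2 * gx, gy, gz)
    left_mask = np.zeros(shape, dtype=bool)
    left_mask[:gx] = True
    right_mask = ~left_mask

    n_b, n_te = len(protocol.b_values), len(protocol.echo_times_ms)
    dwi = np.zeros(shape + (n_b,))
    gre = np.zeros(shape + (n_te,))
    sigma = protocol.SI0 / cfg.snr
    b = np.asarray(protocol.b_values)
    te = np.asarray(protocol.echo_times_ms)

    for truth, mask in ((rat.left, left_mask), (rat.right, right_mask)):
        idx = np.nonzero(mask)
        n_vox = idx[0].size
        jitter = 1.0 + cfg.heterogeneity * rng.standard_normal((n_vox, 4))
        for k in range(n_vox):
            dsj, dj, fj, r2j = (
                max(truth.D_star * jitter[k, 0], 1e-6),
                max(truth.D * jitter[k, 1], 1e-6),
                float(np.clip(truth.f * jitter[k, 2], 0.0, 1.0)),
                max(truth.R2_star * jitter[k, 3], 0.0),
            )
            p = IvimParameters(D=dj * 1e-3, D_star=dsj * 1e-3, f=fj)
            dwi[idx[0][k], idx[1][k], idx[2][k], :] = ivim_signal(p, b, protocol.SI0)
            gre[idx[0][k], idx[1][k], idx[2][k], :] = r2star_signal(
                RelaxometryParameters(r2j, protocol.SI0), te
            )
    if sigma > 0:
        dwi = np.hypot(dwi + rng.normal(0, sigma, dwi.shape), rng.normal(0, sigma, dwi.shape))
        gre = np.hypot(gre + rng.normal(0, sigma, gre.shape), rng.normal(0, sigma, gre.shape))
        dwi[~(left_mask | right_mask)] = 0.0
        gre[~(left_mask | right_mask)] = 0.0
    return {"dwi": dwi, "gre": gre, "left_mask": left_mask, "right_mask": right_mask}
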