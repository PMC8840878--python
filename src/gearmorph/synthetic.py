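"""Synthetic cohorts with known ground truth for the morphometric pipeline.

Generates landmark configurations, covariates and fishing-trial outcomes
with the statistical structure the analysis assumes: a stylized
zebrafish landmark template (19 fixed landmarks + 72 semi-landmarks on 6
outline curves), group/sex/allometric shape effects plus isotropic
landmark noise, a mass-length power law with lognormal error, and trial
outcomes driven by a latent vulnerability coupled to body depth
(shallower-bodied fish are more catchable, the direction reported for
both gears).

Everything is drawn from a single seeded ``numpy.random.default_rng``
(PCG64), so a cohort is fully reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .tps_io import (
    CovariateTable,
    LandmarkConfiguration,
    LandmarkDataset,
    SliderTable,
    write_sliders,
    write_tps,
)

__all__ = [
    "SynthParams",
    "SyntheticCohort",
    "make_template",
    "template_sliders",
    "simulate_cohort",
    "simulate_trawl_trials",
    "simulate_trap_trials",
    "body_depth",
    "write_cohort",
]

# Stylized zebrafish fixed landmarks (mm, image convention: y increases
# ventrally).  Snout at the origin, standard length ~30 mm, body depth
# ~7 mm.  Numbering follows the usual lateral-photograph template:
# 1 snout, 2 lower mandible, 3-4 eye, 5 occiput, 6-9 opercular series,
# 10-11 pectoral insertions, 12 dorsal-fin origin, 13-14 anal-fin
# insertions, 15-19 caudal-fin points.
_FIXED_LANDMARKS = np.array(
    [
        [0.0, 5.0],  # 1  anterior tip of snout
        [1.5, 6.3],  # 2  posterior tip of lower mandible
        [1.8, 4.2],  # 3  anterior middle axis of eye
        [3.2, 4.2],  # 4  posterior middle axis of eye
        [4.5, 2.8],  # 5  occiput
        [4.0, 5.2],  # 6  anterior tip of opercular bone
        [5.5, 7.0],  # 7  inferior edge of opercular bone
        [6.5, 5.5],  # 8  maximal exertion of operculum
        [5.8, 3.8],  # 9  antedorsal origin of opercle
        [7.0, 5.8],  # 10 superior insertion of pectoral fin
        [7.0, 6.8],  # 11 inferior insertion of pectoral fin
        [15.0, 2.2],  # 12 anterior insertion of dorsal fin
        [16.5, 8.0],  # 13 anterior insertion of anal fin
        [21.0, 7.2],  # 14 posterior insertion of anal fin
        [25.0, 3.6],  # 15 superior insertion of caudal fin
        [25.0, 6.6],  # 16 inferior insertion of caudal fin
        [29.0, 2.6],  # 17 superior tip of caudal fin
        [28.2, 5.1],  # 18 posterior central edge of caudal fin
        [29.0, 7.6],  # 19 inferior tip of caudal fin
    ]
)

# Outline curves carrying the semi-landmarks: (anchor_start, anchor_end,
# bow) with 1-based fixed-landmark anchors; ``bow`` bows the chord
# outward (negative = dorsally) so the outline is not collinear.
_CURVES = (
    ("a", 1, 5, -1.0),  # dorsal head profile
    ("b", 5, 12, -0.8),  # dorsal back
    ("c", 12, 15, -0.5),  # dorsal caudal peduncle (behind the dorsal fin)
    ("d", 13, 16, 0.5),  # ventral caudal peduncle
    ("e", 7, 13, 1.0),  # belly
    ("f", 2, 7, 0.6),  # ventral head
)
_DEFAULT_CURVE_COUNTS = (8, 15, 10, 14, 17, 8)


def make_template(
    n_fixed: int = 19, curve_counts: tuple[int, ...] = _DEFAULT_CURVE_COUNTS
) -> LandmarkDataset:
    """Single-specimen template dataset: fixed landmarks, semi-landmarks
    equally spaced along the 6 outline curves, roles and curve ids.

    Defaults give 19 fixed + 72 semi = 91 landmarks.
    """
    if n_fixed != len(_FIXED_LANDMARKS):
        raise ValueError(f"template defines {len(_FIXED_LANDMARKS)} fixed landmarks")
    if len(curve_counts) != len(_CURVES) or any(c < 1 for c in curve_counts):
        raise ValueError(f"need {len(_CURVES)} positive curve counts")
    points = [_FIXED_LANDMARKS]
    roles = ["fixed"] * n_fixed
    memberships: dict[int, str] = {}
    idx = n_fixed
    for (name, a, b, bow), count in zip(_CURVES, curve_counts):
        start = _FIXED_LANDMARKS[a - 1]
        end = _FIXED_LANDMARKS[b - 1]
        chord = end - start
        normal = np.array([-chord[1], chord[0]])
        normal = normal / np.linalg.norm(normal)
        ts = np.linspace(0, 1, count + 2)[1:-1]
        semis = start + ts[:, None] * chord + (bow * np.sin(np.pi * ts))[:, None] * normal
        points.append(semis)
        for _ in range(count):
            roles.append("semi")
            memberships[idx] = name
            idx += 1
    pts = np.vstack(points)
    return LandmarkDataset(
        configurations=[LandmarkConfiguration(points=pts, specimen_id="template")],
        landmark_roles=roles,
        curve_memberships=memberships,
    )


def template_sliders(template: LandmarkDataset) -> SliderTable:
    """Slider rows (before, slide, after; 1-based) chaining each curve's
    semi-landmarks between their anchoring fixed landmarks."""
    counts: dict[str, list[int]] = {}
    for idx, curve in sorted(template.curve_memberships.items()):
        counts.setdefault(curve, []).append(idx + 1)  # to 1-based
    rows = []
    anchors = {name: (a, b) for name, a, b, _ in _CURVES}
    for curve, semis in counts.items():
        a, b = anchors[curve]
        chain = [a] + semis + [b]
        for i in range(1, len(chain) - 1):
            rows.append((chain[i - 1], chain[i], chain[i + 1]))
    return SliderTable(np.array(rows, int))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _deformation_basis(template_pts: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-norm k x 2 deformation fields applied to the unit-size template.

    ``depth``: contracts dorsoventral spread (every landmark moves toward
    the anteroposterior axis in proportion to its offset) — a fish pushed
    along +depth becomes shallower bodied.
    ``sex``: ventral mid-body (abdominal) bulge, the female-like belly.
    ``allometry``: relative head enlargement with growth.
    """
    pts = template_pts
    centred = pts - pts.mean(axis=0)
    depth = np.zeros_like(pts)
    depth[:, 1] = -centred[:, 1]
    sex = np.zeros_like(pts)
    x_rel = (pts[:, 0] - pts[:, 0].min()) / np.ptp(pts[:, 0])
    ventral = centred[:, 1] > 0
    sex[:, 1] = np.where(ventral, np.exp(-((x_rel - 0.45) ** 2) / 0.02), 0.0)
    allo = np.zeros_like(pts)
    head = np.exp(-((x_rel - 0.0) ** 2) / 0.08)
    allo += head[:, None] * centred * 0.5
    return {"depth": _unit(depth), "sex": _unit(sex), "allometry": _unit(allo)}


@dataclass
class SynthParams:
    """Generator settings; defaults emulate the study's cohort scale.

    Magnitudes are in units of 1% of centroid size (Procrustes distance
    ~0.01 per unit per standard deviation of the underlying trait), the
    order of the ~1% shape variance the vulnerability effect explained.
    """

    seed: int
    n_fish: int = 111
    sex_ratio: float = 0.5
    gear: str = "trawl"
    landmark_noise_sd: float = 0.01
    vulnerability_effect_magnitude: float = 2.0
    sex_effect_magnitude: float = 2.0
    allometry_slope: float = 2.0
    depth_vulnerability_coupling: float = 0.8
    mass_length_intercept: float = 1.5e-5  # g / mm^b
    mass_length_exponent: float = 3.0
    mass_noise_sd: float = 0.05
    mean_log_length: float = float(np.log(30.0))
    sd_log_length: float = 0.08
    trawl_outcome_slope: float = 1.5
    trawl_cutpoints: tuple[float, float, float] = (-1.1, 0.0, 1.1)
    trap_intercept: float = -0.4
    trap_slope: float = 1.0
    n_tanks: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.depth_vulnerability_coupling <= 1:
            raise ValueError("depth_vulnerability_coupling must lie in [0, 1]")
        for name in (
            "landmark_noise_sd",
            "vulnerability_effect_magnitude",
            "sex_effect_magnitude",
            "mass_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gear not in ("trawl", "trap"):
            raise ValueError(f"gear must be 'trawl' or 'trap', got {self.gear!r}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    landmarks: LandmarkDataset
    sliders: SliderTable
    covariates: CovariateTable
    params: SynthParams
    ground_truth: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return self.landmarks.ids


# magnitude unit: 1 unit = 1% of centroid size per SD of the driving trait
_EFFECT_UNIT = 0.01


def simulate_cohort(params: SynthParams) -> SyntheticCohort:
    """Draw a cohort of landmark configurations, covariates and latent
    vulnerabilities from the stated generative model.

    Per fish: shape = template (unit centroid size) + sex effect + allometric
    effect in ln(length) + depth effect scaled by a standard-normal
    shallowness trait + isotropic landmark noise, then scaled so centroid
    size is proportional to standard length.  Latent vulnerability is
    beta * shallowness + (1 - beta) * independent normal noise.
    """
    rng = np.random.default_rng(params.seed)
    template = make_template()
    sliders = template_sliders(template)
    t_pts = template.configurations[0].points
    t_centred = t_pts - t_pts.mean(axis=0)
    t_unit = t_centred / np.sqrt((t_centred**2).sum())
    basis = _deformation_basis(t_pts)

    n = params.n_fish
    ids = [f"fish{j:03d}" for j in range(n)]
    sex = np.where(rng.random(n) < params.sex_ratio, "F", "M")
    length = np.exp(rng.normal(params.mean_log_length, params.sd_log_length, n))
    mass = (
        params.mass_length_intercept
        * length**params.mass_length_exponent
        * np.exp(rng.normal(0.0, params.mass_noise_sd, n))
    )
    shallow = rng.standard_normal(n)
    noise_v = rng.standard_normal(n)
    beta = params.depth_vulnerability_coupling
    latent = beta * shallow + (1 - beta) * noise_v

    log_len_c = np.log(length) - np.log(length).mean()
    sex_sign = np.where(sex == "F", 0.5, -0.5)
    configs = []
    for j in range(n):
        shape = (
            t_unit
            + _EFFECT_UNIT * params.sex_effect_magnitude * sex_sign[j] * basis["sex"]
            + _EFFECT_UNIT * params.allometry_slope * log_len_c[j] * basis["allometry"]
            + _EFFECT_UNIT
            * params.vulnerability_effect_magnitude
            * shallow[j]
            * basis["depth"]
        )
        shape = shape + rng.normal(0.0, params.landmark_noise_sd, shape.shape)
        pts = shape * length[j]  # centroid size proportional to standard length
        configs.append(LandmarkConfiguration(points=pts, specimen_id=ids[j]))

    # caudal fin measured quantities, scaled with length and lightly noisy
    rel = length / 30.0
    caudal_height = 6.0 * rel * np.exp(rng.normal(0, 0.05, n))
    caudal_area = 24.0 * rel**2 * np.exp(rng.normal(0, 0.08, n))

    cov = CovariateTable(
        pd.DataFrame(
            {
                "id": ids,
                "mass": mass,
                "standard_length": length,
                "sex": sex,
                "gear": params.gear,
                "tank": [f"T{j % params.n_tanks + 1}" for j in range(n)],
                "caudal_height": caudal_height,
                "caudal_area": caudal_area,
            }
        )
    )
    landmarks = LandmarkDataset(
        configurations=configs,
        landmark_roles=list(template.landmark_roles),
        curve_memberships=dict(template.curve_memberships),
    )
    truth = {
        "shallowness": dict(zip(ids, shallow.tolist())),
        "latent_vulnerability": dict(zip(ids, latent.tolist())),
        "depth_vector": basis["depth"].tolist(),
        "sex_vector": basis["sex"].tolist(),
        "allometry_vector": basis["allometry"].tolist(),
    }
    return SyntheticCohort(
        landmarks=landmarks,
        sliders=sliders,
        covariates=cov,
        params=params,
        ground_truth=truth,
    )


def _trial_seed(params: SynthParams, offset: int) -> int:
    return (params.seed * 7919 + offset) % (2**31 - 1)


def simulate_trawl_trials(cohort: SyntheticCohort, params: SynthParams | None = None) -> pd.DataFrame:
    """Three trawl trials per fish from an ordered-outcome model.

    Outcome severity (E_B < E_F < C_N < C_C) follows a proportional-odds
    model whose linear predictor is ``trawl_outcome_slope *
    latent_vulnerability``; cod-end capture times are uniform on
    [0, 600] s.  Returns the long trial table the scoring module reads.
    """
    params = params or cohort.params
    rng = np.random.default_rng(_trial_seed(params, 1))
    latent = np.array(
        [cohort.ground_truth["latent_vulnerability"][i] for i in cohort.ids]
    )
    cuts = np.asarray(params.trawl_cutpoints, float)
    codes = ["E_B", "E_F", "C_N", "C_C"]
    rows = []
    for j, fish in enumerate(cohort.ids):
        # P(severity >= level l) = expit(slope * v - cut_l)
        p_ge = expit(params.trawl_outcome_slope * latent[j] - cuts)
        for trial in (1, 2, 3):
            u = rng.random()
            level = int((u < p_ge).sum())  # 0..3
            outcome = codes[level]
            t = round(float(rng.uniform(0.0, 600.0)), 1) if outcome == "C_C" else np.nan
            rows.append(
                {
                    "fish_id": fish,
                    "gear": "trawl",
                    "trial_index": trial,
                    "outcome": outcome,
                    "capture_time_s": t,
                    "captured": np.nan,
                }
            )
    return pd.DataFrame(rows)


def simulate_trap_trials(cohort: SyntheticCohort, params: SynthParams | None = None) -> pd.DataFrame:
    """Three trap trials per fish: Bernoulli captures with logit linear in
    latent vulnerability."""
    params = params or cohort.params
    rng = np.random.default_rng(_trial_seed(params, 2))
    latent = np.array(
        [cohort.ground_truth["latent_vulnerability"][i] for i in cohort.ids]
    )
    rows = []
    for j, fish in enumerate(cohort.ids):
        p = expit(params.trap_intercept + params.trap_slope * latent[j])
        for trial in (1, 2, 3):
            rows.append(
                {
                    "fish_id": fish,
                    "gear": "trap",
                    "trial_index": trial,
                    "outcome": np.nan,
                    "capture_time_s": np.nan,
                    "captured": bool(rng.random() < p),
                }
            )
    return pd.DataFrame(rows)


def body_depth(points: np.ndarray) -> float:
    """Dorsoventral landmark spread (max minus min y) of a configuration."""
    pts = np.asarray(points, float)
    return float(np.ptp(pts[:, 1]))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, trials: pd.DataFrame | None = None) -> dict[str, Path]:
    """Emit the cohort in the file formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": out / "landmarks.tps",
        "sliders": out / "sliders.csv",
        "covariates": out / "covariates.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_tps(cohort.landmarks, paths["tps"])
    write_sliders(cohort.sliders, paths["sliders"])
    cohort.covariates.to_csv(paths["covariates"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {"params": asdict(cohort.params), **cohort.ground_truth}, fh, indent=1
        )
    if trials is not None:
        paths["trials"] = out / "trials.csv"
        trials.to_csv(paths["trials"], index=False)
    return paths
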