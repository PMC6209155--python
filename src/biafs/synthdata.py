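"""Synthetic bioimpedance cohorts with known relevant/redundant structure.

The generator emulates the shape of a segmental multi-frequency body-
composition data set: five impedance channels (bilateral limb pairs
nearly collinear), anthropometrics, a binary sex indicator, and
continuous targets (BFM, TBW) produced by a noisy linear model of a
known subset of the expanded features.

Planted structure (defaults):

* legs (R4, R5): a bilateral pair with correlation >= 0.98 whose shared
  latent is driven by height, BMI and sex; the conductance index
  H^2 / R̄leg enters the BFM equation, so reciprocal and product
  expansions of the leg channels are genuinely informative;
* arms (R1, R2): a bilateral pair driven by a latent independent of the
  target — a planted *irrelevant* redundant block;
* trunk (R3): weakly correlated with the arm latent (|r| ~ 0.3) and
  independent of the target.

BFM = c0 + c1*W + c2*G + c3*A - c4*H^2/R̄leg + N(0, sigma); TBW is the
analogous water model.  All coefficients are visible on
:class:`CohortParams` so tests can tighten or loosen effect sizes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import IMPEDANCE_COLUMNS, SampleTable

__all__ = ["CohortParams", "GroundTruth", "RecoveryReport",
           "simulate_cohort", "recovery_report", "primaries_of"]

#: impedance falls with measurement frequency; 250 kHz is the reference scale
BAND_SCALES = {"1kHz": 1.15, "250kHz": 1.0, "500kHz": 0.88}


@dataclass
class CohortParams:
    """Generator settings; defaults give a realistic adult cohort."""

    # anthropometrics: G ~ Bernoulli(0.5); A ~ U(18, 65);
    # H ~ N(163 + 12 G, 6) cm; W = BMI (H/100)^2 with BMI ~ N(23, 3)
    p_male: float = 0.5
    age_range: tuple[float, float] = (18.0, 65.0)
    height_base: float = 163.0
    height_sex_shift: float = 12.0
    height_sd: float = 6.0
    bmi_mean: float = 23.0
    bmi_sd: float = 3.0

    # leg impedance latent (ohms at 250 kHz): taller/heavier/male -> lower
    leg_base: float = 320.0
    leg_height_slope: float = -1.5
    leg_bmi_slope: float = -7.0
    leg_sex_shift: float = -10.0
    leg_latent_sd: float = 15.0
    leg_pair_sd: float = 3.0          # bilateral asymmetry; keeps r(R4,R5) >= 0.98

    # arm impedance latent: independent of the target (planted noise block)
    arm_base: float = 340.0
    arm_latent_sd: float = 30.0
    arm_pair_sd: float = 4.0

    # trunk: low-impedance segment, weakly tied to the arm latent
    trunk_base: float = 30.0
    trunk_arm_loading: float = 0.04   # ~0.3 correlation with arms
    trunk_sd: float = 3.8

    # BFM = c0 + c_w W + c_g G + c_a A - c_cond H^2/R̄leg + N(0, sigma_bfm)
    c0: float = -12.0
    c_w: float = 0.75
    c_g: float = -7.0
    c_a: float = 0.18
    c_cond: float = 0.20
    sigma_bfm: float = 1.5

    # TBW = t0 + t_cond H^2/R̄leg + t_w W + t_g G + t_a A + N(0, sigma_tbw)
    t0: float = 1.0
    t_cond: float = 0.30
    t_w: float = 0.10
    t_g: float = 2.0
    t_a: float = -0.02
    sigma_tbw: float = 1.0

    def validate(self) -> None:
        if not (0 <= self.p_male <= 1):
            raise ValueError("p_male must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        for name in ("height_sd", "bmi_sd", "leg_latent_sd", "leg_pair_sd",
                     "arm_latent_sd", "arm_pair_sd", "trunk_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_bfm < 0 or self.sigma_tbw < 0:
            raise ValueError("noise sds must be >= 0")


_PRIMARY_RE = re.compile(r"R[1-5]|[AHWG]")


def primaries_of(feature_name: str) -> frozenset[str]:
    """Primary variables an expanded feature is built from
    (``"R1R2"`` -> {R1, R2}; ``"1/R3"`` -> {R3}; ``"A"`` -> {A})."""
    return frozenset(_PRIMARY_RE.findall(feature_name))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    relevant_primaries: frozenset[str]
    noise_primaries: frozenset[str]
    redundancy_groups: tuple[frozenset[str], ...]
    relevant_groups: dict[str, frozenset[str]]   # generative signal -> expanded names
    coefficients: dict[str, float]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.relevant_primaries & self.noise_primaries:
            raise ValueError("relevant and noise primaries must be disjoint")
        seen: set[str] = set()
        for g in self.redundancy_groups:
            if g & seen:
                raise ValueError("redundancy groups must be disjoint")
            seen |= g

    def is_pure_noise(self, feature_name: str) -> bool:
        """True iff every primary the feature involves is a noise primary."""
        p = primaries_of(feature_name)
        return bool(p) and p <= self.noise_primaries


def simulate_cohort(
    n: int = 100,
    seed: int | None = None,
    params: CohortParams | None = None,
    band: str = "250kHz",
    target_names: tuple[str, ...] = ("BFM", "TBW"),
) -> tuple[SampleTable, GroundTruth]:
    """Draw a synthetic cohort of ``n`` adults for one frequency band.

    Targets are generated from the band-independent (250 kHz-scale)
    latents so that the same subjects re-simulated at another band carry
    the same BFM/TBW; the stored impedance columns are scaled by the
    band's factor.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    p = params or CohortParams()
    p.validate()
    rng = np.random.default_rng(seed)

    G = rng.binomial(1, p.p_male, n).astype(float)
    A = rng.uniform(*p.age_range, n)
    H = p.height_base + p.height_sex_shift * G + rng.normal(0, p.height_sd, n)
    bmi = rng.normal(p.bmi_mean, p.bmi_sd, n)
    W = bmi * (H / 100.0) ** 2

    leg_latent = (p.leg_base + p.leg_height_slope * (H - 170.0)
                  + p.leg_bmi_slope * (bmi - p.bmi_mean)
                  + p.leg_sex_shift * G
                  + rng.normal(0, p.leg_latent_sd, n))
    R4 = leg_latent + rng.normal(0, p.leg_pair_sd, n)
    R5 = leg_latent + rng.normal(0, p.leg_pair_sd, n)

    arm_latent = p.arm_base + rng.normal(0, p.arm_latent_sd, n)
    R1 = arm_latent + rng.normal(0, p.arm_pair_sd, n)
    R2 = arm_latent + rng.normal(0, p.arm_pair_sd, n)

    R3 = (p.trunk_base + p.trunk_arm_loading * (arm_latent - p.arm_base)
          + rng.normal(0, p.trunk_sd, n))

    for name, arr in (("R1", R1), ("R2", R2), ("R3", R3), ("R4", R4), ("R5", R5)):
        if np.any(arr <= 0):
            raise ValueError(f"generated non-positive impedance in {name}; "
                             "check params")

    cond = H ** 2 / ((R4 + R5) / 2.0)
    bfm = (p.c0 + p.c_w * W + p.c_g * G + p.c_a * A - p.c_cond * cond
           + rng.normal(0, p.sigma_bfm, n))
    tbw = (p.t0 + p.t_cond * cond + p.t_w * W + p.t_g * G + p.t_a * A
           + rng.normal(0, p.sigma_tbw, n))

    scale = BAND_SCALES.get(band, 1.0)
    data = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "R1": scale * R1, "R2": scale * R2, "R3": scale * R3,
        "R4": scale * R4, "R5": scale * R5,
        "A": A, "H": H, "W": W, "G": G,
        "BFM": bfm, "TBW": tbw,
    })
    wanted = [t for t in target_names if t in ("BFM", "TBW")]
    table = SampleTable(data=data, band=band, target_names=tuple(wanted))

    truth = GroundTruth(
        relevant_primaries=frozenset({"A", "H", "W", "G", "R4", "R5"}),
        noise_primaries=frozenset({"R1", "R2", "R3"}),
        redundancy_groups=(frozenset({"R1", "R2"}), frozenset({"R4", "R5"})),
        relevant_groups={
            "weight": frozenset({"W"}),
            "sex": frozenset({"G"}),
            "age": frozenset({"A"}),
            "leg_conductance": frozenset({"H", "R4", "R5", "1/R4", "1/R5",
                                          "R4^2", "R5^2", "R4R5"}),
        },
        coefficients={"c0": p.c0, "W": p.c_w, "G": p.c_g, "A": p.c_a,
                      "H^2/Rleg": -p.c_cond},
        noise_sd=p.sigma_bfm,
    )
    return table, truth


@dataclass
class RecoveryReport:
    """How well a selection run recovered the planted structure."""

    relevant_coverage: float     # fraction of relevant groups with >= 1 selected member
    n_noise_selected: int        # selected features built only from noise primaries
    n_multi_redundant: int       # redundancy groups with > 1 selected member
    selected: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return {"relevant_coverage": self.relevant_coverage,
                "n_noise_selected": self.n_noise_selected,
                "n_multi_redundant": self.n_multi_redundant}


def recovery_report(selected, truth: GroundTruth) -> RecoveryReport:
    """Score a selected feature set against the generator's ground truth.

    ``selected`` may be a list of feature names or any object with a
    ``selected`` attribute (e.g. a pipeline SelectionResult).
    """
    names = list(getattr(selected, "selected", selected))
    chosen = set(names)
    covered = sum(1 for g in truth.relevant_groups.values() if g & chosen)
    coverage = covered / len(truth.relevant_groups) if truth.relevant_groups else 1.0
    n_noise = sum(1 for f in names if truth.is_pure_noise(f))
    n_multi = sum(1 for g in truth.redundancy_groups if len(g & chosen) > 1)
    return RecoveryReport(relevant_coverage=coverage, n_noise_selected=n_noise,
                          n_multi_redundant=n_multi, selected=tuple(names))


def write_cohort(table: SampleTable, truth: GroundTruth, path, truth_path=None) -> None:
    """Write the cohort CSV (dataio schema) and an optional ground-truth sidecar."""
    table.data.to_csv(path, index=False)
    if truth_path is not None:
        rows = []
        for kind, names in (("relevant_primary", sorted(truth.relevant_primaries)),
                            ("noise_primary", sorted(truth.noise_primaries))):
            rows += [{"kind": kind, "name": nm, "group": ""} for nm in names]
        for i, g in enumerate(truth.redundancy_groups):
            rows += [{"kind": "redundancy_group", "name": nm, "group": str(i)}
                     for nm in sorted(g)]
        for gname, members in truth.relevant_groups.items():
            rows += [{"kind": "relevant_group", "name": nm, "group": gname}
                     for nm in sorted(members)]
        pd.DataFrame(rows).to_csv(truth_path, index=False)
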