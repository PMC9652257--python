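"""Synthetic cohort generator with configurable difficulty→outcome effects.

The generator emulates a single-center minimally-invasive liver surgery
registry: baseline features are drawn from configured marginal frequencies
(defaults reproduce the published single-center case mix of 346 patients),
resection targets are assembled from a configurable mix of resection types
with anatomically coherent segment sets, and every binary outcome is drawn
from a logistic model whose linear predictor rises with the collapsed
Kawaguchi difficulty level of the generated resection:

    logit P(outcome) = b_outcome + beta_outcome * (level - 1),   level in 1..3

Difficulty therefore enters through the resection/tumor features themselves,
so all four scores are computable and mutually correlated, as in real
cohorts.  Intercepts ``b_outcome`` are solved at generation time (Brent root
finding on the realized level distribution) so that the cohort-level
prevalence matches the configured target regardless of the effect size —
injecting a stronger effect redistributes events across difficulty levels
without inflating the overall rate.

Continuous outcomes (operative time, blood loss, stay) are drawn from
difficulty-consistent discretized log-normal/uniform families conditioned on
their binary flag, so flags and underlying values never contradict.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import CohortTable, OutcomeRecord, PatientRecord, ResectionTarget
from .errors import ConfigError
from .outcomes import outcome_flags
from .scores import collapse_kawaguchi, kawaguchi_group
from .segments import DEFAULT_SEGMENT_CONFIG, SegmentConfig

__all__ = ["SimConfig", "GenerationReport", "default_config", "generate_cohort", "generation_report"]

#: Outcomes driven by the logistic difficulty link.
OUTCOME_NAMES = (
    "long_operative_time",
    "high_blood_loss",
    "conversion",
    "prolonged_los",
    "any_complication",
    "severe_complication",
    "satava_gt1",
    "margin_r1",
    "readmission_90d",
    "mortality_90d",
    "transfusion",
)

_DEFAULT_MARGINALS: Mapping[str, float] = {
    "male": 0.581,
    "age_ge65": 0.537,
    "bmi_ge25": 0.564,
    "asa_3_4": 0.329,
    "cardiologic": 0.147,
    "vascular": 0.529,
    "diabetes": 0.214,
    "respiratory": 0.084,
    "neurologic": 0.058,
    "ckd": 0.145,
    "steatosis": 0.185,
    "cirrhosis": 0.344,
    "portal_hypertension": 0.182,
    "platelets_le100": 0.127,
    # 13% receiving neoadjuvant chemotherapy (the published frequency table
    # prints the yes/no rows the other way around, which is clinically
    # implausible; exposed here as an ordinary configurable marginal)
    "neoadjuvant_chemotherapy": 0.13,
    "previous_open_liver_resection": 0.05,
    "malignant": 0.826,
    "child_pugh_b": 0.033,
    "hybrid_approach": 0.05,
    "proximity_major_vessels": 0.15,
    "tumor_ge3cm": 0.45,
    "second_resection": 0.10,
}

_DEFAULT_RESECTION_MIX: Mapping[str, float] = {
    "wedge": 0.43,
    "left_lateral_sectionectomy": 0.17,
    "anatomical_segmentectomy": 0.22,
    "sectionectomy_other": 0.03,
    "left_hepatectomy": 0.05,
    "right_hepatectomy": 0.06,
    "central_hepatectomy": 0.01,
    "extended_hepatectomy": 0.03,
}

#: Cohort-level target prevalences of the generated outcomes (defaults from
#: the published frequency table; mortality 0 — no 90-day deaths observed).
_DEFAULT_TARGET_PREVALENCE: Mapping[str, float] = {
    "long_operative_time": 0.486,
    "high_blood_loss": 0.069,
    "conversion": 0.081,
    "prolonged_los": 0.393,
    "any_complication": 0.273,
    "severe_complication": 0.037,
    "satava_gt1": 0.081,
    "margin_r1": 0.098,
    "readmission_90d": 0.012,
    "mortality_90d": 0.0,
    "transfusion": 0.061,
}

#: Per-collapsed-level log odds ratios (difficulty effect).  Chosen so that
#: higher difficulty raises the odds of every operative/short-term adverse
#: outcome, with magnitudes loosely in the range reported for per-class
#: contrasts in single-center series; purely patient-driven endpoints
#: (margin, readmission, mortality) carry no difficulty effect by default.
_DEFAULT_EFFECT_LOG_OR: Mapping[str, float] = {
    "long_operative_time": 1.0,
    "high_blood_loss": 0.55,
    "conversion": 0.75,
    "prolonged_los": 0.7,
    "any_complication": 0.15,
    "severe_complication": 0.8,
    "satava_gt1": 0.5,
    "margin_r1": 0.0,
    "readmission_90d": 0.0,
    "mortality_90d": 0.0,
    "transfusion": 0.55,
}

# Relative draw weights of the segment hosting a wedge / segmentectomy.
_SEGMENT_DRAW_WEIGHTS: Mapping[str, float] = {
    "1": 0.02,
    "2": 0.08,
    "3": 0.12,
    "4a": 0.06,
    "4b": 0.12,
    "5": 0.15,
    "6": 0.18,
    "7": 0.12,
    "8": 0.15,
}

_FIXED_SEGMENT_SETS = {
    "left_lateral_sectionectomy": ("2", "3"),
    "left_hepatectomy": ("2", "3", "4a", "4b"),
    "right_hepatectomy": ("5", "6", "7", "8"),
    "central_hepatectomy": ("4a", "4b", "5", "8"),
}

_SEGMENT_NEIGHBORS = {
    "1": ("7", "8"),
    "2": ("3",),
    "3": ("2", "4b"),
    "4a": ("4b", "8"),
    "4b": ("4a", "5"),
    "5": ("6", "8"),
    "6": ("5", "7"),
    "7": ("6", "8"),
    "8": ("5", "7"),
}


@dataclass
class SimConfig:
    """Generator configuration.

    ``target_prevalence`` sets the cohort-level rate of each outcome;
    the logistic intercepts are solved from it at generation time unless
    ``baseline_logit`` supplies them explicitly.
    """

    n: int = 346
    seed: int = 0
    marginals: dict = field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    resection_mix: dict = field(default_factory=lambda: dict(_DEFAULT_RESECTION_MIX))
    effect_log_or: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECT_LOG_OR))
    target_prevalence: dict = field(
        default_factory=lambda: dict(_DEFAULT_TARGET_PREVALENCE)
    )
    baseline_logit: Optional[dict] = None
    segment_config: SegmentConfig = field(default_factory=lambda: DEFAULT_SEGMENT_CONFIG)

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        for name, p in {**self.marginals, **self.target_prevalence}.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigError(f"probability {name}={p} outside [0, 1]")
        total = sum(self.resection_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"resection_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.resection_mix.values()):
            raise ConfigError("resection_mix probabilities must be >= 0")
        unknown = set(self.effect_log_or) - set(OUTCOME_NAMES)
        if unknown:
            raise ConfigError(f"unknown outcome(s) in effect_log_or: {sorted(unknown)}")

    def hash(self) -> str:
        payload = {
            "n": self.n,
            "seed": self.seed,
            "marginals": self.marginals,
            "resection_mix": self.resection_mix,
            "effect_log_or": self.effect_log_or,
            "target_prevalence": self.target_prevalence,
            "baseline_logit": self.baseline_logit,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GenerationReport:
    """Realized frequencies of one generated cohort."""

    n: int
    seed: int
    config_hash: str
    realized_marginals: dict
    realized_outcomes: dict
    kawaguchi_level_freq: dict


def default_config(n: int = 346, seed: int = 0) -> SimConfig:
    """The study conditions: published marginals, moderate difficulty effects."""
    return SimConfig(n=n, seed=seed)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent, named sub-stream of the root seed.

    Streams are keyed by variable name, so adding a new variable never
    perturbs the draws of existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _solve_intercept(p_target: float, beta: float, levels: np.ndarray) -> float:
    """Intercept b with mean(expit(b + beta*(levels-1))) == p_target."""
    if p_target <= 0.0:
        return -np.inf
    if p_target >= 1.0:
        return np.inf
    if beta == 0.0:
        return float(logit(p_target))

    def f(b: float) -> float:
        return float(np.mean(expit(b + beta * (levels - 1)))) - p_target

    return float(brentq(f, -40.0, 40.0, xtol=1e-12))


def _draw_segments(rng: np.random.Generator, rtype: str) -> frozenset[str]:
    labels = list(_SEGMENT_DRAW_WEIGHTS)
    weights = np.array(list(_SEGMENT_DRAW_WEIGHTS.values()))
    weights = weights / weights.sum()
    if rtype in _FIXED_SEGMENT_SETS:
        return frozenset(_FIXED_SEGMENT_SETS[rtype])
    if rtype == "extended_hepatectomy":
        side = ("5", "6", "7", "8", "4a", "4b") if rng.random() < 0.6 else (
            "2", "3", "4a", "4b", "5", "8")
        return frozenset(side)
    if rtype == "sectionectomy_other":
        return frozenset(("5", "8")) if rng.random() < 0.5 else frozenset(("6", "7"))
    # wedge / anatomical segmentectomy
    first = rng.choice(labels, p=weights)
    if rtype == "anatomical_segmentectomy" and rng.random() < 0.2:
        second = rng.choice(_SEGMENT_NEIGHBORS[first])
        return frozenset((first, second))
    return frozenset((first,))


def generate_cohort(config: SimConfig) -> CohortTable:
    """Draw a full synthetic cohort; deterministic under (config, seed)."""
    config.validate()
    n, seed = config.n, config.seed
    m = config.marginals

    def bern(name: str, p: float) -> np.ndarray:
        return _rng(seed, name).random(n) < p

    male = bern("sex", m["male"])
    age_hi = bern("age", m["age_ge65"])
    age = np.where(
        age_hi,
        _rng(seed, "age_value_hi").integers(65, 86, n),
        _rng(seed, "age_value_lo").integers(30, 65, n),
    )
    bmi_hi = bern("bmi", m["bmi_ge25"])
    bmi = np.where(
        bmi_hi,
        np.round(_rng(seed, "bmi_value_hi").uniform(25.0, 35.0, n), 1),
        np.round(_rng(seed, "bmi_value_lo").uniform(19.0, 24.9, n), 1),
    )
    asa_hi = bern("asa", m["asa_3_4"])
    asa = np.where(
        asa_hi,
        np.where(_rng(seed, "asa_split_hi").random(n) < 0.85, 3, 4),
        np.where(_rng(seed, "asa_split_lo").random(n) < 0.35, 1, 2),
    )
    u_hist = _rng(seed, "histology").random(n)
    histology = np.where(
        u_hist < m["cirrhosis"],
        "cirrhosis",
        np.where(u_hist < m["cirrhosis"] + m["steatosis"], "steatosis", "healthy"),
    )
    child_b = bern("child_pugh", m["child_pugh_b"])
    portal = bern("portal_hypertension", m["portal_hypertension"])
    plt_lo = bern("platelets", m["platelets_le100"])
    platelets = np.where(
        plt_lo,
        np.round(_rng(seed, "platelets_value_lo").uniform(45.0, 100.0, n), 0),
        np.round(_rng(seed, "platelets_value_hi").uniform(105.0, 420.0, n), 0),
    )
    comorb = {
        name: bern(f"comorb_{name}", m[name])
        for name in ("cardiologic", "vascular", "diabetes", "respiratory", "neurologic", "ckd")
    }
    chemo = bern("neoadjuvant_chemotherapy", m["neoadjuvant_chemotherapy"])
    prev_open = bern("previous_open_liver_resection", m["previous_open_liver_resection"])
    hybrid = bern("approach", m["hybrid_approach"])
    malignant = bern("malignant", m["malignant"])
    vessels = bern("proximity_major_vessels", m["proximity_major_vessels"])
    size_hi = bern("tumor_ge3cm", m["tumor_ge3cm"])
    tumor_size = np.where(
        size_hi,
        np.round(np.minimum(3.0 + _rng(seed, "tumor_size_hi").lognormal(0.3, 0.7, n), 15.0), 1),
        np.round(_rng(seed, "tumor_size_lo").uniform(0.5, 2.9, n), 1),
    )
    second = bern("second_resection", m["second_resection"])

    mix_types = list(config.resection_mix)
    mix_p = np.array([config.resection_mix[t] for t in mix_types], dtype=float)
    mix_p = mix_p / mix_p.sum()
    rtype_idx = _rng(seed, "resection_type").choice(len(mix_types), size=n, p=mix_p)
    seg_rng = _rng(seed, "segments")
    extra_rng = _rng(seed, "second_target")

    patients: list[PatientRecord] = []
    levels = np.empty(n, dtype=int)
    width = len(str(n))
    for i in range(n):
        rtype = mix_types[rtype_idx[i]]
        targets = [
            ResectionTarget(
                resection_type=rtype,
                segments=_draw_segments(seg_rng, rtype),
                tumor_size_cm=float(tumor_size[i]),
                malignant=bool(malignant[i]),
                proximity_major_vessels=bool(vessels[i]),
            )
        ]
        if second[i]:
            # an additional minor (wedge) target, typical of multifocal disease
            targets.append(
                ResectionTarget(
                    resection_type="wedge",
                    segments=_draw_segments(extra_rng, "wedge"),
                    tumor_size_cm=float(
                        np.round(extra_rng.uniform(0.5, min(float(tumor_size[i]) + 0.1, 3.0)), 1)
                    ),
                    malignant=bool(malignant[i]),
                    proximity_major_vessels=False,
                )
            )
        patient = PatientRecord(
            patient_id=f"SYN{i + 1:0{width}d}",
            age_years=int(age[i]),
            sex="M" if male[i] else "F",
            bmi=float(bmi[i]),
            asa=int(asa[i]),
            child_pugh="B" if child_b[i] else "A",
            platelets_1e9_per_L=float(platelets[i]),
            portal_hypertension=bool(portal[i]),
            liver_histology=str(histology[i]),
            previous_open_liver_resection=bool(prev_open[i]),
            neoadjuvant_chemotherapy=bool(chemo[i]),
            comorb_cardiologic=bool(comorb["cardiologic"][i]),
            comorb_vascular=bool(comorb["vascular"][i]),
            comorb_diabetes=bool(comorb["diabetes"][i]),
            comorb_respiratory=bool(comorb["respiratory"][i]),
            comorb_neurologic=bool(comorb["neurologic"][i]),
            comorb_ckd=bool(comorb["ckd"][i]),
            approach="hybrid_or_hand_assisted" if hybrid[i] else "pure_laparoscopic",
            resections=tuple(targets),
        )
        patients.append(patient)
        levels[i] = max(
            collapse_kawaguchi(kawaguchi_group(t, config.segment_config))
            for t in targets
        )

    # --- binary outcomes through the logistic difficulty link -------------
    def draw_outcome(name: str, p_target: float) -> np.ndarray:
        beta = float(config.effect_log_or.get(name, 0.0))
        if config.baseline_logit is not None and name in config.baseline_logit:
            b = float(config.baseline_logit[name])
        else:
            b = _solve_intercept(p_target, beta, levels)
        if b == -np.inf:
            return np.zeros(n, dtype=bool)
        if b == np.inf:
            return np.ones(n, dtype=bool)
        p = expit(b + beta * (levels - 1))
        return _rng(seed, f"outcome_{name}").random(n) < p

    tp = config.target_prevalence
    severe = draw_outcome("severe_complication", tp["severe_complication"])
    # draw the non-severe complication component so that the union hits the
    # overall complication target (independence approximation)
    p_sev = tp["severe_complication"]
    p_any_extra = (
        (tp["any_complication"] - p_sev) / (1.0 - p_sev) if p_sev < 1.0 else 0.0
    )
    any_extra = draw_outcome("any_complication", max(p_any_extra, 0.0))
    any_comp = severe | any_extra

    long_time = draw_outcome("long_operative_time", tp["long_operative_time"])
    high_loss = draw_outcome("high_blood_loss", tp["high_blood_loss"])
    conversion = draw_outcome("conversion", tp["conversion"])
    prolonged = draw_outcome("prolonged_los", tp["prolonged_los"])
    satava_hi = draw_outcome("satava_gt1", tp["satava_gt1"])
    margin_r1 = draw_outcome("margin_r1", tp["margin_r1"])
    readmit = draw_outcome("readmission_90d", tp["readmission_90d"])
    mortality = draw_outcome("mortality_90d", tp["mortality_90d"])
    transfusion = draw_outcome("transfusion", tp["transfusion"])

    # --- continuous outcomes conditioned on their flags -------------------
    op_time = np.where(
        long_time,
        241 + np.floor(_rng(seed, "op_time_hi").lognormal(4.0, 0.7, n)).astype(int),
        _rng(seed, "op_time_lo").integers(90, 241, n),
    )
    blood = np.where(
        high_loss,
        501 + np.floor(_rng(seed, "blood_hi").lognormal(5.0, 0.8, n)).astype(int),
        _rng(seed, "blood_lo").integers(0, 501, n),
    )
    los = np.where(
        prolonged,
        5 + _rng(seed, "los_hi").geometric(0.35, n),
        _rng(seed, "los_lo").choice([1, 2, 3, 4, 5], size=n, p=[0.05, 0.1, 0.15, 0.3, 0.4]),
    )
    # Clavien-Dindo grade consistent with the complication flags; death = 5
    cd_sev = np.where(_rng(seed, "cd_severe_split").random(n) < 0.7, 3, 4)
    cd_mild = np.where(_rng(seed, "cd_mild_split").random(n) < 0.6, 1, 2)
    clavien = np.where(mortality, 5, np.where(severe, cd_sev, np.where(any_comp, cd_mild, 0)))
    # Satava grade: flag True -> II (no grade-III events at the default
    # calibration); otherwise none vs I
    sat_low = np.where(
        _rng(seed, "satava_low_split").random(n) < 0.041, "I", "none"
    )
    satava = np.where(satava_hi, "II", sat_low)

    rows = []
    for i, patient in enumerate(patients):
        outcome = OutcomeRecord(
            operative_time_min=int(op_time[i]),
            blood_loss_ml=int(blood[i]),
            conversion=bool(conversion[i]),
            transfusion=bool(transfusion[i]),
            satava_grade=str(satava[i]),
            clavien_dindo=int(clavien[i]),
            los_days=int(los[i]),
            margin="R1" if margin_r1[i] else "R0",
            readmission_90d=bool(readmit[i]),
            mortality_90d=bool(mortality[i]),
        )
        rows.append((patient, outcome))
    return CohortTable(rows=rows, provenance="synthetic", generator_seed=seed)


def generation_report(cohort: CohortTable, config: SimConfig) -> GenerationReport:
    """Realized marginal and outcome frequencies of a generated cohort."""
    if cohort.provenance != "synthetic":
        raise ConfigError("generation_report requires a synthetic cohort")
    n = len(cohort)
    ps = cohort.patients()
    os_ = cohort.outcomes()

    def frac(flags) -> float:
        return float(sum(flags)) / n

    realized_marginals = {
        "male": frac(p.sex == "M" for p in ps),
        "age_ge65": frac(p.age_years >= 65 for p in ps),
        "bmi_ge25": frac(p.bmi >= 25 for p in ps),
        "asa_3_4": frac(p.asa >= 3 for p in ps),
        "cardiologic": frac(p.comorb_cardiologic for p in ps),
        "vascular": frac(p.comorb_vascular for p in ps),
        "diabetes": frac(p.comorb_diabetes for p in ps),
        "respiratory": frac(p.comorb_respiratory for p in ps),
        "neurologic": frac(p.comorb_neurologic for p in ps),
        "ckd": frac(p.comorb_ckd for p in ps),
        "steatosis": frac(p.liver_histology == "steatosis" for p in ps),
        "cirrhosis": frac(p.liver_histology == "cirrhosis" for p in ps),
        "portal_hypertension": frac(p.portal_hypertension for p in ps),
        "platelets_le100": frac(p.platelets_1e9_per_L <= 100 for p in ps),
        "neoadjuvant_chemotherapy": frac(p.neoadjuvant_chemotherapy for p in ps),
        "previous_open_liver_resection": frac(p.previous_open_liver_resection for p in ps),
        "malignant": frac(any(t.malignant for t in p.resections) for p in ps),
        "child_pugh_b": frac(p.child_pugh == "B" for p in ps),
        "hybrid_approach": frac(p.approach == "hybrid_or_hand_assisted" for p in ps),
        "second_resection": frac(len(p.resections) > 1 for p in ps),
    }
    flags = [outcome_flags(o) for o in os_]
    realized_outcomes = {
        "long_operative_time": frac(f.long_operative_time for f in flags),
        "high_blood_loss": frac(f.high_blood_loss for f in flags),
        "conversion": frac(f.conversion for f in flags),
        "prolonged_los": frac(f.prolonged_los for f in flags),
        "any_complication": frac(f.any_complication for f in flags),
        "severe_complication": frac(f.severe_complication for f in flags),
        "satava_gt1": frac(o.satava_grade in ("II", "III") for o in os_),
        "margin_r1": frac(o.margin == "R1" for o in os_),
        "readmission_90d": frac(o.readmission_90d for o in os_),
        "mortality_90d": frac(o.mortality_90d for o in os_),
        "transfusion": frac(o.transfusion for o in os_),
    }
    level_of = lambda p: max(
        collapse_kawaguchi(kawaguchi_group(t, config.segment_config)) for t in p.resections
    )
    level_counts = {1: 0, 2: 0, 3: 0}
    for p in ps:
        level_counts[level_of(p)] += 1
    return GenerationReport(
        n=n,
        seed=cohort.generator_seed if cohort.generator_seed is not None else config.seed,
        config_hash=config.hash(),
        realized_marginals=realized_marginals,
        realized_outcomes=realized_outcomes,
        kawaguchi_level_freq={k: v / n for k, v in level_counts.items()},
    )
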