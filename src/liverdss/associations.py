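"""Score concordance, per-class odds ratios, and forest variable importance.

This is the comparison machinery for the four difficulty scores on a cohort:

* pairwise Spearman rank correlation of the (collapsed) difficulty levels;
* one logistic model per score and per outcome, indicator-coded against the
  lowest difficulty class, with Wald intervals and explicit flagging of
  (quasi-)separation — a class with zero events yields an unbounded ML
  estimate, reported as an undefined confidence interval rather than a
  number;
* random-forest permutation importance (out-of-bag): for every tree the
  drop in accuracy on that tree's out-of-bag samples when one predictor is
  permuted, averaged over trees.

No multiplicity correction is applied to the odds-ratio p values; each
score/outcome model stands alone.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .cohort import CohortTable, summarize_cohort
from .errors import DegenerateDesignError, DegenerateOutcomeError
from .outcomes import (
    composite_flags,
    los_percentile_threshold,
    outcome_flags,
)
from .scores import ScorePanel, score_panel
from .segments import DEFAULT_SEGMENT_CONFIG, SegmentConfig

__all__ = [
    "ORRow",
    "ConcordanceMatrix",
    "ImportanceRanking",
    "ForestSettings",
    "AnalysisConfig",
    "AssociationReport",
    "spearman_matrix",
    "fit_class_logistic",
    "per_level_odds_ratio",
    "rf_importance",
    "run_full_analysis",
]

DSS_NAMES = ("halls", "hasegawa", "kawaguchi", "iwate")

#: The nine modelled endpoints: five single outcomes plus failure of the
#: three composites (failure, so that higher difficulty raises the odds).
ANALYSIS_OUTCOMES = (
    "long_operative_time",
    "high_blood_loss",
    "conversion",
    "prolonged_los",
    "any_complication",
    "severe_complication",
    "oo_failure",
    "po_failure",
    "to_failure",
)

#: Standard-error ceiling (log-odds scale) above which a Wald interval is
#: considered divergent and reported as undefined.
SE_DIVERGENCE_LIMIT = 50.0


@dataclass(frozen=True)
class ORRow:
    """One line of a per-class odds-ratio table."""

    dss_name: str
    class_label: str
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    reference: bool
    converged: bool
    n: int
    n_events: int


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Symmetric rank-correlation matrix over the four scores."""

    names: tuple[str, ...]
    values: np.ndarray  # nan marks an undefined (zero-variance) entry

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "rho": [
                [None if np.isnan(v) else float(v) for v in row] for row in self.values
            ],
        }


@dataclass(frozen=True)
class ForestSettings:
    """Random-forest settings recorded with every importance ranking."""

    n_trees: int = 500
    seed: int = 0
    max_features: str = "sqrt"
    mode: str = "classification"


@dataclass(frozen=True)
class ImportanceRanking:
    """Permutation importances for one outcome, sorted by decreasing value
    (ties broken by variable name)."""

    outcome: str
    entries: tuple[tuple[str, float], ...]
    settings: ForestSettings
    metric: str = "oob_accuracy_decrease"

    def top(self) -> str:
        return self.entries[0][0]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "metric": self.metric,
            "settings": {
                "n_trees": self.settings.n_trees,
                "seed": self.settings.seed,
                "max_features": self.settings.max_features,
                "mode": self.settings.mode,
            },
            "importances": [
                {"variable": v, "importance": float(x)} for v, x in self.entries
            ],
        }


# ---------------------------------------------------------------------------
# Spearman concordance
# ---------------------------------------------------------------------------


def _collapsed_matrix(panels: Sequence[ScorePanel]) -> np.ndarray:
    return np.array(
        [
            [p.halls_collapsed, p.hasegawa_collapsed, p.kawaguchi_collapsed, p.iwate_collapsed]
            for p in panels
        ],
        dtype=float,
    )


_NATIVE_ORDINALS = {
    "halls": {"low": 1, "moderate": 2, "high": 3, "extremely_high": 4},
    "hasegawa": {"low": 1, "medium": 2, "high": 3},
    "kawaguchi": {"I": 1, "II": 2, "III": 3},
    "iwate": {"low": 1, "intermediate": 2, "advanced": 3, "expert": 4},
}


def _native_matrix(panels: Sequence[ScorePanel]) -> np.ndarray:
    return np.array(
        [
            [
                _NATIVE_ORDINALS["halls"][p.halls_class],
                _NATIVE_ORDINALS["hasegawa"][p.hasegawa_class],
                _NATIVE_ORDINALS["kawaguchi"][p.kawaguchi_group],
                _NATIVE_ORDINALS["iwate"][p.iwate_class],
            ]
            for p in panels
        ],
        dtype=float,
    )


def spearman_matrix(panels: Sequence[ScorePanel], collapsed: bool = True) -> ConcordanceMatrix:
    """Pairwise Spearman rho (average ranks for ties) over the four scores.

    Computed on the collapsed three-level ordinals by default; set
    ``collapsed=False`` for the native classes.  An entry involving a score
    that is constant across the cohort is undefined and reported as NaN.
    """
    if len(panels) < 3:
        raise ValueError("need at least 3 panels for a rank correlation")
    data = _collapsed_matrix(panels) if collapsed else _native_matrix(panels)
    k = data.shape[1]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = data[:, i], data[:, j]
            if np.all(a == a[0]) or np.all(b == b[0]):
                rho = np.nan
            else:
                rho = scipy.stats.spearmanr(a, b).statistic
            out[i, j] = out[j, i] = rho
    return ConcordanceMatrix(names=DSS_NAMES, values=out)


# ---------------------------------------------------------------------------
# Per-class logistic odds ratios
# ---------------------------------------------------------------------------


def fit_class_logistic(
    outcome: Sequence[bool],
    classes: Sequence,
    dss_name: str = "",
    labels: Optional[dict] = None,
) -> list[ORRow]:
    """Logistic fit of one binary outcome on difficulty class indicators.

    The lowest observed class is the reference.  Each remaining class gets
    an odds ratio (exponentiated ML coefficient), a 95% Wald interval
    ``exp(beta +/- 1.96*SE)`` and a two-sided Wald p value.  Under complete
    or quasi-separation (zero or all events in a class) the estimate
    diverges: the row is flagged ``converged=False`` and its interval is
    undefined, while the p value (computed against the divergent SE) is
    retained.
    """
    y = np.asarray(outcome, dtype=float)
    cls = np.asarray(classes)
    if y.shape[0] != cls.shape[0]:
        raise ValueError("outcome and classes must have the same length")
    levels = np.unique(cls)
    if len(levels) < 2:
        raise DegenerateDesignError(
            f"only one difficulty level observed ({levels.tolist()}); "
            "per-class odds ratios are undefined"
        )
    labels = labels or {}
    n = len(y)
    X = np.column_stack(
        [np.ones(n)] + [(cls == lv).astype(float) for lv in levels[1:]]
    )

    params = bse = None
    fit_converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            params, bse = res.params, res.bse
            fit_converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            try:
                res = model.fit(method="lbfgs", maxiter=500, disp=0)
                params, bse = res.params, res.bse
                fit_converged = False
            except Exception:
                params = bse = None

    rows = [
        ORRow(
            dss_name=dss_name,
            class_label=str(labels.get(levels[0], levels[0])),
            odds_ratio=None,
            ci_low=None,
            ci_high=None,
            p_value=None,
            reference=True,
            converged=True,
            n=int(np.sum(cls == levels[0])),
            n_events=int(np.sum(y[cls == levels[0]])),
        )
    ]
    for j, lv in enumerate(levels[1:], start=1):
        mask = cls == lv
        n_events = int(np.sum(y[mask]))
        separated = n_events == 0 or n_events == int(np.sum(mask))
        if params is None:
            rows.append(
                ORRow(dss_name, str(labels.get(lv, lv)), None, None, None, None,
                      False, False, int(np.sum(mask)), n_events)
            )
            continue
        beta = float(params[j])
        se = float(bse[j])
        ok = (
            fit_converged
            and not separated
            and np.isfinite(se)
            and se <= SE_DIVERGENCE_LIMIT
        )
        orr = float(np.exp(beta)) if np.isfinite(beta) else None
        if np.isfinite(se) and se > 0:
            p = float(2.0 * scipy.stats.norm.sf(abs(beta) / se))
        else:
            p = None
        rows.append(
            ORRow(
                dss_name=dss_name,
                class_label=str(labels.get(lv, lv)),
                odds_ratio=orr,
                ci_low=float(np.exp(beta - 1.96 * se)) if ok else None,
                ci_high=float(np.exp(beta + 1.96 * se)) if ok else None,
                p_value=p,
                reference=False,
                converged=ok,
                n=int(np.sum(mask)),
                n_events=n_events,
            )
        )
    return rows


def per_level_odds_ratio(rows: Sequence[ORRow]) -> float:
    """Pooled per-level odds ratio from a per-class OR table.

    Under a linear-in-level effect the class-k contrast estimates
    ``(k-1) * beta``; each converged non-reference row therefore yields a
    per-level estimate, combined here by inverse-variance weighting on the
    log scale.  This is the natural summary when checking that an injected
    per-level effect is recovered.
    """
    num = den = 0.0
    for step, row in enumerate(r for r in rows if not r.reference):
        if not row.converged or row.odds_ratio is None:
            continue
        k = step + 1  # levels above reference
        beta_k = np.log(row.odds_ratio) / k
        se_k = (np.log(row.ci_high) - np.log(row.ci_low)) / (2 * 1.96 * k)
        w = 1.0 / se_k**2
        num += w * beta_k
        den += w
    if den == 0.0:
        raise DegenerateDesignError("no converged non-reference rows")
    return float(np.exp(num / den))


# ---------------------------------------------------------------------------
# Random forest permutation importance
# ---------------------------------------------------------------------------


def _bootstrap_indices(tree_seed: int, n: int) -> np.ndarray:
    # the resampling scheme used by sklearn forests for each tree
    return np.random.RandomState(tree_seed).randint(0, n, n)


def rf_importance(
    features: pd.DataFrame,
    outcome: Sequence[bool],
    settings: ForestSettings = ForestSettings(),
) -> ImportanceRanking:
    """Out-of-bag permutation importance of every feature for one outcome.

    For each tree, accuracy is measured on the tree's out-of-bag rows, then
    re-measured with one feature's values permuted among those rows; the
    importance of a feature is the mean accuracy decrease over trees.
    Deterministic given ``settings.seed``.
    """
    y = np.asarray(outcome, dtype=int)
    if np.all(y == y[0]):
        raise DegenerateOutcomeError("outcome is constant; importance is undefined")
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    forest = RandomForestClassifier(
        n_estimators=settings.n_trees,
        max_features=settings.max_features,
        bootstrap=True,
        random_state=settings.seed,
        n_jobs=1,
    )
    forest.fit(X, y)

    perm_rng = np.random.default_rng(
        np.random.SeedSequence([settings.seed & 0x7FFFFFFF, zlib.crc32(b"oob-permutation")])
    )
    drops = np.zeros(p)
    used = 0
    all_idx = np.arange(n)
    for tree in forest.estimators_:
        in_bag = np.zeros(n, dtype=bool)
        in_bag[_bootstrap_indices(tree.random_state, n)] = True
        oob = all_idx[~in_bag]
        if oob.size == 0:
            continue
        Xo = X[oob].copy()
        yo = y[oob]
        base = float(np.mean(tree.predict(Xo) == yo))
        for j in range(p):
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[perm_rng.permutation(oob.size)]
            drops[j] += base - float(np.mean(tree.predict(Xo) == yo))
            Xo[:, j] = saved
        used += 1
    if used == 0:
        raise DegenerateOutcomeError("no tree had out-of-bag samples")
    drops /= used
    names = list(features.columns)
    order = sorted(range(p), key=lambda j: (-drops[j], names[j]))
    return ImportanceRanking(
        outcome="",
        entries=tuple((names[j], float(drops[j])) for j in order),
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    seed: int = 0
    trees: int = 500
    max_features: str = "sqrt"
    los_threshold: Optional[int] = None  # None = 75th percentile of the cohort
    collapsed_concordance: bool = True
    forest_mode: str = "classification"
    segment_config: SegmentConfig = field(default_factory=lambda: DEFAULT_SEGMENT_CONFIG)


@dataclass
class AssociationReport:
    """Bundle of everything the comparison produces for one cohort."""

    summary: pd.DataFrame
    panels: list[ScorePanel]
    concordance: ConcordanceMatrix
    or_tables: dict  # outcome -> dss -> list[ORRow]
    importance: dict  # outcome -> ImportanceRanking | None
    metadata: dict
    notes: list[str]

    def or_table_frame(self) -> pd.DataFrame:
        records = []
        for outcome, per_dss in self.or_tables.items():
            for dss, rows in per_dss.items():
                for r in rows:
                    records.append(
                        {
                            "outcome": outcome,
                            "dss": dss,
                            "class_label": r.class_label,
                            "odds_ratio": r.odds_ratio,
                            "ci_low": r.ci_low,
                            "ci_high": r.ci_high,
                            "p_value": r.p_value,
                            "reference": r.reference,
                            "converged": r.converged,
                            "n": r.n,
                            "n_events": r.n_events,
                        }
                    )
        return pd.DataFrame.from_records(records)


_CLASS_LABELS = {
    "halls": {1: "low", 2: "moderate", 3: "high_extremely_high"},
    "hasegawa": {1: "low", 2: "medium", 3: "high"},
    "kawaguchi": {1: "I", 2: "II", 3: "III"},
    "iwate": {1: "low", 2: "intermediate", 3: "advanced_expert"},
}

#: Forest candidate predictors besides the four collapsed scores.
_FOREST_COVARIATES = (
    "bmi",
    "asa",
    "sex_male",
    "histology_steatosis",
    "histology_cirrhosis",
    "comorb_cardiologic",
    "comorb_vascular",
    "comorb_ckd",
    "comorb_diabetes",
    "portal_hypertension",
)


def _forest_features(cohort: CohortTable, panels: Sequence[ScorePanel]) -> pd.DataFrame:
    ps = cohort.patients()
    return pd.DataFrame(
        {
            "halls": [p.halls_collapsed for p in panels],
            "hasegawa": [p.hasegawa_collapsed for p in panels],
            "kawaguchi": [p.kawaguchi_collapsed for p in panels],
            "iwate": [p.iwate_collapsed for p in panels],
            "bmi": [p.bmi for p in ps],
            "asa": [p.asa for p in ps],
            "sex_male": [1 if p.sex == "M" else 0 for p in ps],
            "histology_steatosis": [1 if p.liver_histology == "steatosis" else 0 for p in ps],
            "histology_cirrhosis": [1 if p.liver_histology == "cirrhosis" else 0 for p in ps],
            "comorb_cardiologic": [int(p.comorb_cardiologic) for p in ps],
            "comorb_vascular": [int(p.comorb_vascular) for p in ps],
            "comorb_ckd": [int(p.comorb_ckd) for p in ps],
            "comorb_diabetes": [int(p.comorb_diabetes) for p in ps],
            "portal_hypertension": [int(p.portal_hypertension) for p in ps],
        }
    )


def run_full_analysis(cohort: CohortTable, config: AnalysisConfig = AnalysisConfig()) -> AssociationReport:
    """Score, binarize, and compare: the whole pipeline on one cohort.

    Produces the cohort summary, the concordance matrix, one odds-ratio
    block per score and per endpoint (five single outcomes and failure of
    the three composites), and a forest importance ranking per endpoint.
    Degenerate fits are flagged in ``notes`` instead of aborting the run.
    """
    notes: list[str] = []
    panels = [score_panel(p, config.segment_config) for p in cohort.patients()]
    flags = [outcome_flags(o) for o in cohort.outcomes()]
    threshold = (
        config.los_threshold
        if config.los_threshold is not None
        else los_percentile_threshold(cohort)
    )
    composites = [composite_flags(o, threshold) for o in cohort.outcomes()]

    outcome_vectors = {
        "long_operative_time": np.array([f.long_operative_time for f in flags]),
        "high_blood_loss": np.array([f.high_blood_loss for f in flags]),
        "conversion": np.array([f.conversion for f in flags]),
        "prolonged_los": np.array([f.prolonged_los for f in flags]),
        "any_complication": np.array([f.any_complication for f in flags]),
        "severe_complication": np.array([f.severe_complication for f in flags]),
        "oo_failure": np.array([not c.oo for c in composites]),
        "po_failure": np.array([not c.po for c in composites]),
        "to_failure": np.array([not c.to for c in composites]),
    }
    collapsed = {
        "halls": np.array([p.halls_collapsed for p in panels]),
        "hasegawa": np.array([p.hasegawa_collapsed for p in panels]),
        "kawaguchi": np.array([p.kawaguchi_collapsed for p in panels]),
        "iwate": np.array([p.iwate_collapsed for p in panels]),
    }

    or_tables: dict = {}
    for outcome, y in outcome_vectors.items():
        or_tables[outcome] = {}
        for dss in DSS_NAMES:
            try:
                or_tables[outcome][dss] = fit_class_logistic(
                    y, collapsed[dss], dss_name=dss, labels=_CLASS_LABELS[dss]
                )
            except DegenerateDesignError as exc:
                notes.append(f"{outcome}/{dss}: {exc}")
                or_tables[outcome][dss] = []

    try:
        concordance = spearman_matrix(panels, collapsed=config.collapsed_concordance)
    except ValueError as exc:
        notes.append(f"concordance: {exc}")
        concordance = ConcordanceMatrix(names=DSS_NAMES, values=np.full((4, 4), np.nan))

    features = _forest_features(cohort, panels)
    importance: dict = {}
    for outcome, y in outcome_vectors.items():
        if len(cohort) < 50:
            notes.append(f"importance/{outcome}: skipped (fewer than 50 rows)")
            importance[outcome] = None
            continue
        settings = ForestSettings(
            n_trees=config.trees,
            seed=config.seed,
            max_features=config.max_features,
            mode=config.forest_mode,
        )
        try:
            ranking = rf_importance(features, y, settings)
            importance[outcome] = ImportanceRanking(
                outcome=outcome,
                entries=ranking.entries,
                settings=settings,
                metric=ranking.metric,
            )
        except DegenerateOutcomeError as exc:
            notes.append(f"importance/{outcome}: {exc}")
            importance[outcome] = None

    metadata = {
        "n": len(cohort),
        "seed": config.seed,
        "to_los_threshold_days": int(threshold),
        "trees": config.trees,
        "max_features": config.max_features,
        "forest_mode": config.forest_mode,
        "concordance_levels": "collapsed" if config.collapsed_concordance else "native",
        "categorical_encoding": "ordinal difficulty levels; histology indicator-expanded",
        "multiple_testing_correction": "none",
        "provenance": cohort.provenance,
    }
    return AssociationReport(
        summary=summarize_cohort(cohort),
        panels=panels,
        concordance=concordance,
        or_tables=or_tables,
        importance=importance,
        metadata=metadata,
        notes=notes,
    )
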