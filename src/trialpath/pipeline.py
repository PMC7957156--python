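"""Cohort-level analyses: per-indication and pooled model comparisons.

Each analysis fits two multi-state models to a panel cohort — one with a
biomarker covariate on the progression intensities, one without — and
compares them with a likelihood-ratio test.  Reports carry the fitted
per-phase intensities at each covariate level (the hazard-by-phase
quantities of the figure-style summaries), an overall intensity ratio
from a shared-effect model, and drug counts.  LRT p-values are reported
raw, with no multiple-testing adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from . import msm
from .msm import (
    PROGRESSION_TRANSITIONS,
    FitResult,
    LRTResult,
    PanelDataset,
    Subject,
    Transition,
    default_spec,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "SubtypeReport",
    "run_indication_analysis",
    "run_pooled_analysis",
    "run_biomarker_subtype_analysis",
]

CITriple = Tuple[float, Optional[float], Optional[float]]


@dataclass(frozen=True)
class AnalysisConfig:
    """Options shared by the cohort analyses.

    ``attach_to`` selects the transitions that carry the covariate effect
    (default: the three progression transitions — advancement and approval;
    failure intensities are covariate-free).  The overall intensity ratio
    comes from a separate fit with a single beta shared across those
    transitions.
    """

    covariate: str = "biomarker"
    attach_to: Tuple[Transition, ...] = PROGRESSION_TRANSITIONS
    exact_absorbing: Tuple[int, ...] = (4, 5)
    alpha: float = 0.05


@dataclass
class AnalysisReport:
    indication: str
    fit_no_covariate: FitResult
    fit_with_covariate: Optional[FitResult]
    fit_shared: Optional[FitResult]
    lrt: Optional[LRTResult]
    per_phase_hazards: Dict[str, Dict[str, CITriple]]
    overall_hr: Optional[CITriple]
    sample_sizes: Dict[str, int]
    counts: Dict[str, Dict[str, int]]
    diagnostics: List[str] = field(default_factory=list)


@dataclass
class SubtypeReport:
    indication: str
    fit_no_covariate: FitResult
    fit_any: Optional[FitResult]
    fit_subtype: Optional[FitResult]
    lrt_any_vs_none: Optional[LRTResult]
    lrt_exploratory_vs_validated: Optional[LRTResult]
    lrt_exploratory_vs_none: Optional[LRTResult]
    exploratory_hr: Optional[CITriple]
    per_phase_hazards: Dict[str, Dict[str, CITriple]]
    sample_sizes: Dict[str, int]
    counts: Dict[str, Dict[str, int]]
    diagnostics: List[str] = field(default_factory=list)


def _phase_label(tr: Transition) -> str:
    names = {1: "PhaseI", 2: "PhaseII", 3: "PhaseIII", 4: "Approved", 5: "Failed"}
    return f"{names[tr[0]]}->{names[tr[1]]}"


def _sample_sizes(data: PanelDataset) -> Dict[str, int]:
    """Drugs ever observed in each transient phase."""
    sizes = {"PhaseI": 0, "PhaseII": 0, "PhaseIII": 0}
    label = {1: "PhaseI", 2: "PhaseII", 3: "PhaseIII"}
    for subj in data.subjects:
        seen = {
            int(s) for s in subj.states if not isinstance(s, (frozenset, set))
        }
        for st, name in label.items():
            if st in seen:
                sizes[name] += 1
    return sizes


def _counts(data: PanelDataset, covariate: str) -> Dict[str, Dict[str, int]]:
    out: Dict[str, Dict[str, int]] = {}
    for subj in data.subjects:
        ind = subj.indication or "unknown"
        level = "with" if subj.covariates.get(covariate, 0.0) else "without"
        out.setdefault(ind, {"with": 0, "without": 0})[level] += 1
    return out


def _covariate_levels(data: PanelDataset, covariate: str) -> set:
    return {float(s.covariates.get(covariate, 0.0)) for s in data.subjects}


def _analyze(data: PanelDataset, indication: str, config: AnalysisConfig) -> AnalysisReport:
    diagnostics: List[str] = []
    logger.info("analysis cohort %s: %d drugs, %d observations",
                indication, len(data), data.n_observations)
    spec0 = default_spec(exact_absorbing=config.exact_absorbing)
    fit0 = msm.fit(data, spec0)

    levels = _covariate_levels(data, config.covariate)
    fit1 = fit_shared = None
    lrt = overall = None
    hazards: Dict[str, Dict[str, CITriple]] = {}
    if len(levels) < 2:
        diagnostics.append(
            f"covariate {config.covariate!r} has a single level in this cohort; "
            "covariate fit skipped, LRT absent"
        )
        logger.warning(diagnostics[-1])
    else:
        spec1 = default_spec(
            covariates=(config.covariate,),
            attach_to=config.attach_to,
            exact_absorbing=config.exact_absorbing,
        )
        fit1 = msm.fit(data, spec1)
        lrt = msm.likelihood_ratio_test(fit0, fit1)
        spec_sh = replace(spec1, shared_effects=True)
        fit_shared = msm.fit(data, spec_sh)
        overall = fit_shared.hazard_ratios[("shared", config.covariate)]
        for tr in config.attach_to:
            hazards[_phase_label(tr)] = {
                "without": fit1.intensity(tr, {config.covariate: 0.0}),
                "with": fit1.intensity(tr, {config.covariate: 1.0}),
            }
    return AnalysisReport(
        indication=indication,
        fit_no_covariate=fit0,
        fit_with_covariate=fit1,
        fit_shared=fit_shared,
        lrt=lrt,
        per_phase_hazards=hazards,
        overall_hr=overall,
        sample_sizes=_sample_sizes(data),
        counts=_counts(data, config.covariate),
        diagnostics=diagnostics,
    )


def run_indication_analysis(
    data: PanelDataset, indication: str, config: Optional[AnalysisConfig] = None
) -> AnalysisReport:
    """Fit and compare the with/without-covariate models on one indication."""
    config = config or AnalysisConfig()
    sub = data.filter(lambda s: s.indication == indication)
    if len(sub) == 0:
        raise ValueError(f"no drugs with indication {indication!r}")
    return _analyze(sub, indication, config)


def run_pooled_analysis(
    data: PanelDataset, config: Optional[AnalysisConfig] = None
) -> AnalysisReport:
    """Pooled analysis over all indications (indication not a covariate)."""
    config = config or AnalysisConfig()
    if len(data) == 0:
        raise ValueError("empty dataset")
    return _analyze(data, "pooled", config)


def _with_any_flag(data: PanelDataset) -> PanelDataset:
    subjects = []
    for s in data.subjects:
        covs = dict(s.covariates)
        covs["biomarker_any"] = float(
            bool(covs.get("exploratory", 0.0)) or bool(covs.get("validated", 0.0))
        )
        subjects.append(
            Subject(s.drug_id, s.times.copy(), s.states, covs, s.indication)
        )
    return PanelDataset(subjects)


def run_biomarker_subtype_analysis(
    data: PanelDataset, config: Optional[AnalysisConfig] = None
) -> SubtypeReport:
    """Three-level biomarker analysis: none (reference) / exploratory / validated.

    Subjects must carry ``exploratory`` and ``validated`` indicator
    covariates.  Single shared betas (one per indicator, common to the
    progression transitions) keep the contrasts one degree of freedom each:

    * any-biomarker vs none — base model against a single any-biomarker beta;
    * exploratory vs validated — equal-betas model against separate betas
      (the equality constraint is the nesting, asserted with df=1);
    * exploratory vs none — fitted on the cohort without validated drugs.
    """
    config = config or AnalysisConfig()
    diagnostics: List[str] = []
    data = _with_any_flag(data)
    spec0 = default_spec(exact_absorbing=config.exact_absorbing)
    fit0 = msm.fit(data, spec0)

    levels = {
        (float(s.covariates.get("exploratory", 0)), float(s.covariates.get("validated", 0)))
        for s in data.subjects
    }
    has_expl = any(l[0] for l in levels)
    has_valid = any(l[1] for l in levels)
    has_none = (0.0, 0.0) in levels

    fit_any = fit_sub = None
    lrt_any = lrt_ev = lrt_en = None
    expl_hr = None
    hazards: Dict[str, Dict[str, CITriple]] = {}

    if not (has_expl or has_valid) or not has_none:
        diagnostics.append("degenerate biomarker levels; covariate fits skipped")
        return SubtypeReport(
            "pooled", fit0, None, None, None, None, None, None, {},
            _sample_sizes(data), _counts(data, "biomarker_any"), diagnostics,
        )

    spec_any = default_spec(
        covariates=("biomarker_any",), attach_to=config.attach_to,
        shared_effects=True, exact_absorbing=config.exact_absorbing,
    )
    fit_any = msm.fit(data, spec_any)
    lrt_any = msm.likelihood_ratio_test(fit0, fit_any)

    if has_expl and has_valid:
        spec_sub = default_spec(
            covariates=("exploratory", "validated"), attach_to=config.attach_to,
            shared_effects=True, exact_absorbing=config.exact_absorbing,
        )
        fit_sub = msm.fit(data, spec_sub)
        # null: equal exploratory/validated effects == the any-biomarker model
        lrt_ev = msm.likelihood_ratio_test(fit_any, fit_sub, df=1)
        for tr in config.attach_to:
            hazards[_phase_label(tr)] = {
                "none": fit_sub.intensity(tr, {}),
                "exploratory": fit_sub.intensity(tr, {"exploratory": 1.0}),
                "validated": fit_sub.intensity(tr, {"validated": 1.0}),
            }
    else:
        diagnostics.append("one biomarker subtype level empty; subtype contrast skipped")

    if has_expl:
        no_valid = data.filter(lambda s: not s.covariates.get("validated", 0.0))
        f0 = msm.fit(no_valid, spec0)
        spec_e = default_spec(
            covariates=("exploratory",), attach_to=config.attach_to,
            shared_effects=True, exact_absorbing=config.exact_absorbing,
        )
        fe = msm.fit(no_valid, spec_e)
        lrt_en = msm.likelihood_ratio_test(f0, fe)
        expl_hr = fe.hazard_ratios[("shared", "exploratory")]
    else:
        diagnostics.append("no exploratory drugs; exploratory-vs-none contrast skipped")

    return SubtypeReport(
        indication="pooled",
        fit_no_covariate=fit0,
        fit_any=fit_any,
        fit_subtype=fit_sub,
        lrt_any_vs_none=lrt_any,
        lrt_exploratory_vs_validated=lrt_ev,
        lrt_exploratory_vs_none=lrt_en,
        exploratory_hr=expl_hr,
        per_phase_hazards=hazards,
        sample_sizes=_sample_sizes(data),
        counts=_counts(data, "biomarker_any"),
        diagnostics=diagnostics,
    )
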