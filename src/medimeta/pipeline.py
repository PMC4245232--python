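"""End-to-end orchestration: per-study mediation fits, estimate selection,
two random-effects meta-analyses, and report writing.

The pipeline mirrors how a combined analysis of the neurogenesis
literature is run: each study is standardised and fitted separately, the
fitted effects are oriented so that positive always means better
performance, one estimate per study (the most precise) enters each pooled
analysis, and the mediated (indirect) and other-mechanisms (direct)
effects are pooled in two independent meta-analyses.  Studies that fail
their preconditions are recorded as skipped with the reason and the run
continues.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .association import AssociationResult, within_group_association
from .data_model import StudyDataset, prepare_study
from .errors import EmptyInputError, MediMetaError
from .mediation import (
    EffectEstimate,
    MediationConfig,
    effect_estimate,
    fit_mediation,
    orient_effects,
    percent_mediated,
)
from .meta import MetaResult, random_effects_meta, select_most_precise

__all__ = [
    "PipelineConfig",
    "StudyResult",
    "AnalysisReport",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger("medimeta")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full combined analysis.

    ``seed`` drives every sampler; each study's chains get an independent
    stream derived from (seed, study index) so reruns are bit-reproducible
    and studies can be added without perturbing earlier ones' draws.
    """

    mediation: MediationConfig = MediationConfig()
    seed: int = 0
    primary_outcome_order: tuple[str, ...] = ()
    clamp_percent: bool = False


@dataclass
class StudyResult:
    study_id: str
    outcome: str
    indirect: EffectEstimate
    direct: EffectEstimate
    max_rhat: float
    converged: bool | None
    sign_flipped: bool
    association: AssociationResult


@dataclass
class AnalysisReport:
    per_study: list[StudyResult]
    combined: dict[str, MetaResult]  # keys: "indirect", "direct"
    percent_contribution: float
    skipped: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _study_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def run_full_analysis(
    studies: list[StudyDataset], config: PipelineConfig | None = None
) -> AnalysisReport:
    """Run the whole combined analysis over a list of study datasets.

    Per study: standardise, fit the mediation model, orient effects by the
    declared outcome orientation, summarise indirect and direct effects,
    and run the within-group association check.  Then select the most
    precise estimate per study and pool indirect and direct effects in two
    independent random-effects meta-analyses.  The headline percent
    contribution of the mediator is computed from the two pooled means.
    """
    config = config or PipelineConfig()
    if not studies:
        raise EmptyInputError("no studies supplied")

    results: list[StudyResult] = []
    skipped: list[tuple[str, str]] = []
    for i, ds in enumerate(studies):
        sid = ds.meta.study_id
        try:
            std = prepare_study(ds, clamp_percent=config.clamp_percent)
            med_cfg = replace(config.mediation, seed=_study_seed(config.seed, i))
            post = fit_mediation(std, med_cfg)
            rhat = max(post.rhat.values()) if med_cfg.n_chains >= 2 else float("nan")
            post = orient_effects(post, ds.meta.orientation)
            outcome = ds.meta.behaviour_test
            results.append(
                StudyResult(
                    study_id=sid,
                    outcome=outcome,
                    indirect=effect_estimate(post, "indirect", outcome=outcome),
                    direct=effect_estimate(post, "direct", outcome=outcome),
                    max_rhat=rhat,
                    converged=post.converged,
                    sign_flipped=post.sign_flipped,
                    association=within_group_association(std),
                )
            )
            log.info("fitted study %s (max R-hat %.4f)", sid, rhat)
        except MediMetaError as exc:
            skipped.append((sid, str(exc)))
            log.warning("skipping study %s: %s", sid, exc)

    if not results:
        raise EmptyInputError(
            "no study could be analysed; reasons: "
            + "; ".join(f"{s}: {r}" for s, r in skipped)
        )

    order = list(config.primary_outcome_order)
    combined = {}
    selected_ids: dict[str, list[str]] = {}
    for quantity in ("indirect", "direct"):
        ests = [getattr(r, quantity) for r in results]
        chosen = select_most_precise(ests, primary_outcome_order=order)
        selected_ids[quantity] = [f"{e.study_id}:{e.outcome}" for e in chosen]
        combined[quantity] = random_effects_meta(chosen)

    pct = percent_mediated(combined["indirect"].pooled, combined["direct"].pooled)

    # one row per selected study in the report
    keep = {s.split(":")[0] for s in selected_ids["indirect"]}
    per_study, seen = [], set()
    for r in results:
        if r.study_id in keep and r.study_id not in seen:
            per_study.append(r)
            seen.add(r.study_id)

    provenance = {
        "package": "medimeta",
        "version": __version__,
        "seed": config.seed,
        "mediation_config": dataclasses.asdict(config.mediation),
        "selected_estimates": selected_ids,
        "n_input_datasets": len(studies),
        "n_fitted": len(results),
    }
    return AnalysisReport(
        per_study=per_study,
        combined=combined,
        percent_contribution=pct,
        skipped=skipped,
        provenance=provenance,
    )


def _estimate_row(e: EffectEstimate) -> dict:
    return {
        "study_id": e.study_id,
        "quantity": e.quantity,
        "y": e.y,
        "v": e.v,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "sign_flipped": e.sign_flipped,
        "outcome": e.outcome,
    }


def write_report(report: AnalysisReport, out_dir) -> dict[str, Path]:
    """Write the forest table (CSV), full-precision JSON report, and a
    human-readable log of decisions taken during the run.

    The forest CSV has one row per study and quantity plus two combined
    rows (indirect, direct).  Reruns with identical inputs and seeds
    produce byte-identical files.
    """
    if not report.per_study:
        raise EmptyInputError("report contains no studies")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    forest_path = out / "forest.csv"
    cols = ["study_id", "quantity", "y", "v", "ci_low", "ci_high", "sign_flipped", "outcome"]
    with forest_path.open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for r in report.per_study:
            w.writerow(_estimate_row(r.indirect))
            w.writerow(_estimate_row(r.direct))
        for quantity in ("indirect", "direct"):
            m = report.combined[quantity]
            w.writerow(
                {
                    "study_id": "COMBINED",
                    "quantity": quantity,
                    "y": m.pooled,
                    "v": m.se**2,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "sign_flipped": False,
                    "outcome": "",
                }
            )

    json_path = out / "report.json"
    payload = {
        "per_study": [
            {
                "study_id": r.study_id,
                "outcome": r.outcome,
                "indirect": _estimate_row(r.indirect),
                "direct": _estimate_row(r.direct),
                "max_rhat": r.max_rhat,
                "converged": r.converged,
                "sign_flipped": r.sign_flipped,
                "association": dataclasses.asdict(r.association),
            }
            for r in report.per_study
        ],
        "combined": {q: dataclasses.asdict(m) for q, m in report.combined.items()},
        "percent_contribution": report.percent_contribution,
        "skipped": report.skipped,
        "provenance": report.provenance,
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    log_path = out / "run_log.txt"
    lines = [
        f"medimeta combined analysis ({len(report.per_study)} studies pooled)",
        "",
    ]
    for r in report.per_study:
        lines.append(
            f"{r.study_id}: indirect {r.indirect.y:+.3f} "
            f"[{r.indirect.ci_low:+.3f}, {r.indirect.ci_high:+.3f}], "
            f"direct {r.direct.y:+.3f}, max R-hat {r.max_rhat:.4f}"
            + (" (sign reversed)" if r.sign_flipped else "")
            + ("" if r.converged in (True, None) else " [CONVERGENCE WARNING]")
        )
    for sid, reason in report.skipped:
        lines.append(f"SKIPPED {sid}: {reason}")
    mi, md = report.combined["indirect"], report.combined["direct"]
    lines += [
        "",
        f"pooled indirect: {mi.pooled:+.3f} [{mi.ci_low:+.3f}, {mi.ci_high:+.3f}], "
        f"p = {mi.p:.3g}; tau^2 = {mi.tau2:.3g} (SE {mi.tau2_se:.3g}), "
        f"Q({mi.df}) = {mi.Q:.2f}, p = {mi.p_Q:.3g}",
        f"pooled direct:   {md.pooled:+.3f} [{md.ci_low:+.3f}, {md.ci_high:+.3f}], "
        f"p = {md.p:.3g}",
        f"percent of total effect through the mediator: "
        f"{report.percent_contribution:.1f}%",
    ]
    log_path.write_text("\n".join(lines) + "\n")

    return {"forest": forest_path, "json": json_path, "log": log_path}
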