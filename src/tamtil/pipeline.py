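"""End-to-end deconvolution pipeline: discovery -> signature -> scores.

Chains the per-target stages -- design construction, per-CpG linear
models, empirical-Bayes moderation, top-K selection, the
hypomethylated-only filter and elastic-net training -- so a cohort with
measured infiltration yields ready-to-apply TAM and TIL signatures in one
call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffmeth import (
    ModeratedStats,
    SelectionResult,
    build_design,
    empirical_bayes_moderation,
    filter_hypomethylated,
    fit_cpg_linear_models,
    rank_and_select,
)
from .signature import SignatureModel, TrainingConfig, train_signature

__all__ = ["TargetResult", "learn_signature", "learn_signatures"]


@dataclass
class TargetResult:
    """Everything the discovery stage produces for one immune-cell target."""

    target: str
    stats: ModeratedStats
    selection: SelectionResult
    hypo_cpgs: pd.Index
    model: SignatureModel


def learn_signature(
    beta: pd.DataFrame,
    clinical: pd.DataFrame,
    target: str = "tam",
    k_per_direction: int = 300,
    padj_threshold: float | None = None,
    adjust_grade: bool = True,
    training: TrainingConfig = TrainingConfig(),
) -> TargetResult:
    """Discover infiltration-associated CpGs and train one signature.

    ``beta`` must be complete (merged and filtered); ``clinical`` provides
    the measured ``<target>_pct`` outcome and WHO grade for every sample
    in ``beta``.
    """
    design = build_design(clinical.loc[beta.columns], outcome=target,
                          adjust_grade=adjust_grade)
    fits = fit_cpg_linear_models(beta, design)
    stats = empirical_bayes_moderation(fits)
    selection = rank_and_select(stats, k_per_direction=k_per_direction,
                                padj_threshold=padj_threshold)
    hypo = filter_hypomethylated(selection)
    model = train_signature(
        beta.loc[hypo], clinical[f"{target}_pct"], training, target=target
    )
    return TargetResult(target=target, stats=stats, selection=selection,
                        hypo_cpgs=hypo, model=model)


def learn_signatures(
    beta: pd.DataFrame,
    clinical: pd.DataFrame,
    targets: tuple[str, ...] = ("tam", "til"),
    **kwargs,
) -> dict[str, TargetResult]:
    """Run :func:`learn_signature` independently per target (TAM and TIL)."""
    return {t: learn_signature(beta, clinical, target=t, **kwargs) for t in targets}
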