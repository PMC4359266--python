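"""End-to-end orchestration: universe → gold standards → evidence → model
→ evaluation → network → hubs.

This is the programmatic equivalent of the CLI's ``run-all``: generate (or
accept) a synthetic universe, build GSP/GSN and the held-out standard test
set, assemble evidence, fit the binned likelihood-ratio model, evaluate on
the test set, threshold the global network and call hubs. All stages are
deterministic given the universe configuration's seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .bayes import (
    BinningConfig,
    DEFAULT_LR_CUTOFF,
    LikelihoodModel,
    PredictedNetwork,
    build_network,
    fit_likelihood_model,
)
from .evaluation import RocCurve, evaluate_on_sts
from .evidence import build_evidence_table
from .gold_standards import GoldStandard, build_gsn, build_gsp, build_sts
from .hub_analysis import HubThresholds, identify_hubs
from .pairs import ProteinPair
from .synthgen import Universe, UniverseConfig, generate_universe


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    universe: Universe
    gold: GoldStandard
    sts: list[tuple[ProteinPair, bool]]
    evidence: pd.DataFrame
    model: LikelihoodModel
    roc: RocCurve
    evaluation_summary: dict[str, float]
    network: PredictedNetwork | None = None
    hub_report: pd.DataFrame | None = None


def run_pipeline(
    config: UniverseConfig,
    *,
    universe: Universe | None = None,
    binning: BinningConfig | None = None,
    pseudocount: float = 1.0,
    prior_odds: float = 1.0,
    lr_cutoff: float = DEFAULT_LR_CUTOFF,
    n_sts_negative: int | None = None,
    build_full_network: bool = True,
    hub_thresholds: HubThresholds | None = None,
) -> PipelineResult:
    """Run the full inference pipeline on a (generated) synthetic universe.

    ``n_sts_negative`` defaults to the number of held-out positives, giving a
    balanced test set. When ``build_full_network`` is set, every protein pair
    in the universe is scored as a network candidate and hubs are called on
    the thresholded network; otherwise only the gold and test pairs are
    scored, which is much cheaper.
    """
    if universe is None:
        universe = generate_universe(config)

    gsp, source_counts = build_gsp(universe.sources)
    gold = build_gsn(universe.localization, gsp)
    gold.source_counts = source_counts

    positives = universe.heldout_edges
    if not positives:
        raise ValueError(
            "universe has no held-out true edges; increase sts_holdout_frac"
            " or true_density"
        )
    n_neg = len(positives) if n_sts_negative is None else n_sts_negative
    sts = build_sts(
        positives,
        universe.proteins,
        n_negative=n_neg,
        seed=config.seed,
        exclude=universe.true_edges | gsp,
    )

    if build_full_network:
        pairs = set(itertools.combinations(sorted(universe.proteins), 2))
    else:
        pairs = set(gold.gsp) | set(gold.gsn) | {p for p, _ in sts}
    evidence = build_evidence_table(pairs, universe)

    model = fit_likelihood_model(
        evidence,
        gold,
        binning,
        pseudocount=pseudocount,
        prior_odds=prior_odds,
    )
    roc, summary = evaluate_on_sts(sts, evidence, model, lr_cutoff=lr_cutoff)

    network = None
    hub_report = None
    if build_full_network:
        candidates = pairs - gold.gsp
        network = build_network(
            candidates, evidence, model, lr_cutoff=lr_cutoff, gsp=gold.gsp
        )
        hub_report = identify_hubs(
            network,
            universe.cancer_proteins,
            universe.expression,
            universe.sample_labels,
            thresholds=hub_thresholds,
        )
    return PipelineResult(
        universe=universe,
        gold=gold,
        sts=sts,
        evidence=evidence,
        model=model,
        roc=roc,
        evaluation_summary=summary,
        network=network,
        hub_report=hub_report,
    )


def sts_auc(config: UniverseConfig, **kwargs) -> float:
    """Convenience: held-out test-set AUC for a configuration (no network)."""
    result = run_pipeline(config, build_full_network=False, **kwargs)
    return result.roc.auc
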