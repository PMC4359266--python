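"""Naive Bayesian integration of evidence channels into composite LRs.

Each evidence channel is discretized into bins and, for every bin, a
likelihood ratio is estimated from the gold standards:

    LR(bin) = P(value in bin | interacting) / P(value in bin | non-interacting)

with add-pseudocount smoothing so every LR is finite and positive. Under the
naive (conditional independence) assumption the composite likelihood ratio
of a pair is the product of its per-channel bin LRs,

    LR(E1, ..., En) = Π LR(Ei),        O_posterior = O_prior · LR,

accumulated in log space. A channel with missing evidence for a pair
contributes a factor of 1 (uninformative). The predicted network keeps every
candidate pair whose composite LR clears a cutoff (113 by default, the
conventional operating point for this procedure at proteome scale) and
appends the gold-positive pairs wholesale, flagged by provenance.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .evidence import CHANNELS
from .gold_standards import GoldStandard
from .pairs import ProteinPair

logger = logging.getLogger(__name__)

DEFAULT_LR_CUTOFF = 113.0


@dataclass(frozen=True)
class BinningConfig:
    """How each channel is discretized before LR estimation.

    Correlation is cut at quantile edges computed on the pooled gold values
    (``n_rho_bins`` equal-frequency bins). Domain support is presence/absence
    by default (``{0, ≥1}``). Interolog counts get one bin per observed
    count. Shared-process size is cut at fixed thresholds: with the default
    interior edges the bins are [2,5), [5,10), [10,25), [25,100), [100,∞).
    """

    n_rho_bins: int = 10
    ssbp_edges: tuple[float, ...] = (5.0, 10.0, 25.0, 100.0)
    ddi_presence: bool = True


@dataclass
class ChannelLR:
    """Bin edges and per-bin likelihood ratios for one evidence channel.

    ``edges`` is ascending with −inf/+inf sentinels; bin *i* covers
    ``[edges[i], edges[i+1])``, so any finite value falls in exactly one bin
    and out-of-range values land in an edge bin.
    """

    name: str
    edges: np.ndarray
    count_gsp: np.ndarray
    count_gsn: np.ndarray
    lr: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_index(self, value: float) -> int:
        return int(np.searchsorted(self.edges, value, side="right")) - 1

    def bin_indices(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges, values, side="right") - 1

    def lr_for(self, value: float) -> float:
        return float(self.lr[self.bin_index(value)])


@dataclass
class LikelihoodModel:
    """Fitted per-channel binned likelihood ratios plus the prior odds."""

    channels: dict[str, ChannelLR]
    pseudocount: float = 1.0
    prior_odds: float = 1.0
    n_gsp: int = 0
    n_gsn: int = 0
    training_gsp: frozenset[ProteinPair] | None = None

    def to_json(self, path: str | Path) -> None:
        doc = {
            "pseudocount": self.pseudocount,
            "prior_odds": self.prior_odds,
            "n_gsp": self.n_gsp,
            "n_gsn": self.n_gsn,
            "channels": {
                name: {
                    "edges": [*map(float, ch.edges)],
                    "count_gsp": [*map(int, ch.count_gsp)],
                    "count_gsn": [*map(int, ch.count_gsn)],
                    "lr": [*map(float, ch.lr)],
                }
                for name, ch in self.channels.items()
            },
            "training_gsp": None
            if self.training_gsp is None
            else sorted(map(list, self.training_gsp)),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "LikelihoodModel":
        with open(path) as fh:
            doc = json.load(fh)
        channels = {
            name: ChannelLR(
                name=name,
                edges=np.asarray(payload["edges"], dtype=float),
                count_gsp=np.asarray(payload["count_gsp"], dtype=int),
                count_gsn=np.asarray(payload["count_gsn"], dtype=int),
                lr=np.asarray(payload["lr"], dtype=float),
            )
            for name, payload in doc["channels"].items()
        }
        training = doc.get("training_gsp")
        return cls(
            channels=channels,
            pseudocount=doc["pseudocount"],
            prior_odds=doc["prior_odds"],
            n_gsp=doc["n_gsp"],
            n_gsn=doc["n_gsn"],
            training_gsp=None
            if training is None
            else frozenset(tuple(p) for p in training),
        )


def _channel_edges(
    name: str, pooled: np.ndarray, config: BinningConfig
) -> np.ndarray | None:
    """Interior-edge selection per channel; None means 'cannot bin'."""
    if name == "rho":
        qs = np.linspace(0.0, 1.0, config.n_rho_bins + 1)[1:-1]
        interior = np.unique(np.quantile(pooled, qs))
    elif name == "ddi_hit":
        if config.ddi_presence:
            interior = np.array([1.0])
        else:
            interior = np.unique(pooled)[1:]
    elif name == "interolog_count":
        interior = np.unique(pooled)[1:]
    elif name == "ssbp_size":
        interior = np.asarray(config.ssbp_edges, dtype=float)
    else:  # pragma: no cover - guarded by CHANNELS
        raise ValueError(f"unknown channel {name!r}")
    return np.concatenate(([-np.inf], interior, [np.inf]))


def fit_likelihood_model(
    evidence: pd.DataFrame,
    gold: GoldStandard,
    bins_config: BinningConfig | None = None,
    *,
    pseudocount: float = 1.0,
    prior_odds: float = 1.0,
) -> LikelihoodModel:
    """Estimate per-bin likelihood ratios from the gold standards.

    For each channel the gold pairs with observed values are counted per bin
    and smoothed:

        lr = ((c_gsp + k) / (N_gsp + k·B)) / ((c_gsn + k) / (N_gsn + k·B))

    with ``k`` the pseudocount, ``B`` the number of bins and ``N`` the
    per-side totals of non-missing gold pairs. A channel with no observed
    value on either gold side is dropped with a warning. The training GSP is
    recorded on the model so later evaluation can detect leakage.
    """
    if bins_config is None:
        bins_config = BinningConfig()
    if not gold.gsp:
        raise ValueError("empty GSP: cannot fit likelihood model")
    if not gold.gsn:
        raise ValueError("empty GSN: cannot fit likelihood model")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    idx_pairs = set(evidence.index)
    gsp_idx = sorted(p for p in gold.gsp if p in idx_pairs)
    gsn_idx = sorted(p for p in gold.gsn if p in idx_pairs)
    if not gsp_idx or not gsn_idx:
        raise ValueError("evidence table lacks rows for one of the gold sets")
    ev_gsp = evidence.loc[gsp_idx]
    ev_gsn = evidence.loc[gsn_idx]

    channels: dict[str, ChannelLR] = {}
    for name in CHANNELS:
        vp = ev_gsp[name].dropna().to_numpy()
        vn = ev_gsn[name].dropna().to_numpy()
        if vp.size == 0 or vn.size == 0:
            logger.warning(
                "channel %r has no observed values in %s; dropped",
                name,
                "GSP" if vp.size == 0 else "GSN",
            )
            continue
        edges = _channel_edges(name, np.concatenate([vp, vn]), bins_config)
        n_bins = len(edges) - 1
        bp = np.searchsorted(edges, vp, side="right") - 1
        bn = np.searchsorted(edges, vn, side="right") - 1
        count_gsp = np.bincount(bp, minlength=n_bins)
        count_gsn = np.bincount(bn, minlength=n_bins)
        k = pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            p_pos = (count_gsp + k) / (vp.size + k * n_bins)
            p_neg = (count_gsn + k) / (vn.size + k * n_bins)
            lr = p_pos / p_neg
        channels[name] = ChannelLR(
            name=name,
            edges=edges,
            count_gsp=count_gsp,
            count_gsn=count_gsn,
            lr=lr,
        )
    return LikelihoodModel(
        channels=channels,
        pseudocount=pseudocount,
        prior_odds=prior_odds,
        n_gsp=len(gold.gsp),
        n_gsn=len(gold.gsn),
        training_gsp=frozenset(gold.gsp),
    )


def composite_lr(
    pair_evidence: Mapping[str, float | None], model: LikelihoodModel
) -> float:
    """Composite likelihood ratio for one pair: product of per-bin LRs.

    Missing channels (``None`` or NaN) contribute a factor of 1. The product
    is accumulated in log space and returned on the natural scale.
    """
    log_lr = 0.0
    for name, channel in model.channels.items():
        value = pair_evidence.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        log_lr += math.log(channel.lr_for(float(value)))
    return math.exp(log_lr)


def score_table(evidence: pd.DataFrame, model: LikelihoodModel) -> pd.Series:
    """Composite LR for every pair in an evidence table (vectorized)."""
    log_lr = np.zeros(len(evidence))
    for name, channel in model.channels.items():
        values = evidence[name].to_numpy(dtype=float)
        observed = ~np.isnan(values)
        if observed.any():
            bins = channel.bin_indices(values[observed])
            log_lr[observed] += np.log(channel.lr[bins])
    return pd.Series(np.exp(log_lr), index=evidence.index, name="composite_lr")


def posterior_odds(composite: float, prior_odds: float) -> float:
    """Posterior odds of interaction: prior odds times the composite LR."""
    if composite <= 0:
        raise ValueError(f"composite LR must be positive, got {composite}")
    if prior_odds <= 0:
        raise ValueError(f"prior odds must be positive, got {prior_odds}")
    return prior_odds * composite


@dataclass
class PredictedNetwork:
    """LR-thresholded predicted edges plus the appended gold positives."""

    edges: dict[ProteinPair, float]
    lr_cutoff: float
    provenance: dict[ProteinPair, str] = field(default_factory=dict)

    @property
    def proteins(self) -> set[str]:
        return {p for pair in self.edges for p in pair}

    def summary(self) -> dict[str, int]:
        n_pred = sum(1 for v in self.provenance.values() if v == "prediction")
        return {
            "n_edges": len(self.edges),
            "n_proteins": len(self.proteins),
            "n_predicted": n_pred,
            "n_gold_positive": len(self.edges) - n_pred,
        }

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        for (a, b), lr in self.edges.items():
            g.add_edge(a, b, lr=lr, provenance=self.provenance[(a, b)])
        return g


def build_network(
    candidate_pairs: Iterable[ProteinPair],
    evidence: pd.DataFrame,
    model: LikelihoodModel,
    lr_cutoff: float = DEFAULT_LR_CUTOFF,
    gsp: set[ProteinPair] | None = None,
) -> PredictedNetwork:
    """Threshold composite LRs into the predicted global network.

    Candidate pairs scoring ``composite LR ≥ lr_cutoff`` (inclusive) are kept
    as predictions; gold-positive pairs are then appended wholesale with
    ``gold_positive`` provenance regardless of score. An empty result is a
    warning, not an error.
    """
    if lr_cutoff <= 0:
        raise ValueError("lr_cutoff must be positive")
    gsp = gsp or set()
    candidates = set(candidate_pairs)
    in_table = set(evidence.index)
    rows = sorted((candidates | gsp) & in_table)
    scored = (
        score_table(evidence.loc[rows], model)
        if rows
        else pd.Series(dtype=float)
    )

    edges: dict[ProteinPair, float] = {}
    provenance: dict[ProteinPair, str] = {}
    for pair in sorted(candidates & in_table):
        lr = float(scored[pair])
        if lr >= lr_cutoff and pair not in gsp:
            edges[pair] = lr
            provenance[pair] = "prediction"
    for pair in gsp:
        edges[pair] = float(scored[pair]) if pair in in_table else float("nan")
        provenance[pair] = "gold_positive"
    if not edges:
        logger.warning("no edge survives lr_cutoff=%g and GSP is empty", lr_cutoff)
    return PredictedNetwork(edges=edges, lr_cutoff=lr_cutoff, provenance=provenance)
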