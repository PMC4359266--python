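"""Gold-standard positive/negative interaction sets and the held-out test set.

The positive set (GSP) is the deduplicated union of several curated
interaction sources. The negative set (GSN) exploits compartment
incompatibility: proteins annotated to the plasma membrane rarely interact
with proteins annotated to the nucleus, so all membrane-only × nucleus-only
pairs are presumed non-interacting. Proteins annotated to both compartments
are removed before pairing, and any candidate negative that appears in the
GSP is dropped and recorded. A standard test set (STS) of held-out labelled
pairs supports honest evaluation of a model trained on GSP/GSN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pairs import ProteinPair, canonical_pair, canonical_pair_set

logger = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    """Disjoint positive and negative pair sets with construction provenance."""

    gsp: set[ProteinPair]
    gsn: set[ProteinPair]
    removed_dual_proteins: set[str] = field(default_factory=set)
    overlap_removed: set[ProteinPair] = field(default_factory=set)
    source_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert not (self.gsp & self.gsn), "GSP and GSN must be disjoint"


def build_gsp(
    sources: dict[str, set[tuple[str, str]]],
) -> tuple[set[ProteinPair], dict[str, dict[str, int]]]:
    """Union the source interactomes into the Gold Standard Positive set.

    Pairs are canonicalized and deduplicated; self-pairs are dropped with a
    logged warning. Returns the GSP plus per-source tallies of pair and
    unique-protein counts (with a ``"union"`` entry for the total).

    Raises
    ------
    ValueError
        If no sources are given or the union is empty.
    """
    if not sources:
        raise ValueError("at least one source is required")
    gsp: set[ProteinPair] = set()
    counts: dict[str, dict[str, int]] = {}
    for name, pairs in sources.items():
        canon = canonical_pair_set(pairs, drop_self=True)
        proteins = {p for pair in canon for p in pair}
        counts[name] = {"pairs": len(canon), "proteins": len(proteins)}
        gsp |= canon
    if not gsp:
        raise ValueError("no positive pairs: union of sources is empty")
    counts["union"] = {
        "pairs": len(gsp),
        "proteins": len({p for pair in gsp for p in pair}),
    }
    return gsp, counts


def build_gsn(
    localization: dict[str, frozenset[str] | set[str]],
    gsp: set[ProteinPair],
) -> GoldStandard:
    """Build the Gold Standard Negative set from compartment incompatibility.

    Candidate negatives are all (membrane-only, nucleus-only) protein pairs.
    Proteins localized to both compartments are excluded before pairing and
    reported in ``removed_dual_proteins``; candidates present in the GSP are
    excluded and reported in ``overlap_removed``. Proteins annotated only to
    other compartments never enter the GSN.
    """
    membrane = {p for p, loc in localization.items() if "membrane" in loc}
    nuclear = {p for p, loc in localization.items() if "nucleus" in loc}
    dual = membrane & nuclear
    membrane_only = membrane - dual
    nuclear_only = nuclear - dual
    if not membrane_only:
        raise ValueError("no membrane-only proteins: cannot build GSN")
    if not nuclear_only:
        raise ValueError("no nucleus-only proteins: cannot build GSN")

    gsn: set[ProteinPair] = set()
    overlap_removed: set[ProteinPair] = set()
    for m in membrane_only:
        for nu in nuclear_only:
            pair = canonical_pair(m, nu)
            if pair in gsp:
                overlap_removed.add(pair)
            else:
                gsn.add(pair)
    return GoldStandard(
        gsp=set(gsp),
        gsn=gsn,
        removed_dual_proteins=dual,
        overlap_removed=overlap_removed,
    )


def build_sts(
    truth_pairs: set[ProteinPair],
    universe_proteins: list[str],
    n_negative: int,
    seed: int,
    *,
    exclude: set[ProteinPair] | None = None,
) -> list[tuple[ProteinPair, bool]]:
    """Assemble the labelled Standard Test Set.

    ``truth_pairs`` are held-out positives (disjoint from the training GSP by
    construction upstream). Negatives are ``n_negative`` pairs sampled
    uniformly without replacement from pairs that are neither positives nor
    in ``exclude`` (pass the full true interactome to keep negative labels
    honest). Returns ``[(pair, is_positive), ...]`` sorted for
    reproducibility; sampling is driven by ``seed`` alone.
    """
    if n_negative < 1:
        raise ValueError("n_negative must be >= 1")
    positives = canonical_pair_set(truth_pairs)
    excluded = positives | (canonical_pair_set(exclude) if exclude else set())
    prots = sorted(universe_proteins)
    candidates = [
        (a, b)
        for i, a in enumerate(prots)
        for b in prots[i + 1 :]
        if (a, b) not in excluded
    ]
    if n_negative > len(candidates):
        raise ValueError(
            f"n_negative={n_negative} exceeds the {len(candidates)}"
            " available non-positive pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_negative, replace=False)
    negatives = {candidates[i] for i in idx}
    labelled = [(p, True) for p in sorted(positives)] + [
        (p, False) for p in sorted(negatives)
    ]
    return labelled


def write_gold_standard(gold: GoldStandard, directory: str | Path) -> None:
    """Serialize GSP/GSN/overlap TSVs plus a JSON provenance sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for fname, pairs in (
        ("gsp.tsv", gold.gsp),
        ("gsn.tsv", gold.gsn),
        ("overlap_removed.tsv", gold.overlap_removed),
    ):
        with open(d / fname, "w") as fh:
            fh.write("#protein_a\tprotein_b\n")
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\n")
    sidecar = {
        "n_gsp": len(gold.gsp),
        "n_gsn": len(gold.gsn),
        "n_overlap_removed": len(gold.overlap_removed),
        "removed_dual_proteins": sorted(gold.removed_dual_proteins),
        "source_counts": gold.source_counts,
    }
    with open(d / "gold_provenance.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
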