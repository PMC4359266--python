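"""Per-pair evidence channels for interaction inference.

Four independent lines of evidence are computed for each candidate pair:

co-expression (``rho``)
    Pearson correlation between the two proteins' expression profiles,
    using sample (n−1) standard deviations. Interacting partners tend to be
    co-expressed.
domain support (``ddi_hit``)
    Number of unordered domain pairs, one domain from each protein, present
    in a known domain–domain interaction list. Physical association between
    domains can mediate the interaction of the proteins carrying them.
interologs (``interolog_count``)
    Number of model organisms in which both proteins have an ortholog and
    the ortholog pair interacts. Interactions conserved across species are
    likely real.
smallest shared biological process (``ssbp_size``)
    Minimum membership size over annotation terms containing both proteins;
    proteins sharing a small, specific process are more likely to interact
    than proteins sharing only broad ones.

Missing evidence is explicit (``None`` per pair, ``NaN`` in the table) and
never conflated with an observed zero — an interolog count of 0 means "both
mappable, no conserved interaction seen", which is informative, while a pair
with no mappable organism carries no interolog information at all.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .pairs import ProteinPair
from .synthgen import Organism, Universe

CHANNELS = ("rho", "ddi_hit", "interolog_count", "ssbp_size")


def pearson_rho(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> float | None:
    """Pearson correlation ρ = Σ(Xᵢ−X̄)(Yᵢ−Ȳ) / ((n−1) σX σY).

    σ are sample standard deviations (n−1 denominator). Returns ``None``
    (undefined correlation, recorded as missing) when either vector is
    constant; raises on length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(dx @ dx / (n - 1))
    sy = np.sqrt(dy @ dy / (n - 1))
    if sx == 0.0 or sy == 0.0:
        return None
    rho = (dx @ dy) / ((n - 1) * sx * sy)
    return float(np.clip(rho, -1.0, 1.0))


def ddi_support(
    pair: ProteinPair,
    domain_map: Mapping[str, frozenset[str] | set[str]],
    ddi: set[tuple[str, str]],
) -> int | None:
    """Count interacting domain pairs bridging the two proteins.

    Counts unordered domain pairs (d₁, d₂) with d₁ from one protein and d₂
    from the other that appear in the interaction list ``ddi`` (canonical
    domain pairs; self-pairs allowed when both proteins carry the domain).
    Missing when either protein has no domain assignment.
    """
    a, b = pair
    if a not in domain_map or b not in domain_map:
        return None
    hits = set()
    for da in domain_map[a]:
        for db in domain_map[b]:
            key = (da, db) if da <= db else (db, da)
            if key in ddi:
                hits.add(key)
    return len(hits)


def interolog_count(
    pair: ProteinPair, organisms: Mapping[str, Organism]
) -> int | None:
    """Number of organisms whose ortholog pair interacts.

    Organisms lacking an ortholog for either protein are uninformative; if no
    organism can map both proteins the channel is missing.
    """
    a, b = pair
    count = 0
    mappable = 0
    for org in organisms.values():
        oa = org.orthologs.get(a)
        ob = org.orthologs.get(b)
        if oa is None or ob is None:
            continue
        mappable += 1
        key = (oa, ob) if oa <= ob else (ob, oa)
        if key in org.interactome:
            count += 1
    return count if mappable else None


def ssbp_size(
    pair: ProteinPair, bp_annotation: Mapping[str, frozenset[str] | set[str]]
) -> int | None:
    """Size of the smallest biological-process term containing both proteins.

    Term size counts all member proteins, including the pair itself, so the
    value is ≥ 2 whenever defined; ``None`` when no term is shared. Smaller
    values indicate a more specific shared function.
    """
    a, b = pair
    best: int | None = None
    for members in bp_annotation.values():
        if a in members and b in members:
            size = len(members)
            if best is None or size < best:
                best = size
    return best


def build_evidence_table(
    pairs: Iterable[ProteinPair], universe: Universe
) -> pd.DataFrame:
    """Assemble the four evidence channels for a set of pairs.

    Returns a DataFrame indexed by the (canonical) pair with float columns
    ``rho``, ``ddi_hit``, ``interolog_count``, ``ssbp_size``; missing values
    are ``NaN``. The full protein × protein correlation matrix is computed
    once, so large pair sets stay cheap.
    """
    pair_list = sorted(set(pairs))
    if not pair_list:
        raise ValueError("pairs must be non-empty")

    expr = universe.expression
    values = expr.to_numpy()
    sd = values.std(axis=1, ddof=1)
    pos = {p: i for i, p in enumerate(expr.index)}
    corr = np.corrcoef(values) if len(expr) > 1 else np.ones((1, 1))

    # protein -> term sizes, for a fast per-pair minimum
    term_sizes = {t: len(m) for t, m in universe.bp_annotation.items()}
    terms_of: dict[str, set[str]] = {}
    for t, members in universe.bp_annotation.items():
        for p in members:
            terms_of.setdefault(p, set()).add(t)

    rows = np.empty((len(pair_list), 4))
    rows.fill(np.nan)
    for r, (a, b) in enumerate(pair_list):
        ia, ib = pos.get(a), pos.get(b)
        if ia is not None and ib is not None and sd[ia] > 0 and sd[ib] > 0:
            rows[r, 0] = np.clip(corr[ia, ib], -1.0, 1.0)
        hit = ddi_support((a, b), universe.domain_map, universe.ddi)
        if hit is not None:
            rows[r, 1] = hit
        ic = interolog_count((a, b), universe.organisms)
        if ic is not None:
            rows[r, 2] = ic
        shared = terms_of.get(a, set()) & terms_of.get(b, set())
        if shared:
            rows[r, 3] = min(term_sizes[t] for t in shared)
    index = pd.MultiIndex.from_tuples(pair_list, names=["protein_a", "protein_b"])
    return pd.DataFrame(rows, index=index, columns=list(CHANNELS))


def write_evidence_table(table: pd.DataFrame, path: str) -> None:
    """Serialize an evidence table as TSV with missing values as ``NA``."""
    table.to_csv(path, sep="\t", na_rep="NA")


def read_evidence_table(path: str) -> pd.DataFrame:
    """Read an evidence table written by :func:`write_evidence_table`."""
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], index_col=["protein_a", "protein_b"]
    )
    return df[list(CHANNELS)].astype(float)
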