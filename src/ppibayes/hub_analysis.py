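"""Hub-protein identification by four conjunctive network/expression filters.

A hub candidate must simultaneously (1) be highly connected — degree at or
above a threshold; (2) link many cancer-related proteins — at the classical
or the novel tier; (3) sit in a dense network module — here a connected
component of the maximal k-core, a deterministic proxy for "dense area"
enrichment; and (4) show divergent expression between tumor and normal
samples by a SAM-style moderated difference statistic with permutation-based
significance. Classical hubs pass all four at the classical cancer-link
tier; novel hubs pass at the relaxed novel tier.

The default degree/link thresholds (300 / 300 / 200) are the proteome-scale
operating points; analyses of small synthetic universes scale them down in
their own configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .bayes import PredictedNetwork


@dataclass(frozen=True)
class HubThresholds:
    """Operating points for the four hub filters."""

    degree: int = 300
    classical_links: int = 300
    novel_links: int = 200
    k_core: int = 5
    sam_s0: float | None = None  # None -> median of per-gene standard errors
    sam_delta: float = 1.0
    sam_permutations: int = 200
    sam_seed: int = 0


def _as_graph(network: PredictedNetwork | nx.Graph) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.to_graph()


def degree_filter(
    network: PredictedNetwork | nx.Graph, threshold: int = 300
) -> pd.DataFrame:
    """Per-protein degree (simple graph, no self-loops) and pass flag.

    A protein passes iff its degree is greater than or equal to the
    threshold (inclusive boundary).
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if next(iter(nx.selfloop_edges(g)), None) is not None:
        g = g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
    rows = [(n, d, d >= threshold) for n, d in g.degree()]
    df = pd.DataFrame(rows, columns=["protein", "degree", "passes"])
    return df.sort_values("protein").set_index("protein")


def cancer_link_filter(
    network: PredictedNetwork | nx.Graph,
    cancer_proteins: set[str],
    classical_threshold: int = 300,
    novel_threshold: int = 200,
) -> pd.DataFrame:
    """Count neighbors that are cancer-related and assign a hub tier.

    Tier is ``classical`` when the count reaches ``classical_threshold``,
    ``novel`` when it reaches only ``novel_threshold``, otherwise ``none``.
    """
    g = _as_graph(network)
    rows = []
    for node in g.nodes:
        links = sum(1 for nb in g.neighbors(node) if nb in cancer_proteins)
        if links >= classical_threshold:
            tier = "classical"
        elif links >= novel_threshold:
            tier = "novel"
        else:
            tier = "none"
        rows.append((node, links, tier))
    df = pd.DataFrame(rows, columns=["protein", "cancer_links", "tier"])
    return df.sort_values("protein").set_index("protein")


def module_filter(
    network: PredictedNetwork | nx.Graph, k: int = 5
) -> dict[str, int | None]:
    """Assign proteins to dense modules: components of the maximal k-core.

    Every member of a module has at least ``k`` neighbors inside the module
    subgraph. Proteins outside every module map to ``None``. Module ids are
    assigned in order of each component's lexicographically smallest member,
    so the labelling is deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    g = _as_graph(network)
    if next(iter(nx.selfloop_edges(g)), None) is not None:
        g = g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
    core = nx.k_core(g, k=k)
    assignment: dict[str, int | None] = {n: None for n in g.nodes}
    components = sorted(nx.connected_components(core), key=min)
    for mid, comp in enumerate(components):
        for n in comp:
            assignment[n] = mid
    return assignment


def sam_statistic(
    expression: pd.DataFrame,
    group_labels: list[str],
    s0: float | None = None,
    n_permutations: int = 200,
    seed: int = 0,
    delta: float = 1.0,
) -> pd.DataFrame:
    """SAM-style moderated difference statistic with permutation calling.

    For gene *i*, ``d_i = (mean_tumor − mean_normal) / (s_i + s0)`` with
    ``s_i`` the pooled two-sample standard error. With ``s0 = 0`` this is
    exactly the pooled-variance two-sample t statistic. ``s0`` defaults to
    the median of the ``s_i`` (the usual exchangeability fudge). Significance
    compares the ordered observed statistics with the mean ordered statistics
    over seeded label permutations; gene ranks where the observed value
    departs from the expectation by more than ``delta`` are called
    significant.

    Returns a DataFrame indexed by gene with columns ``d``, ``expected_d``
    (at the gene's rank) and ``significant``.
    """
    labels = np.asarray(group_labels)
    tumor = labels == "tumor"
    normal = labels == "normal"
    if tumor.sum() < 2 or normal.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    values = expression.to_numpy(dtype=float)

    def d_stat(t_mask: np.ndarray, n_mask: np.ndarray, s0_val: float) -> np.ndarray:
        nt, nn = int(t_mask.sum()), int(n_mask.sum())
        xt = values[:, t_mask]
        xn = values[:, n_mask]
        diff = xt.mean(axis=1) - xn.mean(axis=1)
        ss = xt.var(axis=1, ddof=1) * (nt - 1) + xn.var(axis=1, ddof=1) * (nn - 1)
        pooled = ss / (nt + nn - 2)
        s = np.sqrt(pooled * (1.0 / nt + 1.0 / nn))
        return diff / (s + s0_val), s

    _, s = d_stat(tumor, normal, 0.0)
    s0_val = float(np.median(s)) if s0 is None else float(s0)
    d, _ = d_stat(tumor, normal, s0_val)

    rng = np.random.default_rng(seed)
    order = np.argsort(d)
    sorted_d = d[order]
    perm_sorted = np.zeros_like(sorted_d)
    n_samples = len(labels)
    n_tumor = int(tumor.sum())
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        t_mask = np.zeros(n_samples, dtype=bool)
        t_mask[perm[:n_tumor]] = True
        dp, _ = d_stat(t_mask, ~t_mask, s0_val)
        perm_sorted += np.sort(dp)
    perm_sorted /= max(n_permutations, 1)

    significant_sorted = np.abs(sorted_d - perm_sorted) > delta
    out = pd.DataFrame(
        {
            "d": sorted_d,
            "expected_d": perm_sorted,
            "significant": significant_sorted,
        },
        index=expression.index[order],
    )
    return out.loc[expression.index]


def identify_hubs(
    network: PredictedNetwork | nx.Graph,
    cancer_proteins: set[str],
    expression: pd.DataFrame,
    group_labels: list[str],
    thresholds: HubThresholds | None = None,
) -> pd.DataFrame:
    """Apply all four filters and report per-protein hub verdicts.

    A classical hub passes degree, classical-tier cancer links, module
    membership and SAM significance; a novel hub passes the same with the
    relaxed novel cancer-link tier. Each filter's outcome is reported
    per protein so alternative combinations can be recovered. Sorted by
    degree descending, ties broken lexicographically by protein id.
    """
    if thresholds is None:
        thresholds = HubThresholds()
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=[
                "degree",
                "cancer_links",
                "module_id",
                "module_member",
                "sam_d",
                "sam_significant",
                "is_classical_hub",
                "is_novel_hub",
            ]
        )
    deg = degree_filter(g, thresholds.degree)
    links = cancer_link_filter(
        g, cancer_proteins, thresholds.classical_links, thresholds.novel_links
    )
    modules = module_filter(g, thresholds.k_core)
    sam = sam_statistic(
        expression,
        group_labels,
        s0=thresholds.sam_s0,
        n_permutations=thresholds.sam_permutations,
        seed=thresholds.sam_seed,
        delta=thresholds.sam_delta,
    )

    rows = []
    for p in sorted(g.nodes):
        degree = int(deg.loc[p, "degree"])
        n_links = int(links.loc[p, "cancer_links"])
        module_id = modules[p]
        in_sam = p in sam.index
        sam_d = float(sam.loc[p, "d"]) if in_sam else float("nan")
        sam_sig = bool(sam.loc[p, "significant"]) if in_sam else False
        deg_ok = bool(deg.loc[p, "passes"])
        classical = (
            deg_ok
            and n_links >= thresholds.classical_links
            and module_id is not None
            and sam_sig
        )
        novel = (
            deg_ok
            and n_links >= thresholds.novel_links
            and module_id is not None
            and sam_sig
        )
        rows.append(
            (
                p,
                degree,
                n_links,
                module_id,
                module_id is not None,
                sam_d,
                sam_sig,
                classical,
                novel,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "protein",
            "degree",
            "cancer_links",
            "module_id",
            "module_member",
            "sam_d",
            "sam_significant",
            "is_classical_hub",
            "is_novel_hub",
        ],
    )
    report = report.sort_values(
        ["degree", "protein"], ascending=[False, True]
    ).set_index("protein")
    return report
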