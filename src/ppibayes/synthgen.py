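"""Synthetic interactome universe with known ground truth.

The generator emulates the kind of heterogeneous inputs a human PPI-inference
study assembles — several partially overlapping, noisy interaction databases,
GO-style localization and biological-process annotation, a tumor/normal
expression matrix, Pfam-style domain assignments with a domain–domain
interaction list, and model-organism interactomes linked through ortholog
maps — but with a planted true interactome, so that every downstream stage
(gold-standard construction, evidence channels, Bayesian integration,
evaluation, hub calling) can be tested against known truth.

Signal knobs
------------
``rho_signal``
    Target Pearson correlation between expression profiles of interacting
    partners. Each true edge contributes a shared latent factor; a protein of
    true-degree *k* spreads its loading across its *k* factors, so the
    realized correlation of an edge (i, j) is ``rho_signal / sqrt(k_i k_j)``
    — exact for degree-1 partners, attenuated for hubs. Non-interacting
    pairs share no factor and have expected correlation 0.
``ddi_signal``
    Probability that a true edge plants one of its cross-domain pairs into
    the domain–domain interaction list.
``interolog_fidelity``
    Probability that a true human edge is mirrored in each model organism's
    interactome, restricted to proteins with an ortholog there.
``source_noise``
    Fraction of each source database (and of each organism interactome) made
    up of spurious pairs drawn uniformly from non-true pairs.

Biological-process terms are assigned at random (no planted functional
coherence), so the shared-process channel is exercised structurally but
carries no signal about the planted edges.

A held-out fraction of true edges (``sts_holdout_frac``) is excluded from
every source database so that a standard test set built on it is free of
training leakage.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pairs import ProteinPair, canonical_pair

ORGANISM_NAMES = (
    "celegans",
    "dmelanogaster",
    "scerevisiae",
    "rnorvegicus",
    "mmusculus",
    "ecoli",
)

LOCALIZATIONS = ("membrane", "nucleus", "other")


class ConfigError(ValueError):
    """Invalid universe configuration; the message names the offending field."""


@dataclass(frozen=True)
class UniverseConfig:
    """Parameters of the synthetic universe.

    Fractions are proportions of ``n_proteins``; signal knobs are documented
    in the module docstring.
    """

    n_proteins: int = 300
    frac_membrane: float = 0.25
    frac_nuclear: float = 0.20
    frac_both: float = 0.05
    n_bp_terms: int = 150
    bp_size_skew: float = 1.5
    true_density: float = 0.01
    n_sources: int = 5
    source_coverage: float = 0.5
    source_noise: float = 0.2
    rho_signal: float = 0.5
    n_samples: int = 50
    n_organisms: int = 6
    ortholog_coverage: float = 0.7
    interolog_fidelity: float = 0.5
    n_domains: int = 200
    ddi_signal: float = 0.5
    frac_cancer: float = 0.10
    frac_diff_expr: float = 0.10
    diff_expr_shift: float = 1.5
    sts_holdout_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_membrane",
            "frac_nuclear",
            "frac_both",
            "true_density",
            "source_coverage",
            "ortholog_coverage",
            "interolog_fidelity",
            "ddi_signal",
            "frac_cancer",
            "frac_diff_expr",
            "sts_holdout_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.source_noise < 1.0:
            raise ConfigError(
                f"source_noise must be in [0, 1), got {self.source_noise}"
            )
        if not 0.0 <= self.rho_signal < 1.0:
            raise ConfigError(f"rho_signal must be in [0, 1), got {self.rho_signal}")
        if self.frac_membrane + self.frac_nuclear + self.frac_both > 1.0 + 1e-12:
            raise ConfigError(
                "frac_membrane + frac_nuclear + frac_both must be <= 1"
            )
        if self.n_proteins < 2:
            raise ConfigError(f"n_proteins must be >= 2, got {self.n_proteins}")
        if self.n_samples < 3:
            raise ConfigError(f"n_samples must be >= 3, got {self.n_samples}")
        if self.n_sources < 1:
            raise ConfigError(f"n_sources must be >= 1, got {self.n_sources}")
        if not 0 <= self.n_organisms <= len(ORGANISM_NAMES):
            raise ConfigError(
                f"n_organisms must be in [0, {len(ORGANISM_NAMES)}],"
                f" got {self.n_organisms}"
            )
        for name in ("n_bp_terms", "n_domains"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.bp_size_skew <= 0:
            raise ConfigError(f"bp_size_skew must be > 0, got {self.bp_size_skew}")

    def with_seed(self, seed: int) -> "UniverseConfig":
        return replace(self, seed=seed)


@dataclass
class Organism:
    """One model organism: its ortholog map and its interactome."""

    name: str
    orthologs: dict[str, str]  # human protein -> organism protein
    interactome: set[tuple[str, str]]  # canonical organism-protein pairs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Organism):
            return NotImplemented
        return (
            self.name == other.name
            and self.orthologs == other.orthologs
            and self.interactome == other.interactome
        )


@dataclass
class Universe:
    """A fully generated synthetic universe with ground truth attached."""

    proteins: list[str]
    localization: dict[str, frozenset[str]]
    bp_annotation: dict[str, frozenset[str]]  # term -> member proteins
    true_edges: set[ProteinPair]
    heldout_edges: set[ProteinPair]  # subset of true_edges, absent from sources
    sources: dict[str, set[ProteinPair]]
    expression: pd.DataFrame  # proteins x samples
    sample_labels: list[str]  # "tumor" / "normal" per sample column
    domain_map: dict[str, frozenset[str]]
    ddi: set[tuple[str, str]]  # canonical domain pairs
    organisms: dict[str, Organism]
    cancer_proteins: set[str]
    diff_expr_truth: set[str]
    config: UniverseConfig | None = None

    @property
    def training_edges(self) -> set[ProteinPair]:
        """True edges available to the source databases (holdout removed)."""
        return self.true_edges - self.heldout_edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Universe):
            return NotImplemented
        return (
            self.proteins == other.proteins
            and self.localization == other.localization
            and self.bp_annotation == other.bp_annotation
            and self.true_edges == other.true_edges
            and self.heldout_edges == other.heldout_edges
            and self.sources == other.sources
            and self.expression.equals(other.expression)
            and self.sample_labels == other.sample_labels
            and self.domain_map == other.domain_map
            and self.ddi == other.ddi
            and self.organisms == other.organisms
            and self.cancer_proteins == other.cancer_proteins
            and self.diff_expr_truth == other.diff_expr_truth
        )


def _all_pairs(proteins: list[str]) -> list[ProteinPair]:
    return list(itertools.combinations(proteins, 2))


def _truncated_power_law_sizes(
    rng: np.random.Generator, n: int, exponent: float, lo: int, hi: int
) -> np.ndarray:
    """Term sizes from a truncated power law P(s) ∝ s^-exponent on [lo, hi]."""
    u = rng.random(n)
    a = exponent
    if abs(a - 1.0) < 1e-9:
        s = lo * (hi / lo) ** u
    else:
        lo_p, hi_p = lo ** (1.0 - a), hi ** (1.0 - a)
        s = (lo_p + u * (hi_p - lo_p)) ** (1.0 / (1.0 - a))
    return np.clip(np.floor(s).astype(int), lo, hi)


def _sample_spurious(
    rng: np.random.Generator,
    non_true: list[ProteinPair],
    n_true_drawn: int,
    noise_frac: float,
) -> set[ProteinPair]:
    """Spurious pairs so that ``noise_frac`` of the final set is spurious."""
    if noise_frac <= 0.0 or n_true_drawn == 0 or not non_true:
        n_spurious = 0
        if noise_frac > 0.0 and n_true_drawn == 0:
            n_spurious = 0
    else:
        n_spurious = round(n_true_drawn * noise_frac / (1.0 - noise_frac))
    n_spurious = min(n_spurious, len(non_true))
    if n_spurious == 0:
        return set()
    idx = rng.choice(len(non_true), size=n_spurious, replace=False)
    return {non_true[i] for i in idx}


def generate_universe(config: UniverseConfig) -> Universe:
    """Generate a synthetic universe from a validated configuration.

    All randomness derives from ``config.seed`` through one root generator
    whose deterministic child streams drive the independent components, so an
    identical configuration reproduces the universe bit-for-bit.
    """
    root = np.random.default_rng(config.seed)
    (
        rng_loc,
        rng_edges,
        rng_sources,
        rng_expr,
        rng_domains,
        rng_org,
        rng_bp,
        rng_misc,
    ) = root.spawn(8)

    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]

    # --- localization ---------------------------------------------------
    order = rng_loc.permutation(n)
    n_mem = round(config.frac_membrane * n)
    n_nuc = round(config.frac_nuclear * n)
    n_both = round(config.frac_both * n)
    localization: dict[str, frozenset[str]] = {}
    for rank, pi in enumerate(order):
        p = proteins[pi]
        if rank < n_mem:
            loc = frozenset({"membrane"})
        elif rank < n_mem + n_nuc:
            loc = frozenset({"nucleus"})
        elif rank < n_mem + n_nuc + n_both:
            loc = frozenset({"membrane", "nucleus"})
        else:
            loc = frozenset({"other"})
        localization[p] = loc

    # --- true interactome + holdout -------------------------------------
    all_pairs = _all_pairs(proteins)
    mask = rng_edges.random(len(all_pairs)) < config.true_density
    true_list = [all_pairs[i] for i in np.flatnonzero(mask)]
    true_edges = set(true_list)
    perm = rng_edges.permutation(len(true_list))
    n_held = round(config.sts_holdout_frac * len(true_list))
    heldout_edges = {true_list[i] for i in perm[:n_held]}
    training_list = [true_list[i] for i in perm[n_held:]]

    non_true = [all_pairs[i] for i in np.flatnonzero(~mask)]

    # --- source databases ------------------------------------------------
    sources: dict[str, set[ProteinPair]] = {}
    for s in range(config.n_sources):
        srng = rng_sources.spawn(1)[0]
        keep = srng.random(len(training_list)) < config.source_coverage
        drawn = {training_list[i] for i in np.flatnonzero(keep)}
        spurious = _sample_spurious(srng, non_true, len(drawn), config.source_noise)
        sources[f"source{s:02d}"] = drawn | spurious

    # --- expression (edge latent factors + tumor/normal shift) ----------
    m = config.n_samples
    n_tumor = m // 2
    sample_labels = ["tumor"] * n_tumor + ["normal"] * (m - n_tumor)
    sample_names = [f"{lab}_{i:03d}" for i, lab in enumerate(sample_labels)]
    noise = rng_expr.normal(size=(n, m))
    expr = np.sqrt(1.0 - config.rho_signal) * noise
    if config.rho_signal > 0 and true_list:
        degree = np.zeros(n, dtype=int)
        p_index = {p: i for i, p in enumerate(proteins)}
        for a, b in true_list:
            degree[p_index[a]] += 1
            degree[p_index[b]] += 1
        factor_sum = np.zeros((n, m))
        for a, b in true_list:
            f = rng_expr.normal(size=m)
            factor_sum[p_index[a]] += f
            factor_sum[p_index[b]] += f
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(degree > 0, np.sqrt(config.rho_signal / np.maximum(degree, 1)), 0.0)
        expr = expr + scale[:, None] * factor_sum
        # degree-0 proteins: restore unit variance
        expr[degree == 0] = noise[degree == 0]
    else:
        expr = noise

    n_diff = round(config.frac_diff_expr * n)
    diff_idx = rng_expr.choice(n, size=n_diff, replace=False) if n_diff else np.array([], dtype=int)
    diff_expr_truth = {proteins[i] for i in diff_idx}
    if n_diff and config.diff_expr_shift != 0:
        signs = rng_expr.choice([-1.0, 1.0], size=n_diff)
        expr[diff_idx, :n_tumor] += (config.diff_expr_shift * signs)[:, None]
    expression = pd.DataFrame(expr, index=proteins, columns=sample_names)

    # --- domains and DDI -------------------------------------------------
    domain_names = [f"D{i:04d}" for i in range(config.n_domains)]
    domain_map: dict[str, frozenset[str]] = {}
    for p in proteins:
        k = int(rng_domains.integers(1, 4))
        doms = rng_domains.choice(config.n_domains, size=k, replace=False)
        domain_map[p] = frozenset(domain_names[d] for d in doms)
    ddi: set[tuple[str, str]] = set()
    for a, b in true_list:
        if rng_domains.random() < config.ddi_signal:
            da = sorted(domain_map[a])[int(rng_domains.integers(len(domain_map[a])))]
            db = sorted(domain_map[b])[int(rng_domains.integers(len(domain_map[b])))]
            ddi.add((da, db) if da <= db else (db, da))
    n_bg = config.n_domains // 2
    for _ in range(n_bg):
        i, j = rng_domains.integers(config.n_domains, size=2)
        da, db = domain_names[i], domain_names[j]
        ddi.add((da, db) if da <= db else (db, da))

    # --- model organisms --------------------------------------------------
    organisms: dict[str, Organism] = {}
    for o in range(config.n_organisms):
        orng = rng_org.spawn(1)[0]
        name = ORGANISM_NAMES[o]
        has = orng.random(n) < config.ortholog_coverage
        orthologs = {
            proteins[i]: f"{name}_{proteins[i]}" for i in np.flatnonzero(has)
        }
        inter: set[tuple[str, str]] = set()
        mirrored = 0
        for a, b in true_list:
            if a in orthologs and b in orthologs:
                if orng.random() < config.interolog_fidelity:
                    oa, ob = orthologs[a], orthologs[b]
                    inter.add((oa, ob) if oa <= ob else (ob, oa))
                    mirrored += 1
        mappable_non_true = [
            (a, b) for a, b in non_true if a in orthologs and b in orthologs
        ]
        for a, b in _sample_spurious(
            orng, mappable_non_true, mirrored, config.source_noise
        ):
            oa, ob = orthologs[a], orthologs[b]
            inter.add((oa, ob) if oa <= ob else (ob, oa))
        organisms[name] = Organism(name=name, orthologs=orthologs, interactome=inter)

    # --- biological-process terms (random membership, no planted signal) --
    max_size = max(3, n // 5)
    sizes = _truncated_power_law_sizes(
        rng_bp, config.n_bp_terms, config.bp_size_skew, 2, max_size
    )
    bp_annotation: dict[str, frozenset[str]] = {}
    covered: set[str] = set()
    for t, size in enumerate(sizes):
        members = rng_bp.choice(n, size=int(size), replace=False)
        term = f"BP{t:04d}"
        bp_annotation[term] = frozenset(proteins[i] for i in members)
        covered.update(bp_annotation[term])
    term_names = sorted(bp_annotation)
    for p in proteins:
        if p not in covered:
            t = term_names[int(rng_bp.integers(len(term_names)))]
            bp_annotation[t] = bp_annotation[t] | {p}

    # --- cancer-related proteins ------------------------------------------
    n_cancer = round(config.frac_cancer * n)
    cancer_idx = (
        rng_misc.choice(n, size=n_cancer, replace=False)
        if n_cancer
        else np.array([], dtype=int)
    )
    cancer_proteins = {proteins[i] for i in cancer_idx}

    return Universe(
        proteins=proteins,
        localization=localization,
        bp_annotation=bp_annotation,
        true_edges=true_edges,
        heldout_edges=heldout_edges,
        sources=sources,
        expression=expression,
        sample_labels=sample_labels,
        domain_map=domain_map,
        ddi=ddi,
        organisms=organisms,
        cancer_proteins=cancer_proteins,
        diff_expr_truth=diff_expr_truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_PAIR_HEADER = "#protein_a\tprotein_b\n"


def _write_pairs(path: Path, pairs: set[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write(_PAIR_HEADER)
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def _read_pairs(path: Path) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")
            pairs.add((a, b) if a <= b else (b, a))
    return pairs


def write_universe(universe: Universe, directory: str | Path) -> list[Path]:
    """Serialize a universe as plain-text files; returns the paths written.

    Layout: one pair TSV per source and per organism interactome, an ortholog
    TSV per organism, a GMT of biological-process terms, localization /
    domain / DDI TSVs, an expression TSV (samples as columns), plain lists of
    cancer and differentially-expressed proteins, ground-truth edge TSVs and
    a JSON manifest. :func:`read_universe` round-trips to an equal universe.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def reg(p: Path) -> Path:
        written.append(p)
        return p

    for name, pairs in universe.sources.items():
        _write_pairs(reg(d / f"source_{name}.tsv"), pairs)
    _write_pairs(reg(d / "true_edges.tsv"), universe.true_edges)
    _write_pairs(reg(d / "heldout_edges.tsv"), universe.heldout_edges)
    _write_pairs(reg(d / "ddi.tsv"), universe.ddi)

    with open(reg(d / "localization.tsv"), "w") as fh:
        fh.write("#protein\tcompartments\n")
        for p in universe.proteins:
            fh.write(f"{p}\t{','.join(sorted(universe.localization[p]))}\n")

    with open(reg(d / "bp_terms.gmt"), "w") as fh:
        for term in sorted(universe.bp_annotation):
            members = "\t".join(sorted(universe.bp_annotation[term]))
            fh.write(f"{term}\tsynthetic biological process\t{members}\n")

    with open(reg(d / "domains.tsv"), "w") as fh:
        fh.write("#protein\tdomain\n")
        for p in universe.proteins:
            for dom in sorted(universe.domain_map[p]):
                fh.write(f"{p}\t{dom}\n")

    universe.expression.to_csv(reg(d / "expression.tsv"), sep="\t", index_label="protein")

    for name, org in universe.organisms.items():
        with open(reg(d / f"organism_{name}_orthologs.tsv"), "w") as fh:
            fh.write("#human\torganism\n")
            for h in sorted(org.orthologs):
                fh.write(f"{h}\t{org.orthologs[h]}\n")
        _write_pairs(reg(d / f"organism_{name}_interactions.tsv"), org.interactome)

    for fname, items in (
        ("cancer_proteins.txt", universe.cancer_proteins),
        ("diff_expr_truth.txt", universe.diff_expr_truth),
    ):
        with open(reg(d / fname), "w") as fh:
            for p in sorted(items):
                fh.write(p + "\n")

    manifest = {
        "proteins": universe.proteins,
        "sample_labels": universe.sample_labels,
        "sources": sorted(universe.sources),
        "organisms": sorted(universe.organisms),
        "config": None
        if universe.config is None
        else {f.name: getattr(universe.config, f.name) for f in fields(UniverseConfig)},
    }
    with open(reg(d / "universe.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return written


def read_universe(directory: str | Path) -> Universe:
    """Read a universe previously written by :func:`write_universe`."""
    d = Path(directory)
    with open(d / "universe.json") as fh:
        manifest = json.load(fh)
    proteins: list[str] = manifest["proteins"]

    localization: dict[str, frozenset[str]] = {}
    with open(d / "localization.tsv") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p, locs = line.split("\t")
            localization[p] = frozenset(locs.split(","))

    bp_annotation: dict[str, frozenset[str]] = {}
    with open(d / "bp_terms.gmt") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            bp_annotation[parts[0]] = frozenset(parts[2:])

    domain_map: dict[str, set[str]] = {p: set() for p in proteins}
    with open(d / "domains.tsv") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p, dom = line.split("\t")
            domain_map[p].add(dom)

    expression = pd.read_csv(
        d / "expression.tsv", sep="\t", index_col="protein",
        float_precision="round_trip",
    )

    sources = {
        name: _read_pairs(d / f"source_{name}.tsv") for name in manifest["sources"]
    }
    organisms: dict[str, Organism] = {}
    for name in manifest["organisms"]:
        orthologs: dict[str, str] = {}
        with open(d / f"organism_{name}_orthologs.tsv") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                h, o = line.split("\t")
                orthologs[h] = o
        organisms[name] = Organism(
            name=name,
            orthologs=orthologs,
            interactome=_read_pairs(d / f"organism_{name}_interactions.tsv"),
        )

    def _read_list(fname: str) -> set[str]:
        with open(d / fname) as fh:
            return {line.strip() for line in fh if line.strip()}

    cfg = manifest.get("config")
    return Universe(
        proteins=proteins,
        localization=localization,
        bp_annotation=bp_annotation,
        true_edges=_read_pairs(d / "true_edges.tsv"),
        heldout_edges=_read_pairs(d / "heldout_edges.tsv"),
        sources=sources,
        expression=expression,
        sample_labels=manifest["sample_labels"],
        domain_map={p: frozenset(s) for p, s in domain_map.items()},
        ddi=_read_pairs(d / "ddi.tsv"),
        organisms=organisms,
        cancer_proteins=_read_list("cancer_proteins.txt"),
        diff_expr_truth=_read_list("diff_expr_truth.txt"),
        config=None if cfg is None else UniverseConfig(**cfg),
    )
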