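"""Synthetic three-species expression data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
ancestral log2 expression per gene and tissue, independent Brownian-style
drift along each lineage (per-tissue Gaussian with SD √branch_length, so
squared profile distances grow roughly linearly with branch length), a small
fraction of genes carrying a large single-tissue, single-lineage shift,
sequence-divergence and interaction-count tables correlated with the
realized divergence, and a small GO DAG with a planted enriched term.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlates import normalized_scores
from .enrichment import AnnotationSet, GoDag
from .profiles import TRIPLE_AXES, TissueExpressionTable

__all__ = [
    "SimulationConfig",
    "simulate_triplet_expression",
    "simulate_correlates",
    "simulate_go",
    "write_bundle",
]

#: the nine tissues profiled in the grass expression atlas
DEFAULT_TISSUES = (
    "leaf",
    "early_inflorescence",
    "emerging_inflorescence",
    "anther",
    "pistil",
    "seed_5dap",
    "seed_10dap",
    "embryo",
    "endosperm",
)

DEFAULT_SPECIES = ("bdistachyon", "osativa", "sbicolor")


@dataclass
class SimulationConfig:
    """Conditions for the synthetic triplet-expression study.

    Defaults mirror the real study's shape: ~10^4 ortholog triples over nine
    tissues in three grasses, branch lengths in the 50:50:60 ratio of the
    species' divergence times, 1% of genes carrying a single-tissue
    expression shift of 4 log2 units (a 16-fold change, several drift SDs)
    concentrated in anther.
    """

    n_genes: int = 10_000
    n_tissues: int = 9
    tissue_names: Sequence[str] = DEFAULT_TISSUES
    species: Sequence[str] = DEFAULT_SPECIES
    #: per-axis drift scale (variance of per-tissue log2 drift)
    branch_lengths: tuple[float, float, float] = (0.25, 0.25, 0.30)
    shift_fraction: float = 0.01
    shift_magnitude: float = 4.0
    shift_lineage_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: tissue receiving the planted shift; "random" draws one per gene
    shift_tissue: str = "anther"
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.tissue_names = tuple(self.tissue_names)[: self.n_tissues]
        if len(self.tissue_names) != self.n_tissues:
            extra = [
                f"tissue{i}" for i in range(len(self.tissue_names), self.n_tissues)
            ]
            self.tissue_names = tuple(self.tissue_names) + tuple(extra)
        if self.n_genes < 1 or self.n_tissues < 2:
            raise ValueError("need at least 1 gene and 2 tissues")
        if len(self.species) != 3:
            raise ValueError("exactly three species required")
        if any(b <= 0 for b in self.branch_lengths):
            raise ValueError("branch lengths must be strictly positive")
        if not 0 <= self.shift_fraction < 1:
            raise ValueError("shift_fraction must be in [0, 1)")
        if self.shift_magnitude <= 0 or self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("scales must be strictly positive")
        w = np.asarray(self.shift_lineage_weights, dtype=float)
        if w.size != 3 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("shift_lineage_weights must be 3 probabilities summing to 1")
        if self.shift_tissue != "random" and self.shift_tissue not in self.tissue_names:
            raise ValueError(
                f"shift_tissue {self.shift_tissue!r} not among tissues"
            )


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_triplet_expression(
    cfg: SimulationConfig,
) -> tuple[dict[str, TissueExpressionTable], pd.DataFrame, pd.DataFrame]:
    """Simulate TPM tables for three species plus ortholog triples and truth.

    Returns ``(tables, triples, truth)`` where ``tables`` maps the axis
    ("x"/"y"/"z") to a validated :class:`TissueExpressionTable`, ``triples``
    has columns gene_x/gene_y/gene_z, and ``truth`` records per gene whether
    a shift was planted, on which lineage and tissue, its magnitude, and the
    realized per-lineage drift norms (log2 scale, shift included).
    """
    n, T = cfg.n_genes, cfg.n_tissues
    rng_anc, rng_shift, rng_drift, rng_noise = _streams(cfg.seed, 4)

    ancestral = rng_anc.normal(cfg.baseline_mean, cfg.baseline_sd, size=(n, T))

    shifted = rng_shift.random(n) < cfg.shift_fraction
    lineage_idx = rng_shift.choice(3, size=n, p=np.asarray(cfg.shift_lineage_weights))
    if cfg.shift_tissue == "random":
        tissue_idx = rng_shift.integers(0, T, size=n)
    else:
        tissue_idx = np.full(n, cfg.tissue_names.index(cfg.shift_tissue))

    tables: dict[str, TissueExpressionTable] = {}
    drift_norms = np.zeros((n, 3))
    gene_ids: dict[str, list[str]] = {}
    for k, axis in enumerate(TRIPLE_AXES):
        sd = float(np.sqrt(cfg.branch_lengths[k]))
        drift = rng_drift.normal(0.0, sd, size=(n, T))
        on_this = shifted & (lineage_idx == k)
        drift[on_this, tissue_idx[on_this]] += cfg.shift_magnitude
        drift_norms[:, k] = np.sqrt((drift**2).sum(axis=1))
        v = ancestral + drift + rng_noise.normal(0.0, cfg.noise_sd, size=(n, T))
        tpm = np.clip(np.exp2(v) - 1.0, 0.0, None)
        species = cfg.species[k]
        ids = [f"{species}_g{i:05d}" for i in range(n)]
        gene_ids[axis] = ids
        tables[axis] = TissueExpressionTable(
            species=species,
            data=pd.DataFrame(
                tpm, index=pd.Index(ids, name="gene"), columns=cfg.tissue_names
            ),
        )

    triples = pd.DataFrame(
        {f"gene_{a}": gene_ids[a] for a in TRIPLE_AXES}
    )
    truth = pd.DataFrame(
        {
            "gene_x": gene_ids["x"],
            "gene_y": gene_ids["y"],
            "gene_z": gene_ids["z"],
            "shifted": shifted,
            "shift_axis": [
                TRIPLE_AXES[k] if s else "" for s, k in zip(shifted, lineage_idx)
            ],
            "shift_tissue": [
                cfg.tissue_names[t] if s else ""
                for s, t in zip(shifted, tissue_idx)
            ],
            "shift_magnitude": np.where(shifted, cfg.shift_magnitude, 0.0),
            "drift_norm_x": drift_norms[:, 0],
            "drift_norm_y": drift_norms[:, 1],
            "drift_norm_z": drift_norms[:, 2],
        }
    )
    return tables, triples, truth


def simulate_correlates(
    led_scores: pd.Series,
    beta: tuple[float, float] = (0.5, -1.0),
    divergence_slope: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequence-divergence and interaction tables correlated with divergence.

    ``led_scores`` maps gene id → LED for one species.  Scores are
    normalized to quantile ranks x ∈ (0, 1] (see :func:`normalized_scores`;
    scale-free, so the planted coefficients do not depend on the absolute
    LED magnitude); branch length and Ka means increase linearly in x
    (slope ``divergence_slope``) with mean-one lognormal noise, Ks is
    divergence-independent, and interaction counts are Poisson with
    log-mean ``beta[0] + beta[1]·x`` — recoverable by regressing counts on
    the same normalized score.  Missing LED for a gene is an error by
    construction (the scores define the gene set).
    """
    if led_scores.isna().any():
        bad = led_scores.index[led_scores.isna()][0]
        raise ValueError(f"missing LED for gene {bad!r}")
    rng = np.random.default_rng(seed)
    x = normalized_scores(led_scores.to_numpy(dtype=float))
    n = x.size

    def lognoise(sigma: float) -> np.ndarray:
        return rng.lognormal(-0.5 * sigma**2, sigma, size=n)

    branch_length = (0.3 + 0.6 * divergence_slope * x) * lognoise(0.3)
    ka = (0.05 + 0.15 * divergence_slope * x) * lognoise(0.3)
    ks = 0.5 * lognoise(0.2)
    divergence = pd.DataFrame(
        {
            "gene": led_scores.index,
            "branch_length": branch_length,
            "ka": ka,
            "ka_ks": ka / ks,
        }
    )
    counts = rng.poisson(np.exp(beta[0] + beta[1] * x))
    interactions = pd.DataFrame(
        {"gene": led_scores.index, "n_partners": counts}
    )
    return divergence, interactions


def simulate_go(
    scores: pd.Series,
    n_background_terms: int = 100,
    planted_term_size: int = 20,
    seed: int = 0,
) -> tuple[GoDag, AnnotationSet, str]:
    """A small three-level GO DAG with one planted enriched term.

    The planted biological_process term annotates exactly the
    ``planted_term_size`` top-scoring genes; background terms annotate
    uniform random gene sets of size 10–40.  Returns the DAG, the *direct*
    (unpropagated) annotations, and the planted term's id.
    """
    if planted_term_size > len(scores):
        raise ValueError("planted_term_size exceeds the number of genes")
    import networkx as nx

    rng = np.random.default_rng(seed)
    genes = list(scores.index)
    graph = nx.DiGraph()
    terms: dict[str, dict[str, str]] = {}

    def add(term: str, name: str, ns: str, parent: str | None = None) -> None:
        terms[term] = {"name": name, "namespace": ns}
        graph.add_node(term)
        if parent is not None:
            graph.add_edge(term, parent)

    namespaces = {
        "biological_process": "GO:0008150",
        "molecular_function": "GO:0003674",
        "cellular_component": "GO:0005575",
    }
    mids: dict[str, list[str]] = {ns: [] for ns in namespaces}
    counter = 1
    for ns, root in namespaces.items():
        add(root, f"{ns} root", ns)
        for _ in range(3):
            mid = f"GO:{counter:07d}"
            counter += 1
            add(mid, f"synthetic mid {mid}", ns, parent=root)
            mids[ns].append(mid)

    mapping: dict[str, set[str]] = {}

    def annotate(term: str, members) -> None:
        for g in members:
            mapping.setdefault(g, set()).add(term)

    planted = f"GO:{counter:07d}"
    counter += 1
    add(
        planted,
        "planted divergence module",
        "biological_process",
        parent=mids["biological_process"][0],
    )
    top_genes = list(scores.sort_values(ascending=False).index[:planted_term_size])
    annotate(planted, top_genes)

    ns_cycle = list(namespaces)
    for i in range(n_background_terms):
        ns = ns_cycle[i % 3]
        term = f"GO:{counter:07d}"
        counter += 1
        parent = mids[ns][int(rng.integers(0, len(mids[ns])))]
        add(term, f"synthetic background {term}", ns, parent=parent)
        size = int(rng.integers(10, 41))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        annotate(term, members)

    dag = GoDag(graph=graph, terms=terms)
    direct = AnnotationSet(
        mapping={g: frozenset(t) for g, t in mapping.items()}, propagated=False
    )
    return dag, direct, planted


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialize a GoDag to a minimal OBO file (is_a only)."""
    lines = ["format-version: 1.2", "ontology: go", ""]
    for term in sorted(dag.terms):
        rec = dag.terms[term]
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: {rec['name']}",
            f"namespace: {rec['namespace']}",
        ]
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent} ! {dag.terms[parent]['name']}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic input bundle for a pipeline run.

    Produces three TPM TSVs, the ortholog-triple TSV, per-species
    divergence and interaction TSVs, a GO OBO plus per-species annotation
    TSVs, and the ground-truth TSV.  The correlate and GO tables are driven
    by the divergence each species' genes actually realized, computed with
    the analysis modules themselves.

    Returns a name → path mapping of everything written.
    """
    from . import led as led_mod
    from . import profiles as prof_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, triples, truth = simulate_triplet_expression(cfg)

    paths: dict[str, Path] = {}
    for axis, table in tables.items():
        p = outdir / f"tpm_{table.species}.tsv"
        table.data.to_csv(p, sep="\t")
        paths[f"tpm_{axis}"] = p
    p = outdir / "triples.tsv"
    triples.to_csv(p, sep="\t", index=False)
    paths["triples"] = p
    p = outdir / "truth.tsv"
    truth.to_csv(p, sep="\t", index=False)
    paths["truth"] = p

    # realized per-species LED drives the correlate and GO tables
    retained = {a: prof_mod.filter_expressed(t) for a, t in tables.items()}
    kept, _ = prof_mod.align_triples(triples, tables, retained)
    profs = {
        a: prof_mod.make_profiles(tables[a], kept[f"gene_{a}"]) for a in tables
    }
    led = led_mod.led_table(kept, profs)

    corr_seeds = np.random.SeedSequence(cfg.seed).spawn(7)
    for k, axis in enumerate(TRIPLE_AXES):
        species = cfg.species[k]
        scores = pd.Series(
            led[f"led_{axis}"].to_numpy(), index=led[f"gene_{axis}"]
        )
        div, inter = simulate_correlates(
            scores, seed=int(corr_seeds[3 + k].generate_state(1)[0] % 2**31)
        )
        p = outdir / f"divergence_{species}.tsv"
        div.to_csv(p, sep="\t", index=False)
        paths[f"divergence_{axis}"] = p
        p = outdir / f"interactions_{species}.tsv"
        inter.to_csv(p, sep="\t", index=False)
        paths[f"interactions_{axis}"] = p

    # one shared DAG; per-species annotations planted on that species' top genes
    go_seed = int(corr_seeds[6].generate_state(1)[0] % 2**31)
    dag = None
    for k, axis in enumerate(TRIPLE_AXES):
        species = cfg.species[k]
        scores = pd.Series(
            led[f"led_{axis}"].to_numpy(), index=led[f"gene_{axis}"]
        )
        dag_k, direct, _ = simulate_go(scores, seed=go_seed)
        if dag is None:
            dag = dag_k
            p = outdir / "go.obo"
            write_obo(dag, p)
            paths["obo"] = p
        rows = [
            {"gene": g, "term": t}
            for g in sorted(direct.mapping)
            for t in sorted(direct.mapping[g])
        ]
        p = outdir / f"annotations_{species}.tsv"
        pd.DataFrame(rows, columns=["gene", "term"]).to_csv(
            p, sep="\t", index=False
        )
        paths[f"annotations_{axis}"] = p
    return paths
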