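"""End-to-end pipeline: config, stage functions, manifest.

The pipeline sequences the analysis stages — ingest and filter expression
tables, build profiles, compute LED and its per-generation scaling, compare
LED distributions between species, correlate LED with genic properties, fit
the interaction-count Poisson regression, run the primary-tissue enrichment
battery, and the GO enrichment — writing one TSV per stage plus a manifest.
Reruns with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import correlates as corr_mod
from . import enrichment as enr_mod
from . import led as led_mod
from . import profiles as prof_mod
from . import stats as stats_mod
from .profiles import TRIPLE_AXES

__all__ = ["SpeciesConfig", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class SpeciesConfig:
    """One species' inputs and branch constants, bound to a triple axis."""

    name: str
    days_to_anthesis: float
    divergence_my: float
    tpm_path: str
    divergence_path: str | None = None
    interactions_path: str | None = None
    annotations_path: str | None = None

    def branch_scale(self) -> led_mod.BranchScale:
        return led_mod.BranchScale(
            species=self.name,
            days_to_anthesis=self.days_to_anthesis,
            divergence_my=self.divergence_my,
        )


@dataclass
class RunConfig:
    """Validated run configuration (parsed from a YAML file).

    ``species`` maps the triple axes "x", "y", "z" — the two ingroups and
    the outgroup of the three-taxon tree — to :class:`SpeciesConfig`.
    Thresholds default to the analysis' standard constants: expression
    filter log2(TPM) > 2, top 1% of LED, enrichment alpha 0.01 with
    node_size 10, and 1,000 permutations.
    """

    species: dict[str, SpeciesConfig]
    triples_path: str
    obo_path: str | None = None
    outdir: str = "ledkit_out"
    expression_threshold: float = 2.0
    pseudocount: float = 1.0
    profile_scale: str = "log"
    top_fraction: float = 0.01
    n_permutations: int = 1000
    enrichment_alpha: float = 0.01
    node_size: int = 10
    go_algorithm: str = "elim"
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [a for a in TRIPLE_AXES if a not in self.species]
        if missing:
            raise ValueError(f"config missing species block(s) for axes {missing}")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.enrichment_alpha < 1:
            raise ValueError("enrichment_alpha must be in (0, 1)")
        if self.node_size < 1:
            raise ValueError("node_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = {
            axis: SpeciesConfig(**block)
            for axis, block in raw.pop("species", {}).items()
        }
        return cls(species=species, **raw)

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "species"
        }
        d["species"] = {a: dict(s.__dict__) for a, s in self.species.items()}
        return d


def _load_tables(cfg: RunConfig) -> dict[str, prof_mod.TissueExpressionTable]:
    tables = {}
    tissues = None
    for axis in TRIPLE_AXES:
        sp = cfg.species[axis]
        tables[axis] = prof_mod.read_tpm_table(
            sp.tpm_path, sp.name, expected_tissues=tissues
        )
        if tissues is None:
            tissues = tables[axis].tissues
    return tables


def _spawn_seed(root: int, index: int) -> int:
    """A reproducible sub-seed (< 2^31) for the index-th consumer."""
    child = np.random.SeedSequence(root).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % 2**31)


def stage_led(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Ingestion through LED, per-generation scaling, and the
    between-species distribution tests."""
    tables = _load_tables(cfg)
    triples = prof_mod.read_triples(cfg.triples_path)
    logger.info("loaded %d ortholog triples", len(triples))

    retained = {
        a: prof_mod.filter_expressed(tables[a], cfg.expression_threshold)
        for a in TRIPLE_AXES
    }
    for a in TRIPLE_AXES:
        logger.info(
            "%s: %d/%d genes pass the expression filter",
            tables[a].species, len(retained[a]), len(tables[a].genes),
        )
    kept, dropped = prof_mod.align_triples(triples, tables, retained)
    logger.info(
        "retained %d/%d triples (dropped per axis: %s)",
        len(kept), len(triples), dropped,
    )
    profiles = {
        a: prof_mod.make_profiles(
            tables[a], kept[f"gene_{a}"], cfg.pseudocount, cfg.profile_scale
        )
        for a in TRIPLE_AXES
    }
    led = led_mod.led_table(kept, profiles)
    scales = {a: cfg.species[a].branch_scale() for a in TRIPLE_AXES}
    led_scaled = led_mod.scale_per_generation(led, scales)

    # pairwise permutation tests on LED distributions, raw and per-generation
    rows = []
    pairs = [("x", "y"), ("x", "z"), ("y", "z")]
    for j, scaled in enumerate((False, True)):
        suffix = "_per_generation" if scaled else ""
        for i, (a, b) in enumerate(pairs):
            res = stats_mod.permutation_test_median_diff(
                led_scaled[f"led_{a}{suffix}"],
                led_scaled[f"led_{b}{suffix}"],
                n_perm=cfg.n_permutations,
                seed=_spawn_seed(cfg.seed, 3 * j + i),
                exact=False,
            )
            rows.append(
                {
                    "comparison": f"{cfg.species[a].name}_vs_{cfg.species[b].name}",
                    "scaled": scaled,
                    "observed_median_diff": res.observed_stat,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            )
    dist_tests = pd.DataFrame(rows)

    counts = {
        "triples_in": len(triples),
        "triples_retained": len(kept),
        **{
            f"genes_pass_filter_{cfg.species[a].name}": len(retained[a])
            for a in TRIPLE_AXES
        },
    }
    return {
        "led": led,
        "led_per_generation": led_scaled,
        "distribution_tests": dist_tests,
        "_tables": tables,
        "_counts": counts,
    }


def stage_correlates(
    cfg: RunConfig,
    led: pd.DataFrame,
    tables: Mapping[str, prof_mod.TissueExpressionTable],
) -> dict[str, pd.DataFrame]:
    """Per-species tau/primary tissue, correlations of LED with genic
    properties, the Poisson fit, and the primary-tissue enrichment."""
    corr_rows, poisson_rows, enrich_rows = [], [], []
    for axis in TRIPLE_AXES:
        sp = cfg.species[axis]
        genes = led[f"gene_{axis}"].tolist()
        scores = pd.Series(led[f"led_{axis}"].to_numpy(), index=genes)

        tau = corr_mod.tau_table(tables[axis], genes, cfg.pseudocount)
        divergence = (
            corr_mod.read_divergence_table(sp.divergence_path)
            if sp.divergence_path
            else None
        )
        interactions = (
            corr_mod.read_interactions(sp.interactions_path)
            if sp.interactions_path
            else None
        )
        gen_corr = corr_mod.build_correlates(tau, divergence, interactions)

        for prop in ("tau", "branch_length", "ka", "ka_ks"):
            values = gen_corr[prop]
            ok = values.notna()
            if ok.sum() < 3 or values[ok].nunique() < 2:
                continue
            for method in ("pearson", "spearman"):
                res = stats_mod.correlation_test(
                    scores[ok].to_numpy(), values[ok].to_numpy(), method
                )
                corr_rows.append(
                    {
                        "species": sp.name,
                        "property": prop,
                        "method": method,
                        "r": res.r,
                        "t_stat": res.t_stat,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )

        if interactions is not None:
            counts = gen_corr["n_partners"]
            ok = counts.notna()
            fit = stats_mod.fit_poisson_regression(
                counts[ok].to_numpy(),
                corr_mod.normalized_scores(scores[ok].to_numpy()),
            )
            poisson_rows.append(
                {
                    "species": sp.name,
                    "beta0": fit.beta0,
                    "beta1": fit.beta1,
                    "se1": fit.se1,
                    "wald_p": fit.wald_p,
                    "residual_deviance": fit.residual_deviance,
                    "gof_p": fit.gof_p,
                    "converged": fit.converged,
                    "n": fit.n,
                }
            )

        top = corr_mod.select_top_fraction(scores, cfg.top_fraction)
        chi2_stat, chi2_p, df, rows = stats_mod.tissue_enrichment(
            gen_corr.loc[top, "primary_tissue"],
            gen_corr["primary_tissue"],
            tissue_order=tables[axis].tissues,
        )
        rows.insert(0, "species", sp.name)
        rows["chi2_stat"] = chi2_stat
        rows["chi2_p"] = chi2_p
        rows["chi2_df"] = df
        enrich_rows.append(rows)

    return {
        "correlations": pd.DataFrame(corr_rows),
        "poisson": pd.DataFrame(poisson_rows),
        "tissue_enrichment": pd.concat(enrich_rows, ignore_index=True),
    }


def stage_enrich(cfg: RunConfig, led: pd.DataFrame) -> pd.DataFrame:
    """GO enrichment of LED ranks, per species with annotations."""
    if cfg.obo_path is None:
        logger.info("no OBO configured; skipping GO enrichment")
        return pd.DataFrame()
    dag = enr_mod.parse_obo_subset(cfg.obo_path)
    out = []
    for axis in TRIPLE_AXES:
        sp = cfg.species[axis]
        if not sp.annotations_path:
            continue
        direct = enr_mod.read_annotations(sp.annotations_path)
        annotated = set(direct.mapping)
        scores = pd.Series(
            led[f"led_{axis}"].to_numpy(), index=led[f"gene_{axis}"]
        )
        covered = annotated & set(scores.index)
        if not covered:
            logger.warning(
                "%s: no annotated gene has an LED score; skipping", sp.name
            )
            continue
        direct = enr_mod.AnnotationSet(
            mapping={g: direct.mapping[g] for g in covered}, propagated=False
        )
        propagated = enr_mod.propagate_annotations(dag, direct)
        rows = enr_mod.ks_enrichment(
            dag,
            propagated,
            scores.to_dict(),
            node_size=cfg.node_size,
            algorithm=cfg.go_algorithm,
        )
        rows.insert(0, "species", sp.name)
        rows["significant"] = rows["p_value"] < cfg.enrichment_alpha
        out.append(rows)
    return (
        pd.concat(out, ignore_index=True) if out else pd.DataFrame()
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the result bundle to ``cfg.outdir``.

    Returns a name → path mapping of the written files.  Outputs are
    deterministic: identical config and inputs reproduce identical bytes.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    led_out = stage_led(cfg)
    tables = led_out.pop("_tables")
    counts = led_out.pop("_counts")
    for name, df in led_out.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p

    corr_out = stage_correlates(cfg, led_out["led"], tables)
    for name, df in corr_out.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p

    go_rows = stage_enrich(cfg, led_out["led"])
    p = outdir / "go_enrichment.tsv"
    go_rows.to_csv(p, sep="\t", index=False)
    written["go_enrichment"] = p

    manifest = {
        "ledkit_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "counts": counts,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = p
    logger.info("pipeline complete: %d outputs in %s", len(written), outdir)
    return written
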