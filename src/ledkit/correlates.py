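"""Per-gene properties that expression divergence is compared against.

Covers the tissue-specificity index tau, the primary (highest-expressed)
tissue, selection of the top LED fraction, and ingestion of externally
computed sequence-divergence (gene-tree branch length, Ka, Ka/Ks) and
interaction-count tables.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_tau",
    "primary_tissue",
    "tau_table",
    "select_top_fraction",
    "read_divergence_table",
    "read_interactions",
    "build_correlates",
]


def compute_tau(x) -> float:
    """Tissue-specificity index tau = Σ_i (1 − x_i/x_max) / (T − 1).

    Ranges from 0 (identical expression in every tissue) to 1 (expression
    confined to a single tissue).  ``x`` is an expression vector over T ≥ 2
    tissues; in the pipeline it is the gene's log2(TPM + 1) vector.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a 1-d vector over at least 2 tissues")
    if not np.isfinite(x).all() or (x < 0).any():
        raise ValueError("tau requires finite, non-negative expression values")
    xmax = x.max()
    if xmax <= 0:
        raise ValueError("tau undefined for an all-zero expression vector")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def primary_tissue(x, tissues: Sequence[str]) -> str:
    """Name of the tissue with maximal expression; ties go to the first
    occurrence in the canonical tissue order."""
    x = np.asarray(x, dtype=float)
    if x.size != len(tissues):
        raise ValueError("expression vector and tissue list differ in length")
    if x.max() <= 0:
        raise ValueError("primary tissue undefined for an all-zero vector")
    return str(tissues[int(np.argmax(x))])


def tau_table(
    table, genes: Sequence[str], pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene tau and primary tissue for one species' expression table.

    tau is computed on log2(TPM + pseudocount) — the same transform used for
    profiles — while the primary tissue is the raw-TPM argmax (the argmax is
    the same on either scale; raw TPM is used for definiteness).
    """
    tpm = table.data.loc[list(genes)]
    log_expr = np.log2(tpm.to_numpy(dtype=float) + pseudocount)
    taus = [compute_tau(row) for row in log_expr]
    primaries = [
        primary_tissue(row, table.tissues)
        for row in tpm.to_numpy(dtype=float)
    ]
    return pd.DataFrame(
        {"tau": taus, "primary_tissue": primaries},
        index=pd.Index(list(genes), name="gene"),
    )


def normalized_scores(scores) -> np.ndarray:
    """Quantile-rank normalization of divergence scores to (0, 1].

    x_i = rank(score_i) / N with mid-ranks for ties.  Monotone and
    scale-free, which keeps regression coefficients on x comparable across
    species regardless of the absolute magnitude of the scores.
    """
    import scipy.stats as sps

    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    return sps.rankdata(scores) / scores.size


def select_top_fraction(
    scores: Mapping[str, float] | pd.Series, fraction: float = 0.01
) -> list[str]:
    """The ⌈fraction × N⌉ genes with the largest scores.

    Deterministic: sorted by descending score, ties broken by ascending
    (lexicographic) gene id.  Raises on an empty score table or a fraction
    outside (0, 1].
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    series = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    if series.empty:
        raise ValueError("empty score table")
    k = math.ceil(fraction * len(series))
    order = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    return [gene for gene, _ in order[:k]]


def _read_required(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={columns[0]: str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_divergence_table(path: str | Path) -> pd.DataFrame:
    """Read per-gene sequence divergence: gene, branch_length, ka, ka_ks.

    ``ka_ks`` may be blank (undefined when Ks = 0 upstream) and is kept as
    missing; negative values in any numeric column are rejected.
    """
    df = _read_required(path, ["gene", "branch_length", "ka", "ka_ks"])
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r}")
    for col in ("branch_length", "ka", "ka_ks"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{path}: negative value in column {col!r}")
    return df.set_index("gene")


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read per-gene interaction-partner counts: gene, n_partners.

    Counts must be non-negative integers; a fractional count is a type error.
    """
    df = _read_required(path, ["gene", "n_partners"])
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r}")
    counts = pd.to_numeric(df["n_partners"], errors="raise")
    if not np.allclose(counts, np.round(counts)):
        bad = df["gene"][~np.isclose(counts, np.round(counts))].iloc[0]
        raise ValueError(
            f"{path}: non-integer interaction count for gene {bad!r}"
        )
    if (counts < 0).any():
        raise ValueError(f"{path}: negative interaction count")
    df["n_partners"] = counts.astype(int)
    return df.set_index("gene")


def build_correlates(
    tau: pd.DataFrame,
    divergence: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Outer-join tau/primary-tissue with the consumed divergence and
    interaction tables into one per-gene frame.

    Genes missing from a table carry NaN in its columns; every downstream
    statistic drops incomplete cases and reports its own n.
    """
    out = tau.copy()
    if divergence is not None:
        out = out.join(divergence, how="left")
    else:
        out[["branch_length", "ka", "ka_ks"]] = np.nan
    if interactions is not None:
        out = out.join(interactions, how="left")
    else:
        out["n_partners"] = np.nan
    return out
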