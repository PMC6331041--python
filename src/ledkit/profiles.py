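"""Ingestion of per-species TPM tables and construction of expression profiles.

A gene's expression profile is its vector of relative abundances across
tissues: TPM values are log-transformed (log2(TPM + pseudocount)) and each
gene's vector is normalized to sum to one.  Profiles built this way are
directly comparable across species, which is what the downstream
branch-length statistic requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueExpressionTable",
    "read_tpm_table",
    "filter_expressed",
    "make_profiles",
    "align_triples",
]

#: axis labels of the three-taxon tree; species are bound to axes by the run
#: configuration, in (ingroup, ingroup, outgroup) order.
TRIPLE_AXES = ("x", "y", "z")


@dataclass
class TissueExpressionTable:
    """A genes × tissues matrix of TPM values for one species.

    Parameters
    ----------
    species:
        Species identifier.
    data:
        DataFrame indexed by unique gene id, columns are tissue names,
        cells are non-negative finite TPM values.
    """

    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(
                f"{self.species}: duplicate gene identifier {dup!r}"
            )
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"{self.species}: non-finite TPM value present")
        if (values < 0).any():
            gi, ti = np.argwhere(values < 0)[0]
            raise ValueError(
                f"{self.species}: negative TPM at gene "
                f"{self.data.index[gi]!r}, tissue {self.data.columns[ti]!r}"
            )

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_tissues(self) -> int:
        return self.data.shape[1]


def read_tpm_table(
    path: str | Path,
    species: str,
    expected_tissues: Sequence[str] | None = None,
) -> TissueExpressionTable:
    """Read a TSV of TPM values (first column gene id, remaining columns tissues).

    ``expected_tissues`` enforces that the tissue header matches (same names,
    same order) a previously loaded table of the same run.

    Raises
    ------
    ValueError
        On duplicate gene ids, non-numeric or negative cells (the offending
        gene/tissue is named), or a tissue-header mismatch.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")

    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        gi, ti = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {raw.index[gi]!r}, "
            f"tissue {raw.columns[ti]!r} (value {raw.iat[gi, ti]!r})"
        )
    if (numeric.to_numpy() < 0).any():
        gi, ti = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValueError(
            f"{path}: negative TPM at gene {raw.index[gi]!r}, "
            f"tissue {raw.columns[ti]!r}"
        )
    if expected_tissues is not None and list(raw.columns) != list(expected_tissues):
        raise ValueError(
            f"{path}: tissue header {list(raw.columns)} does not match the "
            f"run's tissue order {list(expected_tissues)}"
        )
    return TissueExpressionTable(species=species, data=numeric.astype(float))


def filter_expressed(
    table: TissueExpressionTable, threshold: float = 2.0
) -> list[str]:
    """Genes with log2(TPM) strictly above ``threshold`` in at least one tissue.

    The comparison is done on raw TPM against ``2**threshold`` (so zeros are
    excluded automatically and no pseudocount enters the filter).  The
    returned list preserves the table's gene order.
    """
    cutoff = 2.0**threshold
    mask = (table.data.to_numpy(dtype=float) > cutoff).any(axis=1)
    return [g for g, keep in zip(table.genes, mask) if keep]


def make_profiles(
    table: TissueExpressionTable,
    genes: Iterable[str],
    pseudocount: float = 1.0,
    scale: str = "log",
) -> pd.DataFrame:
    """Build relative-abundance profiles for the requested genes.

    With ``scale="log"`` (default) the profile is v_t / Σ v_t with
    v_t = log2(TPM_t + pseudocount); with ``scale="linear"`` the raw TPM
    shares are used instead.  Every returned row sums to one.

    Raises
    ------
    KeyError
        If a requested gene is absent from the table.
    ValueError
        If a gene's transformed vector sums to zero (undefined profile) —
        cannot occur for genes that pass :func:`filter_expressed` at a
        non-negative threshold.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in table.data.index]
    if missing:
        raise KeyError(
            f"{table.species}: gene(s) absent from table: {missing[:5]}"
        )
    tpm = table.data.loc[genes].to_numpy(dtype=float)
    if scale == "log":
        v = np.log2(tpm + pseudocount)
    elif scale == "linear":
        v = tpm
    else:
        raise ValueError(f"unknown profile scale {scale!r}")
    totals = v.sum(axis=1)
    if (totals <= 0).any():
        g = genes[int(np.argmax(totals <= 0))]
        raise ValueError(
            f"{table.species}: profile undefined for gene {g!r} "
            "(transformed expression sums to zero)"
        )
    profiles = v / totals[:, None]
    return pd.DataFrame(profiles, index=pd.Index(genes, name="gene"),
                        columns=table.tissues)


def _check_unique_triples(triples: pd.DataFrame) -> None:
    for axis in TRIPLE_AXES:
        col = triples[f"gene_{axis}"]
        if col.duplicated().any():
            dup = col[col.duplicated()].iloc[0]
            raise ValueError(
                f"gene {dup!r} appears in more than one ortholog triple"
            )


def read_triples(path: str | Path) -> pd.DataFrame:
    """Read a 1:1:1 ortholog table with columns gene_x, gene_y, gene_z."""
    triples = pd.read_csv(path, sep="\t", dtype=str)
    required = [f"gene_{a}" for a in TRIPLE_AXES]
    missing = [c for c in required if c not in triples.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    _check_unique_triples(triples)
    return triples[required].reset_index(drop=True)


def align_triples(
    triples: pd.DataFrame,
    tables: Mapping[str, TissueExpressionTable],
    retained: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep the triples whose three members all passed the expression filter.

    Parameters
    ----------
    triples:
        DataFrame with columns ``gene_x``, ``gene_y``, ``gene_z``.
    tables:
        Per-axis (``"x"``/``"y"``/``"z"``) expression tables, used to verify
        that every referenced gene exists.
    retained:
        Per-axis collections of genes that passed :func:`filter_expressed`.

    Returns
    -------
    (kept, dropped)
        The retained triples (original order) and the count of triples whose
        member failed the filter, per axis.  A triple failing on several axes
        is counted once per failing axis.

    Raises
    ------
    ValueError
        If a triple references a gene absent from its species' table.
    """
    _check_unique_triples(triples)
    keep = np.ones(len(triples), dtype=bool)
    dropped: dict[str, int] = {}
    for axis in TRIPLE_AXES:
        col = triples[f"gene_{axis}"]
        table = tables[axis]
        present = col.isin(table.data.index)
        if not present.all():
            i = int(np.argmax(~present.to_numpy()))
            raise ValueError(
                f"triple {i} references gene {col.iloc[i]!r} absent from the "
                f"{table.species} table"
            )
        ok = col.isin(set(retained[axis]))
        dropped[axis] = int((~ok).sum())
        keep &= ok.to_numpy()
    kept = triples.loc[keep].reset_index(drop=True)
    return kept, dropped
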