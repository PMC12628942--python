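"""Rarefaction, domain merging, prevalence filtering and abundance transform.

The preprocessing chain mirrors standard molecular-ecology practice: each
marker-gene table is rarefied to an even depth, the four domain tables are
merged into one multitrophic table, the table is split by climatic group,
taxa seen in at most half of that group's samples are discarded, and the
retained counts are zero-filled and log10-transformed for correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import DOMAIN_PREFIX, CountTable, TableFormatError

logger = logging.getLogger(__name__)

#: Published per-marker rarefaction depths (reads per sample).
DEFAULT_DEPTHS = {"bacteria": 4485, "fungi": 10526, "protist": 1079, "nematode": 412}


@dataclass
class AbundanceMatrix:
    """Taxa x samples matrix of log10-transformed abundances."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise TableFormatError("duplicate taxon ids in abundance matrix")
        if self.values.columns.has_duplicates:
            raise TableFormatError("duplicate sample ids in abundance matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise TableFormatError("non-finite abundance values")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a logged warning
    (rarefying them is impossible without replacement).  Subsampling is
    multivariate hypergeometric, seeded for reproducibility.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    kept_cols: list[str] = []
    columns: list[np.ndarray] = []
    dropped: list[str] = []
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            columns.append(col.copy())
        else:
            columns.append(rng.multivariate_hypergeometric(col, depth))
        kept_cols.append(sample)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    counts = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((table.n_taxa, 0), dtype=np.int64),
        index=table.counts.index, columns=kept_cols, dtype=np.int64,
    )
    return CountTable(counts, table.domain.copy())


def merge_domains(tables: Sequence[CountTable]) -> CountTable:
    """Row-concatenate per-domain tables into one multitrophic table.

    All tables must cover the identical sample set (order may differ); taxon
    ids are prefixed with the domain initial (B_/F_/P_/N_) so identical ASV
    labels from different markers cannot collide.
    """
    if not tables:
        raise ValueError("merge_domains requires at least one table")
    ref = set(tables[0].sample_ids)
    for t in tables[1:]:
        other = set(t.sample_ids)
        if other != ref:
            diff = sorted(ref.symmetric_difference(other))
            raise ValueError(f"sample-id mismatch between domain tables: {diff}")
    order = tables[0].sample_ids
    frames = []
    domains = []
    for t in tables:
        prefixes = t.domain.map(DOMAIN_PREFIX)
        new_ids = prefixes.str.cat(t.counts.index.astype(str), sep="_")
        counts = t.counts[order].copy()
        counts.index = new_ids
        dom = t.domain.copy()
        dom.index = new_ids
        frames.append(counts)
        domains.append(dom)
    return CountTable(pd.concat(frames), pd.concat(domains))


def prevalence_filter(table: CountTable, min_frac: float = 0.5) -> CountTable:
    """Keep taxa detected in strictly more than ``min_frac`` of samples.

    The threshold is strict: with 18 samples and ``min_frac=0.5`` a taxon
    present in exactly 9 samples is removed.
    """
    if not 0 <= min_frac < 1:
        raise ValueError(f"min_frac must be in [0, 1), got {min_frac}")
    present = (table.counts > 0).sum(axis=1)
    keep = present > min_frac * table.n_samples
    if not keep.any():
        logger.warning("prevalence_filter: no taxa pass %.0f%% prevalence", 100 * min_frac)
    return CountTable(table.counts.loc[keep].copy(), table.domain.loc[keep].copy())


def transform_abundance(table: CountTable, pseudo: float = 0.01) -> AbundanceMatrix:
    """Zero-fill with ``pseudo`` then log10 (strictly monotone in counts)."""
    if pseudo <= 0:
        raise ValueError(f"pseudo-count must be positive, got {pseudo}")
    values = table.counts.astype(float)
    values = values.where(values > 0, pseudo)
    return AbundanceMatrix(np.log10(values))
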