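"""OTU dominance, occupancy, and group-level composition summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otu_io import OtuTable, relative_abundance

__all__ = [
    "OtuGroupMap",
    "top_otu_summary",
    "sample_contribution_matrix",
    "occupancy",
    "group_composition",
]

UNGROUPED = "ungrouped"


@dataclass
class OtuGroupMap:
    """Mapping from OTU id to a group label; unmapped OTUs fall back to
    ``"ungrouped"``."""

    mapping: dict

    @classmethod
    def read_csv(cls, path: str | Path) -> "OtuGroupMap":
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise ValueError("group map CSV needs two columns: otu_id, group")
        col_otu, col_group = df.columns[:2]
        return cls(mapping=dict(zip(df[col_otu], df[col_group])))

    def group_of(self, otu_id: str) -> str:
        return self.mapping.get(otu_id, UNGROUPED)

    def validate_against(self, table: OtuTable) -> None:
        missing = sorted(set(self.mapping) - set(table.otu_ids))
        if missing:
            warnings.warn(
                f"group map names OTUs absent from the table (ignored): {missing}",
                UserWarning,
            )


def top_otu_summary(
    table: OtuTable,
    thresholds: Sequence[float] = (0.01, 0.001, 0.0001),
) -> pd.DataFrame:
    """Global per-OTU shares, ranked, with cumulative top-k shares.

    Returns one row per OTU (descending global count) with columns
    ``otu_id, count, share, cumulative_share, rank``.  The attached
    ``attrs["threshold_counts"]`` maps each fraction threshold to the
    number of OTUs whose global share meets it.
    """
    totals = table.counts.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("empty table")
    order = np.argsort(-totals, kind="stable")
    share = totals[order] / grand
    df = pd.DataFrame(
        {
            "otu_id": [table.otu_ids[i] for i in order],
            "count": totals[order],
            "share": share,
            "cumulative_share": np.cumsum(share),
            "rank": np.arange(1, len(order) + 1),
        }
    )
    df.attrs["threshold_counts"] = {
        thr: int(np.sum(share >= thr)) for thr in thresholds
    }
    return df


def sample_contribution_matrix(
    table: OtuTable,
    min_fraction: float = 0.01,
    global_threshold: float = 0.001,
    sample_threshold: float = 0.01,
) -> pd.DataFrame:
    """Samples x panel-OTUs fractions with sub-threshold entries masked.

    The OTU panel is the union of OTUs holding at least
    ``global_threshold`` of all sequences and OTUs holding at least
    ``sample_threshold`` of any single sample; it is recomputed from the
    table (never user-supplied).  Entries below ``min_fraction`` are NaN
    (masked), not zero.
    """
    frac = relative_abundance(table)
    totals = table.counts.sum(axis=0)
    global_share = totals / totals.sum()
    panel_global = set(np.array(table.otu_ids)[global_share >= global_threshold])
    panel_sample = set(
        np.array(table.otu_ids)[(frac.to_numpy() >= sample_threshold).any(axis=0)]
    )
    panel = [o for o in table.otu_ids if o in (panel_global | panel_sample)]
    # order panel by global abundance, largest first
    rank = {o: -totals[j] for j, o in enumerate(table.otu_ids)}
    panel.sort(key=lambda o: (rank[o], o))
    out = frac[panel].copy()
    return out.where(out >= min_fraction)


def occupancy(
    table: OtuTable,
    presence_fraction: float = 0.01,
    persistent_cutoff: float = 0.90,
    sporadic_cutoff: float = 0.25,
    presence_mode: str = "fraction",
) -> pd.DataFrame:
    """Per-OTU occupancy: in how many samples is each OTU "present"?

    Presence defaults to holding at least ``presence_fraction`` of a
    sample; ``presence_mode="reads"`` uses >= 1 read instead.  OTUs
    occupying at least ``persistent_cutoff`` of samples are labelled
    persistent, at most ``sporadic_cutoff`` sporadic, otherwise
    intermittent.
    """
    if presence_mode == "fraction":
        present = relative_abundance(table).to_numpy() >= presence_fraction
    elif presence_mode == "reads":
        present = table.counts >= 1
    else:
        raise ValueError(f"unknown presence_mode {presence_mode!r}")
    n_present = present.sum(axis=0)
    frac_present = n_present / table.n_samples
    label = np.where(
        frac_present >= persistent_cutoff,
        "persistent",
        np.where(frac_present <= sporadic_cutoff, "sporadic", "intermittent"),
    )
    return pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "n_samples_present": n_present,
            "occupancy": frac_present,
            "class": label,
        }
    )


def group_composition(table: OtuTable, group_map: OtuGroupMap) -> pd.DataFrame:
    """Samples x groups fraction matrix; rows sum to 1 (incl. "ungrouped")."""
    group_map.validate_against(table)
    frac = relative_abundance(table)
    groups = [group_map.group_of(o) for o in table.otu_ids]
    out = frac.T.groupby(np.array(groups)).sum().T
    ordered = sorted([c for c in out.columns if c != UNGROUPED])
    if UNGROUPED in out.columns:
        ordered.append(UNGROUPED)
    return out[ordered]
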