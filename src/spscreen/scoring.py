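"""Sort-seq bin-count scoring: occupancy normalization, depth filtering and
the weighted-average (WA) secretion-efficiency statistic.

Each SP variant is sequenced out of B sorting bins (default 10, bin 1 = best
secretion).  Because a different number of compartments (NLRs) is collected
per bin, raw read counts are first rescaled so every bin represents the same
number of NLRs.  Variants whose most populated bin holds fewer reads than a
depth threshold (default 255) are discarded as uninformative.  The remaining
variants are scored as WA = sum_b b * f_b with f_b the relative read
frequency in bin b, so WA ranges from 1 (all reads in bin 1, best) to B
(all reads in bin B, worst).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

DEFAULT_MIN_MAX_BIN_READS = 255


@dataclass
class BinCountTable:
    """SP x bin read counts plus optional controls and NLR occupancy."""

    counts: pd.DataFrame  # index: sp_id; columns: bin_1..bin_B
    nlr_per_bin: pd.Series | None = None  # index aligned to counts.columns
    controls: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.nlr_per_bin is not None:
            self.nlr_per_bin = self.nlr_per_bin.reindex(self.counts.columns)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_values(self) -> np.ndarray:
        return np.arange(1, self.n_bins + 1, dtype=float)


@dataclass(frozen=True)
class EfficiencyScore:
    sp_id: str
    wa: float
    total_reads: float
    frequencies: tuple[float, ...]


def normalize_bins(table: BinCountTable) -> BinCountTable:
    """Rescale counts so each bin represents the mean NLR occupancy.

    Counts in bin b are multiplied by mean(N) / N_b; control columns are
    untouched and zero counts stay zero.
    """
    if table.nlr_per_bin is None:
        raise ValueError("bin normalization requires nlr_per_bin occupancy metadata")
    occ = table.nlr_per_bin.to_numpy(dtype=float)
    if np.any(~np.isfinite(occ)) or np.any(occ <= 0):
        raise ValueError("nlr_per_bin must be strictly positive for all bins")
    factors = occ.mean() / occ
    scaled = table.counts.astype(float) * factors
    return replace(table, counts=scaled)


def filter_informative(
    table: BinCountTable, min_max_bin_reads: int = DEFAULT_MIN_MAX_BIN_READS
) -> tuple[BinCountTable, list[str]]:
    """Keep SPs whose most populated bin holds >= ``min_max_bin_reads`` reads."""
    keep = table.counts.max(axis=1) >= min_max_bin_reads
    discarded = list(table.counts.index[~keep])
    return replace(table, counts=table.counts.loc[keep]), discarded


def compute_wa(
    counts: Sequence[float] | np.ndarray | pd.Series,
    bin_values: Sequence[float] | None = None,
    sp_id: str = "",
) -> EfficiencyScore:
    """WA = sum_b value_b * f_b over relative read frequencies f."""
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a single row of per-bin counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero bin counts: WA undefined")
    values = (
        np.arange(1, arr.size + 1, dtype=float)
        if bin_values is None
        else np.asarray(bin_values, dtype=float)
    )
    freqs = arr / total
    return EfficiencyScore(
        sp_id=sp_id,
        wa=float(freqs @ values),
        total_reads=float(total),
        frequencies=tuple(freqs),
    )


def score_library(
    table: BinCountTable,
    min_max_bin_reads: int = DEFAULT_MIN_MAX_BIN_READS,
    normalize: bool = True,
    filter_on_raw: bool = True,
    bin_values: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Normalize, filter and score a bin-count table.

    The depth filter is applied to raw counts by default (the threshold is a
    sequencing-depth criterion); set ``filter_on_raw=False`` to filter on the
    occupancy-normalized counts instead.

    Returns a DataFrame (index sp_id, columns wa/total_reads) and the list of
    discarded ids.
    """
    normalize = normalize and table.nlr_per_bin is not None
    if filter_on_raw:
        kept, discarded = filter_informative(table, min_max_bin_reads)
        if normalize:
            kept = normalize_bins(kept)
    else:
        work = normalize_bins(table) if normalize else table
        kept, discarded = filter_informative(work, min_max_bin_reads)
    scores = [
        compute_wa(row.to_numpy(), bin_values=bin_values, sp_id=str(sp_id))
        for sp_id, row in kept.counts.iterrows()
    ]
    result = pd.DataFrame(
        {"wa": [s.wa for s in scores], "total_reads": [s.total_reads for s in scores]},
        index=[s.sp_id for s in scores],
    )
    result.index.name = "id"
    return result, discarded


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_CONTROL_COLUMNS = ("occupation_control", "original_library")


def read_bin_counts(
    counts_tsv: str | Path, occupancy: str | Path | None = None
) -> BinCountTable:
    """Read a bin-count TSV (first column sp_id, then bin_1..bin_B and
    optional control columns) plus optional occupancy sidecar (YAML or TSV)."""
    df = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    control_cols = [c for c in df.columns if c in _CONTROL_COLUMNS]
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    nlr = None
    if occupancy is not None:
        occupancy = Path(occupancy)
        if occupancy.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(occupancy.read_text())
            nlr = pd.Series({str(k): float(v) for k, v in payload.items()})
        else:
            occ = pd.read_csv(occupancy, sep="\t")
            nlr = pd.Series(occ.iloc[:, 1].to_numpy(dtype=float), index=occ.iloc[:, 0].astype(str))
    return BinCountTable(
        counts=df[bin_cols],
        nlr_per_bin=nlr,
        controls=df[control_cols] if control_cols else None,
    )


def write_bin_counts(
    table: BinCountTable, counts_tsv: str | Path, occupancy_tsv: str | Path | None = None
) -> None:
    out = table.counts.copy()
    if table.controls is not None:
        out = pd.concat([out, table.controls], axis=1)
    out.to_csv(counts_tsv, sep="\t", index_label="id")
    if occupancy_tsv is not None and table.nlr_per_bin is not None:
        table.nlr_per_bin.rename("nlr").to_csv(occupancy_tsv, sep="\t", index_label="bin")
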