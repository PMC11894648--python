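"""PSM-level quantification: filters, weights, and weighted-median normalization.

A PSM (peptide-spectrum match) carries one reporter-intensity vector per
n-plex.  Protein-group values are obtained either by plain summation of
reporter intensities over all applicable PSMs, or by weighted-median (WM)
normalization: the weighted median over PSMs of the ratio of each sample
channel to a reference intensity.  The reference intensity is the summed
intensity of the plex's reference channels, or — in no-reference mode — the
sum of all sample channels of the PSM.  PSM weights are
``(precursor intensity x fill time) ** exponent``, an estimate of the number
of ions that were fragmented, exponentiated by the user-settable isobaric
weight exponent.

Because every sample value is a within-PSM ratio, a global intensity scale
factor applied to one plex (a batch effect) cancels exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .label_model import LabelSet

logger = logging.getLogger(__name__)

__all__ = [
    "PSMTable",
    "ExperimentalDesign",
    "WMConfig",
    "QuantMatrix",
    "psm_weight",
    "weighted_median",
    "reference_intensity",
    "compute_pif",
    "pif_filter",
    "base_peak_ratio_filter",
    "aggregate_sum",
    "wm_normalize",
]

ROLES = ("sample", "reference", "carrier", "empty")

#: metadata columns every PSM table carries
META_COLUMNS = [
    "psm_id",
    "protein_group",
    "plex",
    "experiment",
    "precursor_intensity",
    "fill_time",
    "pif",
    "base_peak_ratio",
]


@dataclass
class PSMTable:
    """PSM-level quantification table for one label set.

    ``meta`` holds one row per PSM (columns :data:`META_COLUMNS`); ``raw``
    and optional ``corrected`` are aligned ``(n_psms, n_channels)`` arrays of
    reporter intensities in label-set channel order.
    """

    label_set: LabelSet
    meta: pd.DataFrame
    raw: np.ndarray
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"PSM metadata missing columns: {missing}")
        if self.raw.shape != (len(self.meta), self.label_set.n):
            raise ValueError(
                f"raw reporter array shape {self.raw.shape} does not match "
                f"{len(self.meta)} PSMs x {self.label_set.n} channels"
            )
        if self.corrected is not None:
            self.corrected = np.asarray(self.corrected, dtype=float)
            if self.corrected.shape != self.raw.shape:
                raise ValueError("corrected reporter array shape differs from raw")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.meta)

    def intensities(self, use_corrected: bool) -> np.ndarray:
        if use_corrected:
            if self.corrected is None:
                raise ValueError("table has no corrected reporter intensities")
            return self.corrected
        return self.raw

    def select(self, mask: np.ndarray) -> "PSMTable":
        """New table restricted to PSMs where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return PSMTable(
            label_set=self.label_set,
            meta=self.meta.loc[mask].reset_index(drop=True),
            raw=self.raw[mask],
            corrected=None if self.corrected is None else self.corrected[mask],
        )

    def with_corrected(self, corrected: np.ndarray) -> "PSMTable":
        return PSMTable(self.label_set, self.meta.copy(), self.raw.copy(), np.asarray(corrected, float))


@dataclass(frozen=True)
class ExperimentalDesign:
    """Per-plex mapping of channels to roles and sample annotations.

    ``table`` has one row per (plex, channel) with columns ``plex``,
    ``channel``, ``role`` (sample / reference / carrier / empty), ``sample``
    (name, sample channels only) and ``group`` (biological grouping label).
    """

    label_set: LabelSet
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("plex", "channel", "role"):
            if col not in t.columns:
                raise ValueError(f"design table missing column {col!r}")
        t = t.copy()
        if "sample" not in t.columns:
            t["sample"] = pd.NA
        if "group" not in t.columns:
            t["group"] = pd.NA
        bad_roles = set(t["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown channel roles: {sorted(bad_roles)}")
        for plex, sub in t.groupby("plex", sort=False):
            if list(sub["channel"]) != list(self.label_set.channels):
                raise ValueError(
                    f"plex {plex!r}: design channels must list all {self.label_set.n} "
                    f"channels of {self.label_set.name!r} in label-set order"
                )
            if not (sub["role"] == "sample").any():
                raise ValueError(f"plex {plex!r} has no sample channel")
        samples = t.loc[t["role"] == "sample", "sample"]
        if samples.isna().any():
            raise ValueError("every sample channel needs a sample name")
        if samples.duplicated().any():
            dup = samples[samples.duplicated()].tolist()
            raise ValueError(f"duplicate sample names across design: {dup}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def plexes(self) -> list:
        return list(dict.fromkeys(self.table["plex"]))

    @property
    def samples(self) -> list[str]:
        return self.table.loc[self.table["role"] == "sample", "sample"].tolist()

    def sample_groups(self) -> pd.Series:
        """Series mapping sample name -> biological group label."""
        sub = self.table[self.table["role"] == "sample"]
        return pd.Series(sub["group"].values, index=sub["sample"].values)

    def sample_plexes(self) -> pd.Series:
        """Series mapping sample name -> plex id."""
        sub = self.table[self.table["role"] == "sample"]
        return pd.Series(sub["plex"].values, index=sub["sample"].values)

    def channel_indices(self, plex, role: str) -> np.ndarray:
        sub = self.table[self.table["plex"] == plex]
        if sub.empty:
            raise KeyError(f"plex {plex!r} not in design")
        sel = sub[sub["role"] == role]
        return np.array([self.label_set.index(c) for c in sel["channel"]], dtype=int)

    def sample_names(self, plex) -> list[str]:
        sub = self.table[(self.table["plex"] == plex) & (self.table["role"] == "sample")]
        return sub["sample"].tolist()


@dataclass(frozen=True)
class WMConfig:
    """Configuration for weighted-median normalization.

    mode
        ``"reference"`` divides each sample channel by the summed reference
        channels; ``"all_sample_sum"`` divides by the sum of all sample
        channels of the PSM (no reference channels needed).
    weight_exponent
        The isobaric weight exponent applied to
        ``precursor intensity x fill time``; 0 gives the unweighted median.
    use_corrected
        Normalize impurity-corrected instead of raw reporter intensities.
    min_psms
        Minimum surviving ratios per cell; below it the cell is missing.
    pif_threshold
        Optional precursor-intensity-fraction filter applied before
        normalization.
    """

    mode: Literal["reference", "all_sample_sum"] = "all_sample_sum"
    weight_exponent: float = 1.0
    use_corrected: bool = False
    min_psms: int = 1
    pif_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("reference", "all_sample_sum"):
            raise ValueError(f"unknown WM mode {self.mode!r}")
        if self.weight_exponent < 0:
            raise ValueError("weight exponent must be >= 0")
        if self.min_psms < 1:
            raise ValueError("min_psms must be >= 1")
        if self.pif_threshold is not None and not 0.0 <= self.pif_threshold <= 1.0:
            raise ValueError("pif_threshold must be in [0, 1]")

    def validate_against(self, design: ExperimentalDesign) -> None:
        if self.mode == "reference":
            for plex in design.plexes:
                if design.channel_indices(plex, "reference").size == 0:
                    raise ValueError(
                        f"reference-mode normalization requires a reference channel "
                        f"in every plex, but plex {plex!r} has none"
                    )


@dataclass
class QuantMatrix:
    """Protein groups x samples matrix with provenance.

    ``values`` is indexed by protein group with one column per design sample;
    ``support`` counts the PSMs behind each cell.
    """

    values: pd.DataFrame
    kind: Literal["summed_raw", "summed_corrected", "wm_normalized"]
    support: pd.DataFrame
    config: dict = field(default_factory=dict)


def psm_weight(
    precursor_intensity: float | np.ndarray,
    fill_time: float | np.ndarray,
    exponent: float,
) -> float | np.ndarray:
    """PSM weight ``(precursor_intensity * fill_time) ** exponent``.

    Missing factors (NaN) fall back to 1 so a PSM lacking, say, a recorded
    fill time still contributes with the remaining information.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    p = np.where(np.isnan(precursor_intensity), 1.0, precursor_intensity)
    f = np.where(np.isnan(fill_time), 1.0, fill_time)
    w = (p * f) ** exponent
    if np.ndim(w) == 0:
        return float(w)
    return w


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half
    the total; an exact half-split returns the midpoint with the next order
    statistic, so equal weights reproduce the ordinary median exactly,
    duplicates included.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if np.any(w < 0):
        raise ValueError("negative weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    order = np.argsort(v, kind="stable")
    v = v[order]
    w = w[order]
    cum = np.cumsum(w)
    half = total / 2.0
    k = min(int(np.searchsorted(cum, half, side="left")), v.size - 1)
    if cum[k] == half and k + 1 < v.size:
        return float(0.5 * (v[k] + v[k + 1]))
    return float(v[k])


def compute_pif(
    precursor_peak_intensities: Sequence[float],
    window_peak_intensities: Sequence[float],
) -> float:
    """Precursor intensity fraction: share of isolation-window intensity that
    belongs to the targeted precursor's isotope peaks."""
    window = np.asarray(window_peak_intensities, dtype=float)
    if window.size == 0 or window.sum() <= 0:
        raise ValueError("isolation window is empty")
    prec = np.asarray(precursor_peak_intensities, dtype=float)
    return float(np.clip(prec.sum() / window.sum(), 0.0, 1.0))


def reference_intensity(
    table: PSMTable,
    design: ExperimentalDesign,
    mode: str,
    use_corrected: bool = False,
) -> np.ndarray:
    """Per-PSM reference intensity.

    ``reference`` mode sums the plex's reference channels; ``all_sample_sum``
    sums its sample channels.  Carrier and empty channels never contribute.
    """
    role = {"reference": "reference", "all_sample_sum": "sample"}.get(mode)
    if role is None:
        raise ValueError(f"unknown reference mode {mode!r}")
    Y = table.intensities(use_corrected)
    out = np.full(len(table), np.nan)
    for plex in design.plexes:
        rows = (table.meta["plex"] == plex).to_numpy()
        if not rows.any():
            continue
        idx = design.channel_indices(plex, role)
        if idx.size == 0:
            raise ValueError(f"plex {plex!r} has no {role} channels for mode {mode!r}")
        out[rows] = Y[rows][:, idx].sum(axis=1)
    return out


def pif_filter(table: PSMTable, threshold: float) -> PSMTable:
    """Keep PSMs with PIF >= threshold; missing PIF passes only at threshold 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("PIF threshold must be in [0, 1]")
    pif = table.meta["pif"].to_numpy(dtype=float)
    if threshold == 0.0:
        mask = np.ones(len(table), dtype=bool)
    else:
        mask = pif >= threshold  # NaN compares False
    kept = table.select(mask)
    logger.info("pif_filter(threshold=%g): %d -> %d PSMs", threshold, len(table), len(kept))
    return kept


def base_peak_ratio_filter(table: PSMTable, threshold: float) -> PSMTable:
    """Keep PSMs with base peak ratio >= threshold; missing passes only at 0."""
    if threshold < 0:
        raise ValueError("base peak ratio threshold must be >= 0")
    bpr = table.meta["base_peak_ratio"].to_numpy(dtype=float)
    if threshold == 0.0:
        mask = np.ones(len(table), dtype=bool)
    else:
        mask = bpr >= threshold
    kept = table.select(mask)
    logger.info(
        "base_peak_ratio_filter(threshold=%g): %d -> %d PSMs", threshold, len(table), len(kept)
    )
    return kept


def aggregate_sum(
    table: PSMTable, design: ExperimentalDesign, use_corrected: bool = False
) -> QuantMatrix:
    """Summed roll-up: per protein group and sample, the sum of reporter
    intensities over all PSMs of that group in the sample's plex.

    Fractions sharing an experiment are summed together by construction.
    Groups with no PSMs for a sample's plex are missing, not zero.
    """
    Y = table.intensities(use_corrected)
    blocks: list[pd.DataFrame] = []
    supports: list[pd.DataFrame] = []
    for plex in design.plexes:
        rows = (table.meta["plex"] == plex).to_numpy()
        idx = design.channel_indices(plex, "sample")
        names = design.sample_names(plex)
        sub = pd.DataFrame(Y[rows][:, idx], columns=names)
        sub["protein_group"] = table.meta.loc[rows, "protein_group"].to_numpy()
        g = sub.groupby("protein_group", sort=True)
        blocks.append(g.sum(min_count=1))
        supports.append(pd.DataFrame({name: g.size() for name in names}))
    values = pd.concat(blocks, axis=1)
    support = pd.concat(supports, axis=1).reindex(index=values.index).fillna(0).astype(int)
    values = values.reindex(columns=design.samples)
    support = support.reindex(columns=design.samples, fill_value=0)
    kind = "summed_corrected" if use_corrected else "summed_raw"
    return QuantMatrix(values=values, kind=kind, support=support, config={"use_corrected": use_corrected})


def wm_normalize(
    table: PSMTable, design: ExperimentalDesign, cfg: WMConfig
) -> QuantMatrix:
    """Weighted-median normalized protein-group values.

    For every protein group and sample channel, collects over the group's
    PSMs in that sample's plex the ratios of sample intensity to the PSM's
    reference intensity and returns their weighted median.  PSMs with zero
    sample or zero reference intensity are skipped for that cell; cells with
    fewer than ``cfg.min_psms`` surviving ratios are missing.
    """
    cfg.validate_against(design)
    if cfg.pif_threshold is not None:
        table = pif_filter(table, cfg.pif_threshold)
    Y = table.intensities(cfg.use_corrected)
    ref = reference_intensity(table, design, cfg.mode, cfg.use_corrected)
    weights = psm_weight(
        table.meta["precursor_intensity"].to_numpy(dtype=float),
        table.meta["fill_time"].to_numpy(dtype=float),
        cfg.weight_exponent,
    )
    records: list[pd.DataFrame] = []
    for plex in design.plexes:
        rows = np.nonzero((table.meta["plex"] == plex).to_numpy())[0]
        if rows.size == 0:
            continue
        idx = design.channel_indices(plex, "sample")
        names = design.sample_names(plex)
        r = ref[rows]
        ok_ref = r > 0
        for ci, name in zip(idx, names):
            vals = Y[rows, ci]
            keep = ok_ref & (vals > 0)
            if not keep.any():
                continue
            records.append(
                pd.DataFrame(
                    {
                        "protein_group": table.meta["protein_group"].to_numpy()[rows[keep]],
                        "sample": name,
                        "ratio": vals[keep] / r[keep],
                        "weight": np.asarray(weights)[rows[keep]],
                    }
                )
            )
    if not records:
        empty = pd.DataFrame(columns=design.samples)
        return QuantMatrix(values=empty, kind="wm_normalized", support=empty.astype(int), config=vars(cfg).copy())
    long = pd.concat(records, ignore_index=True)
    grouped = long.groupby(["protein_group", "sample"], sort=True)
    cells = grouped.apply(
        lambda d: weighted_median(d["ratio"].to_numpy(), d["weight"].to_numpy()),
        include_groups=False,
    )
    counts = grouped.size()
    cells = cells[counts >= cfg.min_psms]
    values = cells.unstack("sample").reindex(columns=design.samples)
    support = counts.unstack("sample").reindex(index=values.index, columns=design.samples).fillna(0).astype(int)
    values.index.name = "protein_group"
    cfg_dict = {k: getattr(cfg, k) for k in ("mode", "weight_exponent", "use_corrected", "min_psms", "pif_threshold")}
    return QuantMatrix(values=values, kind="wm_normalized", support=support, config=cfg_dict)
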