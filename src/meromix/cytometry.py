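"""Flow-cytometry gating and enumeration of phototrophic sulfur bacteria.

Events from a small benchtop cytometer (two scatter, four fluorescence
detectors) are reduced to three phototroph phenotypes by a fixed,
deterministic rule set:

1. Acquisition thresholds — keep events with FSC-H > 2000 (removes most
   abiotic debris) and FL3-A > 1100 (red autofluorescence from
   (bacterio)chlorophyll; removes non-phototrophs).  Both comparisons
   are strict.
2. Size gating — split retained events on log10(FSC-A) at two cut
   points: below the first cut are green sulfur bacteria (GSB, sub-µm
   cells), between the cuts small-celled purple sulfur bacteria (PSB),
   above large-celled PSB (Chromatium-type, ~10 µm).

Concentrations are event counts divided by the acquired sample volume;
the bacterial-layer summary is the arithmetic mean ± sample standard
deviation across the three in-layer sampling positions (top, 50 cm
within, bottom).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, MissingChannelError, SchemaError

PHENOTYPES = ("gsb", "small_psb", "large_psb")
BL_POSITIONS = ("bl_top", "bl_mid_50cm", "bl_bottom")
SAMPLE_POSITIONS = ("above_1m",) + BL_POSITIONS + ("below_1m",)

REQUIRED_CHANNELS = ("FSC-H", "FSC-A", "FL3-A")
ALL_CHANNELS = ("FSC-H", "FSC-A", "FL1-A", "FL2-A", "FL3-A", "FL4-A")


@dataclass(frozen=True)
class GatingConfig:
    """Acquisition thresholds and size-gate geometry."""

    fsch_threshold: float = 2000.0
    fl3a_threshold: float = 1100.0
    size_cuts: tuple[float, float] = (4.5, 5.5)  # log10(FSC-A) boundaries

    def __post_init__(self) -> None:
        if self.fsch_threshold < 0 or self.fl3a_threshold < 0:
            raise DomainError("thresholds must be >= 0")
        if not self.size_cuts[0] < self.size_cuts[1]:
            raise DomainError("size_cuts must be strictly increasing")


@dataclass
class EventTable:
    """Cytometer events for one sample, with acquisition metadata."""

    events: pd.DataFrame            # one row per event, channel columns
    acquired_volume_ml: float
    sample_label: str | None = None  # one of SAMPLE_POSITIONS, or free text
    n_unclassifiable: int = 0

    def __post_init__(self) -> None:
        if self.acquired_volume_ml <= 0:
            raise DomainError("acquired_volume_ml must be > 0")
        present = [c for c in ALL_CHANNELS if c in self.events.columns]
        if len(self.events) and present:
            vals = self.events[present].to_numpy(float)
            if np.any(vals < 0):
                raise DomainError("channel values must be >= 0")

    def __len__(self) -> int:
        return len(self.events)

    def require(self, *channels: str) -> None:
        missing = [c for c in channels if c not in self.events.columns]
        if missing:
            raise MissingChannelError(f"missing channels: {missing}")


def read_event_table(
    path: str | Path,
    acquired_volume_ml: float,
    sample_label: str | None = None,
    channel_aliases: Mapping[str, str] | None = None,
) -> EventTable:
    """Read a delimited event export (one row per event).

    ``channel_aliases`` maps file column names to canonical channel
    names (e.g. ``{"FSC.H": "FSC-H"}``) for exports that mangle
    punctuation.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if channel_aliases:
        df = df.rename(columns=dict(channel_aliases))
    if not any(c in df.columns for c in ALL_CHANNELS):
        raise SchemaError(
            f"no recognizable cytometer channels in {list(df.columns)}")
    return EventTable(df, acquired_volume_ml, sample_label)


def apply_acquisition_thresholds(
    table: EventTable, config: GatingConfig = GatingConfig()
) -> EventTable:
    """Keep events with FSC-H and FL3-A strictly above their thresholds."""
    table.require("FSC-H", "FL3-A")
    ev = table.events
    keep = (ev["FSC-H"].to_numpy(float) > config.fsch_threshold) & (
        ev["FL3-A"].to_numpy(float) > config.fl3a_threshold)
    return replace(table, events=ev.loc[keep].reset_index(drop=True))


def classify_phenotypes(
    table: EventTable, config: GatingConfig = GatingConfig()
) -> EventTable:
    """Label thresholded events by size class on log10(FSC-A).

    Left-closed intervals: an event exactly at a cut belongs to the
    class above it.  Events with FSC-A = 0 (no area signal) cannot be
    placed on the log scale; they are dropped from the labeled table and
    tallied in ``n_unclassifiable``.
    """
    table.require("FSC-A")
    ev = table.events
    if not len(ev):
        out = ev.assign(label=pd.Series(dtype=str))
        return replace(table, events=out)
    fsca = ev["FSC-A"].to_numpy(float)
    ok = fsca > 0
    log_size = np.log10(fsca[ok])
    lo, hi = config.size_cuts
    label = np.where(log_size < lo, "gsb",
                     np.where(log_size < hi, "small_psb", "large_psb"))
    out = ev.loc[ok].reset_index(drop=True).assign(label=label)
    return replace(table, events=out,
                   n_unclassifiable=table.n_unclassifiable + int((~ok).sum()))


@dataclass
class PhenotypeCounts:
    """Per-sample phenotype concentrations and the in-layer summary."""

    table: pd.DataFrame       # sample_label, phenotype, count, volume_ml,
    #                           cells_per_ml — one row per combination
    bl_summary: pd.DataFrame  # phenotype, mean/sd cells_per_ml, n_positions

    def concentration(self, sample_label: str, phenotype: str) -> float:
        sel = self.table[(self.table.sample_label == sample_label)
                         & (self.table.phenotype == phenotype)]
        return float(sel.cells_per_ml.iloc[0]) if len(sel) else np.nan


def concentration_and_summary(
    tables: Iterable[EventTable],
    bl_positions: tuple[str, ...] = BL_POSITIONS,
) -> PhenotypeCounts:
    """Concentrations per sample and phenotype, plus the layer summary.

    Each input table must be labeled (see :func:`classify_phenotypes`)
    and carry its acquired volume and sampling position.  Concentration
    is count / volume (cells ml⁻¹).  The bacterial-layer summary is the
    arithmetic mean and sample standard deviation (n−1 denominator) of
    each phenotype's concentration over the in-layer positions; above-
    and below-layer samples are reported in ``table`` but excluded from
    the summary.  With a single in-layer position the sd is absent (NaN).
    """
    rows = []
    for t in tables:
        if t.sample_label is None:
            raise SchemaError("every event table needs a sample_label")
        if "label" not in t.events.columns:
            raise SchemaError(
                f"table {t.sample_label!r} is unlabeled; run "
                "classify_phenotypes first")
        counts = t.events["label"].value_counts()
        for ph in PHENOTYPES:
            n = int(counts.get(ph, 0))
            rows.append({
                "sample_label": t.sample_label,
                "phenotype": ph,
                "count": n,
                "volume_ml": t.acquired_volume_ml,
                "cells_per_ml": n / t.acquired_volume_ml,
            })
    table = pd.DataFrame(rows, columns=["sample_label", "phenotype", "count",
                                        "volume_ml", "cells_per_ml"])

    summary_rows = []
    in_layer = table[table.sample_label.isin(bl_positions)]
    for ph in PHENOTYPES:
        conc = in_layer.loc[in_layer.phenotype == ph, "cells_per_ml"]
        n_pos = len(conc)
        mean = float(conc.mean()) if n_pos else np.nan
        sd = float(conc.std(ddof=1)) if n_pos >= 2 else np.nan
        summary_rows.append({"phenotype": ph, "mean_cells_per_ml": mean,
                             "sd_cells_per_ml": sd, "n_positions": n_pos})
    return PhenotypeCounts(table=table, bl_summary=pd.DataFrame(summary_rows))
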