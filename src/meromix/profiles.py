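"""CTD cast ingestion, quality control, and conductivity normalization.

A cast is a single vertical multiparametric-probe profile: depth (or
pressure), temperature, in-situ conductivity, and optional dissolved
oxygen, turbidity, phycocyanin (BGA-PC) and PAR channels.  Casts arrive
as delimited text exported by the instrument software; this module
standardizes them into :class:`CTDProfile` objects on a strictly
increasing depth grid, normalizes conductivity to the 20 °C reference
(κ20), despikes, and regrids for downstream integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import (
    DomainError,
    InsufficientDataError,
    ParseError,
    SchemaError,
)

#: Freshwater hydrostatic conversion, metres of water per millibar
#: (rho = 1000 kg m^-3, g = 9.81 m s^-2): 1 / (rho * g) * 1e5 Pa/bar.
MBAR_TO_M = 0.010197

#: Default maximum plausible depth for QC range checks (m).
Z_BOT_DEFAULT = 21.0

#: Optional channels, in canonical order.  Canonical CSV column names are
#: the values; attribute names on CTDProfile are the keys.
OPTIONAL_CHANNELS = {
    "dissolved_oxygen": "do_mgL",
    "turbidity": "turb_ftu",
    "bga_pc": "bgapc_ppb",
    "par": "par",
}

CANONICAL_COLUMNS = {
    "depth": "depth_m",
    "temperature": "temp_c",
    "conductivity_raw": "cond_raw_uScm",
    "k20": "k20_uScm",
    **OPTIONAL_CHANNELS,
}


@dataclass
class CTDProfile:
    """One standardized CTD cast.

    Depths are metres, positive downward, strictly increasing.  Every
    present channel has the same length as ``depth``.  Optional channels
    are ``None`` when the sensor was absent or broken.
    """

    cast_id: str
    timestamp: datetime | None
    depth: np.ndarray
    temperature: np.ndarray
    conductivity_raw: np.ndarray
    k20: np.ndarray | None = None
    dissolved_oxygen: np.ndarray | None = None
    turbidity: np.ndarray | None = None
    bga_pc: np.ndarray | None = None
    par: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        for name in ("temperature", "conductivity_raw", "k20",
                     *OPTIONAL_CHANNELS):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()

    def validate(self, z_bot_max: float = Z_BOT_DEFAULT + 5.0) -> None:
        z = self.depth
        if z.ndim != 1 or len(z) < 1:
            raise DomainError("depth must be a non-empty 1-D sequence")
        if np.any(np.diff(z) <= 0):
            raise DomainError("depth must be strictly increasing")
        if z[0] < 0 or z[-1] > z_bot_max:
            raise DomainError(
                f"depths must lie in [0, {z_bot_max}] m; got "
                f"[{z[0]:.3f}, {z[-1]:.3f}]"
            )
        for name in ("temperature", "conductivity_raw", "k20",
                     *OPTIONAL_CHANNELS):
            v = getattr(self, name)
            if v is not None and len(v) != len(z):
                raise DomainError(f"channel {name!r} length mismatch")
        if self.turbidity is not None and np.nanmin(self.turbidity) < 0:
            raise DomainError("turbidity must be >= 0")
        if (self.dissolved_oxygen is not None
                and np.nanmin(self.dissolved_oxygen) < 0):
            raise DomainError("dissolved_oxygen must be >= 0")

    @property
    def channels(self) -> dict[str, np.ndarray]:
        """Present channels (everything except depth), by attribute name."""
        out = {}
        for name in ("temperature", "conductivity_raw", "k20",
                     *OPTIONAL_CHANNELS):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form with fixed column names."""
        data = {"depth_m": self.depth}
        for attr, col in CANONICAL_COLUMNS.items():
            if attr == "depth":
                continue
            v = getattr(self, attr)
            if v is not None:
                data[col] = v
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_profile_csv(path: str | Path, cast_id: str | None = None,
                     timestamp: datetime | None = None) -> CTDProfile:
    """Read a canonical profile CSV written by :meth:`CTDProfile.write_csv`."""
    df = pd.read_csv(path)
    kwargs: dict = {}
    for attr, col in CANONICAL_COLUMNS.items():
        if col in df.columns:
            kwargs[attr] = df[col].to_numpy(float)
    missing = {"depth", "temperature", "conductivity_raw"} - kwargs.keys()
    if missing:
        raise SchemaError(f"profile CSV missing columns for {sorted(missing)}")
    return CTDProfile(cast_id=cast_id or Path(path).stem,
                      timestamp=timestamp, **kwargs)


def _downcast_segment(depth: np.ndarray) -> np.ndarray:
    """Indices of the leading monotone-increasing (downcast) segment."""
    if len(depth) < 2:
        return np.arange(len(depth))
    end = len(depth)
    for i in range(1, len(depth)):
        if depth[i] < depth[i - 1]:
            end = i
            break
    return np.arange(end)


def parse_ctd_table(
    source: str | Path | pd.DataFrame,
    column_map: Mapping[str, str],
    pressure_mode: bool = False,
    surface_offset_mbar: float | None = None,
    cast_id: str = "cast",
    timestamp: datetime | None = None,
) -> CTDProfile:
    """Ingest a raw instrument export into a :class:`CTDProfile`.

    ``column_map`` maps canonical channel names (``depth`` or ``pressure``,
    ``temperature``, ``conductivity_raw``, plus optional channels) to the
    header names in the file.  With ``pressure_mode``, depth is derived
    hydrostatically: ``depth_m = 0.010197 * (p_mbar - surface_offset)``,
    where the offset defaults to the minimum pressure in the cast
    (atmospheric + sensor start).

    Rows are sorted by depth; where an up-cast follows the down-cast only
    the leading monotone segment is kept; duplicate depths are averaged.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")

    vertical_key = "pressure" if pressure_mode else "depth"
    required = [vertical_key, "temperature", "conductivity_raw"]
    for key in required:
        col = column_map.get(key)
        if col is None or col not in df.columns:
            raise SchemaError(
                f"required column for {key!r} "
                f"({col!r}) not found in {list(df.columns)}"
            )
    if len(df) < 3:
        raise InsufficientDataError(
            f"cast has {len(df)} rows; at least 3 required"
        )

    def numeric(key: str) -> np.ndarray:
        col = column_map[key]
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
        bad = np.nonzero(np.isnan(vals) & df[col].notna().to_numpy())[0]
        if len(bad):
            raise ParseError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} at row "
                f"{bad[0]} in column {col!r}"
            )
        return vals

    if pressure_mode:
        p = numeric("pressure")
        offset = surface_offset_mbar if surface_offset_mbar is not None \
            else float(np.nanmin(p))
        depth = MBAR_TO_M * (p - offset)
    else:
        depth = numeric("depth")

    channels = {"temperature": numeric("temperature"),
                "conductivity_raw": numeric("conductivity_raw")}
    for key in OPTIONAL_CHANNELS:
        col = column_map.get(key)
        if col is not None and col in df.columns:
            channels[key] = numeric(key)

    # Raw casts may mix down- and up-cast: keep the leading downcast when
    # the sequence as recorded reverses direction, then sort as a safety
    # net for shuffled exports.
    if np.any(np.diff(depth) < 0) and np.any(np.diff(depth) > 0):
        keep = _downcast_segment(depth)
        if len(keep) >= 3:
            depth = depth[keep]
            channels = {k: v[keep] for k, v in channels.items()}

    order = np.argsort(depth, kind="stable")
    depth = depth[order]
    channels = {k: v[order] for k, v in channels.items()}

    # Collapse duplicate depths by averaging every channel.
    uniq, inverse, counts = np.unique(depth, return_inverse=True,
                                      return_counts=True)
    if len(uniq) < len(depth):
        channels = {
            k: np.bincount(inverse, weights=v) / counts
            for k, v in channels.items()
        }
        depth = uniq
    if len(depth) < 3:
        raise InsufficientDataError("fewer than 3 distinct depths after QC")

    return CTDProfile(cast_id=cast_id, timestamp=timestamp, depth=depth,
                      **channels)


def normalize_conductivity_k20(
    conductivity_raw: np.ndarray | float,
    temperature: np.ndarray | float,
    alpha_t: float = 0.020,
) -> np.ndarray | float:
    """Normalize in-situ conductivity to the 20 °C reference (κ20).

    Uses the linear temperature-compensation model standard in
    freshwater limnology::

        κ20 = κ_T / (1 + alpha_t * (T - 20))

    with ``alpha_t`` ≈ 0.02 °C⁻¹ (2 % per degree).  Identity at T = 20 °C.
    """
    if not 0.0 < alpha_t < 0.1:
        raise DomainError(f"alpha_t must be in (0, 0.1); got {alpha_t}")
    k = np.asarray(conductivity_raw, dtype=float)
    if np.any(k < 0):
        raise DomainError("conductivity_raw must be >= 0")
    denom = 1.0 + alpha_t * (np.asarray(temperature, dtype=float) - 20.0)
    if np.any(denom <= 0):
        raise DomainError(
            f"temperature below {20 - 1 / alpha_t:.1f} °C makes the linear "
            "compensation denominator non-positive"
        )
    out = k / denom
    return out if out.shape else float(out)


def with_k20(profile: CTDProfile, alpha_t: float = 0.020) -> CTDProfile:
    """Return a copy of *profile* with the κ20 channel computed."""
    k20 = normalize_conductivity_k20(profile.conductivity_raw,
                                     profile.temperature, alpha_t)
    return replace(profile, k20=np.asarray(k20, dtype=float))


def qc_and_regrid(
    profile: CTDProfile,
    grid_step: float = 0.1,
    despike_window: int = 5,
) -> CTDProfile:
    """Despike every channel and interpolate onto a uniform depth grid.

    Each channel is median-filtered with an odd ``despike_window`` (1 =
    off), then linearly interpolated onto a uniform grid spanning the
    observed depth range — never beyond it.  Idempotent on an
    already-gridded, spike-free profile.
    """
    if grid_step <= 0:
        raise DomainError("grid_step must be > 0")
    if despike_window < 1 or despike_window % 2 == 0:
        raise DomainError("despike_window must be odd and >= 1")
    z = profile.depth
    span = z[-1] - z[0]
    if grid_step > span:
        raise InsufficientDataError(
            f"grid_step {grid_step} m exceeds cast span {span:.3f} m"
        )
    n = int(np.floor(span / grid_step + 1e-9)) + 1
    grid = z[0] + grid_step * np.arange(n)

    new = {}
    for name, vals in profile.channels.items():
        clean = vals if despike_window == 1 else median_filter(
            vals, size=despike_window, mode="nearest")
        new[name] = np.interp(grid, z, clean)
    out = replace(profile, depth=grid, **new)
    out.flags = dict(profile.flags, regridded=grid_step)
    return out
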