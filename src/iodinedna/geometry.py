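"""Charlton-style helical DNA geometry.

The duplex is modelled as a central cylinder of bases (1 nm diameter)
surrounded by two backbone arches per base slab, the whole fibre 2.3 nm
across.  Each base occupies a 0.34 nm slab along the helix axis (the z
axis), and the backbone arches rotate by 36 degrees per slab, ten bases per
turn.  This module classifies raw 3D points (as scored by a transport code)
into base/backbone volumes, applies the OH scavenging radius, and converts
raw-position event files into the per-(strand, base) schema used by
:mod:`iodinedna.tracks`.

The azimuthal extent of each arch is configurable; the default of 180
degrees per strand tiles the backbone annulus with two semicircular arcs on
opposite sides, the simplest reading of "two semi-circular backbone
strands".  Slab intervals and arc intervals are half-open so the
classification is an exact partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .tracks import TrackDataset

__all__ = [
    "Classification",
    "GeometryParams",
    "bases_per_turn",
    "classify_point",
    "classify_points",
    "is_scavenged",
    "read_position_events",
]


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the helix model (all lengths in nm, angles in degrees)."""

    base_radius: float = 0.5
    outer_radius: float = 1.15
    slab_thickness: float = 0.34
    twist_step: float = 36.0
    n_bases: int = 40
    scavenge_radius: float = 1.65
    iodine_offset: float = 0.15  # toward strand 0, within base 0
    arc_width: float = 180.0  # azimuthal extent of each backbone arch

    def __post_init__(self) -> None:
        if not 0 < self.base_radius < self.outer_radius:
            raise ValueError("need 0 < base_radius < outer_radius")
        if self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be > 0")
        if self.twist_step <= 0 or abs(360.0 / self.twist_step - round(360.0 / self.twist_step)) > 1e-9:
            raise ValueError("twist_step must divide 360")
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        if not 0 < self.arc_width <= 180.0:
            raise ValueError("arc_width must lie in (0, 180] degrees")
        if self.scavenge_radius <= 0:
            raise ValueError("scavenge_radius must be > 0")

    def iodine_position(self) -> np.ndarray:
        """Centre of the iodine atom: mid-slab of base 0, offset toward the
        strand-0 arch (azimuth 0 at slab 0)."""
        return np.array([self.iodine_offset, 0.0, 0.5 * self.slab_thickness])


class Classification(NamedTuple):
    """Region tag plus base/strand indices (None where not applicable)."""

    region: str  # 'outside' | 'base' | 'backbone'
    base: int | None = None
    strand: int | None = None


def bases_per_turn(params: GeometryParams) -> int:
    """Number of base slabs in one full helical turn (360 / twist)."""
    turns = 360.0 / params.twist_step
    if abs(turns - round(turns)) > 1e-9:
        raise ValueError("twist_step must divide 360")
    return int(round(turns))


def classify_points(xyz: np.ndarray, params: GeometryParams):
    """Vectorised classification of points, shape (n, 3), in nm.

    Returns ``(region, base, strand)`` arrays where ``region`` is one of
    ``'outside'``, ``'base'``, ``'backbone'`` and base/strand are -1 where
    not applicable.

    Base ``i`` occupies the half-open slab ``z in [i*t, (i+1)*t)``.  Within
    the backbone annulus, the strand-0 arch at slab ``i`` is centred on
    azimuth ``i * twist_step`` and spans ``arc_width`` degrees (half-open);
    the strand-1 arch sits diametrically opposite.
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    r = np.hypot(x, y)
    t = params.slab_thickness

    slab = np.floor(z / t).astype(int)
    in_z = (z >= 0) & (slab < params.n_bases)
    # floor can round z just below a boundary into the slab above on exact ties
    slab = np.clip(slab, 0, params.n_bases - 1)

    region = np.full(x.shape, "outside", dtype=object)
    base = np.full(x.shape, -1, dtype=int)
    strand = np.full(x.shape, -1, dtype=int)

    is_base = in_z & (r < params.base_radius)
    region[is_base] = "base"
    base[is_base] = slab[is_base]

    annulus = in_z & (r >= params.base_radius) & (r < params.outer_radius)
    if annulus.any():
        theta = np.degrees(np.arctan2(y[annulus], x[annulus]))
        phase = slab[annulus] * params.twist_step
        # signed offset from the strand-0 arch centre, in [-180, 180)
        d0 = (theta - phase + 180.0) % 360.0 - 180.0
        half = 0.5 * params.arc_width
        on0 = (d0 >= -half) & (d0 < half)
        d1 = (d0 + 360.0) % 360.0 - 180.0  # offset from the opposite arch
        on1 = ~on0 & (d1 >= -half) & (d1 < half)
        idx = np.nonzero(annulus)[0]
        hit = on0 | on1
        region[idx[hit]] = "backbone"
        base[idx[hit]] = slab[annulus][hit]
        strand[idx[hit]] = np.where(on0, 0, 1)[hit]

    return region, base, strand


def classify_point(p, params: GeometryParams) -> Classification:
    """Classify a single 3D point (nm) into outside / base(i) / backbone(i, s)."""
    region, base, strand = classify_points(np.asarray(p, dtype=float).reshape(1, 3), params)
    if region[0] == "outside":
        return Classification("outside")
    if region[0] == "base":
        return Classification("base", int(base[0]))
    return Classification("backbone", int(base[0]), int(strand[0]))


def is_scavenged(p, params: GeometryParams) -> bool:
    """True iff the point's radial distance from the helix axis is strictly
    below the scavenging radius (1.65 nm by default)."""
    p = np.asarray(p, dtype=float)
    return bool(np.hypot(p[0], p[1]) < params.scavenge_radius)


def read_position_events(path, params: GeometryParams, n_decays: int | None = None,
                         label: str = "") -> TrackDataset:
    """Ingest a raw-position event file and classify it onto the helix.

    Expected columns: ``event_id, record_type (EDEP|OH), x_nm, y_nm, z_nm,
    energy_eV`` (energy empty for OH rows).  EDEP rows are kept only when
    they fall inside a backbone volume.  OH rows are kept when inside the
    scavenging radius and within the strand's z extent; they are assigned
    the slab's base index and the azimuthally nearer strand, matching how a
    scavenging scorer records radical arrival.
    """
    df = pd.read_csv(path, comment="#")
    required = {"event_id", "record_type", "x_nm", "y_nm", "z_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"position file missing columns: {sorted(missing)}")
    if n_decays is None:
        n_decays = int(df["event_id"].max()) + 1 if len(df) else 0

    xyz = df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    region, base, strand = classify_points(xyz, params)
    rt = df["record_type"].astype(str).str.upper().to_numpy()

    keep_e = (rt == "EDEP") & (region == "backbone")
    inter = pd.DataFrame(
        {
            "event_id": df["event_id"].to_numpy(int)[keep_e],
            "strand": strand[keep_e],
            "base": base[keep_e],
            "energy_eV": df["energy_eV"].to_numpy(float)[keep_e],
        }
    )

    r = np.hypot(xyz[:, 0], xyz[:, 1])
    t = params.slab_thickness
    slab = np.clip(np.floor(xyz[:, 2] / t).astype(int), 0, params.n_bases - 1)
    in_z = (xyz[:, 2] >= 0) & (xyz[:, 2] < params.n_bases * t)
    keep_o = (rt == "OH") & (r < params.scavenge_radius) & in_z
    theta = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0]))
    d0 = (theta - slab * params.twist_step + 180.0) % 360.0 - 180.0
    near_strand = (np.abs(d0) > 90.0).astype(int)  # nearer arch: 0 within 90 deg
    oh = pd.DataFrame(
        {
            "event_id": df["event_id"].to_numpy(int)[keep_o],
            "strand": near_strand[keep_o],
            "base": slab[keep_o],
        }
    )
    return TrackDataset(inter, oh, n_decays=n_decays, n_bases=params.n_bases, label=label)
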