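"""Channelized sparse voxel density maps of fused reference IPAs.

The fused IPAs of all reference complexes are binned, per channel, into a
cubic grid of 0.1 A edge voxels spanning the bounding box of the IPAs (the
two furthest IPAs sit at voxel centers).  The density read out at a voxel is
the number of same-channel reference IPAs in that voxel plus those in voxels
within a Manhattan distance of 0.5 A — i.e. an L1 index distance of
``neighborhood/edge`` voxels.  A dense 0.1 A grid over a binding site would
need ~1e8 voxels per channel, so only occupied voxels are stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .interactions import IPA, Channel, all_channels, channel_code, parse_channel_code

VoxelIndex = tuple[int, int, int]


class MapBuildError(ValueError):
    pass


class MapLoadError(ValueError):
    pass


@dataclass
class GridSpec:
    origin: np.ndarray       # min corner, Angstrom
    edge: float              # voxel edge length, Angstrom
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.edge <= 0:
            raise ValueError("edge must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 on every axis")

    def voxel_of(self, point: np.ndarray) -> VoxelIndex:
        """Half-open binning: boundary points go to the higher index."""
        idx = np.floor((np.asarray(point, float) - self.origin) / self.edge)
        return (int(idx[0]), int(idx[1]), int(idx[2]))

    def contains(self, voxel: VoxelIndex) -> bool:
        return all(0 <= voxel[k] < self.dims[k] for k in range(3))


@dataclass
class ChannelMap:
    channel: Channel
    counts: dict[VoxelIndex, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, voxel: VoxelIndex) -> None:
        self.counts[voxel] = self.counts.get(voxel, 0) + 1


def _l1_offsets(radius: int) -> list[VoxelIndex]:
    offs = []
    for di in range(-radius, radius + 1):
        rj = radius - abs(di)
        for dj in range(-rj, rj + 1):
            rk = rj - abs(dj)
            for dk in range(-rk, rk + 1):
                offs.append((di, dj, dk))
    return offs


@dataclass
class LIDMapSet:
    """The 21 per-channel sparse density grids plus their shared geometry."""

    spec: GridSpec
    channels: dict[Channel, ChannelMap]
    n_references: int = 1
    neighborhood: float = 0.5
    provenance: list[str] = field(default_factory=list)
    _dilated: dict[Channel, dict[VoxelIndex, int]] = field(
        default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.neighborhood < 0:
            raise ValueError("neighborhood must be >= 0")
        for ch in all_channels():
            self.channels.setdefault(ch, ChannelMap(ch))

    @property
    def l1_radius(self) -> int:
        return int(self.neighborhood / self.spec.edge + 1e-9)

    def density_at(self, point: np.ndarray, channel: Channel,
                   method: Literal["lazy", "dilated"] = "lazy") -> int:
        """Reference-IPA count of *channel* within the L1 voxel neighborhood
        of *point*.  Points whose voxel falls outside the grid score 0."""
        if channel not in self.channels:
            raise KeyError(f"unknown channel {channel!r}")
        voxel = self.spec.voxel_of(point)
        if not self.spec.contains(voxel):
            return 0
        if method == "dilated":
            return self._dilated_table(channel).get(voxel, 0)
        counts = self.channels[channel].counts
        if not counts:
            return 0
        r = self.l1_radius
        total = 0
        for di, dj, dk in _l1_offsets(r):
            total += counts.get((voxel[0] + di, voxel[1] + dj, voxel[2] + dk), 0)
        return total

    def _dilated_table(self, channel: Channel) -> dict[VoxelIndex, int]:
        table = self._dilated.get(channel)
        if table is None:
            table = {}
            r = self.l1_radius
            offsets = _l1_offsets(r)
            for (i, j, k), c in self.channels[channel].counts.items():
                for di, dj, dk in offsets:
                    key = (i + di, j + dj, k + dk)
                    table[key] = table.get(key, 0) + c
            self._dilated[channel] = table
        return table

    def channel_totals(self) -> dict[Channel, int]:
        return {ch: cm.total for ch, cm in self.channels.items()}


def build_maps(ipas: Sequence[IPA], edge: float = 0.1,
               neighborhood: float = 0.5,
               n_references: int = 1,
               provenance: Sequence[str] = ()) -> LIDMapSet:
    """Fuse reference IPAs (already in the representative frame) into maps.

    The grid spans the IPA bounding box with the extreme IPAs at voxel
    centers (origin = min corner minus half an edge).
    """
    if not ipas:
        raise MapBuildError("no reference interactions: cannot build LID maps")
    coords = np.array([ipa.coords for ipa in ipas])
    origin = coords.min(axis=0) - edge / 2.0
    dims_f = np.floor((coords.max(axis=0) - origin) / edge) + 1
    spec = GridSpec(origin=origin, edge=edge,
                    dims=(int(dims_f[0]), int(dims_f[1]), int(dims_f[2])))
    channels = {ch: ChannelMap(ch) for ch in all_channels()}
    for ipa in ipas:
        channels[ipa.channel].add(spec.voxel_of(ipa.coords))
    return LIDMapSet(spec=spec, channels=channels, n_references=n_references,
                     neighborhood=neighborhood, provenance=list(provenance))


def density_at(mapset: LIDMapSet, point: np.ndarray, channel: Channel,
               method: Literal["lazy", "dilated"] = "lazy") -> int:
    return mapset.density_at(point, channel, method=method)


# ---------------------------------------------------------------------------
# serialization: versioned plain-text format
# ---------------------------------------------------------------------------
# Header lines (key value), then per-channel blocks:
#   LIDMAPS 1
#   edge <float>
#   origin <x> <y> <z>
#   dims <nx> <ny> <nz>
#   neighborhood <float>
#   n_references <int>
#   provenance <comma-separated ids>      (optional)
#   channel <CODE> <n_voxels>
#   <i> <j> <k> <count>                   (n_voxels rows)

_MAGIC = "LIDMAPS"
_VERSION = 1


def save_maps(mapset: LIDMapSet, path: str | Path) -> None:
    lines = [f"{_MAGIC} {_VERSION}"]
    o = [float(v) for v in mapset.spec.origin]
    lines.append(f"edge {float(mapset.spec.edge)!r}")
    lines.append(f"origin {o[0]!r} {o[1]!r} {o[2]!r}")
    lines.append("dims {} {} {}".format(*mapset.spec.dims))
    lines.append(f"neighborhood {float(mapset.neighborhood)!r}")
    lines.append(f"n_references {mapset.n_references}")
    if mapset.provenance:
        lines.append("provenance " + ",".join(mapset.provenance))
    for ch in all_channels():
        cm = mapset.channels[ch]
        lines.append(f"channel {channel_code(ch)} {len(cm.counts)}")
        for (i, j, k), c in sorted(cm.counts.items()):
            lines.append(f"{i} {j} {k} {c}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_maps(path: str | Path) -> LIDMapSet:
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise MapLoadError(str(exc)) from exc
    if not lines or not lines[0].startswith(_MAGIC):
        raise MapLoadError(f"{path}: not a LID map file (bad magic)")
    try:
        version = int(lines[0].split()[1])
    except (IndexError, ValueError) as exc:
        raise MapLoadError(f"{path}: malformed header") from exc
    if version != _VERSION:
        raise MapLoadError(f"{path}: unsupported map version {version}")

    header: dict[str, list[str]] = {}
    pos = 1
    while pos < len(lines) and not lines[pos].startswith("channel "):
        key, *vals = lines[pos].split()
        header[key] = vals
        pos += 1
    try:
        spec = GridSpec(
            origin=np.array([float(v) for v in header["origin"]]),
            edge=float(header["edge"][0]),
            dims=tuple(int(v) for v in header["dims"]),  # type: ignore[arg-type]
        )
        neighborhood = float(header["neighborhood"][0])
        n_references = int(header["n_references"][0])
    except (KeyError, ValueError, IndexError) as exc:
        raise MapLoadError(f"{path}: incomplete header") from exc
    provenance = header.get("provenance", [""])[0].split(",") \
        if "provenance" in header else []
    provenance = [p for p in provenance if p]

    channels = {ch: ChannelMap(ch) for ch in all_channels()}
    n_blocks = 0
    while pos < len(lines):
        parts = lines[pos].split()
        if len(parts) != 3 or parts[0] != "channel":
            raise MapLoadError(f"{path}: expected channel line at {pos + 1}")
        ch = parse_channel_code(parts[1])
        n_vox = int(parts[2])
        pos += 1
        if pos + n_vox > len(lines):
            raise MapLoadError(f"{path}: truncated channel block {parts[1]}")
        for _ in range(n_vox):
            i, j, k, c = (int(v) for v in lines[pos].split())
            channels[ch].counts[(i, j, k)] = c
            pos += 1
        n_blocks += 1
    if n_blocks != len(channels):
        raise MapLoadError(
            f"{path}: truncated file ({n_blocks} of {len(channels)} channel blocks)")
    return LIDMapSet(spec=spec, channels=channels, n_references=n_references,
                     neighborhood=neighborhood, provenance=provenance)
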