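"""Whole-volume prediction by non-overlapping output tiling.

A valid-padding network shrinks its input, so a whole volume is predicted by
padding it (mirror by default) and running the network on a lattice of input
windows whose *output* windows are pairwise disjoint and exactly cover the
original grid — every voxel of the prediction is produced by exactly one
tile, which avoids blending artifacts at tile borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import EncoderDecoder3D, InadmissibleShapeError, NetworkConfig, output_shape
from .volume import Volume


def admissible_tile_shape(net_cfg: NetworkConfig, target_shape, max_extra: int = 64
                          ) -> tuple[int, ...]:
    """Per axis, the smallest admissible tile extent >= the target extent.

    Valid-padding arithmetic is independent per axis, so each axis is grown
    until the shape survives the full layer trace.
    """
    out = []
    for n in target_shape:
        for m in range(int(n), int(n) + max_extra + 1):
            try:
                output_shape(net_cfg, (m, m, m))
            except InadmissibleShapeError:
                continue
            out.append(m)
            break
        else:
            raise InadmissibleShapeError(
                f"no admissible tile extent within {max_extra} voxels of {n}"
            )
    return tuple(out)


@dataclass
class Tile:
    #: start of the input window in padded-volume coordinates
    in_start: tuple[int, int, int]
    #: output window in original-volume coordinates (start, stop per axis)
    out_window: tuple[tuple[int, int], ...]


@dataclass
class TilePlan:
    volume_shape: tuple[int, int, int]
    tile_input_shape: tuple[int, int, int]
    tile_output_shape: tuple[int, int, int]
    pad_lo: tuple[int, int, int]
    padded_shape: tuple[int, int, int]
    tiles: list[Tile]

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def coverage_count(self) -> np.ndarray:
        """Times each original voxel is written; all-ones iff a valid plan."""
        count = np.zeros(self.volume_shape, dtype=np.int32)
        for t in self.tiles:
            sl = tuple(slice(a, b) for a, b in t.out_window)
            count[sl] += 1
        return count


def _axis_layout(length: int, out_len: int, crop: int = 0
                 ) -> list[tuple[int, int, int]]:
    """Per-axis tile layout: (natural output start, window start, window stop).

    With ``crop`` > 0 only the central ``out_len - 2*crop`` voxels of each
    tile's output are kept (except at the volume edges), so every retained
    voxel has generous receptive-field context; input windows overlap but
    output windows stay pairwise disjoint and exactly cover [0, length).
    The final tile is shifted flush to the volume edge rather than into
    padding.
    """
    core = out_len - 2 * crop
    if core < 1:
        raise ValueError(f"output crop {crop} leaves no core of tile output {out_len}")
    if length <= out_len:
        return [(0, 0, length)]
    span = length - out_len
    n_tiles = -(-span // core) + 1
    # spread window starts evenly over [0, span]; windows whose content is
    # centered on the volume behave best, so assignment is greedy from the
    # most central window outward: it claims its whole output range, and
    # windows toward the edges claim only what remains on their side
    starts = sorted({round(i * span / (n_tiles - 1)) for i in range(n_tiles)})
    mid = min(range(len(starts)),
              key=lambda i: abs(starts[i] + out_len / 2 - length / 2))
    claims: dict[int, tuple[int, int]] = {}
    left, right = starts[mid], min(starts[mid] + out_len, length)
    claims[mid] = (left, right)
    for i in range(mid - 1, -1, -1):  # leftward
        lo = starts[i] if i > 0 else 0
        claims[i] = (lo, left)
        left = lo
    for i in range(mid + 1, len(starts)):  # rightward
        hi = min(starts[i] + out_len, length) if i < len(starts) - 1 else length
        claims[i] = (right, hi)
        right = hi
    return [(starts[i], *claims[i]) for i in sorted(claims) if claims[i][1] > claims[i][0]]


def default_output_crop(out_len: int) -> int:
    """Default context crop for pipeline inference: a quarter of the tile
    output per side, so retained voxels keep substantial receptive-field
    context while tile counts stay modest."""
    return out_len // 4


def plan_tiles(volume_shape, tile_input_shape, net_cfg: NetworkConfig,
               output_crop: int | None = 0) -> TilePlan:
    """Lay out input windows whose outputs tile the volume without overlap.

    Every original voxel is produced by exactly one tile (disjoint exact
    cover in output space); with ``output_crop`` 0, tiles per axis =
    ceil(axis_len / tile_output_len).  A positive ``output_crop`` keeps only
    the central part of each tile's output (borders have poor context),
    at the cost of more tiles.  Input windows are kept over real volume
    content — edge tiles shift inward instead of running into padding — so
    only the small valid-padding margin is mirror-padded.
    """
    volume_shape = tuple(int(n) for n in volume_shape)
    tile_input_shape = tuple(int(n) for n in tile_input_shape)
    out_sp, _ = output_shape(net_cfg, tile_input_shape)  # raises if inadmissible
    margin = tuple(i - o for i, o in zip(tile_input_shape, out_sp))
    if any(m < 0 for m in margin):
        raise ValueError("tile output larger than input is not supported")
    pad_lo = tuple(m // 2 for m in margin)
    # padded extent: margin plus any shortfall of a volume smaller than one tile
    padded = tuple(max(L + m, i) for L, m, i in zip(volume_shape, margin, tile_input_shape))
    crops = (tuple(default_output_crop(o) for o in out_sp)
             if output_crop is None else (int(output_crop),) * 3)
    layouts = [_axis_layout(L, o, c) for L, o, c in zip(volume_shape, out_sp, crops)]
    tiles = []
    for lx in layouts[0]:
        for ly in layouts[1]:
            for lz in layouts[2]:
                tiles.append(Tile(
                    in_start=(lx[0], ly[0], lz[0]),
                    out_window=((lx[1], lx[2]), (ly[1], ly[2]), (lz[1], lz[2])),
                ))
    return TilePlan(volume_shape, tile_input_shape, out_sp, pad_lo, padded, tiles)


def _pad_mirror(a: np.ndarray, pad_lo, padded_shape, mode: str = "reflect") -> np.ndarray:
    """Pad to ``padded_shape`` with ``pad_lo`` leading voxels per axis.

    Mirror padding is applied in repeated passes so pads wider than the
    current extent (tiny volumes, large tiles) still work; ``mode`` may be
    "reflect" or "zero".
    """
    want = [(lo, ps - lo - n) for lo, ps, n in zip(pad_lo, padded_shape, a.shape)]
    if mode == "zero":
        return np.pad(a, want)
    out = a
    while any(lo > 0 or hi > 0 for lo, hi in want):
        step = [(min(lo, out.shape[i] - 1), min(hi, out.shape[i] - 1))
                for i, (lo, hi) in enumerate(want)]
        out = np.pad(out, step, mode="reflect")
        want = [(lo - s[0], hi - s[1]) for (lo, hi), s in zip(want, step)]
    return out


def predict_volume(model: EncoderDecoder3D, t1: Volume | np.ndarray, plan: TilePlan,
                   pad_mode: str = "reflect") -> Volume:
    """Tiled whole-volume inference; each voxel written by exactly one tile."""
    vals = t1.values if isinstance(t1, Volume) else np.asarray(t1)
    voxel_size = t1.voxel_size if isinstance(t1, Volume) else (1.0, 1.0, 1.0)
    if vals.shape != plan.volume_shape:
        raise ValueError(f"volume shape {vals.shape} does not match plan {plan.volume_shape}")
    padded = _pad_mirror(vals.astype(np.float32), plan.pad_lo, plan.padded_shape, pad_mode)
    out = np.zeros(plan.volume_shape, dtype=np.float32)
    tin = plan.tile_input_shape
    for tile in plan.tiles:
        sl_in = tuple(slice(s, s + n) for s, n in zip(tile.in_start, tin))
        pred = model.forward(padded[sl_in][None, None])[0, 0]
        # the tile's output voxel j corresponds to original voxel in_start + j
        keep = tuple(slice(a - s, b - s)
                     for (a, b), s in zip(tile.out_window, tile.in_start))
        sl_out = tuple(slice(a, b) for a, b in tile.out_window)
        out[sl_out] = pred[keep]
    return Volume(out, voxel_size)
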