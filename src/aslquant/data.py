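"""ASL data model: timing metadata, label-control differencing, time-encoded
decoding and NIfTI I/O.

An :class:`ASLSeries` couples a 4D voxel array with an :class:`ASLTimingSpec`
describing what each volume is (label/control, delay, repeat, encoding row).
All images are handled as NIfTI via nibabel; data are kept on the native
acquisition voxel grid throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from ._exceptions import ConfigurationError, DataError

__all__ = [
    "ASLTimingSpec",
    "ASLSeries",
    "load_asl",
    "subtract_pairs",
    "hadamard_decode",
    "write_map",
    "load_hadamard_matrix",
]

#: recognised acquisition volume orderings (label/control pairs are always
#: adjacent; what varies is whether delays or repeats cycle faster)
VOLUME_ORDERS = ("pairs_then_delays", "delays_then_pairs")


@dataclass(frozen=True)
class ASLTimingSpec:
    """Acquisition timing and ordering metadata for an ASL series.

    Parameters
    ----------
    labelling:
        ``"pcasl"`` or ``"pasl"``. Determines whether ``delays`` are
        post-labelling delays (PLD) or inversion times (TI).
    label_duration:
        Labelling bolus duration tau in seconds (total encoded duration for
        time-encoded acquisitions).
    delays:
        PLDs (pcasl) or TIs (pasl) in seconds, one per delay; a time-encoded
        acquisition declares the single nominal PLD of the whole block.
    repeats_per_delay:
        Number of label-control pairs (or encoded blocks) per delay.
    volume_order:
        ``"delays_then_pairs"``: all repeats of delay 1 first, then delay 2...
        ``"pairs_then_delays"``: one pair at each delay, cycling, then the
        next repeat. Pairs are adjacent in both.
    label_first:
        Whether the label image precedes the control in each pair.
    encoding:
        Optional Hadamard encoding matrix (N x N, entries +/-1, orthogonal
        columns) for time-encoded data.
    sub_durations:
        Optional per-sub-bolus durations (seconds) for time-encoded data,
        ordered from the sub-bolus nearest imaging outwards; defaults to
        ``label_duration / N`` each.
    """

    labelling: str
    label_duration: float
    delays: tuple
    repeats_per_delay: int = 1
    volume_order: str = "delays_then_pairs"
    label_first: bool = True
    encoding: Optional[np.ndarray] = None
    sub_durations: Optional[tuple] = None

    def __post_init__(self):
        if self.labelling not in ("pcasl", "pasl"):
            raise ConfigurationError(f"unknown labelling scheme {self.labelling!r}")
        if self.label_duration <= 0:
            raise ConfigurationError("label_duration must be positive")
        object.__setattr__(self, "delays", tuple(float(d) for d in self.delays))
        if len(self.delays) == 0 or any(d <= 0 for d in self.delays):
            raise ConfigurationError("delays must be a non-empty list of positive seconds")
        if list(self.delays) != sorted(self.delays):
            raise ConfigurationError("delays must be non-decreasing")
        if self.repeats_per_delay < 1:
            raise ConfigurationError("repeats_per_delay must be >= 1")
        if self.volume_order not in VOLUME_ORDERS:
            raise ConfigurationError(
                f"volume_order must be one of {VOLUME_ORDERS}, got {self.volume_order!r}"
            )
        if self.encoding is not None:
            enc = np.asarray(self.encoding, dtype=float)
            if enc.ndim != 2 or enc.shape[0] != enc.shape[1]:
                raise ConfigurationError("encoding matrix must be square")
            if not np.all(np.isin(enc, (-1.0, 1.0))):
                raise ConfigurationError("encoding matrix entries must be +/-1")
            n = enc.shape[0]
            if not np.allclose(enc.T @ enc, n * np.eye(n)):
                raise ConfigurationError("encoding matrix columns must be orthogonal")
            object.__setattr__(self, "encoding", enc)
            if len(self.delays) != 1:
                raise ConfigurationError(
                    "time-encoded data declare a single nominal delay"
                )
            subs = self.sub_durations
            if subs is None:
                subs = tuple([self.label_duration / n] * n)
            else:
                subs = tuple(float(s) for s in subs)
                if len(subs) != n or any(s <= 0 for s in subs):
                    raise ConfigurationError(
                        f"sub_durations must be {n} positive values"
                    )
            object.__setattr__(self, "sub_durations", subs)

    @property
    def n_delays(self) -> int:
        return len(self.delays)

    @property
    def n_volumes(self) -> int:
        """Number of raw acquired volumes this spec declares."""
        if self.encoding is not None:
            return self.encoding.shape[0] * self.repeats_per_delay
        return 2 * self.n_delays * self.repeats_per_delay


@dataclass
class ASLSeries:
    """A 4D ASL voxel array plus the metadata describing each volume.

    ``kind`` tracks the processing state: ``"raw"`` (acquired label/control
    volumes), ``"differenced"`` (one volume per label-control pair) or
    ``"decoded"`` (one volume per sub-bolus of a time-encoded acquisition).
    Differenced/decoded volumes are stored in canonical delay-major order
    (all repeats of the first delay, then the second...). Decoded series
    carry per-volume effective timing in ``eff_pld`` / ``eff_ld``.
    """

    voxels: np.ndarray
    affine: np.ndarray
    timing: ASLTimingSpec
    mask: np.ndarray
    kind: str = "raw"
    eff_pld: Optional[np.ndarray] = None
    eff_ld: Optional[np.ndarray] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise DataError(f"expected a 4D array, got shape {self.voxels.shape}")
        bad = ~np.isfinite(self.voxels)
        if bad.any():
            idx = tuple(int(i[0]) for i in np.nonzero(bad))
            raise DataError(f"non-finite voxel value at index {idx}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spatial_shape:
            raise DataError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.spatial_shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def spatial_shape(self):
        return self.voxels.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.voxels.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def delay_per_volume(self) -> np.ndarray:
        """Nominal delay (PLD or TI) for each differenced/decoded volume."""
        if self.kind == "decoded":
            return np.asarray(self.eff_pld, dtype=float)
        if self.kind != "differenced":
            raise ConfigurationError("delay_per_volume applies to differenced data")
        t = self.timing
        return np.repeat(np.asarray(t.delays), t.repeats_per_delay)

    def data_matrix(self) -> np.ndarray:
        """Masked voxel time courses as an (n_voxels, n_volumes) matrix."""
        return self.voxels[self.mask]


def _auto_mask(mean_vol: np.ndarray, frac: float = 0.10) -> np.ndarray:
    # threshold at `frac` of the 99th-percentile intensity: robust to hot voxels
    robust_max = np.percentile(mean_vol, 99)
    return mean_vol > frac * robust_max


def load_asl(
    path,
    timing: ASLTimingSpec,
    mask: Optional[object] = None,
) -> ASLSeries:
    """Load a 4D NIfTI ASL series, validating it against the declared timing.

    If no mask is given, one is formed by thresholding the mean volume at
    10% of its robust (99th percentile) maximum.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise DataError(f"{path}: expected a 3D/4D NIfTI, got {data.ndim} dimensions")
    bad = ~np.isfinite(data)
    if bad.any():
        idx = tuple(int(i[0]) for i in np.nonzero(bad))
        raise DataError(f"{path}: non-finite voxel value at index {idx}")
    if data.shape[3] != timing.n_volumes:
        raise ConfigurationError(
            f"{path}: file contains {data.shape[3]} volumes but the timing "
            f"specification declares {timing.n_volumes}"
        )
    if mask is not None:
        mask_arr = np.asarray(nib.load(str(mask)).dataobj) > 0
    else:
        mask_arr = _auto_mask(data.mean(axis=3))
    return ASLSeries(voxels=data, affine=img.affine, timing=timing, mask=mask_arr)


def _pair_indices(timing: ASLTimingSpec):
    """Indices of (label, control) volumes per (delay, repeat), delay-major."""
    nd, nr = timing.n_delays, timing.repeats_per_delay
    out = []
    for d in range(nd):
        for r in range(nr):
            if timing.volume_order == "delays_then_pairs":
                pair = (d * nr + r) * 2
            else:  # pairs_then_delays
                pair = (r * nd + d) * 2
            if timing.label_first:
                out.append((pair, pair + 1))
            else:
                out.append((pair + 1, pair))
    return out


def subtract_pairs(series: ASLSeries) -> ASLSeries:
    """Difference label-control pairs (control - label, tissue signal positive).

    Output volumes are in canonical delay-major order, one per pair.
    """
    if series.kind != "raw":
        raise ConfigurationError("series is already differenced")
    if series.timing.encoding is not None:
        raise ConfigurationError(
            "time-encoded data must be decoded with hadamard_decode, not subtracted"
        )
    if series.n_volumes % 2:
        raise DataError(f"odd number of volumes ({series.n_volumes}) cannot be paired")
    pairs = _pair_indices(series.timing)
    diffs = np.stack(
        [series.voxels[..., c] - series.voxels[..., l] for (l, c) in pairs], axis=3
    )
    return ASLSeries(
        voxels=diffs,
        affine=series.affine,
        timing=replace(series.timing, volume_order="delays_then_pairs"),
        mask=series.mask,
        kind="differenced",
    )


def hadamard_decode(series: ASLSeries) -> ASLSeries:
    """Decode a Hadamard time-encoded series into per-sub-bolus volumes.

    Decoding applies the scaled transpose of the encoding matrix to each
    block of encoded volumes, so ``decode(encode(x)) == x``. Sub-bolus k
    (k = 0 nearest imaging) receives label duration equal to its block
    sub-duration and effective PLD = nominal PLD plus the durations of all
    sub-boluses played later (nearer imaging).
    """
    enc = series.timing.encoding
    if enc is None:
        raise ConfigurationError("series has no encoding matrix to decode")
    n = enc.shape[0]
    if series.n_volumes % n:
        raise DataError(
            f"volume count {series.n_volumes} not divisible by encoding size {n}"
        )
    n_blocks = series.n_volumes // n
    decode = enc.T / n
    vox = series.voxels
    out = np.empty_like(vox)
    for b in range(n_blocks):
        block = vox[..., b * n : (b + 1) * n]
        out[..., b * n : (b + 1) * n] = block @ decode.T
    # reorder to delay-major: sub-bolus index is the "delay" axis
    order = np.concatenate([[b * n + k for b in range(n_blocks)] for k in range(n)])
    out = out[..., order]
    subs = np.asarray(series.timing.sub_durations)
    pld0 = series.timing.delays[0]
    eff_pld_per_sub = pld0 + np.concatenate([[0.0], np.cumsum(subs[:-1])])
    eff_pld = np.repeat(eff_pld_per_sub, n_blocks)
    eff_ld = np.repeat(subs, n_blocks)
    return ASLSeries(
        voxels=out,
        affine=series.affine,
        timing=series.timing,
        mask=series.mask,
        kind="decoded",
        eff_pld=eff_pld,
        eff_ld=eff_ld,
    )


def hadamard_encode(sub_volumes: np.ndarray, encoding: np.ndarray) -> np.ndarray:
    """Encode per-sub-bolus volumes (..., N) with an encoding matrix (N x N)."""
    enc = np.asarray(encoding, dtype=float)
    return sub_volumes @ enc.T


def load_hadamard_matrix(path) -> np.ndarray:
    """Read a +/-1 encoding matrix from a whitespace-separated text file."""
    mat = np.loadtxt(str(path))
    return np.atleast_2d(mat)


def write_map(volume: np.ndarray, affine: np.ndarray, path, mask: Optional[np.ndarray] = None):
    """Write a 3D map to NIfTI; values inside the mask must be finite."""
    volume = np.asarray(volume, dtype=float)
    check = volume if mask is None else volume[np.asarray(mask, dtype=bool)]
    if not np.all(np.isfinite(check)):
        raise DataError("non-finite value inside mask; refusing to write map")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(volume, np.asarray(affine, dtype=float)), str(path))
    return path
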