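"""Ground-truth ASL phantom generator.

Synthesises raw label-control series (plus an M0 calibration image and a
truth bundle) from known physiological maps, using the same kinetic forward
model the pipeline fits — so a noiseless phantom is exactly identifiable.
Perfusion truth is stated in ml/100 g/min and converted internally to signal
units via f_signal = perfusion * m0_blood / 6000; the control (static tissue)
baseline is the PV-weighted water density times m0_blood, giving a realistic
~1% difference-to-control ratio. All randomness is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from ._exceptions import ConfigurationError
from .data import ASLSeries, ASLTimingSpec, write_map
from .kinetics import (
    DEFAULT_ALPHA,
    NOMINAL_PHYS_PERFUSION,
    arterial_curve,
    measurement_times,
    tissue_curve,
)

__all__ = ["PhantomSpec", "generate", "standard_phantoms", "write_phantom",
           "noise_sd_for_snr"]

#: water density relative to blood, used for the static-tissue baseline
DENSITY = {"gm": 0.9, "wm": 0.82, "csf": 1.15}
#: longitudinal relaxation times (s) used when saturating the M0 image
T1_TISSUE = {"gm": 1.3, "wm": 1.1, "csf": 4.3}

DEFAULT_TIMING = ASLTimingSpec(
    labelling="pcasl",
    label_duration=1.4,
    delays=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
    repeats_per_delay=4,
)


@dataclass
class PhantomSpec:
    """Ground-truth maps plus acquisition description for one phantom.

    ``perfusion_gm``/``perfusion_wm`` are in ml/100 g/min on the phantom
    grid; ``att_gm``/``att_wm`` in seconds; ``acbv`` is the arterial blood
    volume fraction and ``bat`` its arrival time. PV maps default to pure GM.
    ``noise_sd`` is the white-noise standard deviation added independently to
    every acquired (label and control) volume, in signal units.
    """

    shape: tuple
    seed: int
    voxel_size: tuple = (3.4, 3.4, 5.0)
    perfusion_gm: Optional[np.ndarray] = None   # default 50 everywhere
    perfusion_wm: Optional[np.ndarray] = None   # default 20 everywhere
    att_gm: Optional[np.ndarray] = None         # default 1.3 s
    att_wm: Optional[np.ndarray] = None         # default att_gm + 0.3
    acbv: Optional[np.ndarray] = None           # default 0
    bat: Optional[np.ndarray] = None            # default 1.0 s
    pv_gm: Optional[np.ndarray] = None          # default 1
    pv_wm: Optional[np.ndarray] = None          # default 0
    pv_csf: Optional[np.ndarray] = None         # default 1 - gm - wm
    timing: ASLTimingSpec = field(default_factory=lambda: DEFAULT_TIMING)
    m0_blood: float = 1000.0
    noise_sd: float = 0.0
    tr_m0: float = 4.0
    t1_gm: float = 1.3
    t1_wm: float = 1.1
    t1_blood: float = 1.65
    alpha: Optional[float] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        shp = tuple(self.shape)
        object.__setattr__(self, "shape", shp)

        def fill(value):
            return np.full(shp, float(value))

        if self.perfusion_gm is None:
            self.perfusion_gm = fill(50.0)
        if self.perfusion_wm is None:
            self.perfusion_wm = fill(20.0)
        if self.att_gm is None:
            self.att_gm = fill(1.3)
        if self.att_wm is None:
            self.att_wm = np.asarray(self.att_gm, float) + 0.3
        if self.acbv is None:
            self.acbv = fill(0.0)
        if self.bat is None:
            self.bat = fill(1.0)
        if self.pv_gm is None:
            self.pv_gm = fill(1.0)
        if self.pv_wm is None:
            self.pv_wm = fill(0.0)
        if self.pv_csf is None:
            self.pv_csf = np.clip(
                1.0 - np.asarray(self.pv_gm, float) - np.asarray(self.pv_wm, float),
                0.0, 1.0,
            )
        if self.alpha is None:
            self.alpha = DEFAULT_ALPHA[self.timing.labelling]
        if self.mask is None:
            self.mask = np.ones(shp, dtype=bool)
        for name in ("perfusion_gm", "perfusion_wm", "att_gm", "att_wm",
                     "acbv", "bat", "pv_gm", "pv_wm", "pv_csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shp:
                raise ConfigurationError(f"{name} map shape {arr.shape} != {shp}")
            setattr(self, name, arr)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


def _difference_signal(spec: PhantomSpec) -> np.ndarray:
    """Noiseless differenced signal, (x, y, z, n_diff) in delay-major order."""
    times, taus = measurement_times(spec.timing)
    shp = spec.shape
    nt = len(times)
    out = np.zeros(shp + (nt,))
    fg = spec.perfusion_gm * spec.m0_blood / 6000.0
    fw = spec.perfusion_wm * spec.m0_blood / 6000.0
    acbv_sig = spec.acbv * spec.m0_blood
    it = np.ndindex(shp)
    for idx in it:
        if not spec.mask[idx]:
            continue
        sig = np.zeros(nt)
        if spec.pv_gm[idx] > 0:
            sig += spec.pv_gm[idx] * tissue_curve(
                times, fg[idx], spec.att_gm[idx], taus, spec.t1_gm,
                spec.t1_blood, 0.9, spec.alpha, labelling=spec.timing.labelling,
                f_outflow=NOMINAL_PHYS_PERFUSION,
            )
        if spec.pv_wm[idx] > 0:
            sig += spec.pv_wm[idx] * tissue_curve(
                times, fw[idx], spec.att_wm[idx], taus, spec.t1_wm,
                spec.t1_blood, 0.9, spec.alpha, labelling=spec.timing.labelling,
                f_outflow=NOMINAL_PHYS_PERFUSION,
            )
        if acbv_sig[idx] > 0:
            sig += arterial_curve(
                times, acbv_sig[idx], spec.bat[idx], taus, spec.t1_blood,
                spec.alpha, labelling=spec.timing.labelling,
            )
        out[idx] = sig
    return out


def _baseline(spec: PhantomSpec) -> np.ndarray:
    """Static-tissue control-image baseline: PV-weighted water density x M0."""
    return spec.m0_blood * (
        DENSITY["gm"] * spec.pv_gm
        + DENSITY["wm"] * spec.pv_wm
        + DENSITY["csf"] * spec.pv_csf
    )


def _m0_image(spec: PhantomSpec) -> np.ndarray:
    """M0 calibration image with per-tissue T1 saturation at the M0 TR."""
    sat = {t: 1.0 - np.exp(-spec.tr_m0 / T1_TISSUE[t]) for t in T1_TISSUE}
    return spec.m0_blood * (
        DENSITY["gm"] * sat["gm"] * spec.pv_gm
        + DENSITY["wm"] * sat["wm"] * spec.pv_wm
        + DENSITY["csf"] * sat["csf"] * spec.pv_csf
    )


def noise_sd_for_snr(spec: PhantomSpec, snr: float) -> float:
    """Per-volume noise sd giving the requested differenced-series SNR.

    SNR is defined as peak differenced signal / differenced-noise sd; each
    difference of two noisy volumes carries sqrt(2) times the per-volume sd.
    """
    peak = float(np.abs(_difference_signal(spec)).max())
    return peak / (snr * np.sqrt(2.0))


def generate(spec: PhantomSpec):
    """Generate (raw label-control ASLSeries, M0 image, truth bundle)."""
    diff = _difference_signal(spec)
    base = _baseline(spec)
    t = spec.timing
    nd, nr = t.n_delays, t.repeats_per_delay
    n_raw = t.n_volumes
    shp = spec.shape
    raw = np.zeros(shp + (n_raw,))
    for d in range(nd):
        for r in range(nr):
            if t.volume_order == "delays_then_pairs":
                pair = (d * nr + r) * 2
            else:
                pair = (r * nd + d) * 2
            label_pos, control_pos = (pair, pair + 1) if t.label_first else (
                pair + 1, pair)
            k = d * nr + r  # canonical delay-major diff index
            raw[..., control_pos] = base
            raw[..., label_pos] = base - diff[..., k]
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.noise_sd, size=raw.shape)
    m0 = _m0_image(spec)
    series = ASLSeries(
        voxels=raw, affine=spec.affine, timing=t, mask=spec.mask.copy(),
        kind="raw",
    )
    truth = {
        "perfusion_gm": spec.perfusion_gm,
        "perfusion_wm": spec.perfusion_wm,
        "att_gm": spec.att_gm,
        "att_wm": spec.att_wm,
        "acbv": spec.acbv,
        "bat": spec.bat,
        "pv_gm": spec.pv_gm,
        "pv_wm": spec.pv_wm,
        "pv_csf": spec.pv_csf,
        "m0_blood": spec.m0_blood,
        "f_signal_gm": spec.perfusion_gm * spec.m0_blood / 6000.0,
        "f_signal_wm": spec.perfusion_wm * spec.m0_blood / 6000.0,
        "noise_sd": spec.noise_sd,
        "noiseless_diff": diff,
    }
    return series, m0, truth


def standard_phantoms(seed: int = 0) -> Dict[str, PhantomSpec]:
    """Named phantom presets covering the pipeline's structural features.

    * ``uniform_gm`` — homogeneous pure-GM slab at 50 ml/100 g/min, ATT 1.3 s.
    * ``step_edge`` — two homogeneous regions (60 / 30) with a sharp in-plane
      edge, for edge-preservation checks.
    * ``two_tissue`` — mixed GM (60) / WM (20) with smoothly varying PV maps,
      for PVEc recovery.
    * ``arterial_strip`` — uniform GM with a strip of 1% arterial blood
      volume contamination.
    * ``ventricle`` — GM background with a central CSF ventricle block, for
      reference-region calibration.
    """
    presets: Dict[str, PhantomSpec] = {}
    shape = (12, 12, 3)

    presets["uniform_gm"] = PhantomSpec(shape=shape, seed=seed)

    perf = np.full(shape, 60.0)
    perf[6:, :, :] = 30.0
    presets["step_edge"] = PhantomSpec(
        shape=shape, seed=seed, perfusion_gm=perf,
    )

    # anatomy-like layout: a large, mostly pure WM core surrounded by a GM
    # cortex, partial voluming confined to a thin interface shell -- as at
    # real ASL resolution, where interface voxels are a minority
    from scipy import ndimage as _ndi

    tt_shape = (16, 16, 3)
    core = np.zeros(tt_shape)
    core[3:13, 3:13, :] = 1.0
    core = _ndi.uniform_filter(core, size=(3, 3, 1))
    pv_wm = 0.95 * core
    pv_gm = 0.95 * (1.0 - core)
    presets["two_tissue"] = PhantomSpec(
        shape=tt_shape, seed=seed,
        perfusion_gm=np.full(tt_shape, 60.0),
        perfusion_wm=np.full(tt_shape, 20.0),
        pv_gm=pv_gm, pv_wm=pv_wm,
    )

    acbv = np.zeros(shape)
    acbv[5:7, :, :] = 0.01
    presets["arterial_strip"] = PhantomSpec(shape=shape, seed=seed, acbv=acbv)

    pv_gm_v = np.ones(shape)
    pv_csf = np.zeros(shape)
    pv_gm_v[3:9, 3:9, :] = 0.0
    pv_csf[3:9, 3:9, :] = 1.0
    presets["ventricle"] = PhantomSpec(
        shape=shape, seed=seed, pv_gm=pv_gm_v, pv_wm=np.zeros(shape),
        pv_csf=pv_csf,
    )
    return presets


def write_phantom(spec: PhantomSpec, outdir) -> dict:
    """Write phantom NIfTI files and a truth JSON; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, m0, truth = generate(spec)
    files = {}
    import nibabel as nib

    nib.save(nib.Nifti1Image(series.voxels, series.affine),
             str(outdir / "asl.nii.gz"))
    files["asl"] = str(outdir / "asl.nii.gz")
    for name, arr in (("m0", m0), ("mask", spec.mask.astype(np.uint8)),
                      ("pv_gm", spec.pv_gm), ("pv_wm", spec.pv_wm)):
        p = outdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=float), spec.affine), str(p))
        files[name] = str(p)
    truth_json = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in truth.items() if k != "noiseless_diff"
    }
    truth_json["timing"] = {
        "labelling": spec.timing.labelling,
        "label_duration": spec.timing.label_duration,
        "delays": list(spec.timing.delays),
        "repeats_per_delay": spec.timing.repeats_per_delay,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh)
    files["truth"] = str(outdir / "truth.json")
    return files
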