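"""Synthetic force-distance curve generation.

Stands in for the AFM instrument: each curve is a WLC sawtooth built from a
template of contour-length peaks with per-peak occurrence probabilities and
rupture-force statistics, plus Gaussian force noise, a slow baseline drift,
and a uniform attachment offset (the +/- 5 nm non-specific tip-sample
attachment variability the clustering step must absorb).

The bundled template library (:func:`published_templates`) is parameterized
from published SMFS statistics of rod outer-segment membrane proteins:
the CNGA1 channel subunit in the closed and open states and rhodopsin
pulled from the N- or C-terminal in disc and plasma membranes. Templates
whose statistics are printed in residues are converted with the rhodopsin
convention of 0.36 nm per stretched residue; CNG templates use 0.4 nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fd import ForceDistanceTrace, WLCParams, wlc_extension, wlc_force

__all__ = ["CurveTemplate", "DatasetSpec", "generate_curve", "generate_dataset",
           "published_templates"]

#: Rupture forces are truncated below at the analysis filter threshold.
FORCE_FLOOR_PN = 35.0


@dataclass
class CurveTemplate:
    """Ground truth for one unfolding pathway (cluster)."""

    name: str
    lc_nm: np.ndarray              # strictly increasing peak contour lengths
    prob: np.ndarray               # per-peak occurrence probability
    force_mean_pn: np.ndarray
    force_sd_pn: np.ndarray
    lc_sd_nm: np.ndarray | None = None   # per-peak Lc scatter (0 if None)
    detachment_lc_nm: float | None = None  # defaults to last included peak
    noise_sd_pn: float = 10.0
    offset_range_nm: float = 5.0   # attachment offset ~ U(-range, +range)
    drift_pn: float = 3.0          # slow baseline drift amplitude
    step_nm: float = 0.5           # sampling step
    residue_length_nm: float = 0.4

    def __post_init__(self) -> None:
        self.lc_nm = np.asarray(self.lc_nm, float)
        self.prob = np.asarray(self.prob, float)
        self.force_mean_pn = np.asarray(self.force_mean_pn, float)
        self.force_sd_pn = np.asarray(self.force_sd_pn, float)
        if self.lc_sd_nm is None:
            self.lc_sd_nm = np.zeros_like(self.lc_nm)
        self.lc_sd_nm = np.asarray(self.lc_sd_nm, float)
        if np.any(np.diff(self.lc_nm) <= 0):
            raise ValueError("peak Lc values must be strictly increasing")
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("occurrence probabilities must lie in [0, 1]")
        if self.noise_sd_pn < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def n_peaks(self) -> int:
        return len(self.lc_nm)

    def wlc(self) -> WLCParams:
        return WLCParams(residue_length_nm=self.residue_length_nm)


@dataclass
class DatasetSpec:
    templates: list[tuple[CurveTemplate, float]]   # (template, mixture weight)
    n_curves: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_curves < 1:
            raise ValueError("need at least one curve")
        w = np.array([w for _, w in self.templates], float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float) -> float:
    """Gaussian truncated below at ``floor`` (rejection; falls back to floor
    reflection when the mean sits far below the floor)."""
    if sd <= 0:
        return max(mean, floor)
    for _ in range(200):
        v = rng.normal(mean, sd)
        if v >= floor:
            return v
    return floor + abs(rng.normal(0.0, sd))


def generate_curve(template: CurveTemplate, rng: np.random.Generator,
                   wlc: WLCParams | None = None) -> ForceDistanceTrace:
    """One synthetic F-D retraction curve; realized peaks land in ``meta``."""
    wlc = wlc or template.wlc()
    include = rng.random(template.n_peaks) < template.prob
    lcs = template.lc_nm[include] + rng.normal(0.0, 1.0, int(include.sum())) * template.lc_sd_nm[include]
    order = np.argsort(lcs)
    lcs = lcs[order]
    f_rupt = np.array([
        _truncated_normal(rng, m, s, FORCE_FLOOR_PN)
        for m, s in zip(template.force_mean_pn[include][order],
                        template.force_sd_pn[include][order])])
    offset = rng.uniform(-template.offset_range_nm, template.offset_range_nm)

    if lcs.size == 0:
        x = np.arange(0.0, 40.0, template.step_nm)
        force = np.zeros_like(x)
    else:
        x_rupt = wlc_extension(f_rupt, lcs, wlc)
        x_rupt = np.maximum.accumulate(x_rupt + 1e-9 * np.arange(len(x_rupt)))
        x_end = x_rupt[-1] + 15.0
        x = np.arange(0.0, x_end, template.step_nm)
        force = np.zeros_like(x)
        prev = 0.0
        for lc, xr in zip(lcs, x_rupt):
            seg = (x > prev) & (x <= xr) & (x < lc)
            force[seg] = wlc_force(x[seg], lc, wlc)
            prev = xr
    if template.noise_sd_pn > 0:
        force = force + rng.normal(0.0, template.noise_sd_pn, len(force))
    if template.drift_pn > 0 and len(x) > 1:
        force = force + rng.uniform(-1, 1) * template.drift_pn * (x / x[-1])
    meta = {
        "template": template.name,
        "included_peaks": np.flatnonzero(include).tolist(),
        "true_lc_nm": [float(v) for v in lcs],
        "true_force_pn": [float(v) for v in f_rupt],
        "offset_nm": float(offset),
    }
    return ForceDistanceTrace(tss=x + offset, force=force, meta=meta)


def generate_dataset(spec: DatasetSpec,
                     ) -> tuple[list[ForceDistanceTrace], pd.DataFrame]:
    """Draw curves from the template mixture; returns (curves, manifest)."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, w in spec.templates])
    choice = rng.choice(len(spec.templates), size=spec.n_curves, p=weights)
    curves, rows = [], []
    for cid, t_idx in enumerate(choice):
        template = spec.templates[t_idx][0]
        trace = generate_curve(template, rng)
        trace.meta["curve_id"] = cid
        curves.append(trace)
        rows.append({
            "curve_id": cid,
            "template": template.name,
            "n_peaks": len(trace.meta["true_lc_nm"]),
            "true_lc_nm": json.dumps(trace.meta["true_lc_nm"]),
            "true_force_pn": json.dumps(trace.meta["true_force_pn"]),
            "offset_nm": trace.meta["offset_nm"],
        })
    return curves, pd.DataFrame(rows)


def published_templates() -> dict[str, CurveTemplate]:
    """Bundled templates parameterized from published peak statistics."""
    rl_rhod = 0.36  # nm per residue, rhodopsin convention
    aa = lambda v: np.asarray(v, float) * rl_rhod

    lib = {
        "cng_closed": CurveTemplate(
            name="cng_closed",
            lc_nm=[114, 153, 186, 229, 273],
            lc_sd_nm=[4, 3, 4, 6, 5],
            prob=[0.98, 0.98, 1.0, 1.00, 0.21],
            force_mean_pn=[95] * 5,        # dataset-level 95 +/- 45 pN
            force_sd_pn=[45] * 5,
            residue_length_nm=0.4,
        ),
        "cng_open": CurveTemplate(
            name="cng_open",
            lc_nm=[48, 84, 113, 140, 172, 191, 234, 276],
            lc_sd_nm=[2, 2, 3, 3, 3, 5, 4, 6],
            prob=[0.57, 0.65, 0.94, 0.98, 0.98, 1.00, 0.91, 1.00],
            force_mean_pn=[120] * 8,       # dataset-level 120 +/- 39 pN
            force_sd_pn=[39] * 8,
            residue_length_nm=0.4,
        ),
        "rhod_disc_N": CurveTemplate(
            name="rhod_disc_N",
            lc_nm=aa([36, 56, 109, 152, 210, 245]),
            lc_sd_nm=aa([8, 5, 9, 6, 4, 10]),
            prob=[0.34, 0.68, 1.00, 0.88, 1.00, 0.74],
            force_mean_pn=[130, 90, 80, 85, 62, 65],
            force_sd_pn=[19, 26, 19, 22, 31, 19],
            residue_length_nm=rl_rhod,
        ),
        "rhod_disc_C": CurveTemplate(
            name="rhod_disc_C",
            lc_nm=aa([31, 50, 112, 175, 240]),
            lc_sd_nm=aa([6, 5, 8, 10, 8]),
            prob=[0.75, 0.66, 1.00, 1.00, 1.00],
            force_mean_pn=[127, 98, 86, 55, 57],
            force_sd_pn=[19, 18, 15, 10, 20],
            residue_length_nm=rl_rhod,
        ),
        "rhod_pm_C": CurveTemplate(
            name="rhod_pm_C",
            lc_nm=aa([31, 67, 97, 115, 154, 185, 238]),
            lc_sd_nm=aa([6, 4, 4, 8, 8, 10, 6]),
            prob=[1.00, 0.78, 0.89, 0.64, 1.00, 1.00, 0.84],
            force_mean_pn=[118, 145, 145, 95, 150, 155, 125],
            force_sd_pn=[45, 30, 25, 20, 10, 15, 30],
            residue_length_nm=rl_rhod,
        ),
    }
    return lib
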