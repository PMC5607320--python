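"""Single-molecule force-spectroscopy (SMFS) curve analysis.

The pipeline mirrors standard AFM unfolding analysis:

1. each force-distance (F-D) retraction curve is a sawtooth whose rising
   edges follow worm-like-chain (WLC) elasticity; every sampled point
   (x, F) is inverted through the Marko-Siggia interpolation to the unique
   contour length Lc that would produce that force at that extension,
   yielding a per-curve F-Lc histogram;
2. rupture peaks are detected on the smoothed curve and each rising edge
   is least-squares fitted with the WLC model to give (Lc, rupture force);
3. curves are filtered (all peaks above a force threshold; last peak below
   a maximum contour length);
4. F-Lc histograms are clustered by average-linkage hierarchical
   clustering on a shift-tolerant overlap similarity (curves may slide by
   at most 5 nm, the assumed variability of the non-specific tip-sample
   attachment);
5. peaks are pooled across the members of each cluster into peak groups
   reported as mean +/- SD contour length (in nm and in residues, dividing
   by the stretched length per residue), occurrence probability, and mean
   +/- SD rupture force.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial.distance import squareform

__all__ = [
    "ForceDistanceTrace", "WLCParams", "FLcHistogram", "PeakGroup",
    "ClusterStats", "ClusterReport", "wlc_force", "wlc_extension",
    "wlc_contour_length", "read_curves", "fd_to_flc", "filter_curves",
    "detect_peaks", "cluster_curves", "alignment_shifts", "peak_statistics", "lc_to_aa",
    "aa_to_lc", "analyze_curves",
]

log = logging.getLogger(__name__)

BOLTZMANN_PN_NM_PER_K = 0.0138065  # pN nm / K


@dataclass
class WLCParams:
    """Worm-like chain parameters.

    ``residue_length_nm`` is the stretched length per amino acid used for
    the Lc -> residues conversion: 0.4 nm/a.a. is the stated convention;
    rhodopsin-facing analyses conventionally use 0.36 nm/a.a. (125 nm for
    348 a.a.).
    """

    persistence_nm: float = 0.4
    temperature_k: float = 298.0
    residue_length_nm: float = 0.4

    def __post_init__(self) -> None:
        if self.persistence_nm <= 0 or self.residue_length_nm <= 0:
            raise ValueError("persistence and residue length must be positive")

    @property
    def kbt_pn_nm(self) -> float:
        return BOLTZMANN_PN_NM_PER_K * self.temperature_k


@dataclass
class ForceDistanceTrace:
    """One retraction curve: tip-sample separation (nm) vs force (pN)."""

    tss: np.ndarray
    force: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tss = np.asarray(self.tss, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.tss.shape != self.force.shape or self.tss.ndim != 1:
            raise ValueError("tss and force must be 1-D arrays of equal length")
        if np.any(np.diff(self.tss) < 0):
            raise ValueError("tip-sample separation must be non-decreasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")


@dataclass
class FLcHistogram:
    """Per-curve histogram of force mass over contour length."""

    edges: np.ndarray      # nm, contiguous
    counts: np.ndarray     # force-weighted mass per bin, >= 0
    normalized: bool = False

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def normalize(self) -> "FLcHistogram":
        total = self.counts.sum()
        counts = self.counts / total if total > 0 else self.counts.copy()
        return FLcHistogram(self.edges, counts, normalized=True)


@dataclass
class PeakGroup:
    lc_mean_nm: float
    lc_sd_nm: float
    lc_mean_aa: float
    occurrence: float          # fraction of cluster members showing the peak
    force_mean_pn: float
    force_sd_pn: float
    n_curves: int


@dataclass
class ClusterStats:
    members: list[int]                 # indices into the filtered curve list
    occurrence_fraction: float         # of the filtered set
    peak_groups: list[PeakGroup]


@dataclass
class ClusterReport:
    clusters: list[ClusterStats]
    n_filtered: int
    n_total: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "n_total": self.n_total,
            "n_filtered": self.n_filtered,
            "config": self.config,
            "clusters": [
                {
                    "members": c.members,
                    "occurrence_fraction": c.occurrence_fraction,
                    "peaks": [vars(g) for g in c.peak_groups],
                }
                for c in self.clusters
            ],
        }
        return json.dumps(doc, indent=1)


# ----------------------------------------------------------------- WLC model

def wlc_force(x, lc, wlc: WLCParams):
    """Marko-Siggia interpolation force (pN) at extension x (nm), contour lc.

    F = (kBT/p) [ 1/(4 (1 - x/lc)^2) - 1/4 + x/lc ].
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= np.asarray(lc)):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    xi = x / lc
    out = wlc.kbt_pn_nm / wlc.persistence_nm * (0.25 / (1 - xi) ** 2 - 0.25 + xi)
    return float(out) if out.ndim == 0 else out


def _ms_reduced(xi):
    return 0.25 / (1.0 - xi) ** 2 - 0.25 + xi


def wlc_extension(force_pn, lc, wlc: WLCParams):
    """Extension (nm) at which the WLC reaches ``force_pn``; inverse of wlc_force."""
    xi = _invert_reduced(np.asarray(force_pn, float) * wlc.persistence_nm / wlc.kbt_pn_nm)
    out = xi * lc
    return float(out) if np.ndim(out) == 0 else out


def wlc_contour_length(x, force_pn, wlc: WLCParams):
    """Unique Lc (nm) with wlc_force(x, Lc) = force, for x > 0 and force > 0."""
    x = np.asarray(x, float)
    f = np.asarray(force_pn, float)
    xi = _invert_reduced(f * wlc.persistence_nm / wlc.kbt_pn_nm)
    out = np.where(xi > 0, x / np.where(xi > 0, xi, 1.0), np.inf)
    return float(out) if out.ndim == 0 else out


def _invert_reduced(fred):
    """Solve _ms_reduced(xi) = fred for xi in [0, 1) by bisection (monotone)."""
    fred = np.asarray(fred, dtype=float)
    lo = np.zeros_like(fred)
    hi = np.full_like(fred, 1.0 - 1e-12)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        high = _ms_reduced(mid) > fred
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def lc_to_aa(lc_nm, wlc: WLCParams):
    """Contour length -> number of residues (raw float; round for display)."""
    out = np.asarray(lc_nm, float) / wlc.residue_length_nm
    return float(out) if out.ndim == 0 else out


def aa_to_lc(n_aa, wlc: WLCParams):
    out = np.asarray(n_aa, float) * wlc.residue_length_nm
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------- curve IO

UNIT_FACTORS_FORCE = {"pn": 1.0, "nn": 1e3}
UNIT_FACTORS_DIST = {"nm": 1.0, "um": 1e3, "a": 0.1, "angstrom": 0.1}


def read_curves(path, force_unit: str = "pN", distance_unit: str = "nm",
                pattern: str = "*.tsv") -> list[ForceDistanceTrace]:
    """Read two-column (distance, force) text curves from a file or directory.

    Delimiter is sniffed by pandas; a ``# force_unit:`` / ``# distance_unit:``
    header line overrides the arguments. Malformed or empty files are
    skipped with a log entry so a batch survives stray files.
    """
    path = Path(path)
    files = sorted(path.glob(pattern)) if path.is_dir() else [path]
    traces: list[ForceDistanceTrace] = []
    for fp in files:
        try:
            text = fp.read_text()
            f_unit, d_unit = force_unit, distance_unit
            for line in text.splitlines():
                if not line.startswith("#"):
                    break
                if "force_unit:" in line:
                    f_unit = line.split("force_unit:")[1].strip()
                if "distance_unit:" in line:
                    d_unit = line.split("distance_unit:")[1].strip()
            df = pd.read_csv(
                Path(fp), sep=None, engine="python", comment="#", header=None,
                skiprows=_n_header_rows(text))
            if df.shape[0] == 0:
                log.warning("%s: empty curve file, skipped", fp)
                continue
            if df.shape[1] < 2:
                raise ValueError("need two numeric columns")
            d = df.iloc[:, 0].to_numpy(float) * UNIT_FACTORS_DIST[d_unit.lower()]
            f = df.iloc[:, 1].to_numpy(float) * UNIT_FACTORS_FORCE[f_unit.lower()]
            d, f = _retraction_branch(d, f)
            order = np.argsort(d, kind="stable")
            traces.append(ForceDistanceTrace(d[order], f[order], meta={"source": str(fp)}))
        except Exception as exc:  # per-file failure must not kill the batch
            log.warning("%s: unreadable curve (%s), skipped", fp, exc)
    return traces


def _retraction_branch(d: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep the retraction branch of an approach+retract record.

    Approach brings the tip to the surface (separation decreasing), the
    retraction pulls away (increasing); when both are present in one file
    the retraction is everything from the point of closest approach on.
    """
    if len(d) < 3 or np.all(np.diff(d) >= 0):
        return d, f
    turn = int(np.argmin(d))
    if turn >= len(d) - 2:  # a retract recorded backwards
        return d[::-1].copy(), f[::-1].copy()
    return d[turn:], f[turn:]


def _n_header_rows(text: str) -> int:
    """Count leading non-numeric, non-comment rows (a column-name header)."""
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        tok = line.replace(",", " ").replace("\t", " ").split()[0]
        try:
            float(tok)
            return 0
        except ValueError:
            return 1
    return 0


# ------------------------------------------------------------ transformation

def fd_to_flc(trace: ForceDistanceTrace, wlc: WLCParams,
              bin_width_nm: float = 3.0, lc_max_nm: float = 320.0,
              min_force_pn: float = 10.0) -> FLcHistogram:
    """Point-by-point WLC inversion of a curve into an F-Lc histogram.

    Every sample with force above ``min_force_pn`` and positive separation
    contributes its force as mass at the Lc solving the WLC equation;
    unphysical points (force with no extension) are skipped.
    """
    edges = np.arange(0.0, lc_max_nm + bin_width_nm, bin_width_nm)
    keep = (trace.force >= min_force_pn) & (trace.tss > 0)
    n_unphysical = int(np.sum((trace.force >= min_force_pn) & (trace.tss <= 0)))
    if n_unphysical:
        log.debug("%d unphysical points (F > 0 at x <= 0) skipped", n_unphysical)
    if not np.any(keep):
        return FLcHistogram(edges, np.zeros(len(edges) - 1))
    lc = wlc_contour_length(trace.tss[keep], trace.force[keep], wlc)
    ok = np.isfinite(lc) & (lc < lc_max_nm)
    counts, _ = np.histogram(lc[ok], bins=edges, weights=trace.force[keep][ok])
    return FLcHistogram(edges, counts)


# ------------------------------------------------------------- peak analysis

def detect_peaks(trace: ForceDistanceTrace, wlc: WLCParams,
                 smooth_window: int = 7, prominence_pn: float = 25.0,
                 height_pn: float = 20.0, fit_floor_pn: float = 10.0,
                 ) -> list[tuple[float, float]]:
    """Detect rupture peaks and WLC-fit each rising edge.

    Returns (Lc nm, rupture force pN) per peak, sorted by Lc. The rupture
    force is the raw-trace maximum near the smoothed peak; Lc comes from a
    least-squares fit of the Marko-Siggia force to the rising edge.
    """
    f = trace.force
    x = trace.tss
    if len(f) < 5:
        return []
    win = min(smooth_window, len(f) - (1 - len(f) % 2))
    fs = savgol_filter(f, win, polyorder=2) if win >= 5 else f
    idx, _ = find_peaks(fs, height=height_pn, prominence=prominence_pn)
    out = []
    prev_valley = 0
    for k, p in enumerate(idx):
        lo = prev_valley
        seg = slice(lo, p + 1)
        nxt = idx[k + 1] if k + 1 < len(idx) else len(fs)
        prev_valley = p + int(np.argmin(fs[p:nxt])) if p < nxt else p
        xs, ys = x[seg], f[seg]
        mask = (ys >= fit_floor_pn) & (xs > 0)
        if mask.sum() < 3:
            continue
        lc = _fit_wlc_segment(xs[mask], ys[mask], wlc)
        if lc is None:
            log.debug("WLC fit failed for peak at x=%.1f nm; peak dropped", x[p])
            continue
        peak_force = float(np.max(f[max(p - 2, 0):p + 3]))
        out.append((lc, peak_force))
    out.sort(key=lambda t: t[0])
    return out


def _fit_wlc_segment(xs: np.ndarray, ys: np.ndarray, wlc: WLCParams) -> float | None:
    x_max = float(xs.max())

    def sse(lc: float) -> float:
        if lc <= x_max:
            return 1e12
        pred = wlc.kbt_pn_nm / wlc.persistence_nm * _ms_reduced(xs / lc)
        return float(np.sum((pred - ys) ** 2))

    res = minimize_scalar(sse, bounds=(x_max + 1e-6, 1500.0), method="bounded",
                          options={"xatol": 1e-4})
    if not res.success or res.fun >= 1e11:
        return None
    return float(res.x)


def filter_curves(peaks_per_curve: list[list[tuple[float, float]]],
                  min_peak_force_pn: float = 35.0,
                  max_last_peak_lc_nm: float = 200.0,
                  min_last_peak_lc_nm: float | None = None) -> list[int]:
    """Indices of curves whose peaks all exceed the force threshold and whose
    final peak lies in the allowed contour-length window."""
    kept = []
    for i, peaks in enumerate(peaks_per_curve):
        if not peaks:
            continue
        forces = [f for _, f in peaks]
        last_lc = peaks[-1][0]
        if min(forces) < min_peak_force_pn:
            continue
        if last_lc > max_last_peak_lc_nm:
            continue
        if min_last_peak_lc_nm is not None and last_lc < min_last_peak_lc_nm:
            continue
        kept.append(i)
    return kept


# ----------------------------------------------------------------- clustering

def _normalized_matrix(histograms: list[FLcHistogram]) -> tuple[np.ndarray, float]:
    width = histograms[0].edges[1] - histograms[0].edges[0]
    for h in histograms:
        if abs((h.edges[1] - h.edges[0]) - width) > 1e-9 or len(h.edges) != len(histograms[0].edges):
            raise ValueError("histograms must share a common grid")
    mats = np.array([h.normalize().counts for h in histograms])
    if not mats.sum():
        raise ValueError("all histograms are empty")
    return mats, float(width)


def _overlap_similarity(mats: np.ndarray, smax_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise best shifted overlap of unit-mass histograms.

    Returns (similarity, best_shift_bins); best_shift[i, j] is the shift of
    row i (in bins) that maximizes its overlap with row j.
    """
    n = len(mats)
    sim = np.zeros((n, n))
    best_shift = np.zeros((n, n), dtype=int)
    for s in range(-smax_bins, smax_bins + 1):
        mat_s = np.roll(mats, s, axis=1)
        if s > 0:
            mat_s[:, :s] = 0.0
        elif s < 0:
            mat_s[:, s:] = 0.0
        for i in range(n):
            overlap = np.minimum(mat_s[i][None, :], mats).sum(axis=1)
            better = overlap > sim[i]
            sim[i, better] = overlap[better]
            best_shift[i, better] = s
    sim = 0.5 * (sim + sim.T)
    np.fill_diagonal(sim, 1.0)
    return sim, best_shift


def cluster_curves(histograms: list[FLcHistogram], max_shift_nm: float = 5.0,
                   distance_threshold: float = 0.6) -> np.ndarray:
    """Average-linkage clustering on shift-tolerant histogram overlap.

    Similarity of two unit-mass histograms is the maximum over integer-bin
    shifts of the summed bin-wise minimum; since each curve's attachment
    offset may be as large as ``max_shift_nm`` in either direction, the
    pairwise search spans twice that. Distance = 1 - similarity; the
    dendrogram is cut at ``distance_threshold``. Returns 1-based labels.
    """
    if len(histograms) < 2:
        return np.ones(len(histograms), dtype=int)
    mats, width = _normalized_matrix(histograms)
    smax = int(2 * max_shift_nm // width)
    sim, _ = _overlap_similarity(mats, smax)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=distance_threshold, criterion="distance")


def alignment_shifts(histograms: list[FLcHistogram],
                     max_shift_nm: float = 5.0) -> np.ndarray:
    """Per-curve attachment-offset estimates (nm) within one cluster.

    Each histogram is aligned (best shifted overlap) to the cluster medoid
    — the member most similar to all others — and the shifts are
    re-centered to zero mean, so subtracting them from a member's peak
    positions removes the attachment jitter without moving the cluster's
    mean frame.
    """
    if len(histograms) < 2:
        return np.zeros(len(histograms))
    mats, width = _normalized_matrix(histograms)
    smax = int(2 * max_shift_nm // width)
    sim, best_shift = _overlap_similarity(mats, smax)
    medoid = int(np.argmax(sim.sum(axis=1)))
    shifts = best_shift[:, medoid] * width
    shifts[medoid] = 0.0
    return shifts - shifts.mean()


def _density_modes(values: np.ndarray, bandwidth_nm: float) -> np.ndarray:
    """Mode positions of a 1-D Gaussian kernel density over peak Lc values.

    Peaks across curves scatter around the pathway's true rupture
    positions; the modes of the pooled density are the group centers and
    every value is assigned to its nearest mode.
    """
    if len(values) == 1:
        return values.copy()
    grid = np.arange(values.min() - 3 * bandwidth_nm,
                     values.max() + 3 * bandwidth_nm, 0.25)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / bandwidth_nm) ** 2).sum(axis=1)
    idx, _ = find_peaks(dens, prominence=0.02 * dens.max())
    if idx.size == 0:
        idx = np.array([int(np.argmax(dens))])
    return grid[idx]


def peak_statistics(member_peaks: list[list[tuple[float, float]]],
                    wlc: WLCParams, tolerance_nm: float = 6.0,
                    min_occurrence: float = 0.0,
                    shifts_nm: np.ndarray | None = None) -> list[PeakGroup]:
    """Pool detected peaks across cluster members into peak groups.

    Group centers are the modes of a kernel density over the pooled Lc
    values (bandwidth = ``tolerance_nm`` / 3); every peak joins its nearest
    mode. Occurrence is the fraction of member curves contributing at
    least one peak to the group. ``shifts_nm`` (one per member, e.g. from
    :func:`alignment_shifts`) removes per-curve attachment offsets before
    grouping.
    """
    n_members = len(member_peaks)
    if shifts_nm is None:
        shifts_nm = np.zeros(n_members)
    flat = [(lc + shifts_nm[i], f, i)
            for i, peaks in enumerate(member_peaks) for lc, f in peaks]
    flat.sort(key=lambda t: t[0])
    if not flat:
        return []
    centers = _density_modes(np.array([t[0] for t in flat]), tolerance_nm / 3.0)
    assign = [int(np.argmin(np.abs(centers - lc))) for lc, _, _ in flat]
    groups: list[list[tuple[float, float, int]]] = [[] for _ in centers]
    for a, item in zip(assign, flat):
        groups[a].append(item)
    groups = [g for g in groups if g]
    out = []
    for g in groups:
        lcs = np.array([t[0] for t in g])
        fs = np.array([t[1] for t in g])
        curves = {t[2] for t in g}
        occ = len(curves) / n_members if n_members else 0.0
        if occ < min_occurrence:
            continue
        out.append(PeakGroup(
            lc_mean_nm=float(lcs.mean()),
            lc_sd_nm=float(lcs.std(ddof=1)) if len(lcs) > 1 else 0.0,
            lc_mean_aa=float(lcs.mean() / wlc.residue_length_nm),
            occurrence=occ,
            force_mean_pn=float(fs.mean()),
            force_sd_pn=float(fs.std(ddof=1)) if len(fs) > 1 else 0.0,
            n_curves=len(curves),
        ))
    return out


# ------------------------------------------------------------------ pipeline

def analyze_curves(traces: list[ForceDistanceTrace], wlc: WLCParams | None = None,
                   bin_width_nm: float = 3.0, lc_max_nm: float = 320.0,
                   min_peak_force_pn: float = 35.0,
                   max_last_peak_lc_nm: float = 200.0,
                   min_last_peak_lc_nm: float | None = None,
                   max_shift_nm: float = 5.0, distance_threshold: float = 0.6,
                   cluster_bin_width_nm: float = 3.0,
                   tolerance_nm: float = 6.0, min_occurrence: float = 0.1,
                   **detect_kwargs) -> ClusterReport:
    """Full SMFS pipeline: peaks -> filter -> F-Lc -> cluster -> statistics."""
    wlc = wlc or WLCParams()
    peaks = [detect_peaks(t, wlc, **detect_kwargs) for t in traces]
    kept = filter_curves(peaks, min_peak_force_pn, max_last_peak_lc_nm,
                         min_last_peak_lc_nm)
    log.info("filtering kept %d of %d curves", len(kept), len(traces))
    config = {
        "bin_width_nm": bin_width_nm, "lc_max_nm": lc_max_nm,
        "min_peak_force_pn": min_peak_force_pn,
        "max_last_peak_lc_nm": max_last_peak_lc_nm,
        "min_last_peak_lc_nm": min_last_peak_lc_nm,
        "max_shift_nm": max_shift_nm, "distance_threshold": distance_threshold,
        "cluster_bin_width_nm": cluster_bin_width_nm,
        "tolerance_nm": tolerance_nm, "min_occurrence": min_occurrence,
        "persistence_nm": wlc.persistence_nm,
        "residue_length_nm": wlc.residue_length_nm,
    }
    if not kept:
        return ClusterReport([], 0, len(traces), config)
    # clustering runs on its own (coarser) grid: overlap similarity needs
    # bins wide enough to absorb the per-peak Lc scatter, while the
    # reported F-Lc histograms may be much finer
    hists = [fd_to_flc(traces[i], wlc, cluster_bin_width_nm, lc_max_nm) for i in kept]
    if len(kept) == 1:
        labels = np.array([1])
    else:
        labels = cluster_curves(hists, max_shift_nm, distance_threshold)
    clusters = []
    for lab in sorted(set(labels), key=lambda L: -np.sum(labels == L)):
        members = [k for k, L in zip(range(len(kept)), labels) if L == lab]
        member_peaks = [peaks[kept[k]] for k in members]
        shifts = alignment_shifts([hists[k] for k in members], max_shift_nm)
        groups = peak_statistics(member_peaks, wlc, tolerance_nm, min_occurrence,
                                 shifts_nm=shifts)
        clusters.append(ClusterStats(
            members=[kept[k] for k in members],
            occurrence_fraction=len(members) / len(kept),
            peak_groups=groups,
        ))
    return ClusterReport(clusters, len(kept), len(traces), config)
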