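"""Correlation-optimized warping (COW) and match between runs (MBR).

Chromatographic retention times drift between LC-MS runs acquired at
different labeling durations, and stochastic DDA precursor selection
leaves many peptides unidentified in some runs.  COW aligns a target
run's elution profile to a reference run: a whole-window
cross-correlation estimates the bulk shift, then a dynamic program
places fixed-length target segments onto reference stretches within a
bounded slack, maximizing the intensity-weighted sum of per-segment
Pearson correlations (deterministic tie-break toward the smallest
cumulative shift).  MBR then transfers the quantification window of a
peptide identified in one run to a run where it was not identified,
centered at the warped retention time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Chromatogram",
    "WarpMap",
    "FeatureMatch",
    "cow_align",
    "apply_warp",
    "match_between_runs",
]

DEFAULT_SEGMENT_LEN = 25  # scans
DEFAULT_SLACK = 5  # scans
DEFAULT_PPM_TOL = 10.0
DEFAULT_RT_TOL = 30.0  # seconds


@dataclass
class Chromatogram:
    """Intensity vs retention time for one run (or one peptide window)."""

    rt: np.ndarray  # seconds, strictly increasing
    intensity: np.ndarray
    run_id: str = ""
    label_time: float = 0.0

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size < 2 or self.rt.size != self.intensity.size:
            raise ValueError("chromatogram needs >= 2 length-matched samples")
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass
class WarpMap:
    """Piecewise-linear monotone map from target rt to reference rt."""

    target_rt: np.ndarray  # segment boundary positions, target run
    reference_rt: np.ndarray  # matching positions, reference run
    benefit: float = 0.0  # alignment benefit of the chosen path

    def __post_init__(self) -> None:
        self.target_rt = np.asarray(self.target_rt, dtype=float)
        self.reference_rt = np.asarray(self.reference_rt, dtype=float)
        if self.target_rt.size != self.reference_rt.size or self.target_rt.size < 2:
            raise ValueError("warp map needs >= 2 boundary pairs")
        if np.any(np.diff(self.target_rt) < 0) or np.any(
            np.diff(self.reference_rt) < 0
        ):
            raise ValueError("warp map must be monotone nondecreasing")

    def __call__(self, rt):
        """Map target-run retention times onto the reference time axis."""
        rt = np.asarray(rt, dtype=float)
        out = np.interp(rt, self.target_rt, self.reference_rt)
        # linear extrapolation beyond the fitted range
        lo_slope = self._edge_slope(0)
        hi_slope = self._edge_slope(-2)
        out = np.where(
            rt < self.target_rt[0],
            self.reference_rt[0] + (rt - self.target_rt[0]) * lo_slope,
            out,
        )
        out = np.where(
            rt > self.target_rt[-1],
            self.reference_rt[-1] + (rt - self.target_rt[-1]) * hi_slope,
            out,
        )
        return float(out) if out.ndim == 0 else out

    def _edge_slope(self, i: int) -> float:
        dt = self.target_rt[i + 1] - self.target_rt[i]
        if dt <= 0:
            return 1.0
        return (self.reference_rt[i + 1] - self.reference_rt[i]) / dt

    def inverted(self) -> "WarpMap":
        """Map from reference rt back to target rt."""
        return WarpMap(self.reference_rt.copy(), self.target_rt.copy())

    @classmethod
    def identity(cls, rt_min: float, rt_max: float) -> "WarpMap":
        ends = np.array([rt_min, rt_max])
        return cls(ends, ends.copy())


@dataclass
class FeatureMatch:
    """A quantification window transferred between runs by MBR."""

    sequence: str
    charge: int
    source_run: str
    target_run: str
    mz: float
    ppm_tol: float
    rt_center: float  # warped rt in the target run, seconds
    rt_tol: float
    quant_source: str = "mbr_transferred"


def _segment_correlation(ref_seg: np.ndarray, tgt_seg: np.ndarray) -> float:
    """Pearson correlation after interpolating the target segment onto
    the reference segment's length; 0 for zero-variance segments."""
    m = ref_seg.size
    if tgt_seg.size != m:
        x_old = np.linspace(0.0, 1.0, tgt_seg.size)
        x_new = np.linspace(0.0, 1.0, m)
        tgt_seg = np.interp(x_new, x_old, tgt_seg)
    if np.ptp(ref_seg) == 0 or np.ptp(tgt_seg) == 0:
        return 0.0
    # rescale before forming dot products: raw intensities can under- or
    # overflow when squared (chromatographic tails, detector counts)
    rc = ref_seg - ref_seg.mean()
    tc = tgt_seg - tgt_seg.mean()
    rc = rc / np.abs(rc).max()
    tc = tc / np.abs(tc).max()
    denom = (rc @ rc) * (tc @ tc)
    if not np.isfinite(denom) or denom <= 0:
        return 0.0
    corr = float(rc @ tc / np.sqrt(denom))
    return corr if np.isfinite(corr) else 0.0


def cow_align(
    reference: Chromatogram,
    target: Chromatogram,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    slack: int = DEFAULT_SLACK,
) -> WarpMap:
    """Correlation-optimized warping of ``target`` onto ``reference``.

    The target is cut into segments of ``segment_len`` scans.  After a
    coarse whole-window cross-correlation shift, each internal boundary
    may land on any reference scan within ``slack`` scans of its
    coarse-registered nominal position, with warped stretch lengths
    constrained to +-``slack`` of the segment length and monotonicity
    enforced.  Dynamic programming maximizes the per-segment Pearson
    correlations between each target segment and the reference stretch
    it is warped onto, weighted by the segment's share of total target
    intensity; among equal-benefit paths the smallest cumulative
    absolute shift wins, so equal inputs yield the identity map.
    Endpoints map to endpoints.  A chromatogram shorter than one
    segment falls back to a single-segment global shift.
    """
    if not (segment_len > slack >= 1):
        raise ValueError("require segment_len > slack >= 1")
    tgt = target.intensity
    ref = reference.intensity
    n_t, n_r = tgt.size, ref.size
    if n_t <= segment_len + 1 or n_r <= segment_len + 1:
        return _global_shift_align(reference, target, slack)

    bounds_t = list(range(0, n_t, segment_len))
    if bounds_t[-1] != n_t - 1:
        if n_t - 1 - bounds_t[-1] <= segment_len // 2 and len(bounds_t) > 1:
            bounds_t[-1] = n_t - 1
        else:
            bounds_t.append(n_t - 1)
    n_seg = len(bounds_t) - 1
    # coarse registration first: a whole-window cross-correlation shift
    # anchors the boundary search, so the slack handles local drift
    # rather than the bulk displacement
    g = _best_global_shift(ref, tgt, slack)
    # nominal reference boundary = target boundary scaled to reference
    # length, displaced by the coarse shift
    scale = (n_r - 1) / (n_t - 1)
    nominal = [int(round(b * scale)) + g for b in bounds_t]
    nominal[0], nominal[-1] = 0, n_r - 1

    # candidate reference positions per boundary; endpoints pinned
    candidates: list[np.ndarray] = []
    for i, nom in enumerate(nominal):
        if i == 0:
            candidates.append(np.array([0]))
        elif i == n_seg:
            candidates.append(np.array([n_r - 1]))
        else:
            lo = max(1, min(nom - slack, n_r - 2))
            hi = min(n_r - 2, max(nom + slack, 1))
            candidates.append(np.arange(lo, hi + 1))

    # each segment's correlation is weighted by the (path-independent)
    # fraction of total target intensity it carries: baseline-only
    # segments then cannot outvote the elution peak with noise
    # correlations, and equal inputs score maximally on the identity path
    tgt_total = max(float(tgt.sum()), np.finfo(float).tiny)
    seg_weight = [
        float(tgt[bounds_t[i - 1] : bounds_t[i] + 1].sum()) / tgt_total
        for i in range(1, n_seg + 1)
    ]

    NEG = -np.inf
    # DP tables: best benefit and (tie-break) cumulative |shift| per state
    benefit = [np.full(c.size, NEG) for c in candidates]
    tiecost = [np.full(c.size, np.inf) for c in candidates]
    parent = [np.full(c.size, -1, dtype=int) for c in candidates]
    benefit[0][0] = 0.0
    tiecost[0][0] = 0.0
    for i in range(1, n_seg + 1):
        seg = tgt[bounds_t[i - 1] : bounds_t[i] + 1]
        seg_len_t = bounds_t[i] - bounds_t[i - 1]
        for a, pos in enumerate(candidates[i]):
            shift_cost = abs(pos - nominal[i])
            best_b, best_c, best_p = NEG, np.inf, -1
            for b, prev in enumerate(candidates[i - 1]):
                if prev >= pos or benefit[i - 1][b] == NEG:
                    continue
                # a warped stretch may shrink or grow by at most the
                # slack: correlations on degenerate stretches are
                # meaningless
                if not (seg_len_t - slack <= pos - prev <= seg_len_t + slack):
                    continue
                corr = seg_weight[i - 1] * _segment_correlation(
                    ref[prev : pos + 1], seg
                )
                cand_b = benefit[i - 1][b] + corr
                cand_c = tiecost[i - 1][b] + shift_cost
                if cand_b > best_b + 1e-9 or (
                    abs(cand_b - best_b) <= 1e-9 and cand_c < best_c
                ):
                    best_b, best_c, best_p = cand_b, cand_c, b
            benefit[i][a], tiecost[i][a], parent[i][a] = best_b, best_c, best_p

    # backtrack from the single pinned final state
    path = [0]
    for i in range(n_seg, 0, -1):
        path.append(int(parent[i][path[-1]]))
    path.reverse()
    ref_positions = [int(candidates[i][path[i]]) for i in range(n_seg + 1)]
    return WarpMap(
        target_rt=target.rt[np.array(bounds_t)],
        reference_rt=reference.rt[np.array(ref_positions)],
        benefit=float(benefit[n_seg][0]),
    )


def _best_global_shift(ref: np.ndarray, tgt: np.ndarray, slack: int) -> int:
    """Rigid shift (scans) maximizing whole-window correlation; target
    index i corresponds to reference index i + shift."""
    n = min(ref.size, tgt.size)
    best_shift, best_corr = 0, -np.inf
    for s in range(-slack, slack + 1):
        if s >= 0:
            r, t = ref[s:n], tgt[: n - s]
        else:
            r, t = ref[: n + s], tgt[-s:n]
        if r.size < 2:
            continue
        corr = _segment_correlation(r, t)
        if corr > best_corr + 1e-12 or (
            abs(corr - best_corr) <= 1e-12 and abs(s) < abs(best_shift)
        ):
            best_corr, best_shift = corr, s
    return best_shift


def _global_shift_align(
    reference: Chromatogram, target: Chromatogram, slack: int
) -> WarpMap:
    """Best single rigid shift (in scans) within +-slack."""
    best_shift = _best_global_shift(reference.intensity, target.intensity, slack)
    dt = float(np.median(np.diff(target.rt)))
    offset = best_shift * dt
    return WarpMap(
        target_rt=np.array([target.rt[0], target.rt[-1]]),
        reference_rt=np.array([target.rt[0] + offset, target.rt[-1] + offset]),
    )


def apply_warp(
    warp: WarpMap, chrom: Chromatogram, grid: np.ndarray | None = None
) -> Chromatogram:
    """Remap a chromatogram onto the reference time axis.

    Retention times are passed through the warp; when ``grid`` is given
    the intensities are linearly interpolated onto it (zero outside the
    warped range).
    """
    warped_rt = np.asarray(warp(chrom.rt), dtype=float)
    if grid is None:
        return Chromatogram(
            rt=warped_rt,
            intensity=chrom.intensity.copy(),
            run_id=chrom.run_id,
            label_time=chrom.label_time,
        )
    grid = np.asarray(grid, dtype=float)
    intensity = np.interp(grid, warped_rt, chrom.intensity, left=0.0, right=0.0)
    return Chromatogram(
        rt=grid,
        intensity=intensity,
        run_id=chrom.run_id,
        label_time=chrom.label_time,
    )


def match_between_runs(
    identified: list,
    target_identified_keys: set[tuple[str, int]],
    target_run: str,
    target_rt_range: tuple[float, float],
    warp_to_target: WarpMap,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> list[FeatureMatch]:
    """Transfer features identified elsewhere into ``target_run``.

    ``identified`` holds objects with sequence/charge/mz/rt/run_id
    attributes from a source run; peptides already identified in the
    target are skipped; a warped rt outside the target run's time range
    skips the feature.  ``warp_to_target`` maps source-run rt to
    target-run rt.
    """
    matches: list[FeatureMatch] = []
    lo, hi = target_rt_range
    for ident in identified:
        key = (ident.sequence, ident.charge)
        if key in target_identified_keys:
            continue
        rt_target = float(warp_to_target(ident.rt))
        if not (lo <= rt_target <= hi):
            continue
        matches.append(
            FeatureMatch(
                sequence=ident.sequence,
                charge=ident.charge,
                source_run=ident.run_id,
                target_run=target_run,
                mz=ident.mz,
                ppm_tol=ppm_tol,
                rt_center=rt_target,
                rt_tol=rt_tol,
            )
        )
    return matches
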