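"""EHH curves, integrated haplotype homozygosity and cross-population XP-EHH.

EHH at marker x is the probability that two haplotypes drawn at random from
the panel are identical over every marker from the core out to x:
EHH(x) = sum_h C(n_h, 2) / C(n, 2) over extended-haplotype classes h. iHH is
the trapezoidal integral of the EHH curve against physical distance (bp),
summed over both flanks; the curve is truncated at the first marker where
EHH falls below a cutoff (default 0.05). XP-EHH at a site is
ln(iHH_case / iHH_control), normalized genome-wide to mean 0 / SD 1.

Physical distance is used throughout (no genetic map). Integration is
bounded: each flank extends at most ``max_extend_bp`` from the core (the
usual bounded-integration practice of haplotype scanners). In closely
related panels — a handful of founder haplotypes copied down a pedigree —
EHH plateaus above the cutoff at the level set by identical-by-descent
sharing, so an unbounded integral would run to the chromosome end and
measure segment length, not haplotype contrast. A cap-stop is part of the
statistic's definition and is not flagged; sites whose EHH is still above
the cutoff when the scanned interval ends before the cap are flagged
``edge_truncated`` and excluded from the normalization statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EhhCurve",
    "XpehhScore",
    "ehh",
    "ihh",
    "xpehh_scan",
    "call_xpehh_regions",
    "scores_table",
]


@dataclass
class EhhCurve:
    """EHH values of one flank, in order of increasing distance from the core.

    ``positions``/``values`` start at the core itself (EHH = 1) and include
    the truncation marker (first value below the cutoff) when one was
    reached; ``edge_truncated`` marks curves that ran off the scanned
    interval while still above the cutoff.
    """

    core_pos: int
    positions: np.ndarray
    values: np.ndarray
    edge_truncated: bool


@dataclass
class XpehhScore:
    chrom: str
    pos: int
    ihh_case: float
    ihh_control: float
    raw: float
    normalized: float = float("nan")
    flags: set[str] = field(default_factory=set)


def _ehh_steps(haps: np.ndarray, core: int, direction: int, cutoff: float,
               max_steps: int | None = None):
    """Yield (marker_index, ehh) walking away from the core; stops after the
    first value below ``cutoff`` (or after ``max_steps`` markers)."""
    n, m = haps.shape
    pairs = n * (n - 1)
    base = int(max(2, haps.max() + 1))
    # classes start undifferentiated at the core (EHH(core) = 1); the first
    # flank marker partitions haplotypes purely by its own allele
    ids = np.zeros(n, dtype=np.int64)
    j = core
    taken = 0
    while True:
        j += direction
        if j < 0 or j >= m:
            return
        if max_steps is not None and taken >= max_steps:
            return
        key = ids * base + haps[:, j]
        counts = np.bincount(key)
        ehh_val = float((counts * (counts - 1)).sum()) / pairs
        yield j, ehh_val
        taken += 1
        if ehh_val < cutoff:
            return
        # renumber classes to keep keys small
        nz = counts > 0
        remap = np.cumsum(nz) - 1
        ids = remap[key]


def ehh(
    core_index: int,
    haplotypes: np.ndarray,
    positions: np.ndarray,
    direction: int,
    cutoff: float = 0.05,
    max_extend_bp: int | None = None,
) -> EhhCurve:
    """EHH curve on one flank of the core marker.

    ``haplotypes`` is an (n_haplotypes, n_sites) 0/1 array over phased,
    non-missing sites; ``direction`` is +1 (downstream) or -1 (upstream).
    EHH at the core is 1 by definition (requires >= 2 haplotypes). Markers
    farther than ``max_extend_bp`` from the core are not visited.
    """
    n = haplotypes.shape[0]
    if n < 2:
        raise ValueError("EHH undefined for fewer than 2 haplotypes")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    core_pos = int(positions[core_index])
    pos_list = [core_pos]
    val_list = [1.0]
    reason = "edge"
    for j, v in _ehh_steps(haplotypes, core_index, direction, cutoff):
        if max_extend_bp is not None and abs(int(positions[j]) - core_pos) > max_extend_bp:
            reason = "cap"
            break
        pos_list.append(int(positions[j]))
        val_list.append(v)
        if v < cutoff:
            reason = "cutoff"
    return EhhCurve(
        core_pos=core_pos,
        positions=np.array(pos_list),
        values=np.array(val_list),
        edge_truncated=reason == "edge",
    )


def ihh(curve: EhhCurve) -> float:
    """Area under one flank's EHH curve against physical distance (bp)."""
    if curve.positions.size < 2:
        return 0.0
    x = np.abs(curve.positions.astype(float) - curve.core_pos)
    return float(np.trapezoid(curve.values, x))


def _flank_area(
    haps: np.ndarray,
    core: int,
    positions: np.ndarray,
    direction: int,
    cutoff: float,
    max_extend_bp: float = np.inf,
) -> tuple[float, bool]:
    """iHH contribution of one flank without materializing the curve.

    Returns (area, edge) where edge is True only when the scanned interval
    ended (chromosome edge) while EHH was still above the cutoff and within
    the extension cap.
    """
    area = 0.0
    prev_x = 0.0
    prev_v = 1.0
    core_pos = float(positions[core])
    edge = True
    for j, v in _ehh_steps(haps, core, direction, cutoff):
        x = abs(float(positions[j]) - core_pos)
        if x > max_extend_bp:
            edge = False
            break
        area += 0.5 * (prev_v + v) * (x - prev_x)
        prev_x, prev_v = x, v
        if v < cutoff:
            edge = False
            break
    return area, edge


def _make_scan_kernel():
    """Compile the per-chromosome scan with numba when available."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a soft dependency
        return None

    @njit(cache=False)
    def kernel(haps_a, haps_c, positions, cutoff, max_extend):
        m = positions.shape[0]
        out = np.empty((m, 2), dtype=np.float64)
        edge = np.zeros(m, dtype=np.uint8)
        for grp in range(2):
            haps = haps_a if grp == 0 else haps_c
            n = haps.shape[0]
            pairs = n * (n - 1)
            base = 2
            for h in range(n):
                for s in range(m):
                    if haps[h, s] + 1 > base:
                        base = haps[h, s] + 1
            ids = np.zeros(n, dtype=np.int64)
            counts = np.zeros(base * n + base, dtype=np.int64)
            remap = np.zeros(base * n + base, dtype=np.int64)
            for i in range(m):
                total_area = 0.0
                core_pos = positions[i]
                for direction in (-1, 1):
                    for h in range(n):
                        ids[h] = 0
                    n_classes = 1
                    prev_x = 0.0
                    prev_v = 1.0
                    j = i
                    while True:
                        j += direction
                        if j < 0 or j >= m:
                            edge[i] |= 1 << grp
                            break
                        x = abs(positions[j] - core_pos)
                        if x > max_extend:
                            break
                        hi = n_classes * base
                        for k in range(hi):
                            counts[k] = 0
                        for h in range(n):
                            counts[ids[h] * base + haps[h, j]] += 1
                        tot = 0
                        for k in range(hi):
                            tot += counts[k] * (counts[k] - 1)
                        v = tot / pairs
                        total_area += 0.5 * (prev_v + v) * (x - prev_x)
                        prev_x = x
                        prev_v = v
                        if v < cutoff:
                            break
                        nxt = 0
                        for k in range(hi):
                            if counts[k] > 0:
                                remap[k] = nxt
                                nxt += 1
                        for h in range(n):
                            ids[h] = remap[ids[h] * base + haps[h, j]]
                        n_classes = nxt
                out[i, grp] = total_area
        return out, edge

    return kernel


_SCAN_KERNEL = None


def _scan_areas(
    haps_case: np.ndarray,
    haps_control: np.ndarray,
    positions: np.ndarray,
    cutoff: float,
    max_extend_bp: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(m, 2) iHH areas (case, control) and per-site edge flags."""
    global _SCAN_KERNEL
    if _SCAN_KERNEL is None:
        _SCAN_KERNEL = _make_scan_kernel() or _scan_areas_python
    if _SCAN_KERNEL is _scan_areas_python:
        return _scan_areas_python(haps_case, haps_control, positions, cutoff, max_extend_bp)
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    cap = float(max_extend_bp) if np.isfinite(max_extend_bp) else float(pos[-1] - pos[0] + 1)
    return _SCAN_KERNEL(haps_case, haps_control, pos, float(cutoff), cap)


def _scan_areas_python(haps_case, haps_control, positions, cutoff, max_extend_bp):
    m = positions.size
    out = np.empty((m, 2))
    edge = np.zeros(m, dtype=np.uint8)
    for i in range(m):
        for grp, haps in enumerate((haps_case, haps_control)):
            a_up, e1 = _flank_area(haps, i, positions, -1, cutoff, max_extend_bp)
            a_dn, e2 = _flank_area(haps, i, positions, +1, cutoff, max_extend_bp)
            out[i, grp] = a_up + a_dn
            if e1 or e2:
                edge[i] |= 1 << grp
    return out, edge


def xpehh_scan(
    haps_case: np.ndarray,
    haps_control: np.ndarray,
    positions: np.ndarray,
    chrom: str = "1",
    cutoff: float = 0.05,
    normalize: bool = True,
    max_extend_bp: float = 100_000.0,
) -> list[XpehhScore]:
    """XP-EHH at every site: raw = ln(iHH_case / iHH_control).

    Positive scores mean longer shared haplotypes in the case group. Sites
    where either group's iHH is 0 are skipped (logged by absence);
    normalization (mean 0 / SD 1) is computed over sites not flagged
    ``edge_truncated`` and then applied to all scored sites. Flank
    integration is capped at ``max_extend_bp`` from the core (pass
    ``numpy.inf`` for an unbounded scan).
    """
    if haps_case.shape[0] < 2 or haps_control.shape[0] < 2:
        raise ValueError("both groups need at least 2 haplotypes")
    if haps_case.shape[1] != positions.size or haps_control.shape[1] != positions.size:
        raise ValueError("haplotype matrices and positions disagree on site count")
    haps_case = np.ascontiguousarray(haps_case, dtype=np.int64)
    haps_control = np.ascontiguousarray(haps_control, dtype=np.int64)

    areas, edges = _scan_areas(haps_case, haps_control, positions, cutoff, max_extend_bp)
    scores: list[XpehhScore] = []
    for i in range(positions.size):
        ihh_a, ihh_c = float(areas[i, 0]), float(areas[i, 1])
        if ihh_c == 0.0 or ihh_a == 0.0:
            continue
        flags: set[str] = set()
        if edges[i]:
            flags.add("edge_truncated")
        # log difference (not log of ratio) so a group swap negates exactly
        raw = float(np.log(ihh_a) - np.log(ihh_c))
        scores.append(XpehhScore(chrom, int(positions[i]), ihh_a, ihh_c, raw, flags=flags))
    if normalize and scores:
        core = np.array([s.raw for s in scores if "edge_truncated" not in s.flags])
        if core.size >= 2 and core.std() > 0:
            mu, sd = core.mean(), core.std()
        else:  # degenerate: fall back to the full scored set
            allraw = np.array([s.raw for s in scores])
            mu, sd = allraw.mean(), (allraw.std() if allraw.std() > 0 else 1.0)
        for s in scores:
            s.normalized = (s.raw - mu) / sd
    return scores


def call_xpehh_regions(
    scores: Sequence[XpehhScore],
    span_bp: int = 10_000,
    step_bp: int = 2_000,
    threshold: float = 2.0,
    chrom_length: int | None = None,
) -> list[tuple[str, int, int]]:
    """Regions where the windowed mean normalized XP-EHH exceeds ``threshold``.

    Windows reuse the F_ST grid (span/step, anchored at position 1); windows
    whose mean normalized score is strictly above the threshold are merged
    into regions when they overlap or abut.
    """
    if span_bp < step_bp:
        raise ValueError("window span must be >= step")
    by_chrom: dict[str, list[XpehhScore]] = {}
    for s in scores:
        by_chrom.setdefault(s.chrom, []).append(s)
    passing: list[tuple[str, int, int]] = []
    for chrom, ss in by_chrom.items():
        ss.sort(key=lambda s: s.pos)
        pos = np.array([s.pos for s in ss])
        val = np.array([s.normalized for s in ss])
        last = chrom_length if chrom_length is not None else int(pos.max(initial=1))
        start = 1
        while start <= last:
            end = start + span_bp - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            if hi > lo:
                window = val[lo:hi]
                window = window[np.isfinite(window)]
                if window.size and window.mean() > threshold:
                    passing.append((chrom, start, end))
            start += step_bp
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(passing):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def scores_table(scores: Sequence[XpehhScore]) -> pd.DataFrame:
    """Per-site score table (CHROM, POS, IHH_CASE, IHH_CONTROL, RAW, NORMALIZED, FLAGS)."""
    return pd.DataFrame(
        {
            "CHROM": [s.chrom for s in scores],
            "POS": [s.pos for s in scores],
            "IHH_CASE": [s.ihh_case for s in scores],
            "IHH_CONTROL": [s.ihh_control for s in scores],
            "RAW": [s.raw for s in scores],
            "NORMALIZED": [s.normalized for s in scores],
            "FLAGS": [";".join(sorted(s.flags)) or "." for s in scores],
        }
    )
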