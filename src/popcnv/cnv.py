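"""Window-merging CNV caller, B-contig classification and summaries.

Copy-number-variable regions are detected on the exon-normalized 5-kbp
window matrix by merging adjacent windows, per contig:

1. a window is a *seed* iff its cross-library SD exceeds ``sd_threshold``;
2. two adjacent seed windows belong to the same CNV iff their per-library
   coverage vectors are significantly correlated (``p < alpha``; partial
   Pearson controlling for prep batch by default);
3. the very first and last window of a contig — which often show deviant
   coverage — are merged into an adjacent CNV when their neighbor belongs
   to one;
4. two CNVs separated by exactly one window (a "stopping breakpoint") are
   merged iff the two windows flanking the gap are significantly
   correlated, iterated to a fixpoint;
5. finally, runs shorter than ``min_windows`` windows are discarded.

Contigs consisting almost entirely of CNV windows are flagged as
"B-contigs" (>= 90% / 95% of contig length), in analogy to B-chromosomes.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import batch_design, partial_pearson
from .windows import WindowCoverageMatrix, WindowSet, window_sd

__all__ = [
    "DetectorParams",
    "CNVRegion",
    "BContigCall",
    "detect_cnvs",
    "classify_b_contigs",
    "cnv_summary",
    "placement",
    "cnvs_to_bed",
]


@dataclasses.dataclass(frozen=True)
class DetectorParams:
    """Tuning of the window-merging detector.

    ``sd_threshold`` is the seed threshold on cross-library SD (0.7, the
    empirically determined value for exon-normalized data); ``alpha`` the
    significance level of the window-window correlation tests;
    ``min_windows`` the minimum CNV length in windows; ``bridge_gap`` the
    exact gap (in windows) bridged by criterion 4.  ``correlation`` is
    "partial" (prep batch partialled out; requires library metadata) or
    "pearson".
    """

    sd_threshold: float = 0.7
    alpha: float = 0.05
    min_windows: int = 3
    bridge_gap: int = 1
    correlation: str = "partial"

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_windows < 1:
            raise ValueError("min_windows must be >= 1")


@dataclasses.dataclass
class CNVRegion:
    """A maximal merged run of copy-number-variable windows on one contig."""

    contig: str
    start: int
    end: int
    window_indices: np.ndarray          # global indices, contiguous
    mean_coverage: pd.Series            # per-library mean normalized DOC
    mean_sd: float
    placement: str = "internal"

    @property
    def n_windows(self) -> int:
        return len(self.window_indices)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class BContigCall:
    contig: str
    contig_bp: int
    cnv_bp: int
    cnv_fraction: float
    is_b90: bool
    is_b95: bool


def _correlation_design(params: DetectorParams,
                        matrix: WindowCoverageMatrix,
                        library_meta: pd.DataFrame | None) -> np.ndarray | None:
    if params.correlation == "pearson":
        return None
    if params.correlation != "partial":
        raise ValueError(f"unknown correlation kind {params.correlation!r}")
    if library_meta is None:
        warnings.warn(
            "no library metadata supplied; falling back to plain Pearson "
            "correlation between windows"
        )
        return None
    batches = (library_meta.set_index("library_id")
               .loc[matrix.library_ids, "prep_batch"])
    return batch_design(batches)


def windows_correlated(v1, v2, alpha: float,
                       design: np.ndarray | None = None) -> bool:
    """Significance of the (partial) Pearson correlation of two windows.

    Undefined correlations (constant coverage vectors) count as *not*
    significant.
    """
    r, p = partial_pearson(v1, v2, design)
    return bool(np.isfinite(p) and p < alpha)


def detect_cnvs(
    matrix: WindowCoverageMatrix,
    params: DetectorParams = DetectorParams(),
    library_meta: pd.DataFrame | None = None,
) -> list[CNVRegion]:
    """Run the window-merging detector on a normalized coverage matrix."""
    if not matrix.normalized:
        raise ValueError("detect_cnvs requires an exon-normalized matrix")
    sd = window_sd(matrix)
    design = _correlation_design(params, matrix, library_meta)
    values = matrix.values.to_numpy()
    ws = matrix.window_set
    regions: list[CNVRegion] = []
    for contig in ws.contig_lengths:
        idx = ws.contig_window_indices(contig)
        if len(idx) < params.min_windows:
            warnings.warn(
                f"contig {contig!r} has fewer than {params.min_windows} "
                "windows; skipped"
            )
            continue
        runs = _contig_runs(values, sd, idx, params, design)
        for run in runs:
            gwin = idx[run]
            regions.append(_make_region(matrix, sd, contig, gwin))
    return regions


def _contig_runs(values: np.ndarray, sd: np.ndarray, idx: np.ndarray,
                 params: DetectorParams,
                 design: np.ndarray | None) -> list[np.ndarray]:
    """Apply merge criteria 1-5 on one contig; returns local index runs."""
    m = len(idx)
    seed = sd[idx] > params.sd_threshold

    def corr(i: int, j: int) -> bool:
        return windows_correlated(values[idx[i]], values[idx[j]],
                                  params.alpha, design)

    # criteria 1+2: maximal blocks of adjacent seeds whose neighbors correlate
    runs: list[list[int]] = []
    i = 0
    while i < m:
        if not seed[i]:
            i += 1
            continue
        run = [i]
        while i + 1 < m and seed[i + 1] and corr(i, i + 1):
            run.append(i + 1)
            i += 1
        runs.append(run)
        i += 1

    # criterion 3: fold deviant contig-end windows into an adjacent CNV
    if runs:
        if runs[0][0] == 1:
            runs[0].insert(0, 0)
        elif len(runs) > 1 and runs[0] == [0] and runs[1][0] == 1:
            runs[1].insert(0, 0)
            runs.pop(0)
        if runs[-1][-1] == m - 2:
            runs[-1].append(m - 1)
        elif len(runs) > 1 and runs[-1] == [m - 1] and runs[-2][-1] == m - 2:
            runs[-2].append(m - 1)
            runs.pop()

    # criterion 4: bridge single-window stopping breakpoints, to fixpoint
    changed = True
    while changed and len(runs) > 1:
        changed = False
        merged: list[list[int]] = [runs[0]]
        for nxt in runs[1:]:
            cur = merged[-1]
            gap = nxt[0] - cur[-1] - 1
            if gap == params.bridge_gap and corr(cur[-1], nxt[0]):
                merged[-1] = cur + list(range(cur[-1] + 1, nxt[0])) + nxt
                changed = True
            else:
                merged.append(nxt)
        runs = merged

    # criterion 5: minimum length, applied last
    return [np.asarray(r) for r in runs if len(r) >= params.min_windows]


def _make_region(matrix: WindowCoverageMatrix, sd: np.ndarray,
                 contig: str, gwin: np.ndarray) -> CNVRegion:
    wdf = matrix.window_set.df
    region = CNVRegion(
        contig=contig,
        start=int(wdf["start"].iloc[gwin[0]]),
        end=int(wdf["end"].iloc[gwin[-1]]),
        window_indices=gwin,
        mean_coverage=matrix.values.iloc[gwin].mean(axis=0),
        mean_sd=float(sd[gwin].mean()),
    )
    region.placement = placement(region, matrix.window_set)
    return region


def placement(cnv: CNVRegion, window_set: WindowSet) -> str:
    """Locate a CNV on its contig: internal, contig-edge or whole-contig."""
    idx = window_set.contig_window_indices(cnv.contig)
    covered = set(cnv.window_indices.tolist())
    if covered >= set(idx.tolist()):
        return "whole-contig"
    if idx[0] in covered or idx[-1] in covered:
        return "contig-edge"
    return "internal"


def classify_b_contigs(
    cnvs: Sequence[CNVRegion],
    window_set: WindowSet,
    fraction: float = 0.90,
    fraction_strict: float = 0.95,
) -> list[BContigCall]:
    """Flag contigs whose length is almost entirely covered by CNVs."""
    cnv_bp: dict[str, int] = {}
    for c in cnvs:
        cnv_bp[c.contig] = cnv_bp.get(c.contig, 0) + c.length_bp
    calls = []
    for contig, length in window_set.contig_lengths.items():
        bp = cnv_bp.get(contig, 0)
        frac = bp / length
        calls.append(BContigCall(
            contig=contig, contig_bp=length, cnv_bp=bp, cnv_fraction=frac,
            is_b90=frac >= fraction, is_b95=frac >= fraction_strict,
        ))
    return calls


def cnv_summary(cnvs: Sequence[CNVRegion], assembly_bp: int) -> dict:
    """Count, total bp, assembly fraction and N50 of the CNV regions.

    N50 is the length L such that CNVs of length >= L sum to at least half
    the total CNV bp.
    """
    if assembly_bp <= 0:
        raise ValueError("assembly_bp must be positive")
    if not cnvs:
        return {"count": 0, "total_bp": 0, "assembly_fraction": 0.0, "n50_bp": 0}
    lengths = np.sort([c.length_bp for c in cnvs])[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2.0)])
    return {
        "count": len(cnvs),
        "total_bp": total,
        "assembly_fraction": total / assembly_bp,
        "n50_bp": n50,
    }


def cnvs_to_bed(cnvs: Sequence[CNVRegion], path) -> None:
    rows = [
        (c.contig, c.start, c.end, f"CNV{i:04d}", round(c.mean_sd, 4), c.placement)
        for i, c in enumerate(cnvs)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
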