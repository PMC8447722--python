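"""Fixed-size genomic windows and exon-normalized depth of coverage.

The unit of all downstream CNV analysis is a fixed-size window (5 kbp or
50 kbp) tiled across the assembly.  Per-window mean per-base depth of
coverage (DOC) is normalized by **half** the library's mean exon coverage,
so that diploid regions score 2 and the normalized value of a window reads
directly as a copy number.  Cross-library variability is quantified as the
sample standard deviation of normalized DOC per window and windows are
classified as lowSD (sd <= 0.7), interSD (0.7 < sd <= 2.0) or highSD
(sd > 2.0).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import batch_design, partial_pearson

__all__ = [
    "WindowSet",
    "WindowCoverageMatrix",
    "VariabilityProfile",
    "tile_windows",
    "normalize_coverage",
    "window_sd",
    "classify_variability",
    "class_coverage_vs_genome_size",
    "VARIABILITY_CLASSES",
]

VARIABILITY_CLASSES = ("lowSD", "interSD", "highSD")


@dataclasses.dataclass(frozen=True)
class WindowSet:
    """An ordered tiling of an assembly into half-open windows.

    ``df`` has columns contig, start, end; the row position is the global
    window index.  Coordinates are 0-based half-open (BED convention).
    """

    df: pd.DataFrame
    contig_lengths: dict[str, int]
    window_size: int

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def contig_window_indices(self, contig: str) -> np.ndarray:
        """Global indices of the windows on ``contig``, in genomic order."""
        return np.flatnonzero((self.df["contig"] == contig).to_numpy())

    def to_bed(self, path, names: Sequence[str] | None = None) -> None:
        out = self.df.copy()
        out["name"] = names if names is not None else [
            f"w{i}" for i in range(len(out))
        ]
        out.to_csv(path, sep="\t", header=False, index=False)


def tile_windows(
    contig_lengths: Mapping[str, int],
    window_size: int,
    drop_partial: bool = False,
) -> WindowSet:
    """Tile each contig into consecutive ``window_size`` windows.

    A terminal partial window is emitted when the contig length is not a
    multiple of ``window_size`` (dropped when ``drop_partial`` is set).
    """
    if not contig_lengths:
        raise ValueError("contig_lengths is empty")
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    records = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length {length}")
        starts = np.arange(0, length, window_size)
        for s in starts:
            e = min(s + window_size, length)
            if drop_partial and e - s < window_size:
                continue
            records.append((contig, int(s), int(e)))
    df = pd.DataFrame(records, columns=["contig", "start", "end"])
    return WindowSet(df=df, contig_lengths=dict(contig_lengths), window_size=window_size)


@dataclasses.dataclass
class WindowCoverageMatrix:
    """Per-(window x library) mean per-base depth of coverage.

    ``values`` is a DataFrame indexed like the window set with one column
    per library; ``normalized`` records whether exon normalization has been
    applied.
    """

    window_set: WindowSet
    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(self.window_set):
            raise ValueError("coverage rows do not match window count")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.window_set.df.copy()
        out.insert(0, "window_id", [f"w{i}" for i in range(len(out))])
        out = pd.concat([out, self.values.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, window_size: int | None = None,
                 normalized: bool = False) -> "WindowCoverageMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = df[["contig", "start", "end"]]
        values = df.drop(columns=["window_id", "contig", "start", "end"])
        contig_lengths = meta.groupby("contig", sort=False)["end"].max().to_dict()
        if window_size is None:
            window_size = int((meta["end"] - meta["start"]).max())
        ws = WindowSet(df=meta.reset_index(drop=True),
                       contig_lengths=contig_lengths, window_size=window_size)
        return cls(window_set=ws, values=values.astype(float), normalized=normalized)


def normalize_coverage(
    matrix: WindowCoverageMatrix,
    exon_mean: Mapping[str, float],
) -> WindowCoverageMatrix:
    """Divide each library's raw window DOC by half its mean exon coverage.

    Diploid-behaved windows score ~2 after normalization, so values read as
    copy numbers against an unphased (collapsed) reference.
    """
    norm = {}
    for lib in matrix.library_ids:
        if lib not in exon_mean:
            raise ValueError(f"no exon mean coverage for library {lib!r}")
        em = float(exon_mean[lib])
        if em <= 0:
            raise ValueError(f"exon mean coverage for library {lib!r} must be > 0")
        norm[lib] = matrix.values[lib] / (em / 2.0)
    return WindowCoverageMatrix(
        window_set=matrix.window_set,
        values=pd.DataFrame(norm, columns=matrix.library_ids),
        normalized=True,
    )


@dataclasses.dataclass
class VariabilityProfile:
    """Per-window cross-library SD and lowSD/interSD/highSD class."""

    window_set: WindowSet
    sd: np.ndarray
    classes: np.ndarray

    def to_bed(self, path) -> None:
        out = self.window_set.df.copy()
        out["name"] = self.classes
        out["score"] = np.round(self.sd, 4)
        out.to_csv(path, sep="\t", header=False, index=False)

    def class_regions(self, label: str) -> pd.DataFrame:
        """Merged (contig, start, end) intervals of windows in ``label``."""
        sel = self.window_set.df[self.classes == label]
        return merge_adjacent(sel)


def merge_adjacent(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge book-ended / overlapping intervals of a sorted window subset."""
    if intervals.empty:
        return intervals.copy()
    rows = []
    for contig, grp in intervals.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((contig, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def window_sd(matrix: WindowCoverageMatrix) -> np.ndarray:
    """Sample SD (n-1 denominator) of normalized DOC across libraries."""
    if not matrix.normalized:
        raise ValueError("window_sd expects an exon-normalized matrix")
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 libraries to compute a cross-library SD")
    return matrix.values.to_numpy().std(axis=1, ddof=1)


def classify_variability(
    sd_values: np.ndarray,
    low_hi: float = 0.7,
    inter_hi: float = 2.0,
) -> np.ndarray:
    """Classify windows by cross-library SD.

    sd <= low_hi -> lowSD; low_hi < sd <= inter_hi -> interSD; else highSD.
    """
    if not 0 < low_hi < inter_hi:
        raise ValueError("thresholds must satisfy 0 < low_hi < inter_hi")
    sd = np.asarray(sd_values, dtype=float)
    classes = np.where(sd <= low_hi, "lowSD",
                       np.where(sd <= inter_hi, "interSD", "highSD"))
    return classes.astype(object)


def variability_profile(
    matrix: WindowCoverageMatrix,
    low_hi: float = 0.7,
    inter_hi: float = 2.0,
) -> VariabilityProfile:
    sd = window_sd(matrix)
    return VariabilityProfile(window_set=matrix.window_set, sd=sd,
                              classes=classify_variability(sd, low_hi, inter_hi))


def class_coverage_vs_genome_size(
    matrix: WindowCoverageMatrix,
    classes: np.ndarray,
    library_meta: pd.DataFrame,
    covariates: Sequence[str] = ("prep_batch",),
) -> pd.DataFrame:
    """Partial correlation of per-class mean coverage with 2C genome size.

    For each variability class the mean normalized coverage over the class's
    windows is computed per library and correlated with the library's 2C
    genome size, controlling for the listed (categorical) covariates —
    library-prep batch by default, the confound that inflates coverage at
    CNV regions.

    ``library_meta`` must carry one row per library with columns
    ``library_id``, ``genome_size_2c_mb`` and the covariates.  Undefined
    correlations (zero variance) yield NaN rather than raising.
    """
    if not matrix.normalized:
        raise ValueError("expected an exon-normalized matrix")
    meta = library_meta.set_index("library_id").loc[matrix.library_ids]
    sizes = meta["genome_size_2c_mb"].to_numpy(dtype=float)
    if len(sizes) < 4:
        raise ValueError("need at least 4 libraries")
    if len(np.unique(sizes)) < 2:
        raise ValueError("need at least 2 distinct genome sizes")
    design_cols = [batch_design(meta[c]) for c in covariates]
    design = np.column_stack(design_cols) if design_cols else None
    rows = []
    for label in VARIABILITY_CLASSES:
        mask = classes == label
        if not mask.any():
            rows.append((label, 0, np.nan, np.nan))
            continue
        mean_cov = matrix.values.to_numpy()[mask].mean(axis=0)
        r, p = partial_pearson(mean_cov, sizes, design)
        rows.append((label, int(mask.sum()), r, p))
    return pd.DataFrame(rows, columns=["class", "n_windows", "r", "p"])
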