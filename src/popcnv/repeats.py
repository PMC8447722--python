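"""Repeat contributions and enrichment across genomic region classes.

RepeatMasker hits are parsed from the standard ``.out`` dialect, converted
to 0-based half-open intervals, and per-family *contributions* are computed
as union-merged covered bp (overlapping hits of one family count once).
For a region class occupying ``region_bp`` of an ``assembly_bp`` assembly,
the enrichment index of a family is

    E = (contribution in region / genome-wide contribution)
        / (region_bp / assembly_bp)

so E > 1 means the family is over-represented in the region.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "RepeatAnnotation",
    "RegionSet",
    "parse_repeatmasker",
    "repeat_contribution",
    "enrichment_index",
    "enrichment_table",
    "top_contributors",
]


def _merged_bp(df: pd.DataFrame) -> int:
    """Union-merged covered bp of (contig, start, end) intervals."""
    if df.empty:
        return 0
    g = pr.PyRanges(df.rename(columns={
        "contig": "Chromosome", "start": "Start", "end": "End"})).merge()
    return int((g.End - g.Start).sum())


def _to_pr(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(df.rename(columns={
        "contig": "Chromosome", "start": "Start", "end": "End"}))


@dataclasses.dataclass
class RepeatAnnotation:
    """Masked intervals labeled by repeat family and class/superfamily.

    ``df`` columns: contig, start, end (0-based half-open), family, repclass.
    Hits are stored as parsed; overlap policy is decided by the
    contribution operations.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.df["end"] <= self.df["start"]).any():
            raise ValueError("repeat intervals must satisfy end > start")

    @property
    def families(self) -> list[str]:
        return sorted(self.df["family"].unique())

    def family_hits(self, family: str) -> pd.DataFrame:
        return self.df[self.df["family"] == family]


@dataclasses.dataclass
class RegionSet:
    """A labeled set of genomic intervals (merged on construction)."""

    label: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.df.empty:
            merged = _to_pr(self.df).merge().df
            self.df = merged.rename(columns={
                "Chromosome": "contig", "Start": "start", "End": "end"})
            self.df["contig"] = self.df["contig"].astype(str)

    @property
    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum()) if len(self.df) else 0

    @classmethod
    def from_bed(cls, path, label: str) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["contig", "start", "end"])
        return cls(label=label, df=df)


def parse_repeatmasker(path) -> RepeatAnnotation:
    """Parse a RepeatMasker ``.out`` file.

    The 2-3 header lines are tolerated; query coordinates (1-based
    inclusive) are converted to 0-based half-open.  Family is the
    matching-repeat column, repclass the class/family column.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if fields[0] in {"SW", "score"}:        # header lines
                continue
            try:
                begin, end = int(fields[5]), int(fields[6])
                contig, family, repclass = fields[4], fields[9], fields[10]
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker line {lineno}: {line.rstrip()!r}"
                ) from exc
            rows.append((contig, begin - 1, end, family, repclass))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "family", "repclass"])
    return RepeatAnnotation(df=df)


def repeat_contribution(
    annotation: RepeatAnnotation,
    family: str,
    region: RegionSet,
) -> int:
    """Covered bp of ``family`` inside ``region``.

    Same-family overlapping hits are union-merged before intersection, so
    nested or duplicated hits are counted once.
    """
    hits = annotation.family_hits(family)
    if hits.empty:
        warnings.warn(f"family {family!r} absent from annotation")
        return 0
    if region.df.empty:
        return 0
    inter = _to_pr(hits[["contig", "start", "end"]]).merge() \
        .intersect(_to_pr(region.df))
    return 0 if inter.empty else int((inter.End - inter.Start).sum())


def enrichment_index(
    contrib_in_region: int,
    contrib_genome: int,
    region_bp: int,
    assembly_bp: int,
) -> float:
    """E = (region contribution fraction) / (region size fraction).

    Returns NaN (flagged by a warning) when the family has no genome-wide
    contribution.
    """
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    if assembly_bp <= 0:
        raise ValueError("assembly_bp must be positive")
    if contrib_genome <= 0:
        warnings.warn("family has zero genome-wide contribution; index undefined")
        return float("nan")
    return (contrib_in_region / contrib_genome) / (region_bp / assembly_bp)


def enrichment_table(
    annotation: RepeatAnnotation,
    regions: Sequence[RegionSet],
    assembly_bp: int,
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Enrichment index of each family in each region class."""
    families = list(families) if families is not None else annotation.families
    rows = []
    for fam in families:
        genome_bp = _merged_bp(annotation.family_hits(fam)[["contig", "start", "end"]])
        for region in regions:
            in_region = repeat_contribution(annotation, fam, region)
            rows.append({
                "family": fam,
                "region": region.label,
                "contrib_bp": in_region,
                "genome_bp": genome_bp,
                "enrichment": enrichment_index(
                    in_region, genome_bp, region.total_bp, assembly_bp),
            })
    return pd.DataFrame(rows)


def top_contributors(
    annotation: RepeatAnnotation,
    assembly_bp: int,
    n: int = 36,
) -> pd.DataFrame:
    """The ``n`` largest families by union-merged covered bp.

    Ties are broken alphabetically; ``fraction`` is covered bp over the
    assembly size.
    """
    if assembly_bp <= 0:
        raise ValueError("assembly_bp must be positive")
    rows = [
        (fam, _merged_bp(annotation.family_hits(fam)[["contig", "start", "end"]]))
        for fam in annotation.families
    ]
    tab = pd.DataFrame(rows, columns=["family", "bp"])
    tab = tab.sort_values(["bp", "family"], ascending=[False, True],
                          kind="mergesort").head(n).reset_index(drop=True)
    tab["fraction"] = tab["bp"] / assembly_bp
    tab.index = tab.index + 1
    tab.index.name = "rank"
    return tab
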