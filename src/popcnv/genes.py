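"""Monte Carlo permutation tests for gene placement relative to CNV regions.

Two questions are addressed: (i) is gene density inside CNV regions lower
(or higher) than expected if genes were placed at random across the
assembly, and (ii) are duplication-derived genes over-represented among the
genes that do fall inside CNVs.

Both use empirical permutation p-values with the plus-one correction
``p = (1 + #{null at least as extreme}) / (n_perm + 1)``, so p is never 0.
The density test re-places each gene uniformly at random within the
assembly (length-preserving, staying inside one contig); the enrichment
test permutes the duplication labels across all genes while holding CNV
membership fixed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .repeats import RegionSet, _to_pr

__all__ = [
    "PermutationResult",
    "read_gene_table",
    "genes_in_regions",
    "permutation_test_density",
    "permutation_test_dup_enrichment",
]


@dataclasses.dataclass
class PermutationResult:
    """Observed statistic, its permutation null and the empirical p-value."""

    observed: float
    null: np.ndarray
    p_value: float
    alternative: str
    n_perm: int
    seed: int | None
    scheme: str

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "n_perm": self.n_perm,
            "null_mean": float(self.null.mean()),
            "null_quantiles": {
                q: float(np.quantile(self.null, q))
                for q in (0.025, 0.5, 0.975)
            },
            "seed": self.seed,
            "scheme": self.scheme,
        }


def read_gene_table(gff3_path, duplicated_ids=None,
                    feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from a GFF3 file plus a duplication flag.

    ``duplicated_ids``: iterable of gene IDs labeled as duplication-derived
    by an upstream orthology analysis (or a path to a one-ID-per-line file).
    """
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="warning",
                            keep_order=True)
    if isinstance(duplicated_ids, (str, bytes)) or hasattr(duplicated_ids, "read"):
        with open(duplicated_ids) as fh:
            duplicated_ids = {line.strip() for line in fh if line.strip()}
    dup = set(duplicated_ids or ())
    rows = [
        (g.seqid, g.start - 1, g.end, g.id, g.id in dup)
        for g in db.features_of_type(feature)
    ]
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id",
                                       "duplicated"])


def _membership_midpoint(contigs: np.ndarray, midpoints: np.ndarray,
                         regions: RegionSet) -> np.ndarray:
    member = np.zeros(len(contigs), dtype=bool)
    for contig, grp in regions.df.groupby("contig", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sel = contigs == contig
        if not sel.any():
            continue
        pos = midpoints[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        member[sel] = ok
    return member


def genes_in_regions(
    genes: pd.DataFrame,
    regions: RegionSet,
    rule: str = "midpoint",
    overlap_frac: float = 0.5,
) -> np.ndarray:
    """Boolean membership of each gene in the region set.

    ``rule`` is "midpoint" (gene midpoint contained in a region; default) or
    "overlap" (at least ``overlap_frac`` of gene length overlapped).  Genes
    on contigs absent from the region universe count as outside, with a
    warning.
    """
    contigs = genes["contig"].to_numpy()
    known = set(regions.df["contig"]) if len(regions.df) else set()
    missing = set(contigs) - known
    if missing and known:
        warnings.warn(
            f"{len(missing)} contig(s) absent from the region set; their "
            "genes are counted outside"
        )
    if rule == "midpoint":
        mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
        return _membership_midpoint(contigs, mid, regions)
    if rule == "overlap":
        if regions.df.empty:
            return np.zeros(len(genes), dtype=bool)
        gdf = genes[["contig", "start", "end", "gene_id"]]
        inter = _to_pr(gdf).intersect(_to_pr(regions.df))
        covered = (
            inter.df.assign(length=lambda d: d.End - d.Start)
            .groupby("gene_id")["length"].sum()
            if not inter.empty else pd.Series(dtype=int)
        )
        length = (genes["end"] - genes["start"]).to_numpy()
        cov = genes["gene_id"].map(covered).fillna(0).to_numpy()
        return cov >= overlap_frac * length
    raise ValueError(f"unknown membership rule {rule!r}")


def _empirical_p(observed: float, null: np.ndarray, alternative: str) -> float:
    n = len(null)
    p_ge = (1 + int((null >= observed).sum())) / (n + 1)
    p_le = (1 + int((null <= observed).sum())) / (n + 1)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_ge, p_le))
    raise ValueError(f"unknown alternative {alternative!r}")


def permutation_test_density(
    genes: pd.DataFrame,
    regions: RegionSet,
    contig_lengths: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "less",
    rule: str = "midpoint",
) -> PermutationResult:
    """Test whether the count of genes inside ``regions`` is non-random.

    Null model: each gene is re-placed uniformly at random in the assembly,
    keeping its length and staying within a single contig (contigs sampled
    proportionally to the number of admissible start positions).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if regions.df.empty:
        raise ValueError("region set is empty")
    observed = int(genes_in_regions(genes, regions, rule=rule).sum())
    rng = np.random.default_rng(seed)
    names = list(contig_lengths)
    clens = np.array([contig_lengths[c] for c in names], dtype=np.int64)
    glens = (genes["end"] - genes["start"]).to_numpy()
    null = np.zeros((n_perm, len(genes)), dtype=bool)
    carr = np.array(names, dtype=object)
    for i, glen in enumerate(glens):
        slots = np.maximum(clens - glen + 1, 0)
        if slots.sum() == 0:
            raise ValueError("a gene is longer than every contig")
        pick = rng.choice(len(names), size=n_perm, p=slots / slots.sum())
        start = rng.integers(0, slots[pick])
        mid = start + glen // 2
        null[:, i] = _membership_midpoint(carr[pick], mid, regions)
    null_counts = null.sum(axis=1).astype(float)
    return PermutationResult(
        observed=float(observed), null=null_counts,
        p_value=_empirical_p(observed, null_counts, alternative),
        alternative=alternative, n_perm=n_perm, seed=seed,
        scheme="uniform length-preserving re-placement of genes within contigs",
    )


def permutation_test_dup_enrichment(
    genes: pd.DataFrame,
    cnv_membership: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
) -> PermutationResult:
    """Test enrichment of duplication-derived genes among CNV genes.

    Null model: duplication flags are permuted across all genes while CNV
    membership is held fixed; the statistic is the count of duplicated
    genes among CNV genes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    member = np.asarray(cnv_membership, dtype=bool)
    if member.sum() == 0:
        raise ValueError("no genes fall inside CNV regions")
    dup = genes["duplicated"].to_numpy(dtype=bool)
    observed = int((dup & member).sum())
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(dup, (n_perm, 1)), axis=1)
    null = perms[:, member].sum(axis=1).astype(float)
    return PermutationResult(
        observed=float(observed), null=null,
        p_value=_empirical_p(observed, null, alternative),
        alternative=alternative, n_perm=n_perm, seed=seed,
        scheme="permutation of duplication labels with CNV membership fixed",
    )
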