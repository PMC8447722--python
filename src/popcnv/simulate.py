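"""Synthetic populations of clones carrying independently segregating elements.

This module generates every input the analysis consumes, with the
statistical structure the method assumes:

* a **basal** diploid genome common to all clones, plus 0..max_copies of
  several megabase-scale independently segregating elements (ISEs), so a
  clone's 2C genome size is ``basal_2c_mb + sum(copies_i * size_mb_i)``;
* a collapsed, unphased toy assembly in which each element appears once,
  tiled into fixed windows; raw window coverage scales with copy number
  (diploid windows normalize to 2, element windows to the copy number);
* multiplicative Gamma read-depth noise (mean 1, configurable dispersion)
  and a per-prep-batch GC bias multiplier applied to high-GC windows,
  emulating the batch-wise coverage elevation at CNV regions;
* per-read %GC values drawn from a three-component normal mixture whose
  component weights shift with element content (the low-GC fraction tracks
  the basal genome, the mid/high-GC fractions track element content);
* ddPCR droplet readouts with Poisson droplet occupancy.

Crosses transmit each element copy independently with probability 1/2
(Binomial), so offspring copy numbers are midparent in expectation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .copynum import DdpcrMeasurement
from .windows import WindowCoverageMatrix, WindowSet, tile_windows

__all__ = [
    "ElementDef",
    "CloneGenotype",
    "LibraryMeta",
    "SimConfig",
    "GCReadParams",
    "default_config",
    "simulate_population",
    "cross",
    "assign_libraries",
    "simulate_coverage_matrix",
    "gc_component_weights",
    "simulate_gc_reads",
    "simulate_ddpcr",
    "DEFAULT_GC_BIAS_BY_BATCH",
]

#: Batch-specific multiplier applied to high-GC windows; library preps A-F.
DEFAULT_GC_BIAS_BY_BATCH = {
    "A": 1.00, "B": 1.03, "C": 1.06, "D": 1.09, "E": 1.12, "F": 1.15,
}


@dataclasses.dataclass(frozen=True)
class ElementDef:
    """One independently segregating element.

    ``host_windows`` are half-open global window-index ranges where the
    element's single collapsed copy sits in the toy assembly.
    """

    id: str
    size_mb: float
    gc_pct: float
    host_windows: tuple[tuple[int, int], ...]
    max_copies: int = 6

    def __post_init__(self) -> None:
        if self.size_mb <= 0:
            raise ValueError(f"element {self.id!r}: size_mb must be positive")
        if not 0 <= self.gc_pct <= 100:
            raise ValueError(f"element {self.id!r}: gc_pct outside [0, 100]")
        ranges = sorted(self.host_windows)
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            if s2 < e1:
                raise ValueError(f"element {self.id!r}: host ranges overlap")
        for s, e in ranges:
            if e <= s or s < 0:
                raise ValueError(f"element {self.id!r}: invalid host range ({s}, {e})")

    @property
    def n_windows(self) -> int:
        return sum(e - s for s, e in self.host_windows)


@dataclasses.dataclass(frozen=True)
class CloneGenotype:
    """Per-clone copy numbers of each element plus the basal 2C size."""

    clone_id: str
    copies: dict[str, int]
    basal_2c_mb: float

    def __post_init__(self) -> None:
        if self.basal_2c_mb <= 0:
            raise ValueError("basal_2c_mb must be positive")
        if any(c < 0 for c in self.copies.values()):
            raise ValueError("copy numbers must be non-negative")

    def implied_2c_mb(self, elements: Sequence[ElementDef]) -> float:
        """2C genome size under the additive model: basal + sum(c_i * s_i)."""
        sizes = {e.id: e.size_mb for e in elements}
        return self.basal_2c_mb + sum(
            c * sizes[eid] for eid, c in self.copies.items()
        )


@dataclasses.dataclass(frozen=True)
class LibraryMeta:
    """Sequencing-library metadata (one clone, one prep batch)."""

    library_id: str
    clone_id: str
    prep_batch: str
    genome_size_2c_mb: float
    exon_mean_coverage: float
    gc_bias: float

    def __post_init__(self) -> None:
        if self.exon_mean_coverage <= 0:
            raise ValueError("exon_mean_coverage must be positive")
        if self.gc_bias <= 0:
            raise ValueError("gc_bias must be positive")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic population."""

    n_clones: int
    elements: tuple[ElementDef, ...]
    basal_2c_mb: float
    window_size_bp: int
    contig_lengths: dict[str, int]
    noise_dispersion: float = 0.1
    seed: int = 0
    basal_gc_pct: float = 26.0
    gc_bias_threshold_pct: float = 32.0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.basal_2c_mb <= 0:
            raise ValueError("basal_2c_mb must be positive")
        if self.window_size_bp <= 0:
            raise ValueError("window_size_bp must be positive")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be non-negative")
        n_windows = sum(
            -(-length // self.window_size_bp)
            for length in self.contig_lengths.values()
        )
        occupied: list[tuple[int, int]] = []
        for el in self.elements:
            for s, e in el.host_windows:
                if e > n_windows:
                    raise ValueError(
                        f"element {el.id!r} host range ({s}, {e}) exceeds the "
                        f"{n_windows}-window assembly"
                    )
                occupied.append((s, e))
        occupied.sort()
        for (s1, e1), (s2, _) in zip(occupied, occupied[1:]):
            if s2 < e1:
                raise ValueError("element host ranges overlap between elements")

    @property
    def window_set(self) -> WindowSet:
        return tile_windows(self.contig_lengths, self.window_size_bp)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["elements"] = [
            {**dataclasses.asdict(e),
             "host_windows": [list(r) for r in e.host_windows]}
            for e in self.elements
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["elements"] = tuple(
            ElementDef(**{**e, "host_windows": tuple(map(tuple, e["host_windows"]))})
            for e in doc["elements"]
        )
        return cls(**doc)


def default_config(seed: int = 0) -> SimConfig:
    """The study-scale defaults: 15 clones, a 273-Mb collapsed assembly.

    The basal genome is 414 Mb (2C; core haploid 207 Mb) spread over five
    diploid contigs; three elements segregate independently: a 34-Mb
    high-GC element filling contig 000F (up to 6 copies, the ddPCR locus
    analog), a 20-Mb mid-GC element filling contig 004F, and a 12-Mb
    high-GC element embedded mid-contig in 005F.
    """
    w = 5000
    mb = 1_000_000
    contig_lengths = {
        "000F": 34 * mb, "001F": 50 * mb, "002F": 50 * mb, "003F": 52 * mb,
        "004F": 20 * mb, "005F": 40 * mb, "006F": 27 * mb,
    }
    offsets = {}
    pos = 0
    for name, length in contig_lengths.items():
        offsets[name] = pos
        pos += length // w
    elements = (
        ElementDef("e34", 34.0, 48.0,
                   ((offsets["000F"], offsets["000F"] + 34 * mb // w),),
                   max_copies=6),
        ElementDef("e20", 20.0, 36.0,
                   ((offsets["004F"], offsets["004F"] + 20 * mb // w),),
                   max_copies=4),
        ElementDef("e12", 12.0, 48.0,
                   ((offsets["005F"] + 2800, offsets["005F"] + 2800 + 12 * mb // w),),
                   max_copies=3),
    )
    return SimConfig(
        n_clones=15,
        elements=elements,
        basal_2c_mb=414.0,
        window_size_bp=w,
        contig_lengths=contig_lengths,
        noise_dispersion=0.1,
        seed=seed,
    )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_population(config: SimConfig) -> list[CloneGenotype]:
    """Draw per-clone element copy numbers.

    Copy numbers are uniform on 0..max_copies per element; the first clone
    is anchored at zero copies of every element, mirroring a population
    whose smallest genomes entirely lack segregating elements.
    """
    rng = _rng(config.seed, 0)
    genotypes = []
    for i in range(config.n_clones):
        copies = {
            el.id: 0 if i == 0 else int(rng.integers(0, el.max_copies + 1))
            for el in config.elements
        }
        genotypes.append(
            CloneGenotype(clone_id=f"clone{i:02d}", copies=copies,
                          basal_2c_mb=config.basal_2c_mb)
        )
    return genotypes


def cross(parent_a: CloneGenotype, parent_b: CloneGenotype,
          seed: int, clone_id: str | None = None) -> CloneGenotype:
    """Mate two clones; each element copy transmits independently (p = 1/2).

    Offspring copy numbers are Binomial(c_a, 1/2) + Binomial(c_b, 1/2), so
    the expectation is the midparent value (c_a + c_b) / 2.
    """
    if set(parent_a.copies) != set(parent_b.copies):
        raise ValueError("parents carry different element sets")
    if parent_a.basal_2c_mb != parent_b.basal_2c_mb:
        raise ValueError("parents differ in basal genome size")
    rng = np.random.default_rng(seed)
    copies = {
        eid: int(rng.binomial(parent_a.copies[eid], 0.5)
                 + rng.binomial(parent_b.copies[eid], 0.5))
        for eid in parent_a.copies
    }
    cid = clone_id or f"{parent_a.clone_id}x{parent_b.clone_id}"
    return CloneGenotype(clone_id=cid, copies=copies,
                         basal_2c_mb=parent_a.basal_2c_mb)


def assign_libraries(
    genotypes: Sequence[CloneGenotype],
    elements: Sequence[ElementDef],
    n_libraries: int = 29,
    prep_batches: str = "ABCDEF",
    gc_bias_by_batch: Mapping[str, float] | None = None,
    exon_mean_range: tuple[float, float] = (20.0, 40.0),
    seed: int = 0,
) -> list[LibraryMeta]:
    """Assign sequencing libraries to clones across prep batches.

    Libraries cycle over clones (so with 29 libraries and 15 clones most
    clones are sequenced twice, in different batches) and over batches A-F.
    Mean exon coverage is drawn uniformly from ``exon_mean_range``;
    ``genome_size_2c_mb`` is the flow-cytometry-style ground truth, i.e. the
    genotype's implied 2C size.
    """
    biases = dict(gc_bias_by_batch or DEFAULT_GC_BIAS_BY_BATCH)
    rng = _rng(seed, 1)
    libs = []
    for i in range(n_libraries):
        g = genotypes[i % len(genotypes)]
        batch = prep_batches[i % len(prep_batches)]
        libs.append(LibraryMeta(
            library_id=f"lib{i:02d}",
            clone_id=g.clone_id,
            prep_batch=batch,
            genome_size_2c_mb=g.implied_2c_mb(elements),
            exon_mean_coverage=float(rng.uniform(*exon_mean_range)),
            gc_bias=biases[batch],
        ))
    return libs


def _window_profile(config: SimConfig) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-window GC and, per element, a boolean host mask."""
    n = len(config.window_set)
    gc = np.full(n, config.basal_gc_pct)
    masks = {}
    for el in config.elements:
        mask = np.zeros(n, dtype=bool)
        for s, e in el.host_windows:
            mask[s:e] = True
        gc[mask] = el.gc_pct
        masks[el.id] = mask
    return gc, masks


def simulate_coverage_matrix(
    genotypes: Sequence[CloneGenotype],
    libraries: Sequence[LibraryMeta],
    config: SimConfig,
) -> tuple[WindowCoverageMatrix, dict[str, float]]:
    """Simulate the raw window-coverage matrix and per-library exon means.

    Expected raw coverage of a diploid window equals the library's mean exon
    coverage; an element window in a clone with ``c`` copies has expectation
    ``(c / 2) * exon_mean * gc_bias`` (the bias applies only to windows whose
    GC exceeds ``config.gc_bias_threshold_pct``).  Multiplicative Gamma noise
    with mean 1 and SD ``noise_dispersion`` is applied per window.
    """
    window_gc, masks = _window_profile(config)
    by_clone = {g.clone_id: g for g in genotypes}
    rng = _rng(config.seed, 2)
    n = len(window_gc)
    biased = window_gc > config.gc_bias_threshold_pct
    cols = {}
    exon_means = {}
    for lib in libraries:
        g = by_clone[lib.clone_id]
        cn = np.full(n, 2.0)
        for el in config.elements:
            cn[masks[el.id]] = g.copies[el.id]
        expected = lib.exon_mean_coverage * cn / 2.0
        expected = np.where(biased, expected * lib.gc_bias, expected)
        if config.noise_dispersion > 0:
            d2 = config.noise_dispersion ** 2
            expected = expected * rng.gamma(shape=1.0 / d2, scale=d2, size=n)
        cols[lib.library_id] = expected
        exon_means[lib.library_id] = lib.exon_mean_coverage
    matrix = WindowCoverageMatrix(
        window_set=config.window_set,
        values=pd.DataFrame(cols),
        normalized=False,
    )
    return matrix, exon_means


@dataclasses.dataclass(frozen=True)
class GCReadParams:
    """Three-component GC mixture and how genome content maps to weights.

    ``basal_fractions`` is the composition of the basal genome over the
    components (the mid/high entries are the configured floors reached by
    zero-element clones).  ``element_fractions`` is the composition of
    element sequence: segregating elements are built from satellite arrays
    with elevated GC spanning the mid and high peaks, so their mass feeds
    the mid- and high-GC components and dilutes the low-GC one.
    """

    means: tuple[float, float, float] = (26.0, 36.0, 48.0)
    sds: tuple[float, float, float] = (6.0, 2.5, 3.0)
    basal_fractions: tuple[float, float, float] = (0.70, 0.25, 0.05)
    element_fractions: tuple[float, float, float] = (0.0, 0.45, 0.55)

    def __post_init__(self) -> None:
        if abs(sum(self.basal_fractions) - 1.0) > 1e-9:
            raise ValueError("basal_fractions must sum to 1")
        if abs(sum(self.element_fractions) - 1.0) > 1e-9:
            raise ValueError("element_fractions must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("component SDs must be positive")


def gc_component_weights(
    genotype: CloneGenotype,
    elements: Sequence[ElementDef],
    params: GCReadParams = GCReadParams(),
) -> np.ndarray:
    """Mixture weights implied by a genotype's basal and element content."""
    mass = genotype.basal_2c_mb * np.asarray(params.basal_fractions)
    element_mb = sum(genotype.copies[el.id] * el.size_mb for el in elements)
    mass = mass + element_mb * np.asarray(params.element_fractions)
    return mass / mass.sum()


def simulate_gc_reads(
    genotype: CloneGenotype,
    elements: Sequence[ElementDef],
    n_reads: int,
    params: GCReadParams = GCReadParams(),
    seed: int = 0,
    return_components: bool = False,
):
    """Draw per-read %GC values for one library of ``genotype``.

    Values are clipped to [0, 100].  With ``return_components`` the latent
    component index of each read is returned alongside the values.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    weights = gc_component_weights(genotype, elements, params)
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n_reads, p=weights)
    vals = rng.normal(np.asarray(params.means)[comp], np.asarray(params.sds)[comp])
    vals = np.clip(vals, 0.0, 100.0)
    return (vals, comp) if return_components else vals


def simulate_ddpcr(
    true_cn: int,
    n_droplets: int,
    seed: int = 0,
    genome_equiv_per_droplet: float = 0.1,
    droplet_volume_ul: float = 0.00085,
    locus: str = "locus",
) -> DdpcrMeasurement:
    """Simulate a ddPCR readout for a locus present in ``true_cn`` copies.

    Template molecules partition into droplets as Poisson counts; the two
    reference amplicons correspond to 2 copies per genome, the target to
    ``true_cn``.  Concentrations (copies/ul) are recovered per amplicon as
    ``-ln(fraction negative) / droplet_volume`` with binomial 95% CIs.
    """
    if true_cn < 0:
        raise ValueError("true_cn must be non-negative")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    rng = np.random.default_rng(seed)

    def one(lam: float) -> tuple[float, tuple[float, float]]:
        p_pos = 1.0 - np.exp(-lam)
        k = int(rng.binomial(n_droplets, p_pos))
        if k >= n_droplets:
            raise ValueError("all droplets positive; template too concentrated")
        phat = k / n_droplets
        lam_hat = -np.log1p(-phat)
        se = np.sqrt(phat / ((1.0 - phat) * n_droplets))
        lo, hi = max(lam_hat - 1.96 * se, 0.0), lam_hat + 1.96 * se
        v = droplet_volume_ul
        return lam_hat / v, (lo / v, hi / v)

    lam_ref = 2.0 * genome_equiv_per_droplet
    lam_tgt = true_cn * genome_equiv_per_droplet
    t, t_ci = one(lam_tgt)
    r1, r1_ci = one(lam_ref)
    r2, r2_ci = one(lam_ref)
    return DdpcrMeasurement(locus=locus, target=t, ref1=r1, ref2=r2,
                            target_ci=t_ci, ref1_ci=r1_ci, ref2_ci=r2_ci,
                            n_reference_copies=2)


# ---------------------------------------------------------------------------
# plain-text writers for the CLI

def genotypes_frame(genotypes: Sequence[CloneGenotype],
                    elements: Sequence[ElementDef]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        row = {"clone_id": g.clone_id, "basal_2c_mb": g.basal_2c_mb}
        row.update({f"copies_{eid}": c for eid, c in g.copies.items()})
        row["implied_2c_mb"] = g.implied_2c_mb(elements)
        rows.append(row)
    return pd.DataFrame(rows)


def library_meta_frame(libraries: Sequence[LibraryMeta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(l) for l in libraries])
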