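"""Locus copy-number estimation from ddPCR and coverage conversions.

Droplet digital PCR quantifies absolute amplicon concentrations by Poisson
statistics over partitioned droplets.  With a target amplicon concentration
``T`` and two diploid reference amplicons ``R1``/``R2`` (``N_R = 2`` copies
per genome), the copy number of the target locus is

    CN = T / ((R1 + R2) / 2) * N_R

Confidence intervals on CN are propagated conservatively from the per-
concentration 95% CIs by taking the extremes of the ratio over the CI box;
a delta-method variant is available.
"""

from __future__ import annotations

import dataclasses
import math

__all__ = [
    "DdpcrMeasurement",
    "CopyNumberEstimate",
    "ddpcr_cn",
    "kmer_to_base_coverage",
    "naive_coverage",
]


@dataclasses.dataclass(frozen=True)
class DdpcrMeasurement:
    """One ddPCR readout: target and two reference amplicon concentrations.

    Concentrations are in copies/ul; CI bounds are optional (lo, hi) tuples
    in the same units.  ``n_reference_copies`` is the per-genome copy number
    of the reference loci (2 for diploid references).
    """

    locus: str
    target: float
    ref1: float
    ref2: float
    target_ci: tuple[float, float] | None = None
    ref1_ci: tuple[float, float] | None = None
    ref2_ci: tuple[float, float] | None = None
    n_reference_copies: int = 2

    def __post_init__(self) -> None:
        if min(self.target, self.ref1, self.ref2) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.n_reference_copies < 1:
            raise ValueError("n_reference_copies must be >= 1")


@dataclasses.dataclass(frozen=True)
class CopyNumberEstimate:
    locus: str
    cn: float
    ci: tuple[float, float] | None

    def rounded(self) -> tuple[int, float]:
        """Nearest integer copy number and its distance from the estimate."""
        n = round(self.cn)
        return int(n), abs(self.cn - n)


def ddpcr_cn(m: DdpcrMeasurement, ci_method: str = "box") -> CopyNumberEstimate:
    """Estimate locus copy number from a ddPCR measurement.

    ``ci_method``: "box" takes min/max of the ratio over the concentration
    CI box (conservative); "delta" propagates first-order variances assuming
    the 95% CIs are +/-1.96 SE.
    """
    ref_mean = (m.ref1 + m.ref2) / 2.0
    if ref_mean <= 0:
        raise ValueError("both reference concentrations are zero")
    cn = m.target / ref_mean * m.n_reference_copies
    cis = (m.target_ci, m.ref1_ci, m.ref2_ci)
    if any(c is None for c in cis):
        return CopyNumberEstimate(m.locus, cn, None)
    t_lo, t_hi = m.target_ci
    r_lo = (m.ref1_ci[0] + m.ref2_ci[0]) / 2.0
    r_hi = (m.ref1_ci[1] + m.ref2_ci[1]) / 2.0
    if ci_method == "box":
        lo = t_lo / r_hi * m.n_reference_copies if r_hi > 0 else 0.0
        hi = t_hi / r_lo * m.n_reference_copies if r_lo > 0 else math.inf
    elif ci_method == "delta":
        se_t = (t_hi - t_lo) / (2 * 1.96)
        se_r = (r_hi - r_lo) / (2 * 1.96)
        var_rel = (se_t / m.target) ** 2 if m.target > 0 else 0.0
        var_rel += (se_r / ref_mean) ** 2
        half = 1.96 * cn * math.sqrt(var_rel)
        lo, hi = max(cn - half, 0.0), cn + half
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return CopyNumberEstimate(m.locus, cn, (lo, hi))


def kmer_to_base_coverage(c_k: float, read_length: float, k: int) -> float:
    """Convert kmer coverage to per-base coverage: C = C_K * R / (R - K + 1)."""
    if k < 1:
        raise ValueError("kmer size must be >= 1")
    if k > read_length:
        raise ValueError("kmer size cannot exceed read length")
    if c_k < 0:
        raise ValueError("kmer coverage must be non-negative")
    return c_k * read_length / (read_length - k + 1)


def naive_coverage(total_bp_in_library: float, genome_size_1c_bp: float) -> float:
    """Sequencing-effort coverage: library bp over 1C genome size."""
    if total_bp_in_library <= 0:
        raise ValueError("total_bp_in_library must be positive")
    if genome_size_1c_bp <= 0:
        raise ValueError("genome_size_1c_bp must be positive")
    return total_bp_in_library / genome_size_1c_bp
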