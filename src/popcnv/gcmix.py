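"""Gaussian-mixture decomposition of per-read GC content.

Whole-genome short-read libraries of this system show a trimodal GC
distribution: a broad low-GC fraction from the basal genome and two
narrower fractions (around 36% and 48% GC) contributed by satellite-rich
segregating elements.  A 3-component univariate normal mixture is fitted to
per-read %GC values by expectation-maximization; the per-library component
weights estimate the relative proportion of each fraction and can be
correlated with flow-cytometry genome size.

Two fitting modes are provided: a full per-library fit, and a
*fixed-components* mode that re-estimates only the weights under component
means/SDs taken from a pooled fit — the default when comparing libraries,
so that fractions keep the same meaning across libraries.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "GCMixtureModel",
    "read_gc",
    "read_gc_from_file",
    "fit_gc_mixture",
    "fraction_report",
    "fraction_vs_genome_size",
]

_COMPONENT_LABELS = ("low", "mid", "high")


@dataclasses.dataclass
class GCMixtureModel:
    """A fitted k-component univariate normal mixture (sorted by mean)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    n: int

    @property
    def k(self) -> int:
        return len(self.means)

    def to_json(self, path) -> None:
        doc = {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n": self.n,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def read_gc(sequences) -> np.ndarray:
    """Percent GC of each read: 100 * (G+C) / (A+C+G+T).

    Ambiguous bases are excluded from numerator and denominator; reads with
    no unambiguous base are skipped (a warning reports how many).
    """
    values = []
    skipped = 0
    for seq in sequences:
        s = str(getattr(seq, "seq", seq)).upper()
        gc = s.count("G") + s.count("C")
        acgt = gc + s.count("A") + s.count("T")
        if acgt == 0:
            skipped += 1
            continue
        values.append(100.0 * gc / acgt)
    if skipped:
        warnings.warn(f"skipped {skipped} read(s) with only ambiguous bases")
    if not values:
        raise ValueError("no sequences with unambiguous bases")
    return np.asarray(values)


def read_gc_from_file(path, fmt: str | None = None) -> np.ndarray:
    """Per-read %GC from a FASTA/FASTQ file (gzip-aware)."""
    import gzip

    from Bio import SeqIO

    path = str(path)
    if fmt is None:
        stem = path[:-3] if path.endswith(".gz") else path
        fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return read_gc(SeqIO.parse(fh, fmt))


def _log_density(x: np.ndarray, means, sds, weights) -> np.ndarray:
    """(n, k) matrix of log(w_k) + log N(x | mu_k, sd_k)."""
    return (np.log(weights)[None, :]
            + stats.norm.logpdf(x[:, None], means[None, :], sds[None, :]))


def fit_gc_mixture(
    values,
    k: int = 3,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
    restarts: int = 0,
    fixed_means: Sequence[float] | None = None,
    fixed_sds: Sequence[float] | None = None,
) -> GCMixtureModel:
    """Fit a k-component normal mixture to %GC values by EM.

    Initialization is quantile-based (means at the (2i+1)/(2k) sample
    quantiles, equal weights, pooled SD); ``restarts`` adds random
    perturbed restarts keeping the best log-likelihood.  Convergence is a
    relative log-likelihood improvement below ``tol``.  With ``fixed_means``
    and ``fixed_sds``, only the weights are re-estimated (fixed-components
    mode); the EM ascent property holds in both modes.
    """
    x = np.asarray(values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(x) < 10 * k:
        raise ValueError(f"need at least {10 * k} values to fit k={k} components")
    if np.std(x) == 0:
        raise ValueError("input values have zero variance")
    fixed = fixed_means is not None or fixed_sds is not None
    if fixed and (fixed_means is None or fixed_sds is None):
        raise ValueError("fixed-components mode needs both fixed_means and fixed_sds")

    def initial() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if fixed:
            return (np.asarray(fixed_means, float), np.asarray(fixed_sds, float),
                    np.full(k, 1.0 / k))
        if init is not None:
            return tuple(np.asarray(a, float).copy() for a in init)
        q = (2 * np.arange(k) + 1) / (2 * k)
        return np.quantile(x, q), np.full(k, np.std(x)), np.full(k, 1.0 / k)

    rng = np.random.default_rng(seed)
    best: GCMixtureModel | None = None
    for attempt in range(restarts + 1):
        means, sds, weights = initial()
        if attempt > 0 and not fixed:
            means = means + rng.normal(0.0, np.std(x) / 2, size=k)
        model = _em(x, means, sds, weights, max_iter, tol, update_components=not fixed)
        if best is None or model.loglik > best.loglik:
            best = model
    return best


def _em(x, means, sds, weights, max_iter, tol, update_components=True) -> GCMixtureModel:
    n = len(x)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logdens = _log_density(x, means, sds, weights)
        norm = logsumexp(logdens, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(logdens - norm[:, None])        # responsibilities
        nk = resp.sum(axis=0)
        weights = nk / n
        if update_components:
            means = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.sqrt(np.maximum(var, 1e-6))      # floor avoids collapse
        if ll - prev < tol * abs(ll):
            converged = True
            break
        prev = ll
    order = np.argsort(means)
    final_ll = float(logsumexp(_log_density(x, means, sds, weights), axis=1).sum())
    trace.append(final_ll)
    return GCMixtureModel(
        means=means[order], sds=sds[order], weights=weights[order],
        loglik=final_ll, loglik_trace=np.asarray(trace), n_iter=it,
        converged=converged, n=n,
    )


def fraction_report(models: Mapping[str, GCMixtureModel]) -> pd.DataFrame:
    """Per-library weights of the low/mid/high-GC components.

    Components are matched across libraries by ascending mean (models store
    them sorted).  Non-converged fits are kept but flagged.
    """
    ks = {m.k for m in models.values()}
    if len(ks) != 1:
        raise ValueError("all models must share the same component count")
    k = ks.pop()
    labels = _COMPONENT_LABELS if k == 3 else tuple(f"c{i}" for i in range(k))
    rows = []
    for lib, m in models.items():
        row = {"library_id": lib, "converged": m.converged}
        for lab, mu, w in zip(labels, m.means, m.weights):
            row[f"mean_{lab}"] = mu
            row[f"weight_{lab}"] = w
        rows.append(row)
        if not m.converged:
            warnings.warn(f"mixture fit for library {lib!r} did not converge")
    return pd.DataFrame(rows)


def fraction_vs_genome_size(
    report: pd.DataFrame,
    library_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of each component weight with 2C genome size."""
    merged = report.merge(
        library_meta[["library_id", "genome_size_2c_mb"]], on="library_id"
    )
    if len(merged) < 4:
        raise ValueError("need at least 4 libraries")
    sizes = merged["genome_size_2c_mb"].to_numpy(dtype=float)
    rows = []
    for col in [c for c in report.columns if c.startswith("weight_")]:
        w = merged[col].to_numpy(dtype=float)
        if np.std(w) == 0 or np.std(sizes) == 0:
            rows.append((col.removeprefix("weight_"), np.nan, np.nan))
            continue
        r, p = stats.pearsonr(w, sizes)
        rows.append((col.removeprefix("weight_"), float(r), float(p)))
    return pd.DataFrame(rows, columns=["component", "r", "p"])
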