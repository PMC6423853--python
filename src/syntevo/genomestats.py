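"""Distributional and arithmetic genome statistics.

Covers the study's supporting numerics: G-tests of feature counts against a
chromosome-length expectation, sliding-window repeat-density profiles with
Monte-Carlo random-placement envelopes, density regressions and
correlations, sequencing coverage, gene density, assembly summary metrics
(N50/L50/GC) and flow-cytometry genome sizing.

Raw values are always retained; display helpers apply the reporting
conventions (rates to 2 significant figures, densities to 2 decimals, fold
coverage to the nearest integer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import RepeatRecord


# ---------------------------------------------------------------------------
# G-test of counts vs length expectation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p: float
    categories: tuple[str, ...]
    observed: tuple[float, ...]
    expected: tuple[float, ...]

    @property
    def deviations(self) -> tuple[float, ...]:
        """Observed minus expected per category."""
        return tuple(o - e for o, e in zip(self.observed, self.expected))


def g_test(
    observed, lengths, categories: tuple[str, ...] | None = None
) -> GTestResult:
    """Log-likelihood-ratio goodness-of-fit test of counts against the
    expectation proportional to chromosome length:

        G = 2 * sum_i O_i * ln(O_i / E_i),   E_i = (sum O) * L_i / (sum L)

    with natural logs; zero observed cells contribute 0. p is the chi-square
    upper tail with k-1 degrees of freedom."""
    O = np.asarray(observed, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if O.shape != L.shape or O.ndim != 1 or len(O) < 2:
        raise ValueError("observed and lengths must be 1-d arrays of equal length >= 2")
    if np.any(L <= 0):
        raise ValueError("all lengths must be positive")
    if np.any(O < 0) or O.sum() <= 0:
        raise ValueError("observed counts must be non-negative with a positive total")
    E = O.sum() * L / L.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    G = float(2.0 * terms.sum())
    df = len(O) - 1
    p = float(stats.chi2.sf(G, df))
    if categories is None:
        categories = tuple(f"cat{i + 1}" for i in range(len(O)))
    return GTestResult(G, df, p, tuple(categories), tuple(O), tuple(E))


# ---------------------------------------------------------------------------
# windowed repeat density and random-placement envelopes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowProfile:
    windows: tuple[tuple[int, int], ...]
    density: tuple[int, ...]
    env_low: tuple[float, ...] | None = None
    env_high: tuple[float, ...] | None = None

    @property
    def midpoints(self) -> tuple[float, ...]:
        return tuple((a + b) / 2 for a, b in self.windows)


def _window_starts(chrom_length: int, window: int, step: int) -> np.ndarray:
    if not 0 < step <= window:
        raise ValueError("need window >= step > 0")
    return np.arange(0, chrom_length, step, dtype=np.int64)


def window_density(
    repeats: list[RepeatRecord], chrom: str, chrom_length: int, window: int, step: int
) -> WindowProfile:
    """Repeat counts (by midpoint membership) in windows tiled centromere to
    telomere; the final windows may overhang the chromosome end."""
    starts = _window_starts(chrom_length, window, step)
    mids = np.sort([ (r.start + r.end) // 2 for r in repeats if r.chrom == chrom ])
    lo = np.searchsorted(mids, starts, side="left")
    hi = np.searchsorted(mids, starts + window, side="left")
    return WindowProfile(
        windows=tuple((int(s), int(s + window)) for s in starts),
        density=tuple(int(x) for x in hi - lo),
    )


def random_placement_envelope(
    n_repeats: int,
    chrom_length: int,
    window: int,
    step: int,
    B: int = 1000,
    seed: int = 0,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-window 2.5%/97.5% envelope of window counts over ``B`` uniform
    placements of ``n_repeats`` midpoints — the null profile if repeats were
    distributed at random."""
    if B < 100:
        raise ValueError("need B >= 100 replicates")
    starts = _window_starts(chrom_length, window, step)
    if n_repeats == 0:
        zeros = tuple(0.0 for _ in starts)
        return zeros, zeros
    rng = np.random.default_rng(seed)
    counts = np.empty((B, len(starts)), dtype=np.int64)
    for b in range(B):
        mids = np.sort(rng.random(n_repeats) * chrom_length)
        lo = np.searchsorted(mids, starts, side="left")
        hi = np.searchsorted(mids, starts + window, side="left")
        counts[b] = hi - lo
    low = np.percentile(counts, 2.5, axis=0)
    high = np.percentile(counts, 97.5, axis=0)
    return tuple(float(x) for x in low), tuple(float(x) for x in high)


def profile_with_envelope(
    repeats: list[RepeatRecord],
    chrom: str,
    chrom_length: int,
    window: int,
    step: int,
    B: int = 1000,
    seed: int = 0,
) -> WindowProfile:
    """Observed windowed density plus its random-placement envelope."""
    prof = window_density(repeats, chrom, chrom_length, window, step)
    n = sum(1 for r in repeats if r.chrom == chrom)
    low, high = random_placement_envelope(n, chrom_length, window, step, B=B, seed=seed)
    return WindowProfile(prof.windows, prof.density, low, high)


# ---------------------------------------------------------------------------
# regressions and correlations
# ---------------------------------------------------------------------------


def linreg_density(positions, densities) -> dict[str, float]:
    """Ordinary least squares of density on position: slope, intercept, r2
    and the two-sided t-test p for the slope."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(densities, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


def pearson(x, y) -> dict[str, float]:
    """Pearson correlation with its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


# ---------------------------------------------------------------------------
# arithmetic summaries
# ---------------------------------------------------------------------------


def coverage(total_bp: float, genome_size: float) -> float:
    """Fold coverage total_bp / genome_size (display: nearest integer,
    '~67-fold')."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if total_bp < 0:
        raise ValueError("total_bp must be non-negative")
    return total_bp / genome_size


def format_coverage(fold: float) -> str:
    return f"~{round(fold)}-fold"


def gene_density(assembly_length: float, n_genes: int) -> float:
    """One gene every N kb: assembly_length / n_genes in kb (display: 2
    decimals)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return assembly_length / n_genes / 1000.0


@dataclass(frozen=True)
class AssemblyStats:
    N50: int
    L50: int
    total_length: int
    n_scaffolds: int
    GC: float | None = None


def assembly_stats(scaffold_lengths, sequences=None) -> AssemblyStats:
    """N50 (length of the scaffold at which half the assembly is contained
    in scaffolds that size or larger) and L50 (that scaffold's rank), plus
    totals and GC over any provided sequences."""
    lengths = sorted((int(x) for x in scaffold_lengths), reverse=True)
    if not lengths or lengths[-1] <= 0:
        raise ValueError("scaffold lengths must be a non-empty list of positive values")
    total = sum(lengths)
    acc = 0
    for rank, L in enumerate(lengths, start=1):
        acc += L
        if 2 * acc >= total:
            n50, l50 = L, rank
            break
    gc = None
    if sequences is not None:
        at = gc_count = 0
        for s in sequences:
            s = s.upper()
            gc_count += s.count("G") + s.count("C")
            at += s.count("A") + s.count("T")
        denom = at + gc_count
        gc = gc_count / denom if denom else 0.0
    return AssemblyStats(N50=n50, L50=l50, total_length=total, n_scaffolds=len(lengths), GC=gc)


def flow_cytometry_size(gs_standard_mb: float, fluor_ratio: float) -> float:
    """Genome size from propidium-iodide flow cytometry: standard genome
    size times the target/standard fluorescence ratio (Mb, display 3
    decimals)."""
    if gs_standard_mb <= 0 or fluor_ratio <= 0:
        raise ValueError("standard size and fluorescence ratio must be positive")
    return gs_standard_mb * fluor_ratio
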