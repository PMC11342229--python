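"""Patterson's D on concatenated genes with gene-level bootstrap inference.

D = (nABBA - nBABA) / (nABBA + nBABA), computed on site totals summed
over genes (never a mean of per-gene D values). Uncertainty comes from
resampling *genes* with replacement: genes are the exchangeable unit
because sites within a gene share a genealogy. For each replicate the
concatenated D is recomputed; the 95% CI is the percentile interval of
the replicate distribution, Z = D / sd(replicates), and the one-tailed
p-value is the upper normal tail for the hypothesis D > 0 (gene flow in
the tested direction produces positive D only).

Replicates whose resample has zero informative sites cannot define D;
they are dropped and counted in ``n_failed_reps`` rather than redrawn,
so "n_reps" keeps its plain meaning.

All randomness flows from the single seed in :class:`BootstrapConfig`
through one numpy Generator; identical seeds give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .site_patterns import SitePatternCounts

_CHUNK = 256  # bootstrap replicates per vectorized block


class DStatError(Exception):
    pass


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 10_000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class DStatResult:
    direction: str
    d_hat: float
    ci_low: float
    ci_high: float
    boot_sd: float
    z: float
    p_one_tailed: float
    n_genes: int
    total_abba: int
    total_baba: int
    n_failed_reps: int
    n_reps: int
    seed: int
    flags: Tuple[str, ...] = ()
    p_holm: Optional[float] = None


@dataclass(frozen=True)
class CompareResult:
    """Paired-bootstrap comparison of two D estimates (Delta = D_a - D_b)."""

    delta_hat: float
    z: float
    p_one_tailed: float
    boot_sd: float
    n_genes: int
    n_failed_reps: int
    n_reps: int
    seed: int
    flags: Tuple[str, ...] = ()


def compute_D(total_abba: int, total_baba: int) -> float:
    """D = (nABBA - nBABA)/(nABBA + nBABA); error when both are zero."""
    if total_abba < 0 or total_baba < 0:
        raise ValueError("site totals must be non-negative")
    denom = total_abba + total_baba
    if denom == 0:
        raise DStatError("no informative sites (nABBA = nBABA = 0)")
    return (total_abba - total_baba) / denom


def concatenated_D(counts: Sequence[SitePatternCounts]) -> Tuple[float, int, int]:
    """Concatenated D over genes: totals summed, then one D."""
    counts = list(counts)
    if not counts:
        raise DStatError("empty gene list")
    directions = {c.direction for c in counts}
    if len(directions) != 1:
        raise DStatError(f"mixed directions: {sorted(directions)}")
    total_abba = sum(c.n_abba for c in counts)
    total_baba = sum(c.n_baba for c in counts)
    return compute_D(total_abba, total_baba), total_abba, total_baba


def z_to_p_one_tailed(z: float) -> float:
    """Upper-tail standard-normal probability (test of D > 0)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(stats.norm.sf(z))


def _replicate_D(
    abba: np.ndarray, baba: np.ndarray, n_reps: int, rng: np.random.Generator
) -> Tuple[np.ndarray, int]:
    """Gene-level bootstrap replicate D values (failed reps dropped).

    Resampling n genes with replacement is realized as multinomial
    resample weights, equivalent in distribution to index draws and
    vectorizable as a matrix product.
    """
    n = len(abba)
    pvals = np.full(n, 1.0 / n)
    reps: List[np.ndarray] = []
    n_failed = 0
    done = 0
    while done < n_reps:
        m = min(_CHUNK, n_reps - done)
        w = rng.multinomial(n, pvals, size=m)
        tot_a = w @ abba
        tot_b = w @ baba
        denom = tot_a + tot_b
        valid = denom > 0
        n_failed += int((~valid).sum())
        reps.append((tot_a[valid] - tot_b[valid]) / denom[valid])
        done += m
    return np.concatenate(reps), n_failed


def bootstrap_D(
    counts: Sequence[SitePatternCounts], cfg: BootstrapConfig
) -> DStatResult:
    """Point D plus gene-level bootstrap CI, Z and one-tailed p."""
    counts = list(counts)
    d_hat, total_abba, total_baba = concatenated_D(counts)
    direction = counts[0].direction
    abba = np.array([c.n_abba for c in counts], dtype=np.float64)
    baba = np.array([c.n_baba for c in counts], dtype=np.float64)

    rng = np.random.default_rng(cfg.seed)
    reps, n_failed = _replicate_D(abba, baba, cfg.n_reps, rng)

    flags: List[str] = []
    if n_failed:
        flags.append(f"failed_reps:{n_failed}")
    alpha = 1.0 - cfg.ci_level
    if reps.size == 0:
        flags.append("all_replicates_failed")
        ci_low = ci_high = boot_sd = z = p = float("nan")
    else:
        ci_low = float(np.percentile(reps, 100 * alpha / 2))
        ci_high = float(np.percentile(reps, 100 * (1 - alpha / 2)))
        if reps.size <= 1 or np.all(reps == reps[0]):
            boot_sd = 0.0  # degenerate resample (e.g. one gene)
        else:
            boot_sd = float(np.std(reps, ddof=1))
        if boot_sd > 0:
            z = d_hat / boot_sd
            p = z_to_p_one_tailed(z)
        else:
            z = p = float("nan")
            flags.append("z_undefined:boot_sd_zero")
        if not (ci_low <= d_hat <= ci_high):
            flags.append("d_hat_outside_ci")  # extreme bootstrap skew; reported
    return DStatResult(
        direction=direction,
        d_hat=d_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        boot_sd=boot_sd,
        z=z,
        p_one_tailed=p,
        n_genes=len(counts),
        total_abba=total_abba,
        total_baba=total_baba,
        n_failed_reps=n_failed,
        n_reps=cfg.n_reps,
        seed=cfg.seed,
        flags=tuple(flags),
    )


def bootstrap_replicates(
    counts: Sequence[SitePatternCounts], cfg: BootstrapConfig
) -> np.ndarray:
    """Raw replicate D values (for density plots); same stream as bootstrap_D."""
    counts = list(counts)
    abba = np.array([c.n_abba for c in counts], dtype=np.float64)
    baba = np.array([c.n_baba for c in counts], dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    reps, _ = _replicate_D(abba, baba, cfg.n_reps, rng)
    return reps


def compare_D(
    counts_a: Sequence[SitePatternCounts],
    counts_b: Sequence[SitePatternCounts],
    cfg: BootstrapConfig,
) -> CompareResult:
    """Paired gene-level bootstrap of Delta = D_a - D_b.

    The two series come from the same genes, so each replicate applies
    one resample of gene indices to both series (paired resampling).
    Requires equal length and matching gene order.
    """
    counts_a, counts_b = list(counts_a), list(counts_b)
    if not counts_a or not counts_b:
        raise DStatError("empty input")
    if len(counts_a) != len(counts_b):
        raise DStatError("paired comparison needs equal-length gene series")
    ids_a = [c.gene_id for c in counts_a]
    ids_b = [c.gene_id for c in counts_b]
    if ids_a != ids_b:
        raise DStatError("paired comparison needs matching gene ids/order")

    d_a, _, _ = concatenated_D(counts_a)
    d_b, _, _ = concatenated_D(counts_b)
    a_abba = np.array([c.n_abba for c in counts_a], dtype=np.float64)
    a_baba = np.array([c.n_baba for c in counts_a], dtype=np.float64)
    b_abba = np.array([c.n_abba for c in counts_b], dtype=np.float64)
    b_baba = np.array([c.n_baba for c in counts_b], dtype=np.float64)

    n = len(counts_a)
    pvals = np.full(n, 1.0 / n)
    rng = np.random.default_rng(cfg.seed)
    deltas: List[np.ndarray] = []
    n_failed = 0
    done = 0
    while done < cfg.n_reps:
        m = min(_CHUNK, cfg.n_reps - done)
        w = rng.multinomial(n, pvals, size=m)
        den_a = w @ (a_abba + a_baba)
        den_b = w @ (b_abba + b_baba)
        valid = (den_a > 0) & (den_b > 0)
        n_failed += int((~valid).sum())
        da = (w @ (a_abba - a_baba))[valid] / den_a[valid]
        db = (w @ (b_abba - b_baba))[valid] / den_b[valid]
        deltas.append(da - db)
        done += m
    delta = np.concatenate(deltas)

    flags: List[str] = []
    if n_failed:
        flags.append(f"failed_reps:{n_failed}")
    if delta.size == 0:
        flags.append("all_replicates_failed")
        sd = z = p = float("nan")
    else:
        if delta.size <= 1 or np.all(delta == delta[0]):
            sd = 0.0
        else:
            sd = float(np.std(delta, ddof=1))
        if sd > 0:
            z = float(np.mean(delta) / sd)
            p = z_to_p_one_tailed(z)
        else:
            z = p = float("nan")
            flags.append("z_undefined:sd_zero")
    return CompareResult(
        delta_hat=d_a - d_b,
        z=z,
        p_one_tailed=p,
        boot_sd=sd,
        n_genes=n,
        n_failed_reps=n_failed,
        n_reps=cfg.n_reps,
        seed=cfg.seed,
        flags=tuple(flags),
    )


def holm_adjust(pvalues: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])
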