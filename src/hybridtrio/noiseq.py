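"""No-replicate differential-expression probability via simulated replicates.

With one library per condition there is no empirical noise to estimate, so
technical replicates are simulated by multinomial resampling of each
observed library at a fraction of its depth. Within-condition replicate
pairs define an empirical noise cloud of (|M*|, D*) values pooled across
genes; a gene's between-condition signal (M, D) — signed log2 fold change
and absolute difference of normalized expression — is scored against the
cloud, giving the probability

    q = #{noise points with |M*| < |M| and D* < D} / #cloud

that the observed change exceeds noise in both coordinates. A gene is
called up (down) when M >= +lfc_threshold (<= -lfc_threshold) and
q > q_threshold; the package default thresholds are |M| >= 1 and q > 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import sample_rng
from .expression import ExpressionTable, NormFactors

#: spawn-key offset separating replicate-simulation streams from other uses
_REPLICATE_STREAM = 1000
_CLOUD_STREAM = 999


@dataclass
class NoiseParams:
    """Parameters of the replicate simulation and noise scoring.

    nss
        simulated technical replicates per condition (>= 2).
    pnr
        simulated library depth as a fraction of the observed depth.
    v
        relative variability of the simulated depth: replicate r has size
        round(N * pnr * (1 + u_r)) with u_r uniform on [-v, +v].
    k
        zero-replacement offset on the count scale; a normalized value of
        zero is replaced by the normalized equivalent of ``k`` before the
        log-ratio (never before the difference D).
    max_cloud
        noise clouds larger than this are uniformly subsampled (seeded)
        to bound memory.
    """

    nss: int = 5
    pnr: float = 0.2
    v: float = 0.02
    k: float = 0.5
    seed: int = 0
    max_cloud: int = 5_000_000

    def __post_init__(self) -> None:
        if self.nss < 2:
            raise ValueError("nss must be >= 2")
        if not 0 < self.pnr <= 1:
            raise ValueError("pnr must be in (0, 1]")
        if not 0 <= self.v < 1:
            raise ValueError("v must be in [0, 1)")
        if self.k <= 0:
            raise ValueError("k must be positive")


def simulate_replicates(
    sample_counts: np.ndarray, params: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial technical replicates of one library.

    Returns an (n_genes, nss) integer matrix; replicate r is a multinomial
    draw of size round(N * pnr * (1 + u_r)) with per-gene probabilities
    c_g / N, where N is the observed (rounded) library total.
    """
    counts = np.rint(np.asarray(sample_counts, dtype=float)).astype(np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("cannot simulate replicates of an all-zero sample")
    probs = counts / total
    u = rng.uniform(-params.v, params.v, size=params.nss)
    sizes = np.maximum(np.rint(total * params.pnr * (1.0 + u)).astype(np.int64), 1)
    reps = np.column_stack([rng.multinomial(s, probs) for s in sizes])
    return reps


def md_signal(x_a, x_b, k_a, k_b=None):
    """(M, D) between two expression vectors on a common normalized scale.

    Zeros are replaced by ``k_a`` / ``k_b`` (the normalized equivalent of
    the count-scale offset) before the log-ratio; D = |x_a - x_b| uses the
    unreplaced values. Returns (M, D) arrays (or scalars for scalar input).
    """
    xa = np.asarray(x_a, dtype=float)
    xb = np.asarray(x_b, dtype=float)
    if (xa < 0).any() or (xb < 0).any():
        raise ValueError("normalized expression must be non-negative")
    if k_b is None:
        k_b = k_a
    ra = np.where(xa == 0, k_a, xa)
    rb = np.where(xb == 0, k_b, xb)
    m = np.log2(ra / rb)
    d = np.abs(xa - xb)
    if np.isscalar(x_a) and np.isscalar(x_b):
        return float(m), float(d)
    return m, d


def noise_distribution(
    reps_a: np.ndarray,
    reps_b: np.ndarray,
    k_a: np.ndarray,
    k_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-condition noise cloud of (|M*|, D*).

    ``reps_a`` / ``reps_b`` are (n_genes, nss) matrices of *normalized*
    replicate expression; ``k_a`` / ``k_b`` give the per-replicate
    zero-replacement value on the same scale. Every unordered replicate
    pair within each condition contributes one (|M*|, D*) point per gene.
    """
    clouds_m, clouds_d = [], []
    for reps, ks in ((reps_a, k_a), (reps_b, k_b)):
        if reps.ndim != 2 or reps.shape[1] < 2:
            raise ValueError("need at least 2 replicates per condition")
        ks = np.broadcast_to(np.asarray(ks, dtype=float), (reps.shape[1],))
        nss = reps.shape[1]
        for i in range(nss):
            for j in range(i + 1, nss):
                m, d = md_signal(reps[:, i], reps[:, j], ks[i], ks[j])
                clouds_m.append(np.abs(m))
                clouds_d.append(d)
    return np.concatenate(clouds_m), np.concatenate(clouds_d)


def de_probability(
    signal_m, signal_d, cloud_m: np.ndarray, cloud_d: np.ndarray, chunk: int = 512
):
    """Empirical probability that a signal exceeds the noise cloud.

    q = #{|M*| < |M| and D* < D} / #cloud with strict inequalities, so
    ties count against significance. Accepts scalars or vectors of
    signals; the cloud is given as parallel |M*| and D* arrays.
    """
    if cloud_m.size == 0:
        raise ValueError("noise cloud is empty")
    scalar = np.isscalar(signal_m) and np.isscalar(signal_d)
    m = np.abs(np.atleast_1d(np.asarray(signal_m, dtype=float)))
    d = np.atleast_1d(np.asarray(signal_d, dtype=float))
    q = np.empty(m.size)
    size = cloud_m.size
    for i in range(0, m.size, chunk):
        mm = m[i : i + chunk, None]
        dd = d[i : i + chunk, None]
        q[i : i + chunk] = (
            ((cloud_m[None, :] < mm) & (cloud_d[None, :] < dd)).sum(axis=1) / size
        )
    return float(q[0]) if scalar else q


def _resolve_sample(table: ExpressionTable, name_or_role: str) -> str:
    if name_or_role in table.counts.columns:
        return name_or_role
    return table.sample_for_role(name_or_role)


def run_contrast(
    table: ExpressionTable,
    role_a: str,
    role_b: str,
    norm: NormFactors,
    params: NoiseParams | None = None,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.9,
    signal: str = "replicate_mean",
) -> pd.DataFrame:
    """Score one pairwise contrast (condition A over condition B).

    Simulates ``params.nss`` technical replicates per condition, puts
    signal and replicates on the same TMM-scaled per-million scale, takes
    the per-gene signal between condition means of the replicates (or the
    raw observed samples with ``signal='observed'``), scores it against
    the pooled within-condition noise cloud and applies the DEG rule.

    Returns a DataFrame indexed by gene_id with columns x_A, x_B, M, D,
    q, call. Replicate streams are keyed by sample identity, so swapping
    A and B flips the sign of M and leaves q unchanged.
    """
    params = params or NoiseParams()
    sample_a = _resolve_sample(table, role_a)
    sample_b = _resolve_sample(table, role_b)
    cols = list(table.counts.columns)

    per_side = {}
    for s in (sample_a, sample_b):
        col = cols.index(s)
        rng = sample_rng(params.seed, _REPLICATE_STREAM + col)
        reps = simulate_replicates(table.counts[s].to_numpy(), params, rng)
        totals = reps.sum(axis=0).astype(float)
        f = float(norm.factors[s])
        x_reps = reps / (totals * f) * 1e6
        k_reps = params.k / (totals * f) * 1e6
        if signal == "replicate_mean":
            x_sig = x_reps.mean(axis=1)
            k_sig = params.k / (totals.mean() * f) * 1e6
        elif signal == "observed":
            eff = float(norm.effective_sizes[s])
            x_sig = table.counts[s].to_numpy() / eff * 1e6
            k_sig = params.k / eff * 1e6
        else:
            raise ValueError("signal must be 'replicate_mean' or 'observed'")
        per_side[s] = (col, x_reps, k_reps, x_sig, k_sig)

    col_a, reps_a, k_a, x_a, ks_a = per_side[sample_a]
    col_b, reps_b, k_b, x_b, ks_b = per_side[sample_b]
    m, d = md_signal(x_a, x_b, ks_a, ks_b)

    # pool the cloud in canonical (column-index) order so that (A,B) and
    # (B,A) see the identical cloud even after subsampling
    if col_a <= col_b:
        cloud_m, cloud_d = noise_distribution(reps_a, reps_b, k_a, k_b)
    else:
        cloud_m, cloud_d = noise_distribution(reps_b, reps_a, k_b, k_a)
    if cloud_m.size > params.max_cloud:
        rng = sample_rng(params.seed, _CLOUD_STREAM)
        idx = rng.choice(cloud_m.size, size=params.max_cloud, replace=False)
        cloud_m, cloud_d = cloud_m[idx], cloud_d[idx]

    q = de_probability(m, d, cloud_m, cloud_d)
    call = np.where(
        (m >= lfc_threshold) & (q > q_threshold),
        "up",
        np.where((m <= -lfc_threshold) & (q > q_threshold), "down", "non"),
    )
    out = pd.DataFrame(
        {"x_A": x_a, "x_B": x_b, "M": m, "D": d, "q": q, "call": call},
        index=table.counts.index,
    )
    out.attrs["sample_A"] = sample_a
    out.attrs["sample_B"] = sample_b
    out.attrs["lfc_threshold"] = lfc_threshold
    out.attrs["q_threshold"] = q_threshold
    return out


def md_plot_table(contrast: pd.DataFrame) -> pd.DataFrame:
    """MD-plot export: M, D, q plus a significance flag per gene."""
    out = contrast[["M", "D", "q"]].copy()
    out["significant"] = (contrast["call"] != "non").astype(int)
    return out
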