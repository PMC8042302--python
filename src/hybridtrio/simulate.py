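"""Synthetic hybrid-trio count tables with planted inheritance modes.

The generator emulates the statistical structure of single-sample-per-
condition RSEM gene-level output for a trio (parent1, parent2, hybrid):
log-normal baseline expression, a planted parental log2 fold change for
non-conserved genes, hybrid means placed according to the planted
inheritance mode, negative-binomial sampling noise with dispersion phi
(variance = mu + phi mu^2), unequal library sizes and per-gene lengths.

Modes and their mean profiles (log2 scale, b = baseline, L = parental_lfc,
d = dominance_delta; the higher parent is drawn 50/50):

========================  =================================================
conserved                 P1 = P2 = H = b
additive                  parents at b +/- L/2, H at the log2 midpoint b
dominant_P1               parents at b +/- L/2, H = P1
dominant_P2               parents at b +/- L/2, H = P2
over_dominant             H = max(P1, P2) + d
under_dominant            H = min(P1, P2) - d
========================  =================================================
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import sample_rng
from .expression import ExpressionTable, compute_tpm

MODES = (
    "conserved",
    "additive",
    "dominant_P1",
    "dominant_P2",
    "over_dominant",
    "under_dominant",
)

#: default trio sample names, in fixed column order
DEFAULT_SAMPLES = ("parent1", "parent2", "hybrid")

_ROLE_OF = {"parent1": "parent1", "parent2": "parent2", "hybrid": "hybrid"}


@dataclass
class SimConfig:
    """Parameters of the synthetic trio generator.

    Defaults are the package's reference recovery scenario: 5,000 genes,
    70% conserved and 6% of each other mode, a 2 log2-unit parental fold
    change, a 2 log2-unit dominance shift, NB dispersion 0.05 and three
    5-million-read libraries.
    """

    n_genes: int = 5000
    mode_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "conserved": 0.70,
            "additive": 0.06,
            "dominant_P1": 0.06,
            "dominant_P2": 0.06,
            "over_dominant": 0.06,
            "under_dominant": 0.06,
        }
    )
    base_mean_log2: float = 5.0
    base_sd_log2: float = 2.0
    parental_lfc: float = 2.0
    dominance_delta: float = 2.0
    dispersion: float = 0.05
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {s: 5_000_000 for s in DEFAULT_SAMPLES}
    )
    gene_length_range: tuple[int, int] = (500, 5000)
    orf_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        unknown = set(self.mode_proportions) - set(MODES)
        if unknown:
            raise ValueError(f"unknown inheritance modes: {sorted(unknown)}")
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.mode_proportions.values()):
            raise ValueError("mode proportions must be non-negative")
        if self.parental_lfc <= 0 or self.dominance_delta <= 0:
            raise ValueError("parental_lfc and dominance_delta must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(n <= 0 for n in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be positive and ordered")
        if not 0.0 <= self.orf_fraction <= 1.0:
            raise ValueError("orf_fraction must be in [0, 1]")


def assign_modes(config: SimConfig) -> pd.DataFrame:
    """Draw per-gene inheritance modes and expected mean profiles.

    Returns the truth table: gene_id (index), true_mode, mu_P1, mu_P2,
    mu_H (linear scale, arbitrary units), length_bp, has_orf. The mean
    profiles satisfy the mode definitions exactly; the identity of the
    higher parent is drawn 50/50 per non-conserved gene.
    """
    rng = sample_rng(config.seed, 0)
    n = config.n_genes
    labels = list(config.mode_proportions)
    probs = np.array([config.mode_proportions[m] for m in labels])
    modes = rng.choice(labels, size=n, p=probs / probs.sum())

    base = rng.normal(config.base_mean_log2, config.base_sd_log2, n)
    p1_high = rng.random(n) < 0.5
    half = config.parental_lfc / 2.0

    log_p1 = np.where(p1_high, base + half, base - half)
    log_p2 = np.where(p1_high, base - half, base + half)
    conserved = modes == "conserved"
    log_p1[conserved] = base[conserved]
    log_p2[conserved] = base[conserved]

    log_h = np.empty(n)
    log_h[conserved] = base[conserved]
    log_h[modes == "additive"] = base[modes == "additive"]
    log_h[modes == "dominant_P1"] = log_p1[modes == "dominant_P1"]
    log_h[modes == "dominant_P2"] = log_p2[modes == "dominant_P2"]
    over = modes == "over_dominant"
    log_h[over] = np.maximum(log_p1, log_p2)[over] + config.dominance_delta
    under = modes == "under_dominant"
    log_h[under] = np.minimum(log_p1, log_p2)[under] - config.dominance_delta

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    orf = rng.random(n) < config.orf_fraction

    ids = [f"gene{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "true_mode": modes,
            "mu_P1": 2.0 ** log_p1,
            "mu_P2": 2.0 ** log_p2,
            "mu_H": 2.0 ** log_h,
            "length_bp": lengths,
            "has_orf": orf,
        },
        index=pd.Index(ids, name="gene_id"),
    )


def simulate_counts(truth: pd.DataFrame, config: SimConfig) -> ExpressionTable:
    """Draw negative-binomial counts for the trio from a truth table.

    The count of gene g in sample s is NB with mean
    mu_gs * library_size_s / sum_g mu_gs and variance mu + phi mu^2;
    dispersion below 1e-8 falls back to Poisson. Each sample uses its own
    seed stream so results do not depend on simulation order.
    """
    if len(truth) != config.n_genes:
        raise ValueError("truth table and config disagree on n_genes")
    mu_cols = {"parent1": "mu_P1", "parent2": "mu_P2", "hybrid": "mu_H"}
    counts = {}
    for j, (sample, lib) in enumerate(config.library_sizes.items()):
        role = _ROLE_OF.get(sample, sample)
        if role not in mu_cols:
            raise ValueError(f"cannot map sample {sample!r} to a trio role")
        mu = truth[mu_cols[role]].to_numpy(dtype=float)
        mean = mu * (lib / mu.sum())
        rng = sample_rng(config.seed, j + 1)
        if config.dispersion < 1e-8:
            counts[sample] = rng.poisson(mean)
        else:
            r = 1.0 / config.dispersion
            counts[sample] = rng.negative_binomial(r, r / (r + mean))
    count_df = pd.DataFrame(counts, index=truth.index, dtype=float)
    return ExpressionTable(
        counts=count_df,
        lengths_bp=truth["length_bp"],
        has_orf=truth["has_orf"],
        sample_roles={s: _ROLE_OF[s] for s in config.library_sizes},
    )


def write_rsem_like(
    table: ExpressionTable, truth: pd.DataFrame | None, directory: str | os.PathLike
) -> dict[str, str]:
    """Write one RSEM-like TSV per sample, plus truth.tsv and orf_ids.txt.

    Sample files carry gene_id, length, expected_count, TPM (counts with
    two fixed decimals, never scientific notation). Returns a manifest of
    written paths. Reading the files back reproduces the counts exactly.
    """
    os.makedirs(directory, exist_ok=True)
    tpm = compute_tpm(table.counts, table.lengths_bp)
    written = {}
    for sample in table.samples:
        df = pd.DataFrame(
            {
                "gene_id": table.counts.index,
                "length": table.lengths_bp.to_numpy(),
                "expected_count": [f"{c:.2f}" for c in table.counts[sample]],
                "TPM": [f"{t:.6f}" for t in tpm[sample]],
            }
        )
        path = os.path.join(directory, f"{sample}.genes.results")
        df.to_csv(path, sep="\t", index=False)
        written[sample] = path
    orf_path = os.path.join(directory, "orf_ids.txt")
    with open(orf_path, "w") as fh:
        for gid in table.counts.index[table.has_orf.to_numpy(dtype=bool)]:
            fh.write(f"{gid}\n")
    written["orf_ids"] = orf_path
    if truth is not None:
        truth_path = os.path.join(directory, "truth.tsv")
        truth.reset_index()[["gene_id", "true_mode", "mu_P1", "mu_P2", "mu_H"]].to_csv(
            truth_path, sep="\t", index=False
        )
        written["truth"] = truth_path
    return written


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def simulate_trio(config: SimConfig) -> tuple[ExpressionTable, pd.DataFrame]:
    """Convenience wrapper: assign modes, then draw counts."""
    truth = assign_modes(config)
    return simulate_counts(truth, config), truth


def evaluate_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion matrix and per-mode recall of classifier calls vs truth.

    ``calls`` needs a ``primary_label`` column indexed by gene_id (the
    classifier output); genes absent from ``calls`` or without any label
    count in the ``unclassified`` column. Two recall variants are
    reported: ``recall`` on the primary label (matches the confusion
    matrix) and, when a ``labels`` column is present, ``recall_label`` by
    label-set membership — a gene of true mode m counts as recovered when
    m appears anywhere in its label set, reflecting that the categories
    are not a partition. Accuracy is the confusion-matrix trace over the
    full truth total.
    """
    if not set(truth.index).issubset(set(calls.index)) and not set(
        calls.index
    ).issubset(set(truth.index)):
        raise ValueError("calls and truth gene sets do not overlap consistently")
    pred = calls["primary_label"].reindex(truth.index).fillna("unclassified")
    cols = list(MODES) + ["unclassified"]
    pred = pred.where(pred.isin(cols), "unclassified")
    confusion = (
        pd.crosstab(truth["true_mode"], pred)
        .reindex(index=list(MODES), columns=cols)
        .fillna(0)
        .astype(int)
    )
    diag = sum(confusion.loc[m, m] for m in MODES if m in confusion.index)
    total = int(confusion.to_numpy().sum())
    recall = {}
    for m in MODES:
        row = confusion.loc[m]
        recall[m] = float(row[m] / row.sum()) if row.sum() > 0 else float("nan")
    report = {
        "confusion": confusion,
        "accuracy": diag / total if total else float("nan"),
        "recall": recall,
        "n_genes": total,
    }
    if "labels" in calls.columns:
        label_sets = (
            calls["labels"].reindex(truth.index).fillna("").str.split(",")
        )
        recall_label = {}
        for m in MODES:
            mask = truth["true_mode"] == m
            if mask.any():
                recall_label[m] = float(
                    label_sets[mask].apply(lambda labs, m=m: m in labs).mean()
                )
            else:
                recall_label[m] = float("nan")
        report["recall_label"] = recall_label
    return report
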