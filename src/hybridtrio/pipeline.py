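"""End-to-end trio analysis: filter -> TMM -> three contrasts -> classify.

`run_trio` is the library entry point; `run_to_dir` additionally writes
the standard output set (contrast TSVs, MD-plot data, calls table,
summary JSON, provenance) that the command-line interface exposes.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .expression import (
    ExpressionTable,
    compute_tpm,
    filter_expressed,
    normalized_expression,
    tmm_factors,
)
from .inheritance import (
    TrioContrasts,
    classify_trio,
    summarize_inheritance,
    summarize_pairwise,
)
from .noiseq import NoiseParams, md_plot_table, run_contrast

CONTRAST_NAMES = ("HvP1", "HvP2", "P1vP2")


@dataclass
class TrioResult:
    """Everything `run_trio` computes for one trio."""

    table: ExpressionTable            # expressed genes only
    kept_genes: pd.Index
    norm: "object"                    # NormFactors
    normalized: pd.DataFrame          # per-million, expressed genes
    contrasts: dict[str, pd.DataFrame]
    calls: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_trio(
    table: ExpressionTable,
    params: NoiseParams | None = None,
    min_tpm: float = 1.0,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.9,
    tpm_require: str = "any",
) -> TrioResult:
    """Run the full inheritance analysis on one hybrid trio.

    TPM is recomputed from counts and lengths; genes pass the expressed
    filter with an ORF and TPM >= min_tpm; TMM factors are computed on the
    expressed matrix; the three contrasts (hybrid vs each parent, parent1
    vs parent2) are scored and the six-way classification applied.
    """
    params = params or NoiseParams()
    tpm = compute_tpm(table.counts, table.lengths_bp)
    expressed, kept = filter_expressed(table, tpm, min_tpm=min_tpm, require=tpm_require)
    if expressed.n_genes == 0:
        raise ValueError("no gene passes the expressed filter")
    norm = tmm_factors(expressed.counts)
    x = normalized_expression(expressed.counts, norm)

    pairs = {
        "HvP1": ("hybrid", "parent1"),
        "HvP2": ("hybrid", "parent2"),
        "P1vP2": ("parent1", "parent2"),
    }
    contrasts = {
        name: run_contrast(
            expressed, a, b, norm, params,
            lfc_threshold=lfc_threshold, q_threshold=q_threshold,
        )
        for name, (a, b) in pairs.items()
    }

    x_roles = pd.DataFrame(
        {role: x[expressed.sample_for_role(role)] for role in ("hybrid", "parent1", "parent2")}
    )
    trio = TrioContrasts(
        hvp1=contrasts["HvP1"], hvp2=contrasts["HvP2"],
        p1vp2=contrasts["P1vP2"], x=x_roles,
    )
    calls = classify_trio(trio)

    total = expressed.n_genes
    summary = {
        "n_genes_input": table.n_genes,
        "n_genes_expressed": total,
        "thresholds": {
            "min_tpm": min_tpm,
            "lfc_threshold": lfc_threshold,
            "q_threshold": q_threshold,
        },
        "noise_params": asdict(params),
        "tmm_factors": {s: float(v) for s, v in norm.factors.items()},
        "pairwise": {
            name: summarize_pairwise(contrasts[name], total) for name in CONTRAST_NAMES
        },
        "inheritance": summarize_inheritance(calls),
    }
    return TrioResult(
        table=expressed, kept_genes=kept, norm=norm, normalized=x,
        contrasts=contrasts, calls=calls, summary=summary,
    )


def run_to_dir(
    table: ExpressionTable,
    out_dir: str | os.PathLike,
    params: NoiseParams | None = None,
    **kwargs,
) -> TrioResult:
    """`run_trio` plus the standard on-disk output set.

    Writes contrast_<name>.tsv, mdplot_<name>.tsv, calls.tsv,
    summary.json and provenance.json into ``out_dir`` and records the
    manifest in ``result.summary['outputs']``.
    """
    result = run_trio(table, params=params, **kwargs)
    os.makedirs(out_dir, exist_ok=True)
    outputs = {}
    for name, contrast in result.contrasts.items():
        path = os.path.join(out_dir, f"contrast_{name}.tsv")
        contrast.rename_axis("gene_id").to_csv(path, sep="\t")
        outputs[f"contrast_{name}"] = path
        md_path = os.path.join(out_dir, f"mdplot_{name}.tsv")
        md_plot_table(contrast).rename_axis("gene_id").to_csv(md_path, sep="\t")
        outputs[f"mdplot_{name}"] = md_path
    calls_path = os.path.join(out_dir, "calls.tsv")
    result.calls.rename_axis("gene_id").to_csv(calls_path, sep="\t")
    outputs["calls"] = calls_path

    summary_path = os.path.join(out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["summary"] = summary_path

    prov_path = os.path.join(out_dir, "provenance.json")
    with open(prov_path, "w") as fh:
        json.dump(
            {
                "tool": "hybridtrio",
                "version": __version__,
                "thresholds": result.summary["thresholds"],
                "noise_params": result.summary["noise_params"],
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    outputs["provenance"] = prov_path

    for path in outputs.values():
        if not os.path.exists(path) or os.path.getsize(path) == 0:
            raise RuntimeError(f"declared output missing or empty: {path}")
    result.summary["outputs"] = outputs
    return result
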