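"""Relative RT-qPCR quantification by the 2^-ddCt method.

Expression of a target gene is measured in PCR cycles to threshold (Ct)
alongside an endogenous control gene; dCt = Ct_target - Ct_control removes
loading differences, ddCt = dCt_sample - dCt_calibrator references a chosen
calibrator sample, and fold change = 2^-ddCt (log2 fold = -ddCt). Technical
replicates are averaged within each biological replicate, dCt is formed per
biological replicate, and ddCt averages over biological replicates. No
amplification-efficiency correction is applied.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

CT_COLUMNS = ("gene_id", "sample_id", "role", "bio_rep", "tech_rep", "Ct")


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Long-format Ct table: gene_id, sample_id, role, bio_rep, tech_rep, Ct."""
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return validate_ct_table(df)


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    if (ct["Ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    bad = set(ct["role"]) - {"target", "endogenous_control"}
    if bad:
        raise ValueError(f"unknown roles {sorted(bad)}")
    return ct


def _mean_dct_per_sample(ct: pd.DataFrame, target_gene: str) -> pd.Series:
    """Mean dCt per sample: technical reps averaged within biological reps,
    dCt per biological rep, then averaged over biological reps."""
    tech_mean = (
        ct.groupby(["sample_id", "role", "gene_id", "bio_rep"])["Ct"]
        .mean()
        .reset_index()
    )
    out = {}
    for sample, sub in tech_mean.groupby("sample_id"):
        tgt = sub[(sub["role"] == "target") & (sub["gene_id"] == target_gene)]
        ctl = sub[sub["role"] == "endogenous_control"]
        if tgt.empty:
            raise ValueError(f"no target Ct for gene {target_gene!r} in sample {sample!r}")
        if ctl.empty:
            raise ValueError(f"no endogenous-control Ct in sample {sample!r}")
        tgt_by_rep = tgt.set_index("bio_rep")["Ct"]
        ctl_by_rep = ctl.groupby("bio_rep")["Ct"].mean()
        common = tgt_by_rep.index.intersection(ctl_by_rep.index)
        if len(common) == 0:
            raise ValueError(
                f"no biological replicate with both target and control in sample {sample!r}"
            )
        out[sample] = float((tgt_by_rep.loc[common] - ctl_by_rep.loc[common]).mean())
    return pd.Series(out, name="dCt")


def delta_delta_ct(
    ct: pd.DataFrame, target_gene: str, calibrator_sample: str
) -> pd.DataFrame:
    """Per-sample fold change of ``target_gene`` relative to the calibrator.

    Returns a DataFrame indexed by sample with columns dCt, ddCt, fold
    (= 2^-ddCt) and log2_fold (= -ddCt). The calibrator's fold is exactly 1.
    """
    validate_ct_table(ct)
    dct = _mean_dct_per_sample(ct[ct["gene_id"].isin([target_gene]) | (ct["role"] == "endogenous_control")], target_gene)
    if calibrator_sample not in dct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in Ct table")
    ddct = dct - dct[calibrator_sample]
    return pd.DataFrame(
        {
            "dCt": dct,
            "ddCt": ddct,
            "fold": 2.0 ** (-ddct),
            "log2_fold": -ddct,
        }
    )


def compare_to_wts(
    qpcr_log2fc: pd.Series, contrast: pd.DataFrame, genes=None
) -> tuple[pd.DataFrame, float]:
    """Sign agreement between qPCR log2 fold changes and sequencing M values.

    ``qpcr_log2fc`` is indexed by gene_id; ``contrast`` is a contrast
    table with an M column. Returns the per-gene table (both log2 fold
    changes, both signs, agree flag) and the fraction agreeing.
    """
    if genes is None:
        genes = [g for g in qpcr_log2fc.index if g in contrast.index]
    rows = []
    for g in genes:
        lq = float(qpcr_log2fc[g])
        lw = float(contrast.loc[g, "M"])
        rows.append(
            {
                "gene_id": g,
                "qpcr_log2fc": lq,
                "wts_log2fc": lw,
                "qpcr_sign": int(np.sign(lq)),
                "wts_sign": int(np.sign(lw)),
                "agree": np.sign(lq) == np.sign(lw),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    fraction = float(table["agree"].mean()) if len(table) else float("nan")
    return table, fraction
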