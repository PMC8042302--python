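"""Expression-matrix data model, TPM, the expressed-gene filter and TMM.

The central container is :class:`ExpressionTable`: a genes x samples matrix
of raw RSEM-style expected counts (non-integers allowed) together with
per-gene lengths, per-gene ORF flags, and a mapping of samples to trio
roles (``hybrid`` / ``parent1`` / ``parent2``).

Normalization follows the trimmed-mean-of-M-values (TMM) procedure of
Robinson & Oshlack as implemented canonically in edgeR: per-gene log-ratios
(M) and average log-abundances (A) against a reference sample, double
trimming (30% on M, 5% on A), and an inverse-binomial-variance weighted
mean of the surviving M values. Factors are re-centred to geometric mean 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

ROLES = ("hybrid", "parent1", "parent2")


@dataclass
class ExpressionTable:
    """Gene-level expression for a set of samples.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative expected counts; the
        index holds unique gene ids.
    lengths_bp
        Per-gene length in bp (positive), aligned to ``counts.index``.
    has_orf
        Per-gene boolean flag: gene carries a potential open reading frame.
    sample_roles
        Maps sample name -> role in the trio. At most one sample per role.
    """

    counts: pd.DataFrame
    lengths_bp: pd.Series
    has_orf: pd.Series
    sample_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.lengths_bp = self.lengths_bp.reindex(self.counts.index)
        self.has_orf = self.has_orf.reindex(self.counts.index)
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lengths_bp.isna().any() or (self.lengths_bp <= 0).any():
            raise ValueError("every gene needs a positive length")
        for sample, role in self.sample_roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for sample {sample!r}")
            if sample not in self.counts.columns:
                raise ValueError(f"sample {sample!r} not in counts")
        roles = list(self.sample_roles.values())
        for r in set(roles):
            if roles.count(r) > 1:
                raise ValueError(f"role {r!r} assigned to more than one sample")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample_for_role(self, role: str) -> str:
        for sample, r in self.sample_roles.items():
            if r == role:
                return sample
        raise KeyError(f"no sample with role {role!r}")

    def subset(self, gene_ids) -> "ExpressionTable":
        """Restrict to ``gene_ids`` (order preserved)."""
        return ExpressionTable(
            counts=self.counts.loc[gene_ids],
            lengths_bp=self.lengths_bp.loc[gene_ids],
            has_orf=self.has_orf.loc[gene_ids],
            sample_roles=dict(self.sample_roles),
        )


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and library sizes."""

    factors: pd.Series       # f_s, geometric mean 1
    lib_sizes: pd.Series     # N_s, raw column totals

    @property
    def effective_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


# ---------------------------------------------------------------------------
# TPM and filtering
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Transcripts per million from counts and gene lengths.

    TPM_gs = 1e6 * (c_gs / l_g) / sum_g'(c_g's / l_g'); every column with
    any signal sums to 1e6; an all-zero column stays all-zero.
    """
    lengths = lengths_bp.reindex(counts.index).to_numpy(dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive and finite")
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    colsum = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(colsum > 0, 1e6 * rate / colsum, 0.0)
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def filter_expressed(
    table: ExpressionTable,
    tpm: pd.DataFrame,
    min_tpm: float = 1.0,
    require: str = "any",
) -> tuple[ExpressionTable, pd.Index]:
    """Keep genes with an ORF and TPM >= ``min_tpm`` (boundary inclusive).

    ``require='any'`` demands the TPM threshold in at least one sample of
    the trio (the default, least destructive reading of a "minimum one
    TPM" filter); ``require='all'`` demands it in every sample.
    """
    if require not in ("any", "all"):
        raise ValueError("require must be 'any' or 'all'")
    tpm = tpm.reindex(index=table.counts.index, columns=table.counts.columns)
    above = tpm.to_numpy() >= min_tpm
    hit = above.any(axis=1) if require == "any" else above.all(axis=1)
    keep = table.has_orf.to_numpy(dtype=bool) & hit
    kept = table.counts.index[keep]
    return table.subset(kept), kept


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_one(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    a_floor: float,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_floor)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0:
        raise ValueError("no genes with positive counts in both samples")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    A_floor: float = -1e10,
    lib_sizes: pd.Series | None = None,
) -> NormFactors:
    """TMM scaling factors for every sample of ``counts``.

    The reference sample, when not given, is the one whose 75th-percentile
    count-to-library-size ratio is closest to the mean of those ratios
    across samples (ties broken by column order). Factors are re-centred
    so their geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    if lib_sizes is None:
        lib = x.sum(axis=0)
    else:
        lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")

    if ref_sample is None:
        f75 = np.quantile(x, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            factors[j] = _tmm_one(
                x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_M, trim_A, A_floor
            )
            continue
        both = (x[:, j] > 0) & (x[:, ref_idx] > 0)
        if not both.any():
            raise ValueError(
                f"samples {counts.columns[j]!r} and {counts.columns[ref_idx]!r} "
                "share no gene with positive counts"
            )
        factors[j] = _tmm_one(
            x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_M, trim_A, A_floor
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=counts.columns, name="lib_size"),
    )


def normalized_expression(counts: pd.DataFrame, factors: NormFactors) -> pd.DataFrame:
    """Counts per effectively-normalized million: c_gs / (N_s f_s) * 1e6."""
    eff = factors.effective_sizes.reindex(counts.columns).to_numpy(dtype=float)
    return counts / eff * 1e6


# ---------------------------------------------------------------------------
# I/O: RSEM-like tables and design files
# ---------------------------------------------------------------------------

def read_rsem_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an RSEM ``*.genes.results``-like TSV.

    Requires columns ``gene_id``, ``length``, ``expected_count``, ``TPM``;
    extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "length", "expected_count", "TPM"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index("gene_id")[["length", "expected_count", "TPM"]]


def read_design(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column design file: sample_path <tab> role.

    Roles must cover hybrid, parent1 and parent2 exactly once each.
    """
    design = pd.read_csv(
        path, sep="\t", header=None, names=["sample_path", "role"], comment="#"
    )
    roles = list(design["role"])
    if sorted(roles) != sorted(ROLES):
        raise ValueError(
            f"design must assign each of {ROLES} exactly once, got {roles}"
        )
    return dict(zip(design["sample_path"], design["role"]))


def load_trio(
    design: dict[str, str],
    orf_ids: set[str] | None = None,
    base_dir: str | os.PathLike | None = None,
) -> ExpressionTable:
    """Assemble an :class:`ExpressionTable` from per-sample RSEM-like files.

    ``design`` maps file path -> role. Sample names are the file basenames
    without extension. ``orf_ids`` optionally restricts the ORF flag; by
    default every gene is flagged as ORF-bearing.
    """
    counts, lengths, roles = {}, None, {}
    for path, role in design.items():
        full = os.path.join(base_dir, path) if base_dir else path
        if not os.path.exists(full):
            raise FileNotFoundError(f"sample table not found: {full}")
        df = read_rsem_table(full)
        name = os.path.splitext(os.path.basename(str(path)))[0]
        if name.endswith(".genes"):
            name = name[: -len(".genes")]
        counts[name] = df["expected_count"]
        roles[name] = role
        if lengths is None:
            lengths = df["length"].rename("length_bp")
        elif not lengths.index.equals(df.index):
            raise ValueError(f"gene ids in {full} do not match the other samples")
    count_df = pd.DataFrame(counts)
    if orf_ids is None:
        orf = pd.Series(True, index=count_df.index, name="has_orf")
    else:
        orf = pd.Series(count_df.index.isin(sorted(orf_ids)), index=count_df.index, name="has_orf")
    return ExpressionTable(
        counts=count_df,
        lengths_bp=lengths.astype(int),
        has_orf=orf,
        sample_roles=roles,
    )
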