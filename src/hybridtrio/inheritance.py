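"""Six-way inheritance-mode classification of hybrid gene expression.

Given the three pairwise DE calls of a trio — hybrid vs parent1 (HvP1),
hybrid vs parent2 (HvP2) and parent1 vs parent2 (P1vP2) — plus normalized
expression levels, each gene is assigned a *set* of inheritance labels:

conserved       no DE anywhere in the trio
over_dominant   hybrid significantly above both parents (up, up), or up
                vs one parent with x_H at least lfc log2 units above both
under_dominant  symmetric below
additive        parents differ, hybrid strictly between them on the
                normalized scale, and hybrid DE vs at least one parent
dominant_P1     hybrid at the parent1 level (no DE vs parent1 and within
                lfc log2 units of it) but DE vs parent2, with the parents
                themselves DE (dominant_P2 symmetric)

Expression levels matter because with one library per condition the three
calls alone cannot separate the patterns: an additive gene whose hybrid
drifts toward one parent and a parent-dominant gene whose hybrid drifts
toward the midpoint produce the same call pattern, and a strongly
under-dominant gene at moderate expression can lose one ``down`` call to
the D/q criterion while matching the parental-dominance pattern. Where
the calls are ambiguous, the hybrid's position on the log2 scale decides:
the nearest of the three archetype levels (parent1, parental midpoint,
parent2) — see `classify_gene` and the methods note.

The categories are not a strict partition (a gene can, e.g., satisfy both
additive and a parental-dominance rule), so labels form a set; a single
``primary_label`` is reported with precedence conserved > over_dominant >
under_dominant, then additive vs parental dominance resolved by the
nearest archetype. Genes matching no rule are flagged unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._utils import int_percent

CALLS = ("up", "down", "non")

PRECEDENCE = (
    "conserved",
    "over_dominant",
    "under_dominant",
    "additive",
    "dominant_P1",
    "dominant_P2",
)

#: floor (normalized per-million scale) applied before log2 position math
_POSITION_FLOOR = 1e-3


def _log2pos(x: float) -> float:
    return math.log2(max(float(x), _POSITION_FLOOR))


@dataclass
class TrioContrasts:
    """The three pairwise contrast tables plus normalized expression.

    ``hvp1``, ``hvp2``, ``p1vp2`` are contrast results (columns M, D, q,
    call) over an identical gene universe; ``x`` has one column per role
    (hybrid, parent1, parent2) of normalized expression.
    """

    hvp1: pd.DataFrame
    hvp2: pd.DataFrame
    p1vp2: pd.DataFrame
    x: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.hvp1.index
        for other in (self.hvp2, self.p1vp2, self.x):
            if not idx.equals(other.index):
                raise ValueError("contrast tables must share one gene universe")
        missing = {"hybrid", "parent1", "parent2"} - set(self.x.columns)
        if missing:
            raise ValueError(f"normalized expression lacks columns {sorted(missing)}")


def classify_gene(
    call_hvp1: str,
    call_hvp2: str,
    call_p1vp2: str,
    x_h: float,
    x_p1: float,
    x_p2: float,
    lfc_threshold: float = 1.0,
) -> set[str]:
    """Label set for one gene from its three calls and expression levels.

    Rules (lh, lp1, lp2 = log2 normalized expression):

    * conserved — all three calls non (always a singleton label).
    * over_dominant — up vs both parents, or up vs one parent with
      lh >= max(lp1, lp2) + lfc and no down call; under_dominant
      symmetric.
    * additive — parents DE, hybrid strictly between them (ties fail),
      and hybrid DE vs at least one parent.
    * dominant_P1 — parents DE, no DE vs parent1 but DE vs parent2, and
      |lh - lp1| < lfc (the hybrid actually sits at the parent1 level);
      dominant_P2 symmetric.
    * pattern (non, non, DE) — hybrid significantly resembles neither
      parent exclusively; assigned the nearest archetype among the
      parent1 level, the parental midpoint and the parent2 level.

    Genes matching no rule return an empty set (unclassified).
    """
    for c in (call_hvp1, call_hvp2, call_p1vp2):
        if c not in CALLS:
            raise ValueError(f"invalid DE call {c!r}")
    if call_hvp1 == "non" and call_hvp2 == "non" and call_p1vp2 == "non":
        return {"conserved"}

    labels: set[str] = set()
    lh, lp1, lp2 = _log2pos(x_h), _log2pos(x_p1), _log2pos(x_p2)
    hi, lo = max(lp1, lp2), min(lp1, lp2)
    de1 = call_hvp1 != "non"
    de2 = call_hvp2 != "non"
    any_up = call_hvp1 == "up" or call_hvp2 == "up"
    any_down = call_hvp1 == "down" or call_hvp2 == "down"

    if (call_hvp1 == "up" and call_hvp2 == "up") or (
        any_up and not any_down and lh >= hi + lfc_threshold
    ):
        labels.add("over_dominant")
    if (call_hvp1 == "down" and call_hvp2 == "down") or (
        any_down and not any_up and lh <= lo - lfc_threshold
    ):
        labels.add("under_dominant")

    parents_de = call_p1vp2 != "non"
    if parents_de and min(x_p1, x_p2) < x_h < max(x_p1, x_p2) and (de1 or de2):
        labels.add("additive")
    if parents_de and not de1 and de2 and abs(lh - lp1) < lfc_threshold:
        labels.add("dominant_P1")
    if parents_de and not de2 and de1 and abs(lh - lp2) < lfc_threshold:
        labels.add("dominant_P2")

    if not labels and parents_de and not de1 and not de2:
        mid = (lp1 + lp2) / 2.0
        dists = {
            "additive": abs(lh - mid),
            "dominant_P1": abs(lh - lp1),
            "dominant_P2": abs(lh - lp2),
        }
        labels.add(min(PRECEDENCE[3:], key=lambda lab: dists[lab]))
    return labels


def primary_label(
    labels: set[str], x_h: float, x_p1: float, x_p2: float
) -> str:
    """One reporting label from a label set.

    Precedence conserved > over_dominant > under_dominant; a gene carrying
    both additive and a parental-dominance label is assigned by the
    nearest archetype (parental midpoint vs the matching parent's level,
    log2 scale, ties to additive). Empty set -> ``unclassified``.
    """
    if not labels:
        return "unclassified"
    for lab in ("conserved", "over_dominant", "under_dominant"):
        if lab in labels:
            return lab
    if "additive" in labels:
        dom = next((d for d in ("dominant_P1", "dominant_P2") if d in labels), None)
        if dom is None:
            return "additive"
        lh = _log2pos(x_h)
        mid = (_log2pos(x_p1) + _log2pos(x_p2)) / 2.0
        lp = _log2pos(x_p1 if dom == "dominant_P1" else x_p2)
        return "additive" if abs(lh - mid) <= abs(lh - lp) else dom
    return next(lab for lab in PRECEDENCE if lab in labels)


def classify_trio(trio: TrioContrasts, lfc_threshold: float | None = None) -> pd.DataFrame:
    """Per-gene label sets and primary labels for a whole trio.

    ``lfc_threshold`` defaults to the threshold recorded on the HvP1
    contrast (1.0 when absent). Returns a DataFrame indexed by gene_id
    with columns ``labels`` (comma-joined in precedence order),
    ``primary_label`` (or ``unclassified``), ``unclassified`` flag, the
    three calls and the three normalized expression values.
    """
    if lfc_threshold is None:
        lfc_threshold = float(trio.hvp1.attrs.get("lfc_threshold", 1.0))
    c1 = trio.hvp1["call"]
    c2 = trio.hvp2["call"]
    c12 = trio.p1vp2["call"]
    xh = trio.x["hybrid"]
    xp1 = trio.x["parent1"]
    xp2 = trio.x["parent2"]
    rows = []
    for g in trio.hvp1.index:
        labels = classify_gene(
            c1[g], c2[g], c12[g], xh[g], xp1[g], xp2[g], lfc_threshold
        )
        ordered = [lab for lab in PRECEDENCE if lab in labels]
        rows.append(
            {
                "labels": ",".join(ordered),
                "primary_label": primary_label(labels, xh[g], xp1[g], xp2[g]),
                "unclassified": not ordered,
            }
        )
    out = pd.DataFrame(rows, index=trio.hvp1.index)
    out["call_HvP1"] = c1
    out["call_HvP2"] = c2
    out["call_P1vP2"] = c12
    out["x_H"] = xh
    out["x_P1"] = xp1
    out["x_P2"] = xp2
    return out


def summarize_inheritance(calls: pd.DataFrame) -> dict:
    """Category counts and percentages over the expressed-gene total.

    Counts are reported both by set membership (a gene with two labels
    counts in both) and by primary label (a partition, including
    ``unclassified``); percentages come with unrounded and integer
    (half-away-from-zero) forms.
    """
    total = len(calls)
    label_counts = {lab: 0 for lab in PRECEDENCE}
    for labs in calls["labels"]:
        for lab in labs.split(","):
            if lab:
                label_counts[lab] += 1
    primary_counts = (
        calls["primary_label"].value_counts().reindex(
            list(PRECEDENCE) + ["unclassified"], fill_value=0
        )
    ).to_dict()
    out = {
        "total_genes": total,
        "label_counts": label_counts,
        "primary_counts": {k: int(v) for k, v in primary_counts.items()},
    }
    if total:
        out["primary_percent"] = {
            k: 100.0 * v / total for k, v in out["primary_counts"].items()
        }
        out["primary_percent_int"] = {
            k: int_percent(v, total) for k, v in out["primary_counts"].items()
        }
    return out


def summarize_pairwise(contrast, total_expressed: int) -> dict:
    """Up/down counts and the integer percent DE of one contrast.

    ``contrast`` may be a contrast DataFrame (with a ``call`` column) or a
    pair ``(n_up, n_down)`` of already-tallied counts — the latter lets
    published count tables be re-summarized directly.
    """
    if isinstance(contrast, pd.DataFrame):
        n_up = int((contrast["call"] == "up").sum())
        n_down = int((contrast["call"] == "down").sum())
    else:
        n_up, n_down = (int(v) for v in contrast)
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_de": n_up + n_down,
        "total_expressed": int(total_expressed),
        "percent_de": int_percent(n_up + n_down, total_expressed),
    }
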