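"""Composite severity ranking and extreme sib-pair selection.

Each patient receives an ascending rank (average ranks on ties) for each of
the two severity traits — weight as % predicted weight-for-height and the CF
population centile of FEV1%pred — so that a higher rank means a milder
phenotype on that trait.  The composite is the unweighted sum of the two
ranks.  Pairs are then classified into the most discordant pairs (DIS), the
most mildly affected concordant pairs (CON+) and the most severely affected
concordant pairs (CON-); the three groups are disjoint by construction
because DIS is removed before the concordant candidates are ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import PhenotypeTable, ValidationError

logger = logging.getLogger("sibscan")

LABEL_DIS = "DIS"
LABEL_CON_MILD = "CON+"
LABEL_CON_SEVERE = "CON-"
LABEL_UNSELECTED = "unselected"


class SelectionError(ValueError):
    """Requested group sizes cannot be satisfied."""


def compute_composite_rank(phenotypes: PhenotypeTable) -> tuple[pd.DataFrame, list]:
    """Per-sample trait ranks and their sum.

    Returns ``(ranking, rejects)`` where ranking has columns sample_id,
    rank_weight, rank_fev1, composite and rejects lists (sample_id, reason)
    for samples missing either trait.  Ranks are ascending (higher trait
    value = higher rank = milder), ties get average ranks, so any strictly
    monotone transform of either trait leaves the result unchanged.
    """
    df = phenotypes.data
    ok = df["weight_pct_pred"].notna() & df["fev1_centile"].notna()
    rejects = [(sid, "missing trait value")
               for sid in df.loc[~ok, "sample_id"]]
    if rejects:
        logger.warning("composite ranking: excluded %d samples with missing traits",
                       len(rejects))
    sub = df.loc[ok]
    rank_weight = rankdata(sub["weight_pct_pred"].to_numpy(), method="average")
    rank_fev1 = rankdata(sub["fev1_centile"].to_numpy(), method="average")
    ranking = pd.DataFrame({
        "sample_id": sub["sample_id"].to_numpy(),
        "rank_weight": rank_weight,
        "rank_fev1": rank_fev1,
        "composite": rank_weight + rank_fev1,
    })
    return ranking, rejects


@dataclass
class PairClassification:
    """Per-pair selection outcome (one row per family in ``table``).

    columns: family_id, pair_mean, pair_discordance, label, mild_sib,
    severe_sib.  mild_sib always has composite >= severe_sib; on an exact
    tie the lexicographically smaller sample_id is called mild.
    """

    table: pd.DataFrame

    def members(self, label: str) -> list[str]:
        sub = self.table[self.table["label"] == label]
        return sub["mild_sib"].tolist() + sub["severe_sib"].tolist()

    def pair_links(self, label: str) -> list[tuple[str, str]]:
        sub = self.table[self.table["label"] == label]
        return list(zip(sub["mild_sib"], sub["severe_sib"]))

    def families_of(self, label: str) -> dict[str, str]:
        """sample_id -> family_id for members of one label."""
        sub = self.table[self.table["label"] == label]
        out = {}
        for _, row in sub.iterrows():
            out[row.mild_sib] = row.family_id
            out[row.severe_sib] = row.family_id
        return out


def classify_pairs(ranking: pd.DataFrame, pairs: dict[str, tuple[str, str]],
                   n_dis: int, n_con_mild: int, n_con_severe: int,
                   ) -> PairClassification:
    """Select the extreme pairs.

    DIS = the ``n_dis`` pairs with the largest intrapair composite
    difference; from the remaining pairs, CON+ = the ``n_con_mild`` with the
    largest pair mean and CON- = the ``n_con_severe`` with the smallest.
    Ties are broken by family_id lexicographic order (deterministic).
    """
    if min(n_dis, n_con_mild, n_con_severe) < 0:
        raise SelectionError("group sizes must be non-negative")
    if n_dis + n_con_mild + n_con_severe > len(pairs):
        raise SelectionError(
            f"requested {n_dis}+{n_con_mild}+{n_con_severe} pairs from {len(pairs)}")
    comp = dict(zip(ranking["sample_id"], ranking["composite"]))
    rows = []
    for fam in sorted(pairs):
        s1, s2 = pairs[fam]
        if s1 not in comp or s2 not in comp:
            raise ValidationError(f"family {fam}: sibling missing from ranking")
        c1, c2 = comp[s1], comp[s2]
        mild, severe = (s1, s2) if (c1 > c2 or (c1 == c2 and s1 < s2)) else (s2, s1)
        rows.append({
            "family_id": fam,
            "pair_mean": 0.5 * (c1 + c2),
            "pair_discordance": abs(c1 - c2),
            "label": LABEL_UNSELECTED,
            "mild_sib": mild,
            "severe_sib": severe,
        })
    table = pd.DataFrame(rows)
    by_disc = table.sort_values(["pair_discordance", "family_id"],
                                ascending=[False, True], kind="mergesort")
    dis_fams = by_disc["family_id"].iloc[:n_dis].tolist()
    table.loc[table["family_id"].isin(dis_fams), "label"] = LABEL_DIS
    rest = table[table["label"] == LABEL_UNSELECTED]
    if n_con_mild + n_con_severe > len(rest):
        raise SelectionError("concordant group sizes exceed remaining pairs")
    by_mean_desc = rest.sort_values(["pair_mean", "family_id"],
                                    ascending=[False, True], kind="mergesort")
    mild_fams = by_mean_desc["family_id"].iloc[:n_con_mild].tolist()
    remaining = rest[~rest["family_id"].isin(mild_fams)]
    by_mean_asc = remaining.sort_values(["pair_mean", "family_id"],
                                        ascending=[True, True], kind="mergesort")
    severe_fams = by_mean_asc["family_id"].iloc[:n_con_severe].tolist()
    table.loc[table["family_id"].isin(mild_fams), "label"] = LABEL_CON_MILD
    table.loc[table["family_id"].isin(severe_fams), "label"] = LABEL_CON_SEVERE
    return PairClassification(table=table)


def write_classification(cls: PairClassification, path) -> None:
    cls.table.to_csv(path, sep="\t", index=False)


def read_classification(path) -> PairClassification:
    return PairClassification(table=pd.read_csv(path, sep="\t"))
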