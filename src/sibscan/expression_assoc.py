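"""Expression-by-genotype comparison at an index marker.

Normalized expression values keyed by sample and index-SNP genotype are
compared between genotype groups with a two-sample t-test — Welch by default
(no equal-variance assumption), with the pooled-variance test available.
Two groupings are exposed: carriers vs non-carriers of a named allele (the
default contrast) and all three pairwise genotype contrasts; group means for
all three genotypes are always reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("sibscan")


@dataclass
class ExpressionContrast:
    name: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class ExpressionTestReport:
    contrasts: list[ExpressionContrast]
    genotype_means: dict[str, float]
    genotype_n: dict[str, int]


def _validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "genotype", "expression"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    expr = table["expression"].to_numpy(dtype=float)
    if not np.all(np.isfinite(expr)):
        raise ValueError("expression values must be finite")
    return table


def _ttest(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float, float, float]:
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def group_expression_test(table: pd.DataFrame, grouping: str = "carrier_vs_noncarrier",
                          allele: str | None = None, welch: bool = True,
                          ) -> ExpressionTestReport:
    """Compare expression between genotype groups at the index marker.

    ``grouping='carrier_vs_noncarrier'`` contrasts carriers of ``allele``
    (genotype contains it) against non-carriers; ``grouping='genotype_pairwise'``
    emits all three pairwise genotype contrasts.  Welch's t with
    Welch-Satterthwaite df is the default; ``welch=False`` switches to the
    pooled-variance test.  A contrast with a group of fewer than 2 samples is
    skipped with a report rather than an error.
    """
    table = _validate_expression_table(table)
    genos = sorted(table["genotype"].unique())
    by_geno = {g: table.loc[table["genotype"] == g, "expression"].to_numpy(dtype=float)
               for g in genos}
    genotype_means = {g: float(v.mean()) for g, v in by_geno.items()}
    genotype_n = {g: int(len(v)) for g, v in by_geno.items()}
    contrasts: list[ExpressionContrast] = []

    def run(name, label_x, x, label_y, y):
        if len(x) < 2 or len(y) < 2:
            contrasts.append(ExpressionContrast(
                name=name, group_labels=(label_x, label_y),
                n=(len(x), len(y)),
                means=(float(x.mean()) if len(x) else float("nan"),
                       float(y.mean()) if len(y) else float("nan")),
                t_statistic=float("nan"), df=float("nan"), p_value=float("nan"),
                skipped=True, skip_reason="group with < 2 samples"))
            logger.warning("expression contrast %s skipped: group with < 2 samples", name)
            return
        t, df, p = _ttest(x, y, welch)
        contrasts.append(ExpressionContrast(
            name=name, group_labels=(label_x, label_y), n=(len(x), len(y)),
            means=(float(x.mean()), float(y.mean())),
            t_statistic=t, df=df, p_value=p))

    if grouping == "carrier_vs_noncarrier":
        if allele is None:
            raise ValueError("carrier grouping needs the allele to test")
        carrier = table["genotype"].str.contains(allele, regex=False)
        x = table.loc[carrier, "expression"].to_numpy(dtype=float)
        y = table.loc[~carrier, "expression"].to_numpy(dtype=float)
        run(f"carrier({allele})_vs_noncarrier", f"{allele} carrier", x,
            "non-carrier", y)
    elif grouping == "genotype_pairwise":
        for i in range(len(genos)):
            for j in range(i + 1, len(genos)):
                run(f"{genos[i]}_vs_{genos[j]}", genos[i], by_geno[genos[i]],
                    genos[j], by_geno[genos[j]])
    else:
        raise ValueError("grouping must be 'carrier_vs_noncarrier' or 'genotype_pairwise'")
    return ExpressionTestReport(contrasts=contrasts, genotype_means=genotype_means,
                                genotype_n=genotype_n)


def write_expression_report(report: ExpressionTestReport, path) -> None:
    rows = []
    for c in report.contrasts:
        rows.append({
            "contrast": c.name, "group_a": c.group_labels[0],
            "group_b": c.group_labels[1], "n_a": c.n[0], "n_b": c.n[1],
            "mean_a": c.means[0], "mean_b": c.means[1],
            "t": c.t_statistic, "df": c.df, "p": c.p_value,
            "skipped": c.skipped, "skip_reason": c.skip_reason})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
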