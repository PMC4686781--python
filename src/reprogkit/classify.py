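"""Four-way reprogramming-completeness classification of signature genes.

Signature genes are those significantly differentially expressed between
the fibroblast (EF) line and either of two embryonic stem (ES) reference
lines.  For each iPS line, every signature gene is placed in exactly one
category by a fixed-order decision tree:

1. not significantly different from *both* ES lines -> CORRECT
   (the iPS cells express the gene at ES level);
2. otherwise, not significantly different from EF -> NOT_REPROGRAMMED
   (somatic memory: the gene kept its fibroblast level);
3. otherwise, the iPS normalized mean lies strictly between the EF mean
   and the pooled ES mean -> INTERMEDIATE;
4. otherwise -> NOVEL (a level outside the EF-ES interval, pointing to a
   reprogramming error rather than incomplete promoter switching).

Rule 1 firing first makes the four categories a true partition, so the
per-line category counts always sum to the signature-set size.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np
import pandas as pd

DEFAULT_ALPHA_SIG = 0.05


class Category(str, Enum):
    CORRECT = "correct"
    INTERMEDIATE = "intermediate"
    NOT_REPROGRAMMED = "not_reprogrammed"
    NOVEL = "novel"


CATEGORY_ORDER = (
    Category.CORRECT,
    Category.INTERMEDIATE,
    Category.NOT_REPROGRAMMED,
    Category.NOVEL,
)

CATEGORY_TITLES = {
    Category.CORRECT: "Correctly reprogrammed",
    Category.INTERMEDIATE: "Intermediate pattern",
    Category.NOT_REPROGRAMMED: "Not reprogrammed",
    Category.NOVEL: '"Novel" pattern',
}


@dataclass(frozen=True)
class SignatureGeneSet:
    """Genes significant vs either ES line, with the reference means.

    ``table`` is indexed by gene and records per-ES-line significance
    plus the EF and per-ES normalized means; ``mu_es_pooled`` is the
    unweighted mean of the two ES lines' normalized means.
    """

    table: pd.DataFrame
    alpha_sig: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def select_signature_genes(de_es1, de_es2, alpha_sig: float = DEFAULT_ALPHA_SIG) -> SignatureGeneSet:
    """Union of genes with q < alpha_sig in the EF-vs-ES1 or EF-vs-ES2 test.

    Both tests must share the gene universe and the EF reference group
    (group a).  Stores per-gene EF normalized mean and the pooled ES mean.
    """
    t1, t2 = de_es1.table, de_es2.table
    if not t1.index.equals(t2.index):
        raise ValueError("ES contrasts computed on different gene universes")
    if not np.allclose(t1["base_mean_a"], t2["base_mean_a"]):
        raise ValueError("ES contrasts do not share the EF reference group")
    sig1 = t1["qvalue"] < alpha_sig
    sig2 = t2["qvalue"] < alpha_sig
    keep = sig1 | sig2
    table = pd.DataFrame(
        {
            "sig_vs_es1": sig1[keep],
            "sig_vs_es2": sig2[keep],
            "mu_ef": t1.loc[keep, "base_mean_a"],
            "mu_es1": t1.loc[keep, "base_mean_b"],
            "mu_es2": t2.loc[keep, "base_mean_b"],
        }
    )
    table["mu_es_pooled"] = (table["mu_es1"] + table["mu_es2"]) / 2.0
    return SignatureGeneSet(table=table, alpha_sig=alpha_sig)


def classify_gene(
    q_vs_ef: float,
    q_vs_es1: float,
    q_vs_es2: float,
    mu_ef: float,
    mu_es_pooled: float,
    mu_ips: float,
    alpha_sig: float = DEFAULT_ALPHA_SIG,
) -> Category:
    """Classify one signature gene in one iPS line (see module docstring).

    Between-ness (rule 3) is strict and evaluated on the normalized-mean
    scale; a tie with either boundary falls through to NOVEL.
    """
    for name, q in (("q_vs_ef", q_vs_ef), ("q_vs_es1", q_vs_es1), ("q_vs_es2", q_vs_es2)):
        if q is None or (isinstance(q, float) and np.isnan(q)):
            raise ValueError(f"missing test result {name}")
    diff_es = (q_vs_es1 < alpha_sig) and (q_vs_es2 < alpha_sig)
    if not diff_es:
        return Category.CORRECT
    if q_vs_ef >= alpha_sig:
        return Category.NOT_REPROGRAMMED
    lo, hi = min(mu_ef, mu_es_pooled), max(mu_ef, mu_es_pooled)
    if lo < mu_ips < hi:
        return Category.INTERMEDIATE
    return Category.NOVEL


def classify_all(
    signature: SignatureGeneSet,
    ips_tests: dict[str, pd.DataFrame],
    alpha_sig: float | None = None,
) -> pd.DataFrame:
    """Classify every signature gene in every iPS line.

    ``ips_tests`` maps iPS line id to a per-gene table with columns
    ``q_vs_ef``, ``q_vs_es1``, ``q_vs_es2`` and ``mu_ips`` covering the
    whole signature set.  Returns a long-format table (gene_id, ips_line,
    category, the three q-values and three means) with exactly one row
    per (gene, line).
    """
    if alpha_sig is None:
        alpha_sig = signature.alpha_sig
    sig = signature.table
    frames = []
    for line, tests in ips_tests.items():
        missing = sig.index.difference(tests.index)
        if len(missing):
            raise ValueError(
                f"iPS line {line!r}: tests missing for {len(missing)} signature genes"
            )
        t = tests.reindex(sig.index)
        for col in ("q_vs_ef", "q_vs_es1", "q_vs_es2"):
            if t[col].isna().any():
                raise ValueError(f"iPS line {line!r}: NaN in {col}")
        diff_es = (t["q_vs_es1"] < alpha_sig) & (t["q_vs_es2"] < alpha_sig)
        ef_like = t["q_vs_ef"] >= alpha_sig
        lo = np.minimum(sig["mu_ef"], sig["mu_es_pooled"])
        hi = np.maximum(sig["mu_ef"], sig["mu_es_pooled"])
        between = (lo < t["mu_ips"]) & (t["mu_ips"] < hi)
        category = np.select(
            [~diff_es, ef_like, between],
            [Category.CORRECT.value, Category.NOT_REPROGRAMMED.value, Category.INTERMEDIATE.value],
            default=Category.NOVEL.value,
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": sig.index,
                    "ips_line": line,
                    "category": category,
                    "q_vs_ef": t["q_vs_ef"].to_numpy(),
                    "q_vs_es1": t["q_vs_es1"].to_numpy(),
                    "q_vs_es2": t["q_vs_es2"].to_numpy(),
                    "mu_ef": sig["mu_ef"].to_numpy(),
                    "mu_es_pooled": sig["mu_es_pooled"].to_numpy(),
                    "mu_ips": t["mu_ips"].to_numpy(),
                    "single_es_signature": (~(sig["sig_vs_es1"] & sig["sig_vs_es2"])).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def category_counts(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-line counts by category, in canonical category order."""
    counts = (
        labels.pivot_table(index="ips_line", columns="category", values="gene_id",
                           aggfunc="count", fill_value=0)
        .reindex(columns=[c.value for c in CATEGORY_ORDER], fill_value=0)
    )
    counts.columns.name = None
    return counts


def shared_categories(labels: pd.DataFrame) -> dict[str, int]:
    """Genes assigned the same category in ALL iPS lines, per category."""
    lines = labels["ips_line"].unique()
    if len(lines) < 2:
        raise ValueError("shared categories need >= 2 iPS lines")
    wide = labels.pivot(index="gene_id", columns="ips_line", values="category")
    if wide.isna().any().any():
        raise ValueError("iPS lines classified over different gene universes")
    same = wide.nunique(axis=1) == 1
    shared = wide.loc[same].iloc[:, 0].value_counts()
    return {c.value: int(shared.get(c.value, 0)) for c in CATEGORY_ORDER}


def percent(count: int, total: int, decimals: int = 2) -> float:
    """100*count/total, rounded half-up to ``decimals`` places.

    Two decimals reproduce report-table conventions; one decimal matches
    prose figures such as colony-formation efficiency.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    if decimals not in (1, 2):
        raise ValueError("decimals must be 1 or 2")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(value)


@dataclass(frozen=True)
class ClassificationReport:
    """Per-iPS-line and shared category counts with percentages of the
    signature total, shaped like a completeness summary table."""

    total: int
    rows: pd.DataFrame  # columns: row_id, category, count, percent

    def format_text(self) -> str:
        header = ["", *(CATEGORY_TITLES[c] for c in CATEGORY_ORDER)]
        lines = ["\t".join(header)]
        for row_id in self.rows["row_id"].unique():
            sub = self.rows[self.rows["row_id"] == row_id].set_index("category")
            cells = [row_id]
            for c in CATEGORY_ORDER:
                r = sub.loc[c.value]
                cells.append(f"{int(r['count'])} ({r['percent']:.2f}%)")
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def build_report(
    per_line_counts: pd.DataFrame,
    shared_counts: dict[str, int] | None,
    total: int,
    decimals: int = 2,
) -> ClassificationReport:
    """Assemble the category-count/percentage report.

    ``per_line_counts`` is indexed by iPS line with one column per
    category; each line's counts must sum to ``total`` (the partition
    property).  Shared counts, if given, are reported as an extra row and
    are not required to sum to the total.
    """
    records = []
    for line, row in per_line_counts.iterrows():
        counts = [int(row[c.value]) for c in CATEGORY_ORDER]
        if sum(counts) != total:
            raise ValueError(
                f"line {line!r}: category counts sum to {sum(counts)}, expected {total}"
            )
        for cat, n in zip(CATEGORY_ORDER, counts):
            records.append((str(line), cat.value, n, percent(n, total, decimals)))
    if shared_counts is not None:
        row_id = "Shared between " + " and ".join(str(i) for i in per_line_counts.index)
        for cat in CATEGORY_ORDER:
            n = int(shared_counts[cat.value])
            records.append((row_id, cat.value, n, percent(n, total, decimals)))
    rows = pd.DataFrame(records, columns=["row_id", "category", "count", "percent"])
    return ClassificationReport(total=total, rows=rows)


def write_classification(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def write_report(report: ClassificationReport, structured_path, text_path) -> None:
    report.rows.assign(total=report.total).to_csv(structured_path, sep="\t", index=False)
    with open(text_path, "w", encoding="utf-8") as fh:
        fh.write(report.format_text())
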