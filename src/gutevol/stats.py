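"""Mutation-spectrum classification and cohort statistics.

Each mutation-table row is classified into overlapping categories
{IS, intergenic, synonymous, coding, indel, structural, prophage}:
an intergenic IS insertion counts as both IS and intergenic; a
gene-interrupting IS as IS and coding; a genic frameshift as coding and
indel; inversions are structural (not indel); prophage gains sit outside
every other category and are excluded from total counts. This overlapping
rule set is the one under which per-mouse counts reproduce the published
cohort means simultaneously, and it is pinned by regression tests.

Cohort comparisons report mean +- SEM (sample SD with the n-1 denominator
over the square root of n mice) and a two-sided Mann-Whitney U with
midranks for ties, the reported statistic being min(U1, U2) and the p-value
a tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

CATEGORIES = ("IS", "intergenic", "synonymous", "coding", "indel",
              "structural", "prophage")
COUNT_COLUMNS = ("total",) + CATEGORIES

_SNP_RE = re.compile(r"^[ACGT] → [ACGT]$")
_IS_RE = re.compile(r"^IS\w+$")


# ------------------------------------------------------------ fixtures I/O


def load_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"position": str})
    required = {"mouse", "position", "mutation", "annotation", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    return df


def load_packaged_table(cohort: str) -> pd.DataFrame:
    """The packaged mutation tables for the old and young cohorts."""
    fname = {"old": "table1_old.tsv", "young": "table2_young.tsv"}[cohort]
    with resources.as_file(resources.files("gutevol.data") / fname) as p:
        return load_table(p)


# ----------------------------------------------------------- classification


def classify(record) -> frozenset:
    """Category set of one mutation record (row, dict or MutationRecord)."""
    if isinstance(record, (pd.Series, dict)):
        mutation = str(record["mutation"]).strip()
        annotation = str(record["annotation"]).strip()
    else:
        mutation, annotation = record.mutation.strip(), \
            record.annotation.strip()
    if not mutation or mutation == "nan":
        raise ValueError("record without a mutation descriptor")
    if annotation == "Prophage" or "Prophage" in mutation:
        return frozenset({"prophage"})
    cats: set[str] = set()
    intergenic = annotation == "Intergenic"
    if intergenic:
        cats.add("intergenic")
    if _IS_RE.match(mutation):
        cats.add("IS")
        if not intergenic:
            cats.add("coding")  # gene interrupted
    elif mutation.startswith("Inversion"):
        cats.add("structural")
        if not intergenic:
            cats.add("coding")
    elif mutation.startswith(("+", "Δ")):
        cats.add("indel")
        if not intergenic:
            cats.add("coding")  # frameshift / in-frame codon change
    elif _SNP_RE.match(mutation):
        if annotation == "Synonymous":
            cats.add("synonymous")
        elif not intergenic:
            cats.add("coding")
    else:
        raise ValueError(f"unclassifiable mutation descriptor {mutation!r} "
                         f"/ {annotation!r}")
    if not cats:
        raise ValueError(f"no category for {mutation!r} / {annotation!r}")
    return frozenset(cats)


def cohort_counts(records: pd.DataFrame, cohort: str,
                  mice: list[str] | None = None) -> pd.DataFrame:
    """Per-mouse count table (rows = mice sorted by id, columns = total plus
    each category). Total excludes prophage rows. ``mice`` may declare mice
    with zero mutations so they appear as zero rows."""
    if cohort not in ("old", "young"):
        raise ValueError(f"unknown cohort {cohort!r}")
    df = records
    if "cohort" in df.columns:
        df = df[df["cohort"] == cohort]
    ids = sorted(set(df["mouse"]) | set(mice or []))
    table = pd.DataFrame(0, index=pd.Index(ids, name="mouse"),
                         columns=list(COUNT_COLUMNS))
    for _, row in df.iterrows():
        cats = classify(row)
        for c in cats:
            table.loc[row["mouse"], c] += 1
        if "prophage" not in cats:
            table.loc[row["mouse"], "total"] += 1
    return table


# ------------------------------------------------------------- statistics


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error (sample SD over sqrt(n)); needs n >= 2."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("SEM undefined for fewer than two values")
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(x.size))


@dataclass
class GroupComparison:
    category: str
    n1: int
    n2: int
    mean1: float
    sem1: float
    mean2: float
    sem2: float
    u1: float
    u2: float
    u: float
    p: float

    def summary(self) -> str:
        return (f"{self.category}: {self.mean1:.1f} ± {self.sem1:.1f} vs "
                f"{self.mean2:.1f} ± {self.sem2:.1f} "
                f"(Mann–Whitney U = {self.u:g}, p = {self.p:.2g})")


def mann_whitney(a, b, category: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U with midranks for ties.

    Reports U = min(U1, U2); p from the tie-corrected normal approximation
    without continuity correction (the convention of the graphing software
    the source statistics were computed with: it reproduces the printed
    p = 0.02 at U = 6.0 and p = 0.6 at U = 17.5), clipped at 1 so identical
    groups report p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    N = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        p = 1.0
    else:
        z = (u - n1 * n2 / 2) / math.sqrt(var)
        p = min(1.0, 2 * float(norm.cdf(z)))
    m1, s1 = mean_sem(a) if n1 >= 2 else (float(a.mean()), float("nan"))
    m2, s2 = mean_sem(b) if n2 >= 2 else (float(b.mean()), float("nan"))
    return GroupComparison(category, n1, n2, m1, s1, m2, s2,
                           float(u1), float(u2), float(u), float(p))


@dataclass
class CodingSynRatio:
    coding: int
    synonymous: int

    @property
    def ratio(self) -> float | None:
        if self.synonymous == 0:
            return None
        return round(self.coding / self.synonymous, 2)


def coding_syn_ratio(count_table: pd.DataFrame) -> CodingSynRatio:
    """Cohort-level coding / synonymous count ratio (2 decimals); undefined
    (ratio None, counts still reported) when no synonymous mutations."""
    return CodingSynRatio(int(count_table["coding"].sum()),
                          int(count_table["synonymous"].sum()))


def site_frequency_summary(records: pd.DataFrame, mutation: str,
                           gene: str | None = None,
                           threshold: float = 0.05
                           ) -> tuple[int, float | None]:
    """(number of mice where the site exceeds ``threshold``, max frequency)
    for records matching a mutation descriptor (and optionally a gene
    context)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    df = records[records["mutation"].astype(str).str.strip() == mutation]
    if gene is not None:
        df = df[df["gene"].astype(str).str.strip() == gene]
    if df.empty:
        return 0, None
    freqs = df["frequency"].astype(float)
    per_mouse = freqs.groupby(df["mouse"]).max()
    return int((per_mouse > threshold).sum()), float(freqs.max())


def compare_cohorts(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    categories=("total", "IS", "intergenic", "synonymous",
                                "coding", "indel")) -> pd.DataFrame:
    """Category-by-category comparison of two per-mouse count tables
    (columns: category, means, SEMs, U, p — one row per category)."""
    rows = []
    for cat in categories:
        cmp_ = mann_whitney(table_a[cat], table_b[cat], category=cat)
        rows.append({"category": cat,
                     "mean_old": round(cmp_.mean1, 1),
                     "sem_old": round(cmp_.sem1, 1),
                     "mean_young": round(cmp_.mean2, 1),
                     "sem_young": round(cmp_.sem2, 1),
                     "U": cmp_.u, "p": round(cmp_.p, 4)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ marker series


def marker_series(counts: list[tuple[float, int, int]]) -> pd.DataFrame:
    """Neutral-marker frequency trajectory with binomial SEM per timepoint.

    ``counts`` is a list of (day, marker-positive, total). Timepoints with
    total = 0 are kept but flagged missing (NaN frequency). Plots attach
    +-2*SEM bars.
    """
    rows = []
    for day, pos, total in counts:
        if total > 0:
            f = pos / total
            sem = math.sqrt(f * (1 - f) / total)
            rows.append({"day": day, "positive": pos, "total": total,
                         "frequency": f, "sem": sem, "missing": False})
        else:
            rows.append({"day": day, "positive": pos, "total": total,
                         "frequency": float("nan"), "sem": float("nan"),
                         "missing": True})
    return pd.DataFrame(rows)


def plot_marker_series(series: pd.DataFrame, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = series[~series["missing"]]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(ok["day"], ok["frequency"], yerr=2 * ok["sem"],
                fmt="o-", capsize=3)
    ax.set_xlabel("day post-colonization")
    ax.set_ylabel("marker frequency")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
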