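"""Small quantification utilities: 3C-qPCR ddCt and enrichment-list tools.

``ddct_frequency`` converts qPCR cycle thresholds into a relative
interaction frequency by double normalization: the target amplicon against
a reference amplicon, and the 3C template against a BAC-digest control
template that contains every ligation product at equal molarity.

The enrichment helpers consume a differential-abundance table (e.g. from a
RIP-seq analysis): strict-threshold filtering, multi-way list overlaps with
Venn-region counts, and biotype composition summaries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd


@dataclass(frozen=True)
class QpcrRecord:
    """Cycle thresholds for one amplicon in 3C and BAC-control templates."""

    label: str
    ct_3c_target: float
    ct_3c_ref: float
    ct_bac_target: float
    ct_bac_ref: float

    def __post_init__(self):
        for name in ("ct_3c_target", "ct_3c_ref", "ct_bac_target", "ct_bac_ref"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{self.label}: missing or non-finite Ct in {name}")


def ddct_frequency(rec: QpcrRecord) -> float:
    """Relative interaction frequency: ``2 ** -ddCt``.

    ``ddCt = (Ct_3C_target - Ct_3C_ref) - (Ct_BAC_target - Ct_BAC_ref)``.
    Invariant to adding a constant to all four Ct values; always > 0.
    """
    ddct = (rec.ct_3c_target - rec.ct_3c_ref) - (rec.ct_bac_target - rec.ct_bac_ref)
    return 2.0 ** (-ddct)


def ddct_from_replicates(label, ct_3c_target, ct_3c_ref, ct_bac_target, ct_bac_ref):
    """ddCt frequency from technical replicates, averaged on the Ct scale.

    Each argument is an iterable of replicate Ct values; the arithmetic mean
    of each is taken before the ddCt computation. Returns
    ``(frequency, per_replicate)`` where ``per_replicate`` pairs the i-th
    replicate of every series (diagnostic output).
    """
    series = [list(ct_3c_target), list(ct_3c_ref), list(ct_bac_target), list(ct_bac_ref)]
    if any(len(s) == 0 for s in series):
        raise ValueError(f"{label}: empty replicate series")
    means = [sum(s) / len(s) for s in series]
    freq = ddct_frequency(QpcrRecord(label, *means))
    n = min(len(s) for s in series)
    per_rep = [
        ddct_frequency(QpcrRecord(f"{label}_rep{i}", *(s[i] for s in series)))
        for i in range(n)
    ]
    return freq, per_rep


_REQUIRED = ("rna_id", "fold_change", "adj_p")


def load_enrichment(path, sep: str = "\t") -> pd.DataFrame:
    """Read an enrichment table; validates columns and row contents.

    Expects headered delimited text with at least ``rna_id``,
    ``fold_change``, ``adj_p`` (``biotype`` optional). Malformed rows raise
    a ValueError naming the row.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    validate_enrichment(df, origin=str(path))
    return df


def validate_enrichment(df: pd.DataFrame, origin: str = "table") -> None:
    for i, row in df.iterrows():
        fc, p = row["fold_change"], row["adj_p"]
        if not (isinstance(fc, (int, float)) and math.isfinite(fc) and fc > 0):
            raise ValueError(f"{origin}: row {i} ({row['rna_id']}): invalid fold change {fc!r}")
        if not (isinstance(p, (int, float)) and 0 <= p <= 1):
            raise ValueError(f"{origin}: row {i} ({row['rna_id']}): invalid adjusted p {p!r}")


def filter_enriched(
    df: pd.DataFrame, max_adj_p: float = 0.05, min_fc: float = 1.5
) -> pd.DataFrame:
    """Keep rows with adjusted p strictly below and fold change strictly above.

    Both thresholds are strict inequalities: a row at exactly the fold-change
    or p-value cutoff is dropped.
    """
    return df[(df["adj_p"] < max_adj_p) & (df["fold_change"] > min_fc)].reset_index(drop=True)


def multiway_overlap(lists: dict[str, list]):
    """Full intersection and Venn-region counts of named identifier lists.

    Duplicates within a list are collapsed first. Returns
    ``(intersection, pattern_counts)``: ``intersection`` is the sorted list
    of identifiers present in every input; ``pattern_counts`` maps each
    nonempty membership pattern (a sorted tuple of list names) to the number
    of identifiers belonging to exactly those lists. Pattern counts sum to
    the size of the union.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists to overlap")
    sets = {name: set(ids) for name, ids in lists.items()}
    union = set().union(*sets.values())
    patterns: dict[tuple, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(sorted(sets), r):
            patterns[combo] = 0
    for ident in union:
        members = tuple(sorted(n for n, s in sets.items() if ident in s))
        patterns[members] += 1
    intersection = sorted(set.intersection(*sets.values()))
    return intersection, patterns


def biotype_summary(df: pd.DataFrame, column: str = "biotype") -> pd.DataFrame:
    """Counts, proportions and percentages per biotype label.

    Rows lacking a label are bucketed as ``unlabeled``. Proportions sum to 1.
    """
    labels = (
        df[column].fillna("unlabeled").replace("", "unlabeled")
        if column in df.columns
        else pd.Series(["unlabeled"] * len(df))
    )
    counts = labels.value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "biotype": counts.index,
            "count": counts.to_numpy(),
            "proportion": counts.to_numpy() / total,
        }
    )
    out["percent"] = 100.0 * out["proportion"]
    return out.reset_index(drop=True)
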