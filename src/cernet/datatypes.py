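"""Shared in-memory containers.

Expression data is carried as a plain pandas DataFrame (features x samples)
bundled with per-feature biotypes and per-sample group labels.  Result tables
(differential expression, target hits, triplets, enrichment) are DataFrames
with fixed column contracts documented on the producing functions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: recognized feature biotypes
BIOTYPES = ("mRNA", "lncRNA", "miRNA")


@dataclass
class ExpressionMatrix:
    """A features x samples abundance matrix with feature/sample metadata.

    Parameters
    ----------
    values : DataFrame
        Numeric matrix, index = feature ids, columns = sample ids.
    biotype : Series
        Biotype per feature ("mRNA" | "lncRNA" | "miRNA"), indexed like rows.
    groups : Series
        Group label per sample, indexed like columns.
    """

    values: pd.DataFrame
    biotype: pd.Series
    groups: pd.Series

    def __post_init__(self):
        missing = self.values.index.difference(self.biotype.index)
        if len(missing):
            raise ValueError(f"biotype missing for features: {sorted(missing)[:5]}")
        bad = set(self.biotype.loc[self.values.index]) - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"group label missing for samples: {sorted(missing)[:5]}")

    def subset_biotype(self, biotype: str) -> pd.DataFrame:
        keep = self.biotype.loc[self.values.index] == biotype
        return self.values.loc[keep[keep].index]


@dataclass(frozen=True)
class TargetHit:
    """One miRNA binding site on a transcript (1-based inclusive coordinates)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    seed_class: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer | alignment-only


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    set_id: str
    description: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass(frozen=True)
class CeRNATriplet:
    """A candidate lncRNA-miRNA-mRNA competing-endogenous-RNA circuit.

    Holds the three pairwise Pearson correlations (computed on log2(x+1)
    abundances across the whole cohort), their two-sided p-values, and the
    evidence flags for the four admission criteria:

    - ``c1_db``: both miRNA-target arms admitted by the interaction-map
      database policy (scan hit, plus whitelist support when required);
    - ``c2_shared``: lncRNA and mRNA share at least one miRNA;
    - ``c3_negative``: both miRNA-target correlations negative and significant;
    - ``c4_positive``: lncRNA-mRNA correlation positive and significant.
    """

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    r_lnc_mrna: float
    r_mir_lnc: float
    r_mir_mrna: float
    p_lnc_mrna: float
    p_mir_lnc: float
    p_mir_mrna: float
    c1_db: bool = True
    c2_shared: bool = True
    c3_negative: bool = True
    c4_positive: bool = True

    @property
    def key(self):
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


TRIPLET_COLUMNS = [
    "lncrna_id", "mirna_id", "mrna_id",
    "r_lnc_mrna", "r_mir_lnc", "r_mir_mrna",
    "p_lnc_mrna", "p_mir_lnc", "p_mir_mrna",
    "c1_db", "c2_shared", "c3_negative", "c4_positive",
]


def triplets_to_frame(triplets) -> pd.DataFrame:
    """Tabulate a list of :class:`CeRNATriplet` (stable, sorted order)."""
    rows = [
        {c: getattr(t, c) for c in TRIPLET_COLUMNS}
        for t in sorted(triplets, key=lambda t: t.key)
    ]
    return pd.DataFrame(rows, columns=TRIPLET_COLUMNS)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic cohort generator.

    de_features : set of (feature_id, direction) with direction in {+1, -1}
    circuits : list of (lncrna_id, mirna_id, mrna_id)
    planted_sites : list of (mirna_id, transcript_id, start, end), 1-based
    """

    de_features: set = field(default_factory=set)
    circuits: list = field(default_factory=list)
    planted_sites: list = field(default_factory=list)
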