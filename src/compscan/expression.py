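"""Expression tables, male/female ratios and dosage-compensation calls.

Genes are called expressed when their log2 value reaches the detection
floor (default 6) in every sample considered; a gene is dosage compensated
when it is expressed in both sexes and its male-minus-female log2 ratio
falls strictly inside the reference autosomal arm's mean +/- 1 SD.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionTable:
    """Per-gene log2 expression across named samples.

    ``data`` is indexed by gene id with one column per sample.  Optional
    ``sample_info`` carries (sex, condition, replicate group) per sample;
    replicate collapsing by median happens at read time so analysis code
    sees one column per condition.
    """

    data: pd.DataFrame
    sample_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ExpressionError("expression values must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    def check_annotation(self, annotation: GenomeAnnotation) -> None:
        missing = [g for g in self.data.index if g not in annotation]
        if missing:
            raise ExpressionError(
                f"{len(missing)} genes absent from annotation (first: {missing[0]})"
            )

    def __getitem__(self, sample: str) -> pd.Series:
        if sample not in self.data.columns:
            raise ExpressionError(f"unknown sample {sample!r}")
        return self.data[sample]


def read_expression(
    path: str | os.PathLike,
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
) -> ExpressionTable:
    """Read a TSV of log2 expression (rows = genes, columns = samples).

    When ``replicate_groups`` maps a condition name to replicate column
    names, replicates are collapsed to their median under the condition
    name.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if replicate_groups:
        collapsed = {}
        for cond, cols in replicate_groups.items():
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ExpressionError(f"replicate columns missing: {missing}")
            collapsed[cond] = df[list(cols)].median(axis=1)
        df = pd.DataFrame(collapsed, index=df.index)
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Analysis operations


def filter_expressed(
    table: ExpressionTable,
    samples: Sequence[str],
    threshold: float = 6.0,
) -> set[str]:
    """Genes with expression >= threshold in every named sample.

    With male and female samples this implements "expressed in both
    sexes"; the boundary is inclusive (a value of exactly 6 is expressed).
    """
    for s in samples:
        if s not in table.data.columns:
            raise ExpressionError(f"unknown sample {s!r}")
    if table.data.empty:
        return set()
    mask = (table.data[list(samples)] >= threshold).all(axis=1)
    return set(table.data.index[mask])


def mf_ratio(
    table: ExpressionTable,
    male_sample: str,
    female_sample: str,
    genes: Iterable[str],
) -> pd.Series:
    """Male minus female log2 expression per gene."""
    genes = list(genes)
    for g in genes:
        if g not in table.data.index:
            raise ExpressionError(f"gene {g!r} missing from expression table")
    male = table[male_sample].loc[genes]
    female = table[female_sample].loc[genes]
    return (male - female).rename("mf_ratio")


@dataclass(frozen=True)
class ArmStats:
    """Descriptive ratio statistics for one chromosome arm."""

    arm: str
    n: int
    mean: float
    sd: float
    skewness: float

    @property
    def lower(self) -> float:
        return self.mean - self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.sd


def arm_statistics(
    ratios: pd.Series, annotation: GenomeAnnotation, arm: str
) -> ArmStats:
    """Mean, sample SD (n-1) and skewness of ratios for genes on ``arm``."""
    on_arm = [g for g in ratios.index if g in annotation and annotation[g].arm == arm]
    if len(on_arm) < 2:
        raise ExpressionError(f"arm {arm!r}: need >= 2 genes, have {len(on_arm)}")
    vals = ratios.loc[on_arm].to_numpy(dtype=float)
    return ArmStats(
        arm=arm,
        n=len(vals),
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        skewness=float(stats.skew(vals, bias=False)) if len(vals) > 2 else float("nan"),
    )


def all_arm_statistics(
    ratios: pd.Series, annotation: GenomeAnnotation
) -> pd.DataFrame:
    rows = []
    for arm in annotation.arm_names():
        try:
            s = arm_statistics(ratios, annotation, arm)
        except ExpressionError:
            continue
        rows.append(
            {"arm": s.arm, "n": s.n, "mean": s.mean, "sd": s.sd, "skewness": s.skewness}
        )
    return pd.DataFrame(rows)


def classify_compensation(
    ratios: pd.Series, reference_stats: ArmStats
) -> pd.DataFrame:
    """Call genes compensated when ratio is strictly inside mean +/- 1 SD.

    Both bounds are strict, matching the published rule (ratio > lower and
    ratio < upper).  Returns a frame with the ratio, the call and the
    bounds used.
    """
    lo, hi = reference_stats.lower, reference_stats.upper
    vals = ratios.to_numpy(dtype=float)
    comp = (vals > lo) & (vals < hi)
    return pd.DataFrame(
        {
            "ratio": vals,
            "compensated": comp,
            "bound_low": lo,
            "bound_high": hi,
        },
        index=ratios.index,
    )
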